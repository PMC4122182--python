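"""Slice subject time series into per-condition datasets and standardize them.

Conventions: 0-based TR indices, half-open ``[onset, onset + n_trs)``
windows.  All segments of the same condition are concatenated (row order
preserving time) into one dataset per condition.  Rest segments drop their
first ``ceil(4 s / TR)`` TRs (2 TRs at TR = 2 s) to skip the hemodynamic
carry-over from the preceding task block, keeping the last 3-4 TRs of each
5-6 TR rest period.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .graphs import CONDITIONS
from .synthdata import BlockSchedule, ROITimeSeries

#: Seconds of each rest period discarded before analysis.
REST_TRIM_SECONDS = 4.0


@dataclass(frozen=True)
class ConditionDataset:
    """One subject's time-points x ROIs matrix for one condition."""

    condition: str
    subject_id: str
    roi_labels: tuple[str, ...]
    matrix: np.ndarray
    standardized: bool = False
    zero_variance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(self.roi_labels):
            raise ValueError("matrix must be time-points x ROIs matching roi_labels")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def column(self, roi: str) -> np.ndarray:
        return self.matrix[:, self.roi_labels.index(roi)]


def rest_trim_trs(tr_seconds: float) -> int:
    """Leading rest TRs dropped: ceil(4 s / TR)."""
    return math.ceil(REST_TRIM_SECONDS / tr_seconds - 1e-9)


def segment(ts: ROITimeSeries, schedule: BlockSchedule) -> dict[str, ConditionDataset]:
    """Map each condition present in the schedule to its pooled dataset.

    Preparation and task segments contribute all their rows; rest segments
    contribute rows after the leading trim.  Raises if any segment overruns
    the series or segments overlap.
    """
    rows: dict[str, list[np.ndarray]] = {}
    trim = rest_trim_trs(schedule.tr_seconds)
    prev_end = 0
    for i, seg in enumerate(schedule.segments):
        if seg.onset_tr < prev_end:
            raise ValueError(f"segment {i} ({seg.condition}) overlaps the previous segment")
        end = seg.onset_tr + seg.n_trs
        if end > ts.n_trs:
            raise ValueError(
                f"segment {i} ({seg.condition}) overruns the series: "
                f"needs TRs up to {end}, series has {ts.n_trs}"
            )
        prev_end = end
        start = seg.onset_tr + (trim if seg.condition == "rest" else 0)
        if start < end:
            rows.setdefault(seg.condition, []).append(ts.values[start:end])
    return {
        cond: ConditionDataset(cond, ts.subject_id, ts.roi_labels, np.vstack(chunks))
        for cond, chunks in rows.items()
    }


def standardize(ds: ConditionDataset, on_constant: str = "raise") -> ConditionDataset:
    """Column-wise z-scoring (mean 0, unit sample variance, ddof=1).

    Zero-variance columns cannot be scaled; with ``on_constant="raise"``
    (default) they are an error, with ``"flag"`` they are set to zero and
    recorded in ``zero_variance``.
    """
    if ds.n < 2:
        raise ValueError(f"need at least 2 time points to standardize (got {ds.n})")
    if on_constant not in ("raise", "flag"):
        raise ValueError("on_constant must be 'raise' or 'flag'")
    m = ds.matrix - ds.matrix.mean(axis=0)
    sd = m.std(axis=0, ddof=1)
    constant = sd <= 0
    flagged = tuple(l for l, c in zip(ds.roi_labels, constant) if c)
    if flagged and on_constant == "raise":
        raise ValueError(f"zero-variance columns: {flagged}")
    safe = np.where(constant, 1.0, sd)
    out = m / safe
    out[:, constant] = 0.0
    return replace(ds, matrix=out, standardized=True, zero_variance=flagged)


def condition_datasets(
    subjects: Sequence[ROITimeSeries],
    schedule: BlockSchedule,
    standardized: bool = True,
) -> dict[str, list[ConditionDataset]]:
    """Segment a cohort: condition -> one (optionally standardized) dataset
    per subject, in subject order."""
    out: dict[str, list[ConditionDataset]] = {}
    for ts in subjects:
        for cond, ds in segment(ts, schedule).items():
            out.setdefault(cond, []).append(standardize(ds) if standardized else ds)
    return {c: out[c] for c in CONDITIONS if c in out}


def write_dataset(ds: ConditionDataset, path: str | Path) -> None:
    pd.DataFrame(ds.matrix, columns=list(ds.roi_labels)).to_csv(path, sep="\t", index=False)


def read_dataset(
    path: str | Path, condition: str, subject_id: str, standardized: bool = False
) -> ConditionDataset:
    df = pd.read_csv(path, sep="\t")
    return ConditionDataset(
        condition, subject_id, tuple(df.columns), df.to_numpy(float), standardized
    )
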