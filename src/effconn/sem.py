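"""SEM path-coefficient estimation for a fixed oriented DAG.

For a recursive SEM over a DAG with independent errors, the maximum-
likelihood estimate of each path coefficient is the node-wise ordinary
least-squares regression of the node on its parents (intercept-free on
standardized data), so no iterative optimizer is needed.  Per-subject fits
are aggregated to the across-subject mean and sample SD per edge, the form
in which multi-subject connectivity tables are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .graphs import DAG, Pair, undirected
from .segmentation import ConditionDataset


@dataclass(frozen=True)
class SubjectFit:
    """One subject's SEM fit: edge coefficients, per-node residual
    variances (ML, divisor n), and the Gaussian log-likelihood."""

    subject_id: str
    coefficients: Mapping[Pair, float]
    residual_variance: Mapping[str, float]
    loglik: float


def fit_subject(dag: DAG, ds: ConditionDataset) -> SubjectFit:
    """Node-wise intercept-free OLS of each node on its DAG parents."""
    if not ds.standardized:
        raise ValueError("dataset must be standardized")
    missing = set(dag.nodes) - set(ds.roi_labels)
    if missing:
        raise ValueError(f"DAG nodes absent from dataset: {sorted(missing)}")
    n = ds.n
    coefficients: dict[Pair, float] = {}
    resid_var: dict[str, float] = {}
    loglik = 0.0
    for node in dag.nodes:
        parents = dag.parents(node)
        if len(parents) >= n:
            raise ValueError(
                f"node {node!r} has {len(parents)} parents but only {n} time points"
            )
        y = ds.column(node)
        if parents:
            X = np.column_stack([ds.column(p) for p in parents])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ beta
            for p, b in zip(parents, beta):
                coefficients[(p, node)] = float(b)
        else:
            resid = y
        s2 = max(float(resid @ resid) / n, 1e-300)
        resid_var[node] = s2
        loglik += -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)
    return SubjectFit(ds.subject_id, coefficients, resid_var, loglik)


@dataclass(frozen=True)
class EdgeEstimate:
    """Across-subject summary of one directed edge's coefficient."""

    edge: Pair
    per_subject: tuple[float, ...]
    mean: float
    sd: float
    #: True when only one subject contributed (SD reported as 0 by convention)
    degenerate: bool = False


def aggregate(fits: Sequence[SubjectFit | Mapping[Pair, float]]) -> list[EdgeEstimate]:
    """Mean and sample SD (ddof=1) per edge across subject fits.

    All fits must share one edge set.  A single-subject input yields
    SD = 0 with the ``degenerate`` flag set.
    """
    if not fits:
        raise ValueError("no fits to aggregate")
    maps = [f.coefficients if isinstance(f, SubjectFit) else f for f in fits]
    edges = set(maps[0])
    for i, m in enumerate(maps[1:], start=1):
        if set(m) != edges:
            raise ValueError(f"fit {i} has a different edge set than fit 0")
    single = len(maps) == 1
    out = []
    for edge in sorted(edges):
        vals = tuple(float(m[edge]) for m in maps)
        mean = float(np.mean(vals))
        sd = 0.0 if single else float(np.std(vals, ddof=1))
        out.append(EdgeEstimate(edge, vals, mean, sd, degenerate=single))
    return out


# ---------------------------------------------------------------------------
# per-condition edge tables (the printed-table layout)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Cell:
    """One table cell: direction (ordered pair, or None if unknown),
    coefficient mean and SD.  ``bold`` carries printed emphasis and plays
    no role in any computation."""

    direction: Pair | None
    mean: float
    sd: float
    bold: bool = False
    #: printed-table row label this cell came from, when loaded from a
    #: table fixture; None for tables built from pipeline estimates
    row: str | None = None


@dataclass(frozen=True)
class EdgeTable:
    """One condition's map from unordered ROI pair to its cell."""

    condition: str
    entries: Mapping[Pair, Cell]

    def __post_init__(self) -> None:
        for pair in self.entries:
            if pair != undirected(*pair):
                raise ValueError(f"entry key {pair} is not a canonical unordered pair")

    @property
    def present_pairs(self) -> frozenset:
        return frozenset(self.entries)

    def direction(self, pair: Pair) -> Pair | None:
        return self.entries[pair].direction


def edge_table(condition: str, estimates: Sequence[EdgeEstimate]) -> EdgeTable:
    """Build a per-condition EdgeTable from aggregated edge estimates."""
    entries: dict[Pair, Cell] = {}
    for est in estimates:
        pair = undirected(*est.edge)
        if pair in entries:
            raise ValueError(f"duplicate unordered pair {pair}")
        entries[pair] = Cell(est.edge, est.mean, est.sd)
    return EdgeTable(condition, entries)


def format_cell(cell: Cell) -> str:
    """Render as 'mean (sd)' with mean to 2 decimals, SD to 1-2 decimals."""
    sd = f"{cell.sd:.2f}".rstrip("0")
    if sd.endswith("."):
        sd += "0"
    return f"{cell.mean:.2f} ({sd})"


def write_edge_table(
    table: EdgeTable, path: str | Path, n_subjects: int | None = None
) -> None:
    """TSV with columns source, target, direction_marker, mean, sd, n_subjects."""
    rows = []
    for pair in sorted(table.entries):
        cell = table.entries[pair]
        if cell.direction is None:
            src, tgt, marker = pair[0], pair[1], "unknown"
        else:
            src, tgt = cell.direction
            marker = "forward" if cell.direction == pair else "reversed"
        rows.append((src, tgt, marker, round(cell.mean, 2), round(cell.sd, 2),
                     n_subjects if n_subjects is not None else ""))
    pd.DataFrame(
        rows, columns=["source", "target", "direction_marker", "mean", "sd", "n_subjects"]
    ).to_csv(path, sep="\t", index=False)
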