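"""End-to-end orchestration: search -> orient -> estimate, per condition.

Convenience layer over the stage modules for the common multi-subject
workflow: given per-condition standardized datasets (one per subject),
discover each condition's skeleton with the penalty-escalating greedy BIC
search, orient it by residual non-Gaussianity, estimate SEM coefficients
per subject, and summarize as per-condition edge tables ready for
sub-network classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .graphs import DAG, Skeleton
from .orient import orient_edges
from .search import ScoreParams, SearchResult, find_first_nontriangular
from .segmentation import ConditionDataset
from .sem import EdgeEstimate, EdgeTable, aggregate, edge_table, fit_subject
from .subnetworks import SubNetworkReport, classify_connections


@dataclass(frozen=True)
class ConditionResult:
    """One condition's fitted connectivity model."""

    condition: str
    search: SearchResult
    dag: DAG
    estimates: tuple[EdgeEstimate, ...]
    table: EdgeTable

    @property
    def skeleton(self) -> Skeleton:
        return self.search.skeleton

    @property
    def c_used(self) -> float:
        return self.search.c_used


def fit_condition(
    condition: str,
    datasets: Sequence[ConditionDataset],
    params: ScoreParams = ScoreParams(),
) -> ConditionResult:
    """Full single-condition fit on one subject-per-dataset list."""
    search = find_first_nontriangular(datasets, params)
    dag = orient_edges(search.skeleton, datasets)
    fits = [fit_subject(dag, ds) for ds in datasets]
    estimates = tuple(aggregate(fits))
    return ConditionResult(condition, search, dag, estimates, edge_table(condition, estimates))


def fit_study(
    datasets_by_condition: Mapping[str, Sequence[ConditionDataset]],
    params: ScoreParams = ScoreParams(),
) -> dict[str, ConditionResult]:
    """Fit every condition independently; keys follow the input mapping."""
    return {
        cond: fit_condition(cond, ds_list, params)
        for cond, ds_list in datasets_by_condition.items()
    }


def classify_study(results: Mapping[str, ConditionResult]) -> SubNetworkReport:
    """Classify a fitted study's connections into sub-networks."""
    return classify_connections({c: r.table for c, r in results.items()})
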