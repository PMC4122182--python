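"""Edge orientation on a fixed skeleton by residual non-Gaussianity.

For linear models with independent non-Gaussian innovations, regressing in
the causally correct direction leaves residuals that are as non-Gaussian as
the innovations, while any incorrect direction mixes variables and yields
more Gaussian residuals.  Each skeleton edge {X, Y} is therefore oriented
by comparing, under the two candidate directions, the Anderson-Darling
departure-from-normality of the local regression residuals of X and Y,
summed over subjects (rule: pairwise-AD).  The adjacency structure is never
changed; if the per-edge choices produce a directed cycle, the edge with
the smallest decision margin on a cycle is flipped (and frozen) until the
graph is acyclic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
from scipy.stats import norm

from .graphs import DAG, Pair, Skeleton, undirected
from .segmentation import ConditionDataset

#: Probability clipping bound for CDF values inside the A^2 log terms.
_CDF_EPS = 1e-10


@dataclass(frozen=True)
class ADScore:
    """Anderson-Darling statistic A^2 against the fitted normal, with n."""

    a2: float
    n: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.a2):
            raise ValueError("A^2 must be finite")


def anderson_darling(sample: Sequence[float] | np.ndarray) -> ADScore:
    """A^2 of a sample against normality (location/scale estimated).

    The sample is standardized to mean 0 and unit sample variance (ddof=1),
    then

        A^2 = -n - (1/n) * sum_i (2i - 1) * [ln F(z_(i)) + ln(1 - F(z_(n+1-i)))]

    with F the standard normal CDF and z_(i) the sorted standardized
    values; CDF values are clipped to [1e-10, 1 - 1e-10].  Larger values
    mean stronger departure from normality.  Requires n >= 8.
    """
    x = np.asarray(sample, dtype=float).ravel()
    n = x.size
    if n < 8:
        raise ValueError(f"need at least 8 observations (got {n})")
    sd = x.std(ddof=1)
    if sd <= 0 or not np.isfinite(sd):
        raise ValueError("sample has zero variance")
    z = np.sort((x - x.mean()) / sd)
    u = np.clip(norm.cdf(z), _CDF_EPS, 1.0 - _CDF_EPS)
    i = np.arange(1, n + 1)
    a2 = -n - np.mean((2 * i - 1) * (np.log(u) + np.log(1.0 - u[::-1])))
    return ADScore(float(a2), n)


@dataclass(frozen=True)
class OrientationResult:
    dag: DAG
    #: per undirected pair: |score(X->Y) - score(Y->X)|; +inf marks edges
    #: re-resolved (frozen) during cycle repair
    margins: Mapping[Pair, float]
    #: pairs whose direction was flipped to break cycles
    repaired: frozenset


class _ResidualScorer:
    """Cached sums over subjects of A^2 of intercept-free OLS residuals."""

    def __init__(self, datasets: Sequence[ConditionDataset]):
        if not datasets:
            raise ValueError("need at least one dataset")
        self.labels = datasets[0].roi_labels
        for ds in datasets:
            if ds.roi_labels != self.labels:
                raise ValueError("datasets disagree on ROI labels")
            if not ds.standardized:
                raise ValueError(
                    f"dataset ({ds.subject_id}, {ds.condition}) is not standardized"
                )
        self.index = {l: i for i, l in enumerate(self.labels)}
        self.datasets = datasets
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def ad_sum(self, node: str, parents: Sequence[str]) -> float:
        j = self.index[node]
        pa = tuple(sorted(self.index[q] for q in parents))
        key = (j, pa)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        total = 0.0
        for ds in self.datasets:
            y = ds.matrix[:, j]
            if pa:
                X = ds.matrix[:, pa]
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta
            else:
                resid = y
            total += anderson_darling(resid).a2
        self._cache[key] = total
        return total


def _direction_scores(
    scorer: _ResidualScorer, adj: Mapping[str, set], x: str, y: str
) -> tuple[float, float]:
    """(score of x->y, score of y->x) for edge {x, y} given full adjacency.

    Under x->y the local parent sets are parents(y) = adj(y) (including x)
    and parents(x) = adj(x) \\ {y}; symmetric under y->x.  The score is the
    pooled A^2 of both nodes' residuals across subjects.
    """
    ax_full = sorted(adj[x])
    ay_full = sorted(adj[y])
    ax_minus = [v for v in ax_full if v != y]
    ay_minus = [v for v in ay_full if v != x]
    s_xy = scorer.ad_sum(y, ay_full) + scorer.ad_sum(x, ax_minus)
    s_yx = scorer.ad_sum(x, ax_full) + scorer.ad_sum(y, ay_minus)
    return s_xy, s_yx


def orient_edges(
    skeleton: Skeleton, datasets: Sequence[ConditionDataset]
) -> DAG:
    """Orient every skeleton edge; see :func:`orientation_details`."""
    return orientation_details(skeleton, datasets).dag


def orientation_details(
    skeleton: Skeleton, datasets: Sequence[ConditionDataset]
) -> OrientationResult:
    """Per-edge pairwise Anderson-Darling orientation with margins.

    Ties are broken toward the lexicographically smallest (source, target)
    pair; the output's undirected projection always equals the input
    skeleton.
    """
    scorer = _ResidualScorer(datasets)
    missing = set(skeleton.nodes) - set(scorer.labels)
    if missing:
        raise ValueError(f"skeleton nodes absent from datasets: {sorted(missing)}")
    adj = skeleton.adjacency()

    choice: dict[Pair, Pair] = {}
    margins: dict[Pair, float] = {}
    for x, y in sorted(skeleton.edges):       # x < y canonically
        s_xy, s_yx = _direction_scores(scorer, adj, x, y)
        margins[(x, y)] = abs(s_xy - s_yx)
        if s_xy > s_yx or (s_xy == s_yx and (x, y) <= (y, x)):
            choice[(x, y)] = (x, y)
        else:
            choice[(x, y)] = (y, x)

    # cycle repair: flip the least-confident edge on a cycle, freeze it
    repaired: set[Pair] = set()
    live_margins = dict(margins)
    while True:
        g = nx.DiGraph()
        g.add_nodes_from(skeleton.nodes)
        g.add_edges_from(choice.values())
        if nx.is_directed_acyclic_graph(g):
            break
        cyclic_pairs = set()
        for comp in nx.strongly_connected_components(g):
            if len(comp) > 1:
                for pair, (s, t) in choice.items():
                    if s in comp and t in comp:
                        cyclic_pairs.add(pair)
        flippable = [p for p in cyclic_pairs if p not in repaired]
        if not flippable:
            raise RuntimeError("cycle repair failed: all edges on cycles already frozen")
        target = min(flippable, key=lambda p: (live_margins[p], p))
        s, t = choice[target]
        choice[target] = (t, s)
        repaired.add(target)
        live_margins[target] = float("inf")

    dag = DAG(skeleton.nodes, frozenset(choice.values()))
    return OrientationResult(dag=dag, margins=live_margins, repaired=frozenset(repaired))
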