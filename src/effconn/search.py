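"""Multi-dataset greedy equivalence search with penalty escalation.

The search discovers the connection skeleton shared across subjects.  It
maximizes a Gaussian BIC score averaged over the per-subject datasets:

    score(G) = sum_j local(j, parents_G(j))
    local(j, Pa) = mean over datasets of  -n * ln(sigma2_hat) - c * k * ln(n)

where sigma2_hat is the maximum-likelihood residual variance of the
intercept-free least-squares regression of node j on Pa (divisor n),
k = |Pa| + 1 counts the regression coefficients plus the variance, and
c >= 1 is the penalty discount.  This is 2*logL - c*k*ln(n) with constants
common to all models dropped.

Because Markov-equivalent DAGs receive identical Gaussian BIC scores, the
search moves over equivalence classes (CPDAGs) rather than individual
DAGs: starting from the empty graph, the forward phase repeatedly applies
the best strictly-score-improving single-edge insert operator, the
backward phase the best delete operator, with the standard validity
conditions and completion to a CPDAG after every move.  The skeleton of
the result is the stable output; the reported DAG is a consistent
extension of the final equivalence class.

Triangles (three pairwise-adjacent nodes) can indicate a latent common
cause; ``find_first_nontriangular`` escalates the penalty discount until
the returned skeleton is triangle-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .graphs import DAG, Skeleton, edges_to_dot
from .segmentation import ConditionDataset

#: Minimum score gain for a move to count as a strict improvement
#: (guards against floating-point churn on score-equivalent moves).
MIN_IMPROVEMENT = 1e-9


@dataclass(frozen=True)
class ScoreParams:
    """Penalty-discount escalation schedule for the BIC complexity term."""

    c_start: float = 1.0
    c_step: float = 1.0
    c_max: float = 20.0

    def __post_init__(self) -> None:
        if self.c_start < 1.0:
            raise ValueError("c_start must be >= 1")
        if self.c_step <= 0:
            raise ValueError("c_step must be > 0")
        if self.c_max < self.c_start:
            raise ValueError("c_max must be >= c_start")

    def schedule(self) -> list[float]:
        out, c = [], self.c_start
        while c <= self.c_max + 1e-12:
            out.append(c)
            c += self.c_step
        return out


class Move(NamedTuple):
    op: str          # "add" | "remove"
    source: str
    target: str
    delta: float     # averaged-BIC improvement of the accepted move


@dataclass(frozen=True)
class SearchResult:
    dag: DAG
    skeleton: Skeleton
    c_used: float
    score: float
    trace: tuple[Move, ...]


class TriangleError(RuntimeError):
    """Escalation schedule exhausted with triangles remaining."""

    def __init__(self, c_max: float, triangles: list[tuple[str, str, str]]):
        self.triangles = triangles
        super().__init__(
            f"no triangle-free skeleton found up to penalty discount c={c_max}; "
            f"residual triangles: {triangles}"
        )


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class _Scorer:
    """Averaged local BIC scores from cached per-dataset covariance matrices.

    With standardized, mean-zero data the intercept-free OLS residual
    variance is  C[j,j] - C[j,Pa] C[Pa,Pa]^-1 C[Pa,j]  where C = X'X / n,
    so each local score is a small linear solve against precomputed C.
    """

    def __init__(self, datasets: Sequence[ConditionDataset], c: float):
        if not datasets:
            raise ValueError("need at least one dataset")
        labels = datasets[0].roi_labels
        for ds in datasets:
            if ds.roi_labels != labels:
                raise ValueError("datasets disagree on ROI labels")
            if not ds.standardized:
                raise ValueError(
                    f"dataset ({ds.subject_id}, {ds.condition}) is not standardized"
                )
        self.labels = labels
        self.index = {l: i for i, l in enumerate(labels)}
        self.c = float(c)
        self.n = np.array([ds.n for ds in datasets], dtype=float)
        self.min_n = int(self.n.min())
        self.C = np.stack([ds.matrix.T @ ds.matrix / ds.n for ds in datasets])
        self.log_n = np.log(self.n)
        self._cache: dict[tuple[int, tuple[int, ...]], float] = {}

    def local(self, node: int, parents: tuple[int, ...]) -> float:
        """Mean over datasets of -n*ln(sigma2_hat) - c*(|Pa|+1)*ln(n)."""
        key = (node, parents)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        if len(parents) >= self.min_n - 1:
            raise ValueError(
                f"{len(parents)} parents with only {self.min_n} time points: "
                "regression unidentifiable"
            )
        if parents:
            p = list(parents)
            Cpp = self.C[:, p][:, :, p]                      # (d, k, k)
            Cpj = self.C[:, p, node]                         # (d, k)
            beta = np.linalg.solve(Cpp, Cpj[..., None])[..., 0]
            sigma2 = self.C[:, node, node] - np.einsum("dk,dk->d", Cpj, beta)
        else:
            sigma2 = self.C[:, node, node].copy()
        sigma2 = np.maximum(sigma2, 1e-12)
        k = len(parents) + 1
        scores = -self.n * np.log(sigma2) - self.c * k * self.log_n
        val = float(scores.mean())
        self._cache[key] = val
        return val

    def local_by_label(self, node: str, parents: Sequence[str]) -> float:
        if node in parents:
            raise ValueError("node cannot be its own parent")
        return self.local(self.index[node], tuple(sorted(self.index[p] for p in parents)))


def local_bic(
    datasets: Sequence[ConditionDataset], node: str, parents: Sequence[str], c: float = 1.0
) -> float:
    """Averaged local BIC of ``node`` given ``parents`` (see module docstring)."""
    return _Scorer(datasets, c).local_by_label(node, parents)


# ---------------------------------------------------------------------------
# partially directed graphs (equivalence-class state)
# ---------------------------------------------------------------------------

class _PDAG:
    """Mutable partially directed graph over node indices 0..p-1.

    ``directed`` holds (tail, head) pairs, ``undirected`` canonical
    (min, max) pairs.  Between search moves the state is a CPDAG.
    """

    def __init__(self, p: int):
        self.p = p
        self.parents: list[set[int]] = [set() for _ in range(p)]
        self.children: list[set[int]] = [set() for _ in range(p)]
        self.neighbors: list[set[int]] = [set() for _ in range(p)]  # undirected

    def copy(self) -> "_PDAG":
        g = _PDAG(self.p)
        g.parents = [set(s) for s in self.parents]
        g.children = [set(s) for s in self.children]
        g.neighbors = [set(s) for s in self.neighbors]
        return g

    def adjacent(self, x: int, y: int) -> bool:
        return y in self.parents[x] or y in self.children[x] or y in self.neighbors[x]

    def adjacencies(self, x: int) -> set[int]:
        return self.parents[x] | self.children[x] | self.neighbors[x]

    def add_directed(self, x: int, y: int) -> None:
        self.children[x].add(y)
        self.parents[y].add(x)

    def add_undirected(self, x: int, y: int) -> None:
        self.neighbors[x].add(y)
        self.neighbors[y].add(x)

    def remove_all(self, x: int, y: int) -> None:
        self.children[x].discard(y)
        self.parents[y].discard(x)
        self.children[y].discard(x)
        self.parents[x].discard(y)
        self.neighbors[x].discard(y)
        self.neighbors[y].discard(x)

    def orient(self, x: int, y: int) -> None:
        """Turn undirected x-y into directed x->y."""
        self.neighbors[x].discard(y)
        self.neighbors[y].discard(x)
        self.add_directed(x, y)

    def is_clique(self, nodes: set[int]) -> bool:
        return all(self.adjacent(a, b) for a, b in combinations(sorted(nodes), 2))

    def na(self, y: int, x: int) -> set[int]:
        """Undirected neighbors of y that are adjacent to x."""
        return {n for n in self.neighbors[y] if self.adjacent(n, x)}

    def semi_directed_path(self, start: int, goal: int, blocked: set[int]) -> bool:
        """Is there a path start -> goal following undirected or
        forward-directed edges, avoiding ``blocked`` nodes?"""
        if start in blocked or goal in blocked:
            return goal == start
        seen = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for w in self.children[v] | self.neighbors[v]:
                if w == goal:
                    return True
                if w not in seen and w not in blocked:
                    seen.add(w)
                    stack.append(w)
        return False

    def skeleton_pairs(self) -> set[tuple[int, int]]:
        pairs = set()
        for x in range(self.p):
            for y in self.children[x]:
                pairs.add((min(x, y), max(x, y)))
            for y in self.neighbors[x]:
                pairs.add((min(x, y), max(x, y)))
        return pairs


def _consistent_extension(pdag: _PDAG) -> list[set[int]]:
    """Dor-Tarsi: extend a PDAG to a DAG's parent sets, respecting every
    directed edge and creating no new v-structure.  Raises if none exists."""
    g = pdag.copy()
    parents_out: list[set[int]] = [set(s) for s in g.parents]
    remaining = set(range(g.p))
    while remaining:
        found = None
        for x in sorted(remaining):
            if g.children[x] & remaining:
                continue
            nbrs = g.neighbors[x] & remaining
            adj_x = g.adjacencies(x) & remaining
            if all(adj_x - {n} <= g.adjacencies(n) for n in nbrs):
                found = x
                break
        if found is None:
            raise ValueError("PDAG admits no consistent extension")
        for n in g.neighbors[found] & remaining:
            parents_out[found].add(n)
        remaining.discard(found)
        for n in list(g.neighbors[found]):
            g.neighbors[found].discard(n)
            g.neighbors[n].discard(found)
    return parents_out


def _dag_to_cpdag(parents: list[set[int]], p: int) -> _PDAG:
    """Completed PDAG of a DAG: v-structure edges directed, Meek closure
    (rules R1-R3) of the rest."""
    adj = [set() for _ in range(p)]
    for y in range(p):
        for x in parents[y]:
            adj[x].add(y)
            adj[y].add(x)
    g = _PDAG(p)
    compelled = set()
    for y in range(p):
        for x1, x2 in combinations(sorted(parents[y]), 2):
            if x2 not in adj[x1]:            # v-structure x1 -> y <- x2
                compelled.add((x1, y))
                compelled.add((x2, y))
    for y in range(p):
        for x in parents[y]:
            if (x, y) in compelled:
                g.add_directed(x, y)
            else:
                g.add_undirected(x, y)
    _meek_closure(g)
    return g


def _meek_closure(g: _PDAG) -> None:
    """Orient undirected edges forced by Meek rules R1-R3, to fixpoint."""
    changed = True
    while changed:
        changed = False
        for b in range(g.p):
            for c_ in sorted(g.neighbors[b]):
                # R1: a -> b - c with a, c non-adjacent  =>  b -> c
                if any(not g.adjacent(a, c_) for a in g.parents[b]):
                    g.orient(b, c_)
                    changed = True
                    continue
                # R2: b -> a -> c and b - c  =>  b -> c
                if g.children[b] & g.parents[c_]:
                    g.orient(b, c_)
                    changed = True
                    continue
                # R3: b - a1 -> c, b - a2 -> c, a1, a2 non-adjacent  =>  b -> c
                spouses = sorted(g.neighbors[b] & g.parents[c_])
                if any(
                    not g.adjacent(a1, a2)
                    for a1, a2 in combinations(spouses, 2)
                ):
                    g.orient(b, c_)
                    changed = True


def _recomplete(g: _PDAG) -> _PDAG:
    """Re-complete a PDAG after an operator: consistent extension, then
    back to the CPDAG of that extension."""
    return _dag_to_cpdag(_consistent_extension(g), g.p)


def _subsets(items: list[int]):
    for r in range(len(items) + 1):
        yield from combinations(items, r)


def _best_insert(g: _PDAG, scorer: _Scorer, min_improvement: float):
    """Best valid Insert(x, y, T): returns (delta, y, x, T) or None.

    Validity (standard equivalence-class conditions): x, y non-adjacent;
    T a subset of undirected neighbors of y not adjacent to x;
    NA(y, x) | T a clique; every semi-directed path y ~> x blocked by
    NA(y, x) | T.  Delta scores y with parents Pa(y) | NA | T, with and
    without x.
    """
    best = None
    for y in range(g.p):
        pa_y = tuple(sorted(g.parents[y]))
        for x in range(g.p):
            if x == y or g.adjacent(x, y):
                continue
            na = g.na(y, x)
            t_pool = sorted(g.neighbors[y] - na - g.adjacencies(x))
            for T in _subsets(t_pool):
                s = na | set(T)
                if not g.is_clique(s):
                    continue
                if g.semi_directed_path(y, x, s):
                    continue
                base = tuple(sorted(set(pa_y) | s))
                delta = scorer.local(y, tuple(sorted(set(base) | {x}))) - scorer.local(y, base)
                if delta <= min_improvement:
                    continue
                cand = (delta, y, x, T)
                if best is None or _better_insert(cand, best):
                    best = cand
    return best


def _better_insert(cand, best) -> bool:
    if cand[0] != best[0]:
        return cand[0] > best[0]
    return (cand[1], cand[2], cand[3]) < (best[1], best[2], best[3])


def _best_delete(g: _PDAG, scorer: _Scorer, min_improvement: float):
    """Best valid Delete(x, y, H): returns (delta, y, x, H) or None.

    Applicable to x -> y and to undirected x - y (both orders); H a subset
    of NA(y, x) with NA(y, x) \\ H a clique.  Delta scores y with parents
    Pa(y) | (NA \\ H), without vs with x.
    """
    best = None
    pairs = []
    for y in range(g.p):
        for x in g.parents[y]:
            pairs.append((x, y))
        for x in g.neighbors[y]:
            pairs.append((x, y))          # both orders arise naturally
    for x, y in pairs:
        na = g.na(y, x)
        pa_y = set(g.parents[y])
        for H in _subsets(sorted(na)):
            keep = na - set(H)
            if not g.is_clique(keep):
                continue
            base = tuple(sorted((pa_y | keep) - {x}))
            delta = scorer.local(y, base) - scorer.local(y, tuple(sorted(set(base) | {x})))
            if delta <= min_improvement:
                continue
            cand = (delta, y, x, H)
            if best is None or _better_insert(cand, best):
                best = cand
    return best


# ---------------------------------------------------------------------------
# the search itself
# ---------------------------------------------------------------------------

def greedy_search(
    datasets: Sequence[ConditionDataset],
    c: float = 1.0,
    min_improvement: float = MIN_IMPROVEMENT,
) -> SearchResult:
    """Two-phase greedy equivalence search at a fixed penalty discount.

    Forward: starting from the empty graph, repeatedly apply the single
    insert operator with the best strict improvement of the averaged BIC;
    stop when none improves.  Backward: likewise for delete operators.
    Ties break toward the lexicographically smallest (child, parent) pair.
    The reported DAG is a consistent extension of the final equivalence
    class; the skeleton is the class's adjacency structure.
    """
    scorer = _Scorer(datasets, c)
    labels = scorer.labels
    p = len(labels)
    g = _PDAG(p)
    trace: list[Move] = []

    while True:
        cand = _best_insert(g, scorer, min_improvement)
        if cand is None:
            break
        delta, y, x, T = cand
        g.add_directed(x, y)
        for t in T:
            g.orient(t, y)
        g = _recomplete(g)
        trace.append(Move("add", labels[x], labels[y], delta))

    while True:
        cand = _best_delete(g, scorer, min_improvement)
        if cand is None:
            break
        delta, y, x, H = cand
        g.remove_all(x, y)
        for h in H:
            g.orient(y, h)
            if h in g.neighbors[x]:
                g.orient(x, h)
        g = _recomplete(g)
        trace.append(Move("remove", labels[x], labels[y], delta))

    ext = _consistent_extension(g)
    edges = frozenset(
        (labels[i], labels[j]) for j in range(p) for i in ext[j]
    )
    dag = DAG(tuple(labels), edges)
    score = float(sum(
        scorer.local(j, tuple(sorted(ext[j]))) for j in range(p)
    ))
    return SearchResult(
        dag=dag,
        skeleton=dag.skeleton(),
        c_used=float(c),
        score=score,
        trace=tuple(trace),
    )


def has_triangle(skeleton: Skeleton) -> bool:
    """True iff some three nodes are pairwise adjacent."""
    return skeleton.has_triangle()


def find_first_nontriangular(
    datasets: Sequence[ConditionDataset], params: ScoreParams = ScoreParams()
) -> SearchResult:
    """Escalate the penalty discount until the skeleton is triangle-free.

    Runs ``greedy_search`` at c = c_start, c_start + c_step, ... and returns
    the first triangle-free result (``c_used`` records the accepted
    discount).  Raises :class:`TriangleError` if the schedule is exhausted.
    """
    result = None
    for c in params.schedule():
        result = greedy_search(datasets, c)
        if not has_triangle(result.skeleton):
            return result
    assert result is not None
    raise TriangleError(params.c_max, result.skeleton.triangles())


def write_search_result(result: SearchResult, path: str | Path) -> None:
    """Edge-list TSV + DOT + JSON run record (c_used, score, trace)."""
    import json

    path = Path(path)
    pd.DataFrame(sorted(result.dag.edges), columns=["source", "target"]).to_csv(
        path, sep="\t", index=False
    )
    path.with_suffix(".dot").write_text(edges_to_dot(result.dag.edges))
    record = {
        "c_used": result.c_used,
        "score": result.score,
        "trace": [m._asdict() for m in result.trace],
    }
    path.with_suffix(".json").write_text(json.dumps(record, indent=2))
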