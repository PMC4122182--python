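"""Synthetic multi-subject, multi-condition linear non-Gaussian SEM time series.

The generator emulates a blocked working-memory experiment: each block is an
instruction (preparation) period, a self-paced task period, and a short rest
period, sampled at a fixed TR.  Within a condition, each time point is an
independent draw from a linear structural equation model (SEM)

    x_j = sum_{p in parents(j)} beta_pj * x_p + e_j

over a known condition-specific DAG, with independent non-Gaussian
innovations ``e_j``.  A shared "default" edge set is present in every
condition; condition-specific extra edges model preparation/task-related
connectivity that is absent at rest.  Between-subject variability enters as
multiplicative jitter on the path coefficients.

No hemodynamic convolution or temporal autocorrelation is applied by
default (an optional AR(1) coloring of the innovations is available for
robustness checks only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .graphs import CONDITIONS, DAG, LOADS, Pair, edges_to_dot

NOISE_FAMILIES = ("uniform", "laplace", "exponential-symmetrized", "gaussian")


# ---------------------------------------------------------------------------
# schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScheduleParams:
    """Parameters of the block-design schedule.

    Defaults reproduce the study design: TR = 2 s, an 8-s instruction
    screen before each block (4 TRs), 10 blocks per n-back condition,
    task blocks of at least 21 TRs (self-paced, jittered up to +6 TRs),
    and a 10-12 s rest after each block.
    """

    tr_seconds: float = 2.0
    n_blocks_per_condition: int = 10
    instruction_seconds: float = 8.0
    block_trs_min: int = 21
    block_trs_jitter: int = 6
    rest_seconds_range: tuple[float, float] = (10.0, 12.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be > 0")
        if self.instruction_seconds <= 0:
            raise ValueError("instruction_seconds must be > 0")
        if self.block_trs_min <= 0:
            raise ValueError("block_trs_min must be > 0")
        if self.block_trs_jitter < 0:
            raise ValueError("block_trs_jitter must be >= 0")
        if self.n_blocks_per_condition < 0:
            raise ValueError("n_blocks_per_condition must be >= 0")
        lo, hi = self.rest_seconds_range
        if not (0 < lo <= hi):
            raise ValueError("rest_seconds_range must satisfy 0 < low <= high")

    @property
    def prep_trs(self) -> int:
        """Instruction-period length in whole TRs."""
        ratio = self.instruction_seconds / self.tr_seconds
        trs = round(ratio)
        if abs(ratio - trs) > 1e-9 or trs < 1:
            raise ValueError(
                "instruction_seconds does not convert to a whole number of TRs "
                f"(instruction_seconds={self.instruction_seconds}, tr_seconds={self.tr_seconds})"
            )
        return trs

    @property
    def rest_tr_choices(self) -> tuple[int, ...]:
        """Admissible rest-period lengths in whole TRs."""
        lo, hi = self.rest_seconds_range
        low_tr = math.ceil(lo / self.tr_seconds - 1e-9)
        high_tr = math.floor(hi / self.tr_seconds + 1e-9)
        if high_tr < low_tr or high_tr < 1:
            raise ValueError(
                "rest_seconds_range contains no whole number of TRs "
                f"(rest_seconds_range={self.rest_seconds_range}, tr_seconds={self.tr_seconds})"
            )
        return tuple(range(max(low_tr, 1), high_tr + 1))


class Segment(NamedTuple):
    """One schedule segment: half-open TR window [onset_tr, onset_tr + n_trs)."""

    condition: str
    onset_tr: int
    n_trs: int


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered, non-overlapping condition segments in TR units (0-based)."""

    segments: tuple[Segment, ...]
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        prev_end = 0
        for i, seg in enumerate(self.segments):
            if seg.condition not in CONDITIONS:
                raise ValueError(f"segment {i}: unknown condition {seg.condition!r}")
            if seg.onset_tr < 0 or seg.n_trs <= 0:
                raise ValueError(f"segment {i}: invalid window {seg}")
            if seg.onset_tr < prev_end:
                raise ValueError(f"segment {i} overlaps or is out of order: {seg}")
            prev_end = seg.onset_tr + seg.n_trs

    @property
    def total_trs(self) -> int:
        if not self.segments:
            return 0
        last = self.segments[-1]
        return last.onset_tr + last.n_trs

    def conditions_present(self) -> tuple[str, ...]:
        return tuple(c for c in CONDITIONS if any(s.condition == c for s in self.segments))


def make_schedule(params: ScheduleParams) -> BlockSchedule:
    """Build a randomized block schedule.

    Each block is ``prep_k`` (instruction), ``task_k`` (self-paced n-back
    block), then ``rest``; the per-condition blocks are presented in an
    order randomized by ``params.seed``.
    """
    prep_trs = params.prep_trs
    rest_choices = params.rest_tr_choices
    rng = np.random.default_rng(params.seed)
    loads = np.repeat(LOADS, params.n_blocks_per_condition)
    order = rng.permutation(loads)
    segments: list[Segment] = []
    t = 0
    for load in order:
        segments.append(Segment(f"prep{load}", t, prep_trs))
        t += prep_trs
        task_len = params.block_trs_min + int(rng.integers(0, params.block_trs_jitter + 1))
        segments.append(Segment(f"task{load}", t, task_len))
        t += task_len
        rest_len = int(rng.choice(rest_choices))
        segments.append(Segment("rest", t, rest_len))
        t += rest_len
    return BlockSchedule(tuple(segments), params.tr_seconds)


# ---------------------------------------------------------------------------
# graph sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConditionGraphSet:
    """Ground-truth directed graphs for all seven conditions.

    ``default_edges`` appear in every condition; ``extra_edges`` adds
    condition-specific connections.  ``weights`` maps ``(condition, edge)``
    to the standardized path coefficient used when simulating.
    """

    nodes: tuple[str, ...]
    default_edges: frozenset[Pair]
    extra_edges: Mapping[str, frozenset]
    weights: Mapping[tuple[str, Pair], float]

    def __post_init__(self) -> None:
        for cond in self.extra_edges:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        for cond in CONDITIONS:
            self.graph(cond)  # raises if cyclic / malformed

    def edges(self, condition: str) -> frozenset:
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}")
        return self.default_edges | self.extra_edges.get(condition, frozenset())

    def graph(self, condition: str) -> DAG:
        return DAG(self.nodes, frozenset(self.edges(condition)))

    def weight(self, condition: str, edge: Pair) -> float:
        return self.weights[(condition, edge)]

    def coefficient_matrix(self, condition: str) -> np.ndarray:
        """B with B[i, j] = beta_{i -> j} in node order."""
        idx = {n: i for i, n in enumerate(self.nodes)}
        B = np.zeros((len(self.nodes), len(self.nodes)))
        for s, t in self.edges(condition):
            B[idx[s], idx[t]] = self.weights[(condition, (s, t))]
        return B


def _sample_edges(
    count: int,
    candidates: list[Pair],
    used: set[Pair],
    adjacency: dict[str, set[str]],
    allow_triangles: bool,
    what: str,
) -> set[Pair]:
    """Greedily take ``count`` unused candidate edges, optionally avoiding
    triangles in the undirected graph described by ``adjacency`` (updated
    in place)."""
    chosen: set[Pair] = set()
    for u, v in candidates:
        if len(chosen) == count:
            break
        if (u, v) in used:
            continue
        if not allow_triangles and adjacency[u] & adjacency[v]:
            continue
        chosen.add((u, v))
        used.add((u, v))
        adjacency[u].add(v)
        adjacency[v].add(u)
    if len(chosen) < count:
        raise ValueError(
            f"cannot place {count} {what} edges: only {len(chosen)} feasible "
            f"given acyclicity/triangle constraints on {len(adjacency)} nodes"
        )
    return chosen


def sample_graph_set(
    nodes: Sequence[str],
    n_default_edges: int,
    n_extra_edges_per_condition: Mapping[str, int] | int = 0,
    weight_range: tuple[float, float] = (0.5, 0.9),
    seed: int = 0,
    scenario: str = "paired",
    allow_triangles: bool = False,
) -> ConditionGraphSet:
    """Sample a random ground-truth graph set.

    A single random topological order over ``nodes`` is drawn, and all edges
    (default and extra) respect it, so every condition's union graph is
    acyclic by construction.  With ``scenario="paired"`` the extra edges for
    ``prep_k`` and ``task_k`` are identical (the preparation-related sub-
    network carries over into the task) and are excluded from rest; with
    ``scenario="independent"`` each condition draws its own extras.  Extra
    edge sets are disjoint across conditions and from the default set.
    By default no condition graph contains a triangle (three pairwise-
    adjacent nodes), matching the model class the search stage accepts.
    """
    nodes = tuple(nodes)
    if len(set(nodes)) != len(nodes):
        raise ValueError("duplicate node labels")
    if scenario not in ("paired", "independent"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if isinstance(n_extra_edges_per_condition, int):
        n_extra = {c: n_extra_edges_per_condition for c in CONDITIONS}
    else:
        unknown = set(n_extra_edges_per_condition) - set(CONDITIONS)
        if unknown:
            raise ValueError(f"unknown condition labels {sorted(unknown)}")
        n_extra = {c: int(n_extra_edges_per_condition.get(c, 0)) for c in CONDITIONS}
    max_edges = len(nodes) * (len(nodes) - 1) // 2
    if n_default_edges < 0 or n_default_edges > max_edges:
        raise ValueError(
            f"n_default_edges={n_default_edges} infeasible: an acyclic graph on "
            f"{len(nodes)} nodes holds at most {max_edges} edges"
        )

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(len(nodes)))
    rank = {nodes[i]: r for r, i in enumerate(order)}
    candidates = [
        (u, v) if rank[u] < rank[v] else (v, u)
        for i, u in enumerate(nodes)
        for v in nodes[i + 1:]
    ]
    rng.shuffle(candidates)

    used: set[Pair] = set()
    # per-condition undirected adjacency, for triangle avoidance
    adj = {c: {n: set() for n in nodes} for c in CONDITIONS}

    shared_adj: dict[str, set[str]] = {n: set() for n in nodes}
    default = _sample_edges(n_default_edges, candidates, used, shared_adj,
                            allow_triangles, "default")
    for c in CONDITIONS:
        for n in nodes:
            adj[c][n] = set(shared_adj[n])

    extra: dict[str, set[Pair]] = {c: set() for c in CONDITIONS}
    if scenario == "paired":
        for k in LOADS:
            prep, task = f"prep{k}", f"task{k}"
            if n_extra[prep] != n_extra[task]:
                raise ValueError(
                    f"scenario 'paired' requires equal extras for {prep} and {task} "
                    f"(got {n_extra[prep]} vs {n_extra[task]})"
                )
            chosen = _sample_edges(n_extra[prep], candidates, used, adj[prep],
                                   allow_triangles, prep)
            for u, v in chosen:
                adj[task][u].add(v)
                adj[task][v].add(u)
            extra[prep] = chosen
            extra[task] = set(chosen)
        extra["rest"] = _sample_edges(n_extra["rest"], candidates, used, adj["rest"],
                                      allow_triangles, "rest")
    else:
        for c in CONDITIONS:
            extra[c] = _sample_edges(n_extra[c], candidates, used, adj[c],
                                     allow_triangles, c)

    lo, hi = weight_range
    weights: dict[tuple[str, Pair], float] = {}
    for c in CONDITIONS:
        for e in sorted(default | extra[c]):
            weights[(c, e)] = float(rng.uniform(lo, hi))
    return ConditionGraphSet(
        nodes=nodes,
        default_edges=frozenset(default),
        extra_edges={c: frozenset(extra[c]) for c in CONDITIONS},
        weights=weights,
    )


# ---------------------------------------------------------------------------
# noise and time series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NoiseSpec:
    """Innovation distribution for the SEM error terms.

    ``scale`` is the standard deviation.  The default family is uniform
    (strongly sub-Gaussian), which the orientation stage requires; the
    gaussian family exists for negative-control experiments where
    orientation is expected to be uninformative.
    """

    family: str = "uniform"
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}; choose from {NOISE_FAMILIES}")
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    def sample(self, rng: np.random.Generator, size) -> np.ndarray:
        s = self.scale
        if self.family == "uniform":
            half_width = s * math.sqrt(3.0)
            return rng.uniform(-half_width, half_width, size)
        if self.family == "laplace":
            return rng.laplace(0.0, s / math.sqrt(2.0), size)
        if self.family == "exponential-symmetrized":
            mag = rng.exponential(s / math.sqrt(2.0), size)
            sign = rng.choice((-1.0, 1.0), size)
            return mag * sign
        return rng.normal(0.0, s, size)


@dataclass(frozen=True)
class ROITimeSeries:
    """One subject's BOLD-like series: rows are TRs, columns are ROIs."""

    subject_id: str
    roi_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != len(self.roi_labels):
            raise ValueError("values must be a TRs x ROIs matrix matching roi_labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("values contain non-finite entries")
        object.__setattr__(self, "values", v)

    @property
    def n_trs(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.roi_labels))


def _jittered_matrices(
    graphs: ConditionGraphSet, subject_jitter: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Per-condition mixing matrices (I - B)^-1 with subject-specific
    multiplicative coefficient jitter (drawn once per subject)."""
    p = len(graphs.nodes)
    idx = {n: i for i, n in enumerate(graphs.nodes)}
    factors = {
        key: 1.0 + rng.uniform(-subject_jitter, subject_jitter)
        for key in sorted(graphs.weights)
    } if subject_jitter > 0 else {}
    mix = {}
    for cond in CONDITIONS:
        B = np.zeros((p, p))
        for edge in sorted(graphs.edges(cond)):
            beta = graphs.weights[(cond, edge)]
            beta *= factors.get((cond, edge), 1.0)
            B[idx[edge[0]], idx[edge[1]]] = beta
        mix[cond] = np.linalg.inv(np.eye(p) - B)
    return mix


def _ar1_color(e: np.ndarray, phi: float, rng: np.random.Generator) -> np.ndarray:
    """AR(1)-color innovations along time, preserving marginal variance."""
    out = np.empty_like(e)
    out[0] = e[0]
    w = math.sqrt(1.0 - phi * phi)
    for t in range(1, e.shape[0]):
        out[t] = phi * out[t - 1] + w * e[t]
    return out


def simulate_subject(
    graphs: ConditionGraphSet,
    schedule: BlockSchedule,
    noise: NoiseSpec = NoiseSpec(),
    subject_jitter: float = 0.1,
    seed: int = 0,
    subject_id: str = "s00",
    ar_coeff: float = 0.0,
) -> ROITimeSeries:
    """Simulate one subject's ROI time series over a block schedule.

    Within each segment, rows are i.i.d. draws from the linear SEM of that
    segment's condition.  ``subject_jitter`` multiplies every path
    coefficient by an independent factor in ``1 +- subject_jitter`` (one
    draw per coefficient per subject).  ``ar_coeff`` optionally colors the
    innovations with an AR(1) filter (robustness checks only; off by
    default).
    """
    if not schedule.segments:
        raise ValueError("schedule is empty")
    if not (0.0 <= subject_jitter < 1.0):
        raise ValueError("subject_jitter must be in [0, 1)")
    if not (0.0 <= ar_coeff < 1.0):
        raise ValueError("ar_coeff must be in [0, 1)")
    rng = np.random.default_rng(seed)
    mix = _jittered_matrices(graphs, subject_jitter, rng)
    p = len(graphs.nodes)
    X = np.empty((schedule.total_trs, p))
    X.fill(np.nan)
    for seg in schedule.segments:
        E = noise.sample(rng, (seg.n_trs, p))
        if ar_coeff > 0.0 and seg.n_trs > 1:
            E = _ar1_color(E, ar_coeff, rng)
        X[seg.onset_tr:seg.onset_tr + seg.n_trs] = E @ mix[seg.condition]
    # TRs not covered by any segment (schedules are contiguous by
    # construction, but be safe): fill with pure noise at rest mixing
    if np.isnan(X).any():
        holes = np.isnan(X[:, 0])
        X[holes] = noise.sample(rng, (int(holes.sum()), p)) @ mix["rest"]
    return ROITimeSeries(subject_id, graphs.nodes, X)


def simulate_study(
    graphs: ConditionGraphSet,
    schedule: BlockSchedule,
    noise: NoiseSpec = NoiseSpec(),
    n_subjects: int = 16,
    subject_jitter: float = 0.1,
    seed: int = 0,
) -> list[ROITimeSeries]:
    """Simulate a cohort: ``n_subjects`` independent subjects on one schedule."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    return [
        simulate_subject(
            graphs, schedule, noise, subject_jitter,
            seed=int(subject_seeds[i]), subject_id=f"s{i:02d}",
        )
        for i in range(n_subjects)
    ]


# ---------------------------------------------------------------------------
# single-graph benchmark (50-variable setting)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkTruth:
    """Ground truth of a single-graph benchmark: the DAG and its coefficients."""

    dag: DAG
    weights: Mapping[Pair, float]


def simulate_benchmark(
    n_vars: int = 50,
    n_subjects: int = 10,
    n_timepoints: int = 200,
    edge_density: float = 0.05,
    noise: NoiseSpec = NoiseSpec(),
    weight_range: tuple[float, float] = (0.5, 0.9),
    subject_jitter: float = 0.1,
    seed: int = 0,
    allow_triangles: bool = False,
) -> tuple[list[ROITimeSeries], BenchmarkTruth]:
    """Multi-subject benchmark with one shared truth DAG.

    Emulates the large simulated-network setting used to benchmark
    multi-dataset structure search: ``n_vars`` variables, a sparse random
    acyclic truth graph (triangle-free by default), and ``n_subjects``
    independent SEM datasets whose coefficients carry per-subject jitter.
    ``edge_density`` is the fraction of the ``n_vars * (n_vars - 1) / 2``
    possible adjacencies that are edges (default ~61 edges at 50 variables).
    """
    if n_vars < 2:
        raise ValueError("n_vars must be >= 2")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if n_timepoints < 2:
        raise ValueError("n_timepoints must be >= 2")
    max_edges = n_vars * (n_vars - 1) // 2
    n_edges = round(edge_density * max_edges)
    if n_edges < 1:
        raise ValueError(
            f"edge_density={edge_density} yields {n_edges} edges on {n_vars} variables; need >= 1"
        )

    width = len(str(n_vars))
    nodes = tuple(f"V{i + 1:0{width}d}" for i in range(n_vars))
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n_vars))
    rank = {nodes[i]: r for r, i in enumerate(order)}
    candidates = [
        (u, v) if rank[u] < rank[v] else (v, u)
        for i, u in enumerate(nodes)
        for v in nodes[i + 1:]
    ]
    rng.shuffle(candidates)
    adjacency: dict[str, set[str]] = {n: set() for n in nodes}
    edges = _sample_edges(n_edges, candidates, set(), adjacency,
                          allow_triangles, "benchmark")
    lo, hi = weight_range
    weights = {e: float(rng.uniform(lo, hi)) for e in sorted(edges)}
    truth = BenchmarkTruth(DAG(nodes, frozenset(edges)), weights)

    idx = {n: i for i, n in enumerate(nodes)}
    datasets = []
    subject_seeds = rng.integers(0, 2**31 - 1, size=n_subjects)
    for s in range(n_subjects):
        srng = np.random.default_rng(int(subject_seeds[s]))
        B = np.zeros((n_vars, n_vars))
        for (u, v), beta in weights.items():
            if subject_jitter > 0:
                beta *= 1.0 + srng.uniform(-subject_jitter, subject_jitter)
            B[idx[u], idx[v]] = beta
        E = noise.sample(srng, (n_timepoints, n_vars))
        X = E @ np.linalg.inv(np.eye(n_vars) - B)
        datasets.append(ROITimeSeries(f"s{s:02d}", nodes, X))
    return datasets, truth


# ---------------------------------------------------------------------------
# analytic moments (used as test oracles and for sanity checks)
# ---------------------------------------------------------------------------

def sem_covariance(B: np.ndarray, innovation_variance: float = 1.0) -> np.ndarray:
    """Closed-form covariance of the linear SEM x = B^T x + e:
    (I - B)^-T Sigma_e (I - B)^-1 with Sigma_e = innovation_variance * I."""
    p = B.shape[0]
    inv = np.linalg.inv(np.eye(p) - B)
    return inv.T @ (innovation_variance * np.eye(p)) @ inv


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_timeseries(ts: ROITimeSeries, path: str | Path) -> None:
    """One tab-separated file per subject: header = ROI labels, one row per TR."""
    ts.to_frame().to_csv(path, sep="\t", index=False)


def read_timeseries(path: str | Path, subject_id: str | None = None) -> ROITimeSeries:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    return ROITimeSeries(subject_id or path.stem, tuple(df.columns), df.to_numpy(float))


def write_schedule(schedule: BlockSchedule, path: str | Path) -> None:
    """Three-column TSV: condition, onset_tr (0-based), n_trs (half-open)."""
    pd.DataFrame(schedule.segments, columns=["condition", "onset_tr", "n_trs"]).to_csv(
        path, sep="\t", index=False
    )


def read_schedule(path: str | Path, tr_seconds: float = 2.0) -> BlockSchedule:
    df = pd.read_csv(path, sep="\t")
    segments = tuple(
        Segment(str(r.condition), int(r.onset_tr), int(r.n_trs))
        for r in df.itertuples(index=False)
    )
    return BlockSchedule(segments, tr_seconds)


def write_edges(edges_with_weights: Mapping[Pair, float], path: str | Path) -> None:
    """Edge-list TSV (source, target, weight) plus a sibling .dot file."""
    path = Path(path)
    rows = [(s, t, w) for (s, t), w in sorted(edges_with_weights.items())]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, sep="\t", index=False
    )
    path.with_suffix(".dot").write_text(
        edges_to_dot(edges_with_weights.keys(), weights=dict(edges_with_weights))
    )
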