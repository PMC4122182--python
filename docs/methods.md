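# Methods

## Model class and assumptions

Each condition's data-generating model is a linear recursive structural
equation model (SEM) over a directed acyclic graph (DAG) on the ROI
labels: `x_j = Σ_{p∈Pa(j)} β_pj x_p + e_j`, with mutually independent
innovations `e_j`. Three assumptions carry the whole pipeline:

* **Acyclicity** — contemporaneous influence only, no feedback loops.
* **Shared structure across subjects** — all subjects share one graph per
  condition; coefficients may differ by subject (the score averages
  per-subject fits rather than concatenating time series, which would
  manufacture spurious dependencies).
* **Non-Gaussian innovations** — required only by the orientation stage;
  skeleton discovery and SEM estimation are Gaussian-likelihood-based and
  work regardless.

Time points within a condition are treated as exchangeable draws; the
analysis uses no temporal ordering beyond the segment windows.

## Synthetic data

The generator emulates the blocked working-memory design: per block an
instruction (preparation) segment, a self-paced task segment, and a rest
segment. Defaults are the study's parameters: TR = 2 s, 8-s instruction
(4 TRs), 10 blocks per load, task blocks of at least 21 TRs, rests of
10–12 s. Task-block lengths are drawn uniformly on
[block_trs_min, block_trs_min + 6] TRs to emulate self-paced variability;
rest lengths uniformly over the whole TR counts inside the rest range
(5–6 TRs at the defaults).

Ground truth is a `ConditionGraphSet`: one default edge set shared by all
seven conditions plus condition-specific extras; in the "paired" scenario
the extras for preparation-*k* and task-*k* coincide and are excluded from
rest, which is exactly the structure the classifier is meant to recover.
All edges respect a single random topological order, so every condition
graph is acyclic by construction; by default no condition graph contains a
triangle, since a triangle-free graph is the model class the search stage
accepts (the penalty-escalation rule rejects triangulated skeletons as
potential latent-confounding artifacts). Weights default to 0.5–0.9
(strong, standardized-scale effects); per-subject variability is
multiplicative ±10% jitter on every coefficient, drawn once per subject.

Innovations default to uniform (strongly sub-Gaussian; excess kurtosis
−1.2) because orientation by non-Gaussianity requires a non-Gaussian
source; Laplace and symmetrized-exponential are available, and Gaussian is
reserved for negative controls where orientation is uninformative by
design. Innovation scale is 1.0; scale is irrelevant downstream because
every dataset is standardized.

What the generator does *not* emulate: hemodynamic convolution, temporal
autocorrelation (an optional AR(1) coloring of the innovations exists for
robustness checks but is off by default), physiological noise, motion,
or spatial structure. Passing recovery tests therefore show that the
*statistical* machinery works under the stated model class, not that real
BOLD data satisfy that class — with autocorrelated or hemodynamically
smeared data the effective sample sizes shrink and orientation accuracy in
particular will degrade.

The 50-variable benchmark (`simulate_benchmark`) uses one shared sparse
truth DAG (default density 0.05, ~61 edges), 10 subjects, 200 time points
each — session lengths and density are free parameters since the emulated
large-simulation setting does not pin them down.

## Segmentation

0-based TR indices, half-open `[onset, onset + n_trs)` windows. Same-
condition segments are concatenated (the pooled per-condition data-point
counts imply pooled analysis). Rest segments drop their first
`ceil(4 s / TR)` TRs (2 at TR = 2 s), keeping the last 3–4 TRs of each
5–6-TR rest: this skips the hemodynamic carry-over of the preceding task
block and reproduces the design's "at least 90 rest points" arithmetic.
Standardization is column-wise z-scoring with unit *sample* variance
(ddof = 1); zero-variance columns are an error by default and can be
flagged-and-zeroed instead. No detrending or filtering is applied.

## Structure search

The score of a DAG is decomposable:
`local(j, Pa) = mean over datasets of −n·ln σ̂² − c·(|Pa|+1)·ln n`, with
σ̂² the ML (divisor n) residual variance of the intercept-free OLS of node
j on Pa. This is `2·logL − c·k·ln n` up to constants common to all
models. Subjects enter with equal weight. On standardized data the
regression reduces to covariance algebra, so local scores are small linear
solves against per-dataset covariance matrices, cached by
(node, parent-set).

Because Gaussian BIC is score-equivalent (Markov-equivalent DAGs score
identically — a tested invariant), the search moves over equivalence
classes (CPDAGs), not individual DAGs: standard insert/delete operators
with the usual validity conditions (the insert's
neighbor-clique and semi-directed-path checks; the delete's clique
condition), completion after every move by consistent extension
(Dor–Tarsi) followed by v-structure identification and Meek rules R1–R3.
Forward phase to a local maximum, then backward phase. An earlier design
maintained a single working DAG with add/remove moves only; it was
abandoned because wrongly-oriented working edges induce genuinely
score-improving spurious edges (13–28 false positives on the 50-variable
benchmark), which triangulate the skeleton and force the penalty
escalation to shed true edges. The equivalence-class search returns
essentially false-positive-free skeletons at low penalties.

Numerical choices: strict-improvement threshold 1e−9 on the averaged
score (stops floating-point churn between score-equivalent states); ties
broken toward the lexicographically smallest (child, parent) pair for
determinism; σ̂² floored at 1e−12. Penalty escalation is c = 1, 2, …, 20
by default; the first skeleton with no triangle is accepted and the
discount used is reported as an output, not a target. If c_max is reached
with triangles remaining, the error lists them.

## Orientation

The Anderson–Darling statistic of a sample against normality (location
and scale estimated, ddof = 1 standardization — the same convention as
scipy's implementation, which the tests use as an independent oracle):

    A² = −n − (1/n) Σ_i (2i−1)[ln F(z_(i)) + ln(1 − F(z_(n+1−i)))]

with CDF values clipped to [1e−10, 1−1e−10]; n ≥ 8 required.

Each skeleton edge {X, Y} is scored under both directions: under X→Y the
local parent sets are Pa(Y) = adj(Y) (including X) and
Pa(X) = adj(X) \ {Y}; the direction score is the sum over both nodes and
all subjects of A² of the intercept-free OLS residuals, and the higher
(more non-Gaussian) direction wins — rule "pairwise-AD". Summing across
subjects (rather than voting or averaging) weights subjects by evidence
and is monotone-equivalent to the mean at equal n. The adjacency
structure is never modified. If the per-edge choices form a directed
cycle, the cycle edge with the smallest decision margin is flipped and
frozen, repeatedly, until acyclic — disturbing the least-confident
decisions first. Ties break toward the lexicographically smaller
(source, target).

## SEM estimation and aggregation

For a recursive SEM with independent errors, node-wise OLS of each node on
its DAG parents is the exact ML estimator, so no iterative optimizer is
used. Estimation is intercept-free on standardized data, consistent with
the search's score. Per-node residual variances and the Gaussian
log-likelihood are retained as fit diagnostics; no χ²/fit-index testing is
performed. Across subjects, each edge is summarized by the mean and sample
SD (ddof = 1); a single-subject fit reports SD 0 with an explicit
degenerate flag rather than NaN so rendered tables never contain missing
cells for present edges.

## Sub-network classification

Presence is direction-blind: a connection is identified by its unordered
ROI pair, because the orientation stage may flip a connection between
conditions while the connection itself persists. One refinement: tables
digitized from print can list the same pair as two *separate*,
oppositely-directed rows, and the published bookkeeping counts those rows
as distinct connections (within-row flips are marked with a reversed-
direction marker instead). Classification therefore keys on
(pair, source-row label); pipeline-built tables carry no row labels, so
for them this reduces exactly to unordered-pair identity.

Classes: default = present in all seven conditions;
preparation-related(k) = present in prep-k and task-k, absent at rest;
preparation+rest-only(k) = present in prep-k and rest, absent in every
task condition. A pair's direction markers across the conditions where it
appears feed a `direction_variable` set; bold emphasis in the digitized
tables is carried as metadata and never used. Rows printed with a plain
dash (no arrow) are ingested as direction-unknown; a printed coefficient
of 0.00 still counts as present (presence in the tables encodes that the
search found the edge, not that its weight is large).

`compare_to_truth` scores a report against a generating
`ConditionGraphSet` by building the truth's own per-condition tables,
classifying them with the same function, and reporting per-category
precision/recall (None when a denominator is empty).

## Problem sizes in tests and the acceptance script

The benchmark recovery rates are computed at 50 variables, 10 subjects,
200 time points, five seeds (~15 s total); the study-scale pipeline tests
use 18 ROIs and 16 subjects on the full default schedule (~1 s per
condition set). Exhaustive-enumeration oracles run on 3–4 nodes, where all
25 / 543 DAGs are scored from scratch by an independent lstsq-based
implementation.

## Known limitations

* The i.i.d.-within-segment assumption ignores BOLD autocorrelation; with
  real data the effective n per condition is smaller than the row counts.
* Orientation is only as good as the innovations are non-Gaussian; with
  near-Gaussian sources the direction margins shrink to noise (the
  Gaussian negative-control test asserts exactly this).
* The search assumes causal sufficiency on the chosen ROI set; latent
  confounders outside it can still produce spurious adjacencies (the
  triangle-rejection heuristic mitigates but does not solve this).
* Greedy equivalence search is a local optimizer; the exhaustive-oracle
  guarantee is only verified on small graphs.
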