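# effconn

Multi-subject effective-connectivity analysis for block-design ROI time
series: structure discovery by multi-dataset greedy BIC search, edge
orientation by residual non-Gaussianity, SEM path estimation, and
classification of connections into task-related sub-networks.

## The problem

In a blocked working-memory experiment (1-, 2-, 3-back), each task block is
preceded by an instruction (preparation) period and followed by a short
rest. Given each subject's time series for a set of regions of interest
(ROIs), the question is how the *directed* influence structure among those
regions differs between preparing for a task, performing it, and resting —
in particular, which connections form a **default** sub-network (present in
every condition, rest included) and which are **preparation-related**
(present while preparing for load *k* and performing load *k*, but absent
at rest).

## The method

For each of the seven conditions (three preparation, three task, rest), the
pipeline:

1. **Segments** each subject's series into per-condition datasets
   (half-open TR windows, 0-based; rest periods drop their first
   ⌈4 s / TR⌉ samples) and z-scores each column.
2. **Discovers the skeleton** by greedy equivalence search maximizing a
   Gaussian BIC averaged across subjects,

   `local(j, Pa) = mean_d [ −n·ln σ̂²_d − c·(|Pa|+1)·ln n ]`,

   with σ̂² the ML residual variance of the intercept-free regression of
   node *j* on its parents and *c* ≥ 1 a penalty discount. The discount is
   escalated (*c* = 1, 2, …) until the first skeleton with no triangle —
   three mutually adjacent nodes, a signature of latent confounding.
3. **Orients** every skeleton edge by comparing, under the two candidate
   directions, the Anderson–Darling departure-from-normality (A²) of the
   local regression residuals, summed over subjects: with independent
   non-Gaussian innovations, the causally correct direction leaves the
   more non-Gaussian residuals.
4. **Estimates** per-subject SEM path coefficients by node-wise OLS (the
   exact ML estimator for a recursive SEM) and reports across-subject
   mean (SD) per edge.
5. **Classifies** connections across the seven per-condition edge tables
   into default / preparation-related(k) / preparation+rest-only
   sub-networks by set algebra over unordered ROI pairs.

A synthetic-data module generates the whole study design — block
schedules, condition-specific ground-truth DAGs with a shared default edge
set, and linear-SEM time series with uniform/Laplace innovations and
per-subject coefficient jitter — so every stage is testable end to end.
Digitized transcriptions of the two published connectivity tables ship as
plain-text fixtures.

## Worked example

`python examples/simulate_and_recover.py` simulates 16 subjects on the
default design (10 blocks per load, 4-TR preparation periods, ≥21-TR task
blocks, 5–6-TR rests at TR = 2 s) and recovers the sub-networks:

```
schedule: 90 segments, 998 TRs
data points per condition: {'prep1': 40, 'prep2': 40, 'prep3': 40,
 'task1': 247, 'task2': 241, 'task3': 226, 'rest': 104}
default sub-network: 11 edges recovered, precision=1.00 recall=1.00
preparation-related(1): predicted=1 true=1 precision=1.0 recall=1.0
preparation-related(2): predicted=2 true=2 precision=1.0 recall=1.0
preparation-related(3): predicted=5 true=5 precision=1.0 recall=1.0
```

Every preparation condition yields exactly 40 data points per subject per
ROI, each task condition at least 210, rest at least 90; the classifier
recovers the generating default and preparation-related edge sets exactly
on this run. `examples/printed_tables.py` reproduces the published
sub-network counts from the packaged tables (11 default + 1/2/5
preparation-related connections in the load-increasing network, 10 default
in the load-decreasing network), and `examples/benchmark_recovery.py` runs
one seed of the 50-variable benchmark.

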