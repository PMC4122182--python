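"""Simulate a 16-subject block-design study and recover its sub-networks.

Builds a ground-truth set of condition graphs (11 default edges shared by
all seven conditions plus load-specific preparation/task extras), simulates
every subject's ROI time series from linear SEMs with uniform innovations,
segments and standardizes per condition, runs the penalty-escalating
greedy BIC search and Anderson-Darling orientation per condition, and
compares the classified sub-networks against the generating truth.
"""

import effconn as ec

NODES = tuple(f"R{i:02d}" for i in range(18))
EXTRAS = {"prep1": 1, "task1": 1, "prep2": 2, "task2": 2,
          "prep3": 5, "task3": 5, "rest": 0}

truth = ec.sample_graph_set(NODES, n_default_edges=11,
                            n_extra_edges_per_condition=EXTRAS, seed=5)
schedule = ec.make_schedule(ec.ScheduleParams(seed=5))
print(f"schedule: {len(schedule.segments)} segments, {schedule.total_trs} TRs")

subjects = ec.simulate_study(truth, schedule, n_subjects=16, seed=7)
datasets = ec.condition_datasets(subjects, schedule)
print("data points per condition:", {c: d[0].n for c, d in datasets.items()})

results = ec.fit_study(datasets)
report = ec.classify_study(results)
accuracy = ec.compare_to_truth(report, truth)

print("penalty discount used per condition:",
      {c: r.c_used for c, r in results.items()})
print(f"default sub-network: {len(report.default_edges)} edges recovered, "
      f"precision={accuracy['default'].precision:.2f} "
      f"recall={accuracy['default'].recall:.2f}")
for k in ec.LOADS:
    a = accuracy["prep_related"][k]
    print(f"preparation-related({k}): predicted={a.n_predicted} true={a.n_true} "
          f"precision={a.precision} recall={a.recall}")

cond = "task3"
print(f"\nstrongest estimated paths in {cond} (mean (sd) across subjects):")
for est in sorted(results[cond].estimates, key=lambda e: -abs(e.mean))[:5]:
    print(f"  {est.edge[0]} -> {est.edge[1]}: "
          f"{ec.format_cell(results[cond].table.entries[ec.undirected(*est.edge)])}")
print(
    "\nPrecision/recall of 1.0 means every generated default and "
    "preparation-related connection was recovered with no spurious ones."
)
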