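"""Classify the packaged connectivity tables into sub-networks.

Loads the digitized per-condition connectivity tables of the two
working-memory networks (regions whose activation increases or decreases
with n-back load) and partitions the connections into "default" (present
in every condition including rest) and "preparation-related" (present
during a load's preparation and task periods but absent at rest).
"""

import effconn as ec

for network in ("increase", "decrease"):
    tables = ec.load_printed_table(ec.fixture_path(network))
    report = ec.classify_connections(tables)
    print(f"\n{network.capitalize()} network")
    print(f"  default connections ({len(report.default_edges)}):")
    for a, b in sorted(report.default_edges):
        print(f"    {a} - {b}")
    for k in ec.LOADS:
        pairs = ", ".join(f"{a}-{b}" for a, b in sorted(report.prep_related[k])) or "none"
        print(f"  preparation-related, {k}-back ({len(report.prep_related[k])}): {pairs}")
    for k in ec.LOADS:
        if report.prep_rest_only[k]:
            pairs = ", ".join(f"{a}-{b}" for a, b in sorted(report.prep_rest_only[k]))
            print(f"  preparation+rest only, {k}-back: {pairs}")

print(
    "\nDefault connections persist across preparation, task and rest; "
    "preparation-related connections appear before the task and carry into "
    "it, growing in number with anticipated difficulty."
)
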