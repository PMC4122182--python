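"""Classify connections across the seven condition graphs into sub-networks.

Connection identity is the unordered ROI pair: the orientation stage may
flip a connection's direction between conditions, but a pair present in
two conditions counts as the same connection.  Three classes are formed by
set algebra over per-condition presence:

* default - present in every one of the 7 conditions (all preparation,
  all task, and rest);
* preparation-related(k) - present during preparation for load k AND the
  load-k task, but absent at rest;
* preparation+rest-only(k) - present during preparation for load k AND at
  rest, but absent during every task condition.

Digitized transcriptions of the two published connectivity tables (the
load-increasing and load-decreasing networks) ship with the package as
TSV fixtures; ``load_printed_table`` parses them into per-condition
EdgeTables so the classifier can reproduce the published sub-network
counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

from .graphs import CONDITIONS, LOADS, Pair, undirected
from .sem import Cell, EdgeTable
from .synthdata import ConditionGraphSet

#: Printed column headings and their canonical condition labels.
COLUMN_CONDITIONS: dict[str, str] = {
    "Intro1": "prep1",
    "1-back": "task1",
    "Intro2": "prep2",
    "2-back": "task2",
    "Intro3": "prep3",
    "3-back": "task3",
    "Rest": "rest",
}

_CELL_RE = re.compile(
    r"^(?P<rev><\s*)?(?P<mean>-?\d+(?:\.\d+)?)\s*\((?P<sd>\d+(?:\.\d+)?)\)(?P<bold>\*)?$"
)


@dataclass(frozen=True)
class SubNetworkReport:
    """Edge sets classified by presence pattern across the 7 conditions."""

    default_edges: frozenset
    prep_related: Mapping[int, frozenset]
    prep_rest_only: Mapping[int, frozenset]
    #: pairs whose direction marker differs across the conditions where present
    direction_variable: frozenset


def fixture_path(network: str) -> Path:
    """Path to the packaged table fixture: network 'increase' or 'decrease'."""
    name = {"increase": "table_increase.tsv", "decrease": "table_decrease.tsv"}.get(
        network.lower()
    )
    if name is None:
        raise ValueError("network must be 'increase' or 'decrease'")
    return Path(str(resources.files("effconn").joinpath("data", name)))


def _parse_connection_label(label: str) -> tuple[str, str, bool]:
    """Return (left, right, directed) for a row label like 'A->B' or 'A-B'."""
    if "->" in label:
        left, right = label.split("->")
        directed = True
    elif label.count("-") == 1:
        left, right = label.split("-")
        directed = False
    else:
        raise ValueError(f"cannot parse connection label {label!r}")
    left, right = left.strip(), right.strip()
    if not left or not right or left == right:
        raise ValueError(f"cannot parse connection label {label!r}")
    return left, right, directed


def load_printed_table(path: str | Path) -> dict[str, EdgeTable]:
    """Parse a digitized connectivity-table fixture into per-condition tables.

    The fixture is a TSV with a ``connection`` column followed by the seven
    condition columns.  Cell grammar: empty = connection absent in that
    condition; ``mean (sd)`` = present in the row-label direction;
    a leading ``<`` = present with the direction reversed; a trailing ``*``
    carries the table's bold emphasis (stored, never used).  Rows whose
    label uses ``-`` instead of ``->`` have unknown direction in every cell.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        return {cond: EdgeTable(cond, {}) for cond in CONDITIONS}
    header = lines[0].rstrip("\n").split("\t")
    if header[0] != "connection" or header[1:] != list(COLUMN_CONDITIONS):
        raise ValueError(f"unexpected fixture header: {header}")
    entries: dict[str, dict[Pair, Cell]] = {cond: {} for cond in CONDITIONS}
    seen_labels = set()
    for raw in lines[1:]:
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        label = fields[0]
        if len(fields) != 8:
            raise ValueError(
                f"row {label!r}: expected 7 condition cells, got {len(fields) - 1}"
            )
        if label in seen_labels:
            raise ValueError(f"duplicate connection label {label!r}")
        seen_labels.add(label)
        left, right, directed = _parse_connection_label(label)
        pair = undirected(left, right)
        for col, cell_text in zip(header[1:], fields[1:]):
            cond = COLUMN_CONDITIONS[col]
            text = cell_text.strip()
            if not text:
                continue
            m = _CELL_RE.match(text)
            if m is None:
                raise ValueError(f"row {label!r}, column {col}: malformed cell {text!r}")
            if not directed:
                direction = None
            elif m.group("rev"):
                direction = (right, left)
            else:
                direction = (left, right)
            if pair in entries[cond]:
                raise ValueError(f"row {label!r}: pair {pair} duplicated in column {col}")
            entries[cond][pair] = Cell(
                direction=direction,
                mean=float(m.group("mean")),
                sd=float(m.group("sd")),
                bold=bool(m.group("bold")),
                row=label,
            )
    return {cond: EdgeTable(cond, entries[cond]) for cond in CONDITIONS}


def classify_connections(tables: Mapping[str, EdgeTable]) -> SubNetworkReport:
    """Set algebra over per-condition presence; see module docstring.

    Connection identity is the unordered pair, refined by the printed-table
    row label when one is carried (tables digitized from print can list the
    same pair as two oppositely-directed rows, which count as distinct
    connections); tables built from pipeline estimates carry no row labels,
    so for them identity is exactly the unordered pair.
    """
    missing = set(CONDITIONS) - set(tables)
    if missing:
        raise ValueError(f"missing condition tables: {sorted(missing)}")
    extra = set(tables) - set(CONDITIONS)
    if extra:
        raise ValueError(f"unexpected condition tables: {sorted(extra)}")

    def key(pair, cell):
        return (pair, cell.row)

    present = {
        cond: {key(pair, cell) for pair, cell in tables[cond].entries.items()}
        for cond in CONDITIONS
    }
    all_tasks = present["task1"] | present["task2"] | present["task3"]

    def pairs(keys) -> frozenset:
        return frozenset(pair for pair, _row in keys)

    default = pairs(set.intersection(*(present[c] for c in CONDITIONS)))
    prep_related = {
        k: pairs((present[f"prep{k}"] & present[f"task{k}"]) - present["rest"])
        for k in LOADS
    }
    prep_rest_only = {
        k: pairs((present[f"prep{k}"] & present["rest"]) - all_tasks)
        for k in LOADS
    }

    direction_variable = set()
    every_key = set().union(*present.values())
    for pair, row in every_key:
        dirs = {
            tables[c].entries[pair].direction
            for c in CONDITIONS
            if pair in tables[c].entries and tables[c].entries[pair].row == row
        }
        dirs.discard(None)
        if len(dirs) > 1:
            direction_variable.add(pair)
    return SubNetworkReport(
        default_edges=default,
        prep_related=prep_related,
        prep_rest_only=prep_rest_only,
        direction_variable=frozenset(direction_variable),
    )


def tables_from_graphs(graphs: ConditionGraphSet) -> dict[str, EdgeTable]:
    """Per-condition EdgeTables read straight off a ground-truth graph set."""
    out = {}
    for cond in CONDITIONS:
        entries = {}
        for edge in sorted(graphs.edges(cond)):
            pair = undirected(*edge)
            entries[pair] = Cell(edge, graphs.weights[(cond, edge)], 0.0)
        out[cond] = EdgeTable(cond, entries)
    return out


@dataclass(frozen=True)
class CategoryAccuracy:
    """Precision/recall of one predicted edge class against ground truth.

    ``precision``/``recall`` are None (not-applicable) when the predicted /
    true set is empty."""

    n_true: int
    n_predicted: int
    n_correct: int

    @property
    def precision(self) -> float | None:
        return None if self.n_predicted == 0 else self.n_correct / self.n_predicted

    @property
    def recall(self) -> float | None:
        return None if self.n_true == 0 else self.n_correct / self.n_true


def compare_to_truth(
    report: SubNetworkReport, truth: ConditionGraphSet
) -> dict[str, CategoryAccuracy | dict[int, CategoryAccuracy]]:
    """Precision/recall of the default and preparation-related edge sets
    against the classification implied by a generating graph set."""
    nodes = set(truth.nodes)
    mentioned = {
        n
        for pairs in (
            [report.default_edges]
            + list(report.prep_related.values())
            + list(report.prep_rest_only.values())
        )
        for pair in pairs
        for n in pair
    }
    unknown = mentioned - nodes
    if unknown:
        raise ValueError(f"report references labels outside the truth set: {sorted(unknown)}")
    truth_report = classify_connections(tables_from_graphs(truth))

    def acc(pred: frozenset, true: frozenset) -> CategoryAccuracy:
        return CategoryAccuracy(len(true), len(pred), len(pred & true))

    return {
        "default": acc(report.default_edges, truth_report.default_edges),
        "prep_related": {
            k: acc(report.prep_related[k], truth_report.prep_related[k]) for k in LOADS
        },
    }
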