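"""Printed-table parsing and sub-network classification set algebra."""

import random

import pytest

import effconn as ec
from effconn.sem import Cell, EdgeTable
from effconn.subnetworks import load_printed_table

EMPTY_TABLES = {c: EdgeTable(c, {}) for c in ec.CONDITIONS}


@pytest.fixture(scope="module")
def increase_tables():
    return load_printed_table(ec.fixture_path("increase"))


@pytest.fixture(scope="module")
def decrease_tables():
    return load_printed_table(ec.fixture_path("decrease"))


class TestLoadPrintedTable:
    def test_rfp_rmfg_present_everywhere_with_reversals(self, increase_tables):
        pair = ("RFP", "RMFG")
        for cond in ec.CONDITIONS:
            assert pair in increase_tables[cond].entries
        for cond in ("prep2", "prep3", "rest"):
            assert increase_tables[cond].entries[pair].direction == ("RMFG", "RFP")
        for cond in ("prep1", "task1", "task2", "task3"):
            assert increase_tables[cond].entries[pair].direction == ("RFP", "RMFG")

    def test_rsfg_acc_present_only_at_rest(self, increase_tables):
        pair = ("ACC", "RSFG")
        assert pair in increase_tables["rest"].entries
        for cond in ec.CONDITIONS[:-1]:
            assert pair not in increase_tables[cond].entries

    def test_dash_row_has_unknown_direction(self, increase_tables):
        cell = increase_tables["rest"].entries[("LIPS", "LSFG")]
        assert cell.direction is None

    def test_bold_metadata_carried(self, increase_tables):
        assert increase_tables["prep1"].entries[("ACC", "RFP")].bold
        assert not increase_tables["prep1"].entries[("RFP", "RMFG")].bold

    def test_zero_mean_cell_counts_as_present(self, increase_tables):
        # the load-1 preparation cell of RFP-ACC prints a 0.00 coefficient
        cell = increase_tables["prep1"].entries[("ACC", "RFP")]
        assert cell.mean == 0.0 and cell.direction == ("ACC", "RFP")

    def test_malformed_row_reports_label(self, tmp_path):
        fix = tmp_path / "bad.tsv"
        header = "connection\tIntro1\t1-back\tIntro2\t2-back\tIntro3\t3-back\tRest"
        fix.write_text(header + "\nA->B\t0.5 (0.1)\n")
        with pytest.raises(ValueError, match="A->B"):
            load_printed_table(fix)


class TestClassifyPrintedTables:
    def test_increase_network_headline_counts(self, increase_tables):
        rep = ec.classify_connections(increase_tables)
        assert len(rep.default_edges) == 11
        assert {k: len(v) for k, v in rep.prep_related.items()} == {1: 1, 2: 2, 3: 5}
        assert all(not v for v in rep.prep_rest_only.values())

    def test_increase_prep_related_membership(self, increase_tables):
        rep = ec.classify_connections(increase_tables)
        assert rep.prep_related[1] == frozenset({("ACC", "RFP")})
        assert rep.prep_related[2] == frozenset({("RIPS", "RSFG"), ("ACC", "Lbas")})
        assert rep.prep_related[3] == frozenset(
            {("ACC", "RFP"), ("ACC", "Lbas"), ("ACC", "LSFG"),
             ("LIPS", "LLOCs"), ("RIPS", "Rprecun")}
        )

    def test_decrease_network_counts_and_prep_rest_only(self, decrease_tables):
        rep = ec.classify_connections(decrease_tables)
        assert len(rep.default_edges) == 10
        assert ("RPlanPol", "RTP") in rep.prep_rest_only[1]
        assert rep.prep_rest_only[3] == frozenset(
            {("RPlanPol", "RTP"), ("LPCCa", "RLOCi")}
        )

    def test_empty_tables_give_empty_report(self):
        rep = ec.classify_connections(EMPTY_TABLES)
        assert not rep.default_edges
        assert all(not v for v in rep.prep_related.values())

    def test_missing_condition_rejected(self, increase_tables):
        partial = {c: t for c, t in increase_tables.items() if c != "rest"}
        with pytest.raises(ValueError, match="rest"):
            ec.classify_connections(partial)


class TestSetAlgebraInvariants:
    def test_row_order_permutation_leaves_report_unchanged(self, tmp_path, increase_tables):
        lines = ec.fixture_path("increase").read_text().splitlines()
        rng = random.Random(0)
        body = lines[1:]
        rng.shuffle(body)
        shuffled = tmp_path / "shuffled.tsv"
        shuffled.write_text("\n".join([lines[0]] + body) + "\n")
        assert ec.classify_connections(load_printed_table(shuffled)) == ec.classify_connections(
            increase_tables
        )

    def test_presence_is_direction_blind(self, increase_tables):
        """Reversing every direction marker changes only direction_variable."""
        flipped = {
            cond: EdgeTable(
                cond,
                {
                    pair: Cell(
                        None if cell.direction is None else cell.direction[::-1],
                        cell.mean, cell.sd, cell.bold, cell.row,
                    )
                    for pair, cell in table.entries.items()
                },
            )
            for cond, table in increase_tables.items()
        }
        a = ec.classify_connections(increase_tables)
        b = ec.classify_connections(flipped)
        assert a.default_edges == b.default_edges
        assert a.prep_related == b.prep_related
        assert a.prep_rest_only == b.prep_rest_only

    def test_default_and_prep_related_are_mutually_exclusive(
        self, increase_tables, decrease_tables
    ):
        for tables in (increase_tables, decrease_tables):
            rep = ec.classify_connections(tables)
            for k in ec.LOADS:
                assert not rep.default_edges & rep.prep_related[k]
                assert not rep.prep_related[k] & rep.prep_rest_only[k]


class TestCompareToTruth:
    TRUTH = ec.sample_graph_set(
        tuple(f"R{i}" for i in range(10)), 5,
        {"prep1": 1, "task1": 1, "prep2": 1, "task2": 1, "prep3": 2, "task3": 2, "rest": 0},
        seed=0,
    )

    def test_self_consistency_gives_perfect_scores(self):
        rep = ec.classify_connections(ec.tables_from_graphs(self.TRUTH))
        acc = ec.compare_to_truth(rep, self.TRUTH)
        assert acc["default"].precision == 1.0 and acc["default"].recall == 1.0
        for k in ec.LOADS:
            assert acc["prep_related"][k].precision == 1.0
            assert acc["prep_related"][k].recall == 1.0

    def test_truth_without_extras_flags_recall_not_applicable(self):
        truth = ec.sample_graph_set(tuple("ABCDE"), 3, 0, seed=1)
        rep = ec.classify_connections(ec.tables_from_graphs(truth))
        acc = ec.compare_to_truth(rep, truth)
        for k in ec.LOADS:
            assert acc["prep_related"][k].recall is None

    def test_disjoint_report_scores_zero_precision(self):
        truth_rep = ec.classify_connections(ec.tables_from_graphs(self.TRUTH))
        used = set().union(truth_rep.default_edges, *truth_rep.prep_related.values())
        spare = [p for p in
                 (ec.undirected(f"R{i}", f"R{j}") for i in range(10) for j in range(i + 1, 10))
                 if p not in used]
        wrong = ec.SubNetworkReport(
            default_edges=frozenset(spare[:3]),
            prep_related={k: frozenset() for k in ec.LOADS},
            prep_rest_only={k: frozenset() for k in ec.LOADS},
            direction_variable=frozenset(),
        )
        acc = ec.compare_to_truth(wrong, self.TRUTH)
        assert acc["default"].precision == 0.0

    def test_labels_outside_truth_rejected(self):
        wrong = ec.SubNetworkReport(
            default_edges=frozenset({("X", "Y")}),
            prep_related={k: frozenset() for k in ec.LOADS},
            prep_rest_only={k: frozenset() for k in ec.LOADS},
            direction_variable=frozenset(),
        )
        with pytest.raises(ValueError, match="outside"):
            ec.compare_to_truth(wrong, self.TRUTH)
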