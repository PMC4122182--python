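"""Generator tests: schedules, graph sets, SEM moments, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import effconn as ec
from effconn.synthdata import sem_covariance


class TestSchedule:
    def test_default_design_has_ten_4tr_prep_segments_per_load(self):
        sch = ec.make_schedule(ec.ScheduleParams())
        for load in (1, 2, 3):
            preps = [s for s in sch.segments if s.condition == f"prep{load}"]
            assert len(preps) == 10
            assert all(s.n_trs == 4 for s in preps)

    def test_default_design_block_and_rest_lengths(self):
        sch = ec.make_schedule(ec.ScheduleParams())
        tasks = [s for s in sch.segments if s.condition.startswith("task")]
        rests = [s for s in sch.segments if s.condition == "rest"]
        assert len(tasks) == 30 and len(rests) == 30
        assert all(s.n_trs >= 21 for s in tasks)
        assert all(s.n_trs in (5, 6) for s in rests)

    def test_blocks_come_as_prep_task_rest_triples(self):
        sch = ec.make_schedule(ec.ScheduleParams(seed=3))
        segs = sch.segments
        for i in range(0, len(segs), 3):
            prep, task, rest = segs[i], segs[i + 1], segs[i + 2]
            assert prep.condition.startswith("prep")
            assert task.condition == prep.condition.replace("prep", "task")
            assert rest.condition == "rest"

    def test_same_seed_reproduces_schedule_exactly(self):
        a = ec.make_schedule(ec.ScheduleParams(seed=42))
        b = ec.make_schedule(ec.ScheduleParams(seed=42))
        assert a == b

    def test_zero_blocks_gives_empty_schedule(self):
        sch = ec.make_schedule(ec.ScheduleParams(n_blocks_per_condition=0))
        assert sch.segments == () and sch.total_trs == 0

    def test_non_integer_instruction_trs_rejected_with_parameter_name(self):
        with pytest.raises(ValueError, match="instruction_seconds"):
            ec.make_schedule(ec.ScheduleParams(instruction_seconds=7.0))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        n_blocks=st.integers(0, 6),
        block_min=st.integers(1, 25),
        seed=st.integers(0, 10_000),
    )
    def test_segment_lengths_sum_to_total_trs(self, n_blocks, block_min, seed):
        sch = ec.make_schedule(
            ec.ScheduleParams(n_blocks_per_condition=n_blocks, block_trs_min=block_min, seed=seed)
        )
        assert sum(s.n_trs for s in sch.segments) == sch.total_trs


class TestGraphSet:
    NODES = tuple(f"R{i:02d}" for i in range(18))
    EXTRAS = {"prep1": 1, "task1": 1, "prep2": 2, "task2": 2,
              "prep3": 5, "task3": 5, "rest": 0}

    def test_paired_scenario_set_algebra(self):
        g = ec.sample_graph_set(self.NODES, 11, self.EXTRAS, seed=0)
        shared = set.intersection(*(set(g.edges(c)) for c in ec.CONDITIONS))
        assert shared == set(g.default_edges)
        assert len(g.default_edges) == 11
        prep_task_not_rest = (g.edges("prep3") & g.edges("task3")) - g.edges("rest")
        assert len(prep_task_not_rest - g.default_edges) == 5

    def test_no_extras_means_identical_condition_graphs(self):
        g = ec.sample_graph_set(self.NODES, 8, 0, seed=1)
        assert all(g.edges(c) == g.default_edges for c in ec.CONDITIONS)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_every_condition_graph_is_acyclic_and_triangle_free(self, seed):
        g = ec.sample_graph_set(self.NODES, 11, self.EXTRAS, seed=seed)
        for cond in ec.CONDITIONS:
            dag = g.graph(cond)  # DAG construction enforces acyclicity
            assert not dag.skeleton().has_triangle()

    def test_infeasible_edge_count_reports_bound(self):
        with pytest.raises(ValueError, match="at most"):
            ec.sample_graph_set(("A", "B", "C"), 10)


class TestSimulation:
    def test_two_node_sem_reproduces_analytic_correlation(self):
        # A -> B with beta=0.8, Var(e_B)=0.36, Var(e_A)=1: corr(A, B) =
        # 0.8 / sqrt(0.64 + 0.36) = 0.8
        rng = np.random.default_rng(0)
        n = 10_000
        a = rng.uniform(-np.sqrt(3), np.sqrt(3), n)
        b = 0.8 * a + rng.uniform(-np.sqrt(3 * 0.36), np.sqrt(3 * 0.36), n)
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(0.8, abs=0.02)

    def test_zero_coefficients_leave_rois_uncorrelated(self):
        g = ec.ConditionGraphSet(("A", "B", "C"), frozenset(), {}, {})
        sch = ec.make_schedule(ec.ScheduleParams(n_blocks_per_condition=2, seed=1))
        ts = ec.simulate_subject(g, sch, seed=2)
        corr = np.corrcoef(ts.values.T)
        off = corr[~np.eye(3, dtype=bool)]
        assert np.max(np.abs(off)) < 0.15

    def test_empirical_covariance_matches_closed_form(self):
        """Long segment vs (I-B)^-T Sigma_e (I-B)^-1 within 3 SE."""
        g = ec.sample_graph_set(tuple("ABCDE"), 4, 0, seed=3)
        B = g.coefficient_matrix("rest")
        sigma = sem_covariance(B)
        sch = ec.BlockSchedule((ec.Segment("rest", 0, 20_000),))
        ts = ec.simulate_subject(g, sch, subject_jitter=0.0, seed=4)
        emp = np.cov(ts.values.T, ddof=1)
        n = ts.n_trs
        for i in range(5):
            for j in range(5):
                se = np.sqrt((sigma[i, i] * sigma[j, j] + sigma[i, j] ** 2) / n)
                assert abs(emp[i, j] - sigma[i, j]) < 3 * se, (i, j)

    def test_same_seed_reproduces_subject_exactly(self):
        g = ec.sample_graph_set(tuple("ABCD"), 3, 0, seed=0)
        sch = ec.make_schedule(ec.ScheduleParams(n_blocks_per_condition=1))
        x = ec.simulate_subject(g, sch, seed=9).values
        y = ec.simulate_subject(g, sch, seed=9).values
        np.testing.assert_array_equal(x, y)

    @pytest.mark.parametrize(
        "family,excess",
        [("uniform", -1.2), ("laplace", 3.0), ("gaussian", 0.0)],
    )
    def test_innovation_excess_kurtosis(self, family, excess):
        from scipy.stats import kurtosis

        rng = np.random.default_rng(5)
        x = ec.NoiseSpec(family, 2.0).sample(rng, 200_000)
        assert np.std(x) == pytest.approx(2.0, rel=0.02)
        assert kurtosis(x, fisher=True) == pytest.approx(excess, abs=0.1)

    def test_cyclic_graph_set_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            ec.ConditionGraphSet(
                ("A", "B"),
                frozenset({("A", "B"), ("B", "A")}),
                {},
                {(c, e): 0.5 for c in ec.CONDITIONS for e in [("A", "B"), ("B", "A")]},
            )


class TestBenchmark:
    def test_shapes_edge_count_and_determinism(self):
        data, truth = ec.simulate_benchmark(n_vars=20, n_subjects=4, n_timepoints=50,
                                            edge_density=0.1, seed=7)
        assert len(data) == 4
        assert all(d.values.shape == (50, 20) for d in data)
        assert len(truth.dag.edges) == round(0.1 * 20 * 19 / 2)
        assert not truth.dag.skeleton().has_triangle()
        data2, truth2 = ec.simulate_benchmark(n_vars=20, n_subjects=4, n_timepoints=50,
                                              edge_density=0.1, seed=7)
        assert truth2.dag == truth.dag
        np.testing.assert_array_equal(data[0].values, data2[0].values)

    def test_single_subject_benchmark(self):
        data, _ = ec.simulate_benchmark(n_vars=5, n_subjects=1, n_timepoints=30,
                                        edge_density=0.3, seed=0)
        assert len(data) == 1

    def test_too_sparse_density_rejected(self):
        with pytest.raises(ValueError, match="edge"):
            ec.simulate_benchmark(n_vars=5, edge_density=0.001)
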