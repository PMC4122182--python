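"""Shared fixtures: small SEM dataset builders and the benchmark runs
reused by the recovery tests."""

from __future__ import annotations

import numpy as np
import pytest

import effconn as ec


def make_dataset(matrix, labels, condition="task1", subject="s00", standardized=False):
    ds = ec.ConditionDataset(condition, subject, tuple(labels), np.asarray(matrix, float),
                             standardized=standardized)
    return ds


def standardized_dataset(matrix, labels, condition="task1", subject="s00"):
    return ec.standardize(make_dataset(matrix, labels, condition, subject))


def two_node_datasets(beta=0.8, n=500, n_subjects=10, seed=0, family="uniform"):
    """Subject datasets from the SEM A -> B with coefficient ``beta``."""
    rng = np.random.default_rng(seed)
    noise = ec.NoiseSpec(family, 1.0)
    out = []
    for s in range(n_subjects):
        a = noise.sample(rng, n)
        b = beta * a + noise.sample(rng, n)
        out.append(standardized_dataset(np.column_stack([a, b]), ("A", "B"), subject=f"s{s}"))
    return out


def chain_datasets(beta=0.9, n=500, n_subjects=10, seed=0):
    """Subject datasets from the chain A -> B -> C."""
    rng = np.random.default_rng(seed)
    noise = ec.NoiseSpec("uniform", 0.5)
    out = []
    for s in range(n_subjects):
        a = np.random.default_rng(rng.integers(2**31)).uniform(-1, 1, n)
        e_b = noise.sample(rng, n)
        e_c = noise.sample(rng, n)
        b = beta * a + e_b
        c = beta * b + e_c
        out.append(standardized_dataset(np.column_stack([a, b, c]), ("A", "B", "C"),
                                        subject=f"s{s}"))
    return out


def enumerate_dags(labels):
    """Every DAG over ``labels`` as a node -> parents mapping (brute force)."""
    import itertools

    import networkx as nx

    pairs = list(itertools.combinations(labels, 2))
    for states in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (u, v), s in zip(pairs, states):
            if s == 1:
                edges.append((u, v))
            elif s == 2:
                edges.append((v, u))
        g = nx.DiGraph()
        g.add_nodes_from(labels)
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield {node: tuple(sorted(g.predecessors(node))) for node in labels}


def oracle_total_score(datasets, parent_map, c):
    """From-scratch whole-graph averaged BIC: explicit per-node OLS via
    lstsq, independent of the package's covariance-based scorer."""
    total = 0.0
    for node, parents in parent_map.items():
        vals = []
        for ds in datasets:
            y = ds.column(node)
            n = ds.n
            if parents:
                X = np.column_stack([ds.column(p) for p in parents])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                resid = y - X @ beta
            else:
                resid = y
            s2 = float(resid @ resid) / n
            vals.append(-n * np.log(s2) - c * (len(parents) + 1) * np.log(n))
        total += float(np.mean(vals))
    return total


def skeleton_of_parent_map(parent_map):
    return frozenset(
        ec.undirected(p, node) for node, parents in parent_map.items() for p in parents
    )


@pytest.fixture(scope="session")
def benchmark_runs():
    """Five seeded benchmark searches (structure + orientation), shared by
    the adjacency-recall and orientation-accuracy tests."""
    runs = []
    for seed in range(1, 6):
        data, truth = ec.simulate_benchmark(seed=seed)
        conds = [
            ec.standardize(ec.ConditionDataset("task1", d.subject_id, d.roi_labels, d.values))
            for d in data
        ]
        result = ec.find_first_nontriangular(conds)
        true_pairs = truth.dag.skeleton().edges
        found = result.skeleton.edges
        correct = found & true_pairs
        oriented = ec.orient_edges(ec.Skeleton(result.skeleton.nodes, correct), conds)
        n_orient_ok = sum(1 for e in oriented.edges if e in truth.dag.edges)
        runs.append(
            {
                "recall": len(correct) / len(true_pairs),
                "orientation_accuracy": n_orient_ok / len(correct),
                "false_positives": len(found - true_pairs),
                "c_used": result.c_used,
            }
        )
    return runs
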