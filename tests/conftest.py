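import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ocnkit.io import ExpressionMatrix
from ocnkit.simulate import ScenarioParams, planted_scenario, toy_network


@pytest.fixture(scope="session")
def toy_net():
    return toy_network()


@pytest.fixture(scope="session")
def small_scenario():
    """A compact planted two-cascade scenario for fast stage tests."""
    params = ScenarioParams(
        n_genes=80, cascade_size=10, n_samples=30, inter_cascade_edges=10,
        background_to_cascade_edges=5, n_mutated=10, n_sl_pairs=12,
    )
    return planted_scenario(params, seed=7)


def random_digraph(rng, n_nodes, p_edge, allow_self_loops=True) -> nx.DiGraph:
    net = nx.DiGraph()
    nodes = [f"n{i}" for i in range(n_nodes)]
    net.add_nodes_from(nodes)
    for u in nodes:
        for v in nodes:
            if (u != v or allow_self_loops) and rng.random() < p_edge:
                net.add_edge(u, v)
    return net


def brute_force_matching_size(edges) -> int:
    """Maximum over all edge subsets with distinct sources and targets."""
    edges = list(edges)
    best = 0

    def rec(i, used_src, used_dst, size):
        nonlocal best
        if size + (len(edges) - i) <= best:
            return
        if i == len(edges):
            best = max(best, size)
            return
        u, v = edges[i]
        if u not in used_src and v not in used_dst:
            rec(i + 1, used_src | {u}, used_dst | {v}, size + 1)
        rec(i + 1, used_src, used_dst, size)

    rec(0, frozenset(), frozenset(), 0)
    return best


def expression_from_logs(log_values: np.ndarray, genes, n_case, n_control) -> ExpressionMatrix:
    samples = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_case)]
    condition = pd.Series(["control"] * n_control + ["case"] * n_case, index=samples)
    return ExpressionMatrix(
        values=pd.DataFrame(np.exp(log_values), index=list(genes), columns=samples),
        condition=condition,
    )


def expression_from_values(values: np.ndarray, genes, n_case, n_control) -> ExpressionMatrix:
    """Shift rows to be nonnegative; Pearson correlations are unchanged."""
    shifted = values - values.min(axis=1, keepdims=True) + 1.0
    samples = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_case)]
    condition = pd.Series(["control"] * n_control + ["case"] * n_case, index=samples)
    return ExpressionMatrix(
        values=pd.DataFrame(shifted, index=list(genes), columns=samples),
        condition=condition,
    )
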