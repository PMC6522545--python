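"""Deregulation scores, correlation-weighted influence, and control regions.

A gene's deregulation score (DScore) is ``-log10`` of its BH-adjusted
differential-expression p-value when that p-value passes the FDR cutoff,
and 0 otherwise.

Influence propagates through a correlation-weighted downstream subnetwork:
for a deregulated seed gene j, each edge <u, v> downstream of j carries the
weight

    w = max((|corr(x_j, x_u)| + |corr(x_j, x_v)|) / 2, eps)

with ``eps`` the critical Pearson correlation at p = 0.05 for the sample
size, so weights never vanish.  The indirect control value of gene k with
respect to j is the reciprocal of the total cost of the cheapest path
j -> k under the edge cost ``-log(w) + 1``; genes whose ICV reaches the
threshold ``lambda`` (together with the genes on their optimal paths) form
j's indirect control region.  The control region of gene i under one
structural control configuration is its direct region plus the indirect
regions of every deregulated gene it directly controls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from . import _engine
from .controllability import SCCDecomposition, direct_control_region
from .io import ExpressionMatrix, shuffle_node_labels

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA = 0.3
DEFAULT_FDR_CUTOFF = 0.05


def dscore(de_table: pd.DataFrame, fdr_cutoff: float = DEFAULT_FDR_CUTOFF) -> dict[str, float]:
    """Map each gene to -log10(p_adj) if significant, else 0.

    Genes missing from the table score 0 implicitly (the returned mapping
    only lists tabulated genes; consumers treat absence as 0).
    """
    if (de_table["p_adj"] <= 0).any():
        raise ValueError("adjusted p-values must be > 0")
    if (de_table["p_adj"] > 1).any():
        raise ValueError("adjusted p-values must be <= 1")
    out: dict[str, float] = {}
    for gene, p in zip(de_table["gene"], de_table["p_adj"]):
        out[str(gene)] = -math.log10(p) if p <= fdr_cutoff else 0.0
    return out


def critical_correlation(n_samples: int, alpha: float = 0.05) -> float:
    """Absolute Pearson correlation with two-sided p-value ``alpha``.

    Uses the exact t-transform of the null distribution of the sample
    correlation coefficient: t = r sqrt(n-2) / sqrt(1-r^2) with n-2
    degrees of freedom.
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    df = n_samples - 2
    t_crit = stats.t.ppf(1 - alpha / 2, df)
    return float(t_crit / math.sqrt(df + t_crit**2))


@dataclass
class WeightedSubnetwork:
    """Downstream subnetwork of a root gene with per-edge weights in [eps, 1]."""

    root: str
    graph: nx.DiGraph  # edges carry a 'weight' attribute


def _abs_corr_lookup(expr: ExpressionMatrix | None, condition: str = "case"):
    """Return a function gene-pair -> |Pearson corr| (0 for absent genes)."""
    if expr is None:
        return lambda a, b: 0.0
    samples = expr.samples_of(condition)
    values = expr.values[samples]
    sd = values.std(axis=1, ddof=0)

    def corr(a: str, b: str) -> float:
        if a not in values.index or b not in values.index:
            return 0.0
        if sd[a] == 0 or sd[b] == 0:
            logger.debug("zero-variance row for %s/%s; correlation 0", a, b)
            return 0.0
        return float(abs(np.corrcoef(values.loc[a], values.loc[b])[0, 1]))

    return corr


def edge_weight(
    j: str, u: str, v: str, expr: ExpressionMatrix | None, eps: float,
    condition: str = "case",
) -> float:
    """Weight of edge u->v in the downstream subnetwork of gene j."""
    corr = _abs_corr_lookup(expr, condition)
    return max((corr(j, u) + corr(j, v)) / 2.0, eps)


def weighted_subnetwork(
    j: str, net: nx.DiGraph, expr: ExpressionMatrix | None, eps: float,
    condition: str = "case",
) -> WeightedSubnetwork:
    """Correlation-weighted subgraph induced by the genes reachable from j."""
    downstream = {j} | nx.descendants(net, j)
    corr = _abs_corr_lookup(expr, condition)
    sub = nx.DiGraph()
    sub.add_nodes_from(downstream)
    for u, v in net.edges:
        if u in downstream and v in downstream:
            w = max((corr(j, u) + corr(j, v)) / 2.0, eps)
            sub.add_edge(u, v, weight=w)
    return WeightedSubnetwork(root=j, graph=sub)


def icv(j: str, k: str, weighted: WeightedSubnetwork) -> float:
    """Indirect control value of gene k with respect to seed gene j.

    The reciprocal of the minimum total path cost under the cost
    ``-log(w) + 1`` (natural log); lies in (0, 1].  Raises
    :class:`networkx.NetworkXNoPath` when k is unreachable (no-path is
    signalled, never scored as zero).
    """
    if k == j:
        raise ValueError("ICV is defined for k != j")
    cost = nx.shortest_path_length(
        weighted.graph, j, k,
        weight=lambda u, v, d: 1.0 - math.log(d["weight"]),
    )
    return 1.0 / cost


@dataclass
class ControlRegion:
    """Direct and indirect control regions of one gene under one SCC."""

    gene: str
    scc_id: int
    direct: set[str]
    indirect: set[str]

    @property
    def union(self) -> set[str]:
        return self.direct | self.indirect


def control_region(
    gene: str,
    scc: SCCDecomposition,
    net: nx.DiGraph,
    expr: ExpressionMatrix | None,
    dscores: dict[str, float],
    lam: float = DEFAULT_LAMBDA,
    eps: float = 0.2,
    scc_id: int = 0,
    condition: str = "case",
) -> ControlRegion:
    """Control region of ``gene``: direct plus indirect parts.

    Indirect regions are seeded only from deregulated genes in the direct
    region; each seed contributes every gene whose ICV reaches ``lam``
    along with the genes on the optimal paths (equivalently, the cost ball
    of radius 1/lam around the seed in its weighted downstream subnetwork).
    """
    direct = direct_control_region(gene, scc, net)
    arr = _engine.NetworkArrays.from_network(net)
    abs_corr = _engine.abs_corr_matrix(expr, arr.genes, condition=condition)
    seeds = np.array([arr.pos[g] for g in sorted(direct) if dscores.get(g, 0.0) > 0],
                     dtype=int)
    indirect: set[str] = set()
    if len(seeds):
        masks = _engine.indirect_masks(arr, abs_corr, seeds, eps, lam)
        combined = masks.any(axis=0)
        indirect = arr.genes_of(combined)
    return ControlRegion(gene=gene, scc_id=scc_id, direct=direct, indirect=indirect)


def lambda_threshold(
    net: nx.DiGraph,
    expr: ExpressionMatrix | None,
    dscores: dict[str, float],
    n_random: int = 100,
    p_cut: float = 0.01,
    seed: int | None = None,
    eps: float = 0.2,
    n_sources: int = 50,
    condition: str = "case",
) -> float:
    """Calibrate the ICV threshold from label-shuffled null networks.

    For each of ``n_random`` node-label-shuffled copies of the network,
    ICVs are collected from up to ``n_sources`` deregulated source genes
    (all sources if fewer); the threshold is the smallest ICV whose
    empirical upper-tail probability under the pooled null is below
    ``p_cut``.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    arr0 = _engine.NetworkArrays.from_network(net)
    abs_corr = _engine.abs_corr_matrix(expr, arr0.genes, condition=condition)
    dereg = [g for g in arr0.genes if dscores.get(g, 0.0) > 0]
    if not dereg:
        dereg = list(arr0.genes)
    null_icvs: list[np.ndarray] = []
    for _ in range(n_random):
        shuffled = shuffle_node_labels(net, seed=int(rng.integers(2**31)))
        arr = _engine.NetworkArrays.from_network(shuffled)
        sources = rng.choice(dereg, size=min(n_sources, len(dereg)), replace=False)
        for g in sources:
            j = arr.pos[g]
            costs = _engine.edge_costs(arr, abs_corr, j, eps)
            from scipy.sparse import csr_matrix
            from scipy.sparse.csgraph import dijkstra

            graph = csr_matrix((costs, (arr.src, arr.dst)), shape=(arr.n, arr.n))
            dist = dijkstra(graph, indices=j)
            dist[j] = np.inf
            reach = np.isfinite(dist)
            if reach.any():
                null_icvs.append(1.0 / dist[reach])
    if not null_icvs:
        logger.warning("no reachable pairs in null networks; lambda falls back to %s",
                       DEFAULT_LAMBDA)
        return DEFAULT_LAMBDA
    pooled = np.concatenate(null_icvs)
    return float(np.quantile(pooled, 1 - p_cut))
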