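"""Greedy combinatorial search for optimal control nodes (OCNs).

The objective is the optimal influence o = d - u of a set of control
nodes and their chosen control regions, where d is the fraction of total
deregulation (DScore mass) covered by the union of the regions and u is
the fraction of non-deregulated genes covered.  At each step the search
adds the (gene, region) pair with the largest marginal gain in o,
re-evaluated against the current union; a gene is accepted only if o
strictly improves, and the search stops when the relative growth of o
drops below the stop rate (5% by default) or no improving candidate
remains.

Multiple searches are started from the control nodes of the top-ranked
control regions (ranked by contained DScore).  OCN calls are made by an
empirical false discovery rate over occurrence frequencies: the same
multi-start search is repeated on label-shuffled null networks, and at
each frequency threshold the expected null count of genes at or above the
threshold is compared with the observed count.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._engine import RegionCatalog

logger = logging.getLogger(__name__)

DEFAULT_STOP_RATE = 0.05
DEFAULT_TOP_FRACTION = 0.0001


def influence(
    ocr_union: set[str],
    dscores: dict[str, float],
    net: nx.DiGraph,
) -> tuple[float, float, float]:
    """Desired, undesired and optimal influence (d, u, o) of a region union."""
    nodes = set(net.nodes)
    if not nodes:
        raise ValueError("network is empty")
    if not ocr_union <= nodes:
        raise ValueError("region union contains genes outside the network")
    total = sum(dscores.get(g, 0.0) for g in nodes)
    if total <= 0:
        raise ValueError("total DScore must be positive")
    n_quiet = sum(1 for g in nodes if dscores.get(g, 0.0) == 0)
    if n_quiet == 0:
        raise ValueError("need at least one non-deregulated gene")
    d = sum(dscores.get(g, 0.0) for g in ocr_union) / total
    u = sum(1 for g in ocr_union if dscores.get(g, 0.0) == 0) / n_quiet
    return d, u, d - u


@dataclass
class GreedyResult:
    """One greedy run: selected genes, their chosen regions, trajectory."""

    genes: list[str]
    regions: list[tuple[str, int, frozenset[str]]]  # (gene, scc_id, members)
    trajectory: list[tuple[float, float, float]]    # (o, d, u) after each step
    start: str | None = None

    @property
    def final_o(self) -> float:
        return self.trajectory[-1][0] if self.trajectory else 0.0

    def __iter__(self):
        return iter(self.genes)


def greedy_search(
    catalog: RegionCatalog,
    stop_rate: float = DEFAULT_STOP_RATE,
    start: str | None = None,
) -> GreedyResult:
    """Greedy maximization of o = d - u over the catalog's regions.

    When ``start`` is given, that gene (with its best-gain region) is
    forced as the first selection regardless of its gain.
    """
    if not 0 < stop_rate:
        raise ValueError("stop_rate must be positive")
    dvec = catalog.dscore_vec
    total = float(dvec.sum())
    if total <= 0:
        raise ValueError("total DScore must be positive")
    quiet = catalog.nondereg_mask
    n_quiet = int(quiet.sum())
    if n_quiet == 0:
        raise ValueError("need at least one non-deregulated gene")

    covered = np.zeros(catalog.arr.n, dtype=bool)
    selected_idx: set[int] = set()
    genes: list[str] = []
    regions: list[tuple[str, int, frozenset[str]]] = []
    traj: list[tuple[float, float, float]] = []
    o = 0.0
    forced = start is not None

    while True:
        w = np.where(covered, 0.0, dvec / total - quiet / n_quiet).astype(np.float32)
        gains = catalog.regions_f @ w
        blocked = np.isin(catalog.region_gene, list(selected_idx)) if selected_idx else None
        if blocked is not None:
            gains[blocked] = -np.inf
        if forced:
            if start not in catalog.arr.pos:
                raise KeyError(f"unknown start gene {start!r}")
            allowed = catalog.region_gene == catalog.arr.pos[start]
            if not allowed.any():
                raise KeyError(f"start gene {start!r} has no candidate region")
            gains[~allowed] = -np.inf
        best = int(np.argmax(gains))
        gain = float(gains[best])
        if not forced:
            if not math.isfinite(gain) or gain <= 0:
                break
            if o > 0 and gain / o < stop_rate:
                break
        covered |= catalog.regions[best]
        g_idx = int(catalog.region_gene[best])
        gene = catalog.arr.genes[g_idx]
        selected_idx.add(g_idx)
        genes.append(gene)
        regions.append((gene, int(catalog.region_scc[best]),
                        frozenset(catalog.region_genes(best))))
        d = float(dvec[covered].sum()) / total
        u = float((quiet & covered).sum()) / n_quiet
        o = d - u
        traj.append((o, d, u))
        forced = False
    return GreedyResult(genes=genes, regions=regions, trajectory=traj, start=start)


def multi_start(
    catalog: RegionCatalog,
    top_fraction: float = DEFAULT_TOP_FRACTION,
    stop_rate: float = DEFAULT_STOP_RATE,
) -> list[GreedyResult]:
    """One greedy run per control node of the top-ranked control regions.

    All (gene, configuration) regions are ranked by contained DScore;
    the control nodes of the top ``top_fraction`` of them (at least one)
    become start genes, each forced as the first selection of its run.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    n_candidates = catalog.arr.n * catalog.n_sccs
    k = max(1, math.ceil(top_fraction * n_candidates))
    order = np.argsort(-catalog.mass, kind="stable")
    starts: list[str] = []
    seen: set[str] = set()
    taken = 0
    for row in order:
        gene = catalog.arr.genes[int(catalog.region_gene[row])]
        if gene not in seen:
            seen.add(gene)
            starts.append(gene)
        taken += int(catalog.multiplicity[row])
        if taken >= k:
            break
    return [greedy_search(catalog, stop_rate=stop_rate, start=g) for g in starts]


def occurrence_frequencies(solutions: list) -> dict[str, float]:
    """Fraction of searches whose solution contains each gene."""
    if not solutions:
        return {}
    counts = Counter(g for sol in solutions for g in set(sol))
    return {g: c / len(solutions) for g, c in counts.items()}


@dataclass
class OcnResult:
    """Accepted OCNs with occurrence frequencies and empirical FDR."""

    frequencies: dict[str, float]
    fdr: dict[str, float]
    accepted: set[str]
    threshold_table: pd.DataFrame
    fdr_cutoff: float


def ocn_fdr(
    real_solutions: list,
    null_solutions_per_network: list[list],
    fdr_cutoff: float = 0.05,
    pool_null: bool = True,
) -> OcnResult:
    """Empirical FDR of OCN calls from occurrence frequencies.

    At each observed frequency threshold f, the expected false-positive
    count (genes at frequency >= f in the null searches) is divided by the
    observed count.  With ``pool_null=True`` (default) the null frequency
    of a gene is computed over all null searches pooled across networks;
    with ``pool_null=False`` each null network yields its own frequency
    vector and the null counts are averaged over networks.  A gene is an
    OCN iff the FDR at its own frequency is at or below ``fdr_cutoff``.
    """
    if not real_solutions:
        raise ValueError("need at least one real search")
    if not null_solutions_per_network:
        raise ValueError("need at least one null network")
    real_freq = occurrence_frequencies(real_solutions)
    if pool_null:
        pooled = [sol for network in null_solutions_per_network for sol in network]
        null_freqs = [occurrence_frequencies(pooled)]
    else:
        null_freqs = [occurrence_frequencies(net) for net in null_solutions_per_network]

    thresholds = sorted(set(real_freq.values()), reverse=True)
    rows = []
    fdr_at: dict[float, float] = {}
    for f in thresholds:
        n_obs = sum(1 for v in real_freq.values() if v >= f)
        null_counts = [sum(1 for v in nf.values() if v >= f) for nf in null_freqs]
        n_null = float(np.mean(null_counts))
        fdr = n_null / n_obs
        fdr_at[f] = fdr
        rows.append({"frequency": f, "n_observed": n_obs,
                     "n_null_mean": n_null, "fdr": fdr})
    table = pd.DataFrame(rows, columns=["frequency", "n_observed", "n_null_mean", "fdr"])
    gene_fdr = {g: fdr_at[f] for g, f in real_freq.items()}
    accepted = {g for g, v in gene_fdr.items() if v <= fdr_cutoff}
    return OcnResult(
        frequencies=real_freq, fdr=gene_fdr, accepted=accepted,
        threshold_table=table, fdr_cutoff=fdr_cutoff,
    )


def chosen_ocrs(result: OcnResult, solutions: list[GreedyResult]) -> dict[str, tuple[int, frozenset[str]]]:
    """The optimal control region recorded for each accepted OCN.

    For an accepted gene, the region chosen at its acceptance step in the
    highest-objective solution containing it.
    """
    out: dict[str, tuple[int, frozenset[str]]] = {}
    for sol in sorted(solutions, key=lambda s: -s.final_o):
        for gene, scc_id, members in sol.regions:
            if gene in result.accepted and gene not in out:
                out[gene] = (scc_id, members)
    return out
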