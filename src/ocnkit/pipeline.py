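"""One-command orchestration: SCC sampling -> control regions -> greedy
search -> occurrence-frequency FDR -> synergy -> evaluation.

All stochastic stages draw their streams from a single master seed via
``numpy.random.SeedSequence``, so a rerun with the same configuration and
seed reproduces identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from itertools import combinations
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as ocio
from ._engine import RegionCatalog, abs_corr_matrix, build_region_catalog
from .controllability import sample_sccs
from .evaluation import delta_d, sl_enrichment_table
from .io import ExpressionMatrix, shuffle_node_labels
from .regions import DEFAULT_LAMBDA, critical_correlation, dscore, lambda_threshold
from .search import (GreedyResult, OcnResult, chosen_ocrs, multi_start, ocn_fdr)
from .synergy import synergy_calls

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run.

    Defaults follow the published protocol: 1000 structural control
    configurations, lambda = 0.3, eps calibrated from the sample size,
    DScore FDR cutoff 0.05, 5% greedy stop rate, multi-start from the top
    0.01% of control regions, 10 null networks for the OCN FDR, and
    empirical synergy p-values below 0.05 after BH.
    """

    n_sccs: int = 1000
    lam: float | str = DEFAULT_LAMBDA   # or "calibrate"
    epsilon: float | str = "auto"       # or an explicit float
    fdr_cutoff: float = 0.05            # DScore significance cutoff
    stop_rate: float = 0.05
    top_fraction: float = 0.0001
    n_null_networks: int = 10
    ocn_fdr_cutoff: float = 0.05
    n_null_pairs: int = 100_000
    alpha: float = 0.05
    correlation_condition: str = "case"
    seed: int = 0

    def resolve_epsilon(self, expr: ExpressionMatrix | None) -> float:
        if self.epsilon == "auto":
            if expr is None:
                raise ValueError("epsilon='auto' needs an expression matrix")
            n = len(expr.samples_of(self.correlation_condition))
            return critical_correlation(n, alpha=0.05)
        return float(self.epsilon)


@dataclass
class PipelineResult:
    config: RunConfig
    dscores: dict[str, float]
    epsilon: float
    lam: float
    catalog: RegionCatalog
    real_solutions: list[GreedyResult]
    null_solutions: list[list[GreedyResult]]
    ocns: OcnResult
    ocrs: dict[str, tuple[int, frozenset[str]]]
    synergy: pd.DataFrame | None = None
    sl: pd.DataFrame | None = None
    delta_d: pd.DataFrame | None = None


def _solutions_for_network(
    net: nx.DiGraph,
    dscores: dict[str, float],
    abs_corr: np.ndarray,
    cfg: RunConfig,
    lam: float,
    eps: float,
    seed: int,
) -> tuple[RegionCatalog, list[GreedyResult]]:
    sccs = sample_sccs(net, n_sccs=cfg.n_sccs, seed=seed)
    catalog = build_region_catalog(net, sccs, dscores, lam=lam, eps=eps,
                                  abs_corr=abs_corr)
    solutions = multi_start(catalog, top_fraction=cfg.top_fraction,
                            stop_rate=cfg.stop_rate)
    return catalog, solutions


def find_ocns(
    net: nx.DiGraph,
    expr: ExpressionMatrix | None,
    de_table: pd.DataFrame,
    cfg: RunConfig,
) -> PipelineResult:
    """Run SCC sampling, regions, multi-start search and OCN FDR."""
    streams = np.random.SeedSequence(cfg.seed).spawn(2 + cfg.n_null_networks)
    scores = dscore(de_table, fdr_cutoff=cfg.fdr_cutoff)
    eps = cfg.resolve_epsilon(expr)
    genes = sorted(net.nodes)
    abs_corr = abs_corr_matrix(expr, genes, condition=cfg.correlation_condition)
    if cfg.lam == "calibrate":
        lam = lambda_threshold(net, expr, scores,
                               seed=int(streams[0].generate_state(1)[0] % 2**31),
                               eps=eps, condition=cfg.correlation_condition)
        logger.info("calibrated lambda = %.3f", lam)
    else:
        lam = float(cfg.lam)

    t0 = time.time()
    catalog, real_solutions = _solutions_for_network(
        net, scores, abs_corr, cfg, lam, eps,
        seed=int(streams[1].generate_state(1)[0] % 2**31))
    logger.info("real network: %d searches in %.1fs", len(real_solutions),
                time.time() - t0)

    null_solutions: list[list[GreedyResult]] = []
    for i in range(cfg.n_null_networks):
        s = int(streams[2 + i].generate_state(1)[0] % 2**31)
        null_net = shuffle_node_labels(net, seed=s)
        _, sols = _solutions_for_network(null_net, scores, abs_corr, cfg, lam,
                                         eps, seed=s)
        null_solutions.append(sols)

    ocns = ocn_fdr(real_solutions, null_solutions, fdr_cutoff=cfg.ocn_fdr_cutoff)
    ocrs = chosen_ocrs(ocns, real_solutions)
    return PipelineResult(
        config=cfg, dscores=scores, epsilon=eps, lam=lam, catalog=catalog,
        real_solutions=real_solutions, null_solutions=null_solutions,
        ocns=ocns, ocrs=ocrs,
    )


def run(
    net: nx.DiGraph,
    expr: ExpressionMatrix | None,
    de_table: pd.DataFrame,
    cfg: RunConfig | None = None,
    mutated: set[str] | None = None,
    sl_pairs: set[frozenset[str]] | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Execute all stages and optionally write the results bundle."""
    cfg = cfg or RunConfig()
    result = find_ocns(net, expr, de_table, cfg)

    pairs = sorted(combinations(sorted(result.ocns.accepted), 2))
    if pairs and mutated is not None:
        ocr_of = {g: set(m) for g, (_, m) in result.ocrs.items()}
        best = result.catalog.best_region_lookup()
        syn_seed = int(np.random.SeedSequence((cfg.seed, 1)).generate_state(1)[0] % 2**31)
        result.synergy = synergy_calls(
            pairs, ocr_of, mutated, net, null_ocr_of=best,
            n_null_pairs=cfg.n_null_pairs, alpha=cfg.alpha, seed=syn_seed)
        if sl_pairs is not None:
            result.sl = sl_enrichment_table(pairs, ocr_of, sl_pairs, net)
        if len(pairs) >= 1:
            p, q = pairs[0]
            dd_seed = int(np.random.SeedSequence((cfg.seed, 2)).generate_state(1)[0] % 2**31)
            result.delta_d = delta_d(
                ocr_of[p], ocr_of[q], net,
                n_null_pairs=min(cfg.n_null_pairs, 10_000),
                seed=dd_seed, region_of=best)

    if outdir is not None:
        write_results(result, outdir)
    return result


def write_results(result: PipelineResult, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    freq = result.ocns.frequencies
    ocn_df = pd.DataFrame({
        "gene": sorted(freq),
        "frequency": [freq[g] for g in sorted(freq)],
        "fdr": [result.ocns.fdr[g] for g in sorted(freq)],
        "accepted": [g in result.ocns.accepted for g in sorted(freq)],
    })
    ocn_df.to_csv(outdir / "ocns.tsv", sep="\t", index=False)
    with open(outdir / "ocrs.tsv", "w") as fh:
        fh.write("gene\tscc_id\tmember\n")
        for g in sorted(result.ocrs):
            scc_id, members = result.ocrs[g]
            for m in sorted(members):
                fh.write(f"{g}\t{scc_id}\t{m}\n")
    with open(outdir / "trajectory.tsv", "w") as fh:
        fh.write("search\tstep\to\td\tu\n")
        for i, sol in enumerate(result.real_solutions):
            for step, (o, d, u) in enumerate(sol.trajectory):
                fh.write(f"{i}\t{step}\t{o:.6f}\t{d:.6f}\t{u:.6f}\n")
    if result.synergy is not None:
        result.synergy.to_csv(outdir / "synergy.tsv", sep="\t", index=False)
    if result.sl is not None:
        result.sl.to_csv(outdir / "sl_enrichment.tsv", sep="\t", index=False)
    if result.delta_d is not None:
        result.delta_d.to_csv(outdir / "delta_d.tsv", sep="\t", index=False)
    cfg = asdict(result.config)
    ocio.write_manifest(
        outdir / "manifest.json",
        config=cfg,
        epsilon=result.epsilon,
        lam=result.lam,
        n_real_searches=len(result.real_solutions),
        n_null_networks=len(result.null_solutions),
        accepted_ocns=sorted(result.ocns.accepted),
    )
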