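"""Deterministic generators for test networks and planted scenarios.

``toy_network`` builds the 16-gene worked example used throughout the
documentation: eleven edges whose unique-size maximum matching has ten
links, leaving six driver nodes.

``planted_scenario`` embeds regulator-rooted deregulation cascades in a
random directed background.  Each cascade is a regulator with a fan-out of
direct targets; the targets of the two cascades are cross-linked so the
regulator pair has genuine inter-region crosstalk.  Case-condition
expression of cascade genes is driven by a shared latent factor with
loading sqrt(rho) plus unit Gaussian noise on the log scale (exponentiated
to keep FPKM-like values nonnegative); the differential-expression table
assigns planted genes adjusted p-values below the significance cutoff and
background genes values above it, so the planted cascades carry the entire
DScore mass.  Recurrently mutated genes are oversampled inside the
cascades and synthetic-lethal pairs between them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io as ocio
from .io import ExpressionMatrix

TOY_EDGES = [
    ("g1", "g4"), ("g4", "g9"), ("g9", "g12"),
    ("g10", "g13"),
    ("g2", "g7"), ("g7", "g11"), ("g11", "g15"),
    ("g5", "g16"),
    ("g3", "g6"), ("g6", "g3"),
    ("g1", "g3"),
]


def toy_network() -> nx.DiGraph:
    """The 16-gene, 11-edge worked-example network (g1..g16).

    Its maximum matching has 10 links; the decomposition has six
    elementary paths, one elementary cycle {g3, g6}, one additional link
    g1->g3, and driver nodes {g1, g2, g5, g8, g10, g14}.
    """
    net = nx.DiGraph()
    net.add_nodes_from(f"g{i}" for i in range(1, 17))
    net.add_edges_from(TOY_EDGES)
    return net


@dataclass
class ScenarioParams:
    """Generation parameters of a planted two-cascade scenario."""

    n_genes: int = 300
    n_cascades: int = 2
    cascade_size: int = 30          # direct targets per regulator
    n_samples: int = 50             # per condition
    rho: float = 0.6                # within-cascade latent-factor loading^2
    inter_cascade_edges: int = 30   # crosstalk links between cascade targets
    background_out_degree: float = 2.0
    background_to_cascade_edges: int = 20
    n_mutated: int = 20
    mutated_in_cascade_frac: float = 0.7
    n_sl_pairs: int = 40
    sl_between_frac: float = 0.75
    p_adj_planted: tuple[float, float] = (1e-6, 1e-3)   # log-uniform range
    p_adj_background: tuple[float, float] = (0.2, 1.0)  # uniform range

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError("rho must be in [0, 1)")
        if self.cascade_size < 1:
            raise ValueError("cascade_size must be >= 1")
        if self.n_samples < 4:
            raise ValueError("need at least 4 samples per condition")
        if self.n_genes < self.n_cascades * (self.cascade_size + 1) + 10:
            raise ValueError("n_genes too small for the requested cascades")


@dataclass
class PlantedScenario:
    """A generated network + expression + annotations with known truth."""

    network: nx.DiGraph
    expression: ExpressionMatrix
    de_table: pd.DataFrame
    regulators: list[str]
    cascades: list[list[str]]       # per regulator: its target genes
    deregulated: set[str]
    mutated: set[str]
    sl_pairs: set[frozenset[str]]
    params: ScenarioParams
    seed: int


def planted_scenario(params: ScenarioParams | None = None, seed: int = 0) -> PlantedScenario:
    """Generate a planted scenario; fully reproducible from ``seed``."""
    p = params or ScenarioParams()
    rng = np.random.default_rng(seed)

    genes = [f"G{i:04d}" for i in range(p.n_genes)]
    regulators = []
    cascades = []
    cursor = 0
    for c in range(p.n_cascades):
        regulators.append(genes[cursor])
        cascades.append(genes[cursor + 1: cursor + 1 + p.cascade_size])
        cursor += 1 + p.cascade_size
    background = genes[cursor:]
    planted = set(regulators) | {g for cas in cascades for g in cas}

    net = nx.DiGraph()
    net.add_nodes_from(genes)
    for reg, targets in zip(regulators, cascades):
        for t in targets:
            net.add_edge(reg, t)
    # crosstalk: links from the first cascade's targets into the second's
    # (and onward cyclically for >2 cascades)
    for c in range(p.n_cascades):
        src_pool = cascades[c]
        dst_pool = cascades[(c + 1) % p.n_cascades]
        n_links = p.inter_cascade_edges // p.n_cascades
        added = 0
        while added < n_links:
            u = src_pool[rng.integers(len(src_pool))]
            v = dst_pool[rng.integers(len(dst_pool))]
            if not net.has_edge(u, v):
                net.add_edge(u, v)
                added += 1
    # sparse random background
    n_bg_edges = int(round(p.background_out_degree * len(background)))
    added = 0
    while added < n_bg_edges:
        u = background[rng.integers(len(background))]
        v = background[rng.integers(len(background))]
        if u != v and not net.has_edge(u, v):
            net.add_edge(u, v)
            added += 1
    # a few background regulators feeding into cascade targets
    all_targets = [g for cas in cascades for g in cas]
    added = 0
    while added < p.background_to_cascade_edges:
        u = background[rng.integers(len(background))]
        v = all_targets[rng.integers(len(all_targets))]
        if not net.has_edge(u, v):
            net.add_edge(u, v)
            added += 1

    # expression: log-scale latent factor model per cascade in the case
    # condition, independent noise everywhere else; exponentiated
    n_s = p.n_samples
    samples = [f"ctrl{i}" for i in range(n_s)] + [f"case{i}" for i in range(n_s)]
    condition = pd.Series(["control"] * n_s + ["case"] * n_s, index=samples)
    log_expr = rng.standard_normal((p.n_genes, 2 * n_s))
    pos = {g: i for i, g in enumerate(genes)}
    sq_rho = np.sqrt(p.rho)
    sq_noise = np.sqrt(1 - p.rho)
    for reg, targets in zip(regulators, cascades):
        latent = rng.standard_normal(n_s)
        for g in [reg, *targets]:
            i = pos[g]
            log_expr[i, n_s:] = sq_rho * latent + sq_noise * rng.standard_normal(n_s)
    expression = ExpressionMatrix(
        values=pd.DataFrame(np.exp(log_expr), index=genes, columns=samples),
        condition=condition,
    )

    lo, hi = np.log10(p.p_adj_planted[0]), np.log10(p.p_adj_planted[1])
    p_adj = np.empty(p.n_genes)
    for g in genes:
        i = pos[g]
        if g in planted:
            p_adj[i] = 10 ** rng.uniform(lo, hi)
        else:
            p_adj[i] = rng.uniform(*p.p_adj_background)
    de_table = pd.DataFrame({"gene": genes, "p_adj": p_adj})

    n_mut_in = int(round(p.n_mutated * p.mutated_in_cascade_frac))
    cascade_pool = sorted(planted)
    mutated = set(rng.choice(cascade_pool, size=min(n_mut_in, len(cascade_pool)),
                             replace=False))
    mutated |= set(rng.choice(background, size=p.n_mutated - len(mutated),
                              replace=False))

    sl_pairs: set[frozenset[str]] = set()
    n_between = int(round(p.n_sl_pairs * p.sl_between_frac))
    while len(sl_pairs) < n_between:
        u = cascades[0][rng.integers(len(cascades[0]))]
        v = cascades[-1][rng.integers(len(cascades[-1]))]
        if u != v:
            sl_pairs.add(frozenset((u, v)))
    while len(sl_pairs) < p.n_sl_pairs:
        u, v = rng.choice(genes, size=2, replace=False)
        sl_pairs.add(frozenset((u, v)))

    return PlantedScenario(
        network=net, expression=expression, de_table=de_table,
        regulators=regulators, cascades=cascades, deregulated=planted,
        mutated=mutated, sl_pairs=sl_pairs, params=p, seed=seed,
    )


def write_scenario(scn: PlantedScenario, outdir: str | Path) -> None:
    """Write a scenario to disk in the formats the pipeline reads."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ocio.write_network(scn.network, outdir / "network.tsv")
    ocio.write_expression(scn.expression, outdir / "expression.tsv")
    ocio.write_de_table(scn.de_table, outdir / "de_table.tsv")
    ocio.write_gene_set(scn.mutated, outdir / "mutated.txt")
    ocio.write_gene_pairs(scn.sl_pairs, outdir / "sl_pairs.tsv")
    scn.expression.condition.rename("condition").to_csv(
        outdir / "conditions.tsv", sep="\t", index_label="sample")
    truth = {
        "regulators": scn.regulators,
        "cascades": scn.cascades,
        "deregulated": sorted(scn.deregulated),
        "seed": scn.seed,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(scn.params).items()},
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
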