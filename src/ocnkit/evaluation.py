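"""Downstream characterization of OCN results.

Four independent evaluations:

* enrichment of synthetic-lethal (SL) gene pairs between the two optimal
  control regions of an OCN pair (hypergeometric upper tail over unordered
  gene pairs);
* ranking of crosstalk genes by the drop in inter-region interaction
  density when the gene is removed (Delta-D), with an empirical p-value
  from the crosstalk genes of randomly drawn gene pairs;
* a purely degree-based baseline for control-node identification, where a
  node's regulatory value is its out-degree minus in-degree and control
  nodes are those whose removal increases the number of significantly
  regulatory nodes;
* a genetic-interaction (GI) score calculator for CRISPR double-knockout
  growth assays, comparing the observed double-knockout growth phenotype
  with the sum of the single-knockout phenotypes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._engine import NetworkArrays

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# synthetic-lethal enrichment

def sl_enrichment(
    ocr_p: set[str],
    ocr_q: set[str],
    sl_pairs: set[frozenset[str]],
    net: nx.DiGraph,
) -> float:
    """Upper-tail hypergeometric p for SL pairs between two regions.

    Draws: the unordered cross pairs between the pair-exclusive region
    sets (|A|*|B| of them); successes in the population: all SL pairs
    among network genes; population: all C(N, 2) unordered gene pairs.
    """
    nodes = set(net.nodes)
    sl_net = {p for p in sl_pairs if p <= nodes}
    N = len(nodes)
    total_pairs = N * (N - 1) // 2
    if not sl_net:
        logger.warning("no synthetic-lethal pairs among network genes; p = 1")
        return 1.0
    a = (ocr_p - ocr_q) & nodes
    b = (ocr_q - ocr_p) & nodes
    cross = len(a) * len(b)
    k = sum(1 for pair in sl_net
            if any(x in a for x in pair) and any(x in b for x in pair))
    return float(stats.hypergeom.sf(k - 1, total_pairs, len(sl_net), cross))


def sl_enrichment_table(
    pairs: list[tuple[str, str]],
    ocr_of: dict[str, set[str]],
    sl_pairs: set[frozenset[str]],
    net: nx.DiGraph,
) -> pd.DataFrame:
    """SL enrichment across OCN pairs with BH adjustment."""
    from statsmodels.stats.multitest import multipletests

    pvals = [sl_enrichment(ocr_of[p], ocr_of[q], sl_pairs, net) for p, q in pairs]
    p_adj = multipletests(pvals, method="fdr_bh")[1] if pvals else np.array([])
    return pd.DataFrame({
        "gene_a": [p for p, _ in pairs],
        "gene_b": [q for _, q in pairs],
        "p": pvals,
        "p_adj": p_adj,
    })


# ---------------------------------------------------------------------------
# crosstalk genes and Delta-D

def _density(a: set[str], b: set[str], net: nx.DiGraph) -> float:
    if not a or not b:
        return 0.0
    n_links = sum(1 for u, v in net.edges if (u in a and v in b) or (u in b and v in a))
    return n_links / (2 * len(a) * len(b))


def _delta_d_masks(arr: NetworkArrays, mask_p: np.ndarray, mask_q: np.ndarray) -> dict[int, float]:
    """Delta-D of every crosstalk gene of one region pair (incremental).

    Removing gene g drops the inter-region edges incident to g from the
    numerator and shrinks g's side of the denominator by one; both changes
    are applied.
    """
    a = mask_p & ~mask_q
    b = mask_q & ~mask_p
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 or nb == 0:
        return {}
    inter = (a[arr.src] & b[arr.dst]) | (b[arr.src] & a[arr.dst])
    n_links = int(inter.sum())
    d0 = n_links / (2 * na * nb)
    incident = (np.bincount(arr.src[inter], minlength=arr.n)
                + np.bincount(arr.dst[inter], minlength=arr.n))
    out: dict[int, float] = {}
    for g in np.flatnonzero(incident > 0):
        g = int(g)
        na2 = na - 1 if a[g] else na
        nb2 = nb - 1 if b[g] else nb
        n2 = n_links - int(incident[g])
        d_after = n2 / (2 * na2 * nb2) if na2 > 0 and nb2 > 0 else 0.0
        out[g] = d0 - d_after
    return out


def delta_d(
    ocr_p: set[str],
    ocr_q: set[str],
    net: nx.DiGraph,
    n_null_pairs: int = 100_000,
    seed: int | None = None,
    region_of: dict[str, set[str]] | None = None,
    p_significant: float = 0.1,
) -> pd.DataFrame:
    """Delta-D of each crosstalk gene with an empirical p-value.

    The null pools the Delta-D values of the crosstalk genes of
    ``n_null_pairs`` randomly drawn gene pairs (each null gene carries its
    best control region from ``region_of``; singleton regions if absent).
    Delta-D may be negative when removing a gene raises the density; it is
    recorded as computed.
    """
    rng = np.random.default_rng(seed)
    arr = NetworkArrays.from_network(net)
    observed = _delta_d_masks(arr, arr.mask(ocr_p & set(arr.genes)),
                              arr.mask(ocr_q & set(arr.genes)))
    if region_of is None:
        region_of = {g: {g} for g in arr.genes}
    region_masks = np.zeros((arr.n, arr.n), dtype=bool)
    for g in arr.genes:
        region_masks[arr.pos[g]] = arr.mask(set(region_of.get(g, {g})) & set(arr.genes))
    pi = rng.integers(0, arr.n, size=n_null_pairs)
    qi = rng.integers(0, arr.n - 1, size=n_null_pairs)
    qi[qi >= pi] += 1
    null_vals: list[float] = []
    for i, j in zip(pi, qi):
        vals = _delta_d_masks(arr, region_masks[i], region_masks[j])
        null_vals.extend(vals.values())
    null_arr = np.sort(np.asarray(null_vals)) if null_vals else np.array([0.0])
    rows = []
    for g_idx, dd in sorted(observed.items()):
        n_ge = len(null_arr) - np.searchsorted(null_arr, dd, side="left")
        p = (1 + n_ge) / (1 + len(null_arr))
        rows.append({"gene": arr.genes[g_idx], "delta_d": dd, "p": p,
                     "significant": p < p_significant})
    return pd.DataFrame(rows, columns=["gene", "delta_d", "p", "significant"])


# ---------------------------------------------------------------------------
# degree-based baseline

def regulatory_values(net: nx.DiGraph) -> dict[str, int]:
    """Out-degree minus in-degree for every node."""
    return {v: net.out_degree(v) - net.in_degree(v) for v in net.nodes}


def degree_control_nodes(
    net: nx.DiGraph,
    n_random: int = 100,
    seed: int | None = None,
    alpha: float = 0.05,
) -> set[str]:
    """Degree-based control nodes.

    Null regulatory values come from ``n_random`` networks in which every
    edge keeps its source but is assigned a uniformly random target
    (out-degrees preserved; in-degrees become multinomial), so the
    per-node out/in coupling is broken and the null has genuine spread
    even on regular graphs.  A node is significantly regulatory when its
    value's empirical upper-tail p under the pooled null is below
    ``alpha``; control nodes are those whose single-node removal increases
    the count of significant nodes.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    rng = np.random.default_rng(seed)
    arr = NetworkArrays.from_network(net)
    n = arr.n
    out_deg = np.bincount(arr.src, minlength=n)
    in_deg = np.bincount(arr.dst, minlength=n)
    r = out_deg - in_deg

    null_vals = []
    for _ in range(n_random):
        random_dst = rng.integers(0, n, size=len(arr.dst))
        null_in = np.bincount(random_dst, minlength=n)
        null_vals.append(out_deg - null_in)
    null = np.sort(np.concatenate(null_vals))

    def n_significant(values: np.ndarray, exclude: int | None = None) -> int:
        n_ge = len(null) - np.searchsorted(null, values, side="left")
        p = (1 + n_ge) / (1 + len(null))
        sig = p < alpha
        if exclude is not None:
            sig[exclude] = False
        return int(sig.sum())

    base = n_significant(r)
    controls = set()
    adj = arr.adj
    for v in range(n):
        r_removed = r - adj[:, v].astype(int) + adj[v, :].astype(int)
        if n_significant(r_removed, exclude=v) > base:
            controls.add(arr.genes[v])
    return controls


# ---------------------------------------------------------------------------
# CRISPR growth assay GI score

@dataclass
class GrowthAssay:
    """Fractions of knockout and wild-type cells at assay start and end.

    ``duration`` is the assay length T in hours and ``doubling_time_wt``
    the wild-type doubling time in hours.
    """

    f_wt_begin: float
    f_ko_begin: float
    f_wt_end: float
    f_ko_end: float
    duration: float
    doubling_time_wt: float

    def __post_init__(self) -> None:
        for name in ("f_wt_begin", "f_ko_begin", "f_wt_end", "f_ko_end"):
            val = getattr(self, name)
            if not 0 < val < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.f_wt_begin + self.f_ko_begin > 1 or self.f_wt_end + self.f_ko_end > 1:
            raise ValueError("fractions at one timepoint must sum to <= 1")
        if self.duration <= 0 or self.doubling_time_wt <= 0:
            raise ValueError("duration and doubling time must be positive")


def growth_phenotype(assay: GrowthAssay, doublings: float | None = None) -> float:
    """Per-doubling log2 depletion of knockout relative to wild-type cells.

    The number of doublings of the knockout population is T / d_ko, where
    the knockout doubling time d_ko = d_wt / (1 - (x/T) d_wt) and
    x = log2(f_ko_b f_wt_e / (f_wt_b f_ko_e)) is the normalizing factor.
    ``doublings`` overrides the computed value (used to compare assays at
    matched doublings).
    """
    x = math.log2(assay.f_ko_begin * assay.f_wt_end
                  / (assay.f_wt_begin * assay.f_ko_end))
    if doublings is None:
        denom = 1 - (x / assay.duration) * assay.doubling_time_wt
        if denom <= 0:
            raise ValueError("nonphysical knockout doubling time (denominator <= 0)")
        d_ko = assay.doubling_time_wt / denom
        doublings = assay.duration / d_ko
    ratio = (assay.f_ko_end / assay.f_wt_end) / (assay.f_ko_begin / assay.f_wt_begin)
    return math.log2(ratio) / doublings


def gi_score(
    assay_double: GrowthAssay,
    assay_single_a: GrowthAssay,
    assay_single_b: GrowthAssay,
) -> tuple[dict[str, float], float]:
    """Genetic-interaction score of a double knockout.

    Observed double-knockout growth phenotype minus the expected phenotype
    (the sum of the two single-knockout phenotypes).  Negative GI means
    the double knockout is depleted faster than expected — synergy.
    """
    phenotypes = {
        "double": growth_phenotype(assay_double),
        "single_a": growth_phenotype(assay_single_a),
        "single_b": growth_phenotype(assay_single_b),
    }
    gi = phenotypes["double"] - (phenotypes["single_a"] + phenotypes["single_b"])
    return phenotypes, gi
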