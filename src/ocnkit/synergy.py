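"""Synergy scoring of OCN pairs and the random-pair empirical null.

The synergy score of a pair of control nodes is the product of the
min-max-normalized mutation score and crosstalk score:

* mutation score: geometric mean of the -log upper-tail hypergeometric
  enrichment p-values of recurrently mutated genes in each node's optimal
  control region (universe = the network's node set);
* crosstalk score: interaction density between the two regions — observed
  links (either direction) between the pair-exclusive region sets divided
  by all possible directed links between them.

Significance is assessed against an empirical null of randomly drawn gene
pairs from the network, each null gene carrying its best (highest-DScore)
control region; p-values use the add-one correction and are BH-adjusted
across candidate pairs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._engine import NetworkArrays

logger = logging.getLogger(__name__)


def _hypergeom_logp(k: int, N: int, K: int, n: int) -> float:
    """-log of the upper-tail hypergeometric p-value P(X >= k)."""
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return -math.log(p)


def mutation_score(
    ocr_p: set[str], ocr_q: set[str], mutated: set[str], net: nx.DiGraph
) -> float:
    """Geometric mean of the two regions' -log mutation enrichment p-values."""
    if not ocr_p or not ocr_q:
        raise ValueError("optimal control regions must be nonempty")
    nodes = set(net.nodes)
    N = len(nodes)
    K = len(mutated & nodes)
    logps = []
    for ocr in (ocr_p, ocr_q):
        region = ocr & nodes
        k = len(region & mutated)
        logps.append(_hypergeom_logp(k, N, K, len(region)))
    return math.sqrt(logps[0] * logps[1])


def crosstalk_score(ocr_p: set[str], ocr_q: set[str], net: nx.DiGraph) -> float:
    """Interaction density between pair-exclusive region sets.

    Observed links with one endpoint in each exclusive set, either
    direction, divided by 2*|A|*|B| possible directed links.  Empty
    exclusive sets yield density 0 with a warning.
    """
    a = ocr_p - ocr_q
    b = ocr_q - ocr_p
    if not a or not b:
        logger.warning("pair-exclusive region set empty; crosstalk density 0")
        return 0.0
    n_links = sum(1 for u, v in net.edges if (u in a and v in b) or (u in b and v in a))
    return n_links / (2 * len(a) * len(b))


@dataclass
class _PairArrays:
    """Mask-based precomputation shared by candidate and null pairs."""

    arr: NetworkArrays
    adj_f: np.ndarray  # float32 adjacency

    @classmethod
    def from_network(cls, net: nx.DiGraph) -> "_PairArrays":
        arr = NetworkArrays.from_network(net)
        return cls(arr=arr, adj_f=arr.adj.astype(np.float32))

    def crosstalk(self, mask_p: np.ndarray, mask_q: np.ndarray) -> float:
        a = mask_p & ~mask_q
        b = mask_q & ~mask_p
        na, nb = int(a.sum()), int(b.sum())
        if na == 0 or nb == 0:
            return 0.0
        af = a.astype(np.float32)
        bf = b.astype(np.float32)
        n_links = float(af @ (self.adj_f @ bf) + bf @ (self.adj_f @ af))
        return n_links / (2 * na * nb)


def _minmax(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    if hi <= lo:
        logger.warning("degenerate min-max normalization; all values set to 0")
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def synergy_calls(
    pairs: list[tuple[str, str]],
    ocr_of: dict[str, set[str]],
    mutated: set[str],
    net: nx.DiGraph,
    null_ocr_of: dict[str, set[str]] | None = None,
    n_null_pairs: int = 100_000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Score candidate OCN pairs and call significance against a null.

    ``ocr_of`` maps each candidate gene to its optimal control region;
    ``null_ocr_of`` maps every network gene to its best control region
    (defaults to ``ocr_of`` entries where available, singleton regions
    otherwise — supply the precomputed lookup for real use).  Raw mutation
    and crosstalk scores are min-max normalized over the pooled candidate
    and null pairs before being multiplied into the synergy score.
    """
    if n_null_pairs < 100:
        raise ValueError("n_null_pairs must be >= 100")
    rng = np.random.default_rng(seed)
    pa = _PairArrays.from_network(net)
    nodes = pa.arr.genes
    N = len(nodes)
    K = len(mutated & set(nodes))
    mutated_vec = pa.arr.mask(mutated & set(nodes))

    if null_ocr_of is None:
        null_ocr_of = {g: ocr_of.get(g, {g}) for g in nodes}

    # region masks and per-gene -log enrichment p for every gene involved
    null_masks = np.zeros((N, N), dtype=bool)
    for g, region in null_ocr_of.items():
        null_masks[pa.arr.pos[g]] = pa.arr.mask(set(region) & set(nodes))
    sizes = null_masks.sum(axis=1)
    hits = null_masks.astype(np.int64) @ mutated_vec.astype(np.int64)
    with np.errstate(divide="ignore"):
        pvals = stats.hypergeom.sf(hits - 1, N, K, sizes)
    gene_logp = -np.log(np.clip(pvals, np.finfo(float).tiny, 1.0))

    def pair_scores(mask_p, mask_q):
        kp = int(np.count_nonzero(mask_p & mutated_vec))
        kq = int(np.count_nonzero(mask_q & mutated_vec))
        lp = _hypergeom_logp(kp, N, K, int(mask_p.sum()))
        lq = _hypergeom_logp(kq, N, K, int(mask_q.sum()))
        return math.sqrt(lp * lq), pa.crosstalk(mask_p, mask_q)

    cand_mut, cand_ct = [], []
    for p, q in pairs:
        mp = pa.arr.mask(set(ocr_of[p]) & set(nodes))
        mq = pa.arr.mask(set(ocr_of[q]) & set(nodes))
        if not mp.any() or not mq.any():
            raise ValueError(f"empty control region for pair ({p}, {q})")
        m, c = pair_scores(mp, mq)
        cand_mut.append(m)
        cand_ct.append(c)
    cand_mut = np.array(cand_mut)
    cand_ct = np.array(cand_ct)

    # null pairs: two distinct genes uniformly from the network
    pi = rng.integers(0, N, size=n_null_pairs)
    qi = rng.integers(0, N - 1, size=n_null_pairs)
    qi[qi >= pi] += 1
    null_mut = np.sqrt(gene_logp[pi] * gene_logp[qi])
    null_ct = np.empty(n_null_pairs)
    for i in range(n_null_pairs):
        null_ct[i] = pa.crosstalk(null_masks[pi[i]], null_masks[qi[i]])

    mut_pool = np.concatenate([cand_mut, null_mut])
    ct_pool = np.concatenate([cand_ct, null_ct])
    mut_lo, mut_hi = float(mut_pool.min()), float(mut_pool.max())
    ct_lo, ct_hi = float(ct_pool.min()), float(ct_pool.max())
    cand_syn = _minmax(cand_mut, mut_lo, mut_hi) * _minmax(cand_ct, ct_lo, ct_hi)
    null_syn = _minmax(null_mut, mut_lo, mut_hi) * _minmax(null_ct, ct_lo, ct_hi)

    null_sorted = np.sort(null_syn)
    n_ge = len(null_sorted) - np.searchsorted(null_sorted, cand_syn, side="left")
    p_emp = (1 + n_ge) / (1 + n_null_pairs)
    if len(p_emp):
        p_adj = multipletests(p_emp, method="fdr_bh")[1]
    else:
        p_adj = np.array([])
    return pd.DataFrame({
        "gene_a": [p for p, _ in pairs],
        "gene_b": [q for _, q in pairs],
        "mutation_score": cand_mut,
        "crosstalk_score": cand_ct,
        "synergy_score": cand_syn,
        "p": p_emp,
        "p_adj": p_adj,
        "significant": p_adj < alpha,
    })
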