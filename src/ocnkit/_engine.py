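"""Array-backed machinery for control regions and the greedy search.

Control-region computation over many structural control configurations is
the hot loop of the pipeline, so genes are mapped to integer indices and
regions are held as boolean masks:

* direct regions come in closed form from the path/cycle structure of a
  decomposition (the skeleton has at most one matched out-edge per node,
  additional links all terminate in cycles, and cycles have no skeleton
  out-edges besides their own, so reachability is a path suffix plus the
  cycles linked from its non-terminal nodes);
* indirect regions are per-seed-gene Dijkstra balls of cost radius
  ``1/lambda`` under the edge cost ``1 - log(w)``, which is equivalent to
  collecting every gene whose indirect control value reaches the threshold
  together with all genes on its optimal path (any prefix of an optimal
  path costs less than the whole path, so the ball already contains the
  path genes).

Identical (gene, region) rows across configurations are collapsed, with
multiplicities retained for ranking "all control regions".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .controllability import SCCDecomposition

logger = logging.getLogger(__name__)


@dataclass
class NetworkArrays:
    """Integer-indexed view of a directed network."""

    genes: list[str]
    pos: dict[str, int]
    src: np.ndarray
    dst: np.ndarray
    adj: np.ndarray  # dense boolean adjacency, adj[u, v] = edge u->v

    @classmethod
    def from_network(cls, net: nx.DiGraph) -> "NetworkArrays":
        genes = sorted(net.nodes)
        pos = {g: i for i, g in enumerate(genes)}
        src = np.fromiter((pos[u] for u, v in net.edges), dtype=np.int32,
                          count=net.number_of_edges())
        dst = np.fromiter((pos[v] for u, v in net.edges), dtype=np.int32,
                          count=net.number_of_edges())
        adj = np.zeros((len(genes), len(genes)), dtype=bool)
        adj[src, dst] = True
        return cls(genes=genes, pos=pos, src=src, dst=dst, adj=adj)

    @property
    def n(self) -> int:
        return len(self.genes)

    def mask(self, geneset) -> np.ndarray:
        m = np.zeros(self.n, dtype=bool)
        for g in geneset:
            m[self.pos[g]] = True
        return m

    def genes_of(self, mask: np.ndarray) -> set[str]:
        return {self.genes[i] for i in np.flatnonzero(mask)}


def abs_corr_matrix(expr, genes: list[str], condition: str = "case") -> np.ndarray:
    """Absolute Pearson correlations between genes, over one condition.

    Genes without expression rows, and zero-variance rows, get correlation
    0 everywhere (their incident edge weights fall to the floor).
    """
    n = len(genes)
    if expr is None:
        return np.zeros((n, n))
    samples = expr.samples_of(condition)
    present = [g for g in genes if g in expr.values.index]
    vals = expr.values.loc[present, samples].to_numpy(dtype=float)
    sd = vals.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.info("%d zero-variance expression rows; correlations set to 0",
                    int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(vals)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    out = np.zeros((n, n))
    idx = np.array([genes.index(g) for g in present]) if present else np.array([], int)
    if len(idx):
        out[np.ix_(idx, idx)] = np.abs(corr)
    return out


def edge_costs(arr: NetworkArrays, abs_corr: np.ndarray, j: int, eps: float) -> np.ndarray:
    """Cost ``1 - log(w)`` of every edge in the downstream weighting of gene j."""
    w = np.maximum((abs_corr[j, arr.src] + abs_corr[j, arr.dst]) / 2.0, eps)
    return 1.0 - np.log(w)


def indirect_masks(
    arr: NetworkArrays,
    abs_corr: np.ndarray,
    seed_idx: np.ndarray,
    eps: float,
    lam: float,
) -> np.ndarray:
    """Indirect control region of each seed gene as a boolean mask.

    A gene k belongs to the indirect region of seed j when the minimum
    total cost of a path j->k is at most ``1/lam`` (i.e. its ICV reaches
    the threshold); the seed itself is excluded.
    """
    cutoff = 1.0 / lam
    masks = np.zeros((len(seed_idx), arr.n), dtype=bool)
    for row, j in enumerate(seed_idx):
        costs = edge_costs(arr, abs_corr, int(j), eps)
        graph = csr_matrix((costs, (arr.src, arr.dst)), shape=(arr.n, arr.n))
        dist = dijkstra(graph, indices=int(j), limit=cutoff)
        m = dist <= cutoff
        m[int(j)] = False
        masks[row] = m
    return masks


def direct_mask_matrix(scc: SCCDecomposition, arr: NetworkArrays) -> np.ndarray:
    """Direct control region of every gene under one configuration.

    Row i is the mask of genes reachable from gene i along skeleton edges
    (gene i included).
    """
    n = arr.n
    masks = np.zeros((n, n), dtype=bool)

    cycle_mask_of: dict[str, np.ndarray] = {}
    for cyc in scc.cycles:
        m = arr.mask(cyc)
        for node in cyc:
            cycle_mask_of[node] = m
    for node, m in cycle_mask_of.items():
        masks[arr.pos[node]] = m

    # additional links grouped by tail node
    links_from: dict[str, list[str]] = {}
    for u, v in scc.additional_links:
        links_from.setdefault(u, []).append(v)

    for path in scc.paths:
        acc = np.zeros(n, dtype=bool)
        for depth, node in enumerate(reversed(path)):
            i = arr.pos[node]
            acc = acc.copy()
            acc[i] = True
            # non-terminal nodes (depth > 0 counted from the path end) may
            # carry additional links into cycles
            if depth > 0 and node in links_from:
                for head in links_from[node]:
                    acc |= cycle_mask_of[head]
            masks[i] = acc
    return masks


@dataclass
class RegionCatalog:
    """All candidate (gene, configuration) control regions of one network.

    ``regions`` is a deduplicated boolean matrix (one row per distinct
    (gene, region) pair); ``multiplicity`` counts how many of the
    ``n_genes * n_sccs`` underlying candidates each row represents.
    """

    arr: NetworkArrays
    dscore_vec: np.ndarray
    regions: np.ndarray          # bool, shape (m, n)
    regions_f: np.ndarray        # float32 copy for mat-vec products
    region_gene: np.ndarray      # int, control node of each region
    region_scc: np.ndarray       # int, a representative configuration id
    multiplicity: np.ndarray     # int
    n_sccs: int

    @property
    def mass(self) -> np.ndarray:
        """Total DScore contained in each region."""
        return self.regions_f @ self.dscore_vec.astype(np.float32)

    @property
    def total_dscore(self) -> float:
        return float(self.dscore_vec.sum())

    @property
    def nondereg_mask(self) -> np.ndarray:
        return self.dscore_vec == 0

    def region_genes(self, row: int) -> set[str]:
        return self.arr.genes_of(self.regions[row])

    def best_region_rows(self) -> dict[str, int]:
        """For each gene, the row of its highest-DScore region."""
        mass = self.mass
        best: dict[str, int] = {}
        score: dict[str, float] = {}
        for row, g_idx in enumerate(self.region_gene):
            g = self.arr.genes[int(g_idx)]
            if g not in best or mass[row] > score[g]:
                best[g], score[g] = row, float(mass[row])
        return best

    def best_region_lookup(self) -> dict[str, set[str]]:
        return {g: self.region_genes(row) for g, row in self.best_region_rows().items()}

    @classmethod
    def from_masks(cls, arr, dscore_vec, direct_rows, gene_ids, scc_ids, mults,
                   ind_masks, dereg_idx, n_sccs) -> "RegionCatalog":
        direct = np.asarray(direct_rows, dtype=bool)
        if len(dereg_idx):
            hits = direct[:, dereg_idx].astype(np.float32) @ ind_masks.astype(np.float32)
            regions = direct | (hits > 0)
        else:
            regions = direct
        # regions with identical content for the same gene may have arisen
        # from distinct direct rows; collapse again
        packed = np.packbits(regions, axis=1)
        uniq: dict[tuple[int, bytes], int] = {}
        keep, gene_out, scc_out, mult_out = [], [], [], []
        for row in range(regions.shape[0]):
            key = (int(gene_ids[row]), packed[row].tobytes())
            if key in uniq:
                mult_out[uniq[key]] += int(mults[row])
            else:
                uniq[key] = len(keep)
                keep.append(row)
                gene_out.append(int(gene_ids[row]))
                scc_out.append(int(scc_ids[row]))
                mult_out.append(int(mults[row]))
        regions = regions[keep]
        return cls(
            arr=arr,
            dscore_vec=np.asarray(dscore_vec, dtype=float),
            regions=regions,
            regions_f=regions.astype(np.float32),
            region_gene=np.asarray(gene_out, dtype=np.int64),
            region_scc=np.asarray(scc_out, dtype=np.int64),
            multiplicity=np.asarray(mult_out, dtype=np.int64),
            n_sccs=n_sccs,
        )

    @classmethod
    def from_region_dict(
        cls,
        regions: dict[tuple[str, int], set[str]],
        dscores: dict[str, float],
        genes: list[str] | None = None,
    ) -> "RegionCatalog":
        """Build a catalog from explicit (gene, scc_id) -> gene-set regions."""
        if genes is None:
            universe = set(dscores)
            for members in regions.values():
                universe |= set(members)
            genes = sorted(universe)
        arr = NetworkArrays(
            genes=genes, pos={g: i for i, g in enumerate(genes)},
            src=np.array([], np.int32), dst=np.array([], np.int32),
            adj=np.zeros((len(genes), len(genes)), bool),
        )
        dvec = np.array([float(dscores.get(g, 0.0)) for g in genes])
        rows, gids, sids = [], [], []
        for (gene, scc_id), members in sorted(regions.items()):
            rows.append(arr.mask(members))
            gids.append(arr.pos[gene])
            sids.append(scc_id)
        n_sccs = len({s for _, s in regions}) or 1
        mat = np.asarray(rows, bool)
        return cls(
            arr=arr, dscore_vec=dvec, regions=mat,
            regions_f=mat.astype(np.float32),
            region_gene=np.asarray(gids, np.int64),
            region_scc=np.asarray(sids, np.int64),
            multiplicity=np.ones(len(rows), np.int64),
            n_sccs=n_sccs,
        )


def build_region_catalog(
    net: nx.DiGraph,
    sccs: list[SCCDecomposition],
    dscores: dict[str, float],
    expr=None,
    lam: float = 0.3,
    eps: float = 0.2,
    condition: str = "case",
    abs_corr: np.ndarray | None = None,
) -> RegionCatalog:
    """Assemble every (gene, configuration) control region of a network."""
    arr = NetworkArrays.from_network(net)
    dvec = np.array([float(dscores.get(g, 0.0)) for g in arr.genes])
    dereg_idx = np.flatnonzero(dvec > 0)
    if abs_corr is None:
        abs_corr = abs_corr_matrix(expr, arr.genes, condition=condition)
    ind = indirect_masks(arr, abs_corr, dereg_idx, eps, lam)

    uniq: dict[tuple[int, bytes], int] = {}
    direct_rows, gene_ids, scc_ids, mults = [], [], [], []
    for scc_id, scc in enumerate(sccs):
        dmat = direct_mask_matrix(scc, arr)
        packed = np.packbits(dmat, axis=1)
        for g_idx in range(arr.n):
            key = (g_idx, packed[g_idx].tobytes())
            if key in uniq:
                mults[uniq[key]] += 1
            else:
                uniq[key] = len(direct_rows)
                direct_rows.append(dmat[g_idx])
                gene_ids.append(g_idx)
                scc_ids.append(scc_id)
                mults.append(1)
    return RegionCatalog.from_masks(
        arr, dvec, direct_rows, gene_ids, scc_ids, mults, ind, dereg_idx,
        n_sccs=len(sccs),
    )
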