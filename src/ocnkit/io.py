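"""Readers and writers for the files the pipeline touches.

A regulatory network is held as a :class:`networkx.DiGraph` whose nodes are
gene identifiers (case-sensitive opaque strings).  Edge lists are 2-column
TSV (``source<TAB>target``); the 3-column SIF dialect
(``source<TAB>relation<TAB>target``) is also accepted, with the relation
column ignored.  Duplicate edges are collapsed silently with a logged count.

Expression matrices are genes x samples TSV with FPKM-like nonnegative
values; differential-expression tables carry one BH-adjusted p-value per
gene.  Gene sets are one identifier per line and gene-pair sets are
2-column TSV with unordered pairs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_HEADER_TOKENS = {"source", "target", "from", "to", "gene_a", "gene_b", "regulator"}


class ParseError(ValueError):
    """Raised when an input file does not follow its declared dialect."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a two-condition annotation.

    ``values`` is a DataFrame indexed by gene with one column per sample;
    ``condition`` maps every sample to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    condition: pd.Series

    def __post_init__(self) -> None:
        if self.values.shape[1] < 3:
            raise ValueError("expression matrix needs at least 3 samples")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = set(self.values.columns) - set(self.condition.index)
        if missing:
            raise ValueError(f"samples without condition label: {sorted(missing)}")
        labels = set(self.condition.loc[list(self.values.columns)])
        if not labels <= {"case", "control"}:
            raise ValueError(f"condition labels must be case/control, got {labels}")
        if labels != {"case", "control"}:
            raise ValueError("both conditions must be present")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.condition[s] == condition]


def read_network(path: str | Path) -> nx.DiGraph:
    """Read a directed edge list (2-column TSV or 3-column SIF).

    Returns a DiGraph with duplicate ordered edges collapsed.  Self-loops
    and cycles are permitted.  Raises :class:`ParseError` on malformed or
    empty input, naming the offending line.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) == 2:
                src, dst = fields
            elif len(fields) == 3:
                src, _, dst = fields
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 or 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            src, dst = src.strip(), dst.strip()
            if not src or not dst:
                raise ParseError(f"{path}:{lineno}: empty gene identifier")
            if lineno == 1 and (src.lower() in _HEADER_TOKENS or dst.lower() in _HEADER_TOKENS):
                continue  # optional header row
            edges.append((src, dst))
            n_lines += 1
    if not edges:
        raise ParseError(f"{path}: no edges found")
    net = nx.DiGraph()
    net.add_edges_from(edges)
    n_dup = n_lines - net.number_of_edges()
    if n_dup:
        logger.info("collapsed %d duplicate edges", n_dup)
    logger.info(
        "read network %s: %d nodes, %d edges",
        path.name, net.number_of_nodes(), net.number_of_edges(),
    )
    return net


def write_network(net: nx.DiGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(net.edges()):
            fh.write(f"{u}\t{v}\n")


def read_expression(
    path: str | Path,
    condition_map: dict[str, str] | pd.Series,
    network: nx.DiGraph | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV (header row = sample names).

    ``condition_map`` must assign ``case``/``control`` to every sample.  If a
    network is given, the size of the gene overlap is logged and genes absent
    from the network are retained.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    if df.isna().any().any():
        raise ParseError(f"{path}: missing expression values")
    cond = pd.Series(dict(condition_map)) if not isinstance(condition_map, pd.Series) else condition_map
    expr = ExpressionMatrix(values=df, condition=cond)
    if network is not None:
        overlap = expression_network_overlap(expr, network)
        logger.info("expression/network gene overlap: %d", overlap)
    return expr


def expression_network_overlap(expr: ExpressionMatrix, net: nx.DiGraph) -> int:
    """Number of expression genes that are nodes of the network."""
    return len(set(expr.genes) & set(net.nodes))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a differential-expression table with columns ``gene``, ``p_adj``.

    Extra columns are ignored; one record per gene is enforced and
    ``p_adj`` must lie in (0, 1].
    """
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "p_adj" not in df.columns:
        raise ParseError(f"{path}: need columns 'gene' and 'p_adj'")
    df = df[["gene", "p_adj"]].copy()
    df["gene"] = df["gene"].astype(str)
    if df["gene"].duplicated().any():
        raise ParseError(f"{path}: duplicated gene records")
    if (df["p_adj"] <= 0).any() or (df["p_adj"] > 1).any():
        raise ParseError(f"{path}: adjusted p-values must be in (0, 1]")
    return df


def write_de_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_set(path: str | Path) -> set[str]:
    """One gene identifier per line; duplicates collapsed."""
    with open(path) as fh:
        genes = {line.strip() for line in fh if line.strip()}
    return genes


def write_gene_set(genes: set[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes):
            fh.write(g + "\n")


def read_gene_pairs(path: str | Path) -> set[frozenset[str]]:
    """2-column TSV of unordered gene pairs; self-pairs rejected."""
    pairs: set[frozenset[str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields")
            a, b = fields[0].strip(), fields[1].strip()
            if lineno == 1 and a.lower() in _HEADER_TOKENS:
                continue
            if a == b:
                raise ParseError(f"{path}:{lineno}: pair members must be distinct")
            pairs.add(frozenset((a, b)))
    return pairs


def write_gene_pairs(pairs: set[frozenset[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pair in sorted(tuple(sorted(p)) for p in pairs):
            fh.write("\t".join(pair) + "\n")


def shuffle_node_labels(net: nx.DiGraph, seed: int) -> nx.DiGraph:
    """Return a copy of the network with node labels randomly permuted.

    The result is isomorphic to the input (identical topology and degree
    sequence); only the assignment of gene labels to topological positions
    changes.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes)
    permuted = [nodes[i] for i in rng.permutation(len(nodes))]
    mapping = dict(zip(nodes, permuted))
    return nx.relabel_nodes(net, mapping, copy=True)


def write_manifest(path: str | Path, **entries) -> None:
    """Write a JSON run manifest (resolved parameters, seeds, versions)."""
    import ocnkit

    manifest = {"ocnkit_version": ocnkit.__version__}
    manifest.update(entries)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
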