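"""Tripartite circRNA-miRNA-mRNA network assembly and topology.

An axis (circ, miR, gene) is emitted when the circRNA-mRNA pair passed the
co-expression screen, both members are predicted to bind the same miRNA
(circ-miR by seed site, miR-gene by target table), and that miRNA is
expressed in the samples. The network derived from the axis set is strictly
tripartite: its only edge types are circ-miR "sponges" edges and miR-mRNA
"targets" edges, so it is triangle-free and the Maximal Clique Centrality
(MCC) of any node collapses to its degree - a property used as a built-in
cross-check between the two hub-ranking methods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import networkx as nx
import pandas as pd

from .coexpression import CoexprPair
from .target_prediction import InteractionSet

SPONGES = "sponges"
TARGETS = "targets"
_PREFIX = {"circ": "circ:", "mirna": "miR:", "gene": "gene:"}


@dataclass(frozen=True, order=True)
class CeRNAAxis:
    circ_id: str
    mirna_id: str
    gene_id: str


class NetworkStats(NamedTuple):
    n_axes: int
    n_nodes: int
    n_circ_mir_edges: int
    n_mir_mrna_edges: int


@dataclass(frozen=True)
class CeRNANetwork:
    """A set of ceRNA axes and the tripartite graph they induce."""

    axes: frozenset[CeRNAAxis]

    def __post_init__(self) -> None:
        circ = {a.circ_id for a in self.axes}
        mir = {a.mirna_id for a in self.axes}
        gene = {a.gene_id for a in self.axes}
        overlap = (circ & mir) | (circ & gene) | (mir & gene)
        if overlap:
            raise ValueError(
                f"node IDs appear in more than one partition: {sorted(overlap)[:5]}"
            )

    @property
    def circ_nodes(self) -> set[str]:
        return {a.circ_id for a in self.axes}

    @property
    def mirna_nodes(self) -> set[str]:
        return {a.mirna_id for a in self.axes}

    @property
    def gene_nodes(self) -> set[str]:
        return {a.gene_id for a in self.axes}

    @property
    def sponge_edges(self) -> set[tuple[str, str]]:
        return {(a.circ_id, a.mirna_id) for a in self.axes}

    @property
    def target_edges(self) -> set[tuple[str, str]]:
        return {(a.mirna_id, a.gene_id) for a in self.axes}


@dataclass(frozen=True)
class HubRanking:
    method: str
    scores: dict[str, float] = field(hash=False)
    ranked_nodes: tuple[str, ...] = ()
    k: int = 0


def build_axes(
    pairs: Iterable[CoexprPair] | Iterable[tuple[str, str]],
    inter: InteractionSet,
    expressed: Iterable[str],
) -> CeRNANetwork:
    """Assemble all axes whose co-expressed pair shares an expressed miRNA.

    ``pairs`` may be :class:`CoexprPair` records or raw (circ, gene) tuples.
    """
    pair_set = {
        (p.circ_id, p.gene_id) if isinstance(p, CoexprPair) else tuple(p)
        for p in pairs
    }
    expressed = set(expressed)
    mirs_by_circ: dict[str, set[str]] = {}
    for c, mi in inter.circ_mir:
        if mi in expressed:
            mirs_by_circ.setdefault(c, set()).add(mi)
    mirs_by_gene: dict[str, set[str]] = {}
    for mi, g in inter.mir_mrna:
        if mi in expressed:
            mirs_by_gene.setdefault(g, set()).add(mi)

    axes = set()
    for c, g in pair_set:
        shared = mirs_by_circ.get(c, set()) & mirs_by_gene.get(g, set())
        for mi in shared:
            axes.add(CeRNAAxis(c, mi, g))
    return CeRNANetwork(frozenset(axes))


def network_stats(net: CeRNANetwork) -> NetworkStats:
    nodes = net.circ_nodes | net.mirna_nodes | net.gene_nodes
    return NetworkStats(
        n_axes=len(net.axes),
        n_nodes=len(nodes),
        n_circ_mir_edges=len(net.sponge_edges),
        n_mir_mrna_edges=len(net.target_edges),
    )


def to_networkx(net: CeRNANetwork, node_attrs: Mapping[str, Mapping] | None = None) -> nx.Graph:
    """The induced graph with partition-prefixed node names and typed edges."""
    g = nx.Graph()
    for a in net.axes:
        c = _PREFIX["circ"] + a.circ_id
        mi = _PREFIX["mirna"] + a.mirna_id
        m = _PREFIX["gene"] + a.gene_id
        g.add_node(c, partition="circ", label=a.circ_id)
        g.add_node(mi, partition="mirna", label=a.mirna_id)
        g.add_node(m, partition="gene", label=a.gene_id)
        g.add_edge(c, mi, interaction=SPONGES)
        g.add_edge(mi, m, interaction=TARGETS)
    if node_attrs:
        for name, attrs in node_attrs.items():
            for pref in _PREFIX.values():
                if g.has_node(pref + name):
                    g.nodes[pref + name].update(attrs)
    return g


def rank_hubs(net: CeRNANetwork, method: str = "degree", k: int = 10) -> HubRanking:
    """Rank circRNA nodes by a topological score and return the top ``k``.

    ``degree`` counts distinct incident edges; ``mcc`` is Maximal Clique
    Centrality, the sum over maximal cliques containing the node of
    (|clique| - 1)!. On the triangle-free networks this pipeline builds,
    every maximal clique is an edge, so the two scores coincide. Ties break
    lexicographically by node ID for reproducibility.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if method not in {"degree", "mcc"}:
        raise ValueError(f"unknown hub-ranking method {method!r}")
    g = to_networkx(net)
    circ_nodes = sorted(net.circ_nodes)
    if method == "degree":
        scores = {c: float(g.degree(_PREFIX["circ"] + c)) for c in circ_nodes}
    else:
        import math

        scores = {c: 0.0 for c in circ_nodes}
        for clique in nx.find_cliques(g):
            if len(clique) < 2:
                continue  # isolated nodes score 0
            w = float(math.factorial(len(clique) - 1))
            for node in clique:
                if node.startswith(_PREFIX["circ"]):
                    scores[node[len(_PREFIX["circ"]):]] += w
    if k > len(circ_nodes):
        warnings.warn(
            f"k={k} exceeds the {len(circ_nodes)} circRNA nodes; returning all"
        )
        k = len(circ_nodes)
    ranked = sorted(circ_nodes, key=lambda c: (-scores[c], c))[:k]
    return HubRanking(method=method, scores=scores, ranked_nodes=tuple(ranked), k=k)


def extract_subnetwork(net: CeRNANetwork, hubs: Iterable[str]) -> CeRNANetwork:
    """All axes whose circRNA belongs to ``hubs`` (must be circRNA nodes)."""
    hubs = set(hubs)
    unknown = hubs - net.circ_nodes
    if unknown:
        raise KeyError(f"unknown hub circRNA IDs: {sorted(unknown)[:5]}")
    return CeRNANetwork(frozenset(a for a in net.axes if a.circ_id in hubs))


def export_network(
    net: CeRNANetwork,
    fmt: str,
    path: str | Path,
    node_attrs: Mapping[str, Mapping] | None = None,
) -> Path:
    """Write the network as ``sif``, ``graphml``, or ``edge_tsv``.

    SIF lines are ``source<TAB>interaction<TAB>target`` with interaction in
    {sponges, targets}; GraphML carries the node partition and any supplied
    per-node attributes (e.g. expression fold changes). Node names are
    partition-prefixed ("circ:", "miR:", "gene:") in every format so that a
    circRNA and gene sharing a symbol stay distinct.
    """
    path = Path(path)
    if fmt == "sif":
        lines = []
        for c, mi in sorted(net.sponge_edges):
            lines.append(f"{_PREFIX['circ']}{c}\t{SPONGES}\t{_PREFIX['mirna']}{mi}")
        for mi, m in sorted(net.target_edges):
            lines.append(f"{_PREFIX['mirna']}{mi}\t{TARGETS}\t{_PREFIX['gene']}{m}")
        path.write_text("".join(f"{ln}\n" for ln in lines))
    elif fmt == "graphml":
        nx.write_graphml(to_networkx(net, node_attrs), str(path))
    elif fmt == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("source\tinteraction\ttarget\n")
            for c, mi in sorted(net.sponge_edges):
                fh.write(f"{_PREFIX['circ']}{c}\t{SPONGES}\t{_PREFIX['mirna']}{mi}\n")
            for mi, m in sorted(net.target_edges):
                fh.write(f"{_PREFIX['mirna']}{mi}\t{TARGETS}\t{_PREFIX['gene']}{m}\n")
    else:
        raise ValueError(f"unknown export format {fmt!r}")
    return path


def read_edge_tsv(path: str | Path) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Round-trip reader for ``edge_tsv`` exports -> (sponge, target) edge sets."""
    sponge, target = set(), set()
    for ln, line in enumerate(Path(path).read_text().splitlines()):
        if ln == 0 and line.startswith("source\t"):
            continue
        src, kind, dst = line.split("\t")
        src = src.split(":", 1)[1]
        dst = dst.split(":", 1)[1]
        if kind == SPONGES:
            sponge.add((src, dst))
        elif kind == TARGETS:
            target.add((src, dst))
        else:
            raise ValueError(f"{path}:{ln + 1}: unknown interaction {kind!r}")
    return sponge, target


def axes_table(net: CeRNANetwork) -> pd.DataFrame:
    return pd.DataFrame(
        sorted((a.circ_id, a.mirna_id, a.gene_id) for a in net.axes),
        columns=["circ_id", "mirna_id", "gene_id"],
    )


def write_axes(net: CeRNANetwork, path: str | Path) -> Path:
    axes_table(net).to_csv(path, sep="\t", index=False)
    return Path(path)
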