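"""Coordination networks over gene sets and their remodeling across conditions.

A coordination network has one node per gene-set member present in the
data and one edge per pair whose correlation class is synergistic,
antagonistic or independent; not-significant pairs leave a blank.
Remodeling between two conditions is quantified by per-class edge counts
and the full class-transition table over all C(n, 2) pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .expression import DegenerateInputError, DesignError
from .fabric import ANTAGONISTIC, INDEPENDENT, NOT_SIGNIFICANT, SYNERGISTIC, CorPair

__all__ = [
    "build_network",
    "partner_counts",
    "remodeling_report",
    "network_edge_table",
    "RemodelingReport",
]

EDGE_CLASSES = (SYNERGISTIC, ANTAGONISTIC, INDEPENDENT)
ALL_CLASSES = (*EDGE_CLASSES, NOT_SIGNIFICANT)


def build_network(
    gene_set_name: str, condition: str, nodes: list[str], pairs: list[CorPair]
) -> nx.Graph:
    """Graph of classified pairs; not-significant pairs carry no edge."""
    if len(nodes) < 2:
        raise DegenerateInputError(
            f"gene set {gene_set_name!r}: fewer than 2 members present"
        )
    g = nx.Graph(name=gene_set_name, condition=condition)
    g.add_nodes_from(nodes)
    node_set = set(nodes)
    for p in pairs:
        if p.gene_a in node_set and p.gene_b in node_set and p.klass in EDGE_CLASSES:
            g.add_edge(p.gene_a, p.gene_b, cor=p.cor, klass=p.klass)
    return g


def partner_counts(network: nx.Graph, gene: str) -> dict:
    """Per-class partner counts for one gene; percents of (n_nodes - 1)."""
    if gene not in network:
        raise KeyError(f"gene {gene!r} is not a network node")
    possible = network.number_of_nodes() - 1
    counts = {k: 0 for k in EDGE_CLASSES}
    for _, _, data in network.edges(gene, data=True):
        counts[data["klass"]] += 1
    out = {"gene": gene, "possible": possible}
    for k in EDGE_CLASSES:
        out[k] = counts[k]
        out[f"{k}_pct"] = 100.0 * counts[k] / possible if possible else 0.0
    return out


@dataclass(frozen=True)
class RemodelingReport:
    reference: str
    case: str
    n_nodes: int
    n_pairs: int
    counts_ref: dict
    counts_case: dict
    transitions: pd.DataFrame  # rows = class in reference, cols = class in case

    def pct_ref(self, klass: str) -> float:
        return 100.0 * self.counts_ref[klass] / self.n_pairs

    def pct_case(self, klass: str) -> float:
        return 100.0 * self.counts_case[klass] / self.n_pairs


def _pair_class(network: nx.Graph, a: str, b: str) -> str:
    if network.has_edge(a, b):
        return network.edges[a, b]["klass"]
    return NOT_SIGNIFICANT


def remodeling_report(network_ref: nx.Graph, network_case: nx.Graph) -> RemodelingReport:
    """Class counts per condition plus the 4x4 class-transition table."""
    if set(network_ref.nodes) != set(network_case.nodes):
        raise DesignError("networks must share the same node set")
    nodes = sorted(network_ref.nodes)
    trans = pd.DataFrame(0, index=list(ALL_CLASSES), columns=list(ALL_CLASSES))
    counts_ref = {k: 0 for k in ALL_CLASSES}
    counts_case = {k: 0 for k in ALL_CLASSES}
    n_pairs = 0
    for a, b in itertools.combinations(nodes, 2):
        ka = _pair_class(network_ref, a, b)
        kb = _pair_class(network_case, a, b)
        trans.loc[ka, kb] += 1
        counts_ref[ka] += 1
        counts_case[kb] += 1
        n_pairs += 1
    return RemodelingReport(
        reference=network_ref.graph.get("condition", "ref"),
        case=network_case.graph.get("condition", "case"),
        n_nodes=len(nodes),
        n_pairs=n_pairs,
        counts_ref=counts_ref,
        counts_case=counts_case,
        transitions=trans,
    )


def network_edge_table(network: nx.Graph) -> pd.DataFrame:
    """Edge list as a DataFrame (gene_a, gene_b, condition, cor, class)."""
    rows = [
        {
            "gene_a": a,
            "gene_b": b,
            "condition": network.graph.get("condition", ""),
            "cor": data.get("cor"),
            "class": data["klass"],
        }
        for a, b, data in network.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "condition", "cor", "class"])


def adjacency_table(network: nx.Graph) -> pd.DataFrame:
    """Square class matrix mirroring a colored-square pair plot."""
    nodes = sorted(network.nodes)
    mat = pd.DataFrame("", index=nodes, columns=nodes)
    for n in nodes:
        mat.loc[n, n] = SYNERGISTIC
    for a, b, data in network.edges(data=True):
        mat.loc[a, b] = data["klass"]
        mat.loc[b, a] = data["klass"]
    return mat
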