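"""Signed differential correlation networks over metabolites.

Edges surviving the permutation significance threshold form an undirected
graph whose nodes are metabolites.  An edge is *positive* (drawn red) when
the pair is more positively correlated in non-responders than responders
(r_diff > 0) and *negative* (blue) otherwise.  The *central network* is the
connected component with the largest number of metabolites; the *hub* is the
node of maximal degree.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

_AMINO_ACIDS = {
    "alanine", "arginine", "asparagine", "aspartate", "citrulline",
    "glutamate", "glutamine", "glycine", "histidine", "isoleucine",
    "leucine", "lysine", "methionine", "ornithine", "phenylalanine",
    "proline", "serine", "threonine", "tryptophan", "tyrosine", "valine",
    # Biocrates three-letter style
    "ala", "arg", "asn", "asp", "cit", "gln", "glu", "gly", "his", "ile",
    "leu", "lys", "met", "orn", "phe", "pro", "ser", "thr", "trp", "tyr",
    "val",
}

_BIOGENIC_AMINES = {
    "taurine", "creatinine", "putrescine", "spermidine", "spermine",
    "serotonin", "sarcosine", "kynurenine", "histamine", "dopamine",
    "adma", "sdma", "total dma", "carnosine", "alpha-aaa", "ac-orn",
    "met-so", "nitro-tyr", "oh-pro", "trans-oh-pro", "t4-oh-pro",
    "c4-oh-pro", "dopa", "ph-aa",
}

_ACYLCARNITINE_RE = re.compile(r"^C\d+(:\d+)?(-(OH|DC|M|oxo|OH-M)(\s*\(.*\))?)?$")


def metabolite_class(name: str) -> str:
    """Compound class from a Biocrates-style identifier prefix.

    Recognises glycerophospholipids (PC aa / PC ae), lysoPCs, sphingolipids
    (SM), acylcarnitines (C-number codes), the hexose monosaccharide, amino
    acids and biogenic amines; anything else maps to ``"other"``.
    """
    low = name.strip().lower()
    if low.startswith("lysopc"):
        return "lysoPC"
    if low.startswith("pc aa") or low.startswith("pc ae"):
        return "glycerophospholipid"
    if low.startswith("sm"):
        return "sphingolipid"
    if low in ("h1", "hexose", "glucose"):
        return "monosaccharide"
    if _ACYLCARNITINE_RE.match(name.strip()):
        return "acylcarnitine"
    if low in _AMINO_ACIDS:
        return "amino acid"
    if low in _BIOGENIC_AMINES:
        return "biogenic amine"
    return "other"


_EDGE_ATTRS = ("r_case", "r_control", "r_diff", "p_perm", "sign")


@dataclass
class DifferentialNetwork:
    """Signed graph over metabolites with significance threshold ``alpha``."""

    graph: nx.Graph
    alpha: float
    components: list[set] = field(init=False)

    def __post_init__(self) -> None:
        comps = [set(c) for c in nx.connected_components(self.graph)]
        # largest first; ties by edge count, then by lexicographic smallest node
        comps.sort(
            key=lambda c: (
                -len(c),
                -self.graph.subgraph(c).number_of_edges(),
                min(map(str, c)),
            )
        )
        self.components = comps

    @property
    def central_component(self) -> set:
        return self.components[0] if self.components else set()

    @property
    def component_sizes(self) -> list[int]:
        return [len(c) for c in self.components]

    @property
    def degrees(self) -> dict:
        return dict(self.graph.degree())

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class OverlapReport:
    """Nodes and sign-matched edges common to two outcome networks."""

    shared_nodes: set
    shared_edges: list  # (u, v, sign) triples, u < v


def build_network(edges: pd.DataFrame, alpha: float) -> DifferentialNetwork:
    """Keep edges with permutation p strictly below ``alpha``; build the graph.

    Nodes are the metabolites incident to at least one kept edge.  Positive
    edges carry color "red", negative "blue".  An empty result is returned
    (not raised) when nothing is significant.
    """
    if edges["p_perm"].isna().any():
        raise ValueError("edges must carry permutation p-values; run the test first")
    keep = edges[edges["p_perm"] < alpha]
    graph = nx.Graph()
    for row in keep.itertuples(index=False):
        attrs = {a: getattr(row, a) for a in _EDGE_ATTRS if hasattr(row, a)}
        attrs["color"] = "red" if row.sign == "positive" else "blue"
        graph.add_edge(row.metabolite_i, row.metabolite_j, **attrs)
    for node in graph.nodes:
        graph.nodes[node]["metabolite_class"] = metabolite_class(str(node))
    for node, deg in graph.degree():
        graph.nodes[node]["degree"] = int(deg)
    return DifferentialNetwork(graph=graph, alpha=alpha)


def hub_nodes(net: DifferentialNetwork) -> list[tuple[str, int]]:
    """Nodes ranked by degree, descending; ties broken lexicographically."""
    return sorted(net.graph.degree(), key=lambda kv: (-kv[1], str(kv[0])))


def overlap(net_a: DifferentialNetwork, net_b: DifferentialNetwork) -> OverlapReport:
    """Shared nodes and shared sign-matched edges of two networks."""
    if net_a.alpha != net_b.alpha:
        raise ValueError("networks must be built at the same alpha")
    nodes = set(net_a.graph.nodes) & set(net_b.graph.nodes)
    shared_edges = []
    for u, v, data in net_a.graph.edges(data=True):
        if net_b.graph.has_edge(u, v) and net_b.graph[u][v].get("sign") == data.get("sign"):
            a, b = sorted((str(u), str(v)))
            shared_edges.append((a, b, data.get("sign")))
    shared_edges.sort()
    return OverlapReport(shared_nodes=nodes, shared_edges=shared_edges)


def export_graphml(net: DifferentialNetwork, path) -> None:
    """Write the network as GraphML with node and edge attributes."""
    nx.write_graphml(net.graph, path)


def read_graphml(path, alpha: float) -> DifferentialNetwork:
    return DifferentialNetwork(graph=nx.read_graphml(path), alpha=alpha)


def export_edgelist(net: DifferentialNetwork, path) -> None:
    """Write the kept edges as a tab-delimited table."""
    rows = [
        {"metabolite_i": u, "metabolite_j": v, **{a: d.get(a) for a in _EDGE_ATTRS}}
        for u, v, d in sorted(net.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
    ]
    pd.DataFrame(rows, columns=["metabolite_i", "metabolite_j", *_EDGE_ATTRS]).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def plot_network(net: DifferentialNetwork, path=None, seed: int = 0):
    """Spring-layout rendering; red = positive, blue = negative edges."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    pos = nx.spring_layout(net.graph, seed=seed)
    colors = [d.get("color", "grey") for _, _, d in net.graph.edges(data=True)]
    nx.draw_networkx(net.graph, pos=pos, ax=ax, edge_color=colors,
                     node_color="lightgrey", font_size=7)
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
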