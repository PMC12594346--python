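"""Exporting and rendering the fitted coregulatory network.

The displayed graph is the bipartite miRNA -> mRNA layer; the class
node, being a parent of every expression node, is omitted from the
visual export (it is retained in the JSON model document written by
:mod:`coremir.clg`). Every edge carries the structural score, the
functional score and the final rank of its interaction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .clg import NetworkTopology
from .hierarchy import InteractionRanking

MIRNA_COLOR = "#2ca02c"  # green
MRNA_COLOR = "#1f77b4"  # blue


@dataclass
class NetworkDocument:
    """Serializable view of a fitted network."""

    graph: nx.DiGraph
    metadata: dict = field(default_factory=dict)


def build_document(
    topology: NetworkTopology,
    ranking: InteractionRanking,
    metadata: dict | None = None,
) -> NetworkDocument:
    """Annotated bipartite graph of the fitted top-k network."""
    by_pair = {(i.mirna, i.gene): i for i in ranking.interactions}
    g = nx.DiGraph()
    for node in topology.mirnas:
        g.add_node(node, role="mirna", label=node, color=MIRNA_COLOR)
    for node in topology.mrnas:
        g.add_node(node, role="mrna", label=node, color=MRNA_COLOR)
    for mirna, gene in topology.interactions:
        scored = by_pair[(mirna, gene)]
        g.add_edge(mirna, gene, SI=scored.si, FI=scored.fi,
                   final_rank=scored.final_rank)
    meta = {"k": topology.k, "mode": ranking.mode, "ties": ranking.ties}
    if metadata:
        meta.update(metadata)
    return NetworkDocument(graph=g, metadata=meta)


def export_network(
    document: NetworkDocument,
    path: str | Path,
    format: str = "graphml",
) -> Path:
    """Write the network in GraphML, DOT or JSON node-link form."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(document.graph, path)
    elif format == "dot":
        path.write_text(_to_dot(document))
    elif format == "json":
        doc = nx.node_link_data(document.graph, edges="edges")
        doc["metadata"] = document.metadata
        path.write_text(json.dumps(doc, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}")
    return path


def _to_dot(document: NetworkDocument) -> str:
    """Minimal DOT serialisation (no external graphviz bindings needed)."""
    def q(s: str) -> str:
        return '"' + str(s).replace('"', r'\"') + '"'

    lines = ["digraph coregulatory_network {"]
    for node, attrs in document.graph.nodes(data=True):
        lines.append(
            f'  {q(node)} [role={q(attrs["role"])}, style=filled, '
            f'fillcolor={q(attrs["color"])}];'
        )
    for u, v, attrs in document.graph.edges(data=True):
        lines.append(
            f'  {q(u)} -> {q(v)} [SI={attrs["SI"]:.6g}, FI={attrs["FI"]:.6g}, '
            f'rank={attrs["final_rank"]}];'
        )
    lines.append("}")
    return "\n".join(lines) + "\n"


def render_network(
    document: NetworkDocument,
    output: str | Path,
    seed: int = 0,
    figsize: tuple[float, float] = (9, 7),
) -> Path | None:
    """Draw the network to a static image, green miRNAs and blue mRNAs.

    The spring layout is seeded, so coordinates are deterministic for a
    given document and seed. If no drawing backend is available the
    document is written as GraphML next to the requested path instead,
    with a warning.
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # pragma: no cover
        warnings.warn("matplotlib unavailable; exporting GraphML instead", stacklevel=2)
        fallback = Path(output).with_suffix(".graphml")
        export_network(document, fallback, "graphml")
        return None
    g = document.graph
    pos = nx.spring_layout(g, seed=seed)
    colors = [attrs["color"] for _, attrs in g.nodes(data=True)]
    fig, ax = plt.subplots(figsize=figsize)
    nx.draw_networkx(
        g, pos=pos, ax=ax, node_color=colors, with_labels=True,
        font_size=6, node_size=250, edge_color="#888888", arrowsize=8,
    )
    ax.set_axis_off()
    meta = document.metadata
    ax.set_title(f"coregulatory network (k={meta.get('k')}, mode={meta.get('mode')})")
    fig.tight_layout()
    fig.savefig(output, dpi=150)
    plt.close(fig)
    return Path(output)
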