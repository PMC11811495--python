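"""Gene-network import, PAI/DI annotation, and export.

Networks arrive as edge-list TSV in the dialect exported by the STRING
database (columns ``node1``/``node2`` plus an optional ``combined_score``
confidence in [0, 1]) or as bare two/three-column edge lists.  Edges are
undirected; duplicate (u, v)/(v, u) rows are merged keeping the maximum
weight, and self-loops are permitted but flagged.

Nodes are annotated with a gene's PAI and DI and a deterministic stratum
color from a 10-entry colorblind-safe palette; unscored nodes stay white
(``#FFFFFF``), the neutral color.  Export targets are GraphML,
Cytoscape-JSON and an annotated TSV whose parse round-trips losslessly.
"""

from __future__ import annotations

import json
import logging
from typing import IO, Iterable, Mapping

import networkx as nx

from .divergence import DivergenceIndex
from .taxonomy import PhylostratumAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "NEUTRAL_COLOR",
    "PAI_PALETTE",
    "parse_network_tsv",
    "annotate_network",
    "pai_color",
    "export_network",
    "NetworkParseError",
]

NEUTRAL_COLOR = "#FFFFFF"

# 10-entry colorblind-safe sequential palette (light -> dark blue-purple),
# oldest stratum (smallest PAI) first.
PAI_PALETTE = (
    "#FDE725",
    "#B5DE2B",
    "#6ECE58",
    "#35B779",
    "#1F9E89",
    "#26828E",
    "#31688E",
    "#3E4A89",
    "#482878",
    "#440154",
)


class NetworkParseError(ValueError):
    """Raised for malformed network TSV input (cites the offending row)."""


def parse_network_tsv(stream: IO[str] | Iterable[str]) -> nx.Graph:
    """Parse an edge-list TSV into an undirected :class:`networkx.Graph`.

    Accepts a STRING-export header (``node1``/``node2`` with an optional
    ``combined_score`` column) or headerless two/three-column rows; a third
    column is the edge weight and must lie in [0, 1].
    """
    net = nx.Graph()
    lines = iter(stream)
    header: list[str] | None = None
    weight_col: int | None = 2
    u_col, v_col = 0, 1
    first_data: list[str] | None = None
    try:
        first = next(lines).rstrip("\n")
    except StopIteration:
        return net
    cols = first.split("\t")
    lowered = [c.strip().lower() for c in cols]
    if "node1" in lowered and "node2" in lowered:
        header = lowered
        u_col, v_col = lowered.index("node1"), lowered.index("node2")
        weight_col = (
            lowered.index("combined_score") if "combined_score" in lowered else None
        )
    else:
        first_data = cols

    def add_edge(parts: list[str], lineno: int) -> None:
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise NetworkParseError(f"row {lineno}: fewer than 2 columns")
        u, v = parts[u_col].strip(), parts[v_col].strip()
        weight = None
        if weight_col is not None and len(parts) > weight_col:
            text = parts[weight_col].strip()
            if text:
                try:
                    weight = float(text)
                except ValueError as exc:
                    raise NetworkParseError(
                        f"row {lineno}: bad combined_score {text!r}"
                    ) from exc
                if not 0.0 <= weight <= 1.0:
                    raise NetworkParseError(
                        f"row {lineno}: combined_score {weight} outside [0, 1]"
                    )
        if u == v:
            logger.warning("row %d: self-loop on %r", lineno, u)
        if net.has_edge(u, v):
            old = net.edges[u, v].get("weight")
            if weight is not None and (old is None or weight > old):
                net.edges[u, v]["weight"] = weight
        else:
            net.add_edge(u, v)
            if weight is not None:
                net.edges[u, v]["weight"] = weight

    lineno = 1
    if first_data is not None and first.strip():
        add_edge(first_data, lineno)
    for raw in lines:
        lineno += 1
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        add_edge(line.split("\t"), lineno)
    return net


def pai_color(pai: int, pai_min: int, pai_max: int) -> str:
    """Deterministic monotone color for a stratum within [pai_min, pai_max].

    The stratum range is spread evenly over the fixed palette; the extremes
    map to the palette's extreme entries, and distinct strata get distinct
    colors whenever the range fits the palette size.  A degenerate range
    (pai_min == pai_max) yields the palette's first color.
    """
    if not pai_min <= pai <= pai_max:
        raise ValueError(f"PAI {pai} outside [{pai_min}, {pai_max}]")
    if pai_max == pai_min:
        return PAI_PALETTE[0]
    span = pai_max - pai_min
    idx = round((pai - pai_min) * (len(PAI_PALETTE) - 1) / span)
    return PAI_PALETTE[idx]


def annotate_network(
    net: nx.Graph,
    assignments: Mapping[str, PhylostratumAssignment],
    di: Mapping[str, DivergenceIndex] | None = None,
) -> nx.Graph:
    """Attach pai, di, and color attributes to a copy of ``net``.

    Node and edge sets (and weights) are untouched.  Unannotated nodes get
    the neutral color; annotations for genes absent from the network are
    ignored with a log line.
    """
    di = di or {}
    annotated = net.copy()
    pais = [a.pai for g, a in assignments.items() if g in annotated]
    pai_min, pai_max = (min(pais), max(pais)) if pais else (0, 0)
    n_missing = 0
    for node in annotated.nodes:
        assignment = assignments.get(node)
        if assignment is not None:
            annotated.nodes[node]["pai"] = assignment.pai
            annotated.nodes[node]["color"] = pai_color(
                assignment.pai, pai_min, pai_max
            )
        else:
            annotated.nodes[node]["color"] = NEUTRAL_COLOR
            n_missing += 1
        gene_di = di.get(node)
        if gene_di is not None and gene_di.di is not None:
            annotated.nodes[node]["di"] = gene_di.di
    if n_missing:
        logger.info("%d network nodes without a PAI; neutral color", n_missing)
    for gene in set(assignments) - set(annotated.nodes):
        logger.info("annotation for %r ignored: not in network", gene)
    return annotated


def export_network(
    net: nx.Graph, target: str | IO[str], fmt: str = "tsv"
) -> None:
    """Write ``net`` as ``tsv`` (lossless round trip), ``graphml`` or
    ``cytoscape_json`` (both carry node attributes incl. color)."""
    if fmt == "tsv":
        _write_tsv(net, target)
    elif fmt == "graphml":
        if hasattr(target, "write"):
            nx.write_graphml(net, target)
        else:
            with open(target, "wb") as fh:
                nx.write_graphml(net, fh)
    elif fmt == "cytoscape_json":
        payload = nx.cytoscape_data(net)
        if hasattr(target, "write"):
            json.dump(payload, target, indent=1)
        else:
            with open(target, "w") as fh:
                json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def _write_tsv(net: nx.Graph, target: str | IO[str]) -> None:
    own = not hasattr(target, "write")
    fh = open(target, "w") if own else target
    try:
        fh.write("node1\tnode2\tcombined_score\n")
        for u, v, data in sorted(net.edges(data=True)):
            weight = data.get("weight")
            cell = "" if weight is None else format(weight, ".6g")
            fh.write(f"{u}\t{v}\t{cell}\n")
    finally:
        if own:
            fh.close()
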