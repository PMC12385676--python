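"""Scored protein–protein interaction networks.

A scored network is an undirected :class:`networkx.Graph` whose edges carry a
``confidence`` attribute in [0, 1] and whose graph dict may carry a
``provenance`` label.  Node names are gene symbols, uppercased on ingest;
duplicate edges keep the highest confidence seen.  No alias or ortholog
resolution is attempted — symbol matching is exact after case normalization.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx


class EdgeListError(ValueError):
    """Raised for unparseable edge-list rows (carries the line number)."""


def new_network(provenance: str = "") -> nx.Graph:
    g = nx.Graph()
    g.graph["provenance"] = provenance
    return g


def normalize_symbol(symbol):
    """Uppercase a gene symbol; non-string node labels pass through unchanged."""
    if isinstance(symbol, str):
        return symbol.strip().upper()
    return symbol


def add_scored_edge(net: nx.Graph, a: str, b: str, confidence: float,
                    *, allow_self_loops: bool = False) -> None:
    """Add an undirected scored edge, keeping the max confidence on duplicates."""
    a, b = normalize_symbol(a), normalize_symbol(b)
    if a == "" or b == "":
        raise EdgeListError("empty gene symbol")
    if a == b and not allow_self_loops:
        return
    if not (0.0 <= confidence <= 1.0):
        raise EdgeListError(f"confidence {confidence} out of [0, 1]")
    if net.has_edge(a, b):
        if confidence > net[a][b]["confidence"]:
            net[a][b]["confidence"] = confidence
    else:
        net.add_edge(a, b, confidence=confidence)


def _parse_row(fields: list[str], dialect: str) -> tuple[str, str, float] | None:
    """Return (symbol_a, symbol_b, confidence) or None for an ignorable row."""
    if dialect == "simple_tsv":
        if len(fields) < 3:
            raise EdgeListError(f"expected 3 columns, got {len(fields)}")
        return fields[0], fields[1], float(fields[2])
    if dialect == "hippie":
        # HIPPIE tab dialect: symA, entrezA, symB, entrezB, confidence, evidence
        if len(fields) < 5:
            raise EdgeListError(f"expected >= 5 columns, got {len(fields)}")
        sym_a = fields[0].split("_")[0]
        sym_b = fields[2].split("_")[0]
        if not sym_a or not sym_b:  # unmapped identifiers
            return None
        return sym_a, sym_b, float(fields[4])
    if dialect == "sif":
        # node relation node [node ...]; unscored -> confidence 1.0
        if len(fields) == 1:
            return None  # isolated node line
        if len(fields) < 3:
            raise EdgeListError("SIF row needs 'node relation node'")
        return fields[0], fields[2], 1.0
    raise EdgeListError(f"unknown dialect {dialect!r}")


def read_edge_list(path: str | Path, dialect: str = "simple_tsv",
                   *, header: bool = False) -> nx.Graph:
    """Read a scored edge list into an undirected, deduplicated network.

    Supported dialects: ``simple_tsv`` (nodeA, nodeB, confidence), ``hippie``
    (HIPPIE tab layout, confidence in column 5), ``sif`` (whitespace-split,
    confidence fixed at 1.0).  Duplicate unordered pairs keep the maximum
    confidence; symbols are uppercased.
    """
    path = Path(path)
    net = new_network(provenance=f"{dialect}:{path.name}")
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if dialect != "sif" else line.split()
            try:
                parsed = _parse_row(fields, dialect)
            except (EdgeListError, ValueError) as exc:
                raise EdgeListError(f"{path}:{lineno}: {exc}") from exc
            if parsed is None:
                continue
            a, b, conf = parsed
            try:
                add_scored_edge(net, a, b, conf)
            except EdgeListError as exc:
                raise EdgeListError(f"{path}:{lineno}: {exc}") from exc
            n_rows += 1
    if n_rows == 0:
        warnings.warn(f"{path}: empty edge list", stacklevel=2)
    return net


def filter_confidence(net: nx.Graph, threshold: float) -> nx.Graph:
    """Retain edges with confidence >= threshold; drop nodes left isolated.

    The HIPPIE medium-confidence operating point is threshold 0.63: the
    filtered interactome keeps medium- and high-confidence interactions.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} out of [0, 1]")
    out = new_network(provenance=net.graph.get("provenance", ""))
    for a, b, data in net.edges(data=True):
        if data["confidence"] >= threshold:
            out.add_edge(a, b, confidence=data["confidence"])
    return out


def first_neighbor_subnetwork(net: nx.Graph, query: list[str],
                              *, edges: str = "induced") -> tuple[nx.Graph, list[str]]:
    """Extract the query genes plus their direct neighbors.

    ``edges='induced'`` (default) returns the induced subgraph on
    query ∪ neighbors, so neighbor–neighbor edges are retained;
    ``edges='incident'`` keeps only edges touching a query gene.

    Returns (subnetwork, missing) where ``missing`` lists query symbols absent
    from the network (reported, never fatal).
    """
    if edges not in ("induced", "incident"):
        raise ValueError(f"edges must be 'induced' or 'incident', got {edges!r}")
    symbols = [normalize_symbol(s) for s in query]
    present = [s for s in symbols if s in net]
    missing = [s for s in symbols if s not in net]
    keep = set(present)
    for s in present:
        keep.update(net.neighbors(s))
    sub = new_network(provenance=net.graph.get("provenance", ""))
    sub.add_nodes_from(keep)
    qset = set(present)
    for a, b, data in net.subgraph(keep).edges(data=True):
        if edges == "induced" or a in qset or b in qset:
            sub.add_edge(a, b, confidence=data["confidence"])
    return sub, missing


def merge_networks(a: nx.Graph, b: nx.Graph) -> nx.Graph:
    """Union of nodes and edges; duplicate pairs keep the max confidence."""
    out = new_network(provenance="+".join(
        p for p in (a.graph.get("provenance", ""), b.graph.get("provenance", "")) if p))
    out.add_nodes_from(a.nodes)
    out.add_nodes_from(b.nodes)
    for src in (a, b):
        for u, v, data in src.edges(data=True):
            add_scored_edge(out, u, v, data["confidence"])
    return out


def component_report(net: nx.Graph, query: list[str]) -> dict[str, list[str]]:
    """Bin query genes by their degree inside the network.

    Classes: ``degree_0`` (singletons, incl. symbols absent from the network),
    ``degree_1``, ``degree_2`` and ``degree_3_plus``.
    """
    bins: dict[str, list[str]] = {"degree_0": [], "degree_1": [],
                                  "degree_2": [], "degree_3_plus": []}
    for s in sorted({normalize_symbol(q) for q in query}):
        d = net.degree(s) if s in net else 0
        key = {0: "degree_0", 1: "degree_1", 2: "degree_2"}.get(d, "degree_3_plus")
        bins[key].append(s)
    return bins


def write_edge_list(net: nx.Graph, path: str | Path) -> None:
    """Write a 3-column TSV edge list (nodeA, nodeB, confidence), sorted."""
    rows = sorted((min(a, b), max(a, b), data["confidence"])
                  for a, b, data in net.edges(data=True))
    with open(path, "w") as fh:
        for a, b, conf in rows:
            fh.write(f"{a}\t{b}\t{conf:.6g}\n")


def write_sif(net: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    rows = sorted((min(a, b), max(a, b)) for a, b in net.edges)
    isolated = sorted(n for n in net.nodes if net.degree(n) == 0)
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a} {relation} {b}\n")
        for n in isolated:
            fh.write(f"{n}\n")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, path)


def read_graphml(path: str | Path) -> nx.Graph:
    return nx.read_graphml(path)
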