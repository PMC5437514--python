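"""Reading, normalizing, validating and writing gene networks.

Networks are undirected labeled graphs over opaque, case-sensitive gene-ID
strings. Directionality present in input files is discarded: the downstream
mapping and scoring steps treat pathways as gene-interaction modules and never
use edge direction. Accepted formats are two-column edge lists (whitespace/TSV,
``#`` comments, optional auto-detected header) and GraphML.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .exceptions import FormatError

logger = logging.getLogger(__name__)

#: Advisory size band from practical experience with fingerprint scans:
#: queries far outside it are either too sparse to map or too slow to permute.
RECOMMENDED_NODES = (50, 100)
RECOMMENDED_EDGES = (100, 1000)


@dataclass(frozen=True)
class GeneNetwork:
    """An undirected gene network: the unit of both query and reference.

    Parameters
    ----------
    id
        Network label (file stem by default).
    nodes
        Gene IDs, opaque case-sensitive strings. Isolated nodes are kept.
    edges
        Unordered unique pairs; each pair is stored sorted. No self-loops.
    metadata
        Free-form provenance tags (source file, planted reference, ...).
    """

    id: str
    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    metadata: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop ({a},{b}) in normalized network")
            if a > b:
                raise ValueError(f"edge ({a},{b}) not stored in sorted order")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge endpoint missing from node set: ({a},{b})")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g

    def relabel(self, mapping: Mapping[str, str], new_id: str | None = None) -> "GeneNetwork":
        """Return an isomorphic copy with node labels replaced via `mapping`."""
        nodes = frozenset(mapping[n] for n in self.nodes)
        if len(nodes) != len(self.nodes):
            raise ValueError("relabeling collapses nodes; mapping must be injective")
        edges = frozenset(
            tuple(sorted((mapping[a], mapping[b]))) for a, b in self.edges
        )
        return GeneNetwork(new_id or self.id, nodes, edges, dict(self.metadata))


@dataclass(frozen=True)
class ValidationReport:
    """Advisory size report for a network; warnings never block analysis."""

    network_id: str
    n_nodes: int
    n_edges: int
    warnings: tuple[str, ...]


def build_network(
    id: str,
    edges: Iterable[tuple[str, str]],
    extra_nodes: Iterable[str] = (),
    metadata: Mapping[str, str] | None = None,
) -> GeneNetwork:
    """Normalize raw edge pairs into a :class:`GeneNetwork`.

    Self-loops are dropped (with a logged warning), duplicate and reversed
    duplicates collapsed, endpoints sorted within each edge. Normalization is
    idempotent: applying it to an already-normalized network is a no-op.
    """
    norm_edges: set[tuple[str, str]] = set()
    nodes: set[str] = set(extra_nodes)
    n_loops = 0
    for a, b in edges:
        nodes.add(a)
        nodes.add(b)
        if a == b:
            n_loops += 1
            continue
        norm_edges.add((a, b) if a < b else (b, a))
    if n_loops:
        logger.warning("network %s: %d self-loop(s) dropped", id, n_loops)
    return GeneNetwork(id, frozenset(nodes), frozenset(norm_edges), dict(metadata or {}))


_HEADER_WORDS = {"source", "target", "from", "to", "gene1", "gene2", "genea",
                 "geneb", "node1", "node2", "nodea", "nodeb", "interactor_a",
                 "interactor_b", "gene_a", "gene_b", "protein1", "protein2"}


def _is_header(tokens: list[str], body: list[list[str]]) -> bool:
    # A first line is a header only when both leading tokens are recognizable
    # column names that reappear in no edge; a name-blind heuristic would
    # swallow a legitimate first edge whose genes happen to be unique,
    # breaking write/read round-trips.
    if not body:
        return False
    if not all(t.lower() in _HEADER_WORDS for t in tokens[:2]):
        return False
    seen = {t for row in body for t in row[:2]}
    return not any(t in seen for t in tokens[:2])


def read_edge_list(
    path: str | Path,
    id: str | None = None,
    mapping: Mapping[str, str] | None = None,
) -> GeneNetwork:
    """Read a two-column edge list into a normalized :class:`GeneNetwork`.

    Lines starting with ``#`` are comments; a single header line is skipped
    when its tokens appear in no edge. Extra columns beyond the first two are
    ignored. An optional two-column ID `mapping` is applied at load time.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"edge-list file not found: {path}")
    rows: list[list[str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) < 2:
            raise FormatError(f"{path}:{lineno}: expected >=2 columns, got {len(tokens)}")
        rows.append(tokens)
    if rows and len(rows) > 1 and _is_header(rows[0], rows[1:]):
        logger.info("%s: first line treated as header", path)
        rows = rows[1:]
    if not rows:
        raise FormatError(f"{path}: no edges found")
    pairs = [(r[0], r[1]) for r in rows]
    if mapping:
        pairs = [(mapping.get(a, a), mapping.get(b, b)) for a, b in pairs]
    net = build_network(id or path.stem, pairs, metadata={"source": str(path)})
    if net.n_edges < 1:
        raise FormatError(f"{path}: no valid edges after normalization")
    return net


def read_graphml(
    path: str | Path,
    id: str | None = None,
    label_attribute: str | None = None,
) -> GeneNetwork:
    """Read a GraphML file; edge direction is discarded (undirected model).

    `label_attribute` optionally names a node attribute to use as the gene
    label instead of the GraphML node id.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GraphML file not found: {path}")
    try:
        g = nx.read_graphml(path)
    except Exception as exc:  # lxml/expat errors vary by backend
        raise FormatError(f"{path}: GraphML parse failure: {exc}") from exc
    if g.number_of_nodes() == 0:
        raise FormatError(f"{path}: GraphML file contains zero nodes")
    if label_attribute is not None:
        labels = {}
        for n, data in g.nodes(data=True):
            labels[n] = str(data.get(label_attribute, n))
        g = nx.relabel_nodes(nx.Graph(g), labels)
    nodes = [str(n) for n in g.nodes()]
    edges = [(str(a), str(b)) for a, b in g.edges()]
    return build_network(id or path.stem, edges, extra_nodes=nodes,
                         metadata={"source": str(path)})


def write_edge_list(net: GeneNetwork, path: str | Path) -> None:
    """Write canonical TSV: endpoints sorted within each line, lines sorted.

    Isolated nodes are preserved as comment records so that a write/read
    round-trip reproduces the node set exactly.
    """
    path = Path(path)
    lines = [f"# network: {net.id}"]
    isolated = net.nodes - {g for e in net.edges for g in e}
    for n in sorted(isolated):
        lines.append(f"#node\t{n}")
    lines.extend(f"{a}\t{b}" for a, b in sorted(net.edges))
    path.write_text("\n".join(lines) + "\n")


def read_canonical_edge_list(path: str | Path, id: str | None = None) -> GeneNetwork:
    """Read TSV written by :func:`write_edge_list`, restoring isolated nodes."""
    path = Path(path)
    isolated = []
    for line in path.read_text().splitlines():
        if line.startswith("#node\t"):
            isolated.append(line.split("\t", 1)[1])
    net = read_edge_list(path, id=id)
    if isolated:
        net = build_network(net.id, net.edges, extra_nodes=set(net.nodes) | set(isolated),
                            metadata=net.metadata)
    return net


def validate_network_size(net: GeneNetwork) -> ValidationReport:
    """Advisory check against the recommended 50-100 node / 100-1000 edge band."""
    warnings = []
    lo, hi = RECOMMENDED_NODES
    if not lo <= net.n_nodes <= hi:
        warnings.append(
            f"node count {net.n_nodes} outside recommended range [{lo},{hi}]"
        )
    lo, hi = RECOMMENDED_EDGES
    if not lo <= net.n_edges <= hi:
        warnings.append(
            f"edge count {net.n_edges} outside recommended range [{lo},{hi}]"
        )
    return ValidationReport(net.id, net.n_nodes, net.n_edges, tuple(warnings))
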