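"""Reference pathway sets: loading, filtering, organization, synthesis.

A reference set is an *ordered* collection of curated pathway networks; the
order defines the coordinate order of every fingerprint computed against it,
so it is preserved from the manifest and never implicitly sorted. Pathways
with fewer than 10 edges carry too little topology to map against and are
filtered out, mirroring curation practice for fingerprint reference sets.

The synthetic universe generator builds a complete self-consistent world —
ontology, annotations, reference pathways, and planted-module queries — for
testing and benchmarking without any database access.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .exceptions import DataError, FormatError, ParameterError
from .graphio import GeneNetwork, build_network, read_edge_list, write_edge_list
from .ontology import AnnotationMap, Ontology

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReferencePathway:
    """One curated pathway network plus provenance."""

    network: GeneNetwork
    source: str = "unknown"
    category: str = "uncategorized"

    @property
    def id(self) -> str:
        return self.network.id


@dataclass(frozen=True)
class ReferenceSet:
    """Ordered, categorized collection of reference pathways."""

    id: str
    pathways: tuple[ReferencePathway, ...]

    def __post_init__(self):
        ids = [p.id for p in self.pathways]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise DataError(f"duplicate pathway id(s) in reference set: {dup}")

    @property
    def categories(self) -> tuple[str, ...]:
        seen: list[str] = []
        for p in self.pathways:
            if p.category not in seen:
                seen.append(p.category)
        return tuple(seen)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, ref_id: str) -> ReferencePathway:
        for p in self.pathways:
            if p.id == ref_id:
                return p
        raise KeyError(ref_id)


def load_reference_manifest(path: str | Path, id: str | None = None) -> ReferenceSet:
    """Load a reference set from a manifest (JSON list or TSV).

    JSON: ``[{"id":..., "category":..., "source":..., "path":...}, ...]``.
    TSV: four columns in the same order. Paths are resolved relative to the
    manifest's directory. Manifest order is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"manifest not found: {path}")
    entries: list[dict] = []
    text = path.read_text()
    if path.suffix == ".json" or text.lstrip().startswith("["):
        try:
            raw = json.loads(text)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: invalid JSON manifest: {exc}") from exc
        for rec in raw:
            entries.append({k: str(rec[k]) for k in ("id", "category", "source", "path")})
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split("\t")
            if len(tokens) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 tab-separated columns")
            entries.append(dict(zip(("id", "category", "source", "path"), tokens)))
    pathways = []
    for rec in entries:
        net_path = Path(rec["path"])
        if not net_path.is_absolute():
            net_path = path.parent / net_path
        if not net_path.exists():
            raise FormatError(f"pathway {rec['id']}: file not found: {net_path}")
        net = read_edge_list(net_path, id=rec["id"])
        pathways.append(ReferencePathway(net, source=rec["source"], category=rec["category"]))
    return ReferenceSet(id or path.stem, tuple(pathways))


def save_reference_set(refs: ReferenceSet, out_dir: str | Path) -> Path:
    """Write edge lists + JSON manifest to a directory; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for p in refs.pathways:
        fname = f"{p.id}.tsv"
        write_edge_list(p.network, out_dir / fname)
        records.append({"id": p.id, "category": p.category, "source": p.source,
                        "path": fname})
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps(records, indent=1) + "\n")
    return manifest


def filter_small_pathways(refs: ReferenceSet, min_edges: int = 10) -> ReferenceSet:
    """Drop pathways with fewer than `min_edges` edges; order preserved."""
    kept, dropped = [], []
    for p in refs.pathways:
        (kept if p.network.n_edges >= min_edges else dropped).append(p)
    if dropped:
        logger.info("reference set %s: excluded %d pathway(s) with < %d edges: %s",
                    refs.id, len(dropped), min_edges, [p.id for p in dropped])
    if not kept:
        logger.warning("reference set %s: empty after size filtering", refs.id)
    return ReferenceSet(refs.id, tuple(kept))


def write_gmt(refs: ReferenceSet, path: str | Path) -> None:
    """Export each pathway's gene set in GMT format (name, description, genes)."""
    lines = []
    for p in refs.pathways:
        genes = "\t".join(sorted(p.network.nodes))
        lines.append(f"{p.id}\t{p.source}:{p.category}\t{genes}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# synthetic universe


@dataclass(frozen=True)
class SyntheticParams:
    """Generation parameters for a synthetic benchmarking universe.

    Defaults describe the standard desk-scale scenario: 20 reference pathways
    of 10-15 genes drawn from a 200-gene pool. The ontology mimics the branch
    structure of a functional ontology: a single root over `n_families`
    function families, each a small subtree (family head -> mid terms ->
    leaf terms). Every gene is annotated with `n_background_terms` leaves
    from one uniformly chosen family, so unrelated genes — like unrelated
    real genes — share only near-root ancestors and score near-zero semantic
    similarity, while genes of one family score high. Each reference pathway
    owns one family whose leaves act as its theme terms; pathway genes carry
    each theme term with probability `coherence`, the single knob controlling
    how separable pathways are (0.8 keeps recovery hard but achievable).
    `n_families` exceeds `n_refs` so that some families are pure background
    noise.
    """

    n_refs: int = 20
    node_range: tuple[int, int] = (10, 15)
    coherence: float = 0.8
    pool_size: int = 200
    n_families: int = 30
    n_mid_per_family: int = 2
    n_leaves_per_family: int = 6
    n_theme_terms: int = 3
    n_background_terms: int = 2
    edge_prob: float = 0.35
    min_edges: int = 10


@dataclass(frozen=True)
class SyntheticUniverse:
    """A reproducible synthetic world: same params + seed => identical content."""

    ontology: Ontology
    annotations: AnnotationMap
    references: ReferenceSet
    params: SyntheticParams
    seed: int
    theme_terms: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    @property
    def gene_pool(self) -> tuple[str, ...]:
        return tuple(sorted(self.annotations.gene_terms))

    def serialize(self) -> str:
        """Deterministic text form of the whole universe (for round-trips
        and byte-identity checks)."""
        parts = ["# ontology"]
        for t in sorted(self.ontology.terms):
            for p in sorted(self.ontology.parents.get(t, ())):
                parts.append(f"{t}\t{p}")
        parts.append("# annotations")
        for g in sorted(self.annotations.gene_terms):
            for t in sorted(self.annotations.gene_terms[g]):
                parts.append(f"{g}\t{t}")
        parts.append("# references")
        for ref in self.references.pathways:
            parts.append(f"## {ref.id}\t{ref.category}\t{ref.source}")
            iso = ref.network.nodes - {g for e in ref.network.edges for g in e}
            for n in sorted(iso):
                parts.append(f"node\t{n}")
            for a, b in sorted(ref.network.edges):
                parts.append(f"{a}\t{b}")
        return "\n".join(parts) + "\n"


def _family_ontology(rng: np.random.Generator, p: SyntheticParams
                     ) -> tuple[Ontology, list[list[str]]]:
    """Single-rooted DAG of function-family subtrees.

    Returns the ontology plus, per family, its list of leaf terms. Each leaf
    hangs off 1-2 of the family's mid terms, which hang off the family head,
    which hangs off the root — so two leaves of one family meet at an
    informative mid/head ancestor while leaves of different families meet
    only at the uninformative root.
    """
    root = "T0000"
    terms = [root]
    parents: dict[str, set[str]] = {root: set()}
    family_leaves: list[list[str]] = []
    counter = 1
    for f in range(p.n_families):
        head = f"T{counter:04d}"
        counter += 1
        terms.append(head)
        parents[head] = {root}
        mids = []
        for _ in range(p.n_mid_per_family):
            mid = f"T{counter:04d}"
            counter += 1
            terms.append(mid)
            parents[mid] = {head}
            mids.append(mid)
        leaves = []
        for _ in range(p.n_leaves_per_family):
            leaf = f"T{counter:04d}"
            counter += 1
            terms.append(leaf)
            n_par = 1 + int(rng.random() < 0.3)
            choices = rng.choice(len(mids), size=min(n_par, len(mids)),
                                 replace=False)
            parents[leaf] = {mids[c] for c in choices}
            leaves.append(leaf)
        family_leaves.append(leaves)
    ont = Ontology(frozenset(terms), {t: frozenset(ps) for t, ps in parents.items()})
    return ont, family_leaves


def _random_connected_graph(rng: np.random.Generator, genes: list[str],
                            edge_prob: float, min_edges: int) -> frozenset[tuple[str, str]]:
    n = len(genes)
    edges: set[tuple[str, str]] = set()
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                edges.add(tuple(sorted((genes[i], genes[j]))))
    # connectivity repair: chain components together with random bridges
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(genes)
    g.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort()
    while len(comps) > 1:
        a = comps[0][int(rng.integers(len(comps[0])))]
        b = comps[1][int(rng.integers(len(comps[1])))]
        edges.add(tuple(sorted((a, b))))
        comps = [sorted(set(comps[0]) | set(comps[1]))] + comps[2:]
    # edge-count repair: top up to min_edges where the clique allows it
    all_pairs = [tuple(sorted((genes[i], genes[j])))
                 for i in range(n) for j in range(i + 1, n)]
    missing = sorted(set(all_pairs) - edges)
    while len(edges) < min_edges and missing:
        k = int(rng.integers(len(missing)))
        edges.add(missing.pop(k))
    return frozenset(edges)


def generate_synthetic_universe(params: SyntheticParams | None = None,
                                seed: int = 0) -> SyntheticUniverse:
    """Generate a reproducible ontology + annotations + reference set.

    Construction: a family-structured is_a DAG (see
    :func:`_family_ontology`); a gene pool where every gene carries
    `n_background_terms` leaf terms from one uniformly chosen family; and
    `n_refs` connected random pathways. Pathway r owns family r: its theme
    terms are `n_theme_terms` leaves of that family, and each pathway gene
    carries each theme term with probability `coherence`.
    """
    p = params or SyntheticParams()
    if p.n_refs < 2:
        raise ParameterError("n_refs must be >= 2")
    if p.n_families < p.n_refs:
        raise ParameterError("n_families must be >= n_refs (one family per pathway)")
    if p.n_theme_terms > p.n_leaves_per_family:
        raise ParameterError("n_theme_terms cannot exceed n_leaves_per_family")
    lo, hi = p.node_range
    if not (5 <= lo <= hi <= 200):
        raise ParameterError("pathway node range must lie within [5, 200]")
    if hi > p.pool_size:
        raise ParameterError("pathway size exceeds gene pool size")
    rng = np.random.default_rng(seed)
    ontology, family_leaves = _family_ontology(rng, p)
    pool = [f"G{i:04d}" for i in range(p.pool_size)]

    gene_terms: dict[str, set[str]] = {}
    for g in pool:
        fam = int(rng.integers(p.n_families))
        leaves = family_leaves[fam]
        k = min(p.n_background_terms, len(leaves))
        picks = rng.choice(len(leaves), size=k, replace=False)
        gene_terms[g] = {leaves[i] for i in picks}

    pathways = []
    themes: dict[str, tuple[str, ...]] = {}
    for r in range(p.n_refs):
        ref_id = f"P{r:03d}"
        n_nodes = int(rng.integers(lo, hi + 1))
        idx = rng.choice(p.pool_size, size=n_nodes, replace=False)
        genes = sorted(pool[i] for i in idx)
        leaves = family_leaves[r]
        picks = rng.choice(len(leaves), size=p.n_theme_terms, replace=False)
        theme = tuple(sorted(leaves[i] for i in picks))
        themes[ref_id] = theme
        for g in genes:
            for t in theme:
                if rng.random() < p.coherence:
                    gene_terms[g].add(t)
        edges = _random_connected_graph(rng, genes, p.edge_prob, p.min_edges)
        net = GeneNetwork(ref_id, frozenset(genes), edges,
                          {"source": "synthetic", "theme": ",".join(theme)})
        pathways.append(ReferencePathway(net, source="synthetic",
                                         category=f"cat{r % 4}"))
    annot = AnnotationMap({g: frozenset(ts) for g, ts in gene_terms.items()})
    refs = ReferenceSet(f"synthetic-{seed}", tuple(pathways))
    return SyntheticUniverse(ontology, annot, refs, p, seed, themes)


def plant_query(universe: SyntheticUniverse, ref_id: str, retention: float = 0.9,
                noise_edges: int = 5, n_background: int = 5,
                seed: int = 0) -> GeneNetwork:
    """Embed a reference pathway into a noisy query network.

    The query is the induced subgraph on a `retention`-fraction sample of the
    reference's nodes, plus `n_background` pool genes, plus `noise_edges`
    random edges, followed by connected-component repair. The planted
    reference id is recorded in the query's metadata.
    """
    ref = universe.references[ref_id]
    if not 0 < retention <= 1:
        raise ParameterError("retention must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    ref_nodes = sorted(ref.network.nodes)
    n_keep = int(round(retention * len(ref_nodes)))
    if n_keep < 2:
        raise ParameterError(
            f"retention {retention} keeps {n_keep} node(s); need >= 2")
    keep_idx = rng.choice(len(ref_nodes), size=n_keep, replace=False)
    kept = {ref_nodes[i] for i in keep_idx}
    edges = {e for e in ref.network.edges if e[0] in kept and e[1] in kept}
    nodes = set(kept)
    background = sorted(set(universe.gene_pool) - ref.network.nodes)
    if n_background > 0:
        if n_background > len(background):
            raise ParameterError("n_background exceeds available pool genes")
        bg_idx = rng.choice(len(background), size=n_background, replace=False)
        nodes |= {background[i] for i in bg_idx}
    node_list = sorted(nodes)
    for _ in range(noise_edges):
        i, j = rng.choice(len(node_list), size=2, replace=False)
        edges.add(tuple(sorted((node_list[i], node_list[j]))))
    # repair connectivity exactly as the pathway generator does
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(node_list)
    g.add_edges_from(edges)
    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort()
    while len(comps) > 1:
        a = comps[0][int(rng.integers(len(comps[0])))]
        b = comps[1][int(rng.integers(len(comps[1])))]
        edges.add(tuple(sorted((a, b))))
        comps = [sorted(set(comps[0]) | set(comps[1]))] + comps[2:]
    return build_network(f"query-{ref_id}-s{seed}", edges, extra_nodes=nodes,
                         metadata={"planted_ref": ref_id, "seed": str(seed)})
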