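"""Node-node mapping between a query and a reference network.

The two networks are merged into one graph — their disjoint union plus cross
edges wherever gene-gene attribute similarity reaches a threshold tau — and
the merged nodes are clustered. The default clusterer is affinity propagation
on a blended affinity:

    s(i,j) = w_topo * Jaccard(N(i), N(j)) + (1 - w_topo) * attr(i,j)

where N(.) are merged-graph neighborhoods and attr is the gene-gene attribute
similarity (cross-network pairs from the supplied matrix; same-network pairs
from the same gene-level scorer when available, else 0). The diagonal is the
affinity-propagation preference, controlling exemplar count; "median" of the
off-diagonal values is the conventional default. A greedy best-pair aligner
is provided as a lightweight alternative, and external alignment tools plug
in through a subprocess adapter with a plain-text contract.

Merged nodes carry origin prefixes "Q:"/"R:"; a gene present in both networks
yields two distinct tagged nodes. Every algorithm returns a NodeMapping that
partitions the merged node set.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .exceptions import ExternalToolError, FormatError, ParameterError
from .graphio import GeneNetwork, write_edge_list
from .ontology import SimilarityMatrix

logger = logging.getLogger(__name__)

Q_PREFIX = "Q:"
R_PREFIX = "R:"


def tag(origin: str, gene: str) -> str:
    return f"{origin}:{gene}"


def untag(node: str) -> tuple[str, str]:
    origin, gene = node.split(":", 1)
    return origin, gene


@dataclass(frozen=True)
class MergedGraph:
    """Disjoint union of query and reference plus similarity cross edges."""

    graph: nx.Graph          # nodes are "Q:gene" / "R:gene"
    nodes: tuple[str, ...]   # stable order: sorted query nodes, then reference
    query_id: str
    ref_id: str
    tau: float

    @property
    def n_cross_edges(self) -> int:
        return sum(1 for a, b in self.graph.edges if a[0] != b[0])


@dataclass(frozen=True)
class AffinityMatrix:
    """Square affinity over merged nodes; diagonal holds the preference."""

    nodes: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        n = len(self.nodes)
        if self.matrix.shape != (n, n):
            raise ValueError("affinity matrix shape mismatch")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("affinity matrix contains non-finite entries")


@dataclass(frozen=True)
class Cluster:
    exemplar: str
    members: frozenset[str]

    def __post_init__(self):
        if self.exemplar not in self.members:
            raise ValueError("exemplar must be a member of its cluster")


@dataclass(frozen=True)
class NodeMapping:
    """Disjoint clusters covering all merged nodes, with provenance."""

    clusters: tuple[Cluster, ...]
    algorithm: str
    params: dict

    def __post_init__(self):
        seen: set[str] = set()
        for c in self.clusters:
            if seen & c.members:
                raise ValueError("clusters are not disjoint")
            seen |= c.members

    @property
    def all_nodes(self) -> frozenset[str]:
        return frozenset(n for c in self.clusters for n in c.members)


def merge_networks(q: GeneNetwork, r: GeneNetwork, sim: SimilarityMatrix,
                   tau: float = 0.5) -> MergedGraph:
    """Merge query and reference; add cross edges where similarity >= tau."""
    g = nx.Graph()
    q_nodes = [tag("Q", n) for n in sorted(q.nodes)]
    r_nodes = [tag("R", n) for n in sorted(r.nodes)]
    g.add_nodes_from(q_nodes, origin="Q")
    g.add_nodes_from(r_nodes, origin="R")
    for a, b in q.edges:
        g.add_edge(tag("Q", a), tag("Q", b), kind="within")
    for a, b in r.edges:
        g.add_edge(tag("R", a), tag("R", b), kind="within")
    for qa in sorted(q.nodes):
        for rb in sorted(r.nodes):
            if sim.lookup(qa, rb) >= tau:
                g.add_edge(tag("Q", qa), tag("R", rb), kind="cross")
    return MergedGraph(g, tuple(q_nodes + r_nodes), q.id, r.id, tau)


def build_affinity(mg: MergedGraph, sim: SimilarityMatrix, w_topo: float = 0.5,
                   preference: float | str = "median") -> AffinityMatrix:
    """Blend topological (Jaccard) and attribute similarity into an affinity.

    Jaccard of two empty neighborhoods is defined as 0 (no evidence of
    similarity). `preference` fills the diagonal; "median" uses the median of
    the off-diagonal values, the conventional affinity-propagation default.
    """
    nodes = mg.nodes
    n = len(nodes)
    adj = nx.to_numpy_array(mg.graph, nodelist=nodes, dtype=bool)
    deg = adj.sum(axis=1)
    inter = (adj.astype(np.float64) @ adj.T)
    union = deg[:, None] + deg[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        jac = np.where(union > 0, inter / np.where(union > 0, union, 1), 0.0)

    attr = np.zeros((n, n))
    genes = [untag(x)[1] for x in nodes]
    for i in range(n):
        for j in range(i + 1, n):
            attr[i, j] = attr[j, i] = sim.lookup(genes[i], genes[j])

    s = w_topo * jac + (1.0 - w_topo) * attr
    off = s[~np.eye(n, dtype=bool)]
    if preference == "median":
        pref = float(np.median(off)) if off.size else 0.0
    else:
        pref = float(preference)
    np.fill_diagonal(s, pref)
    return AffinityMatrix(nodes, s)


def _assign_to_exemplars(S: np.ndarray, nodes: Sequence[str],
                         exemplars: np.ndarray) -> tuple[Cluster, ...]:
    labels = exemplars[np.argmax(S[:, exemplars], axis=1)]
    labels[exemplars] = exemplars
    clusters = []
    for k in sorted(set(labels.tolist())):
        members = frozenset(nodes[i] for i in np.where(labels == k)[0])
        clusters.append(Cluster(nodes[k], members))
    return tuple(clusters)


def affinity_propagation(A: AffinityMatrix, damping: float = 0.9,
                         max_iter: int = 1000,
                         convergence_window: int = 50) -> NodeMapping:
    """Affinity propagation by damped message passing.

    Responsibilities and availabilities follow the standard update rules;
    exemplars are nodes with r(k,k) + a(k,k) > 0, each non-exemplar joins the
    exemplar of maximal affinity. Exactly symmetric inputs (common here:
    merged twin nodes of a shared gene) put both nodes of a would-be cluster
    precisely on the exemplar decision boundary and the messages deadlock in
    a singleton fixed point; the usual remedy is random noise, but to keep
    runs reproducible a tiny *deterministic* index-based jitter (< 1e-9,
    orders of magnitude below any meaningful affinity difference) is added
    instead. The procedure is therefore fully deterministic given A and
    parameters. Terminates when the exemplar set is stable for
    `convergence_window` sweeps, else at `max_iter` with a warning.
    """
    if not 0.5 <= damping < 1:
        raise ParameterError("damping must lie in [0.5, 1)")
    nodes = A.nodes
    n = len(nodes)
    if n == 0:
        raise ParameterError("empty affinity matrix")
    if n == 1:
        return NodeMapping((Cluster(nodes[0], frozenset(nodes)),),
                           "apcluster", {"damping": damping})
    S = A.matrix.astype(np.float64, copy=True)
    # deterministic symmetry-breaking jitter (see docstring)
    scale = max(float(np.ptp(S)), 1.0)
    jitter = (np.arange(n * n, dtype=np.float64).reshape(n, n) + 1.0) / (n * n)
    S = S + 1e-9 * scale * jitter
    R = np.zeros((n, n))
    Av = np.zeros((n, n))
    idx = np.arange(n)
    prev_exemplars: frozenset[int] = frozenset()
    stable = 0
    converged = False
    for it in range(max_iter):
        # responsibilities: r(i,k) = s(i,k) - max_{k' != k}(a(i,k') + s(i,k'))
        AS = Av + S
        first_k = np.argmax(AS, axis=1)
        first = AS[idx, first_k]
        AS[idx, first_k] = -np.inf
        second = AS.max(axis=1)
        Rnew = S - first[:, None]
        Rnew[idx, first_k] = S[idx, first_k] - second
        R = damping * R + (1 - damping) * Rnew
        # availabilities
        Rp = np.maximum(R, 0)
        Rp[idx, idx] = R[idx, idx]
        colsum = Rp.sum(axis=0)
        Anew = colsum[None, :] - Rp
        diag = Anew[idx, idx].copy()
        Anew = np.minimum(Anew, 0)
        Anew[idx, idx] = diag
        Av = damping * Av + (1 - damping) * Anew

        exemplars = frozenset(np.where(np.diag(R) + np.diag(Av) > 0)[0].tolist())
        if exemplars and exemplars == prev_exemplars:
            stable += 1
            if stable >= convergence_window:
                converged = True
                break
        else:
            stable = 0
        prev_exemplars = exemplars
    if not converged:
        logger.warning("affinity propagation did not converge in %d sweeps", max_iter)
    ex = np.array(sorted(prev_exemplars), dtype=int)
    if ex.size == 0:
        # degenerate: no node self-elected; fall back to the best candidate
        ex = np.array([int(np.argmax(np.diag(R) + np.diag(Av)))])
        logger.warning("no exemplar emerged; falling back to best self-evidence node")
    clusters = _assign_to_exemplars(S, nodes, ex)
    return NodeMapping(clusters, "apcluster",
                       {"damping": damping, "max_iter": max_iter,
                        "convergence_window": convergence_window,
                        "converged": converged})


def greedy_align(q: GeneNetwork, r: GeneNetwork, sim: SimilarityMatrix,
                 min_sim: float = 0.5) -> NodeMapping:
    """Greedy best-pair alignment: repeatedly emit the globally best
    unmatched (query, reference) pair as a two-node cluster until the best
    remaining similarity drops below `min_sim`. Ties break lexicographically
    by (query gene, reference gene), so the result is independent of input
    order. Unmatched nodes become singletons.
    """
    q_free = sorted(q.nodes)
    r_free = sorted(r.nodes)
    clusters: list[Cluster] = []
    while q_free and r_free:
        best: tuple[float, str, str] | None = None
        for qa in q_free:
            for rb in r_free:
                v = sim.lookup(qa, rb)
                if best is None or v > best[0] or (v == best[0] and (qa, rb) < best[1:]):
                    best = (v, qa, rb)
        if best is None or best[0] < min_sim:
            break
        _, qa, rb = best
        clusters.append(Cluster(tag("Q", qa), frozenset({tag("Q", qa), tag("R", rb)})))
        q_free.remove(qa)
        r_free.remove(rb)
    for qa in q_free:
        clusters.append(Cluster(tag("Q", qa), frozenset({tag("Q", qa)})))
    for rb in r_free:
        clusters.append(Cluster(tag("R", rb), frozenset({tag("R", rb)})))
    return NodeMapping(tuple(clusters), "greedy", {"min_sim": min_sim})


def run_external_aligner(cmd_template: str, q: GeneNetwork,
                         r: GeneNetwork) -> NodeMapping:
    """Invoke an external alignment tool through a plain-text contract.

    `cmd_template` must contain ``{query}``, ``{reference}`` and ``{output}``
    placeholders; the two networks are exported as edge-list TSVs and the
    template is run through the shell. The output file must hold one cluster
    per line: whitespace-separated node ids carrying ``Q:``/``R:`` origin
    prefixes. Nodes absent from the output become singleton clusters.
    """
    with tempfile.TemporaryDirectory(prefix="netfp-align-") as tmp:
        tmp_path = Path(tmp)
        q_path, r_path = tmp_path / "query.tsv", tmp_path / "reference.tsv"
        out_path = tmp_path / "clusters.txt"
        write_edge_list(q, q_path)
        write_edge_list(r, r_path)
        cmd = cmd_template.format(query=q_path, reference=r_path, output=out_path)
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalToolError(
                f"external aligner exited {proc.returncode}: {cmd}",
                stderr=proc.stderr)
        if not out_path.exists():
            raise ExternalToolError(f"external aligner produced no output: {cmd}",
                                    stderr=proc.stderr)
        lines = out_path.read_text().splitlines()

    valid = {tag("Q", n) for n in q.nodes} | {tag("R", n) for n in r.nodes}
    clusters: list[Cluster] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if not tokens:
            continue
        for t in tokens:
            if t not in valid:
                raise FormatError(
                    f"aligner output line {lineno}: unknown node id {t!r} "
                    "(expected Q:/R: prefixed network nodes)")
            if t in seen:
                raise FormatError(
                    f"aligner output line {lineno}: node {t!r} in two clusters")
        seen.update(tokens)
        clusters.append(Cluster(sorted(tokens)[0], frozenset(tokens)))
    for node in sorted(valid - seen):
        clusters.append(Cluster(node, frozenset({node})))
    return NodeMapping(tuple(clusters), "external", {"cmd_template": cmd_template})
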