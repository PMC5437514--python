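"""Similarity scoring and fingerprint assembly.

Given a node mapping between query and reference, each *mixed* cluster (one
containing nodes from both networks) gets a local similarity — the best-match
average of gene-gene similarity between its query-side and reference-side
genes — and the raw network similarity is the unweighted mean of local scores
over *all* clusters. Unmixed clusters count as zeros: a mapping in which the
two networks barely mingle should score low even if one lucky cluster matches
well.

Raw scores are normalized against a permutation null: the query's topology is
kept and its node labels are replaced by a uniform draw from the annotated
gene pool, the identical map+score pipeline is run on each randomized copy,
and the coordinate reported is

    z = (raw - null_mean) / max(null_sd, 1e-8),   clipped to [-1000, 1000]

with the sample (n-1) standard deviation. Label permutation (rather than edge
rewiring) is used because the score depends on node attributes and
cross-network structure: permuting labels isolates exactly the attribute
signal while holding topology fixed. The fingerprint of a query is the
ordered vector of per-reference results; per-reference seeds derive from
(master seed + reference index), so a scan is reproducible and its result is
independent of evaluation order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .config import RunConfig
from .exceptions import ParameterError
from .graphio import GeneNetwork
from .mapping import (NodeMapping, affinity_propagation, build_affinity,
                      greedy_align, merge_networks, run_external_aligner, untag)
from .ontology import AnnotationMap, GoSimilarity, Ontology, SimilarityMatrix
from .refdb import ReferencePathway, ReferenceSet

logger = logging.getLogger(__name__)

EPS_SD = 1e-8
Z_CLIP = 1000.0
_SEED_MOD = 2**31


@dataclass(frozen=True)
class ClusterScore:
    index: int
    local_similarity: float
    mixed: bool


@dataclass(frozen=True)
class SimilarityResult:
    """One fingerprint coordinate: raw score, permutation null, Z-score."""

    ref_id: str
    raw: float
    null_mean: float
    null_sd: float
    z: float
    n_perm: int
    seed: int
    error: str | None = None


@dataclass(frozen=True)
class Fingerprint:
    """Ordered spectrum of similarity results, one per reference pathway."""

    query_id: str
    reference_set_id: str
    results: tuple[SimilarityResult, ...]
    config: dict = field(default_factory=dict)

    def zscores(self) -> np.ndarray:
        return np.array([r.z for r in self.results])

    def top(self, n: int = 5) -> list[SimilarityResult]:
        return sorted(self.results, key=lambda r: -r.z)[:n]


@dataclass
class PipelineContext:
    """Everything a map+score run needs besides the two networks.

    `sim_provider(genes_a, genes_b)` returns a SimilarityMatrix; for the GO
    measure this wraps a shared memoizing scorer so permutation scans reuse
    gene-pair values. `gene_pool` is the label pool for the permutation null
    (default: all annotated genes).
    """

    config: RunConfig
    sim_provider: Callable[[Sequence[str], Sequence[str]], SimilarityMatrix]
    gene_pool: tuple[str, ...]

    @classmethod
    def for_go(cls, config: RunConfig, annot: AnnotationMap, ontology: Ontology,
               gene_pool: Sequence[str] | None = None) -> "PipelineContext":
        scorer = GoSimilarity(annot, ontology)
        pool = tuple(sorted(gene_pool if gene_pool is not None else annot.universe))
        return cls(config, scorer.matrix, pool)

    @classmethod
    def for_precomputed(cls, config: RunConfig, sim: SimilarityMatrix,
                        gene_pool: Sequence[str]) -> "PipelineContext":
        def provider(genes_a, genes_b):
            values = np.array([[sim.lookup(a, b) for b in genes_b] for a in genes_a])
            return SimilarityMatrix(tuple(genes_a), tuple(genes_b), values,
                                    sim.provenance)
        return cls(config, provider, tuple(sorted(gene_pool)))


def cluster_local_score(cluster_nodes: frozenset[str],
                        sim: SimilarityMatrix) -> ClusterScore:
    """Best-match-average similarity between a cluster's two origin sides.

    Single-origin clusters score 0 by definition.
    """
    q_genes = sorted(untag(n)[1] for n in cluster_nodes if n.startswith("Q:"))
    r_genes = sorted(untag(n)[1] for n in cluster_nodes if n.startswith("R:"))
    mixed = bool(q_genes) and bool(r_genes)
    if not mixed:
        return ClusterScore(-1, 0.0, False)
    m = np.array([[sim.lookup(qa, rb) for rb in r_genes] for qa in q_genes])
    local = float((m.max(axis=1).mean() + m.max(axis=0).mean()) / 2.0)
    return ClusterScore(-1, local, True)


def raw_network_similarity(mapping: NodeMapping, sim: SimilarityMatrix) -> float:
    """Unweighted mean of cluster-local scores over all clusters."""
    if not mapping.clusters:
        raise ParameterError("empty node mapping")
    scores = [cluster_local_score(c.members, sim).local_similarity
              for c in mapping.clusters]
    return float(np.mean(scores))


def map_and_score(q: GeneNetwork, ref: GeneNetwork,
                  ctx: PipelineContext) -> tuple[float, NodeMapping, SimilarityMatrix]:
    """One full pipeline pass: similarity -> merge -> cluster -> score."""
    cfg = ctx.config
    q_genes = sorted(q.nodes)
    r_genes = sorted(ref.nodes)
    union = sorted(set(q_genes) | set(r_genes))
    # one square matrix over the union serves cross- and same-origin lookups
    sim = ctx.sim_provider(union, union)
    if cfg.algorithm == "greedy":
        mapping = greedy_align(q, ref, sim, cfg.min_sim)
    elif cfg.algorithm == "external":
        mapping = run_external_aligner(cfg.external_cmd, q, ref)
    else:
        mg = merge_networks(q, ref, sim, cfg.tau)
        A = build_affinity(mg, sim, cfg.w_topo, cfg.preference)
        mapping = affinity_propagation(A, cfg.damping, cfg.max_iter,
                                       cfg.convergence_window)
    raw = raw_network_similarity(mapping, sim)
    return raw, mapping, sim


def randomize_query(q: GeneNetwork, gene_pool: Sequence[str],
                    seed: int) -> GeneNetwork:
    """Topology-preserving label permutation: an isomorphic copy of `q`
    whose labels are a uniform without-replacement sample from `gene_pool`."""
    pool = sorted(set(gene_pool))
    if len(pool) < q.n_nodes:
        raise ParameterError(
            f"gene pool ({len(pool)}) smaller than query node count ({q.n_nodes})")
    rng = np.random.default_rng(seed)
    picks = rng.choice(len(pool), size=q.n_nodes, replace=False)
    mapping = {old: pool[i] for old, i in zip(sorted(q.nodes), picks)}
    return q.relabel(mapping, new_id=f"{q.id}-perm{seed}")


def normalize_z(raw: float, null_scores: Sequence[float]) -> tuple[float, float, float]:
    """(null mean, null sample sd, clipped z) for a raw score against its null."""
    null = np.asarray(null_scores, dtype=float)
    mean = float(null.mean())
    sd = float(null.std(ddof=1))
    z = float(np.clip((raw - mean) / max(sd, EPS_SD), -Z_CLIP, Z_CLIP))
    return mean, sd, z


def permutation_zscore(q: GeneNetwork, ref: ReferencePathway | GeneNetwork,
                       ctx: PipelineContext, n_perm: int | None = None,
                       seed: int = 0) -> SimilarityResult:
    """Raw score plus permutation-null normalization for one reference."""
    ref_net = ref.network if isinstance(ref, ReferencePathway) else ref
    n_perm = ctx.config.n_perm if n_perm is None else n_perm
    if n_perm < 2:
        raise ParameterError("n_perm must be >= 2")
    raw, _, _ = map_and_score(q, ref_net, ctx)
    null_scores = np.empty(n_perm)
    for i in range(n_perm):
        perm_seed = (seed * 10007 + i) % _SEED_MOD
        try:
            q_perm = randomize_query(q, ctx.gene_pool, perm_seed)
            null_scores[i], _, _ = map_and_score(q_perm, ref_net, ctx)
        except Exception as exc:
            raise type(exc)(f"permutation {i}: {exc}") from exc
    mean, sd, z = normalize_z(raw, null_scores)
    return SimilarityResult(ref_net.id, raw, mean, sd, z, n_perm, seed)


def fingerprint_scan(q: GeneNetwork, refs: ReferenceSet, ctx: PipelineContext,
                     seed: int = 0) -> Fingerprint:
    """Scan a query against every reference pathway, in reference order.

    Each reference gets an independent derived seed (master seed + index), so
    results are identical whatever the evaluation order. A failing reference
    is recorded with an error flag and the scan continues.
    """
    if len(refs) == 0:
        raise ParameterError("reference set is empty")
    results = []
    for idx, ref in enumerate(refs.pathways):
        ref_seed = (seed + idx) % _SEED_MOD
        try:
            res = permutation_zscore(q, ref, ctx, seed=ref_seed)
        except Exception as exc:
            logger.warning("reference %s failed: %s", ref.id, exc)
            res = SimilarityResult(ref.id, float("nan"), float("nan"),
                                   float("nan"), 0.0, 0, ref_seed, error=str(exc))
        logger.info("scanned %s against %s: z=%.3f", q.id, ref.id, res.z)
        results.append(res)
    return Fingerprint(q.id, refs.id, tuple(results),
                       config=ctx.config.snapshot())


def fingerprint_diff(f1: Fingerprint, f2: Fingerprint) -> list[dict]:
    """Side-by-side comparison of two fingerprints over the same references.

    Returns one record per reference with z1, z2 and dz = z1 - z2, ranked by
    |dz| descending (ties by reference id).
    """
    ids1 = [r.ref_id for r in f1.results]
    ids2 = [r.ref_id for r in f2.results]
    if f1.reference_set_id != f2.reference_set_id or ids1 != ids2:
        raise ParameterError("fingerprints use different reference sets")
    rows = [{"ref_id": r1.ref_id, "z1": r1.z, "z2": r2.z, "dz": r1.z - r2.z}
            for r1, r2 in zip(f1.results, f2.results)]
    rows.sort(key=lambda r: (-abs(r["dz"]), r["ref_id"]))
    return rows


# ---------------------------------------------------------------------------
# serialization


def fingerprint_to_json(fp: Fingerprint) -> str:
    """Canonical JSON (sorted keys, fixed separators): byte-identical for
    identical runs."""
    payload = {
        "query_id": fp.query_id,
        "reference_set_id": fp.reference_set_id,
        "config": fp.config,
        "results": [
            {"ref_id": r.ref_id, "raw": r.raw, "null_mean": r.null_mean,
             "null_sd": r.null_sd, "z": r.z, "n_perm": r.n_perm,
             "seed": r.seed, "error": r.error}
            for r in fp.results
        ],
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":"),
                      allow_nan=True) + "\n"


def fingerprint_from_json(text: str) -> Fingerprint:
    payload = json.loads(text)
    results = tuple(
        SimilarityResult(r["ref_id"], r["raw"], r["null_mean"], r["null_sd"],
                         r["z"], r["n_perm"], r["seed"], r.get("error"))
        for r in payload["results"])
    return Fingerprint(payload["query_id"], payload["reference_set_id"],
                       results, payload.get("config", {}))


def fingerprint_to_tsv(fp: Fingerprint, refs: ReferenceSet | None = None) -> str:
    categories = {p.id: p.category for p in refs.pathways} if refs else {}
    lines = ["ref_id\tcategory\traw\tz"]
    for r in fp.results:
        lines.append(f"{r.ref_id}\t{categories.get(r.ref_id, 'NA')}"
                     f"\t{r.raw:.6f}\t{r.z:.6f}")
    return "\n".join(lines) + "\n"


def save_fingerprint(fp: Fingerprint, path: str | Path,
                     refs: ReferenceSet | None = None) -> None:
    path = Path(path)
    if path.suffix == ".tsv":
        path.write_text(fingerprint_to_tsv(fp, refs))
    else:
        path.write_text(fingerprint_to_json(fp))
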