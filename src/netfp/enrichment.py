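"""Hypergeometric over-representation analysis with BH correction.

Given a query gene set, a collection of named gene sets (pathways or ontology
terms) and a gene universe, each set is scored with the upper-tail
hypergeometric probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

where N is the universe size, K the set size, n the query size and k the
overlap — computed by exact tail summation in log space, so small p-values
keep full relative precision. P-values are adjusted across all tested sets by
Benjamini-Hochberg step-up (Bonferroni available); the adjusted threshold also
drives the reference-labeling step used in the validation harness (a reference
pathway is "positive" for a query iff its adjusted p < alpha).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .exceptions import FormatError, ParameterError
from .graphio import GeneNetwork
from .refdb import ReferenceSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    set_id: str
    k: int          # overlap of query with the set (within the universe)
    K: int          # set size within the universe
    n: int          # query size within the universe
    N: int          # universe size
    p_value: float
    adj_p: float


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def hypergeometric_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) by log-space summation over the support."""
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(k, K, n, N) < 0:
        raise ParameterError(
            f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    hi = min(K, n)
    log_denom = _log_binom(N, n)
    log_terms = [
        _log_binom(K, i) + _log_binom(N - K, n - i) - log_denom
        for i in range(k, hi + 1)
        if n - i <= N - K
    ]
    if not log_terms:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def bh_adjust(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out.tolist()


def bonferroni_adjust(pvalues: Sequence[float]) -> list[float]:
    p = np.asarray(pvalues, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    return np.minimum(p * p.size, 1.0).tolist()


_ADJUSTERS = {"bh": bh_adjust, "bonferroni": bonferroni_adjust}


def enrich_gene_set(query_genes: Sequence[str] | set[str],
                    collection: Mapping[str, Sequence[str] | set[str]],
                    universe: Sequence[str] | set[str],
                    method: str = "bh") -> list[EnrichmentRow]:
    """Over-representation of each collection set in the query.

    Query and sets are intersected with the universe before testing; only
    sets overlapping the query (k >= 1) are tested and adjusted. Rows come
    back sorted by adjusted p, then raw p, then set id.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ParameterError("empty universe")
    if method not in _ADJUSTERS:
        raise ParameterError(f"unknown adjustment method: {method!r}")
    query = set(query_genes) & universe_set
    N, n = len(universe_set), len(query)
    tested: list[tuple[str, int, int]] = []
    for set_id in sorted(collection):
        members = set(collection[set_id]) & universe_set
        k = len(query & members)
        if k >= 1:
            tested.append((set_id, k, len(members)))
    if not tested:
        return []
    pvals = [hypergeometric_pvalue(k, K, n, N) for _, k, K in tested]
    adjusted = _ADJUSTERS[method](pvals)
    rows = [EnrichmentRow(set_id, k, K, n, N, p, q)
            for (set_id, k, K), p, q in zip(tested, pvals, adjusted)]
    rows.sort(key=lambda r: (r.adj_p, r.p_value, r.set_id))
    return rows


def label_references_by_enrichment(q: GeneNetwork, refs: ReferenceSet,
                                   universe: Sequence[str] | set[str],
                                   alpha: float = 0.05) -> dict[str, bool]:
    """Binary enrichment labels for each reference pathway.

    Each reference's node set is treated as a gene set; a reference is
    positive iff its BH-adjusted p-value < alpha. References with no query
    overlap (k = 0) are negative.
    """
    collection = {p.id: set(p.network.nodes) for p in refs.pathways}
    rows = enrich_gene_set(set(q.nodes), collection, universe)
    adj = {r.set_id: r.adj_p for r in rows}
    return {p.id: adj.get(p.id, 1.0) < alpha for p in refs.pathways}


# ---------------------------------------------------------------------------
# GMT gene-set collections


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"GMT file not found: {path}")
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        tokens = line.rstrip("\n").split("\t")
        if len(tokens) < 3:
            raise FormatError(f"{path}:{lineno}: GMT lines need >= 3 columns")
        if tokens[0] in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {tokens[0]!r}")
        sets[tokens[0]] = {g for g in tokens[2:] if g}
    return sets


def enrichment_to_tsv(rows: Sequence[EnrichmentRow]) -> str:
    lines = ["set_id\tk\tK\tn\tN\tp_value\tadj_p"]
    for r in rows:
        lines.append(f"{r.set_id}\t{r.k}\t{r.K}\t{r.n}\t{r.N}"
                     f"\t{r.p_value:.6g}\t{r.adj_p:.6g}")
    return "\n".join(lines) + "\n"
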