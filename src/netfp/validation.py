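"""Enrichment-anchored validation of fingerprint scores.

The accuracy question is framed as binary classification: for each query, the
reference pathways are labeled positive/negative by over-representation of
the query's genes (adjusted p < alpha), and the fingerprint Z-scores are
treated as prediction scores for those labels. Agreement is summarized per
query by the ROC curve and its AUC, computed through the Mann-Whitney
identity (tied scores credited 0.5), and across queries by the unweighted
mean AUC. The Z-score (not the raw similarity) is the predictor; a flag
switches to raw for ablation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .enrichment import label_references_by_enrichment
from .exceptions import ParameterError
from .graphio import GeneNetwork
from .refdb import ReferenceSet
from .scoring import Fingerprint, PipelineContext, fingerprint_scan

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RocResult:
    auc: float
    n_pos: int
    n_neg: int
    fpr: tuple[float, ...]
    tpr: tuple[float, ...]


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocResult:
    """ROC curve and AUC for real-valued scores against boolean labels.

    AUC is U / (n_pos * n_neg) from the rank-sum statistic, which credits
    tied positive-negative pairs 0.5. Curve points come from thresholding at
    every distinct score, descending, bracketed by (0,0) and (1,1).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ParameterError("scores and labels must have equal length")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ParameterError("AUC undefined: both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties -> 0.5 credit
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    auc = float(u / (n_pos * n_neg))
    fpr, tpr = [0.0], [0.0]
    for thr in sorted(set(s.tolist()), reverse=True):
        predicted = s >= thr
        tpr.append(float((predicted & y).sum() / n_pos))
        fpr.append(float((predicted & ~y).sum() / n_neg))
    if fpr[-1] != 1.0 or tpr[-1] != 1.0:
        fpr.append(1.0)
        tpr.append(1.0)
    return RocResult(auc, n_pos, n_neg, tuple(fpr), tuple(tpr))


@dataclass(frozen=True)
class BenchmarkResult:
    per_query: dict[str, RocResult]
    skipped: tuple[str, ...]
    mean_auc: float
    fingerprints: tuple[Fingerprint, ...]


def benchmark_fingerprint_vs_enrichment(
    queries: Sequence[GeneNetwork],
    refs: ReferenceSet,
    universe: Sequence[str] | set[str],
    ctx: PipelineContext,
    seed: int = 0,
    alpha: float = 0.05,
    use_raw: bool = False,
) -> BenchmarkResult:
    """Fingerprint-vs-enrichment agreement over a batch of queries.

    Per query: enrichment labels over `refs`, fingerprint scan (seed offset
    by 1000 * query index so queries are independent), ROC/AUC. Queries whose
    labels are single-class are skipped with a warning. The summary is the
    unweighted mean AUC over evaluable queries.
    """
    if not queries:
        raise ParameterError("no queries supplied")
    per_query: dict[str, RocResult] = {}
    skipped: list[str] = []
    fingerprints: list[Fingerprint] = []
    for qi, q in enumerate(queries):
        labels = label_references_by_enrichment(q, refs, universe, alpha=alpha)
        label_vec = [labels[p.id] for p in refs.pathways]
        if all(label_vec) or not any(label_vec):
            logger.warning("query %s: single-class labels; skipped", q.id)
            skipped.append(q.id)
            continue
        fp = fingerprint_scan(q, refs, ctx, seed=(seed + 1000 * qi) % 2**31)
        fingerprints.append(fp)
        scores = [r.raw if use_raw else r.z for r in fp.results]
        per_query[q.id] = roc_auc(scores, label_vec)
    if not per_query:
        raise ParameterError("no evaluable query: every query had single-class labels")
    mean_auc = float(np.mean([r.auc for r in per_query.values()]))
    return BenchmarkResult(per_query, tuple(skipped), mean_auc, tuple(fingerprints))


def benchmark_to_tsv(result: BenchmarkResult) -> str:
    lines = ["query_id\tn_pos\tn_neg\tauc"]
    for qid, r in result.per_query.items():
        lines.append(f"{qid}\t{r.n_pos}\t{r.n_neg}\t{r.auc:.4f}")
    lines.append(f"# mean AUC over {len(result.per_query)} queries: "
                 f"{result.mean_auc:.4f}")
    return "\n".join(lines) + "\n"
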