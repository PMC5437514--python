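"""Ontology DAG, gene annotations, and gene-gene semantic similarity.

The attribute-similarity layer of the fingerprint pipeline: edge weights
between networks come from how similar their genes are, measured here over a
GO-style is_a DAG. Information content (IC) of a term is computed from the
supplied annotation corpus itself, with annotations propagated to ancestors:

    IC(t) = -ln( |genes annotated to t or any descendant| / |universe| )

Term-term similarity is Lin's measure, sim(t1,t2) = 2 IC(MICA) / (IC(t1)+IC(t2)),
where MICA is the common ancestor (including the terms themselves) of maximal
IC. Gene-gene similarity aggregates term pairs by best-match average (BMA):
the mean of row-wise and column-wise maxima of the term-pair Lin matrix.
Lin + BMA is bounded in [0,1] and is the standard pairing for gene-level GO
similarity; the scorer interface is pluggable should other measures be needed.

Only is_a edges are used. Unannotated genes get similarity 0 (logged once per
gene) rather than being dropped, preserving network topology downstream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .exceptions import DataError, FormatError, UndefinedICError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Ontology:
    """An is_a DAG of term IDs. `parents` maps term -> set of parents."""

    terms: frozenset[str]
    parents: Mapping[str, frozenset[str]]

    @property
    def roots(self) -> frozenset[str]:
        return frozenset(t for t in self.terms if not self.parents.get(t))

    def ancestors(self, term: str) -> frozenset[str]:
        """All ancestors of `term` including itself."""
        out = {term}
        stack = [term]
        while stack:
            for p in self.parents.get(stack.pop(), ()):
                if p not in out:
                    out.add(p)
                    stack.append(p)
        return frozenset(out)


@dataclass(frozen=True)
class AnnotationMap:
    """gene -> set of directly annotated term IDs; universe = annotated genes."""

    gene_terms: Mapping[str, frozenset[str]]

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(g for g, ts in self.gene_terms.items() if ts)

    def terms_for(self, gene: str) -> frozenset[str]:
        return self.gene_terms.get(gene, frozenset())


@dataclass(frozen=True)
class SimilarityMatrix:
    """Dense gene x gene attribute similarity in [0,1].

    `lookup` is orientation-tolerant: it tries (row, col) then (col, row) and
    returns `default` for absent pairs, so a matrix built over the union of two
    networks' genes serves both cross-network and within-network queries.
    """

    genes_a: tuple[str, ...]
    genes_b: tuple[str, ...]
    values: np.ndarray
    provenance: str  # "go" | "precomputed"
    _ia: Mapping[str, int] = field(repr=False, default=None)
    _ib: Mapping[str, int] = field(repr=False, default=None)

    def __post_init__(self):
        if self.values.shape != (len(self.genes_a), len(self.genes_b)):
            raise ValueError("similarity matrix shape mismatch")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("similarity values must lie in [0,1]")
        object.__setattr__(self, "_ia", {g: i for i, g in enumerate(self.genes_a)})
        object.__setattr__(self, "_ib", {g: i for i, g in enumerate(self.genes_b)})

    def get(self, ga: str, gb: str) -> float:
        return float(self.values[self._ia[ga], self._ib[gb]])

    def lookup(self, g1: str, g2: str, default: float = 0.0) -> float:
        if g1 in self._ia and g2 in self._ib:
            return float(self.values[self._ia[g1], self._ib[g2]])
        if g2 in self._ia and g1 in self._ib:
            return float(self.values[self._ia[g2], self._ib[g1]])
        return default


# ---------------------------------------------------------------------------
# loading


def _check_dag(parents: dict[str, set[str]], terms: set[str]) -> None:
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    for child, ps in parents.items():
        for p in ps:
            if p not in terms:
                raise DataError(f"dangling parent term: {p} (child {child})")
            g.add_edge(child, p)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        path = " -> ".join(a for a, _ in cycle) + f" -> {cycle[-1][1]}"
        raise DataError(f"ontology contains a cycle: {path}")


def _parse_obo(text: str) -> tuple[set[str], dict[str, set[str]]]:
    terms: set[str] = set()
    parents: dict[str, set[str]] = {}
    current: str | None = None
    in_term = False
    obsolete = False
    pending: dict[str, set[str]] = {}

    def flush():
        nonlocal current, obsolete
        if current is not None and not obsolete:
            terms.add(current)
            parents[current] = pending.get(current, set())
        current, obsolete = None, False

    for line in text.splitlines():
        line = line.strip()
        if line == "[Term]":
            flush()
            in_term = True
        elif line.startswith("["):
            flush()
            in_term = False
        elif in_term and line.startswith("id:"):
            current = line[3:].strip()
        elif in_term and line.startswith("is_a:") and current:
            target = line[5:].split("!")[0].strip()
            pending.setdefault(current, set()).add(target)
        elif in_term and line.startswith("is_obsolete:") and "true" in line:
            obsolete = True
    flush()
    # drop is_a links that point at obsolete (hence missing) terms
    for t in parents:
        parents[t] = {p for p in parents[t] if p in terms}
    return terms, parents


def load_ontology(path: str | Path) -> Ontology:
    """Load an ontology from an OBO subset or a two-column child-parent TSV.

    OBO is detected by the presence of a ``[Term]`` stanza. Obsolete terms are
    skipped. Raises :class:`DataError` on cycles or dangling parents.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"ontology file not found: {path}")
    text = path.read_text()
    if "[Term]" in text:
        terms, parents = _parse_obo(text)
    else:
        terms, parents = set(), {}
        for lineno, line in enumerate(text.splitlines(), start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'child parent'")
            child, parent = tokens[0], tokens[1]
            terms.update((child, parent))
            parents.setdefault(child, set()).add(parent)
    if not terms:
        raise FormatError(f"{path}: no terms found")
    for t in terms:
        parents.setdefault(t, set())
    _check_dag(parents, terms)
    return Ontology(frozenset(terms),
                    {t: frozenset(ps) for t, ps in parents.items()})


def load_annotations(path: str | Path, ontology: Ontology | None = None) -> AnnotationMap:
    """Load a two-column (gene, term) TSV into an :class:`AnnotationMap`.

    If an ontology is given, annotations to unknown terms raise DataError.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"annotation file not found: {path}")
    gene_terms: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'gene term'")
        gene, term = tokens[0], tokens[1]
        if ontology is not None and term not in ontology.terms:
            raise DataError(f"{path}:{lineno}: term {term} not in ontology")
        gene_terms.setdefault(gene, set()).add(term)
    return AnnotationMap({g: frozenset(ts) for g, ts in gene_terms.items()})


# ---------------------------------------------------------------------------
# similarity scorer


class GoSimilarity:
    """Memoizing Lin/BMA scorer bound to one (annotations, ontology) corpus.

    Precomputes propagated term->gene counts for IC and caches term-pair and
    gene-pair similarities, so that repeated queries during permutation scans
    cost one dictionary lookup.
    """

    def __init__(self, annot: AnnotationMap, ontology: Ontology):
        self.annot = annot
        self.ontology = ontology
        self._anc: dict[str, frozenset[str]] = {}
        self._term_count: dict[str, int] = {}
        universe = annot.universe
        self.n_universe = len(universe)
        for gene in universe:
            covered: set[str] = set()
            for t in annot.terms_for(gene):
                covered |= self.ancestors(t)
            for t in covered:
                self._term_count[t] = self._term_count.get(t, 0) + 1
        self._ic: dict[str, float] = {}
        self._tsim: dict[tuple[str, str], float] = {}
        self._gsim: dict[tuple[str, str], float] = {}
        self._warned_unannotated: set[str] = set()

    def ancestors(self, term: str) -> frozenset[str]:
        a = self._anc.get(term)
        if a is None:
            a = self.ontology.ancestors(term)
            self._anc[term] = a
        return a

    def term_ic(self, term: str) -> float:
        ic = self._ic.get(term)
        if ic is None:
            if term not in self.ontology.terms:
                raise DataError(f"term not in ontology: {term}")
            count = self._term_count.get(term, 0)
            if count == 0 or self.n_universe == 0:
                raise UndefinedICError(
                    f"term {term} annotates no genes (even via descendants)"
                )
            ic = -math.log(count / self.n_universe)
            self._ic[term] = ic
        return ic

    def term_sim(self, t1: str, t2: str) -> float:
        key = (t1, t2) if t1 <= t2 else (t2, t1)
        s = self._tsim.get(key)
        if s is None:
            ic1, ic2 = self.term_ic(t1), self.term_ic(t2)
            common = self.ancestors(t1) & self.ancestors(t2)
            if not common or ic1 + ic2 == 0:
                s = 0.0
            else:
                mica_ic = max(self.term_ic(t) for t in common)
                s = 2.0 * mica_ic / (ic1 + ic2)
            self._tsim[key] = s
        return s

    def gene_sim(self, g1: str, g2: str) -> float:
        key = (g1, g2) if g1 <= g2 else (g2, g1)
        s = self._gsim.get(key)
        if s is None:
            s = self._gene_sim_uncached(g1, g2)
            self._gsim[key] = s
        return s

    def _gene_sim_uncached(self, g1: str, g2: str) -> float:
        ts1 = sorted(self.annot.terms_for(g1))
        ts2 = sorted(self.annot.terms_for(g2))
        for g, ts in ((g1, ts1), (g2, ts2)):
            if not ts and g not in self._warned_unannotated:
                self._warned_unannotated.add(g)
                logger.debug("gene %s has no annotations; similarity 0", g)
        if not ts1 or not ts2:
            return 0.0
        m = np.array([[self.term_sim(a, b) for b in ts2] for a in ts1])
        return float((m.max(axis=1).mean() + m.max(axis=0).mean()) / 2.0)

    def matrix(self, genes_a: Sequence[str], genes_b: Sequence[str]) -> SimilarityMatrix:
        values = np.empty((len(genes_a), len(genes_b)))
        for i, ga in enumerate(genes_a):
            for j, gb in enumerate(genes_b):
                values[i, j] = self.gene_sim(ga, gb)
        return SimilarityMatrix(tuple(genes_a), tuple(genes_b), values, "go")


# Functional wrappers; each builds a throwaway scorer, so prefer an explicit
# GoSimilarity instance inside loops.

def term_ic(term: str, annot: AnnotationMap, ontology: Ontology) -> float:
    return GoSimilarity(annot, ontology).term_ic(term)


def lin_term_sim(t1: str, t2: str, annot: AnnotationMap, ontology: Ontology) -> float:
    return GoSimilarity(annot, ontology).term_sim(t1, t2)


def gene_sim_bma(g1: str, g2: str, annot: AnnotationMap, ontology: Ontology) -> float:
    return GoSimilarity(annot, ontology).gene_sim(g1, g2)


def build_similarity_matrix(
    genes_a: Sequence[str],
    genes_b: Sequence[str],
    annot: AnnotationMap,
    ontology: Ontology,
    scorer: GoSimilarity | None = None,
) -> SimilarityMatrix:
    """GO-derived similarity matrix for two gene lists (memoized per scorer)."""
    scorer = scorer or GoSimilarity(annot, ontology)
    return scorer.matrix(genes_a, genes_b)


def load_precomputed_matrix(
    path: str | Path,
    genes_a: Sequence[str],
    genes_b: Sequence[str],
) -> SimilarityMatrix:
    """Load a three-column (gene_a, gene_b, value) TSV as a SimilarityMatrix.

    Pairs absent from the file default to 0.0 (a single summary warning
    reports how many). Values outside [0,1] are a :class:`DataError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"similarity file not found: {path}")
    pairs: dict[tuple[str, str], float] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) < 3:
            raise FormatError(f"{path}:{lineno}: expected 'gene_a gene_b value'")
        try:
            value = float(tokens[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value {tokens[2]!r}") from exc
        if not 0.0 <= value <= 1.0:
            raise DataError(f"{path}:{lineno}: value {value} outside [0,1]")
        pairs[(tokens[0], tokens[1])] = value
    values = np.zeros((len(genes_a), len(genes_b)))
    n_missing = 0
    for i, ga in enumerate(genes_a):
        for j, gb in enumerate(genes_b):
            v = pairs.get((ga, gb))
            if v is None:
                v = pairs.get((gb, ga))
            if v is None:
                n_missing += 1
                v = 0.0
            values[i, j] = v
    if n_missing:
        logger.warning("%s: %d gene pair(s) missing; defaulted to 0.0", path, n_missing)
    return SimilarityMatrix(tuple(genes_a), tuple(genes_b), values, "precomputed")
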