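import pytest

from netfp.graphio import build_network
from netfp.ontology import AnnotationMap, Ontology
from netfp.refdb import ReferencePathway, ReferenceSet


@pytest.fixture
def tiny_ontology():
    """root t1; children t2, t3; t4 below t2."""
    return Ontology(
        frozenset({"t1", "t2", "t3", "t4"}),
        {"t1": frozenset(), "t2": frozenset({"t1"}), "t3": frozenset({"t1"}),
         "t4": frozenset({"t2"})},
    )


@pytest.fixture
def tiny_annotations():
    """10-gene universe: t4 covers 1 gene, t2 covers 5 (via t4), t3 covers 5,
    the root covers all 10 through propagation."""
    gene_terms = {"g1": {"t4"}}
    for i in range(2, 6):
        gene_terms[f"g{i}"] = {"t2"}
    for i in range(6, 11):
        gene_terms[f"g{i}"] = {"t3"}
    return AnnotationMap({g: frozenset(ts) for g, ts in gene_terms.items()})


@pytest.fixture
def triangle_net():
    return build_network("tri", [("a", "b"), ("b", "c"), ("a", "c")])


def make_ref(id, edges, source="test", category="cat"):
    return ReferencePathway(build_network(id, edges), source=source,
                            category=category)


def path_edges(id, n_edges):
    """A simple path pathway with exactly n_edges edges."""
    return [(f"{id}n{i}", f"{id}n{i+1}") for i in range(n_edges)]


@pytest.fixture
def small_refset():
    return ReferenceSet("rs", (
        make_ref("p9", path_edges("a", 9)),
        make_ref("p10", path_edges("b", 10)),
        make_ref("p11", path_edges("c", 11)),
    ))
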