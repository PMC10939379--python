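import math

import pytest

from semnetphylo.ontology import OntologyGraph, compute_metrics
from semnetphylo.pipeline import PipelineParams, run_pipeline
from semnetphylo.synth import SynthConfig, generate_dag, generate_kingdom_corpus


def sw(ic: float) -> float:
    """Reference logistic weight, written out independently."""
    return 1.0 if ic == 0 else 1.0 / (1.0 + math.exp(-1.0 / ic))


@pytest.fixture
def diamond():
    """root -> {A, B}, A -> C, B -> C; N=4.

    Hand-derived: IC(root)=0, IC(A)=IC(B)=1, IC(C)=2;
    SV(A)=SV(B)=1, SV(C)=1+2*sw(1).
    """
    g = OntologyGraph.from_edges(
        ["root", "A", "B", "C"],
        [("A", "root"), ("B", "root"), ("C", "A"), ("C", "B")],
    )
    return g, compute_metrics(g)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted corpus (12 species) shared across integration tests."""
    cfg = SynthConfig(seed=11, n_species_per_kingdom=4)
    g = generate_dag(cfg)
    return cfg, g, generate_kingdom_corpus(cfg, g)


def module_branch_terms(pc, res):
    """All retained terms of the branches hosting the planted modules.

    The planted kingdom signal is confined to these ontology regions, so
    excluding them from profiles removes the signal by construction.
    """
    g = pc.graph
    std = res.standardization.std
    module_terms = set(pc.core_terms)
    for ts in pc.kingdom_terms.values():
        module_terms |= ts
    anchors = set()
    for t in module_terms:
        anchors |= g.ancestors(t) & g.children(g.root)
    out = set()
    for a in anchors:
        out |= {u for u in std.retained if u == a or a in g.ancestors(u)}
    return frozenset(out)


@pytest.fixture(scope="session")
def small_pipeline(small_planted):
    """Full pipeline result on the small planted corpus."""
    cfg, g, pc = small_planted
    params = PipelineParams(permutations=100, seed=11)
    res = run_pipeline(g, pc.corpus, pc.gene_sets, params, truth=pc.truth)
    return pc, params, res
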