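"""End-to-end orchestration: corpus -> profiles -> distances -> tree -> components.

Thin glue over the library modules, shared by the command-line
interface and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import components as comp
from .corpus import AnnotationCorpus, SpeciesGeneSet, propagate
from .enrichment import (
    SemanticProfile,
    build_profile,
    hypergeometric_test,
    permutation_prioritize,
    update_profile,
)
from .ontology import (
    OntologyGraph,
    StandardizedGraph,
    TermMetrics,
    build_standardized_graph,
    compute_metrics,
)
from .phylo import ClusterLabels, Dendrogram, cut_clusters, evaluate_clustering, ward_tree
from .semantic_compare import (
    DistanceMatrix,
    SimilarityMatrix,
    build_distance_matrix,
    build_similarity_matrix,
)

__all__ = ["PipelineParams", "PipelineResult", "standardize", "enrich_species", "run_pipeline"]


@dataclass
class PipelineParams:
    """All tunable thresholds, at their reference defaults."""

    percentile: float = 20.0
    p_cut: float = 0.05
    adj_cut: float = 0.05
    floor: int = 100
    ic_min: float = 0.1
    permutations: int = 1000
    core_frac: float = 0.90
    generic_frac: float = 0.50
    coverage_frac: float = 0.75
    nmf_k: int = 3
    n_clusters: int = 3
    seed: int = 0


@dataclass
class Standardization:
    graph: OntologyGraph
    metrics: TermMetrics
    std: StandardizedGraph
    std_graph: OntologyGraph
    std_metrics: TermMetrics
    similarity: SimilarityMatrix


@dataclass
class PipelineResult:
    standardization: Standardization
    profiles: list[SemanticProfile]
    distance: DistanceMatrix
    tree: Dendrogram
    labels: ClusterLabels
    hs: float | None = None
    ss: float | None = None
    component_sets: dict[str, comp.ComponentTermSet] = field(default_factory=dict)
    association: comp.AssociationMatrix | None = None
    decomposition: comp.Decomposition | None = None


def standardize(g: OntologyGraph, params: PipelineParams, universe=None) -> Standardization:
    """Metrics, pruning and the global similarity matrix in one step."""
    m = compute_metrics(g, universe=universe)
    sg = build_standardized_graph(g, m, pct=params.percentile)
    std_graph = sg.subgraph()
    std_metrics = compute_metrics(std_graph)
    S = build_similarity_matrix(std_graph, std_metrics, metric="consensus")
    return Standardization(
        graph=g, metrics=m, std=sg, std_graph=std_graph, std_metrics=std_metrics,
        similarity=S,
    )


def enrich_species(
    query: SpeciesGeneSet,
    corpus: AnnotationCorpus,
    std: Standardization,
    params: PipelineParams,
    seed: int,
) -> SemanticProfile:
    """Full prioritized enrichment for one species, mapped and IC-filtered."""
    records = hypergeometric_test(query, corpus)
    records = permutation_prioritize(
        records, corpus, query.species, R=params.permutations, seed=seed
    )
    profile = build_profile(
        records, query.species,
        p_cut=params.p_cut, adj_cut=params.adj_cut, floor=params.floor,
    )
    return update_profile(profile, std.std, std.std_metrics, ic_min=params.ic_min)


def run_pipeline(
    g: OntologyGraph,
    corpus: AnnotationCorpus,
    gene_sets: Mapping[str, SpeciesGeneSet],
    params: PipelineParams,
    truth: Mapping[str, str] | None = None,
    with_components: bool = True,
    do_propagate: bool = True,
) -> PipelineResult:
    """The complete comparative analysis for a ready-made corpus."""
    if do_propagate:
        corpus = propagate(corpus, g)
    std = standardize(g, params)
    rng = np.random.default_rng(params.seed)
    profiles = [
        enrich_species(gene_sets[sp], corpus, std, params, seed=int(rng.integers(2**31)))
        for sp in sorted(gene_sets)
    ]
    d = build_distance_matrix(profiles, std.similarity)
    tree = ward_tree(d)
    labels = cut_clusters(tree, k=min(params.n_clusters, len(profiles)))
    hs = ss = None
    if truth is not None:
        hs, ss = evaluate_clustering(labels, {s: truth[s] for s in d.ids}, d)
    result = PipelineResult(
        standardization=std, profiles=profiles, distance=d, tree=tree,
        labels=labels, hs=hs, ss=ss,
    )
    if with_components:
        by_kingdom: dict[str, list[SemanticProfile]] = {}
        if truth is not None:
            for p in profiles:
                by_kingdom.setdefault(str(truth[p.species]), []).append(p)
        else:
            by_kingdom["all"] = list(profiles)
        result.component_sets = comp.select_components(
            by_kingdom, std.std_graph,
            core_frac=params.core_frac, generic_frac=params.generic_frac,
        )
        all_terms: set[str] = set()
        for cs in result.component_sets.values():
            all_terms |= cs.terms
        if all_terms:
            result.association = comp.build_association_matrix(all_terms, profiles, g)
            if np.any(result.association.matrix):
                result.decomposition = comp.nmf_decompose(
                    result.association, k=params.nmf_k, seed=params.seed
                )
    return result


def component_union(result: PipelineResult) -> frozenset[str]:
    """Union of component terms over kingdoms (the PN-component set)."""
    out: set[str] = set()
    for cs in result.component_sets.values():
        out |= cs.terms
    return frozenset(out)
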