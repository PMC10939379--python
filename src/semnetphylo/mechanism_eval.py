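"""Evaluation of ontology-defined mechanisms as evolutionary markers.

Feeding a mechanism's full annotation into enrichment would trivially
re-discover the term and its ancestral path.  To compare mechanisms on
equal footing with the reference (proteostasis) analysis, the gene-set
size is calibrated first: a binary search finds the largest random
subset whose most extreme hypergeometric p-value stays within the order
of magnitude of the reference analysis' typical extremes; repeating the
search 30 times gives a sizing distribution that absorbs sampling
noise.  Consensus profiles are then built from repeated draws, keeping
terms enriched in more than 20% of the outputs, and the contribution of
the proteostasis components is measured by re-running the comparative
analysis with those component terms excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .corpus import AnnotationCorpus, SpeciesGeneSet
from .enrichment import (
    EnrichmentError,
    EnrichmentRecord,
    SemanticProfile,
    build_profile,
    hypergeometric_test,
    permutation_prioritize,
)
from .phylo import cut_clusters, evaluate_clustering, ward_tree
from .semantic_compare import SimilarityMatrix, build_distance_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "SizingDistribution",
    "MechanismProfile",
    "pn_target_magnitude",
    "optimal_subset_size",
    "estimate_sizing",
    "build_mechanism_profile",
    "pn_exclusion_eval",
    "ExclusionResult",
]

MIN_SUBSET = 10


@dataclass
class SizingDistribution:
    term: str
    species: str
    sizes: list[int]
    target: float

    @property
    def mean(self) -> float:
        return float(np.mean(self.sizes))


@dataclass
class MechanismProfile:
    species: str
    mechanism: str
    frequencies: dict[str, float]  # term -> inclusion frequency (> 0.20)
    records: list[EnrichmentRecord]
    n_draws: int

    def to_semantic_profile(self) -> SemanticProfile:
        return SemanticProfile(species=self.species, records=sorted(self.records))


def pn_target_magnitude(records: Sequence[EnrichmentRecord], n_lowest: int = 10) -> float:
    """Mean of the *n_lowest* smallest log10 hypergeometric p-values."""
    ps = sorted(r.p_hyper for r in records)[:n_lowest]
    if not ps:
        raise ValueError("no enrichment records")
    return float(np.mean([math.log10(max(p, np.finfo(float).tiny)) for p in ps]))


def _probe_magnitude(
    genes: list[str], size: int, species: str, c: AnnotationCorpus, rng
) -> int:
    subset = frozenset(rng.choice(genes, size=size, replace=False))
    records = hypergeometric_test(
        SpeciesGeneSet(species=species, genes=subset, label="probe"), c
    )
    p_min = min(r.p_hyper for r in records)
    return math.floor(math.log10(max(p_min, np.finfo(float).tiny)))


def optimal_subset_size(
    annotation: SpeciesGeneSet,
    c: AnnotationCorpus,
    target: float,
    seed: int | None = None,
    magnitude_tol: int = 1,
) -> int:
    """Largest subset size whose extreme p stays near the target magnitude.

    *target* is the reference magnitude (mean of the 10 lowest log10
    p-values of the species' reference analysis).  Annotations of fewer
    than 10 genes are used whole.  Otherwise a binary search over the
    subset size probes one random draw per size and returns the maximum
    size whose floor(log10 min-p) does not undershoot
    ``floor(target) - magnitude_tol``.
    """
    genes = sorted(annotation.genes)
    if not genes:
        raise ValueError(f"empty annotation for {annotation.species!r}")
    if len(genes) < MIN_SUBSET:
        return len(genes)
    rng = np.random.default_rng(seed)
    target_mag = math.floor(target)

    def ok(size: int) -> bool:
        return _probe_magnitude(genes, size, annotation.species, c, rng) >= (
            target_mag - magnitude_tol
        )

    lo, hi = MIN_SUBSET, len(genes)
    if ok(hi):
        return hi
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if ok(mid):
            lo = mid
        else:
            hi = mid - 1
    return max(lo, MIN_SUBSET)


def estimate_sizing(
    annotation: SpeciesGeneSet,
    c: AnnotationCorpus,
    target: float,
    mechanism: str = "",
    repeats: int = 30,
    seed: int | None = None,
) -> SizingDistribution:
    """Repeat the size search to absorb its sampling noise."""
    if len(annotation.genes) < MIN_SUBSET:
        sizes = [len(annotation.genes)]
    else:
        rng = np.random.default_rng(seed)
        sizes = [
            optimal_subset_size(
                annotation, c, target, seed=int(rng.integers(2**31))
            )
            for _ in range(repeats)
        ]
    return SizingDistribution(
        term=mechanism, species=annotation.species, sizes=sizes, target=target
    )


def consensus_terms(
    per_draw_terms: Sequence[frozenset[str] | set[str]],
    draws: int,
    frac: float = 0.20,
) -> dict[str, float]:
    """Inclusion frequencies of terms enriched in strictly more than
    *frac* of *draws* outputs; invariant to draw order."""
    counts: dict[str, int] = {}
    for terms in per_draw_terms:
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    return {t: c / draws for t, c in sorted(counts.items()) if c / draws > frac}


def build_mechanism_profile(
    annotation: SpeciesGeneSet,
    sizing: SizingDistribution,
    c: AnnotationCorpus,
    draws: int = 30,
    R: int = 1000,
    seed: int | None = None,
    consensus_frac: float = 0.20,
    p_cut: float = 0.05,
    adj_cut: float = 0.05,
    floor: int = 100,
) -> MechanismProfile:
    """Consensus semantic profile over repeated calibrated gene draws.

    Each draw samples a size from the sizing distribution (forced up to
    10 when the distribution mean is below 10), runs the full
    prioritized enrichment, and the consensus keeps terms enriched in
    more than *consensus_frac* of the draws (strict).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(annotation.genes)
    per_draw: list[frozenset[str]] = []
    best: dict[str, EnrichmentRecord] = {}
    for _ in range(draws):
        size = int(rng.choice(sizing.sizes))
        if sizing.mean < MIN_SUBSET:
            size = MIN_SUBSET
        size = min(size, len(genes))
        subset = frozenset(rng.choice(genes, size=size, replace=False))
        query = SpeciesGeneSet(
            species=annotation.species, genes=subset,
            label=f"mechanism:{sizing.term}",
        )
        try:
            records = hypergeometric_test(query, c)
            records = permutation_prioritize(
                records, c, annotation.species, R=R, seed=int(rng.integers(2**31))
            )
            profile = build_profile(
                records, annotation.species, p_cut=p_cut, adj_cut=adj_cut, floor=floor
            )
        except EnrichmentError:
            continue
        per_draw.append(profile.terms)
        for r in profile.records:
            if r.term not in best or r.p_adj < best[r.term].p_adj:
                best[r.term] = r
    frequencies = consensus_terms(per_draw, draws, frac=consensus_frac)
    records = [best[t] for t in sorted(frequencies)]
    return MechanismProfile(
        species=annotation.species,
        mechanism=sizing.term,
        frequencies=frequencies,
        records=records,
        n_draws=draws,
    )


@dataclass
class ExclusionResult:
    hs_before: float
    ss_before: float
    hs_after: float
    ss_after: float
    dropped_species: tuple[str, ...]


def _exclude_terms(
    p: SemanticProfile, excluded: frozenset[str]
) -> SemanticProfile | None:
    records = []
    mapping = {}
    for r in p.records:
        if r.term in excluded:
            continue
        targets = p.mapping[r.term] - excluded
        if targets:
            records.append(r)
            mapping[r.term] = targets
    if not records:
        return None
    return SemanticProfile(
        species=p.species, records=records, mapping=mapping, ic_filtered=True
    )


def pn_exclusion_eval(
    profiles: Sequence[SemanticProfile],
    pn_terms: frozenset[str],
    truth: Mapping[str, str],
    S: SimilarityMatrix,
    k: int = 3,
) -> ExclusionResult:
    """HS/SS of the k-cluster tree before and after removing PN components.

    Removal drops every mapping target contained in *pn_terms* and every
    enriched term whose targets are all removed (terms "mapping into"
    the components); species whose profile empties are dropped with a
    log record.
    """

    def score(prof: Sequence[SemanticProfile]) -> tuple[float, float]:
        d = build_distance_matrix(prof, S)
        labels = cut_clusters(ward_tree(d), k=min(k, len(prof)))
        sub_truth = {p.species: truth[p.species] for p in prof}
        return evaluate_clustering(labels, sub_truth, d)

    hs_before, ss_before = score(profiles)
    after = []
    dropped = []
    for p in profiles:
        q = _exclude_terms(p, pn_terms)
        if q is None:
            dropped.append(p.species)
            logger.info("%s: profile empty after PN-component exclusion", p.species)
        else:
            after.append(q)
    if len(after) < 2:
        raise ValueError("fewer than two species retain terms after exclusion")
    hs_after, ss_after = score(after)
    return ExclusionResult(
        hs_before=hs_before,
        ss_before=ss_before,
        hs_after=hs_after,
        ss_after=ss_after,
        dropped_species=tuple(dropped),
    )
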