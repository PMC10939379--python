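"""Hypergeometric testing, permutation prioritization and profile selection."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semnetphylo.corpus import AnnotationCorpus, SpeciesGeneSet
from semnetphylo.enrichment import (
    EnrichmentError,
    EnrichmentRecord,
    SemanticProfile,
    build_profile,
    hypergeometric_test,
    permutation_prioritize,
    read_profiles,
    update_profile,
    write_profiles,
)
from semnetphylo.ontology import OntologyGraph, StandardizedGraph, compute_metrics


def make_corpus(universe_size, term_genes, species="sp"):
    """Corpus with explicit term -> gene-index annotations."""
    genes = [f"g{i}" for i in range(universe_size)]
    g2t = {g: set() for g in genes}
    for term, idxs in term_genes.items():
        for i in idxs:
            g2t[genes[i]].add(term)
    return AnnotationCorpus(
        {species: {g: frozenset(ts) for g, ts in g2t.items()}}
    ), genes


def enumeration_tail(U, K, n, k):
    """Brute-force P(X >= k): enumerate every size-n draw from U genes."""
    marked = set(range(K))
    total = hits = 0
    for draw in itertools.combinations(range(U), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeometric:
    def test_full_overlap_closed_form(self):
        c, genes = make_corpus(20, {"T": range(5)})
        q = SpeciesGeneSet("sp", frozenset(genes[:5]))
        (rec,) = [r for r in hypergeometric_test(q, c) if r.term == "T"]
        assert rec.k == 5
        assert rec.p_hyper == pytest.approx(1 / math.comb(20, 5))

    def test_zero_overlap_is_one(self):
        c, genes = make_corpus(20, {"T": range(5)})
        q = SpeciesGeneSet("sp", frozenset(genes[10:15]))
        (rec,) = [r for r in hypergeometric_test(q, c) if r.term == "T"]
        assert rec.p_hyper == 1.0

    @pytest.mark.parametrize("U,K,n", [(8, 3, 4), (10, 5, 3), (11, 4, 5)])
    def test_matches_exhaustive_enumeration(self, U, K, n):
        c, genes = make_corpus(U, {"T": range(K)})
        for k in range(0, min(K, n) + 1):
            query = frozenset(genes[:k] + genes[K : K + (n - k)])
            (rec,) = [r for r in hypergeometric_test(SpeciesGeneSet("sp", query), c)
                      if r.term == "T"]
            assert rec.k == k
            assert rec.p_hyper == pytest.approx(enumeration_tail(U, K, n, k))

    def test_query_outside_universe_dropped(self):
        c, genes = make_corpus(10, {"T": range(3)})
        q = SpeciesGeneSet("sp", frozenset(genes[:2]) | {"alien"})
        recs = hypergeometric_test(q, c)
        assert all(r.n == 2 for r in recs)

    def test_all_query_unknown_fatal(self):
        c, _ = make_corpus(10, {"T": range(3)})
        with pytest.raises(EnrichmentError):
            hypergeometric_test(SpeciesGeneSet("sp", frozenset(["x", "y"])), c)

    def test_supersets_of_contained_genes_monotone(self):
        # growing the query only with genes inside the term can never
        # raise that term's tail p-value
        c, genes = make_corpus(30, {"T": range(10)})
        prev = 1.0
        for size in range(1, 8):
            q = SpeciesGeneSet("sp", frozenset(genes[:size]))
            (rec,) = [r for r in hypergeometric_test(q, c) if r.term == "T"]
            assert rec.p_hyper <= prev + 1e-15
            prev = rec.p_hyper


class TestPermutation:
    def setup_method(self):
        self.c, self.genes = make_corpus(
            60, {"T1": range(8), "T2": range(20, 30), "T3": range(40, 44)}
        )
        self.q = SpeciesGeneSet("sp", frozenset(self.genes[:8]))
        self.records = hypergeometric_test(self.q, self.c)

    def test_deterministic_under_seed(self):
        a = permutation_prioritize(self.records, self.c, "sp", R=50, seed=4)
        b = permutation_prioritize(self.records, self.c, "sp", R=50, seed=4)
        assert [r.p_adj for r in a] == [r.p_adj for r in b]

    def test_lower_bound_when_beating_all_permutations(self):
        out = permutation_prioritize(self.records, self.c, "sp", R=999, seed=0)
        (rec,) = [r for r in out if r.term == "T1"]
        # perfect overlap 8/8 is essentially unbeatable by random draws
        assert rec.p_adj == pytest.approx(1 / 1000)

    def test_p_adj_in_unit_interval(self):
        out = permutation_prioritize(self.records, self.c, "sp", R=19, seed=1)
        assert all(0 < r.p_adj <= 1 for r in out)

    def test_requires_at_least_one_permutation(self):
        with pytest.raises(ValueError):
            permutation_prioritize(self.records, self.c, "sp", R=0)


def make_records(n_terms, p_hyper, p_adj):
    return [
        EnrichmentRecord(
            term=f"T{i:04d}", k=1, K=2, n=5, U=50,
            p_hyper=p_hyper(i), p_adj=p_adj(i),
        )
        for i in range(n_terms)
    ]


class TestBuildProfile:
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_selection_invariants(self, seed):
        """Selected terms always pass the raw cut; the profile never
        exceeds max(floor, #passing both cuts) nor the candidate count."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 150))
        recs = [
            EnrichmentRecord(
                term=f"T{i:04d}", k=1, K=2, n=5, U=50,
                p_hyper=float(rng.uniform(0, 0.2)),
                p_adj=float(rng.uniform(0, 0.2)),
            )
            for i in range(n)
        ]
        candidates = [r for r in recs if r.p_hyper < 0.05]
        both = [r for r in candidates if r.p_adj < 0.05]
        if not candidates:
            with pytest.raises(EnrichmentError):
                build_profile(recs, "sp", floor=20)
            return
        prof = build_profile(recs, "sp", floor=20)
        assert prof.terms <= {r.term for r in candidates}
        assert {r.term for r in both} <= prof.terms
        assert len(prof) <= max(20, len(both))
        assert len(prof) >= min(20, len(candidates))
    def test_floor_extends_to_exactly_100(self):
        # 60 terms pass both cuts, 200 pass the raw cut -> exactly 100 kept
        recs = make_records(
            250,
            p_hyper=lambda i: 0.01 if i < 200 else 0.5,
            p_adj=lambda i: 0.01 if i < 60 else 0.5,
        )
        prof = build_profile(recs, "sp", floor=100)
        assert len(prof) == 100
        assert {r.term for r in recs[:60]} <= prof.terms

    def test_no_truncation_above_floor(self):
        recs = make_records(200, p_hyper=lambda i: 0.01, p_adj=lambda i: 0.01 if i < 150 else 0.9)
        assert len(build_profile(recs, "sp", floor=100)) == 150

    def test_floor_capped_by_raw_candidates(self):
        recs = make_records(60, p_hyper=lambda i: 0.01 if i < 40 else 0.8, p_adj=lambda i: 0.8)
        assert len(build_profile(recs, "sp", floor=100)) == 40

    def test_no_raw_passers_is_fatal(self):
        recs = make_records(5, p_hyper=lambda i: 0.9, p_adj=lambda i: 0.9)
        with pytest.raises(EnrichmentError):
            build_profile(recs, "sp")


class TestUpdateProfile:
    def make_sg(self):
        # r -> A -> C and r -> B; B trimmed
        g = OntologyGraph.from_edges(
            ["r", "A", "B", "C"], [("A", "r"), ("B", "r"), ("C", "A")]
        )
        retained = frozenset({"r", "A", "C"})
        mapping = {t: frozenset({t}) for t in retained}
        mapping["B"] = frozenset({"r"})
        sg = StandardizedGraph(
            source=g, retained=retained, ic_threshold=9.9, sv_threshold=9.9,
            mapping=mapping,
        )
        m = compute_metrics(sg.subgraph())
        return sg, m

    def rec(self, term):
        return EnrichmentRecord(term=term, k=2, K=3, n=5, U=50, p_hyper=0.01, p_adj=0.01)

    def test_retained_term_kept_with_self_mapping(self):
        sg, m = self.make_sg()
        prof = SemanticProfile("sp", [self.rec("C")])
        out = update_profile(prof, sg, m, ic_min=0.1)
        assert out.mapping["C"] == {"C"}

    def test_term_mapping_only_to_root_removed(self):
        sg, m = self.make_sg()
        prof = SemanticProfile("sp", [self.rec("B"), self.rec("C")])
        out = update_profile(prof, sg, m, ic_min=0.1)
        assert "B" not in out.terms  # maps only to root, IC 0
        assert "C" in out.terms

    def test_mixed_mapping_drops_low_ic_targets(self):
        sg, m = self.make_sg()
        sg.mapping["B"] = frozenset({"r", "A"})  # hypothetical mixed mapping
        prof = SemanticProfile("sp", [self.rec("B")])
        out = update_profile(prof, sg, m, ic_min=0.1)
        assert out.mapping["B"] == {"A"}

    def test_empty_result_names_species(self):
        sg, m = self.make_sg()
        prof = SemanticProfile("speciesX", [self.rec("B")])
        with pytest.raises(EnrichmentError, match="speciesX"):
            update_profile(prof, sg, m, ic_min=0.1)


def test_profiles_tsv_round_trip(tmp_path):
    recs = [
        EnrichmentRecord(term="T:1", k=3, K=5, n=10, U=100, p_hyper=0.001, p_adj=0.01),
        EnrichmentRecord(term="T:2", k=2, K=9, n=10, U=100, p_hyper=0.02, p_adj=0.04),
    ]
    p = SemanticProfile(
        "sp1", recs,
        mapping={"T:1": frozenset({"T:1"}), "T:2": frozenset({"T:1", "T:9"})},
        ic_filtered=True,
    )
    write_profiles([p], tmp_path / "prof.tsv")
    (back,) = read_profiles(tmp_path / "prof.tsv")
    assert back.species == "sp1"
    assert back.terms == p.terms
    assert back.mapping == p.mapping
    assert sorted(r.p_adj for r in back.records) == sorted(r.p_adj for r in recs)
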