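"""Ontology loading, structural metrics and standardization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from semnetphylo.ontology import (
    OntologyError,
    OntologyGraph,
    build_standardized_graph,
    compute_metrics,
    load_obo,
    map_to_standard,
    read_standardized,
    write_standardized,
)
from semnetphylo.synth import SynthConfig, generate_dag

from conftest import sw


def brute_force_metrics(g):
    """Independent IC/SV oracle by explicit transitive-closure enumeration."""
    parents = {t: set(g.graph.successors(t)) for t in g.terms}

    def ancestors(t):
        out, stack = set(), list(parents[t])
        while stack:
            a = stack.pop()
            if a not in out:
                out.add(a)
                stack.extend(parents[a])
        return out

    anc = {t: ancestors(t) for t in g.terms}
    desc = {t: {u for u in g.terms if t in anc[u]} for t in g.terms}
    n = len(g.terms)
    ic = {t: -math.log2((len(desc[t]) + 1) / n) for t in g.terms}
    sv = {t: sum(sw(ic[a]) for a in sorted(anc[t])) for t in g.terms}
    return ic, sv


OBO_SMALL = """format-version: 1.2

[Term]
id: T:0
name: root

[Term]
id: T:1
name: a
is_a: T:0

[Term]
id: T:2
name: b
is_a: T:1

[Term]
id: T:3
name: gone
is_a: T:1
is_obsolete: true
"""


class TestLoadObo:
    def test_small_file(self, tmp_path):
        p = tmp_path / "t.obo"
        p.write_text(OBO_SMALL)
        g = load_obo(p)
        assert g.terms == {"T:0", "T:1", "T:2"}
        assert g.graph.number_of_edges() == 2
        assert g.root == "T:0"

    def test_obsolete_excluded(self, tmp_path):
        p = tmp_path / "t.obo"
        p.write_text(OBO_SMALL)
        assert "T:3" not in load_obo(p)

    def test_cycle_fatal(self):
        with pytest.raises(OntologyError, match="cycle"):
            OntologyGraph.from_edges(["A", "B"], [("A", "B"), ("B", "A")])

    def test_multiple_roots_listed(self):
        with pytest.raises(OntologyError, match="R2"):
            OntologyGraph.from_edges(
                ["R1", "R2", "C"], [("C", "R1"), ("C", "R2")]
            )


class TestMetrics:
    def test_diamond_hand_values(self, diamond):
        g, m = diamond
        assert m.ic["root"] == 0.0
        assert m.ic["A"] == 1.0 == m.ic["B"]
        assert m.ic["C"] == 2.0
        assert m.sv["root"] == 0.0
        assert m.sv["A"] == 1.0
        assert m.sv["C"] == pytest.approx(1.0 + 2 * sw(1.0))

    def test_leaf_ic_is_log2_n(self, diamond):
        g, m = diamond
        assert m.ic["C"] == math.log2(g.n_terms)

    def test_child_of_unit_ic_parent(self):
        # ancestors exactly {root, parent with IC=1}: SV = 1 + 1/(1+e^-1)
        g = OntologyGraph.from_edges(
            ["r", "p", "x", "y"], [("p", "r"), ("x", "p"), ("y", "r")]
        )
        m = compute_metrics(g)
        assert m.ic["p"] == 1.0  # D=1 of N=4
        assert m.sv["x"] == pytest.approx(1.0 + 1.0 / (1.0 + math.exp(-1.0)))

    def test_sw_bounds_and_monotonicity(self):
        ics = np.linspace(1e-6, 50, 400)
        sws = [sw(v) for v in ics]
        assert all(0.5 < w <= 1.0 for w in sws)
        assert all(a >= b for a, b in zip(sws, sws[1:]))

    @settings(derandomize=True, max_examples=200)
    @given(
        a=st.floats(min_value=1e-9, max_value=1e6),
        b=st.floats(min_value=1e-9, max_value=1e6),
    )
    def test_sw_property_bounded_and_decreasing(self, a, b):
        lo, hi = sorted((a, b))
        assert 0.5 < sw(hi) <= sw(lo) <= 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_dags(self, seed):
        g = generate_dag(SynthConfig(seed=seed, n_terms=120 + 30 * seed))
        m = compute_metrics(g)
        ic, sv = brute_force_metrics(g)
        assert m.ic == ic
        assert m.sv == sv

    def test_restricted_universe(self, diamond):
        g, _ = diamond
        m = compute_metrics(g, universe={"root", "A", "C"})
        # D(root) within universe = |{A, C}| = 2, N = 3
        assert m.ic["root"] == -math.log2(3 / 3)
        assert m.ic["A"] == -math.log2(2 / 3)


class TestStandardization:
    def test_identity_when_nothing_trimmed(self, diamond):
        g, m = diamond
        sg = build_standardized_graph(g, m, thresholds=(100.0, 100.0))
        assert sg.retained == g.terms
        assert all(sg.mapping[t] == {t} for t in g.terms)

    def test_root_always_retained(self, diamond):
        g, m = diamond
        sg = build_standardized_graph(g, m, pct=20)
        assert g.root in sg.retained

    def test_trim_set_matches_independent_predicate(self):
        g = generate_dag(SynthConfig(seed=3, n_terms=60))
        m = compute_metrics(g)
        sg = build_standardized_graph(g, m, pct=20)
        q_ic = np.percentile([m.ic[t] for t in sorted(g.terms)], 20)
        q_sv = np.percentile([m.sv[t] for t in sorted(g.terms)], 20)
        expect_trimmed = {t for t in g.terms if m.ic[t] > q_ic and m.sv[t] > q_sv}
        assert g.terms - sg.retained == expect_trimmed

    def test_mapping_is_minimal_retained_ancestors(self, diamond):
        g, m = diamond
        sg = build_standardized_graph(g, m, thresholds=(0.0, 0.0))
        # everything with IC>0 and SV>0 trimmed -> only root survives
        assert sg.retained == {"root"}
        assert map_to_standard(sg, "C") == {"root"}

    def test_retained_term_maps_to_itself(self, diamond):
        g, m = diamond
        sg = build_standardized_graph(g, m, pct=20)
        for t in sg.retained:
            assert map_to_standard(sg, t) == {t}

    def test_mapping_targets_are_ancestors_or_self(self):
        g = generate_dag(SynthConfig(seed=5, n_terms=80))
        m = compute_metrics(g)
        sg = build_standardized_graph(g, m, pct=20)
        for t in g.terms:
            targets = sg.mapping[t]
            assert targets
            assert all(u == t or u in g.ancestors(t) for u in targets)
            # minimality: no target strictly above another
            for u in targets:
                assert not any(u in g.ancestors(v) for v in targets if v != u)

    def test_unknown_term_rejected(self, diamond):
        g, m = diamond
        sg = build_standardized_graph(g, m, pct=20)
        with pytest.raises(OntologyError):
            map_to_standard(sg, "nope")

    def test_idempotent_under_fixed_thresholds(self):
        g = generate_dag(SynthConfig(seed=7, n_terms=100))
        m = compute_metrics(g)
        sg = build_standardized_graph(g, m, pct=20)
        sub = sg.subgraph()
        again = build_standardized_graph(
            sub, m, thresholds=(sg.ic_threshold, sg.sv_threshold)
        )
        assert again.retained == sg.retained

    def test_subgraph_preserves_ancestry(self):
        g = generate_dag(SynthConfig(seed=9, n_terms=80))
        m = compute_metrics(g)
        sg = build_standardized_graph(g, m, pct=20)
        sub = sg.subgraph()
        assert sub.terms == sg.retained
        for t in sub.terms:
            assert sub.ancestors(t) == g.ancestors(t) & sg.retained

    def test_tsv_round_trip(self, tmp_path):
        g = generate_dag(SynthConfig(seed=2, n_terms=50))
        m = compute_metrics(g)
        sg = build_standardized_graph(g, m, pct=20)
        write_standardized(sg, m, tmp_path / "std")
        back_sg, back_m = read_standardized(tmp_path / "std", g)
        assert back_sg.retained == sg.retained
        assert back_sg.mapping == sg.mapping
        assert back_m.ic == pytest.approx(m.ic)
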