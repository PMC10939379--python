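"""Ontology graphs, structural information content and the standardized (pruned) graph.

The biological-process ontology is a rooted directed acyclic graph whose
terms become less specific as one ascends toward the root.  Two purely
structural metrics drive the standardization step:

* **IC** (information content): ``IC(t) = -log2((D(t) + 1) / N)`` where
  ``D(t)`` is the number of distinct descendants of ``t`` and ``N`` the
  size of the term universe.  Leaves carry the maximum ``log2(N)``; the
  root carries 0.
* **SV** (semantic value): the mass of a term's ancestral plexus,
  ``SV(t) = sum_{a in ancestors(t)} sw(a)`` with the logistic weight
  ``sw(a) = 1 / (1 + exp(-1 / IC(a)))`` (limit 1 as ``IC -> 0``).

Terms that sit simultaneously above the 20th percentile of both
distributions — very specific terms inside expanded, densely annotated
branches — are trimmed, and every trimmed term is remapped to its most
proximal retained ancestors.  The pruned graph trades annotation detail
for comparability across unevenly annotated genomes.

Both metrics strictly increase from ancestor to descendant, so the
trimmed set is descendant-closed: every ancestor of a retained term is
itself retained, and the standardized subgraph inherits the original
ancestor relation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "OntologyGraph",
    "TermMetrics",
    "StandardizedGraph",
    "load_obo",
    "compute_metrics",
    "build_standardized_graph",
    "map_to_standard",
    "write_standardized",
    "read_standardized",
]


class OntologyError(ValueError):
    """Raised for structurally invalid ontologies or unknown terms."""


@dataclass
class OntologyGraph:
    """A rooted term DAG with child -> parent ``is_a``-style edges.

    ``graph`` stores one directed edge per child -> parent link, so
    following edge direction ascends toward the root.  Ancestor and
    descendant queries are memoised; both exclude the term itself.
    """

    graph: nx.DiGraph
    root: str
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)
    _descendants: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    @classmethod
    def from_edges(cls, terms: Iterable[str], edges: Iterable[tuple[str, str]]) -> "OntologyGraph":
        """Build and validate a graph from explicit (child, parent) pairs."""
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(edges)
        return cls._validated(g)

    @classmethod
    def _validated(cls, g: nx.DiGraph) -> "OntologyGraph":
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise OntologyError(f"ontology contains a cycle: {cycle}")
        roots = [t for t in g.nodes if g.out_degree(t) == 0]
        if len(roots) != 1:
            raise OntologyError(
                f"expected exactly one root term, found {len(roots)}: {sorted(roots)}"
            )
        root = roots[0]
        # every term must reach the root along parent links
        reachable = set(nx.ancestors(g, root)) | {root}
        orphans = set(g.nodes) - reachable
        if orphans:  # unreachable under a single root implies >1 root; defensive
            raise OntologyError(f"terms cannot reach the root: {sorted(orphans)}")
        return cls(graph=g, root=root)

    # -- basic queries -------------------------------------------------

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_terms(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def parents(self, term: str) -> frozenset[str]:
        self._require(term)
        return frozenset(self.graph.successors(term))

    def children(self, term: str) -> frozenset[str]:
        self._require(term)
        return frozenset(self.graph.predecessors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """Strict ancestors of *term* (term itself excluded)."""
        if term not in self._ancestors:
            self._require(term)
            self._ancestors[term] = frozenset(nx.descendants(self.graph, term))
        return self._ancestors[term]

    def descendants(self, term: str) -> frozenset[str]:
        """Strict descendants of *term* (term itself excluded)."""
        if term not in self._descendants:
            self._require(term)
            self._descendants[term] = frozenset(nx.ancestors(self.graph, term))
        return self._descendants[term]

    def root_distance(self, term: str) -> int:
        """Shortest-path edge count from the root down to *term*."""
        self._require(term)
        return nx.shortest_path_length(self.graph, source=term, target=self.root)

    def _require(self, term: str) -> None:
        if term not in self.graph:
            raise OntologyError(f"unknown term: {term!r}")


@dataclass(frozen=True)
class TermMetrics:
    """Per-term IC, SV and SV-contribution weights for one graph.

    ``n_universe`` is the ``N`` of the IC formula; when a restricted
    annotated universe was used it is the universe size, otherwise the
    graph's term count.
    """

    ic: Mapping[str, float]
    sv: Mapping[str, float]
    sw: Mapping[str, float]
    n_universe: int

    @property
    def ic_max(self) -> float:
        return max(self.ic.values())


def _sw_from_ic(ic: float) -> float:
    """Logistic SV-contribution weight; analytic limit 1 at IC == 0."""
    if ic == 0.0:
        return 1.0
    return 1.0 / (1.0 + math.exp(-1.0 / ic))


def load_obo(
    path: str | Path,
    relations: Iterable[str] = ("is_a",),
    namespace: str | None = None,
) -> OntologyGraph:
    """Load an OBO 1.2/1.4 file into a validated :class:`OntologyGraph`.

    Obsolete terms are excluded; only the requested relation types
    (default ``is_a`` only) become edges.  If *namespace* is given,
    terms of other namespaces are dropped first.
    """
    import obonet

    multigraph = obonet.read_obo(str(path), ignore_obsolete=True)
    relations = set(relations)
    g = nx.DiGraph()
    for node, data in multigraph.nodes(data=True):
        if namespace is not None and data.get("namespace") != namespace:
            continue
        g.add_node(node)
    for child, parent, key in multigraph.edges(keys=True):
        if key in relations and child in g and parent in g:
            g.add_edge(child, parent)
    if g.number_of_nodes() == 0:
        raise OntologyError(f"no terms loaded from {path} (namespace={namespace!r})")
    return OntologyGraph._validated(g)


def compute_metrics(g: OntologyGraph, universe: Iterable[str] | None = None) -> TermMetrics:
    """Compute IC, SV and sw for every term of *g*.

    *universe* optionally restricts the IC formula to a subset of terms
    (e.g. terms with at least one annotation): descendant counts and
    ``N`` are then taken within that subset.  By default the whole
    graph is the universe.
    """
    if universe is None:
        uni = set(g.terms)
    else:
        uni = set(universe) & set(g.terms)
        if not uni:
            raise OntologyError("annotation universe shares no terms with the graph")
    n = len(uni)
    order = list(nx.topological_sort(g.graph))  # children before parents
    desc_count: dict[str, int] = {}
    desc_sets: dict[str, set[str]] = {}
    for t in order:
        s: set[str] = set()
        for c in g.graph.predecessors(t):
            s.add(c)
            s |= desc_sets[c]
        desc_sets[t] = s
        desc_count[t] = len(s & uni) if universe is not None else len(s)
    ic = {t: -math.log2((desc_count[t] + 1) / n) for t in g.terms}
    sw = {t: _sw_from_ic(ic[t]) for t in g.terms}
    sv: dict[str, float] = {}
    for t in g.terms:
        # sorted summation keeps SV bit-reproducible across runs
        sv[t] = sum(sw[a] for a in sorted(g.ancestors(t)))
    return TermMetrics(ic=ic, sv=sv, sw=sw, n_universe=n)


@dataclass
class StandardizedGraph:
    """Pruned term subset plus the trimmed-term -> retained-ancestor mapping.

    ``mapping[t]`` is ``{t}`` for retained terms and otherwise the set of
    most proximal retained ancestors of ``t`` (no mapping target is a
    strict ancestor of another).
    """

    source: OntologyGraph
    retained: frozenset[str]
    ic_threshold: float
    sv_threshold: float
    mapping: dict[str, frozenset[str]]

    def subgraph(self) -> OntologyGraph:
        """The standardized sub-DAG over retained terms.

        Because the retained set is ancestor-closed, this is simply the
        induced subgraph re-wired so each retained term points to its
        minimal retained strict ancestors.
        """
        edges: list[tuple[str, str]] = []
        for t in self.retained:
            if t == self.source.root:
                continue
            cand: set[str] = set()
            for p in self.source.graph.successors(t):
                cand |= self.mapping[p]
            for a in _minimal_terms(cand, self.source):
                edges.append((t, a))
        return OntologyGraph.from_edges(self.retained, edges)


def _minimal_terms(terms: set[str] | frozenset[str], g: OntologyGraph) -> frozenset[str]:
    """Drop every term that is a strict ancestor of another term in the set."""
    return frozenset(
        t for t in terms if not any(t in g.ancestors(u) for u in terms if u != t)
    )


def build_standardized_graph(
    g: OntologyGraph,
    m: TermMetrics,
    pct: float = 20.0,
    thresholds: tuple[float, float] | None = None,
) -> StandardizedGraph:
    """Trim terms exceeding the *pct*-th percentile of both IC and SV.

    A term is trimmed iff ``IC > q`` **and** ``SV > q`` (strict, linear
    interpolation percentiles), i.e. the specific terms of expanded
    branches; everything else — in particular the root, whose IC and SV
    are the distribution minima — is retained.  Explicit *thresholds*
    ``(ic_threshold, sv_threshold)`` bypass the percentile computation,
    which makes re-standardization with fixed thresholds idempotent.
    """
    terms = sorted(g.terms)
    if thresholds is None:
        q_ic = float(np.percentile([m.ic[t] for t in terms], pct))
        q_sv = float(np.percentile([m.sv[t] for t in terms], pct))
    else:
        q_ic, q_sv = map(float, thresholds)
    retained = frozenset(t for t in terms if not (m.ic[t] > q_ic and m.sv[t] > q_sv))
    if retained == {g.root}:
        warnings.warn("standardization retained only the root term", stacklevel=2)

    mapping: dict[str, frozenset[str]] = {}

    def targets(t: str) -> frozenset[str]:
        got = mapping.get(t)
        if got is not None:
            return got
        if t in retained:
            res = frozenset((t,))
        else:
            acc: set[str] = set()
            for p in g.graph.successors(t):
                acc |= targets(p)
            res = _minimal_terms(acc, g)
        mapping[t] = res
        return res

    order = list(nx.topological_sort(g.graph))  # children first; ascend parents safely
    for t in reversed(order):  # parents first avoids deep recursion
        targets(t)
    return StandardizedGraph(
        source=g, retained=retained, ic_threshold=q_ic, sv_threshold=q_sv, mapping=mapping
    )


def map_to_standard(sg: StandardizedGraph, term: str) -> frozenset[str]:
    """Most proximal retained ancestors-or-self of *term*."""
    if term not in sg.mapping:
        raise OntologyError(f"unknown term: {term!r}")
    return sg.mapping[term]


# -- TSV round trip ----------------------------------------------------


def write_standardized(sg: StandardizedGraph, m: TermMetrics, prefix: str | Path) -> None:
    """Write ``<prefix>.terms.tsv`` (term, IC, SV, retained) and ``<prefix>.mapping.tsv``."""
    prefix = Path(prefix)
    terms = sorted(sg.source.terms)
    pd.DataFrame(
        {
            "term": terms,
            "ic": [m.ic[t] for t in terms],
            "sv": [m.sv[t] for t in terms],
            "retained": [int(t in sg.retained) for t in terms],
            "ic_threshold": sg.ic_threshold,
            "sv_threshold": sg.sv_threshold,
        }
    ).to_csv(prefix.with_suffix(".terms.tsv"), sep="\t", index=False)
    pd.DataFrame(
        {
            "term": terms,
            "targets": [",".join(sorted(sg.mapping[t])) for t in terms],
        }
    ).to_csv(prefix.with_suffix(".mapping.tsv"), sep="\t", index=False)


def read_standardized(
    prefix: str | Path, g: OntologyGraph
) -> tuple[StandardizedGraph, TermMetrics]:
    """Round-trip reader for :func:`write_standardized` output."""
    prefix = Path(prefix)
    terms_df = pd.read_csv(prefix.with_suffix(".terms.tsv"), sep="\t")
    map_df = pd.read_csv(prefix.with_suffix(".mapping.tsv"), sep="\t")
    ic = dict(zip(terms_df["term"], terms_df["ic"].astype(float)))
    sv = dict(zip(terms_df["term"], terms_df["sv"].astype(float)))
    sw = {t: _sw_from_ic(v) for t, v in ic.items()}
    m = TermMetrics(ic=ic, sv=sv, sw=sw, n_universe=len(ic))
    retained = frozenset(terms_df.loc[terms_df["retained"] == 1, "term"])
    mapping = {
        row.term: frozenset(str(row.targets).split(","))
        for row in map_df.itertuples()
    }
    sg = StandardizedGraph(
        source=g,
        retained=retained,
        ic_threshold=float(terms_df["ic_threshold"].iloc[0]),
        sv_threshold=float(terms_df["sv_threshold"].iloc[0]),
        mapping=mapping,
    )
    return sg, m
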