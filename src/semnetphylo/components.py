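"""Conserved and differential functional components.

Within each taxonomic kingdom, two routes pick out the terms that carry
the kingdom's functional signature on the standardized graph:

* **core** ("quasi-omnipresent") terms: present, through the
  standardized mapping, in more than 90% of the kingdom's species;
  ancestors are dropped when a qualifying descendant also made the
  list, leaving only the most specific representatives;
* **generic** terms: terms exactly two edges below the root that
  aggregate, through descendancy, sub-threshold enrichment from more
  than 50% of the kingdom's species.

The union feeds a non-negative association matrix (term x species,
scores = -log10 adjusted p of the term or of its best-enriched
descendant) which a rank-3 NMF decomposes into conserved and
kingdom-specific components.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import NMF

from .enrichment import SemanticProfile
from .ontology import OntologyGraph
from .semantic_compare import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentTermSet",
    "AssociationMatrix",
    "Decomposition",
    "select_core_terms",
    "select_generic_terms",
    "select_components",
    "build_association_matrix",
    "group_terms",
    "nmf_decompose",
]


@dataclass(frozen=True)
class ComponentTermSet:
    """Selected component terms for one kingdom, by selection route."""

    kingdom: str
    core: frozenset[str]
    generic: frozenset[str]

    @property
    def terms(self) -> frozenset[str]:
        return self.core | self.generic


@dataclass
class AssociationMatrix:
    """Non-negative term(-group) x species score matrix."""

    term_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    matrix: np.ndarray


@dataclass
class Decomposition:
    W: np.ndarray  # terms x k
    H: np.ndarray  # k x species
    term_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    k: int
    error: float

    @property
    def assignments(self) -> dict[str, int]:
        """Species -> component index (argmax of its H column)."""
        idx = np.argmax(self.H, axis=0)
        return {s: int(i) for s, i in zip(self.species_ids, idx)}


def select_core_terms(
    profiles: Sequence[SemanticProfile],
    g: OntologyGraph,
    frac: float = 0.90,
) -> frozenset[str]:
    """Quasi-omnipresent terms: mapped presence in > *frac* of species,
    with ancestors removed when a descendant also qualifies.

    *g* supplies the ancestor relation (the standardized subgraph, whose
    ancestry matches the full graph restricted to retained terms).
    """
    n = len(profiles)
    counts: dict[str, int] = {}
    for p in profiles:
        for t in p.mapped_terms:
            counts[t] = counts.get(t, 0) + 1
    qualifying = {t for t, c in counts.items() if c / n > frac}
    specific = frozenset(
        t for t in qualifying if not (g.descendants(t) & qualifying)
    )
    if not specific:
        logger.warning("no quasi-omnipresent terms at frac=%.2f over %d species", frac, n)
    return specific


def select_generic_terms(
    profiles: Sequence[SemanticProfile],
    g: OntologyGraph,
    frac: float = 0.50,
    core_threshold: float = 0.90,
) -> frozenset[str]:
    """Generic (root-distance-2) ancestors of sub-threshold enrichment.

    Terms below the quasi-omnipresence threshold are screened up their
    ancestral paths; a term at shortest-path distance exactly 2 from the
    root qualifies when such enrichment reaches it from more than
    *frac* of the species.
    """
    n = len(profiles)
    counts: dict[str, int] = {}
    for p in profiles:
        for t in p.mapped_terms:
            counts[t] = counts.get(t, 0) + 1
    sub = {t for t, c in counts.items() if c / n <= core_threshold}
    dist2 = {t for t in g.terms if g.root_distance(t) == 2}
    coverage: dict[str, int] = {}
    for p in profiles:
        hit: set[str] = set()
        for t in p.mapped_terms & sub:
            for a in (g.ancestors(t) | {t}) & dist2:
                hit.add(a)
        for a in hit:
            coverage[a] = coverage.get(a, 0) + 1
    return frozenset(t for t, c in coverage.items() if c / n > frac)


def select_components(
    profiles_by_kingdom: Mapping[str, Sequence[SemanticProfile]],
    g: OntologyGraph,
    core_frac: float = 0.90,
    generic_frac: float = 0.50,
) -> dict[str, ComponentTermSet]:
    """Run both selection routes per kingdom and return the unions."""
    out = {}
    for kingdom, profiles in profiles_by_kingdom.items():
        core = select_core_terms(profiles, g, frac=core_frac)
        generic = select_generic_terms(
            profiles, g, frac=generic_frac, core_threshold=core_frac
        )
        out[kingdom] = ComponentTermSet(kingdom=kingdom, core=core, generic=generic)
    return out


def build_association_matrix(
    terms: Iterable[str],
    profiles: Sequence[SemanticProfile],
    g: OntologyGraph,
) -> AssociationMatrix:
    """-log10 adjusted-p association of component terms with species.

    For each (term, species): the term's own adjusted p if enriched,
    else the minimum adjusted p over its enriched descendants (in the
    full ontology *g*, which covers original enriched terms), else 0.
    Zero p-values are clamped to the smallest positive float.
    """
    term_ids = tuple(sorted(set(terms)))
    profiles = sorted(profiles, key=lambda p: p.species)
    species_ids = tuple(p.species for p in profiles)
    tiny = np.finfo(float).tiny
    A = np.zeros((len(term_ids), len(species_ids)))
    for j, p in enumerate(profiles):
        padj = {r.term: (r.p_adj if r.p_adj is not None else r.p_hyper) for r in p.records}
        for i, t in enumerate(term_ids):
            if t in padj:
                val = padj[t]
            else:
                cand = [padj[d] for d in g.descendants(t) if d in padj]
                if not cand:
                    continue
                val = min(cand)
            if val <= 0:
                logger.warning("adjusted p of 0 clamped for term %s in %s", t, p.species)
                val = tiny
            A[i, j] = -np.log10(val)
    return AssociationMatrix(term_ids=term_ids, species_ids=species_ids, matrix=A)


def group_terms(
    a: AssociationMatrix,
    S: SimilarityMatrix,
    n_groups: int = 50,
) -> AssociationMatrix:
    """Optional reduction: agglomerate terms into semantic groups.

    Terms are clustered on consensus semantic distance (1 - S, average
    linkage); each group's score per species is the mean of its member
    scores.  Group ids list the member terms.
    """
    n_groups = min(n_groups, len(a.term_ids))
    idx = [S.index[t] for t in a.term_ids]
    dist = 1.0 - S.matrix[np.ix_(idx, idx)]
    np.fill_diagonal(dist, 0.0)
    labels = AgglomerativeClustering(
        n_clusters=n_groups, metric="precomputed", linkage="average"
    ).fit_predict(dist)
    group_ids = []
    rows = []
    for gid in range(n_groups):
        members = [t for t, l in zip(a.term_ids, labels) if l == gid]
        group_ids.append("|".join(members))
        rows.append(a.matrix[[a.term_ids.index(t) for t in members]].mean(axis=0))
    order = np.argsort(group_ids)
    return AssociationMatrix(
        term_ids=tuple(group_ids[i] for i in order),
        species_ids=a.species_ids,
        matrix=np.array(rows)[order],
    )


def nmf_decompose(
    a: AssociationMatrix,
    k: int = 3,
    seed: int | None = None,
    max_iter: int = 1000,
    tol: float = 1e-10,
) -> Decomposition:
    """Rank-*k* non-negative factorization of the association matrix.

    Uses coordinate-descent NMF with the deterministic ``nndsvda``
    initialization (seed-independent; *seed* is accepted for interface
    stability and forwarded to scikit-learn).
    """
    if not np.any(a.matrix):
        raise ValueError("association matrix is all zeros")
    if np.any(a.matrix < 0):
        raise ValueError("association matrix must be non-negative")
    model = NMF(
        n_components=k,
        init="nndsvda",
        solver="cd",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    W = model.fit_transform(a.matrix)
    H = model.components_
    err = float(np.linalg.norm(a.matrix - W @ H, "fro"))
    return Decomposition(
        W=W, H=H, term_ids=a.term_ids, species_ids=a.species_ids, k=k, error=err
    )
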