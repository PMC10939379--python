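"""Prioritized pathway analysis.

A species' gene list is translated into a semantic profile in three
steps: an exact upper-tail hypergeometric test per annotated term, a
non-parametric permutation correction that re-ranks terms by how often
same-size random gene draws achieve an equally extreme p-value, and a
profile-selection rule (raw cut 0.05, adjusted cut 0.05, extended down
the ranking to 100 terms when fewer pass) that keeps profile sizes
comparable across species.  Profiles are then projected onto the
standardized ontology graph and stripped of near-root terms
(IC < 0.1), which would otherwise mask inter-species differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .corpus import AnnotationCorpus, SpeciesGeneSet
from .ontology import StandardizedGraph, TermMetrics, map_to_standard

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentRecord",
    "SemanticProfile",
    "hypergeometric_test",
    "permutation_prioritize",
    "build_profile",
    "update_profile",
    "write_profiles",
    "read_profiles",
]


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class EnrichmentRecord:
    """One term's enrichment evidence: overlap k of a query of size n
    with the K genes annotated to the term, in a universe of U genes."""

    term: str
    k: int
    K: int
    n: int
    U: int
    p_hyper: float
    p_adj: float | None = None


@dataclass
class SemanticProfile:
    """A species' enriched-term set, optionally mapped onto the standardized graph."""

    species: str
    records: list[EnrichmentRecord]
    mapping: dict[str, frozenset[str]] = field(default_factory=dict)
    ic_filtered: bool = False

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(r.term for r in self.records)

    @property
    def mapped_terms(self) -> frozenset[str]:
        """Union of standardized mapping targets over the enriched set."""
        out: set[str] = set()
        for ts in self.mapping.values():
            out |= ts
        return frozenset(out)

    def p_adj_of(self, term: str) -> float:
        for r in self.records:
            if r.term == term:
                return r.p_adj if r.p_adj is not None else r.p_hyper
        raise KeyError(term)

    def __len__(self) -> int:
        return len(self.records)


def _query_term_stats(
    query: SpeciesGeneSet, c: AnnotationCorpus
) -> tuple[list[str], np.ndarray, np.ndarray, int, int, frozenset[str]]:
    universe = c.genes(query.species)
    effective = query.genes & universe
    dropped = query.genes - universe
    if dropped:
        logger.warning(
            "%s: %d query genes outside the annotated universe dropped",
            query.species, len(dropped),
        )
    if not effective:
        raise EnrichmentError(f"no query genes of {query.species!r} are annotated")
    t2g = c.term_to_genes(query.species)
    terms = sorted(t2g)
    K = np.array([len(t2g[t]) for t in terms])
    k = np.array([len(t2g[t] & effective) for t in terms])
    return terms, K, k, len(universe), len(effective), effective


def hypergeometric_test(
    query: SpeciesGeneSet, c: AnnotationCorpus
) -> list[EnrichmentRecord]:
    """Exact upper-tail P(X >= k) for every term annotated in the species.

    The universe is the species' annotated gene set; query genes outside
    it are logged and dropped.
    """
    terms, K, k, U, n, _ = _query_term_stats(query, c)
    p = hypergeom.sf(k - 1, U, K, n)
    return [
        EnrichmentRecord(term=t, k=int(ki), K=int(Ki), n=n, U=U, p_hyper=float(pi))
        for t, ki, Ki, pi in zip(terms, k, K, p)
    ]


def permutation_prioritize(
    records: Sequence[EnrichmentRecord],
    c: AnnotationCorpus,
    species: str,
    R: int = 1000,
    seed: int | None = None,
) -> list[EnrichmentRecord]:
    """Permutation-rank adjusted p-values for prioritization.

    ``p_adj = (1 + #{r : p_r <= p_obs}) / (1 + R)`` over *R* uniform
    same-size gene draws from the species' universe; each draw is scored
    with the same hypergeometric test per term.  Deterministic under a
    fixed seed.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if not records:
        return []
    rng = np.random.default_rng(seed)
    universe = sorted(c.genes(species))
    t2g = c.term_to_genes(species)
    terms = [r.term for r in records]
    n, U = records[0].n, records[0].U
    gene_idx = {g: i for i, g in enumerate(universe)}
    # genes x terms incidence for vectorized overlap counting
    M = np.zeros((len(universe), len(terms)), dtype=np.float32)
    for j, t in enumerate(terms):
        for g in t2g[t]:
            M[gene_idx[g], j] = 1.0
    K = np.array([len(t2g[t]) for t in terms])
    p_obs = np.array([r.p_hyper for r in records])
    draws = np.zeros((R, len(universe)), dtype=np.float32)
    for r in range(R):
        draws[r, rng.choice(len(universe), size=n, replace=False)] = 1.0
    k_perm = draws @ M  # R x T overlap counts
    p_perm = hypergeom.sf(k_perm - 1, U, K[None, :], n)
    count = (p_perm <= p_obs[None, :]).sum(axis=0)
    p_adj = (1.0 + count) / (1.0 + R)
    return [replace(r, p_adj=float(pa)) for r, pa in zip(records, p_adj)]


def build_profile(
    records: Sequence[EnrichmentRecord],
    species: str,
    p_cut: float = 0.05,
    adj_cut: float = 0.05,
    floor: int = 100,
) -> SemanticProfile:
    """Select the enriched profile: both cuts, floored at *floor* terms.

    Terms passing both ``p_hyper < p_cut`` and ``p_adj < adj_cut`` are
    kept; if fewer than *floor* pass, selection extends down the ranking
    (p_adj, then p_hyper, then term id) through the raw-cut candidates.
    """
    candidates = [r for r in records if r.p_hyper < p_cut]
    if not candidates:
        raise EnrichmentError(f"no term passes the raw p cut for {species!r}")
    if any(r.p_adj is None for r in candidates):
        raise EnrichmentError("records lack adjusted p-values; run permutation_prioritize")
    selected = [r for r in candidates if r.p_adj < adj_cut]
    if len(selected) < floor:
        ranked = sorted(candidates, key=lambda r: (r.p_adj, r.p_hyper, r.term))
        selected = ranked[: min(floor, len(ranked))]
    return SemanticProfile(species=species, records=sorted(selected))


def update_profile(
    p: SemanticProfile,
    sg: StandardizedGraph,
    m: TermMetrics,
    ic_min: float = 0.1,
) -> SemanticProfile:
    """Map the profile onto the standardized graph and drop near-root terms.

    *m* must carry IC on the standardized subgraph.  Mapping targets
    with ``IC < ic_min`` are dropped; enriched terms left with no
    target are removed from the profile.
    """
    records: list[EnrichmentRecord] = []
    mapping: dict[str, frozenset[str]] = {}
    for r in p.records:
        targets = frozenset(t for t in map_to_standard(sg, r.term) if m.ic[t] >= ic_min)
        if targets:
            records.append(r)
            mapping[r.term] = targets
    if not records:
        raise EnrichmentError(f"profile of {p.species!r} empty after IC filtering")
    return SemanticProfile(
        species=p.species, records=records, mapping=mapping, ic_filtered=True
    )


# -- TSV round trip ----------------------------------------------------


def write_profiles(profiles: Iterable[SemanticProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for r in p.records:
            rows.append(
                {
                    "species": p.species,
                    "term": r.term,
                    "k": r.k,
                    "K": r.K,
                    "n": r.n,
                    "U": r.U,
                    "p_hyper": r.p_hyper,
                    "p_adj": r.p_adj,
                    "targets": ",".join(sorted(p.mapping.get(r.term, ()))),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[SemanticProfile]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])
    out = []
    for sp, grp in df.groupby("species", sort=True):
        records = []
        mapping = {}
        for row in grp.itertuples():
            records.append(
                EnrichmentRecord(
                    term=row.term, k=int(row.k), K=int(row.K), n=int(row.n),
                    U=int(row.U), p_hyper=float(row.p_hyper),
                    p_adj=float(row.p_adj) if str(row.p_adj) else None,
                )
            )
            if str(row.targets):
                mapping[row.term] = frozenset(str(row.targets).split(","))
        out.append(
            SemanticProfile(
                species=str(sp), records=sorted(records), mapping=mapping,
                ic_filtered=bool(mapping),
            )
        )
    return out
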