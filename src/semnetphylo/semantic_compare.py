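"""Consensus semantic similarity and species-level distance matrices.

Term-level similarity on the standardized graph averages three
ancestor-based measures, each bounded in [0, 1]:

* **Resnik** — IC of the most informative common ancestor, normalized by
  the graph's maximum IC;
* **XGraSM** — mean IC of the informative (IC > 0) common ancestors,
  normalized by ``max(IC(a), IC(b))``;
* **AggregateIC** — ``2 * sum sw(c)`` over common ancestors divided by
  ``SV+(a) + SV+(b)``, where ``SV+`` augments a term's SV by its own sw,
  so a term is perfectly similar to itself.

Common-ancestor sets are inclusive (each term counts among its own
ancestors here).  Two enriched terms are compared through the mean
similarity of their standardized mapping sets; two species through the
best-match-average of their enriched sets; distance is 1 - similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enrichment import SemanticProfile
from .ontology import OntologyGraph, TermMetrics

__all__ = [
    "SimilarityMatrix",
    "DistanceMatrix",
    "build_similarity_matrix",
    "pairwise_term_similarity",
    "enriched_term_similarity",
    "species_similarity",
    "build_distance_matrix",
]

METRICS = ("resnik", "xgrasm", "aic", "consensus")


@dataclass
class SimilarityMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.matrix[self.index[a], self.index[b]])

    def to_tsv(self, path: str | Path) -> None:
        _square_to_tsv(self.ids, self.matrix, path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SimilarityMatrix":
        ids, m = _square_from_tsv(path)
        return cls(ids, m)


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self):
        self.index = {t: i for i, t in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        return float(self.matrix[self.index[a], self.index[b]])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = [self.index[i] for i in ids]
        return DistanceMatrix(tuple(ids), self.matrix[np.ix_(idx, idx)])

    def to_tsv(self, path: str | Path) -> None:
        _square_to_tsv(self.ids, self.matrix, path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        """Reader for square TSV matrices, including externally computed
        (e.g. sequence-alignment) distance matrices in the same dialect."""
        ids, m = _square_from_tsv(path)
        return cls(ids, m)


def _square_to_tsv(ids, matrix, path):
    pd.DataFrame(matrix, index=list(ids), columns=list(ids)).to_csv(path, sep="\t")

def _square_from_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: matrix rows and columns differ")
    return tuple(str(i) for i in df.index), df.to_numpy(dtype=float)


def _ancestor_matrix(g: OntologyGraph, ids: Sequence[str]) -> np.ndarray:
    """Boolean T x T matrix of inclusive ancestry: A[i, j] = term j is an
    ancestor-or-self of term i."""
    index = {t: i for i, t in enumerate(ids)}
    A = np.zeros((len(ids), len(ids)), dtype=bool)
    for i, t in enumerate(ids):
        A[i, i] = True
        for a in g.ancestors(t):
            A[i, index[a]] = True
    return A


def build_similarity_matrix(
    g: OntologyGraph, m: TermMetrics, metric: str = "consensus"
) -> SimilarityMatrix:
    """Global term-by-term similarity over all terms of the (standardized) graph.

    *g* should be the standardized subgraph and *m* its recomputed
    metrics, so that every enriched mapping target is covered.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    ids = tuple(sorted(g.terms))
    A = _ancestor_matrix(g, ids)
    ic = np.array([m.ic[t] for t in ids])
    sw = np.array([m.sw[t] for t in ids])
    sv_plus = np.array([m.sv[t] + m.sw[t] for t in ids])
    T = len(ids)

    with np.errstate(invalid="ignore", divide="ignore"):
        parts = []
        if metric in ("resnik", "consensus"):
            ic_max = ic.max()
            mica = np.zeros((T, T))
            # descending-IC sweep: the first ancestor to touch a pair is
            # its most informative common ancestor
            for j in np.argsort(ic, kind="stable")[::-1]:
                desc = np.flatnonzero(A[:, j])  # terms having j as ancestor-or-self
                blk = np.ix_(desc, desc)
                cur = mica[blk]
                mica[blk] = np.where(cur > 0, cur, ic[j])
            parts.append(mica / ic_max if ic_max > 0 else np.zeros((T, T)))
        if metric in ("xgrasm", "consensus"):
            informative = A & (ic > 0)[None, :]
            Af = informative.astype(float)
            ic_sum = (Af * ic[None, :]) @ Af.T
            counts = Af @ Af.T
            denom = np.maximum.outer(ic, ic)
            mean_ic = np.where(counts > 0, ic_sum / np.maximum(counts, 1), 0.0)
            xg = np.where(denom > 0, mean_ic / denom, 0.0)
            parts.append(xg)
        if metric in ("aic", "consensus"):
            Aw = A * sw[None, :]
            common_sw = Aw @ A.T.astype(float)
            aic = 2.0 * common_sw / np.add.outer(sv_plus, sv_plus)
            parts.append(aic)
    S = np.mean(parts, axis=0)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)  # enforce exact symmetry
    return SimilarityMatrix(ids, S)


def pairwise_term_similarity(
    a: str,
    b: str,
    m: TermMetrics,
    g: OntologyGraph,
    metric: str = "consensus",
) -> float:
    """Similarity of two retained terms (scalar form of the global matrix)."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    for t in (a, b):
        if t not in g:
            raise ValueError(f"unknown term: {t!r}")
    anc_a = set(g.ancestors(a)) | {a}
    anc_b = set(g.ancestors(b)) | {b}
    common = anc_a & anc_b
    vals = []
    if metric in ("resnik", "consensus"):
        ic_max = m.ic_max
        mica = max((m.ic[c] for c in common), default=0.0)
        vals.append(mica / ic_max if ic_max > 0 else 0.0)
    if metric in ("xgrasm", "consensus"):
        informative = [m.ic[c] for c in common if m.ic[c] > 0]
        denom = max(m.ic[a], m.ic[b])
        vals.append(
            (sum(informative) / len(informative)) / denom if informative and denom > 0 else 0.0
        )
    if metric in ("aic", "consensus"):
        num = 2.0 * sum(m.sw[c] for c in common)
        den = (m.sv[a] + m.sw[a]) + (m.sv[b] + m.sw[b])
        vals.append(num / den)
    return float(np.clip(np.mean(vals), 0.0, 1.0))


def enriched_term_similarity(
    map_a: Iterable[str], map_b: Iterable[str], S: SimilarityMatrix
) -> float:
    """Mean similarity over the cross product of two mapping-target sets."""
    ia = [S.index[t] for t in map_a]
    ib = [S.index[t] for t in map_b]
    if not ia or not ib:
        raise ValueError("empty mapping set")
    return float(S.matrix[np.ix_(ia, ib)].mean())


def _profile_indicator(p: SemanticProfile, S: SimilarityMatrix) -> np.ndarray:
    """Row-normalized enriched-term x graph-term indicator of mapping sets."""
    if not p.mapping:
        raise ValueError(f"profile of {p.species!r} has no standardized mapping")
    E = np.zeros((len(p.records), len(S.ids)))
    for i, r in enumerate(p.records):
        idx = [S.index[t] for t in p.mapping[r.term]]
        E[i, idx] = 1.0 / len(idx)
    return E


def species_similarity(
    p1: SemanticProfile, p2: SemanticProfile, S: SimilarityMatrix
) -> float:
    """Best-match-average similarity of two semantic profiles.

    Each enriched term contributes its best match against the other
    profile; the two directed sums are divided by the total term count
    ``|N| + |M|``.
    """
    E1 = _profile_indicator(p1, S)
    E2 = _profile_indicator(p2, S)
    cross = E1 @ S.matrix @ E2.T  # enriched-term level similarities
    return float((cross.max(axis=1).sum() + cross.max(axis=0).sum()) / (len(p1) + len(p2)))


def build_distance_matrix(
    profiles: Sequence[SemanticProfile], S: SimilarityMatrix
) -> DistanceMatrix:
    """Species distance matrix ``d = 1 - SSim`` with a forced zero diagonal."""
    if len(profiles) < 2:
        raise ValueError("need at least two species")
    profiles = sorted(profiles, key=lambda p: p.species)
    ids = tuple(p.species for p in profiles)
    E = [_profile_indicator(p, S) for p in profiles]
    P = [e @ S.matrix for e in E]  # precomputed projections
    n = len(profiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            cross = P[i] @ E[j].T
            ssim = (cross.max(axis=1).sum() + cross.max(axis=0).sum()) / (
                len(profiles[i]) + len(profiles[j])
            )
            if not (0.0 <= ssim <= 1.0 + 1e-9):
                raise RuntimeError(
                    f"similarity out of bounds for ({ids[i]}, {ids[j]}): {ssim}"
                )
            d[i, j] = d[j, i] = 1.0 - min(ssim, 1.0)
    return DistanceMatrix(ids, d)
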