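"""Per-species gene annotations, gene lists and the species coverage filter."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationCorpus",
    "SpeciesGeneSet",
    "load_annotations",
    "load_gene_list",
    "propagate",
    "coverage_filter",
]


@dataclass(frozen=True)
class SpeciesGeneSet:
    """A named gene list for one species (e.g. a proteostasis seed list)."""

    species: str
    genes: frozenset[str]
    label: str = ""

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"empty gene set for species {self.species!r}")

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class AnnotationCorpus:
    """gene -> term-set annotation maps, keyed by species."""

    annotations: dict[str, dict[str, frozenset[str]]] = field(default_factory=dict)

    @property
    def species(self) -> list[str]:
        return sorted(self.annotations)

    def genes(self, species: str) -> frozenset[str]:
        """The species' annotated gene universe."""
        return frozenset(self.annotations[species])

    def terms(self, species: str) -> frozenset[str]:
        out: set[str] = set()
        for ts in self.annotations[species].values():
            out |= ts
        return frozenset(out)

    def term_to_genes(self, species: str) -> dict[str, frozenset[str]]:
        """Inverted index: term -> genes annotated to it."""
        inv: dict[str, set[str]] = {}
        for gene, ts in self.annotations[species].items():
            for t in ts:
                inv.setdefault(t, set()).add(gene)
        return {t: frozenset(gs) for t, gs in inv.items()}

    def merge(self, other: "AnnotationCorpus") -> "AnnotationCorpus":
        merged = {sp: dict(g2t) for sp, g2t in self.annotations.items()}
        for sp, g2t in other.annotations.items():
            tgt = merged.setdefault(sp, {})
            for gene, ts in g2t.items():
                tgt[gene] = frozenset(tgt.get(gene, frozenset()) | ts)
        return AnnotationCorpus(merged)


def _parse_gaf(lines: Iterable[str]):
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            logger.warning("skipping malformed GAF line %d (%d columns)", i, len(cols))
            continue
        qualifier = cols[3]
        if "NOT" in qualifier.split("|"):
            continue
        yield cols[1], cols[4]


def _parse_tsv(lines: Iterable[str]):
    for i, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) < 2 or not cols[0] or not cols[1]:
            logger.warning("skipping malformed annotation line %d", i)
            continue
        yield cols[0], cols[1]


def load_annotations(
    path: str | Path,
    species: str,
    ontology: OntologyGraph | None = None,
    fmt: str | None = None,
) -> AnnotationCorpus:
    """Load one species' gene -> term annotations from GAF 2.x or 2-column TSV.

    Format is sniffed from the extension unless *fmt* ("gaf"/"tsv") is
    given.  NOT-qualified GAF rows are skipped, duplicates collapsed,
    and terms absent from *ontology* (when provided) logged and dropped.
    """
    path = Path(path)
    if fmt is None:
        fmt = "gaf" if path.suffix.lower() == ".gaf" else "tsv"
    parser = _parse_gaf if fmt == "gaf" else _parse_tsv
    g2t: dict[str, set[str]] = {}
    n_dropped = 0
    with open(path) as fh:
        for gene, term in parser(fh):
            if ontology is not None and term not in ontology:
                n_dropped += 1
                continue
            g2t.setdefault(gene, set()).add(term)
    if n_dropped:
        logger.warning("%s: dropped %d annotations to unknown terms", path, n_dropped)
    if not g2t:
        raise ValueError(f"no usable annotation rows in {path}")
    return AnnotationCorpus({species: {g: frozenset(ts) for g, ts in g2t.items()}})


def load_gene_list(path: str | Path, species: str, label: str = "") -> SpeciesGeneSet:
    """One identifier per line; blank lines and '#' comments ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.add(line)
    return SpeciesGeneSet(species=species, genes=frozenset(genes), label=label)


def propagate(c: AnnotationCorpus, g: OntologyGraph) -> AnnotationCorpus:
    """Close every gene's term set under ancestors (true-path rule, root excluded)."""
    closure: dict[frozenset[str], frozenset[str]] = {}
    out: dict[str, dict[str, frozenset[str]]] = {}
    for sp, g2t in c.annotations.items():
        new: dict[str, frozenset[str]] = {}
        for gene, ts in g2t.items():
            if ts not in closure:
                acc = set(ts)
                for t in ts:
                    acc |= g.ancestors(t)
                acc.discard(g.root)
                closure[ts] = frozenset(acc)
            new[gene] = closure[ts]
        out[sp] = new
    return AnnotationCorpus(out)


def coverage_filter(
    sets: Iterable[SpeciesGeneSet],
    reference: SpeciesGeneSet | Mapping[str, SpeciesGeneSet],
    frac: float = 0.75,
) -> list[SpeciesGeneSet]:
    """Keep species whose gene list reaches *frac* of the reference size.

    The boundary is inclusive: ``|genes| >= frac * |reference|``.  A
    mapping of per-species references may be supplied for heterogeneous
    reference lists; otherwise one reference applies to all.
    """
    kept = []
    for s in sets:
        ref = reference[s.species] if isinstance(reference, Mapping) else reference
        if len(s) >= frac * len(ref):
            kept.append(s)
        else:
            logger.info(
                "coverage filter dropped %s (%d < %.0f%% of %d)",
                s.species, len(s), 100 * frac, len(ref),
            )
    return kept
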