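"""Synthetic ontologies and annotation corpora with planted kingdom structure.

The generator emulates the study conditions end to end without any
external download: a random rooted DAG stands in for the biological
process ontology, and each simulated species receives a private,
namespaced gene universe annotated over that DAG.  Evolutionary
structure is planted through term modules — one *core* module shared by
every species (the conserved machinery) and one module per kingdom
(kingdom-specific components).  A species' query gene list draws a
configurable fraction of its genes from the gene pools of its modules
(the signal) and the rest uniformly; annotations are independently
rewired at a configurable noise rate.

Defaults are the conditions used throughout the test suite: 3 kingdoms
of 20 species, a 150-term DAG of depth 5, 260 genes per species, query
lists of 50 genes, signal 0.9 and noise 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .corpus import AnnotationCorpus, SpeciesGeneSet
from .ontology import OntologyGraph

__all__ = ["SynthConfig", "PlantedCorpus", "generate_dag", "generate_kingdom_corpus", "write_corpus"]

KINGDOMS = ("archaea", "bacteria", "eukaryota")


@dataclass
class SynthConfig:
    n_terms: int = 300
    depth: int = 6
    n_branches: int = 8
    cross_link_prob: float = 0.25
    n_species_per_kingdom: int = 20
    n_genes: int = 260
    annotations_per_gene: tuple[int, int] = (1, 3)
    core_module_size: int = 4
    kingdom_module_size: int = 8
    genes_per_module_term: int = 5
    query_size: int = 70
    signal: float = 0.9
    noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_terms < 2:
            raise ValueError("n_terms must be >= 2")
        if not 0 <= self.noise < 1:
            raise ValueError("noise must be in [0, 1)")
        if not 0 <= self.signal <= 1:
            raise ValueError("signal must be in [0, 1]")


@dataclass
class PlantedCorpus:
    """A generated corpus together with its ground truth."""

    graph: OntologyGraph
    corpus: AnnotationCorpus
    gene_sets: dict[str, SpeciesGeneSet]
    truth: dict[str, str]  # species -> kingdom
    core_terms: frozenset[str]
    kingdom_terms: dict[str, frozenset[str]] = field(default_factory=dict)


def generate_dag(cfg: SynthConfig) -> OntologyGraph:
    """Random rooted DAG of balanced top-level branches.

    ``n_branches`` depth-1 terms root comparably sized branches, the
    way real process ontologies split into top-level domains.  Within a
    branch, terms spread over ``depth`` layers of geometrically growing
    width, each attaching to one parent of the branch's previous layer;
    with probability ``cross_link_prob`` a term gains a second parent,
    usually within its branch and occasionally across branches (the
    sparse cross-links of real ontologies).  Acyclic by construction;
    every term reaches the root.
    """
    rng = np.random.default_rng(cfg.seed)
    terms = [f"SYN:{i:07d}" for i in range(cfg.n_terms)]
    n_inner = cfg.n_terms - 1 - cfg.n_branches
    if n_inner < cfg.n_branches:
        raise ValueError("n_terms too small for the requested branch count")
    root = terms[0]
    branch_roots = terms[1 : cfg.n_branches + 1]
    edges: list[tuple[str, str]] = [(b, root) for b in branch_roots]
    # per-branch member counts, nearly equal
    counts = [n_inner // cfg.n_branches] * cfg.n_branches
    for i in range(n_inner % cfg.n_branches):
        counts[i] += 1
    weights = np.array([1.6**i for i in range(2, cfg.depth + 1)])
    pos = cfg.n_branches + 1
    branch_layers: list[list[list[str]]] = []
    for b, cnt in enumerate(counts):
        sizes = np.maximum(0, np.round(cnt * weights / weights.sum()).astype(int))
        while sizes.sum() > cnt:
            sizes[np.argmax(sizes)] -= 1
        while sizes.sum() < cnt:
            sizes[np.argmax(weights)] += 1
        layers = [[branch_roots[b]]]
        for s in sizes:
            layers.append(terms[pos : pos + int(s)])
            pos += int(s)
        branch_layers.append(layers)
    all_upper: list[list[str]] = [list(branch_roots)]  # per depth, any branch
    max_layers = max(len(bl) for bl in branch_layers)
    for li in range(1, max_layers):
        this_level: list[str] = []
        for b, layers in enumerate(branch_layers):
            if li >= len(layers) or not layers[li]:
                continue
            prev = next(
                layers[j] for j in range(li - 1, -1, -1) if layers[j]
            )
            for t in layers[li]:
                edges.append((t, str(rng.choice(prev))))
                if rng.random() < cfg.cross_link_prob:
                    pool = prev if rng.random() < 0.8 else all_upper[li - 1]
                    extra = str(rng.choice(pool))
                    if extra != edges[-1][1]:
                        edges.append((t, extra))
            this_level.extend(layers[li])
        all_upper.append(this_level if this_level else all_upper[-1])
    return OntologyGraph.from_edges(terms, edges)


def _layer_of(g: OntologyGraph, term: str) -> int:
    return g.root_distance(term)


def _pick_modules(
    cfg: SynthConfig, g: OntologyGraph, rng
) -> tuple[frozenset[str], dict[str, frozenset[str]]]:
    """Choose module term sets in distinct top-level branches.

    Each module (core plus one per kingdom) is anchored at its own
    depth-1 term and drawn from that branch's exclusive descendants at
    depth >= 2, so modules occupy semantically distant ontology regions
    the way distinct biological machineries do.
    """
    anchors_all = sorted(g.children(g.root))
    # partition deep terms by an owning top-level branch: a term reachable
    # from several depth-1 anchors is owned by exactly one (preferring
    # single-anchor terms keeps modules branch-local)
    desc = {a: set(g.descendants(a)) | {a} for a in anchors_all}
    exclusive: dict[str, list[str]] = {a: [] for a in anchors_all}
    for t in sorted(g.terms):
        if _layer_of(g, t) < 2:
            continue
        owners = [a for a in anchors_all if t in desc[a]]
        if len(owners) == 1:
            exclusive[owners[0]].append(t)
    shared_deep = [
        t for t in sorted(g.terms)
        if _layer_of(g, t) >= 2 and sum(t in desc[a] for a in anchors_all) > 1
    ]
    for t in shared_deep:
        owners = [a for a in anchors_all if t in desc[a]]
        owner = owners[int(rng.integers(len(owners)))]
        exclusive[owner].append(t)
    labelled = sorted(
        [("core", cfg.core_module_size)] + [(kd, cfg.kingdom_module_size) for kd in KINGDOMS],
        key=lambda x: -x[1],
    )
    # largest module gets the branch with the most exclusive capacity
    order = rng.permutation(len(anchors_all))
    ranked = sorted(anchors_all, key=lambda a: (-len(exclusive[a]), order[anchors_all.index(a)]))
    chosen = ranked[: len(labelled)]
    if len(chosen) < len(labelled) or any(
        len(exclusive[a]) < s for a, (_, s) in zip(chosen, labelled)
    ):
        raise ValueError(
            "ontology too small to host disjoint modules: need "
            f"{len(labelled)} branches with exclusive deep terms"
        )
    modules: dict[str, frozenset[str]] = {}
    for a, (label, s) in zip(chosen, labelled):
        # spread module terms over the anchor's child subtrees so they
        # occupy distinct sub-branches of the module's ontology region
        by_child: dict[str, list[str]] = {}
        pool = set(exclusive[a])
        for child in sorted(g.children(a)):
            sub = sorted((set(g.descendants(child)) | {child}) & pool)
            if sub:
                by_child[child] = sub
                pool -= set(sub)
        buckets = [list(rng.permutation(v)) for v in by_child.values()]
        rng.shuffle(buckets)
        picked: list[str] = []
        while len(picked) < s:
            for b in buckets:
                if b and len(picked) < s:
                    picked.append(b.pop())
        modules[label] = frozenset(picked)
    return modules["core"], {kd: modules[kd] for kd in KINGDOMS}


def generate_kingdom_corpus(cfg: SynthConfig, g: OntologyGraph) -> PlantedCorpus:
    """Plant core and kingdom-specific term modules into a species corpus.

    Module terms live in distinct top-level branches (see
    :func:`_pick_modules`).  Every species' query list draws its signal
    genes stratified across the module-term gene pools — so each module
    term individually accumulates enough overlap to be detectable — and
    fills the rest uniformly; each gene-term annotation is rewired to a
    random term with probability ``noise``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    non_root = sorted(g.terms - {g.root})
    core_terms, kingdom_terms = _pick_modules(cfg, g, rng)

    annotations: dict[str, dict[str, frozenset[str]]] = {}
    gene_sets: dict[str, SpeciesGeneSet] = {}
    truth: dict[str, str] = {}
    lo, hi = cfg.annotations_per_gene
    for kd in KINGDOMS:
        for si in range(cfg.n_species_per_kingdom):
            sp = f"{kd}_{si:03d}"
            truth[sp] = kd
            genes = [f"{sp}|g{j:05d}" for j in range(cfg.n_genes)]
            g2t: dict[str, set[str]] = {
                gene: set(rng.choice(non_root, size=int(rng.integers(lo, hi + 1)), replace=False))
                for gene in genes
            }
            # dedicated annotation pools make module terms testable
            module_terms = sorted(core_terms | kingdom_terms[kd])
            pools: dict[str, list[str]] = {}
            for t in module_terms:
                members = rng.choice(cfg.n_genes, size=cfg.genes_per_module_term, replace=False)
                for gi in members:
                    g2t[genes[gi]].add(t)
                pools[t] = [genes[gi] for gi in members]
            # annotation noise: rewire each gene-term link with prob noise
            if cfg.noise > 0:
                for gene in genes:
                    rewired = {
                        (str(rng.choice(non_root)) if rng.random() < cfg.noise else t)
                        for t in sorted(g2t[gene])
                    }
                    g2t[gene] = rewired
            annotations[sp] = {gene: frozenset(ts) for gene, ts in g2t.items()}
            # query gene list: stratified signal over module pools, rest uniform
            n_signal = int(round(cfg.query_size * cfg.signal))
            query: set[str] = set()
            order = [t for t in module_terms]
            rng.shuffle(order)
            shuffled_pools = {t: list(rng.permutation(pools[t])) for t in order}
            while len(query) < n_signal and any(shuffled_pools.values()):
                for t in order:
                    if len(query) >= n_signal:
                        break
                    if shuffled_pools[t]:
                        query.add(shuffled_pools[t].pop())
            others = [gn for gn in genes if gn not in query]
            fill = rng.choice(others, size=cfg.query_size - len(query), replace=False)
            query |= set(fill)
            gene_sets[sp] = SpeciesGeneSet(
                species=sp, genes=frozenset(query), label="PN seed"
            )
    return PlantedCorpus(
        graph=g,
        corpus=AnnotationCorpus(annotations),
        gene_sets=gene_sets,
        truth=truth,
        core_terms=core_terms,
        kingdom_terms=kingdom_terms,
    )


# -- file output (same formats the real pipeline reads) -----------------


def write_obo(g: OntologyGraph, path: str | Path) -> None:
    """Minimal OBO 1.2 serialization (id, name, is_a stanzas)."""
    lines = ["format-version: 1.2", "ontology: synthetic", ""]
    for t in sorted(g.terms):
        lines.append("[Term]")
        lines.append(f"id: {t}")
        lines.append(f"name: synthetic term {t.split(':')[1]}")
        for p in sorted(g.parents(t)):
            lines.append(f"is_a: {p} ! synthetic term")
        lines.append("")
    Path(path).write_text("\n".join(lines))


def write_corpus(pc: PlantedCorpus, outdir: str | Path) -> dict[str, Path]:
    """Write OBO, per-species annotation TSVs, gene lists and truth labels."""
    outdir = Path(outdir)
    ann_dir = outdir / "annotations"
    gl_dir = outdir / "genesets"
    ann_dir.mkdir(parents=True, exist_ok=True)
    gl_dir.mkdir(parents=True, exist_ok=True)
    obo = outdir / "ontology.obo"
    write_obo(pc.graph, obo)
    for sp in pc.corpus.species:
        rows = [
            f"{gene}\t{t}"
            for gene in sorted(pc.corpus.annotations[sp])
            for t in sorted(pc.corpus.annotations[sp][gene])
        ]
        (ann_dir / f"{sp}.tsv").write_text("\n".join(rows) + "\n")
        (gl_dir / f"{sp}.txt").write_text(
            "\n".join(sorted(pc.gene_sets[sp].genes)) + "\n"
        )
    truth_path = outdir / "truth.tsv"
    truth_path.write_text(
        "species\tkingdom\n"
        + "\n".join(f"{sp}\t{kd}" for sp, kd in sorted(pc.truth.items()))
        + "\n"
    )
    return {"obo": obo, "annotations": ann_dir, "genesets": gl_dir, "truth": truth_path}
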