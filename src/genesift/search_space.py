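"""Locus-to-gene search-space construction.

Six alternative SNP-to-gene mapping strategies translate associated loci
into candidate gene sets, under two families of assumption:

* nearest-neighbour (NN) — the causal gene is at or next to the signal:
  ``resident`` (genes containing a member SNP), ``nearest`` (resident
  plus, for each SNP outside every gene, the single closest gene) and
  ``adjacent`` (the four genes nearest to each member SNP, residents
  counting at distance zero);
* bystander (BY) — the causal gene may be under long-range regulation:
  all genes on either strand within flanking windows of total width
  0.1, 0.5 or 1 Mbp centred on each member SNP (half-width = width/2).

Distances are SNP-to-nearest-gene-boundary in base pairs; strand is
ignored throughout.  Coordinates are 0-based half-open (BED native).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
from intervaltree import IntervalTree

from .gwas_io import SnpRecord
from .loci import AssociatedLocus

logger = logging.getLogger(__name__)

__all__ = [
    "GeneModel",
    "GeneCatalog",
    "Approach",
    "APPROACHES",
    "SearchSpace",
    "load_gene_models",
    "build_search_space",
    "genome_coverage",
    "write_search_space",
]


@dataclass(frozen=True)
class GeneModel:
    """One gene interval (0-based half-open) on a chromosome."""

    gene_id: str
    symbol: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start >= end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def distance_to(self, pos: int) -> int:
        """bp distance from a SNP position to the nearest gene boundary; 0 inside."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - (self.end - 1)
        return 0


class GeneCatalog:
    """Indexed gene collection: lookup by id and by interval.

    Iteration order is deterministic (insertion order of the source).
    """

    def __init__(self, genes: Iterable[GeneModel] = ()):  # noqa: D107
        self.by_id: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        self._per_chrom: dict[str, list[GeneModel]] = {}
        self._arrays: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for g in genes:
            self.add(g)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self.by_id:
            raise ValueError(f"duplicate gene id {gene.gene_id!r}")
        self.by_id[gene.gene_id] = gene
        self._trees.setdefault(gene.chromosome, IntervalTree()).addi(
            gene.start, gene.end, gene.gene_id
        )
        self._per_chrom.setdefault(gene.chromosome, []).append(gene)
        self._arrays.pop(gene.chromosome, None)

    def __len__(self) -> int:
        return len(self.by_id)

    def __iter__(self):
        return iter(self.by_id.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.by_id

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._per_chrom)

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        return self._per_chrom.get(chromosome, [])

    def overlapping(self, chromosome: str, start: int, end: int) -> list[GeneModel]:
        """Genes whose interval intersects [start, end)."""
        tree = self._trees.get(chromosome)
        if tree is None:
            return []
        hits = [self.by_id[iv.data] for iv in tree.overlap(start, end)]
        hits.sort(key=lambda g: (g.start, g.gene_id))
        return hits

    def containing(self, chromosome: str, pos: int) -> list[GeneModel]:
        return self.overlapping(chromosome, pos, pos + 1)

    def _distance_arrays(self, chromosome: str) -> tuple[np.ndarray, np.ndarray]:
        # cached starts/ends in per-chromosome gene order, for vector distance
        cached = self._arrays.get(chromosome)
        if cached is None:
            genes = self._per_chrom.get(chromosome, [])
            starts = np.array([g.start for g in genes], dtype=np.int64)
            ends = np.array([g.end for g in genes], dtype=np.int64)
            cached = (starts, ends)
            self._arrays[chromosome] = cached
        return cached

    def distances(self, chromosome: str, pos: int) -> np.ndarray:
        """Boundary distance from pos to every gene on the chromosome."""
        starts, ends = self._distance_arrays(chromosome)
        if starts.size == 0:
            return starts
        return np.maximum(np.maximum(starts - pos, pos - (ends - 1)), 0)

    def k_nearest(self, chromosome: str, pos: int, k: int) -> list[GeneModel]:
        """The k genes with smallest boundary distance to pos.

        Ties break by (distance, start, gene_id) for determinism.
        """
        genes = self._per_chrom.get(chromosome, [])
        if not genes:
            return []
        dist = self.distances(chromosome, pos)
        order = sorted(
            range(len(genes)),
            key=lambda i: (dist[i], genes[i].start, genes[i].gene_id),
        )
        return [genes[i] for i in order[:k]]


@dataclass(frozen=True)
class Approach:
    """One of the six search-space construction strategies."""

    label: str
    family: str  # "NN" or "BY"
    width_bp: int = 0  # BY only: total flanking-interval width

    @property
    def half_width(self) -> int:
        return self.width_bp // 2


APPROACHES: Mapping[str, Approach] = {
    "resident": Approach("resident", "NN"),
    "nearest": Approach("nearest", "NN"),
    "adjacent": Approach("adjacent", "NN"),
    "by100k": Approach("by100k", "BY", 100_000),
    "by500k": Approach("by500k", "BY", 500_000),
    "by1m": Approach("by1m", "BY", 1_000_000),
}

APPROACH_ORDER: Sequence[str] = tuple(APPROACHES)


@dataclass
class SearchSpace:
    """Mapping from associated loci to candidate genes under one approach."""

    approach: Approach
    per_locus: dict[str, list[str]]
    distance: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def all_genes(self) -> set[str]:
        return {g for genes in self.per_locus.values() for g in genes}

    @property
    def loci_of_gene(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for locus_id, genes in self.per_locus.items():
            for g in genes:
                inv.setdefault(g, set()).add(locus_id)
        return inv


def load_gene_models(stream: TextIO | str) -> GeneCatalog:
    """Read gene models from BED6 (chrom, start, end, name, score, strand).

    The score field is ignored; the name field is both gene id and symbol.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return load_gene_models(fh)
    catalog = GeneCatalog()
    for lineno, line in enumerate(stream, 1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise ValueError(f"BED6 line {lineno}: expected 6 fields, got {len(fields)}")
        chrom, start_s, end_s, name, _score, strand = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ValueError(f"BED6 line {lineno}: non-integer coordinates") from exc
        if start >= end:
            raise ValueError(f"BED6 line {lineno}: start >= end for {name!r}")
        catalog.add(GeneModel(name, name, chrom, start, end, strand))
    return catalog


def _genes_for_snp(
    catalog: GeneCatalog, chrom: str, pos: int, approach: Approach
) -> list[GeneModel]:
    """Candidate genes captured by a single SNP under the approach."""
    if approach.family == "BY":
        hw = approach.half_width
        return [
            g
            for g in catalog.genes_on(chrom)
            if g.distance_to(pos) <= hw
        ]
    resident = catalog.containing(chrom, pos)
    if approach.label == "resident":
        return resident
    if approach.label == "nearest":
        if resident:
            return resident
        nearest = catalog.k_nearest(chrom, pos, 1)
        return nearest
    if approach.label == "adjacent":
        return catalog.k_nearest(chrom, pos, 4)
    raise ValueError(f"unknown approach {approach.label!r}")


def build_search_space(
    loci: Sequence[AssociatedLocus],
    catalog: GeneCatalog,
    approach: Approach | str,
) -> SearchSpace:
    """Construct the locus→gene search space for one approach.

    Per-locus gene lists are sorted by (distance to locus, gene id),
    where locus distance is the minimum boundary distance over member
    SNPs (0 for genes overlapping a member SNP).  A locus whose
    chromosome is absent from the catalog maps to an empty list.
    """
    if isinstance(approach, str):
        approach = APPROACHES[approach]
    per_locus: dict[str, list[str]] = {}
    dist_of: dict[tuple[str, str], int] = {}
    for locus in loci:
        if not catalog.genes_on(locus.chromosome):
            logger.warning(
                "locus %s: chromosome %s absent from gene catalog",
                locus.locus_id,
                locus.chromosome,
            )
            per_locus[locus.locus_id] = []
            continue
        captured: dict[str, int] = {}
        for snp in locus.members:
            for gene in _genes_for_snp(catalog, locus.chromosome, snp.position_bp, approach):
                d = gene.distance_to(snp.position_bp)
                prev = captured.get(gene.gene_id)
                if prev is None or d < prev:
                    captured[gene.gene_id] = d
        ordered = sorted(captured, key=lambda gid: (captured[gid], gid))
        per_locus[locus.locus_id] = ordered
        for gid in ordered:
            dist_of[(locus.locus_id, gid)] = captured[gid]
    return SearchSpace(approach=approach, per_locus=per_locus, distance=dist_of)


def genome_coverage(
    catalog: GeneCatalog,
    snp_universe: Sequence[SnpRecord],
    approach: Approach | str,
) -> tuple[float, dict[str, bool]]:
    """Fraction of catalog genes capturable by the chip under an approach.

    Every SNP of the universe is treated as its own singleton locus; a
    gene is covered if at least one SNP would place it in that locus'
    search space.  Returns the fraction and a per-gene flag table.
    """
    if isinstance(approach, str):
        approach = APPROACHES[approach]
    if len(catalog) == 0:
        raise ValueError("genome_coverage requires a non-empty catalog")
    covered: set[str] = set()
    if approach.family == "BY" or approach.label == "resident":
        # vectorized: count SNPs within the capture window of each gene
        pad = approach.half_width if approach.family == "BY" else 0
        by_chrom: dict[str, list[int]] = {}
        for s in snp_universe:
            by_chrom.setdefault(s.chromosome, []).append(s.position_bp)
        pos_sorted = {c: np.sort(np.array(p, dtype=np.int64)) for c, p in by_chrom.items()}
        for gene in catalog:
            pos = pos_sorted.get(gene.chromosome)
            if pos is None:
                continue
            lo = np.searchsorted(pos, gene.start - pad, side="left")
            hi = np.searchsorted(pos, gene.end - 1 + pad, side="right")
            if hi > lo:
                covered.add(gene.gene_id)
    else:
        for s in snp_universe:
            for gene in _genes_for_snp(catalog, s.chromosome, s.position_bp, approach):
                covered.add(gene.gene_id)
    flags = {g.gene_id: g.gene_id in covered for g in catalog}
    return len(covered) / len(catalog), flags


def write_search_space(space: SearchSpace, stream: TextIO) -> None:
    """Serialize as TSV: locus_id, gene_id, approach, distance_bp."""
    stream.write("locus_id\tgene_id\tapproach\tdistance_bp\n")
    for locus_id in sorted(space.per_locus):
        for gid in space.per_locus[locus_id]:
            d = space.distance.get((locus_id, gid), 0)
            stream.write(f"{locus_id}\t{gid}\t{space.approach.label}\t{d}\n")
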