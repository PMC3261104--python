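"""Clustering of significant SNPs into associated loci.

Co-located significant markers are merged by naive distance-based single
linkage: on each chromosome, consecutive markers at most ``gap_bp`` apart
(50 kb by default, roughly the average haplotype-block size) chain into
one maximal cluster, the *associated locus*.  Distance exactly equal to
the gap merges.  Every SNP belongs to exactly one locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO

from .gwas_io import SnpRecord

__all__ = ["AssociatedLocus", "cluster_snps", "write_bed4"]

DEFAULT_GAP_BP = 50_000


@dataclass(frozen=True)
class AssociatedLocus:
    """A maximal cluster of co-located significant SNPs.

    The span is 0-based half-open and covers every member position.
    """

    locus_id: str
    chromosome: str
    span_start: int
    span_end: int
    members: tuple[SnpRecord, ...] = field(repr=False)
    min_p: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("locus must have at least one member")
        if any(m.chromosome != self.chromosome for m in self.members):
            raise ValueError("locus members span chromosomes")
        positions = [m.position_bp for m in self.members]
        if not (self.span_start <= min(positions) and max(positions) < self.span_end):
            raise ValueError("locus span does not cover its members")

    @property
    def positions(self) -> list[int]:
        return [m.position_bp for m in self.members]


def cluster_snps(
    snps: Iterable[SnpRecord], gap_bp: int = DEFAULT_GAP_BP
) -> list[AssociatedLocus]:
    """Single-linkage chain SNPs within ``gap_bp`` of each other.

    Loci are maximal; locus ids are ``<chrom>_L<ordinal>`` with ordinals
    assigned per chromosome in positional order, so the labelling is
    deterministic for a given input set.
    """
    if gap_bp <= 0:
        raise ValueError("gap_bp must be positive")
    by_chrom: dict[str, list[SnpRecord]] = {}
    for s in snps:
        by_chrom.setdefault(s.chromosome, []).append(s)

    loci: list[AssociatedLocus] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda s: (s.position_bp, s.snp_id))
        cluster: list[SnpRecord] = [members[0]]
        ordinal = 1
        for s in members[1:]:
            if s.position_bp - cluster[-1].position_bp <= gap_bp:
                cluster.append(s)
            else:
                loci.append(_make_locus(chrom, ordinal, cluster))
                ordinal += 1
                cluster = [s]
        loci.append(_make_locus(chrom, ordinal, cluster))
    return loci


def _make_locus(chrom: str, ordinal: int, members: Sequence[SnpRecord]) -> AssociatedLocus:
    positions = [m.position_bp for m in members]
    return AssociatedLocus(
        locus_id=f"{chrom}_L{ordinal:03d}",
        chromosome=chrom,
        span_start=min(positions),
        span_end=max(positions) + 1,
        members=tuple(members),
        min_p=min(m.p_gwa for m in members),
    )


def write_bed4(loci: Iterable[AssociatedLocus], stream: TextIO) -> None:
    """Export loci as BED4 (chrom, start, end, locus_id)."""
    for loc in loci:
        stream.write(
            f"{loc.chromosome}\t{loc.span_start}\t{loc.span_end}\t{loc.locus_id}\n"
        )
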