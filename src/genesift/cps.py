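"""Common Pathway Scanning (CPS).

Candidate genes are predicted when a biomolecular pathway is
over-represented among phenotype-associated loci (and, in seeded mode,
known disease genes).  Significance comes from Fisher's exact test on a
2x2 bi-partition of "units" by (associated?, in pathway?).

To avoid inflating evidence from gene clusters, genes from the same
associated locus are deduplicated: each associated locus counts as one
unit, in the pathway if *any* of its search-space genes is a member.
Seed genes lying outside every associated locus contribute one extra
unit each.  The non-associated side counts individual annotated genome
genes outside all loci.  Pathways passing ``p_path < alpha`` (0.05 by
default, uncorrected) emit their search-space members as candidates,
prioritised by the pathway p-value; a gene in several significant
pathways inherits its best pathway's rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import fisher_exact as _scipy_fisher

from .annotations import PathwayDB
from .search_space import SearchSpace

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable2x2",
    "PathwayPrediction",
    "pathway_contingency",
    "fisher_exact_p",
    "cps_predict",
    "rank_candidate_genes",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of units bi-partitioned by (associated, in-pathway).

    a = associated & in pathway, b = associated & not, c = not
    associated & in pathway, d = neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def degenerate(self) -> bool:
        """A zero row or column margin makes the test uninformative."""
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


@dataclass(frozen=True)
class PathwayPrediction:
    """A significant pathway with the candidate genes it implicates."""

    pathway_id: str
    p_path: float
    candidate_genes: frozenset[str]
    supporting_loci: frozenset[str]
    seed_support: frozenset[str] = frozenset()
    rank: int = 0
    table: ContingencyTable2x2 | None = field(default=None, compare=False)


def pathway_contingency(
    pathway_genes: frozenset[str] | set[str],
    space: SearchSpace,
    seeds: Iterable[str],
    universe: set[str],
) -> ContingencyTable2x2:
    """Build the locus-deduplicated 2x2 table for one pathway.

    Associated units: one per locus holding >=1 annotated search-space
    gene (in cell *a* if any such gene is in the pathway), plus one per
    annotated seed not already inside an associated locus (in *a* if the
    seed is a pathway member).  Non-associated units: annotated genome
    genes outside every locus and not seeds.
    """
    if not universe:
        raise ValueError("empty annotated universe")
    seeds = set(seeds)
    space_genes = space.all_genes & universe

    a = b = 0
    for locus_id, genes in space.per_locus.items():
        annotated = [g for g in genes if g in universe]
        if not annotated:
            continue
        if any(g in pathway_genes for g in annotated):
            a += 1
        else:
            b += 1
    for seed in sorted(seeds):
        if seed not in universe or seed in space_genes:
            continue  # seeds inside a locus are merged into the locus unit
        if seed in pathway_genes:
            a += 1
        else:
            b += 1

    outside = universe - space_genes - seeds
    c = sum(1 for g in outside if g in pathway_genes)
    d = len(outside) - c
    return ContingencyTable2x2(a, b, c, d)


def fisher_exact_p(
    table: ContingencyTable2x2, sided: str = "greater"
) -> float:
    """Exact hypergeometric tail probability of the 2x2 table.

    ``greater`` is the over-representation tail (more pathway hits on
    the associated side than expected at fixed margins).  Degenerate
    margins return 1.0 by convention.
    """
    if sided not in ("greater", "two_sided"):
        raise ValueError(f"unknown sidedness {sided!r}")
    if table.degenerate:
        logger.debug("degenerate contingency margins; p = 1.0")
        return 1.0
    alternative = "greater" if sided == "greater" else "two-sided"
    res = _scipy_fisher([[table.a, table.b], [table.c, table.d]], alternative=alternative)
    return float(min(res.pvalue, 1.0))


def _dense_ranks(values: Sequence[float]) -> list[int]:
    """Ordinal ranks on sorted values, ties sharing a rank (1, 1, 2, ...)."""
    ranks: list[int] = []
    rank = 0
    prev: float | None = None
    for v in values:
        if prev is None or v != prev:
            rank += 1
            prev = v
        ranks.append(rank)
    return ranks


def cps_predict(
    space: SearchSpace,
    pdb: PathwayDB,
    universe: set[str],
    mode: str,
    seeds: Iterable[str] = (),
    alpha: float = 0.05,
    sided: str = "greater",
    bonferroni: bool = False,
) -> list[PathwayPrediction]:
    """Predict candidate genes from over-represented pathways.

    Seeded mode tests pathways holding >=1 seed and >=1 annotated
    non-seed search-space gene; ab initio mode tests pathways whose
    search-space members span >=2 distinct loci.  Surviving pathways
    (p_path < alpha, uncorrected by default; ``bonferroni`` divides
    alpha by the number of pathways tested) emit their annotated
    search-space members (excluding seeds) as candidates, sorted by
    ascending p with tied p-values sharing a rank.
    """
    seeds = set(seeds)
    if mode not in ("seeded", "ab_initio"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "seeded" and not seeds:
        raise ValueError("seeded mode requires a non-empty seed list")
    if mode == "ab_initio":
        seeds = set()  # ab initio uses only genes pooled from the search space

    loci_of_gene = space.loci_of_gene
    space_genes = space.all_genes & universe

    testable: list[tuple[str, set[str], set[str]]] = []
    for pid in sorted(pdb.pathways):
        members = pdb.members(pid)
        in_space = {g for g in members if g in space_genes}
        candidates = in_space - seeds
        supporting = {loc for g in in_space for loc in loci_of_gene.get(g, ())}
        if mode == "seeded":
            if not (members & seeds) or not candidates:
                continue
        else:
            if len(supporting) < 2:
                continue  # needs genes from at least two distinct loci
        testable.append((pid, candidates, supporting))

    alpha_eff = alpha / len(testable) if (bonferroni and testable) else alpha
    rows: list[PathwayPrediction] = []
    for pid, candidates, supporting in testable:
        members = pdb.members(pid)
        table = pathway_contingency(members, space, seeds, universe)
        p = fisher_exact_p(table, sided=sided)
        if p >= alpha_eff or not candidates:
            continue
        rows.append(
            PathwayPrediction(
                pathway_id=pid,
                p_path=p,
                candidate_genes=frozenset(candidates),
                supporting_loci=frozenset(supporting),
                seed_support=frozenset(members & seeds),
                table=table,
            )
        )
    rows.sort(key=lambda r: (r.p_path, r.pathway_id))
    ranks = _dense_ranks([r.p_path for r in rows])
    return [
        PathwayPrediction(
            pathway_id=r.pathway_id,
            p_path=r.p_path,
            candidate_genes=r.candidate_genes,
            supporting_loci=r.supporting_loci,
            seed_support=r.seed_support,
            rank=rank,
            table=r.table,
        )
        for r, rank in zip(rows, ranks)
    ]


def rank_candidate_genes(
    predictions: Sequence[PathwayPrediction],
) -> dict[str, int]:
    """Per-gene rank: the best (lowest-p) pathway's rank for each gene."""
    out: dict[str, int] = {}
    for pred in predictions:
        for g in pred.candidate_genes:
            if g not in out or pred.rank < out[g]:
                out[g] = pred.rank
    return out


def write_predictions(
    predictions: Sequence[PathwayPrediction],
    stream,
    phenotype: str = "-",
    approach: str = "-",
    tier: str = "-",
    mode: str = "-",
) -> None:
    """TSV: phenotype, approach, tier, mode, pathway, p, rank, gene, loci, seeds."""
    stream.write(
        "phenotype\tapproach\ttier\tmode\tpathway_id\tp_path\trank\tgene_id\tlocus_id\tseed_support\n"
    )
    for pred in predictions:
        loci = ",".join(sorted(pred.supporting_loci)) or "-"
        seedsup = ",".join(sorted(pred.seed_support)) or "-"
        for g in sorted(pred.candidate_genes):
            stream.write(
                f"{phenotype}\t{approach}\t{tier}\t{mode}\t{pred.pathway_id}\t"
                f"{pred.p_path:.6g}\t{pred.rank}\t{g}\t{loci}\t{seedsup}\n"
            )
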