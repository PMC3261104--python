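"""Common Module Profiling (CMP): domain-content candidate prediction.

Seeded mode scores every annotated search-space gene against every
annotated seed with a weighted-Jaccard similarity over domain multisets
(0 = no shared domains, 1 = identical signature) and keeps pairs at or
above 0.4.

Ab initio mode tests each distinct domain combination found in the
search space for over-representation against the genome background.
With f(d) the fraction of annotated genome genes carrying domain d, the
chance occurrence probability of a combination is bracketed between two
correlation extrema:

* maximal correlation — the combination occurs whenever its rarest
  domain does: ``p_corr = min_d f(d)``;
* full independence counting copies: ``p_indep = prod_d f(d)^copies``
  (duplicated domains drive this anomalously low, hence also the
  copy-blind ``p_indep_unique = prod_d f(d)`` over distinct domains).

Each probability yields an expected count n*p over the n annotated
search-space genes and a one-sided chi-square statistic
``(obs - exp)^2 / exp`` (0 when obs <= exp): chi2_min from p_corr,
chi2_max from p_indep, chi2_max_unique from p_indep_unique.  A value
above 7.88 would be significant at the 0.005 level (1 df), but the
adopted cutoffs are deliberately conservative: chi2_max_unique >= 1e5
for multidomain combinations and chi2_min >= 1e2 for single-domain
ones.  Combinations must be carried by genes in at least two distinct
loci; carriers are emitted ordered by descending chi2_min, the priority
metric.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .annotations import DomainDB
from .search_space import SearchSpace

logger = logging.getLogger(__name__)

__all__ = [
    "DomainCombination",
    "CombinationStats",
    "DomainPrediction",
    "similarity_score",
    "cmp_seeded",
    "combination_stats",
    "cmp_ab_initio",
    "CHI2_SIGNIFICANCE_ANCHOR",
]

#: chi-square value significant at the 0.005 level with 1 df.
CHI2_SIGNIFICANCE_ANCHOR = 7.88

DEFAULT_SIMILARITY_THRESHOLD = 0.4
DEFAULT_CUT_MULTIDOMAIN = 1e5
DEFAULT_CUT_SINGLEDOMAIN = 1e2


@dataclass(frozen=True)
class DomainCombination:
    """A gene's domain signature as a multiset of domain ids."""

    gene_id: str
    domains: tuple[tuple[str, int], ...]  # sorted (domain_id, copies)

    @classmethod
    def from_signature(cls, gene_id: str, signature: Mapping[str, int]) -> "DomainCombination":
        if not signature:
            raise ValueError(f"gene {gene_id!r} has an empty domain signature")
        return cls(gene_id, tuple(sorted(signature.items())))

    @property
    def distinct_domains(self) -> frozenset[str]:
        return frozenset(d for d, _c in self.domains)

    @property
    def is_multidomain(self) -> bool:
        return len(self.domains) >= 2

    @property
    def signature(self) -> Counter:
        return Counter(dict(self.domains))


@dataclass(frozen=True)
class CombinationStats:
    """Occurrence probabilities, expectations and chi-square triple."""

    p_corr: float
    p_indep: float
    p_indep_unique: float
    expected_corr: float
    expected_indep: float
    expected_indep_unique: float
    observed: int
    chi2_min: float
    chi2_max: float
    chi2_max_unique: float


@dataclass(frozen=True)
class DomainPrediction:
    """A candidate gene supported by domain-content evidence."""

    gene_id: str
    mode: str  # "seeded" | "ab_initio"
    score: float  # similarity in [0,1] (seeded) or chi2_min (ab initio)
    combination: DomainCombination
    seed_gene: str | None = None
    supporting_loci: frozenset[str] = frozenset()
    rank: int = 0
    stats: CombinationStats | None = field(default=None, compare=False)


def similarity_score(sig_a: Mapping[str, int], sig_b: Mapping[str, int]) -> float:
    """Weighted Jaccard between two domain multisets.

    sum over domains of min(copies) divided by sum of max(copies);
    symmetric, 1 iff the multisets are identical, 0 iff the domain sets
    are disjoint.
    """
    if not sig_a or not sig_b:
        raise ValueError("similarity_score requires non-empty signatures")
    domains = set(sig_a) | set(sig_b)
    num = sum(min(sig_a.get(d, 0), sig_b.get(d, 0)) for d in domains)
    den = sum(max(sig_a.get(d, 0), sig_b.get(d, 0)) for d in domains)
    return num / den


def _dense_ranks_desc(values: Sequence[float]) -> list[int]:
    ranks: list[int] = []
    rank = 0
    prev: float | None = None
    for v in values:
        if prev is None or v != prev:
            rank += 1
            prev = v
        ranks.append(rank)
    return ranks


def cmp_seeded(
    space: SearchSpace,
    seeds: Iterable[str],
    ddb: DomainDB,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    similarity: Callable[[Mapping[str, int], Mapping[str, int]], float] = similarity_score,
) -> list[DomainPrediction]:
    """Score annotated search-space genes against annotated seeds.

    Each non-seed annotated gene takes its maximum similarity over all
    annotated seeds and is emitted when that score is at or above the
    threshold (0.4 by default, read inclusively).  The pairwise scoring
    function is pluggable; the default is the weighted Jaccard above.
    Output is ordered by descending score; ties share a rank.
    """
    seeds = set(seeds)
    if not seeds:
        raise ValueError("seeded mode requires a non-empty seed list")
    annotated_seeds = sorted(s for s in seeds if s in ddb.signature_of_gene)
    if not annotated_seeds:
        logger.warning("cmp_seeded: no seed carries domain annotation; no predictions")
        return []
    loci_of_gene = space.loci_of_gene
    rows: list[DomainPrediction] = []
    for gene in sorted(space.all_genes - seeds):
        sig = ddb.signature_of_gene.get(gene)
        if not sig:
            continue
        best_score, best_seed = 0.0, None
        for seed in annotated_seeds:
            s = similarity(sig, ddb.signature_of_gene[seed])
            if s > best_score:
                best_score, best_seed = s, seed
        if best_seed is not None and best_score >= threshold:
            rows.append(
                DomainPrediction(
                    gene_id=gene,
                    mode="seeded",
                    score=best_score,
                    combination=DomainCombination.from_signature(gene, sig),
                    seed_gene=best_seed,
                    supporting_loci=frozenset(loci_of_gene.get(gene, ())),
                )
            )
    rows.sort(key=lambda r: (-r.score, r.gene_id))
    ranks = _dense_ranks_desc([r.score for r in rows])
    return [
        DomainPrediction(
            gene_id=r.gene_id,
            mode=r.mode,
            score=r.score,
            combination=r.combination,
            seed_gene=r.seed_gene,
            supporting_loci=r.supporting_loci,
            rank=rank,
        )
        for r, rank in zip(rows, ranks)
    ]


def combination_stats(
    combination: DomainCombination,
    space_genes: Iterable[str],
    ddb: DomainDB,
    match_copies: bool = False,
) -> CombinationStats:
    """Over-representation statistics of one domain combination.

    ``observed`` counts annotated search-space genes whose signature
    contains every distinct domain of the combination; copy counts are
    ignored for matching unless ``match_copies`` demands at least the
    combination's copy number of each domain.  Expected counts are n*p
    for each occurrence probability; each chi-square is (obs-exp)^2/exp,
    floored at 0 when the combination is not over-represented.
    """
    freqs = {d: ddb.frequency(d) for d in combination.distinct_domains}
    p_corr = min(freqs.values())
    p_indep_unique = math.prod(sorted(freqs.values()))
    # factor out the copy-blind product so p_indep <= p_indep_unique exactly,
    # copies == 1 giving bit-identical values
    p_indep = p_indep_unique * math.prod(
        freqs[d] ** (c - 1) for d, c in combination.domains if c > 1
    )

    annotated = [g for g in space_genes if g in ddb.signature_of_gene]
    n = len(annotated)
    if match_copies:
        observed = sum(
            1
            for g in annotated
            if all(ddb.signature_of_gene[g].get(d, 0) >= c for d, c in combination.domains)
        )
    else:
        wanted = combination.distinct_domains
        observed = sum(
            1 for g in annotated if wanted <= set(ddb.signature_of_gene[g])
        )

    def chi2(expected: float) -> float:
        if expected <= 0 or observed <= expected:
            return 0.0
        return (observed - expected) ** 2 / expected

    e_corr = n * p_corr
    e_indep = n * p_indep
    e_indep_unique = n * p_indep_unique
    return CombinationStats(
        p_corr=p_corr,
        p_indep=p_indep,
        p_indep_unique=p_indep_unique,
        expected_corr=e_corr,
        expected_indep=e_indep,
        expected_indep_unique=e_indep_unique,
        observed=observed,
        chi2_min=chi2(e_corr),
        chi2_max=chi2(e_indep),
        chi2_max_unique=chi2(e_indep_unique),
    )


def cmp_ab_initio(
    space: SearchSpace,
    ddb: DomainDB,
    cut_multi: float = DEFAULT_CUT_MULTIDOMAIN,
    cut_single: float = DEFAULT_CUT_SINGLEDOMAIN,
    seeds: Iterable[str] = (),
    match_copies: bool = False,
) -> list[DomainPrediction]:
    """Predict carriers of over-represented domain combinations.

    Distinct combinations among annotated search-space genes are tested;
    one qualifies only if its carriers span >=2 distinct loci and its
    statistic clears the printed cutoff (chi2_max_unique >= cut_multi
    for multidomain, chi2_min >= cut_single for single-domain, both
    inclusive).  Seeds never enter: ab initio uses only genes pooled
    from the search space.  Carriers are ranked by descending chi2_min.
    """
    seeds = set(seeds)
    loci_of_gene = space.loci_of_gene
    annotated = sorted(
        g for g in space.all_genes - seeds if g in ddb.signature_of_gene
    )
    if not annotated:
        return []

    combos: dict[tuple[tuple[str, int], ...], DomainCombination] = {}
    for g in annotated:
        c = DomainCombination.from_signature(g, ddb.signature_of_gene[g])
        combos.setdefault(c.domains, c)

    rows: list[DomainPrediction] = []
    for key in sorted(combos):
        combo = combos[key]
        stats = combination_stats(combo, annotated, ddb, match_copies=match_copies)
        if match_copies:
            carriers = [
                g
                for g in annotated
                if all(ddb.signature_of_gene[g].get(d, 0) >= c for d, c in combo.domains)
            ]
        else:
            carriers = [
                g
                for g in annotated
                if combo.distinct_domains <= set(ddb.signature_of_gene[g])
            ]
        carrier_loci = {loc for g in carriers for loc in loci_of_gene.get(g, ())}
        if len(carrier_loci) < 2:
            continue  # predictions require multiple loci
        if combo.is_multidomain:
            if stats.chi2_max_unique < cut_multi:
                continue
        else:
            if stats.chi2_min < cut_single:
                continue
        for g in carriers:
            rows.append(
                DomainPrediction(
                    gene_id=g,
                    mode="ab_initio",
                    score=stats.chi2_min,
                    combination=combo,
                    supporting_loci=frozenset(loci_of_gene.get(g, ())),
                    stats=stats,
                )
            )
    # a gene may carry several qualifying combinations; keep its best
    best: dict[str, DomainPrediction] = {}
    for r in rows:
        if r.gene_id not in best or r.score > best[r.gene_id].score:
            best[r.gene_id] = r
    out = sorted(best.values(), key=lambda r: (-r.score, r.gene_id))
    ranks = _dense_ranks_desc([r.score for r in out])
    return [
        DomainPrediction(
            gene_id=r.gene_id,
            mode=r.mode,
            score=r.score,
            combination=r.combination,
            supporting_loci=r.supporting_loci,
            rank=rank,
            stats=r.stats,
        )
        for r, rank in zip(out, ranks)
    ]


def write_predictions(predictions: Sequence[DomainPrediction], stream) -> None:
    """TSV: mode, gene, seed, score, chi2 columns, observed/expected, loci."""
    stream.write(
        "mode\tgene_id\tseed_gene\tscore_or_chi2min\tchi2_max_unique\tchi2_max\t"
        "observed\texpected_corr\tloci\n"
    )
    for r in predictions:
        st = r.stats
        stream.write(
            "\t".join(
                [
                    r.mode,
                    r.gene_id,
                    r.seed_gene or "-",
                    f"{r.score:.6g}",
                    f"{st.chi2_max_unique:.6g}" if st else "-",
                    f"{st.chi2_max:.6g}" if st else "-",
                    str(st.observed) if st else "-",
                    f"{st.expected_corr:.6g}" if st else "-",
                    ",".join(sorted(r.supporting_loci)) or "-",
                ]
            )
            + "\n"
        )
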