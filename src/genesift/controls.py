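"""Random-SNP permutation controls.

Random SNP sets are drawn without replacement from the chip SNP
universe, sized to the number of associated loci in the real data (not
the raw significant-SNP count, so clustering driven by linkage
disequilibrium does not inflate the control).  The full prediction
pipeline runs on every replicate; per-cell prediction counts and
per-gene occurrence fractions summarise how often genes arise by
chance.  Phenotype predictions seen in more than ``max_frac`` of random
replicates are post-filtered as likely false positives, and the log10
prediction ratio (real count vs random mean, 0.5 pseudocount) measures
how far the real signal stands above the permutation background.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import cmp as cmp_mod
from . import cps as cps_mod
from .annotations import DomainDB, PathwayDB, annotated_universe
from .gwas_io import SnpRecord
from .loci import DEFAULT_GAP_BP, cluster_snps
from .search_space import GeneCatalog, build_search_space

logger = logging.getLogger(__name__)

__all__ = [
    "ControlConfig",
    "RandomControlSummary",
    "sample_random_snp_sets",
    "predict_genes",
    "random_prediction_profile",
    "filter_by_random_occurrence",
    "log_prediction_ratio",
]

DEFAULT_REPLICATES = 1000
DEFAULT_MAX_OCCURRENCE = 0.05
LOG_RATIO_PSEUDOCOUNT = 0.5


@dataclass
class ControlConfig:
    """Everything needed to rerun the pipeline on random SNP draws."""

    snp_universe: Sequence[SnpRecord]
    catalog: GeneCatalog
    pdb: PathwayDB
    ddb: DomainDB
    set_size: int  # number of associated loci formed by the real data
    approaches: Sequence[str] = ("adjacent",)
    cells: Sequence[tuple[str, str]] = (("cps", "ab_initio"),)
    seeds: frozenset[str] = frozenset()
    gap_bp: int = DEFAULT_GAP_BP
    alpha: float = 0.05
    similarity_threshold: float = cmp_mod.DEFAULT_SIMILARITY_THRESHOLD
    cut_multi: float = cmp_mod.DEFAULT_CUT_MULTIDOMAIN
    cut_single: float = cmp_mod.DEFAULT_CUT_SINGLEDOMAIN
    rng_seed: int = 0


@dataclass
class RandomControlSummary:
    """Aggregate of prediction behaviour across random replicates."""

    replicates: int
    counts: dict[tuple[str, str, str], list[int]]  # (module, mode, approach) -> per-rep
    gene_occurrence: dict[str, float]
    rng_seed: int
    tested: dict[tuple[str, str, str], int] = field(default_factory=dict)

    def mean_count(self, key: tuple[str, str, str] | None = None) -> float:
        if key is None:
            per_rep = np.sum([c for c in self.counts.values()], axis=0)
            return float(np.mean(per_rep)) if len(per_rep) else 0.0
        vals = self.counts.get(key, [])
        return float(np.mean(vals)) if vals else 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "replicates": self.replicates,
                "rng_seed": self.rng_seed,
                "mean_counts": {
                    "|".join(k): self.mean_count(k) for k in self.counts
                },
                "gene_occurrence": dict(sorted(self.gene_occurrence.items())),
            },
            indent=2,
        )


def sample_random_snp_sets(
    snp_universe: Sequence[SnpRecord],
    n_sets: int,
    set_size: int,
    rng_seed: int,
) -> list[list[SnpRecord]]:
    """Draw n_sets duplicate-free SNP sets of set_size from the universe."""
    if set_size > len(snp_universe):
        raise ValueError(
            f"set_size {set_size} exceeds universe size {len(snp_universe)}"
        )
    rng = np.random.default_rng(rng_seed)
    universe = list(snp_universe)
    out = []
    for _ in range(n_sets):
        idx = rng.choice(len(universe), size=set_size, replace=False)
        out.append([universe[i] for i in idx])
    return out


def predict_genes(
    snps: Sequence[SnpRecord],
    catalog: GeneCatalog,
    pdb: PathwayDB,
    ddb: DomainDB,
    approach: str,
    module: str,
    mode: str,
    seeds: Iterable[str] = (),
    gap_bp: int = DEFAULT_GAP_BP,
    alpha: float = 0.05,
    similarity_threshold: float = cmp_mod.DEFAULT_SIMILARITY_THRESHOLD,
    cut_multi: float = cmp_mod.DEFAULT_CUT_MULTIDOMAIN,
    cut_single: float = cmp_mod.DEFAULT_CUT_SINGLEDOMAIN,
):
    """Run one (module, mode, approach) cell end to end on a SNP set.

    Returns ``(predicted_gene_ids, predictions, n_tested)`` where
    ``n_tested`` is the number of hypotheses examined (pathways tested
    for CPS; domain combinations spanning >=2 loci for CMP ab initio).
    """
    seeds = frozenset(seeds)
    if not snps:
        return set(), [], 0
    loci = cluster_snps(snps, gap_bp=gap_bp)
    space = build_search_space(loci, catalog, approach)
    universe = annotated_universe(catalog, pdb, ddb)

    if module == "cps":
        n_tested = _count_tested_pathways(space, pdb, universe, mode, seeds)
        preds = cps_mod.cps_predict(
            space, pdb, universe, mode=mode, seeds=seeds, alpha=alpha
        )
        genes = {g for p in preds for g in p.candidate_genes}
        return genes, preds, n_tested
    if module == "cmp":
        if mode == "seeded":
            preds = cmp_mod.cmp_seeded(space, seeds, ddb, threshold=similarity_threshold)
            n_tested = len(space.all_genes & set(ddb.signature_of_gene)) if preds is not None else 0
        else:
            preds = cmp_mod.cmp_ab_initio(
                space, ddb, cut_multi=cut_multi, cut_single=cut_single, seeds=seeds
            )
            n_tested = len(
                {
                    tuple(sorted(ddb.signature_of_gene[g].items()))
                    for g in space.all_genes
                    if g in ddb.signature_of_gene
                }
            )
        return {p.gene_id for p in preds}, preds, n_tested
    raise ValueError(f"unknown module {module!r}")


def _count_tested_pathways(space, pdb, universe, mode, seeds):
    space_genes = space.all_genes & universe
    loci_of_gene = space.loci_of_gene
    n = 0
    for pid in pdb.pathways:
        members = pdb.members(pid)
        in_space = {g for g in members if g in space_genes}
        if mode == "seeded":
            if (members & seeds) and (in_space - seeds):
                n += 1
        else:
            supporting = {loc for g in in_space for loc in loci_of_gene.get(g, ())}
            if len(supporting) >= 2:
                n += 1
    return n


def random_prediction_profile(
    config: ControlConfig, replicates: int = DEFAULT_REPLICATES
) -> RandomControlSummary:
    """Run the pipeline on random SNP sets and aggregate the outcome.

    One random draw per replicate is shared across all approaches and
    cells so that per-cell counts are comparable.
    """
    snp_sets = sample_random_snp_sets(
        config.snp_universe, replicates, config.set_size, config.rng_seed
    )
    counts: dict[tuple[str, str, str], list[int]] = {
        (module, mode, approach): []
        for module, mode in config.cells
        for approach in config.approaches
    }
    tested: dict[tuple[str, str, str], int] = {k: 0 for k in counts}
    seen_in: dict[str, int] = {}
    for snps in snp_sets:
        rep_genes: set[str] = set()
        for module, mode in config.cells:
            for approach in config.approaches:
                genes, _preds, n_tested = predict_genes(
                    snps,
                    config.catalog,
                    config.pdb,
                    config.ddb,
                    approach,
                    module,
                    mode,
                    seeds=config.seeds,
                    gap_bp=config.gap_bp,
                    alpha=config.alpha,
                    similarity_threshold=config.similarity_threshold,
                    cut_multi=config.cut_multi,
                    cut_single=config.cut_single,
                )
                counts[(module, mode, approach)].append(len(genes))
                tested[(module, mode, approach)] += n_tested
                rep_genes |= genes
        for g in rep_genes:
            seen_in[g] = seen_in.get(g, 0) + 1
    occurrence = {g: c / replicates for g, c in seen_in.items()}
    return RandomControlSummary(
        replicates=replicates,
        counts=counts,
        gene_occurrence=occurrence,
        rng_seed=config.rng_seed,
        tested=tested,
    )


def filter_by_random_occurrence(
    predicted_genes: Iterable[str],
    summary: RandomControlSummary,
    max_frac: float = DEFAULT_MAX_OCCURRENCE,
) -> tuple[list[str], list[str]]:
    """Drop genes seen in more than max_frac of random replicates.

    The comparison is strict: a gene at exactly max_frac is kept.
    Returns (kept, dropped), each in input order.
    """
    kept, dropped = [], []
    for g in predicted_genes:
        if summary.gene_occurrence.get(g, 0.0) > max_frac:
            dropped.append(g)
        else:
            kept.append(g)
    if dropped:
        logger.info(
            "random-occurrence filter dropped %d of %d genes",
            len(dropped),
            len(dropped) + len(kept),
        )
    return kept, dropped


def log_prediction_ratio(
    n_real: int, mean_random: float, pseudocount: float = LOG_RATIO_PSEUDOCOUNT
) -> float:
    """log10 of real-to-random prediction counts with a 0.5 pseudocount.

    Positive values mean the real data yields more predictions than the
    permutation background; the pseudocount keeps zero counts finite
    and maps (0, 0) to exactly 0.
    """
    return float(np.log10((n_real + pseudocount) / (mean_random + pseudocount)))
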