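"""Synthetic GWAS fixture generator with planted causal structure.

The generator emulates the summary-statistic level the pipeline
consumes: a chip SNP map laid uniformly over a multi-chromosome gene
catalog, GMT pathway sets, per-gene domain signatures, and an
association table whose background p-values are uniform(0, 1).  A
planted signal places clusters of strongly associated SNPs (log-uniform
p spanning the genome-wide to moderately-significant range) inside
causal genes that sit in well-separated prospective loci, share one
pathway and carry one rare domain — so pathway- and domain-based
prediction can be tested for recovery against a known ground truth.

It deliberately omits population-genetic realism (no LD, no allele
frequencies, no case/control genotypes): the pipeline never consumes
those, only positions and p-values.
"""

from __future__ import annotations

import json
import os
from collections import Counter
from dataclasses import dataclass, field
import numpy as np

from .annotations import DomainDB, PathwayDB
from .gwas_io import SnpRecord, write_assoc
from .search_space import GeneCatalog, GeneModel

__all__ = ["SyntheticSpec", "GroundTruth", "SyntheticBundle", "generate"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults describe a compact but structured genome: 2,000 genes on 4
    chromosomes (log-normal lengths, exponential intergenic gaps),
    20,000 uniformly placed chip SNPs (≈1 per 6 kb, chip-like density),
    200 pathways, 250 domains.  The planted signal is a causal pathway
    of 4 genes plus one extra causal gene, one causal gene per locus in
    5 well-separated loci, all carrying a causal domain at genome
    frequency 0.005, tagged by 3 SNPs each with p log-uniform on
    [1e-8, 1e-5].
    """

    n_chromosomes: int = 4
    n_genes: int = 2000
    gene_length_median_bp: float = 20_000.0
    gene_length_sigma: float = 0.8
    gene_length_min_bp: int = 2_000
    gene_length_max_bp: int = 300_000
    intergenic_gap_mean_bp: float = 40_000.0
    intergenic_gap_min_bp: int = 1_000
    chromosome_length_bp: int | None = None  # None: computed from the layout
    n_snps: int = 20_000
    n_pathways: int = 200
    pathway_size_min: int = 5
    pathway_size_max: int = 40
    n_domains: int = 250
    frac_multidomain: float = 0.4
    domain_copy_p: float = 0.75  # geometric: mostly single copies
    domain_annotated_frac: float = 0.85
    # planted signal
    plant: bool = True
    causal_pathway_size: int = 4
    n_causal_loci: int = 5
    causal_domain_frequency: float = 0.005
    causal_p_low: float = 1e-8
    causal_p_high: float = 1e-5
    n_causal_snps_per_locus: int = 3
    causal_min_separation_bp: int = 200_000  # >= 2x the 50 kb clustering gap
    rng_seed: int = 0

    def validate(self) -> None:
        if min(self.n_chromosomes, self.n_genes, self.n_snps) <= 0:
            raise ValueError("counts must be positive")
        if self.plant and self.causal_pathway_size > self.n_causal_loci:
            raise ValueError("causal pathway cannot exceed the causal gene count")
        if self.plant and self.n_causal_loci > self.n_genes:
            raise ValueError("more causal loci than genes")
        if not (0 < self.causal_p_low <= self.causal_p_high < 1):
            raise ValueError("causal p range must satisfy 0 < low <= high < 1")


@dataclass(frozen=True)
class GroundTruth:
    """What was planted, for recovery tests."""

    causal_genes: frozenset[str] = frozenset()
    causal_pathway_genes: frozenset[str] = frozenset()
    causal_pathway_id: str | None = None
    causal_domain_id: str | None = None
    causal_snp_ids: frozenset[str] = frozenset()


@dataclass
class SyntheticBundle:
    """In-memory fixture plus writers for the on-disk dialects."""

    spec: SyntheticSpec
    snps: list[SnpRecord]
    catalog: GeneCatalog
    pdb: PathwayDB
    ddb: DomainDB
    truth: GroundTruth

    def write(self, outdir: str) -> dict[str, str]:
        """Emit assoc/BED6/GMT/domain-TSV files plus a truth sidecar."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "assoc": os.path.join(outdir, "study.assoc"),
            "genes": os.path.join(outdir, "genes.bed"),
            "pathways": os.path.join(outdir, "pathways.gmt"),
            "domains": os.path.join(outdir, "domains.tsv"),
            "truth": os.path.join(outdir, "truth.json"),
        }
        with open(paths["assoc"], "w") as fh:
            write_assoc(self.snps, fh)
        with open(paths["genes"], "w") as fh:
            for g in self.catalog:
                fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
        with open(paths["pathways"], "w") as fh:
            for pid in sorted(self.pdb.pathways):
                name, members = self.pdb.pathways[pid]
                fh.write("\t".join([pid, name, *sorted(members)]) + "\n")
        with open(paths["domains"], "w") as fh:
            fh.write("gene_id\tdomain_id\tcopies\n")
            for gene in sorted(self.ddb.signature_of_gene):
                for dom, copies in sorted(self.ddb.signature_of_gene[gene].items()):
                    fh.write(f"{gene}\t{dom}\t{copies}\n")
        with open(paths["truth"], "w") as fh:
            json.dump(
                {
                    "causal_genes": sorted(self.truth.causal_genes),
                    "causal_pathway_genes": sorted(self.truth.causal_pathway_genes),
                    "causal_pathway_id": self.truth.causal_pathway_id,
                    "causal_domain_id": self.truth.causal_domain_id,
                    "causal_snp_ids": sorted(self.truth.causal_snp_ids),
                    "rng_seed": self.spec.rng_seed,
                },
                fh,
                indent=2,
            )
            fh.write("\n")
        return paths


def _layout_genes(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[GeneCatalog, dict[str, int]]:
    catalog = GeneCatalog()
    chrom_len: dict[str, int] = {}
    per_chrom = [spec.n_genes // spec.n_chromosomes] * spec.n_chromosomes
    for i in range(spec.n_genes % spec.n_chromosomes):
        per_chrom[i] += 1
    gene_no = 0
    mu = np.log(spec.gene_length_median_bp)
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        cursor = 0
        for _ in range(per_chrom[c]):
            gap = int(rng.exponential(spec.intergenic_gap_mean_bp)) + spec.intergenic_gap_min_bp
            length = int(
                np.clip(
                    rng.lognormal(mu, spec.gene_length_sigma),
                    spec.gene_length_min_bp,
                    spec.gene_length_max_bp,
                )
            )
            start = cursor + gap
            end = start + length
            cursor = end
            gene_no += 1
            strand = "+" if rng.random() < 0.5 else "-"
            catalog.add(GeneModel(f"G{gene_no:05d}", f"G{gene_no:05d}", chrom, start, end, strand))
        tail = int(rng.exponential(spec.intergenic_gap_mean_bp)) + spec.intergenic_gap_min_bp
        chrom_len[chrom] = cursor + tail
        if spec.chromosome_length_bp is not None:
            if cursor + tail > spec.chromosome_length_bp:
                raise ValueError(
                    f"{chrom}: layout needs {cursor + tail} bp but the spec fixes "
                    f"chromosomes at {spec.chromosome_length_bp} bp"
                )
            chrom_len[chrom] = spec.chromosome_length_bp
    return catalog, chrom_len


def _pick_causal_genes(
    spec: SyntheticSpec, catalog: GeneCatalog, rng: np.random.Generator
) -> list[GeneModel]:
    """Causal genes on distinct prospective loci, pairwise well separated."""
    candidates = [
        g
        for g in catalog
        if g.end - g.start >= max(spec.gene_length_min_bp, 5_000)
    ]
    order = rng.permutation(len(candidates))
    chosen: list[GeneModel] = []
    for i in order:
        g = candidates[i]
        ok = all(
            g.chromosome != h.chromosome
            or min(abs(g.start - h.end), abs(h.start - g.end)) >= spec.causal_min_separation_bp
            for h in chosen
        )
        if ok:
            chosen.append(g)
        if len(chosen) == spec.n_causal_loci:
            return sorted(chosen, key=lambda x: x.gene_id)
    raise ValueError("could not place causal genes with the required separation")


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Build one deterministic synthetic study bundle from the spec."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    catalog, chrom_len = _layout_genes(spec, rng)
    genes = list(catalog)
    gene_ids = [g.gene_id for g in genes]

    # --- chip SNP map: uniform placement, uniform background p ---
    total_len = sum(chrom_len.values())
    snps: list[SnpRecord] = []
    snp_no = 0
    for chrom in sorted(chrom_len):
        n_here = int(round(spec.n_snps * chrom_len[chrom] / total_len))
        positions = np.unique(rng.integers(0, chrom_len[chrom], size=n_here))
        pvals = rng.uniform(0.0, 1.0, size=positions.size)
        for pos, p in zip(positions, pvals):
            snp_no += 1
            snps.append(
                SnpRecord(f"rs{snp_no:07d}", chrom, int(pos), float(max(p, 1e-300)))
            )

    # --- planted causal structure ---
    truth = GroundTruth()
    causal_genes: list[GeneModel] = []
    causal_domain: str | None = None
    if spec.plant:
        causal_genes = _pick_causal_genes(spec, catalog, rng)
        causal_snp_ids = []
        for g in causal_genes:
            window = min(g.end - g.start, 10_000)
            base = int(rng.integers(g.start, g.end - window + 1))
            offsets = np.sort(rng.integers(0, window, size=spec.n_causal_snps_per_locus))
            logp = rng.uniform(
                np.log10(spec.causal_p_low),
                np.log10(spec.causal_p_high),
                size=spec.n_causal_snps_per_locus,
            )
            for off, lp in zip(offsets, logp):
                snp_no += 1
                sid = f"rs{snp_no:07d}"
                causal_snp_ids.append(sid)
                snps.append(SnpRecord(sid, g.chromosome, base + int(off), float(10.0 ** lp)))
        causal_domain = f"D{spec.n_domains:04d}"  # reserved: never background-assigned
        truth = GroundTruth(
            causal_genes=frozenset(g.gene_id for g in causal_genes),
            causal_pathway_genes=frozenset(
                g.gene_id for g in causal_genes[: spec.causal_pathway_size]
            ),
            causal_domain_id=causal_domain,
            causal_snp_ids=frozenset(causal_snp_ids),
        )
    snps.sort(key=lambda s: (s.chromosome, s.position_bp, s.snp_id))

    # --- pathways ---
    pdb = PathwayDB()
    causal_slot = int(rng.integers(spec.n_pathways)) if spec.plant else -1
    causal_pathway_id: str | None = None
    for i in range(spec.n_pathways):
        pid = f"PW{i + 1:04d}"
        if i == causal_slot:
            members = frozenset(truth.causal_pathway_genes)
            causal_pathway_id = pid
        else:
            size = int(rng.integers(spec.pathway_size_min, spec.pathway_size_max + 1))
            members = frozenset(
                gene_ids[j] for j in rng.choice(len(gene_ids), size=size, replace=False)
            )
        pdb.pathways[pid] = (f"pathway {i + 1}", members)
    if spec.plant:
        truth = GroundTruth(
            causal_genes=truth.causal_genes,
            causal_pathway_genes=truth.causal_pathway_genes,
            causal_pathway_id=causal_pathway_id,
            causal_domain_id=truth.causal_domain_id,
            causal_snp_ids=truth.causal_snp_ids,
        )

    # --- domain signatures ---
    n_bg_domains = spec.n_domains - (1 if spec.plant else 0)
    domain_ids = [f"D{k + 1:04d}" for k in range(n_bg_domains)]
    weights = 1.0 / np.arange(1, n_bg_domains + 1)  # Zipf-like frequency skew
    weights /= weights.sum()
    annotated_mask = rng.random(len(gene_ids)) < spec.domain_annotated_frac
    causal_gene_ids = {g.gene_id for g in causal_genes}
    signatures: dict[str, Counter] = {}
    for gid, annotated in zip(gene_ids, annotated_mask):
        if gid in causal_gene_ids:
            continue  # assigned below
        if not annotated:
            continue
        n_distinct = 1
        if rng.random() < spec.frac_multidomain:
            n_distinct = int(rng.integers(2, 5))
        picks = rng.choice(n_bg_domains, size=n_distinct, replace=False, p=weights)
        sig = Counter()
        for k in picks:
            sig[domain_ids[k]] = 1 + int(rng.geometric(spec.domain_copy_p) - 1)
        signatures[gid] = sig
    if spec.plant:
        for gid in sorted(causal_gene_ids):
            signatures[gid] = Counter({causal_domain: 1})
        # pad carriers of the causal domain up to the target genome frequency
        n_annotated = len(signatures)
        target = max(spec.n_causal_loci, int(round(spec.causal_domain_frequency * n_annotated)))
        extra_needed = target - len(causal_gene_ids)
        others = sorted(set(signatures) - causal_gene_ids)
        if extra_needed > 0 and others:
            picks = rng.choice(len(others), size=min(extra_needed, len(others)), replace=False)
            for j in picks:
                signatures[others[j]][causal_domain] = 1
    ddb = DomainDB(signature_of_gene=signatures)

    return SyntheticBundle(spec=spec, snps=snps, catalog=catalog, pdb=pdb, ddb=ddb, truth=truth)
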