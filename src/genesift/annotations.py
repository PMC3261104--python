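"""Pathway membership and protein-domain annotation.

Pathways arrive in GMT format (one set per line: id, description,
member genes); per-gene domain signatures arrive as a three-column TSV
(gene id, domain id, copy count).  A gene's *signature* is the multiset
of Pfam-style domain identifiers it contains.  Genes absent from both
sources are unannotated: they can never be predicted, though they still
occupy search-space and specificity denominators downstream.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import TextIO

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayDB",
    "DomainDB",
    "load_pathways",
    "load_domains",
    "annotated_fraction",
    "annotated_universe",
]


@dataclass
class PathwayDB:
    """Pathway gene sets with a consistent inverse index."""

    pathways: dict[str, tuple[str, frozenset[str]]] = field(default_factory=dict)

    @property
    def pathways_of_gene(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for pid, (_name, members) in self.pathways.items():
            for g in members:
                inv.setdefault(g, set()).add(pid)
        return inv

    @property
    def annotated_genes(self) -> set[str]:
        return {g for _n, members in self.pathways.values() for g in members}

    def members(self, pathway_id: str) -> frozenset[str]:
        return self.pathways[pathway_id][1]

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass
class DomainDB:
    """Per-gene domain signatures (multisets) with an inverse index.

    ``genome_gene_count`` is the size of the annotated universe the
    background domain frequencies f(d) are computed over; it defaults to
    the number of genes carrying at least one domain.
    """

    signature_of_gene: dict[str, Counter] = field(default_factory=dict)
    genome_gene_count: int = 0

    def __post_init__(self) -> None:
        if self.genome_gene_count == 0:
            self.genome_gene_count = len(self.signature_of_gene)

    @property
    def genes_with_domain(self) -> dict[str, set[str]]:
        inv: dict[str, set[str]] = {}
        for gene, sig in self.signature_of_gene.items():
            for d in sig:
                inv.setdefault(d, set()).add(gene)
        return inv

    def frequency(self, domain_id: str) -> float:
        """f(d): fraction of annotated genome genes carrying >=1 copy of d."""
        if self.genome_gene_count <= 0:
            raise ValueError("DomainDB has no annotated genes")
        carriers = self.genes_with_domain.get(domain_id)
        if not carriers:
            raise ValueError(f"domain {domain_id!r} absent from the genome DB")
        return len(carriers) / self.genome_gene_count

    @property
    def annotated_genes(self) -> set[str]:
        return set(self.signature_of_gene)

    def __len__(self) -> int:
        return len(self.signature_of_gene)


def load_pathways(stream: TextIO | str) -> PathwayDB:
    """Read GMT: tab-separated pathway_id, description, member genes...

    Duplicate members within a line are deduplicated (logged); a line
    with fewer than three fields is a format error.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return load_pathways(fh)
    db = PathwayDB()
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"GMT line {lineno}: expected >=3 fields, got {len(fields)}")
        pid, name = fields[0], fields[1]
        members = [g for g in fields[2:] if g]
        unique = frozenset(members)
        if len(unique) < len(members):
            logger.info(
                "pathway %s: %d duplicate members removed", pid, len(members) - len(unique)
            )
        if not unique:
            raise ValueError(f"GMT line {lineno}: pathway {pid!r} has no members")
        if pid in db.pathways:
            raise ValueError(f"duplicate pathway id {pid!r}")
        db.pathways[pid] = (name, unique)
    return db


def load_domains(stream: TextIO | str) -> DomainDB:
    """Read TSV: gene_id, domain_id, copies (header optional).

    Repeated (gene, domain) rows have their copy counts summed (logged);
    a copy count below 1 is a validation error.
    """
    if isinstance(stream, str):
        with open(stream) as fh:
            return load_domains(fh)
    signatures: dict[str, Counter] = {}
    merged = 0
    for lineno, line in enumerate(stream, 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"domain TSV line {lineno}: expected 3 fields")
        gene, domain, copies_s = fields[0], fields[1], fields[2]
        if lineno == 1 and not copies_s.strip().lstrip("-").isdigit():
            continue  # header row
        copies = int(copies_s)
        if copies < 1:
            raise ValueError(f"domain TSV line {lineno}: copies {copies} < 1")
        sig = signatures.setdefault(gene, Counter())
        if domain in sig:
            merged += 1
        sig[domain] += copies
    if merged:
        logger.info("load_domains: summed copies for %d repeated (gene, domain) rows", merged)
    return DomainDB(signature_of_gene=signatures)


def annotated_fraction(catalog, pdb: PathwayDB, ddb: DomainDB) -> dict[str, float]:
    """Fractions of catalog genes annotated by pathways, domains, or either."""
    gene_ids = {g.gene_id for g in catalog}
    if not gene_ids:
        raise ValueError("empty gene catalog")
    in_pw = gene_ids & pdb.annotated_genes
    in_dom = gene_ids & ddb.annotated_genes
    n = len(gene_ids)
    return {
        "pathway_frac": len(in_pw) / n,
        "domain_frac": len(in_dom) / n,
        "either_frac": len(in_pw | in_dom) / n,
    }


def annotated_universe(catalog, pdb: PathwayDB, ddb: DomainDB) -> set[str]:
    """Catalog genes carrying pathway or domain annotation.

    This is the universe over which enrichment contingency tables and
    specificity denominators are formed: unannotated genes carry no
    evidence either way.
    """
    gene_ids = {g.gene_id for g in catalog}
    return gene_ids & (pdb.annotated_genes | ddb.annotated_genes)
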