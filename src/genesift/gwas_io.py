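"""Parsing and tiering of GWAS association summary statistics.

The input is a PLINK-``.assoc``-style whitespace-delimited table with a
header row carrying at least a SNP identifier, chromosome label, base-pair
position and association p-value (by default the columns ``SNP``, ``CHR``,
``BP`` and ``P``, matched case-insensitively).  Positions are 1-based on
disk and converted to 0-based internally; every writer converts back.

Markers are stratified into four significance tiers:

========  ==========  ==========
label     cutoff      comparison
========  ==========  ==========
WS        1e-3        p <= cutoff
MWS       1e-4        p <= cutoff
MHS       1e-5        p <= cutoff
HS        5e-7        p <  cutoff (strict)
========  ==========  ==========

The strict comparison for the highly-significant tier mirrors the
genome-wide threshold convention it reproduces: a marker at exactly
5e-7 is *excluded* from HS but included in every weaker tier.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence, TextIO

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnpRecord",
    "ThresholdLevel",
    "THRESHOLDS",
    "TIER_ORDER",
    "parse_assoc",
    "apply_threshold",
    "qq_points",
    "write_assoc",
]


@dataclass(frozen=True)
class SnpRecord:
    """One genotyped marker with its association p-value.

    ``position_bp`` is 0-based (converted from the 1-based on-disk
    convention by :func:`parse_assoc`).
    """

    snp_id: str
    chromosome: str
    position_bp: int
    p_gwa: float

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"negative position for {self.snp_id}")
        if not (0.0 < self.p_gwa <= 1.0):
            raise ValueError(
                f"p-value {self.p_gwa!r} for {self.snp_id} outside (0, 1]"
            )


@dataclass(frozen=True)
class ThresholdLevel:
    """A named significance tier; ``strict`` selects ``<`` over ``<=``."""

    label: str
    cutoff: float
    strict: bool = False

    def admits(self, p: float) -> bool:
        return p < self.cutoff if self.strict else p <= self.cutoff


#: The four tiers, strongest last.  Only HS compares strictly.
THRESHOLDS: Mapping[str, ThresholdLevel] = {
    "WS": ThresholdLevel("WS", 1e-3),
    "MWS": ThresholdLevel("MWS", 1e-4),
    "MHS": ThresholdLevel("MHS", 1e-5),
    "HS": ThresholdLevel("HS", 5e-7, strict=True),
}

TIER_ORDER: Sequence[str] = ("WS", "MWS", "MHS", "HS")

_DEFAULT_DIALECT = {"snp": "SNP", "chr": "CHR", "bp": "BP", "p": "P"}


def _resolve_columns(
    columns: Sequence[str], dialect: Mapping[str, str]
) -> dict[str, str]:
    lowered = {c.lower(): c for c in columns}
    resolved = {}
    for role, wanted in dialect.items():
        actual = lowered.get(wanted.lower())
        if actual is None:
            raise ValueError(
                f"required column {wanted!r} (role {role!r}) not found; "
                f"available: {list(columns)}"
            )
        resolved[role] = actual
    return resolved


def parse_assoc(
    stream: TextIO | str,
    dialect: Mapping[str, str] | None = None,
    strict: bool = False,
) -> list[SnpRecord]:
    """Parse an association summary table into :class:`SnpRecord` rows.

    Parameters
    ----------
    stream:
        Text stream or path of a whitespace-delimited table with header.
    dialect:
        Overrides for the role→column-name mapping; roles are ``snp``,
        ``chr``, ``bp``, ``p``.  Matching is case-insensitive.
    strict:
        In strict mode any row with a missing, non-numeric or
        out-of-range p-value raises; in the default lenient mode such
        rows are skipped and the skip count logged.
    """
    mapping = dict(_DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    df = pd.read_csv(stream, sep=r"\s+", dtype=str)
    if df.columns.size == 0:
        raise ValueError("input has no header row")
    cols = _resolve_columns(df.columns, mapping)

    records: list[SnpRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        snp_id = str(row_d[cols["snp"]])
        try:
            p = float(row_d[cols["p"]])
            pos = int(row_d[cols["bp"]])
            if math.isnan(p):
                raise ValueError("missing p")
            rec = SnpRecord(
                snp_id=snp_id,
                chromosome=str(row_d[cols["chr"]]),
                position_bp=pos - 1,  # 1-based on disk
                p_gwa=p,
            )
        except (TypeError, ValueError) as exc:
            if strict:
                raise ValueError(f"invalid row for SNP {snp_id!r}: {exc}") from exc
            skipped += 1
            continue
        records.append(rec)
    if skipped:
        logger.info("parse_assoc: skipped %d invalid rows", skipped)
    seen: set[str] = set()
    for rec in records:
        if rec.snp_id in seen:
            raise ValueError(f"duplicate SNP id {rec.snp_id!r}")
        seen.add(rec.snp_id)
    return records


def apply_threshold(
    snps: Iterable[SnpRecord], level: ThresholdLevel | str
) -> list[SnpRecord]:
    """Return markers admitted by *level*, sorted by (chromosome, position)."""
    if isinstance(level, str):
        level = THRESHOLDS[level]
    kept = [s for s in snps if level.admits(s.p_gwa)]
    kept.sort(key=lambda s: (s.chromosome, s.position_bp, s.snp_id))
    return kept


def qq_points(snps: Sequence[SnpRecord]) -> np.ndarray:
    """Quantile-quantile points against the uniform null.

    Returns an ``(n, 2)`` array of ``(expected, observed)`` pairs of
    -log10 p-values, both columns ascending.  Expected quantiles use the
    ``rank / (n + 1)`` plotting position.  Ties in p are broken stably
    by SNP id so the construction is deterministic.
    """
    if not snps:
        raise ValueError("qq_points requires at least one record")
    ordered = sorted(snps, key=lambda s: (-s.p_gwa, s.snp_id))
    n = len(ordered)
    observed = -np.log10([s.p_gwa for s in ordered])
    ranks = np.arange(n, 0, -1)  # n..1: largest p pairs with rank n
    expected = -np.log10(ranks / (n + 1))
    return np.column_stack([expected, observed])


def write_assoc(records: Iterable[SnpRecord], stream: TextIO) -> None:
    """Serialize records in the input dialect (1-based positions)."""
    stream.write("SNP CHR BP P\n")
    for r in records:
        # .17g: p-values survive a write/parse round trip exactly
        stream.write(f"{r.snp_id} {r.chromosome} {r.position_bp + 1} {r.p_gwa:.17g}\n")


def read_gene_list(stream: TextIO | str) -> list[str]:
    """Read a newline-delimited gene list (seed or validation set)."""
    if isinstance(stream, str):
        with open(stream) as fh:
            return read_gene_list(fh)
    out = []
    for line in stream:
        name = line.strip()
        if name and not name.startswith("#"):
            out.append(name)
    return out
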