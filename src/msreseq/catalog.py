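"""Catalogue of HpaII-target CpG sites.

HpaII cuts unmethylated CCGG; the CpG interrogated by MSRE-seq is the
central dinucleotide of that motif ("C(CpG)G"). The catalogue records
every CCGG occurrence in a reference genome, anchored at the 1-based
position of the first C. CCGG is its own reverse complement, so a
forward-strand scan is strand-complete. Sites on sex chromosomes are
excluded by default: cohorts mixing male and female donors would
otherwise contribute sex-linked methylation differences.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

MOTIF = "CCGG"

#: Default sex-chromosome exclusion set.
DEFAULT_EXCLUDE = frozenset({"chrX", "chrY", "X", "Y"})

_SITE_ID_RE = re.compile(r"^(?P<chrom>[^.]+)\.(?P<pos>\d{10})$")
_VALID_SEQ_RE = re.compile(r"^[ACGTN]*$")


def format_site_id(chrom: str, pos: int) -> str:
    """Canonical site identifier, e.g. ``chr2.0003882321``.

    ``pos`` is the 1-based coordinate of the first C of the CCGG motif,
    zero-padded to 10 digits.
    """
    if pos < 1:
        raise ValueError(f"position must be >= 1, got {pos}")
    if pos >= 10**10:
        raise ValueError(f"position {pos} exceeds 10 digits")
    return f"{chrom}.{pos:010d}"


def parse_site_id(site_id: str) -> tuple[str, int]:
    """Inverse of :func:`format_site_id`."""
    m = _SITE_ID_RE.match(site_id)
    if m is None:
        raise ValueError(f"malformed site id: {site_id!r}")
    return m.group("chrom"), int(m.group("pos"))


@dataclass
class SiteCatalog:
    """Ordered CCGG site list with chromosome lengths.

    ``sites`` is a DataFrame with columns ``chrom``, ``pos`` (1-based
    first C), ``site_id``; rows sorted by (chrom, pos) in the order
    chromosomes appear in ``chrom_lengths``.
    """

    sites: pd.DataFrame
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "site_id"}
        missing = required - set(self.sites.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        if self.sites["site_id"].duplicated().any():
            dup = self.sites.loc[self.sites["site_id"].duplicated(), "site_id"].iloc[0]
            raise ValueError(f"duplicate site id: {dup}")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def site_ids(self) -> pd.Series:
        return self.sites["site_id"]

    def to_tsv(self, path: str | Path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 chrom_lengths: Mapping[str, int] | None = None) -> "SiteCatalog":
        sites = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(sites=sites, chrom_lengths=dict(chrom_lengths or {}))

    def to_bed(self, path: str | Path) -> None:
        """BED intervals for the 4-bp motif: 0-based half-open [pos-1, pos+3)."""
        bed = pd.DataFrame({
            "chrom": self.sites["chrom"],
            "start": self.sites["pos"] - 1,
            "end": self.sites["pos"] + 3,
            "name": self.sites["site_id"],
        })
        bed.to_csv(path, sep="\t", index=False, header=False)


def _scan_sequence(seq: str, chrom: str) -> list[tuple[str, int, str]]:
    bad = _VALID_SEQ_RE.match(seq)
    if bad is None:
        offending = next(c for c in seq if c not in "ACGTN")
        raise ValueError(f"non-nucleotide character {offending!r} in {chrom}")
    out = []
    start = 0
    while True:
        i = seq.find(MOTIF, start)
        if i == -1:
            break
        pos = i + 1  # 1-based
        out.append((chrom, pos, format_site_id(chrom, pos)))
        start = i + 1  # overlapping occurrences each reported
    return out


def scan_ccgg_sites(
    genome: Mapping[str, str] | str | Path,
    exclude_chroms: Iterable[str] | None = DEFAULT_EXCLUDE,
) -> SiteCatalog:
    """Scan a genome for HpaII CCGG target sites.

    Parameters
    ----------
    genome
        Mapping of chromosome name to sequence, or a path to a FASTA
        file (multi-record, wrapped or unwrapped).
    exclude_chroms
        Chromosome names to omit (default: sex chromosomes). Pass
        ``None`` or an empty set to keep everything.

    The match is a strict literal scan: windows containing N never
    match, because HpaII recognition cannot be inferred across
    ambiguity codes.
    """
    if isinstance(genome, (str, Path)):
        genome = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")}
    if not genome:
        raise ValueError("empty genome: no sequences provided")
    exclude = set(exclude_chroms or ())
    records: list[tuple[str, int, str]] = []
    chrom_lengths: dict[str, int] = {}
    for chrom, seq in genome.items():
        seq = seq.upper()
        chrom_lengths[chrom] = len(seq)
        if chrom in exclude:
            continue
        records.extend(_scan_sequence(seq, chrom))
    sites = pd.DataFrame(records, columns=["chrom", "pos", "site_id"])
    return SiteCatalog(sites=sites, chrom_lengths=chrom_lengths)
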