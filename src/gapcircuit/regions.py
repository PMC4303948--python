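"""Regulatory regions: predicted binding sites, accessibility and CREs.

Coordinates are 0-based half-open throughout (BED-native); FASTA input is
read with Biopython. A region bundles the sequence of a gene's regulatory
locus, the transcription start offset, the predicted sites, DNase
accessibility intervals and named cis-regulatory elements (CREs).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .motifs import PWM, reverse_complement, scan_words

__all__ = [
    "BindingSite", "RegulatoryRegion", "scan_sequence",
    "filter_sites_by_accessibility", "restrict_sites_to_cre",
    "read_fasta_sequence", "read_bed_intervals", "sites_to_bed6",
]


@dataclass(frozen=True)
class BindingSite:
    """A predicted TF binding site on a regulatory region.

    ``start``/``end`` are 0-based half-open region coordinates; ``word``
    is the matched nucleotide string, reverse-complemented for ``-``.
    """

    tf_name: str
    start: int
    end: int
    strand: str
    word: str
    llr: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, start: int, end: int) -> bool:
        """≥1 bp overlap with the half-open interval [start, end)."""
        return self.start < end and start < self.end


@dataclass
class RegulatoryRegion:
    gene: str
    sequence: str
    tss_offset: int = 0
    sites: list[BindingSite] = field(default_factory=list)
    accessibility: list[tuple[int, int]] = field(default_factory=list)
    cres: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        for s in self.sites:
            if not (0 <= s.start < s.end <= len(self.sequence)):
                raise ValueError(f"site {s} outside region {self.gene}")

    def with_sites(self, sites: list[BindingSite]) -> "RegulatoryRegion":
        return replace(self, sites=list(sites))

    def without_site(self, site: BindingSite) -> "RegulatoryRegion":
        """Copy of the region with one site excluded (for w_r experiments)."""
        if site not in self.sites:
            raise ValueError(f"site {site} not found in region {self.gene}")
        kept = [s for s in self.sites if s != site]
        return self.with_sites(kept)


def scan_sequence(pwm: PWM, region: RegulatoryRegion | str,
                  threshold: float | None = None) -> list[BindingSite]:
    """All windows on both strands scoring ≥ threshold, sorted by start.

    ``threshold`` defaults to ``pwm.threshold``. A palindromic consensus
    yields one site per strand at the same interval.
    """
    seq = region.sequence if isinstance(region, RegulatoryRegion) else region
    if not seq:
        raise ValueError("empty sequence")
    thr = pwm.threshold if threshold is None else threshold
    sites = [
        BindingSite(pwm.tf_name, start, start + pwm.length, strand, word, llr)
        for start, strand, word, llr in scan_words(pwm, seq)
        if llr >= thr
    ]
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def filter_sites_by_accessibility(
        sites: list[BindingSite],
        intervals: list[tuple[int, int]]) -> list[BindingSite]:
    """Keep sites with ≥1 bp overlap with any accessibility interval."""
    ivs = sorted((int(a), int(b)) for a, b in intervals)
    return [s for s in sites if any(s.overlaps(a, b) for a, b in ivs)]


def restrict_sites_to_cre(region: RegulatoryRegion,
                          cre_name: str) -> list[BindingSite]:
    """Subset of the region's sites overlapping the named CRE interval."""
    try:
        a, b = region.cres[cre_name]
    except KeyError:
        raise KeyError(
            f"unknown CRE {cre_name!r} for gene {region.gene}; "
            f"known: {sorted(region.cres)}") from None
    return [s for s in region.sites if s.overlaps(a, b)]


# ---------------------------------------------------------------------------
# I/O helpers


def read_fasta_sequence(path: str | Path, record_id: str | None = None) -> str:
    """Return the (first, or named) sequence of a FASTA file as a string."""
    for rec in SeqIO.parse(str(path), "fasta"):
        if record_id is None or rec.id == record_id:
            return str(rec.seq).upper()
    raise ValueError(f"record {record_id!r} not found in {path}")


def read_bed_intervals(path: str | Path) -> pd.DataFrame:
    """Read a BED3+ file into a DataFrame (chrom, start, end[, name])."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs ≥3 columns")
    cols = ["chrom", "start", "end", "name", "score", "strand"]
    df.columns = cols[: df.shape[1]] + list(df.columns[len(cols):])
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def sites_to_bed6(sites: list[BindingSite], chrom: str,
                  tss_offset: int = 0,
                  tss_relative: bool = False) -> pd.DataFrame:
    """Export sites as BED6 with the log-odds score in the score column.

    With ``tss_relative`` coordinates are shifted so the transcription
    start sits at 0 (reporting convenience; internal coordinates stay
    region-based).
    """
    shift = tss_offset if tss_relative else 0
    rows = [(chrom, s.start - shift, s.end - shift, s.tf_name, s.llr,
             s.strand) for s in sites]
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def region_from_files(gene: str, fasta: str | Path,
                      accessibility_bed: str | Path | None = None,
                      cre_bed: str | Path | None = None,
                      tss_offset: int = 0) -> RegulatoryRegion:
    """Assemble a region from FASTA + optional accessibility/CRE BED files."""
    seq = read_fasta_sequence(fasta)
    acc: list[tuple[int, int]] = []
    if accessibility_bed is not None:
        bed = read_bed_intervals(accessibility_bed)
        acc = list(zip(bed["start"], bed["end"]))
    cres: dict[str, tuple[int, int]] = {}
    if cre_bed is not None:
        bed = read_bed_intervals(cre_bed)
        if "name" not in bed.columns:
            raise ValueError("CRE BED needs a name column")
        cres = {r["name"]: (r["start"], r["end"])
                for _, r in bed.iterrows()}
    return RegulatoryRegion(gene, seq, tss_offset, [], acc, cres)
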