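"""Protein-level consequences of truncating (stop-gain) variants.

Three questions are answered for a premature stop codon:

* how much shorter is the protein (C-terminal truncation in amino acids);
* does the mutant mRNA escape nonsense-mediated decay (NMD) — stops located
  in the last coding exon, or within ~50-55 coding nucleotides upstream of
  the last exon-exon junction, are NMD-insensitive and yield a truncated
  protein rather than a degraded transcript;
* which functional sites (binding domains, point sites) are retained,
  partially lost, or fully lost, against a residue-interval domain map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import Consequence, PipelineConfig, VariantRecord


class SiteStatus:
    retained = "retained"
    partial = "partial"
    lost = "lost"


@dataclass(frozen=True)
class DomainSite:
    """A named functional site as a 1-based closed residue interval.

    A point site (e.g. a single magnesium-coordinating residue) is a
    length-1 interval with ``start == end``.
    """

    name: str
    start: int
    end: int
    family: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"invalid residue interval {self.start}-{self.end}")


@dataclass(frozen=True)
class DomainMap:
    """Functional-site annotation for one protein."""

    protein: str
    protein_length: int
    sites: tuple[DomainSite, ...]

    def __post_init__(self) -> None:
        if self.protein_length < 1:
            raise ValueError("protein_length must be >= 1")
        for s in self.sites:
            if s.end > self.protein_length:
                raise ValueError(
                    f"site {s.name} ends at {s.end}, beyond protein length "
                    f"{self.protein_length}"
                )


@dataclass(frozen=True)
class TranscriptModel:
    """Coding-exon structure of one transcript.

    ``exons`` are genomic (start, end) pairs, 1-based closed, ordered 5'->3'
    in transcription order (descending genomic coordinates on the minus
    strand). Coding length must equal 3 * (protein_length + 1): the CDS
    includes the natural stop codon.
    """

    name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.exons:
            raise ValueError("transcript needs at least one coding exon")
        prev = None
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"exon {s}-{e} reversed")
            if prev is not None:
                ordered = s > prev if self.strand == "+" else e < prev
                if not ordered:
                    raise ValueError("exons must be ordered 5'->3' and non-overlapping")
            prev = e if self.strand == "+" else s

    @property
    def exon_lengths(self) -> tuple[int, ...]:
        return tuple(e - s + 1 for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def cumulative_offsets(self) -> tuple[int, ...]:
        """Cumulative coding nucleotides through each exon (1-based ends)."""
        out, total = [], 0
        for ln in self.exon_lengths:
            total += ln
            out.append(total)
        return tuple(out)

    @property
    def protein_length(self) -> int:
        """Residues encoded, excluding the stop codon."""
        if self.cds_length % 3 != 0:
            raise ValueError("CDS length is not a multiple of 3")
        return self.cds_length // 3 - 1

    def exon_of_cds(self, cds_pos: int) -> int:
        """0-based index of the coding exon containing CDS position ``cds_pos``."""
        if not (1 <= cds_pos <= self.cds_length):
            raise ValueError(f"CDS position {cds_pos} outside 1..{self.cds_length}")
        for i, end in enumerate(self.cumulative_offsets):
            if cds_pos <= end:
                return i
        raise AssertionError("unreachable")

    def genomic_to_cds(self, chrom: str, pos: int) -> Optional[int]:
        """Map a genomic position to a 1-based CDS coordinate, or None."""
        if chrom != self.chrom:
            return None
        offset = 0
        for s, e in self.exons:
            if s <= pos <= e:
                within = (pos - s) if self.strand == "+" else (e - pos)
                return offset + within + 1
            offset += e - s + 1
        return None


def shortening(
    stop_codon_position: int, protein_length: int, convention: str = "reported"
) -> int:
    """C-terminal shortening, in amino acids, caused by a premature stop.

    The default ``reported`` convention is ``protein_length -
    stop_codon_position`` — the convention under which stops at residues 321
    and 302 of the 350-residue rod transducin alpha subunit shorten it by 29
    and 48 residues. The ``peptide`` convention instead compares peptide
    lengths (the mutant peptide has ``stop_codon_position - 1`` residues),
    giving one more.
    """
    if not (1 <= stop_codon_position <= protein_length):
        raise ValueError(
            f"stop codon position {stop_codon_position} outside 1..{protein_length}"
        )
    base = protein_length - stop_codon_position
    if convention == "reported":
        return base
    if convention == "peptide":
        return base + 1
    raise ValueError(f"unknown shortening convention {convention!r}")


def nmd_escape(
    cds_position_of_stop: int, transcript: TranscriptModel, window_nt: int = 50
) -> bool:
    """Whether a premature stop escapes nonsense-mediated decay.

    True iff the stop lies in the last coding exon, or within ``window_nt``
    coding nucleotides (inclusive) upstream of the last exon-exon junction.
    Single-exon transcripts always escape.
    """
    if window_nt < 0:
        raise ValueError("window_nt must be >= 0")
    n = len(transcript.exons)
    if n == 1:
        return True
    if transcript.exon_of_cds(cds_position_of_stop) == n - 1:
        return True
    last_junction = transcript.cumulative_offsets[-2]
    return (last_junction - cds_position_of_stop) <= window_nt


def site_retention(stop_codon_position: int, domain_map: DomainMap) -> dict[str, str]:
    """Status of every functional site given a stop at ``stop_codon_position``.

    Residues 1..stop-1 are retained. A site is ``retained`` iff it ends
    before the stop, ``lost`` iff it starts at or after the stop, and
    ``partial`` otherwise.
    """
    if not (1 <= stop_codon_position <= domain_map.protein_length):
        raise ValueError("stop codon position outside protein")
    out: dict[str, str] = {}
    for s in domain_map.sites:
        if s.end < stop_codon_position:
            out[s.name] = SiteStatus.retained
        elif s.start >= stop_codon_position:
            out[s.name] = SiteStatus.lost
        else:
            out[s.name] = SiteStatus.partial
    return out


@dataclass(frozen=True)
class TruncationReport:
    variant_key: tuple
    stop_codon_position: int
    shortening_aa: int
    nmd_escape: bool
    site_status: dict[str, str] = field(default_factory=dict)
    note: str = (
        "A site whose first residue coincides with the stop codon is "
        "classified lost (the stop replaces its first residue)."
    )


def truncation_report(
    variant: VariantRecord,
    transcript: TranscriptModel,
    domain_map: DomainMap,
    config: Optional[PipelineConfig] = None,
) -> Optional[TruncationReport]:
    """Assemble the full truncation annotation for a stop-gain variant.

    Returns None (with no report) for non-stop-gain variants or variants
    whose genomic position does not fall in a coding exon of ``transcript``.
    """
    config = config or PipelineConfig()
    if variant.consequence is not Consequence.nonsense:
        return None
    cds_pos = transcript.genomic_to_cds(variant.chrom, variant.pos)
    if cds_pos is None:
        return None
    stop_residue = math.ceil(cds_pos / 3)
    plen = transcript.protein_length
    if domain_map.protein_length != plen:
        raise ValueError(
            f"domain map length {domain_map.protein_length} != transcript "
            f"protein length {plen}"
        )
    return TruncationReport(
        variant_key=variant.key,
        stop_codon_position=stop_residue,
        shortening_aa=shortening(stop_residue, plen, config.shortening_convention),
        nmd_escape=nmd_escape(cds_pos, transcript, config.nmd_window_nt),
        site_status=site_retention(stop_residue, domain_map),
    )
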