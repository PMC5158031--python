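"""Homozygosity mapping: runs of homozygous genotype calls (ROH).

In a consanguineous or otherwise autozygous proband, a recessive disease
allele is expected to sit inside a multi-megabase run of homozygosity
inherited twice from a common ancestor. This module finds maximal runs of
homozygous calls in a marker table, keeps the large ones (default: longer
than 30 Mb), and localizes candidate variants within them. A second
sample's calls (typically the carrier mother) can be summarized inside each
region as a descriptive heterozygosity fraction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .model import GenotypeState, VariantRecord

#: One genotyped marker: (chromosome, 1-based position, genotype state).
Marker = tuple[str, int, GenotypeState]

_HOM = {GenotypeState.hom_ref, GenotypeState.hom_alt}


@dataclass(frozen=True)
class RohRegion:
    """A maximal run of homozygous markers.

    Span is measured marker-to-marker: from the first to the last non-missing
    marker of the run, not padded out to the flanking heterozygous markers.
    """

    chrom: str
    start_pos: int
    end_pos: int
    n_markers: int

    def __post_init__(self) -> None:
        if self.end_pos < self.start_pos:
            raise ValueError("end_pos must be >= start_pos")
        if self.n_markers < 2:
            raise ValueError("a run needs at least 2 markers")

    @property
    def length_mb(self) -> float:
        return (self.end_pos - self.start_pos) / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_pos <= pos <= self.end_pos


def detect_runs(markers: Sequence[Marker], het_tolerance: int = 0) -> list[RohRegion]:
    """Find all maximal homozygous runs.

    A run is a maximal stretch of non-missing markers containing at most
    ``het_tolerance`` heterozygous calls (default 0: strictly homozygous),
    starting and ending on a homozygous marker, with at least two markers.
    Missing calls neither break runs nor count as markers; runs never span
    chromosomes. Markers must be position-sorted within each chromosome.
    """
    if het_tolerance < 0:
        raise ValueError("het_tolerance must be >= 0")
    regions: list[RohRegion] = []
    for chrom, chrom_markers in _group_by_chrom(markers):
        informative = [
            (pos, state is GenotypeState.het)
            for _, pos, state in chrom_markers
            if state is not GenotypeState.missing
        ]
        regions.extend(
            _runs_one_chrom(chrom, informative, het_tolerance)
        )
    return regions


def _group_by_chrom(markers: Sequence[Marker]) -> Iterable[tuple[str, list[Marker]]]:
    groups: dict[str, list[Marker]] = {}
    order: list[str] = []
    for m in markers:
        if m[0] not in groups:
            groups[m[0]] = []
            order.append(m[0])
        groups[m[0]].append(m)
    for chrom in order:
        ms = groups[chrom]
        for a, b in zip(ms, ms[1:]):
            if b[1] <= a[1]:
                raise ValueError(
                    f"markers on {chrom} not sorted by position near {b[1]}"
                )
        yield chrom, ms


def _runs_one_chrom(
    chrom: str, informative: list[tuple[int, bool]], k: int
) -> list[RohRegion]:
    """Sliding-window maximal runs with at most k embedded het calls."""
    n = len(informative)
    runs: list[tuple[int, int]] = []
    left = 0
    het_count = 0
    for right in range(n):
        het_count += informative[right][1]
        while het_count > k:
            het_count -= informative[left][1]
            left += 1
        at_end = right == n - 1
        if at_end or het_count + informative[right + 1][1] > k:
            runs.append((left, right))
    # Trim window ends inward to homozygous markers; drop sub-pair runs.
    trimmed: list[tuple[int, int]] = []
    for i, j in runs:
        while i <= j and informative[i][1]:
            i += 1
        while j >= i and informative[j][1]:
            j -= 1
        if j > i:
            trimmed.append((i, j))
    # Remove duplicates and runs contained in another run.
    trimmed = sorted(set(trimmed))
    maximal = [
        (i, j)
        for i, j in trimmed
        if not any((a <= i and j <= b) and (a, b) != (i, j) for a, b in trimmed)
    ]
    return [
        RohRegion(
            chrom=chrom,
            start_pos=informative[i][0],
            end_pos=informative[j][0],
            n_markers=j - i + 1,
        )
        for i, j in maximal
    ]


def merge_overlapping(
    regions: Iterable[RohRegion], markers: Sequence[Marker]
) -> list[RohRegion]:
    """Merge overlapping runs on the same chromosome into their union span.

    With ``het_tolerance`` > 0, two maximal runs can overlap (each absorbing
    a different tolerated het at a flank); downstream containment queries
    need disjoint regions. Marker counts are recomputed over the merged
    span from the non-missing markers in ``markers``.
    """
    by_chrom: dict[str, list[RohRegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged: list[RohRegion] = []
    for chrom, rs in by_chrom.items():
        rs.sort(key=lambda r: r.start_pos)
        spans: list[list[int]] = []
        for r in rs:
            if spans and r.start_pos <= spans[-1][1]:
                spans[-1][1] = max(spans[-1][1], r.end_pos)
            else:
                spans.append([r.start_pos, r.end_pos])
        for start, end in spans:
            n = sum(
                1
                for c, p, s in markers
                if c == chrom and start <= p <= end and s is not GenotypeState.missing
            )
            merged.append(
                RohRegion(chrom=chrom, start_pos=start, end_pos=end, n_markers=n)
            )
    return merged


def filter_large_regions(
    regions: Iterable[RohRegion], min_mb: float = 30.0
) -> list[RohRegion]:
    """Keep regions strictly longer than ``min_mb`` megabases."""
    return [r for r in regions if r.length_mb > min_mb]


def annotate_in_region(
    variant: VariantRecord, regions: Iterable[RohRegion]
) -> Optional[RohRegion]:
    """The region containing the variant's position, or None."""
    for r in regions:
        if r.contains(variant.chrom, variant.pos):
            return r
    return None


def cross_sample_roh(
    regions: Iterable[RohRegion], other_markers: Sequence[Marker]
) -> list[tuple[RohRegion, Optional[float]]]:
    """Annotate each region with another sample's het fraction inside it.

    For each region, the fraction of the other sample's non-missing markers
    within the region span that are heterozygous; None if that sample has no
    non-missing markers there. A carrier parent is expected to be
    heterozygous at roughly the population rate inside the proband's
    autozygous segment.
    """
    out = []
    for region in regions:
        n = n_het = 0
        for chrom, pos, state in other_markers:
            if state is GenotypeState.missing or not region.contains(chrom, pos):
                continue
            n += 1
            n_het += state is GenotypeState.het
        out.append((region, (n_het / n) if n else None))
    return out
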