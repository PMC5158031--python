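"""Mendelian-consistency and Y-chromosome statistics for a trio.

Opposite homozygotes — child homozygous for one allele, a putative parent
homozygous for the other — are impossible under error-free Mendelian
transmission. Their genome-wide count against each parent, together with
allele divergence at Y-chromosome markers between father and son, gives a
simple advisory signal for mis-assigned parentage: a true parent shows a
handful of genotyping-error sites, an unrelated adult shows thousands.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .model import GenotypeState, SampleRole, TrioGenotypes, is_autosome


@dataclass(frozen=True)
class OppositeHomozygotes:
    """Directional opposite-homozygote tallies against one parent."""

    alt_ref: int  # child hom_alt, parent hom_ref
    ref_alt: int  # child hom_ref, parent hom_alt

    @property
    def total(self) -> int:
        return self.alt_ref + self.ref_alt


def opposite_homozygote_count(
    trios: Sequence[TrioGenotypes], parent: SampleRole
) -> OppositeHomozygotes:
    """Count autosomal opposite-homozygote sites against ``parent``.

    Only autosomal records with non-missing child and parent calls are
    considered; the two directions are tallied separately.
    """
    if parent not in (SampleRole.mother, SampleRole.father):
        raise ValueError("parent must be mother or father")
    alt_ref = ref_alt = 0
    for t in trios:
        if not is_autosome(t.variant.chrom):
            continue
        child = t.proband.state
        p = t.state(parent)
        if child is GenotypeState.missing or p is GenotypeState.missing:
            continue
        if child is GenotypeState.hom_alt and p is GenotypeState.hom_ref:
            alt_ref += 1
        elif child is GenotypeState.hom_ref and p is GenotypeState.hom_alt:
            ref_alt += 1
    return OppositeHomozygotes(alt_ref=alt_ref, ref_alt=ref_alt)


def y_marker_divergence(
    father_alleles: Sequence[Optional[int]], son_alleles: Sequence[Optional[int]]
) -> tuple[int, int]:
    """(compared, divergent) over paired haploid Y-marker alleles.

    Sites missing (None) in either sample are not compared. A true
    father-son pair shares the Y haplotype, so divergence beyond genotyping
    error indicates different paternal lineages.
    """
    if len(father_alleles) != len(son_alleles):
        raise ValueError("father and son Y marker lists differ in length")
    compared = divergent = 0
    for f, s in zip(father_alleles, son_alleles):
        if f is None or s is None:
            continue
        compared += 1
        divergent += f != s
    return compared, divergent


@dataclass(frozen=True)
class ConsistencySummary:
    father: OppositeHomozygotes
    mother: OppositeHomozygotes
    n_y_markers_compared: int = 0
    n_y_markers_divergent: int = 0

    def __post_init__(self) -> None:
        if self.n_y_markers_divergent > self.n_y_markers_compared:
            raise ValueError("divergent Y markers cannot exceed compared")


def paternity_signal(
    summary: ConsistencySummary,
    ratio_threshold: float = 20.0,
    min_y_divergent: int = 3,
) -> bool:
    """Advisory flag for probable non-paternity.

    True iff the father's opposite-homozygote total exceeds the mother's by
    the add-one-smoothed ratio ``(father + 1) / (mother + 1) >=
    ratio_threshold``, or at least ``min_y_divergent`` Y markers diverge
    between father and son. The flag is advisory only: it never alters
    variant filtering.
    """
    ratio = (summary.father.total + 1) / (summary.mother.total + 1)
    if ratio >= ratio_threshold:
        return True
    return (
        summary.n_y_markers_divergent >= min_y_divergent
        and summary.n_y_markers_divergent > 0
    )


def haploid_allele(state: GenotypeState, alleles: Optional[tuple]) -> Optional[int]:
    """Best-effort haploid allele from a genotype call (Y-marker encoding)."""
    if alleles is not None and len(alleles) >= 1 and alleles[0] is not None:
        return int(alleles[0])
    if state is GenotypeState.hom_ref:
        return 0
    if state is GenotypeState.hom_alt:
        return 1
    return None


def summarize_trio_consistency(
    autosomal: Sequence[TrioGenotypes],
    father_y: Sequence[Optional[int]] = (),
    son_y: Sequence[Optional[int]] = (),
) -> ConsistencySummary:
    compared, divergent = y_marker_divergence(father_y, son_y)
    return ConsistencySummary(
        father=opposite_homozygote_count(autosomal, SampleRole.father),
        mother=opposite_homozygote_count(autosomal, SampleRole.mother),
        n_y_markers_compared=compared,
        n_y_markers_divergent=divergent,
    )
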