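"""Variant filtering cascade and inheritance-model tagging.

Candidate recessive variants must (1) belong to a putatively damaging
consequence class (nonsense, missense, splice site, small indel), (2) be
rare in every population database that knows them (minor allele frequency
<= 0.005; a database the variant is absent from cannot disqualify it), and
(3) fit an inheritance model. Two model families are evaluated:

* strict trio-recessive: homozygous in the affected child and heterozygous
  in both unaffected parents, or compound heterozygous with one allele
  demonstrably inherited from each parent;
* proband-only fallback: homozygous, or two or more heterozygous variants
  in one gene, in the child alone — the pass used when the strict model
  fails (de novo hypotheses, suspected non-paternity, missing parents).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from .model import (
    DAMAGING_CLASSES,
    GenotypeState,
    InheritanceModel,
    PipelineConfig,
    TrioGenotypes,
    VariantRecord,
)

GeneGrouping = Mapping[str, Sequence[TrioGenotypes]]


def consequence_filter(variant: VariantRecord) -> bool:
    """True iff the variant's consequence class is putatively damaging."""
    return variant.consequence in DAMAGING_CLASSES


def maf_filter(variant: VariantRecord, threshold: float = 0.005) -> bool:
    """True iff every *known* database frequency is <= ``threshold``.

    The bound is inclusive (a frequency of exactly 0.005 passes) and
    unknown frequencies pass: absence from a database is absence of
    evidence, not evidence of commonness.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return all(f <= threshold for f in variant.pop_freqs.values())


def _parental_origin(t: TrioGenotypes) -> Optional[str]:
    """Phase a proband-het variant by parental origin.

    'maternal' / 'paternal' when exactly one parent carries the alternate
    allele; None when unphaseable (both parents carry it, neither does, or
    a parent call is missing).
    """
    carries = {GenotypeState.het, GenotypeState.hom_alt}
    m, f = t.mother.state, t.father.state
    if m is GenotypeState.missing or f is GenotypeState.missing:
        return None
    mom, dad = m in carries, f in carries
    if mom and not dad:
        return "maternal"
    if dad and not mom:
        return "paternal"
    return None


def tag_inheritance_trio(
    t: TrioGenotypes,
    gene_grouping: GeneGrouping,
    missing_parent_disqualifies: bool = False,
) -> InheritanceModel:
    """Strict trio-recessive model tag for one (already filtered) variant.

    Homozygous model: proband hom_alt with both parents het. A missing
    parent call is non-disqualifying by default (configurable). Compound-het
    model: proband het, the variant has a determinate parental origin, and
    another passing variant in the same gene has the opposite origin
    (trans configuration).
    """
    p = t.proband.state
    if p is GenotypeState.hom_alt:
        ok = []
        for parent in (t.mother.state, t.father.state):
            if parent is GenotypeState.missing:
                ok.append(not missing_parent_disqualifies)
            else:
                ok.append(parent is GenotypeState.het)
        if all(ok):
            return InheritanceModel.recessive_hom_trio
        return InheritanceModel.none
    if p is GenotypeState.het and t.variant.gene:
        origin = _parental_origin(t)
        if origin is None:
            return InheritanceModel.none
        for other in gene_grouping.get(t.variant.gene, ()):
            if other.variant.key == t.variant.key:
                continue
            if other.proband.state is not GenotypeState.het:
                continue
            other_origin = _parental_origin(other)
            if other_origin is not None and other_origin != origin:
                return InheritanceModel.compound_het_trio
    return InheritanceModel.none


def tag_inheritance_proband_only(
    t: TrioGenotypes, gene_grouping: GeneGrouping
) -> InheritanceModel:
    """Proband-only fallback tag: parental genotypes are ignored."""
    p = t.proband.state
    if p is GenotypeState.hom_alt:
        return InheritanceModel.hom_proband_only
    if p is GenotypeState.het and t.variant.gene:
        n_het = sum(
            1
            for other in gene_grouping.get(t.variant.gene, ())
            if other.proband.state is GenotypeState.het
        )
        if n_het >= 2:
            return InheritanceModel.comp_het_proband_only
    return InheritanceModel.none


@dataclass(frozen=True)
class FilterResult:
    """Per-variant outcome of the cascade."""

    trio: TrioGenotypes
    passes_consequence: bool
    passes_maf: bool
    strict_tag: InheritanceModel
    proband_tag: InheritanceModel

    @property
    def survives(self) -> bool:
        return self.passes_consequence and self.passes_maf


def group_by_gene(trios: Sequence[TrioGenotypes]) -> dict[str, list[TrioGenotypes]]:
    grouping: dict[str, list[TrioGenotypes]] = defaultdict(list)
    for t in trios:
        if t.variant.gene:
            grouping[t.variant.gene].append(t)
    return dict(grouping)


def filter_cascade(
    trios: Sequence[TrioGenotypes], config: Optional[PipelineConfig] = None
) -> list[FilterResult]:
    """Run the full cascade over a trio variant table.

    Consequence and MAF gates are evaluated per variant; inheritance tags
    are evaluated on the surviving set only (gene grouping, and hence
    compound-het partners, is restricted to survivors). Variants failing a
    gate are returned with tags ``none`` so the caller can audit the
    cascade.
    """
    config = config or PipelineConfig()
    passed = [
        t
        for t in trios
        if consequence_filter(t.variant) and maf_filter(t.variant, config.maf_threshold)
    ]
    grouping = group_by_gene(passed)
    passed_keys = {t.variant.key for t in passed}
    results = []
    for t in trios:
        if t.variant.key in passed_keys:
            strict = tag_inheritance_trio(
                t, grouping, config.missing_parent_disqualifies
            )
            proband = tag_inheritance_proband_only(t, grouping)
            results.append(
                FilterResult(
                    trio=t,
                    passes_consequence=True,
                    passes_maf=True,
                    strict_tag=strict,
                    proband_tag=proband,
                )
            )
        else:
            results.append(
                FilterResult(
                    trio=t,
                    passes_consequence=consequence_filter(t.variant),
                    passes_maf=maf_filter(t.variant, config.maf_threshold),
                    strict_tag=InheritanceModel.none,
                    proband_tag=InheritanceModel.none,
                )
            )
    return results
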