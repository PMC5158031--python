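"""Domain types and configuration shared by every pipeline stage.

The pipeline analyses a sequenced parent-offspring trio (proband, mother,
father) for a recessive retinal-dystrophy diagnosis: genotypes arrive as a
three-sample VCF, read depths as a per-target table, and the downstream
stages (variant filtering, CNV screening, homozygosity mapping, Mendelian
consistency, protein truncation) all consume the types defined here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional


class Consequence(str, enum.Enum):
    """Functional class of a variant as annotated upstream."""

    nonsense = "nonsense"
    missense = "missense"
    splice_site = "splice_site"
    small_insertion = "small_insertion"
    small_deletion = "small_deletion"
    other = "other"


#: Classes retained by the consequence gate (putatively protein-damaging).
DAMAGING_CLASSES = frozenset(
    {
        Consequence.nonsense,
        Consequence.missense,
        Consequence.splice_site,
        Consequence.small_insertion,
        Consequence.small_deletion,
    }
)


class GenotypeState(str, enum.Enum):
    hom_ref = "hom_ref"
    het = "het"
    hom_alt = "hom_alt"
    missing = "missing"


class SampleRole(str, enum.Enum):
    proband = "proband"
    mother = "mother"
    father = "father"
    reference_sample = "reference_sample"


class InheritanceModel(str, enum.Enum):
    """Inheritance hypothesis a variant is compatible with.

    ``recessive_hom_trio`` / ``compound_het_trio`` require support from both
    parents (the strict trio pass); the ``*_proband_only`` models ignore the
    parents (the fallback pass used when the strict model yields nothing,
    e.g. under suspected non-paternity).
    """

    recessive_hom_trio = "recessive_hom_trio"
    compound_het_trio = "compound_het_trio"
    hom_proband_only = "hom_proband_only"
    comp_het_proband_only = "comp_het_proband_only"
    none = "none"


# Chromosome names treated as non-autosomal (with or without "chr" prefix).
_NON_AUTOSOMES = {"X", "Y", "MT", "M"}


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and upper-case; ``chr3`` and ``3`` are equal."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return c.upper()


def is_autosome(chrom: str) -> bool:
    return normalize_chrom(chrom) not in _NON_AUTOSOMES


@dataclass(frozen=True)
class VariantRecord:
    """One genomic variant with its annotations.

    ``pop_freqs`` maps database name (e.g. ``AF_EXAC``) to allele frequency;
    a database the variant is absent from is simply not a key — absence
    means *unknown*, never 0.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    consequence: Consequence = Consequence.other
    pop_freqs: Mapping[str, float] = field(default_factory=dict)
    gene: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        for db, f in self.pop_freqs.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"{db} frequency {f} outside [0, 1]")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass(frozen=True)
class GenotypeCall:
    """A genotype call for one sample at one site.

    ``alleles`` keeps the raw VCF allele indices (supports haploid calls on
    the Y chromosome); ``allele_depths`` is the optional (ref, alt) read
    support, e.g. the candidate's 2 ref / 101 alt reads.
    """

    sample_role: SampleRole
    state: GenotypeState
    allele_depths: Optional[tuple[int, int]] = None
    alleles: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.allele_depths is not None:
            r, a = self.allele_depths
            if r < 0 or a < 0:
                raise ValueError("allele depths must be non-negative")
            if r == 0 and a == 0 and self.state is not GenotypeState.missing:
                raise ValueError("zero total read support only allowed for missing calls")


@dataclass(frozen=True)
class TrioGenotypes:
    """A variant together with exactly one call per trio role."""

    variant: VariantRecord
    calls: Mapping[SampleRole, GenotypeCall]

    def __post_init__(self) -> None:
        required = {SampleRole.proband, SampleRole.mother, SampleRole.father}
        if set(self.calls) != required:
            raise ValueError(
                f"trio requires exactly the roles {sorted(r.value for r in required)}"
            )
        for role, call in self.calls.items():
            if call.sample_role is not role:
                raise ValueError("call role inconsistent with mapping key")

    @property
    def proband(self) -> GenotypeCall:
        return self.calls[SampleRole.proband]

    @property
    def mother(self) -> GenotypeCall:
        return self.calls[SampleRole.mother]

    @property
    def father(self) -> GenotypeCall:
        return self.calls[SampleRole.father]

    def state(self, role: SampleRole) -> GenotypeState:
        return self.calls[role].state


def make_trio(
    variant: VariantRecord,
    proband: GenotypeState,
    mother: GenotypeState,
    father: GenotypeState,
) -> TrioGenotypes:
    """Convenience constructor from three genotype states."""
    return TrioGenotypes(
        variant=variant,
        calls={
            SampleRole.proband: GenotypeCall(SampleRole.proband, proband),
            SampleRole.mother: GenotypeCall(SampleRole.mother, mother),
            SampleRole.father: GenotypeCall(SampleRole.father, father),
        },
    )


@dataclass
class PipelineConfig:
    """All tunable thresholds of the pipeline, in one flat, auditable place.

    Defaults reproduce the published analysis settings: MAF gate ``<= 0.005``
    across population databases; homozygous regions kept if ``> 30`` Mb;
    depth-ratio CNV calls at ``<= 0.5`` (deletion) / ``>= 1.5`` (duplication)
    behind a ``> 0.97`` reference-pool correlation gate, with common CNVs
    (population frequency ``> 0.005``) excluded; NMD-escape window of 50
    coding nucleotides upstream of the last exon-exon junction (the
    conservative end of the 50-55 nt range).
    """

    maf_threshold: float = 0.005
    roh_min_length_mb: float = 30.0
    cnv_del_threshold: float = 0.5
    cnv_dup_threshold: float = 1.5
    cnv_corr_min: float = 0.97
    cnv_common_freq: float = 0.005
    nmd_window_nt: int = 50
    random_seed: int = 0

    # Secondary knobs (advisory statistics / robustness), defaults documented
    # in the methods note.
    het_tolerance: int = 1
    missing_parent_disqualifies: bool = False
    paternity_ratio_threshold: float = 20.0
    y_divergent_min: int = 3
    shortening_convention: str = "reported"  # or "peptide"
    qc_depth_thresholds: tuple[int, ...] = (10, 25)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not (0.0 <= self.maf_threshold <= 1.0):
            raise ValueError("maf_threshold must lie in [0, 1]")
        if not self.cnv_del_threshold < self.cnv_dup_threshold:
            raise ValueError("cnv_del_threshold must be < cnv_dup_threshold")
        if self.nmd_window_nt < 0:
            raise ValueError("nmd_window_nt must be >= 0")
        if self.het_tolerance < 0:
            raise ValueError("het_tolerance must be >= 0")
        if self.shortening_convention not in ("reported", "peptide"):
            raise ValueError("shortening_convention must be 'reported' or 'peptide'")


def prevalence_percent(n_positive: int, n_screened: int, ndigits: int = 2) -> float:
    """Screening prevalence as a percentage, e.g. 1 of 384 probands -> 0.26.

    Raises on a non-positive cohort size.
    """
    if n_screened <= 0:
        raise ValueError("cohort size must be positive")
    if not (0 <= n_positive <= n_screened):
        raise ValueError("positives must lie in [0, cohort size]")
    return round(100.0 * n_positive / n_screened, ndigits)


def allele_frequency(n_alt: int, n_total: int, sig_figs: int = 2) -> float:
    """Allele frequency rounded to ``sig_figs`` significant figures.

    ``allele_frequency(1, 119880)`` -> 8.3e-06, the two-significant-figure
    convention population databases print.
    """
    if n_total <= 0:
        raise ValueError("total allele count must be positive")
    if not (0 <= n_alt <= n_total):
        raise ValueError("alt allele count must lie in [0, total]")
    f = n_alt / n_total
    if f == 0.0:
        return 0.0
    import math

    exponent = math.floor(math.log10(abs(f)))
    return round(f, -exponent + sig_figs - 1)
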