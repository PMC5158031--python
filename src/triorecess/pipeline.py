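"""End-to-end orchestration: from input files to a ranked candidate report.

Stages, in order: read the trio VCF; run the consequence/MAF/inheritance
filter cascade; map runs of homozygosity from the proband's genotypes and
keep regions > 30 Mb; screen the proband's depth profile for CNVs against
the reference pool; compute the Mendelian-consistency / Y-marker summary;
and annotate stop-gain candidates with their protein truncation report.
The result is deterministic given fixed inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import io as tio
from .cnv import (
    CnvCall,
    call_cnv,
    copy_score,
    depth_qc_summary,
    filter_common_cnv,
    reference_correlation,
)
from .consistency import (
    ConsistencySummary,
    haploid_allele,
    paternity_signal,
    summarize_trio_consistency,
)
from .filters import FilterResult, filter_cascade
from .model import (
    Consequence,
    GenotypeState,
    InheritanceModel,
    PipelineConfig,
    SampleRole,
    TrioGenotypes,
    is_autosome,
    normalize_chrom,
)
from .protein import TruncationReport, truncation_report
from .roh import RohRegion, annotate_in_region, cross_sample_roh, detect_runs, \
    filter_large_regions, merge_overlapping

logger = logging.getLogger(__name__)

DEFAULT_ROLE_MAP = {"proband": "proband", "mother": "mother", "father": "father"}


@dataclass
class CandidateReport:
    """Everything the pipeline concluded, ready to serialize."""

    candidates: pd.DataFrame
    roh_regions: list[RohRegion] = field(default_factory=list)
    mother_het_fractions: list = field(default_factory=list)
    cnv_calls: list[CnvCall] = field(default_factory=list)
    cnv_correlation: Optional[float] = None
    cnv_valid: bool = False
    consistency: Optional[ConsistencySummary] = None
    paternity_questioned: bool = False
    truncations: dict[tuple, TruncationReport] = field(default_factory=dict)
    qc: dict = field(default_factory=dict)

    @property
    def strict_candidates(self) -> pd.DataFrame:
        return self.candidates[
            self.candidates["strict_model"] != InheritanceModel.none.value
        ]

    @property
    def proband_only_candidates(self) -> pd.DataFrame:
        return self.candidates[
            self.candidates["proband_model"] != InheritanceModel.none.value
        ]

    def write_tsv(self, path: str | Path) -> None:
        self.candidates.to_csv(path, sep="\t", index=False)


_CANDIDATE_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "consequence", "max_known_af",
    "strict_model", "proband_model", "in_roh", "roh_length_mb",
    "cnv_at_site", "stop_codon_position", "shortening_aa", "nmd_escape",
]


def _split_records(
    trios: Sequence[TrioGenotypes],
) -> tuple[list[TrioGenotypes], list[TrioGenotypes]]:
    autosomal, y = [], []
    for t in trios:
        if is_autosome(t.variant.chrom):
            autosomal.append(t)
        elif normalize_chrom(t.variant.chrom) == "Y":
            y.append(t)
    return autosomal, y


def run_pipeline(
    config: PipelineConfig,
    vcf_path: str | Path,
    depth_path: Optional[str | Path] = None,
    transcript_path: Optional[str | Path] = None,
    domains_path: Optional[str | Path] = None,
    role_map: Optional[Mapping[str, str]] = None,
    population_cnv_path: Optional[str | Path] = None,
) -> CandidateReport:
    """Run every stage over the given inputs and assemble the report.

    ``depth_path``, ``transcript_path`` and ``domains_path`` are optional:
    stages whose inputs are absent are skipped (their report fields stay
    empty). ``role_map`` maps VCF sample names to trio roles; the depth
    table is expected to name the trio columns by role, all other columns
    form the reference pool.
    """
    role_map = dict(role_map or DEFAULT_ROLE_MAP)
    trios = tio.read_trio_vcf(vcf_path, role_map)
    autosomal, y_records = _split_records(trios)

    results = filter_cascade(autosomal, config)

    # Homozygosity mapping from the proband's autosomal genotypes.
    markers = [
        (t.variant.chrom, t.variant.pos, t.proband.state) for t in autosomal
    ]
    mother_markers = [
        (t.variant.chrom, t.variant.pos, t.mother.state) for t in autosomal
    ]
    all_runs = merge_overlapping(detect_runs(markers, config.het_tolerance), markers)
    large = filter_large_regions(all_runs, config.roh_min_length_mb)
    mother_fracs = cross_sample_roh(large, mother_markers)

    # Mendelian consistency + Y-marker divergence.
    father_y = [haploid_allele(t.father.state, t.father.alleles) for t in y_records]
    son_y = [haploid_allele(t.proband.state, t.proband.alleles) for t in y_records]
    consistency = summarize_trio_consistency(autosomal, father_y, son_y)
    questioned = paternity_signal(
        consistency, config.paternity_ratio_threshold, config.y_divergent_min
    )

    # Depth-based CNV screening of the proband.
    cnv_calls: list[CnvCall] = []
    corr = None
    corr_valid = False
    qc: dict = {}
    if depth_path is not None:
        profiles = tio.read_depth_table(depth_path)
        trio_cols = [r for r in ("proband", "mother", "father") if r in profiles]
        pool = [p for s, p in profiles.items() if s not in trio_cols]
        for s in trio_cols:
            qc[s] = depth_qc_summary(profiles[s], config.qc_depth_thresholds)
        if "proband" in profiles and pool:
            gate = reference_correlation(
                profiles["proband"], pool, config.cnv_corr_min
            )
            corr, corr_valid = gate.r, gate.valid
            if gate.valid:
                scores = copy_score(profiles["proband"], pool)
                cnv_calls = call_cnv(scores, profiles["proband"].targets, config)
                if population_cnv_path is not None:
                    table = tio.read_population_cnv_table(population_cnv_path)
                    cnv_calls = filter_common_cnv(
                        cnv_calls, table, config.cnv_common_freq
                    )
            else:
                logger.warning(
                    "proband depth profile failed the correlation gate "
                    "(r=%s <= %.3f); CNV stage skipped", gate.r, config.cnv_corr_min
                )

    # Truncation annotation for stop-gain candidates.
    transcript = (
        tio.read_transcript_gff(transcript_path) if transcript_path else None
    )
    domains = tio.read_domain_map(domains_path) if domains_path else None

    rows = []
    truncations: dict[tuple, TruncationReport] = {}
    for res in results:
        if not res.survives:
            continue
        if (
            res.strict_tag is InheritanceModel.none
            and res.proband_tag is InheritanceModel.none
        ):
            continue
        v = res.trio.variant
        region = annotate_in_region(v, large)
        cnv_here = next(
            (
                c for c in cnv_calls
                if c.target[0] == v.chrom and c.target[1] < v.pos <= c.target[2]
            ),
            None,
        )
        trunc = None
        if (
            transcript is not None
            and domains is not None
            and v.consequence is Consequence.nonsense
        ):
            trunc = truncation_report(v, transcript, domains, config)
            if trunc is not None:
                truncations[v.key] = trunc
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref_allele,
                "alt": v.alt_allele,
                "gene": v.gene,
                "consequence": v.consequence.value,
                "max_known_af": max(v.pop_freqs.values(), default=float("nan")),
                "strict_model": res.strict_tag.value,
                "proband_model": res.proband_tag.value,
                "in_roh": region is not None,
                "roh_length_mb": region.length_mb if region else float("nan"),
                "cnv_at_site": cnv_here.call if cnv_here else "",
                "stop_codon_position": trunc.stop_codon_position if trunc else pd.NA,
                "shortening_aa": trunc.shortening_aa if trunc else pd.NA,
                "nmd_escape": trunc.nmd_escape if trunc else pd.NA,
            }
        )

    candidates = pd.DataFrame(rows, columns=_CANDIDATE_COLUMNS)
    if not candidates.empty:
        candidates = candidates.sort_values(
            by=["in_roh", "consequence", "max_known_af", "chrom", "pos"],
            ascending=[False, True, True, True, True],
            key=_rank_key,
        ).reset_index(drop=True)

    return CandidateReport(
        candidates=candidates,
        roh_regions=large,
        mother_het_fractions=mother_fracs,
        cnv_calls=cnv_calls,
        cnv_correlation=corr,
        cnv_valid=corr_valid,
        consistency=consistency,
        paternity_questioned=questioned,
        truncations=truncations,
        qc=qc,
    )


_SEVERITY = {
    Consequence.nonsense.value: 0,
    Consequence.small_deletion.value: 1,
    Consequence.small_insertion.value: 1,
    Consequence.splice_site.value: 2,
    Consequence.missense.value: 3,
    Consequence.other.value: 4,
}


def _rank_key(s: pd.Series) -> pd.Series:
    if s.name == "consequence":
        return s.map(_SEVERITY)
    if s.name == "chrom":
        return s.map(tio.chrom_sort_key)
    return s
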