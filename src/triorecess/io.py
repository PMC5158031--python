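"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF 4.2 (pysam) with the per-variant annotations in
INFO: ``CSQCLASS`` (consequence class), ``GENE``, and per-database allele
frequencies ``AF_EVS`` / ``AF_HAPMAP`` / ``AF_1KG`` / ``AF_EXAC``. Depth
tables are BED3+N TSV (chrom, start, end, one column per sample; 0-based
half-open intervals). Transcript exon models are GFF3 (CDS features of one
transcript); domain maps are JSON.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import pysam

from .cnv import DepthProfile, PopulationCnv
from .model import (
    Consequence,
    GenotypeCall,
    GenotypeState,
    SampleRole,
    TrioGenotypes,
    VariantRecord,
)
from .protein import DomainMap, DomainSite, TranscriptModel

logger = logging.getLogger(__name__)

FREQ_KEYS = ("AF_EVS", "AF_HAPMAP", "AF_1KG", "AF_EXAC")

_CHROM_ORDER = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def chrom_sort_key(chrom: str) -> tuple:
    from .model import normalize_chrom

    c = normalize_chrom(chrom)
    return (_CHROM_ORDER.get(c, 99), c)


# ---------------------------------------------------------------------------
# VCF


def _state_from_gt(gt: Optional[tuple]) -> GenotypeState:
    if gt is None or all(a is None for a in gt):
        return GenotypeState.missing
    alleles = [a for a in gt if a is not None]
    if len(alleles) < len(gt):
        return GenotypeState.missing
    if len(alleles) == 1:  # haploid (Y markers)
        return GenotypeState.hom_alt if alleles[0] else GenotypeState.hom_ref
    if all(a == 0 for a in alleles):
        return GenotypeState.hom_ref
    if all(a != 0 for a in alleles):
        return GenotypeState.hom_alt
    return GenotypeState.het


def read_trio_vcf(path: str | Path, role_map: Mapping[str, str]) -> list[TrioGenotypes]:
    """Read a three-sample VCF into trio genotype records.

    ``role_map`` maps VCF sample names to roles ('proband', 'mother',
    'father'). Every sample in the file must be mapped and every role
    present, otherwise the error names the offending sample. Records are
    returned sorted by (chromosome, position). Absent frequency keys stay
    absent (unknown), never become 0.
    """
    roles = {name: SampleRole(role) for name, role in role_map.items()}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for s in samples:
            if s not in roles:
                raise ValueError(f"VCF sample {s!r} is not mapped to a trio role")
        present = {roles[s] for s in samples}
        for need in (SampleRole.proband, SampleRole.mother, SampleRole.father):
            if need not in present:
                raise ValueError(f"no VCF sample mapped to role {need.value!r}")
        out: list[TrioGenotypes] = []
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"multi-allelic or ALT-less record at {rec.chrom}:{rec.pos}; "
                    "decompose to bi-allelic records first"
                )
            csq = rec.info.get("CSQCLASS", "other")
            if isinstance(csq, tuple):
                csq = csq[0]
            try:
                consequence = Consequence(csq)
            except ValueError:
                logger.warning(
                    "unknown consequence class %r at %s:%d treated as 'other'",
                    csq, rec.chrom, rec.pos,
                )
                consequence = Consequence.other
            freqs = {}
            for key in FREQ_KEYS:
                if key in rec.info:
                    v = rec.info[key]
                    freqs[key] = float(v[0] if isinstance(v, tuple) else v)
            gene = rec.info.get("GENE", "")
            if isinstance(gene, tuple):
                gene = gene[0]
            variant = VariantRecord(
                chrom=rec.chrom,
                pos=rec.pos,
                ref_allele=rec.ref,
                alt_allele=rec.alts[0],
                consequence=consequence,
                pop_freqs=freqs,
                gene=gene or "",
            )
            calls = {}
            for s in samples:
                sample = rec.samples[s]
                try:
                    state = _state_from_gt(sample.get("GT"))
                    gt = sample.get("GT")
                except Exception:  # pragma: no cover - defensive
                    logger.warning(
                        "unparsable genotype for %s at %s:%d set to missing",
                        s, rec.chrom, rec.pos,
                    )
                    state, gt = GenotypeState.missing, None
                ad = sample.get("AD") if "AD" in sample else None
                if ad is not None and len(ad) == 2 and None not in ad:
                    ad = (int(ad[0]), int(ad[1]))
                    if ad == (0, 0):
                        ad = None
                else:
                    ad = None
                role = roles[s]
                calls[role] = GenotypeCall(
                    sample_role=role, state=state, allele_depths=ad, alleles=gt
                )
            out.append(TrioGenotypes(variant=variant, calls=calls))
    out.sort(key=lambda t: (chrom_sort_key(t.variant.chrom), t.variant.pos))
    return out


_STATE_TO_GT = {
    GenotypeState.hom_ref: (0, 0),
    GenotypeState.het: (0, 1),
    GenotypeState.hom_alt: (1, 1),
    GenotypeState.missing: (None, None),
}


def build_vcf_header(
    sample_names: Sequence[str], contigs: Mapping[str, int]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    header.info.add("CSQCLASS", 1, "String", "Consequence class of the variant")
    header.info.add("GENE", 1, "String", "Gene symbol")
    header.info.add("AF_EVS", 1, "Float", "Allele frequency, Exome Variant Server")
    header.info.add("AF_HAPMAP", 1, "Float", "Allele frequency, HapMap")
    header.info.add("AF_1KG", 1, "Float", "Allele frequency, 1000 Genomes")
    header.info.add("AF_EXAC", 1, "Float", "Allele frequency, ExAC")
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("AD", "R", "Integer", "Allelic read depths")
    for s in sample_names:
        header.add_sample(s)
    return header


def write_trio_vcf(
    trios: Sequence[TrioGenotypes],
    path: str | Path,
    sample_names: Optional[Mapping[str, str]] = None,
    contigs: Optional[Mapping[str, int]] = None,
) -> None:
    """Write trio records as a VCF 4.2 text file.

    ``sample_names`` maps role name -> sample column name (defaults to the
    role names themselves). Contig lengths default to each chromosome's
    maximum observed position.
    """
    sample_names = sample_names or {
        "proband": "proband", "mother": "mother", "father": "father"
    }
    role_of = {v: SampleRole(k) for k, v in sample_names.items()}
    columns = list(sample_names.values())
    if contigs is None:
        contigs = {}
        for t in trios:
            contigs[t.variant.chrom] = max(
                contigs.get(t.variant.chrom, 0), t.variant.pos
            )
        contigs = dict(
            sorted(contigs.items(), key=lambda kv: chrom_sort_key(kv[0]))
        )
    header = build_vcf_header(columns, contigs)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for t in trios:
            v = t.variant
            rec = vcf.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.info["CSQCLASS"] = v.consequence.value
            if v.gene:
                rec.info["GENE"] = v.gene
            for key, f in v.pop_freqs.items():
                rec.info[key] = f
            for col in columns:
                call = t.calls[role_of[col]]
                gt = call.alleles if call.alleles is not None else _STATE_TO_GT[call.state]
                rec.samples[col]["GT"] = gt
                if call.allele_depths is not None:
                    rec.samples[col]["AD"] = call.allele_depths
            vcf.write(rec)


# ---------------------------------------------------------------------------
# Depth tables


def read_depth_table(path: str | Path) -> dict[str, DepthProfile]:
    """Read a BED3+N depth table into one DepthProfile per sample column.

    All samples share the file's target list in file order. Duplicated
    target rows are fatal; an empty file yields an empty profile set with a
    warning.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        logger.warning("depth table %s is empty; no profiles read", path)
        return {}
    required = ["chrom", "start", "end"]
    if list(df.columns[:3]) != required:
        raise ValueError(f"depth table must start with columns {required}")
    samples = list(df.columns[3:])
    if not samples:
        raise ValueError("depth table has no sample columns")
    targets = [(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()]
    if len(set(targets)) != len(targets):
        raise ValueError("depth table contains duplicated target intervals")
    if df[samples].isna().any().any():
        raise ValueError("depth table contains missing depth values (ragged rows)")
    return {
        s: DepthProfile(sample_id=s, targets=targets, depths=df[s].to_numpy(float))
        for s in samples
    }


def write_depth_table(profiles: Sequence[DepthProfile], path: str | Path) -> None:
    if not profiles:
        raise ValueError("no profiles to write")
    targets = list(profiles[0].targets)
    for p in profiles:
        if list(p.targets) != targets:
            raise ValueError("profiles do not share a target list")
    df = pd.DataFrame(targets, columns=["chrom", "start", "end"])
    for p in profiles:
        df[p.sample_id] = p.depths
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Transcript models (GFF3) and domain maps (JSON)

_GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def read_transcript_gff(path: str | Path, name: str = "") -> TranscriptModel:
    """Build a transcript model from the CDS features of a GFF3 file.

    The file is expected to describe a single transcript; CDS rows are
    ordered 5'->3' according to the strand.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", names=_GFF_COLUMNS, header=None, dtype=str
    )
    cds = df[df["type"] == "CDS"].copy()
    if cds.empty:
        raise ValueError(f"no CDS features in {path}")
    strands = set(cds["strand"])
    chroms = set(cds["seqid"])
    if len(strands) != 1 or len(chroms) != 1:
        raise ValueError("transcript CDS features must share one chromosome/strand")
    strand = strands.pop()
    cds["start"] = cds["start"].astype(int)
    cds["end"] = cds["end"].astype(int)
    cds = cds.sort_values("start", ascending=(strand == "+"))
    exons = tuple((int(s), int(e)) for s, e in zip(cds["start"], cds["end"]))
    if not name:
        attrs = cds.iloc[0]["attributes"]
        for kv in str(attrs).split(";"):
            if kv.startswith("Parent="):
                name = kv.split("=", 1)[1]
    return TranscriptModel(name=name or "transcript", chrom=chroms.pop(),
                           strand=strand, exons=exons)


def write_transcript_gff(model: TranscriptModel, path: str | Path) -> None:
    lo = min(s for s, _ in model.exons)
    hi = max(e for _, e in model.exons)
    lines = [
        "##gff-version 3",
        f"{model.chrom}\ttriorecess\tmRNA\t{lo}\t{hi}\t.\t{model.strand}\t.\t"
        f"ID={model.name}",
    ]
    offset = 0
    for i, (s, e) in enumerate(model.exons, start=1):
        phase = (3 - offset % 3) % 3
        lines.append(
            f"{model.chrom}\ttriorecess\tCDS\t{s}\t{e}\t.\t{model.strand}\t{phase}\t"
            f"ID=cds{i};Parent={model.name}"
        )
        offset += e - s + 1
    Path(path).write_text("\n".join(lines) + "\n")


def read_domain_map(path: str | Path) -> DomainMap:
    doc = json.loads(Path(path).read_text())
    sites = tuple(
        DomainSite(
            name=s["name"],
            start=int(s["start"]),
            end=int(s["end"]),
            family=s.get("family", ""),
        )
        for s in doc["sites"]
    )
    return DomainMap(
        protein=doc.get("protein", ""),
        protein_length=int(doc["protein_length"]),
        sites=sites,
    )


def read_population_cnv_table(path: str | Path) -> list[PopulationCnv]:
    """TSV with columns chrom, start, end, freq (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    required = ["chrom", "start", "end", "freq"]
    if list(df.columns[:4]) != required:
        raise ValueError(f"population CNV table must have columns {required}")
    return [
        (str(r.chrom), int(r.start), int(r.end), float(r.freq))
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Packaged fixtures


def _data_path(filename: str) -> Path:
    return Path(__file__).parent / "data" / filename


def load_gnat1_domains() -> DomainMap:
    """The GNAT1 (rod transducin alpha, 350 aa) functional-site map."""
    return read_domain_map(_data_path("gnat1_domains.json"))


def load_gnat1_transcript() -> TranscriptModel:
    """A synthetic 8-coding-exon GNAT1 transcript model.

    Real exon boundaries of NM_144499.2 are not bundled; this synthetic
    stand-in preserves the properties the NMD analysis relies on: total CDS
    of 1053 nt (350 residues + stop) split over 8 coding exons with the
    last coding exon spanning c.851-c.1053, so that the documented stops at
    c.904 and c.963 fall in the last coding exon.
    """
    return read_transcript_gff(
        _data_path("gnat1_transcript_synthetic.gff3"), name="GNAT1-synthetic"
    )
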