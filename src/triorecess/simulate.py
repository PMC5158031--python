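"""Synthetic trio-exome data with planted ground truth.

The generator emulates the inputs the pipeline consumes, at the scale of a
real trio exome (tens of thousands of called variant sites, ~80x mean
depth), with every interesting feature planted and recorded in truth
tables:

* trio genotypes under Hardy-Weinberg equilibrium with Mendelian
  transmission — or, in ``unrelated`` father mode, a father column drawn
  independently of the transmitting haplotypes (the mis-assigned-paternity
  scenario);
* a multi-megabase autozygous (homozygous-by-descent) segment in the child,
  carrying a planted homozygous nonsense variant with its database
  annotations;
* haploid Y-chromosome markers shared (true father) or independent
  (unrelated);
* symmetric genotype error at a configurable rate;
* per-target read depths for the trio plus a reference pool, with
  overdispersed (negative binomial) count noise around a shared
  target-intensity profile, and planted copy-ratio changes.

Everything is driven by one integer seed; a fixed seed yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .cnv import DepthProfile
from .model import (
    Consequence,
    GenotypeCall,
    GenotypeState,
    SampleRole,
    TrioGenotypes,
    VariantRecord,
)

#: Approximate human autosome lengths, megabases.
CHROM_LENGTHS_MB: dict[str, float] = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171, "7": 159,
    "8": 146, "9": 141, "10": 136, "11": 135, "12": 134, "13": 115,
    "14": 107, "15": 103, "16": 90, "17": 81, "18": 78, "19": 59, "20": 63,
    "21": 48, "22": 51,
}
Y_LENGTH_MB = 59.0

_STATES = (GenotypeState.hom_ref, GenotypeState.het, GenotypeState.hom_alt)
_BASES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class PlantedVariant:
    """The causal variant planted inside the autozygous segment.

    Defaults describe a stop-gain in the last coding exon of the packaged
    GNAT1 transcript model (c.963C>A), ultra-rare in ExAC.
    """

    chrom: str = "3"
    pos: int = 50_220_963
    ref: str = "C"
    alt: str = "A"
    gene: str = "GNAT1"
    consequence: str = "nonsense"
    pop_freqs: dict = field(default_factory=lambda: {"AF_EXAC": 8.3e-6})


@dataclass(frozen=True)
class DepthSpec:
    """Depth-of-coverage simulation parameters.

    ``dispersion`` is the negative-binomial overdispersion (variance =
    m + dispersion * m^2); 0, or ``noise='poisson'``, gives Poisson counts.
    ``planted_cnvs`` are (target index, true copy ratio) pairs applied to
    the proband's intensity (0.5 = heterozygous deletion, 1.5 =
    heterozygous duplication).
    """

    n_targets: int = 200
    mean_depth: float = 80.0
    noise: str = "nb"
    dispersion: float = 0.005
    n_pool: int = 10
    intensity_sigma: float = 0.8
    intensity_floor: float = 0.3
    planted_cnvs: tuple[tuple[int, float], ...] = ()
    include_exon_target: bool = True

    def validate(self) -> None:
        if self.n_targets < 1 or self.n_pool < 1:
            raise ValueError("n_targets and n_pool must be >= 1")
        if self.noise not in ("nb", "poisson"):
            raise ValueError("noise must be 'nb' or 'poisson'")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        for idx, ratio in self.planted_cnvs:
            if not (0 <= idx < self.n_targets):
                raise ValueError(f"planted CNV index {idx} out of range")
            if ratio < 0:
                raise ValueError("copy ratio must be >= 0")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of one synthetic trio study.

    Site allele frequencies are a mixture: a ``rare_fraction`` of sites get
    log-uniform rare frequencies (1e-5 .. 5e-3, the regime the MAF gate
    keeps), the rest Beta(``beta_a``, ``beta_b``) clipped to [0.01, 0.99]
    (the common polymorphisms a joint-called trio VCF is dominated by).
    ``father_mode='unrelated'`` reproduces the study condition in which the
    sequenced father is not the biological father.
    """

    n_autosomal_sites: int = 50_000
    n_indel_sites: int = 4_000
    beta_a: float = 0.5
    beta_b: float = 0.5
    rare_fraction: float = 0.08
    chrom_lengths_mb: dict = field(default_factory=lambda: dict(CHROM_LENGTHS_MB))
    planted_roh: tuple[tuple[str, int, float], ...] = (("3", 30_000_000, 40.0),)
    planted_variant: Optional[PlantedVariant] = field(default_factory=PlantedVariant)
    father_mode: str = "unrelated"
    genotype_error_rate: float = 1e-4
    n_y_markers: int = 12
    depth: DepthSpec = field(default_factory=DepthSpec)
    seed: int = 0

    def validate(self) -> None:
        if self.father_mode not in ("true_father", "unrelated"):
            raise ValueError("father_mode must be 'true_father' or 'unrelated'")
        if not (0 <= self.genotype_error_rate < 1):
            raise ValueError("genotype_error_rate must lie in [0, 1)")
        if not (0 <= self.rare_fraction <= 1):
            raise ValueError("rare_fraction must lie in [0, 1]")
        for chrom, start, length_mb in self.planted_roh:
            if chrom not in self.chrom_lengths_mb:
                raise ValueError(f"planted ROH on unknown chromosome {chrom}")
            if start + length_mb * 1e6 > self.chrom_lengths_mb[chrom] * 1e6:
                raise ValueError(
                    f"planted ROH {chrom}:{start}+{length_mb}Mb overruns chromosome"
                )
        if self.planted_variant is not None:
            v = self.planted_variant
            if not any(
                chrom == v.chrom and start <= v.pos < start + length_mb * 1e6
                for chrom, start, length_mb in self.planted_roh
            ):
                raise ValueError("planted variant must lie inside a planted ROH")
        self.depth.validate()


def _roh_mask(spec: SimulationSpec, chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for chrom, start, length_mb in spec.planted_roh:
        mask |= (chroms == chrom) & (pos >= start) & (pos < start + length_mb * 1e6)
    return mask


@dataclass
class TrioSimulation:
    """Generated trio genotypes plus complete truth tables."""

    spec: SimulationSpec
    sites: pd.DataFrame  # autosomal sites, truth + observed states (0/1/2)
    y_sites: pd.DataFrame  # haploid Y markers: father_allele, son_allele

    def trio_genotypes(self) -> list[TrioGenotypes]:
        """Observed autosomal genotypes as pipeline-ready trio records."""
        out = []
        for row in self.sites.itertuples():
            variant = VariantRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref_allele=row.ref,
                alt_allele=row.alt,
                consequence=Consequence(row.consequence),
                pop_freqs={
                    k: getattr(row, a)
                    for k, a in (("AF_EXAC", "af_exac"), ("AF_EVS", "af_evs"),
                                 ("AF_1KG", "af_1kg"))
                    if not np.isnan(getattr(row, a))
                },
                gene=row.gene,
            )
            calls = {
                role: GenotypeCall(sample_role=role, state=_STATES[int(g)])
                for role, g in (
                    (SampleRole.proband, row.proband),
                    (SampleRole.mother, row.mother),
                    (SampleRole.father, row.father),
                )
            }
            out.append(TrioGenotypes(variant=variant, calls=calls))
        return out

    def y_alleles(self) -> tuple[list[int], list[int]]:
        return (
            [int(a) for a in self.y_sites["father_allele"]],
            [int(a) for a in self.y_sites["son_allele"]],
        )

    def write_vcf(self, path: str | Path) -> None:
        contigs = {
            c: int(mb * 1e6) for c, mb in self.spec.chrom_lengths_mb.items()
        }
        contigs["Y"] = int(Y_LENGTH_MB * 1e6)
        columns = ["proband", "mother", "father"]
        header = tio.build_vcf_header(columns, contigs)
        import pysam

        gt_of = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
        with pysam.VariantFile(str(path), "w", header=header) as vcf:
            for row in self.sites.itertuples():
                rec = vcf.new_record(
                    contig=row.chrom, start=int(row.pos) - 1,
                    alleles=(row.ref, row.alt),
                )
                rec.info["CSQCLASS"] = row.consequence
                rec.info["GENE"] = row.gene
                for key, a in (("AF_EXAC", "af_exac"), ("AF_EVS", "af_evs"),
                               ("AF_1KG", "af_1kg")):
                    v = getattr(row, a)
                    if not np.isnan(v):
                        rec.info[key] = float(v)
                for col, g in zip(columns, (row.proband, row.mother, row.father)):
                    rec.samples[col]["GT"] = gt_of[int(g)]
                vcf.write(rec)
            for row in self.y_sites.itertuples():
                rec = vcf.new_record(
                    contig="Y", start=int(row.pos) - 1, alleles=(row.ref, row.alt)
                )
                rec.info["CSQCLASS"] = "other"
                rec.samples["proband"]["GT"] = (int(row.son_allele),)
                rec.samples["mother"]["GT"] = (None,)
                rec.samples["father"]["GT"] = (int(row.father_allele),)
                vcf.write(rec)

    def truth_table(self) -> pd.DataFrame:
        return self.sites.copy()


def simulate_trio(spec: SimulationSpec) -> TrioSimulation:
    """Generate the trio genotype table described by ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_autosomal_sites + spec.n_indel_sites

    chrom_names = list(spec.chrom_lengths_mb)
    lengths = np.array([spec.chrom_lengths_mb[c] for c in chrom_names], float)
    chrom_idx = rng.choice(len(chrom_names), size=n, p=lengths / lengths.sum())
    chroms = np.array(chrom_names, dtype=object)[chrom_idx]
    chrom_len_bp = (lengths * 1e6).astype(np.int64)[chrom_idx]
    pos = rng.integers(1, chrom_len_bp, dtype=np.int64)
    pos = _dedupe_positions(rng, chroms, pos, chrom_len_bp, spec)

    is_indel = np.zeros(n, dtype=bool)
    is_indel[spec.n_autosomal_sites:] = True

    rare = rng.random(n) < spec.rare_fraction
    freq = np.clip(rng.beta(spec.beta_a, spec.beta_b, size=n), 0.01, 0.99)
    freq[rare] = 10 ** rng.uniform(-5.0, np.log10(5e-3), size=int(rare.sum()))

    # Parental haplotypes under Hardy-Weinberg.
    m1, m2 = (rng.random(n) < freq), (rng.random(n) < freq)
    f1, f2 = (rng.random(n) < freq), (rng.random(n) < freq)
    mat = np.where(rng.random(n) < 0.5, m1, m2)
    in_roh = _roh_mask(spec, chroms, pos)

    if spec.father_mode == "true_father":
        pat = np.where(rng.random(n) < 0.5, f1, f2)
        # Autozygosity via a shared founder haplotype carried by both
        # parents: child homozygous, both parents carriers (Mendelian-
        # consistent consanguinity).
        founder = rng.random(n) < freq
        m1 = np.where(in_roh, founder, m1)
        f1 = np.where(in_roh, founder, f1)
        mat = np.where(in_roh, founder, mat)
        pat = np.where(in_roh, founder, pat)
    else:
        # Sequenced father is unrelated; the child's paternal allele comes
        # from the (unsequenced) biological father, drawn from the
        # population. Autozygosity doubles the maternal-lineage allele.
        pat = rng.random(n) < freq
        pat = np.where(in_roh, mat, pat)

    child = mat.astype(np.int8) + pat.astype(np.int8)
    mother = m1.astype(np.int8) + m2.astype(np.int8)
    father = f1.astype(np.int8) + f2.astype(np.int8)

    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + 1 + rng.integers(0, 3, size=n)) % 4
    ref = _BASES[ref_i].astype(object)
    alt = _BASES[alt_i].astype(object)
    indel_del = rng.random(n) < 0.55
    ref = np.where(is_indel & indel_del, ref + alt, ref)
    alt = np.where(is_indel & ~indel_del, alt + ref, alt)
    alt = np.where(is_indel & indel_del, [r[0] for r in ref], alt)
    ref = np.where(is_indel & ~indel_del, [a[0] for a in alt], ref)

    snv_csq = rng.choice(
        ["other", "missense", "splice_site", "nonsense"],
        size=n, p=[0.60, 0.36, 0.03, 0.01],
    )
    consequence = np.where(
        is_indel, np.where(indel_del, "small_deletion", "small_insertion"), snv_csq
    ).astype(object)

    gene = np.array(
        [f"G{c}M{p // 1_000_000}" for c, p in zip(chroms, pos)], dtype=object
    )

    af_exac = freq.copy()
    af_evs = np.where(freq >= 0.01, freq, np.nan)
    af_1kg = np.where(freq >= 0.005, freq, np.nan)

    sites = pd.DataFrame(
        {
            "chrom": chroms, "pos": pos, "ref": ref, "alt": alt, "gene": gene,
            "consequence": consequence, "freq": freq,
            "af_exac": af_exac, "af_evs": af_evs, "af_1kg": af_1kg,
            "true_proband": child, "true_mother": mother, "true_father": father,
            "in_roh": in_roh, "planted": np.zeros(n, dtype=bool),
        }
    )

    if spec.planted_variant is not None:
        sites = pd.concat(
            [sites, _planted_row(spec)], ignore_index=True
        )

    # Observed states = true states + symmetric genotype error; the planted
    # site is exempt so planted truth is exact.
    obs = {}
    n_all = len(sites)
    protect = sites["planted"].to_numpy()
    for col in ("proband", "mother", "father"):
        true = sites[f"true_{col}"].to_numpy(np.int8)
        err = (rng.random(n_all) < spec.genotype_error_rate) & ~protect
        shift = 1 + (rng.random(n_all) < 0.5).astype(np.int8)
        obs[col] = np.where(err, (true + shift) % 3, true).astype(np.int8)
    for col in ("proband", "mother", "father"):
        sites[col] = obs[col]

    sites = sites.sort_values(
        ["chrom", "pos"],
        key=lambda s: s.map(tio.chrom_sort_key) if s.name == "chrom" else s,
    ).reset_index(drop=True)

    y_sites = _simulate_y(spec, rng)
    return TrioSimulation(spec=spec, sites=sites, y_sites=y_sites)


def _planted_row(spec: SimulationSpec) -> pd.DataFrame:
    v = spec.planted_variant
    father_true = 1 if spec.father_mode == "true_father" else 0
    return pd.DataFrame(
        {
            "chrom": [v.chrom], "pos": [v.pos], "ref": [v.ref], "alt": [v.alt],
            "gene": [v.gene], "consequence": [v.consequence],
            "freq": [v.pop_freqs.get("AF_EXAC", 1e-5)],
            "af_exac": [v.pop_freqs.get("AF_EXAC", np.nan)],
            "af_evs": [v.pop_freqs.get("AF_EVS", np.nan)],
            "af_1kg": [v.pop_freqs.get("AF_1KG", np.nan)],
            "true_proband": [2], "true_mother": [1], "true_father": [father_true],
            "in_roh": [True], "planted": [True],
        }
    )


def _dedupe_positions(rng, chroms, pos, chrom_len_bp, spec) -> np.ndarray:
    """Redraw colliding (chrom, pos) pairs; ROH detection needs strictly
    increasing positions per chromosome."""
    forbidden = set()
    if spec.planted_variant is not None:
        forbidden.add((spec.planted_variant.chrom, spec.planted_variant.pos))
    for _ in range(20):
        df = pd.DataFrame({"c": chroms, "p": pos})
        dup = df.duplicated(keep="first").to_numpy()
        dup |= np.array([(c, int(p)) in forbidden for c, p in zip(chroms, pos)])
        if not dup.any():
            return pos
        pos = pos.copy()
        pos[dup] = rng.integers(1, chrom_len_bp[dup], dtype=np.int64)
    raise RuntimeError("could not place unique marker positions")


def _simulate_y(spec: SimulationSpec, rng: np.random.Generator) -> pd.DataFrame:
    m = spec.n_y_markers
    if m == 0:
        return pd.DataFrame(
            columns=["pos", "ref", "alt", "freq", "father_allele", "son_allele"]
        )
    pos = np.sort(
        rng.choice(int(Y_LENGTH_MB * 1e6) - 1, size=m, replace=False) + 1
    )
    # Y markers are chosen for informativeness, so frequencies are
    # moderate rather than SFS-shaped.
    q = rng.uniform(0.2, 0.8, size=m)
    father = (rng.random(m) < q).astype(int)
    if spec.father_mode == "true_father":
        err = rng.random(m) < spec.genotype_error_rate
        son = np.where(err, 1 - father, father)
    else:
        son = (rng.random(m) < q).astype(int)
    ref_i = rng.integers(0, 4, size=m)
    alt_i = (ref_i + 1 + rng.integers(0, 3, size=m)) % 4
    return pd.DataFrame(
        {
            "pos": pos, "ref": _BASES[ref_i], "alt": _BASES[alt_i], "freq": q,
            "father_allele": father, "son_allele": son,
        }
    )


# ---------------------------------------------------------------------------
# Depth simulation


@dataclass
class DepthSimulation:
    spec: SimulationSpec
    profiles: dict[str, DepthProfile]
    truth: pd.DataFrame  # target, sample, true copy ratio for planted CNVs
    intensity: np.ndarray

    @property
    def trio_samples(self) -> list[str]:
        return ["proband", "mother", "father"]

    @property
    def pool_samples(self) -> list[str]:
        return [s for s in self.profiles if s.startswith("ref")]

    def write_depth(self, path: str | Path) -> None:
        tio.write_depth_table(list(self.profiles.values()), path)


def _make_targets(spec: SimulationSpec, rng: np.random.Generator) -> list:
    d = spec.depth
    chrom_names = list(spec.chrom_lengths_mb)
    lengths = np.array([spec.chrom_lengths_mb[c] for c in chrom_names], float)
    n = d.n_targets - (1 if d.include_exon_target else 0)
    chrom_idx = rng.choice(len(chrom_names), size=n, p=lengths / lengths.sum())
    starts = rng.integers(0, (lengths[chrom_idx] * 1e6 - 500).astype(np.int64))
    tlen = rng.integers(150, 351, size=n)
    targets = [
        (chrom_names[c], int(s), int(s + L))
        for c, s, L in zip(chrom_idx, starts, tlen)
    ]
    if d.include_exon_target:
        # A target over the planted variant's exon (coverage check analog).
        targets.append(("3", 50_220_850, 50_221_053))
    targets.sort(key=lambda t: (tio.chrom_sort_key(t[0]), t[1]))
    return targets


def simulate_depth(spec: SimulationSpec) -> DepthSimulation:
    """Generate per-target depths for the trio plus a reference pool."""
    spec.validate()
    d = spec.depth
    # Independent stream so trio and depth simulations can be used alone.
    rng = np.random.default_rng((spec.seed, 7))
    targets = _make_targets(spec, rng)
    intensity = rng.permutation(_capture_profile(d))

    ratios = np.ones(d.n_targets)
    for idx, ratio in d.planted_cnvs:
        ratios[idx] = ratio

    profiles: dict[str, DepthProfile] = {}
    samples = ["proband", "mother", "father"] + [
        f"ref{i + 1:02d}" for i in range(d.n_pool)
    ]
    for s in samples:
        scale = rng.uniform(0.9, 1.1)
        mean = d.mean_depth * intensity * scale
        if s == "proband":
            mean = mean * ratios
        profiles[s] = DepthProfile(
            sample_id=s, targets=targets, depths=_draw_counts(rng, mean, d)
        )
    truth = pd.DataFrame(
        [
            {
                "target_index": idx,
                "chrom": targets[idx][0],
                "start": targets[idx][1],
                "end": targets[idx][2],
                "sample": "proband",
                "copy_ratio": ratio,
            }
            for idx, ratio in d.planted_cnvs
        ],
        columns=["target_index", "chrom", "start", "end", "sample", "copy_ratio"],
    )
    return DepthSimulation(
        spec=spec, profiles=profiles, truth=truth, intensity=intensity
    )


def _capture_profile(d: DepthSpec) -> np.ndarray:
    """Per-target capture efficiency: a fixed lognormal quantile grid.

    Capture efficiency is a property of the target set / capture kit, so it
    is deterministic (the same spread every run; only its assignment to
    targets is shuffled): lognormal quantiles with the given sigma, floored
    at ``intensity_floor`` (a panel retains no hopeless targets), and
    normalized to mean 1.
    """
    from statistics import NormalDist

    nd = NormalDist()
    q = (np.arange(d.n_targets) + 0.5) / d.n_targets
    profile = np.exp(d.intensity_sigma * np.array([nd.inv_cdf(p) for p in q]))
    profile = np.clip(profile, d.intensity_floor, None)
    return profile / profile.mean()


def _draw_counts(
    rng: np.random.Generator, mean: np.ndarray, d: DepthSpec
) -> np.ndarray:
    if d.noise == "poisson" or d.dispersion == 0:
        return rng.poisson(mean).astype(float)
    lam = rng.gamma(shape=1.0 / d.dispersion, scale=mean * d.dispersion)
    return rng.poisson(lam).astype(float)


# ---------------------------------------------------------------------------
# Bundle writer (used by the CLI `simulate` subcommand)


def write_bundle(spec: SimulationSpec, outdir: str | Path) -> dict[str, Path]:
    """Write every pipeline input plus truth tables into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trio = simulate_trio(spec)
    depth = simulate_depth(spec)
    paths = {
        "vcf": outdir / "trio.vcf",
        "depth": outdir / "depth.tsv",
        "transcript": outdir / "transcript.gff3",
        "domains": outdir / "domains.json",
        "population_cnv": outdir / "population_cnv.tsv",
        "sites_truth": outdir / "sites_truth.tsv",
        "y_truth": outdir / "y_truth.tsv",
        "depth_truth": outdir / "depth_truth.tsv",
    }
    trio.write_vcf(paths["vcf"])
    depth.write_depth(paths["depth"])
    import shutil

    shutil.copy(tio._data_path("gnat1_transcript_synthetic.gff3"), paths["transcript"])
    shutil.copy(tio._data_path("gnat1_domains.json"), paths["domains"])
    pd.DataFrame(columns=["chrom", "start", "end", "freq"]).to_csv(
        paths["population_cnv"], sep="\t", index=False
    )
    trio.sites.to_csv(paths["sites_truth"], sep="\t", index=False)
    trio.y_sites.to_csv(paths["y_truth"], sep="\t", index=False)
    depth.truth.to_csv(paths["depth_truth"], sep="\t", index=False)
    return paths
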