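# Methods

This note documents the models implemented in `triorecess`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical/design decisions made where the procedure
was genuinely open.

## Filter cascade

Variants are gated on consequence class (nonsense, missense, splice site,
small insertion/deletion; classes are consumed as input annotations, never
predicted) and on population allele frequency: every *known* database
frequency must be ≤ `maf_threshold` (default 0.005, inclusive — the
boundary value passes). A variant absent from a database is treated as
passing that database: recessive disease alleles are expected to be absent
from population panels, and absence of evidence must not discard them.

Two inheritance model families are tagged on the surviving set:

* **Strict trio.** Homozygous model: proband hom-alt, both parents het. A
  missing parent call is non-disqualifying by default
  (`missing_parent_disqualifies=False`); the strict reading is available
  as a flag. Compound-het model: proband het for two or more variants in
  one gene with opposite, *determinate* parental origin — a variant's
  origin is maternal (paternal) iff exactly the mother (father) carries
  the alternate allele. Variants both parents carry are unphaseable and do
  not form pairs; this is deliberately conservative.
* **Proband-only fallback.** Parental genotypes ignored: hom-alt, or ≥ 2
  proband-het variants in a gene (phase unknowable without parents). Used
  when the strict model fails — de novo hypotheses, sample mix-ups,
  non-paternity.

Multi-allelic sites must be decomposed to bi-allelic records upstream; the
VCF reader rejects undecomposed records rather than guessing.

## Depth-of-coverage CNV screen

Copy number is estimated per capture target from the double-normalized
depth ratio against the per-target **median** of a reference pool (median,
not mean, so CNVs carried by individual pool members do not contaminate
the reference). Library size cancels by construction (scale invariance is
property-tested). The diploid expectation is 1.0; thresholds are the
published working points, inclusive: score ≤ 0.5 suspected deletion,
≥ 1.5 suspected duplication. Scoring is gated on Pearson correlation
> 0.97 between the sample vector and the pool median — Pearson on raw
depths, the conventional choice for depth vectors. Targets whose pool
median is zero are undefined (NaN) and excluded with a warning. Calls
overlapping a population CNV with frequency > 0.005 are removed; calls
with no population annotation are kept.

An important operating characteristic, measured by the acceptance suite
and worth stating plainly: for a *heterozygous* event the true copy ratio
(0.5 or 1.5) sits exactly on the inclusive threshold, so an unbiased score
crosses it with probability ≈ ½ regardless of depth or noise level —
single-target sensitivity for heterozygous events is ~50% at these
thresholds (measured 0.54 over 100 replicates at 80×), while homozygous
deletions (ratio ≈ 0) are called essentially always and the false-call
rate on diploid targets stays below 2% on average. The thresholds are kept
as published rather than re-tuned; the screen is a *suspicion* filter, not
a calibrated caller.

Per-target segmentation into multi-exon events and B-allele-frequency
integration are out of scope.

## Homozygosity mapping

Runs of homozygosity are maximal stretches of non-missing markers with at
most `het_tolerance` embedded heterozygous calls, starting and ending on a
homozygous marker, with ≥ 2 markers; missing calls neither break runs nor
count. Span is measured marker-to-marker (first to last marker), not
padded to flanking-het midpoints: conservative, and reproducible from the
marker table alone. Regions **strictly** longer than `roh_min_length_mb`
(default 30 Mb) are retained.

The `detect_runs` operation defaults to strict tolerance 0. The
orchestrated pipeline defaults to `het_tolerance=1`: with a genotype-error
rate of order 10⁻⁴, a ~700-marker autozygous segment is split by a single
erroneous het with probability of a few percent, while at background
heterozygosity (~0.25 per informative marker) one tolerated het cannot
assemble a spurious > 30 Mb region. This mirrors standard WES/array ROH
practice. With tolerance > 0 two maximal runs can overlap (each absorbing
a different flank het); the pipeline merges overlapping runs into their
union span before filtering, so containment queries see disjoint regions.

The carrier mother's genotypes are summarized *descriptively* inside each
proband region (fraction of her non-missing markers that are het); they
are never used as a hard filter, since a carrier parent is expected to be
heterozygous at the ordinary population rate inside the child's autozygous
segment.

## Mendelian consistency and the paternity flag

Opposite homozygotes are counted over autosomes only (X/Y/MT excluded by
chromosome name), in both directions separately, skipping missing calls.
Y-marker divergence compares haploid father/son alleles at sites
non-missing in both. The advisory flag uses an add-one-smoothed ratio,
(father_total + 1)/(mother_total + 1) ≥ 20, or ≥ 3 divergent Y markers.
The ratio rule and its default are this package's formalization of an
informal judgement (a true parent shows a handful of error sites; an
unrelated adult shows thousands — the observed contrast is ~3 orders of
magnitude); the flag is advisory metadata and never alters filtering.

## Truncation consequences

* **Shortening.** Default convention `reported`: protein_length −
  stop_codon_position (stops at 321 and 302 of 350 → 29 and 48 aa). The
  mutant peptide actually has stop_codon_position − 1 residues, so the
  peptide-length difference is one more (30/49); that alternative is the
  `peptide` convention flag. Neither is asserted as biologically "correct";
  the default matches the reporting convention in the clinical literature
  for these variants.
* **NMD escape.** True iff the stop lies in the last coding exon or within
  `nmd_window_nt` coding nucleotides (inclusive) of the last exon–exon
  junction. Default 50 nt — the conservative end of the 50–55 nt range the
  NMD literature quotes; configurable to 55. Single-exon transcripts
  always escape.
* **Domain retention.** Residues 1..stop−1 are retained; a site interval
  (1-based closed; point sites are length-1) is `retained` iff it ends
  before the stop, `lost` iff it starts at or after the stop (a site whose
  first residue coincides with the stop is lost — the stop replaces it),
  else `partial`.

The packaged GNAT1 domain map (350 aa; Gtβγ 1–23, NLS 21–52, Mg 43 and
177, GTP/GDP 36–43, 171–177, 196–200, 265–268, 321–323, PDE6γ 306–310,
RHO 311–328 and 340–350) is real annotation. The packaged transcript model
is **synthetic**: the true exon boundaries of NM_144499.2 are not bundled,
so an 8-coding-exon model was constructed with CDS 1053 nt (350 residues +
stop) and the last coding exon spanning c.851–c.1053, preserving the one
property the NMD analysis relies on — the documented stops at c.904 and
c.963 fall in the last coding exon.

## Synthetic-data generator

The generator emulates a *called* trio exome at realistic scale (defaults:
50,000 SNV + 4,000 indel sites; mean depth 80×; 200 depth targets; 12 Y
markers), with complete truth tables. Key modelling choices:

* **Site frequencies** are a mixture: 8% "rare" sites log-uniform in
  1e-5..5e-3 (the regime the MAF gate keeps; only these carry sparse
  database annotations) and 92% common Beta(0.5, 0.5) clipped to
  [0.01, 0.99]. Y-marker frequencies are uniform in [0.2, 0.8] — markers
  chosen for informativeness.
* **Transmission.** Parents are Hardy–Weinberg draws; the child receives
  one allele from each parent. Inside the planted autozygous segment the
  child is homozygous for a single lineage allele; in `true_father` mode
  both parents carry that founder allele (Mendelian-consistent
  consanguinity), in `unrelated` mode (the default, the study condition)
  the sequenced father column is drawn independently of the transmitting
  haplotypes and the child's paternal allele comes from the population.
* **Planted variant.** A homozygous stop-gain at chr3:50,220,963 (c.963 of
  the packaged transcript) inside the default 40 Mb segment, mother het,
  ultra-rare in the annotations. The planted site is exempt from the
  genotype-error channel so planted truth is exact.
* **Genotype error** is symmetric at rate 1e-4 per call (an erroneous call
  moves to either other state with equal probability).
* **Depth.** Per-target capture efficiency is a deterministic clipped
  lognormal quantile grid (σ = 0.8, floor 0.3, mean 1), shuffled across
  targets per run — capture efficiency is a property of the kit, so its
  spread should not fluctuate between runs. Counts are negative binomial
  via Gamma–Poisson with dispersion 0.005 (variance m + 0.005 m²; Poisson
  available). The dispersion default is set so the generator honours its
  own contract that pool members pass the > 0.97 correlation gate at
  default noise (min r = 0.976 over 100 seeds); per-target dispersion of
  exome depth after pool normalization is indeed small compared to raw
  library variation, which the per-sample scale factor (uniform 0.9–1.1)
  models separately.

What it does **not** emulate: linkage disequilibrium, recombination maps,
variant-calling artefacts correlated along the genome, batch effects in
capture, allele-specific depth, or population structure. Passing tests
therefore demonstrate correctness of the *inference chain* under its
stated assumptions, not robustness to every failure mode of real exomes.

## Numerical and degenerate-input choices

* Unknown frequencies pass the MAF gate; NaN copy scores are excluded from
  calling; zero-variance depth vectors make the correlation gate invalid
  rather than raising.
* All thresholds are inclusive/exclusive exactly as written above (MAF ≤,
  CNV ≤ / ≥, ROH strictly >, NMD window inclusive).
* QC fractions and mean depth are target-length-weighted, treating a
  target's mean depth as applying to each of its bases.
* Determinism: one integer seed drives all randomness; a fixed seed gives
  byte-identical output files and reports.
* Problem sizes in the test suite are chosen for desk-scale runs: the
  end-to-end check uses the full default 54k-site simulation; replicated
  checks (CNV operating characteristics, Mendelian closure) use 100 and 50
  seeded replicates at 200 targets and ~1.6k sites respectively; oracle
  equivalences run on instances of ≤ 200 elements over 100 seeds.

## Known limitations

* Compound-het detection requires determinate trans phase in trio mode; a
  true compound het whose alleles both parents happen to carry is missed.
* The CNV screen is per-target with published fixed thresholds; see the
  operating-characteristics note above.
* ROH spans are marker-delimited and hence underestimate segment length by
  up to one marker spacing per side (and with tolerance > 0 may overshoot
  to the next het).
* The paternity flag is a heuristic summary, not a likelihood-based
  kinship test (no IBD coefficients).
* The packaged transcript is a synthetic stand-in (see above); analyses of
  real data should supply the real exon model via `--transcript`.
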