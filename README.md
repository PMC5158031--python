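# triorecess

Trio whole-exome variant prioritization for recessive disease, built around
the inference chain that identifies a homozygous truncating variant in a
consanguinity-like setting: consequence and allele-frequency filtering under
two recessive inheritance models, depth-of-coverage CNV screening against a
reference pool, homozygosity mapping, Mendelian-consistency / non-paternity
statistics, and protein-truncation annotation for stop-gain variants. A
synthetic-data generator with planted ground truth makes every stage — and
the end-to-end pipeline — testable without any sequence data.

The motivating use case is a sporadic rod-cone dystrophy (retinitis
pigmentosa) diagnosis: a proband homozygous for a nonsense variant in
*GNAT1* (rod transducin α, 350 aa) that the strict trio model rejects
because the sequenced father does not carry it, resolved by a proband-only
fallback model plus genome-wide non-paternity statistics and localization
of the variant inside a >30 Mb run of homozygosity.

## The models

**Filter cascade.** A variant survives iff its consequence class is
damaging (nonsense, missense, splice site, small indel) and every *known*
population frequency satisfies MAF ≤ 0.005 (absence from a database never
disqualifies). Inheritance models:

* strict trio: proband hom-alt with both parents het, or gene-level
  compound het with one allele of demonstrably maternal and one of paternal
  origin (trans);
* proband-only fallback: hom-alt, or ≥ 2 hets per gene, ignoring parents.

**CNV screen.** With per-target depths d and a reference pool median m,
the copy score at target t is

    score_t = (d_t / Σd) / (m_t / Σm)

(≈1 for two copies). Scoring requires Pearson r(d, m) > 0.97; targets with
score ≤ 0.5 are suspected deletions, ≥ 1.5 suspected duplications, and
calls overlapping population CNVs with frequency > 0.005 are excluded.

**Homozygosity mapping.** Maximal runs of homozygous calls (missing calls
neither break nor count; a configurable number of embedded hets is
tolerated); regions strictly longer than 30 Mb are retained and candidate
variants are annotated with their containing region.

**Consistency statistics.** Opposite homozygotes (child hom-alt & parent
hom-ref, and the reverse, tallied separately per parent) and father–son
Y-marker divergence feed an advisory non-paternity flag:
(father+1)/(mother+1) ≥ 20 or ≥ 3 divergent Y markers.

**Truncation report.** For a stop at codon p of an L-residue protein the
shortening is L − p amino acids (the reporting convention used for the
*GNAT1* mutants: stops at 321 and 302 of 350 → 29 and 48 aa). A stop
escapes nonsense-mediated decay iff it lies in the last coding exon or
within 50 nt (configurable to 55) upstream of the last exon–exon junction.
Functional sites (1-based closed residue intervals) are classified
retained / partial / lost against the stop.

## Worked example

Generate a synthetic trio (50k SNVs + 4k indels, a planted 40 Mb
homozygous-by-descent segment on chromosome 3 carrying a homozygous
nonsense variant, an unrelated sequenced father, 80× depth) and run the
full pipeline:

```
triorecess simulate --seed 7 --out demo/
triorecess run --vcf demo/trio.vcf --depth demo/depth.tsv \
    --transcript demo/transcript.gff3 --domains demo/domains.json \
    --out demo/candidates.tsv
```

which prints:

```
candidates: 2 (strict: 0, proband-only: 2)
ROH regions > threshold: 1
CNV calls: 3 (correlation 0.9889284536425379, valid True)
opposite homozygotes vs father: 2328, vs mother: 7; Y divergent 5/12; paternity questioned: True
report written to demo/candidates.tsv
```

The strict trio model returns nothing (the sequenced father lacks the
causal allele), while the proband-only model ranks the planted stop-gain
first — homozygous, inside a 42.7 Mb detected region, 29 aa shortening,
NMD escape:

```
chrom  pos       ref alt gene  consequence  ... proband_model     in_roh  roh_length_mb  shortening_aa  nmd_escape
3      50220963  C   A   GNAT1 nonsense     ... hom_proband_only  True    42.682236      29             True
```

The consistency summary (`triorecess consistency --vcf demo/trio.vcf`)
shows the asymmetry that suggests non-paternity: 2,328 opposite-homozygote
sites against the father versus 7 against the mother, with 5 of 12 Y
markers divergent. `triorecess protein --pos 50220963` prints the
per-domain report for the truncated protein (PDE6γ site 306–310 retained,
RHO site 311–328 partial, GTP site 321–323 lost).

## Layout

- `triorecess.model` — domain types, configuration, small statistics
- `triorecess.io` — VCF (pysam), depth tables, GFF3 transcripts, domain maps
- `triorecess.filters` — consequence/MAF gates and inheritance tagging
- `triorecess.cnv` — correlation gate, copy scores, CNV calls, depth QC
- `triorecess.roh` — run detection, region filtering, containment
- `triorecess.consistency` — opposite homozygotes, Y divergence, paternity flag
- `triorecess.protein` — shortening, NMD escape, domain retention
- `triorecess.simulate` — synthetic trio/depth generator with truth tables
- `triorecess.pipeline` / `triorecess.cli` — orchestration and CLI

See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
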