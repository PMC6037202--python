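# cpgpipe

Germline cancer-predisposition variant prioritization and cohort
analysis for multiple-primary-tumor (MPT) series.

People who develop two primary tumors by age 60 (or three by 70) are
strongly enriched for inherited cancer predisposition, yet routine
genetic testing targets a handful of genes chosen from the tumor
phenotype. `cpgpipe` implements the analysis layer of a comprehensive,
phenotype-agnostic approach: given annotated small-variant and
structural-variant calls over a panel of cancer-predisposition genes
(CPGs), it prioritizes candidate pathogenic variants through an
auditable multi-rule cascade, combines ACMG evidence codes into the
five-tier classification, annotates genotype–phenotype concordance, and
computes the cohort statistics used to compare an MPT series against
registry and reference-population data. A seeded synthetic-data module
generates complete inputs with planted truth, so the entire pipeline is
testable without access to raw sequencing data.

It is aimed at bioinformaticians building or evaluating germline
prioritization workflows, and at methodologists who need a transparent,
deterministic re-implementation of the filtering rules.

## The core rules

**SNV/indel cascade** — a variant survives iff it passes

1. call quality: GQ ≥ 30, DP ≥ 10, VAF = alt/dp ≥ 33% (compared as
   exact rationals), caller PASS;
2. rarity: max allele frequency ≤ 0.01 in ExAC and 1000 Genomes
   (absent ⇒ 0);
3. retention: truncating SO consequence ∨ ClinVar P/LP (≥ 2★) ∨ HGMD DM
   ∨ CADD ≥ 34 (threshold = median CADD of a known-pathogenic set), or
   an exact positional match to a curated non-coding pathogenic list;
4. none of five exclusions: truncating-with-benign/uncertain-ClinVar
   (≥ 2★), truncating in a proto-oncogene, truncation of < 5% of the
   canonical transcript, a lone variant in a recessive-only gene, or an
   HGMD/CADD-only retention refuted by ClinVar.

**SV prioritization** — merged Canvas/Manta-style calls with quality
≥ 30 and cohort frequency < 1% that affect a panel gene are assigned
`tsg_copy_loss`, `oncogene_copy_gain`, or `breakpoint_disruption`, then
screened for containment in a common-CNV map.

**Cohort statistics** — discordant tumor-combination enumeration
(C(k,2) over distinct categories), uncorrected Pearson χ² on 2×2 burden
tables, sex-composition adjustment of reference carrier frequencies
(female count fixed, males shrunk to `n_f(1−p)/p`), and diagnostic-yield
projection `q + (1−q)r`.

See `docs/methods.md` for the full model description and design choices.

## Worked example

```bash
cpgpipe simulate --seed 5 --n-probands 25 --out-dir sim/
cpgpipe filter-snv --panel sim/panel.tsv --panel-bed sim/panel_exons.bed \
    $(for f in sim/vcf/*.vcf; do echo --vcf $f; done) --out-dir out/
# -> "9 variants retained"
cpgpipe filter-sv --sv-calls sim/sv_calls.tsv --panel sim/panel.tsv \
    --panel-bed sim/panel_exons.bed --cnv-map sim/cnv_map.bed --out-dir out/
# -> "6 SV calls assessed"
```

`out/snv_audit.json` shows the conserved per-stage counts for the
simulated cohort (input = fails + retained):

```json
{
  "input": 139,
  "quality_fail": 65,
  "frequency_fail": 42,
  "not_retained": 18,
  "excluded": 5,
  "retained_for_assessment": 9
}
```

The nine retained variants are exactly the generator's planted
qualifying set (`sim/snv_truth.tsv`: three Bernoulli-planted qualifying
variants plus six variant alleles from three recessive biallelic
cases); the five excluded ones are the decoys built to trip each
exclusion criterion. The six assessed SVs
are the planted archetypes (single-exon deletion, exonic and
intronic-breakpoint inversions, exon duplication, first-exon
translocation, full-gene deletion).

From Python, the statistics are one call each:

```python
>>> from cpgpipe import pearson_chi2, yield_projection
>>> pearson_chi2([[52, 388], [298, 8694]]).statistic   # carrier burden, MPT vs reference
84.90289183576824
>>> yield_projection(0.207, 0.152)                      # stacking 15.2% on a 20.7% prior
0.327536
```

i.e. a χ² of 84.903 for the truncating-variant burden comparison and a
projected first-line diagnostic yield of 32.8%.

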