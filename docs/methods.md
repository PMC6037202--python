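# Methods

`cpgpipe` re-implements, as a reusable and fully tested pipeline, a
germline variant-prioritization and cohort-analysis workflow for adults
with multiple primary tumors (MPT) sequenced against a panel of
cancer-predisposition genes (CPGs). This note documents the models and
procedures, the tunable parameters, the synthetic-data design, numerical
choices, and known limitations.

## Cohort model

An individual is MPT-eligible when they have at least two primary tumors
diagnosed by age 60 or at least three by age 70. "By" is read inclusively
(age ≤ 60 / ≤ 70): the boundary year belongs to the window, and no
downstream quantity is sensitive to this choice. Tumor diagnoses are
pre-adjudicated (deciding whether two lesions are separate primaries is
upstream clinical work) and labeled by site and cell of origin against a
controlled vocabulary shipped as an editable TSV
(`data/tumor_categories.tsv`, with malignancy and CNS flags used by the
registry comparison).

Genotype-phenotype concordance asks whether a carrier of a variant in
gene *g* has any tumor category classically associated with *g*. The
gene→characteristic-tumor map (`data/characteristic_tumors.tsv`) is
configuration, not code: the associations are a best-effort
reconstruction from well-established pairs (BRCA1/2–breast/ovary,
FH–cutaneous leiomyoma/RCC, MAX/SDHB–pheochromocytoma/paraganglioma,
mismatch-repair genes–colorectal/endometrial, FLCN–RCC, ...) and should
be reviewed per deployment.

## SNV/indel prioritization cascade

Every variant receives exactly one terminal disposition with explicit
reason codes; stage counts always sum to the (deduplicated) input count.

1. **Call quality.** GQ ≥ 30, DP ≥ 10, variant allele fraction ≥ 33%,
   caller filter PASS. All boundaries inclusive. The VAF comparison is
   done in integers (`alt_depth · 100 ≥ 33 · dp`), so a 7/22 read call
   (31.8%, printed as 32%) fails and a 33/100 call passes without any
   float-rounding ambiguity at the threshold. A site with zero usable
   depth is routed to quality-fail rather than raising mid-pipeline.
2. **Population frequency.** Fail when the maximum ExAC or 1000 Genomes
   allele frequency is strictly above 0.01. An absent frequency is
   treated as 0 (unobserved): rare pathogenic variants are frequently
   absent from reference panels, and failing on missingness would gut
   sensitivity.
3. **Retention.** Keep for assessment when any route fires: (a) a
   protein-truncating Sequence Ontology consequence (configurable set;
   default: stop_gained, frameshift_variant, splice acceptor/donor,
   start_lost, transcript_ablation); (b) ClinVar pathogenic/likely
   pathogenic with ≥ 2-star review; (c) HGMD disease-mutation status;
   (d) Phred-scaled CADD ≥ 34. The CADD threshold is the median CADD of
   an independently assessed pathogenic set (`derive_cadd_threshold`);
   "exceeding 34" is implemented as ≥ 34 so the defining median itself
   qualifies (configurable). CADD-only retention runs as a second pass
   after routes (a)–(c); an assertion verifies the staged schedule always
   equals single-pass evaluation (it provably does, since routes are
   disjunctive).
4. **Non-coding positional lookup.** Exact (contig, position, ref, alt)
   match against a short curated list of known pathogenic non-coding
   variants carried on the panel. The original workflow's list is not
   public, so it is user-supplied configuration (empty by default).
5. **Exclusion.** A retained variant is excluded when: (1) it is
   truncating and ClinVar holds ≥ 2-star benign/uncertain evidence;
   (2) it is truncating in a proto-oncogene (gain-of-function mechanism —
   truncation is unlikely to raise risk); (3) the truncation removes
   < 5% of the canonical transcript; (4) the gene confers only recessive
   predisposition and the individual does not carry two filtered variant
   alleles in it (homozygous counts as two; two distinct heterozygous
   filtered variants are presumed compound-heterozygous since phase is
   unknown — logged as presumptive); (5) it was retained solely by
   HGMD/CADD and ClinVar refutes it (≥ 2-star benign/uncertain, or
   1-star with ≥ 2 submissions and no P/LP assertion). ClinVar
   "conflicting" maps to uncertain for criteria 1 and 5: a conflicted
   record cannot support a pathogenic claim. A truncating variant
   lacking a truncation fraction skips criterion 3 with a log message
   rather than being silently excluded.

Duplicate records for the same (individual, contig, pos, ref, alt) are
dropped with a warning; records naming genes outside the panel are
quarantined, never silently discarded. Output ordering is deterministic
(contig, position, alt, individual).

## SV prioritization

Calls from a copy-number caller ("canvas", QUAL-scored) and a breakend
caller ("manta", GQ-scored) are first merged per individual: same-type
calls with ≥ 50% reciprocal overlap (breakends within 1 kb for
translocations) are one event, keeping the higher-quality record. The
prefilter requires quality ≥ 30, cohort frequency strictly < 1%, and
gene impact. "Affects at least one exon" is type-dependent: span-type
calls (deletion/duplication/copy-number) must intersect a coding exon;
breakend-type calls (inversion/translocation) qualify when a breakend
falls anywhere inside a gene's transcribed span, because inversions with
purely intronic breakpoints still disrupt the gene and belong in the
output.

Surviving calls are categorized per intersected gene: copy-number loss
covering coding exons of a tumor-suppressor gene (`tsg_copy_loss`);
copy-number gain covering coding exons of a proto-oncogene
(`oncogene_copy_gain`); otherwise any type with a breakend strictly
inside the gene span (`breakpoint_disruption`). Recessive-only genes
yield no category unless the call is homozygous or a second qualifying
SV/SNV hits the same gene in the same individual.

Finally, calls contained within a region of a common copy-number
variation map are excluded. Containment — not mere overlap — is required
(configurable): overlap-based exclusion would discard every whole-gene
deletion whenever any small common CNV lies inside the gene.

## ACMG evidence combination

Evidence codes (PVS1, PS1–4, PM1–6, PP1–5; BA1, BS1–4, BP1–7) are
combined by the published rule table into pathogenic / likely pathogenic
/ uncertain / likely benign / benign. When a pathogenic-side rule and a
benign-side rule fire simultaneously the evidence is contradictory and
the tier is uncertain. Code *assignment* is curator work and arrives as
input; an optional pre-populator (clearly heuristic, off unless called)
derives PVS1 from a truncating consequence in a loss-of-function gene,
PM2 from absence in reference populations, and PP3 from a
threshold-exceeding CADD score. Cohort tallies count unique variants and
variant-individual occurrences per tier; P/LP carriers are
family-deduplicated (one representative per family per variant, probands
preferred) before detection rates are computed.

The published cohort's tier split (22 pathogenic / 23 likely pathogenic /
24 uncertain / 20 likely benign unique variants; 42/24/27/26
occurrences) is not recomputable without the per-variant curation data,
which are not public; it is used as a fixture whose internal consistency
(sums of 89 unique variants and 119 occurrences) the tests verify.

## Cohort statistics

* **Combinations.** Any two discordant primary tumor categories in one
  individual form a combination; an individual with *k* distinct
  categories contributes C(*k*, 2) combinations, and same-category
  repeats (bilateral breast) contribute none. The distribution reports
  per-type counts, each type's share of combinations, and the
  once/twice/three-plus breakdown of types.
* **Registry comparison.** Both cohorts are restricted to malignant (or
  CNS) tumors diagnosed before age 60, then each combination type
  representing > 1% of MPT combinations is tested type-vs-rest on a 2×2
  table.
* **Pearson χ².** 2×2 statistic `N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)]`,
  df = 1, upper-tail p — deliberately *without* Yates continuity
  correction, which common 2×2 defaults apply: the uncorrected form is
  what reproduces the published statistics (84.903, 43.642, 3.2628)
  exactly. Tests cross-check it against the Σ(O−E)²/E formulation and
  against `scipy.stats.chi2_contingency(correction=False)`.
* **Sex adjustment.** To compare carrier frequencies against a reference
  population with a different sex composition, the female count is held
  fixed and the male count shrunk to `n_f(1−p)/p` for target female
  proportion *p*; per-sex carrier frequencies are then averaged with
  those weights. The adjusted male count is kept real-valued. Note: with
  6,929 females and p = 0.77 this gives ≈ 2,069.7 males, whereas the
  source workflow reported 2,064; this package computes from first
  principles and does not force the printed intermediate. Likewise a
  published "13.6%" MPT-side figure does not equal 52/440 (11.8%) and is
  not reproduced.
* **Yield projection.** Stacking comprehensive testing (incremental rate
  *r*) on routine targeted testing (prior rate *q*) projects a total
  yield of `q + (1−q)·r` — e.g. 20.7% + 79.3% × 15.2% = 32.8%.
* **Rates and rounding.** Detection rates keep exact fractions alongside
  half-up one-decimal percentages (67/440 → 15.2%). Coverage summaries
  report mean depth and the fraction of BED-defined bases at or above an
  inclusive threshold (default 10×).

## Synthetic data

Raw WGS data behind such cohorts are not publicly distributable, so the
generator emulates every input on a miniature genome: 24 panel genes
(including four proto-oncogenes and two recessive-only genes) on four
contigs, five 200-bp exons per gene. All sampling uses NumPy's seeded
PCG64 generator; identical seeds give byte-identical outputs.

Defaults are fixed to the published cohort's conditions: 440 probands,
77% female, category weights using the printed top-five tumor shares
(breast 24.6%, colorectal 9.9%, kidney 7.3%, NMSC 5.9%, ovary 5.1%) with
the remainder spread over the reduced vocabulary, 2–4 distinct tumor
categories per proband (ages drawn so every proband is MPT-eligible),
a 15.2% per-proband planted P/LP probability, five background variants
per proband, six planted SV archetypes plus 50 decoys, three recessive
biallelic cases, and a reference population of 8,992 genomes split
55.3%/44.7% male/female carrying qualifying variants at 3.3% per sex.

Planted qualifying variants satisfy every gate (PASS, GQ ≥ 30, DP ≈ 35,
heterozygous VAF resampled from Binomial(dp, 0.5) until ≥ 33%,
homozygous VAF near 1 — the diploid expectations underlying the 33%
gate) and draw their retention route from a mixture (60% truncating, 15%
ClinVar, 15% HGMD, 10% CADD-only, reflecting the predominance of
truncating P/LP findings). Background variants each fail exactly one
named gate; additional decoys trip each exclusion criterion 1–5. SV
decoys rotate over low quality, common cohort frequency, non-exonic
placement, and CNV-map containment (the map region fully contains one
reserved tumor-suppressor gene so map decoys genuinely reach the
exclusion step). Truth tables are first-class TSV outputs recording each
record's construction intent, so tests measure sensitivity/specificity
against intent rather than re-deriving it.

What the generator does **not** emulate: annotation errors (every record
carries consistent, correct annotations), caller false negatives (such
as a real multi-exon deletion a caller simply misses), multi-allelic
sites, phasing information, sequence context, and population structure.
Passing tests therefore demonstrate that the decision logic implements
its rules exactly — not that the rules would achieve this sensitivity on
real sequencing data, where the binding constraints are caller and
annotation quality.

## Problem sizes and numerical choices

Planted-truth recovery runs at 1,000 probands across five seeds
(~5,200 variants and 56 SV calls per seed), a size chosen to exercise
every decoy class many times while keeping the whole suite around five
seconds. The ACMG combiner is verified against an independent
transcription of the rule table over every evidence set of up to four
codes (24,158 sets). Percentage rounding is decimal half-up on the
repr of the fraction, avoiding binary-float round-to-even surprises at
printed precision. Coordinates are 1-based inclusive at VCF interfaces,
0-based half-open internally and in BED I/O.

## Limitations

* The characteristic-tumor map, truncating-term set, and non-coding
  variant list are reconstructions shipped as configuration; deployments
  should review them against current curation sources.
* ACMG evidence assignment is not automated beyond the labeled
  heuristic pre-populator.
* The cohort-frequency and caller-merge rules for SVs (≥ 50% reciprocal
  overlap) and the CNV-map containment semantics are reasonable defaults
  the source workflow did not specify; all are configurable.
* Strength-modified ACMG variants (PVS1 downgrades, Bayesian point
  systems) are out of scope.
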