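"""SNV/indel prioritization cascade.

Stages, in order, each producing an auditable :class:`~cpgpipe.variants.Disposition`:

1. call quality: GQ >= 30, DP >= 10, VAF >= 33%, caller filter PASS;
2. population frequency: drop if ExAC or 1000 Genomes max AF > 0.01
   (absent frequency treated as 0 — unobserved, not unknown);
3. retention: keep if protein-truncating consequence, ClinVar P/LP with
   >= 2-star review, HGMD DM status, or Phred-scaled CADD >= threshold
   (default 34, derivable as the median CADD of an independent pathogenic
   set); CADD-only retention runs as a second pass after the database/
   consequence routes, which provably cannot change the final set;
4. non-coding positional lookup: exact (contig, pos, ref, alt) match
   against a short curated list of known pathogenic non-coding variants;
5. exclusion: five refutation criteria (benign/uncertain ClinVar evidence
   on a truncating call, truncation in a proto-oncogene, truncation of
   < 5% of the canonical transcript, a single variant in a recessive-only
   gene, and database/CADD-retained calls contradicted by ClinVar).

Every input variant receives exactly one terminal disposition and counts
are conserved across stages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

from .panel import GeneRecord, Panel
from .variants import (
    BENIGN_OR_UNCERTAIN,
    PATHOGENIC_OR_LIKELY,
    AnnotatedVariant,
    ClinvarAssertion,
    Disposition,
    Outcome,
    Stage,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SnvFilterConfig",
    "variant_allele_fraction",
    "quality_filter",
    "frequency_filter",
    "retention_rules",
    "derive_cadd_threshold",
    "noncoding_lookup",
    "exclusion_rules",
    "run_snv_pipeline",
    "SnvPipelineResult",
]

#: Sequence Ontology terms treated as protein-truncating. Shipped as a
#: configurable default; deployments may extend it.
DEFAULT_TRUNCATING_TERMS = frozenset({
    "stop_gained",
    "frameshift_variant",
    "splice_acceptor_variant",
    "splice_donor_variant",
    "start_lost",
    "transcript_ablation",
})

#: SO terms the cascade knows about (used only to log unknowns).
_KNOWN_SO_TERMS = DEFAULT_TRUNCATING_TERMS | {
    "missense_variant",
    "inframe_insertion",
    "inframe_deletion",
    "synonymous_variant",
    "stop_lost",
    "splice_region_variant",
    "intron_variant",
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "upstream_gene_variant",
    "downstream_gene_variant",
    "non_coding_transcript_variant",
    "protein_altering_variant",
}


@dataclass(frozen=True)
class SnvFilterConfig:
    min_gq: float = 30.0
    min_dp: int = 10
    #: VAF threshold as an exact rational (numerator, denominator); the
    #: comparison alt_depth/dp >= num/den is done in integers so that a
    #: 7/22 (32%) call fails and a 33/100 call passes without float fuzz.
    vaf_threshold: tuple[int, int] = (33, 100)
    max_af: float = 0.01
    cadd_threshold: float = 34.0
    #: "exceeding a threshold of 34" read inclusively: a score equal to the
    #: defining median qualifies.
    truncating_terms: frozenset[str] = DEFAULT_TRUNCATING_TERMS
    min_truncation_fraction: float = 0.05


def variant_allele_fraction(alt_depth: int, dp: int) -> float:
    """alt-supporting reads / total depth, in [0, 1]. dp must be > 0."""
    if dp <= 0:
        raise ValueError("read depth must be positive to compute a VAF")
    if not 0 <= alt_depth <= dp:
        raise ValueError(f"alt_depth {alt_depth} outside [0, dp={dp}]")
    return alt_depth / dp


def _vaf_passes(alt_depth: int, dp: int, threshold: tuple[int, int]) -> bool:
    num, den = threshold
    return alt_depth * den >= num * dp


def quality_filter(v: AnnotatedVariant, config: SnvFilterConfig | None = None) -> Disposition:
    """Genotype-call quality gate: GQ, DP, VAF and caller PASS status."""
    cfg = config or SnvFilterConfig()
    reasons: list[str] = []
    if v.gq is None or v.dp is None or v.alt_depth is None:
        reasons.append("missing_quality_field")
    else:
        if v.gq < cfg.min_gq:
            reasons.append("low_gq")
        if v.dp < cfg.min_dp:
            reasons.append("low_dp")
        if v.dp == 0 or not _vaf_passes(v.alt_depth, v.dp, cfg.vaf_threshold):
            reasons.append("low_vaf")
    if v.filter_status != "PASS":
        reasons.append("not_pass")
    if reasons:
        return Disposition(Stage.QUALITY, Outcome.FAIL, tuple(reasons))
    return Disposition(Stage.QUALITY, Outcome.PASS)


def frequency_filter(v: AnnotatedVariant, config: SnvFilterConfig | None = None) -> Disposition:
    """Population-frequency gate: strict > 0.01 in ExAC or 1000 Genomes
    fails; an absent frequency counts as 0."""
    cfg = config or SnvFilterConfig()
    reasons = []
    if (v.af_exac or 0.0) > cfg.max_af:
        reasons.append("af_exac_above_threshold")
    if (v.af_1kg or 0.0) > cfg.max_af:
        reasons.append("af_1kg_above_threshold")
    if reasons:
        return Disposition(Stage.FREQUENCY, Outcome.FAIL, tuple(reasons))
    return Disposition(Stage.FREQUENCY, Outcome.PASS)


def _clinvar_plp_two_star(v: AnnotatedVariant) -> bool:
    return (
        v.clinvar_assertion in PATHOGENIC_OR_LIKELY
        and (v.clinvar_stars or 0) >= 2
    )


def retention_rules(
    v: AnnotatedVariant,
    cadd_threshold: float | None = None,
    config: SnvFilterConfig | None = None,
    *,
    include_cadd: bool = True,
) -> Disposition:
    """Retention gate: keep a variant for assessment if any route fires.

    Routes: (a) truncating SO consequence; (b) ClinVar P/LP with >= 2-star
    review; (c) HGMD DM status; (d) CADD >= threshold. ``include_cadd=False``
    evaluates only (a)-(c), supporting the two-pass schedule in which
    CADD-only retention is deferred until database/consequence-retained
    variants have been assessed.
    """
    cfg = config or SnvFilterConfig()
    threshold = cfg.cadd_threshold if cadd_threshold is None else cadd_threshold
    reasons: list[str] = []
    if v.so_consequence not in _KNOWN_SO_TERMS:
        logger.info("unknown SO term %r treated as non-truncating", v.so_consequence)
    if v.so_consequence in cfg.truncating_terms:
        reasons.append("truncating_consequence")
    if _clinvar_plp_two_star(v):
        reasons.append("clinvar_plp_two_star")
    if v.hgmd_dm:
        reasons.append("hgmd_dm")
    if include_cadd and v.cadd_phred is not None and v.cadd_phred >= threshold:
        reasons.append("cadd_above_threshold")
    if reasons:
        return Disposition(Stage.RETENTION, Outcome.RETAINED, tuple(reasons))
    return Disposition(Stage.RETENTION, Outcome.FAIL, ("no_retention_criterion",))


def derive_cadd_threshold(pathogenic_scores: Sequence[float]) -> float:
    """Median Phred-scaled CADD score of an independently assessed
    pathogenic variant set; used as the retention threshold for variants
    carried solely by in-silico evidence."""
    if not pathogenic_scores:
        raise ValueError(
            "cannot derive a CADD threshold from an empty score list; "
            "fall back to the configured default"
        )
    return float(median(pathogenic_scores))


def noncoding_lookup(v: AnnotatedVariant, panel: Panel) -> Disposition:
    """Exact positional/allelic match against the panel's short list of
    known pathogenic non-coding variants."""
    entry = (v.contig, v.position, v.ref, v.alt)
    if entry in set(panel.noncoding_pathogenic_positions):
        return Disposition(
            Stage.NONCODING_LOOKUP, Outcome.RETAINED, ("noncoding_pathogenic_position",)
        )
    return Disposition(Stage.NONCODING_LOOKUP, Outcome.FAIL, ("no_positional_match",))


def _benign_or_uncertain_two_star(v: AnnotatedVariant) -> bool:
    return (
        v.clinvar_assertion in BENIGN_OR_UNCERTAIN and (v.clinvar_stars or 0) >= 2
    )


def exclusion_rules(
    v: AnnotatedVariant,
    gene: GeneRecord,
    retention_reasons: Sequence[str],
    filtered_gene_dose: int,
    config: SnvFilterConfig | None = None,
) -> Disposition:
    """Refutation criteria applied to retained variants.

    ``retention_reasons`` are the reason codes from the retention stage;
    ``filtered_gene_dose`` is the number of filtered variant alleles this
    individual carries in the gene (a homozygous call counts as two),
    used for the recessive-only rule.
    """
    cfg = config or SnvFilterConfig()
    truncating = "truncating_consequence" in retention_reasons
    reasons: list[str] = []

    # 1: truncating but ClinVar (>=2-star) says benign/uncertain
    if truncating and _benign_or_uncertain_two_star(v):
        reasons.append("truncating_with_benign_uncertain_clinvar")
    # 2: truncating in a proto-oncogene (gain-of-function mechanism)
    if truncating and gene.is_proto_oncogene:
        reasons.append("truncating_in_proto_oncogene")
    # 3: truncation removes < 5% of the canonical transcript
    if truncating:
        if v.truncation_fraction is None:
            logger.info(
                "truncating variant %s:%d lacks truncation_fraction; "
                "transcript-fraction criterion not applied", v.contig, v.position,
            )
        elif v.truncation_fraction < cfg.min_truncation_fraction:
            reasons.append("truncation_below_min_fraction")
    # 4: recessive-only gene without a second filtered variant
    if gene.recessive_only and filtered_gene_dose < 2:
        reasons.append("recessive_gene_single_variant")
    # 5: retained solely by HGMD-DM/CADD, contradicted by ClinVar
    solely_insilico = bool(retention_reasons) and set(retention_reasons) <= {
        "hgmd_dm", "cadd_above_threshold",
    }
    if solely_insilico:
        one_star_multi = (
            v.clinvar_stars == 1
            and v.clinvar_submission_count >= 2
            and v.clinvar_assertion not in PATHOGENIC_OR_LIKELY
            and v.clinvar_assertion != ClinvarAssertion.ABSENT
        )
        if _benign_or_uncertain_two_star(v) or one_star_multi:
            reasons.append("insilico_retained_with_clinvar_refutation")

    if reasons:
        return Disposition(Stage.EXCLUSION, Outcome.EXCLUDED, tuple(reasons))
    return Disposition(Stage.EXCLUSION, Outcome.PASS)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

@dataclass
class SnvPipelineResult:
    retained: list[AnnotatedVariant]
    dispositions: dict[tuple, Disposition]
    #: per-stage terminal counts; conserves the (deduplicated) input count
    audit: dict[str, int]
    #: records dropped as exact duplicates of an earlier record
    duplicates: list[AnnotatedVariant] = field(default_factory=list)
    #: malformed/unknown-gene records quarantined, never silently dropped
    quarantined: list[tuple[AnnotatedVariant, str]] = field(default_factory=list)

    @property
    def retained_keys(self) -> set[tuple]:
        return {v.key for v in self.retained}


def run_snv_pipeline(
    cohort_variants: Iterable[AnnotatedVariant],
    panel: Panel,
    config: SnvFilterConfig | None = None,
) -> SnvPipelineResult:
    """Run the full cascade over a cohort's variants.

    Deterministic: the retained list is sorted by
    (contig, position, alt, individual_id) regardless of input order.
    """
    cfg = config or SnvFilterConfig()
    seen: set[tuple] = set()
    variants: list[AnnotatedVariant] = []
    duplicates: list[AnnotatedVariant] = []
    quarantined: list[tuple[AnnotatedVariant, str]] = []
    for v in cohort_variants:
        if v.key in seen:
            warnings.warn(f"duplicate record for {v.key} dropped", stacklevel=2)
            duplicates.append(v)
            continue
        seen.add(v.key)
        if v.gene_symbol not in panel:
            quarantined.append((v, f"gene {v.gene_symbol!r} not in panel"))
            continue
        variants.append(v)

    dispositions: dict[tuple, Disposition] = {}
    audit = {
        "input": len(variants),
        "quality_fail": 0,
        "frequency_fail": 0,
        "not_retained": 0,
        "excluded": 0,
        "retained_for_assessment": 0,
    }

    # --- gates + retention (two-pass CADD schedule) ----------------------
    retained_first: dict[tuple, tuple[str, ...]] = {}
    cadd_candidates: list[AnnotatedVariant] = []
    survivors: dict[tuple, AnnotatedVariant] = {}
    for v in variants:
        q = quality_filter(v, cfg)
        if q.outcome is Outcome.FAIL:
            dispositions[v.key] = q
            audit["quality_fail"] += 1
            continue
        f = frequency_filter(v, cfg)
        if f.outcome is Outcome.FAIL:
            dispositions[v.key] = f
            audit["frequency_fail"] += 1
            continue
        survivors[v.key] = v
        r1 = retention_rules(v, config=cfg, include_cadd=False)
        nc = noncoding_lookup(v, panel)
        if r1.outcome is Outcome.RETAINED or nc.outcome is Outcome.RETAINED:
            reasons = r1.reason_codes if r1.outcome is Outcome.RETAINED else ()
            if nc.outcome is Outcome.RETAINED:
                reasons = reasons + ("noncoding_pathogenic_position",)
            retained_first[v.key] = reasons
        else:
            cadd_candidates.append(v)

    # second pass: CADD-only retention among first-pass leftovers
    retained_all: dict[tuple, tuple[str, ...]] = dict(retained_first)
    for v in cadd_candidates:
        r2 = retention_rules(v, config=cfg, include_cadd=True)
        if r2.outcome is Outcome.RETAINED:
            retained_all[v.key] = r2.reason_codes
        else:
            dispositions[v.key] = r2
            audit["not_retained"] += 1

    # the staged schedule must agree with single-pass evaluation
    single_pass = {
        k for k, v in survivors.items()
        if retention_rules(v, config=cfg).outcome is Outcome.RETAINED
        or noncoding_lookup(v, panel).outcome is Outcome.RETAINED
    }
    assert set(retained_all) == single_pass, (
        "two-pass CADD schedule diverged from single-pass retention"
    )

    # --- per-(individual, gene) filtered dose for the recessive rule ------
    dose: dict[tuple[str, str], int] = {}
    for key, _ in retained_all.items():
        v = survivors[key]
        dose[(v.individual_id, v.gene_symbol)] = dose.get(
            (v.individual_id, v.gene_symbol), 0
        ) + (2 if v.zygosity == "hom" else 1)

    # --- exclusion --------------------------------------------------------
    retained: list[AnnotatedVariant] = []
    for key in retained_all:
        v = survivors[key]
        gene = panel[v.gene_symbol]
        d = exclusion_rules(
            v,
            gene,
            retained_all[key],
            dose.get((v.individual_id, v.gene_symbol), 0),
            cfg,
        )
        if d.outcome is Outcome.EXCLUDED:
            dispositions[key] = d
            audit["excluded"] += 1
        else:
            dispositions[key] = Disposition(
                Stage.RETAINED_FOR_ASSESSMENT, Outcome.RETAINED, retained_all[key]
            )
            audit["retained_for_assessment"] += 1
            retained.append(v)

    retained.sort(key=lambda v: (v.contig, v.position, v.alt, v.individual_id))
    assert audit["input"] == (
        audit["quality_fail"] + audit["frequency_fail"] + audit["not_retained"]
        + audit["excluded"] + audit["retained_for_assessment"]
    ), "stage counts do not conserve the input count"
    return SnvPipelineResult(
        retained=retained,
        dispositions=dispositions,
        audit=audit,
        duplicates=duplicates,
        quarantined=quarantined,
    )
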