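"""Seeded synthetic-input generator with planted truth.

Raw sequencing data behind MPT cohort studies are not publicly
distributable, so every pipeline input is emulated here on a miniature
synthetic genome (a few contigs, kilobase-scale genes): cohort phenotypes,
annotated small-variant records, SV calls, reference-population carrier
counts and registry combination tables. Each generated variant carries a
truth-table row naming the gate it was built to pass or trip, so filter
sensitivity/specificity are measured against construction intent rather
than re-derived from the data.

Defaults parameterize the generator to the published cohort conditions:
77% female probands, tumor-category weights from the most frequent tumor
types of the series (breast 24.6%, colorectal 9.9%, ...), a 15.2%
per-proband planted P/LP rate, and a reference population with a
55.3%/44.7% male/female split carrying qualifying variants at 3.3%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .panel import GeneRecord, Individual, Panel, TumorDiagnosis, load_characteristic_tumors, mpt_eligible
from .stats import ReferencePopulationCounts
from .sv import SVCall
from .variants import AnnotatedVariant, ClinvarAssertion

__all__ = [
    "SimulationConfig",
    "build_synthetic_panel",
    "generate_cohort",
    "generate_variants",
    "generate_svs",
    "generate_reference_population",
    "generate_registry_counts",
    "truth_frame",
]

#: default tumor-category sampling weights; the five most frequent
#: categories use the published cohort shares and the remainder is spread
#: over the rest of the vocabulary.
DEFAULT_TUMOR_WEIGHTS = {
    "breast": 0.246,
    "colorectal": 0.099,
    "kidney": 0.073,
    "nmsc": 0.059,
    "ovary": 0.051,
    "endometrium": 0.045,
    "melanoma": 0.040,
    "thyroid": 0.038,
    "hem_lymphoid": 0.036,
    "lung": 0.030,
    "soft_tissue_sarcoma": 0.025,
    "cns": 0.025,
    "pituitary": 0.020,
    "pheochromocytoma": 0.020,
    "prostate": 0.025,
    "testicular": 0.020,
    "stomach": 0.015,
    "bladder": 0.015,
    "cervix": 0.025,
    "small_bowel": 0.019,
    "leiomyoma_cutaneous": 0.015,
    "gi_net": 0.015,
    "pancreatic_net": 0.012,
    "hem_myeloid": 0.012,
    "paraganglioma": 0.010,
    "parathyroid": 0.010,
}


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_probands: int = 440
    sex_proportion_female: float = 0.77
    tumor_category_frequencies: dict = field(
        default_factory=lambda: dict(DEFAULT_TUMOR_WEIGHTS)
    )
    #: distribution over the number of distinct tumor categories per proband
    tumors_per_individual: dict = field(
        default_factory=lambda: {2: 0.62, 3: 0.28, 4: 0.10}
    )
    planted_plp_rate: float = 0.152
    background_variants_per_proband: int = 5
    planted_sv_count: int = 6
    sv_decoy_count: int = 50
    recessive_biallelic_count: int = 3
    exclusion_decoys_per_criterion: int = 1
    ref_n_male: int = 4972
    ref_n_female: int = 4020
    ref_freq_male: float = 0.033
    ref_freq_female: float = 0.033
    concordance_probability: float = 0.567
    #: mixture over retention routes for planted qualifying variants
    route_weights: dict = field(
        default_factory=lambda: {
            "truncating": 0.60, "clinvar": 0.15, "hgmd": 0.15, "cadd": 0.10,
        }
    )

    def __post_init__(self) -> None:
        total = sum(self.tumor_category_frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tumor category frequencies sum to {total}, not 1")
        for name in ("sex_proportion_female", "planted_plp_rate",
                     "concordance_probability", "ref_freq_male", "ref_freq_female"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.tumor_category_frequencies:
            raise ValueError("at least one tumor category is required")


# ---------------------------------------------------------------------------
# Synthetic genome + panel
# ---------------------------------------------------------------------------

#: (symbol, proto_oncogene, recessive_only)
_PANEL_GENES = [
    ("BRCA1", False, False), ("BRCA2", False, False), ("ATM", False, False),
    ("CHEK2", False, False), ("PALB2", False, False), ("FH", False, False),
    ("PTEN", False, False), ("MLH1", False, False), ("MSH2", False, False),
    ("PMS2", False, False), ("FLCN", False, False), ("SMAD4", False, False),
    ("TSC1", False, False), ("TSC2", False, False), ("MAX", False, False),
    ("SDHB", False, False), ("NF1", False, False), ("BMPR1A", False, False),
    ("RET", True, False), ("MET", True, False), ("KIT", True, False),
    ("ALK", True, False), ("MUTYH", False, True), ("NTHL1", False, True),
]

_EXONS_PER_GENE = 5
_EXON_LEN = 200
_INTRON_LEN = 800
_GENE_GAP = 20_000
_GENES_PER_CONTIG = 6


def build_synthetic_panel(
    noncoding_positions: Sequence[tuple[str, int, str, str]] = (),
) -> Panel:
    """Deterministic miniature panel: 24 genes laid out on 4 contigs, each
    with five 200-bp exons separated by 800-bp introns."""
    characteristic = load_characteristic_tumors()
    genes = []
    for i, (symbol, proto, recessive) in enumerate(_PANEL_GENES):
        contig = f"chr{i // _GENES_PER_CONTIG + 1}"
        offset = 10_000 + (i % _GENES_PER_CONTIG) * _GENE_GAP
        exons = tuple(
            (contig,
             offset + j * (_EXON_LEN + _INTRON_LEN),
             offset + j * (_EXON_LEN + _INTRON_LEN) + _EXON_LEN)
            for j in range(_EXONS_PER_GENE)
        )
        genes.append(GeneRecord(
            symbol=symbol,
            is_proto_oncogene=proto,
            recessive_only=recessive,
            characteristic_tumors=characteristic.get(symbol, frozenset()),
            exons=exons,
        ))
    return Panel(genes=tuple(genes),
                 noncoding_pathogenic_positions=tuple(noncoding_positions))


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def generate_cohort(config: SimulationConfig) -> list[Individual]:
    """Probands with sex ~ Bernoulli(sex_proportion_female) and tumor
    categories drawn without replacement from the category weights; ages
    are drawn so that every proband satisfies MPT eligibility."""
    rng = np.random.default_rng(config.seed)
    cats = sorted(config.tumor_category_frequencies)
    weights = np.array([config.tumor_category_frequencies[c] for c in cats])
    weights = weights / weights.sum()
    k_values = sorted(config.tumors_per_individual)
    k_probs = np.array([config.tumors_per_individual[k] for k in k_values])
    k_probs = k_probs / k_probs.sum()

    individuals = []
    for i in range(config.n_probands):
        sex = "female" if rng.random() < config.sex_proportion_female else "male"
        k = int(rng.choice(k_values, p=k_probs))
        chosen = rng.choice(len(cats), size=min(k, len(cats)), replace=False, p=weights)
        if k >= 3:
            # at least three primaries by 70 (first two still often early)
            ages = rng.integers(25, 71, size=len(chosen))
            ages = np.sort(ages)
        else:
            # two primaries by 60
            ages = np.sort(rng.integers(25, 61, size=len(chosen)))
        tumors = tuple(
            TumorDiagnosis(category=cats[int(c)], age_at_diagnosis=float(a))
            for c, a in zip(chosen, ages)
        )
        ind = Individual(
            individual_id=f"P{i:04d}",
            family_id=f"F{i:04d}",
            sex=sex,
            tumors=tumors,
        )
        assert mpt_eligible(ind.tumors)
        individuals.append(ind)
    return individuals


# ---------------------------------------------------------------------------
# Small variants
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _draw_het_depths(rng: np.random.Generator) -> tuple[int, int]:
    """Depth ~ 35x; heterozygous alt count resampled until VAF >= 33%."""
    dp = int(rng.poisson(35)) + 10
    while True:
        alt = int(rng.binomial(dp, 0.5))
        if alt * 100 >= 33 * dp and alt <= dp:
            return dp, alt


def _draw_hom_depths(rng: np.random.Generator) -> tuple[int, int]:
    dp = int(rng.poisson(35)) + 10
    alt = int(rng.binomial(dp, 0.98))
    return dp, max(alt, int(np.ceil(dp * 0.9)))


def _alleles(rng: np.random.Generator) -> tuple[str, str]:
    ref, alt = rng.choice(4, size=2, replace=False)
    return str(_BASES[ref]), str(_BASES[alt])


class _PositionAllocator:
    """Hands out unique positions inside a gene's exons (1-based)."""

    def __init__(self, panel: Panel, rng: np.random.Generator):
        self._panel = panel
        self._rng = rng
        self._used: set[tuple[str, int]] = set()

    def exonic(self, gene: GeneRecord) -> tuple[str, int]:
        while True:
            contig, s, e = gene.exons[int(self._rng.integers(len(gene.exons)))]
            pos = int(self._rng.integers(s, e)) + 1  # to 1-based
            if (contig, pos) not in self._used:
                self._used.add((contig, pos))
                return contig, pos


def _qualifying_variant(
    rng: np.random.Generator,
    alloc: _PositionAllocator,
    gene: GeneRecord,
    individual_id: str,
    route: str,
    zygosity: str = "het",
) -> AnnotatedVariant:
    contig, pos = alloc.exonic(gene)
    ref, alt = _alleles(rng)
    dp, ad = _draw_hom_depths(rng) if zygosity == "hom" else _draw_het_depths(rng)
    base = dict(
        contig=contig, position=pos, ref=ref, alt=alt,
        gene_symbol=gene.symbol, individual_id=individual_id,
        zygosity=zygosity, gq=float(rng.integers(40, 100)), dp=dp, alt_depth=ad,
        filter_status="PASS", af_exac=None, af_1kg=None,
    )
    if route == "truncating":
        return AnnotatedVariant(
            so_consequence=str(rng.choice(["stop_gained", "frameshift_variant",
                                           "splice_donor_variant"])),
            truncation_fraction=float(rng.uniform(0.10, 0.95)),
            cadd_phred=float(rng.uniform(25, 45)),
            **base,
        )
    if route == "clinvar":
        return AnnotatedVariant(
            so_consequence="missense_variant",
            clinvar_assertion=ClinvarAssertion.PATHOGENIC,
            clinvar_stars=int(rng.integers(2, 4)),
            clinvar_submission_count=int(rng.integers(2, 8)),
            cadd_phred=float(rng.uniform(20, 33)),
            **base,
        )
    if route == "hgmd":
        return AnnotatedVariant(
            so_consequence="missense_variant", hgmd_dm=True,
            cadd_phred=float(rng.uniform(20, 33)),
            **base,
        )
    if route == "cadd":
        return AnnotatedVariant(
            so_consequence="missense_variant",
            cadd_phred=float(rng.uniform(34, 50)),
            **base,
        )
    raise ValueError(f"unknown retention route {route!r}")


def _background_variant(
    rng: np.random.Generator,
    alloc: _PositionAllocator,
    gene: GeneRecord,
    individual_id: str,
    fail_class: str,
) -> AnnotatedVariant:
    """A variant constructed to fail exactly one named gate."""
    contig, pos = alloc.exonic(gene)
    ref, alt = _alleles(rng)
    dp, ad = _draw_het_depths(rng)
    base = dict(
        contig=contig, position=pos, ref=ref, alt=alt,
        gene_symbol=gene.symbol, individual_id=individual_id,
        zygosity="het", gq=float(rng.integers(40, 100)), dp=dp, alt_depth=ad,
        filter_status="PASS", so_consequence="stop_gained",
        truncation_fraction=float(rng.uniform(0.10, 0.95)),
    )
    if fail_class == "low_gq":
        base["gq"] = float(rng.integers(0, 30))
    elif fail_class == "low_dp":
        base["dp"], base["alt_depth"] = int(rng.integers(1, 10)), 0
        base["alt_depth"] = max(1, int(np.ceil(base["dp"] * 0.4)))
    elif fail_class == "low_vaf":
        dp = int(rng.integers(20, 60))
        base["dp"], base["alt_depth"] = dp, int(np.floor(dp * 0.33)) - 1
    elif fail_class == "not_pass":
        base["filter_status"] = "LowQual"
    elif fail_class == "high_af_exac":
        base["af_exac"] = float(rng.uniform(0.011, 0.5))
    elif fail_class == "high_af_1kg":
        base["af_1kg"] = float(rng.uniform(0.011, 0.5))
    elif fail_class == "no_retention":
        base["so_consequence"] = "missense_variant"
        base.pop("truncation_fraction")
        base["cadd_phred"] = float(rng.uniform(0, 20))
    else:
        raise ValueError(f"unknown background class {fail_class!r}")
    return AnnotatedVariant(**base)


_BACKGROUND_CLASSES = [
    "low_gq", "low_dp", "low_vaf", "not_pass",
    "high_af_exac", "high_af_1kg", "no_retention",
]


def _exclusion_decoy(
    rng: np.random.Generator,
    alloc: _PositionAllocator,
    panel: Panel,
    individual_id: str,
    criterion: int,
) -> AnnotatedVariant:
    """A retained-then-excluded variant tripping exactly one refutation
    criterion."""
    dominant = [g for g in panel.genes
                if not g.is_proto_oncogene and not g.recessive_only]
    proto = [g for g in panel.genes if g.is_proto_oncogene]
    recessive = [g for g in panel.genes if g.recessive_only]
    if not proto or not recessive:
        raise ValueError(
            "panel must contain proto-oncogene and recessive-only genes "
            "to construct exclusion decoys"
        )
    dp, ad = _draw_het_depths(rng)
    gene = dominant[int(rng.integers(len(dominant)))]
    if criterion == 2:
        gene = proto[int(rng.integers(len(proto)))]
    elif criterion == 4:
        gene = recessive[int(rng.integers(len(recessive)))]
    contig, pos = alloc.exonic(gene)
    ref, alt = _alleles(rng)
    base = dict(
        contig=contig, position=pos, ref=ref, alt=alt,
        gene_symbol=gene.symbol, individual_id=individual_id,
        zygosity="het", gq=float(rng.integers(40, 100)), dp=dp, alt_depth=ad,
        filter_status="PASS",
    )
    if criterion == 1:
        return AnnotatedVariant(
            so_consequence="stop_gained",
            truncation_fraction=float(rng.uniform(0.10, 0.95)),
            clinvar_assertion=ClinvarAssertion.BENIGN,
            clinvar_stars=2, clinvar_submission_count=4, **base,
        )
    if criterion == 2:
        return AnnotatedVariant(
            so_consequence="stop_gained",
            truncation_fraction=float(rng.uniform(0.10, 0.95)), **base,
        )
    if criterion == 3:
        return AnnotatedVariant(
            so_consequence="stop_gained",
            truncation_fraction=float(rng.uniform(0.005, 0.045)), **base,
        )
    if criterion == 4:
        return AnnotatedVariant(
            so_consequence="stop_gained",
            truncation_fraction=float(rng.uniform(0.10, 0.95)), **base,
        )
    if criterion == 5:
        return AnnotatedVariant(
            so_consequence="missense_variant", hgmd_dm=True,
            clinvar_assertion=ClinvarAssertion.UNCERTAIN,
            clinvar_stars=2, clinvar_submission_count=3, **base,
        )
    raise ValueError(f"unknown exclusion criterion {criterion}")


def generate_variants(
    config: SimulationConfig,
    cohort: Sequence[Individual],
    panel: Panel,
) -> tuple[list[AnnotatedVariant], pd.DataFrame]:
    """Annotated variants plus a truth table.

    Truth-table columns: variant identity, ``truth_class`` (``qualifying``,
    ``background:<gate>``, ``exclusion:<criterion>``), and
    ``expected_retained`` (whether the full cascade should keep it).
    """
    truth_columns = ["individual_id", "contig", "position", "ref", "alt",
                     "gene", "truth_class", "expected_retained"]
    if len(cohort) == 0:
        return [], pd.DataFrame(columns=truth_columns)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    alloc = _PositionAllocator(panel, rng)
    dominant = [g for g in panel.genes
                if not g.is_proto_oncogene and not g.recessive_only]
    recessive = [g for g in panel.genes if g.recessive_only]
    variants: list[AnnotatedVariant] = []
    truth: list[dict] = []
    routes = sorted(config.route_weights)
    route_p = np.array([config.route_weights[r] for r in routes])
    route_p = route_p / route_p.sum()

    def record(v: AnnotatedVariant, truth_class: str, retained: bool) -> None:
        variants.append(v)
        truth.append({
            "individual_id": v.individual_id, "contig": v.contig,
            "position": v.position, "ref": v.ref, "alt": v.alt,
            "gene": v.gene_symbol, "truth_class": truth_class,
            "expected_retained": retained,
        })

    for ind in cohort:
        if rng.random() < config.planted_plp_rate:
            route = str(rng.choice(routes, p=route_p))
            gene = dominant[int(rng.integers(len(dominant)))]
            v = _qualifying_variant(rng, alloc, gene, ind.individual_id, route)
            record(v, "qualifying", True)
        for j in range(config.background_variants_per_proband):
            fail_class = _BACKGROUND_CLASSES[
                int(rng.integers(len(_BACKGROUND_CLASSES)))
            ]
            gene = dominant[int(rng.integers(len(dominant)))]
            v = _background_variant(rng, alloc, gene, ind.individual_id, fail_class)
            record(v, f"background:{fail_class}", False)

    # recessive biallelic cases: two filtered variants in one recessive gene
    n_biallelic = min(config.recessive_biallelic_count, len(cohort))
    if n_biallelic and not recessive:
        raise ValueError("panel lacks a recessive-only gene for biallelic cases")
    chosen = rng.choice(len(cohort), size=n_biallelic, replace=False)
    for idx in chosen:
        ind = cohort[int(idx)]
        gene = recessive[int(rng.integers(len(recessive)))]
        if rng.random() < 0.5:  # homozygous single call counts as two alleles
            v = _qualifying_variant(rng, alloc, gene, ind.individual_id,
                                    "truncating", zygosity="hom")
            record(v, "recessive_biallelic", True)
        else:  # presumed compound het: two distinct het calls
            for _ in range(2):
                v = _qualifying_variant(rng, alloc, gene, ind.individual_id,
                                        "truncating")
                record(v, "recessive_biallelic", True)

    # decoys tripping each exclusion criterion; the recessive-only decoy
    # (criterion 4) must land in an individual without biallelic variants
    # in that gene, or the second-variant escape would fire
    biallelic_ids = {cohort[int(i)].individual_id for i in chosen}
    used_recessive_ids: set[str] = set()
    for criterion in range(1, 6):
        for _ in range(config.exclusion_decoys_per_criterion):
            while True:
                ind = cohort[int(rng.integers(len(cohort)))]
                if criterion != 4:
                    break
                if ind.individual_id not in biallelic_ids | used_recessive_ids:
                    used_recessive_ids.add(ind.individual_id)
                    break
            v = _exclusion_decoy(rng, alloc, panel, ind.individual_id, criterion)
            record(v, f"exclusion:{criterion}", False)

    return variants, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Structural variants
# ---------------------------------------------------------------------------

def generate_svs(
    config: SimulationConfig,
    cohort: Sequence[Individual],
    panel: Panel,
) -> tuple[list[SVCall], pd.DataFrame, list[tuple[str, int, int]]]:
    """SV calls, their truth table, and the common-CNV map (BED-style
    0-based intervals) that contains the CNV-map decoys.

    Planted archetypes mirror the configurations seen in practice: a
    single-exon deletion, an exonic inversion, an intronic-breakpoint
    inversion, a single-exon duplication, a translocation with a breakend
    in the first exon, and a full-gene deletion. Each receives a non-none
    category from the SV pipeline. Decoys rotate over: low quality, common
    cohort frequency, non-exonic placement, and containment in the CNV map.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    if len(cohort) == 0:
        return [], pd.DataFrame(columns=[
            "call_id", "individual_id", "truth_class", "expected_category",
            "expected_cnv_excluded",
        ]), []
    dominant = [g for g in panel.genes
                if not g.is_proto_oncogene and not g.recessive_only]
    # one tumor-suppressor gene is reserved for CNV-map decoys: the map
    # region fully contains that gene's neighborhood so exon-overlapping
    # deletions there pass the prefilter and are then map-excluded
    cnv_gene = dominant[-1]
    dominant = dominant[:-1]
    svs: list[SVCall] = []
    truth: list[dict] = []
    counter = [0]

    def pick_individual() -> str:
        return cohort[int(rng.integers(len(cohort)))].individual_id

    def add(sv: SVCall, truth_class: str, expected: str,
            cnv_excluded: bool = False) -> None:
        svs.append(sv)
        truth.append({
            "call_id": sv.call_id, "individual_id": sv.individual_id,
            "truth_class": truth_class, "expected_category": expected,
            "expected_cnv_excluded": cnv_excluded,
        })

    def next_id() -> str:
        counter[0] += 1
        return f"SV{counter[0]:04d}"

    def gene_at(i: int) -> GeneRecord:
        return dominant[i % len(dominant)]

    archetypes = [
        "exon_deletion", "exonic_inversion", "intronic_inversion",
        "exon_duplication", "utr_translocation", "full_gene_deletion",
    ]
    for i in range(config.planted_sv_count):
        kind = archetypes[i % len(archetypes)]
        gene = gene_at(i)
        iid = pick_individual()
        exon = gene.exons[1]
        quality = float(rng.integers(40, 200))
        if kind == "exon_deletion":
            sv = SVCall("canvas", "deletion", gene.contig, exon[1] - 50 + 1,
                        gene.contig, exon[2] + 50, quality, 0.0, iid,
                        call_id=next_id())
            add(sv, kind, "tsg_copy_loss")
        elif kind == "exonic_inversion":
            sv = SVCall("manta", "inversion", gene.contig, exon[1] - 100 + 1,
                        gene.contig, exon[2] + 100, quality, 0.0, iid,
                        call_id=next_id())
            add(sv, kind, "breakpoint_disruption")
        elif kind == "intronic_inversion":
            # both breakends inside introns of the gene
            s = gene.exons[2][2] + 100
            e = gene.exons[3][2] + 100
            sv = SVCall("manta", "inversion", gene.contig, s + 1,
                        gene.contig, e, quality, 0.0, iid, call_id=next_id())
            add(sv, kind, "breakpoint_disruption")
        elif kind == "exon_duplication":
            sv = SVCall("manta", "duplication", gene.contig, exon[1] - 50 + 1,
                        gene.contig, exon[2] + 50, quality, 0.0, iid,
                        call_id=next_id())
            add(sv, kind, "breakpoint_disruption")
        elif kind == "utr_translocation":
            first_exon = gene.exons[0]
            other_contig = "chrT"
            sv = SVCall("manta", "translocation", gene.contig,
                        first_exon[1] + 10 + 1, other_contig,
                        int(rng.integers(1_000, 500_000)), quality, 0.0, iid,
                        call_id=next_id())
            add(sv, kind, "breakpoint_disruption")
        else:  # full_gene_deletion
            span = gene.span
            sv = SVCall("canvas", "deletion", gene.contig, span[0] - 500 + 1,
                        gene.contig, span[1] + 500, quality, 0.0, iid,
                        call_id=next_id())
            add(sv, kind, "tsg_copy_loss")

    # CNV map region fully containing the reserved gene's neighborhood
    cnv_span = cnv_gene.span
    cnv_region = (cnv_gene.contig, cnv_span[0] - 2_000, cnv_span[1] + 2_000)
    cnv_map = [cnv_region]

    decoy_classes = ["low_quality", "common_frequency", "non_exonic", "cnv_map"]
    for i in range(config.sv_decoy_count):
        kind = decoy_classes[i % len(decoy_classes)]
        gene = gene_at(i)
        iid = pick_individual()
        exon = gene.exons[1]
        if kind == "low_quality":
            sv = SVCall("manta", "deletion", gene.contig, exon[1] - 50 + 1,
                        gene.contig, exon[2] + 50,
                        float(rng.integers(0, 30)), 0.0, iid, call_id=next_id())
            add(sv, f"decoy:{kind}", "none")
        elif kind == "common_frequency":
            sv = SVCall("canvas", "deletion", gene.contig, exon[1] - 50 + 1,
                        gene.contig, exon[2] + 50, float(rng.integers(40, 200)),
                        float(rng.uniform(0.01, 0.3)), iid, call_id=next_id())
            add(sv, f"decoy:{kind}", "none")
        elif kind == "non_exonic":
            # deletion in intergenic space, overlapping no gene
            start = 200_000 + i * 1_000
            sv = SVCall("canvas", "deletion", "chr2", start + 1,
                        "chr2", start + 400, float(rng.integers(40, 200)),
                        0.0, iid, call_id=next_id())
            add(sv, f"decoy:{kind}", "none")
        else:  # cnv_map: exon-overlapping deletion contained in the map
            cexon = cnv_gene.exons[1]
            sv = SVCall("canvas", "deletion", cnv_gene.contig,
                        cexon[1] - 50 + 1, cnv_gene.contig, cexon[2] + 50,
                        float(rng.integers(40, 200)), 0.0, iid,
                        call_id=next_id())
            add(sv, f"decoy:{kind}", "tsg_copy_loss", cnv_excluded=True)
    return svs, pd.DataFrame(truth), cnv_map


# ---------------------------------------------------------------------------
# Reference population & registry
# ---------------------------------------------------------------------------

def generate_reference_population(config: SimulationConfig) -> ReferencePopulationCounts:
    """Carrier counts drawn Binomial(n_sex, f_sex), deterministic in the
    seed."""
    if config.ref_n_male <= 0 or config.ref_n_female <= 0:
        raise ValueError("reference population sizes must be positive")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    return ReferencePopulationCounts(
        n_male=config.ref_n_male,
        n_female=config.ref_n_female,
        carriers_male=int(rng.binomial(config.ref_n_male, config.ref_freq_male)),
        carriers_female=int(rng.binomial(config.ref_n_female, config.ref_freq_female)),
    )


def generate_registry_counts(
    config: SimulationConfig,
    n_individuals: int = 471,
    enriched: dict | None = None,
) -> dict[tuple[str, str], int]:
    """Registry-style tumor-combination counts drawn from the same category
    weights (optionally with per-pair multiplicative enrichment), emulating
    a population registry of double-primary cases."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    cats = sorted(config.tumor_category_frequencies)
    weights = np.array([config.tumor_category_frequencies[c] for c in cats])
    weights = weights / weights.sum()
    enriched = enriched or {}
    counts: dict[tuple[str, str], int] = {}
    for _ in range(n_individuals):
        a, b = rng.choice(len(cats), size=2, replace=False, p=weights)
        pair = tuple(sorted((cats[int(a)], cats[int(b)])))
        counts[pair] = counts.get(pair, 0) + 1
    for pair, factor in enriched.items():
        key = tuple(sorted(pair))
        counts[key] = int(counts.get(key, 0) * factor) + (factor > 1)
    return counts


def truth_frame(variants: Sequence[AnnotatedVariant], truth: pd.DataFrame) -> pd.DataFrame:
    """Join truth rows back onto generated variants (sanity helper)."""
    df = pd.DataFrame([{
        "individual_id": v.individual_id, "contig": v.contig,
        "position": v.position, "ref": v.ref, "alt": v.alt,
    } for v in variants])
    return df.merge(truth, on=["individual_id", "contig", "position", "ref", "alt"])
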