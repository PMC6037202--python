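"""Structural-variant prioritization.

Calls from a copy-number caller ("canvas"-style, QUAL-scored) and a
breakend caller ("manta"-style, GQ-scored) are merged, gated on quality,
cohort frequency and exon overlap, then assigned one of three
pathogenicity categories per intersected panel gene:

* ``tsg_copy_loss`` — copy-number loss covering coding exons of a
  tumor-suppressor gene (loss-of-function mechanism);
* ``oncogene_copy_gain`` — copy-number gain covering coding exons of a
  proto-oncogene (gain-of-function mechanism);
* ``breakpoint_disruption`` — any SV type with a predicted breakend
  strictly inside the gene's transcribed span.

Surviving calls are finally screened against a common copy-number
variation map: a call fully contained in a common-CNV region is excluded.

Coordinates: inputs are 1-based inclusive (VCF convention); internal
arithmetic and BED I/O are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .panel import GeneRecord, Panel
from .variants import Disposition, Outcome, Stage

__all__ = [
    "SVCall",
    "SVAssessment",
    "SvFilterConfig",
    "sv_prefilter",
    "sv_categorize",
    "cnv_map_exclude",
    "merge_caller_duplicates",
    "compute_cohort_frequency",
    "run_sv_pipeline",
    "SvPipelineResult",
    "read_cnv_map_bed",
]

SPAN_TYPES = {"deletion", "duplication", "copy_gain", "copy_loss"}
BREAKEND_TYPES = {"inversion", "translocation"}
LOSS_TYPES = {"deletion", "copy_loss"}
GAIN_TYPES = {"duplication", "copy_gain"}


@dataclass(frozen=True)
class SVCall:
    """One structural-variant call (1-based inclusive coordinates)."""

    caller: str  # "canvas" | "manta"
    sv_type: str
    contig_a: str
    start_a: int
    contig_b: str
    end_b: int
    quality: float
    cohort_frequency: float
    individual_id: str
    zygosity: str = "het"
    call_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.sv_type not in SPAN_TYPES | BREAKEND_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.caller not in ("canvas", "manta"):
            raise ValueError(f"unknown caller {self.caller!r}")
        if not 0 <= self.cohort_frequency <= 1:
            raise ValueError("cohort_frequency must be in [0, 1]")
        if self.sv_type == "translocation":
            if not self.contig_b:
                raise ValueError("translocation requires a second breakend")
        elif self.contig_a != self.contig_b:
            raise ValueError(f"{self.sv_type} breakends must share a contig")
        elif self.start_a >= self.end_b:
            raise ValueError("start must precede end for intra-contig calls")

    @property
    def is_intra_contig(self) -> bool:
        return self.contig_a == self.contig_b

    @property
    def span0(self) -> tuple[str, int, int] | None:
        """0-based half-open span for intra-contig calls; None otherwise."""
        if not self.is_intra_contig:
            return None
        return (self.contig_a, self.start_a - 1, self.end_b)

    @property
    def breakends(self) -> tuple[tuple[str, int], ...]:
        """Breakend point positions, 0-based."""
        return ((self.contig_a, self.start_a - 1), (self.contig_b, self.end_b - 1))


@dataclass(frozen=True)
class SVAssessment:
    sv: SVCall
    category: str  # tsg_copy_loss | oncogene_copy_gain | breakpoint_disruption | none
    gene_symbol: Optional[str] = None
    excluded_by_cnv_map: bool = False

    def __post_init__(self) -> None:
        if self.category != "none" and not self.gene_symbol:
            raise ValueError("a non-none category requires a gene symbol")


@dataclass(frozen=True)
class SvFilterConfig:
    min_quality: float = 30.0
    max_cohort_frequency: float = 0.01  # strict: < 1%
    #: reciprocal-overlap fraction at which two same-type calls are merged
    #: (caller duplicates) or counted as the same event (cohort frequency)
    reciprocal_overlap: float = 0.5
    #: CNV-map exclusion requires full containment (not mere overlap) of the
    #: call within a common-CNV region; overlap-based exclusion would discard
    #: whole-gene deletions whenever any small common CNV lies in the gene.
    cnv_containment: bool = True


def _gene_trees(panel: Panel) -> dict[str, IntervalTree]:
    """Per-contig interval tree of merged exons, data = gene symbol."""
    trees: dict[str, IntervalTree] = {}
    for g in panel.genes:
        for contig, start, end in g.merged_exons():
            trees.setdefault(contig, IntervalTree()).addi(start, end, g.symbol)
    return trees


def _genes_hit(sv: SVCall, panel: Panel) -> set[str]:
    """Panel genes an SV 'affects': span-type calls must intersect an exon;
    breakend-type calls qualify when a breakend falls inside a gene's
    transcribed span (intronic breakpoints of an inversion disrupt the gene
    even though neither breakend touches an exon)."""
    hit: set[str] = set()
    if sv.sv_type in SPAN_TYPES:
        trees = _gene_trees(panel)
        contig, s, e = sv.span0
        if contig in trees:
            hit |= {iv.data for iv in trees[contig].overlap(s, e)}
    else:
        for g in panel.genes:
            span = g.span
            if span is None:
                continue
            for contig, pos in sv.breakends:
                if contig == g.contig and span[0] <= pos < span[1]:
                    hit.add(g.symbol)
    return hit


def sv_prefilter(sv: SVCall, panel: Panel, config: SvFilterConfig | None = None) -> Disposition:
    """Quality >= 30, cohort frequency < 1%, and exon/gene intersection."""
    cfg = config or SvFilterConfig()
    reasons = []
    if sv.quality < cfg.min_quality:
        reasons.append("low_quality")
    if sv.cohort_frequency >= cfg.max_cohort_frequency:
        reasons.append("common_in_cohort")
    if not _genes_hit(sv, panel):
        reasons.append("no_exon_overlap")
    if reasons:
        return Disposition(Stage.QUALITY, Outcome.FAIL, tuple(reasons))
    return Disposition(Stage.QUALITY, Outcome.PASS)


def _breakend_inside(sv: SVCall, gene: GeneRecord) -> bool:
    span = gene.span
    if span is None:
        return False
    return any(
        contig == gene.contig and span[0] <= pos < span[1]
        for contig, pos in sv.breakends
    )


def _covers_exon(sv: SVCall, gene: GeneRecord) -> bool:
    if sv.span0 is None:
        return False
    contig, s, e = sv.span0
    return any(
        contig == gc and s < ee and es < e for gc, es, ee in gene.merged_exons()
    )


def sv_categorize(
    sv: SVCall,
    gene: GeneRecord,
    second_hit_in_gene: bool = False,
) -> SVAssessment:
    """Assign the pathogenicity category of ``sv`` with respect to ``gene``.

    ``second_hit_in_gene``: evidence of homozygosity or compound
    heterozygosity for recessive-only genes (a second qualifying SV or
    small variant in the same gene for the same individual).
    """
    if gene.recessive_only and sv.zygosity != "hom" and not second_hit_in_gene:
        return SVAssessment(sv, "none")
    if sv.sv_type in LOSS_TYPES and not gene.is_proto_oncogene and _covers_exon(sv, gene):
        return SVAssessment(sv, "tsg_copy_loss", gene.symbol)
    if sv.sv_type in GAIN_TYPES and gene.is_proto_oncogene and _covers_exon(sv, gene):
        return SVAssessment(sv, "oncogene_copy_gain", gene.symbol)
    if _breakend_inside(sv, gene):
        return SVAssessment(sv, "breakpoint_disruption", gene.symbol)
    return SVAssessment(sv, "none")


def read_cnv_map_bed(path: str | Path) -> dict[str, IntervalTree]:
    """Load a common-CNV map from BED (0-based half-open)."""
    trees: dict[str, IntervalTree] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            trees.setdefault(contig, IntervalTree()).addi(start, end)
    for t in trees.values():
        t.merge_overlaps()
    return trees


def cnv_map_exclude(
    sv: SVCall,
    cnv_map: dict[str, IntervalTree],
    config: SvFilterConfig | None = None,
) -> bool:
    """True iff the SV's span is contained within a (merged) map region.

    Translocation spans are undefined across contigs and are never excluded.
    """
    cfg = config or SvFilterConfig()
    if sv.span0 is None:
        return False
    contig, s, e = sv.span0
    tree = cnv_map.get(contig)
    if tree is None:
        return False
    if cfg.cnv_containment:
        return any(iv.begin <= s and e <= iv.end for iv in tree.overlap(s, e))
    return bool(tree.overlap(s, e))


def _reciprocal_overlap(a: SVCall, b: SVCall) -> float:
    if a.span0 is None or b.span0 is None:
        return 0.0
    ca, sa, ea = a.span0
    cb, sb, eb = b.span0
    if ca != cb:
        return 0.0
    inter = min(ea, eb) - max(sa, sb)
    if inter <= 0:
        return 0.0
    return min(inter / (ea - sa), inter / (eb - sb))


def _same_event(a: SVCall, b: SVCall, threshold: float) -> bool:
    if a.sv_type != b.sv_type:
        return False
    if a.sv_type == "translocation":
        # breakend proximity (within 1 kb on both ends, same contig pair)
        (ca1, pa1), (ca2, pa2) = a.breakends
        (cb1, pb1), (cb2, pb2) = b.breakends
        return (
            ca1 == cb1 and ca2 == cb2
            and abs(pa1 - pb1) <= 1000 and abs(pa2 - pb2) <= 1000
        )
    return _reciprocal_overlap(a, b) >= threshold


def merge_caller_duplicates(
    svs: Sequence[SVCall], config: SvFilterConfig | None = None
) -> list[SVCall]:
    """Collapse same-individual, same-type calls reported by both callers
    for one event (>= 50% reciprocal overlap), keeping the higher-quality
    record. Deterministic regardless of input order."""
    cfg = config or SvFilterConfig()
    ordered = sorted(
        svs,
        key=lambda s: (-s.quality, s.caller, s.contig_a, s.start_a,
                       s.contig_b, s.end_b, s.individual_id),
    )
    kept: list[SVCall] = []
    for sv in ordered:
        if any(
            k.individual_id == sv.individual_id and _same_event(k, sv, cfg.reciprocal_overlap)
            for k in kept
        ):
            continue
        kept.append(sv)
    kept.sort(key=lambda s: (s.contig_a, s.start_a, s.contig_b, s.end_b,
                             s.individual_id, s.caller))
    return kept


def compute_cohort_frequency(
    sv: SVCall, reference_svs: Sequence[SVCall], n_reference: int,
    config: SvFilterConfig | None = None,
) -> float:
    """Fraction of a reference cohort carrying an equivalent call
    (same type, >= 50% reciprocal overlap / matched breakends)."""
    cfg = config or SvFilterConfig()
    if n_reference <= 0:
        raise ValueError("reference cohort size must be positive")
    carriers = {
        r.individual_id for r in reference_svs if _same_event(sv, r, cfg.reciprocal_overlap)
    }
    return len(carriers) / n_reference


@dataclass
class SvPipelineResult:
    assessments: list[SVAssessment]
    dispositions: list[tuple[SVCall, Disposition]]
    audit: dict[str, int]


def run_sv_pipeline(
    svs: Iterable[SVCall],
    panel: Panel,
    cnv_map: dict[str, IntervalTree] | None = None,
    config: SvFilterConfig | None = None,
    snv_second_hits: set[tuple[str, str]] | None = None,
) -> SvPipelineResult:
    """Merge, prefilter, categorize and CNV-map-screen a cohort's SV calls.

    ``snv_second_hits``: (individual_id, gene_symbol) pairs with a filtered
    small variant, supplying compound-heterozygosity evidence for
    recessive-only genes.
    """
    cfg = config or SvFilterConfig()
    cnv_map = cnv_map or {}
    merged = merge_caller_duplicates(list(svs), cfg)

    audit = {"input": len(merged), "prefilter_fail": 0,
             "category_none": 0, "cnv_map_excluded": 0, "assessed": 0}
    dispositions: list[tuple[SVCall, Disposition]] = []
    passed: list[SVCall] = []
    for sv in merged:
        d = sv_prefilter(sv, panel, cfg)
        dispositions.append((sv, d))
        if d.outcome is Outcome.FAIL:
            audit["prefilter_fail"] += 1
        else:
            passed.append(sv)

    # second-hit evidence: another passing SV or a filtered SNV in the gene
    sv_gene_hits: dict[tuple[str, str], int] = {}
    for sv in passed:
        for sym in _genes_hit(sv, panel):
            key = (sv.individual_id, sym)
            sv_gene_hits[key] = sv_gene_hits.get(key, 0) + (2 if sv.zygosity == "hom" else 1)
    second = set(snv_second_hits or set())

    assessments: list[SVAssessment] = []
    for sv in passed:
        genes = sorted(_genes_hit(sv, panel))
        best: list[SVAssessment] = []
        for sym in genes:
            gene = panel[sym]
            key = (sv.individual_id, sym)
            second_hit = key in second or sv_gene_hits.get(key, 0) >= 2
            a = sv_categorize(sv, gene, second_hit_in_gene=second_hit)
            if a.category != "none":
                best.append(a)
        if not best:
            audit["category_none"] += 1
            assessments.append(SVAssessment(sv, "none"))
            continue
        if cnv_map_exclude(sv, cnv_map, cfg):
            audit["cnv_map_excluded"] += 1
            for a in best:
                assessments.append(SVAssessment(sv, a.category, a.gene_symbol, True))
        else:
            audit["assessed"] += 1
            assessments.extend(best)
    assert audit["input"] == audit["prefilter_fail"] + audit["category_none"] + \
        audit["cnv_map_excluded"] + audit["assessed"]
    return SvPipelineResult(assessments=assessments, dispositions=dispositions, audit=audit)
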