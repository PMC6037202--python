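"""Small-variant record and filter-audit types."""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = ["ClinvarAssertion", "AnnotatedVariant", "Stage", "Outcome", "Disposition"]


class ClinvarAssertion(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    BENIGN = "benign"
    LIKELY_BENIGN = "likely_benign"
    UNCERTAIN = "uncertain"
    CONFLICTING = "conflicting"
    ABSENT = "absent"


#: assertions counted as "benign or uncertain" evidence when refuting
#: putative pathogenicity; "conflicting" maps here because a conflicted
#: record cannot support a P/LP claim.
BENIGN_OR_UNCERTAIN = {
    ClinvarAssertion.BENIGN,
    ClinvarAssertion.LIKELY_BENIGN,
    ClinvarAssertion.UNCERTAIN,
    ClinvarAssertion.CONFLICTING,
}

PATHOGENIC_OR_LIKELY = {
    ClinvarAssertion.PATHOGENIC,
    ClinvarAssertion.LIKELY_PATHOGENIC,
}


@dataclass(frozen=True)
class AnnotatedVariant:
    """One annotated small-variant call for one individual.

    Positions are 1-based (VCF convention). External-evidence annotations
    (population frequencies, ClinVar assertion/review level, HGMD DM flag,
    CADD score, truncated-transcript fraction) arrive on the record; this
    package never queries live databases.
    """

    contig: str
    position: int
    ref: str
    alt: str
    gene_symbol: str
    so_consequence: str
    individual_id: str
    zygosity: str = "het"  # "het" | "hom"
    gq: Optional[float] = None
    dp: Optional[int] = None
    alt_depth: Optional[int] = None
    filter_status: str = "PASS"
    af_exac: Optional[float] = None
    af_1kg: Optional[float] = None
    clinvar_assertion: ClinvarAssertion = ClinvarAssertion.ABSENT
    clinvar_stars: Optional[int] = None
    clinvar_submission_count: int = 0
    hgmd_dm: bool = False
    cadd_phred: Optional[float] = None
    truncation_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.zygosity not in ("het", "hom"):
            raise ValueError(f"zygosity must be het/hom, got {self.zygosity!r}")
        if self.dp is not None and self.alt_depth is not None:
            if not 0 <= self.alt_depth <= self.dp:
                raise ValueError(
                    f"alt_depth {self.alt_depth} outside [0, dp={self.dp}]"
                )
        if (self.clinvar_stars is not None) != (
            self.clinvar_assertion != ClinvarAssertion.ABSENT
        ):
            raise ValueError(
                "clinvar_stars must be present exactly when an assertion is"
            )
        if self.truncation_fraction is not None and not (
            0 <= self.truncation_fraction <= 1
        ):
            raise ValueError("truncation_fraction must be in [0, 1]")
        for name in ("af_exac", "af_1kg"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    @property
    def key(self) -> tuple:
        """Identity of a call: (individual, contig, pos, ref, alt)."""
        return (self.individual_id, self.contig, self.position, self.ref, self.alt)


class Stage(str, Enum):
    QUALITY = "quality"
    FREQUENCY = "frequency"
    RETENTION = "retention"
    NONCODING_LOOKUP = "noncoding_lookup"
    EXCLUSION = "exclusion"
    RETAINED_FOR_ASSESSMENT = "retained_for_assessment"


class Outcome(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    RETAINED = "retained"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class Disposition:
    """Auditable outcome of one filter stage for one variant."""

    stage: Stage
    outcome: Outcome
    reason_codes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.outcome in (Outcome.FAIL, Outcome.EXCLUDED, Outcome.RETAINED):
            if not self.reason_codes:
                raise ValueError(
                    f"{self.outcome.value} disposition requires reason codes"
                )
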