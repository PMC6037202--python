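"""ACMG/AMP evidence combination into the five-tier classification.

Evidence codes carry their strength in the identifier prefix: PVS (very
strong), PS (strong), PM (moderate), PP (supporting) on the pathogenic
side; BA (stand-alone), BS (strong), BP (supporting) on the benign side.
The published combining rules map counts per strength class to a tier;
when both a pathogenic-side and a benign-side rule fire, the evidence is
contradictory and the variant is classified as uncertain.

Code *assignment* (deciding that a given variant merits PS3 rather than
PM2) is curator work and out of scope; an optional, clearly-heuristic
pre-populator derives PVS1/PM2/PP3 from record annotations for convenience.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .variants import AnnotatedVariant, ClinvarAssertion

__all__ = [
    "VALID_CODES",
    "EvidenceSet",
    "Classification",
    "combine_acmg",
    "prepopulate_evidence",
    "tally_classifications",
    "TallySummary",
]

VALID_CODES = frozenset(
    ["PVS1"]
    + [f"PS{i}" for i in range(1, 5)]
    + [f"PM{i}" for i in range(1, 7)]
    + [f"PP{i}" for i in range(1, 6)]
    + ["BA1"]
    + [f"BS{i}" for i in range(1, 5)]
    + [f"BP{i}" for i in range(1, 8)]
)

_STRENGTH_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)\d+$")

TIERS = ("pathogenic", "likely_pathogenic", "uncertain", "likely_benign", "benign")


def strength_class(code: str) -> str:
    m = _STRENGTH_RE.match(code)
    if not m or code not in VALID_CODES:
        raise ValueError(f"unknown ACMG evidence code {code!r}")
    return m.group(1)


@dataclass(frozen=True)
class EvidenceSet:
    codes: frozenset[str]

    def __post_init__(self) -> None:
        for c in self.codes:
            strength_class(c)  # raises on unknown codes

    @classmethod
    def of(cls, *codes: str) -> "EvidenceSet":
        return cls(frozenset(codes))

    def counts(self) -> Counter:
        return Counter(strength_class(c) for c in self.codes)


@dataclass(frozen=True)
class Classification:
    tier: str

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")

    @property
    def is_plp(self) -> bool:
        return self.tier in ("pathogenic", "likely_pathogenic")


def _pathogenic(n: Counter, has_pvs1: bool) -> bool:
    pvs, ps, pm, pp = n["PVS"], n["PS"], n["PM"], n["PP"]
    if has_pvs1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2):
        return True
    if ps >= 2:
        return True
    if ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)):
        return True
    return False


def _likely_pathogenic(n: Counter, has_pvs1: bool) -> bool:
    ps, pm, pp = n["PS"], n["PM"], n["PP"]
    if has_pvs1 and pm == 1:
        return True
    if ps == 1 and 1 <= pm <= 2:
        return True
    if ps == 1 and pp >= 2:
        return True
    if pm >= 3:
        return True
    if pm == 2 and pp >= 2:
        return True
    if pm == 1 and pp >= 4:
        return True
    return False


def _benign(n: Counter, has_ba1: bool) -> bool:
    return has_ba1 or n["BS"] >= 2


def _likely_benign(n: Counter) -> bool:
    return (n["BS"] == 1 and n["BP"] == 1) or n["BP"] >= 2


def combine_acmg(ev: EvidenceSet) -> Classification:
    """Apply the published combining table to an evidence set.

    Conflicting evidence (any pathogenic-side rule and any benign-side
    rule both satisfied) yields ``uncertain``.
    """
    n = ev.counts()
    has_pvs1 = "PVS1" in ev.codes
    has_ba1 = "BA1" in ev.codes
    path_side = _pathogenic(n, has_pvs1) or _likely_pathogenic(n, has_pvs1)
    benign_side = _benign(n, has_ba1) or _likely_benign(n)
    if path_side and benign_side:
        return Classification("uncertain")
    if _pathogenic(n, has_pvs1):
        return Classification("pathogenic")
    if _likely_pathogenic(n, has_pvs1):
        return Classification("likely_pathogenic")
    if _benign(n, has_ba1):
        return Classification("benign")
    if _likely_benign(n):
        return Classification("likely_benign")
    return Classification("uncertain")


def prepopulate_evidence(
    v: AnnotatedVariant,
    lof_gene: bool,
    truncating_terms: Iterable[str],
    cadd_threshold: float = 34.0,
) -> EvidenceSet:
    """Heuristic convenience pre-populator (disable by not calling it).

    PVS1 for a truncating consequence in a loss-of-function gene; PM2 for
    absence from reference populations; PP3 for a CADD score at/above the
    retention threshold. Curator-assigned codes should replace this in any
    real assessment.
    """
    codes = set()
    if lof_gene and v.so_consequence in set(truncating_terms):
        codes.add("PVS1")
    if (v.af_exac or 0.0) == 0.0 and (v.af_1kg or 0.0) == 0.0:
        codes.add("PM2")
    if v.cadd_phred is not None and v.cadd_phred >= cadd_threshold:
        codes.add("PP3")
    return EvidenceSet(frozenset(codes))


@dataclass
class TallySummary:
    """Cohort-level classification tallies.

    ``unique_by_tier`` counts distinct (contig, pos, ref, alt, gene)
    variants; ``occurrences_by_tier`` counts variant-individual pairs.
    ``plp_probands`` are family-deduplicated: when a P/LP variant occurs in
    two members of the same family, only the proband (or the first member)
    contributes to detection rates.
    """

    unique_by_tier: dict[str, int] = field(default_factory=dict)
    occurrences_by_tier: dict[str, int] = field(default_factory=dict)
    unique_by_gene: dict[str, int] = field(default_factory=dict)
    plp_probands: set[str] = field(default_factory=set)

    @property
    def total_unique(self) -> int:
        return sum(self.unique_by_tier.values())

    @property
    def total_occurrences(self) -> int:
        return sum(self.occurrences_by_tier.values())


def tally_classifications(
    classified: Sequence[tuple[AnnotatedVariant, Classification]],
    family_of: Mapping[str, str] | None = None,
    proband_flags: Mapping[str, bool] | None = None,
) -> TallySummary:
    """Tally unique variants and occurrences per tier and per gene.

    ``family_of`` maps individual_id -> family_id; within one family only
    one carrier of a given P/LP variant counts toward proband detection.
    """
    family_of = family_of or {}
    proband_flags = proband_flags or {}
    summary = TallySummary(
        unique_by_tier={t: 0 for t in TIERS},
        occurrences_by_tier={t: 0 for t in TIERS},
    )
    by_variant: dict[tuple, list[tuple[AnnotatedVariant, Classification]]] = {}
    for v, c in classified:
        vkey = (v.contig, v.position, v.ref, v.alt, v.gene_symbol)
        by_variant.setdefault(vkey, []).append((v, c))

    for vkey, items in sorted(by_variant.items()):
        tier = items[0][1].tier
        if any(c.tier != tier for _, c in items):
            raise ValueError(f"inconsistent tiers for variant {vkey}")
        summary.unique_by_tier[tier] += 1
        summary.occurrences_by_tier[tier] += len(items)
        gene = vkey[4]
        summary.unique_by_gene[gene] = summary.unique_by_gene.get(gene, 0) + 1
        if tier in ("pathogenic", "likely_pathogenic"):
            seen_families: set[str] = set()
            # prefer probands as the family representative
            carriers = sorted(
                items,
                key=lambda vc: (not proband_flags.get(vc[0].individual_id, True),
                                vc[0].individual_id),
            )
            for v, _ in carriers:
                fam = family_of.get(v.individual_id, v.individual_id)
                if fam in seen_families:
                    continue
                seen_families.add(fam)
                summary.plp_probands.add(v.individual_id)
    return summary
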