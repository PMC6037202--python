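"""Cohort-level statistics for a multiple-primary-tumor (MPT) series.

Covers: enumeration of discordant tumor-category combinations and their
type distribution; comparison of combination frequencies against a cancer
registry (uncorrected Pearson chi-square on 2x2 tables); sex-adjusted
carrier-frequency comparison against a reference population; diagnostic
yield projection when stacking comprehensive testing on top of routine
targeted testing; and coverage summaries over BED-defined regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .panel import Individual

__all__ = [
    "CombinationRecord",
    "ContingencyResult",
    "ReferencePopulationCounts",
    "enumerate_combinations",
    "combination_distribution",
    "pearson_chi2",
    "registry_comparison",
    "sex_adjusted_frequency",
    "yield_projection",
    "detection_rates",
    "coverage_summary",
    "round_percent",
]


def round_percent(fraction: float, decimals: int = 1) -> float:
    """Percentage with half-up rounding to ``decimals`` places, matching
    conventional reporting (67/440 -> 15.2)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CombinationRecord:
    """An unordered pair of distinct tumor categories in one individual."""

    pair: tuple[str, str]
    individual_id: str

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError("a combination requires two discordant categories")
        if a > b:
            object.__setattr__(self, "pair", (b, a))


@dataclass(frozen=True)
class ContingencyResult:
    statistic: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.statistic < 0 or self.df < 1 or not 0 <= self.p_value <= 1:
            raise ValueError("invalid contingency result")


@dataclass(frozen=True)
class ReferencePopulationCounts:
    """Aggregate carrier counts of qualifying variants, split by sex."""

    n_male: int
    n_female: int
    carriers_male: int
    carriers_female: int

    def __post_init__(self) -> None:
        if self.carriers_male > self.n_male or self.carriers_female > self.n_female:
            raise ValueError("carriers cannot exceed population size")
        if min(self.n_male, self.n_female, self.carriers_male, self.carriers_female) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def freq_male(self) -> float:
        return self.carriers_male / self.n_male

    @property
    def freq_female(self) -> float:
        return self.carriers_female / self.n_female


def enumerate_combinations(individual: Individual) -> list[CombinationRecord]:
    """All unordered pairs over the individual's *distinct* tumor
    categories; same-category repeats (e.g. bilateral breast cancer)
    contribute no pair."""
    cats = sorted(individual.tumor_categories)
    return [
        CombinationRecord(pair=(a, b), individual_id=individual.individual_id)
        for a, b in combinations(cats, 2)
    ]


def combination_distribution(
    cohort: Iterable[Individual],
) -> dict:
    """Per-type combination counts and the once/twice/3+ breakdown.

    Returns a dict with: ``combinations`` (total count), ``type_counts``
    (per pair), ``n_types``, ``type_frequency_breakdown`` with counts and
    half-up percentages of types occurring once / twice / three or more
    times, and ``share_of_combinations`` (each type's percentage of all
    combinations).
    """
    records = [c for ind in cohort for c in enumerate_combinations(ind)]
    type_counts: dict[tuple[str, str], int] = {}
    for rec in records:
        type_counts[rec.pair] = type_counts.get(rec.pair, 0) + 1
    n_types = len(type_counts)
    once = sum(1 for c in type_counts.values() if c == 1)
    twice = sum(1 for c in type_counts.values() if c == 2)
    thrice_plus = n_types - once - twice
    total = len(records)
    return {
        "combinations": total,
        "n_types": n_types,
        "type_counts": dict(sorted(type_counts.items())),
        "type_frequency_breakdown": {
            "once": once,
            "twice": twice,
            "three_or_more": thrice_plus,
            "once_pct": round_percent(once / n_types) if n_types else 0.0,
            "twice_pct": round_percent(twice / n_types) if n_types else 0.0,
            "three_or_more_pct": round_percent(thrice_plus / n_types) if n_types else 0.0,
        },
        "share_of_combinations": {
            pair: round_percent(c / total) for pair, c in sorted(type_counts.items())
        } if total else {},
    }


def pearson_chi2(table: Sequence[Sequence[float]]) -> ContingencyResult:
    """Uncorrected Pearson chi-square on a 2x2 table.

    statistic = N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)], df = 1, upper-tail
    p-value. No Yates continuity correction is applied: the uncorrected
    statistic is what standard R ``chisq.test(..., correct = FALSE)``
    computes and what 2x2 burden comparisons in this package report.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("pearson_chi2 expects a 2x2 table")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    a, b = t[0]
    c, d = t[1]
    n = t.sum()
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("all row and column margins must be positive")
    stat = n * (a * d - b * c) ** 2 / margins
    p = float(chi2_dist.sf(stat, 1))
    return ContingencyResult(statistic=float(stat), df=1, p_value=p)


def registry_comparison(
    cohort: Sequence[Individual],
    registry_counts: Mapping[tuple[str, str], int],
    vocabulary: Mapping[str, Mapping[str, bool]],
    age_limit: float = 60.0,
    min_share: float = 0.01,
    alpha: float = 0.05,
) -> list[dict]:
    """Compare MPT combination-type frequencies with registry counts.

    The registry records individuals with two malignant (or CNS) tumor
    diagnoses before ``age_limit``; the MPT cohort is restricted the same
    way (malignancy/CNS flags from the controlled vocabulary) before
    comparison. Each combination type representing more than ``min_share``
    of the restricted MPT combinations is tested type-vs-rest on a 2x2
    table with an uncorrected chi-square.
    """
    def qualifies(category: str) -> bool:
        meta = vocabulary.get(category)
        if meta is None:
            raise ValueError(f"tumor category {category!r} not in vocabulary")
        return bool(meta["malignant"] or meta["cns"])

    mpt_counts: dict[tuple[str, str], int] = {}
    total_mpt = 0
    for ind in cohort:
        kept = [t for t in ind.tumors
                if qualifies(t.category) and t.age_at_diagnosis < age_limit]
        restricted = Individual(
            individual_id=ind.individual_id, family_id=ind.family_id,
            sex=ind.sex, tumors=tuple(kept), is_proband=ind.is_proband,
        )
        for rec in enumerate_combinations(restricted):
            mpt_counts[rec.pair] = mpt_counts.get(rec.pair, 0) + 1
            total_mpt += 1
    if total_mpt == 0:
        raise ValueError("MPT cohort empty after registry-style restriction")
    total_reg = sum(registry_counts.values())
    if total_reg == 0:
        raise ValueError("registry dataset is empty")

    results = []
    for pair, count in sorted(mpt_counts.items()):
        if count / total_mpt <= min_share:
            continue
        reg = registry_counts.get(pair, 0)
        table = [[count, total_mpt - count], [reg, total_reg - reg]]
        res = pearson_chi2(table)
        results.append({
            "pair": pair,
            "mpt_count": count,
            "mpt_total": total_mpt,
            "registry_count": reg,
            "registry_total": total_reg,
            "chi2": res.statistic,
            "p_value": res.p_value,
            "significant": res.p_value < alpha,
        })
    return results


def sex_adjusted_frequency(
    ref: ReferencePopulationCounts, target_prop_female: float
) -> float:
    """Reference-population carrier frequency re-weighted to a target sex
    distribution.

    The female count is held fixed and the male count shrunk to
    ``n_female * (1 - p) / p`` so that females make up proportion ``p``;
    the per-sex carrier frequencies are then averaged with those weights.
    The adjusted male count is kept as a real number (never rounded).
    """
    if not 0 < target_prop_female < 1:
        raise ValueError("target_prop_female must be in (0, 1)")
    if ref.n_male == 0 or ref.n_female == 0:
        raise ValueError("both sexes must be represented in the reference")
    n_female = ref.n_female
    n_male_adj = n_female * (1 - target_prop_female) / target_prop_female
    return (ref.freq_male * n_male_adj + ref.freq_female * n_female) / (
        n_male_adj + n_female
    )


def yield_projection(prior_rate: float, incremental_rate: float) -> float:
    """Diagnostic yield of comprehensive testing stacked on routine
    targeted testing: prior + (1 - prior) * incremental."""
    for r in (prior_rate, incremental_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must be in [0, 1]")
    return prior_rate + (1 - prior_rate) * incremental_rate


def detection_rates(
    numerators: Mapping[str, int], denominator: int
) -> dict[str, dict]:
    """Detection-rate table keeping exact fractions alongside the half-up
    one-decimal percentage (e.g. 67/440 -> 15.2)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return {
        name: {
            "numerator": k,
            "denominator": denominator,
            "fraction": k / denominator,
            "percent": round_percent(k / denominator),
        }
        for name, k in numerators.items()
    }


def coverage_summary(
    depths: Sequence[float] | np.ndarray, threshold: float = 10
) -> tuple[float, float]:
    """(mean depth, fraction of bases at or above ``threshold``) over a
    BED-defined base set."""
    arr = np.asarray(depths, dtype=float)
    if arr.size == 0:
        raise ValueError("empty region set")
    return float(arr.mean()), float((arr >= threshold).mean())
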