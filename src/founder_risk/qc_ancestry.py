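"""Sample-level, variant-level, relatedness and ancestry-fraction filters.

These mirror the QC stage of a founder-population exome study: samples are
dropped for contamination-like metrics, variants for call rate and allele
balance, related pairs are pruned to an unrelated set, and model-based
ancestry fractions (an ADMIXTURE Q-matrix) are turned into hard population
assignments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SampleMetrics",
    "AncestryFractions",
    "QCThresholds",
    "assign_ancestry",
    "flag_high_ancestry",
    "sample_qc_filter",
    "variant_qc_filter",
    "relatedness_prune",
]


@dataclass(frozen=True)
class SampleMetrics:
    """Per-sample QC metrics as produced by a joint-calling pipeline."""

    sample_id: str
    het_hom_ratio: float
    n_singletons: int
    del_ins_ratio: float
    mean_gq: float
    call_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.het_hom_ratio < 0 or self.del_ins_ratio < 0:
            raise ValueError(f"{self.sample_id}: ratios must be >= 0")
        if not 0 <= self.call_rate <= 1:
            raise ValueError(f"{self.sample_id}: call_rate must be in [0,1]")


@dataclass(frozen=True)
class AncestryFractions:
    """One sample's K ancestry fractions (rows of a Q-matrix)."""

    sample_id: str
    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.fractions) < 2:
            raise ValueError("need K >= 2 ancestry components")
        if any(f < 0 for f in self.fractions):
            raise ValueError(f"{self.sample_id}: fractions must be non-negative")
        if abs(sum(self.fractions) - 1.0) > 1e-6:
            raise ValueError(f"{self.sample_id}: fractions must sum to 1")


@dataclass(frozen=True)
class QCThresholds:
    """Default sample/variant exclusion thresholds.

    A sample is excluded for het/hom ratio below ``min_het_hom`` (possible
    contamination), more than ``max_singletons`` singletons, deletion/
    insertion ratio above ``max_del_ins``, or mean genotype quality below
    ``min_mean_gq``. Variants are excluded for call rate below
    ``min_call_rate`` or heterozygote allele balance outside 70:30 in more
    than ``max_ab_dev_fraction`` of heterozygous samples, provided at least
    ``min_het_for_ab`` heterozygotes were seen.
    """

    min_het_hom: float = 1.0
    max_singletons: int = 2000
    max_del_ins: float = 1.5
    min_mean_gq: float = 40.0
    min_call_rate: float = 0.8
    max_ab_dev_fraction: float = 0.4
    min_het_for_ab: int = 7
    relatedness_cutoff: float = 0.35


def assign_ancestry(
    fractions: AncestryFractions,
    threshold: float = 0.4,
    labels: tuple[str, ...] | None = None,
) -> str:
    """Hard ancestry call from model-based fractions.

    Returns label k iff fraction_k >= threshold and every other fraction is
    strictly below the threshold; otherwise "admixed". With the default 0.4
    this is the standard single-dominant-component rule.
    """
    fr = fractions.fractions
    if labels is None:
        labels = tuple(f"group{i + 1}" for i in range(len(fr)))
    at_or_above = [i for i, f in enumerate(fr) if f >= threshold]
    if len(at_or_above) == 1:
        return labels[at_or_above[0]]
    return "admixed"


def flag_high_ancestry(
    fractions: AncestryFractions,
    target_index: int,
    threshold: float = 0.9,
) -> bool:
    """True iff the target component's fraction strictly exceeds ``threshold``.

    Used to restrict frequency estimation to samples with near-unadmixed
    ancestry (> 0.9 by default).
    """
    if not 0 <= target_index < len(fractions.fractions):
        raise ValueError(f"unknown ancestry group index {target_index}")
    return fractions.fractions[target_index] > threshold


def sample_qc_filter(
    metrics: list[SampleMetrics],
    thresholds: QCThresholds | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Apply the sample-level filters; returns (kept_ids, failures).

    ``failures`` maps each excluded sample to the list of rules it failed.
    """
    t = thresholds or QCThresholds()
    kept: list[str] = []
    failures: dict[str, list[str]] = {}
    for m in metrics:
        reasons = []
        if m.het_hom_ratio < t.min_het_hom:
            reasons.append(f"het_hom_ratio<{t.min_het_hom:g}")
        if m.n_singletons > t.max_singletons:
            reasons.append(f"n_singletons>{t.max_singletons}")
        if m.del_ins_ratio > t.max_del_ins:
            reasons.append(f"del_ins_ratio>{t.max_del_ins:g}")
        if m.mean_gq < t.min_mean_gq:
            reasons.append(f"mean_gq<{t.min_mean_gq:g}")
        if reasons:
            failures[m.sample_id] = reasons
        else:
            kept.append(m.sample_id)
    return kept, failures


def variant_qc_filter(
    table: pd.DataFrame,
    thresholds: QCThresholds | None = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Variant-level call-rate and allele-balance filters.

    ``table`` columns: variant, call_rate, n_het, n_ab_deviating — where
    n_ab_deviating counts heterozygous samples whose ALT read fraction falls
    outside [0.3, 0.7] (boundary values pass). The allele-balance rule only
    activates once at least ``min_het_for_ab`` heterozygotes are observed.
    """
    t = thresholds or QCThresholds()
    kept: list[str] = []
    failures: dict[str, list[str]] = {}
    for row in table.itertuples(index=False):
        if row.n_ab_deviating > row.n_het:
            raise ValueError(f"{row.variant}: deviating count exceeds het count")
        reasons = []
        if row.call_rate < t.min_call_rate:
            reasons.append(f"call_rate<{t.min_call_rate:g}")
        if row.n_het >= t.min_het_for_ab and row.n_ab_deviating / row.n_het > t.max_ab_dev_fraction:
            reasons.append(f"allele_balance_dev>{t.max_ab_dev_fraction:g}")
        if reasons:
            failures[str(row.variant)] = reasons
        else:
            kept.append(str(row.variant))
    return kept, failures


def relatedness_prune(
    pairs: list[tuple[str, str, float]],
    cutoff: float = 0.35,
    call_rates: dict[str, float] | None = None,
) -> set[str]:
    """Greedy pruning of related sample pairs above ``cutoff``.

    Repeatedly removes the sample participating in the most above-cutoff
    pairs; ties are broken by lower call rate, then lexicographically by
    sample id. The returned exclusion set leaves no remaining pair above the
    cutoff. On small graphs the greedy solution coincides with a minimum
    vertex cover.
    """
    call_rates = call_rates or {}
    edges = {
        frozenset((a, b)) for a, b, r in pairs
        if r > cutoff and a != b
    }
    excluded: set[str] = set()
    while edges:
        degree: dict[str, int] = {}
        for e in edges:
            for s in e:
                degree[s] = degree.get(s, 0) + 1
        # max degree, then lowest call rate, then lexicographic id
        victim = min(
            degree,
            key=lambda s: (-degree[s], call_rates.get(s, 1.0), s),
        )
        excluded.add(victim)
        edges = {e for e in edges if victim not in e}
    return excluded
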