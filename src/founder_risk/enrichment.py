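"""Founder-population allele-enrichment scoring and classification.

For each variant the study population's allele counts are compared against
the reference population (among those with adequate coverage and frequency)
in which the allele is most common. The comparison uses a Haldane-Anscombe
bias-corrected log odds ratio (0.5 added to each cell of the 2x2 allele
table) with its Woolf standard error, and a one-sided Fisher exact test
("greater": is the alternate allele over-represented in the study
population?). A variant is classified *enriched* when its study-population
frequency lies in the analysis window [0.002, 0.1) and the one-sided p-value
clears a Bonferroni threshold alpha / n_tests, where n_tests defaults to the
number of in-window variants in the supplied data.

Under Hardy-Weinberg equilibrium an x-fold allele-frequency enrichment
translates into an x^2-fold enrichment of homozygote frequency, hence of
genetic risk for a recessive condition (:func:`recessive_risk_enrichment`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model_io import ValidationError, VariantKey, VariantRecord

__all__ = [
    "EnrichmentResult",
    "bias_corrected_log_or",
    "fisher_one_sided",
    "classify_enrichment",
    "annotation_class_proportions",
    "intersect_pathogenic",
    "recessive_risk_enrichment",
    "AF_WINDOW",
    "MIN_REF_FREQUENCY",
]

#: Study-population allele-frequency window [low, high) for enrichment testing.
AF_WINDOW = (0.002, 0.1)

#: Minimum reference-population frequency for a reference to be eligible.
MIN_REF_FREQUENCY = 1e-4


@dataclass
class EnrichmentResult:
    """Bias-corrected enrichment statistics for one variant."""

    key: VariantKey
    annotation: str
    reference_pop: str | None
    study_af: float
    max_ref_af: float
    beta_hat: float
    se: float
    p_one_sided: float
    in_window: bool
    enriched: bool

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta_hat)

    def to_row(self) -> dict:
        return {
            "variant": str(self.key),
            "annotation": self.annotation,
            "enrichment_odds_ratio": self.odds_ratio,
            "study_af": self.study_af,
            "max_ref_af": self.max_ref_af,
            "reference_pop": self.reference_pop,
            "beta": self.beta_hat,
            "se": self.se,
            "p": self.p_one_sided,
            "in_window": self.in_window,
            "enriched": self.enriched,
        }


def _check_counts(*counts: int) -> None:
    for c in counts:
        if c < 0:
            raise ValidationError(f"allele counts must be non-negative, got {c}")


def bias_corrected_log_or(
    alt_study: int, ref_study: int, alt_ref: int, ref_ref: int
) -> tuple[float, float]:
    """Haldane-Anscombe corrected log odds ratio and Woolf SE for a 2x2 table.

    beta = ln[((0.5+alt_study)(0.5+ref_ref)) / ((0.5+ref_study)(0.5+alt_ref))]
    se   = sqrt(sum of 1/(0.5+cell)) over the four cells.

    The 0.5 correction keeps both finite for any non-negative integer counts.
    """
    _check_counts(alt_study, ref_study, alt_ref, ref_ref)
    a, b, c, d = (0.5 + alt_study, 0.5 + ref_study, 0.5 + alt_ref, 0.5 + ref_ref)
    beta = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return beta, se


def fisher_one_sided(
    alt_study: int, ref_study: int, alt_ref: int, ref_ref: int
) -> float:
    """One-sided ("greater") Fisher exact p for ALT over-representation.

    Equals the upper hypergeometric tail P(X >= alt_study) conditional on the
    table margins.
    """
    _check_counts(alt_study, ref_study, alt_ref, ref_ref)
    table = [[alt_study, ref_study], [alt_ref, ref_ref]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def _select_reference(
    record: VariantRecord, reference_pops: list[str]
) -> str | None:
    """Pick the eligible reference population with the highest ALT frequency.

    Eligibility: coverage flag passes (absent flag counts as passing) and
    frequency >= MIN_REF_FREQUENCY. Ties on frequency break to larger AN,
    then lexicographic label.
    """
    candidates = []
    for pop in reference_pops:
        if pop not in record.counts:
            continue
        if not record.coverage_ok.get(pop, True):
            continue
        pc = record.counts[pop]
        if pc.frequency < MIN_REF_FREQUENCY:
            continue
        candidates.append((pc.frequency, pc.total_alleles, pop))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return candidates[0][2]


def classify_enrichment(
    records: list[VariantRecord],
    study_pop: str,
    reference_pops: list[str],
    af_window: tuple[float, float] = AF_WINDOW,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> list[EnrichmentResult]:
    """Score every variant and classify enrichment at alpha / n_tests.

    ``n_tests`` defaults to the number of variants in the study-AF window
    with an eligible reference population (the Bonferroni denominator is
    data-size dependent); pass the constant explicitly to reproduce an
    external analysis.
    """
    lo, hi = af_window
    prelim = []
    for rec in records:
        if study_pop not in rec.counts:
            raise ValidationError(f"{rec.key}: no counts for study population {study_pop!r}")
        sc = rec.counts[study_pop]
        ref_pop = _select_reference(rec, reference_pops)
        in_window = lo <= sc.frequency < hi
        prelim.append((rec, sc, ref_pop, in_window))

    if n_tests is None:
        # Bonferroni denominator: testable in-window variants
        n_tests = sum(1 for _, _, ref, in_w in prelim if in_w and ref is not None)
    threshold = alpha / n_tests if n_tests > 0 else 0.0

    results = []
    for rec, sc, ref_pop, in_window in prelim:
        if ref_pop is None:
            # unclassifiable: no eligible reference population
            results.append(EnrichmentResult(
                key=rec.key, annotation=rec.annotation, reference_pop=None,
                study_af=sc.frequency, max_ref_af=float("nan"),
                beta_hat=float("nan"), se=float("nan"), p_one_sided=float("nan"),
                in_window=in_window, enriched=False,
            ))
            continue
        rc = rec.counts[ref_pop]
        beta, se = bias_corrected_log_or(
            sc.alt_count, sc.ref_count, rc.alt_count, rc.ref_count
        )
        p = fisher_one_sided(sc.alt_count, sc.ref_count, rc.alt_count, rc.ref_count)
        results.append(EnrichmentResult(
            key=rec.key, annotation=rec.annotation, reference_pop=ref_pop,
            study_af=sc.frequency, max_ref_af=rc.frequency,
            beta_hat=beta, se=se, p_one_sided=p,
            in_window=in_window, enriched=in_window and p < threshold,
        ))
    return results


def two_proportion_test(k1: int, n1: int, k2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z test; returns (z, two-sided p)."""
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    denom = math.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if denom == 0:
        return 0.0, 1.0
    z = (p1 - p2) / denom
    return z, 2 * stats.norm.sf(abs(z))


def annotation_class_proportions(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Per-annotation-class enriched fractions, each compared to SYN.

    Returns one row per class (ALL plus each observed class) with the
    in-window count, enriched count and fraction; non-synonymous classes
    carry a pooled two-proportion z and p against the synonymous class
    (the neutral baseline).
    """
    in_window = [r for r in results if r.in_window]
    by_class: dict[str, list[EnrichmentResult]] = {}
    for r in in_window:
        by_class.setdefault(r.annotation, []).append(r)

    def summarize(label, rs):
        n = len(rs)
        k = sum(r.enriched for r in rs)
        return {"class": label, "n_in_window": n, "n_enriched": k,
                "fraction_enriched": k / n if n else float("nan")}

    rows = [summarize("ALL", in_window)]
    syn = by_class.get("SYN", [])
    for label in sorted(by_class):
        rows.append(summarize(label, by_class[label]))
    frame = pd.DataFrame(rows)
    frame["z_vs_syn"] = np.nan
    frame["p_vs_syn"] = np.nan
    if syn:
        k2, n2 = sum(r.enriched for r in syn), len(syn)
        for i, row in frame.iterrows():
            if row["class"] in ("SYN", "ALL") or row["n_in_window"] == 0:
                continue
            z, p = two_proportion_test(
                int(row["n_enriched"]), int(row["n_in_window"]), k2, n2
            )
            frame.loc[i, ["z_vs_syn", "p_vs_syn"]] = z, p
    return frame


def intersect_pathogenic(
    results: list[EnrichmentResult],
    pathogenic: pd.DataFrame,
    p_cut: float = 0.005,
) -> list[EnrichmentResult]:
    """Variants matching a pathogenic, non-conflicted table row with p < p_cut.

    ``pathogenic`` columns: chrom, pos, ref, alt, clinical_significance,
    conflicted. A row is pathogenic if its significance contains Pathogenic
    or Likely Pathogenic; rows flagged conflicted (also an assertion of
    Benign/Likely Benign) are excluded from matching. The table must be
    unique on chrom,pos,ref,alt.
    """
    keys = pathogenic.apply(
        lambda r: f"{r['chrom']}:{int(r['pos'])}:{r['ref']}:{r['alt']}", axis=1
    ) if len(pathogenic) else pd.Series(dtype=str)
    if keys.duplicated().any():
        dup = keys[keys.duplicated()].iloc[0]
        raise ValidationError(
            f"pathogenic table has duplicate key {dup}; de-duplicate on chrom,pos,ref,alt first"
        )
    eligible = set()
    for i, row in pathogenic.iterrows():
        sig = str(row.get("clinical_significance", ""))
        is_path = "Pathogenic" in sig or "Likely Pathogenic" in sig.replace("_", " ")
        conflicted = bool(row.get("conflicted", False))
        if is_path and not conflicted:
            eligible.add(keys.loc[i])
    return [
        r for r in results
        if str(r.key) in eligible and not math.isnan(r.p_one_sided) and r.p_one_sided < p_cut
    ]


def recessive_risk_enrichment(fold_enrichment: float) -> float:
    """Homozygote-frequency (hence recessive-risk) enrichment under HWE.

    An allele x-fold more frequent in the study population is x^2-fold more
    frequent as a homozygous genotype (f^2 vs (f/x)^2), so a 19-fold allele
    enrichment implies a 361-fold recessive-risk enrichment.
    """
    if not fold_enrichment > 0:
        raise ValidationError(f"fold enrichment must be positive, got {fold_enrichment}")
    return fold_enrichment ** 2


def mean_fold_enrichment(
    results: list[EnrichmentResult], geometric: bool = False
) -> float:
    """Mean odds ratio over the enriched set (arithmetic by default)."""
    ors = [r.odds_ratio for r in results if r.enriched]
    if not ors:
        return float("nan")
    if geometric:
        return float(np.exp(np.mean(np.log(ors))))
    return float(np.mean(ors))
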