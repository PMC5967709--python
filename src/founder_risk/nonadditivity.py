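"""Composite-carrier (1-hit / 2-hit) modelling and additivity testing.

Within a gene's risk-allele set, samples are classed by how many risk
alleles they carry: 0, exactly 1, or 2+ ("composite carriers" — compound
heterozygotes or homozygotes). Under log-additivity the 2-hit odds ratio
should equal the square of the 1-hit odds ratio; a 2-hit effect exceeding
that prediction is deviation from additivity, which NOD2 famously shows for
Crohn's disease. Between two genes the analogous question is whether a
carrier-by-carrier interaction term is needed on the log-odds scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association_meta import firth_logistic
from .data_model_io import GenotypeMatrix, ValidationError, VariantKey

__all__ = [
    "HitModelResult",
    "composite_carrier_coding",
    "hit_model_fit",
    "additivity_deviation_test",
]


@dataclass
class HitModelResult:
    """2x2-derived odds ratios per hit class with Woolf confidence intervals."""

    or_1hit: float
    ci_1hit: tuple[float, float]
    or_2hit: float | None
    ci_2hit: tuple[float, float] | None
    deviation_p: float | None
    haldane_applied: bool = False

    @property
    def additive_prediction(self) -> float:
        """2-hit OR implied by log-additivity: or_1hit squared."""
        return self.or_1hit ** 2

    @property
    def deviation_or(self) -> float | None:
        """Observed 2-hit OR over the additive prediction."""
        if self.or_2hit is None:
            return None
        return self.or_2hit / self.additive_prediction


def composite_carrier_coding(
    matrix: GenotypeMatrix,
    variant_set: list[VariantKey],
    carriers_only: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample hit class over a variant set; returns (classes, flagged).

    The hit count is the total risk-allele dosage across the set, rounded;
    class 2 stands for "2 or more" — a homozygote for a single variant
    counts as two hits (set ``carriers_only=True`` to cap each variant's
    contribution at 1 instead). Samples with missing genotypes in the set
    are classed on their observed variants and flagged.
    """
    cols = []
    for key in variant_set:
        if key not in matrix:
            raise ValidationError(f"variant {key} not in matrix")
        cols.append(matrix.column(key))
    G = np.column_stack(cols)
    flagged = np.isnan(G).any(axis=1)
    G = np.nan_to_num(G, nan=0.0)
    if carriers_only:
        G = np.minimum(np.round(G), 1.0)
    hits = np.round(G.sum(axis=1))
    classes = np.minimum(hits, 2).astype(int)
    return classes, flagged


def _odds_ratio_ci(a: float, b: float, c: float, d: float) -> tuple[float, tuple[float, float], bool]:
    """OR of (a/b)/(c/d) with Woolf 95% CI; Haldane 0.5 on zero cells."""
    haldane = min(a, b, c, d) == 0
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = math.exp(math.log(or_) - 1.96 * se)
    hi = math.exp(math.log(or_) + 1.96 * se)
    return or_, (lo, hi), haldane


def hit_model_fit(
    classes: np.ndarray,
    phenotype: np.ndarray,
) -> HitModelResult:
    """Raw 2x2 odds ratios of the 1-hit and 2+-hit classes against 0-hit.

    The additivity deviation p comes from :func:`additivity_deviation_test`
    on the same coding. If no 2+ carriers exist the 2-hit fields are None.
    """
    classes = np.asarray(classes)
    phenotype = np.asarray(phenotype)
    cases = phenotype == 1
    n = {
        (k, s): int(np.sum((classes == k) & (cases == s)))
        for k in (0, 1, 2) for s in (True, False)
    }
    if n[(0, True)] == 0 and n[(0, False)] == 0:
        raise ValidationError("no 0-hit reference samples")
    if n[(1, True)] + n[(1, False)] == 0:
        raise ValidationError("no 1-hit samples")
    or1, ci1, h1 = _odds_ratio_ci(
        n[(1, True)], n[(1, False)], n[(0, True)], n[(0, False)]
    )
    or2 = ci2 = None
    h2 = False
    dev_p = None
    if n[(2, True)] + n[(2, False)] > 0:
        or2, ci2, h2 = _odds_ratio_ci(
            n[(2, True)], n[(2, False)], n[(0, True)], n[(0, False)]
        )
        dev_p = _lrt_within(classes, phenotype)
    return HitModelResult(
        or_1hit=or1, ci_1hit=ci1, or_2hit=or2, ci_2hit=ci2,
        deviation_p=dev_p, haldane_applied=h1 or h2,
    )


def _penalized_ll(X: np.ndarray, y: np.ndarray, firth: bool) -> float:
    fit = firth_logistic(X, y, penalized=firth)
    return fit.loglik


def _lrt_within(classes: np.ndarray, phenotype: np.ndarray, firth: bool = False) -> float:
    """LRT of free 1-hit/2-hit terms vs the log-additive constraint b2 = 2 b1."""
    y = np.asarray(phenotype, dtype=float)
    i1 = (classes == 1).astype(float)
    i2 = (classes == 2).astype(float)
    ones = np.ones_like(y)
    X_free = np.column_stack([ones, i1, i2])
    X_add = np.column_stack([ones, i1 + 2 * i2])
    ll_free = _penalized_ll(X_free, y, firth)
    ll_add = _penalized_ll(X_add, y, firth)
    lrt = max(0.0, 2 * (ll_free - ll_add))
    return float(stats.chi2.sf(lrt, df=1))


def additivity_deviation_test(
    matrix: GenotypeMatrix,
    set_a: list[VariantKey],
    set_b: list[VariantKey] | None = None,
    firth: bool = False,
) -> float:
    """Likelihood-ratio p-value for deviation from log-additivity.

    Within-gene mode (``set_b`` is None): hit classes 0/1/2+ from ``set_a``;
    the free logistic model has separate 1-hit and 2-hit terms, the
    constrained one imposes beta_2hit = 2 * beta_1hit. Between-gene mode:
    carrier indicators for each set with and without an interaction term.

    The default is a plain maximum-likelihood LRT, which is chi-square
    calibrated. ``firth=True`` compares Jeffreys-penalized likelihoods
    instead — useful when a hit class is nearly empty and ML separates, but
    anti-conservative as a test: the penalty contributes ~ 1/2 log n per
    extra parameter, so the penalized statistic is not chi-square under the
    null at large n.
    """
    y = matrix.phenotype.astype(float)
    if set_b is None:
        classes, _ = composite_carrier_coding(matrix, set_a)
        for k in (0, 1, 2):
            if not np.any(classes == k):
                raise ValidationError(f"empty hit class {k}")
        return _lrt_within(classes, y, firth)
    ca, _ = composite_carrier_coding(matrix, set_a)
    cb, _ = composite_carrier_coding(matrix, set_b)
    a = (ca > 0).astype(float)
    b = (cb > 0).astype(float)
    ones = np.ones_like(y)
    X_free = np.column_stack([ones, a, b, a * b])
    X_add = np.column_stack([ones, a, b])
    ll_free = _penalized_ll(X_free, y, firth)
    ll_add = _penalized_ll(X_add, y, firth)
    lrt = max(0.0, 2 * (ll_free - ll_add))
    return float(stats.chi2.sf(lrt, df=1))
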