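"""Polygenic risk scores and their between-population decomposition.

The score of individual i is PRS_i = sum_m beta_m * G_im on the log-odds
scale. Its population expectation under random mating is sum_m 2 beta_m f_m,
so the expected between-population difference decomposes exactly into
per-variant contributions 2 beta_m (f_m,a - f_m,b) — frequency shifts alone,
no genotypes needed. A genotype-specific (non-additive) extension replaces
2 f beta with 2 f (1-f) beta_het + f^2 beta_hom, which collapses to the
additive form whenever beta_hom = 2 beta_het.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model_io import EffectTable, GenotypeMatrix, ValidationError

__all__ = [
    "PrsScoreSet",
    "compute_prs",
    "expected_prs",
    "expected_prs_difference",
    "expected_prs_nonadditive",
    "expected_prs_difference_nonadditive",
    "standardize_scores",
]

#: Per-variant contribution magnitude at which a variant is highlighted.
HIGHLIGHT_CONTRIBUTION = 0.01


@dataclass
class PrsScoreSet:
    """Per-sample scores plus the population label of each sample."""

    scores: np.ndarray
    populations: np.ndarray
    standardized: bool = False
    reference_population: str | None = None


def compute_prs(
    matrix: GenotypeMatrix,
    effects: EffectTable,
    impute_population: str | None = None,
    populations: np.ndarray | None = None,
) -> PrsScoreSet:
    """Score each sample: sum of beta * dosage over the effect table.

    Missing dosages are replaced by the imputed expected value 2f using the
    ``impute_population`` frequency column; with no frequency available a
    missing call is an error rather than a silent zero.
    """
    n = matrix.n_samples
    scores = np.zeros(n)
    freqs = effects.frequencies(impute_population) if impute_population else None
    for j, (key, beta) in enumerate(zip(effects.keys, effects.betas)):
        if key not in matrix:
            raise ValidationError(f"effect variant {key} absent from genotype matrix")
        g = matrix.column(key)
        missing = np.isnan(g)
        if missing.any():
            if freqs is None:
                raise ValidationError(
                    f"{key}: missing dosages but no imputation frequency supplied"
                )
            g = np.where(missing, 2.0 * freqs[j], g)
        scores += beta * g
    if populations is None:
        populations = np.array(["all"] * n)
    return PrsScoreSet(scores=scores, populations=np.asarray(populations))


def expected_prs(effects: EffectTable, population: str) -> float:
    """Closed-form population expectation sum_m 2 beta_m f_m."""
    f = effects.frequencies(population)
    return float(np.sum(2.0 * effects.betas * f))


def expected_prs_difference(
    effects: EffectTable, pop_a: str, pop_b: str
) -> tuple[float, pd.DataFrame]:
    """Expected PRS difference between populations and its per-variant split.

    Returns (total, frame) where the frame has one row per variant with its
    contribution 2 beta (f_a - f_b), sorted decreasing, and highlight flags
    at |contribution| >= 0.01.
    """
    fa = effects.frequencies(pop_a)
    fb = effects.frequencies(pop_b)
    contrib = 2.0 * effects.betas * (fa - fb)
    frame = pd.DataFrame({
        "variant": [str(k) for k in effects.keys],
        "beta": effects.betas,
        f"freq_{pop_a}": fa,
        f"freq_{pop_b}": fb,
        "contribution": contrib,
    })
    frame["highlight_up"] = frame["contribution"] >= HIGHLIGHT_CONTRIBUTION
    frame["highlight_down"] = frame["contribution"] <= -HIGHLIGHT_CONTRIBUTION
    frame = frame.sort_values("contribution", ascending=False).reset_index(drop=True)
    return float(np.sum(contrib)), frame


def expected_prs_nonadditive(effects: EffectTable, population: str) -> float:
    """Genotype-specific expectation sum_m [2f(1-f) beta_het + f^2 beta_hom]."""
    het, hom = effects.het_hom_betas()
    f = effects.frequencies(population)
    return float(np.sum(2.0 * f * (1.0 - f) * het + f ** 2 * hom))


def expected_prs_difference_nonadditive(
    effects: EffectTable, pop_a: str, pop_b: str
) -> float:
    """Non-additive expected difference, via the expanded per-variant form.

    sum_m 2 beta_het ((f_a - f_b) - (f_a^2 - f_b^2)) + beta_hom (f_a^2 - f_b^2);
    algebraically identical to the difference of the per-population
    expectations.
    """
    het, hom = effects.het_hom_betas()
    fa = effects.frequencies(pop_a)
    fb = effects.frequencies(pop_b)
    d1 = fa - fb
    d2 = fa ** 2 - fb ** 2
    return float(np.sum(2.0 * het * (d1 - d2) + hom * d2))


def standardize_scores(
    scores: PrsScoreSet, reference_population: str
) -> tuple[PrsScoreSet, dict[str, float]]:
    """Scale all scores to the reference subset (mean 0, variance 1 there).

    Returns the transformed score set and, per non-reference population, its
    post-transform mean — the between-group shift in reference-s.d. units.
    """
    ref = scores.populations == reference_population
    if ref.sum() < 2:
        raise ValidationError(
            f"reference population {reference_population!r} needs >= 2 samples"
        )
    mu = scores.scores[ref].mean()
    sd = scores.scores[ref].std(ddof=1)
    if sd == 0:
        raise ValidationError("reference scores have zero variance")
    z = (scores.scores - mu) / sd
    shifts = {
        str(pop): float(z[scores.populations == pop].mean())
        for pop in np.unique(scores.populations)
        if pop != reference_population
    }
    out = PrsScoreSet(
        scores=z, populations=scores.populations,
        standardized=True, reference_population=reference_population,
    )
    return out, shifts
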