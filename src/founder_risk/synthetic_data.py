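"""Synthetic inputs with the statistical structure the pipeline assumes.

Three generators cover every stage: (1) two-population allele counts where
the study population passed through a founder bottleneck — ancestral
frequencies drawn from a 1/x site-frequency spectrum, resampled through a
single-generation binomial bottleneck of ``founder_chromosomes`` copies, so
some alleles are boosted and others lost outright; (2) case-control
genotypes at Hardy-Weinberg equilibrium with logistic disease risk, either
additive in dosage or with het/hom-specific effects; (3) multi-study
association summaries with a shared true effect plus optional per-study
heterogeneity. All generators are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model_io import (
    EffectTable,
    GenotypeMatrix,
    PopulationCounts,
    StudySummary,
    ValidationError,
    VariantKey,
    VariantRecord,
)

import pandas as pd

__all__ = [
    "SimulationConfig",
    "sim_bottleneck_counts",
    "sim_case_control",
    "sim_multistudy_summaries",
    "effect_table_from_arrays",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Shared knobs for the generators.

    The defaults describe the regime the pipeline targets: a site-frequency
    spectrum proportional to 1/x truncated to [1e-4, 0.5]; a bottleneck of
    500 founder chromosomes (a few hundred effective founders, the scale of
    a strong single-generation founder event); a study population of ~2,000
    diploid samples scored against a large (~30,000-sample) reference.
    """

    seed: int = 0
    n_variants: int = 10_000
    spectrum_min: float = 1e-4
    spectrum_max: float = 0.5
    founder_chromosomes: int = 500
    n_study: int = 2_000
    n_reference: int = 30_000
    n_cases: int = 1_000
    n_controls: int = 1_000
    beta0: float = -1.0

    def __post_init__(self) -> None:
        for name in ("n_variants", "founder_chromosomes", "n_study",
                     "n_reference", "n_cases", "n_controls"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.spectrum_min < self.spectrum_max <= 0.5:
            raise ValidationError("need 0 < spectrum_min < spectrum_max <= 0.5")


def _spectrum_draw(rng: np.random.Generator, n: int, lo: float, hi: float) -> np.ndarray:
    """Frequencies with density proportional to 1/x on [lo, hi] (inverse CDF)."""
    u = rng.random(n)
    return lo * (hi / lo) ** u


def sim_bottleneck_counts(
    config: SimulationConfig,
    study_pop: str = "AJ",
    reference_pop: str = "NFE",
) -> list[VariantRecord]:
    """Allele-count records for a bottlenecked study and a large reference.

    Ancestral frequency x ~ 1/x spectrum; the founder frequency is a
    binomial resample of ``founder_chromosomes`` copies (variants drawn to
    zero copies are emitted as lost, AC=0); study counts are binomial at the
    founder frequency, reference counts binomial at the ancestral frequency.
    Annotations are assigned PTV/PRA/SYN at fixed 1:6:3 proportions so the
    class-proportion summary has all classes populated.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_variants
    x = _spectrum_draw(rng, n, config.spectrum_min, config.spectrum_max)
    founder = rng.binomial(config.founder_chromosomes, x) / config.founder_chromosomes
    an_study = 2 * config.n_study
    an_ref = 2 * config.n_reference
    ac_study = rng.binomial(an_study, founder)
    ac_ref = rng.binomial(an_ref, x)
    annotations = rng.choice(["PTV", "PRA", "SYN"], size=n, p=[0.1, 0.6, 0.3])
    records = []
    for i in range(n):
        key = VariantKey(chrom="1", pos=i + 1, ref="A", alt="G")
        records.append(VariantRecord(
            key=key,
            annotation=str(annotations[i]),
            counts={
                study_pop: PopulationCounts(study_pop, int(ac_study[i]), an_study),
                reference_pop: PopulationCounts(reference_pop, int(ac_ref[i]), an_ref),
            },
            coverage_ok={reference_pop: True},
        ))
    return records


def effect_table_from_arrays(
    betas: np.ndarray,
    freqs: dict[str, np.ndarray],
    beta_het: np.ndarray | None = None,
    beta_hom: np.ndarray | None = None,
) -> EffectTable:
    """Build an :class:`EffectTable` from plain arrays (test/simulation helper)."""
    m = len(betas)
    data = {
        "variant": [f"1:{i + 1}:A:G" for i in range(m)],
        "beta": np.asarray(betas, dtype=float),
    }
    if beta_het is not None:
        data["beta_het"] = np.asarray(beta_het, dtype=float)
        data["beta_hom"] = np.asarray(beta_hom, dtype=float)
    for pop, f in freqs.items():
        data[f"freq_{pop}"] = np.asarray(f, dtype=float)
    return EffectTable(pd.DataFrame(data))


def sim_case_control(
    config: SimulationConfig,
    effects: EffectTable,
    frequency_population: str = "AJ",
    het_hom: bool = False,
    n_covariates: int = 0,
    covariate_loading: float = 0.0,
) -> GenotypeMatrix:
    """Case-control genotypes under HWE with logistic risk.

    Samples genotypes for a large pool at the given population's
    frequencies, assigns phenotypes by the logistic model
    logit p = beta0 + sum beta_m G_m (or the het/hom coding when
    ``het_hom``), then draws the requested numbers of cases and controls.
    Optional standard-normal covariates enter the linear predictor with
    ``covariate_loading`` to emulate PC confounding.
    """
    rng = np.random.default_rng(config.seed + 1)
    f = effects.frequencies(frequency_population)
    m = len(effects)
    n_target = config.n_cases + config.n_controls
    # oversample, then split by phenotype
    got_cases: list[np.ndarray] = []
    got_controls: list[np.ndarray] = []
    got_cov_cases: list[np.ndarray] = []
    got_cov_controls: list[np.ndarray] = []
    n_cases = n_controls = 0
    for _ in range(200):
        batch = max(2 * n_target, 1000)
        G = rng.binomial(2, f, size=(batch, m)).astype(float)
        if het_hom:
            het, hom = effects.het_hom_betas()
            eta = config.beta0 + (G == 1) @ het + (G == 2) @ hom
        else:
            eta = config.beta0 + G @ effects.betas
        cov = None
        if n_covariates:
            cov = rng.standard_normal((batch, n_covariates))
            eta = eta + covariate_loading * cov.sum(axis=1)
        y = rng.random(batch) < 1.0 / (1.0 + np.exp(-eta))
        if n_cases < config.n_cases:
            take = np.flatnonzero(y)[: config.n_cases - n_cases]
            got_cases.append(G[take])
            if cov is not None:
                got_cov_cases.append(cov[take])
            n_cases += take.size
        if n_controls < config.n_controls:
            take = np.flatnonzero(~y)[: config.n_controls - n_controls]
            got_controls.append(G[take])
            if cov is not None:
                got_cov_controls.append(cov[take])
            n_controls += take.size
        if n_cases >= config.n_cases and n_controls >= config.n_controls:
            break
    else:
        raise ValidationError(
            "could not reach the requested case count; raise beta0 "
            f"(currently {config.beta0})"
        )
    dosages = np.vstack(got_cases + got_controls)
    phenotype = np.concatenate([
        np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)
    ])
    covariates = None
    if n_covariates:
        covariates = np.vstack(got_cov_cases + got_cov_controls)
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n_target)],
        variant_keys=effects.keys,
        dosages=dosages,
        phenotype=phenotype,
        covariates=covariates,
    )


def sim_multistudy_summaries(
    seed: int,
    true_beta: float,
    se_vector: list[float],
    heterogeneity_sd: float = 0.0,
    study_labels: list[str] | None = None,
) -> list[StudySummary]:
    """Per-study estimates beta_k ~ N(true_beta + delta_k, se_k^2).

    delta_k ~ N(0, heterogeneity_sd^2) adds between-study effect
    heterogeneity; zero gives a shared effect across studies.
    """
    rng = np.random.default_rng(seed)
    se = np.asarray(se_vector, dtype=float)
    if (se <= 0).any():
        raise ValidationError("all standard errors must be positive")
    k = se.size
    delta = rng.normal(0.0, heterogeneity_sd, size=k) if heterogeneity_sd > 0 else np.zeros(k)
    beta = rng.normal(true_beta + delta, se)
    labels = study_labels or [f"study{i + 1}" for i in range(k)]
    return [
        StudySummary(study=labels[i], beta_hat=float(beta[i]), se=float(se[i]))
        for i in range(k)
    ]
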