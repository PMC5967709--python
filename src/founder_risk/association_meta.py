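"""Case-control association and Bayesian cross-study meta-analysis.

Per-study association uses Firth bias-corrected logistic regression — the
Jeffreys-prior-penalized likelihood l(b) + 1/2 log det I(b) — which yields
finite estimates even under complete separation, the regime rare founder
alleles routinely produce. Studies are combined with Gaussian approximate
Bayes factors in the style of Wakefield: each study's (beta_hat, se) is
treated as a Gaussian observation of the true log-OR, the effect prior is
N(0, prior_sd^2), and two alternative models are compared against the point
null — effects correlated equally across studies (one shared true effect)
versus independent per-study effects. The final report is based on the
correlated-effects model; a large independent-vs-correlated Bayes factor
(log10 > 2 by default) flags heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_model_io import GenotypeMatrix, StudySummary, ValidationError, VariantKey

__all__ = [
    "MetaConfig",
    "MetaResult",
    "GwasLocusSet",
    "FirthFit",
    "firth_logistic",
    "firth_logistic_fit",
    "wakefield_abf",
    "meta_bayes",
    "qq_fd_threshold",
    "stratify_gwas_loci",
]


@dataclass(frozen=True)
class MetaConfig:
    """Meta-analysis settings: effect prior sd and heterogeneity cut."""

    prior_sd: float = 0.2
    het_log10bf_cut: float = 2.0
    rho: float = 1.0  # correlation of true effects in the correlated model

    def __post_init__(self) -> None:
        if not self.prior_sd > 0:
            raise ValidationError("prior_sd must be positive")


@dataclass
class MetaResult:
    key: VariantKey | None
    studies: list[StudySummary]
    bf_correlated: float
    bf_independent: float
    combined_beta: float
    combined_se: float
    p_approx: float
    heterogeneity_flag: bool


@dataclass
class GwasLocusSet:
    """Credible-set intervals (chrom, start, end) with a flank in bp."""

    intervals: list[tuple[str, int, int]]
    flank: int = 50_000

    def __post_init__(self) -> None:
        if self.flank < 0:
            raise ValidationError("flank must be >= 0")
        for chrom, start, end in self.intervals:
            if start > end:
                raise ValidationError(f"invalid interval {chrom}:{start}-{end}")

    def contains(self, chrom: str, pos: int) -> bool:
        return any(
            c == chrom and start - self.flank <= pos <= end + self.flank
            for c, start, end in self.intervals
        )


# ---------------------------------------------------------------------------
# Firth-penalized logistic regression
# ---------------------------------------------------------------------------

@dataclass
class FirthFit:
    beta: np.ndarray          # all coefficients, intercept first
    se: np.ndarray
    loglik: float             # penalized log-likelihood at the optimum
    n_iter: int
    converged: bool


def _penalized_loglik(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log-likelihood written to be stable for large |eta|
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    p = 1.0 / (1.0 + np.exp(-eta))
    W = p * (1 - p)
    info = X.T @ (X * W[:, None])
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -np.inf
    return ll + 0.5 * logdet


def firth_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 50,
    penalized: bool = True,
) -> FirthFit:
    """Maximize the (optionally Jeffreys-penalized) logistic likelihood.

    Newton iterations on the modified score with step-halving on the
    penalized log-likelihood; convergence at score norm < ``tol``. With
    ``penalized=False`` this is plain maximum likelihood via the same
    machinery (the hat-correction term is dropped).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    tol = tol * max(1.0, float(n))  # score norm grows with sample size
    beta = np.zeros(k)
    ll = _penalized_loglik(X, y, beta) if penalized else float(
        np.sum(y * (X @ beta) - np.logaddexp(0.0, X @ beta))
    )
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        info = X.T @ (X * W[:, None])
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(f"singular information matrix: {exc}") from exc
        if penalized:
            # hat diagonals of W^1/2 X (X'WX)^-1 X' W^1/2
            XW = X * np.sqrt(W)[:, None]
            h = np.einsum("ij,jk,ik->i", XW, info_inv, XW)
            score = X.T @ (y - p + h * (0.5 - p))
        else:
            score = X.T @ (y - p)
        if np.linalg.norm(score, ord=np.inf) < tol:
            converged = True
            break
        step = info_inv @ score
        # step-halving to guarantee ascent of the target function
        for _ in range(25):
            cand = beta + step
            if penalized:
                cand_ll = _penalized_loglik(X, y, cand)
            else:
                eta_c = X @ cand
                cand_ll = float(np.sum(y * eta_c - np.logaddexp(0.0, eta_c)))
            if cand_ll > ll - 1e-12:
                break
            step = step / 2.0
        beta = beta + step
        ll = cand_ll
    if not converged:
        # final score check after the last update
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1 - p)
        info = X.T @ (X * W[:, None])
        info_inv = np.linalg.inv(info)
        if penalized:
            XW = X * np.sqrt(W)[:, None]
            h = np.einsum("ij,jk,ik->i", XW, info_inv, XW)
            score = X.T @ (y - p + h * (0.5 - p))
        else:
            score = X.T @ (y - p)
        converged = bool(np.linalg.norm(score, ord=np.inf) < tol)
        if not converged:
            raise ValidationError(
                f"logistic fit did not converge in {max_iter} iterations "
                f"(score norm {np.linalg.norm(score, ord=np.inf):.3g})"
            )
    se = np.sqrt(np.diag(info_inv))
    return FirthFit(beta=beta, se=se, loglik=ll, n_iter=it, converged=converged)


def firth_logistic_fit(
    matrix: GenotypeMatrix,
    variant: VariantKey,
    min_mac: int = 1,
    min_call_rate: float = 0.8,
) -> tuple[float, float, float]:
    """Firth association test for one variant, adjusting for covariates.

    Fits phenotype ~ intercept + dosage + covariates on per-variant complete
    cases and returns (beta_hat, se, p) for the dosage term, with a Wald p
    from the penalized information matrix. Variants failing the minor-allele
    -count or call-rate filters are rejected with the reason.
    """
    if variant not in matrix:
        raise ValidationError(f"variant {variant} not in matrix")
    if matrix.call_rate(variant) < min_call_rate:
        raise ValidationError(
            f"{variant}: call rate {matrix.call_rate(variant):.3f} < {min_call_rate}"
        )
    g = matrix.column(variant)
    keep = ~np.isnan(g)
    g = g[keep]
    mac = min(float(np.sum(g)), float(np.sum(2 - g)))
    if mac < min_mac:
        raise ValidationError(f"{variant}: minor allele count {mac:g} < {min_mac}")
    y = matrix.phenotype[keep]
    cols = [np.ones(g.size), g]
    if matrix.covariates is not None:
        cols.extend(matrix.covariates[keep].T)
    X = np.column_stack(cols)
    fit = firth_logistic(X, y)
    beta, se = float(fit.beta[1]), float(fit.se[1])
    p = 2 * stats.norm.sf(abs(beta / se))
    return beta, se, float(p)


# ---------------------------------------------------------------------------
# Approximate Bayes factors and meta-analysis
# ---------------------------------------------------------------------------

def wakefield_abf(summary: StudySummary, config: MetaConfig = MetaConfig()) -> float:
    """Approximate Bayes factor (alternative : null) for one study.

    With V = se^2, W = prior_sd^2 and z = beta_hat / se:
    BF = sqrt(V / (V + W)) * exp(W z^2 / (2 (V + W))).
    """
    V = summary.se ** 2
    W = config.prior_sd ** 2
    z = summary.beta_hat / summary.se
    return math.sqrt(V / (V + W)) * math.exp(W * z * z / (2 * (V + W)))


def _gaussian_bf(beta: np.ndarray, cov_alt: np.ndarray, cov_null: np.ndarray) -> float:
    """exp(log N(beta; 0, cov_alt) − log N(beta; 0, cov_null))."""
    la = stats.multivariate_normal.logpdf(beta, mean=np.zeros(beta.size), cov=cov_alt)
    l0 = stats.multivariate_normal.logpdf(beta, mean=np.zeros(beta.size), cov=cov_null)
    return float(np.exp(la - l0))


def meta_bayes(
    summaries: list[StudySummary],
    config: MetaConfig = MetaConfig(),
    key: VariantKey | None = None,
) -> MetaResult:
    """Correlated- and independent-effects Bayes factors plus fixed-effect combine.

    Marginally, beta_hat ~ N(0, D + W*R) under the alternative where
    D = diag(se^2), W = prior_sd^2, and R is all-ones (correlated model,
    one shared effect) or the identity (independent effects); the null is
    beta_hat ~ N(0, D). The combined estimate is the inverse-variance fixed-
    effect one and p_approx its two-sided normal tail (monotone in the
    correlated-model BF at fixed per-study SEs). Heterogeneity is flagged
    when log10(bf_independent / bf_correlated) exceeds the configured cut.
    """
    if not summaries:
        raise ValidationError("meta_bayes needs at least one study")
    beta = np.array([s.beta_hat for s in summaries])
    se2 = np.array([s.se ** 2 for s in summaries])
    D = np.diag(se2)
    W = config.prior_sd ** 2
    k = beta.size
    R_corr = np.full((k, k), config.rho)
    np.fill_diagonal(R_corr, 1.0)
    bf_corr = _gaussian_bf(beta, D + W * R_corr, D)
    bf_ind = _gaussian_bf(beta, D + W * np.eye(k), D)

    weights = 1.0 / se2
    combined_beta = float(np.sum(weights * beta) / np.sum(weights))
    combined_se = float(1.0 / math.sqrt(np.sum(weights)))
    z = combined_beta / combined_se
    p_approx = float(2 * stats.norm.sf(abs(z)))
    het = math.log10(bf_ind) - math.log10(bf_corr) > config.het_log10bf_cut
    return MetaResult(
        key=key, studies=list(summaries),
        bf_correlated=bf_corr, bf_independent=bf_ind,
        combined_beta=combined_beta, combined_se=combined_se,
        p_approx=p_approx, heterogeneity_flag=het,
    )


def qq_fd_threshold(p_values) -> tuple[float, np.ndarray]:
    """Annotation threshold at which the expected number of false discoveries is 1.

    For n p-values uniform under the null, E[#(p <= t)] = n t, so t = 1/n.
    Returns (t, boolean mask of p-values <= t).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValidationError("need at least one p-value")
    t = 1.0 / p.size
    return t, p <= t


def stratify_gwas_loci(
    variants: list[VariantKey], loci: GwasLocusSet
) -> dict[VariantKey, str]:
    """Assign each variant to the "gwas" or "non-gwas" stratum.

    A variant is "gwas" iff its position falls within the flank (default
    50 kb) of any credible-set interval on the same chromosome.
    """
    return {
        v: "gwas" if loci.contains(v.chrom, v.pos) else "non-gwas"
        for v in variants
    }
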