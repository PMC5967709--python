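import math

import numpy as np
import pytest
from scipy import optimize, stats

from founder_risk.association_meta import (
    GwasLocusSet,
    MetaConfig,
    firth_logistic,
    firth_logistic_fit,
    meta_bayes,
    qq_fd_threshold,
    stratify_gwas_loci,
    wakefield_abf,
)
from founder_risk.data_model_io import (
    GenotypeMatrix,
    StudySummary,
    ValidationError,
    VariantKey,
)
from founder_risk.synthetic_data import (
    SimulationConfig,
    effect_table_from_arrays,
    sim_case_control,
    sim_multistudy_summaries,
)


def brute_force_penalized_mle(X, y, bounds, grid=41):
    """Grid + Nelder-Mead refinement of the Jeffreys-penalized likelihood."""
    def neg_pll(beta):
        eta = X @ np.asarray(beta)
        ll = np.sum(y * eta - np.logaddexp(0, eta))
        p = 1 / (1 + np.exp(-eta))
        info = X.T @ (X * (p * (1 - p))[:, None])
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return np.inf
        return -(ll + 0.5 * logdet)

    axes = [np.linspace(lo, hi, grid) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    vals = np.array([
        neg_pll(point) for point in zip(*[m.ravel() for m in mesh])
    ])
    start = [m.ravel()[vals.argmin()] for m in mesh]
    res = optimize.minimize(neg_pll, start, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-12})
    return res.x


class TestFirthLogistic:
    def test_two_by_two_equals_half_cell_correction(self):
        """On a saturated 2x2 design Firth equals adding 0.5 to each cell."""
        x = np.array([1] * 10 + [0] * 10, float)
        y = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 8, float)
        X = np.column_stack([np.ones(20), x])
        fit = firth_logistic(X, y)
        assert fit.beta[1] == pytest.approx(math.log(8.5 * 8.5 / (2.5 * 2.5)), abs=1e-4)

    def test_matches_brute_force_maximization(self):
        rng = np.random.default_rng(3)
        x = rng.binomial(2, 0.3, 60).astype(float)
        y = (rng.random(60) < 1 / (1 + np.exp(-(-0.5 + 0.8 * x)))).astype(float)
        X = np.column_stack([np.ones(60), x])
        fit = firth_logistic(X, y)
        ref = brute_force_penalized_mle(X, y, [(-3, 3), (-3, 3)])
        assert fit.beta == pytest.approx(ref, abs=1e-4)

    def test_finite_under_complete_separation(self):
        x = np.array([1] * 6 + [0] * 12, float)
        y = np.array([1] * 6 + [0] * 12, float)  # all carriers are cases
        X = np.column_stack([np.ones(18), x])
        fit = firth_logistic(X, y)
        assert np.isfinite(fit.beta).all() and np.isfinite(fit.se).all()
        ref = brute_force_penalized_mle(X, y, [(-6, 6), (-6, 12)], grid=31)
        assert fit.beta == pytest.approx(ref, abs=1e-3)

    def test_null_covariate_within_three_se(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(500)
        y = rng.integers(0, 2, 500).astype(float)
        X = np.column_stack([np.ones(500), x])
        fit = firth_logistic(X, y)
        assert abs(fit.beta[1]) < 3 * fit.se[1]


class TestFirthVariantFit:
    def _matrix(self, dosages, phenotype, **kw):
        n, m = dosages.shape
        return GenotypeMatrix(
            sample_ids=[f"s{i}" for i in range(n)],
            variant_keys=[VariantKey("1", j + 1, "A", "G") for j in range(m)],
            dosages=dosages, phenotype=phenotype, **kw,
        )

    def test_fit_returns_dosage_term(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, 400).astype(float)
        y = (rng.random(400) < 1 / (1 + np.exp(-(-0.5 + 0.7 * g)))).astype(int)
        m = self._matrix(g[:, None], y)
        beta, se, p = firth_logistic_fit(m, VariantKey("1", 1, "A", "G"))
        assert beta == pytest.approx(0.7, abs=3 * se)
        assert 0 < p <= 1

    def test_low_call_rate_variant_rejected(self):
        g = np.full((10, 1), np.nan)
        g[:7, 0] = 1.0  # call rate 0.7 < 0.8
        m = self._matrix(g, np.array([1, 0] * 5))
        with pytest.raises(ValidationError, match="call rate"):
            firth_logistic_fit(m, VariantKey("1", 1, "A", "G"))

    def test_monomorphic_variant_rejected(self):
        g = np.zeros((10, 1))
        m = self._matrix(g, np.array([1, 0] * 5))
        with pytest.raises(ValidationError, match="minor allele count"):
            firth_logistic_fit(m, VariantKey("1", 1, "A", "G"))

    def test_recovers_effect_on_synthetic_cohort(self):
        """Mean Firth estimate near truth ln 2 on simulated case-control data."""
        effects = effect_table_from_arrays([math.log(2)], {"AJ": [0.2]})
        key = VariantKey.parse("1:1:A:G")
        estimates = []
        for rep in range(30):
            config = SimulationConfig(seed=1000 + rep, n_cases=1000, n_controls=1000,
                                      beta0=-1.5)
            matrix = sim_case_control(config, effects)
            beta, _, _ = firth_logistic_fit(matrix, key)
            estimates.append(beta)
        assert np.mean(estimates) == pytest.approx(math.log(2), abs=0.08)


class TestWakefieldAbf:
    def test_closed_form_example(self):
        bf = wakefield_abf(StudySummary("s", 0.2, 0.1), MetaConfig(prior_sd=0.2))
        assert bf == pytest.approx(math.sqrt(0.2) * math.exp(1.6), rel=1e-12)

    def test_null_estimate_favours_null(self):
        bf = wakefield_abf(StudySummary("s", 0.0, 0.1))
        assert bf == pytest.approx(math.sqrt(0.01 / 0.05)) and bf < 1

    def test_vanishing_prior_gives_unit_bf(self):
        bf = wakefield_abf(StudySummary("s", 0.3, 0.1), MetaConfig(prior_sd=1e-8))
        assert bf == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_abs_z(self):
        bfs = [wakefield_abf(StudySummary("s", b, 0.1)) for b in np.linspace(0, 1, 20)]
        assert all(x < y for x, y in zip(bfs, bfs[1:]))


class TestMetaBayes:
    def test_single_study_models_coincide_with_abf(self):
        s = StudySummary("s", 0.17, 0.08)
        r = meta_bayes([s])
        abf = wakefield_abf(s)
        assert r.bf_correlated == pytest.approx(abf, rel=1e-12)
        assert r.bf_independent == pytest.approx(abf, rel=1e-12)

    def test_two_identical_studies_collapse_to_combined_se(self):
        r = meta_bayes([StudySummary("a", 0.2, 0.1), StudySummary("b", 0.2, 0.1)])
        expected = math.sqrt(0.005 / 0.045) * math.exp(0.04 * 8 / (2 * 0.045))
        assert r.bf_correlated == pytest.approx(expected, abs=1e-10)
        # equals a single study at se/sqrt(2)
        collapsed = wakefield_abf(StudySummary("c", 0.2, 0.1 / math.sqrt(2)))
        assert r.bf_correlated == pytest.approx(collapsed, abs=1e-10)

    def test_k_identical_studies_collapse(self):
        for k in (2, 3, 5):
            r = meta_bayes([StudySummary(f"s{i}", 0.15, 0.12) for i in range(k)])
            collapsed = wakefield_abf(StudySummary("c", 0.15, 0.12 / math.sqrt(k)))
            assert r.bf_correlated == pytest.approx(collapsed, abs=1e-10)

    def test_opposite_effects_flag_heterogeneity(self):
        r = meta_bayes([StudySummary("a", 1.0, 0.1), StudySummary("b", -1.0, 0.1)])
        assert r.bf_independent > r.bf_correlated
        assert r.heterogeneity_flag

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            meta_bayes([])

    def test_null_p_approx_uniform(self):
        """KS test of p_approx across 2,000 null simulated summary triplets."""
        ps = []
        for rep in range(2000):
            summaries = sim_multistudy_summaries(
                seed=rep, true_beta=0.0, se_vector=[0.1, 0.15, 0.08]
            )
            ps.append(meta_bayes(summaries).p_approx)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestQqFdThreshold:
    def test_threshold_is_one_over_n(self):
        t, mask = qq_fd_threshold(np.linspace(0.001, 1, 351))
        assert t == pytest.approx(1 / 351)

    def test_single_pvalue_threshold_one(self):
        t, mask = qq_fd_threshold([0.4])
        assert t == 1.0 and mask.all()

    def test_expected_false_discoveries_near_one(self):
        rng = np.random.default_rng(2)
        counts = [qq_fd_threshold(rng.random(1000))[1].sum() for _ in range(200)]
        assert np.mean(counts) == pytest.approx(1.0, abs=0.25)


class TestStratifyGwasLoci:
    def test_flank_membership(self):
        loci = GwasLocusSet([("1", 100_000, 200_000)])
        inside = VariantKey("1", 210_000, "A", "G")     # 10 kb beyond span
        outside = VariantKey("1", 260_000, "A", "G")    # 60 kb beyond span
        other_chrom = VariantKey("2", 150_000, "A", "G")
        strata = stratify_gwas_loci([inside, outside, other_chrom], loci)
        assert strata[inside] == "gwas"
        assert strata[outside] == "non-gwas"
        assert strata[other_chrom] == "non-gwas"

    def test_hand_traced_toy_assignment(self):
        loci = GwasLocusSet([("1", 1_000_000, 1_050_000), ("2", 500_000, 500_000)])
        variants = [
            VariantKey("1", 950_000, "A", "G"),    # within 50 kb left flank
            VariantKey("1", 949_999, "A", "G"),    # 1 bp too far
            VariantKey("1", 1_020_000, "A", "G"),  # inside the span
            VariantKey("2", 549_999, "A", "G"),    # within flank of point locus
            VariantKey("2", 551_000, "A", "G"),    # beyond
            VariantKey("3", 1_000_000, "A", "G"),  # wrong chromosome
        ]
        strata = stratify_gwas_loci(variants, loci)
        expected = ["gwas", "non-gwas", "gwas", "gwas", "non-gwas", "non-gwas"]
        assert [strata[v] for v in variants] == expected
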