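import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founder_risk.data_model_io import (
    PopulationCounts,
    ValidationError,
    VariantKey,
    VariantRecord,
)
from founder_risk.enrichment import (
    annotation_class_proportions,
    bias_corrected_log_or,
    classify_enrichment,
    fisher_one_sided,
    intersect_pathogenic,
    recessive_risk_enrichment,
    two_proportion_test,
)


def exact_fisher_greater(a: int, b: int, c: int, d: int) -> Fraction:
    """Exact-rational upper-tail hypergeometric enumeration oracle."""
    r1, c1, n = a + b, a + c, a + b + c + d
    total = math.comb(n, c1)
    tail = 0
    for k in range(a, min(r1, c1) + 1):
        if c1 - k > n - r1:
            continue
        tail += math.comb(r1, k) * math.comb(n - r1, c1 - k)
    return Fraction(tail, total)


class TestBiasCorrectedLogOr:
    def test_hand_computed_example(self):
        beta, se = bias_corrected_log_or(10, 990, 5, 9995)
        assert beta == pytest.approx(2.9583, abs=1e-4)
        assert se == pytest.approx(0.5274, abs=1e-4)

    def test_symmetric_table_gives_zero(self):
        beta, se = bias_corrected_log_or(5, 5, 5, 5)
        assert beta == 0.0
        assert se == pytest.approx(math.sqrt(4 / 5.5), abs=1e-10)

    def test_finite_even_with_zero_cells(self):
        beta, se = bias_corrected_log_or(0, 100, 0, 100)
        assert math.isfinite(beta) and math.isfinite(se)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            bias_corrected_log_or(-1, 5, 5, 5)

    @given(st.tuples(*[st.integers(0, 50)] * 4))
    @settings(max_examples=100)
    def test_antisymmetry_under_role_swap(self, cells):
        a, b, c, d = cells
        beta_fwd, _ = bias_corrected_log_or(a, b, c, d)
        beta_rev, _ = bias_corrected_log_or(c, d, a, b)
        assert beta_fwd == pytest.approx(-beta_rev, abs=1e-12)

    def test_monotone_in_study_alt_count(self):
        betas = [bias_corrected_log_or(a, 100, 10, 1000)[0] for a in range(0, 30)]
        assert all(x < y for x, y in zip(betas, betas[1:]))


class TestFisherOneSided:
    def test_small_table_exact_value(self):
        # upper tail P(X >= 3) = (1200 + 210) / 4845
        assert fisher_one_sided(3, 7, 1, 9) == pytest.approx(1410 / 4845, abs=1e-12)

    def test_left_extreme_tail_is_one(self):
        assert fisher_one_sided(0, 10, 5, 5) >= 0.999

    def test_monotone_decreasing_in_study_alt(self):
        ps = [fisher_one_sided(a, 100 - a, 10, 990) for a in range(0, 20)]
        assert all(x >= y for x, y in zip(ps, ps[1:]))

    @given(st.tuples(*[st.integers(0, 8)] * 4))
    @settings(max_examples=150)
    def test_matches_exact_enumeration(self, cells):
        a, b, c, d = cells
        expected = float(exact_fisher_greater(a, b, c, d))
        assert fisher_one_sided(a, b, c, d) == pytest.approx(expected, abs=1e-12)


def _record(pos, ac_study, an_study, refs, annotation="PRA", coverage=None):
    counts = {"AJ": PopulationCounts("AJ", ac_study, an_study)}
    cov = {}
    for pop, (ac, an) in refs.items():
        counts[pop] = PopulationCounts(pop, ac, an)
        cov[pop] = True if coverage is None else coverage.get(pop, True)
    return VariantRecord(
        key=VariantKey("1", pos, "A", "G"), annotation=annotation,
        counts=counts, coverage_ok=cov,
    )


class TestClassifyEnrichment:
    def test_below_window_not_enriched(self):
        rec = _record(1, 4, 4000, {"NFE": (60, 60000)})  # AF 0.001
        (res,) = classify_enrichment([rec], "AJ", ["NFE"], n_tests=1)
        assert not res.in_window and not res.enriched

    def test_bonferroni_threshold_arithmetic(self):
        # AF 0.05 vs 0.0002: p well below 0.05/73228 ~ 6.8e-7
        rec = _record(1, 200, 4000, {"NFE": (12, 60000)})
        (res,) = classify_enrichment([rec], "AJ", ["NFE"], n_tests=73228)
        assert res.p_one_sided < 0.05 / 73228
        assert res.enriched

    def test_reference_is_max_frequency_population(self):
        rec = _record(1, 100, 4000, {"NFE": (60, 60000), "AFR": (30, 10000)})
        (res,) = classify_enrichment([rec], "AJ", ["NFE", "AFR"])
        assert res.reference_pop == "AFR"  # 0.003 > 0.001
        assert res.max_ref_af == pytest.approx(0.003)

    def test_low_frequency_reference_ineligible(self):
        rec = _record(1, 40, 4000, {"NFE": (3, 60000)})  # ref AF 5e-5 < 1e-4
        (res,) = classify_enrichment([rec], "AJ", ["NFE"])
        assert res.reference_pop is None and not res.enriched

    def test_failed_coverage_excludes_reference(self):
        rec = _record(
            1, 100, 4000, {"NFE": (60, 60000), "AFR": (50, 10000)},
            coverage={"AFR": False},
        )
        (res,) = classify_enrichment([rec], "AJ", ["NFE", "AFR"])
        assert res.reference_pop == "NFE"

    def test_deterministic_rerun(self, counts_records):
        a = classify_enrichment(counts_records, "AJ", ["NFE"])
        b = classify_enrichment(counts_records, "AJ", ["NFE"])
        assert [r.enriched for r in a] == [r.enriched for r in b]
        np.testing.assert_array_equal(
            [r.p_one_sided for r in a], [r.p_one_sided for r in b]
        )

    def test_enriched_implies_in_window(self, counts_records):
        for r in classify_enrichment(counts_records, "AJ", ["NFE"]):
            assert not r.enriched or r.in_window


class TestAnnotationClassProportions:
    def test_two_proportion_example(self):
        z, p = two_proportion_test(100, 300, 150, 300)
        assert z == pytest.approx(-4.14, abs=0.01)
        assert p == pytest.approx(3.5e-5, rel=0.05)

    def test_identical_proportions_give_zero(self):
        z, p = two_proportion_test(50, 100, 50, 100)
        assert z == 0.0 and p == 1.0

    def test_schema_has_all_and_per_class_rows(self, counts_records):
        results = classify_enrichment(counts_records, "AJ", ["NFE"])
        frame = annotation_class_proportions(results)
        assert "ALL" in set(frame["class"])
        assert {"n_in_window", "n_enriched", "fraction_enriched",
                "z_vs_syn", "p_vs_syn"} <= set(frame.columns)


class TestIntersectPathogenic:
    def _results(self, ps):
        out = []
        for i, p in enumerate(ps):
            rec = _record(i + 1, 100, 4000, {"NFE": (60, 60000)})
            res = classify_enrichment([rec], "AJ", ["NFE"], n_tests=1)[0]
            res.p_one_sided = p
            out.append(res)
        return out

    def _pathogenic(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                           "clinical_significance", "conflicted"])

    def test_conflicted_rows_excluded(self):
        results = self._results([1e-6] * 5)
        table = self._pathogenic([
            ("1", 1, "A", "G", "Pathogenic", False),
            ("1", 2, "A", "G", "Pathogenic", True),   # conflicted
        ])
        hits = intersect_pathogenic(results, table)
        assert [str(h.key) for h in hits] == ["1:1:A:G"]

    def test_p_cut_is_strict(self):
        results = self._results([0.005, 0.0049])
        table = self._pathogenic([
            ("1", 1, "A", "G", "Likely Pathogenic", False),
            ("1", 2, "A", "G", "Likely Pathogenic", False),
        ])
        hits = intersect_pathogenic(results, table)
        assert [str(h.key) for h in hits] == ["1:2:A:G"]

    def test_empty_table_empty_result(self):
        assert intersect_pathogenic(self._results([1e-6]), self._pathogenic([])) == []

    def test_duplicate_keys_rejected(self):
        table = self._pathogenic([
            ("1", 1, "A", "G", "Pathogenic", False),
            ("1", 1, "A", "G", "Benign", False),
        ])
        with pytest.raises(ValidationError, match="de-duplicate"):
            intersect_pathogenic(self._results([1e-6]), table)


class TestRecessiveRiskEnrichment:
    @pytest.mark.parametrize("fold,expected", [(19, 361), (1, 1), (2.5, 6.25)])
    def test_squared_enrichment(self, fold, expected):
        assert recessive_risk_enrichment(fold) == pytest.approx(expected)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            recessive_risk_enrichment(0)


def test_null_enrichment_rate_bounded():
    """Both populations drawn from one frequency: per-variant enrichment
    probability at the Bonferroni level stays below alpha/n."""
    rng = np.random.default_rng(11)
    n = 10_000
    f = rng.uniform(0.005, 0.08, n)
    an_s, an_r = 4000, 60000
    records = [
        _record(i + 1, int(rng.binomial(an_s, f[i])), an_s,
                {"NFE": (int(rng.binomial(an_r, f[i])), an_r)})
        for i in range(n)
    ]
    results = classify_enrichment(records, "AJ", ["NFE"])
    n_in = sum(r.in_window for r in results)
    n_enr = sum(r.enriched for r in results)
    # expected false enrichments = n_in * alpha / n_tests ~ 0.05; 95% band
    assert n_enr <= 3
    assert n_in > 0.5 * n
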