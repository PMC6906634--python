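"""Hierarchical inference: MANOVA, Wilcoxon, BH, median split, summary t."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cerephys import InvalidSpecification
from cerephys import group_stats as gs


class TestWilksManova:
    def test_identical_groups_give_lambda_one(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(10, 3))
        X = np.vstack([block, block])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        r = gs.wilks_manova(X, labels)
        assert r.wilks_lambda == pytest.approx(1.0)
        assert r.f_stat == pytest.approx(0.0, abs=1e-10)
        assert r.p == pytest.approx(1.0)

    @pytest.mark.parametrize("lam,n,expected_p,tol", [
        (0.9028, 94, 0.026, 0.002),
        (0.8266, 48, 0.0371, 0.002),
    ])
    def test_lambda_to_f_reproduces_published_p(self, lam, n, expected_p, tol):
        _, df_h, df_e, p = gs.wilks_lambda_to_f(lam, n, 3)
        assert (df_h, df_e) == (3, n - 4)
        assert p == pytest.approx(expected_p, abs=tol)

    def test_oracle_equivalence_statsmodels(self):
        from statsmodels.multivariate.manova import MANOVA

        rng = np.random.default_rng(42)
        for _ in range(30):
            X = rng.normal(size=(20, 3))
            labels = np.array(["a"] * 10 + ["b"] * 10)
            df = pd.DataFrame(X, columns=["y1", "y2", "y3"])
            df["g"] = labels
            tbl = MANOVA.from_formula("y1 + y2 + y3 ~ g",
                                      data=df).mv_test().results["g"]["stat"]
            r = gs.wilks_manova(X, labels)
            assert r.wilks_lambda == pytest.approx(
                tbl.loc["Wilks' lambda", "Value"], abs=1e-8)
            assert r.f_stat == pytest.approx(
                tbl.loc["Wilks' lambda", "F Value"], abs=1e-8)
            assert r.p == pytest.approx(
                tbl.loc["Wilks' lambda", "Pr > F"], abs=1e-8)

    def test_location_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(16, 3))
        labels = np.array(["a"] * 8 + ["b"] * 8)
        r0 = gs.wilks_manova(X, labels)
        r1 = gs.wilks_manova(X + 7.5, labels)
        assert r1.wilks_lambda == pytest.approx(r0.wilks_lambda, rel=1e-9)

    def test_requires_two_groups(self):
        X = np.random.default_rng(0).normal(size=(10, 3))
        with pytest.raises(InvalidSpecification):
            gs.wilks_manova(X, np.array(["a"] * 10))


class TestWilcoxonRankSum:
    def test_hand_computed_example(self):
        z, p = gs.wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert z == pytest.approx(-1.9640, abs=1e-4)
        assert p == pytest.approx(0.0495, abs=5e-4)

    def test_identical_multisets_give_zero(self):
        z, p = gs.wilcoxon_ranksum([1.0, 2.0, 2.0], [2.0, 1.0, 2.0])
        assert z == 0.0
        assert p == 1.0

    def test_sign_positive_when_first_sample_larger(self):
        z, _ = gs.wilcoxon_ranksum([10, 11, 12], [1, 2, 3])
        assert z > 0

    def test_oracle_equivalence_continuous(self):
        from scipy.stats import ranksums

        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.normal(size=24)
            y = rng.normal(size=24)
            z, p = gs.wilcoxon_ranksum(x, y)
            ref = ranksums(x, y)
            assert z == pytest.approx(ref.statistic, abs=1e-8)
            assert p == pytest.approx(ref.pvalue, abs=1e-8)

    def test_oracle_equivalence_with_ties(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(8)
        for _ in range(100):
            x = rng.integers(0, 5, 15).astype(float)
            y = rng.integers(0, 5, 12).astype(float)
            _, p = gs.wilcoxon_ranksum(x, y)
            ref = mannwhitneyu(x, y, use_continuity=False,
                               method="asymptotic", alternative="two-sided")
            assert p == pytest.approx(ref.pvalue, abs=1e-8)


class TestBenjaminiHochberg:
    def test_all_rejected_example(self):
        reject, crit = gs.benjamini_hochberg([0.01, 0.03, 0.04], fdr=0.2)
        assert np.allclose(crit, [0.2 / 3, 0.4 / 3, 0.2])
        assert reject.all()

    def test_none_rejected(self):
        reject, _ = gs.benjamini_hochberg([0.9, 0.95], fdr=0.2)
        assert not reject.any()

    def test_empty_input(self):
        reject, crit = gs.benjamini_hochberg([])
        assert reject.size == 0 and crit.size == 0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12),
           st.floats(0.01, 0.5))
    def test_brute_force_step_up_oracle(self, pvals, fdr):
        reject, _ = gs.benjamini_hochberg(pvals, fdr)
        m = len(pvals)
        order = np.argsort(np.asarray(pvals), kind="stable")
        ks = [i + 1 for i in range(m)
              if pvals[order[i]] <= (i + 1) / m * fdr]
        expected = np.zeros(m, dtype=bool)
        if ks:
            expected[order[:max(ks)]] = True
        assert np.array_equal(reject, expected)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=10))
    def test_monotone_in_fdr(self, pvals):
        r1, _ = gs.benjamini_hochberg(pvals, 0.05)
        r2, _ = gs.benjamini_hochberg(pvals, 0.2)
        assert np.all(r2 | ~r1)  # raising fdr never shrinks the set


class TestMedianSplit:
    def test_even_split(self):
        labels, degenerate = gs.median_split([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]
        assert not degenerate

    def test_all_equal_is_degenerate(self):
        _, degenerate = gs.median_split([5, 5, 5])
        assert degenerate

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=31,
                    unique=True))
    def test_odd_n_splits_within_one(self, values):
        labels, _ = gs.median_split(values)
        n_low = int((labels == "low").sum())
        n_high = len(values) - n_low
        if len(values) % 2 == 1:
            assert abs(n_low - n_high) == 1


class TestTFromSummary:
    @pytest.mark.parametrize("args,expected_t", [
        ((152.3, 3.7, 3, 155.7, 4.0, 3), -0.623),
        ((569.2, 32.7, 3, 578.7, 6.7, 3), -0.286),
        ((36.11, 3.12, 3, 33.19, 1.14, 3), 0.880),
    ])
    def test_published_anatomy_t_statistics(self, args, expected_t):
        r = gs.t_from_summary(*args)
        assert r.t == pytest.approx(expected_t, abs=0.01)
        assert r.df == 4

    def test_equal_means_give_zero(self):
        r = gs.t_from_summary(5.0, 1.0, 3, 5.0, 1.0, 3)
        assert r.t == 0.0 and r.p == pytest.approx(1.0)

    def test_zero_sem_flagged_infinite(self):
        r = gs.t_from_summary(5.0, 0.0, 3, 6.0, 0.0, 3)
        assert np.isinf(r.t)


@pytest.fixture(scope="module")
def metrics():
    from cerephys import synthdata as sd
    from cerephys.spike_metrics import metrics_frame

    return metrics_frame(sd.gen_cohort(sd.awake_purkinje_cohort(2)))


class TestAnalysisWorkflow:
    def test_genotype_effect_detected_and_rate_rejected(self, metrics):
        report = gs.analysis_workflow(metrics, "ss")
        entry = report.predictors["genotype"]
        assert entry["gate_passed"]
        by_resp = {p.response: p for p in entry["pairwise"]}
        assert by_resp["rate_hz"].rejected
        assert by_resp["rate_hz"].direction == "control > mdx"

    def test_numeric_predictors_are_median_split(self, metrics):
        report = gs.analysis_workflow(metrics, "ss")
        assert report.predictors["depth_mm"]["binarized"]

    def test_constant_predictor_skipped(self, metrics):
        m = metrics.copy()
        m["days_post_surgery"] = 5.0
        report = gs.analysis_workflow(m, "ss")
        assert "skipped" in report.predictors["days_post_surgery"]

    def test_report_serializes_to_json(self, metrics):
        import json

        report = gs.analysis_workflow(metrics, "ss")
        data = json.loads(report.to_json())
        assert data["unit_type"] == "ss"
        assert "manova" in data["predictors"]["genotype"]
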