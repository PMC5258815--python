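"""Exact contingency tests, confusion metrics, rank tests, IQR fences."""

from __future__ import annotations

import subprocess

import numpy as np
import pytest

from camrspot.errors import CapabilityError, InsufficientDataError
from camrspot.records import CoarseCategory, FinePattern
from camrspot.stats import (
    OutlierFlag,
    TestMethod,
    confusion_metrics,
    exact_pvalue_cdf_terms,
    fisher_exact_2x2,
    fisher_exact_rxc,
    iqr_outliers,
    kruskal_wallis,
    mann_whitney,
    association_report,
)

from _oracles import (
    fisher2x2_oracle,
    freeman_halton_oracle,
    tukey_fences_oracle,
)


class TestFisher2x2:
    def test_symmetric_margins_give_p_one(self):
        assert fisher_exact_2x2([[2, 3], [3, 2]]).p_value == pytest.approx(1.0)

    def test_proteinuria_failure_table(self):
        res = fisher_exact_2x2([[10, 15], [1, 26]])
        assert res.p_value == pytest.approx(0.002, abs=5e-4)

    def test_matches_enumeration_oracle_on_random_small_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tab = rng.integers(0, 8, size=(2, 2))
            if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                continue
            ours = fisher_exact_2x2(tab).p_value
            oracle = float(fisher2x2_oracle(tab.tolist()))
            assert ours == pytest.approx(oracle, rel=1e-9)

    def test_empty_margin_is_degenerate_p_one(self):
        res = fisher_exact_2x2([[0, 0], [3, 5]])
        assert res.p_value == 1.0 and res.degenerate

    def test_two_sided_at_least_one_sided(self):
        import scipy.stats as st

        rng = np.random.default_rng(1)
        for _ in range(50):
            tab = rng.integers(0, 10, size=(2, 2))
            if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                continue
            two = fisher_exact_2x2(tab).p_value
            one = min(
                st.fisher_exact(tab, alternative="less")[1],
                st.fisher_exact(tab, alternative="greater")[1],
            )
            assert two >= one - 1e-12


class TestFreemanHalton:
    def test_2x2_reduces_to_fisher(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            tab = rng.integers(0, 10, size=(2, 2))
            if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                continue
            assert fisher_exact_rxc(tab).p_value == pytest.approx(
                fisher_exact_2x2(tab).p_value, rel=1e-9
            )

    def test_transition_table_p_value(self):
        # three phenotype-trajectory groups × stable/deteriorating
        res = fisher_exact_rxc([[8, 2], [10, 8], [2, 7]])
        assert res.p_value == pytest.approx(0.04795131, abs=1e-6)

    def test_matches_enumeration_oracle_on_3x2_tables(self):
        rng = np.random.default_rng(3)
        checked = 0
        while checked < 40:
            tab = rng.integers(0, 5, size=(3, 2))
            if tab.sum() == 0 or tab.sum() > 12:
                continue
            if tab.sum(axis=0).min() == 0 or tab.sum(axis=1).min() == 0:
                continue
            ours = fisher_exact_rxc(tab).p_value
            oracle = float(freeman_halton_oracle(tab))
            assert ours == pytest.approx(oracle, rel=1e-9)
            checked += 1

    def test_agrees_with_r_fisher_test(self):
        """Independent cross-check against R's fisher.test network algorithm."""
        out = subprocess.run(
            ["Rscript", "-e",
             "cat(fisher.test(matrix(c(8,2,10,8,2,7),nrow=3,byrow=TRUE))$p.value)"],
            capture_output=True, text=True, timeout=120,
        )
        r_p = float(out.stdout.strip())
        ours = fisher_exact_rxc([[8, 2], [10, 8], [2, 7]]).p_value
        assert ours == pytest.approx(r_p, rel=1e-6)

    def test_large_table_requires_monte_carlo(self):
        big = [[60, 80], [70, 50], [40, 90]]
        with pytest.raises(CapabilityError):
            fisher_exact_rxc(big)
        mc = fisher_exact_rxc(big, monte_carlo=True, n_draws=20000, seed=9)
        assert mc.method is TestMethod.FISHER_RXC_MC
        exact = fisher_exact_rxc(big, max_n=1000)
        assert mc.p_value == pytest.approx(exact.p_value, abs=0.02)

    def test_randomized_pvalue_terms_are_coherent(self):
        p_less, p_equal = exact_pvalue_cdf_terms([[8, 2], [10, 8], [2, 7]])
        p = fisher_exact_rxc([[8, 2], [10, 8], [2, 7]]).p_value
        assert p_less + p_equal == pytest.approx(p, abs=1e-9)
        assert 0 <= p_less <= 1 and 0 < p_equal <= 1


class TestConfusionMetrics:
    def test_proteinuria_graft_failure_footnote(self):
        m = confusion_metrics([[10, 15], [1, 26]])
        assert (m.sensitivity, m.ppv, m.npv, m.specificity) == (91, 40, 96, 63)

    def test_ptc_score_footnote_fraction_derived(self):
        m = confusion_metrics([[7, 8], [4, 33]])
        assert (m.sensitivity, m.npv, m.specificity) == (64, 89, 80)
        assert m.ppv == 47  # 7/15, printed footnote value is inconsistent

    def test_half_up_rounding(self):
        # 28/32 = 87.5 rounds up to 88
        m = confusion_metrics([[7, 11], [4, 28]])
        assert m.npv == 88
        assert m.specificity == 72  # 28/39

    def test_perfect_classifier(self):
        m = confusion_metrics([[12, 0], [0, 30]])
        assert (m.sensitivity, m.specificity, m.ppv, m.npv) == (100, 100, 100, 100)

    def test_zero_denominator_reported_absent(self):
        m = confusion_metrics([[0, 0], [5, 7]])
        assert m.sensitivity is None or m.ppv is None

    def test_transposed_orientation_swaps_sensitivity_and_ppv(self):
        tab = np.array([[9, 4], [3, 21]])
        m = confusion_metrics(tab)
        mt = confusion_metrics(tab.T)
        assert m.fractions["sensitivity"] == mt.fractions["ppv"]
        assert m.fractions["ppv"] == mt.fractions["sensitivity"]


class TestRankTests:
    def test_identical_samples_do_not_reject(self):
        res = mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value >= 0.99

    def test_exact_small_sample_p(self):
        # fully separated 3 vs 3: two orderings of C(6,3) = 20 are as extreme
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, rel=1e-9)

    def test_kruskal_all_equal_groups(self):
        res = kruskal_wallis([[5.0, 5.0], [5.0, 5.0, 5.0]])
        assert res.p_value == pytest.approx(1.0)

    def test_kruskal_separated_groups(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(mu, 1.0, 10) for mu in (0, 3, 6)]
        assert kruskal_wallis(groups).p_value < 0.01

    def test_two_group_kruskal_consistent_with_mann_whitney(self):
        rng = np.random.default_rng(5)
        agree = 0
        for _ in range(100):
            a = rng.normal(0, 1, 12)
            b = rng.normal(rng.choice([0.0, 1.5]), 1, 12)
            kw = kruskal_wallis([a, b]).p_value < 0.05
            mw = mann_whitney(a, b).p_value < 0.05
            agree += kw == mw
        assert agree >= 95  # same decision except tie-handling edge cases


class TestIqrOutliers:
    def test_extreme_outlier_detected(self):
        flags = iqr_outliers([1, 2, 3, 4, 100])
        assert flags[-1] is OutlierFlag.EXTREME
        assert all(f is OutlierFlag.INLIER for f in flags[:-1])

    def test_constant_values_have_no_outliers(self):
        assert set(iqr_outliers([7.0] * 6)) == {OutlierFlag.INLIER}

    def test_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            iqr_outliers([1.0, 2.0, 3.0])

    def test_agrees_with_direct_fence_arithmetic(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            values = rng.standard_cauchy(rng.integers(4, 40))
            ours = [f.value for f in iqr_outliers(values)]
            assert ours == tukey_fences_oracle(values)


@pytest.fixture(scope="module")
def engineered():
    """Cohort where the t2 category drives eGFR decline (default scenario)."""
    from camrspot.classify import classify_cohort
    from camrspot.simulate import SyntheticCohortConfig, generate_cohort
    from camrspot.trajectory import compute_delta_egfr, dichotomize

    config = SyntheticCohortConfig(
        n_protcl=30, n_bfc=70, nonviable_prob=0.05, residual_sd=2.0
    )
    cohort, _ = generate_cohort(config, seed=21)
    calls = classify_cohort(cohort)
    deltas = []
    for series in cohort.egfr:
        try:
            deltas.append(compute_delta_egfr(series))
        except Exception:
            pass
    labels = dichotomize(
        deltas, {p.patient_id: p.subgroup for p in cohort.patients}
    )
    return cohort, calls, labels


class TestAssociationReport:
    def test_engineered_signal_detected(self, engineered):
        cohort, calls, labels = engineered
        reports = association_report(cohort, calls, labels)
        det = reports["deteriorating"].set_index("predictor")
        assert det.loc["bdep_t2", "fisher_p"] < 0.05

    def test_row_counts_and_columns(self, engineered):
        cohort, calls, labels = engineered
        reports = association_report(cohort, calls, labels)
        for frame in reports.values():
            assert list(frame.columns) == [
                "predictor", "a", "b", "c", "d", "fisher_p",
                "sens", "spec", "ppv", "npv",
            ]
            assert len(frame) <= 15  # predictors minus skips
            assert (frame["fisher_p"] <= 1).all()
            # counts reconcile with per-predictor complete cases
            assert (frame[["a", "b", "c", "d"]].sum(axis=1) > 0).all()
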