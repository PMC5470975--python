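import itertools

import numpy as np
import pandas as pd
import pytest

from lncprog.exceptions import ConvergenceError, DegenerateSplitError, DomainError
from lncprog.survival import (
    KMCurve,
    chi_square_association,
    cox_fit,
    ipi_stratified_analysis,
    km_estimate,
    log_rank,
    mean_split,
    roc_auc,
    survival_report,
)

from .oracles import brute_force_cox_coef, hand_product_limit


class TestMeanSplit:
    def test_rule_application(self):
        split = mean_split(pd.Series([1, 2, 3, 4, 5, 15]))
        assert split.threshold == 5.0
        assert split.n_low == 4 and split.n_high == 2

    def test_value_at_mean_goes_high(self):
        split = mean_split(pd.Series([4.0, 6.0, 5.0]))  # mean 5: the 5 is "high"
        assert split.labels.iloc[2] == "high"

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateSplitError):
            mean_split(pd.Series([2.0, 2.0, 2.0]))


class TestKaplanMeier:
    def test_all_events_product_limit(self):
        curve = km_estimate([5, 10, 15], [1, 1, 1])
        assert curve.survival == pytest.approx([2 / 3, 1 / 3, 0.0])
        assert curve.survival_at(0) == 1.0
        assert curve.survival_at(12) == pytest.approx(1 / 3)

    def test_censoring_removes_subject_without_step(self):
        curve = km_estimate([5, 10, 15], [1, 0, 1])
        assert curve.survival == pytest.approx([2 / 3, 0.0])
        assert curve.survival_at(10) == pytest.approx(2 / 3)  # unchanged at censor time

    def test_no_events_flat_at_one(self):
        curve = km_estimate([3, 6, 9], [0, 0, 0])
        assert curve.survival_at(9) == 1.0
        assert len(curve.event_times) == 0

    def test_matches_hand_product_limit_on_random_data(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = rng.integers(3, 30)
            times = rng.integers(1, 15, n).astype(float)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                continue
            curve = km_estimate(times, events)
            hand = hand_product_limit(times, events)
            assert curve.event_times == pytest.approx([h[0] for h in hand])
            assert curve.survival == pytest.approx([h[3] for h in hand])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(9)
        times = rng.exponential(10, 40)
        curve = km_estimate(times, np.ones(40, int))
        for t in [1.0, 5.0, 12.0]:
            assert curve.survival_at(t) == pytest.approx((times > t).mean())

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups_null(self):
        times = [5, 10, 15, 5, 10, 15]
        events = [1, 1, 1, 1, 1, 1]
        chi2, df, p = log_rank(times, events, ["a"] * 3 + ["b"] * 3)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 1
        assert p == pytest.approx(1.0)

    def test_invariant_to_time_rescaling(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, 60)
        events = rng.integers(0, 2, 60)
        groups = np.repeat(["a", "b"], 30)
        chi2a, _, pa = log_rank(times, events, groups)
        chi2b, _, pb = log_rank(times * 7.3, events, groups)
        assert chi2a == pytest.approx(chi2b)
        assert pa == pytest.approx(pb)

    def test_single_group_rejected(self):
        with pytest.raises(DomainError):
            log_rank([1, 2], [1, 1], ["a", "a"])

    def test_power_at_planted_hazard_ratio(self):
        # cohort shaped like the emulated study: 116 low / 54 high, HR 1.7
        rng = np.random.default_rng(31)
        pvals = []
        for _ in range(60):
            lam = np.log(2) / 78.0
            t_low = rng.exponential(1 / (lam * 1.7), 116)
            t_high = rng.exponential(1 / lam, 54)
            times = np.concatenate([t_low, t_high])
            events = np.ones(170, int)
            _, _, p = log_rank(times, events, np.repeat(["low", "high"], [116, 54]))
            pvals.append(p)
        assert np.median(pvals) < 0.05


class TestCoxFit:
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_matches_brute_force_on_small_instances(self, ties):
        rng = np.random.default_rng(13)
        instances = []
        # untied instances plus heavily tied ones, n <= 8, binary covariate
        for _ in range(6):
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 2, n).astype(float)
            if len(set(x)) < 2:
                x[0] = 1 - x[0]
            times = rng.choice([1.0, 2.0, 3.0, 5.0, 8.0], n)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            instances.append((x, times, events))
        instances.append(
            (np.array([1.0, 1, 0, 0, 1, 0]), np.array([3.0, 1, 4, 1, 5, 9]),
             np.array([1, 1, 1, 0, 1, 1]))
        )
        for x, times, events in instances:
            fit = cox_fit(pd.DataFrame({"x": x}), times, events, ties=ties)
            if fit.diverged:
                continue  # monotone likelihood: brute force hits the bound too
            oracle = brute_force_cox_coef(x, times, events, ties)
            assert fit.coef[0] == pytest.approx(oracle, abs=1e-6)

    def test_constant_covariate_is_uninformative(self):
        fit = cox_fit(
            pd.DataFrame({"x": np.ones(6)}), [1, 2, 3, 4, 5, 6], [1, 1, 1, 0, 1, 1]
        )
        assert fit.coef[0] == 0.0
        assert fit.hazard_ratio[0] == 1.0
        assert fit.p[0] == 1.0

    def test_agrees_with_lifelines_efron(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(8)
        n = 80
        x = rng.normal(size=n)
        times = rng.exponential(np.exp(-0.5 * x))
        events = rng.integers(0, 2, n)
        events[0] = 1
        frame = pd.DataFrame({"t": times, "e": events, "x": x})
        cph = CoxPHFitter().fit(frame, duration_col="t", event_col="e")
        fit = cox_fit(pd.DataFrame({"x": x}), times, events, ties="efron")
        assert fit.coef[0] == pytest.approx(cph.params_["x"], abs=1e-6)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_hazard_ratio_recovery_at_study_size(self):
        rng = np.random.default_rng(21)
        hrs = []
        for _ in range(100):
            x = (rng.random(170) < 116 / 170).astype(float)
            lam = np.log(2) / 78.0 * np.where(x == 1, 1.7, 1.0)
            times = rng.exponential(1 / lam)
            fit = cox_fit(pd.DataFrame({"low": x}), times, np.ones(170, int))
            hrs.append(fit.hazard_ratio[0])
        assert 1.6 <= np.mean(hrs) <= 1.8

    def test_wald_interval_contains_hr(self):
        rng = np.random.default_rng(5)
        x = (rng.random(50) < 0.5).astype(float)
        times = rng.exponential(10, 50)
        fit = cox_fit(pd.DataFrame({"x": x}), times, np.ones(50, int))
        assert fit.ci_low[0] <= fit.hazard_ratio[0] <= fit.ci_high[0]

    def test_separation_flagged_not_crashed(self):
        # covariate perfectly ordering survival: monotone likelihood
        x = np.array([1.0, 1, 1, 0, 0, 0])
        times = np.array([1.0, 2, 3, 10, 11, 12])
        with pytest.warns(RuntimeWarning):
            fit = cox_fit(pd.DataFrame({"x": x}), times, np.ones(6, int))
        assert fit.diverged

    def test_no_events_rejected(self):
        with pytest.raises(DomainError):
            cox_fit(pd.DataFrame({"x": [1.0, 0.0]}), [1, 2], [0, 0])


class TestRocAuc:
    def test_perfect_and_constant_markers(self):
        perfect = roc_auc([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert perfect.auc == 1.0
        flat = roc_auc([2.0] * 6, [0, 0, 0, 1, 1, 1])
        assert flat.auc == 0.5

    def test_curve_endpoints(self):
        res = roc_auc([1, 3, 2, 8, 7, 9], [0, 0, 0, 1, 1, 1])
        assert (res.fpr[0], res.tpr[0]) == (0.0, 0.0)
        assert (res.fpr[-1], res.tpr[-1]) == (1.0, 1.0)

    def test_auc_complement_under_negation(self):
        rng = np.random.default_rng(1)
        marker = rng.normal(size=100)
        outcome = (rng.random(100) < 0.4).astype(int)
        a = roc_auc(marker, outcome).auc
        b = roc_auc(-marker, outcome).auc
        assert a + b == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        marker = rng.normal(size=200)
        outcome = (rng.random(200) < 0.5).astype(int)
        outcome[0], outcome[1] = 0, 1
        a = roc_auc(marker, outcome).auc
        b = roc_auc(np.exp(2 * marker), outcome).auc
        assert a == pytest.approx(b)

    def test_single_class_rejected(self):
        with pytest.raises(DomainError):
            roc_auc([1, 2, 3], [1, 1, 1])


class TestChiSquare:
    def test_printed_genotype_table(self):
        # GCB 26 low / 44 high vs non-GCB 90 low / 10 high
        chi2, df, p = chi_square_association([[26, 44], [90, 10]])
        assert chi2 == pytest.approx(53.0, abs=0.2)
        assert df == 1
        assert p < 1e-10

    def test_identical_proportions_null(self):
        chi2, _, p = chi_square_association([[10, 20], [30, 60]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_squared_two_proportion_z(self):
        table = np.array([[35, 15], [20, 30]])
        chi2, _, _ = chi_square_association(table)
        n1, n2 = table.sum(axis=1)
        p1, p2 = table[0, 0] / n1, table[1, 0] / n2
        pooled = table[:, 0].sum() / table.sum()
        z = (p1 - p2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        assert chi2 == pytest.approx(z**2)

    def test_zero_margin_rejected(self):
        with pytest.raises(DomainError):
            chi_square_association([[0, 0], [5, 3]])


class TestStratifiedAndReport:
    def _cohort(self, rng, n=200, hr=2.0):
        marker = rng.normal(5, 1, n)
        low = marker < marker.mean()
        lam = 0.01 * np.where(low, hr, 1.0)
        sheet = pd.DataFrame(
            {
                "sample_id": [f"P{i}" for i in range(n)],
                "group": "DLBCL",
                "subtype": rng.choice(["GCB", "non-GCB"], n),
                "time": rng.exponential(1 / lam),
                "event": 1,
                "endpoint": "OS",
                "gender": rng.choice(["Male", "Female"], n),
                "age": 60,
                "ipi": rng.choice(6, n),
            }
        ).set_index("sample_id", drop=False)
        return pd.Series(marker, index=sheet.index), sheet

    def test_effect_detected_in_both_ipi_strata(self):
        rng = np.random.default_rng(42)
        marker, sheet = self._cohort(rng, n=340, hr=2.0)
        strata = ipi_stratified_analysis(marker, sheet)
        assert set(strata) == {"ipi_low_0_2", "ipi_high_3_5"}
        for res in strata.values():
            assert res["log_rank"]["p"] < 0.05
            assert res["cox"].hazard_ratio[0] > 1.0

    def test_all_ipi_missing_skips_cleanly(self):
        rng = np.random.default_rng(0)
        marker, sheet = self._cohort(rng, n=40)
        sheet["ipi"] = np.nan
        assert ipi_stratified_analysis(marker, sheet) == {}

    def test_null_marker_hr_near_one(self):
        rng = np.random.default_rng(77)
        hrs = []
        for _ in range(60):
            n = 120
            marker = pd.Series(rng.normal(size=n), index=[f"P{i}" for i in range(n)])
            sheet = pd.DataFrame(
                {
                    "sample_id": marker.index,
                    "group": "DLBCL",
                    "time": rng.exponential(50, n),
                    "event": 1,
                    "endpoint": "OS",
                },
                index=marker.index,
            )
            split_low = (marker < marker.mean()).astype(float)
            fit = cox_fit(
                pd.DataFrame({"low": split_low}),
                sheet["time"].to_numpy(),
                sheet["event"].to_numpy(),
            )
            hrs.append(fit.hazard_ratio[0])
        assert 0.9 <= np.mean(hrs) <= 1.1

    def test_survival_report_bookkeeping(self):
        rng = np.random.default_rng(3)
        marker, sheet = self._cohort(rng)
        report = survival_report(sheet, marker, covariates=["gender", "subtype", "ipi_group"])
        assert report["n_low"] + report["n_high"] == report["n"]
        assert set(report["five_year"]) == {"low", "high"}
        assert report["univariate"]["low_vs_high"].hazard_ratio[0] > 1
        assert "multivariate" in report and "low_vs_high" in report["multivariate"].names

    def test_report_without_covariates_omits_multivariate(self):
        rng = np.random.default_rng(3)
        marker, sheet = self._cohort(rng, n=60)
        report = survival_report(sheet, marker)
        assert "multivariate" not in report
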