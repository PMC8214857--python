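import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from irgpi import (
    EmptyInputError,
    ParameterError,
    SimulationConfig,
    ValidationError,
    cox_multivariate,
    evaluate,
    harrell_c,
    km_logrank,
    resample_c,
    rms_ratio,
    simulate_cohort,
    time_dependent_auc,
)

from _oracles import (
    efron_log_partial_likelihood,
    naive_harrell_c,
    naive_ipcw_auc,
    naive_logrank_chi2,
    naive_rms,
)
from conftest import random_survival


def _groups_from(scores):
    return np.where(np.asarray(scores) > np.median(scores), "HRisk", "LRisk")


class TestKmLogrank:
    def test_null_split_gives_small_statistic(self, rng):
        n = 400
        surv = random_survival(rng, n, tie_heavy=False)
        groups = np.where(rng.random(n) > 0.5, "HRisk", "LRisk")
        res = km_logrank(groups, surv)
        assert res.p > 0.01  # random labels: no separation expected
        assert res.chi2 < 7

    def test_matches_textbook_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 25))
            surv = random_survival(rng, n, tie_heavy=True)
            if surv["event"].sum() == 0:
                continue
            groups = np.where(rng.random(n) > 0.5, "HRisk", "LRisk")
            if len(set(groups)) < 2:
                continue
            res = km_logrank(groups, surv)
            oracle = naive_logrank_chi2(
                surv["time"].to_numpy(), surv["event"].to_numpy(),
                (groups == "HRisk").astype(int),
            )
            assert res.chi2 == pytest.approx(oracle, rel=1e-8)

    def test_empty_group_errors(self, toy_surv):
        with pytest.raises(EmptyInputError):
            km_logrank(["HRisk"] * 5, toy_surv)

    def test_km_curves_match_product_limit(self, rng):
        from _oracles import naive_km

        surv = random_survival(rng, 20, tie_heavy=True)
        groups = np.array(["HRisk"] * 10 + ["LRisk"] * 10)
        res = km_logrank(groups, surv)
        for label in ("HRisk", "LRisk"):
            mask = groups == label
            kt, ks = naive_km(surv["time"].to_numpy()[mask], surv["event"].to_numpy()[mask])
            curve = res.km_curves[label]["survival"]
            for t, s in zip(kt, ks):
                assert curve.loc[t] == pytest.approx(s, rel=1e-10)


class TestCoxMultivariate:
    def test_null_covariate_hr_near_one(self, rng):
        n = 600
        surv = random_survival(rng, n, tie_heavy=False)
        surv["noise"] = rng.normal(size=n)
        out = cox_multivariate(surv)
        assert out.loc["noise", "hr"] == pytest.approx(1.0, abs=0.2)
        assert out.loc["noise", "ci_low"] < 1 < out.loc["noise", "ci_high"]

    def test_matches_partial_likelihood_maximiser(self, rng):
        n = 50
        surv = random_survival(rng, n, tie_heavy=False)
        x1 = rng.integers(0, 2, n).astype(float)
        x2 = rng.normal(size=n)
        surv["time"] = rng.exponential(1 / np.exp(0.8 * x1 - 0.5 * x2) / 0.1)
        surv["event"] = 1
        surv["x1"], surv["x2"] = x1, x2
        out = cox_multivariate(surv)
        X = np.column_stack([x1, x2])
        res = minimize(
            lambda b: -efron_log_partial_likelihood(
                b, X, surv["time"].to_numpy(), surv["event"].to_numpy()
            ),
            x0=[0.0, 0.0],
            method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-12},
        )
        assert np.log(out["hr"].to_numpy()) == pytest.approx(res.x, abs=1e-3)

    def test_constant_covariate_rejected(self, toy_surv):
        surv = toy_surv.copy()
        surv["flat"] = 1.0
        with pytest.raises(ValidationError, match="flat"):
            cox_multivariate(surv)


class TestHarrellC:
    def test_perfect_and_reversed_concordance(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        surv = pd.DataFrame({"time": time, "event": [1] * 5},
                            index=[f"r{i}" for i in range(5)])
        assert harrell_c(-time, surv) == 1.0  # score = negated time: perfect
        assert harrell_c(time, surv) == 0.0

    def test_matches_pairwise_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(10, 21))
            surv = random_survival(rng, n, tie_heavy=True)
            scores = rng.integers(0, 6, size=n).astype(float)
            try:
                oracle = naive_harrell_c(scores, surv["time"].to_numpy(),
                                         surv["event"].to_numpy())
            except ZeroDivisionError:
                with pytest.raises(EmptyInputError):
                    harrell_c(scores, surv)
                continue
            assert harrell_c(scores, surv) == pytest.approx(oracle, abs=1e-12)

    def test_complement_identity_without_ties(self, rng):
        n = 40
        surv = random_survival(rng, n, tie_heavy=False)
        scores = rng.normal(size=n)
        assert harrell_c(scores, surv) + harrell_c(-scores, surv) == pytest.approx(1.0)


class TestResampleC:
    def test_full_fraction_is_degenerate(self, rng):
        n = 100
        surv = random_survival(rng, n, tie_heavy=False)
        scores = rng.normal(size=n)
        mean, sd, _ = resample_c(scores, surv, fraction=1.0, reps=50, seed=1)
        assert sd == 0.0
        assert mean == pytest.approx(harrell_c(scores, surv))

    def test_fixed_seed_bit_identical(self, rng):
        n = 80
        surv = random_survival(rng, n, tie_heavy=False)
        scores = rng.normal(size=n)
        out1 = resample_c(scores, surv, reps=200, seed=42)
        out2 = resample_c(scores, surv, reps=200, seed=42)
        assert out1 == out2

    def test_bad_fraction_rejected(self, toy_surv):
        with pytest.raises(ParameterError):
            resample_c([1, 2, 3, 4, 5], toy_surv, fraction=1.5, reps=10)


class TestTimeDependentAuc:
    def test_null_score_near_half(self):
        cohort = simulate_cohort(
            SimulationConfig(n_samples=2000, n_genes=10, n_true_pairs=1,
                             beta_range=(1e-8, 1e-8), seed=3)
        )
        rng = np.random.default_rng(5)
        noise = rng.normal(size=2000)
        aucs = time_dependent_auc(noise, cohort.surv, [36.0, 60.0, 120.0])
        for v in aucs.values():
            assert v == pytest.approx(0.5, abs=0.05)

    def test_perfect_score_is_one(self):
        time = np.arange(1.0, 21.0)
        surv = pd.DataFrame({"time": time, "event": [1] * 20},
                            index=[f"r{i}" for i in range(20)])
        aucs = time_dependent_auc(-time, surv, [10.5])
        assert aucs[10.5] == 1.0

    def test_matches_ipcw_oracle_under_censoring(self, rng):
        for _ in range(25):
            n = 15
            surv = random_survival(rng, n, tie_heavy=True)
            scores = rng.normal(size=n)
            horizon = float(np.quantile(surv["time"], 0.6))
            ok = ((surv["event"] == 1) & (surv["time"] <= horizon)).any() and (
                surv["time"] > horizon
            ).any()
            if not ok or horizon >= surv["time"].max():
                continue
            mine = time_dependent_auc(scores, surv, [horizon])[horizon]
            oracle = naive_ipcw_auc(
                scores, surv["time"].to_numpy(), surv["event"].to_numpy(), horizon
            )
            assert mine == pytest.approx(oracle, abs=1e-12)

    def test_agrees_with_sksurv_estimator(self, rng):
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv

        n = 120
        surv = random_survival(rng, n, tie_heavy=False)
        scores = rng.normal(size=n)
        horizon = float(np.quantile(surv["time"], 0.5))
        y = Surv.from_arrays(event=surv["event"].to_numpy().astype(bool),
                             time=surv["time"].to_numpy())
        reference, _ = cumulative_dynamic_auc(y, y, scores, [horizon])
        mine = time_dependent_auc(scores, surv, [horizon])[horizon]
        assert mine == pytest.approx(reference[0], abs=1e-10)

    def test_no_events_before_horizon_errors(self):
        surv = pd.DataFrame({"time": [5.0, 6.0, 7.0], "event": [0, 1, 1]},
                            index=["a", "b", "c"])
        with pytest.raises(ValidationError):
            time_dependent_auc([1.0, 2.0, 3.0], surv, [2.0])


class TestRmsRatio:
    def test_identical_groups_ratio_one(self, rng):
        base = random_survival(rng, 60, tie_heavy=False)
        doubled = pd.concat([base, base.set_index(base.index + "_copy")])
        groups = ["HRisk"] * 60 + ["LRisk"] * 60  # literally the same survival
        assert rms_ratio(groups, doubled) == pytest.approx(1.0, abs=1e-12)

    def test_step_area_arithmetic(self):
        # HRisk: all events at t=1; LRisk: no events before tau=10
        surv = pd.DataFrame(
            {"time": [1.0, 1.0, 1.0, 10.0, 10.0, 10.0], "event": [1, 1, 1, 0, 0, 0]},
            index=[f"r{i}" for i in range(6)],
        )
        groups = ["HRisk"] * 3 + ["LRisk"] * 3
        assert rms_ratio(groups, surv, tau=10.0) == pytest.approx(0.1)

    def test_matches_step_integration_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(12, 30))
            surv = random_survival(rng, n, tie_heavy=True)
            groups = np.where(rng.random(n) > 0.5, "HRisk", "LRisk")
            if len(set(groups)) < 2:
                continue
            t, e = surv["time"].to_numpy(), surv["event"].to_numpy()
            tau = float(min(t[groups == "HRisk"].max(), t[groups == "LRisk"].max()))
            mine = rms_ratio(groups, surv, tau=tau)
            oracle = naive_rms(t[groups == "HRisk"], e[groups == "HRisk"], tau) / naive_rms(
                t[groups == "LRisk"], e[groups == "LRisk"], tau
            )
            assert mine == pytest.approx(oracle, rel=1e-9)

    def test_dominated_curve_gives_ratio_below_one(self, rng):
        n = 300
        t_h = rng.exponential(5, n // 2)
        t_l = rng.exponential(20, n // 2)
        surv = pd.DataFrame(
            {"time": np.concatenate([t_h, t_l]) + 0.01, "event": [1] * n},
            index=[f"r{i}" for i in range(n)],
        )
        groups = ["HRisk"] * (n // 2) + ["LRisk"] * (n // 2)
        assert rms_ratio(groups, surv) < 1.0

    def test_tau_beyond_positive_curve_rejected(self):
        # HRisk ends censored with S > 0: no extrapolation allowed past it
        surv = pd.DataFrame(
            {"time": [1.0, 2.0, 5.0, 1.0, 2.0, 9.0], "event": [1, 1, 0, 1, 1, 1]},
            index=[f"r{i}" for i in range(6)],
        )
        groups = ["HRisk"] * 3 + ["LRisk"] * 3
        with pytest.raises(ParameterError):
            rms_ratio(groups, surv, tau=8.0)


def test_statistics_invariant_to_sample_reordering(rng):
    n = 60
    surv = random_survival(rng, n, tie_heavy=True)
    scores = rng.normal(size=n)
    groups = _groups_from(scores)
    horizon = float(np.quantile(surv["time"], 0.6))
    perm = rng.permutation(n)
    surv_p = surv.iloc[perm]
    c1, c2 = harrell_c(scores, surv), harrell_c(scores[perm], surv_p)
    assert c1 == pytest.approx(c2, abs=1e-12)
    assert km_logrank(groups, surv).chi2 == pytest.approx(
        km_logrank(groups[perm], surv_p).chi2, abs=1e-9
    )
    a1 = time_dependent_auc(scores, surv, [horizon])[horizon]
    a2 = time_dependent_auc(scores[perm], surv_p, [horizon])[horizon]
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_true_predictor_beats_noise_at_every_horizon(default_cohort):
    rng = np.random.default_rng(0)
    noise = rng.normal(size=default_cohort.surv.shape[0])
    horizons = [36.0, 60.0, 120.0]
    true_auc = time_dependent_auc(default_cohort.eta, default_cohort.surv, horizons)
    noise_auc = time_dependent_auc(noise, default_cohort.surv, horizons)
    for h in horizons:
        assert true_auc[h] > noise_auc[h]


def test_evaluate_report_assembly(default_cohort):
    scores = default_cohort.eta.to_numpy()
    groups = _groups_from(scores)
    report = evaluate(scores, groups, default_cohort.surv, times=[36.0, 60.0],
                      reps=100, seed=2)
    assert 0 <= report.c_index <= 1
    assert all(0 <= v <= 1 for v in report.auc_at_times.values())
    assert report.rms_ratio > 0
    assert report.hr_with_ci["irgpi"]["hr"] > 1  # higher score, higher hazard
    d = report.to_dict()
    assert set(d) >= {"logrank_chi2", "c_index", "auc_at_times", "rms_ratio"}
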