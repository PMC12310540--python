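"""Long-format construction, KM, Cox partial likelihood, AJ, stepwise."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from pvhmr.multistate import (ConvergenceError, TransitionCox, aalen_johansen,
                              kaplan_meier, stepwise_select, to_multistate)
from pvhmr.simulate import simulate_event_histories


# ---------------------------------------------------------------------------
# oracle: naive Breslow partial log-likelihood (single covariate)
# ---------------------------------------------------------------------------

def naive_breslow_loglik(beta, entry, exit_, status, x):
    ll = 0.0
    for t in sorted({e for e, s in zip(exit_, status) if s == 1}):
        D = [i for i in range(len(x)) if exit_[i] == t and status[i] == 1]
        R = [i for i in range(len(x)) if entry[i] < t <= exit_[i]]
        ll += sum(beta * x[i] for i in D)
        ll -= len(D) * np.log(sum(np.exp(beta * x[j]) for j in R))
    return ll


def brute_force_beta(entry, exit_, status, x):
    res = optimize.minimize_scalar(
        lambda b: -naive_breslow_loglik(b, entry, exit_, status, x),
        bounds=(-6, 6), method="bounded",
        options={"xatol": 1e-10})
    return res.x


def cox_df(entry, exit_, status, x):
    return pd.DataFrame({"entry": entry, "exit": exit_, "status": status,
                         "x": x})


# ---------------------------------------------------------------------------
# long format
# ---------------------------------------------------------------------------

class TestToMultistate:
    def test_transformed_then_died(self, clinical_frame):
        ds = to_multistate(clinical_frame)
        p1 = ds.loc[ds.patient_id == "p1"].set_index("transition")
        assert p1.loc["1->2", ["entry", "exit", "status"]].tolist() == [0, 5, 1]
        assert p1.loc["1->3", ["entry", "exit", "status"]].tolist() == [0, 5, 0]
        assert p1.loc["2->3", ["entry", "exit", "status"]].tolist() == [5, 7, 1]

    def test_censored_alive(self, clinical_frame):
        p2 = to_multistate(clinical_frame).query("patient_id == 'p2'")
        assert len(p2) == 2
        assert (p2["exit"] == 10).all() and (p2["status"] == 0).all()

    def test_death_without_transformation(self, clinical_frame):
        p3 = to_multistate(clinical_frame).set_index(
            ["patient_id", "transition"]).loc["p3"]
        assert p3.loc["1->2", "status"] == 0
        assert p3.loc["1->3", ["exit", "status"]].tolist() == [4, 1]

    def test_one_event_row_per_patient_per_origin(self, clinical_frame):
        ds = to_multistate(clinical_frame)
        from_chronic = ds[ds.transition.isin(["1->2", "1->3"])]
        assert (from_chronic.groupby("patient_id")["status"].sum() <= 1).all()

    def test_death_before_transformation_fatal(self, clinical_frame):
        bad = clinical_frame.copy()
        bad.loc[0, "time_death"] = 3.0  # before transformation at 5
        with pytest.raises(ValueError, match="death at or before"):
            to_multistate(bad)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKaplanMeier:
    def test_uncensored_product_formula(self):
        curve = kaplan_meier([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(curve.values, [2 / 3, 1 / 3, 0.0])

    def test_all_censored_survival_one(self):
        curve = kaplan_meier([1, 2, 3], [0, 0, 0])
        assert curve.at([10.0])[0] == 1.0

    def test_mixed_fixture_manual_risk_sets(self):
        # events at 1, 2, 4; censorings at 2 (after the event) and 3
        curve = kaplan_meier([1, 2, 2, 3, 4], [1, 1, 0, 0, 1])
        np.testing.assert_allclose(curve.times, [1, 2, 4])
        np.testing.assert_allclose(curve.values, [4 / 5, 3 / 5, 0.0])
        np.testing.assert_allclose(curve.at_risk, [5, 4, 1])

    def test_empty_input_fatal(self):
        with pytest.raises(ValueError):
            kaplan_meier([], [])


# ---------------------------------------------------------------------------
# Cox fitting
# ---------------------------------------------------------------------------

class TestTransitionCox:
    FIXTURES = [
        # (entry, exit, status, x) — small designs incl. ties & truncation
        ([0, 0, 0, 0, 0, 0], [1, 2, 3, 4, 5, 6], [1, 0, 1, 1, 0, 1],
         [1, 1, 0, 0, 1, 0]),
        ([0, 0, 0, 0, 0, 0], [2, 2, 3, 3, 5, 7], [1, 1, 1, 0, 1, 1],
         [1, 0, 1, 0, 0, 1]),
        ([0, 0, 1, 1, 2, 0, 0, 0], [2, 3, 4, 5, 6, 7, 8, 9],
         [1, 1, 1, 0, 1, 1, 0, 1], [0, 1, 1, 0, 1, 0, 0, 1]),
        ([0, 0, 0, 0, 0], [1, 1, 2, 3, 4], [1, 1, 1, 1, 0],
         [0.5, -1.0, 2.0, 0.0, 1.0]),
    ]

    @pytest.mark.parametrize("fixture", FIXTURES)
    def test_beta_matches_brute_force_maximizer(self, fixture):
        entry, exit_, status, x = fixture
        model = TransitionCox().fit(cox_df(entry, exit_, status, x), ["x"])
        oracle = brute_force_beta(entry, exit_, status, x)
        assert model.coef_["x"] == pytest.approx(oracle, abs=1e-4)

    def test_matches_lifelines_on_tie_free_data(self):
        # Breslow == Efron without ties; lifelines is the independent route
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(0)
        n = 80
        x = rng.normal(size=n)
        t = rng.exponential(1 / np.exp(0.5 * x))
        status = (rng.random(n) < 0.7).astype(int)
        df = cox_df(np.zeros(n), t, status, x)
        mine = TransitionCox().fit(df, ["x"])
        ll = CoxPHFitter().fit(df.drop(columns="entry"), duration_col="exit",
                               event_col="status")
        assert mine.coef_["x"] == pytest.approx(
            ll.params_["x"], abs=1e-4)
        assert mine.se_["x"] == pytest.approx(
            ll.standard_errors_["x"], abs=1e-4)

    def test_left_truncation_matches_lifelines(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(1)
        n = 60
        x = rng.normal(size=n)
        entry = rng.uniform(0, 0.5, n)
        t = entry + rng.exponential(1 / np.exp(0.4 * x))
        df = cox_df(entry, t, np.ones(n, int), x)
        mine = TransitionCox().fit(df, ["x"])
        ll = CoxPHFitter().fit(df, duration_col="exit", event_col="status",
                               entry_col="entry")
        assert mine.coef_["x"] == pytest.approx(ll.params_["x"], abs=1e-4)

    def test_constant_covariate_errors(self):
        df = cox_df([0, 0, 0], [1, 2, 3], [1, 1, 0], [1, 1, 1])
        with pytest.raises(ValueError, match="constant covariate"):
            TransitionCox().fit(df, ["x"])

    def test_no_events_errors(self):
        df = cox_df([0, 0], [1, 2], [0, 0], [0, 1])
        with pytest.raises(ValueError, match="no events"):
            TransitionCox().fit(df, ["x"])

    def test_perfect_separation_reported(self):
        # all events in the high-risk arm, ordered before all others
        df = cox_df([0] * 6, [1, 2, 3, 10, 11, 12], [1, 1, 1, 0, 0, 0],
                    [1, 1, 1, 0, 0, 0])
        with pytest.raises(ConvergenceError, match="x"):
            TransitionCox().fit(df, ["x"])

    def test_baseline_is_nelson_aalen_with_no_covariates(self):
        times = [1.0, 2.0, 2.0, 3.0, 4.0]
        status = [1, 1, 1, 0, 1]
        df = cox_df([0] * 5, times, status, [0.0] * 5)
        model = TransitionCox().fit(df, [])
        # Nelson-Aalen: 1/5 at t=1, +2/4 at t=2, +1/1 at t=4
        np.testing.assert_allclose(model.baseline_cumhaz_.to_numpy(),
                                   [0.2, 0.7, 1.7])

    def test_parameter_recovery_exponential(self):
        rng = np.random.default_rng(2)
        n = 2000
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.1 * np.exp(0.7 * x)))
        cens = rng.uniform(0, 30, n)
        df = cox_df(np.zeros(n), np.minimum(t, cens),
                    (t <= cens).astype(int), x)
        model = TransitionCox().fit(df, ["x"])
        assert abs(model.coef_["x"] - 0.7) < 3 * model.se_["x"]

    def test_efron_agrees_with_lifelines_on_ties(self):
        from lifelines import CoxPHFitter
        df = cox_df([0] * 8, [2, 2, 2, 3, 3, 5, 7, 7],
                    [1, 1, 0, 1, 1, 1, 1, 0],
                    [1, 0, 1, 0, 1, 0, 1, 0])
        mine = TransitionCox(ties="efron").fit(df, ["x"])
        ll = CoxPHFitter().fit(df.drop(columns="entry"), duration_col="exit",
                               event_col="status")
        assert mine.coef_["x"] == pytest.approx(ll.params_["x"], abs=1e-4)

    def test_wald_ci_covers_truth(self):
        # generator log HR inside the 95% CI in >=90/100 seeded replicates
        from pvhmr.simulate import group_effect_recovery
        df = group_effect_recovery("1->2", hr_high=2.0, n_patients=600,
                                   n_reps=100, seed=10,
                                   baseline={"1->2": 0.05, "1->3": 0.03,
                                             "2->3": 0.2})
        covered = ((df["lo_group_high"] <= 2.0)
                   & (2.0 <= df["hi_group_high"])).sum()
        assert covered >= 90


# ---------------------------------------------------------------------------
# Aalen-Johansen
# ---------------------------------------------------------------------------

def _clinical_from_outcomes(out: pd.DataFrame) -> pd.DataFrame:
    out = out.copy()
    out.insert(0, "patient_id", [f"s{i}" for i in range(len(out))])
    return out


class TestAalenJohansen:
    def test_no_events_chronic_probability_one(self):
        clin = _clinical_from_outcomes(pd.DataFrame({
            "time_transformation": [np.nan] * 3,
            "event_transformation": [0] * 3,
            "time_death": [np.nan] * 3, "event_death": [0] * 3,
            "time_censor": [5.0, 6.0, 7.0]}))
        aj = aalen_johansen(to_multistate(clin))
        assert aj["chronic"].at([10.0])[0] == 1.0

    def test_two_state_degenerate_equals_kaplan_meier(self):
        rng = np.random.default_rng(3)
        n = 200
        t = rng.exponential(5, n)
        c = rng.uniform(0, 10, n)
        dead = t <= c
        clin = _clinical_from_outcomes(pd.DataFrame({
            "time_transformation": [np.nan] * n,
            "event_transformation": [0] * n,
            "time_death": np.where(dead, t, np.nan),
            "event_death": dead.astype(int),
            "time_censor": c}))
        aj = aalen_johansen(to_multistate(clin))
        km = kaplan_meier(np.minimum(t, c), dead.astype(int))
        grid = np.linspace(0.1, 9, 25)
        np.testing.assert_allclose(aj["chronic"].at(grid), km.at(grid),
                                   atol=1e-12)

    def test_constant_hazard_closed_form(self):
        n = 10000
        cov = pd.DataFrame(index=range(n))
        out = simulate_event_histories(
            cov, {"baseline": {"1->2": 0.1, "1->3": 0.1, "2->3": 0.15},
                  "effects": {}},
            {"admin_horizon": 50.0, "dropout_rate": 0.0}, seed=4)
        aj = aalen_johansen(to_multistate(_clinical_from_outcomes(out)))
        for t in (2.0, 5.0):
            expected = np.exp(-0.2 * t)
            assert aj["chronic"].at([t])[0] == pytest.approx(expected,
                                                             rel=0.02)

    def test_occupation_sums_to_one_and_dead_monotone(self, clinical_frame):
        aj = aalen_johansen(to_multistate(clinical_frame))
        total = (aj["chronic"].values + aj["transformed"].values
                 + aj["dead"].values)
        np.testing.assert_allclose(total, 1.0, atol=1e-10)
        assert np.all(np.diff(aj["dead"].values) >= -1e-12)


# ---------------------------------------------------------------------------
# stepwise selection
# ---------------------------------------------------------------------------

class TestStepwise:
    def _dataset(self, seed, n=2000, noise_cols=("noise",)):
        rng = np.random.default_rng(seed)
        x = (rng.random(n) < 0.3).astype(float)
        cov = pd.DataFrame({"group_high": x})
        out = simulate_event_histories(
            cov, {"baseline": {"1->2": 0.05, "1->3": 0.02, "2->3": 0.2},
                  "effects": {"1->2": {"group_high": np.log(3.0)}}},
            {"admin_horizon": 12.0, "dropout_rate": 0.02}, seed=seed + 1)
        clin = _clinical_from_outcomes(out)
        clin["signal"] = x
        for i, c in enumerate(noise_cols):
            clin[c] = rng.normal(size=n)
        return to_multistate(clin, covariates=["signal", *noise_cols])

    def test_strong_covariates_kept(self):
        ds = self._dataset(0)
        selected, model, log = stepwise_select(ds, "1->2", ["signal"])
        assert selected == ["signal"] and log == []

    def test_noise_dropped_in_most_replicates(self):
        drops = 0
        for seed in range(20):
            ds = self._dataset(100 + seed)
            selected, _, _ = stepwise_select(ds, "1->2", ["signal", "noise"])
            drops += "noise" not in selected
        assert drops >= 18  # >= 90% of replicates under the null

    def test_tied_p_drops_lexicographically_first(self):
        # symmetric design: swapping the two covariates permutes subjects,
        # so their Wald statistics are exactly tied
        df = pd.DataFrame({
            "patient_id": list("abcdefgh"),
            "time_transformation": [np.nan] * 8,
            "event_transformation": [0] * 8,
            "time_death": [1, 1, 2, 2, 3, 3, 4, 4],
            "event_death": [1] * 8,
            "time_censor": [9.0] * 8,
            "noise_a": [1, 0, 0, 0, 1, 0, 0, 0],
            "noise_b": [0, 1, 0, 0, 0, 1, 0, 0],
        })
        ds = to_multistate(df, covariates=["noise_a", "noise_b"])
        selected, model, log = stepwise_select(ds, "1->3",
                                               ["noise_a", "noise_b"],
                                               alpha=1e-6)
        assert log[0]["dropped"] == "noise_a"
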