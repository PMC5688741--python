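import numpy as np
import pandas as pd
import pytest

import worklife as wl
from worklife.cox import SeparationError, StepFunction
from worklife.states import StateSpace, Transition


@pytest.fixture(scope="module")
def single_transition_space():
    return StateSpace(
        states={"W": "transdurable", "D": "absorbing"},
        transitions=[Transition(("W",), "D")],
        wle_states={"W"}, pension_age=100.0,
    )


def hr2_cohort(n=2000, seed=5, rate=0.3, hr=2.0, horizon=3.0):
    """Single W->D transition, binary covariate with true hazard ratio."""
    rng = np.random.default_rng(seed)
    x = (rng.random(n) < 0.5).astype(float)
    lam = rate * np.where(x == 1, hr, 1.0)
    t = rng.exponential(1.0 / lam)
    exit_age = np.minimum(t, horizon)
    event = t <= horizon
    return pd.DataFrame(
        {"subject_id": np.arange(n), "entry_age": 0.0, "exit_age": exit_age,
         "from_state": "W",
         "to_state": np.where(event, "D", wl.CENSORED), "x": x,
         "weight": 1.0}
    )


class TestBreslowBaseline:
    def test_no_covariates_equals_nelson_aalen(self, labor_cohort):
        cfg, df = labor_cohort
        fit = wl.fit_multistate_cox(df, cfg.space)
        rs = fit.riskset
        for tr in cfg.space.transitions:
            tf = fit[tr.name]
            d = rs.d[tr.name].to_numpy()
            n = rs.n_for(tr.origins)
            keep = d > 0
            assert np.allclose(tf.baseline_ages, rs.ages[keep])
            assert np.allclose(tf.baseline_increments, d[keep] / n[keep],
                               atol=1e-12)

    def test_d_over_n_arithmetic(self, single_transition_space):
        # d/n sequence (1/10, 1/8): cumulative 0.1 then 0.225
        # one death at t=1 (n=10), one censor at 1.5, one death at 2 (n=8)
        rows = []
        for i in range(10):
            t = {0: 1.0, 1: 1.5, 2: 2.0}.get(i, 3.0)
            to = "D" if i in (0, 2) else wl.CENSORED
            rows.append({"subject_id": i, "entry_age": 0.0, "exit_age": t,
                         "from_state": "W", "to_state": to})
        fit = wl.fit_multistate_cox(pd.DataFrame(rows),
                                    single_transition_space)
        base = wl.baseline_cumulative_hazard(fit, "W->D")
        assert np.allclose(base.increments, [0.1, 1 / 8])
        assert np.allclose(base.cumulative, [0.1, 0.225])

    def test_right_continuity_and_no_events(self, single_transition_space):
        step = StepFunction(np.array([1.0, 2.0]), np.array([0.1, 0.125]))
        assert step(0.5) == 0.0
        assert step(1.0) == 0.1
        assert step(1.7) == 0.1  # between jumps: value at previous jump
        assert step(2.5) == pytest.approx(0.225)
        empty = StepFunction(np.zeros(0), np.zeros(0))
        assert np.all(empty(np.array([0.0, 5.0])) == 0.0)
        df = pd.DataFrame(
            {"subject_id": [0], "entry_age": [0.0], "exit_age": [1.0],
             "from_state": ["W"], "to_state": [wl.CENSORED]}
        )
        fit = wl.fit_multistate_cox(df, single_transition_space)
        assert len(fit["W->D"].baseline_ages) == 0
        with pytest.raises(KeyError):
            wl.baseline_cumulative_hazard(fit, "nope")


class TestCoefficientRecovery:
    def test_hr_recovery_within_3se(self, single_transition_space):
        df = hr2_cohort()
        fit = wl.fit_multistate_cox(df, single_transition_space, ["x"])
        tf = fit["W->D"]
        assert abs(tf.beta[0] - np.log(2.0)) < 3 * tf.se[0]

    def test_agrees_with_lifelines_per_transition(self, labor_cohort):
        lifelines = pytest.importorskip("lifelines")
        cfg, df = labor_cohort
        fit = wl.fit_multistate_cox(df, cfg.space, ["srh_poor"])
        for name in ("W->S", "S->W", "W+S+U->E"):
            tr = cfg.space.transition_by_name(name)
            sub = df[df.from_state.isin(tr.origins)].copy()
            sub["event"] = (sub.to_state == tr.to_state).astype(int)
            ctv = lifelines.CoxTimeVaryingFitter()
            ctv.fit(
                sub[["subject_id", "entry_age", "exit_age", "event",
                     "srh_poor"]],
                id_col="subject_id", start_col="entry_age",
                stop_col="exit_age", event_col="event",
            )
            assert fit[name].beta[0] == pytest.approx(
                ctv.params_.iloc[0], abs=1e-6
            )

    def test_long_format_stratified_equals_per_transition(self, labor_cohort):
        """The two data arrangements give identical coefficients."""
        cfg, df = labor_cohort
        per = wl.fit_multistate_cox(df, cfg.space, ["srh_poor"])
        stacked = wl.stack_transitions(df, cfg.space, ["srh_poor"])
        strat = wl.fit_stratified_long(stacked, cfg.space, ["srh_poor"])
        for tr in cfg.space.transitions:
            a, b = per[tr.name], strat[tr.name]
            assert np.allclose(a.beta, b.beta, atol=1e-8, equal_nan=True)
            assert np.allclose(a.baseline_increments, b.baseline_increments,
                               atol=1e-10)

    def test_stratified_long_matches_lifelines_strata_fit(self, labor_cohort):
        """External stratified fit on the stacked data: the dual route."""
        lifelines = pytest.importorskip("lifelines")
        cfg, df = labor_cohort
        per = wl.fit_multistate_cox(df, cfg.space, ["srh_poor"])
        stacked = wl.stack_transitions(df, cfg.space, ["srh_poor"])
        stacked["row_id"] = np.arange(len(stacked))
        cols = [f"srh_poor__{t.name}" for t in cfg.space.transitions]
        ctv = lifelines.CoxTimeVaryingFitter()
        ctv.fit(
            stacked[["row_id", "entry_age", "exit_age", "event",
                     "transition"] + cols],
            id_col="row_id", start_col="entry_age", stop_col="exit_age",
            event_col="event", strata=["transition"],
        )
        for tr in cfg.space.transitions:
            mine = per[tr.name].beta[0]
            theirs = ctv.params_[f"srh_poor__{tr.name}"]
            assert mine == pytest.approx(theirs, abs=1e-5)


class TestWeightsAndFrailty:
    def test_constant_weights_cancel(self, labor_cohort):
        cfg, df = labor_cohort
        fit1 = wl.fit_multistate_cox(df, cfg.space, ["srh_poor"])
        fit2 = wl.fit_multistate_cox(
            df, cfg.space, ["srh_poor"], weights=np.full(len(df), 3.0)
        )
        for tr in cfg.space.transitions:
            assert np.allclose(fit1[tr.name].beta, fit2[tr.name].beta,
                               atol=1e-8)
            assert np.allclose(fit1[tr.name].baseline_increments,
                               fit2[tr.name].baseline_increments, atol=1e-10)

    def test_frailty_theta_to_zero_matches_no_frailty(self, labor_cohort):
        cfg, df = labor_cohort
        plain = wl.fit_multistate_cox(df, cfg.space, ["srh_poor"])
        tiny = wl.fit_multistate_cox(df, cfg.space, ["srh_poor"],
                                     frailty_theta=1e-8)
        for tr in cfg.space.transitions:
            assert np.allclose(plain[tr.name].beta, tiny[tr.name].beta,
                               atol=1e-4)

    def test_separation_raises_named_error(self, single_transition_space):
        df = hr2_cohort(n=60, seed=1)
        df["sep"] = (df["to_state"] == "D").astype(float)  # perfect predictor
        with pytest.raises(SeparationError, match="W->D"):
            wl.fit_multistate_cox(df, single_transition_space, ["sep"])


class TestProportionalityDiagnostics:
    def test_identical_strata_identical_curves(self, survival_space,
                                               survival_toy):
        df = pd.concat(
            [survival_toy.assign(g=0, subject_id=lambda d: d.subject_id),
             survival_toy.assign(g=1,
                                 subject_id=lambda d: d.subject_id + 100)],
            ignore_index=True,
        )
        out = wl.proportionality_diagnostics(df, survival_space, "g")
        c0 = out[out.level == 0].set_index("age")["cumhaz"]
        c1 = out[out.level == 1].set_index("age")["cumhaz"]
        assert np.allclose(c0, c1)

    def test_proportional_strata_log_ratio(self, single_transition_space):
        df = hr2_cohort(n=4000, seed=9)
        out = wl.proportionality_diagnostics(df, single_transition_space, "x")
        late = out[(out.level == 1) & (out.age > 1.5) & (out.age < 2.5)]
        assert abs(late["log_ratio_vs_ref"].mean() - np.log(2.0)) < 0.15

    def test_single_stratum_no_ratio_table(self, survival_space,
                                           survival_toy):
        df = survival_toy.assign(g=1)
        out = wl.proportionality_diagnostics(df, survival_space, "g")
        assert "log_ratio_vs_ref" not in out.columns
        assert out["level"].nunique() == 1
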