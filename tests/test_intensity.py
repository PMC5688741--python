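import numpy as np
import pandas as pd
import pytest

import worklife as wl
from worklife.states import StateSpace, Transition


@pytest.fixture(scope="module")
def wsu_space():
    return StateSpace(
        states={"W": "transdurable", "S": "transdurable",
                "U": "transdurable", "D": "absorbing"},
        transitions=[
            Transition(("W",), "S"), Transition(("W",), "U"),
            Transition(("S",), "W"), Transition(("U",), "W"),
            Transition(("W", "S", "U"), "D"),
        ],
        wle_states={"W", "S", "U"}, pension_age=100.0,
    )


def episodes(rows):
    return pd.DataFrame(
        rows, columns=["subject_id", "entry_age", "exit_age", "from_state",
                       "to_state"]
    ).assign(weight=1.0)


class TestNonparametric:
    def test_d_over_n_and_diagonal(self, wsu_space):
        # at t=1: 10 at risk in W, 2 -> S, 1 -> U  => alpha_WS=0.2, WU=0.1
        rows = [("w%d" % i, 0.0, 1.0, "W", "S") for i in range(2)]
        rows += [("u0", 0.0, 1.0, "W", "U")]
        rows += [("c%d" % i, 0.0, 2.0, "W", wl.CENSORED) for i in range(7)]
        rs = wl.build_risk_sets(episodes(rows), wsu_space)
        series = wl.nonparametric_intensities(rs, wsu_space)
        A = series.matrices[0]
        i, j, k = (wsu_space.index(s) for s in "WSU")
        assert A[i, j] == pytest.approx(0.2)
        assert A[i, k] == pytest.approx(0.1)
        assert A[i, i] == pytest.approx(-0.3)
        series.validate()

    def test_no_events_empty_series(self, wsu_space):
        rows = [("a", 0.0, 2.0, "W", wl.CENSORED)]
        rs = wl.build_risk_sets(episodes(rows), wsu_space)
        series = wl.nonparametric_intensities(rs, wsu_space)
        assert len(series.ages) == 0

    def test_weight_scaling_leaves_intensities_unchanged(self, labor_cohort):
        cfg, df = labor_cohort
        rs1 = wl.build_risk_sets(df, cfg.space)
        rs2 = wl.build_risk_sets(df.assign(weight=2.5), cfg.space)
        s1 = wl.nonparametric_intensities(rs1, cfg.space)
        s2 = wl.nonparametric_intensities(rs2, cfg.space)
        assert np.allclose(s1.matrices, s2.matrices)

    def test_absorbing_rows_zero_everywhere(self, labor_cohort):
        cfg, df = labor_cohort
        series = wl.nonparametric_intensities(
            wl.build_risk_sets(df, cfg.space), cfg.space
        )
        for s in cfg.space.absorbing_states:
            i = cfg.space.index(s)
            assert np.abs(series.matrices[:, i, :]).max(initial=0) == 0


class TestCoxIntensities:
    def test_zero_profile_equals_baseline(self, labor_cohort):
        cfg, df = labor_cohort
        fit = wl.fit_multistate_cox(df, cfg.space, ["srh_poor"])
        series = wl.cox_intensities(fit, {"srh_poor": 0.0})
        for tr in cfg.space.transitions:
            tf = fit[tr.name]
            j = cfg.space.index(tr.to_state)
            idx = np.searchsorted(series.ages, tf.baseline_ages)
            h = cfg.space.index(tr.origins[0])
            assert np.allclose(series.matrices[idx, h, j],
                               tf.baseline_increments)

    def test_known_beta_doubles_intensity(self, wsu_space):
        # single covariate with beta = ln 2, Z=1 doubles that transition
        rng = np.random.default_rng(2)
        n = 500
        x = (rng.random(n) < 0.5).astype(float)
        t = rng.exponential(1 / (0.5 * np.exp(np.log(2) * x)))
        df = pd.DataFrame(
            {"subject_id": np.arange(n), "entry_age": 0.0,
             "exit_age": np.minimum(t, 3.0), "from_state": "W",
             "to_state": np.where(t <= 3.0, "S", wl.CENSORED), "x": x}
        )
        fit = wl.fit_multistate_cox(df, wsu_space, ["x"])
        s0 = wl.cox_intensities(fit, {"x": 0.0})
        s1 = wl.cox_intensities(fit, {"x": 1.0})
        i, j = wsu_space.index("W"), wsu_space.index("S")
        hr = np.exp(fit["W->S"].beta[0])
        nz = s0.matrices[:, i, j] > 0
        ratio = s1.matrices[nz, i, j] / s0.matrices[nz, i, j]
        assert np.allclose(ratio, hr, rtol=1e-10)
        # diagonal recomputed
        assert np.allclose(s1.matrices.sum(axis=2), 0.0, atol=1e-12)

    def test_multiplicative_in_profile_shift(self, labor_cohort):
        cfg, df = labor_cohort
        fit = wl.fit_multistate_cox(df, cfg.space, ["srh_poor"])
        s0 = wl.cox_intensities(fit, {"srh_poor": 0.0})
        s1 = wl.cox_intensities(fit, {"srh_poor": 1.0})
        for tr in cfg.space.transitions:
            h = cfg.space.index(tr.origins[0])
            j = cfg.space.index(tr.to_state)
            beta = fit[tr.name].beta[0]
            nz = s0.matrices[:, h, j] > 0
            assert np.allclose(
                s1.matrices[nz, h, j] / s0.matrices[nz, h, j],
                np.exp(beta), rtol=1e-10,
            )

    def test_no_covariate_fit_equals_nonparametric(self, labor_cohort):
        """Cox route with empty covariate set == occurrence/exposure rates."""
        cfg, df = labor_cohort
        rs = wl.build_risk_sets(df, cfg.space)
        nonp = wl.nonparametric_intensities(rs, cfg.space)
        fit = wl.fit_multistate_cox(df, cfg.space)
        coxs = wl.cox_intensities(fit, {})
        assert np.allclose(nonp.ages, coxs.ages)
        assert np.allclose(nonp.matrices, coxs.matrices, atol=1e-12)

    def test_missing_covariate_in_profile_named(self, labor_cohort):
        cfg, df = labor_cohort
        fit = wl.fit_multistate_cox(df, cfg.space, ["srh_poor"])
        with pytest.raises(KeyError, match="srh_poor"):
            wl.cox_intensities(fit, {})


class TestCombinedRedistribution:
    def combined_toy(self, wsu_space):
        # D-events only from W; S and U occupied by others
        rows = [("a", 0.0, 1.0, "W", "D"), ("b", 0.0, 2.0, "W", wl.CENSORED),
                ("c", 0.0, 2.0, "S", wl.CENSORED),
                ("d", 0.0, 2.0, "U", wl.CENSORED)]
        return episodes(rows)

    def test_equal_mode_rows_identical(self, wsu_space):
        df = self.combined_toy(wsu_space)
        rs = wl.build_risk_sets(df, wsu_space)
        series = wl.nonparametric_intensities(rs, wsu_space,
                                              combined_mode="equal")
        A = series.matrices[0]
        jD = wsu_space.index("D")
        vals = [A[wsu_space.index(s), jD] for s in "WSU"]
        assert vals[0] == vals[1] == vals[2] == pytest.approx(1 / 4)

    def test_crude_frequency_flow_conservation(self, wsu_space):
        df = self.combined_toy(wsu_space)
        rs = wl.build_risk_sets(df, wsu_space)
        series = wl.nonparametric_intensities(
            rs, wsu_space, combined_mode="crude_frequency", episodes=df
        )
        A = series.matrices[0]
        jD = wsu_space.index("D")
        # f_W = 1: row W gets lambda_c * n_c / n_W = (1/4)*(4/2); S,U get 0
        assert A[wsu_space.index("W"), jD] == pytest.approx(0.5)
        assert A[wsu_space.index("S"), jD] == 0.0
        assert A[wsu_space.index("U"), jD] == 0.0
        # flow conservation: sum_h n_h * entry_h == d_c
        n = {s: rs.n.loc[1.0, s] for s in "WSU"}
        flow = sum(n[s] * A[wsu_space.index(s), jD] for s in "WSU")
        assert flow == pytest.approx(1.0)

    def test_single_origin_combined_degenerate(self):
        space = StateSpace(
            states={"W": "transdurable", "S": "transdurable",
                    "D": "absorbing"},
            transitions=[Transition(("W", "S"), "D"),
                         Transition(("W",), "S"), Transition(("S",), "W")],
            wle_states={"W"}, pension_age=100.0,
        )
        rows = [("a", 0.0, 1.0, "W", "D"),
                ("b", 0.0, 2.0, "W", wl.CENSORED)]
        df = episodes(rows)
        rs = wl.build_risk_sets(df, space)
        s_eq = wl.nonparametric_intensities(rs, space, combined_mode="equal")
        s_cf = wl.nonparametric_intensities(
            rs, space, combined_mode="crude_frequency", episodes=df
        )
        # S never occupied: n_S = 0, so both modes put everything on row W
        assert np.allclose(s_eq.matrices[:, space.index("W"), :],
                           s_cf.matrices[:, space.index("W"), :])

    def test_crude_frequency_zero_events_falls_back(self, wsu_space):
        rows = [("a", 0.0, 1.0, "W", "S"),
                ("b", 0.0, 2.0, "W", wl.CENSORED)]
        df = episodes(rows)
        rs = wl.build_risk_sets(df, wsu_space)
        with pytest.warns(UserWarning, match="equal"):
            series = wl.nonparametric_intensities(
                rs, wsu_space, combined_mode="crude_frequency", episodes=df
            )
        series.validate()
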