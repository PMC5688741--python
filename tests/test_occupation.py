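import numpy as np
import pandas as pd
import pytest
from scipy.linalg import expm

import worklife as wl
from worklife.states import StateSpace, Transition
from tests.conftest import illness_death_config


@pytest.fixture(scope="module")
def three_state_space():
    return StateSpace(
        states={"a": "transdurable", "b": "transdurable", "c": "absorbing"},
        transitions=[Transition(("a",), "b"), Transition(("b",), "a"),
                     Transition(("a",), "c"), Transition(("b",), "c")],
        wle_states={"a"}, pension_age=100.0,
    )


def constant_series(G, T, steps, space):
    ages = np.linspace(T / steps, T, steps)
    A = np.repeat((G * (T / steps))[None], steps, axis=0)
    return wl.IntensityMatrixSeries(space.state_order, ages, A, space)


class TestProductIntegral:
    def test_empty_product_is_identity(self, three_state_space):
        series = wl.IntensityMatrixSeries(
            three_state_space.state_order, np.zeros(0), np.zeros((0, 3, 3)),
            three_state_space,
        )
        curve = wl.product_integral(series, 0.0, 1.0)
        assert np.array_equal(curve.terminal(), np.eye(3))

    def test_single_factor(self, three_state_space):
        A = np.zeros((1, 3, 3))
        A[0, 0, 1] = 0.2
        A[0, 0, 0] = -0.2
        series = wl.IntensityMatrixSeries(
            three_state_space.state_order, np.array([0.5]), A,
            three_state_space,
        )
        P = wl.product_integral(series, 0.0, 1.0).terminal()
        assert P[0, 0] == pytest.approx(0.8)
        assert P[0, 1] == pytest.approx(0.2)

    def test_matches_matrix_exponential(self, three_state_space):
        G = np.array([[-0.5, 0.3, 0.2], [0.4, -0.5, 0.1], [0.0, 0.0, 0.0]])
        T = 2.0
        series = constant_series(G, T, 10**4, three_state_space)
        P = wl.product_integral(series, 0.0, T).terminal()
        assert np.abs(P - expm(G * T)).max() < 1e-3

    def test_chapman_kolmogorov_exact(self, labor_cohort):
        cfg, df = labor_cohort
        series = wl.nonparametric_intensities(
            wl.build_risk_sets(df, cfg.space), cfg.space
        )
        s, u, t = 55.0, 58.0, 63.0
        P_st = wl.product_integral(series, s, t).terminal()
        P_su = wl.product_integral(series, s, u).terminal()
        P_ut = wl.product_integral(series, u, t).terminal()
        assert np.allclose(P_su @ P_ut, P_st, atol=1e-13)

    def test_rows_sum_to_one(self, labor_cohort):
        cfg, df = labor_cohort
        series = wl.nonparametric_intensities(
            wl.build_risk_sets(df, cfg.space), cfg.space
        )
        curve = wl.product_integral(series, 55.0, 65.0)
        assert np.abs(curve.probs.sum(axis=2) - 1.0).max() < 1e-10
        assert curve.probs.min() >= -1e-15

    def test_negative_factor_raises(self, three_state_space):
        A = np.zeros((1, 3, 3))
        A[0, 0, 1] = 1.2  # off-diagonal d/n > 1
        A[0, 0, 0] = -1.2
        series = wl.IntensityMatrixSeries(
            three_state_space.state_order, np.array([0.5]), A,
            three_state_space,
        )
        with pytest.raises(ValueError, match="exceeded 1"):
            wl.product_integral(series, 0.0, 1.0)

    def test_large_cohort_converges_to_truth(self):
        """Estimator consistency against the matrix-exponential oracle."""
        cfg = illness_death_config(20_000, seed=21)
        df = wl.simulate_cohort(cfg)
        series = wl.nonparametric_intensities(
            wl.build_risk_sets(df, cfg.space), cfg.space
        )
        P = wl.product_integral(series, 55.0, 60.0).terminal()
        truth = wl.true_occupation(cfg, {}, 55.0, 60.0)
        assert np.abs(P - truth).max() < 0.01


class TestGreenwoodCovariance:
    def test_no_events_zero_variance(self, three_state_space):
        series = wl.IntensityMatrixSeries(
            three_state_space.state_order, np.zeros(0), np.zeros((0, 3, 3)),
            three_state_space,
        )
        curve = wl.product_integral(series, 0.0, 1.0)
        rs = wl.build_risk_sets(
            pd.DataFrame(
                {"subject_id": [0], "entry_age": [0.0], "exit_age": [1.0],
                 "from_state": ["a"], "to_state": [wl.CENSORED],
                 "weight": [1.0]}
            ),
            three_state_space,
        )
        wl.greenwood_covariance(rs, curve)
        assert curve.cov.shape[0] == 0

    def test_pure_survival_equals_classical_greenwood(self, survival_space,
                                                      survival_toy):
        rs = wl.build_risk_sets(survival_toy, survival_space)
        series = wl.nonparametric_intensities(rs, survival_space)
        curve = wl.product_integral(series, 0.0, 6.0)
        wl.greenwood_covariance(rs, curve)
        se = curve.standard_errors()
        S, acc = 1.0, 0.0
        for k in range(5):
            n, d = 10 - k, 1
            S *= 1 - d / n
            acc += d / (n * (n - d))
            assert se[k, 0, 0] ** 2 == pytest.approx(S * S * acc, rel=1e-12)

    def test_recursion_matches_bootstrap(self, illness_death_space):
        """Recursion variance within 20% of a nonparametric bootstrap."""
        cfg = illness_death_config(500, seed=13)
        df = wl.simulate_cohort(cfg)
        rs = wl.build_risk_sets(df, cfg.space)
        series = wl.nonparametric_intensities(rs, cfg.space)
        curve = wl.product_integral(series, 55.0, 60.0)
        wl.greenwood_covariance(rs, curve)
        iW = cfg.space.index("W")
        var_rec = curve.standard_errors()[-1, iW, iW] ** 2

        rng = np.random.default_rng(99)
        subjects = df["subject_id"].unique()
        groups = dict(tuple(df.groupby("subject_id")))
        stats = []
        for _ in range(200):
            pick = rng.choice(subjects, size=len(subjects), replace=True)
            boot = pd.concat(
                [groups[s].assign(subject_id=f"{s}_{k}")
                 for k, s in enumerate(pick)],
                ignore_index=True,
            )
            rsb = wl.build_risk_sets(boot, cfg.space)
            sb = wl.nonparametric_intensities(rsb, cfg.space)
            stats.append(
                wl.product_integral(sb, 55.0, 60.0).terminal()[iW, iW]
            )
        var_boot = float(np.var(stats, ddof=1))
        assert abs(var_rec - var_boot) < 0.2 * var_boot

    def test_mismatched_ages_error(self, survival_space, survival_toy):
        rs = wl.build_risk_sets(survival_toy, survival_space)
        series = wl.nonparametric_intensities(rs, survival_space)
        curve = wl.product_integral(series, 0.0, 6.0)
        other = survival_toy.copy()
        other["exit_age"] = other["exit_age"] + 0.25
        rs_other = wl.build_risk_sets(other, survival_space)
        with pytest.raises(ValueError, match="not found"):
            wl.greenwood_covariance(rs_other, curve)


class TestPointwiseCI:
    def test_wald_limits_arithmetic(self):
        # P=0.5, SE=0.1 -> (0.304, 0.696); P=0.98, SE=0.05 -> upper clipped
        space = StateSpace(
            states={"a": "transdurable", "b": "absorbing"},
            transitions=[Transition(("a",), "b")], wle_states={"a"},
            pension_age=100.0,
        )
        curve = wl.OccupationCurve(
            s=0.0, t=1.0, states=["a", "b"], ages=np.array([0.5]),
            probs=np.array([[[0.5, 0.98], [0.0, 1.0]]]),
            series=wl.IntensityMatrixSeries(
                ["a", "b"], np.array([0.5]), np.zeros((1, 2, 2)), space
            ),
            cov=np.array([np.diag([0.1**2, 0.05**2, 0.0, 0.0])]),
        )
        wl.pointwise_ci(curve, 0.95)
        assert curve.lower[0, 0, 0] == pytest.approx(0.30400, abs=5e-4)
        assert curve.upper[0, 0, 0] == pytest.approx(0.69600, abs=5e-4)
        assert curve.upper[0, 0, 1] == 1.0  # clipped

    def test_zero_variance_limits_equal_estimate(self, survival_space,
                                                 survival_toy):
        rs = wl.build_risk_sets(survival_toy, survival_space)
        series = wl.nonparametric_intensities(rs, survival_space)
        curve = wl.product_integral(series, 0.0, 6.0)
        curve.cov = np.zeros_like(
            wl.greenwood_covariance(rs, curve).cov
        )
        wl.pointwise_ci(curve)
        assert np.array_equal(curve.lower, curve.probs)
        assert np.array_equal(curve.upper, curve.probs)

    def test_ci_requires_covariance(self, three_state_space):
        series = wl.IntensityMatrixSeries(
            three_state_space.state_order, np.zeros(0), np.zeros((0, 3, 3)),
            three_state_space,
        )
        curve = wl.product_integral(series, 0.0, 1.0)
        with pytest.raises(ValueError, match="covariance"):
            wl.pointwise_ci(curve)
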