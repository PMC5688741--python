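"""Worklife expectancy: integrating occupation probabilities over age.

The expected time spent in state ``h`` between a starting age ``s`` and the
pension age ``t_p``, conditional on occupying a starting state at ``s``, is

    E(h) = integral_s^{t_p} P_{start,h}(s, u) du,

and worklife expectancy is the sum of E(h) over the states that count as
labor-market affiliation (by default work, sickness absence, unemployment).
Because the Aalen-Johansen curve is piecewise constant, the primary
quadrature is the exact step-function integral; a trapezium rule on a
user grid (default: whole ages) is available as an alternative that mirrors
common life-table practice.  Confidence bounds on E(h) are the areas under
the pointwise lower/upper probability limits, computed with the same
quadrature; they ignore the dependence of the pointwise limits across ages
and should be read as approximate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intensity import IntensityMatrixSeries
from .occupation import OccupationCurve, greenwood_covariance, pointwise_ci, \
    product_integral
from .states import StateSpace


@dataclass
class WLEEstimate:
    """Expected years per state from ``s`` to pension age, with bounds."""

    s: float
    start_state: str
    horizon: float
    expected: dict[str, float]
    lower: dict[str, float] = field(default_factory=dict)
    upper: dict[str, float] = field(default_factory=dict)
    wle_states: tuple[str, ...] = ("W", "S", "U")

    @property
    def total_wle(self) -> float:
        return float(sum(self.expected[h] for h in self.wle_states))

    @property
    def total_lower(self) -> float | None:
        if not self.lower:
            return None
        return float(sum(self.lower[h] for h in self.wle_states))

    @property
    def total_upper(self) -> float | None:
        if not self.upper:
            return None
        return float(sum(self.upper[h] for h in self.wle_states))

    def validate(self) -> None:
        assert all(-1e-10 <= e <= self.horizon + 1e-8
                   for e in self.expected.values())
        assert abs(sum(self.expected.values()) - self.horizon) < 1e-8, \
            "occupancy conservation violated"
        for h in self.lower:
            assert self.lower[h] <= self.expected[h] + 1e-10 <= \
                self.upper[h] + 2e-10


def years_to_months(years: float) -> int:
    """Years -> whole months, rounded half-up (0.60 yr -> 7, 1.15 yr -> 14)."""
    return int(math.floor(years * 12.0 + 0.5))


def _step_integral(ages, values, s, t_p):
    """Exact integral of the right-continuous step curve on [s, t_p].

    ``values[k]`` applies on ``[ages[k], ages[k+1])``; before the first event
    age the initial value (identity row) applies — the caller passes it as a
    leading entry.
    """
    knots = np.concatenate([[s], ages, [t_p]])
    widths = np.diff(knots)
    return np.tensordot(widths, values, axes=(0, 0))


def _curve_row_values(curve: OccupationCurve, start_state: str, which: str):
    """Step values of row `start_state` incl. the [s, first-event) identity."""
    m = len(curve.states)
    i = curve.states.index(start_state)
    ident = np.eye(m)[i]
    if which == "point":
        vals = curve.probs[:, i, :]
    elif which == "lower":
        vals = curve.lower[:, i, :]
    elif which == "upper":
        vals = curve.upper[:, i, :]
    else:  # pragma: no cover
        raise ValueError(which)
    return np.vstack([ident, vals])


def expected_durations(
    curve: OccupationCurve,
    space: StateSpace,
    start_state: str = "W",
    quadrature: str = "step",
    grid: np.ndarray | None = None,
    with_bounds: bool = False,
) -> WLEEstimate:
    """Integrate a probability curve into expected state durations.

    Parameters
    ----------
    curve : OccupationCurve
        Must span ``(s, pension_age]`` (i.e. be built with ``t`` at or past
        the pension age).
    quadrature : {"step", "trapezium"}
        ``step`` integrates the piecewise-constant estimator exactly;
        ``trapezium`` applies the half-weighted-endpoint rule on ``grid``
        (default: whole ages from ``s`` to pension age).
    with_bounds : bool
        Also integrate the pointwise confidence limits (requires them on the
        curve) into lower/upper bounds per state.
    """
    t_p = space.pension_age
    if curve.t < t_p - 1e-9:
        raise ValueError(
            f"curve reaches only age {curve.t:g}; follow-up must cover the "
            f"horizon up to pension age {t_p:g}"
        )
    s = curve.s
    if with_bounds and curve.lower is None:
        raise ValueError("curve has no pointwise limits; run pointwise_ci")

    keep = curve.ages <= t_p + 1e-12
    ages = curve.ages[keep]

    def integrate(which):
        vals = _curve_row_values(curve, start_state, which)
        vals = np.vstack([vals[:1], vals[1:][keep]])
        if quadrature == "step":
            return _step_integral(ages, vals, s, t_p)
        if quadrature == "trapezium":
            g = grid if grid is not None else np.arange(np.ceil(s), t_p + 0.5)
            g = np.unique(np.concatenate([[s], np.asarray(g, float), [t_p]]))
            # evaluate the step curve at grid ages
            idx = np.searchsorted(ages, g, side="right")
            pts = vals[idx]
            return np.trapezoid(pts, g, axis=0)
        raise ValueError(f"unknown quadrature {quadrature!r}")

    point = integrate("point")
    states = curve.states
    est = WLEEstimate(
        s=s,
        start_state=start_state,
        horizon=t_p - s,
        expected={st: float(v) for st, v in zip(states, point)},
        wle_states=tuple(st for st in states if st in space.wle_states),
    )
    if with_bounds:
        lo = integrate("lower")
        hi = integrate("upper")
        est.lower = {st: float(v) for st, v in zip(states, lo)}
        est.upper = {st: float(v) for st, v in zip(states, hi)}
    if quadrature == "step":
        est.validate()
    return est


def wle_bounds(curve: OccupationCurve, space: StateSpace,
               start_state: str = "W", quadrature: str = "step") -> WLEEstimate:
    """Expected durations with CI bounds (areas under the pointwise limits)."""
    return expected_durations(
        curve, space, start_state=start_state, quadrature=quadrature,
        with_bounds=True,
    )


def curve_with_ci(
    series: IntensityMatrixSeries,
    riskset,
    s: float,
    t: float,
    level: float = 0.95,
) -> OccupationCurve:
    """Product integral + Greenwood covariance + pointwise Wald limits."""
    curve = product_integral(series, s, t)
    greenwood_covariance(riskset, curve)
    return pointwise_ci(curve, level)


def wle_by_starting_age(
    series: IntensityMatrixSeries,
    space: StateSpace,
    ages: np.ndarray,
    start_state: str = "W",
    riskset=None,
    level: float = 0.95,
) -> list[WLEEstimate]:
    """One WLE estimate per starting age (the WLE-by-age curve).

    Each estimate conditions only on occupying ``start_state`` at its
    starting age; the product integral is recomputed from scratch at every
    age.  Passing ``riskset`` also computes confidence bounds.
    """
    t_p = space.pension_age
    out = []
    for s in np.asarray(ages, float):
        if s >= t_p:
            zero = {st: 0.0 for st in space.state_order}
            out.append(
                WLEEstimate(
                    s=float(s), start_state=start_state, horizon=0.0,
                    expected=zero,
                    wle_states=tuple(st for st in space.state_order
                                     if st in space.wle_states),
                )
            )
            continue
        if riskset is not None:
            curve = curve_with_ci(series, riskset, s, t_p, level)
            out.append(wle_bounds(curve, space, start_state))
        else:
            curve = product_integral(series, s, t_p)
            out.append(expected_durations(curve, space, start_state))
    return out


def wle_curve_frame(estimates: list[WLEEstimate],
                    state: str = "W") -> pd.DataFrame:
    """Starting-age curve export: starting_age, expected years (+ bounds)."""
    rows = []
    for e in estimates:
        row = {
            "starting_age": e.s,
            f"expected_{state}_years": e.expected.get(state, 0.0),
            "total_wle": e.total_wle,
        }
        if e.lower:
            row["lower"] = e.lower.get(state, np.nan)
            row["upper"] = e.upper.get(state, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def expectancy_report(
    estimates: dict[str, WLEEstimate],
    space: StateSpace,
    months: bool = False,
) -> pd.DataFrame:
    """Tabulate expectancies per group/profile, one row per group and state.

    ``estimates`` maps a group label (covariate profile or stratum) to its
    WLE estimate.  Columns: group, state, years, lower, upper (and months if
    requested); a ``total_wle`` row per group sums the WLE states.  Bound
    columns carry the approximate areas under the pointwise limits.
    """
    rows = []
    for group, est in estimates.items():
        for st in est.wle_states:
            row = {
                "group": group, "state": st,
                "years": est.expected[st],
                "lower": est.lower.get(st, np.nan),
                "upper": est.upper.get(st, np.nan),
            }
            if months:
                row["months"] = years_to_months(est.expected[st])
            rows.append(row)
        row = {
            "group": group, "state": "total_wle",
            "years": est.total_wle,
            "lower": est.total_lower if est.lower else np.nan,
            "upper": est.total_upper if est.upper else np.nan,
        }
        if months:
            row["months"] = years_to_months(est.total_wle)
        rows.append(row)
    return pd.DataFrame(rows)
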