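"""Aalen-Johansen occupation probabilities with Greenwood-type covariance.

The transition-probability matrix from age ``s`` to ``t`` is estimated by the
product integral over the event ages ``u`` in ``(s, t]``:

    P(s, t) = prod_u ( I + A(u) ),

where ``A(u)`` are the intensity-matrix increments.  Every factor is row-
stochastic when off-diagonal row sums are <= 1, so P is a proper transition
matrix; intermediate products are retained at every event age, which makes
the occupation-probability curves piecewise constant and right-continuous.

The covariance of the estimator follows the recursion of the Aalen-Johansen
covariance estimator (the form implemented in the etm/mstate R packages):
writing ``G_k = I + dA(t_k)`` and vec for row-major vectorization,

    V_k = (I x G_k') V_{k-1} (I x G_k')' + (P_{k-1} x I) C_k (P_{k-1} x I)',

where ``C_k`` is the multinomial (Greenwood-type) covariance of the increment
entries: within origin row ``h`` with at-risk count ``n_h`` and event counts
``d_hj``, ``cov(dA_hj, dA_hj') = d_hj (n_h - d_hj) / n_h^3`` for ``j = j'``
and ``- d_hj d_hj' / n_h^3`` otherwise, with the diagonal entry obtained by
linearity (it is minus the row sum); rows are treated as independent.  In
the pure-survival special case this recursion reproduces the classical
Greenwood variance of the Kaplan-Meier estimator exactly.

Only the variability of the (baseline) hazard is propagated; the sampling
variability of Cox coefficient estimates is deliberately not included.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .events import RiskSetTable
from .intensity import IntensityMatrixSeries


@dataclass
class OccupationCurve:
    """P(s, t_k) at every event age ``t_k`` in ``(s, t]``, plus CI machinery.

    ``probs[k]`` is the full matrix P(s, ages[k]); the curve is piecewise
    constant between event ages (P = I on ``[s, ages[0])``).  ``cov`` holds
    the m^2 x m^2 covariance of vec(P) per age when attached.
    """

    s: float
    t: float
    states: list[str]
    ages: np.ndarray
    probs: np.ndarray  # (K, m, m)
    series: IntensityMatrixSeries
    cov: np.ndarray | None = None  # (K, m*m, m*m)
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    level: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def has_covariance(self) -> bool:
        return self.cov is not None

    def terminal(self) -> np.ndarray:
        """P(s, t): the last retained matrix (identity if no events)."""
        if len(self.ages) == 0:
            return np.eye(len(self.states))
        return self.probs[-1]

    def standard_errors(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("covariance not attached; run greenwood_covariance")
        m = len(self.states)
        var = np.stack([np.diag(c) for c in self.cov]) if len(self.ages) else \
            np.zeros((0, m * m))
        return np.sqrt(np.maximum(var, 0.0)).reshape(-1, m, m)

    def to_frame(self) -> pd.DataFrame:
        """Long export: s, t, from_state, to_state, probability[, se, ci]."""
        m = len(self.states)
        se = self.standard_errors() if self.cov is not None else None
        rows = []
        for k, age in enumerate(self.ages):
            for h in range(m):
                for j in range(m):
                    row = {
                        "s": self.s, "t": age,
                        "from_state": self.states[h],
                        "to_state": self.states[j],
                        "probability": self.probs[k, h, j],
                    }
                    if se is not None:
                        row["se"] = se[k, h, j]
                    if self.lower is not None:
                        row["lower"] = self.lower[k, h, j]
                        row["upper"] = self.upper[k, h, j]
                    rows.append(row)
        return pd.DataFrame(rows)


def product_integral(
    series: IntensityMatrixSeries, s: float, t: float
) -> OccupationCurve:
    """Aalen-Johansen product integral of an intensity series over (s, t].

    Raises
    ------
    ValueError
        If ``s >= t``, or if any factor ``I + A(u)`` has a negative entry
        (an off-diagonal ``d/n`` exceeded 1 — a data or weighting problem).
    """
    if not s < t:
        raise ValueError("need s < t")
    sub = series.restrict(s, t)
    m = len(sub.states)
    eye = np.eye(m)
    P = eye.copy()
    probs = np.empty((len(sub.ages), m, m))
    for k, A in enumerate(sub.matrices):
        factor = eye + A
        if (factor < 0).any():
            raise ValueError(
                f"factor I + A({sub.ages[k]:g}) has a negative entry: an "
                "off-diagonal intensity increment exceeded 1 (check the data "
                "or the weights)"
            )
        P = P @ factor
        probs[k] = P
    curve = OccupationCurve(
        s=s, t=t, states=list(sub.states), ages=sub.ages, probs=probs,
        series=sub,
    )
    # row-stochasticity is preserved by every factor
    if len(curve.ages):
        assert np.abs(probs.sum(axis=2) - 1.0).max() < 1e-10
    return curve


def _increment_covariance(A_k: np.ndarray, n_by_state: np.ndarray) -> np.ndarray:
    """Multinomial covariance of vec(dA) (row-major), rows independent.

    Effective event counts are read off the assembled increment itself
    (``d_eff = a * n_h``), which handles combined-transition redistribution
    and reduces to the exact counts for plain transitions.
    """
    m = A_k.shape[0]
    C = np.zeros((m * m, m * m))
    for h in range(m):
        n_h = n_by_state[h]
        if n_h <= 0:
            continue
        a = A_k[h].copy()
        a[h] = 0.0
        d = a * n_h
        if not d.any():
            continue
        # covariance of the off-diagonal entries
        cov_off = -np.outer(d, d) / n_h**3
        np.fill_diagonal(cov_off, d * (n_h - d) / n_h**3)
        # extend to the diagonal entry by linearity: dA_hh = -sum_j dA_hj
        T = np.eye(m)
        T[h, :] = -1.0
        T[h, h] = 0.0
        # rows of T express full-row entries in terms of off-diagonal ones
        cov_row = T @ cov_off @ T.T
        sl = slice(h * m, (h + 1) * m)
        C[sl, sl] = cov_row
    return C


def greenwood_covariance(
    riskset: RiskSetTable, curve: OccupationCurve
) -> OccupationCurve:
    """Attach the recursive Aalen-Johansen covariance to a curve in place.

    ``riskset`` must be the table the curve's intensities were built from
    (its event-age grid must contain the curve's ages).
    """
    ages = curve.ages
    pos = np.searchsorted(riskset.ages, ages)
    ok = pos < len(riskset.ages)
    if len(ages) and (not ok.all()
                      or not np.allclose(riskset.ages[pos], ages)):
        raise ValueError("curve event ages not found in the risk-set table")

    m = len(curve.states)
    n_mat = riskset.n[list(curve.states)].to_numpy()
    eye_m = np.eye(m)
    V = np.zeros((m * m, m * m))
    covs = np.empty((len(ages), m * m, m * m))
    P_prev = np.eye(m)
    for k in range(len(ages)):
        A_k = curve.series.matrices[k]
        G = eye_m + A_k
        C_k = _increment_covariance(A_k, n_mat[pos[k]])
        left = np.kron(eye_m, G.T)
        right = np.kron(P_prev, eye_m)
        V = left @ V @ left.T + right @ C_k @ right.T
        covs[k] = V
        P_prev = curve.probs[k]
    curve.cov = covs
    return curve


def pointwise_ci(curve: OccupationCurve, level: float = 0.95) -> OccupationCurve:
    """Wald limits ``P +/- z * SE`` per entry, clipped to [0, 1], in place."""
    if curve.cov is None:
        raise ValueError("attach covariance first (greenwood_covariance)")
    z = norm.ppf(0.5 + level / 2.0)
    se = curve.standard_errors()
    curve.lower = np.clip(curve.probs - z * se, 0.0, 1.0)
    curve.upper = np.clip(curve.probs + z * se, 0.0, 1.0)
    curve.level = level
    return curve
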