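"""Time-indexed intensity matrices for the multi-state model.

At every distinct event age ``t`` the model is summarized by a square matrix
``A(t)`` over the state order of the :class:`~worklife.states.StateSpace`:
off-diagonal entry ``(h, j)`` holds the instantaneous transition quantity
``alpha_hj(t)`` (nonparametrically ``d_hj(t)/n_h(t)``; from a Cox fit the
Breslow baseline increment times ``exp(beta' Z)`` for a covariate profile),
the diagonal holds minus the row sum, and rows of absorbing states are
identically zero.  The series is sparse in time: only event ages are stored,
because the product integral changes nowhere else.

Combined transitions (e.g. ``{W,S,U} -> D``) are estimated on the pooled risk
set and must be redistributed over their origin rows to make ``A(t)`` a valid
generator increment.  Two redistribution modes are provided:

``equal``
    every origin row receives the pooled value ``d_c/n_c`` unchanged — the
    matrix's printed canonical form;
``crude_frequency``
    origin row ``h`` receives ``(d_c/n_c) * f_h * n_c(t)/n_h(t)`` where
    ``f_h`` is the whole-follow-up share of the combined events that
    originated in ``h``; this preserves the total expected event flow
    ``sum_h n_h(t) * entry_h = d_c(t)`` at every age.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cox import CoxFit
from .events import RiskSetTable
from .states import StateSpace

#: redistribution modes for combined transitions
COMBINED_MODES = ("equal", "crude_frequency")


@dataclass
class IntensityMatrixSeries:
    """Square intensity matrices at strictly increasing event ages."""

    states: list[str]
    ages: np.ndarray
    matrices: np.ndarray  # (K, m, m)
    space: StateSpace

    def __post_init__(self):
        self.ages = np.asarray(self.ages, float)
        self.matrices = np.asarray(self.matrices, float)

    def validate(self, atol: float = 1e-12) -> None:
        """Assert row-sum-zero on transdurable rows and zero absorbing rows."""
        m = len(self.states)
        assert self.matrices.shape[1:] == (m, m)
        assert np.all(np.diff(self.ages) > 0), "ages must strictly increase"
        off = self.matrices.copy()
        off[:, np.arange(m), np.arange(m)] = 0.0
        assert (off >= -atol).all(), "negative off-diagonal intensity"
        rowsum = self.matrices.sum(axis=2)
        assert np.abs(rowsum).max(initial=0.0) <= 1e-10, "rows must sum to 0"
        for s in self.space.absorbing_states:
            i = self.states.index(s)
            assert np.abs(self.matrices[:, i, :]).max(initial=0.0) == 0.0

    def restrict(self, s: float, t: float) -> "IntensityMatrixSeries":
        """Sub-series with event ages in (s, t]."""
        keep = (self.ages > s) & (self.ages <= t)
        return IntensityMatrixSeries(
            self.states, self.ages[keep], self.matrices[keep], self.space
        )

    def to_frame(self) -> pd.DataFrame:
        """Long export: age, from_state, to_state, intensity (nonzero only)."""
        rows = []
        for age, A in zip(self.ages, self.matrices):
            hs, js = np.nonzero(A)
            for h, j in zip(hs, js):
                rows.append(
                    {"age": age, "from_state": self.states[h],
                     "to_state": self.states[j], "intensity": A[h, j]}
                )
        return pd.DataFrame(rows, columns=["age", "from_state", "to_state",
                                           "intensity"])


def _crude_frequencies(riskset: RiskSetTable, df: pd.DataFrame | None,
                       origins, to_state) -> dict[str, float]:
    """Whole-follow-up share of combined events per origin state."""
    if df is None:
        raise ValueError(
            "crude_frequency mode needs the episode table to attribute "
            "combined events to origin states"
        )
    ev = df[(df["to_state"] == to_state) & df["from_state"].isin(origins)]
    w = ev["weight"] if "weight" in ev else pd.Series(1.0, index=ev.index)
    totals = w.groupby(ev["from_state"]).sum()
    total = float(totals.sum())
    if total == 0:
        return {}
    return {h: float(totals.get(h, 0.0)) / total for h in origins}


def assemble_matrix_series(
    alphas: dict[str, np.ndarray],
    riskset: RiskSetTable,
    space: StateSpace,
    ages: np.ndarray | None = None,
    combined_mode: str = "equal",
    episodes: pd.DataFrame | None = None,
) -> IntensityMatrixSeries:
    """Assemble per-transition intensities into full matrices.

    Parameters
    ----------
    alphas : dict
        Transition name -> intensity value at every age of ``ages`` (for a
        combined transition: the pooled value ``d_c/n_c``).
    riskset : RiskSetTable
        Supplies per-state at-risk counts for crude-frequency redistribution.
    ages : ndarray, optional
        Age grid of the ``alphas`` arrays; defaults to ``riskset.ages``.
    combined_mode : {"equal", "crude_frequency"}
    episodes : DataFrame, optional
        Needed for ``crude_frequency`` (origin attribution of pooled events).
    """
    if combined_mode not in COMBINED_MODES:
        raise ValueError(f"combined_mode must be one of {COMBINED_MODES}")
    if ages is None:
        ages = riskset.ages
    ages = np.asarray(ages, float)
    states = space.state_order
    m = len(states)
    K = len(ages)
    A = np.zeros((K, m, m))

    # map riskset per-state n onto this age grid (grids coincide for the
    # nonparametric route; the Cox route uses the same event ages subset)
    pos = np.searchsorted(riskset.ages, ages)
    if K:
        ok = pos < len(riskset.ages)
        if not ok.all() or not np.allclose(riskset.ages[pos[ok]], ages[ok]):
            raise ValueError(
                "age grid is not a subset of the risk-set event ages"
            )

    for tr in space.transitions:
        a = np.asarray(alphas.get(tr.name, np.zeros(K)), float)
        j = states.index(tr.to_state)
        if not tr.combined:
            h = states.index(tr.origins[0])
            A[:, h, j] += a
            continue
        if combined_mode == "crude_frequency":
            f = _crude_frequencies(riskset, episodes, tr.origins, tr.to_state)
            if not f:
                warnings.warn(
                    f"transition {tr.name}: no observed origin events; "
                    "falling back to equal redistribution"
                )
            else:
                n_c = riskset.n_for(tr.origins)[pos]
                for h_state in tr.origins:
                    h = states.index(h_state)
                    n_h = riskset.n[h_state].to_numpy()[pos]
                    with np.errstate(divide="ignore", invalid="ignore"):
                        scale = np.where(n_h > 0, f[h_state] * n_c / n_h, 0.0)
                    A[:, h, j] += a * scale
                continue
        # equal mode (and crude fallback): pooled value in every origin row
        for h_state in tr.origins:
            A[:, states.index(h_state), j] += a

    # diagonals = minus row sums; absorbing rows zeroed
    for i, s in enumerate(states):
        if space.is_absorbing(s):
            A[:, i, :] = 0.0
    diag = -A.sum(axis=2)
    A[:, np.arange(m), np.arange(m)] = diag

    series = IntensityMatrixSeries(states, ages, A, space)
    series.validate()
    return series


def nonparametric_intensities(
    riskset: RiskSetTable,
    space: StateSpace,
    combined_mode: str = "equal",
    episodes: pd.DataFrame | None = None,
) -> IntensityMatrixSeries:
    """Occurrence/exposure intensities ``alpha_hj(t) = d_hj(t)/n_h(t)``.

    Combined transitions use the pooled risk set ``d_c / sum_h n_h``.  Ages
    with no events anywhere are omitted (the risk-set grid already is the
    event-age grid).
    """
    alphas = {}
    for tr in space.transitions:
        d = riskset.d[tr.name].to_numpy()
        n = riskset.n_for(tr.origins)
        assert not np.any((n <= 0) & (d > 0)), "event without risk set"
        with np.errstate(divide="ignore", invalid="ignore"):
            alphas[tr.name] = np.where(n > 0, d / np.maximum(n, 1e-300), 0.0)
    return assemble_matrix_series(
        alphas, riskset, space, combined_mode=combined_mode, episodes=episodes
    )


def cox_intensities(
    fit: CoxFit,
    profile: dict[str, float],
    combined_mode: str = "equal",
    episodes: pd.DataFrame | None = None,
) -> IntensityMatrixSeries:
    """Profile-adjusted intensities from a Cox fit.

    Per transition, the intensity at each baseline jump age is the Breslow
    baseline increment times ``exp(beta' Z)`` with ``Z`` taken from
    ``profile``; frailty (if any) enters at its mean 1, giving population-
    level intensities.  The union of jump ages over transitions forms the
    series grid.
    """
    space = fit.space
    missing = [c for c in fit.covariate_names if c not in profile]
    if missing:
        raise KeyError(f"profile missing covariate(s): {missing}")
    ages = np.unique(
        np.concatenate(
            [fit[tr.name].baseline_ages for tr in space.transitions]
            or [np.zeros(0)]
        )
    )
    alphas = {}
    for tr in space.transitions:
        tf = fit[tr.name]
        a = np.zeros(len(ages))
        if len(tf.baseline_ages):
            hr = np.exp(tf.linear_predictor(profile))
            idx = np.searchsorted(ages, tf.baseline_ages)
            a[idx] = tf.baseline_increments * hr
        alphas[tr.name] = a
    return assemble_matrix_series(
        alphas, fit.riskset, space, ages=ages, combined_mode=combined_mode,
        episodes=episodes,
    )
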