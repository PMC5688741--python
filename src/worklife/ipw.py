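"""Stabilized inverse-propensity weights for exposure and censoring.

To read a covariate effect (e.g. poor self-rated health) marginally rather
than conditionally, the transition-specific Cox models can be weighted by
record-level stabilized inverse-propensity scores: the weight of a record is

    w = [ p0 / p(Z) ] * [ c0 / c(Z) ],

where ``p(Z)`` is the conditional probability of the record's *observed*
exposure level given the adjusters, ``p0`` the marginal (intercept-only)
probability of that level, and ``c(Z)``, ``c0`` the analogous conditional and
marginal probabilities of remaining uncensored (loss to follow-up only —
administrative censoring at pension age or study end is covariate-independent
by design and is not modeled).  Both component models are ordinary logistic
regressions fit on records; because covariates are episode-constant
snapshots of time-varying quantities, every record gets its own weight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .events import CENSORED
from .states import StateSpace


class PropensityError(ValueError):
    """Degenerate or separated propensity model."""


@dataclass
class WeightTable:
    """Per-record propensity components and the final stabilized weight."""

    table: pd.DataFrame  # subject_id, entry_age, components, weight, truncated

    @property
    def weights(self) -> np.ndarray:
        return self.table["weight"].to_numpy()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _check_separation(df, outcome, adjusters):
    """Name an adjuster that perfectly predicts the outcome, if any."""
    y = df[outcome]
    for a in adjusters:
        x = df[a]
        if x.nunique() <= 10:  # categorical-ish
            tab = pd.crosstab(x, y)
            if tab.shape[1] == 2 and (tab == 0).any(axis=None):
                levels = tab.index[(tab == 0).any(axis=1)].tolist()
                return a, levels
    return None


def _fit_logistic(df, outcome, adjusters):
    y = df[outcome].to_numpy(float)
    # zero-variance adjusters carry no information; dropping them keeps the
    # degenerate all-constant case exactly intercept-only
    adjusters = [a for a in adjusters if df[a].nunique() > 1]
    if not adjusters:
        return np.full(len(df), np.clip(y.mean(), 1e-12, 1 - 1e-12))
    X = sm.add_constant(df[list(adjusters)].astype(float), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
        if not np.isfinite(res.params).all() or np.abs(res.params).max() > 20:
            raise RuntimeError("diverging coefficients")
    except Exception as err:
        sep = _check_separation(df, outcome, adjusters)
        if sep:
            raise PropensityError(
                f"separation: adjuster {sep[0]!r} perfectly predicts "
                f"{outcome!r} at level(s) {sep[1]}"
            ) from err
        raise PropensityError(f"logistic model for {outcome!r} failed: {err}")
    return np.clip(res.predict(X), 1e-12, 1 - 1e-12)


def fit_propensity(
    df: pd.DataFrame, exposure: str, adjusters: list[str]
) -> pd.DataFrame:
    """Record-level exposure propensities (conditional and marginal).

    Returns a DataFrame aligned with ``df``: ``p_conditional`` = P(observed
    exposure level | adjusters), ``p_marginal`` = intercept-only probability
    of the observed level (the sample exposure fraction for the exposed).
    """
    e = df[exposure].to_numpy(float)
    if len(np.unique(e)) < 2:
        raise PropensityError(
            f"exposure {exposure!r} has no variation (all "
            f"{'exposed' if e.size and e[0] else 'unexposed'})"
        )
    if not set(np.unique(e)) <= {0.0, 1.0}:
        raise PropensityError(f"exposure {exposure!r} must be binary 0/1")
    missing = [a for a in adjusters if a not in df.columns]
    if missing:
        raise KeyError(f"adjuster column(s) not in data: {missing}")

    p1 = _fit_logistic(df, exposure, adjusters)
    p1_marg = float(e.mean())
    out = pd.DataFrame(index=df.index)
    out["p_conditional"] = np.where(e == 1, p1, 1 - p1)
    out["p_marginal"] = np.where(e == 1, p1_marg, 1 - p1_marg)
    return out


def censoring_weights(
    df: pd.DataFrame,
    adjusters: list[str],
    space: StateSpace | None = None,
    administrative_age: float | None = None,
) -> pd.DataFrame:
    """Stabilized uncensored-probability ratio per record.

    A record counts as (non-administratively) censored when its destination
    is the censoring marker and its exit age falls strictly before the
    administrative age (pension age by default).  Returns ``c_conditional``,
    ``c_marginal`` and their stabilized ratio ``c_ratio = c_marginal /
    c_conditional``; with no censoring events all ratios are exactly 1.
    """
    if administrative_age is None:
        administrative_age = space.pension_age if space is not None else np.inf
    cens = (
        (df["to_state"] == CENSORED)
        & (df["exit_age"] < administrative_age - 1e-9)
    )
    out = pd.DataFrame(index=df.index)
    if not cens.any():
        warnings.warn("no non-administrative censoring events; ratios are 1")
        out["c_conditional"] = 1.0
        out["c_marginal"] = 1.0
        out["c_ratio"] = 1.0
        return out
    work = df.copy()
    work["_uncensored"] = (~cens).astype(float)
    c_cond = _fit_logistic(work, "_uncensored", adjusters)
    c_marg = float(work["_uncensored"].mean())
    out["c_conditional"] = c_cond
    out["c_marginal"] = c_marg
    out["c_ratio"] = c_marg / c_cond
    return out


def stabilized_weights(
    df: pd.DataFrame,
    exposure: str,
    adjusters: list[str] | None = None,
    space: StateSpace | None = None,
    truncate: tuple[float, float] | None = None,
) -> WeightTable:
    """Final per-record stabilized weights for the weighted Cox fit.

    ``weight = (p_marginal / p_conditional) * (c_marginal / c_conditional)``.

    Parameters
    ----------
    adjusters : list of str, optional
        Defaults to every covariate column except the exposure.
    truncate : (low, high) percentiles, optional
        E.g. ``(0.5, 99.5)``; truncated records are flagged.  Off by default.
    """
    from .events import covariate_columns

    if adjusters is None:
        adjusters = [c for c in covariate_columns(df) if c != exposure]
    prop = fit_propensity(df, exposure, adjusters)
    cens = censoring_weights(df, adjusters, space=space)
    w = (prop["p_marginal"] / prop["p_conditional"]) * cens["c_ratio"]
    if (w <= 0).any() or not np.isfinite(w).all():
        raise PropensityError("nonpositive or nonfinite stabilized weight")
    truncated = pd.Series(False, index=df.index)
    if truncate is not None:
        lo, hi = np.percentile(w, truncate)
        truncated = (w < lo) | (w > hi)
        w = w.clip(lo, hi)
    table = pd.DataFrame(
        {
            "subject_id": df["subject_id"],
            "entry_age": df["entry_age"],
            "p_conditional": prop["p_conditional"],
            "p_marginal": prop["p_marginal"],
            "c_conditional": cens["c_conditional"],
            "c_marginal": cens["c_marginal"],
            "weight": w,
            "truncated": truncated,
        }
    )
    return WeightTable(table)
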