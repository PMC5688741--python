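"""Transition-stratified Cox proportional-hazards engine.

The multi-state proportional-hazards model puts one Cox model on every
transition ``h -> j`` of the state space:

    lambda_hj(t | Z, u_i) = u_i * lambda_hj0(t) * exp(beta_hj' Z),

with age ``t`` as the time scale, transition-specific coefficients
``beta_hj``, an unrestricted baseline hazard ``lambda_hj0`` and an optional
shared per-subject gamma frailty ``u_i`` (mean 1, variance theta).  Episodes
enter each transition's risk set by delayed entry at ``entry_age`` and leave
at ``exit_age``; a combined transition pools episodes from all its origin
states into one risk set.

Fitting maximizes the weighted partial likelihood with the Breslow
approximation for ties (Newton-Raphson); the baseline cumulative hazard is
the weighted Breslow estimator, which with no covariates reduces exactly to
the Nelson-Aalen ``d/n`` increments.  Fitting each transition separately is
equivalent to one fit on stacked long-format data stratified by transition
with transition-specific covariate interactions, because the stratified
partial likelihood factorizes over strata.

Gamma frailty is estimated by an EM algorithm (posterior frailty means given
subject event counts and accumulated hazard) with the frailty variance theta
chosen by profile marginal likelihood; it is off by default so the headline
pipeline stays deterministic and fast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .events import CENSORED, RiskSetTable, build_risk_sets
from .states import StateSpace, Transition


class ConvergenceError(RuntimeError):
    """Newton iteration failed; carries the partial log-likelihood trace."""

    def __init__(self, msg, trace=None):
        super().__init__(msg)
        self.trace = list(trace or [])


class SeparationError(RuntimeError):
    """Monotone likelihood (complete separation) for a named covariate."""


class StepFunction:
    """Right-continuous nondecreasing step function from jump ages/increments."""

    def __init__(self, ages: np.ndarray, increments: np.ndarray):
        self.ages = np.asarray(ages, float)
        self.increments = np.asarray(increments, float)
        self.cumulative = np.cumsum(self.increments)

    def __call__(self, t):
        idx = np.searchsorted(self.ages, np.asarray(t, float), side="right")
        cum = np.concatenate([[0.0], self.cumulative])
        return cum[idx]


@dataclass
class TransitionFit:
    """Per-transition Cox results: coefficients and Breslow baseline."""

    transition: Transition
    covariates: list[str]
    beta: np.ndarray | None
    se: np.ndarray | None
    cov: np.ndarray | None
    loglik: float
    baseline_ages: np.ndarray
    baseline_increments: np.ndarray
    n_events: float
    n_episodes: int
    dropped_covariates: list[str] = field(default_factory=list)
    n_iter: int = 0

    @property
    def baseline(self) -> StepFunction:
        return StepFunction(self.baseline_ages, self.baseline_increments)

    def linear_predictor(self, profile: dict[str, float]) -> float:
        """beta' Z for a covariate profile (dropped covariates contribute 0)."""
        if self.beta is None or not self.covariates:
            return 0.0
        missing = [c for c in self.covariates if c not in profile]
        if missing:
            raise KeyError(
                f"profile missing covariate(s) {missing} for transition "
                f"{self.transition.name}"
            )
        z = np.array([profile[c] for c in self.covariates], float)
        return float(self.beta @ z)

    def summary(self) -> pd.DataFrame:
        """HR table row block: covariate, HR, 95% CL, p (Wald)."""
        from scipy.stats import norm

        if self.beta is None or not self.covariates:
            return pd.DataFrame(
                columns=["transition", "covariate", "coef", "HR", "lower95",
                         "upper95", "p"]
            )
        z975 = norm.ppf(0.975)
        se = self.se
        zstat = np.where(se > 0, self.beta / np.where(se > 0, se, 1.0), np.nan)
        return pd.DataFrame(
            {
                "transition": self.transition.name,
                "covariate": self.covariates,
                "coef": self.beta,
                "HR": np.exp(self.beta),
                "lower95": np.exp(self.beta - z975 * se),
                "upper95": np.exp(self.beta + z975 * se),
                "p": 2 * norm.sf(np.abs(zstat)),
            }
        )


@dataclass
class CoxFit:
    """Fitted multi-state Cox model: one :class:`TransitionFit` per transition."""

    space: StateSpace
    covariate_names: list[str]
    transitions: dict[str, TransitionFit]
    riskset: RiskSetTable
    frailty_variance: float | None = None
    frailty_estimates: pd.Series | None = None
    weights_used: bool = False

    def __getitem__(self, name: str) -> TransitionFit:
        if name not in self.transitions:
            raise KeyError(f"unknown transition {name!r}")
        return self.transitions[name]

    def summary(self) -> pd.DataFrame:
        parts = [tf.summary() for tf in self.transitions.values()]
        parts = [p for p in parts if len(p)]
        if not parts:
            return pd.DataFrame(
                columns=["transition", "covariate", "coef", "HR", "lower95",
                         "upper95", "p"]
            )
        return pd.concat(parts, ignore_index=True)

    def baseline_table(self) -> pd.DataFrame:
        rows = []
        for name, tf in self.transitions.items():
            cum = np.cumsum(tf.baseline_increments)
            for a, inc, c in zip(tf.baseline_ages, tf.baseline_increments, cum):
                rows.append(
                    {"transition": name, "age": a, "increment": inc,
                     "cumulative": c}
                )
        return pd.DataFrame(rows, columns=["transition", "age", "increment",
                                           "cumulative"])


# ---------------------------------------------------------------------------
# core partial-likelihood solver
# ---------------------------------------------------------------------------

def _risk_suffix_sums(sort_entry, sort_exit, entry, exit_, values, ages):
    """Sum of `values` over episodes at risk (entry < t <= exit) per age.

    `values` has shape (n, ...); returns shape (len(ages), ...).
    Uses suffix sums: [exit >= t] - [entry >= t].
    """
    def suffix(sorted_times, order):
        v = values[order]
        csum = np.concatenate([np.zeros((1,) + v.shape[1:]), np.cumsum(v, axis=0)])
        total = csum[-1]
        idx = np.searchsorted(sorted_times, ages, side="left")
        return total - csum[idx]

    return suffix(exit_[sort_exit], sort_exit) - suffix(entry[sort_entry], sort_entry)


def _newton_cox(entry, exit_, event, Z, w, offset, tol=1e-9, max_iter=100):
    """Weighted Breslow Cox on counting-process data for one transition.

    Returns (beta, cov, loglik, n_iter, event_ages, baseline_increments).
    ``Z`` may have zero columns, in which case the baseline is the weighted
    Nelson-Aalen estimator.
    """
    n, p = Z.shape
    ev = event.astype(bool)
    t_ev = exit_[ev]
    order = np.argsort(t_ev)
    t_sorted = t_ev[order]
    ages, first = np.unique(t_sorted, return_index=True)
    K = len(ages)
    # per-event-age sums over the tied event set
    w_ev, Z_ev = w[ev][order], Z[ev][order]
    dsum = np.add.reduceat(w_ev, first) if K else np.zeros(0)
    sZw = (
        np.add.reduceat(w_ev[:, None] * Z_ev, first, axis=0)
        if K and p
        else np.zeros((K, p))
    )

    sort_entry = np.argsort(entry)
    sort_exit = np.argsort(exit_)

    def risk_sums(beta):
        x = w * np.exp(Z @ beta + offset)
        S0 = _risk_suffix_sums(sort_entry, sort_exit, entry, exit_, x, ages)
        if p:
            S1 = _risk_suffix_sums(
                sort_entry, sort_exit, entry, exit_, x[:, None] * Z, ages
            )
            zz = Z[:, :, None] * Z[:, None, :]
            S2 = _risk_suffix_sums(
                sort_entry, sort_exit, entry, exit_, x[:, None, None] * zz, ages
            )
        else:
            S1 = np.zeros((K, 0))
            S2 = np.zeros((K, 0, 0))
        return x, S0, S1, S2

    beta = np.zeros(p)
    if K == 0:
        return beta, np.zeros((p, p)), 0.0, 0, ages, np.zeros(0)

    def loglik_of(beta):
        x, S0, S1, S2 = risk_sums(beta)
        ll = float(np.sum(sZw @ beta) + np.sum(w_ev * offset[ev][order])
                   - np.sum(dsum * np.log(S0)))
        return ll, S0, S1, S2

    ll, S0, S1, S2 = loglik_of(beta)
    trace = [ll]
    n_iter = 0
    info = np.zeros((p, p))
    for n_iter in range(1, max_iter + 1):
        if p == 0:
            break
        Ebar = S1 / S0[:, None]
        U = sZw.sum(axis=0) - (dsum[:, None] * Ebar).sum(axis=0)
        V = S2 / S0[:, None, None] - Ebar[:, :, None] * Ebar[:, None, :]
        info = (dsum[:, None, None] * V).sum(axis=0)
        try:
            step = np.linalg.solve(info, U)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "singular information matrix (possible complete separation)"
            )
        # step-halving line search
        for _ in range(30):
            cand = beta + step
            ll_new, S0n, S1n, S2n = loglik_of(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            step = step / 2
        else:
            raise ConvergenceError("step-halving failed", trace)
        beta, S0, S1, S2 = cand, S0n, S1n, S2n
        trace.append(ll_new)
        if np.max(np.abs(beta)) > 20:
            raise SeparationError(
                "coefficient diverging (monotone likelihood / separation)"
            )
        if abs(ll_new - ll) < tol * (abs(ll) + tol):
            ll = ll_new
            break
        ll = ll_new
    else:
        if p:
            raise ConvergenceError(
                f"no convergence in {max_iter} Newton iterations", trace
            )

    cov = np.linalg.inv(info) if p else np.zeros((0, 0))
    increments = dsum / S0  # weighted Breslow; == d/n when p == 0, offset == 0
    return beta, cov, ll, n_iter, ages, increments


def _transition_arrays(df, tr: Transition, covariates, offset_map=None):
    m = df["from_state"].isin(tr.origins).to_numpy()
    sub = df[m]
    entry = sub["entry_age"].to_numpy(float)
    exit_ = sub["exit_age"].to_numpy(float)
    event = (sub["to_state"] == tr.to_state).to_numpy()
    Z = sub[list(covariates)].to_numpy(float) if covariates else np.zeros((m.sum(), 0))
    w = sub["weight"].to_numpy(float) if "weight" in sub else np.ones(m.sum())
    if offset_map is None:
        offset = np.zeros(m.sum())
    else:
        offset = sub["subject_id"].map(offset_map).to_numpy(float)
    return sub, entry, exit_, event, Z, w, offset


def _fit_one_transition(df, tr, covariates, offset_map=None, tol=1e-9,
                        max_iter=100) -> TransitionFit:
    sub, entry, exit_, event, Z, w, offset = _transition_arrays(
        df, tr, covariates, offset_map
    )
    n_events = float(w[event].sum())
    use_cov, dropped = [], []
    if event.sum() >= 1:
        for j, c in enumerate(covariates):
            (use_cov if np.ptp(Z[:, j]) > 0 else dropped).append(c)
    else:
        dropped = list(covariates)
    Zu = sub[use_cov].to_numpy(float) if use_cov else np.zeros((len(sub), 0))
    try:
        beta, cov, ll, n_iter, ages, incr = _newton_cox(
            entry, exit_, event, Zu, w, offset, tol, max_iter
        )
    except SeparationError as e:
        worst = use_cov[-1] if use_cov else "?"
        raise SeparationError(
            f"transition {tr.name}: {e} (covariates {use_cov}, suspect {worst!r})"
        ) from e
    except ConvergenceError as e:
        raise ConvergenceError(
            f"transition {tr.name}: {e}; loglik trace {e.trace}", e.trace
        ) from e
    # report full covariate vector with dropped entries at 0 / NaN SE
    if covariates:
        full_beta = np.zeros(len(covariates))
        full_se = np.full(len(covariates), np.nan)
        full_cov = np.full((len(covariates), len(covariates)), np.nan)
        idx = [covariates.index(c) for c in use_cov]
        full_beta[idx] = beta
        if len(idx):
            full_se[idx] = np.sqrt(np.maximum(np.diag(cov), 0.0))
            full_cov[np.ix_(idx, idx)] = cov
    else:
        full_beta = None if not covariates else np.zeros(0)
        full_se, full_cov = None, None
    return TransitionFit(
        transition=tr,
        covariates=list(covariates),
        beta=full_beta if covariates else None,
        se=full_se,
        cov=full_cov,
        loglik=ll,
        baseline_ages=ages,
        baseline_increments=incr,
        n_events=n_events,
        n_episodes=len(sub),
        dropped_covariates=dropped,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# public fitting API
# ---------------------------------------------------------------------------

def fit_multistate_cox(
    df: pd.DataFrame,
    space: StateSpace,
    covariate_names: list[str] | None = None,
    weights=None,
    frailty: bool = False,
    frailty_theta: float | None = None,
    tol: float = 1e-9,
    max_iter: int = 100,
) -> CoxFit:
    """Fit one Cox model per transition of ``space`` on long-format episodes.

    Parameters
    ----------
    df : DataFrame
        Validated long-format event history (see :mod:`worklife.events`).
    covariate_names : list of str, optional
        Covariate columns; effects are transition-specific.  ``None`` or empty
        fits baseline-only models (Nelson-Aalen increments).
    weights : array-like, optional
        Per-record weights overriding the ``weight`` column (e.g. stabilized
        IPW weights).
    frailty : bool
        Estimate a shared per-subject gamma frailty (variance by profile
        marginal likelihood); ``frailty_theta`` fixes the variance instead.

    Returns
    -------
    CoxFit
    """
    covariate_names = list(covariate_names or [])
    df = df.copy()
    if weights is not None:
        df["weight"] = np.asarray(weights, float)
    elif "weight" not in df.columns:
        df["weight"] = 1.0
    missing = [c for c in covariate_names if c not in df.columns]
    if missing:
        raise KeyError(f"covariate column(s) not in data: {missing}")

    riskset = build_risk_sets(df, space)
    weights_used = bool((df["weight"] != 1.0).any())

    if frailty or frailty_theta is not None:
        return _fit_with_frailty(
            df, space, covariate_names, riskset, weights_used,
            frailty_theta, tol, max_iter,
        )

    fits = {
        tr.name: _fit_one_transition(df, tr, covariate_names, None, tol, max_iter)
        for tr in space.transitions
    }
    return CoxFit(
        space=space,
        covariate_names=covariate_names,
        transitions=fits,
        riskset=riskset,
        weights_used=weights_used,
    )


def baseline_cumulative_hazard(fit: CoxFit, transition: str) -> StepFunction:
    """Breslow baseline cumulative hazard of one transition, as a step function."""
    return fit[transition].baseline


# ---------------------------------------------------------------------------
# gamma frailty via EM + profile likelihood
# ---------------------------------------------------------------------------

def _subject_event_counts_and_hazard(df, space, fits):
    """Per subject: event count N_i and accumulated hazard H_i (u-free)."""
    subjects = pd.unique(df["subject_id"])
    N = pd.Series(0.0, index=subjects)
    H = pd.Series(0.0, index=subjects)
    for tr in space.transitions:
        tf = fits[tr.name]
        sub = df[df["from_state"].isin(tr.origins)]
        ev = sub["to_state"] == tr.to_state
        N = N.add(ev.groupby(sub["subject_id"]).sum(), fill_value=0.0)
        lp = np.zeros(len(sub))
        if tf.beta is not None and tf.covariates:
            ok = ~np.isnan(tf.beta)
            Z = sub[list(tf.covariates)].to_numpy(float)
            lp = Z[:, ok] @ tf.beta[ok]
        base = tf.baseline
        dH = (base(sub["exit_age"].to_numpy()) - base(sub["entry_age"].to_numpy()))
        H = H.add(
            pd.Series(dH * np.exp(lp)).groupby(sub["subject_id"].to_numpy()).sum(),
            fill_value=0.0,
        )
    return N, H


def _em_given_theta(df, space, covariates, theta, tol, max_iter, em_iter=25):
    u = pd.Series(1.0, index=pd.unique(df["subject_id"]))
    fits = None
    for _ in range(em_iter):
        offset_map = np.log(u)
        fits = {
            tr.name: _fit_one_transition(df, tr, covariates, offset_map, tol,
                                         max_iter)
            for tr in space.transitions
        }
        N, H = _subject_event_counts_and_hazard(df, space, fits)
        # NB: H here includes the frailty offsets through the baselines'
        # denominators only; posterior mean uses the subject's own u-free H.
        u_new = (1.0 / theta + N) / (1.0 / theta + H)
        if np.max(np.abs(u_new - u)) < 1e-6:
            u = u_new
            break
        u = u_new
    return fits, u


def _marginal_loglik(df, space, fits, theta):
    N, H = _subject_event_counts_and_hazard(df, space, fits)
    inv = 1.0 / theta
    frail_part = float(
        np.sum(gammaln(inv + N) - gammaln(inv) + inv * np.log(inv)
               - (inv + N) * np.log(inv + H))
    )
    event_part = 0.0
    for tr in space.transitions:
        tf = fits[tr.name]
        sub = df[df["from_state"].isin(tr.origins)]
        ev = sub["to_state"] == tr.to_state
        if not ev.any():
            continue
        lp = np.zeros(ev.sum())
        if tf.beta is not None and tf.covariates:
            ok = ~np.isnan(tf.beta)
            Z = sub.loc[ev, list(tf.covariates)].to_numpy(float)
            lp = Z[:, ok] @ tf.beta[ok]
        incr = pd.Series(tf.baseline_increments, index=tf.baseline_ages)
        d_at = incr.reindex(sub.loc[ev, "exit_age"].to_numpy()).to_numpy()
        d_at = np.where(np.isfinite(d_at) & (d_at > 0), d_at, np.nan)
        with np.errstate(invalid="ignore"):
            event_part += float(np.nansum(np.log(d_at) + lp))
    return frail_part + event_part


def _fit_with_frailty(df, space, covariates, riskset, weights_used,
                      frailty_theta, tol, max_iter):
    if weights_used:
        warnings.warn("frailty with non-unit weights is approximate")

    if frailty_theta is not None:
        theta = float(frailty_theta)
        fits, u = _em_given_theta(df, space, covariates, max(theta, 1e-10),
                                  tol, max_iter)
    else:
        def neg_profile(log_theta):
            th = float(np.exp(log_theta))
            f, _ = _em_given_theta(df, space, covariates, th, tol, max_iter,
                                   em_iter=10)
            return -_marginal_loglik(df, space, f, th)

        res = minimize_scalar(neg_profile, bounds=(np.log(1e-4), np.log(4.0)),
                              method="bounded",
                              options={"xatol": 0.05, "maxiter": 20})
        theta = float(np.exp(res.x))
        fits, u = _em_given_theta(df, space, covariates, theta, tol, max_iter)

    return CoxFit(
        space=space,
        covariate_names=list(covariates),
        transitions=fits,
        riskset=riskset,
        frailty_variance=theta,
        frailty_estimates=u,
        weights_used=weights_used,
    )


# ---------------------------------------------------------------------------
# long-format stacking (transition-stratified single fit)
# ---------------------------------------------------------------------------

def stack_transitions(
    df: pd.DataFrame, space: StateSpace, covariate_names: list[str] | None = None
) -> pd.DataFrame:
    """Stack episodes into one transition-stratified long-format table.

    Every episode is replicated once per transition for which its origin
    state is at risk.  The result carries a ``transition`` stratum column, a
    0/1 ``event`` column and, for each covariate ``c`` and transition name
    ``T``, an interaction column ``c__T`` equal to ``c`` inside stratum ``T``
    and 0 elsewhere — so a single Cox fit stratified by ``transition`` yields
    the same transition-specific coefficients as separate per-transition fits.
    """
    covariate_names = list(covariate_names or [])
    parts = []
    for tr in space.transitions:
        sub = df[df["from_state"].isin(tr.origins)].copy()
        sub["transition"] = tr.name
        sub["event"] = (sub["to_state"] == tr.to_state).astype(int)
        parts.append(sub)
    out = pd.concat(parts, ignore_index=True)
    for c in covariate_names:
        for tr in space.transitions:
            out[f"{c}__{tr.name}"] = np.where(
                out["transition"] == tr.name, out[c], 0.0
            )
    return out


def fit_stratified_long(
    stacked: pd.DataFrame, space: StateSpace,
    covariate_names: list[str] | None = None, **kwargs
) -> CoxFit:
    """Fit the stacked long-format table, stratifying by ``transition``.

    The stratified partial likelihood factorizes over strata, so this routes
    each stratum through the same per-transition solver; it exists so both
    data arrangements are first-class (and testable against an external
    stratified fit).
    """
    covariate_names = list(covariate_names or [])
    fits = {}
    for tr in space.transitions:
        sub = stacked[stacked["transition"] == tr.name].copy()
        sub = sub.rename(columns={})
        # reconstruct destination marker so the per-transition solver applies
        sub["to_state"] = np.where(sub["event"] == 1, tr.to_state, CENSORED)
        sub["from_state"] = tr.origins[0]
        one = Transition((tr.origins[0],), tr.to_state)
        cols = [f"{c}__{tr.name}" for c in covariate_names]
        tf = _fit_one_transition(sub, one, cols, None,
                                 kwargs.get("tol", 1e-9),
                                 kwargs.get("max_iter", 100))
        tf.transition = tr
        tf.covariates = list(covariate_names)
        fits[tr.name] = tf
    riskset = kwargs.get("riskset")
    return CoxFit(
        space=space,
        covariate_names=covariate_names,
        transitions=fits,
        riskset=riskset,
        weights_used=bool((stacked.get("weight", pd.Series(1.0)) != 1.0).any()),
    )


# ---------------------------------------------------------------------------
# proportionality diagnostics
# ---------------------------------------------------------------------------

def proportionality_diagnostics(
    df: pd.DataFrame, space: StateSpace, covariate: str
) -> pd.DataFrame:
    """Stratified Nelson-Aalen cumulative hazards for a categorical covariate.

    Returns a long table (transition, level, age, cumhaz, zero_events flag)
    for visual proportionality checks; with >= 2 levels a log cumulative-
    hazard ratio column ``log_ratio_vs_ref`` is added on the union age grid
    (reference = first level).
    """
    levels = sorted(pd.unique(df[covariate]))
    rows = []
    funcs: dict[tuple, StepFunction] = {}
    for lev in levels:
        sub = df[df[covariate] == lev]
        rs = build_risk_sets(sub, space)
        for tr in space.transitions:
            d = rs.d[tr.name].to_numpy()
            n = rs.n_for(tr.origins)
            keep = d > 0
            with np.errstate(divide="ignore", invalid="ignore"):
                inc = np.where(n[keep] > 0, d[keep] / n[keep], 0.0)
            if not keep.any():
                warnings.warn(
                    f"{covariate}={lev}, transition {tr.name}: zero events"
                )
            sf = StepFunction(rs.ages[keep], inc)
            funcs[(lev, tr.name)] = sf
            cum = np.cumsum(inc)
            for a, c in zip(rs.ages[keep], cum):
                rows.append(
                    {"transition": tr.name, "level": lev, "age": a,
                     "cumhaz": c, "zero_events": False}
                )
            if not keep.any():
                rows.append(
                    {"transition": tr.name, "level": lev, "age": np.nan,
                     "cumhaz": 0.0, "zero_events": True}
                )
    out = pd.DataFrame(rows)
    if len(levels) >= 2 and len(out):
        ref = levels[0]
        with np.errstate(divide="ignore", invalid="ignore"):
            out["log_ratio_vs_ref"] = [
                float(
                    np.log(r.cumhaz)
                    - np.log(funcs[(ref, r.transition)]([r.age])[0])
                )
                if np.isfinite(r.age)
                else np.nan
                for r in out.itertuples()
            ]
    return out
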