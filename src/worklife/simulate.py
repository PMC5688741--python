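"""Register-style cohort simulator with exact Markov oracles.

Generates long-format multi-state event histories from known piecewise-
constant baseline transition intensities with multiplicative covariate
effects (log hazard ratios per transition), an optional shared gamma frailty,
dynamic no->yes covariate flips (e.g. a long-term-sickness indicator that
switches on once a sickness-absence episode exceeds four weeks, splitting the
episode at the flip), covariate-dependent loss to follow-up, and
administrative censoring at the end of the age window.

Sojourn times are drawn by exact inversion of the piecewise-constant
cumulative hazard of the sum of outgoing intensities; the destination is then
drawn from the relative intensities at the event age.  For the Markov case
(no frailty; a fixed covariate profile) the implied occupation probabilities
and expected state durations have closed matrix-exponential forms, exposed as
:func:`true_occupation` and :func:`true_wle` — the oracles the estimators are
tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.linalg import expm

from .events import CENSORED
from .states import StateSpace, Transition, danish_labor_market


@dataclass
class PiecewiseRate:
    """Piecewise-constant rate per year: value ``rates[i]`` on
    ``[breaks[i], breaks[i+1])``, last piece open-ended."""

    breaks: tuple[float, ...]  # ordered ages; first applies from -inf
    rates: tuple[float, ...]

    def __post_init__(self):
        self.breaks = tuple(float(b) for b in self.breaks)
        self.rates = tuple(float(r) for r in self.rates)
        if len(self.breaks) != len(self.rates):
            raise ValueError("breaks and rates must have equal length")
        if any(r < 0 for r in self.rates):
            raise ValueError("rates must be nonnegative")
        if any(b1 <= b0 for b0, b1 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly increasing")

    @classmethod
    def constant(cls, rate: float, start: float = 0.0) -> "PiecewiseRate":
        return cls((start,), (rate,))

    def at(self, age: float) -> float:
        i = np.searchsorted(self.breaks, age, side="right") - 1
        return self.rates[i] if i >= 0 else 0.0


@dataclass
class DynamicRule:
    """Flip a 0/1 covariate to 1 after dwelling in a state long enough.

    The flip happens *at* ``entry + dwell_years`` into any episode in
    ``trigger_state``, splitting that episode so covariates stay
    episode-constant.
    """

    covariate: str
    trigger_state: str
    dwell_years: float = 28.0 / 365.25  # "more than 4 weeks"


@dataclass
class SimulationConfig:
    """Study-condition container for the cohort generator.

    Defaults mirror the emulated register cohort: ages 55-65 with
    administrative censoring at 65, sample size 5212, work as the starting
    state, and the eight-transition labor-market state space.
    """

    space: StateSpace = field(default_factory=danish_labor_market)
    n_subjects: int = 5212
    age_min: float = 55.0
    age_max: float = 65.0
    baseline: dict[str, PiecewiseRate] = field(default_factory=dict)
    log_hr: dict[str, dict[str, float]] = field(default_factory=dict)
    covariate_prevalence: dict[str, float] = field(default_factory=dict)
    covariate_dependence: dict[str, dict[str, float]] = field(
        default_factory=dict
    )  # cov -> {"intercept": b0, other_cov: b} on the logit scale
    dynamic_rules: list[DynamicRule] = field(default_factory=list)
    frailty_variance: float = 0.0
    censoring_rate: float = 0.0
    censoring_log_hr: dict[str, float] = field(default_factory=dict)
    start_state: str = "W"
    seed: int = 0

    def __post_init__(self):
        for name in self.baseline:
            self.space.transition_by_name(name)  # raises on unknown
        if self.frailty_variance < 0:
            raise ValueError("frailty_variance must be >= 0")
        if self.age_min >= self.age_max:
            raise ValueError("need age_min < age_max")

    # -- YAML round trip (scenario files) ----------------------------------
    def to_yaml(self, path) -> None:
        def plain(x):
            if isinstance(x, dict):
                return {k: plain(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [plain(v) for v in x]
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            return x

        d = {
            "statespace": self.space.to_dict(),
            "n_subjects": self.n_subjects,
            "age_min": self.age_min,
            "age_max": self.age_max,
            "baseline": {
                k: {"breaks": list(v.breaks), "rates": list(v.rates)}
                for k, v in self.baseline.items()
            },
            "log_hr": self.log_hr,
            "covariate_prevalence": self.covariate_prevalence,
            "covariate_dependence": self.covariate_dependence,
            "dynamic_rules": [
                {"covariate": r.covariate, "trigger_state": r.trigger_state,
                 "dwell_years": r.dwell_years}
                for r in self.dynamic_rules
            ],
            "frailty_variance": self.frailty_variance,
            "censoring_rate": self.censoring_rate,
            "censoring_log_hr": self.censoring_log_hr,
            "start_state": self.start_state,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(plain(d), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            space=StateSpace.from_dict(d["statespace"]),
            n_subjects=int(d["n_subjects"]),
            age_min=float(d["age_min"]),
            age_max=float(d["age_max"]),
            baseline={
                k: PiecewiseRate(tuple(v["breaks"]), tuple(v["rates"]))
                for k, v in d.get("baseline", {}).items()
            },
            log_hr=d.get("log_hr", {}),
            covariate_prevalence=d.get("covariate_prevalence", {}),
            covariate_dependence=d.get("covariate_dependence", {}),
            dynamic_rules=[
                DynamicRule(r["covariate"], r["trigger_state"],
                            r["dwell_years"])
                for r in d.get("dynamic_rules", [])
            ],
            frailty_variance=float(d.get("frailty_variance", 0.0)),
            censoring_rate=float(d.get("censoring_rate", 0.0)),
            censoring_log_hr=d.get("censoring_log_hr", {}),
            start_state=d.get("start_state", "W"),
            seed=int(d.get("seed", 0)),
        )


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------

def _transition_rate(config, tr_name, age, profile, frail):
    base = config.baseline.get(tr_name)
    if base is None:
        return 0.0
    lhr = config.log_hr.get(tr_name, {})
    lp = sum(b * profile.get(c, 0.0) for c, b in lhr.items())
    return base.at(age) * np.exp(lp) * frail


def _breakpoints(config, lo, hi, extra=()):
    pts = {lo, hi, *extra}
    for pr in config.baseline.values():
        pts.update(b for b in pr.breaks if lo < b < hi)
    return sorted(pts)


def _draw_sojourn(rng, config, state, age, profile, frail, horizon, flip_age):
    """Exact inversion sampling of the next event within [age, horizon].

    Returns (event_age or None, kind, destination) where kind is "event",
    "censor" or "flip"; None means nothing happened before `horizon`.
    Rates are constant between breakpoints; `flip_age` (if inside) is an
    extra breakpoint where the caller flips a dynamic covariate.
    """
    out = [tr for tr in config.space.transitions if state in tr.origins]
    target = rng.exponential()
    cens_target = (
        rng.exponential() if config.censoring_rate > 0 else np.inf
    )
    cens_lp = sum(
        b * profile.get(c, 0.0) for c, b in config.censoring_log_hr.items()
    )
    cens_rate = config.censoring_rate * np.exp(cens_lp)

    extra = (flip_age,) if flip_age is not None and age < flip_age < horizon \
        else ()
    pts = _breakpoints(config, age, horizon, extra)
    acc = 0.0
    acc_c = 0.0
    for lo, hi in zip(pts, pts[1:]):
        mid = 0.5 * (lo + hi)
        lam = sum(
            _transition_rate(config, tr.name, mid, profile, frail)
            for tr in out
        )
        piece = lam * (hi - lo)
        piece_c = cens_rate * (hi - lo)
        t_event = np.inf
        t_cens = np.inf
        if acc + piece >= target and lam > 0:
            t_event = lo + (target - acc) / lam
        if acc_c + piece_c >= cens_target and cens_rate > 0:
            t_cens = lo + (cens_target - acc_c) / cens_rate
        if min(t_event, t_cens) < np.inf:
            if t_cens < t_event:
                return t_cens, "censor", None
            rates = np.array(
                [_transition_rate(config, tr.name, t_event, profile, frail)
                 for tr in out]
            )
            dest = out[rng.choice(len(out), p=rates / rates.sum())].to_state
            return t_event, "event", dest
        acc += piece
        acc_c += piece_c
        if flip_age is not None and np.isclose(hi, flip_age):
            return hi, "flip", None
    return None, "none", None


def _draw_covariates(rng, config):
    prof = {}
    for c, p in config.covariate_prevalence.items():
        prof[c] = float(rng.random() < p)
    for c, spec in config.covariate_dependence.items():
        lp = spec.get("intercept", 0.0) + sum(
            b * prof.get(other, 0.0)
            for other, b in spec.items() if other != "intercept"
        )
        prof[c] = float(rng.random() < 1.0 / (1.0 + np.exp(-lp)))
    return prof


def simulate_cohort(config: SimulationConfig,
                    seed: int | None = None) -> pd.DataFrame:
    """Generate a validated long-format cohort from the configuration.

    Every subject starts in ``config.start_state`` at ``age_min``, moves
    through competing-risk sojourns until absorption, loss to follow-up, or
    administrative censoring at ``age_max``; dynamic covariate flips split
    episodes at the flip age.  Deterministic given the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    space = config.space
    cov_names = sorted(
        set(config.covariate_prevalence)
        | set(config.covariate_dependence)
        | {r.covariate for r in config.dynamic_rules}
    )
    rows = []
    for i in range(config.n_subjects):
        sid = f"s{i:06d}"
        profile = _draw_covariates(rng, config)
        for rule in config.dynamic_rules:
            profile.setdefault(rule.covariate, 0.0)
        frail = (
            rng.gamma(1.0 / config.frailty_variance,
                      config.frailty_variance)
            if config.frailty_variance > 0 else 1.0
        )
        age = config.age_min
        state = config.start_state
        state_entered_at = age
        while age < config.age_max - 1e-12:
            flip_age = None
            flip_cov = None
            for rule in config.dynamic_rules:
                if rule.trigger_state == state and not profile.get(
                        rule.covariate, 0.0):
                    cand = state_entered_at + rule.dwell_years
                    if cand > age and (flip_age is None or cand < flip_age):
                        flip_age, flip_cov = cand, rule.covariate
            t, kind, dest = _draw_sojourn(
                rng, config, state, age, profile, frail, config.age_max,
                flip_age,
            )
            if kind == "flip":
                rows.append(
                    {"subject_id": sid, "entry_age": age, "exit_age": t,
                     "from_state": state, "to_state": state, **profile}
                )
                profile = dict(profile)
                profile[flip_cov] = 1.0
                age = t
                continue
            if kind == "none":
                rows.append(
                    {"subject_id": sid, "entry_age": age,
                     "exit_age": config.age_max, "from_state": state,
                     "to_state": CENSORED, **profile}
                )
                break
            if kind == "censor":
                rows.append(
                    {"subject_id": sid, "entry_age": age, "exit_age": t,
                     "from_state": state, "to_state": CENSORED, **profile}
                )
                break
            rows.append(
                {"subject_id": sid, "entry_age": age, "exit_age": t,
                 "from_state": state, "to_state": dest, **profile}
            )
            age = t
            state = dest
            state_entered_at = t
            if space.is_absorbing(state):
                break

    cols = ["subject_id", "entry_age", "exit_age", "from_state", "to_state"]
    df = pd.DataFrame(rows, columns=cols + cov_names)
    df["weight"] = 1.0
    return df


# ---------------------------------------------------------------------------
# self-transition splitting note: a "flip" row has to_state == from_state,
# which the validator treats as an ordinary chained event.  The estimators
# never see it as a transition because no Transition maps a state to itself.
# ---------------------------------------------------------------------------


def _generator(config: SimulationConfig, profile, age: float) -> np.ndarray:
    """Profile-adjusted generator matrix at one age (frailty excluded)."""
    states = config.space.state_order
    m = len(states)
    G = np.zeros((m, m))
    for tr in config.space.transitions:
        lam = _transition_rate(config, tr.name, age, profile, 1.0)
        j = states.index(tr.to_state)
        for o in tr.origins:
            G[states.index(o), j] += lam
    for i, s in enumerate(states):
        if config.space.is_absorbing(s):
            G[i, :] = 0.0
    np.fill_diagonal(G, np.diag(G) - G.sum(axis=1))
    return G


def true_occupation(
    config: SimulationConfig, profile: dict[str, float], s: float, t: float
) -> np.ndarray:
    """Exact Markov occupation-probability matrix P(s, t) for a fixed profile.

    Product of matrix exponentials of the profile-adjusted generator over its
    constant pieces.  Only valid without frailty (the frailty-mixed process
    is not Markov marginally).
    """
    if config.frailty_variance > 0:
        raise ValueError("exact oracle requires frailty_variance == 0")
    if t < s:
        raise ValueError("need s <= t")
    m = len(config.space.state_order)
    P = np.eye(m)
    if t == s:
        return P
    for lo, hi in zip(*(lambda p: (p, p[1:]))(_breakpoints(config, s, t))):
        G = _generator(config, profile, 0.5 * (lo + hi))
        P = P @ expm(G * (hi - lo))
    return P


def true_wle(
    config: SimulationConfig, profile: dict[str, float], s: float,
    t_p: float | None = None,
) -> dict[str, float]:
    """Exact expected state durations ``E(h)`` from ``s`` to pension age.

    Uses the augmented-matrix identity ``expm([[G, I], [0, 0]] * dt)`` whose
    upper-right block is ``int_0^dt expm(G u) du``, accumulated across the
    constant pieces — exact regardless of singular generators.
    """
    if config.frailty_variance > 0:
        raise ValueError("exact oracle requires frailty_variance == 0")
    space = config.space
    if t_p is None:
        t_p = space.pension_age
    states = space.state_order
    m = len(states)
    start = states.index(config.start_state)
    P = np.eye(m)
    E = np.zeros(m)
    if t_p > s:
        for lo, hi in zip(*(lambda p: (p, p[1:]))(_breakpoints(config, s, t_p))):
            G = _generator(config, profile, 0.5 * (lo + hi))
            M = np.zeros((2 * m, 2 * m))
            M[:m, :m] = G
            M[:m, m:] = np.eye(m)
            ex = expm(M * (hi - lo))
            E = E + P[start] @ ex[:m, m:]
            P = P @ ex[:m, :m]
    return {st: float(E[i]) for i, st in enumerate(states)}


# ---------------------------------------------------------------------------
# shipped illustrative scenario
# ---------------------------------------------------------------------------

def default_scenario(
    erp_member: bool = True,
    n_subjects: int = 5212,
    seed: int = 0,
    poor_prevalence: float = 0.10,
    censoring_rate: float = 0.0,
) -> SimulationConfig:
    """Illustrative four-group labor-market scenario (synthetic).

    Rates are loosely shaped so the group orderings of real register cohorts
    emerge — ERP members with poor self-rated health have the lowest expected
    work duration, non-members with good health the highest — without being
    calibrated to any real data set.  Members can retire through E from age
    60; poor health (``srh_poor``) raises entry into sickness absence,
    unemployment, disability and early retirement and slows return to work.
    """
    space = danish_labor_market(erp=erp_member)
    baseline = {
        "W->S": PiecewiseRate.constant(0.18),
        "W->U": PiecewiseRate.constant(0.15),
        "S->W": PiecewiseRate.constant(2.4),
        "S->U": PiecewiseRate.constant(0.12),
        "U->W": PiecewiseRate.constant(0.85),
        "U->S": PiecewiseRate.constant(0.10),
        "W+S+U->D": PiecewiseRate.constant(0.006),
    }
    log_hr = {
        "W->S": {"srh_poor": np.log(2.2)},
        "W->U": {"srh_poor": np.log(1.45)},
        "S->W": {"srh_poor": np.log(0.75)},
        "S->U": {"srh_poor": np.log(0.60)},
        "U->W": {"srh_poor": np.log(0.80)},
        "U->S": {"srh_poor": np.log(0.90)},
        "W+S+U->D": {"srh_poor": np.log(6.0)},
    }
    if erp_member:
        baseline["W+S+U->E"] = PiecewiseRate((55.0, 60.0), (0.0, 0.22))
        log_hr["W+S+U->E"] = {"srh_poor": np.log(1.65)}
    return SimulationConfig(
        space=space,
        n_subjects=n_subjects,
        baseline=baseline,
        log_hr=log_hr,
        covariate_prevalence={"srh_poor": poor_prevalence},
        censoring_rate=censoring_rate,
        seed=seed,
    )
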