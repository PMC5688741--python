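"""Estimator classes fronting the two worklife-expectancy pipelines.

Both estimators follow scikit-learn conventions: hyper-parameters are set in
``__init__`` and introspectable through ``get_params`` / ``set_params``,
``fit`` consumes a long-format event-history DataFrame and stores fitted
state in trailing-underscore attributes, and downstream quantities
(occupation probabilities, expectancies) are methods of the fitted object.

:class:`MultiStateLifeTable`
    the nonparametric multi-state life table: occurrence/exposure intensities
    ``d/n`` at the observed event ages, Aalen-Johansen occupation
    probabilities, step-integral expectancies.  Strata are handled by
    fitting one estimator per stratum subset.

:class:`CoxMultiStateLifeTable`
    the Cox-adjusted life table: transition-specific proportional-hazards
    fits supply Breslow baseline increments that are multiplicatively
    adjusted to any covariate profile before the same product-integral and
    integration machinery runs.  ``predict`` maps a DataFrame of covariate
    profiles to total worklife expectancy in years, so the fitted object
    composes with sklearn model-selection tooling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import wle as _wle
from .cox import CoxFit, fit_multistate_cox
from .events import build_risk_sets, validate_episodes
from .intensity import cox_intensities, nonparametric_intensities
from .occupation import OccupationCurve, product_integral
from .states import StateSpace, danish_labor_market
from .wle import WLEEstimate, curve_with_ci, expected_durations, wle_bounds


class _LifeTableBase(BaseEstimator):
    def _space(self) -> StateSpace:
        return self.space if self.space is not None else danish_labor_market()

    def _validate_input(self, X) -> pd.DataFrame:
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a long-format event-history DataFrame")
        return validate_episodes(X, self._space())

    def _check_fitted(self):
        if not hasattr(self, "intensities_") and not hasattr(self, "cox_fit_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    # shared downstream machinery ------------------------------------------
    def occupation(self, s: float, t: float | None = None,
                   ci: bool = False, **kw) -> OccupationCurve:
        """Aalen-Johansen occupation-probability curve from age ``s``."""
        self._check_fitted()
        space = self.space_
        t = space.pension_age if t is None else t
        series = self._series(**kw)
        if ci:
            return curve_with_ci(series, self.riskset_, s, t, self.ci_level)
        return product_integral(series, s, t)

    def worklife_expectancy(self, s: float, start_state: str = "W",
                            ci: bool = True, **kw) -> WLEEstimate:
        """Expected years per state (and total WLE) from age ``s``."""
        curve = self.occupation(s, ci=ci, **kw)
        if ci:
            return wle_bounds(curve, self.space_, start_state)
        return expected_durations(curve, self.space_, start_state)

    def wle_by_starting_age(self, ages, start_state: str = "W",
                            ci: bool = False, **kw) -> list[WLEEstimate]:
        self._check_fitted()
        return _wle.wle_by_starting_age(
            self._series(**kw), self.space_, ages, start_state,
            riskset=self.riskset_ if ci else None, level=self.ci_level,
        )


class MultiStateLifeTable(_LifeTableBase):
    """Nonparametric multi-state life table (MSLT) estimator.

    Parameters
    ----------
    space : StateSpace, optional
        Defaults to the five-primary-state labor-market model.
    combined_mode : {"equal", "crude_frequency"}
        Redistribution of pooled-transition intensities over origin rows.
    ci_level : float
        Level of the pointwise Wald limits (Greenwood-type variance).

    Attributes
    ----------
    episodes_ : DataFrame
        Validated long-format input.
    riskset_ : RiskSetTable
    intensities_ : IntensityMatrixSeries
    n_subjects_ : int
    """

    def __init__(self, space: StateSpace | None = None,
                 combined_mode: str = "equal", ci_level: float = 0.95):
        self.space = space
        self.combined_mode = combined_mode
        self.ci_level = ci_level

    def fit(self, X: pd.DataFrame, y=None) -> "MultiStateLifeTable":
        df = self._validate_input(X)
        self.space_ = self._space()
        self.episodes_ = df
        self.riskset_ = build_risk_sets(df, self.space_)
        self.intensities_ = nonparametric_intensities(
            self.riskset_, self.space_, combined_mode=self.combined_mode,
            episodes=df,
        )
        self.n_subjects_ = df["subject_id"].nunique()
        return self

    def _series(self, **kw):
        return self.intensities_


class CoxMultiStateLifeTable(_LifeTableBase):
    """Cox-regression-adjusted multi-state life table (Cox-MSLT) estimator.

    Parameters
    ----------
    covariates : list of str
        Covariate columns; effects are transition-specific.
    space : StateSpace, optional
    combined_mode : {"equal", "crude_frequency"}
    frailty : bool
        Shared per-subject gamma frailty (variance by profile likelihood).
    frailty_theta : float, optional
        Fix the frailty variance instead of estimating it.
    weight_col : str, optional
        Column of per-record weights (e.g. stabilized IPW weights).
    ci_level : float

    Attributes
    ----------
    cox_fit_ : CoxFit
        Per-transition coefficients and Breslow baselines.
    riskset_ : RiskSetTable
    """

    def __init__(self, covariates=None, space: StateSpace | None = None,
                 combined_mode: str = "equal", frailty: bool = False,
                 frailty_theta: float | None = None,
                 weight_col: str | None = None, ci_level: float = 0.95):
        self.covariates = covariates
        self.space = space
        self.combined_mode = combined_mode
        self.frailty = frailty
        self.frailty_theta = frailty_theta
        self.weight_col = weight_col
        self.ci_level = ci_level

    def fit(self, X: pd.DataFrame, y=None) -> "CoxMultiStateLifeTable":
        df = self._validate_input(X)
        self.space_ = self._space()
        if self.weight_col is not None:
            df = df.assign(weight=df[self.weight_col].astype(float))
        self.episodes_ = df
        self.cox_fit_: CoxFit = fit_multistate_cox(
            df, self.space_, covariate_names=list(self.covariates or []),
            frailty=self.frailty, frailty_theta=self.frailty_theta,
        )
        self.riskset_ = self.cox_fit_.riskset
        self.n_subjects_ = df["subject_id"].nunique()
        return self

    def _series(self, profile: dict[str, float] | None = None):
        profile = profile or {c: 0.0 for c in (self.covariates or [])}
        return cox_intensities(
            self.cox_fit_, profile, combined_mode=self.combined_mode,
            episodes=self.episodes_,
        )

    def hazard_ratios(self) -> pd.DataFrame:
        """Per-transition HR table (covariate, HR, 95% CL, p)."""
        self._check_fitted()
        return self.cox_fit_.summary()

    def predict(self, X: pd.DataFrame, s: float | None = None,
                start_state: str = "W") -> np.ndarray:
        """Total WLE (years) for each covariate profile row of ``X``."""
        self._check_fitted()
        s = self.space_.pension_age - 10.0 if s is None else s
        out = []
        for _, row in X.iterrows():
            est = self.worklife_expectancy(
                s, start_state=start_state, ci=False,
                profile=row.to_dict(),
            )
            out.append(est.total_wle)
        return np.asarray(out)

    def expectancy_report(self, profiles: dict[str, dict[str, float]],
                          s: float, start_state: str = "W",
                          months: bool = False) -> pd.DataFrame:
        """Per-profile expectancy table with bounds (approximate areas)."""
        ests = {
            name: self.worklife_expectancy(
                s, start_state=start_state, ci=True, profile=prof
            )
            for name, prof in profiles.items()
        }
        return _wle.expectancy_report(ests, self.space_, months=months)
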