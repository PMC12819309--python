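"""Frequency-angle regression and interval-wise linear mixed-effects models.

The amplitude decrement of repetitive toe tapping is modelled on
per-(trial, interval) medians across four consecutive 5-s intervals as

    angle ~ 1 + time,    random: (1 + time + dominance | participant)

fitted by REML, with time the interval index (1..4, continuous) and
dominance coded 0/1 (non-dominant reference); an analogous model is fitted
for frequency. Estimation rides on statsmodels' MixedLM; when the full
random-effects structure does not converge or is singular, a documented
simplification ladder is walked (drop random-effect correlations, then the
dominance random slope, then the time random slope) and the rung used is
reported. Diagnostics cover homogeneity of residual variance across leg
dominance (Brown-Forsythe/Levene), multicollinearity (VIF) and exported
residual/fitted/Q-Q values.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLMParams

from .cohort_stats import classify_r2


class DegenerateFitError(ValueError):
    """Raised when a model cannot be estimated from the given data."""


@dataclasses.dataclass
class OlsFit:
    """Ordinary least-squares fit of angle on frequency."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float           # two-sided, slope
    n_samples: int
    r2_class: str
    slope_se: float
    intercept_se: float

    def summary(self) -> str:
        return (
            f"OLS angle ~ frequency (n={self.n_samples})\n"
            f"  intercept {self.intercept:8.3f} (SE {self.intercept_se:.3f})\n"
            f"  slope     {self.slope:8.3f} (SE {self.slope_se:.3f}), "
            f"p={self.p_value:.3g}\n"
            f"  R^2 = {self.r_squared:.3f} ({self.r2_class})"
        )


def ols_frequency_angle(
    samples: pd.DataFrame,
    x: str = "frequency",
    y: str = "angle",
) -> OlsFit:
    """OLS regression of per-cycle angle on per-cycle frequency.

    Requires >= 3 samples and a non-constant predictor; returns slope,
    intercept, R^2 (with its strength class) and the two-sided slope p.
    """
    df = samples[[x, y]].dropna()
    if len(df) < 3:
        raise DegenerateFitError(f"need >= 3 samples, got {len(df)}")
    xv = df[x].to_numpy(dtype=float)
    if np.ptp(xv) == 0:
        raise DegenerateFitError("constant predictor: regression is degenerate")
    res = sm.OLS(df[y].to_numpy(dtype=float), sm.add_constant(xv)).fit()
    r2 = float(res.rsquared)
    return OlsFit(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        r_squared=r2, p_value=float(res.pvalues[1]), n_samples=len(df),
        r2_class=classify_r2(min(max(r2, 0.0), 1.0)),
        slope_se=float(res.bse[1]), intercept_se=float(res.bse[0]),
    )


#: random-effects simplification ladder: (rung name, re_formula, diagonal?)
_LADDER = (
    ("full", "~time + dominance", False),
    ("uncorrelated", "~time + dominance", True),
    ("no_dominance_slope", "~time", False),
    ("intercept_only", "~1", False),
)

_SINGULAR_REL_TOL = 1e-6


@dataclasses.dataclass
class IntervalMixedModelResults:
    """REML fit of an interval-wise mixed model.

    ``fixed_effects`` maps term -> (estimate, standard error);
    ``random_effect_covariance`` is the participant-level covariance of the
    terms in ``random_effect_names`` (units of the response).
    """

    response: str
    fixed_effects: dict[str, tuple[float, float]]
    random_effect_names: tuple[str, ...]
    random_effect_covariance: np.ndarray
    residual_sd: float
    converged: bool
    singular: bool
    rung: str
    n_obs: int
    n_groups: int
    fitted_values: np.ndarray
    residuals: np.ndarray
    data: pd.DataFrame = dataclasses.field(repr=False, default=None)

    @property
    def intercept(self) -> float:
        return self.fixed_effects["Intercept"][0]

    @property
    def time_slope(self) -> float:
        return self.fixed_effects["time"][0]

    def summary(self) -> str:
        lines = [
            f"Linear mixed model (REML): {self.response} ~ time, "
            f"random ({' + '.join(self.random_effect_names)} | participant)",
            f"  rung: {self.rung}   converged: {self.converged}   "
            f"singular: {self.singular}",
            f"  n_obs = {self.n_obs}, n_participants = {self.n_groups}",
            "  fixed effects:",
        ]
        for name, (est, se) in self.fixed_effects.items():
            lines.append(f"    {name:<12} {est:10.4f}  (SE {se:.4f})")
        lines.append(f"  residual SD: {self.residual_sd:.4f}")
        with np.printoptions(precision=4, suppress=True):
            lines.append(f"  random-effect covariance:\n{self.random_effect_covariance}")
        return "\n".join(lines)


class IntervalMixedModel:
    """Mixed-effects model of a per-interval response with participant-level
    random intercept and slopes.

    ``data`` needs columns ``participant_id``, ``interval`` (1..4),
    ``dominant`` (bool) and the response column (``angle`` or
    ``frequency``); rows with a missing response are dropped.
    """

    def __init__(self, data: pd.DataFrame, response: str = "angle",
                 include_dominance_fixed: bool = False) -> None:
        df = data.copy()
        # the interval decrement models are defined on the toe-tapping task
        if "task" in df.columns and df["task"].nunique() > 1:
            df = df[df["task"] == "TT"]
        df["time"] = df["interval"].astype(float)
        df["dominance"] = df["dominant"].astype(int)
        df["participant"] = df["participant_id"].astype(str)
        df = df.dropna(subset=[response])
        if df["participant"].nunique() < 2:
            raise DegenerateFitError("need >= 2 participants")
        per_group_intervals = df.groupby("participant")["time"].nunique()
        if (per_group_intervals < 2).any():
            raise DegenerateFitError("every participant needs >= 2 intervals")
        self.response = response
        self.include_dominance_fixed = include_dominance_fixed
        self.data = df

    @classmethod
    def from_interval_medians(cls, interval_medians: pd.DataFrame,
                              response: str = "angle", **kw
                              ) -> "IntervalMixedModel":
        return cls(interval_medians, response=response, **kw)

    def _fit_once(self, re_formula: str, diagonal: bool):
        fixed = f"{self.response} ~ time"
        if self.include_dominance_fixed:
            fixed += " + dominance"
        model = smf.mixedlm(fixed, self.data, groups=self.data["participant"],
                            re_formula=re_formula)
        fit_kw = {"reml": True}
        if diagonal:
            k_re = model.k_re
            free = MixedLMParams.from_components(
                fe_params=np.ones(model.k_fe), cov_re=np.eye(k_re))
            fit_kw["free"] = free
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return model.fit(**fit_kw)

    def fit(self) -> IntervalMixedModelResults:
        """Walk the simplification ladder until a usable REML fit emerges."""
        last_exc: Exception | None = None
        for rung, re_formula, diagonal in _LADDER:
            try:
                res = self._fit_once(re_formula, diagonal)
            except Exception as exc:  # pragma: no cover - optimizer failures
                last_exc = exc
                continue
            ok = (bool(res.converged)
                  and np.all(np.isfinite(np.asarray(res.fe_params)))
                  and np.all(np.isfinite(np.asarray(res.bse_fe))))
            if not ok:
                continue
            return self._package(res, rung)
        degenerate = self._degenerate_fit()
        if degenerate is not None:
            return degenerate
        raise DegenerateFitError(
            f"mixed model did not converge on any ladder rung ({last_exc!r})"
        )

    def _degenerate_fit(self) -> IntervalMixedModelResults | None:
        """Exactly deterministic data (zero residual variance) breaks the
        REML optimizer; a pooled OLS then recovers the fixed effects with
        all variance components at zero, flagged singular."""
        cols = ["time"] + (["dominance"] if self.include_dominance_fixed else [])
        X = sm.add_constant(self.data[cols].to_numpy(dtype=float))
        y = self.data[self.response].to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        resid = y - res.fittedvalues
        scale = max(float(np.abs(y).max()), 1.0)
        if np.abs(resid).max() > 1e-8 * scale:
            return None
        names = ["Intercept"] + cols
        fe = {name: (float(b), 0.0) for name, b in zip(names, res.params)}
        k_re = 3
        return IntervalMixedModelResults(
            response=self.response, fixed_effects=fe,
            random_effect_names=("Intercept", "time", "dominance"),
            random_effect_covariance=np.zeros((k_re, k_re)),
            residual_sd=0.0, converged=True, singular=True,
            rung="degenerate", n_obs=int(len(y)),
            n_groups=int(self.data["participant"].nunique()),
            fitted_values=np.asarray(res.fittedvalues, dtype=float),
            residuals=resid, data=self.data,
        )

    def _package(self, res, rung: str) -> IntervalMixedModelResults:
        cov = np.atleast_2d(np.asarray(res.cov_re, dtype=float))
        eig = np.linalg.eigvalsh(cov)
        singular = bool(eig.min() < _SINGULAR_REL_TOL * max(eig.max(), 1e-12))
        fe = {}
        for name, est, se in zip(res.model.exog_names, res.fe_params, res.bse_fe):
            fe[name] = (float(est), float(se))
        re_names = tuple(res.model.data.exog_re_names or ("Intercept",))
        fitted = np.asarray(res.fittedvalues, dtype=float)
        resid = np.asarray(res.resid, dtype=float)
        return IntervalMixedModelResults(
            response=self.response, fixed_effects=fe,
            random_effect_names=re_names, random_effect_covariance=cov,
            residual_sd=float(np.sqrt(res.scale)),
            converged=bool(res.converged), singular=singular, rung=rung,
            n_obs=int(res.model.nobs), n_groups=len(res.model.group_labels),
            fitted_values=fitted, residuals=resid, data=self.data,
        )


def fit_lmm(data: pd.DataFrame, response: str = "angle",
            include_dominance_fixed: bool = False) -> IntervalMixedModelResults:
    """Convenience wrapper: build and fit an :class:`IntervalMixedModel`."""
    return IntervalMixedModel(
        data, response=response,
        include_dominance_fixed=include_dominance_fixed,
    ).fit()


def levene_test(values, groups, center: str = "median") -> tuple[float, float]:
    """Homogeneity-of-variance test across groups.

    Default ``center="median"`` is the Brown-Forsythe variant
    (median-centred absolute deviations, one-way ANOVA F);
    ``center="mean"`` gives classical Levene. Degenerate input (all group
    values identical) returns (nan, nan).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    arrays = [values[groups == g] for g in np.unique(groups)]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.ptp(a) == 0 for a in arrays):
        return float("nan"), float("nan")
    stat, p = stats.levene(*arrays, center=center)
    return float(stat), float(p)


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per fixed-effect column.

    VIF_j = 1 / (1 - R^2_j) where R^2_j comes from regressing column j on
    the remaining columns (plus an intercept); perfectly collinear columns
    report inf.
    """
    if design.shape[1] < 2:
        raise ValueError("need >= 2 fixed-effect columns")
    out = {}
    X = design.to_numpy(dtype=float)
    for j, name in enumerate(design.columns):
        others = np.delete(X, j, axis=1)
        res = sm.OLS(X[:, j], sm.add_constant(others)).fit()
        r2 = float(res.rsquared)
        out[name] = float("inf") if r2 > 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclasses.dataclass
class DiagnosticsReport:
    """Exported model diagnostics (values only; plotting is the caller's)."""

    levene_statistic: float
    levene_p: float
    vif: pd.Series
    residuals: np.ndarray
    fitted_values: np.ndarray
    qq_theoretical: np.ndarray
    qq_sample: np.ndarray

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            "residuals": pd.DataFrame({
                "fitted": self.fitted_values, "residual": self.residuals,
            }),
            "qq": pd.DataFrame({
                "theoretical_quantile": self.qq_theoretical,
                "sample_quantile": self.qq_sample,
            }),
            "tests": pd.DataFrame({
                "levene_statistic": [self.levene_statistic],
                "levene_p": [self.levene_p],
                **{f"vif_{k}": [v] for k, v in self.vif.items()},
            }),
        }


def export_diagnostics(
    fit: IntervalMixedModelResults,
    out_dir: str | Path | None = None,
) -> DiagnosticsReport:
    """Diagnostics for a converged interval model.

    Levene (Brown-Forsythe) compares residual spread across leg dominance;
    VIF covers the time and dominance fixed-effect columns; residuals,
    fitted values and normal Q-Q quantile pairs are exported (optionally as
    CSVs under ``out_dir``).
    """
    if not fit.converged:
        raise ValueError("diagnostics require a converged fit")
    data = fit.data
    lev_stat, lev_p = levene_test(fit.residuals, data["dominance"].to_numpy())
    v = vif(data[["time", "dominance"]])
    resid = fit.residuals
    n = resid.size
    order = np.argsort(resid)
    qq_sample = resid[order]
    qq_theoretical = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    report = DiagnosticsReport(
        levene_statistic=lev_stat, levene_p=lev_p, vif=v,
        residuals=resid, fitted_values=fit.fitted_values,
        qq_theoretical=qq_theoretical, qq_sample=qq_sample,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in report.to_frames().items():
            frame.to_csv(out / f"diagnostics_{fit.response}_{name}.csv",
                         index=False, lineterminator="\n")
    return report
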