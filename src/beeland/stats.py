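"""Condition comparison by linear mixed models with back-transformed means.

For each per-landing metric, the model is::

    f(value) ~ light_condition + (1 | day)

with ``f`` an automatically selected transform (identity, log, or double
log, the first whose model residuals pass a Shapiro-Wilk normality check at
alpha = 0.05), fitted by REML. The condition effect is tested with an
F-statistic (squared Wald t) on 1 numerator and ``n - n_days - 1``
denominator degrees of freedom — the within-group convention of
nlme-style conditional F-tests. Condition means and their Wald 95%
confidence intervals are back-transformed to natural units by applying the
inverse transform to the point estimates and interval endpoints (no
smearing correction).

The stage follows the statsmodels idiom: :class:`ConditionLMM` is built
from a long-format metric table and ``fit()`` returns a
:class:`ConditionLMMResults` carrying estimates, intervals, the F-test and
a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

TRANSFORMS = ("none", "log", "loglog")

_FORWARD = {
    "none": lambda y: y,
    "log": np.log,
    "loglog": lambda y: np.log(np.log(y)),
}
_INVERSE = {
    "none": lambda y: y,
    "log": np.exp,
    "loglog": lambda y: np.exp(np.exp(y)),
}


class DegenerateResponseError(ValueError):
    """The response carries (almost) no variance."""


def _applicable(values: np.ndarray, transform: str) -> bool:
    if transform == "none":
        return True
    if transform == "log":
        return bool(np.all(values > 0))
    return bool(np.all(values > 1))


def _lmm_residuals(y: np.ndarray, condition: np.ndarray, day: np.ndarray) -> np.ndarray:
    exog = sm.add_constant((condition == condition[0]).astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(y, exog, groups=day).fit(reml=True)
            return np.asarray(res.resid)
        except Exception:
            return y - exog @ np.linalg.lstsq(exog, y, rcond=None)[0]


def select_transform(
    values: np.ndarray,
    condition: np.ndarray | None = None,
    day: np.ndarray | None = None,
    alpha: float = 0.05,
) -> str:
    """Pick the first of (none, log, loglog) whose model residuals look normal.

    Residual normality is checked by Shapiro-Wilk at ``alpha`` on the mixed
    model's residuals (or plain demeaned residuals when no design labels are
    given). If no applicable transform passes, the applicable one with the
    largest Shapiro-Wilk p-value is returned.
    """
    y = np.asarray(values, dtype=float)
    if y.size < 8:
        raise ValueError("too few values to select a transform")
    if np.std(y) < 1e-12 * max(1.0, np.abs(np.mean(y))):
        raise DegenerateResponseError("response variance is (near) zero")
    pvals = {}
    for tf in TRANSFORMS:
        if not _applicable(y, tf):
            continue
        ty = _FORWARD[tf](y)
        if not np.all(np.isfinite(ty)) or np.std(ty) < 1e-12:
            continue
        if condition is not None and day is not None:
            resid = _lmm_residuals(ty, np.asarray(condition), np.asarray(day))
        else:
            resid = ty - ty.mean()
        p = float(sps.shapiro(resid).pvalue)
        if p >= alpha:
            return tf
        pvals[tf] = p
    if not pvals:
        raise DegenerateResponseError("no applicable transform")
    return max(pvals, key=pvals.get)


@dataclass(frozen=True)
class ConditionLMMResults:
    """Fitted condition comparison for one metric in one phase."""

    metric: str
    phase: str
    transform: str
    mean_w: float
    mean_rb: float
    ci95_w: tuple[float, float]
    ci95_rb: tuple[float, float]
    F: float
    df_num: int
    df_den: int
    p: float
    n_w: int
    n_rb: int
    effect_transformed: float
    se_transformed: float
    random_intercept: bool = True
    warning: str | None = None

    @property
    def effect_ci95(self) -> tuple[float, float]:
        """95% CI of the condition effect on the transformed scale."""
        tcrit = sps.t.ppf(0.975, self.df_den)
        return (
            self.effect_transformed - tcrit * self.se_transformed,
            self.effect_transformed + tcrit * self.se_transformed,
        )

    @property
    def multiplier_ci95(self) -> tuple[float, float]:
        """95% CI of the red-blue/white ratio (log transform only)."""
        if self.transform != "log":
            raise ValueError("multiplier CI defined for the log transform only")
        lo, hi = self.effect_ci95
        return float(np.exp(lo)), float(np.exp(hi))

    def summary(self) -> pd.DataFrame:
        """One-row results table in the layout of the study's results table."""
        return pd.DataFrame(
            [
                {
                    "metric": self.metric,
                    "phase": self.phase,
                    "transform": self.transform,
                    "mean_w": self.mean_w,
                    "ci95_w_lo": self.ci95_w[0],
                    "ci95_w_hi": self.ci95_w[1],
                    "mean_rb": self.mean_rb,
                    "ci95_rb_lo": self.ci95_rb[0],
                    "ci95_rb_hi": self.ci95_rb[1],
                    "F": self.F,
                    "df_num": self.df_num,
                    "df_den": self.df_den,
                    "p": self.p,
                    "n_w": self.n_w,
                    "n_rb": self.n_rb,
                }
            ]
        )


class ConditionLMM:
    """Linear mixed model of one metric: condition fixed, day random intercept.

    Build with :meth:`from_dataframe` on the long-format metric table
    (columns landing_id, condition, day, phase, metric, value) or directly
    from arrays, then call :meth:`fit`.
    """

    def __init__(
        self,
        values: np.ndarray,
        condition: np.ndarray,
        day: np.ndarray,
        metric: str = "",
        phase: str = "",
    ):
        self.values = np.asarray(values, dtype=float)
        self.condition = np.asarray(condition)
        self.day = np.asarray(day)
        self.metric = metric
        self.phase = phase
        if not (len(self.values) == len(self.condition) == len(self.day)):
            raise ValueError("values, condition and day must share length")
        levels = set(np.unique(self.condition))
        if levels != {"white", "red_blue"}:
            raise ValueError(
                f"need both conditions 'white' and 'red_blue', got {sorted(levels)}"
            )

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, metric: str, phase: str) -> "ConditionLMM":
        sub = table[(table["metric"] == metric) & (table["phase"] == phase)]
        if sub.empty:
            raise ValueError(f"no rows for metric={metric!r}, phase={phase!r}")
        return cls(
            sub["value"].to_numpy(),
            sub["condition"].to_numpy(),
            sub["day"].to_numpy(),
            metric=metric,
            phase=phase,
        )

    def fit(self, transform: str = "auto", reml: bool = True) -> ConditionLMMResults:
        y_raw = self.values
        warning = None
        if transform == "auto":
            transform = select_transform(y_raw, self.condition, self.day)
        if transform not in TRANSFORMS:
            raise ValueError(f"transform must be 'auto' or one of {TRANSFORMS}")
        if not _applicable(y_raw, transform):
            warning = f"transform {transform!r} inapplicable to non-positive values; using 'none'"
            transform = "none"
        y = _FORWARD[transform](y_raw)

        rb = (self.condition == "red_blue").astype(float)
        exog = sm.add_constant(rb)
        n = len(y)
        n_days = len(np.unique(self.day))

        random_intercept = n_days >= 2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if random_intercept:
                try:
                    res = sm.MixedLM(y, exog, groups=self.day).fit(reml=reml)
                    params = np.asarray(res.fe_params)
                    cov = np.asarray(res.cov_params())[:2, :2]
                except Exception as exc:  # singular fits fall back to OLS
                    warning = f"mixed fit failed ({exc}); refit without random intercept"
                    random_intercept = False
            if not random_intercept:
                if n_days < 2:
                    warning = warning or "single day: refit without random intercept"
                ols = sm.OLS(y, exog).fit()
                params = np.asarray(ols.params)
                cov = np.asarray(ols.cov_params())

        df_den = n - n_days - 1
        if df_den < 1:
            raise ValueError("not enough observations for the denominator df")
        b0, b1 = params
        se1 = float(np.sqrt(cov[1, 1]))
        F = float((b1 / se1) ** 2)
        p = float(sps.f.sf(F, 1, df_den))

        mu_w, mu_rb = b0, b0 + b1
        se_w = float(np.sqrt(max(cov[0, 0], 0.0)))
        # clipped at zero: boundary REML fits can make the quadratic form
        # marginally negative through rounding
        se_rb = float(np.sqrt(max(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1], 0.0)))
        tcrit = float(sps.t.ppf(0.975, df_den))
        inv = _INVERSE[transform]
        return ConditionLMMResults(
            metric=self.metric,
            phase=self.phase,
            transform=transform,
            mean_w=float(inv(mu_w)),
            mean_rb=float(inv(mu_rb)),
            ci95_w=(float(inv(mu_w - tcrit * se_w)), float(inv(mu_w + tcrit * se_w))),
            ci95_rb=(float(inv(mu_rb - tcrit * se_rb)), float(inv(mu_rb + tcrit * se_rb))),
            F=F,
            df_num=1,
            df_den=df_den,
            p=p,
            n_w=int(np.sum(self.condition == "white")),
            n_rb=int(np.sum(self.condition == "red_blue")),
            effect_transformed=float(b1),
            se_transformed=se1,
            random_intercept=random_intercept,
            warning=warning,
        )


def fit_condition_model(
    table: pd.DataFrame, metric: str, phase: str, transform: str = "auto"
) -> ConditionLMMResults:
    """Convenience wrapper: build and fit the model for one metric/phase."""
    return ConditionLMM.from_dataframe(table, metric, phase).fit(transform=transform)


def run_stats(table: pd.DataFrame, transform: str = "auto") -> pd.DataFrame:
    """Fit every metric/phase combination in the table; results-table layout."""
    out = []
    for (metric, phase), _ in table.groupby(["metric", "phase"], sort=False):
        res = fit_condition_model(table, metric, phase, transform=transform)
        out.append(res.summary())
    return pd.concat(out, ignore_index=True)
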