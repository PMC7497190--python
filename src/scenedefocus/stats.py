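"""Cohort statistics: refraction summaries, normalising transform, rank-based
partial correlation, backward-stepwise regression, and univariate group tests.

The modelling surface follows the statsmodels convention: :class:`StepwiseOLS`
is a model object constructed from data whose :meth:`~StepwiseOLS.fit` returns
a :class:`StepwiseOLSResults` carrying coefficient estimates, confidence
intervals, standardized coefficients, collinearity diagnostics and a
``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .exceptions import (CollinearityError, DegenerateInputError,
                         InsufficientGroupError)

BLOM_C = 0.375  # fractional-rank constant (r - c) / (n + 1 - 2c)


def spherical_equivalent(sphere, cylinder):
    """Spherical equivalent refraction M = S + C/2, in dioptres."""
    return np.asarray(sphere, dtype=float) + np.asarray(cylinder, dtype=float) / 2.0


def two_step_transform(values, c: float = BLOM_C) -> np.ndarray:
    """Rank-based inverse-normal transform, rescaled to the input mean and SD.

    Step 1 maps each value's (mean-tie) rank r to the fractional rank
    ``(r - c) / (n + 1 - 2c)`` (Blom constant c = 3/8 by default); step 2
    applies the inverse standard-normal CDF and linearly rescales the scores
    to the sample mean and sample (n-1) SD of the input.  The result is an
    approximately normal, strictly rank-preserving version of the input.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise DegenerateInputError("two_step_transform needs a 1-D sample of n >= 3")
    if np.ptp(x) == 0:
        raise DegenerateInputError("two_step_transform is undefined for a "
                                   "constant sample")
    n = x.size
    r = sps.rankdata(x)
    frac = (r - c) / (n + 1 - 2 * c)
    z = sps.norm.ppf(frac)
    z = (z - z.mean()) / z.std(ddof=1)
    return x.mean() + x.std(ddof=1) * z


@dataclass(frozen=True)
class CorrelationResult:
    """A (partial) Spearman correlation with its significance test."""

    rho: float
    p_value: float
    n: int
    control: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"correlation {self.rho} outside [-1, 1]")


def spearman_partial(x, y, control=None, *,
                     control_label: str | None = None) -> CorrelationResult:
    """Spearman correlation of x and y, optionally partialling out a control.

    All variables are rank-transformed (mean ranks for ties); the first-order
    partial correlation formula is applied on the ranks,

        rho_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2)),

    and the p-value uses the t approximation with n - 3 degrees of freedom
    (n - 2 when no control is given).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DegenerateInputError("x and y must be equal-length 1-D samples")
    n = x.size
    if n < 5:
        raise DegenerateInputError("spearman_partial needs n >= 5")
    rx, ry = sps.rankdata(x), sps.rankdata(y)

    def _pearson(a, b):
        return float(np.corrcoef(a, b)[0, 1])

    if control is None:
        rho = _pearson(rx, ry)
        df = n - 2
    else:
        control = np.asarray(control, dtype=float)
        if control.shape != x.shape:
            raise DegenerateInputError("control must match x and y in length")
        rz = sps.rankdata(control)
        r_xy, r_xz, r_yz = _pearson(rx, ry), _pearson(rx, rz), _pearson(ry, rz)
        if min(1 - r_xz**2, 1 - r_yz**2) <= 1e-12:
            raise DegenerateInputError(
                "control is perfectly rank-correlated with x or y"
            )
        rho = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
        df = n - 3
    rho = float(np.clip(rho, -1.0, 1.0))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1 - rho**2))
        p = float(2 * sps.t.sf(abs(t), df))
    label = control_label if control_label is not None else (
        None if control is None else "control")
    return CorrelationResult(rho=rho, p_value=p, n=n, control=label)


# -- backward stepwise regression ------------------------------------------


class StepwiseOLS:
    """Ordinary least squares with backward elimination of predictors.

    The full model (all predictors plus intercept) is fitted first; the single
    term with the largest p-value at or above ``p_threshold`` is removed and
    the model refitted, repeating until every remaining term is significant
    (or no terms remain).  Exact p-value ties are broken by removing the
    later column.

    Parameters
    ----------
    endog : array-like or Series
        Response variable.
    exog : DataFrame
        Predictors, one column per term (categoricals pre-coded as
        indicators); no constant column — an intercept is added internally.
    p_threshold : float
        Retention threshold on term p-values (default 0.05).
    """

    def __init__(self, endog, exog: pd.DataFrame, p_threshold: float = 0.05):
        self.endog = pd.Series(np.asarray(endog, dtype=float),
                               name=getattr(endog, "name", "y"))
        self.exog = pd.DataFrame(exog).astype(float)
        self.exog.index = self.endog.index
        if not 0 < p_threshold < 1:
            raise ValueError("p_threshold must lie in (0, 1)")
        self.p_threshold = float(p_threshold)
        n, k = self.exog.shape
        if n <= k + 1:
            raise DegenerateInputError(
                f"n = {n} observations cannot support {k} predictors plus an "
                "intercept"
            )
        self._check_rank()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       predictors: list[str],
                       p_threshold: float = 0.05) -> "StepwiseOLS":
        return cls(data[response], data[list(predictors)], p_threshold)

    def _check_rank(self) -> None:
        design = np.column_stack([np.ones(len(self.exog)), self.exog.to_numpy()])
        rank = np.linalg.matrix_rank(design)
        if rank < design.shape[1]:
            # pivoted QR flags the dependent columns
            _, r = np.linalg.qr(design)
            diag = np.abs(np.diag(r))
            bad = diag < diag.max() * 1e-10
            names = ["const"] + list(self.exog.columns)
            offenders = [names[i] for i in np.nonzero(bad)[0]]
            raise CollinearityError(
                "design matrix is singular; dependent terms: "
                + ", ".join(offenders), terms=offenders,
            )

    @staticmethod
    def _ols(y: pd.Series, X: pd.DataFrame):
        if X.shape[1] == 0:
            design = pd.DataFrame({"const": np.ones(len(y))}, index=X.index)
        else:
            design = sm.add_constant(X, has_constant="add")
        return sm.OLS(np.asarray(y), design).fit(), list(design.columns)

    def fit(self) -> "StepwiseOLSResults":
        y, X = self.endog, self.exog.copy()
        trace: list[dict] = []
        step = 0
        while X.shape[1] > 0:
            res, _ = self._ols(y, X)
            pvals = res.pvalues[1:]  # term p-values, constant excluded
            worst_p = pvals.max()
            if worst_p < self.p_threshold:
                break
            # ties broken by removing the later column
            tied = np.nonzero(pvals.to_numpy() == worst_p)[0]
            name = X.columns[tied[-1]]
            step += 1
            trace.append({"term": str(name), "p_at_removal": float(worst_p),
                          "step": step})
            X = X.drop(columns=name)
        final, names = self._ols(y, X)

        terms = list(X.columns)
        if terms:
            zX = (X - X.mean()) / X.std(ddof=1)
            zy = (y - y.mean()) / y.std(ddof=1)
            zres, _ = self._ols(zy, zX)
            std_params = pd.Series(zres.params[1:].to_numpy(), index=terms)
            design = sm.add_constant(X, has_constant="add").to_numpy()
            vif = pd.Series(
                [variance_inflation_factor(design, i + 1)
                 for i in range(len(terms))], index=terms,
            )
        else:
            std_params = pd.Series(dtype=float)
            vif = pd.Series(dtype=float)
        return StepwiseOLSResults(
            model=self, sm_results=final, retained=terms,
            std_params=std_params, vif=vif, removal_trace=trace,
        )


class StepwiseOLSResults:
    """Fit results of :class:`StepwiseOLS`.

    Exposes ``params``, ``bse``, ``pvalues``, ``conf_int()``, ``std_params``,
    ``vif``, ``rsquared_adj``, ``fvalue``, ``f_pvalue``, the removal trace,
    and a ``summary()`` table.  The underlying statsmodels results object for
    the final model is available as ``sm_results``.
    """

    def __init__(self, model, sm_results, retained, std_params, vif,
                 removal_trace):
        self.model = model
        self.sm_results = sm_results
        self.retained = list(retained)
        self.std_params = std_params
        self.vif = vif
        self.removal_trace = removal_trace

    # statsmodels-style accessors -------------------------------------------
    @property
    def params(self) -> pd.Series:
        return self.sm_results.params

    @property
    def bse(self) -> pd.Series:
        return self.sm_results.bse

    @property
    def pvalues(self) -> pd.Series:
        return self.sm_results.pvalues

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.sm_results.conf_int(alpha)

    @property
    def rsquared_adj(self) -> float:
        return float(self.sm_results.rsquared_adj)

    @property
    def fvalue(self) -> float:
        return float(self.sm_results.fvalue) if self.retained else float("nan")

    @property
    def f_pvalue(self) -> float:
        return float(self.sm_results.f_pvalue) if self.retained else float("nan")

    @property
    def df_model(self) -> int:
        return int(self.sm_results.df_model)

    @property
    def df_resid(self) -> int:
        return int(self.sm_results.df_resid)

    @property
    def nobs(self) -> int:
        return int(self.sm_results.nobs)

    def to_dict(self) -> dict:
        ci = self.conf_int()
        out = {
            "retained": {
                t: {
                    "b": float(self.params[t]),
                    "ci95": [float(ci.loc[t, 0]), float(ci.loc[t, 1])],
                    "std_b": float(self.std_params[t]),
                    "p": float(self.pvalues[t]),
                    "vif": float(self.vif[t]),
                }
                for t in self.retained
            },
            "intercept": float(self.params["const"]),
            "adj_r2": self.rsquared_adj,
            "f": self.fvalue,
            "f_p": self.f_pvalue,
            "df": [self.df_model, self.df_resid],
            "n": self.nobs,
            "removal_trace": self.removal_trace,
        }
        return out

    def summary(self) -> str:
        lines = [
            "Backward-stepwise OLS results",
            f"n = {self.nobs}, adjusted R^2 = {self.rsquared_adj:.3f}, "
            f"F({self.df_model}, {self.df_resid}) = {self.fvalue:.2f}, "
            f"p = {self.f_pvalue:.4g}",
            "",
            f"{'term':<22}{'B':>9}{'95% CI':>22}{'std B':>9}"
            f"{'p':>10}{'VIF':>7}",
        ]
        ci = self.conf_int()
        for t in ["const"] + self.retained:
            lo, hi = ci.loc[t]
            sb = f"{self.std_params[t]:9.2f}" if t in self.std_params else " " * 9
            vf = f"{self.vif[t]:7.2f}" if t in self.vif else " " * 7
            lines.append(
                f"{t:<22}{self.params[t]:9.2f}"
                f"{f'[{lo:.2f}, {hi:.2f}]':>22}{sb}"
                f"{self.pvalues[t]:10.4f}{vf}"
            )
        if self.removal_trace:
            lines.append("")
            lines.append("removed: " + ", ".join(
                f"{d['term']} (p={d['p_at_removal']:.3f}, step {d['step']})"
                for d in self.removal_trace))
        return "\n".join(lines)


def stepwise_backward(predictors: pd.DataFrame, response,
                      p_threshold: float = 0.05) -> StepwiseOLSResults:
    """Convenience wrapper: build a :class:`StepwiseOLS` and fit it."""
    return StepwiseOLS(response, predictors, p_threshold).fit()


# -- univariate group comparisons ------------------------------------------


def _group_summary(values: pd.Series) -> dict:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {"n": int(values.size), "mean": float(values.mean()),
            "sd": float(values.std(ddof=1)), "median": float(med),
            "iqr": [float(q1), float(q3)]}


def _check_groups(groups: dict) -> None:
    for lab, vals in groups.items():
        if len(vals) < 2:
            raise InsufficientGroupError(
                f"group {lab!r} has {len(vals)} observation(s); need >= 2"
            )


def bonferroni_pairwise(groups: dict[str, np.ndarray],
                        equal_var: bool = True) -> dict[str, float]:
    """Pairwise pooled t-tests with exact Bonferroni correction (p x m, cap 1)."""
    labels = list(groups)
    m = len(labels) * (len(labels) - 1) // 2
    out = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            p = sps.ttest_ind(groups[a], groups[b], equal_var=equal_var).pvalue
            out[f"{a}_vs_{b}"] = float(min(1.0, p * m))
    return out


def anova_oneway(groups: dict[str, np.ndarray]) -> dict:
    _check_groups(groups)
    res = sps.f_oneway(*groups.values())
    k = len(groups)
    n = sum(len(v) for v in groups.values())
    return {"F": float(res.statistic), "df": [k - 1, n - k],
            "p": float(res.pvalue)}


def kruskal_wallis(groups: dict[str, np.ndarray]) -> dict:
    _check_groups(groups)
    res = sps.kruskal(*groups.values())
    return {"H": float(res.statistic), "df": len(groups) - 1,
            "p": float(res.pvalue)}


def independent_t(low: np.ndarray, high: np.ndarray,
                  equal_var: bool = True) -> dict:
    _check_groups({"low": low, "high": high})
    res = sps.ttest_ind(low, high, equal_var=equal_var)
    df = len(low) + len(high) - 2 if equal_var else float(res.df)
    return {"t": float(res.statistic), "df": df, "p": float(res.pvalue)}


def group_comparisons(cohort: pd.DataFrame, *, desk_cut: float = 2.0,
                      outdoor_cut: float = 2.0,
                      equal_var: bool = True) -> dict:
    """Univariate analyses of 1-year refraction change across exposure groups.

    Produces: one-way ANOVA of delta_m across home-size groups with
    Bonferroni-adjusted pairwise tests; Kruskal-Wallis tests of dv / dv_2m /
    sd_d across home-size groups; ANOVA of delta_m across parental-myopia
    levels; and pooled independent t-tests of delta_m for Low/High daily desk
    time (cut ``desk_cut`` h/day) and Low/High weekly outdoor time (cut
    ``outdoor_cut`` h/week).  The cohort frame must already carry a
    ``home_size_group`` column.
    """
    dm = cohort["delta_m"]
    out: dict = {"overall": _group_summary(dm)}

    hs_groups = {lab: dm[cohort["home_size_group"] == lab].to_numpy()
                 for lab in ("Small", "Medium", "Large")}
    out["home_size"] = {
        "groups": {lab: _group_summary(pd.Series(v))
                   for lab, v in hs_groups.items()},
        "anova_delta_m": anova_oneway(hs_groups),
        "bonferroni_delta_m": bonferroni_pairwise(hs_groups, equal_var),
        "kruskal": {},
    }
    for metric in ("dv", "dv_2m", "sd_d"):
        mg = {lab: cohort.loc[cohort["home_size_group"] == lab,
                              metric].to_numpy()
              for lab in hs_groups}
        out["home_size"]["kruskal"][metric] = kruskal_wallis(mg)
        out["home_size"]["kruskal"][metric]["groups"] = {
            lab: _group_summary(pd.Series(v)) for lab, v in mg.items()}

    pm_groups = {str(k): dm[cohort["parental_myopia"] == k].to_numpy()
                 for k in sorted(cohort["parental_myopia"].unique())}
    out["parental_myopia"] = {
        "groups": {lab: _group_summary(pd.Series(v))
                   for lab, v in pm_groups.items()},
        "anova_delta_m": anova_oneway(pm_groups),
        "bonferroni_delta_m": bonferroni_pairwise(pm_groups, equal_var),
    }

    for name, col, cut in (("desk_time", "desk_time", desk_cut),
                           ("outdoor_time", "outdoor_time", outdoor_cut)):
        low = dm[cohort[col] < cut].to_numpy()
        high = dm[cohort[col] >= cut].to_numpy()
        out[name] = {
            "cut": cut,
            "low": _group_summary(pd.Series(low)),
            "high": _group_summary(pd.Series(high)),
            "t_test": independent_t(low, high, equal_var),
        }
    return out
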