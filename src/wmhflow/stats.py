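"""Association statistics for flow features and WMH burden.

Ordinary least squares of natural-log WMH volume on a hemodynamic
predictor, either bivariable or adjusted: model 1 adds age and sex, model 2
additionally adds the cerebrovascular risk factors (smoking, alcohol,
diabetes, hyperlipidemia, hypertension, cardiovascular history).
Coefficients are reported with Wald 95% CIs (t reference) and two-sided p
values, matching standard "beta (95% CI)" tables.  No multiplicity
correction is applied to the regression tables; the Bonferroni 0.05/6 level
belongs to the six ALTAB feature comparisons only.

Also provided: lesion-level analysis of log volume by ALTAB-count category,
a tenth-subsample reproducibility procedure, and stratified fits.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import InvalidParameterError, ModelError

__all__ = [
    "RegressionResult",
    "MODEL_COVARIATES",
    "fit_association",
    "lesion_count_analysis",
    "subsample_reproducibility",
    "stratified_fit",
    "association_table",
]

log = logging.getLogger(__name__)

def safe_ttest(a, b):
    """Two-sample Student t-test robust to degenerate inputs.

    Groups with fewer than 2 observations yield (nan, nan); identical
    zero-variance groups yield (0, 1) instead of scipy's nan.
    """
    if len(a) < 2 or len(b) < 2:
        return float("nan"), float("nan")
    if np.var(a) == 0 and np.var(b) == 0:
        return (0.0, 1.0) if np.mean(a) == np.mean(b) else (float("inf"), 0.0)
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


RISK_FACTORS = [
    "smoking", "alcohol", "diabetes",
    "hyperlipidemia", "hypertension", "cardiovascular_history",
]

MODEL_COVARIATES = {
    "bivariable": [],
    "model1": ["age", "sex"],
    "model2": ["age", "sex"] + RISK_FACTORS,
}


@dataclass(frozen=True)
class RegressionResult:
    predictor: str
    outcome: str
    model: str
    beta: float
    ci_low: float
    ci_high: float
    p: float
    n: int

    def __post_init__(self):
        if not self.ci_low <= self.beta <= self.ci_high:
            raise ModelError("confidence interval does not bracket the estimate")


def _design(records: pd.DataFrame, predictor: str, covariates: list) -> pd.DataFrame:
    cols = [predictor] + covariates
    missing = [c for c in cols if c not in records.columns]
    if missing:
        raise InvalidParameterError(f"records lack columns {missing}")
    X = records[cols].astype(float)
    return sm.add_constant(X, has_constant="add")


def fit_association(
    records: pd.DataFrame,
    outcome: str,
    predictor: str,
    model: str = "model2",
) -> RegressionResult:
    """OLS of ``outcome`` on ``predictor`` with the model's covariate set.

    Rows with non-finite outcome values (e.g. log of a zero WMH volume,
    excluded upstream) are dropped with a logged count.  Rank-deficient
    designs raise :class:`ModelError` naming the aliased columns.
    """
    if model not in MODEL_COVARIATES:
        raise InvalidParameterError(f"unknown model tag {model!r}")
    covariates = MODEL_COVARIATES[model]
    if outcome not in records.columns:
        raise InvalidParameterError(f"records lack outcome column {outcome!r}")
    data = records.copy()
    y = data[outcome].astype(float)
    keep = np.isfinite(y)
    if (~keep).sum():
        log.info("excluding %d subject(s) with undefined log volume", int((~keep).sum()))
    data = data[keep]
    y = y[keep]
    X = _design(data, predictor, covariates)
    if len(data) <= X.shape[1] + 1:
        raise ModelError(f"n={len(data)} too small for {X.shape[1]} parameters")

    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # name the aliased columns by testing rank drop per column
        aliased = []
        for col in X.columns:
            if np.linalg.matrix_rank(X.drop(columns=col).values) == rank:
                aliased.append(col)
        raise ModelError(f"design matrix is rank deficient; aliased columns: {aliased}")

    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        predictor=predictor,
        outcome=outcome,
        model=model,
        beta=float(fit.params[predictor]),
        ci_low=float(ci.loc[predictor, 0]),
        ci_high=float(ci.loc[predictor, 1]),
        p=float(fit.pvalues[predictor]),
        n=int(fit.nobs),
    )


def association_table(
    records: pd.DataFrame,
    outcomes: list,
    predictors: list,
    models: tuple = ("bivariable", "model1", "model2"),
) -> pd.DataFrame:
    """All (outcome, predictor, model) fits as one tidy table."""
    rows = []
    for outcome, predictor, model in itertools.product(outcomes, predictors, models):
        r = fit_association(records, outcome, predictor, model)
        rows.append({
            "outcome": outcome, "predictor": predictor, "model": model,
            "beta": r.beta, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p": r.p, "n": r.n,
        })
    return pd.DataFrame(rows)


def lesion_count_analysis(
    lesion_df: pd.DataFrame,
    volume_col: str = "log_volume",
    category_col: str = "altab_category",
    class_col: str | None = "wmh_class",
) -> pd.DataFrame:
    """Log lesion volume by ALTAB-count category {0, 1, 2+}.

    Returns per-stratum (overall plus PWMH/DWMH when available) category
    means/SDs and pairwise two-sample t-tests.  Empty categories are simply
    absent from the output; with a single populated category only summaries
    are produced.
    """
    strata = {"all": lesion_df}
    if class_col and class_col in lesion_df.columns:
        for cls, sub in lesion_df.groupby(class_col, observed=True):
            strata[str(cls)] = sub
    rows = []
    for stratum, df in strata.items():
        groups = {str(cat): sub[volume_col].dropna()
                  for cat, sub in df.groupby(category_col, observed=True)
                  if len(sub) > 0}
        if len(groups) == 0:
            continue
        for cat, vals in groups.items():
            rows.append({
                "stratum": stratum, "kind": "summary", "groups": cat,
                "n": len(vals), "mean_log_volume": float(vals.mean()),
                "sd_log_volume": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "t": np.nan, "p": np.nan,
            })
        for (c1, v1), (c2, v2) in itertools.combinations(sorted(groups.items()), 2):
            if len(v1) < 2 or len(v2) < 2:
                continue
            t, p = safe_ttest(v1, v2)
            rows.append({
                "stratum": stratum, "kind": "test", "groups": f"{c1} vs {c2}",
                "n": len(v1) + len(v2), "mean_log_volume": np.nan,
                "sd_log_volume": np.nan, "t": float(t), "p": float(p),
            })
    if len({r["groups"] for r in rows if r["kind"] == "summary"}) < 2:
        log.info("fewer than two ALTAB categories populated; summaries only")
    return pd.DataFrame(rows)


def subsample_reproducibility(
    records: pd.DataFrame,
    outcome: str,
    predictor: str,
    model: str = "model2",
    fraction: float = 0.1,
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit the model on random subsamples to probe reproducibility.

    Each rep draws ``fraction`` of the subjects uniformly without
    replacement and refits; the returned table carries one row per rep plus
    a sign-consistency summary column.  ``fraction=1.0`` reproduces the
    full-data fit in every rep.
    """
    if not 0 < fraction <= 1:
        raise InvalidParameterError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    n = len(records)
    k = int(round(fraction * n))
    full = fit_association(records, outcome, predictor, model)
    rows = []
    for rep in range(reps):
        idx = rng.choice(n, size=k, replace=False) if k < n else np.arange(n)
        sub = records.iloc[np.sort(idx)]
        try:
            r = fit_association(sub, outcome, predictor, model)
        except ModelError as exc:
            log.warning("rep %d skipped: %s", rep, exc)
            continue
        rows.append({
            "rep": rep, "beta": r.beta, "ci_low": r.ci_low, "ci_high": r.ci_high,
            "p": r.p, "n": r.n,
            "same_sign_as_full": bool(np.sign(r.beta) == np.sign(full.beta)),
            "significant": bool(r.p < 0.05),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out.attrs["full_beta"] = full.beta
        out.attrs["sign_consistency"] = float(out["same_sign_as_full"].mean())
    return out


def stratified_fit(
    records: pd.DataFrame,
    stratum_col: str,
    outcome: str,
    predictor: str,
    model: str = "model2",
) -> dict:
    """Fit the same model within each level of a stratifying column.

    Strata too small for the design are omitted with a logged notice.  Note
    the stratifier is dropped from the covariate set when it appears there
    (it is constant within a stratum).
    """
    out = {}
    for level, sub in records.groupby(stratum_col):
        sub = sub.drop(columns=[]) if stratum_col not in MODEL_COVARIATES[model] else sub
        try:
            if stratum_col in MODEL_COVARIATES[model]:
                # refit with the stratifier excluded to avoid a constant column
                covs = [c for c in MODEL_COVARIATES[model] if c != stratum_col]
                data = sub.copy()
                y = data[outcome].astype(float)
                keep = np.isfinite(y)
                data, y = data[keep], y[keep]
                X = sm.add_constant(data[[predictor] + covs].astype(float), has_constant="add")
                if len(data) <= X.shape[1] + 1:
                    raise ModelError(f"stratum {level!r} too small")
                fit = sm.OLS(y, X).fit()
                ci = fit.conf_int()
                out[level] = RegressionResult(
                    predictor, outcome, model, float(fit.params[predictor]),
                    float(ci.loc[predictor, 0]), float(ci.loc[predictor, 1]),
                    float(fit.pvalues[predictor]), int(fit.nobs))
            else:
                out[level] = fit_association(sub, outcome, predictor, model)
        except ModelError as exc:
            log.warning("stratum %r omitted: %s", level, exc)
    return out
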