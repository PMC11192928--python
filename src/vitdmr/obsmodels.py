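"""Observational regression stages.

Cross-sectional and prospective associations between the season-standardized
biomarker and blood pressure / hypertension, with the adjustment set encoded
by :mod:`vitdmr.pheno`, plus a restricted-cubic-spline non-linearity test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from . import _lm, pheno
from ._lm import Z95
from .errors import DegenerateInputError, ValidationError

log = logging.getLogger(__name__)

PER25 = 25.0


@dataclass(frozen=True)
class AssocResult:
    """A single regression coefficient with Wald inference.

    ``scale`` labels the unit convention: "per-unit", "per-25-nmol/L" or
    "log-odds".
    """

    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    scale: str = "per-unit"

    def __post_init__(self):
        if self.se < 0:
            raise ValidationError("standard error must be non-negative")

    @property
    def odds_ratio(self) -> float:
        if self.scale != "log-odds":
            raise ValueError("odds_ratio only defined on the log-odds scale")
        return math.exp(self.beta)

    def rescaled(self, factor: float, scale: str) -> "AssocResult":
        """Multiply coefficient and SE by ``factor`` (unit change)."""
        return replace(
            self,
            beta=self.beta * factor,
            se=self.se * factor,
            ci_low=self.ci_low * factor,
            ci_high=self.ci_high * factor,
            scale=scale,
        )


def _result(beta: float, se: float, n: int, scale: str) -> AssocResult:
    p = float(_lm.wald_p(beta, se)) if se > 0 else (0.0 if beta != 0 else 1.0)
    return AssocResult(
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - Z95 * se),
        ci_high=float(beta + Z95 * se),
        p=p,
        n=int(n),
        scale=scale,
    )


def _as_design(predictors) -> tuple[np.ndarray, list[str]]:
    if isinstance(predictors, pd.DataFrame):
        return predictors.to_numpy(dtype=float), list(predictors.columns)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X, [f"x{j}" for j in range(X.shape[1])]


def fit_linear(outcome, predictors, add_intercept: bool = True) -> dict[str, AssocResult]:
    """OLS of ``outcome`` on ``predictors``; one :class:`AssocResult` per column.

    Collinear columns are dropped with a warning. Intercept is added (and not
    reported) unless ``add_intercept`` is False.
    """
    y = np.asarray(outcome, dtype=float)
    X, names = _as_design(predictors)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["_const"] + names
    X, names, dropped = _lm.drop_collinear(X, names)
    if dropped:
        log.warning("dropping collinear columns: %s", dropped)
    fit = _lm.ols(y, X)
    out = {}
    for j, name in enumerate(names):
        if name == "_const":
            continue
        out[name] = _result(fit["beta"][j], fit["se"][j], fit["n"], "per-unit")
    return out


def fit_logistic(outcome, predictors, add_intercept: bool = True) -> dict[str, AssocResult]:
    """Logistic regression by IRLS; per-column log-odds results (OR = exp(beta))."""
    y = np.asarray(outcome, dtype=float)
    X, names = _as_design(predictors)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["_const"] + names
    X, names, dropped = _lm.drop_collinear(X, names)
    if dropped:
        log.warning("dropping collinear columns: %s", dropped)
    fit = _lm.logistic_irls(y, X)
    out = {}
    for j, name in enumerate(names):
        if name == "_const":
            continue
        out[name] = _result(fit["beta"][j], fit["se"][j], fit["n"], "log-odds")
    return out


# ---------------------------------------------------------------------------
# Table-style analyses
# ---------------------------------------------------------------------------

def _tidy_row(outcome, term, res: AssocResult, reference=False) -> dict:
    return {
        "outcome": outcome,
        "term": term,
        "n": res.n,
        "beta": 0.0 if reference else res.beta,
        "se": 0.0 if reference else res.se,
        "ci_low": 0.0 if reference else res.ci_low,
        "ci_high": 0.0 if reference else res.ci_high,
        "p": float("nan") if reference else res.p,
        "scale": res.scale,
        "reference": bool(reference),
    }


def _category_design(cat: pd.Series) -> pd.DataFrame:
    """Dummies against the reference biomarker band (50.0-74.9)."""
    cols = {}
    for level in pheno.VITD_CATEGORIES:
        if level == pheno.VITD_REFERENCE:
            continue
        col = (cat == level).astype(float)
        if col.sum() == 0:
            log.warning("empty biomarker category %s dropped", level)
            continue
        cols[f"vitd_{level}"] = col
    return pd.DataFrame(cols, index=cat.index)


def _exposure_models(df, covars, outcome_col, binary, baseline_col=None):
    """Continuous (per-25) and categorical exposure results for one outcome."""
    rows = []
    mask = df[outcome_col].notna() & df["vitd_std"].notna()
    sub = df.loc[mask]
    X_cov = covars.loc[sub.index]
    extra = {}
    if baseline_col is not None:
        extra[baseline_col] = sub[baseline_col].to_numpy(dtype=float)
    fitter = fit_logistic if binary else fit_linear
    scale = "log-odds" if binary else "per-25-nmol/L"

    design = pd.concat(
        [pd.DataFrame({"vitd_std": sub["vitd_std"]}), pd.DataFrame(extra, index=sub.index), X_cov],
        axis=1,
    )
    res = fitter(sub[outcome_col], design)["vitd_std"]
    if not binary:
        res = res.rescaled(PER25, scale)
    rows.append(_tidy_row(outcome_col, "per_25_increase", res))

    cat_design = _category_design(sub["vitd_category"])
    design = pd.concat([cat_design, pd.DataFrame(extra, index=sub.index), X_cov], axis=1)
    fits = fitter(sub[outcome_col], design)
    for level in pheno.VITD_CATEGORIES:
        term = f"vitd_{level}"
        n_level = int((sub["vitd_category"] == level).sum())
        if level == pheno.VITD_REFERENCE:
            ref = AssocResult(0.0, 0.0, 0.0, 0.0, 1.0, n_level, scale)
            rows.append(_tidy_row(outcome_col, level, ref, reference=True))
        elif term in fits:
            r = fits[term]
            rows.append(_tidy_row(outcome_col, level, replace(r, n=n_level, scale=scale)))
    return rows


def cross_sectional_analysis(df: pd.DataFrame, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Baseline associations of the standardized biomarker with SBP, DBP and
    hypertension, continuous (per 25 nmol/L) and categorical against the
    reference band."""
    sub = df.loc[df["vitd_std"].notna()]
    covars = covariates.loc[sub.index] if covariates is not None else pheno.encode_covariates(sub)
    rows = []
    rows += _exposure_models(sub, covars, "sbp_w1", binary=False)
    rows += _exposure_models(sub, covars, "dbp_w1", binary=False)
    sub2 = sub.assign(hypertensive_w1=sub["hypertensive_w1"].astype(float))
    rows += _exposure_models(sub2, covars, "hypertensive_w1", binary=True)
    return pd.DataFrame(rows)


def prospective_analysis(df: pd.DataFrame, covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Wave-2 outcomes on wave-1 exposure.

    BP models additionally adjust for the baseline reading; the hypertension
    model is restricted to baseline-normotensive participants (incident cases).
    """
    if "sbp_w2" not in df.columns:
        raise ValidationError("no wave-2 outcomes present")
    followed = df.loc[df["sbp_w2"].notna() & df["vitd_std"].notna()]
    covars = covariates.loc[followed.index] if covariates is not None else pheno.encode_covariates(followed)
    rows = []
    rows += _exposure_models(followed, covars, "sbp_w2", binary=False, baseline_col="sbp_w1")
    rows += _exposure_models(followed, covars, "dbp_w2", binary=False, baseline_col="dbp_w1")
    risk_set = pheno.select_prospective_sample(df)
    risk_set = risk_set.loc[risk_set["vitd_std"].notna()].copy()
    risk_set["incident_hypertension"] = risk_set["hypertensive_w2"].astype(float)
    cov_risk = pheno.encode_covariates(risk_set)
    rows += _exposure_models(risk_set, cov_risk, "incident_hypertension", binary=True)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Restricted cubic splines
# ---------------------------------------------------------------------------

def rcs_knots(x: np.ndarray, n_knots: int) -> np.ndarray:
    """Quantile-based knot placement (outer knots at 5/95 percentiles)."""
    if n_knots not in (3, 4, 5):
        raise ValidationError("n_knots must be 3, 4 or 5")
    qs = {
        3: [10, 50, 90],
        4: [5, 35, 65, 95],
        5: [5, 27.5, 50, 72.5, 95],
    }[n_knots]
    knots = np.percentile(np.asarray(x, dtype=float), qs)
    if np.unique(knots).size < n_knots:
        raise ValidationError("too few unique exposure values for knot placement")
    return knots


def rcs_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Restricted cubic spline basis (linear tails); columns: x, then k-2
    non-linear terms."""
    x = np.asarray(x, dtype=float)
    t = np.asarray(knots, dtype=float)
    k = t.size
    denom = (t[-1] - t[0]) ** 2
    cols = [x]
    for j in range(k - 2):
        term = (
            np.clip(x - t[j], 0, None) ** 3
            - np.clip(x - t[-2], 0, None) ** 3 * (t[-1] - t[j]) / (t[-1] - t[-2])
            + np.clip(x - t[-1], 0, None) ** 3 * (t[-2] - t[j]) / (t[-1] - t[-2])
        )
        cols.append(term / denom)
    return np.column_stack(cols)


def rcs_nonlinearity_test(
    outcome,
    exposure,
    covariates=None,
    n_knots: int = 4,
    binary: bool = False,
) -> float:
    """Joint Wald test that all non-linear spline terms are zero; returns p."""
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(exposure, dtype=float)
    if np.unique(x).size < 2 * n_knots:
        raise ValidationError("too few unique exposure values for a spline fit")
    knots = rcs_knots(x, n_knots)
    B = rcs_basis(x, knots)
    parts = [np.ones(len(x)), B]
    if covariates is not None:
        C, _ = _as_design(covariates)
        parts.append(C)
    X = np.column_stack(parts)
    X, names, _ = _lm.drop_collinear(X, [f"c{j}" for j in range(X.shape[1])])
    nl_idx = [i for i, nm in enumerate(names) if nm in {f"c{j}" for j in range(2, n_knots)}]
    if not nl_idx:
        raise DegenerateInputError("all non-linear spline terms were collinear")
    if binary:
        fit = _lm.logistic_irls(y, X)
        cov = fit["cov"]
    else:
        fit = _lm.ols(y, X)
        cov = fit["cov"]
    b = fit["beta"][nl_idx]
    V = cov[np.ix_(nl_idx, nl_idx)]
    w = float(b @ np.linalg.solve(V, b))
    return float(stats.chi2.sf(w, df=len(nl_idx)))
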