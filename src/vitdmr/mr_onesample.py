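"""Split-sample one-sample MR via a Wald ratio on the weighted allele score.

The score-exposure coefficient comes from the sub-cohort with measured
biomarker values; the score-outcome coefficient from the total cohort. Both
regressions share the adjustment set (age, sex, batch, ancestry PCs).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._lm import Z95, wald_p
from .errors import ValidationError, WeakFirstStageError
from .grs import GrsVector
from .obsmodels import AssocResult, fit_linear, fit_logistic

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class WaldEstimate:
    """Ratio IV estimate with delta-method inference.

    ``ratio`` (and se/ci) are on the reported scale: per unit of exposure
    when ``scale == 1`` and per ``scale`` units otherwise. ``or_scale`` is
    exp(ratio) for log-odds outcome coefficients. ``components`` stores the
    raw (beta_y, se_y, beta_x, se_x).
    """

    ratio: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    components: tuple[float, float, float, float]
    scale: float = 1.0
    or_scale: float | None = None


def _adjustment(df: pd.DataFrame, adjust: list[str] | None) -> pd.DataFrame:
    if adjust is None:
        adjust = [c for c in df.columns if c in ("age", "sex", "batch") or c.startswith("pc")]
    cols = {}
    for c in adjust:
        if c not in df.columns:
            raise ValidationError(f"adjustment column {c!r} missing")
        v = df[c]
        if v.dtype == object:
            levels = sorted(set(v.dropna()))
            for lev in levels[1:]:
                cols[f"{c}_{lev}"] = (v == lev).astype(float)
        else:
            cols[c] = v.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=df.index)


def grs_exposure_assoc(
    subcohort: pd.DataFrame,
    grs: GrsVector | np.ndarray,
    adjust: list[str] | None = None,
    exposure_col: str = "vitd_std",
) -> AssocResult:
    """Linear regression of the standardized biomarker on the score in the
    sub-cohort."""
    score = grs.score if isinstance(grs, GrsVector) else np.asarray(grs, dtype=float)
    df = subcohort.loc[subcohort[exposure_col].notna()]
    s = pd.Series(score, index=subcohort.index).loc[df.index]
    if s.var() == 0:
        raise ValidationError("zero-variance score")
    design = pd.concat([pd.DataFrame({"grs": s}), _adjustment(df, adjust)], axis=1)
    return fit_linear(df[exposure_col], design)["grs"]


def grs_outcome_assoc(
    cohort: pd.DataFrame,
    grs: GrsVector | np.ndarray,
    outcome: str,
    adjust: list[str] | None = None,
    binary: bool | None = None,
) -> AssocResult:
    """Score-outcome regression in the total cohort (linear BP, logistic
    hypertension)."""
    score = grs.score if isinstance(grs, GrsVector) else np.asarray(grs, dtype=float)
    df = cohort.loc[cohort[outcome].notna()]
    s = pd.Series(score, index=cohort.index).loc[df.index]
    y = df[outcome]
    if binary is None:
        binary = set(pd.unique(y.dropna())) <= {0, 1, True, False}
    design = pd.concat([pd.DataFrame({"grs": s}), _adjustment(df, adjust)], axis=1)
    fitter = fit_logistic if binary else fit_linear
    return fitter(y.astype(float), design)["grs"]


def wald_ratio(
    assoc_y: AssocResult,
    assoc_x: AssocResult,
    scale: float = 1.0,
) -> WaldEstimate:
    """ratio = beta_y / beta_x with a second-order delta-method SE.

    The two coefficients are treated as independent (split samples):
    var = se_y^2/beta_x^2 + beta_y^2 * se_x^2 / beta_x^4. ``scale`` rescales
    ratio/SE/CI (e.g. 25 for per-25-unit reporting). When the outcome
    coefficient is on the log-odds scale, ``or_scale`` = exp(scale * ratio).
    """
    by, sy, bx, sx = assoc_y.beta, assoc_y.se, assoc_x.beta, assoc_x.se
    if bx == 0:
        raise WeakFirstStageError("weak/degenerate first stage: beta_x = 0")
    if sx > 0 and abs(bx) / sx < 1:
        log.warning("first-stage |beta/se| < 1: ratio estimate unreliable")
    ratio = by / bx
    var = sy**2 / bx**2 + by**2 * sx**2 / bx**4
    se = math.sqrt(var)
    ratio_s, se_s = ratio * scale, se * scale
    p = float(wald_p(ratio_s, se_s)) if se_s > 0 else (0.0 if ratio_s else 1.0)
    or_scale = math.exp(scale * ratio) if assoc_y.scale == "log-odds" else None
    return WaldEstimate(
        ratio=ratio_s,
        se=se_s,
        ci_low=ratio_s - Z95 * se_s,
        ci_high=ratio_s + Z95 * se_s,
        p=p,
        components=(by, sy, bx, sx),
        scale=scale,
        or_scale=or_scale,
    )


def one_sample_mr(
    cohort: pd.DataFrame,
    grs: GrsVector | np.ndarray,
    outcomes: dict[str, bool] | None = None,
    adjust: list[str] | None = None,
    scale: float = 25.0,
) -> pd.DataFrame:
    """Run the full split-sample analysis; one row per outcome.

    ``outcomes`` maps outcome column -> binary flag; defaults to wave-1 SBP,
    DBP (linear) and hypertension (logistic).
    """
    if outcomes is None:
        outcomes = {"sbp_w1": False, "dbp_w1": False, "hypertensive_w1": True}
    score = grs.score if isinstance(grs, GrsVector) else np.asarray(grs, dtype=float)
    sub = cohort.loc[cohort["vitd_std"].notna()]
    assoc_x = grs_exposure_assoc(cohort, score, adjust=adjust)
    rows = []
    for outcome, binary in outcomes.items():
        assoc_y = grs_outcome_assoc(cohort, score, outcome, adjust=adjust, binary=binary)
        est = wald_ratio(assoc_y, assoc_x, scale=scale)
        rows.append(
            {
                "outcome": outcome,
                "estimate": est.or_scale if binary else est.ratio,
                "measure": "OR" if binary else "coef",
                "ratio": est.ratio,
                "se": est.se,
                "ci_low": math.exp(est.ci_low) if binary else est.ci_low,
                "ci_high": math.exp(est.ci_high) if binary else est.ci_high,
                "p": est.p,
                "n_exposure": assoc_x.n,
                "n_outcome": assoc_y.n,
                "scale": f"per-{est.scale:g}-nmol/L",
            }
        )
    log.info("one-sample MR: first stage n=%d (sub-cohort of %d)", assoc_x.n, len(sub))
    return pd.DataFrame(rows)
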