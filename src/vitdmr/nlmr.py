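"""Non-linear MR by residual and doubly-ranked stratification.

Stratum-specific Wald ratio estimates plus heterogeneity (Cochran's Q) and
trend (weighted meta-regression on stratum exposure means) tests for
non-linearity of the causal effect.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _lm
from ._lm import Z95, wald_p
from .errors import DegenerateInputError, ValidationError
from .grs import GrsVector
from .mr_onesample import WaldEstimate, wald_ratio
from .obsmodels import fit_linear, fit_logistic

log = logging.getLogger(__name__)

MIN_STRATUM_SIZE = 20


@dataclass(frozen=True)
class StratumEstimate:
    stratum: int  # 1-based index, increasing exposure
    n: int
    exposure_mean: float
    exposure_range: tuple[float, float]
    wald: WaldEstimate | None  # None when the first stage is degenerate


def _score_array(iv) -> np.ndarray:
    return iv.score if isinstance(iv, GrsVector) else np.asarray(iv, dtype=float)


def residual_stratify(iv, exposure, k: int) -> np.ndarray:
    """Equal-size strata on exposure residuals after removing the
    instrument-predicted component.

    Returns 1-based stratum labels; with n = q*k + r the first r strata take
    one extra member.
    """
    score = _score_array(iv)
    x = np.asarray(exposure, dtype=float)
    n = len(x)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if n < 2 * k:
        raise ValidationError(f"need n >= 2*k (= {2 * k}) observations")
    if n < 10 * k:
        log.warning("n=%d < 10*k=%d: residual strata will be noisy", n, 10 * k)
    if np.var(score) == 0:
        raise DegenerateInputError("zero instrument variance")
    fit = _lm.ols(x, _lm.add_intercept(score))
    residual = fit["resid"]
    order = np.argsort(residual, kind="stable")
    sizes = [n // k + (1 if j < n % k else 0) for j in range(k)]
    labels = np.empty(n, dtype=int)
    start = 0
    for j, size in enumerate(sizes, start=1):
        labels[order[start : start + size]] = j
        start += size
    return labels


def doubly_ranked_stratify(iv, exposure, k: int) -> np.ndarray:
    """Rank by instrument, form consecutive blocks of k, rank by exposure
    within each block; the j-th exposure-ranked member of every block joins
    stratum j. The final partial block (n mod k members) is assigned to
    strata 1..r in exposure-rank order. Ties broken by original order."""
    score = _score_array(iv)
    x = np.asarray(exposure, dtype=float)
    n = len(x)
    if k < 1:
        raise ValidationError("k must be >= 1")
    if k == 1:
        return np.ones(n, dtype=int)
    if n < k * k:
        log.warning("n=%d < k^2=%d: strata may be unstable", n, k * k)
    iv_order = np.argsort(score, kind="stable")
    labels = np.empty(n, dtype=int)
    for start in range(0, n, k):
        block = iv_order[start : start + k]
        within = block[np.argsort(x[block], kind="stable")]
        for j, idx in enumerate(within, start=1):
            labels[idx] = j
    return labels


def stratum_estimates(
    assignment: np.ndarray,
    iv,
    exposure,
    outcome,
    adjust=None,
    binary: bool = False,
    min_size: int = MIN_STRATUM_SIZE,
) -> list[StratumEstimate]:
    """Per-stratum instrument-exposure and instrument-outcome regressions
    and a Wald ratio, using the same delta-method inference as the
    one-sample stage. Strata with a degenerate first stage are flagged
    (estimate withheld)."""
    score = _score_array(iv)
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(outcome, dtype=float)
    labels = np.asarray(assignment)
    adjust_arr = None if adjust is None else np.asarray(adjust, dtype=float)
    out: list[StratumEstimate] = []
    for j in sorted(np.unique(labels)):
        mask = labels == j
        n_j = int(mask.sum())
        if n_j < min_size:
            raise ValidationError(f"stratum {j} has {n_j} < {min_size} members")
        xm = float(x[mask].mean())
        xr = (float(x[mask].min()), float(x[mask].max()))
        design = score[mask][:, None]
        if adjust_arr is not None:
            design = np.column_stack([design, adjust_arr[mask]])
        names = ["grs"] + [f"a{i}" for i in range(design.shape[1] - 1)]
        design_df = pd.DataFrame(design, columns=names)
        try:
            ax = fit_linear(x[mask], design_df)["grs"]
            fitter = fit_logistic if binary else fit_linear
            ay = fitter(y[mask], design_df)["grs"]
            if abs(ax.beta) <= 2 * ax.se:  # effectively uninformative first stage
                raise DegenerateInputError("first stage indistinguishable from zero")
            wald = wald_ratio(ay, ax)
        except (DegenerateInputError, ValidationError) as exc:
            log.warning("stratum %d estimate withheld: %s", j, exc)
            wald = None
        out.append(
            StratumEstimate(stratum=int(j), n=n_j, exposure_mean=xm, exposure_range=xr, wald=wald)
        )
    return out


def nonlinearity_test(estimates: list[StratumEstimate]) -> tuple[float, float]:
    """(q_p, trend_p) over stratum-specific IV estimates.

    q_p: Cochran's Q of the stratum Wald ratios around their
    inverse-variance-weighted mean. trend_p: Wald p of the slope from an
    inverse-variance-weighted meta-regression of stratum estimates on
    stratum exposure means.
    """
    usable = [e for e in estimates if e.wald is not None and e.wald.se > 0]
    if len(usable) < 3:
        raise ValidationError("need >= 3 strata with usable estimates")
    b = np.array([e.wald.ratio for e in usable])
    se = np.array([e.wald.se for e in usable])
    xm = np.array([e.exposure_mean for e in usable])
    w = 1.0 / se**2
    b_ivw = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - b_ivw) ** 2))
    q_p = float(stats.chi2.sf(q, len(usable) - 1))
    X = np.column_stack([np.ones(len(b)), xm])
    fit = _lm.wls(b, X, w)
    slope = float(fit["beta"][1])
    slope_se = float(math.sqrt(fit["cov_unscaled"][1, 1]))
    trend_p = float(wald_p(slope, slope_se)) if slope_se > 0 else (0.0 if slope else 1.0)
    return q_p, trend_p


def stratum_table(estimates: list[StratumEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append(
            {
                "stratum": e.stratum,
                "n": e.n,
                "exposure_mean": e.exposure_mean,
                "exposure_min": e.exposure_range[0],
                "exposure_max": e.exposure_range[1],
                "estimate": e.wald.ratio if e.wald else float("nan"),
                "se": e.wald.se if e.wald else float("nan"),
                "ci_low": e.wald.ci_low if e.wald else float("nan"),
                "ci_high": e.wald.ci_high if e.wald else float("nan"),
                "p": e.wald.p if e.wald else float("nan"),
            }
        )
    return pd.DataFrame(rows)
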