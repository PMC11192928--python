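"""Summary-statistics MR estimators implemented from first principles.

Allele harmonization, inverse-variance-weighted (IVW) regression through the
origin, Egger regression with an intercept, the weighted median, Cochran's Q
and a residual-sum-of-squares outlier procedure (global test, per-variant
outlier p-values, outlier-corrected re-estimate and distortion test).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._lm import Z95, wald_p, wls
from .errors import DegenerateInputError, ValidationError

log = logging.getLogger(__name__)

COLUMNS = [
    "rsid",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta_exposure",
    "se_exposure",
    "beta_outcome",
    "se_outcome",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)


class SummaryStatSet:
    """Per-SNP exposure/outcome effect pairs for two-sample MR.

    Thin wrapper over a DataFrame with columns ``rsid, effect_allele,
    other_allele, eaf, beta_exposure, se_exposure, beta_outcome, se_outcome``.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"summary stats missing columns: {missing}")
        df = df[COLUMNS].reset_index(drop=True)
        if df["rsid"].duplicated().any():
            dups = df.loc[df["rsid"].duplicated(), "rsid"].tolist()
            raise ValidationError(f"duplicate rsids: {dups}")
        if (df[["se_exposure", "se_outcome"]] <= 0).any().any():
            raise ValidationError("all standard errors must be positive")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, SummaryStatSet) and self.df.equals(other.df)

    @property
    def beta_exposure(self) -> np.ndarray:
        return self.df["beta_exposure"].to_numpy(dtype=float)

    @property
    def se_exposure(self) -> np.ndarray:
        return self.df["se_exposure"].to_numpy(dtype=float)

    @property
    def beta_outcome(self) -> np.ndarray:
        return self.df["beta_outcome"].to_numpy(dtype=float)

    @property
    def se_outcome(self) -> np.ndarray:
        return self.df["se_outcome"].to_numpy(dtype=float)

    def oriented(self) -> "SummaryStatSet":
        """Flip SNPs so every exposure effect is positive."""
        df = self.df.copy()
        flip = df["beta_exposure"] < 0
        df.loc[flip, "beta_exposure"] *= -1
        df.loc[flip, "beta_outcome"] *= -1
        return SummaryStatSet(df)

    def drop(self, indices) -> "SummaryStatSet":
        return SummaryStatSet(self.df.drop(index=list(indices)).reset_index(drop=True))

    @classmethod
    def from_tsv(cls, path) -> "SummaryStatSet":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.10g")


@dataclass(frozen=True)
class TwoSampleResult:
    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n_snps: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_stat: float | None = None
    q_p: float | None = None
    outliers: tuple[int, ...] | None = None
    outlier_rsids: tuple[str, ...] | None = None
    global_p: float | None = None
    distortion_p: float | None = None

    def as_row(self) -> dict:
        return {
            "method": self.method,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p": self.p,
            "n_snps": self.n_snps,
            "intercept": self.intercept,
            "intercept_p": self.intercept_p,
            "q_stat": self.q_stat,
            "q_p": self.q_p,
            "outliers": ",".join(self.outlier_rsids) if self.outlier_rsids else "",
            "global_p": self.global_p,
            "distortion_p": self.distortion_p,
        }


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> SummaryStatSet:
    """Align outcome effects to the exposure's effect alleles.

    Inputs are single-trait frames with columns ``rsid, effect_allele,
    other_allele, eaf, beta, se``. Swapped allele coding flips the outcome
    beta (and frequency); palindromic SNPs with intermediate frequency
    (eaf in [0.42, 0.58]) are dropped, otherwise aligned by frequency;
    irreconcilable allele sets are dropped with a warning.
    """
    exp = exposure.df if isinstance(exposure, SummaryStatSet) else exposure
    out = outcome.df if isinstance(outcome, SummaryStatSet) else outcome
    merged = exp.merge(out, on="rsid", suffixes=("_x", "_y"))
    if len(merged) < 2:
        raise ValidationError("fewer than 2 overlapping rsids after merge")
    rows = []
    for _, r in merged.iterrows():
        ea_x, oa_x = r["effect_allele_x"].upper(), r["other_allele_x"].upper()
        ea_y, oa_y = r["effect_allele_y"].upper(), r["other_allele_y"].upper()
        beta_y, eaf_y = float(r["beta_y"]), float(r["eaf_y"])
        palindromic = _is_palindromic(ea_x, oa_x)
        if palindromic:
            lo, hi = PALINDROMIC_EAF_WINDOW
            if lo <= float(r["eaf_x"]) <= hi:
                log.warning("palindromic SNP %s with intermediate eaf dropped", r["rsid"])
                continue
            # align by frequency: flip when outcome eaf is on the other side
            if (float(r["eaf_x"]) > 0.5) != (eaf_y > 0.5):
                beta_y, eaf_y = -beta_y, 1.0 - eaf_y
                log.info("palindromic SNP %s frequency-flipped", r["rsid"])
        elif (ea_y, oa_y) == (ea_x, oa_x):
            pass
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            log.info("SNP %s allele order flipped", r["rsid"])
        elif (ea_y, oa_y) == (_COMPLEMENT.get(ea_x), _COMPLEMENT.get(oa_x)):
            pass  # strand flip, same orientation
        elif (ea_y, oa_y) == (_COMPLEMENT.get(oa_x), _COMPLEMENT.get(ea_x)):
            beta_y, eaf_y = -beta_y, 1.0 - eaf_y
            log.info("SNP %s strand+order flipped", r["rsid"])
        else:
            log.warning("SNP %s alleles irreconcilable (%s/%s vs %s/%s); dropped",
                        r["rsid"], ea_x, oa_x, ea_y, oa_y)
            continue
        rows.append(
            {
                "rsid": r["rsid"],
                "effect_allele": ea_x,
                "other_allele": oa_x,
                "eaf": float(r["eaf_x"]),
                "beta_exposure": float(r["beta_x"]),
                "se_exposure": float(r["se_x"]),
                "beta_outcome": beta_y,
                "se_outcome": float(r["se_y"]),
            }
        )
    if not rows:
        raise ValidationError("no SNPs left after harmonization")
    return SummaryStatSet(pd.DataFrame(rows))


def _ivw_core(bx, by, sy):
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    beta = float(np.sum(w * bx * by)) / denom
    se_fixed = math.sqrt(1.0 / denom)
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


def ivw(stats_set: SummaryStatSet, model: str = "random") -> TwoSampleResult:
    """Inverse-variance-weighted estimate: weighted regression of outcome on
    exposure effects through the origin with weights 1/se_outcome^2.

    ``model`` is "fixed" or "random" (multiplicative random effects inflates
    the SE by max(1, sqrt(Q/(m-1)))). A single SNP falls back to the Wald
    ratio with a warning.
    """
    if model not in ("fixed", "random"):
        raise ValidationError("model must be 'fixed' or 'random'")
    m = len(stats_set)
    bx, by, sy = stats_set.beta_exposure, stats_set.beta_outcome, stats_set.se_outcome
    if m == 0:
        raise ValidationError("empty summary-stat set")
    if m == 1:
        log.warning("single SNP: IVW degenerates to the Wald ratio")
        beta = float(by[0] / bx[0])
        se = float(sy[0] / abs(bx[0]))
        return TwoSampleResult(
            method=f"ivw-{model}", beta=beta, se=se,
            ci_low=beta - Z95 * se, ci_high=beta + Z95 * se,
            p=float(wald_p(beta, se)), n_snps=1, q_stat=0.0, q_p=1.0,
        )
    beta, se, q = _ivw_core(bx, by, sy)
    q_p = float(stats.chi2.sf(q, m - 1))
    if model == "random":
        se = se * max(1.0, math.sqrt(q / (m - 1)))
    return TwoSampleResult(
        method=f"ivw-{model}",
        beta=beta,
        se=se,
        ci_low=beta - Z95 * se,
        ci_high=beta + Z95 * se,
        p=float(wald_p(beta, se)),
        n_snps=m,
        q_stat=q,
        q_p=q_p,
    )


def egger(stats_set: SummaryStatSet) -> TwoSampleResult:
    """Egger regression: weighted fit of outcome on exposure effects with an
    intercept (directional pleiotropy), exposure effects oriented positive.

    SEs use a dispersion factor max(1, rss_w/(m-2)); p-values from a t
    distribution with m-2 df.
    """
    m = len(stats_set)
    if m < 3:
        raise ValidationError("Egger regression needs >= 3 SNPs")
    s = stats_set.oriented()
    bx, by, sy = s.beta_exposure, s.beta_outcome, s.se_outcome
    X = np.column_stack([np.ones(m), bx])
    fit = wls(by, X, 1.0 / sy**2)
    phi = max(1.0, fit["rss_w"] / (m - 2))
    cov = fit["cov_unscaled"] * phi
    icpt, slope = fit["beta"]
    se_i, se_b = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    tdist = stats.t(df=m - 2)
    p_b = float(2 * tdist.sf(abs(slope) / se_b)) if se_b > 0 else 0.0
    p_i = float(2 * tdist.sf(abs(icpt) / se_i)) if se_i > 0 else 0.0
    q = float(np.sum((by - icpt - slope * bx) ** 2 / sy**2))
    return TwoSampleResult(
        method="egger",
        beta=float(slope),
        se=se_b,
        ci_low=float(slope - Z95 * se_b),
        ci_high=float(slope + Z95 * se_b),
        p=p_b,
        n_snps=m,
        intercept=float(icpt),
        intercept_se=se_i,
        intercept_p=p_i,
        q_stat=q,
        q_p=float(stats.chi2.sf(q, m - 2)),
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w  # mid-point cumulative weight
    if s[0] >= 0.5:
        return float(r[0])
    if s[-1] <= 0.5:
        return float(r[-1])
    j = int(np.searchsorted(s, 0.5, side="right")) - 1
    if s[j] == 0.5:
        return float(r[j])
    return float(r[j] + (r[j + 1] - r[j]) * (0.5 - s[j]) / (s[j + 1] - s[j]))


def weighted_median(
    stats_set: SummaryStatSet, n_boot: int = 1000, seed: int = 0
) -> TwoSampleResult:
    """Weighted median of per-SNP ratios, weights (beta_exposure/se_outcome)^2
    (first-order inverse variance of the ratio); SE by seeded parametric
    bootstrap."""
    m = len(stats_set)
    if m < 3:
        raise ValidationError("weighted median needs >= 3 SNPs")
    bx, sx = stats_set.beta_exposure, stats_set.se_exposure
    by, sy = stats_set.beta_outcome, stats_set.se_outcome
    if np.any(bx == 0):
        raise DegenerateInputError("zero exposure effect gives an undefined ratio")
    ratios = by / bx
    weights = (bx / sy) ** 2
    est = _weighted_median(ratios, weights)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(m)
        by_b = by + sy * rng.standard_normal(m)
        bx_b = np.where(bx_b == 0, 1e-12, bx_b)
        boots[b] = _weighted_median(by_b / bx_b, (bx_b / sy) ** 2)
    se = float(np.std(boots, ddof=1))
    return TwoSampleResult(
        method="weighted-median",
        beta=est,
        se=se,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        p=float(wald_p(est, se)) if se > 0 else (0.0 if est else 1.0),
        n_snps=m,
    )


def cochran_q(stats_set: SummaryStatSet, estimate: float) -> tuple[float, int, float]:
    """Heterogeneity of per-SNP ratios around ``estimate`` with first-order
    weights w_j = (beta_exposure/se_outcome)^2; returns (Q, df, p)."""
    m = len(stats_set)
    if m < 2:
        raise ValidationError("Cochran's Q needs >= 2 SNPs")
    bx, by, sy = stats_set.beta_exposure, stats_set.beta_outcome, stats_set.se_outcome
    ratios = by / bx
    w = (bx / sy) ** 2
    q = float(np.sum(w * (ratios - estimate) ** 2))
    df = m - 1
    return q, df, float(stats.chi2.sf(q, df))


def _loo_ivw(bx, by, sy):
    """Leave-one-out IVW estimates, vectorized."""
    w = 1.0 / sy**2
    sw_xy = np.sum(w * bx * by)
    sw_xx = np.sum(w * bx**2)
    return (sw_xy - w * bx * by) / (sw_xx - w * bx**2)


def mr_presso(
    stats_set: SummaryStatSet,
    n_sim: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> TwoSampleResult:
    """Residual-sum-of-squares outlier procedure.

    Global test: the observed weighted RSS of each SNP against its
    leave-one-out IVW prediction is compared with ``n_sim`` parametric draws
    under the no-pleiotropy model. Per-SNP outlier p-values are
    Bonferroni-corrected across SNPs; the corrected estimate is IVW on the
    non-outliers; the distortion test compares the observed correction with
    corrections from random same-size SNP subsets.
    """
    m = len(stats_set)
    if m < 4:
        raise ValidationError("outlier procedure needs >= 4 SNPs")
    if n_sim < 100:
        raise ValidationError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    bx, sx = stats_set.beta_exposure, stats_set.se_exposure
    by, sy = stats_set.beta_outcome, stats_set.se_outcome
    w = 1.0 / sy**2

    beta_loo = _loo_ivw(bx, by, sy)
    obs_res2 = w * (by - bx * beta_loo) ** 2
    rss_obs = float(obs_res2.sum())

    # parametric null draws around the leave-one-out predictions
    bx_sim = bx + sx * rng.standard_normal((n_sim, m))
    by_sim = bx * beta_loo + sy * rng.standard_normal((n_sim, m))
    sim_res2 = w * (by_sim - bx_sim * beta_loo) ** 2
    rss_sim = sim_res2.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    snp_p = (1 + np.sum(sim_res2 >= obs_res2, axis=0)) / (n_sim + 1)
    outliers = tuple(int(i) for i in np.flatnonzero(snp_p * m < alpha))

    raw = ivw(stats_set, model="random")
    if outliers and len(outliers) < m - 1:
        corrected_set = stats_set.drop(outliers)
        corrected = ivw(corrected_set, model="random")
        # distortion null: corrections from random same-size subsets
        n_out = len(outliers)
        dist_obs = (raw.beta - corrected.beta) / abs(corrected.beta) if corrected.beta != 0 else 0.0
        sims = []
        for _ in range(n_sim):
            drop_idx = rng.choice(m, size=n_out, replace=False)
            keep = np.setdiff1d(np.arange(m), drop_idx)
            b, _, _ = _ivw_core(bx[keep], by[keep], sy[keep])
            sims.append((raw.beta - b) / abs(b) if b != 0 else 0.0)
        sims = np.asarray(sims)
        distortion_p = float((1 + np.sum(np.abs(sims) >= abs(dist_obs))) / (n_sim + 1))
        result = corrected
    else:
        corrected_set = stats_set
        result = raw
        distortion_p = None
    return TwoSampleResult(
        method="mr-presso",
        beta=result.beta,
        se=result.se,
        ci_low=result.ci_low,
        ci_high=result.ci_high,
        p=result.p,
        n_snps=m,
        q_stat=raw.q_stat,
        q_p=raw.q_p,
        outliers=outliers,
        outlier_rsids=tuple(stats_set.df.loc[list(outliers), "rsid"]) if outliers else (),
        global_p=global_p,
        distortion_p=distortion_p,
    )


def run_all_methods(
    stats_set: SummaryStatSet,
    seed: int = 0,
    ivw_model: str = "random",
    n_boot: int = 1000,
    presso_sims: int = 1000,
) -> pd.DataFrame:
    """IVW, Egger, weighted median, (+ outlier procedure when m >= 4) on one
    harmonized set; tidy one-row-per-method frame."""
    results = [ivw(stats_set, model=ivw_model)]
    if len(stats_set) >= 3:
        results.append(egger(stats_set))
        results.append(weighted_median(stats_set, n_boot=n_boot, seed=seed))
    if len(stats_set) >= 4:
        results.append(mr_presso(stats_set, n_sim=presso_sims, seed=seed + 1))
    return pd.DataFrame([r.as_row() for r in results])
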