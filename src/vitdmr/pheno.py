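"""Phenotype processing rules.

Blood-pressure summarization and medication amendment, hypertension coding,
seasonal standardization of the serum biomarker, category bands, covariate
encoding and prospective-sample selection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import SeasonalSpreadError, ValidationError

log = logging.getLogger(__name__)

PERIOD_DAYS = 365.25
ASSAY_MIN, ASSAY_MAX = 10.0, 375.0

SBP_AMEND, DBP_AMEND = 10.0, 5.0
SBP_THRESHOLD, DBP_THRESHOLD = 140.0, 90.0

VITD_CATEGORIES = ("lt30", "30to49.9", "50to74.9", "ge75")
VITD_REFERENCE = "50to74.9"
_VITD_EDGES = (30.0, 50.0, 75.0)

# Categorical covariates: allowed levels, first level is the reference.
COVARIATE_LEVELS = {
    "smoking": (
        "never",
        "former_lt10",
        "former_10to20",
        "former_gt20",
        "current_lt10",
        "current_10to20",
        "current_gt20",
        "unknown",
    ),
    "alcohol": ("never", "1to4", "ge5", "unknown"),
    "activity": ("inactive", "low", "moderate", "high", "unknown"),
    "education": ("lt10", "10to12", "ge13", "unknown"),
    "econ_difficulty": ("no", "yes", "unknown"),
}
BMI_LEVELS = ("lt25", "25to29.9", "ge30", "unknown")


def summarize_bp(readings) -> float:
    """Mean of the last two usable readings; NaN when fewer than two usable."""
    vals = [float(v) for v in readings if v is not None and np.isfinite(v)]
    if len(vals) < 2:
        log.warning("fewer than two usable BP readings: %s", readings)
        return float("nan")
    return (vals[-2] + vals[-1]) / 2.0


def summarize_bp_series(readings: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`summarize_bp` over a frame of reading columns."""
    arr = readings.to_numpy(dtype=float)
    finite = np.isfinite(arr)
    n_ok = finite.sum(axis=1)
    out = np.full(len(arr), np.nan)
    complete = finite.all(axis=1)
    out[complete] = (arr[complete, -2] + arr[complete, -1]) / 2.0
    # rows with gaps: take the last two finite readings individually
    for i in np.flatnonzero(~complete & (n_ok >= 2)):
        vals = arr[i][finite[i]]
        out[i] = (vals[-2] + vals[-1]) / 2.0
    n_bad = int((n_ok < 2).sum())
    if n_bad:
        log.warning("%d participants with <2 usable BP readings set to missing", n_bad)
    return pd.Series(out, index=readings.index)


def adjust_bp_for_medication(sbp, dbp, med_use):
    """Add 10/5 mmHg to SBP/DBP for medication users; others unchanged."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    med = np.asarray(med_use, dtype=bool)
    return sbp + SBP_AMEND * med, dbp + DBP_AMEND * med


def define_hypertension(sbp_measured, dbp_measured, med_use):
    """SBP >= 140 or DBP >= 90 (measured, unamended) or medication use."""
    sbp = np.asarray(sbp_measured, dtype=float)
    dbp = np.asarray(dbp_measured, dtype=float)
    med = np.asarray(med_use, dtype=bool)
    return (sbp >= SBP_THRESHOLD) | (dbp >= DBP_THRESHOLD) | med


def season_standardize(values, day_of_year) -> np.ndarray:
    """Remove the fitted one-harmonic seasonal component, preserving the mean.

    Fits ``v = m + a*cos(2*pi*d/365.25) + b*sin(2*pi*d/365.25)`` by least
    squares and subtracts the fitted seasonal deviation, giving each
    participant's annual-average value. The grand mean is preserved exactly
    for draw dates balanced over the year (the fitted seasonal component then
    averages to zero); re-standardizing is a no-op.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(day_of_year, dtype=float)
    ok = np.isfinite(v) & np.isfinite(d)
    if ok.sum() < 20:
        raise SeasonalSpreadError("need >= 20 non-missing value/day pairs")
    quarters = np.unique((d[ok] - 1) // 91.3125)
    if quarters.size < 2:
        raise SeasonalSpreadError("day-of-year values span fewer than two seasons")
    ang = 2.0 * np.pi * d / PERIOD_DAYS
    X = np.column_stack([np.ones(ok.sum()), np.cos(ang[ok]), np.sin(ang[ok])])
    coef, *_ = np.linalg.lstsq(X, v[ok], rcond=None)
    seasonal = coef[1] * np.cos(ang) + coef[2] * np.sin(ang)
    out = np.full_like(v, np.nan)
    out[ok] = v[ok] - seasonal[ok]
    return out


def categorize_vitd(value):
    """Four half-open bands: [0,30), [30,50), [50,75), [75,inf)."""
    v = np.asarray(value, dtype=float)
    scalar = v.ndim == 0
    v = np.atleast_1d(v)
    if np.any(v[np.isfinite(v)] < 0):
        raise ValidationError("biomarker value cannot be negative")
    idx = np.searchsorted(_VITD_EDGES, v, side="right")
    out = np.array([VITD_CATEGORIES[i] for i in idx], dtype=object)
    out[~np.isfinite(v)] = None
    return out[0] if scalar else out


def bin_bmi(bmi) -> np.ndarray:
    b = np.asarray(bmi, dtype=float)
    out = np.where(b < 25, "lt25", np.where(b < 30, "25to29.9", "ge30")).astype(object)
    out[~np.isfinite(b)] = "unknown"
    return out


def encode_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Design matrix for the adjustment set.

    Continuous age and binary sex enter as-is; BMI is binned (<25 / 25-29.9 /
    >=30); the remaining lifestyle covariates are dummy-coded against their
    first level with missing values mapped to the "unknown" level.
    """
    cols: dict[str, np.ndarray] = {}
    cols["age"] = table["age"].to_numpy(dtype=float)
    cols["sex"] = table["sex"].to_numpy(dtype=float)

    cat_values = {"bmi_cat": (bin_bmi(table["bmi"]), BMI_LEVELS)}
    for name, levels in COVARIATE_LEVELS.items():
        if name not in table.columns:
            continue
        raw = table[name].astype(object).where(table[name].notna(), "unknown")
        bad = sorted(set(raw) - set(levels))
        if bad:
            raise ValidationError(f"unrecognized {name} levels: {bad}")
        cat_values[name] = (raw.to_numpy(dtype=object), levels)
    for name, (vals, levels) in cat_values.items():
        observed = set(vals)
        for level in levels[1:]:
            if level not in observed:
                continue
            cols[f"{name}_{level}"] = (vals == level).astype(float)
    return pd.DataFrame(cols, index=table.index)


def process_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Derive analysis phenotypes on a wide participant table.

    Adds per-wave summarized + amended BP (``sbp_w*``/``dbp_w*``), measured
    (unamended) BP, hypertension flags, the season-standardized biomarker
    (``vitd_std``, within rows where the raw value is present) and its
    category band.
    """
    out = df.copy()
    for wave in (1, 2):
        r_sbp = [f"sbp_w{wave}_r{i}" for i in (1, 2, 3)]
        r_dbp = [f"dbp_w{wave}_r{i}" for i in (1, 2, 3)]
        if r_sbp[0] not in df.columns:
            continue
        med = df[f"med_use_w{wave}"].fillna(False).astype(bool)
        sbp_m = summarize_bp_series(df[r_sbp])
        dbp_m = summarize_bp_series(df[r_dbp])
        sbp_a, dbp_a = adjust_bp_for_medication(sbp_m, dbp_m, med)
        out[f"sbp_measured_w{wave}"] = sbp_m
        out[f"dbp_measured_w{wave}"] = dbp_m
        out[f"sbp_w{wave}"] = sbp_a
        out[f"dbp_w{wave}"] = dbp_a
        hyp = define_hypertension(sbp_m, dbp_m, med)
        hyp = np.where(np.isfinite(sbp_m) & np.isfinite(dbp_m), hyp, med)
        out[f"hypertensive_w{wave}"] = hyp.astype(bool)
        if f"followup_w{wave}" in df.columns:
            lost = ~df[f"followup_w{wave}"].astype(bool)
            for c in (f"sbp_w{wave}", f"dbp_w{wave}", f"sbp_measured_w{wave}", f"dbp_measured_w{wave}"):
                out.loc[lost, c] = np.nan
    if "vitd_raw" in df.columns:
        vitd = np.full(len(df), np.nan)
        present = df["vitd_raw"].notna().to_numpy()
        if present.sum() >= 20:
            vitd[present] = season_standardize(
                df.loc[present, "vitd_raw"], df.loc[present, "day_of_year"]
            )
        out["vitd_std"] = vitd
        # standardization can push a low winter value slightly below zero;
        # the bottom band is unbounded below, so clamp for banding only
        out["vitd_category"] = categorize_vitd(np.clip(vitd, 0.0, None))
    return out


def select_prospective_sample(df: pd.DataFrame) -> pd.DataFrame:
    """Participants followed to wave 2 and normotensive at wave 1."""
    if "sbp_w2" not in df.columns or df["sbp_w2"].notna().sum() == 0:
        raise ValidationError("no wave-2 data available")
    followed = df["sbp_w2"].notna()
    baseline_hyp = df["hypertensive_w1"].astype(bool)
    keep = followed & ~baseline_hyp
    log.info(
        "prospective sample: %d followed, %d excluded for baseline hypertension, %d retained",
        int(followed.sum()),
        int((followed & baseline_hyp).sum()),
        int(keep.sum()),
    )
    return df.loc[keep]
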