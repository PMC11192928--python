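"""Externally weighted genetic risk score and instrument diagnostics."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _lm
from .errors import DegenerateInputError, PanelError, ValidationError
from .obsmodels import fit_linear, fit_logistic

log = logging.getLogger(__name__)

WEAK_F_THRESHOLD = 10.0


@dataclass(frozen=True)
class GrsVector:
    """Per-participant weighted allele score."""

    score: np.ndarray
    n_snps_used: int
    missing_imputed: int

    def __len__(self) -> int:
        return len(self.score)


@dataclass(frozen=True)
class InstrumentDiagnostics:
    f_stat: float
    r2: float
    n: int

    @property
    def weak(self) -> bool:
        return self.f_stat <= WEAK_F_THRESHOLD


def compute_grs(genotypes, panel) -> GrsVector:
    """score_i = sum_j w_j * g_ij over the panel SNPs present in ``genotypes``.

    Missing dosages are imputed to the expected dosage 2*eaf. Panel SNPs
    absent from the genotype table are dropped with a warning (no
    re-weighting); an empty intersection is an error.
    """
    if isinstance(genotypes, pd.DataFrame):
        cols = list(genotypes.columns)
        G = genotypes.to_numpy(dtype=float)
    else:
        G = np.asarray(genotypes, dtype=float)
        cols = [rec.rsid for rec in panel]
        if G.shape[1] != len(cols):
            raise ValidationError("genotype matrix width does not match panel size")
    finite = G[np.isfinite(G)]
    if finite.size and (finite.min() < 0 or finite.max() > 2):
        raise ValidationError("dosages must lie in [0, 2]")
    score = np.zeros(G.shape[0])
    used = 0
    imputed = 0
    for rec in panel:
        if rec.rsid not in cols:
            log.warning("panel SNP %s absent from genotypes; dropped", rec.rsid)
            continue
        g = G[:, cols.index(rec.rsid)].copy()
        miss = ~np.isfinite(g)
        if miss.any():
            g[miss] = 2.0 * rec.eaf
            imputed += int(miss.sum())
        score += rec.weight * g
        used += 1
    if used == 0:
        raise PanelError("no panel SNPs present in the genotype table")
    return GrsVector(score=score, n_snps_used=used, missing_imputed=imputed)


def instrument_strength(grs: GrsVector | np.ndarray, exposure) -> InstrumentDiagnostics:
    """Simple first-stage regression of exposure on the score.

    F = (n-2) * R^2 / (1 - R^2); a weak-instrument flag is raised (logged)
    when F <= 10.
    """
    score = grs.score if isinstance(grs, GrsVector) else np.asarray(grs, dtype=float)
    x = np.asarray(exposure, dtype=float)
    ok = np.isfinite(score) & np.isfinite(x)
    score, x = score[ok], x[ok]
    n = len(x)
    if n < 10:
        raise ValidationError("need at least 10 observations")
    if np.var(score) == 0:
        raise DegenerateInputError("zero score variance")
    if np.var(x) == 0:
        raise DegenerateInputError("zero exposure variance")
    fit = _lm.ols(x, _lm.add_intercept(score))
    r2 = float(fit["r2"])
    f = (n - 2) * r2 / (1.0 - r2) if r2 < 1 else float("inf")
    diag = InstrumentDiagnostics(f_stat=float(f), r2=r2, n=n)
    if diag.weak:
        log.warning("weak instrument: F = %.2f <= 10", diag.f_stat)
    return diag


def confounder_balance(grs: GrsVector | np.ndarray, covariates: pd.DataFrame) -> pd.DataFrame:
    """Regress each covariate on the score (linear; logistic for binaries).

    Returns one row per covariate column with beta, se, ci, p, n. Constant
    columns are skipped with a warning; a constant score is an error.
    """
    score = grs.score if isinstance(grs, GrsVector) else np.asarray(grs, dtype=float)
    if np.var(score) == 0:
        raise DegenerateInputError("zero score variance")
    rows = []
    for name in covariates.columns:
        y = covariates[name].to_numpy(dtype=float)
        ok = np.isfinite(y) & np.isfinite(score)
        yv, sv = y[ok], score[ok]
        uniq = np.unique(yv)
        if uniq.size < 2:
            log.warning("constant confounder %s skipped", name)
            continue
        X = pd.DataFrame({"grs": sv})
        if uniq.size == 2 and set(uniq) <= {0.0, 1.0}:
            res = fit_logistic(yv, X)["grs"]
            kind = "logistic"
        else:
            res = fit_linear(yv, X)["grs"]
            kind = "linear"
        rows.append(
            {
                "confounder": name,
                "model": kind,
                "beta": res.beta,
                "se": res.se,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "p": res.p,
                "n": res.n,
            }
        )
    return pd.DataFrame(rows)
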