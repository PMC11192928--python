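"""Synthetic cohort and summary-statistic generation.

Produces cohorts with the statistical structure the downstream analysis
assumes: independent SNP dosages under Hardy-Weinberg equilibrium, a serum
biomarker with additive genetic effects, a one-harmonic seasonal component
and shared (partly unmeasured) confounding with blood pressure; two survey
waves; antihypertensive medication whose treatment effect is exactly undone
by the +10/+5 amendment rule.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import PanelError, ValidationError
from .mr_twosample import SummaryStatSet
from .pheno import ASSAY_MAX, ASSAY_MIN, PERIOD_DAYS

log = logging.getLogger(__name__)

_VALID_BASES = {"A", "C", "G", "T"}


@dataclass(frozen=True)
class SnpRecord:
    """One instrument SNP: alleles, frequency and external per-allele weight
    (biomarker units per effect allele)."""

    rsid: str
    effect_allele: str
    other_allele: str
    eaf: float
    weight: float

    def __post_init__(self):
        if self.effect_allele not in _VALID_BASES or self.other_allele not in _VALID_BASES:
            raise PanelError(f"{self.rsid}: alleles must be one of ACGT")
        if self.effect_allele == self.other_allele:
            raise PanelError(f"{self.rsid}: effect and other allele identical")
        if not (0.0 < self.eaf < 1.0):
            raise PanelError(f"{self.rsid}: eaf must lie strictly in (0, 1)")
        if not np.isfinite(self.weight):
            raise PanelError(f"{self.rsid}: weight must be finite")


class SnpPanel:
    """Ordered collection of :class:`SnpRecord`."""

    def __init__(self, records):
        records = list(records)
        if not records:
            raise PanelError("panel must be non-empty")
        rsids = [r.rsid for r in records]
        if len(set(rsids)) != len(rsids):
            raise PanelError("duplicate rsids in panel")
        self.records = records

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    @property
    def eafs(self) -> np.ndarray:
        return np.array([r.eaf for r in self.records])

    @property
    def weights(self) -> np.ndarray:
        return np.array([r.weight for r in self.records])

    def score_variance(self) -> float:
        """Analytic variance of the weighted score under HWE independence."""
        p = self.eafs
        return float(np.sum(self.weights**2 * 2 * p * (1 - p)))

    @classmethod
    def from_tsv(cls, path) -> "SnpPanel":
        df = pd.read_csv(path, sep="\t")
        need = ["rsid", "effect_allele", "other_allele", "eaf", "weight"]
        missing = [c for c in need if c not in df.columns]
        if missing:
            raise PanelError(f"panel file missing columns: {missing}")
        return cls(
            SnpRecord(r.rsid, r.effect_allele, r.other_allele, float(r.eaf), float(r.weight))
            for r in df.itertuples()
        )

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [
                {
                    "rsid": r.rsid,
                    "effect_allele": r.effect_allele,
                    "other_allele": r.other_allele,
                    "eaf": r.eaf,
                    "weight": r.weight,
                }
                for r in self.records
            ]
        ).to_csv(path, sep="\t", index=False)


# A 19-SNP default instrument panel (synthetic identifiers; weights chosen so
# the score explains roughly 5-6% of biomarker variance in the default cohort).
_DEFAULT_PANEL_ROWS = [
    ("rs1000101", "A", "G", 0.21, 2.55),
    ("rs1000102", "C", "T", 0.28, 1.90),
    ("rs1000103", "G", "A", 0.71, 1.40),
    ("rs1000104", "T", "C", 0.35, 1.10),
    ("rs1000105", "A", "C", 0.42, 0.90),
    ("rs1000106", "G", "T", 0.30, 1.70),
    ("rs1000107", "C", "A", 0.25, 1.30),
    ("rs1000108", "T", "G", 0.64, 0.80),
    ("rs1000109", "A", "G", 0.18, 2.10),
    ("rs1000110", "C", "T", 0.33, 1.00),
    ("rs1000111", "G", "A", 0.47, 0.70),
    ("rs1000112", "T", "C", 0.55, 0.60),
    ("rs1000113", "A", "C", 0.26, 1.50),
    ("rs1000114", "G", "T", 0.39, 0.90),
    ("rs1000115", "C", "A", 0.15, 2.30),
    ("rs1000116", "T", "G", 0.68, 0.70),
    ("rs1000117", "A", "G", 0.31, 1.20),
    ("rs1000118", "C", "T", 0.24, 1.60),
    ("rs1000119", "G", "A", 0.52, 0.80),
]


def default_panel(n_snps: int = 19) -> SnpPanel:
    if not (1 <= n_snps <= len(_DEFAULT_PANEL_ROWS)):
        raise ValidationError(f"n_snps must be in 1..{len(_DEFAULT_PANEL_ROWS)}")
    return SnpPanel(SnpRecord(*row) for row in _DEFAULT_PANEL_ROWS[:n_snps])


@dataclass
class ConfounderEffect:
    on_exposure: float
    on_sbp: float
    on_dbp: float


def default_confounder_effects() -> dict[str, ConfounderEffect]:
    """Measured confounders plus an unmeasured one ("latent") that induces
    the cross-sectional bias the triangulation is designed to expose."""
    return {
        "age": ConfounderEffect(-0.05, 0.50, 0.25),
        "sex": ConfounderEffect(2.0, -5.0, -3.0),
        "bmi": ConfounderEffect(-0.50, 0.80, 0.50),
        "active": ConfounderEffect(3.0, -2.0, -1.0),
        "latent": ConfounderEffect(8.0, -1.65, -0.85),
    }


@dataclass
class SimConfig:
    """Generating parameters for a synthetic cohort.

    ``theta_sbp``/``theta_dbp`` are the true causal effects of the annual-mean
    biomarker on blood pressure (mmHg per nmol/L); default null.
    """

    n_total: int = 20000
    n_subcohort: int = 2000
    n_snps: int = 19
    theta_sbp: float = 0.0
    theta_dbp: float = 0.0
    confounder_effects: dict = field(default_factory=default_confounder_effects)
    exposure_mean: float = 51.0
    seasonal_amplitude: float = 10.0
    seasonal_phase: float = 20.0  # day-of-year of the seasonal peak
    noise_sd_exposure: float = 12.0
    noise_sd_outcome: float = 10.0
    reading_sd: float = 3.0
    sbp_mean: float = 131.0
    dbp_mean: float = 79.0
    med_model: dict = field(
        default_factory=lambda: {"intercept": -2.2, "age": 0.03, "sbp": 0.05}
    )
    pleiotropy: tuple = (0.0, 0.0, 0.0)  # (mean, sd, fraction of SNPs affected)
    followup_fraction: float = 0.75
    seed: int = 0

    def validate(self) -> None:
        if self.n_subcohort > self.n_total:
            raise ValidationError("n_subcohort cannot exceed n_total")
        if self.n_total < 1:
            raise ValidationError("n_total must be >= 1")
        for name in ("noise_sd_exposure", "noise_sd_outcome", "reading_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        mean, sd, frac = self.pleiotropy
        if sd < 0 or not (0.0 <= frac <= 1.0):
            raise ValidationError("pleiotropy must be (mean, sd>=0, fraction in [0,1])")
        if not (0.0 <= self.followup_fraction <= 1.0):
            raise ValidationError("followup_fraction must lie in [0,1]")


@dataclass
class SimulatedCohort:
    participants: pd.DataFrame
    genotypes: pd.DataFrame  # dosage matrix, columns = rsids
    truth: dict
    panel: SnpPanel


def simulate_genotypes(panel: SnpPanel, n: int, seed: int = 0) -> np.ndarray:
    """n x m dosage matrix: two Bernoulli(eaf) draws per person per SNP
    (HWE, no LD); column order matches the panel."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, panel.eafs, size=(n, len(panel))).astype(float)


def simulate_cohort(config: SimConfig, panel: SnpPanel | None = None, seed: int | None = None) -> SimulatedCohort:
    """Generate a wide participant table plus genotypes and a truth record."""
    config.validate()
    if panel is None:
        panel = default_panel(config.n_snps)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_total
    m = len(panel)

    G = rng.binomial(2, panel.eafs, size=(n, m)).astype(float)
    w = panel.weights
    genetic = G @ w
    genetic_c = genetic - 2 * panel.eafs @ w  # analytic centering

    age = rng.uniform(20, 80, n)
    sex = rng.binomial(1, 0.53, n).astype(float)
    bmi = rng.normal(26.9, 4.4, n)
    activity_lvl = rng.choice(["inactive", "low", "moderate", "high", "unknown"],
                              size=n, p=[0.19, 0.20, 0.20, 0.11, 0.30])
    active = np.isin(activity_lvl, ["low", "moderate", "high"]).astype(float)
    latent = rng.standard_normal(n)
    smoking = rng.choice(
        ["never", "former_lt10", "former_10to20", "current_10to20", "current_gt20", "unknown"],
        size=n, p=[0.43, 0.12, 0.10, 0.15, 0.08, 0.12],
    )
    alcohol = rng.choice(["never", "1to4", "ge5", "unknown"], size=n, p=[0.24, 0.58, 0.12, 0.06])
    education = rng.choice(["lt10", "10to12", "ge13", "unknown"], size=n, p=[0.33, 0.33, 0.29, 0.05])
    econ = rng.choice(["no", "yes", "unknown"], size=n, p=[0.51, 0.21, 0.28])
    batch = rng.choice(["b1", "b2"], size=n)
    pcs = rng.standard_normal((n, 20))

    conf = {
        "age": age - 50.0,
        "sex": sex - 0.53,
        "bmi": bmi - 26.9,
        "active": active - active.mean(),
        "latent": latent,
    }
    eff = config.confounder_effects
    conf_x = sum(e.on_exposure * conf[c] for c, e in eff.items() if c in conf)
    conf_sbp = sum(e.on_sbp * conf[c] for c, e in eff.items() if c in conf)
    conf_dbp = sum(e.on_dbp * conf[c] for c, e in eff.items() if c in conf)

    day = rng.integers(1, 366, n).astype(float)
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (day - config.seasonal_phase) / PERIOD_DAYS
    )
    eps = config.noise_sd_exposure * rng.standard_normal(n)
    annual_mean = config.exposure_mean + genetic_c + conf_x + eps
    exposure = np.clip(annual_mean + seasonal, ASSAY_MIN, ASSAY_MAX)

    # optional direct (pleiotropic) SNP effects on the outcomes
    pl_mean, pl_sd, pl_frac = config.pleiotropy
    pleio = np.zeros(n)
    pleio_effects = np.zeros(m)
    if pl_frac > 0 and (pl_sd > 0 or pl_mean != 0):
        affected = rng.random(m) < pl_frac
        pleio_effects = np.where(affected, rng.normal(pl_mean, pl_sd, m), 0.0)
        pleio = G @ pleio_effects

    def latent_bp(mean, theta, conf_term, drift=0.0):
        return (
            mean
            + theta * (annual_mean - config.exposure_mean)
            + conf_term
            + pleio
            + drift
            + config.noise_sd_outcome * rng.standard_normal(n)
        )

    sbp1 = latent_bp(config.sbp_mean, config.theta_sbp, conf_sbp)
    dbp1 = latent_bp(config.dbp_mean, config.theta_dbp, conf_dbp)
    sbp2 = sbp1 + 3.0 + 5.0 * rng.standard_normal(n)
    dbp2 = dbp1 + 1.5 + 3.0 * rng.standard_normal(n)

    mm = config.med_model
    logit1 = mm["intercept"] + mm["age"] * (age - 50.0) + mm["sbp"] * (sbp1 - 135.0)
    med1 = rng.random(n) < expit(logit1)
    logit2 = mm["intercept"] + mm["age"] * (age - 47.0) + mm["sbp"] * (sbp2 - 135.0)
    med2 = med1 | (rng.random(n) < expit(logit2))

    cols = {
        "id": np.arange(1, n + 1),
        "age": age,
        "sex": sex,
        "bmi": bmi,
        "smoking": smoking,
        "alcohol": alcohol,
        "activity": activity_lvl,
        "education": education,
        "econ_difficulty": econ,
        "day_of_year": day,
        "batch": batch,
    }
    for j in range(20):
        cols[f"pc{j + 1}"] = pcs[:, j]

    sub_idx = rng.choice(n, size=config.n_subcohort, replace=False)
    subcohort = np.zeros(n, dtype=bool)
    subcohort[sub_idx] = True
    vitd_raw = np.where(subcohort, exposure, np.nan)
    cols["subcohort"] = subcohort
    cols["vitd_raw"] = vitd_raw

    # medication lowers measured BP by exactly the amendment amounts, so the
    # amended values recover the latent (untreated) pressure
    for wave, (sbp_l, dbp_l, med) in enumerate(
        [(sbp1, dbp1, med1), (sbp2, dbp2, med2)], start=1
    ):
        sbp_obs = sbp_l - 10.0 * med
        dbp_obs = dbp_l - 5.0 * med
        for r in (1, 2, 3):
            cols[f"sbp_w{wave}_r{r}"] = sbp_obs + config.reading_sd * rng.standard_normal(n)
            cols[f"dbp_w{wave}_r{r}"] = dbp_obs + config.reading_sd * rng.standard_normal(n)
        cols[f"med_use_w{wave}"] = med
    followed = rng.random(n) < config.followup_fraction
    cols["followup_w2"] = followed

    participants = pd.DataFrame(cols)
    genotypes = pd.DataFrame(G, columns=panel.rsids)
    truth = {
        "theta_sbp": config.theta_sbp,
        "theta_dbp": config.theta_dbp,
        "config": asdict(config),
        "annual_mean_exposure": annual_mean,
        "latent_sbp_w1": sbp1,
        "latent_dbp_w1": dbp1,
        "pleiotropy_effects": pleio_effects,
    }
    return SimulatedCohort(participants=participants, genotypes=genotypes, truth=truth, panel=panel)


def _simple_slopes(y: np.ndarray, G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column simple-regression slope and SE of y on each dosage column."""
    n = len(y)
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = (gc**2).sum(axis=0)
    beta = gc.T @ yc / sxx
    resid_var = np.array(
        [float(np.sum((yc - beta[j] * gc[:, j]) ** 2)) / (n - 2) for j in range(G.shape[1])]
    )
    se = np.sqrt(resid_var / sxx)
    return beta, se


def make_summary_stats(
    cohort: SimulatedCohort,
    panel: SnpPanel | None = None,
    outcome: str = "sbp",
) -> SummaryStatSet:
    """Per-SNP exposure coefficients from the sub-cohort and outcome
    coefficients from the total cohort, packaged for two-sample MR.

    Monomorphic SNPs are excluded with a warning. ``outcome`` selects the
    wave-1 amended blood pressure ("sbp" or "dbp").
    """
    panel = panel or cohort.panel
    if len(panel) < 2:
        raise ValidationError("need >= 2 SNPs for a summary-stat set")
    df = cohort.participants
    G = cohort.genotypes[panel.rsids].to_numpy(dtype=float)

    sub = df["subcohort"].to_numpy(dtype=bool)
    x = df["vitd_raw"].to_numpy(dtype=float)[sub]
    Gs = G[sub]

    med = df["med_use_w1"].to_numpy(dtype=bool)
    if outcome not in ("sbp", "dbp"):
        raise ValidationError("outcome must be 'sbp' or 'dbp'")
    # observed amended BP: mean of last two readings plus the amendment
    r2 = df[f"{outcome}_w1_r2"].to_numpy(dtype=float)
    r3 = df[f"{outcome}_w1_r3"].to_numpy(dtype=float)
    amend = 10.0 if outcome == "sbp" else 5.0
    y = (r2 + r3) / 2.0 + amend * med

    keep = [j for j in range(len(panel)) if np.var(G[:, j]) > 0 and np.var(Gs[:, j]) > 0]
    dropped = [panel.rsids[j] for j in range(len(panel)) if j not in keep]
    if dropped:
        log.warning("monomorphic SNPs excluded from summary stats: %s", dropped)
    if len(keep) < 2:
        raise ValidationError("fewer than 2 polymorphic SNPs")

    bx, sx = _simple_slopes(x, Gs[:, keep])
    by, sy = _simple_slopes(y, G[:, keep])
    rows = []
    for i, j in enumerate(keep):
        rec = panel[j]
        rows.append(
            {
                "rsid": rec.rsid,
                "effect_allele": rec.effect_allele,
                "other_allele": rec.other_allele,
                "eaf": rec.eaf,
                "beta_exposure": bx[i],
                "se_exposure": sx[i],
                "beta_outcome": by[i],
                "se_outcome": sy[i],
            }
        )
    return SummaryStatSet(pd.DataFrame(rows))


def simulate_summary_stats(
    m: int = 19,
    theta: float = 0.0,
    seed: int = 0,
    se_exposure: float = 0.01,
    se_outcome: float = 0.02,
    pleiotropy_sd: float = 0.0,
    pleiotropy_mean: float = 0.0,
) -> SummaryStatSet:
    """Direct summary-statistic simulator for estimator calibration studies.

    True exposure effects are drawn uniform in [0.5, 2]; outcome effects are
    theta * beta_x plus optional per-SNP direct effects, observed with the
    given standard errors.
    """
    rng = np.random.default_rng(seed)
    bx_true = rng.uniform(0.5, 2.0, m)
    alpha = rng.normal(pleiotropy_mean, pleiotropy_sd, m) if (pleiotropy_sd > 0 or pleiotropy_mean != 0) else np.zeros(m)
    bx = bx_true + se_exposure * rng.standard_normal(m)
    by = theta * bx_true + alpha + se_outcome * rng.standard_normal(m)
    bases = ["A", "C", "G", "T"]
    rows = []
    for j in range(m):
        ea = bases[j % 4]
        oa = bases[(j + 1) % 4]
        rows.append(
            {
                "rsid": f"rs{2000000 + j}",
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": float(rng.uniform(0.1, 0.9)),
                "beta_exposure": bx[j],
                "se_exposure": se_exposure,
                "beta_outcome": by[j],
                "se_outcome": se_outcome,
            }
        )
    return SummaryStatSet(pd.DataFrame(rows))


def plant_outlier(stats: SummaryStatSet, index: int, offset: float) -> SummaryStatSet:
    """Return a copy with beta_outcome at ``index`` shifted by ``offset``."""
    if not (0 <= index < len(stats)):
        raise ValidationError(f"index {index} out of range for {len(stats)} SNPs")
    df = stats.df.copy()
    df.loc[index, "beta_outcome"] += offset
    return SummaryStatSet(df)


def write_cohort(cohort: SimulatedCohort, outdir, write_vcf: bool = False) -> dict:
    """Write phenotypes, genotype dosages and the panel as TSV (optionally a
    minimal GT-only VCF); returns the path map."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "phenotypes": outdir / "phenotypes.tsv",
        "genotypes": outdir / "genotypes.tsv",
        "panel": outdir / "panel.tsv",
    }
    cohort.participants.to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.10g")
    cohort.genotypes.to_csv(paths["genotypes"], sep="\t", index=False, float_format="%g")
    cohort.panel.to_tsv(paths["panel"])
    if write_vcf:
        paths["vcf"] = outdir / "genotypes.vcf"
        _write_minimal_vcf(cohort, paths["vcf"])
    return paths


def _write_minimal_vcf(cohort: SimulatedCohort, path) -> None:
    ids = [f"S{j}" for j in cohort.participants["id"]]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        G = cohort.genotypes.to_numpy(dtype=float)
        gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, rec in enumerate(cohort.panel):
            gts = [gt_codes.get(int(round(g)), "./.") for g in G[:, j]]
            fh.write(
                f"1\t{1000 + j}\t{rec.rsid}\t{rec.other_allele}\t{rec.effect_allele}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )
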