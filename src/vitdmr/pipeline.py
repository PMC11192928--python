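"""End-to-end orchestration of the triangulation analysis.

Simulates (or loads) a cohort, then runs the observational, one-sample MR,
two-sample MR and non-linear MR stages, writing per-stage TSVs, a combined
summary table and a JSON metadata record. A single seed fans out to
deterministic per-stage child seeds so every stage is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, grs, mr_onesample, mr_twosample, nlmr, obsmodels, pheno, simdata
from .errors import ValidationError

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclasses.dataclass
class RunConfig:
    """Pipeline configuration: either a simulation spec or input paths."""

    outdir: str = "vitdmr_out"
    seed: int = 0
    sim: dict | None = None
    inputs: dict | None = None  # phenotypes / genotypes / panel TSV paths
    scale: float = 25.0
    ivw_model: str = "random"
    presso_sims: int = 1000
    strata_k: int = 4
    nlmr_outcome: str = "sbp_w1"
    adjust: list | None = None

    def __post_init__(self):
        if (self.sim is None) == (self.inputs is None):
            raise ValidationError("exactly one of 'sim' and 'inputs' must be set")

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _child_seeds(seed: int, n: int = 8) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def _load_cohort(config: RunConfig) -> simdata.SimulatedCohort:
    if config.sim is not None:
        sim_cfg = simdata.SimConfig(**config.sim)
        return simdata.simulate_cohort(sim_cfg, seed=_child_seeds(config.seed)[0])
    paths = config.inputs
    for key in ("phenotypes", "genotypes", "panel"):
        if key not in paths:
            raise ValidationError(f"inputs must provide a '{key}' path")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"input file not found: {paths[key]}")
    panel = simdata.SnpPanel.from_tsv(paths["panel"])
    participants = pd.read_csv(paths["phenotypes"], sep="\t")
    genotypes = pd.read_csv(paths["genotypes"], sep="\t")
    return simdata.SimulatedCohort(
        participants=participants, genotypes=genotypes, truth={}, panel=panel
    )


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns {"errors": {...}, "outputs": {...}, ...}.

    Stage failures are recorded (partial report) rather than aborting the
    whole run; callers decide the exit status.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _child_seeds(config.seed)
    errors: dict[str, str] = {}
    outputs: dict[str, str] = {}
    summary_rows: list[dict] = []

    cohort = _load_cohort(config)
    processed = pheno.process_phenotypes(cohort.participants)
    score = grs.compute_grs(cohort.genotypes, cohort.panel)

    def stage(name, fn):
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - partial report by design
            log.error("stage %s failed: %s", name, exc)
            errors[name] = f"{type(exc).__name__}: {exc}"

    def obs_stage():
        cs = obsmodels.cross_sectional_analysis(processed)
        _write(cs, outdir / "cross_sectional.tsv")
        outputs["cross_sectional"] = "cross_sectional.tsv"
        pr = obsmodels.prospective_analysis(processed)
        _write(pr, outdir / "prospective.tsv")
        outputs["prospective"] = "prospective.tsv"
        for frame, design in ((cs, "cross-sectional"), (pr, "prospective")):
            for _, r in frame.iterrows():
                if r["term"] == "per_25_increase":
                    summary_rows.append(
                        {
                            "design": design,
                            "outcome": r["outcome"],
                            "estimate": np.exp(r["beta"]) if r["scale"] == "log-odds" else r["beta"],
                            "ci_low": np.exp(r["ci_low"]) if r["scale"] == "log-odds" else r["ci_low"],
                            "ci_high": np.exp(r["ci_high"]) if r["scale"] == "log-odds" else r["ci_high"],
                            "p": r["p"],
                            "scale": "OR per 25" if r["scale"] == "log-odds" else "mmHg per 25",
                        }
                    )

    def grs_stage():
        sub = processed.loc[processed["vitd_std"].notna()]
        sub_score = score.score[processed["vitd_std"].notna().to_numpy()]
        diag = grs.instrument_strength(sub_score, sub["vitd_std"])
        covars = pheno.encode_covariates(sub)
        balance = grs.confounder_balance(sub_score, covars)
        _write(balance, outdir / "grs_confounder_balance.tsv")
        diag_df = pd.DataFrame(
            [{"f_stat": diag.f_stat, "r2": diag.r2, "n": diag.n, "weak": diag.weak,
              "n_snps_used": score.n_snps_used, "missing_imputed": score.missing_imputed}]
        )
        _write(diag_df, outdir / "grs_diagnostics.tsv")
        outputs["grs_diagnostics"] = "grs_diagnostics.tsv"
        outputs["grs_confounder_balance"] = "grs_confounder_balance.tsv"

    def mr1_stage():
        res = mr_onesample.one_sample_mr(processed, score, adjust=config.adjust, scale=config.scale)
        _write(res, outdir / "mr_onesample.tsv")
        outputs["mr_onesample"] = "mr_onesample.tsv"
        for _, r in res.iterrows():
            summary_rows.append(
                {
                    "design": "one-sample MR",
                    "outcome": r["outcome"],
                    "estimate": r["estimate"],
                    "ci_low": r["ci_low"],
                    "ci_high": r["ci_high"],
                    "p": r["p"],
                    "scale": ("OR per 25" if r["measure"] == "OR" else "mmHg per 25"),
                }
            )

    def mr2s_stage():
        frames = []
        for outcome in ("sbp", "dbp"):
            stats_set = simdata.make_summary_stats(cohort, outcome=outcome)
            res = mr_twosample.run_all_methods(
                stats_set,
                seed=seeds[3],
                ivw_model=config.ivw_model,
                presso_sims=config.presso_sims,
            )
            res.insert(0, "outcome", outcome)
            frames.append(res)
            stats_set.to_tsv(outdir / f"summary_stats_{outcome}.tsv")
            ivw_row = res.loc[res["method"] == f"ivw-{config.ivw_model}"].iloc[0]
            summary_rows.append(
                {
                    "design": "two-sample MR (IVW)",
                    "outcome": outcome,
                    "estimate": ivw_row["beta"] * config.scale,
                    "ci_low": ivw_row["ci_low"] * config.scale,
                    "ci_high": ivw_row["ci_high"] * config.scale,
                    "p": ivw_row["p"],
                    "scale": "mmHg per 25",
                }
            )
        all_res = pd.concat(frames, ignore_index=True)
        _write(all_res, outdir / "mr_twosample.tsv")
        outputs["mr_twosample"] = "mr_twosample.tsv"

    def nlmr_stage():
        sub_mask = processed["vitd_std"].notna().to_numpy()
        sub = processed.loc[sub_mask]
        sub_score = score.score[sub_mask]
        x = sub["vitd_std"].to_numpy(dtype=float)
        y = sub[config.nlmr_outcome].to_numpy(dtype=float)
        frames = []
        for method, fn in (
            ("residual", nlmr.residual_stratify),
            ("doubly-ranked", nlmr.doubly_ranked_stratify),
        ):
            labels = fn(sub_score, x, config.strata_k)
            ests = nlmr.stratum_estimates(labels, sub_score, x, y)
            table = nlmr.stratum_table(ests)
            table.insert(0, "method", method)
            q_p, trend_p = nlmr.nonlinearity_test(ests)
            table["q_p"] = q_p
            table["trend_p"] = trend_p
            frames.append(table)
        _write(pd.concat(frames, ignore_index=True), outdir / "nlmr.tsv")
        outputs["nlmr"] = "nlmr.tsv"

    stage("observational", obs_stage)
    stage("grs", grs_stage)
    stage("mr_onesample", mr1_stage)
    stage("mr_twosample", mr2s_stage)
    stage("nlmr", nlmr_stage)

    summary = pd.DataFrame(summary_rows)
    _write(summary, outdir / "summary.tsv")
    outputs["summary"] = "summary.tsv"

    meta = {
        "seed": config.seed,
        "child_seeds": seeds,
        "version": __version__,
        "settings": {
            "scale": config.scale,
            "ivw_model": config.ivw_model,
            "presso_sims": config.presso_sims,
            "strata_k": config.strata_k,
            "nlmr_outcome": config.nlmr_outcome,
        },
        "sim": config.sim,
        "inputs": config.inputs,
        "errors": errors,
        "outputs": outputs,
    }
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True, default=str)
    return meta
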