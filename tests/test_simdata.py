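import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitdmr import pheno, simdata
from vitdmr.errors import PanelError, ValidationError
from vitdmr.simdata import SimConfig, SnpPanel, SnpRecord


def null_config(**kw):
    """Config with confounding and noise switched off unless overridden."""
    defaults = dict(
        n_total=500,
        n_subcohort=200,
        confounder_effects={},
        seasonal_amplitude=0.0,
        noise_sd_exposure=0.0,
        noise_sd_outcome=0.0,
        reading_sd=0.0,
        med_model={"intercept": -50.0, "age": 0.0, "sbp": 0.0},
    )
    defaults.update(kw)
    return SimConfig(**defaults)


class TestSnpRecord:
    def test_rejects_bad_eaf(self):
        with pytest.raises(PanelError):
            SnpRecord("rs1", "A", "G", 0.0, 1.0)
        with pytest.raises(PanelError):
            SnpRecord("rs1", "A", "G", 1.0, 1.0)

    def test_rejects_identical_alleles(self):
        with pytest.raises(PanelError):
            SnpRecord("rs1", "A", "A", 0.5, 1.0)

    def test_rejects_nonfinite_weight(self):
        with pytest.raises(PanelError):
            SnpRecord("rs1", "A", "G", 0.5, float("nan"))

    def test_rejects_non_acgt(self):
        with pytest.raises(PanelError):
            SnpRecord("rs1", "X", "G", 0.5, 1.0)


class TestPanel:
    def test_duplicate_rsids_rejected(self):
        rec = SnpRecord("rs1", "A", "G", 0.5, 1.0)
        with pytest.raises(PanelError):
            SnpPanel([rec, rec])

    def test_tsv_roundtrip(self, panel, tmp_path):
        path = tmp_path / "panel.tsv"
        panel.to_tsv(path)
        back = SnpPanel.from_tsv(path)
        assert back.rsids == panel.rsids
        np.testing.assert_allclose(back.weights, panel.weights)


class TestSimulateGenotypes:
    def test_high_eaf_gives_mostly_twos(self):
        p = SnpPanel([SnpRecord("rs1", "A", "G", 0.999, 1.0)])
        G = simdata.simulate_genotypes(p, 10, seed=0)
        assert G.shape == (10, 1)
        assert G.mean() > 1.9

    def test_binomial_mean_oracle(self):
        # mean dosage 2*0.3 = 0.6, var 2*0.3*0.7 = 0.42
        p = SnpPanel([SnpRecord("rs1", "A", "G", 0.3, 1.0)])
        G = simdata.simulate_genotypes(p, 10_000, seed=1)
        tol = 3 * np.sqrt(0.42 / 10_000)
        assert abs(G.mean() - 0.6) < tol

    def test_same_seed_identical(self, panel):
        a = simdata.simulate_genotypes(panel, 100, seed=5)
        b = simdata.simulate_genotypes(panel, 100, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_n_zero_rejected(self, panel):
        with pytest.raises(ValidationError):
            simdata.simulate_genotypes(panel, 0)

    def test_column_means_match_2eaf(self, panel):
        G = simdata.simulate_genotypes(panel, 20_000, seed=2)
        expect = 2 * panel.eafs
        sd = np.sqrt(2 * panel.eafs * (1 - panel.eafs) / 20_000)
        assert np.all(np.abs(G.mean(axis=0) - expect) < 4 * sd)


class TestSimulateCohort:
    def test_subcohort_bigger_than_total_rejected(self):
        with pytest.raises(ValidationError):
            simdata.simulate_cohort(SimConfig(n_total=10, n_subcohort=11))

    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_total=300, n_subcohort=100)
        a = simdata.simulate_cohort(cfg, seed=3)
        b = simdata.simulate_cohort(cfg, seed=3)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        pd.testing.assert_frame_equal(a.genotypes, b.genotypes)

    def test_serialization_roundtrip_identical(self, tmp_path):
        cfg = SimConfig(n_total=200, n_subcohort=50)
        for run in ("a", "b"):
            c = simdata.simulate_cohort(cfg, seed=9)
            simdata.write_cohort(c, tmp_path / run)
        for name in ("phenotypes.tsv", "genotypes.tsv", "panel.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_exposure_respects_assay_range(self):
        cfg = SimConfig(
            n_total=5000, n_subcohort=5000, seasonal_amplitude=150.0, noise_sd_exposure=80.0
        )
        c = simdata.simulate_cohort(cfg, seed=4)
        v = c.participants["vitd_raw"]
        assert v.min() >= pheno.ASSAY_MIN and v.max() <= pheno.ASSAY_MAX

    def test_missingness_pattern(self):
        cfg = SimConfig(n_total=500, n_subcohort=120)
        c = simdata.simulate_cohort(cfg, seed=5)
        df = c.participants
        assert df.loc[df["subcohort"], "vitd_raw"].notna().all()
        assert df.loc[~df["subcohort"], "vitd_raw"].isna().all()
        assert df["subcohort"].sum() == 120

    def test_no_seasonality_when_amplitude_zero(self):
        cfg = SimConfig(n_total=4000, n_subcohort=4000, seasonal_amplitude=0.0)
        c = simdata.simulate_cohort(cfg, seed=6)
        d = c.participants["day_of_year"].to_numpy()
        v = c.participants["vitd_raw"].to_numpy()
        ang = 2 * np.pi * d / 365.25
        for basis in (np.cos(ang), np.sin(ang)):
            r, p = stats.pearsonr(basis, v)
            assert p > 1e-4

    def test_noiseless_limit_outcome_linear_in_annual_mean(self):
        cfg = null_config(theta_sbp=-0.07)
        c = simdata.simulate_cohort(cfg, seed=7)
        x = c.truth["annual_mean_exposure"]
        y = c.truth["latent_sbp_w1"]
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(-0.07, abs=1e-10)

    def test_null_with_confounding_biases_observational_not_grs(self):
        # exposure-outcome correlated through confounding; score independent
        corr_xy, corr_g = [], []
        for r in range(25):
            cfg = SimConfig(n_total=2000, n_subcohort=2000)
            c = simdata.simulate_cohort(cfg, seed=100 + r)
            x = c.truth["annual_mean_exposure"]
            y = c.truth["latent_sbp_w1"]
            g = c.genotypes.to_numpy() @ c.panel.weights
            lat = c.participants["bmi"]  # measured confounder
            corr_xy.append(stats.pearsonr(x, y)[0])
            corr_g.append(stats.pearsonr(g, lat)[0])
        assert np.mean(corr_xy) < -0.05  # confounding induces association
        assert abs(np.mean(corr_g)) < 3 * np.std(corr_g) / np.sqrt(25)


class TestSummaryStats:
    def test_noiseless_betas_recover_weights(self):
        # outcome noise kept so outcome-side SEs are well defined; the
        # exposure side stays noiseless
        cfg = null_config(n_total=6000, n_subcohort=6000, noise_sd_outcome=5.0)
        c = simdata.simulate_cohort(cfg, seed=8)
        ss = simdata.make_summary_stats(c)
        w = c.panel.weights
        p = c.panel.eafs
        other_var = np.array([c.panel.score_variance() - w[j] ** 2 * 2 * p[j] * (1 - p[j])
                              for j in range(len(w))])
        se = np.sqrt(other_var / (6000 * 2 * p * (1 - p)))
        assert np.all(np.abs(ss.beta_exposure - w) < 4 * se + 1e-9)

    def test_null_outcome_effects_jointly_zero(self):
        cfg = SimConfig(n_total=8000, n_subcohort=2000)
        c = simdata.simulate_cohort(cfg, seed=9)
        ss = simdata.make_summary_stats(c)
        chi2 = np.sum((ss.beta_outcome / ss.se_outcome) ** 2)
        p = stats.chi2.sf(chi2, len(ss))
        assert p > 1e-4

    def test_monomorphic_snp_excluded(self):
        base = simdata.default_panel(4)
        rare = simdata.SnpPanel(
            list(base.records) + [SnpRecord("rs_rare", "A", "G", 1e-5, 1.0)]
        )
        cfg = SimConfig(n_total=300, n_subcohort=100, n_snps=5)
        c = simdata.simulate_cohort(cfg, panel=rare, seed=10)
        assert c.genotypes["rs_rare"].var() == 0  # seed chosen: all-zero column
        ss = simdata.make_summary_stats(c)
        assert "rs_rare" not in set(ss.df["rsid"])


class TestPlantOutlier:
    def test_zero_offset_identity(self):
        ss = simdata.simulate_summary_stats(m=6, seed=0)
        assert simdata.plant_outlier(ss, 2, 0.0) == ss

    def test_offsets_compose_additively(self):
        ss = simdata.simulate_summary_stats(m=6, seed=0)
        once = simdata.plant_outlier(ss, 1, 0.3)
        twice = simdata.plant_outlier(once, 1, 0.2)
        direct = simdata.plant_outlier(ss, 1, 0.5)
        np.testing.assert_allclose(twice.beta_outcome, direct.beta_outcome)

    def test_out_of_range_rejected(self):
        ss = simdata.simulate_summary_stats(m=6, seed=0)
        with pytest.raises(ValidationError):
            simdata.plant_outlier(ss, 6, 1.0)


def test_score_variance_formula_matches_simulation(panel):
    G = simdata.simulate_genotypes(panel, 50_000, seed=11)
    observed = (G @ panel.weights).var()
    analytic = panel.score_variance()
    # MC error of a variance estimate ~ var * sqrt(2/n)
    assert abs(observed - analytic) < 3 * analytic * np.sqrt(2 / 50_000)


def test_minimal_vcf_output(tmp_path):
    cfg = SimConfig(n_total=30, n_subcohort=10)
    c = simdata.simulate_cohort(cfg, seed=12)
    paths = simdata.write_cohort(c, tmp_path, write_vcf=True)
    lines = paths["vcf"].read_text().splitlines()
    assert lines[0] == "##fileformat=VCFv4.2"
    data = [l for l in lines if not l.startswith("#")]
    assert len(data) == len(c.panel)
    assert data[0].split("\t")[9] in {"0/0", "0/1", "1/1"}
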