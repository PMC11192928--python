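import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from vitdmr import mr_twosample, simdata
from vitdmr.errors import ValidationError
from vitdmr.mr_twosample import SummaryStatSet, cochran_q, egger, harmonize, ivw, mr_presso, weighted_median


def make_set(bx, by, sx=None, sy=None):
    m = len(bx)
    sx = sx if sx is not None else np.full(m, 0.01)
    sy = sy if sy is not None else np.full(m, 0.05)
    bases = [("A", "C"), ("G", "T"), ("C", "A"), ("T", "G")]
    return SummaryStatSet(
        pd.DataFrame(
            {
                "rsid": [f"rs{i}" for i in range(m)],
                "effect_allele": [bases[i % 4][0] for i in range(m)],
                "other_allele": [bases[i % 4][1] for i in range(m)],
                "eaf": np.linspace(0.2, 0.8, m),
                "beta_exposure": bx,
                "se_exposure": sx,
                "beta_outcome": by,
                "se_outcome": sy,
            }
        )
    )


def single_trait(rsids, ea, oa, eaf, beta, se):
    return pd.DataFrame(
        {
            "rsid": rsids,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
        }
    )


class TestSummaryStatSet:
    def test_duplicate_rsids_rejected(self):
        df = make_set([1.0, 1.0], [0.1, 0.1]).df
        df["rsid"] = ["rs0", "rs0"]
        with pytest.raises(ValidationError):
            SummaryStatSet(df)

    def test_nonpositive_se_rejected(self):
        df = make_set([1.0, 1.0], [0.1, 0.1]).df
        df.loc[0, "se_outcome"] = 0.0
        with pytest.raises(ValidationError):
            SummaryStatSet(df)

    def test_tsv_roundtrip(self, tmp_path):
        ss = simdata.simulate_summary_stats(m=8, seed=3)
        ss.to_tsv(tmp_path / "ss.tsv")
        back = SummaryStatSet.from_tsv(tmp_path / "ss.tsv")
        np.testing.assert_allclose(back.beta_exposure, ss.beta_exposure, rtol=1e-9)


class TestHarmonize:
    def test_identity_when_aligned(self):
        exp = single_trait(["rs1", "rs2"], ["A", "G"], ["C", "T"], [0.3, 0.4], [1.0, 0.8], [0.1, 0.1])
        out = single_trait(["rs1", "rs2"], ["A", "G"], ["C", "T"], [0.3, 0.4], [0.2, 0.1], [0.05, 0.05])
        h = harmonize(exp, out)
        np.testing.assert_allclose(h.beta_outcome, [0.2, 0.1])

    def test_swapped_alleles_flip_sign(self):
        exp = single_trait(["rs1", "rs2"], ["A", "G"], ["C", "T"], [0.3, 0.4], [1.0, 0.8], [0.1, 0.1])
        out = single_trait(["rs1", "rs2"], ["C", "T"], ["A", "G"], [0.7, 0.6], [0.2, 0.1], [0.05, 0.05])
        h = harmonize(exp, out)
        np.testing.assert_allclose(h.beta_outcome, [-0.2, -0.1])

    def test_palindromic_intermediate_dropped(self):
        exp = single_trait(["rs1", "rs2", "rs3"], ["A", "A", "G"], ["T", "T", "C"],
                           [0.50, 0.20, 0.4], [1.0, 0.9, 0.8], [0.1, 0.1, 0.1])
        out = single_trait(["rs1", "rs2", "rs3"], ["A", "A", "G"], ["T", "T", "C"],
                           [0.50, 0.20, 0.4], [0.2, 0.1, 0.3], [0.05, 0.05, 0.05])
        h = harmonize(exp, out)
        assert list(h.df["rsid"]) == ["rs2", "rs3"]  # rs1 eaf 0.5 dropped

    def test_palindromic_frequency_alignment(self):
        # outcome frequency on the other side of 0.5 -> flipped
        exp = single_trait(["rs1", "rs2", "rs3"], "A", "T", [0.2, 0.2, 0.3], [1.0, 1.0, 1.0], 0.1)
        out = single_trait(["rs1", "rs2", "rs3"], "A", "T", [0.8, 0.2, 0.3], [0.5, 0.5, 0.5], 0.05)
        h = harmonize(exp, out)
        assert h.df.loc[h.df.rsid == "rs1", "beta_outcome"].iloc[0] == pytest.approx(-0.5)
        assert h.df.loc[h.df.rsid == "rs2", "beta_outcome"].iloc[0] == pytest.approx(0.5)

    def test_irreconcilable_dropped(self):
        exp = single_trait(["rs1", "rs2"], ["A", "G"], ["C", "T"], [0.3, 0.4], [1.0, 0.8], [0.1, 0.1])
        out = single_trait(["rs1", "rs2"], ["A", "G"], ["G", "T"], [0.3, 0.4], [0.2, 0.1], [0.05, 0.05])
        h = harmonize(exp, out)
        assert list(h.df["rsid"]) == ["rs2"]

    def test_too_little_overlap_rejected(self):
        exp = single_trait(["rs1", "rs2"], "A", "C", 0.3, 1.0, 0.1)
        out = single_trait(["rsX", "rsY"], "A", "C", 0.3, 0.2, 0.05)
        with pytest.raises(ValidationError):
            harmonize(exp, out)


class TestIvw:
    def test_single_snp_equals_wald_ratio(self):
        ss = make_set([0.8], [0.2])
        res = ivw(ss)
        assert res.beta == pytest.approx(0.25)
        assert res.se == pytest.approx(0.05 / 0.8)

    def test_exact_shared_ratio(self):
        bx = np.array([0.5, 1.0, 1.5, 2.0])
        ss = make_set(bx, 0.3 * bx)
        res = ivw(ss)
        assert res.beta == pytest.approx(0.3, abs=1e-12)
        assert res.q_stat == pytest.approx(0.0, abs=1e-20)

    def test_matches_weighted_ls_oracle(self, rng):
        bx = rng.uniform(0.5, 2, 5)
        by = rng.normal(0.2 * bx, 0.1)
        sy = rng.uniform(0.02, 0.1, 5)
        ss = make_set(bx, by, sy=sy)
        w = 1 / sy**2
        oracle = math.fsum(w * bx * by) / math.fsum(w * bx * bx)
        assert ivw(ss, model="fixed").beta == pytest.approx(oracle, abs=1e-10)

    def test_fixed_se_never_exceeds_random(self, rng):
        for r in range(20):
            rg = np.random.default_rng(r)
            bx = rg.uniform(0.5, 2, 8)
            by = rg.normal(0.1 * bx, 0.2)
            ss = make_set(bx, by, sy=rg.uniform(0.02, 0.2, 8))
            assert ivw(ss, model="fixed").se <= ivw(ss, model="random").se + 1e-15

    def test_snp_order_and_signflip_invariance(self, rng):
        bx = rng.uniform(0.5, 2, 6)
        by = rng.normal(0.3 * bx, 0.1)
        sy = rng.uniform(0.02, 0.1, 6)
        ss = make_set(bx, by, sy=sy)
        perm = rng.permutation(6)
        ss_perm = make_set(bx[perm], by[perm], sy=sy[perm])
        bx2, by2 = bx.copy(), by.copy()
        bx2[0] *= -1
        by2[0] *= -1
        ss_flip = make_set(bx2, by2, sy=sy)
        for other in (ss_perm, ss_flip):
            assert ivw(other).beta == pytest.approx(ivw(ss).beta, rel=1e-12)

    def test_bad_model_rejected(self):
        with pytest.raises(ValidationError):
            ivw(make_set([1.0, 1.0], [0.1, 0.2]), model="bogus")


class TestEgger:
    def test_line_through_origin(self):
        bx = np.array([0.5, 1.0, 1.5, 2.0])
        res = egger(make_set(bx, 0.4 * bx))
        assert res.beta == pytest.approx(0.4, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-10)

    def test_constant_offset_moves_intercept_only(self):
        bx = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        base = egger(make_set(bx, 0.4 * bx + np.array([0.01, -0.02, 0.0, 0.02, -0.01])))
        shifted = egger(make_set(bx, 0.4 * bx + np.array([0.01, -0.02, 0.0, 0.02, -0.01]) + 0.3))
        assert shifted.beta == pytest.approx(base.beta, rel=1e-9)
        assert shifted.intercept == pytest.approx(base.intercept + 0.3, rel=1e-9)

    def test_matches_wls_oracle(self, rng):
        bx = rng.uniform(0.5, 2, 7)
        by = rng.normal(0.2 * bx + 0.05, 0.1)
        sy = rng.uniform(0.02, 0.1, 7)
        ss = make_set(bx, by, sy=sy)
        w = 1 / sy**2
        sw, swx = math.fsum(w), math.fsum(w * bx)
        swxx, swy, swxy = math.fsum(w * bx * bx), math.fsum(w * by), math.fsum(w * bx * by)
        det = sw * swxx - swx**2
        slope_oracle = (sw * swxy - swx * swy) / det
        icpt_oracle = (swxx * swy - swx * swxy) / det
        res = egger(ss)
        assert res.beta == pytest.approx(slope_oracle, abs=1e-10)
        assert res.intercept == pytest.approx(icpt_oracle, abs=1e-10)

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValidationError):
            egger(make_set([1.0, 1.2], [0.1, 0.2]))


def brute_force_weighted_median(ratios, weights):
    """Independent oracle: cumulative mid-weight interpolation."""
    weights = np.asarray(weights, dtype=float)
    total = weights.sum()  # reduce in original order (bitwise-stable vs impl)
    order = np.argsort(ratios)
    r = np.asarray(ratios, dtype=float)[order]
    w = weights[order] / total
    cum = np.cumsum(w) - w / 2
    for j in range(len(r) - 1):
        if cum[j] == 0.5:
            return r[j]
        if cum[j] < 0.5 < cum[j + 1]:
            return r[j] + (r[j + 1] - r[j]) * (0.5 - cum[j]) / (cum[j + 1] - cum[j])
    if cum[-1] == 0.5:
        return r[-1]
    return r[0] if cum[0] >= 0.5 else r[-1]


class TestWeightedMedian:
    def test_three_equal_weights(self):
        ss = make_set([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert weighted_median(ss, n_boot=100, seed=0).beta == pytest.approx(2.0)

    def test_majority_weight_snp_returned(self):
        # middle-ratio SNP carries 60% of the weight
        bx = np.array([1.0, np.sqrt(3.0), 1.0])
        by = np.array([1.0, 2.0 * np.sqrt(3.0), 3.0])
        ss = make_set(bx, by, sy=np.full(3, 0.05))
        w = (bx / 0.05) ** 2
        assert w[1] / w.sum() == pytest.approx(0.6, abs=1e-12)
        assert weighted_median(ss, n_boot=100, seed=0).beta == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, rng):
        bx = rng.uniform(0.5, 2, 5)
        by = rng.normal(0.3 * bx, 0.3)
        sy = rng.uniform(0.02, 0.1, 5)
        ss = make_set(bx, by, sy=sy)
        oracle = brute_force_weighted_median(by / bx, (bx / sy) ** 2)
        assert weighted_median(ss, n_boot=100, seed=0).beta == pytest.approx(oracle, abs=1e-12)

    def test_bootstrap_seeded(self):
        ss = simdata.simulate_summary_stats(m=10, theta=0.1, seed=5)
        a = weighted_median(ss, n_boot=200, seed=11)
        b = weighted_median(ss, n_boot=200, seed=11)
        assert a.se == b.se

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValidationError):
            weighted_median(make_set([1.0, 1.2], [0.1, 0.2]))


class TestCochranQ:
    def test_identical_ratios(self):
        bx = np.array([0.5, 1.0, 2.0])
        ss = make_set(bx, 0.7 * bx)
        q, df, p = cochran_q(ss, 0.7)
        assert q == pytest.approx(0.0, abs=1e-18)
        assert (df, p) == (2, 1.0)

    def test_two_snp_hand_algebra(self):
        # equal first-order ratio SEs sigma; ratios differ by d
        # IVW estimate is the midpoint -> Q = d^2 / (2 sigma^2)
        sigma, d = 0.2, 0.5
        bx = np.array([1.0, 1.0])
        by = np.array([0.3, 0.3 + d])
        ss = make_set(bx, by, sy=np.full(2, sigma))
        est = ivw(ss, model="fixed").beta
        q, df, p = cochran_q(ss, est)
        assert q == pytest.approx(d**2 / (2 * sigma**2), rel=1e-10)

    def test_homogeneous_simulation_rejects_at_nominal_rate(self):
        rejections = 0
        reps = 500
        for r in range(reps):
            ss = simdata.simulate_summary_stats(m=15, theta=0.2, seed=4000 + r,
                                                se_exposure=0.001, se_outcome=0.05)
            est = ivw(ss, model="fixed").beta
            _, _, p = cochran_q(ss, est)
            rejections += p < 0.05
        assert 0.02 <= rejections / reps <= 0.10


class TestMrPresso:
    def test_no_outliers_on_ivw_line(self):
        bx = np.linspace(0.5, 2, 8)
        ss = make_set(bx, 0.3 * bx)
        res = mr_presso(ss, n_sim=300, seed=0)
        assert res.outliers == ()
        assert res.global_p > 0.5

    def test_planted_outlier_flagged_and_corrected(self):
        ss = simdata.simulate_summary_stats(m=12, theta=0.1, seed=9)
        bad = simdata.plant_outlier(ss, 4, 10 * ss.se_outcome[4])
        res = mr_presso(bad, n_sim=500, seed=1)
        assert 4 in res.outliers
        corrected_oracle = ivw(bad.drop(res.outliers), model="random")
        assert res.beta == corrected_oracle.beta  # exact equality by definition
        assert res.distortion_p is not None

    def test_too_few_snps_rejected(self):
        with pytest.raises(ValidationError):
            mr_presso(make_set([1.0, 1.0, 1.0], [0.1, 0.2, 0.3]))

    def test_small_nsim_rejected(self):
        ss = simdata.simulate_summary_stats(m=6, seed=2)
        with pytest.raises(ValidationError):
            mr_presso(ss, n_sim=50)


class TestRunAll:
    def test_contains_all_methods(self):
        ss = simdata.simulate_summary_stats(m=10, theta=0.0, seed=8)
        res = mr_twosample.run_all_methods(ss, seed=1, presso_sims=200, n_boot=100)
        assert {"ivw-random", "egger", "weighted-median", "mr-presso"} <= set(res["method"])
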