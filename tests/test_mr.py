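"""Mendelian randomization estimators and sensitivity battery."""

import numpy as np
import pandas as pd
import pytest

from comorbigen import mr
from comorbigen.simulate import ArchitectureConfig, TraitSpec, simulate_study


def make_instruments(bx, by, sx=0.01, sy=0.01, n=1e5):
    L = len(bx)
    sx = np.full(L, sx) if np.ndim(sx) == 0 else np.asarray(sx)
    sy = np.full(L, sy) if np.ndim(sy) == 0 else np.asarray(sy)
    return mr.InstrumentSet("X", "Y", pd.DataFrame({
        "SNP": [f"rs{i}" for i in range(L)],
        "beta_exp": np.asarray(bx, float), "se_exp": sx,
        "beta_out": np.asarray(by, float), "se_out": sy,
        "n_exp": n, "n_out": n}))


class TestSteiger:
    def test_exposure_stronger_retained(self):
        inst = make_instruments([0.1], [0.01], sx=0.01, sy=0.01)
        out = mr.steiger_filter(inst)
        assert len(out) == 1 and out.steiger_removed == 0

    def test_outcome_stronger_removed(self):
        inst = make_instruments([0.01, 0.1], [0.1, 0.05], sx=0.01, sy=0.01)
        out = mr.steiger_filter(inst)
        assert out.steiger_removed == 1
        assert list(out.df["SNP"]) == ["rs1"]

    def test_equal_strength_retained(self):
        inst = make_instruments([0.05], [0.05])
        assert len(mr.steiger_filter(inst)) == 1

    def test_all_removed_raises(self):
        inst = make_instruments([0.001], [0.5])
        with pytest.raises(mr.EmptyInstrumentsError):
            mr.steiger_filter(inst)


class TestIvw:
    def test_proportional_truth_exact(self):
        bx = np.array([0.1, 0.2, 0.15])
        fit = mr.ivw(make_instruments(bx, 0.5 * bx))
        assert fit.beta == pytest.approx(0.5, abs=1e-12)
        assert fit.Q == pytest.approx(0.0, abs=1e-12)

    def test_null_outcome(self):
        bx = np.array([0.1, 0.2, 0.15])
        fit = mr.ivw(make_instruments(bx, np.zeros(3)))
        assert fit.beta == 0.0 and fit.p == pytest.approx(1.0)

    def test_single_instrument_rejected(self):
        with pytest.raises(ValueError):
            mr.ivw(make_instruments([0.1], [0.05]))

    def test_simulation_bias_and_coverage(self):
        rng = np.random.default_rng(0)
        beta_true = 0.2
        est, cover = [], 0
        reps = 300
        for _ in range(reps):
            L = 50
            bx = rng.normal(0.1, 0.03, L)
            sx, sy = 0.005, 0.01
            bxh = bx + sx * rng.standard_normal(L)
            byh = beta_true * bx + sy * rng.standard_normal(L)
            fit = mr.ivw(make_instruments(bxh, byh, sx, sy))
            est.append(fit.beta)
            cover += fit.ci[0] <= beta_true <= fit.ci[1]
        assert abs(np.mean(est) - beta_true) < 0.02
        assert 0.90 <= cover / reps <= 0.98


class TestEgger:
    def test_exact_affine_fixture(self):
        bx = np.array([0.1, 0.2, 0.15])
        fit = mr.egger(make_instruments(bx, 0.02 + 0.5 * bx))
        assert fit.egger_intercept == pytest.approx(0.02, abs=1e-12)
        assert fit.beta == pytest.approx(0.5, abs=1e-12)

    def test_balanced_pleiotropy(self):
        rng = np.random.default_rng(1)
        L = 100
        bx = rng.normal(0.1, 0.03, L)
        pleio = rng.normal(0, 0.005, L)   # mean-zero direct effects
        by = 0.3 * bx + pleio + 0.005 * rng.standard_normal(L)
        fit = mr.egger(make_instruments(bx + 0.002 * rng.standard_normal(L), by,
                                        sx=0.002, sy=0.005))
        assert abs(fit.egger_intercept) < 2 * fit.egger_intercept_se
        assert fit.beta == pytest.approx(0.3, abs=3 * fit.se)

    def test_weak_instruments_suppressed(self):
        rng = np.random.default_rng(2)
        L = 30
        bx_true = np.full(L, 0.02)
        bx = bx_true + 0.02 * rng.standard_normal(L)  # huge relative error
        fit = mr.egger(make_instruments(bx, 0.5 * bx_true, sx=0.02))
        assert fit.i2_gx < 0.9 and fit.suppressed


class TestWeightedMedian:
    def test_constant_ratios(self):
        bx = np.array([0.1, 0.2, 0.15, 0.12])
        fit = mr.weighted_median(make_instruments(bx, 0.3 * bx, sx=1e-6, sy=1e-6))
        assert fit.beta == pytest.approx(0.3, abs=1e-9)
        assert fit.se < 1e-4

    def test_breakdown_under_minority_invalid(self):
        rng = np.random.default_rng(3)
        L = 51
        bx = rng.normal(0.1, 0.02, L)
        by = 0.2 * bx
        by[:25] += 1.0  # 49% wildly invalid
        fit = mr.weighted_median(make_instruments(bx, by, sy=0.002))
        assert fit.beta == pytest.approx(0.2, abs=2 * fit.se + 0.05)

    def test_seed_reproducible(self):
        bx = np.array([0.1, 0.2, 0.15, 0.12])
        by = np.array([0.03, 0.05, 0.05, 0.04])
        a = mr.weighted_median(make_instruments(bx, by), seed=5)
        b = mr.weighted_median(make_instruments(bx, by), seed=5)
        assert a.se == b.se


class TestWeightedMode:
    def test_tight_cluster(self):
        rng = np.random.default_rng(4)
        bx = rng.normal(0.15, 0.02, 20)
        fit = mr.weighted_mode(make_instruments(bx, 0.3 * bx, sy=0.001))
        assert fit.beta == pytest.approx(0.3, abs=0.02)

    def test_bimodal_heavier_cluster_wins(self):
        bx = np.full(10, 0.2)
        by = np.concatenate([np.full(6, 0.1 * 0.2), np.full(4, 0.5 * 0.2)])
        fit = mr.weighted_mode(make_instruments(bx, by, sy=0.002))
        assert fit.beta == pytest.approx(0.1, abs=0.03)

    def test_infinite_bandwidth_tends_to_weighted_mean(self):
        bx = np.array([0.1, 0.2, 0.15, 0.3])
        by = np.array([0.05, 0.02, 0.06, 0.03])
        inst = make_instruments(bx, by)
        fit = mr.weighted_mode(inst, bandwidth_multiplier=1e4, n_boot=10)
        ratios = by / bx
        w = (np.abs(bx) / 0.01) ** 2
        wmean = np.sum(w * ratios) / np.sum(w)
        assert fit.beta == pytest.approx(wmean, abs=0.02)


@pytest.fixture(scope="module")
def causal_study():
    """X causally upstream of Y via a shared factor; NULLCOV has no effects."""
    config = ArchitectureConfig(
        traits=[TraitSpec("X", h2=0.3, n=200_000, loading=np.sqrt(0.3)),
                TraitSpec("Y", h2=0.1, n=200_000, loading=0.4 * np.sqrt(0.3))],
        m_variants=10_000, n_blocks=100, pi_shared=0.05, seed=22)
    return simulate_study(config)


class TestMvmr:
    def test_null_covariate_matches_univariable(self, causal_study):
        ref, _, tables = causal_study
        from comorbigen.sumstats import SumStatsTable
        null_df = tables[0].df.copy()
        null_df[["BETA", "Z"]] = 0.0
        null_df["P"] = 1.0
        nullcov = SumStatsTable("NULLCOV", null_df)
        inst = mr.build_instruments(tables[0], tables[1], ref)
        uni = mr.ivw(inst, random_effects=False)
        fits = mr.mvmr([tables[0], nullcov], tables[1], ref)
        assert fits[0].beta == pytest.approx(uni.beta, abs=1e-6)

    def test_identical_exposures_collinear(self, causal_study):
        ref, _, tables = causal_study
        with pytest.raises(ValueError, match="collinear"):
            mr.mvmr([tables[0], tables[0]], tables[1], ref)

    def test_full_mediation_attenuates_conditional_effect(self, mediation_study):
        ref = mediation_study["reference"]
        tables = mediation_study["tables"]  # X, M, Y with X -> M -> Y
        x, m, y = tables
        uni = mr.ivw(mr.build_instruments(x, y, ref))
        # Steiger disabled: under full mediation the mediator's instruments
        # rightly explain more outcome variance than the primary exposure
        fits = mr.mvmr([x, m], y, ref, steiger_alpha=None)
        assert uni.p < 0.05                        # total effect present
        assert abs(fits[0].beta) < 2 * fits[0].se  # conditional effect ~ 0
        assert fits[1].beta == pytest.approx(0.6, abs=0.05)


class TestOrientationInvariance:
    def test_flip_both_studies_leaves_estimates(self):
        rng = np.random.default_rng(6)
        L = 20
        bx = rng.normal(0.1, 0.05, L)
        by = 0.25 * bx + 0.005 * rng.standard_normal(L)
        inst = make_instruments(bx, by)
        flipped = inst.df.copy()
        flipped.loc[::2, ["beta_exp", "beta_out"]] *= -1.0
        inst_f = mr.InstrumentSet("X", "Y", flipped)
        # orient both to the exposure-increasing allele
        for i in (inst, inst_f):
            neg = i.df["beta_exp"] < 0
            i.df.loc[neg, ["beta_exp", "beta_out"]] *= -1.0
        for est in (mr.ivw, mr.egger):
            assert est(inst).beta == pytest.approx(est(inst_f).beta, abs=1e-12)


class TestSensitivity:
    def _fits(self, ivw_p=0.001, egger_icpt_p=0.8, signs=(1, 1, 1)):
        f = [mr.MRFit("IVW", "X", "Y", 0.3 * signs[0], 0.05, ivw_p, (0.2, 0.4), 10),
             mr.MRFit("weighted-median", "X", "Y", 0.25 * signs[1], 0.06, 0.01,
                      (0.1, 0.4), 10),
             mr.MRFit("weighted-mode", "X", "Y", 0.28 * signs[2], 0.07, 0.01,
                      (0.1, 0.4), 10),
             mr.MRFit("Egger", "X", "Y", 0.27, 0.1, 0.02, (0.1, 0.5), 10,
                      egger_intercept=0.01, egger_intercept_se=0.01,
                      egger_intercept_p=egger_icpt_p, i2_gx=0.95)]
        return f

    def test_all_consistent_robust(self):
        v = mr.sensitivity_report(self._fits())
        assert v.robust

    def test_significant_intercept_flags_pleiotropy(self):
        v = mr.sensitivity_report(self._fits(egger_icpt_p=0.001))
        assert not v.robust and v.pleiotropy_detected
        assert "not be interpreted" in v.note

    def test_nonsignificant_ivw_not_robust(self):
        v = mr.sensitivity_report(self._fits(ivw_p=0.2))
        assert not v.robust and not v.ivw_significant

    def test_sign_disagreement_not_robust(self):
        v = mr.sensitivity_report(self._fits(signs=(1, -1, 1)))
        assert not v.robust and not v.signs_consistent
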