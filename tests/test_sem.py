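"""Genomic SEM: fitting, fit indices, factor GWAS, adjustment, mediation."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from comorbigen import ldsc, sem
from comorbigen.simulate import ArchitectureConfig, TraitSpec, simulate_study


def one_factor_gencov(lam, theta, v_scale=1e-4):
    S = np.outer(lam, lam) + np.diag(theta)
    k = len(lam)
    p = k * (k + 1) // 2
    return ldsc.GenCov(traits=[f"t{i}" for i in range(k)], S=S,
                       V=np.eye(p) * v_scale, intercepts=np.eye(k))


def one_factor_spec(k):
    lines = [f"F -> t0 @1"] + [f"F -> t{i}" for i in range(1, k)]
    return sem.parse_model("\n".join(lines), observed=[f"t{i}" for i in range(k)])


class TestFitModel:
    def test_exact_recovery(self):
        lam = np.array([1.0, 0.8, 0.6, 0.9])
        theta = np.array([0.3, 0.4, 0.5, 0.2])
        gc = one_factor_gencov(lam, theta)
        fit = sem.fit_model(gc, one_factor_spec(4))
        for i in range(1, 4):
            assert fit.estimate(f"t{i}~F") == pytest.approx(lam[i], abs=1e-6)
            assert fit.estimate(f"t{i}~~t{i}") == pytest.approx(theta[i], abs=1e-6)
        assert fit.chi2 == pytest.approx(0.0, abs=1e-8)
        assert fit.cfi == 1.0
        assert fit.srmr <= 1e-8

    def test_df_bookkeeping(self):
        gc = one_factor_gencov(np.array([1.0, 0.8, 0.6, 0.9]),
                               np.array([0.3, 0.4, 0.5, 0.2]))
        spec = one_factor_spec(4)
        fit = sem.fit_model(gc, spec)
        assert fit.df == 10 - spec.n_free

    def test_cfi_zero_for_fixed_misfit_on_diagonal(self):
        # fixed nonzero loadings cannot fit a diagonal S; baseline fits it
        S = np.diag([1.3, 1.4, 1.5, 1.2])
        gc = ldsc.GenCov(traits=[f"t{i}" for i in range(4)], S=S,
                         V=np.eye(10) * 1e-4, intercepts=np.eye(4))
        lines = [f"F -> t{i} @0.7" for i in range(4)] + ["F ~~ @1"]
        spec = sem.parse_model("\n".join(lines), observed=[f"t{i}" for i in range(4)])
        fit = sem.fit_model(gc, spec)
        assert fit.cfi < 0.1

    def test_scale_equivariance(self):
        lam = np.array([1.0, 0.8, 0.6, 0.9])
        theta = np.array([0.3, 0.4, 0.5, 0.2])
        gc = one_factor_gencov(lam, theta)
        fit = sem.fit_model(gc, one_factor_spec(4))
        c = 2.0
        S2 = gc.S.copy()
        S2[1, :] *= c
        S2[:, 1] *= c
        gc2 = ldsc.GenCov(traits=gc.traits, S=S2, V=gc.V, intercepts=gc.intercepts)
        fit2 = sem.fit_model(gc2, one_factor_spec(4))
        assert fit2.estimate("t1~F") == pytest.approx(c * fit.estimate("t1~F"), abs=1e-6)
        std1 = fit.standardized_loadings()
        std2 = fit2.standardized_loadings()
        assert std2["t1~F"] == pytest.approx(std1["t1~F"], abs=1e-8)
        assert fit2.cfi == pytest.approx(fit.cfi, abs=1e-8)
        assert fit2.srmr == pytest.approx(fit.srmr, abs=1e-8)

    def test_unidentified_model_rejected(self):
        gc = one_factor_gencov(np.array([1.0, 0.8]), np.array([0.3, 0.4]))
        spec = sem.parse_model("F -> t0\nF -> t1", observed=["t0", "t1"])
        with pytest.raises(sem.SemError):
            sem.fit_model(gc, spec)


class TestComorbidityDesign:
    def test_exact_two_level_truth(self):
        lam_ascvd = np.array([1.0, 1.03, 1.08, 0.79])
        b_high = 2.46
        phi = 0.02
        w = np.concatenate([[1.0], b_high * lam_ascvd])
        resid = np.array([0.08, 0.05, 0.06, 0.055, 0.045])
        S = phi * np.outer(w, w) + np.diag(resid)
        gc = ldsc.GenCov(traits=["MDD", "CAD", "PAD", "HF", "STROKE"], S=S,
                         V=np.eye(15) * 1e-6, intercepts=np.eye(5))
        fit = sem.fit_mdd_ascvd(gc)
        assert fit.estimate("ASCVD~COMORB") == pytest.approx(b_high, abs=1e-4)
        assert fit.estimate("PAD~ASCVD") == pytest.approx(1.03, abs=1e-4)
        assert fit.cfi > 0.999 and fit.srmr < 1e-6
        # ASCVD residual variance forced to zero: its variance all comes
        # from the higher-order factor
        std = fit.standardized_loadings()
        assert std["ASCVD~COMORB"] == pytest.approx(1.0, abs=1e-6)

    def test_recovery_on_simulated_study(self, factor_study):
        fit = sem.fit_mdd_ascvd(factor_study["gencov"])
        assert fit.converged
        assert fit.cfi > 0.9
        # truth: all traits load on one factor, so standardized ASCVD loading ~ 1
        assert fit.estimate("ASCVD~COMORB") > 0

    def test_uncorrelated_mdd_zero_higher_loading(self):
        lam_ascvd = np.array([1.0, 1.03, 1.08, 0.79])
        S = np.zeros((5, 5))
        S[1:, 1:] = 0.05 * np.outer(lam_ascvd, lam_ascvd) + np.diag([.05, .06, .055, .045])
        S[0, 0] = 0.1
        gc = ldsc.GenCov(traits=["MDD", "CAD", "PAD", "HF", "STROKE"], S=S,
                         V=np.eye(15) * 1e-6, intercepts=np.eye(5))
        fit = sem.fit_mdd_ascvd(gc)
        # MDD uncorrelated: the comorbidity factor explains no MDD variance,
        # i.e. its variance estimate is ~0 (MDD loading fixed at 1)
        assert fit.estimate("COMORB~~COMORB") == pytest.approx(0.0, abs=1e-4)


class TestFactorGwas:
    def test_proportional_betas_no_heterogeneity(self, factor_study):
        fit = sem.fit_mdd_ascvd(factor_study["gencov"])
        tables = factor_study["tables"]
        res = sem.factor_gwas(fit, tables)
        assert len(res) == 20_000
        assert (res["chi2_independent"] <= res["chi2_common"] + 1e-6).all()
        assert (res["Q"] >= -1e-9).all()

    def test_single_trait_signal_flagged(self, factor_study):
        fit = sem.fit_mdd_ascvd(factor_study["gencov"])
        tables = [t.subset(np.arange(len(t)) < 50) for t in factor_study["tables"]]
        # inject a variant affecting only MDD, strongly
        df = tables[0].df.copy()
        df.loc[0, "Z"] = 30.0
        df.loc[0, "BETA"] = 30.0 * df.loc[0, "SE"]
        from comorbigen.sumstats import SumStatsTable
        tables[0] = SumStatsTable("MDD", df)
        res = sem.factor_gwas(fit, tables)
        assert bool(res.loc[res["SNP"] == df.loc[0, "SNP"], "heterogeneous"].iloc[0])

    def test_null_q_calibrated(self, factor_study):
        fit = sem.fit_mdd_ascvd(factor_study["gencov"])
        null_config = ArchitectureConfig(
            traits=[TraitSpec(t.name, h2=0.0, n=t.n) for t in factor_study["config"].traits],
            m_variants=10_000, n_blocks=100, ar1_rho=0.0, pi_shared=0.0, seed=9)
        _, _, null_tables = simulate_study(null_config)
        res = sem.factor_gwas(fit, null_tables)
        assert kstest(res["p_Q"], "uniform").pvalue > 0.01
        rate = res["heterogeneous"].mean()
        assert abs(rate - 0.05) < 2 * np.sqrt(0.05 * 0.95 / len(res))


class TestFilterHeterogeneous:
    def _frame(self, flags, p=1e-9):
        return pd.DataFrame({"SNP": [f"s{i}" for i in range(len(flags))],
                             "P": p, "heterogeneous": flags})

    def test_no_flags_identity(self):
        out, share = sem.filter_heterogeneous(self._frame([False] * 3))
        assert len(out) == 3 and share == 0.0

    def test_all_flagged_empty(self):
        out, share = sem.filter_heterogeneous(self._frame([True] * 3))
        assert len(out) == 0 and share == 1.0

    def test_three_of_four(self):
        out, share = sem.filter_heterogeneous(self._frame([True, True, True, False]))
        assert share == 0.75 and len(out) == 1


class TestAdjustedRg:
    def test_empty_covariates_equals_raw(self, factor_study):
        gc = factor_study["gencov"]
        adj = sem.adjusted_rg(gc, "MDD", "CAD", [])
        raw = gc.S[0, 1] / np.sqrt(gc.S[0, 0] * gc.S[1, 1])
        assert adj.rg_adj == pytest.approx(raw, abs=1e-10)

    def test_perfectly_collinear_covariate_degenerate(self, factor_study):
        gc = factor_study["gencov"]
        # covariate identical to x: partialled x variance -> 0
        S = gc.S.copy()
        S[2, :] = S[0, :]
        S[:, 2] = S[:, 0]
        S[2, 2] = S[0, 0]
        gc2 = ldsc.GenCov(traits=gc.traits, S=S, V=gc.V, intercepts=gc.intercepts)
        adj = sem.adjusted_rg(gc2, "MDD", "CAD", ["PAD"])
        assert adj.degenerate or adj.ridge_used

    def test_full_mediation_drives_adjusted_to_zero(self, mediation_study):
        gc = mediation_study["gencov"]
        raw = sem.adjusted_rg(gc, "X", "Y", [])
        adj = sem.adjusted_rg(gc, "X", "Y", ["M"])
        assert abs(raw.rg_adj) > 0.3
        assert abs(adj.rg_adj) < 2 * adj.se


class TestMediation:
    def test_full_mediation_direct_zero(self, mediation_study):
        gc = mediation_study["gencov"]
        med = sem.mediation_model(gc, "X", ["M"], "Y")
        assert abs(med.direct) < 2 * med.direct_se
        a, b = mediation_study["a_path"], mediation_study["b_path"]
        assert med.indirect == pytest.approx(a * b, abs=0.1)

    def test_zero_mediator_paths(self):
        # X and Y correlated; M independent of both
        S = np.array([[0.3, 0.0, 0.12], [0.0, 0.2, 0.0], [0.12, 0.0, 0.25]])
        gc = ldsc.GenCov(traits=["X", "M", "Y"], S=S, V=np.eye(6) * 1e-6,
                         intercepts=np.eye(3))
        med = sem.mediation_model(gc, "X", ["M"], "Y")
        assert med.indirect == pytest.approx(0.0, abs=1e-4)
        assert med.direct == pytest.approx(0.12 / 0.3, abs=1e-3)

    def test_mediator_identical_to_x_fails(self, mediation_study):
        gc = mediation_study["gencov"]
        S = gc.S.copy()
        S[1, :] = S[0, :]
        S[:, 1] = S[:, 0]
        S[1, 1] = S[0, 0]
        gc2 = ldsc.GenCov(traits=gc.traits, S=S, V=gc.V, intercepts=gc.intercepts)
        with pytest.raises(Exception):
            med = sem.mediation_model(gc2, "X", ["M"], "Y")
            if not (med.fit.heywood or not med.fit.converged):
                raise RuntimeError("degenerate mediator not flagged")
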