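import numpy as np
import pandas as pd
import pytest

from comorbigen.ldref import LDBlock, LDReference
from comorbigen.simulate import ArchitectureConfig, TraitSpec, TruthRecord, simulate_study
from comorbigen.sumstats import SumStatsTable


def make_table(trait, snps, chrom, bp, beta, se, n=10000.0, freq=0.3,
               a1="A", a2="G", p=None):
    m = len(snps)
    beta = np.asarray(beta, float)
    se = np.asarray(se, float) if np.ndim(se) else np.full(m, se, float)
    z = beta / se
    from scipy.stats import norm
    if p is None:
        p = 2 * norm.sf(np.abs(z))
    df = pd.DataFrame({
        "SNP": snps, "CHR": chrom, "BP": bp,
        "A1": a1, "A2": a2, "FREQ": freq,
        "BETA": beta, "SE": se, "Z": z,
        "P": np.clip(p, np.finfo(float).tiny, 1.0), "N": n,
    })
    return SumStatsTable(trait, df)


@pytest.fixture
def tiny_reference():
    """Three blocks on two chromosomes with distinct LD profiles."""
    b1 = LDBlock(1, 100, 300, ["rs0", "rs1"], np.array([100, 300]),
                 np.array([[1.0, 0.6], [0.6, 1.0]]))
    r = 0.5
    R3 = np.array([[1, r, r ** 2], [r, 1, r], [r ** 2, r, 1.0]])
    b2 = LDBlock(1, 10_000, 10_400, ["rs2", "rs3", "rs4"],
                 np.array([10_000, 10_200, 10_400]), R3)
    b3 = LDBlock(2, 500, 900, ["rs5", "rs6"], np.array([500, 900]), np.eye(2))
    return LDReference([b1, b2, b3])


@pytest.fixture(scope="session")
def factor_study():
    """5-trait comorbidity-structured synthetic study with its LDSC GenCov."""
    from comorbigen import ldsc

    h2s = dict(MDD=0.3, CAD=0.2, PAD=0.18, HF=0.15, STROKE=0.12)
    lam = dict(MDD=0.25, CAD=0.32, PAD=0.30, HF=0.27, STROKE=0.20)
    traits = [TraitSpec(n_, h2=h2s[n_], n=100_000, loading=lam[n_]) for n_ in h2s]
    config = ArchitectureConfig(traits=traits, m_variants=20_000, n_blocks=100,
                                pi_shared=0.05, seed=42)
    reference, truth, tables = simulate_study(config)
    gencov = ldsc.multivariable_ldsc(tables, reference)
    return dict(config=config, reference=reference, truth=truth,
                tables=tables, gencov=gencov)


@pytest.fixture(scope="session")
def mediation_study():
    """Full-mediation architecture: Y's genetic effects run entirely via M."""
    from comorbigen import ldsc
    from comorbigen.simulate import simulate_ld, simulate_sumstats

    rng = np.random.default_rng(77)
    M = 20_000
    config = ArchitectureConfig(
        traits=[TraitSpec("X", h2=0.3, n=1_000_000),
                TraitSpec("M", h2=0.25, n=1_000_000),
                TraitSpec("Y", h2=0.11, n=1_000_000)],
        m_variants=M, n_blocks=100, seed=77)
    reference = simulate_ld(config.n_blocks, config.block_size, config.ar1_rho)
    bx = np.zeros(M)
    idx = rng.choice(M, 500, replace=False)
    bx[idx] = rng.standard_normal(500)
    bx *= np.sqrt(0.3) / np.linalg.norm(bx)
    dm = np.zeros(M)
    idx2 = rng.choice(M, 500, replace=False)
    dm[idx2] = rng.standard_normal(500)
    dm -= (dm @ bx) / (bx @ bx) * bx
    a_path, b_path = 0.7, 0.6
    resid_m = np.sqrt(max(0.25 - a_path ** 2 * 0.3, 0.0))
    bm = a_path * bx + resid_m * dm / np.linalg.norm(dm)
    dy = np.zeros(M)                       # small Y-unique component so the
    idx3 = rng.choice(M, 500, replace=False)   # partialled Y variance stays
    dy[idx3] = rng.standard_normal(500)        # positive (h2 unique = 0.02)
    for v in (bx, bm):
        dy -= (dy @ v) / (v @ v) * v
    by = b_path * bm + np.sqrt(0.02) * dy / np.linalg.norm(dy)  # no direct X -> Y path
    beta = np.column_stack([bx, bm, by])
    causal = beta != 0
    truth = TruthRecord(config, beta, causal, beta.T @ beta,
                        np.zeros(3), np.zeros((config.n_blocks, 3, 3)))
    tables = simulate_sumstats(truth, reference, seed=78)
    gencov = ldsc.multivariable_ldsc(tables, reference)
    return dict(config=config, reference=reference, truth=truth,
                tables=tables, gencov=gencov,
                a_path=a_path, b_path=b_path)
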