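"""Synthetic multi-trait GWAS summary statistics with known truth.

The generator draws per-variant joint (true) effects on the standardized
genotype scale under a configurable architecture — sparse causal sets, a
latent-factor structure across traits (or, for a pair, an explicit
shared/unique causal-mixture decomposition) — and then samples marginal
z-statistics under block LD:

    z_t = sqrt(n_t) * R @ beta_t + eps,   eps ~ MN(0, R, C)

where ``R`` is the block correlation matrix and ``C`` the cross-trait error
correlation induced by overlapping samples.  This reproduces the regression
model behind LD score regression exactly: E[chi^2_j] = 1 + n h2 l_j / M and
cross-trait intercept C_{tu} for fully overlapping samples.

Effect vectors in factor mode are rescaled (and residual components
orthogonalized against the factor component) so that realized per-trait
genetic variance and pairwise genetic covariance equal their configured
values exactly; in mixture mode effects keep their per-variant Gaussian
shape so that causal-mixture likelihoods see the distribution they model.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd
import yaml
from scipy.linalg import cholesky, toeplitz
from scipy.stats import norm

from .ldref import LDBlock, LDReference
from .sumstats import SumStatsTable

__all__ = ["TraitSpec", "ArchitectureConfig", "TruthRecord",
           "simulate_ld", "simulate_effects", "simulate_sumstats", "simulate_study"]


class ConfigError(ValueError):
    pass


@dataclass
class TraitSpec:
    """One trait's architecture: target h2, GWAS sample size, polygenicity.

    ``loading`` is the trait's loading on the shared latent genetic factor in
    genetic-SD units (so loading**2 is the factor-explained share of genetic
    variance and must not exceed ``h2``); ``pi`` is the proportion of
    variants carrying trait-specific residual effects.
    """

    name: str
    h2: float
    n: int
    pi: float = 0.1
    loading: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.h2 <= 1.0:
            raise ConfigError(f"{self.name}: h2 must be in [0,1]")
        if self.loading ** 2 > self.h2 + 1e-9:
            raise ConfigError(f"{self.name}: loading^2 exceeds h2")
        if not 0.0 <= self.pi <= 1.0:
            raise ConfigError(f"{self.name}: pi must be in [0,1]")

    @property
    def residual_var(self) -> float:
        return max(self.h2 - self.loading ** 2, 0.0)


@dataclass
class ArchitectureConfig:
    traits: list[TraitSpec]
    m_variants: int = 20_000
    n_blocks: int = 100
    ar1_rho: float | tuple[float, float] = (0.0, 0.9)
    pi_shared: float = 0.05          # causal proportion of the latent factor
    overlap: np.ndarray | None = None  # k x k phenotypic-error correlation
    seed: int = 0
    # pair-mixture mode (exactly two traits): explicit Venn decomposition
    pair_pi12: float | None = None   # shared causal proportion
    pair_rho12: float = 0.0          # effect correlation in the shared set

    def __post_init__(self) -> None:
        k = len(self.traits)
        if self.overlap is None:
            self.overlap = np.eye(k)
        self.overlap = np.asarray(self.overlap, dtype=float)
        if self.overlap.shape != (k, k):
            raise ConfigError("overlap matrix has wrong shape")
        if not np.allclose(self.overlap, self.overlap.T) or not np.allclose(np.diag(self.overlap), 1.0):
            raise ConfigError("overlap must be symmetric with unit diagonal")
        if self.m_variants % self.n_blocks:
            raise ConfigError("m_variants must be divisible by n_blocks")
        if not np.isscalar(self.ar1_rho):
            self.ar1_rho = tuple(float(r) for r in self.ar1_rho)
        rho_vals = [self.ar1_rho] if np.isscalar(self.ar1_rho) else list(self.ar1_rho)
        if any(abs(r) >= 1.0 for r in rho_vals):
            raise ConfigError("|ar1_rho| must be < 1")
        if self.pair_pi12 is not None:
            if k != 2:
                raise ConfigError("pair-mixture mode requires exactly two traits")
            if self.pair_pi12 > min(t.pi for t in self.traits) + 1e-12:
                raise ConfigError("pair_pi12 exceeds a trait's total causal proportion")

    @property
    def block_size(self) -> int:
        return self.m_variants // self.n_blocks

    @classmethod
    def from_yaml(cls, path) -> "ArchitectureConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        traits = [TraitSpec(**t) for t in raw.pop("traits")]
        if "overlap" in raw and raw["overlap"] is not None:
            raw["overlap"] = np.asarray(raw["overlap"], dtype=float)
        return cls(traits=traits, **raw)


@dataclass
class TruthRecord:
    """Ground truth behind one simulated study."""

    config: ArchitectureConfig
    beta: np.ndarray               # M x k true joint effects, standardized scale
    causal: np.ndarray             # M x k boolean causal indicators
    gencov: np.ndarray             # k x k true genetic covariance
    loadings: np.ndarray           # k, configured factor loadings
    local_cov: np.ndarray          # n_blocks x k x k per-block genetic covariance

    @property
    def h2(self) -> np.ndarray:
        return np.diag(self.gencov)

    @property
    def rg(self) -> np.ndarray:
        d = np.sqrt(np.clip(self.h2, 1e-30, None))
        return self.gencov / np.outer(d, d)

    def to_frame(self) -> pd.DataFrame:
        names = [t.name for t in self.config.traits]
        cols = {}
        for i, nm in enumerate(names):
            cols[f"beta_{nm}"] = self.beta[:, i]
            cols[f"causal_{nm}"] = self.causal[:, i].astype(int)
        return pd.DataFrame(cols)


def simulate_ld(n_blocks: int, block_size: int,
                ar1_rho: float | tuple[float, float] = (0.0, 0.9),
                within_spacing_bp: int = 5_000, gap_bp: int = 2_000_000,
                seed: int = 0) -> LDReference:
    """Build an AR(1)-profile block LD reference.

    Each block's correlation matrix is Toeplitz with entries rho**|i-j|
    (positive definite for |rho| < 1).  ``ar1_rho`` may be a scalar or a
    (low, high) range spread linearly across blocks — heterogeneous LD
    strength across the genome is what makes the LD-score regressor vary,
    so the range form is the default.  Blocks are laid out round-robin over
    chromosomes 1-22 with a physical gap so that clumping windows never span
    blocks.  Deterministic given the spec; ``seed`` is accepted for
    interface symmetry.
    """
    if np.isscalar(ar1_rho):
        rhos = np.full(n_blocks, float(ar1_rho))
    else:
        lo, hi = ar1_rho
        rhos = np.linspace(lo, hi, n_blocks) if n_blocks > 1 else np.array([(lo + hi) / 2])
    if np.any(np.abs(rhos) >= 1.0):
        raise ConfigError("|ar1_rho| must be < 1 for a positive-definite block")
    blocks = []
    next_pos = {c: 1 for c in range(1, 23)}
    for b in range(n_blocks):
        rho = rhos[b]
        R = toeplitz(rho ** np.arange(block_size)) if block_size > 1 else np.ones((1, 1))
        chrom = (b % 22) + 1
        start = next_pos[chrom]
        pos = start + within_spacing_bp * np.arange(block_size)
        end = int(pos[-1])
        next_pos[chrom] = end + gap_bp
        snps = [f"rs{b}_{j}" for j in range(block_size)]
        blocks.append(LDBlock(chrom, int(start), end, snps, pos, R))
    return LDReference(blocks)


def _orthonormalize(vectors: list[np.ndarray]) -> list[np.ndarray]:
    """Gram-Schmidt to unit norm; degenerate inputs raise."""
    out: list[np.ndarray] = []
    for v in vectors:
        w = v.astype(float).copy()
        for u in out:
            w -= (w @ u) * u
        nrm = np.linalg.norm(w)
        if nrm < 1e-12:
            raise ConfigError("degenerate effect component (zero after orthogonalization)")
        out.append(w / nrm)
    return out


def simulate_effects(config: ArchitectureConfig, reference: LDReference,
                     rng: np.random.Generator | None = None) -> TruthRecord:
    """Draw true joint effects under the configured architecture."""
    rng = rng or np.random.default_rng(config.seed)
    M = reference.m
    k = len(config.traits)
    if M != config.m_variants:
        raise ConfigError("reference and config disagree on variant count")
    beta = np.zeros((M, k))
    causal = np.zeros((M, k), dtype=bool)

    if config.pair_pi12 is not None:
        _mixture_pair_effects(config, rng, M, beta, causal)
        gencov = _realized_gencov(beta)
    else:
        gencov = _factor_effects(config, rng, M, beta, causal)

    bs = config.block_size
    local = np.stack([beta[i * bs:(i + 1) * bs].T @ beta[i * bs:(i + 1) * bs]
                      for i in range(config.n_blocks)])
    loadings = np.array([t.loading for t in config.traits])
    return TruthRecord(config, beta, causal, gencov, loadings, local)


def _factor_effects(config, rng, M, beta, causal) -> np.ndarray:
    """Latent-factor architecture: beta_t = loading_t * gamma + delta_t.

    gamma (factor) and delta_t (residual) are sparse Gaussian vectors,
    orthonormalized so realized variances and covariances are exact.
    """
    n_shared = int(round(config.pi_shared * M))
    any_loading = any(abs(t.loading) > 0 for t in config.traits)
    comps: list[np.ndarray] = []
    if any_loading:
        if n_shared < 1:
            raise ConfigError("factor loadings set but pi_shared yields no causal variants")
        g = np.zeros(M)
        idx = rng.choice(M, size=n_shared, replace=False)
        g[idx] = rng.standard_normal(n_shared)
        comps.append(g)
    deltas = []
    for t in config.traits:
        if t.residual_var > 0:
            n_res = int(round(t.pi * M))
            if n_res < 1:
                raise ConfigError(f"{t.name}: pi yields no residual causal variants")
            d = np.zeros(M)
            idx = rng.choice(M, size=n_res, replace=False)
            d[idx] = rng.standard_normal(n_res)
            deltas.append(d)
        else:
            deltas.append(None)
    ortho = _orthonormalize(([comps[0]] if any_loading else []) +
                            [d for d in deltas if d is not None])
    pos = 0
    gamma = None
    if any_loading:
        gamma = ortho[pos]
        pos += 1
    for i, t in enumerate(config.traits):
        v = t.loading * gamma if gamma is not None else 0.0
        if deltas[i] is not None:
            v = v + np.sqrt(t.residual_var) * ortho[pos]
            pos += 1
        beta[:, i] = v
        causal[:, i] = beta[:, i] != 0.0
    lam = np.array([t.loading for t in config.traits])
    gencov = np.outer(lam, lam) + np.diag([t.residual_var for t in config.traits])
    return gencov


def _mixture_pair_effects(config, rng, M, beta, causal) -> None:
    """Explicit shared/unique causal-mixture architecture for a trait pair."""
    t1, t2 = config.traits
    n12 = int(round(config.pair_pi12 * M))
    n1 = int(round((t1.pi - config.pair_pi12) * M))
    n2 = int(round((t2.pi - config.pair_pi12) * M))
    perm = rng.permutation(M)
    shared, only1, only2 = perm[:n12], perm[n12:n12 + n1], perm[n12 + n1:n12 + n1 + n2]
    s1 = np.sqrt(t1.h2 / (t1.pi * M))   # per-causal effect SD, trait 1
    s2 = np.sqrt(t2.h2 / (t2.pi * M))
    rho = config.pair_rho12
    if n12:
        L = np.array([[1.0, 0.0], [rho, np.sqrt(1.0 - rho ** 2)]])
        e = rng.standard_normal((n12, 2)) @ L.T
        beta[shared, 0] = s1 * e[:, 0]
        beta[shared, 1] = s2 * e[:, 1]
        causal[shared, :] = True
    if n1:
        beta[only1, 0] = s1 * rng.standard_normal(n1)
        causal[only1, 0] = True
    if n2:
        beta[only2, 1] = s2 * rng.standard_normal(n2)
        causal[only2, 1] = True


def _realized_gencov(beta: np.ndarray) -> np.ndarray:
    return beta.T @ beta


def simulate_sumstats(truth: TruthRecord, reference: LDReference,
                      seed: int | None = None) -> list[SumStatsTable]:
    """Sample marginal association statistics for every trait.

    Per block, z-columns are drawn from the matrix normal with mean
    sqrt(n) R beta, row covariance R and column covariance the overlap
    matrix; betas are reported on the standardized scale (beta = z/sqrt(n),
    se = 1/sqrt(n)).
    """
    config = truth.config
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    k = len(config.traits)
    n = np.array([t.n for t in config.traits], float)
    Lc = cholesky(config.overlap + 1e-12 * np.eye(k), lower=True)
    bs = config.block_size
    z = np.empty((reference.m, k))
    row = 0
    for bi, block in enumerate(reference.blocks):
        m = len(block)
        Lr = cholesky(block.R + 1e-10 * np.eye(m), lower=True)
        mean = (block.R @ truth.beta[row:row + m]) * np.sqrt(n)
        eps = Lr @ rng.standard_normal((m, k)) @ Lc.T
        z[row:row + m] = mean + eps
        row += m
    pos = reference.positions()
    freq = rng.uniform(0.05, 0.95, size=reference.m)
    snps = reference.snp
    tables = []
    for i, t in enumerate(config.traits):
        se = 1.0 / np.sqrt(n[i])
        df = pd.DataFrame({
            "SNP": snps,
            "CHR": pos["CHR"].to_numpy(),
            "BP": pos["BP"].to_numpy(),
            "A1": "A", "A2": "G",
            "FREQ": freq,
            "BETA": z[:, i] * se,
            "SE": se,
            "Z": z[:, i],
            "P": np.clip(2.0 * norm.sf(np.abs(z[:, i])), np.finfo(float).tiny, 1.0),
            "N": t.n,
        })
        tables.append(SumStatsTable(t.name, df))
    return tables


def simulate_study(config: ArchitectureConfig):
    """Convenience wrapper: LD reference + truth + sumstats in one call."""
    reference = simulate_ld(config.n_blocks, config.block_size, config.ar1_rho,
                            seed=config.seed)
    rng = np.random.default_rng(config.seed)
    truth = simulate_effects(config, reference, rng)
    tables = simulate_sumstats(truth, reference)
    return reference, truth, tables
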