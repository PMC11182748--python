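"""LD score regression: h2, genetic covariance/correlation, S/V matrices,
and partitioned heritability enrichment with expression-derived annotations.

The regression model is the standard one for GWAS summary statistics

    E[chi^2_j]   = intercept + n * h2 * l_j / M
    E[z1_j z2_j] = intercept_x + sqrt(n1 n2) * gencov * l_j / M

fit by two-step weighted least squares (an unweighted pass sets the
heteroskedasticity weights for the final pass) with standard errors from a
delete-one block jackknife over contiguous variant spans.  The cross-trait
intercept absorbs sample overlap (overlap fraction times phenotypic
correlation) and is reported alongside every genetic-covariance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .ldref import LDReference
from .sumstats import SumStatsTable

__all__ = ["H2Estimate", "RgEstimate", "GenCov", "EnrichmentResult",
           "estimate_h2", "estimate_rg", "sample_overlap_flag",
           "multivariable_ldsc", "tdep_annotation", "partitioned_enrichment"]


# ---------------------------------------------------------------------------
# block-jackknife weighted least squares
# ---------------------------------------------------------------------------

def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _wls_jackknife(X: np.ndarray, y: np.ndarray, w: np.ndarray, n_blocks: int):
    """Weighted LS fit plus delete-one-block coefficient estimates.

    Returns (coef, coef_delete) with coef_delete of shape (g, p).  Weights
    are held fixed across jackknife replicates (the usual convention).
    """
    m, p = X.shape
    g = min(n_blocks, m)
    bounds = _block_bounds(m, g)
    Xw = X * w[:, None]
    A_blocks = np.empty((g, p, p))
    c_blocks = np.empty((g, p))
    for i in range(g):
        s = slice(bounds[i], bounds[i + 1])
        A_blocks[i] = X[s].T @ Xw[s]
        c_blocks[i] = Xw[s].T @ y[s]
    A = A_blocks.sum(axis=0)
    c = c_blocks.sum(axis=0)
    coef = np.linalg.solve(A, c)
    if g == 1:
        return coef, coef[None, :].copy()
    coef_del = np.empty((g, p))
    for i in range(g):
        coef_del[i] = np.linalg.solve(A - A_blocks[i], c - c_blocks[i])
    return coef, coef_del


def _jackknife_cov(delete_values: np.ndarray) -> np.ndarray:
    """Delete-one jackknife covariance of a vector statistic."""
    g = delete_values.shape[0]
    centred = delete_values - delete_values.mean(axis=0)
    return (g - 1) / g * centred.T @ centred


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class H2Estimate:
    trait: str
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    mean_chi2: float
    n_blocks: int
    negative_flag: bool = False
    delete_values: np.ndarray | None = field(default=None, repr=False)


@dataclass
class RgEstimate:
    traits: tuple[str, str]
    gencov: float
    gencov_se: float
    intercept: float
    intercept_se: float
    rg: float
    rg_se: float
    p: float
    ci: tuple[float, float]
    clipped: bool = False
    unstable: bool = False
    delete_values: np.ndarray | None = field(default=None, repr=False)


@dataclass
class GenCov:
    """Multi-trait genetic covariance S with sampling covariance V.

    ``V`` covers the k(k+1)/2 unique elements of S in row-major
    upper-triangle order (the order given by ``index_of``).
    """

    traits: list[str]
    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    v_projected: bool = False

    def __post_init__(self) -> None:
        k = len(self.traits)
        p = k * (k + 1) // 2
        if self.S.shape != (k, k) or self.V.shape != (p, p):
            raise ValueError("GenCov dimensions inconsistent")

    def index_of(self, i: int, j: int) -> int:
        """Position of S[i, j] (i <= j) in the flattened unique-element order."""
        i, j = min(i, j), max(i, j)
        k = len(self.traits)
        return i * k - i * (i - 1) // 2 + (j - i)

    def flat(self) -> np.ndarray:
        k = len(self.traits)
        iu = np.triu_indices(k)
        return self.S[iu]


@dataclass
class EnrichmentResult:
    label: str
    tau: float
    z: float
    p: float
    p_fdr: float = np.nan
    non_identifiable: bool = False


# ---------------------------------------------------------------------------
# univariate and bivariate LDSC
# ---------------------------------------------------------------------------

def _check_harmonized(table: SumStatsTable, reference: LDReference) -> np.ndarray:
    snps = reference.snp
    if len(table) != len(snps) or list(table.df["SNP"]) != snps:
        raise ValueError("table must be harmonized to the reference (same variants, same order)")
    return table.z


def estimate_h2(table: SumStatsTable, reference: LDReference,
                n_jackknife_blocks: int = 200, intercept_free: bool = True) -> H2Estimate:
    """SNP heritability by LD score regression of chi^2 on l_j."""
    z = _check_harmonized(table, reference)
    l = reference.ld_scores().to_numpy()
    M = reference.m
    n = float(np.mean(table.n))
    chi2 = z ** 2
    y = chi2 if intercept_free else chi2 - 1.0
    X = np.column_stack([np.ones(M), l]) if intercept_free else l[:, None]

    # two-step WLS: an unweighted pass sets the heteroskedasticity weights
    coef, _ = _wls_jackknife(X, y, np.ones(M), 1)
    h2_hat = np.clip(coef[-1] * M / n, 0.0, 1.0)
    icpt = coef[0] if intercept_free else 1.0
    v = np.maximum(icpt + n * h2_hat * l / M, 0.1)
    w = 1.0 / (2.0 * v ** 2)
    coef, coef_del = _wls_jackknife(X, y, w, n_jackknife_blocks)
    g = coef_del.shape[0]
    scale = M / n
    if intercept_free:
        est = np.array([coef[0], coef[1] * scale])
        dels = np.column_stack([coef_del[:, 0], coef_del[:, 1] * scale])
    else:
        est = np.array([1.0, coef[0] * scale])
        dels = np.column_stack([np.ones(g), coef_del[:, 0] * scale])
    cov = _jackknife_cov(dels)
    return H2Estimate(
        trait=table.trait, h2=float(est[1]), h2_se=float(np.sqrt(cov[1, 1])),
        intercept=float(est[0]),
        intercept_se=float(np.sqrt(cov[0, 0])) if intercept_free else 0.0,
        mean_chi2=float(chi2.mean()), n_blocks=g,
        negative_flag=bool(est[1] <= 0), delete_values=dels)


def _gencov_regression(z1, z2, n1, n2, l, M, n_jackknife_blocks):
    """Cross-trait regression of z1*z2 on l with variance-matched weights.

    The weight 1/(v1 v2 + m_xy^2) uses per-trait variance curves and the
    cross-product mean, all from unweighted first passes, so that with
    identical inputs it reduces exactly to the chi-square weight 1/(2 v^2)
    and the self-covariance equals the heritability estimate.
    """
    y = z1 * z2
    X = np.column_stack([np.ones(M), l])
    scale = M / np.sqrt(n1 * n2)
    v = []
    for z, n in ((z1, n1), (z2, n2)):
        c, _ = _wls_jackknife(X, z ** 2, np.ones(M), 1)
        h2_hat = np.clip(c[1] * M / n, 0.0, 1.0)
        v.append(np.maximum(c[0] + n * h2_hat * l / M, 0.1))
    c, _ = _wls_jackknife(X, y, np.ones(M), 1)
    rho_hat = np.clip(c[1] * scale, -1.0, 1.0)
    mean_xy = np.clip(c[0] + np.sqrt(n1 * n2) * rho_hat * l / M,
                      -np.sqrt(v[0] * v[1]), np.sqrt(v[0] * v[1]))
    w = 1.0 / (v[0] * v[1] + mean_xy ** 2)
    coef, coef_del = _wls_jackknife(X, y, w, n_jackknife_blocks)
    dels = np.column_stack([coef_del[:, 0], coef_del[:, 1] * scale])
    return np.array([coef[0], coef[1] * scale]), dels


def estimate_rg(t1: SumStatsTable, t2: SumStatsTable, reference: LDReference,
                n_jackknife_blocks: int = 200) -> RgEstimate:
    """Genetic covariance and correlation between two traits.

    The free intercept of the cross-trait regression is the sample-overlap
    term; rg = gencov / sqrt(h2_1 * h2_2) with a delete-one block jackknife
    propagating uncertainty through all three regressions jointly.
    """
    e1 = estimate_h2(t1, reference, n_jackknife_blocks)
    e2 = estimate_h2(t2, reference, n_jackknife_blocks)
    if e1.h2 <= 0 or e2.h2 <= 0:
        raise ValueError("rg undefined: non-positive heritability estimate")
    z1, z2 = _check_harmonized(t1, reference), _check_harmonized(t2, reference)
    l = reference.ld_scores().to_numpy()
    M = reference.m
    n1, n2 = float(np.mean(t1.n)), float(np.mean(t2.n))
    est, dels = _gencov_regression(z1, z2, n1, n2, l, M, n_jackknife_blocks)
    gencov = est[1]
    rg_full = gencov / np.sqrt(e1.h2 * e2.h2)
    denom = np.sqrt(np.clip(e1.delete_values[:, 1] * e2.delete_values[:, 1], 1e-12, None))
    rg_del = dels[:, 1] / denom
    cov = _jackknife_cov(np.column_stack([dels, rg_del]))
    rg_se = float(np.sqrt(cov[2, 2]))
    clipped = abs(rg_full) > 1.0
    unstable = abs(rg_full) > 1.25
    rg_val = float(np.clip(rg_full, -1.0, 1.0))
    zstat = rg_full / rg_se if rg_se > 0 else np.inf
    p = float(2.0 * norm.sf(abs(zstat)))
    return RgEstimate(
        traits=(t1.trait, t2.trait), gencov=float(gencov),
        gencov_se=float(np.sqrt(cov[1, 1])), intercept=float(est[0]),
        intercept_se=float(np.sqrt(cov[0, 0])), rg=rg_val, rg_se=rg_se, p=p,
        ci=(float(rg_full - 1.96 * rg_se), float(rg_full + 1.96 * rg_se)),
        clipped=clipped, unstable=unstable,
        delete_values=np.column_stack([dels, rg_del]))


def sample_overlap_flag(rg: RgEstimate) -> bool:
    """True when the cross-trait intercept sits more than 1 SE from zero."""
    return abs(rg.intercept) > rg.intercept_se


def multivariable_ldsc(tables: Sequence[SumStatsTable], reference: LDReference,
                       n_jackknife_blocks: int = 200) -> GenCov:
    """Genetic covariance matrix S with jackknife sampling covariance V.

    Every pairwise regression shares the same block partition so that the
    delete-one values of all k(k+1)/2 unique S elements can be combined into
    one sampling covariance matrix; V is projected to the PSD cone (with a
    flag) if numerical noise pushes an eigenvalue below zero.
    """
    k = len(tables)
    if k < 2:
        raise ValueError("need at least two traits")
    l = reference.ld_scores().to_numpy()
    M = reference.m
    h2s = [estimate_h2(t, reference, n_jackknife_blocks) for t in tables]
    g = h2s[0].n_blocks
    p = k * (k + 1) // 2
    dels = np.empty((g, p))
    S = np.zeros((k, k))
    icpts = np.zeros((k, k))
    col = 0
    singular = False
    for i in range(k):
        for j in range(i, k):
            if i == j:
                S[i, i] = h2s[i].h2
                icpts[i, i] = h2s[i].intercept
                dels[:, col] = h2s[i].delete_values[:, 1]
            else:
                zi, zj = tables[i].z, tables[j].z
                ni, nj = float(np.mean(tables[i].n)), float(np.mean(tables[j].n))
                est, d = _gencov_regression(zi, zj, ni, nj, l, M,
                                            n_jackknife_blocks)
                S[i, j] = S[j, i] = est[1]
                icpts[i, j] = icpts[j, i] = est[0]
                dels[:, col] = d[:, 1]
            col += 1
    V = _jackknife_cov(dels)
    w, Q = np.linalg.eigh(V)
    projected = False
    if w.min() < 0:
        projected = True
        V = (Q * np.maximum(w, 1e-12)) @ Q.T
    if np.linalg.matrix_rank(S, tol=1e-10) < k:
        singular = True
    gc = GenCov(traits=[t.trait for t in tables], S=S, V=V,
                intercepts=icpts, v_projected=projected)
    gc.singular = singular
    return gc


# ---------------------------------------------------------------------------
# expression-specificity annotations and partitioned enrichment
# ---------------------------------------------------------------------------

def tdep_annotation(expression: pd.DataFrame, gene_intervals: pd.DataFrame,
                    reference: LDReference, flank_kb: float = 100.0,
                    decile: int = 10) -> pd.DataFrame:
    """Top-decile expression-proportion (TDEP) variant annotations.

    ``expression`` is genes x categories (non-negative); specificity is each
    gene's expression share across categories.  Per category the genes in
    the top 1/decile of specificity form the TDEP set; the annotation marks
    every reference variant within a flank-extended TDEP gene interval.
    ``gene_intervals`` needs columns gene, chrom, start, end (1-based).
    """
    if (expression.to_numpy() < 0).any():
        raise ValueError("expression must be non-negative")
    zero_cat = expression.sum(axis=0) == 0
    if zero_cat.any():
        raise ValueError(f"categories with all-zero expression: {list(expression.columns[zero_cat])}")
    total = expression.sum(axis=1)
    expr = expression.loc[total > 0]
    spec = expr.div(expr.sum(axis=1), axis=0)
    n_top = max(1, int(np.ceil(len(spec) / decile)))
    pos = reference.positions().reset_index()
    gi = gene_intervals.set_index("gene")
    out = {}
    flank = flank_kb * 1000.0
    for cat in spec.columns:
        top = spec[cat].nlargest(n_top).index
        mask = np.zeros(len(pos), dtype=bool)
        for gene in top:
            row = gi.loc[gene]
            hit = ((pos["CHR"] == row["chrom"])
                   & (pos["BP"] >= row["start"] - flank)
                   & (pos["BP"] <= row["end"] + flank))
            mask |= hit.to_numpy()
        out[cat] = mask.astype(int)
    return pd.DataFrame(out, index=pos["SNP"])


def _annotation_ld_scores(reference: LDReference, annot: np.ndarray) -> np.ndarray:
    """l_aj = sum over block members k of r^2_jk * a_k."""
    out = np.empty(reference.m)
    row = 0
    for block in reference.blocks:
        m = len(block)
        out[row:row + m] = (block.R ** 2) @ annot[row:row + m]
        row += m
    return out


def partitioned_enrichment(table: SumStatsTable, reference: LDReference,
                           target_annotations: pd.DataFrame,
                           baseline_annotations: pd.DataFrame | None = None,
                           n_jackknife_blocks: int = 200) -> list[EnrichmentResult]:
    """Multi-annotation LDSC with one-sided enrichment tests per target.

    chi^2 is regressed on per-annotation LD scores (baseline always includes
    the all-ones annotation); each target's coefficient is tested one-sided
    for positive enrichment and BH-FDR is applied over the targets tested in
    this call.  Collinear target columns are flagged non-identifiable.
    """
    z = _check_harmonized(table, reference)
    M = reference.m
    n = float(np.mean(table.n))
    chi2 = z ** 2
    base = {"__all__": np.ones(M)}
    if baseline_annotations is not None:
        for c in baseline_annotations.columns:
            base[c] = baseline_annotations[c].to_numpy(float)
    cols, names = [], []
    for name, a in base.items():
        cols.append(_annotation_ld_scores(reference, a))
        names.append(name)
    target_cols = []
    for c in target_annotations.columns:
        target_cols.append(_annotation_ld_scores(reference, target_annotations[c].to_numpy(float)))
    Xb = np.column_stack([np.ones(M)] + cols)
    results: list[EnrichmentResult] = []
    l_tot = cols[0]
    for name, lx in zip(target_annotations.columns, target_cols):
        X = np.column_stack([Xb, lx])
        if np.linalg.matrix_rank(X, tol=1e-8) < X.shape[1]:
            results.append(EnrichmentResult(name, np.nan, np.nan, np.nan,
                                            non_identifiable=True))
            continue
        w = np.ones(M)
        for _ in range(2):
            coef, _ = _wls_jackknife(X, chi2, w, 1)
            fitted = np.maximum(X @ coef, 0.1)
            w = 1.0 / (2.0 * fitted ** 2)
        coef, coef_del = _wls_jackknife(X, chi2, w, n_jackknife_blocks)
        cov = _jackknife_cov(coef_del)
        tau, se = coef[-1], np.sqrt(cov[-1, -1])
        zstat = tau / se if se > 0 else 0.0
        results.append(EnrichmentResult(name, float(tau * M / n), float(zstat),
                                        float(norm.sf(zstat))))
    tested = [r for r in results if not r.non_identifiable]
    if tested:
        padj = multipletests([r.p for r in tested], method="fdr_bh")[1]
        for r, q in zip(tested, padj):
            r.p_fdr = float(q)
    return results
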