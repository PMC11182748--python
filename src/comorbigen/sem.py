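"""Structural equation modelling on genetic covariance matrices.

Models are specified in RAM form: a directed-path matrix A (regressions and
factor loadings), a symmetric matrix S2 (variances and covariances of
exogenous terms and residuals) and a filter onto the observed traits, so the
model-implied genetic covariance is

    Sigma(theta) = F (I - A)^-1 S2 (I - A)^-T F'

Estimation is diagonally weighted least squares on the unique elements of
the LDSC genetic covariance matrix S, with the diagonal of its sampling
covariance V as weights and sandwich standard errors using the full V.
This supports higher-order factors (a latent ASCVD factor over the
atherosclerotic traits, and a comorbidity factor over MDD plus ASCVD),
per-SNP common-versus-independent pathway contrasts (the Q heterogeneity
test), covariate-adjusted genetic correlations, and mediation models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2 as chi2_dist, norm

from .ldsc import GenCov
from .sumstats import SumStatsTable

__all__ = ["ModelSpec", "FactorModelFit", "parse_model", "fit_model",
           "mdd_ascvd_spec", "fit_mdd_ascvd", "factor_gwas",
           "filter_heterogeneous", "adjusted_rg", "mediation_model",
           "AdjustedRg", "MediationResult"]


class SemError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# model specification
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """RAM-form model: observed + latent variables, paths, (co)variances.

    ``paths`` entries are (child, parent, fixed) with ``fixed=None`` for a
    free loading/regression; ``variances`` entries are (a, b, fixed) for
    S2[a, b] (a == b gives a variance).  Any variable without an explicit
    variance line receives a free one.
    """

    observed: list[str]
    latent: list[str] = field(default_factory=list)
    paths: list[tuple[str, str, float | None]] = field(default_factory=list)
    variances: list[tuple[str, str, float | None]] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = self.observed + self.latent
        if len(set(names)) != len(names):
            raise SemError("duplicate variable names")
        have_var = {(a, b) for a, b, _ in self.variances}
        for v in names:
            if (v, v) not in have_var:
                self.variances.append((v, v, None))
        self._index = {v: i for i, v in enumerate(names)}

    @property
    def names(self) -> list[str]:
        return self.observed + self.latent

    @property
    def free_labels(self) -> list[str]:
        labels = [f"{c}~{p}" for c, p, f in self.paths if f is None]
        labels += [f"{a}~~{b}" for a, b, f in self.variances if f is None]
        return labels

    @property
    def n_free(self) -> int:
        return len(self.free_labels)

    def matrices(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        nv = len(self.names)
        A = np.zeros((nv, nv))
        S2 = np.zeros((nv, nv))
        it = iter(theta)
        for c, p, fixedv in self.paths:
            A[self._index[c], self._index[p]] = next(it) if fixedv is None else fixedv
        for a, b, fixedv in self.variances:
            val = next(it) if fixedv is None else fixedv
            i, j = self._index[a], self._index[b]
            S2[i, j] = S2[j, i] = val
        return A, S2


def parse_model(text: str, observed: Sequence[str]) -> ModelSpec:
    """Parse the small model DSL.

    One statement per line: ``FACTOR -> trait`` (free loading),
    ``FACTOR -> trait @1`` (fixed), ``trait ~~ @0`` (fixed variance),
    ``a ~~ b`` (free covariance).  Variables not in ``observed`` are latent.
    """
    paths: list[tuple[str, str, float | None]] = []
    variances: list[tuple[str, str, float | None]] = []
    seen: set[str] = set()
    for raw in text.strip().splitlines():
        line = raw.split("#")[0].strip()
        if not line:
            continue
        if "->" in line:
            lhs, rhs = [s.strip() for s in line.split("->")]
            parts = rhs.split()
            child = parts[0]
            fixedv = float(parts[1][1:]) if len(parts) > 1 and parts[1].startswith("@") else None
            paths.append((child, lhs, fixedv))
            seen.update([lhs, child])
        elif "~~" in line:
            lhs, rhs = [s.strip() for s in line.split("~~")]
            parts = rhs.split()
            if parts and parts[0].startswith("@"):
                variances.append((lhs, lhs, float(parts[0][1:])))
                seen.add(lhs)
            else:
                other = parts[0]
                fixedv = float(parts[1][1:]) if len(parts) > 1 and parts[1].startswith("@") else None
                variances.append((lhs, other, fixedv))
                seen.update([lhs, other])
        else:
            raise SemError(f"unparseable model line: {raw!r}")
    latent = [v for v in seen if v not in observed]
    return ModelSpec(observed=list(observed), latent=sorted(latent),
                     paths=paths, variances=variances)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FactorModelFit:
    spec: ModelSpec
    theta: np.ndarray
    se: np.ndarray
    theta_cov: np.ndarray
    chi2: float
    df: int
    p: float
    cfi: float
    srmr: float
    converged: bool
    heywood: bool
    implied: np.ndarray

    @property
    def params(self) -> dict[str, tuple[float, float]]:
        return {lab: (float(t), float(s))
                for lab, t, s in zip(self.spec.free_labels, self.theta, self.se)}

    def estimate(self, label: str) -> float:
        return self.params[label][0]

    def se_of(self, label: str) -> float:
        return self.params[label][1]

    def standardized_loadings(self) -> dict[str, float]:
        """Loadings scaled by parent-SD / child-SD (genetic-variance metric)."""
        A, S2 = self.spec.matrices(self.theta)
        nv = A.shape[0]
        B = np.linalg.solve(np.eye(nv) - A, S2)
        C = np.linalg.solve(np.eye(nv) - A, B.T).T  # (I-A)^-1 S2 (I-A)^-T
        sd = np.sqrt(np.clip(np.diag(C), 1e-30, None))
        idx = self.spec._index
        out = {}
        for c, p, fixedv in self.spec.paths:
            val = A[idx[c], idx[p]]
            out[f"{c}~{p}"] = float(val * sd[idx[p]] / sd[idx[c]])
        return out


def _vech(M: np.ndarray) -> np.ndarray:
    return M[np.triu_indices(M.shape[0])]


def _implied(spec: ModelSpec, theta: np.ndarray) -> np.ndarray:
    A, S2 = spec.matrices(theta)
    nv = A.shape[0]
    ImA = np.eye(nv) - A
    T = np.linalg.solve(ImA, S2)
    C = np.linalg.solve(ImA, T.T).T
    k = len(spec.observed)
    return C[:k, :k]


def _start_values(spec: ModelSpec, S: np.ndarray, jitter: float, rng) -> np.ndarray:
    theta = []
    mean_var = float(np.mean(np.diag(S)))
    for c, p, fixedv in spec.paths:
        if fixedv is None:
            theta.append(0.5 + jitter * rng.standard_normal())
    for a, b, fixedv in spec.variances:
        if fixedv is None:
            theta.append((0.5 * mean_var if a == b else 0.0) + jitter * 0.1 * rng.standard_normal())
    return np.array(theta)


def _model_chi2(s_obs: np.ndarray, s_hat: np.ndarray, V: np.ndarray) -> float:
    r = s_obs - s_hat
    return float(r @ np.linalg.pinv(V, rcond=1e-10) @ r)


def fit_model(gencov: GenCov, spec: ModelSpec, n_starts: int = 3,
              seed: int = 0) -> FactorModelFit:
    """Diagonally weighted least squares fit with sandwich standard errors.

    The objective is (s - sigma(theta))' D^-1 (s - sigma(theta)) with
    D = diag(V); three deterministically jittered starts guard against local
    minima; CFI is computed against the independence model (all covariances
    zero) and SRMR on the correlation-scale residual matrix.
    """
    if spec.observed != list(gencov.traits):
        raise SemError("spec observed traits must match GenCov traits (order included)")
    S, V = gencov.S, gencov.V
    s_obs = _vech(S)
    d = np.sqrt(np.clip(np.diag(V), 1e-30, None))
    k = len(spec.observed)
    n_moments = k * (k + 1) // 2
    df = n_moments - spec.n_free
    if df < 0:
        raise SemError("model has more free parameters than moments")

    def resid(theta):
        return (s_obs - _vech(_implied(spec, theta))) / d

    rng = np.random.default_rng(seed)
    # local identifiability: Jacobian rank at start values
    theta0 = _start_values(spec, S, 0.0, rng)
    J0 = _num_jac(lambda t: _vech(_implied(spec, t)), theta0)
    if np.linalg.matrix_rank(J0, tol=1e-10) < spec.n_free:
        raise SemError("model not locally identified at start values")

    best = None
    for i in range(n_starts):
        x0 = _start_values(spec, S, 0.0 if i == 0 else 0.3, rng)
        res = least_squares(resid, x0, method="lm" if spec.n_free < n_moments else "trf",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise SemError("optimizer failed from all starts")
    theta = best.x
    s_hat = _vech(_implied(spec, theta))

    # sandwich covariance of theta using the full sampling covariance V
    Delta = _num_jac(lambda t: _vech(_implied(spec, t)), theta)
    W = np.diag(1.0 / np.clip(np.diag(V), 1e-30, None))
    bread = np.linalg.pinv(Delta.T @ W @ Delta, rcond=1e-12)
    meat = Delta.T @ W @ V @ W @ Delta
    theta_cov = bread @ meat @ bread
    se = np.sqrt(np.clip(np.diag(theta_cov), 0.0, None))

    chi2 = _model_chi2(s_obs, s_hat, V)
    p = float(chi2_dist.sf(chi2, df)) if df > 0 else np.nan
    # independence baseline: diagonal of S, zero covariances
    s_base = _vech(np.diag(np.diag(S)))
    chi2_b = _model_chi2(s_obs, s_base, V)
    df_b = n_moments - k
    num = max(chi2 - df, 0.0)
    den = max(chi2_b - df_b, num, 1e-30)
    cfi = 1.0 - num / den if den > 0 else 1.0
    dsd = np.sqrt(np.clip(np.diag(S), 1e-30, None))
    resmat = (S - _implied(spec, theta)) / np.outer(dsd, dsd)
    srmr = float(np.sqrt(np.mean(_vech(resmat) ** 2)))
    heywood = any(
        theta[i] < 0
        for i, (a, b, f) in enumerate(
            [(a, b, f) for a, b, f in spec.variances if f is None],
            start=sum(1 for _, _, f in spec.paths if f is None))
        if a == b
    )
    return FactorModelFit(spec=spec, theta=theta, se=se, theta_cov=theta_cov,
                          chi2=chi2, df=df, p=p, cfi=float(min(cfi, 1.0)),
                          srmr=srmr, converged=bool(best.success), heywood=heywood,
                          implied=_implied(spec, theta))


def _num_jac(f, x, eps: float = 1e-6) -> np.ndarray:
    f0 = f(x)
    J = np.empty((len(f0), len(x)))
    for i in range(len(x)):
        xp = x.copy()
        xp[i] += eps
        J[:, i] = (f(xp) - f0) / eps
    return J


# ---------------------------------------------------------------------------
# the comorbidity factor design
# ---------------------------------------------------------------------------

def mdd_ascvd_spec(traits: Sequence[str]) -> ModelSpec:
    """Two-level design: an ASCVD factor over the four atherosclerotic
    traits (first loading fixed to 1) and a higher-order comorbidity factor
    over MDD plus ASCVD, with the MDD loading fixed to 1 and the ASCVD
    factor's residual variance fixed to 0 so all its variance is forced into
    the higher-order factor.

    ``traits`` order: (MDD, CAD, PAD, HF, STROKE) — names are free, roles
    are positional.
    """
    mdd, cad, pad, hf, stroke = traits
    lines = [
        f"ASCVD -> {cad} @1",
        f"ASCVD -> {pad}",
        f"ASCVD -> {hf}",
        f"ASCVD -> {stroke}",
        f"COMORB -> {mdd} @1",
        "COMORB -> ASCVD",
        "ASCVD ~~ @0",
    ]
    return parse_model("\n".join(lines), observed=list(traits))


def fit_mdd_ascvd(gencov: GenCov, seed: int = 0) -> FactorModelFit:
    """Fit the two-level comorbidity-factor model to a 5-trait GenCov."""
    if len(gencov.traits) != 5:
        raise SemError("expected a 5-trait genetic covariance matrix")
    return fit_model(gencov, mdd_ascvd_spec(gencov.traits), seed=seed)


# ---------------------------------------------------------------------------
# per-SNP factor GWAS with heterogeneity filtering
# ---------------------------------------------------------------------------

def factor_gwas(fit: FactorModelFit, tables: Sequence[SumStatsTable],
                factor: str = "COMORB", q_alpha: float = 0.05) -> pd.DataFrame:
    """Summary-statistics GWAS on a latent factor with the Q heterogeneity test.

    Works on the standardized-genotype scale: each trait's per-variant
    standardized effect g_t = z_t / sqrt(n_t) estimates cov(SNP, trait) with
    sampling variance 1/n_t.  Under the common-pathway model those
    covariances are proportional to the traits' model-implied total loadings
    w on the target factor; the weighted projection gives the SNP's factor
    effect, and the weighted residual is the common-pathway chi-square.  The
    independent-pathway model regresses every trait on the SNP directly and
    saturates those moments (chi-square 0), so

        Q = chi2_common - chi2_independent ~ chi2_{k-1}  under homogeneity.

    Cross-trait sampling covariance of g (sample overlap) is approximated as
    zero, a stated limitation.  Returns one row per variant shared by all
    tables, flagged heterogeneous when p_Q < ``q_alpha``.
    """
    spec = fit.spec
    if factor not in spec.latent:
        raise SemError(f"{factor!r} is not a latent variable of the fitted model")
    A, S2 = spec.matrices(fit.theta)
    nv = A.shape[0]
    total = np.linalg.inv(np.eye(nv) - A)
    k = len(spec.observed)
    w = total[:k, spec._index[factor]]
    if np.allclose(w, 0.0):
        raise SemError("target factor has no pathway to any observed trait")

    common = set(tables[0].df["SNP"])
    for t in tables[1:]:
        common &= set(t.df["SNP"])
    base = tables[0].indexed()
    order = [s for s in tables[0].df["SNP"] if s in common]
    n_skipped = len(tables[0]) - len(order)
    G = np.empty((len(order), k))
    Vg = np.empty(k)
    for j, t in enumerate(tables):
        dfj = t.indexed().loc[order]
        nj = dfj["N"].to_numpy(float)
        G[:, j] = dfj["Z"].to_numpy(float) / np.sqrt(nj)
        Vg[j] = 1.0 / float(np.mean(nj))
    iv = 1.0 / Vg
    denom = float(w @ (iv * w))
    b = (G * (iv * w)).sum(axis=1) / denom
    se_b = 1.0 / np.sqrt(denom)
    chi2_common = (G ** 2 * iv).sum(axis=1) - b ** 2 * denom
    chi2_common = np.maximum(chi2_common, 0.0)
    chi2_independent = np.zeros_like(chi2_common)
    q = chi2_common - chi2_independent
    p_q = chi2_dist.sf(q, df=k - 1)
    z = b / se_b
    p = 2.0 * norm.sf(np.abs(z))
    ref = base.loc[order]
    out = pd.DataFrame({
        "SNP": order,
        "CHR": ref["CHR"].to_numpy(),
        "BP": ref["BP"].to_numpy(),
        "A1": ref["A1"].to_numpy(),
        "A2": ref["A2"].to_numpy(),
        "FREQ": ref["FREQ"].to_numpy(),
        "BETA": b,
        "SE": se_b,
        "Z": z,
        "P": np.clip(p, np.finfo(float).tiny, 1.0),
        "N": 1.0 / se_b ** 2,
        "chi2_common": chi2_common,
        "chi2_independent": chi2_independent,
        "Q": q,
        "p_Q": p_q,
        "heterogeneous": p_q < q_alpha,
    })
    out.attrs["n_skipped"] = n_skipped
    return out


def filter_heterogeneous(results: pd.DataFrame, gws_p: float = 5e-8):
    """Drop heterogeneity-flagged variants; report the flagged share among
    genome-wide significant variants.  Returns (filtered frame, share)."""
    sig = results.loc[results["P"] < gws_p]
    share = float(sig["heterogeneous"].mean()) if len(sig) else 0.0
    return results.loc[~results["heterogeneous"]].reset_index(drop=True), share


def factor_sumstats(results: pd.DataFrame, trait: str = "factor") -> SumStatsTable:
    """Package factor-GWAS output in the sumstats dialect for clumping/MR."""
    df = results[["SNP", "CHR", "BP", "A1", "A2", "FREQ",
                  "BETA", "SE", "Z", "P", "N"]].reset_index(drop=True)
    return SumStatsTable(trait, df.copy())


# ---------------------------------------------------------------------------
# adjusted genetic correlation and mediation
# ---------------------------------------------------------------------------

@dataclass
class AdjustedRg:
    x: str
    y: str
    covariates: list[str]
    rg_adj: float
    se: float
    ci: tuple[float, float]
    ridge_used: bool = False
    degenerate: bool = False


def _partial_rg_from_flat(flat: np.ndarray, k: int, ix: int, iy: int,
                          ic: list[int], ridge: float = 0.0):
    S = np.zeros((k, k))
    S[np.triu_indices(k)] = flat
    S = S + np.triu(S, 1).T
    if not ic:
        return S[ix, iy] / np.sqrt(S[ix, ix] * S[iy, iy]), False
    Scc = S[np.ix_(ic, ic)]
    ridge_used = False
    try:
        cond = np.linalg.cond(Scc)
    except np.linalg.LinAlgError:
        cond = np.inf
    if cond > 1e10:
        Scc = Scc + ridge * np.eye(len(ic))
        ridge_used = True
    inv = np.linalg.solve(Scc, np.column_stack([S[ic, ix], S[ic, iy]]))
    pxy = S[ix, iy] - S[ix, ic] @ inv[:, 1]
    pxx = S[ix, ix] - S[ix, ic] @ inv[:, 0]
    pyy = S[iy, iy] - S[iy, ic] @ np.linalg.solve(Scc, S[ic, iy])
    if pxx <= 0 or pyy <= 0:
        return np.nan, ridge_used
    return pxy / np.sqrt(pxx * pyy), ridge_used


def adjusted_rg(gencov: GenCov, x: str, y: str,
                covariates: Sequence[str] = ()) -> AdjustedRg:
    """Genetic correlation of x and y partialled on a covariate set.

    The partial genetic covariance S_xy - S_xc S_cc^-1 S_cy is standardized
    by the analogously partialled variances; the SE comes from the delta
    method on the sampling covariance V (numeric gradient over the unique
    elements of S).  A near-singular covariate block is ridge-regularized
    with a flag; a non-positive partialled variance marks the estimate
    degenerate.
    """
    traits = gencov.traits
    ix, iy = traits.index(x), traits.index(y)
    ic = [traits.index(c) for c in covariates]
    if ix in ic or iy in ic:
        raise SemError("covariates must exclude x and y")
    k = len(traits)
    flat = gencov.flat()
    ridge = 1e-4 * float(np.mean(np.diag(gencov.S)))
    val, ridge_used = _partial_rg_from_flat(flat, k, ix, iy, ic, ridge)
    if not np.isfinite(val):
        return AdjustedRg(x, y, list(covariates), np.nan, np.nan,
                          (np.nan, np.nan), ridge_used, degenerate=True)
    eps = 1e-7
    grad = np.empty(len(flat))
    for i in range(len(flat)):
        fp = flat.copy()
        fp[i] += eps
        vp, _ = _partial_rg_from_flat(fp, k, ix, iy, ic, ridge)
        grad[i] = (vp - val) / eps
    var = float(grad @ gencov.V @ grad)
    se = float(np.sqrt(max(var, 0.0)))
    return AdjustedRg(x, y, list(covariates), float(val), se,
                      (float(val - 1.96 * se), float(val + 1.96 * se)), ridge_used)


@dataclass
class MediationResult:
    x: str
    y: str
    mediators: list[str]
    direct: float
    direct_se: float
    direct_ci: tuple[float, float]
    direct_std: float
    indirect: float
    indirect_se: float
    total: float
    covariate_estimate: AdjustedRg
    mediation_supported: bool
    fit: FactorModelFit


def mediation_model(gencov: GenCov, x: str, mediators: Sequence[str], y: str,
                    seed: int = 0) -> MediationResult:
    """Explicit mediation SEM x -> m -> y versus the covariate-adjusted model.

    Fits the path model with x -> each mediator, each mediator -> y and the
    direct path x -> y (mediator residuals covary freely); the indirect
    effect is the sum of path products with a delta-method SE.  The decision
    rule mirrors covariate-versus-mediator comparison practice: mediation is
    supported when the mediator-model direct effect's 95% CI and the
    covariate-model (partialled) estimate's 95% CI do not overlap.
    """
    traits = [x] + list(mediators) + [y]
    idx = [gencov.traits.index(t) for t in traits]
    k = len(traits)
    S = gencov.S[np.ix_(idx, idx)]
    flat_idx = [gencov.index_of(i, j) for a, i in enumerate(idx) for j in idx[a:]]
    # rebuild index list in the sub-matrix's own upper-triangle order
    flat_idx = []
    for a in range(k):
        for b_ in range(a, k):
            flat_idx.append(gencov.index_of(idx[a], idx[b_]))
    V = gencov.V[np.ix_(flat_idx, flat_idx)]
    sub = GenCov(traits=traits, S=S, V=V,
                 intercepts=gencov.intercepts[np.ix_(idx, idx)])
    # x and the mediators enter one regression equation for y: their genetic
    # covariance block must be well-conditioned for the paths to separate
    pred = S[:-1, :-1]
    d = np.sqrt(np.clip(np.diag(pred), 1e-30, None))
    corr = pred / np.outer(d, d)
    if np.linalg.cond(corr) > 1e6:
        raise SemError("mediator set collinear with the exposure: paths not identified")
    lines = []
    for m in mediators:
        lines.append(f"{x} -> {m}")
        lines.append(f"{m} -> {y}")
    lines.append(f"{x} -> {y}")
    for i, m1 in enumerate(mediators):
        for m2 in list(mediators)[i + 1:]:
            lines.append(f"{m1} ~~ {m2}")
    spec = parse_model("\n".join(lines), observed=traits)
    fit = fit_model(sub, spec, seed=seed)
    params = fit.params
    direct, direct_se = params[f"{y}~{x}"]
    labels = fit.spec.free_labels
    cov = fit.theta_cov
    ind = 0.0
    grad = np.zeros(len(labels))
    for m in mediators:
        a_lab, b_lab = f"{m}~{x}", f"{y}~{m}"
        ia, ib = labels.index(a_lab), labels.index(b_lab)
        a_val, b_val = fit.theta[ia], fit.theta[ib]
        ind += a_val * b_val
        grad[ia] += b_val
        grad[ib] += a_val
    ind_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    sd_x = np.sqrt(S[0, 0])
    sd_y = np.sqrt(S[-1, -1])
    direct_std = float(direct * sd_x / sd_y)
    cov_est = adjusted_rg(gencov, x, y, mediators)
    lo_m = direct_std - 1.96 * direct_se * sd_x / sd_y
    hi_m = direct_std + 1.96 * direct_se * sd_x / sd_y
    supported = bool(np.isfinite(cov_est.se)
                     and (hi_m < cov_est.ci[0] or lo_m > cov_est.ci[1]))
    return MediationResult(
        x=x, y=y, mediators=list(mediators), direct=float(direct),
        direct_se=float(direct_se),
        direct_ci=(float(direct - 1.96 * direct_se), float(direct + 1.96 * direct_se)),
        direct_std=direct_std, indirect=float(ind), indirect_se=ind_se,
        total=float(direct + ind), covariate_estimate=cov_est,
        mediation_supported=supported, fit=fit)
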