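"""Two-sample and multivariable Mendelian randomization.

Instruments are independent lead variants for the exposure, oriented to the
exposure-increasing allele and Steiger-filtered (variants explaining
significantly more variance in the outcome than the exposure are removed as
likely reverse-causal).  The estimator battery is inverse-variance weighting
(multiplicative random effects by default), MR-Egger with the I2_GX
no-measurement-error guard, weighted median and weighted mode, plus a
multivariable IVW for risk-factor adjustment.  Effects are on the scale of
the input betas (log odds ratios for binary outcomes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist, norm

from .ldref import EmptyInstrumentsError, LDReference, clump, select_instruments
from .sumstats import SumStatsTable

__all__ = ["InstrumentSet", "MRFit", "build_instruments", "steiger_filter",
           "ivw", "egger", "weighted_median", "weighted_mode", "mvmr",
           "sensitivity_report", "SensitivityVerdict"]


@dataclass
class InstrumentSet:
    """Harmonized instrument effects for one exposure-outcome pair."""

    exposure: str
    outcome: str
    df: pd.DataFrame  # SNP, beta_exp, se_exp, beta_out, se_out, n_exp, n_out
    threshold_used: float = 5e-8
    steiger_removed: int = 0

    def __post_init__(self) -> None:
        if self.df["SNP"].duplicated().any():
            raise ValueError("duplicate instrument variants")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def bx(self) -> np.ndarray:
        return self.df["beta_exp"].to_numpy(float)

    @property
    def by(self) -> np.ndarray:
        return self.df["beta_out"].to_numpy(float)

    @property
    def sx(self) -> np.ndarray:
        return self.df["se_exp"].to_numpy(float)

    @property
    def sy(self) -> np.ndarray:
        return self.df["se_out"].to_numpy(float)

    @property
    def mean_f(self) -> float:
        return float(np.mean((self.bx / self.sx) ** 2))


@dataclass
class MRFit:
    method: str
    exposure: str
    outcome: str
    beta: float
    se: float
    p: float
    ci: tuple[float, float]
    n_instruments: int
    Q: float = np.nan
    Q_p: float = np.nan
    egger_intercept: float = np.nan
    egger_intercept_se: float = np.nan
    egger_intercept_p: float = np.nan
    i2_gx: float = np.nan
    mean_f: float = np.nan
    suppressed: bool = False   # Egger slope withheld under NOME violation
    steiger_removed: int = 0
    threshold_used: float = np.nan


def build_instruments(exposure: SumStatsTable, outcome: SumStatsTable,
                      reference: LDReference, orient: bool = True,
                      apply_steiger: bool = True, **select_kwargs) -> InstrumentSet:
    """Select, harmonize and filter instruments for one exposure-outcome pair.

    Lead variants come from :func:`comorbigen.ldref.select_instruments`
    (genome-wide threshold with relaxed fallback); effects are joined from
    the two studies (which must already be allele-harmonized to the same
    reference), oriented so every exposure beta is non-negative, and Steiger
    filtered.
    """
    loci, threshold = select_instruments(exposure, reference, **select_kwargs)
    leads = [l.lead_snp for l in loci]
    e = exposure.indexed()
    o = outcome.indexed()
    leads = [s for s in leads if s in o.index]
    if not leads:
        raise EmptyInstrumentsError("no instrument present in the outcome study")
    df = pd.DataFrame({
        "SNP": leads,
        "beta_exp": e.loc[leads, "BETA"].to_numpy(float),
        "se_exp": e.loc[leads, "SE"].to_numpy(float),
        "beta_out": o.loc[leads, "BETA"].to_numpy(float),
        "se_out": o.loc[leads, "SE"].to_numpy(float),
        "n_exp": e.loc[leads, "N"].to_numpy(float),
        "n_out": o.loc[leads, "N"].to_numpy(float),
    })
    if orient:
        flip = df["beta_exp"] < 0
        df.loc[flip, ["beta_exp", "beta_out"]] *= -1.0
    inst = InstrumentSet(exposure.trait, outcome.trait, df, threshold_used=threshold)
    return steiger_filter(inst) if apply_steiger else inst


def steiger_filter(instruments: InstrumentSet, alpha: float = 0.05) -> InstrumentSet:
    """Remove instruments explaining significantly more outcome variance.

    Per variant, r^2 = z^2/(z^2 + n - 2) on each side; a one-sided Steiger
    z-test (Fisher-transformed correlation difference) at ``alpha`` removes
    variants whose outcome r^2 significantly exceeds the exposure r^2.
    """
    df = instruments.df
    zx = df["beta_exp"] / df["se_exp"]
    zy = df["beta_out"] / df["se_out"]
    nx, ny = df["n_exp"].to_numpy(float), df["n_out"].to_numpy(float)
    r2x = zx ** 2 / (zx ** 2 + nx - 2)
    r2y = zy ** 2 / (zy ** 2 + ny - 2)
    rx = np.sqrt(np.clip(r2x, 0, 1 - 1e-12))
    ry = np.sqrt(np.clip(r2y, 0, 1 - 1e-12))
    zstat = (np.arctanh(ry) - np.arctanh(rx)) / np.sqrt(
        1.0 / np.maximum(ny - 3, 1) + 1.0 / np.maximum(nx - 3, 1))
    remove = (r2y > r2x) & (norm.sf(zstat) < alpha)
    kept = df.loc[~remove.to_numpy()].reset_index(drop=True)
    if len(kept) == 0:
        raise EmptyInstrumentsError("Steiger filter removed every instrument")
    return InstrumentSet(instruments.exposure, instruments.outcome, kept,
                         threshold_used=instruments.threshold_used,
                         steiger_removed=instruments.steiger_removed + int(remove.sum()))


def _cochran_q(bx, by, sy, beta) -> float:
    return float(np.sum((by - beta * bx) ** 2 / sy ** 2))


def ivw(instruments: InstrumentSet, random_effects: bool = True) -> MRFit:
    """Inverse-variance-weighted estimate: weighted regression through origin.

    With multiplicative random effects (the default) the standard error is
    scaled by sqrt(Q / (L - 1)) when Cochran's Q exceeds its degrees of
    freedom, absorbing balanced heterogeneity.
    """
    L = len(instruments)
    if L < 2:
        raise ValueError("IVW needs >= 2 instruments (use a Wald ratio for one)")
    bx, by, sy = instruments.bx, instruments.by, instruments.sy
    w = 1.0 / sy ** 2
    denom = float(np.sum(w * bx ** 2))
    beta = float(np.sum(w * bx * by) / denom)
    se = 1.0 / np.sqrt(denom)
    Q = _cochran_q(bx, by, sy, beta)
    if random_effects:
        se *= np.sqrt(max(Q / (L - 1), 1.0))
    p = float(2 * norm.sf(abs(beta / se)))
    return MRFit("IVW", instruments.exposure, instruments.outcome, beta, float(se), p,
                 (beta - 1.96 * se, beta + 1.96 * se), L,
                 Q=Q, Q_p=float(chi2_dist.sf(Q, L - 1)),
                 mean_f=instruments.mean_f,
                 steiger_removed=instruments.steiger_removed,
                 threshold_used=instruments.threshold_used)


def egger(instruments: InstrumentSet, i2_threshold: float = 0.9) -> MRFit:
    """MR-Egger: weighted regression with a free (pleiotropy) intercept.

    I2_GX quantifies exposure-side measurement error; below ``i2_threshold``
    the NO-Measurement-Error assumption is considered violated and the slope
    is reported with a suppression flag.
    """
    L = len(instruments)
    if L < 3:
        raise ValueError("Egger needs >= 3 instruments")
    bx, by, sy, sx = instruments.bx, instruments.by, instruments.sy, instruments.sx
    w = 1.0 / sy ** 2
    X = np.column_stack([np.ones(L), bx])
    A = X.T @ (X * w[:, None])
    c = X.T @ (w * by)
    icpt, beta = np.linalg.solve(A, c)
    resid = by - icpt - beta * bx
    Q = float(np.sum(w * resid ** 2))
    sigma2 = max(Q / (L - 2), 1.0)  # multiplicative overdispersion
    cov = np.linalg.inv(A) * sigma2
    se_i, se_b = np.sqrt(np.diag(cov))
    wx = 1.0 / sx ** 2
    bx_bar = float(np.sum(wx * bx) / np.sum(wx))
    q_gx = float(np.sum(wx * (bx - bx_bar) ** 2))
    i2_gx = max((q_gx - (L - 1)) / q_gx, 0.0) if q_gx > 0 else 0.0
    p = float(2 * norm.sf(abs(beta / se_b)))
    return MRFit("Egger", instruments.exposure, instruments.outcome,
                 float(beta), float(se_b), p,
                 (float(beta - 1.96 * se_b), float(beta + 1.96 * se_b)), L,
                 Q=Q, Q_p=float(chi2_dist.sf(Q, L - 2)),
                 egger_intercept=float(icpt), egger_intercept_se=float(se_i),
                 egger_intercept_p=float(2 * norm.sf(abs(icpt / se_i))),
                 i2_gx=float(i2_gx), mean_f=instruments.mean_f,
                 suppressed=bool(i2_gx < i2_threshold),
                 steiger_removed=instruments.steiger_removed,
                 threshold_used=instruments.threshold_used)


def _weighted_median_estimate(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r, w = ratios[order], weights[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= w.sum()
    return float(np.interp(0.5, cw, r))


def weighted_median(instruments: InstrumentSet, n_boot: int = 1000,
                    seed: int = 0) -> MRFit:
    """Inverse-variance-weighted median of per-variant ratio estimates.

    Consistent when instruments carrying at least half the weight are valid;
    SE by parametric bootstrap with a fixed seed.
    """
    L = len(instruments)
    if L < 3:
        raise ValueError("weighted median needs >= 3 instruments")
    bx, by, sy = instruments.bx, instruments.by, instruments.sy
    ratios = by / bx
    se_r = sy / np.abs(bx)
    w = 1.0 / se_r ** 2
    beta = _weighted_median_estimate(ratios, w)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    sx = instruments.sx
    for i in range(n_boot):
        bx_b = bx + sx * rng.standard_normal(L)
        by_b = by + sy * rng.standard_normal(L)
        r_b = by_b / bx_b
        se_b = sy / np.abs(bx_b)
        boots[i] = _weighted_median_estimate(r_b, 1.0 / se_b ** 2)
    se = float(np.std(boots, ddof=1))
    p = float(2 * norm.sf(abs(beta / se))) if se > 0 else (0.0 if beta != 0 else 1.0)
    return MRFit("weighted-median", instruments.exposure, instruments.outcome,
                 beta, se, p, (beta - 1.96 * se, beta + 1.96 * se), L,
                 mean_f=instruments.mean_f,
                 steiger_removed=instruments.steiger_removed,
                 threshold_used=instruments.threshold_used)


def _mode_estimate(ratios: np.ndarray, weights: np.ndarray, h: float) -> float:
    lo, hi = ratios.min() - 3 * h, ratios.max() + 3 * h
    grid = np.linspace(lo, hi, 1024)
    dens = (weights[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2)).sum(axis=1)
    i = int(np.argmax(dens))
    if 0 < i < len(grid) - 1:  # parabolic refinement
        y0, y1, y2 = dens[i - 1], dens[i], dens[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            return float(grid[i] + 0.5 * (y0 - y2) / denom * (grid[1] - grid[0]))
    return float(grid[i])


def weighted_mode(instruments: InstrumentSet, bandwidth_multiplier: float = 1.0,
                  n_boot: int = 1000, seed: int = 0) -> MRFit:
    """Mode of the smoothed weighted density of ratio estimates.

    Consistent when the largest group of instruments sharing one ratio is
    valid (ZEMPA); normal-kernel bandwidth follows the modified Silverman
    rule scaled by ``bandwidth_multiplier``; SE by parametric bootstrap.
    """
    L = len(instruments)
    if L < 3:
        raise ValueError("weighted mode needs >= 3 instruments")
    bx, by, sy = instruments.bx, instruments.by, instruments.sy
    ratios = by / bx
    se_r = sy / np.abs(bx)
    w = 1.0 / se_r ** 2
    w = w / w.sum()
    spread = min(np.std(ratios, ddof=1) if L > 1 else 1.0,
                 (np.percentile(ratios, 75) - np.percentile(ratios, 25)) / 1.349 or 1.0)
    spread = max(spread, 1e-8)
    h = bandwidth_multiplier * 0.9 * spread * L ** (-0.2)
    beta = _mode_estimate(ratios, w, h)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    sx = instruments.sx
    for i in range(n_boot):
        r_b = (by + sy * rng.standard_normal(L)) / (bx + sx * rng.standard_normal(L))
        boots[i] = _mode_estimate(r_b, w, h)
    se = float(np.std(boots, ddof=1))
    p = float(2 * norm.sf(abs(beta / se))) if se > 0 else (0.0 if beta != 0 else 1.0)
    return MRFit("weighted-mode", instruments.exposure, instruments.outcome,
                 beta, se, p, (beta - 1.96 * se, beta + 1.96 * se), L,
                 mean_f=instruments.mean_f,
                 steiger_removed=instruments.steiger_removed,
                 threshold_used=instruments.threshold_used)


def mvmr(exposures: Sequence[SumStatsTable], outcome: SumStatsTable,
         reference: LDReference, p_threshold: float = 5e-8,
         r2_threshold: float = 0.001, window_kb: float = 5000.0,
         steiger_alpha: float | None = 0.05) -> list[MRFit]:
    """Multivariable IVW: outcome betas regressed on the exposure-beta matrix.

    Instruments are the union of per-exposure clump leads, re-clumped with
    the same parameters; effects are aligned to the first (primary)
    exposure's increasing allele; Steiger filtering runs on the primary
    exposure-outcome pair (``steiger_alpha=None`` disables it — under
    strong mediation the mediator's own instruments legitimately explain
    more outcome than primary-exposure variance, and filtering them removes
    the variation that identifies the conditional model).  Returns one
    MRFit per exposure (conditional estimates); the primary exposure first.
    """
    lead_sets = []
    for exp in exposures:
        loci = clump(exp, reference, p_threshold, r2_threshold, window_kb)
        lead_sets.append({l.lead_snp for l in loci})
    union = sorted(set().union(*lead_sets))
    if not union:
        raise EmptyInstrumentsError("no genome-wide-significant instruments in any exposure")
    primary = exposures[0].indexed()
    pseudo = primary.loc[[s for s in union if s in primary.index]].copy()
    for exp in exposures[1:]:
        e = exp.indexed()
        shared = pseudo.index.intersection(e.index)
        pseudo.loc[shared, "P"] = np.minimum(pseudo.loc[shared, "P"], e.loc[shared, "P"])
    pseudo_table = SumStatsTable("union", pseudo.reset_index(drop=True))
    loci = clump(pseudo_table, reference, 1.0, r2_threshold, window_kb)
    leads = [l.lead_snp for l in loci]
    o = outcome.indexed()
    leads = [s for s in leads
             if s in o.index and all(s in e.indexed().index for e in exposures)]
    k = len(exposures)
    if len(leads) < k + 2:
        raise EmptyInstrumentsError(f"need >= {k + 2} instruments, got {len(leads)}")
    B = np.column_stack([e.indexed().loc[leads, "BETA"].to_numpy(float) for e in exposures])
    SX = np.column_stack([e.indexed().loc[leads, "SE"].to_numpy(float) for e in exposures])
    by = o.loc[leads, "BETA"].to_numpy(float)
    sy = o.loc[leads, "SE"].to_numpy(float)
    flip = B[:, 0] < 0
    B[flip] *= -1.0
    by[flip] *= -1.0
    # Steiger on the primary exposure-outcome pair
    n_removed = 0
    if steiger_alpha is not None:
        inst0 = InstrumentSet(exposures[0].trait, outcome.trait, pd.DataFrame({
            "SNP": leads, "beta_exp": B[:, 0], "se_exp": SX[:, 0],
            "beta_out": by, "se_out": sy,
            "n_exp": exposures[0].indexed().loc[leads, "N"].to_numpy(float),
            "n_out": o.loc[leads, "N"].to_numpy(float)}))
        filt = steiger_filter(inst0, steiger_alpha)
        n_removed = filt.steiger_removed
        keep = filt.df["SNP"].tolist()
        sel = [leads.index(s) for s in keep]
        B, SX, by, sy = B[sel], SX[sel], by[sel], sy[sel]
        leads = keep
    L = len(leads)
    if L < k + 2:
        raise EmptyInstrumentsError(f"need >= {k + 2} instruments after Steiger, got {L}")
    w = 1.0 / sy ** 2
    Bw = B * np.sqrt(w)[:, None]
    norms = np.linalg.norm(Bw, axis=0)
    active = norms > 1e-12
    cond = np.linalg.cond(Bw[:, active]) if active.sum() > 1 else 1.0
    if cond > 1e6:
        corr = np.corrcoef(B[:, active].T)
        iu = np.triu_indices_from(corr, 1)
        worst = int(np.argmax(np.abs(corr[iu])))
        i, j = iu[0][worst], iu[1][worst]
        names = [e.trait for e, a in zip(exposures, active) if a]
        raise ValueError(f"collinear exposures: {names[i]} and {names[j]}")
    A = B.T @ (B * w[:, None])
    # all-zero covariate columns contribute nothing; regularize only those
    for j in range(k):
        if A[j, j] < 1e-24:
            A[j, j] = 1.0
    coef = np.linalg.solve(A, B.T @ (w * by))
    resid = by - B @ coef
    Q = float(np.sum(w * resid ** 2))
    sigma2 = max(Q / max(L - k, 1), 1.0)
    cov = np.linalg.inv(A) * sigma2
    fits = []
    for j, exp in enumerate(exposures):
        se = float(np.sqrt(cov[j, j]))
        beta = float(coef[j])
        # conditional instrument strength: residualize exposure j on the others
        others = [i for i in range(k) if i != j and active[i]]
        if others:
            Bo = B[:, others]
            proj = Bo @ np.linalg.lstsq(Bo, B[:, j], rcond=None)[0]
            rj = B[:, j] - proj
        else:
            rj = B[:, j]
        f_cond = float(np.mean(rj ** 2 / SX[:, j] ** 2))
        fits.append(MRFit("MVMR-IVW", exp.trait, outcome.trait, beta, se,
                          float(2 * norm.sf(abs(beta / se))) if se > 0 else np.nan,
                          (beta - 1.96 * se, beta + 1.96 * se), L,
                          Q=Q, Q_p=float(chi2_dist.sf(Q, max(L - k, 1))),
                          mean_f=f_cond, steiger_removed=n_removed,
                          threshold_used=p_threshold))
    return fits


@dataclass
class SensitivityVerdict:
    exposure: str
    outcome: str
    ivw_significant: bool
    signs_consistent: bool
    pleiotropy_detected: bool
    robust: bool
    note: str


def sensitivity_report(fits: Sequence[MRFit], alpha: float = 0.05) -> SensitivityVerdict:
    """Structured verdict over one exposure-outcome pair's estimator battery.

    "Robust" requires a significant IVW estimate, no significant Egger
    intercept, and sign-consistent sensitivity estimates (suppressed Egger
    slopes are excluded from the sign check).  A significant intercept marks
    the pair pleiotropy-detected: the causal estimate should not be
    interpreted.
    """
    by_method = {f.method: f for f in fits}
    main = by_method.get("IVW")
    if main is None:
        raise ValueError("sensitivity report requires an IVW fit")
    ivw_sig = main.p < alpha
    eg = by_method.get("Egger")
    pleio = bool(eg is not None and np.isfinite(eg.egger_intercept_p)
                 and eg.egger_intercept_p < alpha)
    others = [f for f in fits
              if f.method != "IVW" and not (f.method == "Egger" and f.suppressed)]
    signs = [np.sign(f.beta) for f in others if f.beta != 0]
    consistent = all(s == np.sign(main.beta) for s in signs) if main.beta != 0 else False
    robust = bool(ivw_sig and not pleio and consistent)
    if pleio:
        note = "significant Egger intercept: possible causal effect should not be interpreted"
    elif not ivw_sig:
        note = "IVW estimate not significant"
    elif not consistent:
        note = "sensitivity estimators disagree in sign"
    else:
        note = "consistent across sensitivity analyses"
    return SensitivityVerdict(main.exposure, main.outcome, bool(ivw_sig),
                              bool(consistent), pleio, robust, note)
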