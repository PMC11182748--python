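"""End-to-end orchestration: simulate -> clean -> correlate -> factor -> MR.

One YAML config drives the whole analysis on synthetic (or user-supplied)
summary statistics; every stage writes TSV outputs into the run directory
and registers them in a manifest with content hashes, so a rerun with the
same config and seed is bit-identical.  A single global seed is fanned out
to the stages by fixed offsets.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ldsc, localrg, mixture, mr as mr_mod, sem
from .ldref import CLUMP_PRESETS, LDReference, clump, intersect_loci
from .simulate import ArchitectureConfig, TraitSpec, simulate_study
from .sumstats import (DEFAULT_HLA_REGION, SumStatsTable, exclude_region,
                       filter_maf, harmonize, write_sumstats)

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]

STAGES = ["simulate", "clean", "rg", "local", "mixture", "factor",
          "enrichment", "adjusted", "mr"]

SEED_OFFSETS = {s: 1000 * (i + 1) for i, s in enumerate(STAGES)}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    simulation: dict = field(default_factory=dict)
    maf: float = 0.05
    exclude_hla: bool = False
    local_pair: tuple[str, str] | None = None
    mixture_pair: tuple[str, str] | None = None
    mixture_m_ref: int | None = None
    factor_traits: list[str] | None = None  # MDD, CAD, PAD, HF, STROKE roles
    adjust_covariates: list[str] = field(default_factory=list)
    mr_exposure: str | None = None
    qsnp_alpha: float = 0.05
    clump_preset: str = "loci-fine"
    enrichment_fraction: float = 0.1

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise PipelineError(f"unknown stages: {sorted(unknown)}")
        for s in self.stages:
            needs = {"clean": "simulate", "rg": "clean", "local": "clean",
                     "mixture": "clean", "factor": "rg", "enrichment": "clean",
                     "adjusted": "rg", "mr": "clean"}.get(s)
            if needs and needs not in self.stages:
                raise PipelineError(f"stage {s!r} requires {needs!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["outdir"] = Path(raw.get("outdir", "comorbigen_run"))
        for key in ("local_pair", "mixture_pair"):
            if raw.get(key):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path, manifest: dict) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    manifest["files"][path.name] = _sha256(path)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; return the manifest."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": [], "files": {}}
    log_lines: list[str] = []
    state: dict = {}
    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        try:
            _STAGE_FNS[stage](config, state, manifest)
        except Exception as exc:
            manifest["failed_stage"] = stage
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        dt = time.perf_counter() - t0
        manifest["stages"].append(stage)
        log_lines.append(f"stage={stage} seed={config.seed + SEED_OFFSETS[stage]} wall_s={dt:.2f}")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _stage_simulate(config: PipelineConfig, state: dict, manifest: dict) -> None:
    sim = dict(config.simulation)
    traits = [TraitSpec(**t) for t in sim.pop("traits")]
    if "overlap" in sim and sim["overlap"] is not None:
        sim["overlap"] = np.asarray(sim["overlap"], float)
    arch = ArchitectureConfig(traits=traits, seed=config.seed + SEED_OFFSETS["simulate"], **sim)
    reference, truth, tables = simulate_study(arch)
    state.update(reference=reference, truth=truth, tables=tables, arch=arch)
    refdir = config.outdir / "ld_reference"
    reference.write(refdir)
    for p in sorted(refdir.iterdir()):
        manifest["files"][f"ld_reference/{p.name}"] = _sha256(p)
    _write(truth.to_frame(), config.outdir / "truth.tsv", manifest)
    for t in tables:
        path = config.outdir / f"sumstats_{t.trait}.tsv"
        write_sumstats(t, path)
        manifest["files"][path.name] = _sha256(path)


def _stage_clean(config: PipelineConfig, state: dict, manifest: dict) -> None:
    reference = state["reference"]
    tables, reports = harmonize(state["tables"], reference)
    cleaned = []
    for t in tables:
        t = filter_maf(t, config.maf)
        if config.exclude_hla:
            t = exclude_region(t, DEFAULT_HLA_REGION)
        cleaned.append(t)
    # LD methods need the reference and tables on the same variant grid
    common = set(cleaned[0].df["SNP"])
    for t in cleaned[1:]:
        common &= set(t.df["SNP"])
    from .ldref import LDBlock
    blocks = []
    for b in reference.blocks:
        keep = [i for i, s in enumerate(b.snp) if s in common]
        if not keep:
            continue
        blocks.append(LDBlock(b.chrom, int(b.pos[keep[0]]), int(b.pos[keep[-1]]),
                              [b.snp[i] for i in keep], b.pos[keep],
                              b.R[np.ix_(keep, keep)]))
    sub_ref = LDReference(blocks, alleles=reference.alleles)
    order = sub_ref.snp
    cleaned = [SumStatsTable(t.trait, t.indexed().loc[order].reset_index(drop=True))
               for t in cleaned]
    state.update(clean_tables=cleaned, clean_reference=sub_ref, harmonization=reports)
    rep = pd.DataFrame([r.__dict__ for r in reports])
    _write(rep, config.outdir / "harmonization.tsv", manifest)


def _stage_rg(config: PipelineConfig, state: dict, manifest: dict) -> None:
    tables, reference = state["clean_tables"], state["clean_reference"]
    gencov = ldsc.multivariable_ldsc(tables, reference)
    state["gencov"] = gencov
    rows = []
    k = len(tables)
    for i in range(k):
        for j in range(i + 1, k):
            hi, hj = gencov.S[i, i], gencov.S[j, j]
            rg = gencov.S[i, j] / np.sqrt(hi * hj) if hi > 0 and hj > 0 else np.nan
            rows.append({"trait1": gencov.traits[i], "trait2": gencov.traits[j],
                         "gencov": gencov.S[i, j], "rg": rg,
                         "intercept": gencov.intercepts[i, j]})
    _write(pd.DataFrame(rows), config.outdir / "rg_matrix.tsv", manifest)


def _stage_local(config: PipelineConfig, state: dict, manifest: dict) -> None:
    tables, reference = state["clean_tables"], state["clean_reference"]
    pair = config.local_pair or (tables[0].trait, tables[1].trait)
    lookup = {t.trait: t for t in tables}
    t1, t2 = lookup[pair[0]], lookup[pair[1]]
    results = localrg.local_rg_scan(t1, t2, reference,
                                    seed=config.seed + SEED_OFFSETS["local"])
    localrg.fdr_adjust(results)
    frac, n_sig = localrg.concordance_summary(results)
    df = pd.DataFrame([r.__dict__ for r in results]).drop(columns=["withheld_reason"])
    df.attrs.clear()
    _write(df, config.outdir / "local_rg.tsv", manifest)
    state["local_results"] = results
    state["local_concordance"] = (frac, n_sig)


def _stage_mixture(config: PipelineConfig, state: dict, manifest: dict) -> None:
    tables, reference = state["clean_tables"], state["clean_reference"]
    pair = config.mixture_pair or (tables[0].trait, tables[1].trait)
    lookup = {t.trait: t for t in tables}
    m_ref = config.mixture_m_ref or reference.m
    p1 = mixture.prune_for_mixture(lookup[pair[0]], reference)
    p2 = mixture.prune_for_mixture(lookup[pair[1]], reference)
    u1 = mixture.fit_univariate(p1, m_ref, min_variants=min(5000, len(p1)))
    u2 = mixture.fit_univariate(p2, m_ref, min_variants=min(5000, len(p2)))
    biv = mixture.fit_bivariate(p1, p2, m_ref, u1, u2)
    f1, f2 = biv.shared_fraction
    row = {"trait1": pair[0], "trait2": pair[1],
           "n_causal_1": u1.n_causal, "n_causal_2": u2.n_causal,
           "n90_1": u1.n90, "n90_2": u2.n90,
           "pi12": biv.pi12, "shared_frac_1": f1, "shared_frac_2": f2,
           "rho12": biv.rho12, "concordance": biv.concordance,
           "implied_rg": biv.implied_rg,
           "aic_free": biv.aic_free, "aic_min_overlap": biv.aic_min_overlap,
           "aic_max_overlap": biv.aic_max_overlap,
           "overlap_not_identified": biv.overlap_not_identified}
    _write(pd.DataFrame([row]), config.outdir / "mixture.tsv", manifest)
    state["mixture_fit"] = biv


def _stage_factor(config: PipelineConfig, state: dict, manifest: dict) -> None:
    tables = state["clean_tables"]
    gencov = state["gencov"]
    trait_names = config.factor_traits or [t.trait for t in tables[:5]]
    if len(trait_names) != 5:
        raise PipelineError("factor stage needs five traits (MDD + four ASCVD roles)")
    idx = [gencov.traits.index(t) for t in trait_names]
    flat_idx = []
    for a in range(5):
        for b in range(a, 5):
            flat_idx.append(gencov.index_of(idx[a], idx[b]))
    sub = ldsc.GenCov(traits=trait_names, S=gencov.S[np.ix_(idx, idx)],
                      V=gencov.V[np.ix_(flat_idx, flat_idx)],
                      intercepts=gencov.intercepts[np.ix_(idx, idx)])
    fit = sem.fit_mdd_ascvd(sub, seed=config.seed + SEED_OFFSETS["factor"])
    std = fit.standardized_loadings()
    rows = [{"parameter": lab, "estimate": est, "se": se,
             "standardized": std.get(lab, np.nan)}
            for lab, (est, se) in fit.params.items()]
    rows.append({"parameter": "CFI", "estimate": fit.cfi, "se": np.nan, "standardized": np.nan})
    rows.append({"parameter": "SRMR", "estimate": fit.srmr, "se": np.nan, "standardized": np.nan})
    _write(pd.DataFrame(rows), config.outdir / "factor_fit.tsv", manifest)

    lookup = {t.trait: t for t in tables}
    gtables = [lookup[t] for t in trait_names]
    snp_results = sem.factor_gwas(fit, gtables, q_alpha=config.qsnp_alpha)
    filtered, het_share = sem.filter_heterogeneous(snp_results)
    _write(snp_results.drop(columns=["heterogeneous"]).assign(
        heterogeneous=snp_results["heterogeneous"].astype(int)),
        config.outdir / "factor_gwas.tsv", manifest)
    fac_table = sem.factor_sumstats(filtered, trait="MDD_ASCVD")
    reference = state["clean_reference"]
    preset = CLUMP_PRESETS[config.clump_preset]
    loci = clump(fac_table, reference, **preset)
    loci_df = pd.DataFrame([{"chrom": l.chrom, "start": l.start, "end": l.end,
                             "lead_snp": l.lead_snp, "lead_p": l.lead_p,
                             "n_members": len(l.member_snps)} for l in loci])
    _write(loci_df, config.outdir / "factor_loci.tsv", manifest)
    constituent = []
    for t in trait_names:
        constituent.extend(clump(lookup[t], reference, **preset))
    _, novel = intersect_loci(loci, constituent)
    state.update(factor_fit=fit, factor_gwas=snp_results, factor_filtered=filtered,
                 het_share=het_share, factor_loci=loci, novel_loci=novel)
    summary = pd.DataFrame([{"n_snps": len(snp_results),
                             "n_filtered_out": int(snp_results["heterogeneous"].sum()),
                             "het_share_gws": het_share,
                             "n_loci": len(loci), "n_novel": len(novel)}])
    _write(summary, config.outdir / "factor_summary.tsv", manifest)


def _stage_enrichment(config: PipelineConfig, state: dict, manifest: dict) -> None:
    tables, reference = state["clean_tables"], state["clean_reference"]
    rng = np.random.default_rng(config.seed + SEED_OFFSETS["enrichment"])
    m = reference.m
    target = pd.DataFrame({"random_set": (rng.random(m) < config.enrichment_fraction).astype(int)},
                          index=reference.snp)
    results = ldsc.partitioned_enrichment(tables[0], reference, target)
    df = pd.DataFrame([{"annotation": r.label, "tau": r.tau, "z": r.z,
                        "p": r.p, "p_fdr": r.p_fdr,
                        "non_identifiable": r.non_identifiable} for r in results])
    _write(df, config.outdir / "enrichment.tsv", manifest)


def _stage_adjusted(config: PipelineConfig, state: dict, manifest: dict) -> None:
    gencov = state["gencov"]
    pair = config.local_pair or (gencov.traits[0], gencov.traits[1])
    covs = [c for c in config.adjust_covariates if c in gencov.traits]
    raw = sem.adjusted_rg(gencov, pair[0], pair[1], [])
    rows = [{"x": pair[0], "y": pair[1], "covariates": "", "rg": raw.rg_adj,
             "se": raw.se, "ci_lo": raw.ci[0], "ci_hi": raw.ci[1]}]
    if covs:
        adj = sem.adjusted_rg(gencov, pair[0], pair[1], covs)
        rows.append({"x": pair[0], "y": pair[1], "covariates": ",".join(covs),
                     "rg": adj.rg_adj, "se": adj.se,
                     "ci_lo": adj.ci[0], "ci_hi": adj.ci[1]})
        med = sem.mediation_model(gencov, pair[0], covs, pair[1],
                                  seed=config.seed + SEED_OFFSETS["adjusted"])
        med_df = pd.DataFrame([{"x": med.x, "y": med.y, "mediators": ",".join(med.mediators),
                                "direct": med.direct, "direct_se": med.direct_se,
                                "direct_std": med.direct_std,
                                "indirect": med.indirect, "indirect_se": med.indirect_se,
                                "total": med.total,
                                "covariate_rg": med.covariate_estimate.rg_adj,
                                "mediation_supported": med.mediation_supported}])
        _write(med_df, config.outdir / "mediation.tsv", manifest)
        state["mediation"] = med
    _write(pd.DataFrame(rows), config.outdir / "adjusted_rg.tsv", manifest)


def _stage_mr(config: PipelineConfig, state: dict, manifest: dict) -> None:
    tables, reference = state["clean_tables"], state["clean_reference"]
    exposure_name = config.mr_exposure or tables[0].trait
    lookup = {t.trait: t for t in tables}
    exposure = lookup[exposure_name]
    rows = []
    for t in tables:
        if t.trait == exposure_name:
            continue
        try:
            inst = mr_mod.build_instruments(exposure, t, reference)
        except Exception:
            continue
        fits = [mr_mod.ivw(inst)]
        if len(inst) >= 3:
            fits.append(mr_mod.egger(inst))
            fits.append(mr_mod.weighted_median(inst, seed=config.seed + SEED_OFFSETS["mr"]))
            fits.append(mr_mod.weighted_mode(inst, seed=config.seed + SEED_OFFSETS["mr"]))
        verdict = mr_mod.sensitivity_report(fits)
        for f in fits:
            rows.append({"exposure": f.exposure, "outcome": f.outcome,
                         "method": f.method, "beta": f.beta, "se": f.se, "p": f.p,
                         "ci_lo": f.ci[0], "ci_hi": f.ci[1], "Q": f.Q, "Q_p": f.Q_p,
                         "egger_intercept": f.egger_intercept,
                         "egger_p": f.egger_intercept_p, "I2_GX": f.i2_gx,
                         "mean_F": f.mean_f, "n_instruments": f.n_instruments,
                         "steiger_removed": f.steiger_removed,
                         "threshold_used": f.threshold_used,
                         "robust": verdict.robust})
    _write(pd.DataFrame(rows), config.outdir / "mr_results.tsv", manifest)


_STAGE_FNS = {
    "simulate": _stage_simulate,
    "clean": _stage_clean,
    "rg": _stage_rg,
    "local": _stage_local,
    "mixture": _stage_mixture,
    "factor": _stage_factor,
    "enrichment": _stage_enrichment,
    "adjusted": _stage_adjusted,
    "mr": _stage_mr,
}

REPORT_TABLES = {
    "rg_matrix": "rg_matrix.tsv",
    "local_rg": "local_rg.tsv",
    "mixture": "mixture.tsv",
    "factor_fit": "factor_fit.tsv",
    "factor_loci": "factor_loci.tsv",
    "enrichment": "enrichment.tsv",
    "adjusted_rg": "adjusted_rg.tsv",
    "mr": "mr_results.tsv",
}


def make_report(manifest: dict, outdir) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Collect the report tables recorded in a manifest.

    Returns (tables, notices): one DataFrame per available table and a
    notice string per table whose stage did not run.
    """
    outdir = Path(outdir)
    tables: dict[str, pd.DataFrame] = {}
    notices: list[str] = []
    for name, fname in REPORT_TABLES.items():
        if fname in manifest.get("files", {}):
            tables[name] = pd.read_csv(outdir / fname, sep="\t")
        else:
            notices.append(f"table {name!r} unavailable: stage output {fname} missing")
    return tables, notices
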