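"""Reading, validation, harmonization and filtering of GWAS summary statistics.

The canonical in-memory container is :class:`SumStatsTable`, a thin wrapper
around a :class:`pandas.DataFrame` with one row per autosomal biallelic
variant and the columns

    SNP, CHR, BP, A1, A2, FREQ, BETA, SE, Z, P, N

where ``A1`` is the effect allele and ``Z = BETA / SE``.  Files either supply
(BETA, SE) or Z directly; in the latter case BETA/SE are carried as NaN and
flagged derivable.  All downstream modules (LDSC, local correlation, mixture
models, factor GWAS, MR) consume this container.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SumStatsTable",
    "HarmonizationReport",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_HLA_REGION",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "filter_maf",
    "exclude_region",
]

CANONICAL_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "Z", "P", "N"]

#: default header names recognised in input files, mapping file -> canonical
DEFAULT_COLUMN_MAP: dict[str, str] = {c: c for c in CANONICAL_COLUMNS}

#: extended MHC span on chromosome 6, the usual exclusion for LD-based methods
#: (complex long-range LD biases h2 and rg there); build-agnostic default,
#: overridable everywhere it is used.
DEFAULT_HLA_REGION: tuple[int, int, int] = (6, 26_000_000, 34_000_000)

VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class SumStatsError(ValueError):
    """Raised for unusable summary-statistics input."""


@dataclass
class HarmonizationReport:
    """Per-table bookkeeping of the allele-alignment step."""

    trait: str
    n_input: int
    n_aligned: int
    n_flipped: int
    n_removed_ambiguous: int
    n_removed_mismatch: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_aligned + self.n_removed_ambiguous + self.n_removed_mismatch:
            raise ValueError("harmonization counts do not sum to n_input")
        if self.n_flipped > self.n_aligned:
            raise ValueError("n_flipped exceeds n_aligned")


@dataclass
class SumStatsTable:
    """Harmonized per-variant association records for one trait."""

    trait: str
    df: pd.DataFrame
    beta_derivable: bool = False  # True when BETA/SE absent but recoverable from Z, N

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumStatsError(f"missing canonical columns: {missing}")
        if self.df["SNP"].duplicated().any():
            raise SumStatsError("duplicate variant IDs in table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def z(self) -> np.ndarray:
        return self.df["Z"].to_numpy(float)

    @property
    def n(self) -> np.ndarray:
        return self.df["N"].to_numpy(float)

    def subset(self, mask) -> "SumStatsTable":
        return SumStatsTable(self.trait, self.df.loc[mask].reset_index(drop=True),
                             self.beta_derivable)

    def indexed(self) -> pd.DataFrame:
        return self.df.set_index("SNP", drop=False)


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "r")


def read_sumstats(path, column_map: Mapping[str, str] | None = None,
                  trait: str | None = None) -> SumStatsTable:
    """Read a whitespace/tab-delimited summary-statistics file.

    ``column_map`` maps file headers to canonical names; unmapped headers are
    ignored.  Records failing basic sanity rules (non-autosomal chromosome,
    invalid alleles, se <= 0, p outside (0, 1], n <= 0, freq outside [0, 1])
    are dropped silently but counted on the returned table's ``df.attrs``.

    Either (BETA, SE) or Z must be present together with N.  Z is recomputed
    as BETA/SE when absent; the file's P is retained as authoritative.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(_open_text(path), sep=r"\s+")
    rename = {src: dst for src, dst in cmap.items() if src in raw.columns}
    df = raw.rename(columns=rename)

    have_beta = "BETA" in df.columns and "SE" in df.columns
    have_z = "Z" in df.columns
    if not (have_beta or have_z):
        raise SumStatsError("file must provide (BETA, SE) or Z")
    required = ["SNP", "CHR", "BP", "A1", "A2", "N"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SumStatsError(f"required columns absent: {missing}")

    for c in CANONICAL_COLUMNS:
        if c not in df.columns:
            df[c] = np.nan
    df = df[CANONICAL_COLUMNS].copy()
    df["A1"] = df["A1"].astype(str).str.upper()
    df["A2"] = df["A2"].astype(str).str.upper()
    for c in ("CHR", "BP"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in ("FREQ", "BETA", "SE", "Z", "P", "N"):
        df[c] = pd.to_numeric(df[c], errors="coerce")

    n_raw = len(df)
    ok = (
        df["CHR"].between(1, 22)
        & df["BP"].notna() & (df["BP"] >= 1)
        & df["A1"].isin(VALID_ALLELES) & df["A2"].isin(VALID_ALLELES)
        & (df["A1"] != df["A2"])
        & df["N"].notna() & (df["N"] > 0)
    )
    if have_beta:
        ok &= df["BETA"].notna() & df["SE"].notna() & (df["SE"] > 0)
    else:
        ok &= df["Z"].notna()
    # p, if present, must be a valid probability; absent p is recomputed
    has_p = df["P"].notna()
    ok &= ~has_p | ((df["P"] > 0) & (df["P"] <= 1))

    df = df.loc[ok].reset_index(drop=True)
    if len(df) == 0:
        raise SumStatsError(f"no usable records in {path}")
    df["CHR"] = df["CHR"].astype(int)
    df["BP"] = df["BP"].astype(int)

    beta_derivable = not have_beta
    if have_beta:
        df["Z"] = df["BETA"] / df["SE"]
    from scipy.stats import norm
    p_from_z = 2.0 * norm.sf(np.abs(df["Z"].to_numpy(float)))
    df.loc[df["P"].isna(), "P"] = np.clip(p_from_z, np.finfo(float).tiny, 1.0)[df["P"].isna().to_numpy()]

    df = df.drop_duplicates(subset="SNP", keep="first").reset_index(drop=True)
    table = SumStatsTable(trait or path.stem, df, beta_derivable=beta_derivable)
    table.df.attrs["n_input_records"] = n_raw
    table.df.attrs["n_rejected"] = n_raw - len(df)
    return table


def write_sumstats(table: SumStatsTable, path) -> None:
    """Write a table in the canonical tab-delimited dialect (gzip by suffix)."""
    path = Path(path)
    opener = gzip.open(path, "wt") if str(path).endswith(".gz") else open(path, "w")
    with opener as fh:
        table.df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def harmonize(tables: Sequence[SumStatsTable], reference) -> tuple[list[SumStatsTable], list[HarmonizationReport]]:
    """Align one or more tables to an LD reference's variants and alleles.

    All tables are restricted to the intersection of their variants with the
    reference *and with each other*.  When a record's allele pair is the
    reverse of the reference's, BETA and Z are negated and FREQ replaced by
    1 - FREQ (allele-order swap); strand-ambiguous A/T and C/G pairs are
    removed; pairs matching neither orientation are removed as mismatches.
    Idempotent: a harmonized table passes through unchanged.
    """
    ref = reference.variants_frame()  # columns SNP, A1, A2, indexed by SNP
    aligned: list[pd.DataFrame] = []
    reports: list[HarmonizationReport] = []
    for table in tables:
        df = table.df.copy()
        n_input = len(df)
        a1, a2 = df["A1"].to_numpy(), df["A2"].to_numpy()
        ambiguous = np.array([(x, y) in _AMBIGUOUS_PAIRS for x, y in zip(a1, a2)])
        df = df.loc[~ambiguous]
        in_ref = df["SNP"].isin(ref.index).to_numpy()
        n_not_in_ref = int((~in_ref).sum())
        df = df.loc[in_ref]
        r = ref.loc[df["SNP"]]
        same = (df["A1"].to_numpy() == r["A1"].to_numpy()) & (df["A2"].to_numpy() == r["A2"].to_numpy())
        swap = (df["A1"].to_numpy() == r["A2"].to_numpy()) & (df["A2"].to_numpy() == r["A1"].to_numpy())
        mismatch = ~(same | swap)
        n_mismatch = int(mismatch.sum()) + n_not_in_ref
        df = df.loc[~mismatch].copy()
        swap = swap[~mismatch]
        df.loc[swap, ["BETA", "Z"]] *= -1.0
        df.loc[swap, "FREQ"] = 1.0 - df.loc[swap, "FREQ"]
        df.loc[swap, ["A1", "A2"]] = df.loc[swap, ["A2", "A1"]].to_numpy()
        aligned.append(df)
        reports.append(HarmonizationReport(
            trait=table.trait, n_input=n_input,
            n_aligned=len(df), n_flipped=int(swap.sum()),
            n_removed_ambiguous=int(ambiguous.sum()), n_removed_mismatch=n_mismatch,
        ))
    common = set(ref.index)
    for df in aligned:
        common &= set(df["SNP"])
    order = [s for s in ref.index if s in common]
    out = []
    for table, df in zip(tables, aligned):
        df = df.set_index("SNP", drop=False).loc[order].reset_index(drop=True)
        out.append(SumStatsTable(table.trait, df, table.beta_derivable))
    return out, reports


def filter_maf(table: SumStatsTable, threshold: float) -> SumStatsTable:
    """Keep records with minor-allele frequency >= threshold."""
    freq = table.df["FREQ"].to_numpy(float)
    maf = np.minimum(freq, 1.0 - freq)
    return table.subset(maf >= threshold)


def exclude_region(table: SumStatsTable, region: tuple[int, int, int] = DEFAULT_HLA_REGION) -> SumStatsTable:
    """Drop variants inside (chrom, start, end), 1-based inclusive."""
    chrom, start, end = region
    df = table.df
    inside = (df["CHR"] == chrom) & (df["BP"] >= start) & (df["BP"] <= end)
    return table.subset(~inside.to_numpy())
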