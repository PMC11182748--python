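"""Block-diagonal LD reference: LD scores, clumping, loci, instrument selection.

The reference models linkage disequilibrium as non-overlapping blocks of
variants, each with a dense correlation matrix ``R``; correlation between
variants in different blocks is defined as zero.  This mirrors the standard
partition of the autosomes into approximately LD-independent regions used by
local-correlation methods, and makes LD scores, clumping and pruning exact
within the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["LDBlock", "LDReference", "Locus", "clump", "intersect_loci",
           "select_instruments", "read_bed_intervals", "CLUMP_PRESETS"]

#: named clumping parameterizations (p threshold, r2, window in kb)
CLUMP_PRESETS = {
    "loci-fine": {"p_threshold": 5e-8, "r2_threshold": 0.1, "window_kb": 250.0},
    "loci-fuma": {"p_threshold": 5e-8, "r2_threshold": 0.36, "window_kb": 250.0},
    "loci-novel": {"p_threshold": 5e-8, "r2_threshold": 0.1, "window_kb": 3000.0},
    "instruments": {"p_threshold": 5e-8, "r2_threshold": 0.001, "window_kb": 5000.0},
}


class EmptyInstrumentsError(RuntimeError):
    """No usable instruments even at the fallback p-value threshold."""


@dataclass
class LDBlock:
    chrom: int
    start: int
    end: int
    snp: list[str]
    pos: np.ndarray
    R: np.ndarray

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=int)
        self.R = np.asarray(self.R, dtype=float)
        m = len(self.snp)
        if self.R.shape != (m, m):
            raise ValueError("R shape does not match variant count")
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-8):
            raise ValueError("R must have unit diagonal")
        if np.any(np.diff(self.pos) < 0):
            raise ValueError("variants must be position-sorted")
        # PSD to tolerance: floor tiny negative eigenvalues
        w = np.linalg.eigvalsh(self.R)
        if w.min() < -1e-8:
            raise ValueError(f"R not PSD (min eigenvalue {w.min():.3g})")

    def __len__(self) -> int:
        return len(self.snp)

    @property
    def ld_scores(self) -> np.ndarray:
        """l_j = sum_k r^2_jk over block members (includes self: l >= 1)."""
        return (self.R ** 2).sum(axis=1)


@dataclass
class LDReference:
    blocks: list[LDBlock]
    alleles: pd.DataFrame | None = None  # optional SNP -> (A1, A2)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b in self.blocks:
            dup = seen.intersection(b.snp)
            if dup:
                raise ValueError(f"variants in multiple blocks: {sorted(dup)[:3]}")
            seen.update(b.snp)
        if self.alleles is None:
            # fabricate a fixed non-ambiguous allele pair per variant
            ids = [s for b in self.blocks for s in b.snp]
            self.alleles = pd.DataFrame({"SNP": ids, "A1": "A", "A2": "G"}).set_index("SNP", drop=False)

    @property
    def snp(self) -> list[str]:
        return [s for b in self.blocks for s in b.snp]

    @property
    def m(self) -> int:
        return sum(len(b) for b in self.blocks)

    def variants_frame(self) -> pd.DataFrame:
        return self.alleles

    def ld_scores(self) -> pd.Series:
        """Per-variant LD score l_j, concatenated in block order."""
        vals = np.concatenate([b.ld_scores for b in self.blocks]) if self.blocks else np.array([])
        return pd.Series(vals, index=self.snp, name="L")

    def block_of(self) -> dict[str, int]:
        return {s: i for i, b in enumerate(self.blocks) for s in b.snp}

    def positions(self) -> pd.DataFrame:
        rows = []
        for b in self.blocks:
            for s, p in zip(b.snp, b.pos):
                rows.append((s, b.chrom, int(p)))
        return pd.DataFrame(rows, columns=["SNP", "CHR", "BP"]).set_index("SNP")

    # ---- serialization -------------------------------------------------
    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        idx = pd.DataFrame(
            [(i, b.chrom, b.start, b.end, len(b)) for i, b in enumerate(self.blocks)],
            columns=["block", "chrom", "start", "end", "n_variants"])
        idx.to_csv(outdir / "blocks.tsv", sep="\t", index=False)
        scores = self.ld_scores()
        pos = self.positions()
        pd.DataFrame({"SNP": scores.index, "CHR": pos["CHR"].to_numpy(),
                      "BP": pos["BP"].to_numpy(), "L": scores.to_numpy()}
                     ).to_csv(outdir / "ldscores.tsv", sep="\t", index=False)
        for i, b in enumerate(self.blocks):
            hdr = "\t".join(b.snp)
            np.savetxt(outdir / f"block_{i}.R.txt", b.R, fmt="%.8g",
                       header=hdr, comments="#")
            pd.DataFrame({"SNP": b.snp, "BP": b.pos}).to_csv(
                outdir / f"block_{i}.variants.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, indir) -> "LDReference":
        indir = Path(indir)
        idx = pd.read_csv(indir / "blocks.tsv", sep="\t")
        blocks = []
        for _, row in idx.iterrows():
            i = int(row["block"])
            var = pd.read_csv(indir / f"block_{i}.variants.tsv", sep="\t")
            R = np.loadtxt(indir / f"block_{i}.R.txt")
            R = np.atleast_2d(R)
            blocks.append(LDBlock(int(row["chrom"]), int(row["start"]), int(row["end"]),
                                  list(var["SNP"].astype(str)), var["BP"].to_numpy(), R))
        return cls(blocks)


@dataclass
class Locus:
    chrom: int
    start: int
    end: int
    lead_snp: str
    lead_p: float
    member_snps: list[str] = field(default_factory=list)

    def overlaps(self, other: "Locus") -> bool:
        return self.chrom == other.chrom and self.start <= other.end and other.start <= self.end


def _block_r2(block: LDBlock) -> np.ndarray:
    return block.R ** 2


def clump(table, reference: LDReference, p_threshold: float = 5e-8,
          r2_threshold: float = 0.1, window_kb: float = 250.0,
          distance_absorbs: bool = False) -> list[Locus]:
    """Greedy LD clumping of significant variants into lead-SNP loci.

    Variants with p < ``p_threshold`` are sorted by p; the best remaining
    variant becomes a lead and absorbs all remaining significant variants
    with r^2 >= ``r2_threshold`` to the lead (cross-block r^2 is 0).  With
    ``distance_absorbs=True``, physical proximity within ``window_kb`` alone
    also absorbs (the alternative reading of distance-based clumping); by
    default distance only bounds the LD search, the standard semantics.
    """
    df = table.df
    sig = df.loc[df["P"] < p_threshold]
    if len(sig) == 0:
        return []
    block_of = reference.block_of()
    pos_in_block: dict[str, tuple[int, int]] = {}
    for bi, b in enumerate(reference.blocks):
        for k, s in enumerate(b.snp):
            pos_in_block[s] = (bi, k)
    order = sig.sort_values("P", kind="mergesort")
    remaining = {row.SNP: (row.CHR, row.BP, row.P) for row in order.itertuples()}
    loci: list[Locus] = []
    for lead in order["SNP"]:
        if lead not in remaining:
            continue
        chrom, bp, p = remaining.pop(lead)
        members = [lead]
        positions = [bp]
        bi_lead, k_lead = pos_in_block.get(lead, (None, None))
        for snp in list(remaining):
            c2, bp2, _ = remaining[snp]
            if c2 != chrom:
                continue
            near = abs(bp2 - bp) <= window_kb * 1000.0
            r2 = 0.0
            loc = pos_in_block.get(snp)
            if bi_lead is not None and loc is not None and loc[0] == bi_lead:
                r2 = reference.blocks[bi_lead].R[k_lead, loc[1]] ** 2
            absorb = (near and r2 >= r2_threshold) or (distance_absorbs and near)
            if absorb:
                remaining.pop(snp)
                members.append(snp)
                positions.append(bp2)
        loci.append(Locus(chrom=int(chrom), start=int(min(positions)),
                          end=int(max(positions)), lead_snp=lead,
                          lead_p=float(p), member_snps=members))
    return loci


def intersect_loci(a: Sequence[Locus], b: Sequence[Locus]) -> tuple[list[tuple[Locus, Locus]], list[Locus]]:
    """Overlap loci in ``a`` against ``b``; return (overlap pairs, novel in a).

    A locus in ``a`` is novel iff it shares no base pair with any locus in
    ``b`` (>= 1 bp overlap counts).
    """
    overlaps: list[tuple[Locus, Locus]] = []
    novel: list[Locus] = []
    for la in a:
        hits = [lb for lb in b if la.overlaps(lb)]
        if hits:
            overlaps.extend((la, lb) for lb in hits)
        else:
            novel.append(la)
    return overlaps, novel


def select_instruments(table, reference: LDReference, p_primary: float = 5e-8,
                       r2: float = 0.001, window_kb: float = 5000.0,
                       min_instruments: int = 10, p_fallback: float = 1e-5):
    """Lead SNPs for MR instruments, with a relaxed-threshold fallback.

    Clump at the genome-wide threshold; when fewer than ``min_instruments``
    leads result, re-clump at ``p_fallback`` and return the best
    ``min_instruments`` leads.  Returns (list of lead Locus, threshold used).
    """
    loci = clump(table, reference, p_primary, r2, window_kb)
    if len(loci) >= min_instruments:
        return loci, p_primary
    loci = clump(table, reference, p_fallback, r2, window_kb)
    loci = sorted(loci, key=lambda l: l.lead_p)[:min_instruments]
    if not loci:
        raise EmptyInstrumentsError(
            f"no instruments at fallback threshold {p_fallback}")
    return loci, p_fallback


def read_bed_intervals(path) -> pd.DataFrame:
    """Read BED (0-based half-open) intervals to 1-based inclusive coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end"], usecols=[0, 1, 2])
    df["chrom"] = df["chrom"].astype(str).str.replace("chr", "", regex=False).astype(int)
    df["start"] = df["start"].astype(int) + 1
    df["end"] = df["end"].astype(int)
    return df
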