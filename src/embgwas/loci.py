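"""Greedy LD clumping of summary statistics into independent loci."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

__all__ = ["compute_r2", "clump", "LocusTable"]


def compute_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (mean-imputed)."""
    a = _fill(np.asarray(g1, dtype=float))
    b = _fill(np.asarray(g2, dtype=float))
    if a.shape != b.shape:
        raise ValueError("dosage vectors differ in length")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _fill(g: np.ndarray) -> np.ndarray:
    miss = np.isnan(g)
    if miss.any():
        g = np.where(miss, g[~miss].mean(), g)
    return g


@dataclass
class Locus:
    lead_id: str
    chrom: str
    pos: int
    lead_p: float
    clumped_ids: list[str]

    @property
    def n_clumped(self) -> int:
        return len(self.clumped_ids)


@dataclass
class LocusTable:
    loci: list[Locus]

    def __len__(self) -> int:
        return len(self.loci)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "LEAD_ID": [l.lead_id for l in self.loci],
                "CHR": [l.chrom for l in self.loci],
                "POS": [l.pos for l in self.loci],
                "LEAD_P": [l.lead_p for l in self.loci],
                "N_CLUMPED": [l.n_clumped for l in self.loci],
                "CLUMPED_IDS": [";".join(l.clumped_ids) for l in self.loci],
            }
        )


def clump(
    records: pd.DataFrame,
    genotypes: GenotypeMatrix,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.1,
    window_bp: int = 5_000_000,
    window_convention: str = "span",
) -> LocusTable:
    """Greedy clumping: repeatedly promote the smallest-p unclaimed
    significant variant to lead and claim all unclaimed variants in LD with
    it inside the window (claimed variants need not be significant).

    ``records`` needs columns ``ID, CHR, POS, P``.  ``window_convention``:
    ``"span"`` reads the window as a total span (claim within +-window/2 of
    the lead); ``"index"`` claims within +-window of the lead, the
    distance-from-index convention.  Ties in p break by (chrom, pos).
    """
    if window_convention not in ("span", "index"):
        raise ValueError("window_convention must be 'span' or 'index'")
    half = window_bp // 2 if window_convention == "span" else window_bp

    pcol = "P" if "P" in records.columns else "P_ACAT"
    df = records[["ID", "CHR", "POS", pcol]].rename(columns={pcol: "P"}).copy()
    df = df.dropna(subset=["P"])

    idx_of = {vid: j for j, vid in enumerate(genotypes.variants["id"])}
    missing = [v for v in df["ID"] if v not in idx_of]
    if missing:
        raise ValueError(f"variants absent from genotypes: {missing[:5]}")

    dos = genotypes.dosages
    sig = df[df["P"] < p_threshold].sort_values(
        ["P", "CHR", "POS"], kind="mergesort"
    )
    unclaimed = set(df["ID"])
    loci: list[Locus] = []
    for row in sig.itertuples(index=False):
        if row.ID not in unclaimed:
            continue
        unclaimed.discard(row.ID)
        lead_g = dos[:, idx_of[row.ID]]
        claimed: list[str] = []
        near = df[
            (df["CHR"] == row.CHR)
            & (df["POS"] - row.POS).abs().le(half)
            & df["ID"].isin(unclaimed)
        ]
        for cand in near.itertuples(index=False):
            g = dos[:, idx_of[cand.ID]]
            if np.nanstd(g) == 0:
                continue
            if compute_r2(lead_g, g) >= r2_threshold:
                claimed.append(cand.ID)
                unclaimed.discard(cand.ID)
        loci.append(
            Locus(
                lead_id=row.ID,
                chrom=str(row.CHR),
                pos=int(row.POS),
                lead_p=float(row.P),
                clumped_ids=claimed,
            )
        )
    loci.sort(key=lambda l: (l.lead_p, l.chrom, l.pos))
    return LocusTable(loci=loci)
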