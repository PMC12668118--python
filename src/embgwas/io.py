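"""File I/O: VCF read/write, dosage TSV, and schema-checked sample tables.

Coordinates are VCF 1-based throughout.  All tabular formats are TSV with a
header row and sample ids in the first column.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import EmbeddingMatrix, FeatureMatrix, GenotypeMatrix

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_table",
    "write_table",
    "feature_matrix_to_frame",
    "frame_to_feature_matrix",
    "align_samples",
]


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Plain-text VCF with GT calls (dosages rounded to allele counts)."""
    path = Path(path)
    var = genotypes.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(var["chrom"]):
            maxpos = int(var.loc[var["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.sample_ids)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for v in range(genotypes.n_variants):
            row = var.iloc[v]
            calls = []
            for d in genotypes.dosages[:, v]:
                if np.isnan(d):
                    calls.append("./.")
                else:
                    calls.append(gt_map[int(round(d))])
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{row['id']}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path, prefer_ds: bool = True) -> GenotypeMatrix:
    """Load dosages from a VCF: DS field when present (and preferred), else
    GT allele counts.  Missing genotypes stay missing (NaN); multi-allelic
    records are rejected."""
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError("VCF has zero samples")
    dosage_rows = []
    meta = {"chrom": [], "pos": [], "id": [], "ref": [], "alt": []}
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {rec.CHROM}:{rec.POS} (record {i + 1}); split first"
            )
        ds = None
        if prefer_ds:
            try:
                ds = rec.format("DS")
            except KeyError:
                ds = None
        if ds is not None:
            row = np.asarray(ds, dtype=float).ravel()
            row = np.where(row < 0, np.nan, row)
        else:
            gts = rec.genotype.array()
            alleles = gts[:, :2].astype(float)
            alleles[alleles < 0] = np.nan
            row = alleles.sum(axis=1)
        dosage_rows.append(row)
        meta["chrom"].append(str(rec.CHROM))
        meta["pos"].append(int(rec.POS))
        meta["id"].append(rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}")
        meta["ref"].append(rec.REF)
        meta["alt"].append(rec.ALT[0])
    if not dosage_rows:
        raise ValueError("VCF contains no variant records")
    dosages = np.vstack(dosage_rows).T
    return GenotypeMatrix(sample_ids=samples, dosages=dosages, variants=pd.DataFrame(meta))


def write_dosage_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Rows = variants: chrom, pos, id, ref, alt, then one dosage column per sample."""
    var = genotypes.variants.copy()
    dos = pd.DataFrame(genotypes.dosages.T, columns=genotypes.sample_ids)
    pd.concat([var.reset_index(drop=True), dos], axis=1).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta_cols = ["chrom", "pos", "id", "ref", "alt"]
    if list(df.columns[:5]) != meta_cols:
        raise ValueError(f"dosage TSV must start with columns {meta_cols}")
    samples = list(df.columns[5:])
    dosages = df[samples].to_numpy(dtype=float).T
    return GenotypeMatrix(
        sample_ids=samples,
        dosages=dosages,
        variants=df[meta_cols].astype({"pos": int}).reset_index(drop=True),
    )


def write_table(df: pd.DataFrame, path: str | Path, id_column: str = "sample_id") -> None:
    """TSV with header; the id column written first, remaining columns in
    deterministic (input) order."""
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r}")
    cols = [id_column] + [c for c in df.columns if c != id_column]
    df[cols].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(df_path: str | Path, id_column: str = "sample_id") -> pd.DataFrame:
    df = pd.read_csv(df_path, sep="\t", na_values=["NA"])
    if id_column not in df.columns:
        raise ValueError(f"missing id column {id_column!r} in {df_path}")
    ids = df[id_column].astype(str)
    dup = ids[ids.duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicated sample ids: {sorted(set(dup))[:5]}")
    df[id_column] = ids
    return df


def feature_matrix_to_frame(features: FeatureMatrix | EmbeddingMatrix, prefix: str = "f") -> pd.DataFrame:
    df = pd.DataFrame(
        features.values, columns=[f"{prefix}{j + 1}" for j in range(features.values.shape[1])]
    )
    df.insert(0, "sample_id", features.sample_ids)
    if isinstance(features, FeatureMatrix) and features.participants is not None:
        df.insert(1, "participant", features.participants)
    return df


def frame_to_feature_matrix(df: pd.DataFrame) -> FeatureMatrix:
    parts = df["participant"].tolist() if "participant" in df.columns else None
    value_cols = [c for c in df.columns if c not in ("sample_id", "participant")]
    return FeatureMatrix(
        sample_ids=df["sample_id"].astype(str).tolist(),
        values=df[value_cols].to_numpy(dtype=float),
        participants=parts,
    )


def align_samples(*frames: pd.DataFrame, id_column: str = "sample_id") -> list[pd.DataFrame]:
    """Canonically sort every frame by sample id; error on any mismatch,
    naming the unmatched ids."""
    id_sets = [set(f[id_column]) for f in frames]
    common = set.intersection(*id_sets)
    problems = []
    for i, ids in enumerate(id_sets):
        extra = ids - common
        if extra:
            problems.append(f"table {i}: {sorted(extra)[:5]}")
    if problems:
        raise ValueError("sample ids not shared across tables: " + "; ".join(problems))
    return [f.sort_values(id_column, kind="mergesort").reset_index(drop=True) for f in frames]
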