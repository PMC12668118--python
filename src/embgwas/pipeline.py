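"""End-to-end orchestration: simulate/ingest -> (optionally train) -> embed
-> associate (+ univariate baseline) -> clump -> trait axis, with a
reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, axes, contrastive, embedding, io, loci, synthcohort
from .config import PipelineConfig, save_config
from .datatypes import EmbeddingMatrix

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapper

    return deco


def run_pipeline(cfg: PipelineConfig) -> Path:
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genotypes, features, truth = _stage("simulate")(_inputs)(cfg)
    io.write_dosage_tsv(genotypes, out / "genotypes.tsv")
    io.write_table(io.feature_matrix_to_frame(features), out / "features.tsv")

    if cfg.train_encoder:
        enc_log = _stage("train")(_train)(cfg, features, truth, out)
    else:
        enc_log = None

    proj, emb, pheno, covars = _stage("embed")(_embed)(cfg, features, truth)
    io.write_table(io.feature_matrix_to_frame(pheno, prefix="PC"), out / "embeddings.tsv")

    records = _stage("gwas")(assoc.run_gwas)(
        genotypes, pheno, covars, maf_min=cfg.maf_min, mode=cfg.assoc_mode
    )
    sumstats = assoc.records_to_frame(records)
    sumstats.to_csv(out / "sumstats.tsv", sep="\t", index=False)

    if cfg.run_univariate:
        uni = _stage("gwas_univariate")(assoc.test_univariate_acat)(
            genotypes, pheno, covars, maf_min=cfg.maf_min
        )
        uni.to_csv(out / "sumstats_univariate.tsv", sep="\t", index=False)

    if cfg.n_perm > 0:
        report = _stage("permute")(assoc.permutation_null)(
            genotypes, pheno, covars, n_perm=cfg.n_perm, seed=_substream(cfg.seed, "perm")
        )
        pd.DataFrame(
            {"alpha": report.alpha_grid, "empirical": report.empirical_alpha}
        ).to_csv(out / "calibration.tsv", sep="\t", index=False)
        (out / "calibration.json").write_text(
            json.dumps(
                {
                    "lambda_gc": report.lambda_gc,
                    "ks_p_value": report.ks_p_value,
                    "n_statistics": int(report.statistics.size),
                }
            )
        )

    table = _stage("clump")(loci.clump)(
        sumstats,
        genotypes,
        p_threshold=cfg.p_threshold,
        r2_threshold=cfg.r2_threshold,
        window_bp=cfg.window_bp,
        window_convention=cfg.window_convention,
    )
    table.to_frame().to_csv(out / "loci.tsv", sep="\t", index=False)

    axis_df = _stage("axis")(_axis)(cfg, emb, truth, covars)
    axis_df.to_csv(out / "axis.tsv", sep="\t", index=False)

    manifest = {
        "seed": cfg.seed,
        "config_hash": hashlib.sha256(
            json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "n_participants": genotypes.n_samples,
        "n_variants": genotypes.n_variants,
        "n_loci": len(table),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    save_config(cfg, out / "config_used.yaml")
    if enc_log is not None:
        enc_log.to_csv(out / "training_log.tsv", sep="\t", index=False)
    return out


def _substream(seed: int, name: str) -> int:
    return int.from_bytes(hashlib.sha256(f"{seed}:{name}".encode()).digest()[:4], "little")


def _inputs(cfg: PipelineConfig):
    if cfg.genotypes_path:
        genotypes = (
            io.read_vcf(cfg.genotypes_path)
            if str(cfg.genotypes_path).endswith(".vcf")
            else io.read_dosage_tsv(cfg.genotypes_path)
        )
        features = io.frame_to_feature_matrix(io.read_table(cfg.features_path))
        return genotypes, features, None
    scfg = synthcohort.SyntheticConfig(**{**cfg.cohort, "seed": cfg.seed})
    genotypes = synthcohort.simulate_genotypes(scfg)
    features, truth = synthcohort.simulate_cohort(scfg, genotypes)
    return genotypes, features, truth


def _train(cfg: PipelineConfig, features, truth, out: Path):
    ages_row = np.array(
        [truth.age_vector[int(p[1:])] for p in features.participants]
    )
    plan = contrastive.make_split_plan(features.participants, seed=_substream(cfg.seed, "split"))
    tcfg = contrastive.TrainConfig(**{**cfg.encoder, "seed": _substream(cfg.seed, "train")})
    enc, log = contrastive.train_encoder(
        features, ages_row, features.participants, tcfg, plan
    )
    enc.save(out / "encoder.npz")
    return log


def _embed(cfg: PipelineConfig, features, truth):
    averaged = embedding.average_eyes(features)
    n_comp = min(cfg.n_components, averaged.n_features, averaged.n_samples - 1)
    proj, emb = embedding.fit_pca(averaged, n_components=n_comp)
    values = emb.values
    if cfg.rank_normalize:
        values = embedding.rank_inverse_normal(values)
    pheno = EmbeddingMatrix(
        sample_ids=emb.sample_ids,
        values=values,
        provenance={**emb.provenance, "rank_normalized": cfg.rank_normalize, "averaged_eyes": True},
    )
    if truth is not None:
        covars = embedding.build_covariates(
            pheno.sample_ids, truth.age_vector, truth.sex_vector
        )
    else:
        raise RuntimeError("external covariate ingestion requires covariates_path")
    return proj, emb, pheno, covars


def _axis(cfg: PipelineConfig, emb, truth, covars):
    trait = truth.disease_labels.astype(float) if truth is not None else None
    if trait is None:
        raise RuntimeError("axis stage requires a trait")
    model = axes.fit_axis(trait, emb, covars)
    scores = axes.loo_scores(model, trait, emb, covars)
    x_low, x_high = axes.extreme_means(emb, scores, q=cfg.axis_q)
    rows = []
    for alpha in cfg.axis_alphas:
        x = axes.interpolate(x_low, x_high, float(alpha))
        rows.append({"alpha": float(alpha), **{f"PC{j + 1}": x[j] for j in range(x.size)}})
    return pd.DataFrame(rows)
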