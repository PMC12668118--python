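"""Frozen desk-scale benchmark experiments.

Each function regenerates its synthetic inputs from a seed, runs the method
under test through the public package surface, and returns summary numbers.
Used by the acceptance suite and the acceptance report script.
"""

from __future__ import annotations

import numpy as np

from . import assoc, axes, embedding, synthcohort

__all__ = [
    "calibration_benchmark",
    "power_benchmark",
    "axis_recovery_benchmark",
]


def _phenotypes(cfg: synthcohort.SyntheticConfig, n_components: int):
    genotypes = synthcohort.simulate_genotypes(cfg)
    features, truth = synthcohort.simulate_cohort(cfg, genotypes)
    averaged = embedding.average_eyes(features)
    proj, emb = embedding.fit_pca(averaged, n_components=n_components)
    Y = embedding.rank_inverse_normal(emb.values)
    C = embedding.build_covariates(
        averaged.sample_ids, truth.age_vector, truth.sex_vector
    )
    return genotypes, features, truth, proj, emb, Y, C


def calibration_benchmark(seed: int = 1, n_perm: int = 5) -> dict:
    """Null multivariate GWAS (N=500, K=10, 2000 variants): type-I error,
    genomic inflation, and permutation-null uniformity."""
    cfg = synthcohort.SyntheticConfig(
        n_participants=500,
        n_variants=2000,
        n_causal_variants=0,
        n_raw_features=10,
        ld_decay=0.3,
        noise_sd=1.0,
        seed=seed,
    )
    genotypes, _, _, _, _, Y, C = _phenotypes(cfg, n_components=10)
    records = assoc.run_gwas(genotypes, Y, C, maf_min=0.01)
    pvals = np.array([r.p_value for r in records])
    report = assoc.permutation_null(
        genotypes, Y, C, n_perm=n_perm, seed=seed + 1, maf_min=0.01
    )
    return {
        "type_i_error_005": float((pvals < 0.05).mean()),
        "lambda_gc": assoc.genomic_inflation(records),
        "perm_ks_p": report.ks_p_value,
        "perm_lambda_gc": report.lambda_gc,
        "n_variants": int(pvals.size),
        "n_perm_stats": int(report.statistics.size),
    }


POWER_COHORT = dict(
    n_participants=800,
    n_variants=300,
    n_causal_variants=20,
    n_raw_features=10,
    effect_dims=6,
    effect_size=0.1,
    noise_sd=1.0,
    ld_decay=0.0,
    p_both_eyes=0.0,
    age_signal_scale=0.5,
)


def power_benchmark(n_seeds: int = 20, p_cut: float = 1e-5, seed0: int = 0) -> dict:
    """Dense-effect discovery comparison: multivariate K-df test versus the
    univariate + Cauchy-aggregation baseline, per seed."""
    mv_counts, uv_counts = [], []
    for seed in range(seed0, seed0 + n_seeds):
        cfg = synthcohort.SyntheticConfig(**POWER_COHORT, seed=seed)
        genotypes, _, _, _, _, Y, C = _phenotypes(cfg, n_components=10)
        records = assoc.run_gwas(genotypes, Y, C, maf_min=0.01)
        pvals = np.array([r.p_value for r in records])
        uni = assoc.test_univariate_acat(genotypes, Y, C, maf_min=0.01)
        mv_counts.append(int((pvals < p_cut).sum()))
        uv_counts.append(int((uni["P_ACAT"] < p_cut).sum()))
    mv = np.array(mv_counts)
    uv = np.array(uv_counts)
    return {
        "multivariate_counts": mv,
        "acat_counts": uv,
        "multivariate_mean": float(mv.mean()),
        "acat_mean": float(uv.mean()),
        "strict_wins": int((mv > uv).sum()),
        "n_seeds": n_seeds,
    }


def axis_recovery_benchmark(
    n: int = 2000, seed: int = 7, trait_seed: int = 99, n_null: int = 200
) -> dict:
    """Planted trait-direction recovery plus a permutation null band."""
    cfg = synthcohort.SyntheticConfig(
        n_participants=n,
        n_variants=20,
        n_causal_variants=0,
        n_raw_features=40,
        noise_sd=0.5,
        age_signal_scale=0.1,
        p_both_eyes=0.8,
        seed=seed,
    )
    genotypes, features, truth, proj, emb, _, C = _phenotypes(cfg, n_components=40)
    averaged = embedding.average_eyes(features)
    rng = np.random.default_rng(trait_seed)
    trait = averaged.values @ truth.trait_direction + 0.2 * rng.standard_normal(n)

    def recover(t: np.ndarray) -> float:
        model = axes.fit_axis(t, emb, C)
        scores = axes.loo_scores(model, t, emb, C)
        x_low, x_high = axes.extreme_means(emb, scores, q=0.05)
        return axes.axis_recovery_report(
            x_low, x_high, proj, truth.trait_direction
        )["abs_cosine"]

    observed = recover(trait)
    null_cosines = np.array(
        [recover(rng.permutation(trait)) for _ in range(n_null)]
    )
    return {
        "abs_cosine": observed,
        "null_band_upper": float(np.quantile(null_cosines, 0.99)),
        "null_cosines": null_cosines,
        "n": n,
    }
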