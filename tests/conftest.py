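import numpy as np
import pytest

from embgwas import embedding, synthcohort


@pytest.fixture(scope="session")
def small_cohort():
    """500-participant cohort with a handful of planted effects."""
    cfg = synthcohort.SyntheticConfig(
        n_participants=500,
        n_variants=200,
        n_causal_variants=5,
        n_raw_features=16,
        effect_dims=4,
        effect_size=0.4,
        noise_sd=0.5,
        ld_decay=0.3,
        seed=42,
    )
    genotypes = synthcohort.simulate_genotypes(cfg)
    features, truth = synthcohort.simulate_cohort(cfg, genotypes)
    return cfg, genotypes, features, truth


@pytest.fixture(scope="session")
def null_phenotypes(small_cohort):
    """Rank-normalized PCA phenotypes plus covariates from the small cohort."""
    cfg, genotypes, features, truth = small_cohort
    averaged = embedding.average_eyes(features)
    proj, emb = embedding.fit_pca(averaged, n_components=8)
    Y = embedding.rank_inverse_normal(emb.values)
    C = embedding.build_covariates(averaged.sample_ids, truth.age_vector, truth.sex_vector)
    return Y, C


def random_covariates(n, n_extra=1, seed=0):
    rng = np.random.default_rng(seed)
    cols = [np.ones(n)] + [rng.standard_normal(n) for _ in range(n_extra)]
    return embedding.CovariateMatrix(
        sample_ids=[f"s{i:04d}" for i in range(n)],
        values=np.column_stack(cols),
        columns=["intercept"] + [f"c{j}" for j in range(n_extra)],
    )
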