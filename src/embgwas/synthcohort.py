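"""Seeded synthetic cohort generator.

Produces genotypes with tunable first-order LD, age-structured image
features with planted per-variant effects, and binary disease labels from a
logistic liability — a self-contained test surface for every downstream
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import FeatureMatrix, GenotypeMatrix

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "simulate_genotypes",
    "simulate_cohort",
    "default_config",
]


@dataclass
class SyntheticConfig:
    n_participants: int = 1000
    p_both_eyes: float = 0.8
    n_variants: int = 500
    maf_range: tuple[float, float] = (0.05, 0.45)
    ld_decay: float = 0.5
    n_raw_features: int = 256
    age_range: tuple[float, float] = (40.0, 70.0)
    n_causal_variants: int = 10
    effect_dims: int = 8
    effect_size: float = 0.3
    noise_sd: float = 1.0
    seed: int = 0
    # extras beyond the minimal surface
    pos_spacing: int = 10_000
    prevalence: float = 0.10
    missing_rate: float = 0.0
    age_signal_scale: float = 1.0
    # weight of the linear age term relative to the curved terms; 0 makes the
    # age signal invisible to a linear probe on raw features
    age_linear_weight: float = 0.0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high < 0.5")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError("ld_decay must be in [0, 1)")
        if not (0.0 <= self.p_both_eyes <= 1.0):
            raise ValueError("p_both_eyes must be a probability")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        for name in (
            "n_participants",
            "n_variants",
            "n_raw_features",
            "effect_dims",
            "pos_spacing",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_causal_variants < 0 or self.n_causal_variants > self.n_variants:
            raise ValueError("n_causal_variants out of range")
        if self.effect_dims > self.n_raw_features:
            raise ValueError("effect_dims exceeds n_raw_features")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if not (0.0 < self.prevalence < 1.0):
            raise ValueError("prevalence must be in (0, 1)")


@dataclass
class SyntheticTruth:
    causal_variant_ids: list[str]
    effect_matrix: np.ndarray  # n_variants x n_raw_features
    age_vector: np.ndarray  # per participant, years
    sex_vector: np.ndarray  # per participant, {0, 1}
    trait_direction: np.ndarray  # unit vector in raw feature space
    disease_labels: np.ndarray  # per participant, {0, 1}
    liability: np.ndarray = field(default=None)  # continuous liability score


def default_config(**overrides) -> SyntheticConfig:
    """The documented default desk-scale cohort (fixed seed)."""
    cfg = SyntheticConfig(**overrides)
    cfg.validate()
    return cfg


def simulate_genotypes(config: SyntheticConfig) -> GenotypeMatrix:
    """Draw dosages as sums of two haplotypes with Markov neighbor-copying LD.

    Each haplotype state at variant ``v`` copies the state at ``v - 1`` with
    probability ``ld_decay`` and is otherwise a fresh ``Bernoulli(f_v)`` draw,
    giving block-like adjacent r-squared tunable from 0 (independent) towards 1.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    n, m = config.n_participants, config.n_variants
    freqs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)

    haps = np.empty((2 * n, m), dtype=np.int8)
    fresh = rng.random((2 * n, m)) < freqs[None, :]
    copy = rng.random((2 * n, m)) < config.ld_decay
    haps[:, 0] = fresh[:, 0]
    for v in range(1, m):
        haps[:, v] = np.where(copy[:, v], haps[:, v - 1], fresh[:, v])
    dosages = (haps[0::2] + haps[1::2]).astype(float)

    if config.missing_rate > 0:
        miss = rng.random((n, m)) < config.missing_rate
        dosages[miss] = np.nan

    variants = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(1, m + 1, dtype=np.int64) * config.pos_spacing,
            "id": [f"var{v:06d}" for v in range(m)],
            "ref": "A",
            "alt": "G",
        }
    )
    sample_ids = [f"P{i:06d}" for i in range(n)]
    return GenotypeMatrix(sample_ids=sample_ids, dosages=dosages, variants=variants)


def _age_basis(age: np.ndarray, age_range: tuple[float, float], linear_weight: float) -> np.ndarray:
    """Smooth nonlinear basis of age on [-1, 1]: Legendre P2, P3 (+ optional P1).

    P2 and P3 are orthogonal to the linear term under a uniform age draw, so
    with ``linear_weight = 0`` the age signal carried by the features is
    invisible to a purely linear probe — nonlinear alignment has to earn it.
    """
    lo, hi = age_range
    z = 2.0 * (age - lo) / (hi - lo) - 1.0
    p1 = z
    p2 = 1.5 * z**2 - 0.5
    p3 = 2.5 * z**3 - 1.5 * z
    basis = np.column_stack([linear_weight * p1, p2, p3])
    return basis


def simulate_cohort(
    config: SyntheticConfig, genotypes: GenotypeMatrix
) -> tuple[FeatureMatrix, SyntheticTruth]:
    """Build per-image raw features and disease labels on top of genotypes.

    Features per image: ``f = W phi(age) + sum_v g_v * effect_v + eps`` with
    ``phi`` a fixed smooth nonlinear age basis, ``W`` a seeded loading matrix,
    ``g_v`` standardized dosage and i.i.d. Gaussian image noise ``eps``.
    Participants with two images share all systematic terms and differ only in
    the noise draw.
    """
    config.validate()
    if genotypes.n_samples != config.n_participants:
        raise ValueError(
            f"genotypes carry {genotypes.n_samples} samples, config expects "
            f"{config.n_participants}"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 23]))
    n, d = config.n_participants, config.n_raw_features

    age = rng.uniform(config.age_range[0], config.age_range[1], size=n)
    sex = rng.integers(0, 2, size=n).astype(float)
    basis = _age_basis(age, config.age_range, config.age_linear_weight)
    loadings = rng.standard_normal((basis.shape[1], d)) * config.age_signal_scale

    systematic = basis @ loadings

    # planted genetic effects on standardized dosages
    effect_matrix = np.zeros((genotypes.n_variants, d))
    causal_idx = np.sort(
        rng.choice(genotypes.n_variants, size=config.n_causal_variants, replace=False)
    )
    dos = genotypes.dosages
    dos_filled = np.where(np.isnan(dos), np.nanmean(dos, axis=0), dos)
    for v in causal_idx:
        dims = rng.choice(d, size=config.effect_dims, replace=False)
        signs = rng.choice([-1.0, 1.0], size=config.effect_dims)
        effect_matrix[v, dims] = signs * config.effect_size
        g = dos_filled[:, v]
        sd = g.std()
        if sd > 0:
            g_std = (g - g.mean()) / sd
            systematic = systematic + np.outer(g_std, effect_matrix[v])

    # per-image rows: every participant has >= 1 image, some have two
    both = rng.random(n) < config.p_both_eyes
    image_ids: list[str] = []
    participants: list[str] = []
    rows: list[int] = []
    for i, pid in enumerate(genotypes.sample_ids):
        image_ids.append(f"{pid}_L")
        participants.append(pid)
        rows.append(i)
        if both[i]:
            image_ids.append(f"{pid}_R")
            participants.append(pid)
            rows.append(i)
    noise = rng.standard_normal((len(rows), d)) * config.noise_sd
    values = systematic[rows] + noise

    # disease liability: age plus the projection of the participant-level
    # systematic features onto a random unit direction
    trait_direction = rng.standard_normal(d)
    trait_direction /= np.linalg.norm(trait_direction)
    z_age = 2.0 * (age - config.age_range[0]) / (
        config.age_range[1] - config.age_range[0]
    ) - 1.0
    proj = systematic @ trait_direction
    proj_sd = proj.std()
    lin = 1.0 * z_age + (proj - proj.mean()) / (proj_sd if proj_sd > 0 else 1.0)
    intercept = _prevalence_intercept(lin, config.prevalence)
    prob = 1.0 / (1.0 + np.exp(-(lin + intercept)))
    labels = (rng.random(n) < prob).astype(int)

    features = FeatureMatrix(
        sample_ids=image_ids, values=values, participants=participants
    )
    truth = SyntheticTruth(
        causal_variant_ids=[genotypes.variants["id"].iloc[v] for v in causal_idx],
        effect_matrix=effect_matrix,
        age_vector=age,
        sex_vector=sex,
        trait_direction=trait_direction,
        disease_labels=labels,
        liability=lin + intercept,
    )
    return features, truth


def _prevalence_intercept(lin: np.ndarray, prevalence: float) -> float:
    """Bisection for the intercept giving mean sigmoid(lin + b) = prevalence."""
    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        p = np.mean(1.0 / (1.0 + np.exp(-(lin + mid))))
        if p < prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
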