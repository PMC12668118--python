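"""Per-image features -> per-participant GWAS-ready phenotypes.

Eye averaging, PCA reduction with a fixed sign convention, rank-based
inverse normal transformation, and covariate design construction /
residualization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .datatypes import EmbeddingMatrix, FeatureMatrix

__all__ = [
    "average_eyes",
    "PCAProjection",
    "fit_pca",
    "rank_inverse_normal",
    "build_covariates",
    "CovariateMatrix",
    "residualize",
]


def average_eyes(features: FeatureMatrix, participant_map: dict[str, str] | None = None) -> FeatureMatrix:
    """Collapse per-image rows to one row per participant by arithmetic mean.

    ``participant_map`` maps image id -> participant id; if omitted the
    ``participants`` attribute of ``features`` is used.  Single-image
    participants pass through unchanged.  Participants appear in sorted-id
    order (the canonical sample ordering used throughout).
    """
    if participant_map is not None:
        parts = [participant_map[s] for s in features.sample_ids]
    elif features.participants is not None:
        parts = list(features.participants)
    else:
        raise ValueError("no participant mapping available")

    order: dict[str, list[int]] = {}
    for i, p in enumerate(parts):
        order.setdefault(p, []).append(i)
    pids = sorted(order)
    out = np.empty((len(pids), features.n_features))
    for j, pid in enumerate(pids):
        out[j] = features.values[order[pid]].mean(axis=0)
    return FeatureMatrix(sample_ids=pids, values=out, participants=pids)


@dataclass
class PCAProjection:
    """Centered PCA projection reusable on new samples.

    ``components`` is ``n_components x n_features`` with a deterministic sign
    convention: the largest-magnitude loading of each component is positive.
    """

    mean: np.ndarray
    components: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) @ self.components.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, dtype=float) @ self.components + self.mean

    def to_feature_space(self, direction: np.ndarray) -> np.ndarray:
        """Map a direction in component space back to raw feature space."""
        return np.asarray(direction, dtype=float) @ self.components


def fit_pca(
    features: FeatureMatrix, n_components: int = 40
) -> tuple[PCAProjection, EmbeddingMatrix]:
    X = features.values
    n, d = X.shape
    if n_components > min(n, d):
        raise ValueError(
            f"n_components={n_components} exceeds min(n={n}, d={d})"
        )
    if n <= n_components:
        raise ValueError("need more samples than components")
    mean = X.mean(axis=0)
    Xc = X - mean
    # thin SVD: deterministic and exact; sign fixed below
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    comps = vt[:n_components]
    ev = (s[:n_components] ** 2) / (n - 1)
    total_var = (s**2).sum() / (n - 1)
    for k in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[k]))
        if comps[k, j] < 0:
            comps[k] = -comps[k]
    proj = PCAProjection(
        mean=mean,
        components=comps,
        explained_variance=ev,
        explained_variance_ratio=ev / total_var if total_var > 0 else ev,
    )
    emb = EmbeddingMatrix(
        sample_ids=list(features.sample_ids),
        values=proj.transform(X),
        provenance={"pca_reduced": True, "n_components": n_components},
    )
    return proj, emb


def rank_inverse_normal(values: np.ndarray) -> np.ndarray:
    """Map values to normal quantiles of their (average) ranks.

    ``out_i = Phi^-1((r_i - 0.5) / n)``; ties get average ranks.  Applied
    column-wise when given a matrix.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim == 2:
        return np.column_stack([rank_inverse_normal(x[:, j]) for j in range(x.shape[1])])
    if x.size < 2:
        raise ValueError("need at least 2 values")
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    if np.all(x == x[0]):
        raise ValueError("degenerate column: all values equal")
    r = rankdata(x, method="average")
    return norm.ppf((r - 0.5) / x.size)


@dataclass
class CovariateMatrix:
    """Full-column-rank design matrix including the intercept."""

    sample_ids: list[str]
    values: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.columns)):
            raise ValueError("covariate shape mismatch")
        r = np.linalg.matrix_rank(self.values)
        if r < len(self.columns):
            culprits = _collinear_columns(self.values, self.columns)
            raise ValueError(
                f"rank-deficient covariate design (rank {r} < {len(self.columns)}); "
                f"suspect columns: {culprits}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    kept: list[int] = []
    bad: list[str] = []
    for j in range(X.shape[1]):
        cand = kept + [j]
        if np.linalg.matrix_rank(X[:, cand]) == len(cand):
            kept.append(j)
        else:
            bad.append(names[j])
    return bad


def build_covariates(
    sample_ids: list[str],
    age: np.ndarray,
    sex: np.ndarray,
    genetic_pcs: np.ndarray | None = None,
    batch: np.ndarray | None = None,
) -> CovariateMatrix:
    """Standard design: intercept, age, sex, age^2, sex*age, sex*age^2, PCs,
    one-hot batch columns.  Age is centered before squaring to curb
    collinearity; sex is coded {0, 1}.
    """
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    ac = age - age.mean()
    cols = [np.ones_like(ac), ac, sex, ac**2, sex * ac, sex * ac**2]
    names = ["intercept", "age", "sex", "age2", "sex_age", "sex_age2"]
    if genetic_pcs is not None:
        pcs = np.asarray(genetic_pcs, dtype=float)
        for k in range(pcs.shape[1]):
            cols.append(pcs[:, k])
            names.append(f"gpc{k + 1}")
    if batch is not None:
        levels = sorted(set(batch))
        for lev in levels[1:]:  # first level absorbed by intercept
            cols.append((np.asarray(batch) == lev).astype(float))
            names.append(f"batch_{lev}")
    return CovariateMatrix(
        sample_ids=list(sample_ids), values=np.column_stack(cols), columns=names
    )


def residualize(Y: np.ndarray, C: CovariateMatrix) -> np.ndarray:
    """Project ``Y`` onto the orthogonal complement of the covariate span."""
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] != C.n_samples:
        raise ValueError("row count mismatch between Y and covariates")
    q, _ = np.linalg.qr(C.values)
    return Y - q @ (q.T @ Y)
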