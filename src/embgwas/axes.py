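"""Trait-axis construction: ridge-BLUP mixed model over embedding
dimensions, closed-form leave-one-out random-effect predictions,
extreme-quantile mean embeddings and linear interpolation between them."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .datatypes import EmbeddingMatrix
from .embedding import CovariateMatrix, PCAProjection

__all__ = [
    "AxisModel",
    "fit_axis",
    "loo_scores",
    "extreme_means",
    "interpolate",
    "axis_recovery_report",
]


@dataclass
class AxisModel:
    """Fitted trait-axis mixed model ``t = C b + X u + e`` with isotropic
    random-effect covariance ``u ~ N(0, sigma_u^2 I_K)``."""

    sigma2_u: float
    sigma2_e: float
    fixed_effects: np.ndarray  # per covariate column
    random_effects: np.ndarray  # u-hat, length K
    delta: float  # sigma2_e / sigma2_u (ridge penalty)
    loo: np.ndarray | None = None  # per-sample LOO scores, filled on demand
    x_low: np.ndarray | None = None
    x_high: np.ndarray | None = None
    quantile: float | None = None


def _reml_neg_loglik(log_gamma: float, s2: np.ndarray, a2: np.ndarray, b: float, n_eff: int) -> float:
    """Profiled restricted log-likelihood (negated) at variance ratio
    gamma = sigma_u^2 / sigma_e^2, in the eigenbasis of the residualized
    embedding Gram matrix.

    ``s2``: squared singular values of M X; ``a2``: squared projections of
    M t onto the corresponding left singular vectors; ``b``: residual sum of
    squares of M t outside that span; ``n_eff = N - rank(C)``.
    """
    gamma = np.exp(log_gamma)
    d = gamma * s2 + 1.0
    sigma2_e = (np.sum(a2 / d) + b) / n_eff
    return 0.5 * (n_eff * np.log(sigma2_e) + np.sum(np.log(d)))


def fit_axis(
    trait: np.ndarray,
    X: EmbeddingMatrix | np.ndarray,
    C: CovariateMatrix,
) -> AxisModel:
    """REML fit over the one-dimensional variance-ratio profile, then BLUP.

    Binary traits are fitted on the 0/1 scale.  Works for K >= N thanks to
    the ridge-type shrinkage.
    """
    t = np.asarray(trait, dtype=float)
    Xv = X.values if isinstance(X, EmbeddingMatrix) else np.asarray(X, dtype=float)
    n, k = Xv.shape
    if t.shape[0] != n or C.n_samples != n:
        raise ValueError("sample count mismatch")
    if t.std() == 0:
        raise ValueError("zero-variance trait")

    q, _ = np.linalg.qr(C.values)
    rank_c = C.values.shape[1]
    mt = t - q @ (q.T @ t)
    mx = Xv - q @ (q.T @ Xv)
    u_svd, s, _ = np.linalg.svd(mx, full_matrices=False)
    s2 = s**2
    proj = u_svd.T @ mt
    a2 = proj**2
    b = float(mt @ mt - a2.sum())
    b = max(b, 0.0)
    n_eff = n - rank_c

    grid = np.linspace(-18.0, 18.0, 73)
    vals = [_reml_neg_loglik(lg, s2, a2, b, n_eff) for lg in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        _reml_neg_loglik,
        bounds=(lo, hi),
        args=(s2, a2, b, n_eff),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_gamma = float(res.x)
    # boundary: essentially no random-effect variance
    if i == 0 and vals[0] <= min(vals):
        log_gamma = min(log_gamma, grid[0])
    gamma = np.exp(log_gamma)
    d = gamma * s2 + 1.0
    sigma2_e = float((np.sum(a2 / d) + b) / n_eff)
    sigma2_u = gamma * sigma2_e
    delta = 1.0 / gamma

    theta = _solve_mme(t, Xv, C.values, delta)
    return AxisModel(
        sigma2_u=sigma2_u,
        sigma2_e=sigma2_e,
        fixed_effects=theta[: C.values.shape[1]],
        random_effects=theta[C.values.shape[1] :],
        delta=delta,
    )


def _mme_matrix(Xv: np.ndarray, Cv: np.ndarray, delta: float) -> np.ndarray:
    D = np.hstack([Cv, Xv])
    A = D.T @ D
    c = Cv.shape[1]
    A[c:, c:] += delta * np.eye(Xv.shape[1])
    return A


def _solve_mme(t: np.ndarray, Xv: np.ndarray, Cv: np.ndarray, delta: float) -> np.ndarray:
    D = np.hstack([Cv, Xv])
    A = _mme_matrix(Xv, Cv, delta)
    return np.linalg.solve(A, D.T @ t)


def loo_scores(
    model: AxisModel,
    trait: np.ndarray,
    X: EmbeddingMatrix | np.ndarray,
    C: CovariateMatrix,
) -> np.ndarray:
    """``score_i = X_i u^(-i)``: random-effect prediction with sample i left
    out, via the rank-one downdate identity at fixed variance components."""
    t = np.asarray(trait, dtype=float)
    Xv = X.values if isinstance(X, EmbeddingMatrix) else np.asarray(X, dtype=float)
    Cv = C.values
    D = np.hstack([Cv, Xv])
    c = Cv.shape[1]
    A = _mme_matrix(Xv, Cv, model.delta)
    Ainv = np.linalg.inv(A)
    theta = Ainv @ (D.T @ t)
    fitted = D @ theta
    AinvD = D @ Ainv  # n x (c+K); row i = (A^-1 d_i)^T
    h = np.einsum("ij,ij->i", AinvD, D)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("leverage >= 1: exact interpolation, LOO undefined")
    # Sherman-Morrison: u^(-i) = u - (A^-1 d_i)_u * resid_i / (1 - h_ii)
    xu = np.einsum("ij,ij->i", Xv, AinvD[:, c:])
    resid = t - fitted
    return Xv @ theta[c:] - xu * resid / (1.0 - h)


def extreme_means(
    X: EmbeddingMatrix | np.ndarray,
    scores: np.ndarray,
    q: float = 0.001,
    sample_ids: list[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean embeddings over the bottom and top ``ceil(q*N)`` samples by
    score; ties at the cut break by sample-id order."""
    Xv = X.values if isinstance(X, EmbeddingMatrix) else np.asarray(X, dtype=float)
    if sample_ids is None:
        sample_ids = (
            X.sample_ids
            if isinstance(X, EmbeddingMatrix)
            else [f"s{i:09d}" for i in range(Xv.shape[0])]
        )
    s = np.asarray(scores, dtype=float)
    n = s.size
    if not (0.0 < q < 0.5):
        raise ValueError("q must be in (0, 0.5)")
    m = int(np.ceil(q * n))
    if m < 1 or q * n < 1e-12:
        raise ValueError("q*N < 1: increase q for small cohorts")
    if np.all(s == s[0]):
        warnings.warn("constant scores: extreme tails are arbitrary (degenerate)")
    ids = np.asarray(sample_ids)
    order_low = np.lexsort((ids, s))
    order_high = np.lexsort((ids, -s))
    x_low = Xv[order_low[:m]].mean(axis=0)
    x_high = Xv[order_high[:m]].mean(axis=0)
    return x_low, x_high


def interpolate(x_low: np.ndarray, x_high: np.ndarray, alpha: float, allow_extrapolation: bool = False) -> np.ndarray:
    """Exact affine combination ``(1 - alpha) x_low + alpha x_high``."""
    x_low = np.asarray(x_low, dtype=float)
    x_high = np.asarray(x_high, dtype=float)
    if x_low.shape != x_high.shape:
        raise ValueError("endpoint shapes differ")
    if not allow_extrapolation and not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha outside [0, 1] (extrapolation not enabled)")
    if alpha == 0.0:
        return x_low.copy()
    if alpha == 1.0:
        return x_high.copy()
    return (1.0 - alpha) * x_low + alpha * x_high


def axis_recovery_report(
    x_low: np.ndarray,
    x_high: np.ndarray,
    projection: PCAProjection,
    trait_direction: np.ndarray,
) -> dict:
    """Cosine similarity between the recovered raw-space axis and a planted
    feature-space direction (validation harness for synthetic cohorts)."""
    delta = np.asarray(x_high, dtype=float) - np.asarray(x_low, dtype=float)
    raw_axis = projection.to_feature_space(delta)
    t = np.asarray(trait_direction, dtype=float)
    denom = np.linalg.norm(raw_axis) * np.linalg.norm(t)
    cos = float(raw_axis @ t / denom) if denom > 0 else np.nan
    return {
        "cosine": cos,
        "abs_cosine": abs(cos),
        "axis_norm": float(np.linalg.norm(raw_axis)),
    }
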