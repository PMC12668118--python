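"""Multivariate association engine.

Each variant (or gene burden score) is tested against the K-dimensional
embedding phenotype with a chi-squared statistic on K degrees of freedom;
a univariate per-dimension test combined with Cauchy aggregation serves as
the baseline, and permutation runs calibrate the null.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .datatypes import EmbeddingMatrix, GenotypeMatrix
from .embedding import CovariateMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "NullModel",
    "AssociationRecord",
    "fit_null",
    "test_score",
    "test_refined",
    "run_gwas",
    "acat_combine",
    "test_univariate_acat",
    "permutation_null",
    "test_burden",
    "genomic_inflation",
    "records_to_frame",
]

_COLLINEAR_TOL = 1e-10


@dataclass
class NullModel:
    """Null multivariate regression of phenotypes on covariates only."""

    coefficients: np.ndarray  # C-cols x K
    sigma: np.ndarray  # K x K residual covariance, dof-corrected
    sigma_chol: tuple  # cho_factor of sigma
    q_basis: np.ndarray  # N x rank(C) orthonormal covariate basis
    residuals: np.ndarray  # N x K null residuals (M Y)
    n_samples: int
    rank_c: int

    @property
    def n_dims(self) -> int:
        return self.sigma.shape[0]

    def project_out(self, g: np.ndarray) -> np.ndarray:
        """Apply the covariate residual projector M to a vector/matrix."""
        return g - self.q_basis @ (self.q_basis.T @ g)


@dataclass
class AssociationRecord:
    variant_id: str
    beta: np.ndarray | None  # length-K effect vector per dosage unit
    statistic: float
    dof: int
    p_value: float
    maf: float = np.nan
    callrate: float = np.nan
    flag: str = ""
    chrom: str = ""
    pos: int = -1


def fit_null(Y: EmbeddingMatrix | np.ndarray, C: CovariateMatrix) -> NullModel:
    """Least-squares null fit with dof-corrected residual covariance.

    ``Sigma = E'E / (N - rank(C))`` from the null residuals ``E``; the
    Cholesky factor is cached for the per-variant quadratic forms.
    """
    Yv = Y.values if isinstance(Y, EmbeddingMatrix) else np.asarray(Y, dtype=float)
    if Yv.ndim == 1:
        Yv = Yv[:, None]
    n, k = Yv.shape
    if n != C.n_samples:
        raise ValueError("sample count mismatch between phenotypes and covariates")
    c = C.values.shape[1]
    if n <= c + k:
        raise ValueError(
            f"insufficient residual degrees of freedom: N={n}, covariates={c}, K={k}"
        )
    q, r = np.linalg.qr(C.values)
    rank_c = int(np.sum(np.abs(np.diag(r)) > _COLLINEAR_TOL * max(n, c)))
    if rank_c < c:
        raise ValueError("rank-deficient covariate design")
    coeff = np.linalg.solve(r, q.T @ Yv)
    resid = Yv - C.values @ coeff
    sigma = resid.T @ resid / (n - rank_c)
    sigma = 0.5 * (sigma + sigma.T)
    eigmin = np.linalg.eigvalsh(sigma)[0]
    if eigmin <= 1e-10 * max(1.0, np.trace(sigma) / k):
        raise ValueError(
            "residual covariance is not positive definite; consider adding "
            "ridge jitter to the phenotypes or dropping collinear dimensions"
        )
    return NullModel(
        coefficients=coeff,
        sigma=sigma,
        sigma_chol=cho_factor(sigma, lower=True),
        q_basis=q,
        residuals=resid,
        n_samples=n,
        rank_c=rank_c,
    )


def _prepare_dosage(g: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Mean-impute missing dosages; return (filled, maf, callrate)."""
    g = np.asarray(g, dtype=float)
    miss = np.isnan(g)
    callrate = 1.0 - miss.mean()
    if miss.all():
        return np.zeros_like(g), np.nan, 0.0
    mu = g[~miss].mean()
    if miss.any():
        g = np.where(miss, mu, g)
    freq = mu / 2.0
    return g, min(freq, 1.0 - freq), callrate


def test_score(
    null: NullModel,
    g: np.ndarray,
    C: CovariateMatrix | None = None,
    Y: np.ndarray | None = None,
    variant_id: str = "",
) -> AssociationRecord:
    """Score-type multivariate test of one dosage vector.

    With M the covariate residual projector, ``beta = (g'M Y) / (g'M g)`` and
    ``lambda = (g'M g) * beta' Sigma^-1 beta`` compared to chi2_K.
    """
    g, maf, callrate = _prepare_dosage(g)
    if g.shape[0] != null.n_samples:
        raise ValueError("dosage length does not match null model")
    gm = null.project_out(g)
    den = float(gm @ gm)
    k = null.n_dims
    if den <= _COLLINEAR_TOL * null.n_samples:
        return AssociationRecord(
            variant_id=variant_id,
            beta=None,
            statistic=np.nan,
            dof=k,
            p_value=np.nan,
            maf=maf,
            callrate=callrate,
            flag="monomorphic/collinear",
        )
    beta = (gm @ null.residuals) / den
    lam = den * float(beta @ cho_solve(null.sigma_chol, beta))
    p = float(stats.chi2.sf(lam, k))
    p = max(p, np.exp(stats.chi2.logsf(lam, k)))  # log-space guard vs underflow
    return AssociationRecord(
        variant_id=variant_id,
        beta=beta,
        statistic=lam,
        dof=k,
        p_value=max(p, 5e-324),
        maf=maf,
        callrate=callrate,
    )


def test_refined(
    null: NullModel,
    g: np.ndarray,
    C: CovariateMatrix | None = None,
    Y: np.ndarray | None = None,
    n_iter: int = 1,
    variant_id: str = "",
) -> AssociationRecord:
    """One-step refinement: re-estimate the residual covariance under the
    alternative once and report the likelihood-ratio statistic on K df.

    ``n_iter=0`` reduces exactly to :func:`test_score`.
    """
    if n_iter == 0:
        return test_score(null, g, C, Y, variant_id=variant_id)
    if n_iter != 1:
        raise ValueError("n_iter must be 0 or 1")
    g, maf, callrate = _prepare_dosage(g)
    gm = null.project_out(g)
    den = float(gm @ gm)
    k = null.n_dims
    n = null.n_samples
    if den <= _COLLINEAR_TOL * n:
        return AssociationRecord(
            variant_id=variant_id,
            beta=None,
            statistic=np.nan,
            dof=k,
            p_value=np.nan,
            maf=maf,
            callrate=callrate,
            flag="monomorphic/collinear",
        )
    beta = (gm @ null.residuals) / den
    e0 = null.residuals
    e1 = e0 - np.outer(gm, beta)
    s0 = e0.T @ e0 / n
    s1 = e1.T @ e1 / n
    sign0, logdet0 = np.linalg.slogdet(s0)
    sign1, logdet1 = np.linalg.slogdet(s1)
    if sign0 <= 0 or sign1 <= 0:
        raise ValueError("degenerate residual covariance in refined test")
    lam = n * (logdet0 - logdet1)
    lam = max(lam, 0.0)
    p = float(np.exp(stats.chi2.logsf(lam, k)))
    return AssociationRecord(
        variant_id=variant_id,
        beta=beta,
        statistic=lam,
        dof=k,
        p_value=max(p, 5e-324),
        maf=maf,
        callrate=callrate,
    )


def _impute_matrix(G: np.ndarray) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if not np.isnan(G).any():
        return G
    mu = np.nanmean(G, axis=0)
    idx = np.where(np.isnan(G))
    G = G.copy()
    G[idx] = np.take(mu, idx[1])
    return G


def run_gwas(
    genotypes: GenotypeMatrix,
    Y: EmbeddingMatrix | np.ndarray,
    C: CovariateMatrix,
    maf_min: float = 0.01,
    mode: str = "score",
) -> list[AssociationRecord]:
    """Test every variant passing the MAF filter; null fitted once.

    MAF is computed after mean imputation.  ``mode`` selects the pure
    score test or the one-step refined likelihood-ratio variant.
    """
    if mode not in ("score", "refined"):
        raise ValueError(f"unknown mode {mode!r}")
    null = fit_null(Y, C)
    G = _impute_matrix(genotypes.dosages)
    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.where(maf >= maf_min)[0]
    if keep.size == 0:
        raise ValueError(f"no variants pass MAF >= {maf_min}")
    records: list[AssociationRecord] = []
    test = test_score if mode == "score" else test_refined
    meta = genotypes.variants
    for v in keep:
        rec = test(null, G[:, v], variant_id=meta["id"].iloc[v])
        rec.chrom = str(meta["chrom"].iloc[v])
        rec.pos = int(meta["pos"].iloc[v])
        records.append(rec)
    lam_gc = genomic_inflation(records)
    logger.info(
        "tested %d variants (%d excluded at MAF<%g), lambda_GC=%.3f",
        keep.size,
        genotypes.n_variants - keep.size,
        maf_min,
        lam_gc,
    )
    return records


def genomic_inflation(records: list[AssociationRecord]) -> float:
    """median(statistic) / median(chi2_K) over non-flagged records."""
    stats_ = np.array([r.statistic for r in records if not r.flag])
    if stats_.size == 0:
        return np.nan
    k = records[0].dof
    return float(np.median(stats_) / stats.chi2.ppf(0.5, k))


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "CHR": [r.chrom for r in records],
            "POS": [r.pos for r in records],
            "ID": [r.variant_id for r in records],
            "MAF": [r.maf for r in records],
            "DF": [r.dof for r in records],
            "CHI2": [r.statistic for r in records],
            "P": [r.p_value for r in records],
            "FLAG": [r.flag for r in records],
        }
    )


def acat_combine(p_values: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Aggregated Cauchy combination:
    ``T = sum_k w_k tan((0.5 - p_k) pi)``, ``p = 0.5 - arctan(T)/pi``.

    Equal weights by default.  Degenerate p of exactly 0 or 1 are clipped to
    machine-safe bounds with a warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-d array")
    if weights is None:
        w = np.full(p.size, 1.0 / p.size)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != p.shape or (w < 0).any() or w.sum() <= 0:
            raise ValueError("invalid weights")
        w = w / w.sum()
    tiny = 1e-300
    if ((p <= 0) | (p >= 1)).any():
        warnings.warn("p-values at 0/1 clipped to machine-safe bounds")
        p = np.clip(p, tiny, 1 - 1e-16)
    t = float(np.sum(w * np.tan((0.5 - p) * np.pi)))
    combined = 0.5 - np.arctan(t) / np.pi
    return float(min(max(combined, 5e-324), 1.0))


def test_univariate_acat(
    genotypes: GenotypeMatrix,
    Y: EmbeddingMatrix | np.ndarray,
    C: CovariateMatrix,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Per-dimension K=1 score tests combined with Cauchy aggregation."""
    Yv = Y.values if isinstance(Y, EmbeddingMatrix) else np.asarray(Y, dtype=float)
    n, k = Yv.shape
    null = fit_null(Yv, C)  # reuse residuals; per-dim variances on diagonal
    G = _impute_matrix(genotypes.dosages)
    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = np.where(maf >= maf_min)[0]
    if keep.size == 0:
        raise ValueError(f"no variants pass MAF >= {maf_min}")
    Gm = null.project_out(G[:, keep])
    den = np.einsum("ij,ij->j", Gm, Gm)
    num = Gm.T @ null.residuals  # n_keep x K
    # per-dimension univariate score statistic with per-dim null variance
    sig2 = np.diag(null.sigma)
    with np.errstate(invalid="ignore", divide="ignore"):
        chi = (num**2) / den[:, None] / sig2[None, :]
    pmat = stats.chi2.sf(chi, 1)
    combined = np.array([acat_combine(pmat[i]) for i in range(pmat.shape[0])])
    meta = genotypes.variants.iloc[keep]
    return pd.DataFrame(
        {
            "CHR": meta["chrom"].to_numpy(),
            "POS": meta["pos"].to_numpy(),
            "ID": meta["id"].to_numpy(),
            "MAF": maf[keep],
            "P_ACAT": combined,
            "P_MIN_DIM": pmat.min(axis=1),
        }
    )


@dataclass
class CalibrationReport:
    statistics: np.ndarray
    p_values: np.ndarray
    ks_statistic: float
    ks_p_value: float
    lambda_gc: float
    alpha_grid: np.ndarray
    empirical_alpha: np.ndarray
    qq_expected: np.ndarray = field(default=None)
    qq_observed: np.ndarray = field(default=None)


def permutation_null(
    genotypes: GenotypeMatrix,
    Y: EmbeddingMatrix | np.ndarray,
    C: CovariateMatrix,
    n_perm: int,
    seed: int,
    maf_min: float = 0.0,
    permutations: list[np.ndarray] | None = None,
) -> CalibrationReport:
    """Recompute the multivariate statistic under genotype-label permutations.

    Sample indices of the genotype matrix are permuted (one permutation per
    replicate, shared across variants) while phenotypes and covariates stay
    aligned with each other, so the null model is identical across
    replicates.  ``permutations`` overrides the random draws (testing hook).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    null = fit_null(Y, C)
    G = _impute_matrix(genotypes.dosages)
    freq = G.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    G = G[:, maf >= maf_min]
    rng = np.random.default_rng(seed)
    n = null.n_samples
    k = null.n_dims
    all_stats = []
    for b in range(n_perm):
        if permutations is not None:
            perm = np.asarray(permutations[b])
        else:
            perm = rng.permutation(n)
        Gp = G[perm]
        Gm = null.project_out(Gp)
        den = np.einsum("ij,ij->j", Gm, Gm)
        num = Gm.T @ null.residuals  # V x K
        beta = num / den[:, None]
        lam = den * np.einsum(
            "vk,vk->v", beta, cho_solve(null.sigma_chol, beta.T).T
        )
        all_stats.append(lam)
    lam = np.concatenate(all_stats)
    pvals = stats.chi2.sf(lam, k)
    ks = stats.kstest(pvals, "uniform")
    alpha_grid = np.array([0.1, 0.05, 0.01, 0.001])
    emp = np.array([(pvals < a).mean() for a in alpha_grid])
    m = lam.size
    qq_exp = stats.chi2.ppf((np.arange(1, m + 1) - 0.5) / m, k)
    return CalibrationReport(
        statistics=lam,
        p_values=pvals,
        ks_statistic=float(ks.statistic),
        ks_p_value=float(ks.pvalue),
        lambda_gc=float(np.median(lam) / stats.chi2.ppf(0.5, k)),
        alpha_grid=alpha_grid,
        empirical_alpha=emp,
        qq_expected=qq_exp,
        qq_observed=np.sort(lam),
    )


def test_burden(
    burden_scores: np.ndarray,
    Y: EmbeddingMatrix | np.ndarray,
    C: CovariateMatrix,
    gene_ids: list[str] | None = None,
) -> list[AssociationRecord]:
    """Test gene-level burden scores with the same machinery as variants.

    ``burden_scores`` is genes x samples; no MAF filter applies.  Constant
    burden vectors yield flagged records with p = NA.
    """
    B = np.asarray(burden_scores, dtype=float)
    if B.ndim == 1:
        B = B[None, :]
    null = fit_null(Y, C)
    if B.shape[1] != null.n_samples:
        raise ValueError("burden score sample count mismatch")
    if gene_ids is None:
        gene_ids = [f"gene{i}" for i in range(B.shape[0])]
    records = []
    for i in range(B.shape[0]):
        rec = test_score(null, B[i], variant_id=gene_ids[i])
        rec.maf = np.nan
        records.append(rec)
    return records
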