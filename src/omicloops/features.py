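"""Per-age microbiome phenotypes: alpha diversity and composition PCs.

The microbiome's dimensionality is reduced to four per-age phenotypes used as
mGWAS responses: genus richness, Shannon diversity (nats), and the first two
microbiome composition principal components (MCPC1/MCPC2) from a robust
Aitchison PCA — a PCA of the robust centered log-ratio (rclr) transform in
which zero counts are treated as missing and completed by iterative
rank-k SVD imputation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .tables import MicrobiomeCounts

logger = logging.getLogger("omicloops")

__all__ = [
    "MicrobiomeFeatures",
    "alpha_diversity",
    "rclr_transform",
    "robust_aitchison_pca",
    "compute_features",
]


@dataclass
class MicrobiomeFeatures:
    """Alpha diversity plus robust-Aitchison PC scores for one age."""

    age_years: float
    richness: pd.Series
    shannon: pd.Series
    mcpc_scores: pd.DataFrame
    mcpc_loadings: pd.DataFrame
    explained_norm_fraction: np.ndarray
    converged: bool = True
    n_iter: int = 0

    def frame(self) -> pd.DataFrame:
        """Tested-phenotype table: richness, shannon, mcpc1..k per sample."""
        out = pd.DataFrame({"richness": self.richness, "shannon": self.shannon})
        for j, col in enumerate(self.mcpc_scores.columns, start=1):
            out[f"mcpc{j}"] = self.mcpc_scores[col]
        return out


def alpha_diversity(counts: MicrobiomeCounts) -> tuple[pd.Series, pd.Series]:
    """Genus richness and Shannon diversity (natural log) per sample.

    Richness is the number of genera with a nonzero count; Shannon is
    -sum p_i ln p_i over the nonzero genus proportions.
    """
    mat = counts.counts.to_numpy(dtype=float)
    richness = pd.Series((mat > 0).sum(axis=1), index=counts.counts.index, name="richness")
    shannon = pd.Series(entropy(mat, axis=1), index=counts.counts.index, name="shannon")
    return richness, shannon


def rclr_transform(counts) -> pd.DataFrame:
    """Robust centered log-ratio transform; zeros become missing (NaN).

    For each nonzero cell: ln(count) minus the mean of ln(count) over that
    sample's nonzero cells. Invariant to per-sample rescaling of the counts.
    """
    if isinstance(counts, MicrobiomeCounts):
        counts = counts.counts
    mat = np.asarray(counts, dtype=float)
    if (mat.sum(axis=1) <= 0).any():
        raise ValueError("rclr requires positive per-sample totals")
    logs = np.full(mat.shape, np.nan)
    np.log(mat, out=logs, where=mat > 0)
    center = np.nanmean(logs, axis=1, keepdims=True)
    out = logs - center
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(out, index=counts.index, columns=counts.columns)
    return pd.DataFrame(out)


def _svd_rank_k(M: np.ndarray, k: int):
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return U[:, :k], s[:k], Vt[:k], s


def robust_aitchison_pca(
    rclr_matrix,
    k: int = 2,
    max_iter: int = 5000,
    tol: float = 1e-6,
):
    """Rank-k PCA of an rclr matrix fitted on observed cells only.

    Missing cells (structural zeros under rclr) are completed by iterative
    SVD imputation: start them at 0, alternate a rank-k truncated SVD with
    refilling the missing cells from the reconstruction, until the
    reconstruction change on observed cells drops below ``tol`` (relative
    Frobenius) or ``max_iter`` is reached. On a dense matrix this reduces to
    classical PCA of the row-centered data.

    Returns ``(scores, loadings, explained_norm_fraction, converged, n_iter)``
    where scores are the sample coordinates (U * s) and each loading vector is
    sign-flipped so its largest-magnitude entry is positive.
    """
    X = rclr_matrix.to_numpy(dtype=float) if isinstance(rclr_matrix, pd.DataFrame) else np.asarray(
        rclr_matrix, dtype=float
    )
    n, p = X.shape
    if not (1 <= k <= min(n, p)):
        raise ValueError(f"k must be in [1, {min(n, p)}], got {k}")
    if n < k + 1:
        raise ValueError("need at least k+1 samples")
    obs = np.isfinite(X)
    # column-center over observed cells so the dense case is classical PCA
    with np.errstate(invalid="ignore"):
        col_mean = np.nanmean(np.where(obs, X, np.nan), axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    X = X - col_mean
    M = np.where(obs, X, 0.0)
    converged = False
    it = 0
    prev_recon = None
    for it in range(1, max_iter + 1):
        U, s, Vt, s_all = _svd_rank_k(M, k)
        recon = (U * s) @ Vt
        if prev_recon is not None:
            num = np.linalg.norm((recon - prev_recon)[obs])
            den = np.linalg.norm(recon[obs]) or 1.0
            if num / den < tol:
                converged = True
                break
        prev_recon = recon
        M = np.where(obs, X, recon)
        if obs.all():  # dense: one SVD is exact, nothing to impute
            converged = True
            break
    if not converged:
        logger.warning("robust Aitchison PCA did not converge in %d iterations", max_iter)

    scores = U * s
    loadings = Vt.T
    # deterministic sign convention
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    total = float((s_all**2).sum()) or 1.0
    explained = (s[:k] ** 2) / total

    cols = [f"PC{j + 1}" for j in range(k)]
    if isinstance(rclr_matrix, pd.DataFrame):
        scores = pd.DataFrame(scores, index=rclr_matrix.index, columns=cols)
        loadings = pd.DataFrame(loadings, index=rclr_matrix.columns, columns=cols)
    else:
        scores = pd.DataFrame(scores, columns=cols)
        loadings = pd.DataFrame(loadings, columns=cols)
    return scores, loadings, explained, converged, it


def compute_features(
    counts: MicrobiomeCounts, k: int = 2, max_iter: int = 5000, tol: float = 1e-6
) -> MicrobiomeFeatures:
    """Alpha diversity + robust Aitchison PCA for one age's count table."""
    richness, shannon = alpha_diversity(counts)
    rclr = rclr_transform(counts)
    scores, loadings, explained, converged, n_iter = robust_aitchison_pca(
        rclr, k=k, max_iter=max_iter, tol=tol
    )
    return MicrobiomeFeatures(
        age_years=counts.age_years,
        richness=richness,
        shannon=shannon,
        mcpc_scores=scores,
        mcpc_loadings=loadings,
        explained_norm_fraction=explained,
        converged=converged,
        n_iter=n_iter,
    )
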