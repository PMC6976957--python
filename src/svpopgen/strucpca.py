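"""PCA of the genotype matrix, k-means+BIC cluster discovery, a
PC-regression outlier scan (pcadapt-style), and a PC1 ancestry proxy.

Missing dosages are mean-imputed *only* here (PCA and the outlier scan);
all other modules treat missingness explicitly.  Columns are centered but
not scaled to unit variance, so common alleles contribute more inertia —
the convention for genotype PCA of closely related populations.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans

from .geno_io import MISSING, GenotypeMatrix

__all__ = [
    "pca",
    "find_clusters",
    "pcadapt_scan",
    "ancestry_proxy",
    "PCAResult",
    "ClusterAssignment",
]


@dataclasses.dataclass
class PCAResult:
    """Scores, loadings and per-component variance fractions."""

    scores: np.ndarray  # individuals x components
    loadings: np.ndarray  # loci x components
    variance_explained: np.ndarray
    n_imputed: int

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _impute_center(g: GenotypeMatrix) -> tuple[np.ndarray, int]:
    x = g.dosages.astype(float)
    miss = g.missing_mask()
    col_mean = np.where(
        (~miss).sum(axis=0) > 0,
        np.where(miss, 0, x).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
        0.0,
    )
    x = np.where(miss, col_mean[None, :], x)
    x -= x.mean(axis=0)
    return x, int(miss.sum())


def pca(g: GenotypeMatrix, n_components: int | None = None) -> PCAResult:
    """Centered, unscaled PCA of mean-imputed dosages.

    Deterministic: each component's sign is fixed by making its
    largest-magnitude loading positive.
    """
    if g.n_individuals < 2:
        raise ValueError("need at least two individuals")
    x, n_imputed = _impute_center(g)
    k_max = min(x.shape)
    k = k_max if n_components is None else min(n_components, k_max)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    total_var = float((x**2).sum())
    var = s**2 / total_var if total_var > 0 else np.zeros_like(s)
    # sign convention
    for c in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[c])))
        if vt[c, j] < 0:
            vt[c] *= -1
            u[:, c] *= -1
    scores = u[:, :k] * s[:k]
    return PCAResult(
        scores=scores,
        loadings=vt[:k].T,
        variance_explained=var[:k],
        n_imputed=n_imputed,
    )


@dataclasses.dataclass
class ClusterAssignment:
    """k-means labels with the BIC trace used to choose k."""

    labels: np.ndarray  # values in 1..k, ordered by cluster mean PC1
    k: int
    bic: dict[int, float]
    n_pcs: int
    seed: int | None


def find_clusters(
    scores: np.ndarray,
    k_max: int = 5,
    n_pcs: int = 1,
    seed: int | None = None,
    k: int | None = None,
) -> ClusterAssignment:
    """k-means over the leading PCs with BIC model choice.

    The number of clusters minimizes the BIC of a Gaussian mixture fitted to
    the same PC subspace (a hard-assignment WSS-based BIC systematically
    overfits in few dimensions: splitting one true Gaussian cluster always
    shrinks WSS enough to beat the k ln n penalty at realistic n).  Final
    labels come from k-means with 20 restarts at the chosen k, renumbered
    1..k by ascending cluster mean PC1.  ``k`` overrides the choice.
    """
    from sklearn.mixture import GaussianMixture

    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    if n_pcs > scores.shape[1]:
        raise ValueError("n_pcs exceeds available components")
    x = scores[:, :n_pcs]
    n = x.shape[0]
    bic: dict[int, float] = {}
    degenerate = bool(np.allclose(x, x[0]))
    for kk in range(1, min(k_max, n) + 1):
        if degenerate:
            # identical points: any k fits perfectly; penalty alone decides
            bic[kk] = float(kk)
            continue
        gm = GaussianMixture(
            n_components=kk, n_init=5, reg_covar=1e-10, random_state=seed
        ).fit(x)
        bic[kk] = float(gm.bic(x))
    chosen = k if k is not None else min(bic, key=bic.get)
    if chosen < 1 or chosen > min(k_max, n):
        raise ValueError(f"k={chosen} outside the evaluated range")
    if degenerate:
        lab = np.zeros(n, dtype=int)
        chosen = 1
    else:
        km = KMeans(n_clusters=chosen, n_init=20, random_state=seed)
        lab = km.fit_predict(x)
    order = np.argsort([x[lab == c, 0].mean() for c in range(chosen)])
    remap = {int(c): i + 1 for i, c in enumerate(order)}
    return ClusterAssignment(
        labels=np.array([remap[int(c)] for c in lab]),
        k=chosen,
        bic=bic,
        n_pcs=n_pcs,
        seed=seed,
    )


def pcadapt_scan(
    g: GenotypeMatrix,
    K: int = 1,
    fdr: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """PC-regression outlier scan over loci.

    Each (imputed, centered) locus is regressed on the first K PC score
    vectors; the K-vector of regression z-scores per locus gets a robust
    Mahalanobis distance, rescaled by a genomic inflation factor
    (median distance / chi2_K median), and an upper-tail chi2_K p-value.
    Returns ``(outlier_indices, p_values)`` with outliers at
    Bonferroni-adjusted p < ``fdr``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    x, _ = _impute_center(g)
    res = pca(g, n_components=K)
    u = res.scores / np.linalg.norm(res.scores, axis=0)  # orthonormal basis
    n, L = x.shape
    beta = u.T @ x  # K x L
    resid = x - u @ beta
    dof = max(n - K, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / np.sqrt(sigma2)[None, :]
    z = np.nan_to_num(z, nan=0.0).T  # L x K
    if K == 1:
        center = np.median(z)
        scale = _MAD_SCALE * np.median(np.abs(z - center))
        if scale == 0:
            scale = 1.0
        stat = ((z[:, 0] - center) / scale) ** 2
    else:
        from sklearn.covariance import MinCovDet

        mcd = MinCovDet(random_state=0).fit(z)
        stat = mcd.mahalanobis(z)
    gif = np.median(stat) / stats.chi2.ppf(0.5, K)
    if gif <= 0 or not np.isfinite(gif):
        gif = 1.0
    p = stats.chi2.sf(stat / gif, K)
    p_adj = np.minimum(p * L, 1.0)
    outliers = np.flatnonzero(p_adj < fdr)
    return outliers, p


_MAD_SCALE = 1.4826


def ancestry_proxy(scores: np.ndarray) -> np.ndarray:
    """Min-max rescaled PC1 as a per-individual ancestry coefficient.

    A documented proxy for a model-based two-lineage admixture Q: with two
    divergent haplotype backgrounds, PC1 position is nearly collinear with
    the derived-haplotype dosage.
    """
    scores = np.asarray(scores, dtype=float)
    pc1 = scores[:, 0] if scores.ndim > 1 else scores
    lo, hi = pc1.min(), pc1.max()
    if hi - lo == 0:
        raise ValueError("degenerate PC1: zero variance")
    return (pc1 - lo) / (hi - lo)
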