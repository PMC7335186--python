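"""Gene filtering, normalization and k-means initialization for EM.

Mixture models are sensitive to starting values, so the fit is seeded from a
k-means clustering of the higher-quality droplets. The steps, in order:
restrict to expressed genes (CPM > 0, i.e. any count at all); split droplets
into the fixed debris set (total counts below the threshold) and the test
set; define the *cluster set* as droplets with enough genes detected to
carry cluster structure; depth-normalize and log-transform; pick the most
variable genes after removing the mean-variance trend with a locally
weighted regression; embed in principal-component space; run k-means; and
convert the resulting labels into initial multinomial parameters, with the
pooled fixed-debris droplets providing the initial debris profile.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from statsmodels.nonparametric.smoothers_lowess import lowess

from .em import MixtureParams
from .io_counts import SparseCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "filter_expressed_genes",
    "split_sets",
    "normalize_for_init",
    "select_variable_genes",
    "pca_embed",
    "kmeans_init",
    "initial_parameters",
]

FIXED_DEBRIS = "fixed_debris"
TEST = "test"


def filter_expressed_genes(matrix: SparseCountMatrix) -> np.ndarray:
    """Boolean mask of genes with any count at all.

    A gene has CPM > 0 over the whole matrix exactly when its total count is
    nonzero, so the filter reduces to a row-sum check.
    """
    row_sums = np.asarray(matrix.counts.sum(axis=1)).ravel()
    mask = row_sums > 0
    if not mask.any():
        raise ValueError("no expressed genes")
    return mask


def split_sets(
    stats: pd.DataFrame,
    fixed_threshold: int = 100,
    cluster_set_min_genes: int = 200,
) -> pd.DataFrame:
    """Assign droplets to the fixed debris set or the test set.

    Droplets with ``total_counts < fixed_threshold`` are ``fixed_debris``
    (their mixture label is pinned to the debris component during EM); the
    rest form the ``test`` set. ``cluster_set_member`` flags test droplets
    with at least ``cluster_set_min_genes`` genes detected — the subset used
    for k-means initialization, so that near-empty droplets cannot seed
    clusters of their own.
    """
    if fixed_threshold < 0 or cluster_set_min_genes < 0:
        raise ValueError("thresholds must be >= 0")
    membership = np.where(
        stats["total_counts"].to_numpy() < fixed_threshold, FIXED_DEBRIS, TEST
    )
    if not (membership == TEST).any():
        raise ValueError("no droplets above fixed threshold")
    cluster_member = (
        stats["genes_detected"].to_numpy() >= cluster_set_min_genes
    ) & (membership == TEST)
    return pd.DataFrame(
        {
            "barcode": stats["barcode"],
            "set_membership": membership,
            "cluster_set_member": cluster_member,
        }
    )


def normalize_for_init(
    matrix: SparseCountMatrix, droplet_mask: np.ndarray | None = None
) -> sp.csc_matrix:
    """Scale each included droplet to the median depth, then log-transform.

    Each droplet's counts are multiplied by (median total / droplet total)
    and the result is natural-log transformed after adding 1, so zeros stay
    zero and sparsity is preserved. Returns a genes x n_included sparse
    matrix over the masked droplets (all droplets if no mask).
    """
    csc = matrix.counts.tocsc()
    if droplet_mask is not None:
        csc = csc[:, np.asarray(droplet_mask, dtype=bool)]
    totals = np.asarray(csc.sum(axis=0)).ravel().astype(float)
    if np.any(totals == 0):
        raise ValueError("normalize_for_init requires droplets with nonzero totals")
    med = float(np.median(totals))
    scaled = csc.astype(float) @ sp.diags(med / totals)
    scaled = sp.csc_matrix(scaled)
    scaled.data = np.log1p(scaled.data)
    return scaled


def select_variable_genes(
    matrix: SparseCountMatrix,
    droplet_mask: np.ndarray | None = None,
    v: int = 2000,
    span: float = 0.3,
) -> pd.DataFrame:
    """Rank genes by mean-variance-corrected variability of raw counts.

    Per gene, the mean and variance of the raw counts over the included
    droplets are natural-log transformed; a locally weighted regression of
    log variance on log mean (lowess, fraction ``span``, no robustness
    iterations) captures the expected variance at each expression level, and
    the standardized variance is the observed minus fitted log variance.
    The top ``v`` genes by standardized variance are returned (all genes,
    with a warning, if fewer are available). Genes with zero mean or zero
    variance in the included droplets are excluded from the fit. Ties break
    by gene id for determinism.
    """
    csc = matrix.counts.tocsc()
    if droplet_mask is not None:
        csc = csc[:, np.asarray(droplet_mask, dtype=bool)]
    n = csc.shape[1]
    if n < 2:
        raise ValueError("need at least 2 droplets for variance estimation")
    mean = np.asarray(csc.mean(axis=1)).ravel()
    sq = csc.copy()
    sq.data = sq.data.astype(float) ** 2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    var = (ex2 - mean**2) * n / (n - 1)
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 genes with positive variance")
    log_mean = np.log(mean[ok])
    log_var = np.log(var[ok])
    fitted = lowess(
        log_var, log_mean, frac=span, it=0, return_sorted=False
    )
    standardized = log_var - fitted
    tab = pd.DataFrame(
        {
            "gene_id": [matrix.gene_ids[i] for i in np.flatnonzero(ok)],
            "gene_index": np.flatnonzero(ok),
            "log_mean": log_mean,
            "log_variance": log_var,
            "fitted_variance": fitted,
            "standardized_variance": standardized,
        }
    )
    tab = tab.sort_values(
        ["standardized_variance", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    tab["rank"] = np.arange(1, len(tab) + 1)
    if len(tab) < v:
        logger.warning("only %d genes available for top-%d selection", len(tab), v)
    return tab.head(min(v, len(tab)))


def pca_embed(
    normalized: sp.spmatrix,
    gene_indices: np.ndarray,
    n_pcs: int = 30,
) -> np.ndarray:
    """Droplet coordinates on the top principal components.

    ``normalized`` is genes x droplets (cluster set); rows are restricted to
    ``gene_indices`` (positions within ``normalized``), genes are centered
    (no unit-variance scaling) and a full SVD is taken for determinism up to
    component sign. If ``n_pcs`` exceeds what the data support it is reduced
    with a warning.
    """
    x = np.asarray(normalized.tocsr()[np.asarray(gene_indices, dtype=int), :].todense()).T
    max_pcs = min(x.shape[0], x.shape[1])
    if n_pcs > max_pcs:
        logger.warning("reducing n_pcs from %d to %d (matrix is %s)", n_pcs, max_pcs, x.shape)
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="full")
    return pca.fit_transform(x)


def kmeans_init(
    embedding: np.ndarray, k: int = 20, seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """k-means labels (1..k) for the cluster-set droplets.

    Uses k-means++ seeding with ``n_init`` restarts under ``seed``; the best
    inertia wins, so reruns with the same seed are identical. Labels are
    shifted to 1..k because component 0 is reserved for debris.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if embedding.shape[0] < k:
        raise ValueError(
            f"k={k} exceeds the {embedding.shape[0]} droplets in the cluster set"
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    return km.fit_predict(embedding) + 1


def initial_parameters(
    matrix: SparseCountMatrix,
    labels: np.ndarray,
    pseudocount: float = 1e-10,
) -> MixtureParams:
    """Starting mixture parameters from an initial labeling.

    ``labels`` holds, per droplet, 0 for the fixed debris set, 1..k for
    k-means clusters, and -1 for droplets left out of initialization (test
    droplets below the cluster-set gene cutoff). Each component's alpha is
    its pooled gene counts plus a pseudocount, renormalized; pi is the label
    frequency among labeled droplets. Empty k-means clusters are dropped and
    the rest renumbered.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != matrix.n_droplets:
        raise ValueError("labels length must equal number of droplets")
    used = sorted(set(labels[labels >= 0]))
    if 0 not in used:
        raise ValueError("no fixed-debris droplets; component 0 would be empty")
    dropped = [k for k in range(max(used) + 1) if k not in used]
    if dropped:
        logger.warning("dropping empty initial cluster(s) %s and renumbering", dropped)
    csc = matrix.counts.tocsc()
    alpha = np.empty((len(used), matrix.n_genes), dtype=float)
    sizes = np.empty(len(used), dtype=float)
    for row, k in enumerate(used):
        cols = np.flatnonzero(labels == k)
        pooled = np.asarray(csc[:, cols].sum(axis=1)).ravel().astype(float)
        alpha[row] = pooled + pseudocount
        sizes[row] = cols.size
    alpha /= alpha.sum(axis=1, keepdims=True)
    pi = sizes / sizes.sum()
    return MixtureParams(alpha=alpha, pi=pi, debris_index=0)
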