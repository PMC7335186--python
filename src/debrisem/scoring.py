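"""Debris-enriched genes, per-droplet debris scores, and filtering.

After the mixture fit, clusters are divided into a debris set (the fixed
component plus any cluster whose droplets average fewer than ``d`` genes
detected) and cell-type clusters. Genes over-represented in the debris set
are found by a Welch's t-test on log-normalized proportions between the two
groups of test-set droplets; genes with positive log fold change and
FDR < 0.05 are debris-enriched. A droplet's raw debris score is the sum of
its normalized expression over those genes. Raw scores are rescaled so the
cleanest cluster averages 0 and the debris cluster(s) average 1; droplets
are kept when the normalized score falls below the cutoff ``t`` (or, in
cluster mode, when they sit outside the debris clusters). Low-count fixed
droplets are always removed.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats as sp_stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "define_debris_clusters",
    "normalize_for_de",
    "debris_de",
    "score_droplets",
    "normalize_scores",
    "filter_droplets",
]


def define_debris_clusters(
    assignments: np.ndarray,
    genes_detected: np.ndarray,
    d: int = 200,
    debris_index: int = 0,
) -> set[int]:
    """Clusters treated as debris: the fixed component, always, plus any
    cluster whose mean genes-detected is below ``d``.

    Raises if every populated cluster lands in the debris set — scoring
    needs at least one cell-type cluster to contrast against.
    """
    assignments = np.asarray(assignments)
    genes_detected = np.asarray(genes_detected)
    debris = {debris_index}
    populated = set(np.unique(assignments).tolist())
    for k in populated:
        if k == debris_index:
            continue
        if genes_detected[assignments == k].mean() < d:
            debris.add(k)
    if not populated - debris:
        raise ValueError("no cell-type clusters; cannot score")
    return debris


def normalize_for_de(matrix_counts: sp.spmatrix) -> sp.csc_matrix:
    """Per-droplet proportions, then log(p + 1).

    Counts are scaled to sum to 1 within each droplet and natural-log
    transformed after adding 1. Zero-total droplets come out all-zero (they
    are fixed debris and never enter the t-test, but they still receive a
    score). The transform is invariant to scaling a droplet's counts.
    """
    csc = sp.csc_matrix(matrix_counts, dtype=float)
    totals = np.asarray(csc.sum(axis=0)).ravel()
    scale = np.divide(1.0, totals, out=np.zeros_like(totals), where=totals > 0)
    out = sp.csc_matrix(csc @ sp.diags(scale))
    out.data = np.log1p(out.data)
    return out


def debris_de(
    normalized: sp.spmatrix,
    debris_cols: np.ndarray,
    cell_cols: np.ndarray,
    gene_ids: list[str],
) -> pd.DataFrame:
    """Welch's t-test per gene between debris and cell-type droplets.

    Both column index arrays must hold at least two droplets. Returns one
    row per gene: ``log_fold_change`` (mean debris minus mean cell-type, on
    the log-normalized scale), the Welch ``t`` statistic, two-sided
    ``p_value``, Benjamini-Hochberg ``q_value``, and the ``enriched`` flag
    (log_fold_change > 0 and q_value < 0.05). Genes with zero variance in
    both groups get t = 0, p = 1.
    """
    debris_cols = np.asarray(debris_cols, dtype=int)
    cell_cols = np.asarray(cell_cols, dtype=int)
    if debris_cols.size < 2 or cell_cols.size < 2:
        raise ValueError("each group needs at least 2 droplets for Welch's t-test")
    csr = normalized.tocsr()
    a = np.asarray(csr[:, debris_cols].todense())
    b = np.asarray(csr[:, cell_cols].todense())
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sp_stats.ttest_ind(a, b, axis=1, equal_var=False)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    lfc = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log_fold_change": lfc,
            "t_statistic": t,
            "p_value": p,
            "q_value": q,
            "enriched": (lfc > 0) & (q < 0.05),
        }
    )


def score_droplets(
    normalized: sp.spmatrix, enriched_gene_indices: np.ndarray
) -> np.ndarray:
    """Raw debris score: sum of normalized expression over the enriched
    genes, for every droplet (fixed ones included)."""
    idx = np.asarray(enriched_gene_indices, dtype=int)
    if idx.size == 0:
        raise ValueError(
            "no debris-enriched genes; scoring unreliable without an elevated "
            "background signature"
        )
    return np.asarray(normalized.tocsr()[idx, :].sum(axis=0)).ravel()


def normalize_scores(
    raw: np.ndarray,
    assignments: np.ndarray,
    debris_clusters: set[int],
    mode: str = "anchored",
) -> np.ndarray:
    """Rescale raw scores against the cleanest and the debris clusters.

    With ``m_low`` the smallest per-cluster mean raw score and ``m_deb`` the
    mean raw score over droplets in the debris clusters, the default
    ("anchored") rescaling is (raw - m_low) / (m_deb - m_low), which pins
    the cleanest cluster's average at 0 and the debris average at 1. The
    "literal" variant divides by ``m_deb`` alone ((raw - m_low) / m_deb);
    it anchors the debris average at 1 only when m_low is 0.
    """
    raw = np.asarray(raw, dtype=float)
    assignments = np.asarray(assignments)
    means = pd.Series(raw).groupby(assignments).mean()
    m_low = float(means.min())
    deb_mask = np.isin(assignments, list(debris_clusters))
    if not deb_mask.any():
        raise ValueError("debris clusters contain no droplets")
    m_deb = float(raw[deb_mask].mean())
    if mode == "anchored":
        if m_deb <= m_low:
            raise ValueError(
                "debris clusters do not have elevated scores; the upstream "
                "differential expression likely failed to find a background signature"
            )
        return (raw - m_low) / (m_deb - m_low)
    if mode == "literal":
        if m_deb <= 0:
            raise ValueError("debris cluster mean score is not positive")
        return (raw - m_low) / m_deb
    raise ValueError(f"unknown score normalization mode {mode!r}")


def filter_droplets(
    score_table: pd.DataFrame,
    t: float = 0.5,
    mode: str = "score",
    debris_clusters: set[int] | None = None,
) -> np.ndarray:
    """Keep/remove call per droplet.

    ``score_table`` needs columns ``normalized_score``, ``cluster`` and
    ``set_membership``. In score mode a droplet is kept iff its normalized
    score is below ``t``; in cluster mode iff its cluster is outside the
    debris set. Fixed (low-count) droplets are always removed.
    """
    fixed = (score_table["set_membership"] == "fixed_debris").to_numpy()
    if mode == "score":
        keep = score_table["normalized_score"].to_numpy() < t
    elif mode == "cluster":
        if debris_clusters is None:
            raise ValueError("cluster mode requires the debris cluster set")
        keep = ~score_table["cluster"].isin(list(debris_clusters)).to_numpy()
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return keep & ~fixed
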