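"""Contamination metrics from spliced/unspliced counts and marker genes.

In single-nucleus data most genuine nuclear transcripts are unspliced
pre-mRNA, while ambient RNA — cytoplasmic or cell-free — is mostly spliced
mRNA. The fraction of spliced molecules per droplet therefore tracks
ambient contamination and is typically bimodal across droplets: a nuclear
mode low and a background mode high. This module computes per-droplet
percent spliced (mitochondrial genes excluded, since MT genes lack introns
and would confound the ratio), the fraction of counts on an arbitrary gene
set (MT%, MALAT1%), and a two-Gaussian midpoint classifier that separates
the two modes at the point of equal mixture density.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .io_counts import SparseCountMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MidpointModel",
    "percent_spliced",
    "fraction_of_counts",
    "fit_midpoint",
    "classify_droplets",
    "classify_clusters",
]

BACKGROUND = "background"
NUCLEAR = "nuclear"
UNCLASSIFIED = "unclassified"


@dataclass
class MidpointModel:
    """Two-component Gaussian mixture with its equal-density midpoint."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    midpoint: float


def percent_spliced(
    splice_table: pd.DataFrame, mt_gene_ids: set[str] | None = None
) -> pd.DataFrame:
    """Aggregate a splice-count table to per-droplet percent spliced.

    ``splice_table`` is either per-gene (columns barcode, gene_id, spliced,
    unspliced, ambiguous) or already per-droplet (no gene_id column). For
    the per-gene form, rows whose gene id is in ``mt_gene_ids`` are dropped
    before aggregation. Percent spliced is spliced / (spliced + unspliced) —
    ambiguous molecules enter neither numerator nor denominator — and is NaN
    (never silently zero) when the denominator is zero.
    """
    required = {"barcode", "spliced", "unspliced"}
    missing = required - set(splice_table.columns)
    if missing:
        raise ValueError(f"splice table missing column(s): {sorted(missing)}")
    tab = splice_table
    if "gene_id" in tab.columns:
        all_barcodes = tab["barcode"].drop_duplicates()
        if mt_gene_ids:
            tab = tab[~tab["gene_id"].isin(mt_gene_ids)]
        agg_cols = [c for c in ("spliced", "unspliced", "ambiguous") if c in tab.columns]
        tab = tab.groupby("barcode", sort=False)[agg_cols].sum()
        # droplets whose every record was mitochondrial keep a row (all zero,
        # hence undefined pct) rather than vanishing
        tab = tab.reindex(all_barcodes, fill_value=0).reset_index()
    else:
        tab = tab.copy()
    if "ambiguous" not in tab.columns:
        tab["ambiguous"] = 0
    denom = tab["spliced"] + tab["unspliced"]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(denom > 0, tab["spliced"] / denom, np.nan)
    tab["pct_spliced"] = pct
    return tab.reset_index(drop=True)


def fraction_of_counts(
    matrix: SparseCountMatrix, gene_ids: set[str] | list[str]
) -> pd.Series:
    """Per-droplet fraction of UMI counts on a gene set.

    Used for MT% (fraction on mitochondrial genes, an extranuclear-RNA
    marker) and MALAT1% (fraction on the nuclear-retained lincRNA, a nuclear
    marker). Zero-total droplets yield NaN. Unknown gene ids are an error.
    """
    gene_ids = set(gene_ids)
    if not gene_ids:
        raise ValueError("empty gene set")
    known = set(matrix.gene_ids)
    unknown = sorted(gene_ids - known)
    if unknown:
        raise ValueError(f"gene id(s) not in matrix: {unknown}")
    idx = [i for i, g in enumerate(matrix.gene_ids) if g in gene_ids]
    sub = np.asarray(matrix.counts[idx, :].sum(axis=0)).ravel().astype(float)
    totals = np.asarray(matrix.counts.sum(axis=0)).ravel().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, sub / totals, np.nan)
    return pd.Series(frac, index=matrix.barcodes, name="fraction")


def _equal_density_roots(m: np.ndarray, s: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Real solutions of w1 N(x; m1, s1) = w2 N(x; m2, s2).

    Taking logs gives a quadratic in x; with equal variances it degenerates
    to a linear equation.
    """
    a = 1.0 / (2 * s[1] ** 2) - 1.0 / (2 * s[0] ** 2)
    b = m[0] / s[0] ** 2 - m[1] / s[1] ** 2
    c = (
        m[1] ** 2 / (2 * s[1] ** 2)
        - m[0] ** 2 / (2 * s[0] ** 2)
        + np.log(w[0] * s[1] / (w[1] * s[0]))
    )
    if abs(a) < 1e-12:
        if abs(b) < 1e-12:
            return np.array([])
        return np.array([-c / b])
    disc = b * b - 4 * a * c
    if disc < 0:
        return np.array([])
    r = np.sqrt(disc)
    return np.array([(-b - r) / (2 * a), (-b + r) / (2 * a)])


def fit_midpoint(values: np.ndarray, seed: int = 0) -> MidpointModel:
    """Fit a two-Gaussian mixture to percent-spliced values and locate the
    equal-density midpoint between the modes.

    The mixture is fit by EM with means initialized at the 25th and 75th
    percentiles for determinism. The midpoint solves the weighted-density
    equality w1*phi1(x) = w2*phi2(x); the root strictly between the two means
    is returned. If no root lies between the means (possible with very
    unequal variances or weights) the equal-density root closest to the
    means' midpoint is used, with a warning; if the fit is degenerate
    (single mode), the overall mean is returned, with a warning.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 20:
        raise ValueError("need at least 20 defined values to fit the midpoint")
    if np.ptp(values) <= 0:
        logger.warning("values have no spread; midpoint set to the overall mean")
        m = float(values.mean())
        return MidpointModel(np.array([m, m]), np.array([0.0, 0.0]), np.array([0.5, 0.5]), m)
    q25, q75 = np.quantile(values, [0.25, 0.75])
    gm = GaussianMixture(
        n_components=2,
        means_init=np.array([[q25], [q75]]),
        random_state=seed,
    ).fit(values.reshape(-1, 1))
    order = np.argsort(gm.means_.ravel())
    means = gm.means_.ravel()[order]
    sds = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    # a unimodal sample still yields two overlapping components; two equal-
    # variance Gaussians produce a bimodal density only when their means are
    # more than two standard deviations apart, so that is the degeneracy rule
    if means[1] - means[0] < max(2 * sds.max(), 1e-12):
        logger.warning("degenerate single-mode fit; midpoint set to the overall mean")
        return MidpointModel(means, sds, weights, float(values.mean()))
    roots = _equal_density_roots(means, sds, weights)
    between = roots[(roots > means[0]) & (roots < means[1])] if roots.size else roots
    if between.size:
        midpoint = float(between[0])
    elif roots.size:
        center = means.mean()
        midpoint = float(roots[np.argmin(np.abs(roots - center))])
        logger.warning(
            "no equal-density root between the component means; using the "
            "closest root %.4f", midpoint
        )
    else:
        midpoint = float(means.mean())
        logger.warning("no real equal-density root; falling back to the means' midpoint")
    return MidpointModel(means, sds, weights, midpoint)


def classify_droplets(records: pd.DataFrame, midpoint: float) -> pd.Series:
    """Label droplets background/nuclear by percent spliced vs the midpoint.

    At or above the midpoint -> background; below -> nuclear (ties go to
    background by convention); NaN percent spliced -> unclassified.
    """
    pct = records["pct_spliced"].to_numpy(dtype=float)
    labels = np.where(pct >= midpoint, BACKGROUND, NUCLEAR)
    labels = np.where(np.isnan(pct), UNCLASSIFIED, labels)
    return pd.Series(labels, index=records["barcode"].to_numpy(), name="class")


def classify_clusters(
    assignments: np.ndarray,
    pct_spliced: np.ndarray,
    cutoff: float = 0.5,
) -> dict[int, str]:
    """Label clusters debris/cell-type by mean percent spliced.

    Mean of at least ``cutoff`` (inclusive) -> debris; below -> cell type; a
    cluster with no defined percent-spliced values is unclassified, with a
    warning.
    """
    assignments = np.asarray(assignments)
    pct = np.asarray(pct_spliced, dtype=float)
    out: dict[int, str] = {}
    for k in np.unique(assignments):
        vals = pct[assignments == k]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            logger.warning("cluster %s has no defined percent-spliced values", k)
            out[int(k)] = UNCLASSIFIED
        else:
            out[int(k)] = "debris" if vals.mean() >= cutoff else "cell_type"
    return out
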