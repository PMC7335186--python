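"""End-to-end debris filtering: configuration and orchestration.

`run_pipeline` wires the stages in order: expressed-gene filter, fixed/test
split, k-means initialization on the cluster set, semi-supervised EM,
cluster assignment, debris-cluster definition, differential expression,
per-droplet scoring and the final keep/remove call. `quantile_baseline`
runs the hard-count comparison filter on the same matrix.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import em as em_mod
from . import io_counts, preprocess, scoring

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "quantile_baseline"]


@dataclass
class RunConfig:
    """All tunables of the filtering pipeline, with their defaults.

    ``fixed_threshold`` — total-count cutoff below which droplets are fixed
    to the debris component (counts). ``k`` — number of cell-type clusters
    for k-means/EM. ``eps`` — EM convergence tolerance on the max absolute
    parameter change. ``pseudocount`` — added to every gene when estimating
    component probabilities. ``cluster_set_min_genes`` — genes detected
    required to enter the k-means cluster set. ``debris_min_genes`` — a
    cluster averaging fewer detected genes than this is treated as debris.
    ``score_cutoff`` — normalized debris score below which a droplet is
    kept. ``n_variable_genes``, ``loess_span``, ``n_pcs`` — variable-gene
    selection and embedding. ``quantile_top``/``quantile``/``quantile_divisor``
    — the hard-count baseline rule. ``filter_mode`` — "score" or "cluster".
    ``score_norm`` — "anchored" (default) or "literal" rescaling.
    """

    fixed_threshold: int = 100
    k: int = 20
    eps: float = 1e-4
    max_iter: int = 1000
    pseudocount: float = 1e-10
    cluster_set_min_genes: int = 200
    debris_min_genes: int = 200
    score_cutoff: float = 0.5
    n_variable_genes: int = 2000
    loess_span: float = 0.3
    n_pcs: int = 30
    quantile_top: int = 3000
    quantile: float = 0.99
    quantile_divisor: float = 10.0
    seed: int = 1
    filter_mode: str = "score"
    score_norm: str = "anchored"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    """Everything a filtering run produces.

    ``score_table`` has one row per droplet: barcode, total_counts,
    genes_detected, set_membership, cluster, raw_score, normalized_score,
    keep. ``gene_table`` is the differential-expression table with the
    enriched flag. ``debris_clusters`` is the set of component indices
    treated as debris. ``em`` carries parameters, posteriors and the
    likelihood trace.
    """

    score_table: pd.DataFrame
    gene_table: pd.DataFrame
    debris_clusters: set[int]
    em: em_mod.EMResult
    variable_genes: pd.DataFrame
    expressed_gene_ids: list[str]
    config: RunConfig
    manifest: dict = field(default_factory=dict)

    @property
    def kept_barcodes(self) -> list[str]:
        tab = self.score_table
        return tab.loc[tab["keep"], "barcode"].tolist()


def run_pipeline(matrix: io_counts.SparseCountMatrix, config: RunConfig) -> PipelineResult:
    """Run the full debris-filtering procedure on a count matrix."""
    t0 = time.time()
    stats = io_counts.droplet_stats(matrix)

    expressed = preprocess.filter_expressed_genes(matrix)
    mat = matrix.subset_genes(expressed)
    logger.info("stage=genes expressed=%d/%d", mat.n_genes, matrix.n_genes)

    sets = preprocess.split_sets(
        stats, config.fixed_threshold, config.cluster_set_min_genes
    )
    fixed_mask = (sets["set_membership"] == preprocess.FIXED_DEBRIS).to_numpy()
    cluster_mask = sets["cluster_set_member"].to_numpy()
    logger.info(
        "stage=split fixed=%d test=%d cluster_set=%d",
        int(fixed_mask.sum()),
        int((~fixed_mask).sum()),
        int(cluster_mask.sum()),
    )

    norm = preprocess.normalize_for_init(mat, cluster_mask)
    vg = preprocess.select_variable_genes(
        mat, cluster_mask, v=config.n_variable_genes, span=config.loess_span
    )
    emb = preprocess.pca_embed(norm, vg["gene_index"].to_numpy(), n_pcs=config.n_pcs)
    km = preprocess.kmeans_init(emb, k=config.k, seed=config.seed)
    init_labels = np.full(mat.n_droplets, -1, dtype=int)
    init_labels[fixed_mask] = 0
    init_labels[cluster_mask] = km
    init_params = preprocess.initial_parameters(mat, init_labels, config.pseudocount)
    logger.info("stage=init components=%d", init_params.n_components)

    em_res = em_mod.run_em(
        mat.counts,
        init_params,
        fixed_mask,
        eps=config.eps,
        max_iter=config.max_iter,
        pseudocount=config.pseudocount,
    )
    clusters = em_mod.assign_clusters(em_res.posteriors)
    logger.info(
        "stage=em iterations=%d converged=%s", em_res.n_iter, em_res.converged
    )

    genes_detected = stats["genes_detected"].to_numpy()
    debris_set = scoring.define_debris_clusters(
        clusters, genes_detected, d=config.debris_min_genes
    )
    norm_de = scoring.normalize_for_de(mat.counts)
    in_debris = np.isin(clusters, list(debris_set))
    debris_cols = np.flatnonzero(~fixed_mask & in_debris)
    cell_cols = np.flatnonzero(~fixed_mask & ~in_debris)
    gene_table = scoring.debris_de(norm_de, debris_cols, cell_cols, mat.gene_ids)
    enriched_idx = np.flatnonzero(gene_table["enriched"].to_numpy())
    logger.info(
        "stage=de debris_clusters=%s enriched_genes=%d",
        sorted(debris_set),
        enriched_idx.size,
    )

    raw = scoring.score_droplets(norm_de, enriched_idx)
    normalized = scoring.normalize_scores(
        raw, clusters, debris_set, mode=config.score_norm
    )
    score_table = pd.DataFrame(
        {
            "barcode": matrix.barcodes,
            "total_counts": stats["total_counts"],
            "genes_detected": genes_detected,
            "set_membership": sets["set_membership"],
            "cluster": clusters,
            "raw_score": raw,
            "normalized_score": normalized,
        }
    )
    score_table["keep"] = scoring.filter_droplets(
        score_table,
        t=config.score_cutoff,
        mode=config.filter_mode,
        debris_clusters=debris_set,
    )
    logger.info(
        "stage=filter kept=%d removed=%d elapsed=%.1fs",
        int(score_table["keep"].sum()),
        int((~score_table["keep"]).sum()),
        time.time() - t0,
    )
    manifest = {
        "config": config.to_dict(),
        "n_genes": matrix.n_genes,
        "n_expressed_genes": mat.n_genes,
        "n_droplets": matrix.n_droplets,
        "em_converged": bool(em_res.converged),
        "em_iterations": int(em_res.n_iter),
        "debris_clusters": sorted(int(c) for c in debris_set),
        "n_enriched_genes": int(enriched_idx.size),
        "n_kept": int(score_table["keep"].sum()),
    }
    return PipelineResult(
        score_table=score_table,
        gene_table=gene_table,
        debris_clusters=debris_set,
        em=em_res,
        variable_genes=vg,
        expressed_gene_ids=list(mat.gene_ids),
        config=config,
        manifest=manifest,
    )


def quantile_baseline(
    matrix: io_counts.SparseCountMatrix, config: RunConfig
) -> tuple[float, list[str], list[str]]:
    """The hard-count comparison filter: threshold, kept, removed."""
    stats = io_counts.droplet_stats(matrix)
    threshold = io_counts.quantile_threshold(
        stats,
        top_c=config.quantile_top,
        quantile=config.quantile,
        divisor=config.quantile_divisor,
    )
    kept, removed = io_counts.filter_by_count(matrix, threshold)
    return threshold, kept, removed
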