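"""Gene-module discovery.

Subcluster-level pseudobulk expression (library-size normalized, log1p) is
filtered to genes that are (i) expressed — normalized value >= 1 in at least
one subcluster — and (ii) variable — fold change between the maximum and the
median subcluster >= 5. Retained genes are embedded in 2D with UMAP
(cosine metric, min_dist 0.01, n_neighbors 30) and grouped by density-peak
clustering on the 2D coordinates: module centers are points whose local
density rho and separation delta (distance to the nearest higher-density
point) both exceed their thresholds; every other gene joins the module of
its nearest higher-density neighbor.

The density kernel is Gaussian with bandwidth dc fixed at the 2nd percentile
of the pairwise-distance distribution, which pins down the otherwise
implementation-defined density scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .config import PipelineConfig


def filter_module_genes(pseudobulk: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Filter a subcluster x gene normalized pseudobulk matrix by expression
    and variance. Genes whose median is zero pass the fold-change filter
    whenever their maximum passes the expression floor (the ratio is taken
    against the smallest positive value, hence effectively infinite)."""
    vals = pseudobulk.to_numpy(dtype=float)
    gmax = vals.max(axis=0)
    gmed = np.median(vals, axis=0)
    pos = vals[vals > 0]
    floor = pos.min() if pos.size else 1.0
    fc = gmax / np.where(gmed > 0, gmed, floor)
    keep = (gmax >= config.gm_min_expr) & (fc >= config.gm_min_fc)
    return pseudobulk.loc[:, keep]


def embed_genes(filtered: pd.DataFrame, config: PipelineConfig, seed: int = 0) -> pd.DataFrame:
    """UMAP-embed genes (rows = genes after transpose) in 2D."""
    n_genes = filtered.shape[1]
    if n_genes < config.gm_umap_n_neighbors:
        raise ValueError(
            f"only {n_genes} genes retained; need >= {config.gm_umap_n_neighbors}"
        )
    import umap

    coords = umap.UMAP(
        metric="cosine",
        min_dist=config.gm_umap_min_dist,
        n_neighbors=config.gm_umap_n_neighbors,
        random_state=seed,
    ).fit_transform(filtered.to_numpy(dtype=float).T)
    return pd.DataFrame(coords, index=filtered.columns, columns=["umap1", "umap2"])


@dataclass
class GeneModuleResult:
    assignments: pd.Series  # gene -> module id
    rho: pd.Series
    delta: pd.Series
    centers: list


def density_cluster(
    coords: pd.DataFrame, rho_min: float = 1.0, delta_min: float = 1.0
) -> GeneModuleResult:
    """Density-peak clustering on 2D coordinates.

    rho_i = sum_j exp(-(d_ij/dc)^2) with dc the 2nd percentile of pairwise
    distances; delta_i = distance to the nearest point of higher density
    (the global density peak takes the maximum pairwise distance). Centers
    satisfy rho > rho_min and delta > delta_min; remaining points are
    assigned, in decreasing density order, to the module of their nearest
    higher-density neighbor.
    """
    X = coords.to_numpy(dtype=float)
    n = X.shape[0]
    if not np.isfinite(X).all():
        raise ValueError("non-finite coordinates")
    D = squareform(pdist(X))
    tri = D[np.triu_indices(n, 1)]
    dc = np.percentile(tri, 2) if tri.size else 1.0
    if dc <= 0:
        dc = max(tri[tri > 0].min(), 1e-12) if (tri > 0).any() else 1.0
    rho = np.exp(-((D / dc) ** 2)).sum(axis=1) - 1.0  # exclude self

    # order by decreasing density; ties broken by index for determinism
    order = np.lexsort((np.arange(n), -rho))
    delta = np.zeros(n)
    parent = np.full(n, -1)
    for rank, i in enumerate(order):
        if rank == 0:
            delta[i] = D[i].max() if n > 1 else 0.0
            continue
        higher = order[:rank]
        j = higher[np.argmin(D[i, higher])]
        delta[i] = D[i, j]
        parent[i] = j

    centers = [int(i) for i in range(n) if rho[i] > rho_min and delta[i] > delta_min]
    labels = np.full(n, -1)
    if not centers:
        labels[:] = 0
    else:
        for m, c in enumerate(centers):
            labels[c] = m
        for i in order:
            if labels[i] == -1:
                if parent[i] >= 0:
                    labels[i] = labels[parent[i]]
                else:  # global peak that is not itself a center
                    labels[i] = labels[centers[int(np.argmin(D[i, centers]))]]
    genes = list(coords.index)
    return GeneModuleResult(
        pd.Series(labels, index=genes, name="module"),
        pd.Series(rho, index=genes, name="rho"),
        pd.Series(delta, index=genes, name="delta"),
        [genes[c] for c in centers],
    )


def find_gene_modules(
    pseudobulk: pd.DataFrame, config: PipelineConfig, seed: int = 0
) -> tuple[GeneModuleResult, pd.DataFrame]:
    """Full pipeline: filter -> embed -> density-peak cluster."""
    filtered = filter_module_genes(pseudobulk, config)
    coords = embed_genes(filtered, config, seed)
    return density_cluster(coords, config.gm_rho, config.gm_delta), coords
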