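"""Clustering, exon-aware subclustering, differential expression and marker
selection.

Subclustering concatenates 30 principal components of the log-normalized
gene matrix with 10 principal components of the log-normalized exon matrix,
so that transcript-isoform differences invisible at the gene level still
separate subpopulations. Clustering is Louvain community detection on a kNN
graph of that embedding. Differential expression is a negative-binomial GLM
likelihood-ratio test (full: group + covariates; reduced: covariates) with a
per-cell log-library-size offset, BH-corrected.

Marker selection modes:

* ``mouse_marker`` — q < 0.05, fold change > 2 between the first- and
  second-ranked groups, and TPM > 50 in the first-ranked group;
* ``human_de`` — q < 0.05, fold change > 1.5, TPM > 50.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import igraph
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .config import PipelineConfig
from .matrix import CountMatrix, normalize_log, tpm_aggregate
from .stats import bh_adjust, nb_lrt


@dataclass
class Embedding:
    cells: list
    coords_pca: np.ndarray
    coords_2d: Optional[np.ndarray]
    n_gene_pcs: int
    n_exon_pcs: int
    seed: int


def _pca_block(normed: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    # cap at the achievable rank so degenerate blocks shrink instead of fail
    rank = min(n_pcs, min(normed.shape) - 1, np.linalg.matrix_rank(normed))
    if rank <= 0:
        return np.zeros((normed.shape[0], 0))
    return PCA(n_components=rank, svd_solver="full", random_state=seed).fit_transform(normed)


def combined_pca_embedding(
    gene: CountMatrix,
    exon: Optional[CountMatrix],
    config: PipelineConfig,
    seed: int = 0,
    compute_2d: bool = True,
) -> Embedding:
    """PCA on log-normalized gene counts (30 PCs) concatenated with PCA on
    log-normalized exon counts (10 PCs); gene PCs first."""
    if exon is not None and list(exon.cells) != list(gene.cells):
        raise ValueError("gene and exon matrices must cover the same cells")
    gnorm, _ = normalize_log(gene.counts, config.norm_scale)
    gpcs = _pca_block(gnorm, config.n_gene_pcs, seed)
    if exon is not None and exon.counts.nnz > 0:
        enorm, _ = normalize_log(exon.counts, config.norm_scale)
        epcs = _pca_block(enorm, config.n_exon_pcs, seed)
    else:
        epcs = np.zeros((len(gene.cells), 0))
    coords = np.hstack([gpcs, epcs])
    coords_2d = None
    if compute_2d:
        import umap

        nn = min(config.cluster_n_neighbors, len(gene.cells) - 1)
        coords_2d = umap.UMAP(
            n_neighbors=max(2, nn), min_dist=0.1, random_state=seed
        ).fit_transform(coords)
    return Embedding(list(gene.cells), coords, coords_2d, gpcs.shape[1], epcs.shape[1], seed)


def cluster_cells(
    coords: np.ndarray,
    resolution: float = 1.0,
    n_neighbors: int = 15,
    seed: int = 0,
) -> np.ndarray:
    """Louvain community detection on a symmetrized kNN graph."""
    n = coords.shape[0]
    if n < 10:
        return np.zeros(n, dtype=int)
    k = min(n_neighbors, n - 1)
    nbrs = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nbrs.kneighbors(coords)
    edges = set()
    for i in range(n):
        for j in idx[i, 1:]:
            edges.add((min(i, int(j)), max(i, int(j))))
    g = igraph.Graph(n=n, edges=sorted(edges))
    igraph.set_random_number_generator(random.Random(seed))
    part = g.community_multilevel(resolution=resolution)
    return np.asarray(part.membership, dtype=int)


def merge_indistinct_subclusters(
    labels: np.ndarray, coords_2d: np.ndarray, min_sep: float = 1.0
) -> Tuple[np.ndarray, list]:
    """Iteratively merge label pairs whose 2D centroids are closer than
    ``min_sep`` times the median within-cluster radius; returns relabeled
    array (labels compacted to 0..k-1) and a merge log."""
    labels = np.asarray(labels).copy()
    log = []
    while True:
        uniq = np.unique(labels)
        cents = {l: coords_2d[labels == l].mean(axis=0) for l in uniq}
        radii = []
        for l in uniq:
            pts = coords_2d[labels == l]
            radii.append(np.median(np.linalg.norm(pts - cents[l], axis=1)))
        med_radius = float(np.median(radii))
        best = None
        for i, a in enumerate(uniq):
            for b in uniq[i + 1 :]:
                d = float(np.linalg.norm(cents[a] - cents[b]))
                if d < min_sep * med_radius and (best is None or d < best[0]):
                    best = (d, a, b)
        if best is None:
            break
        _, a, b = best
        labels[labels == b] = a
        log.append((int(a), int(b), best[0]))
    # compact labels
    remap = {l: i for i, l in enumerate(np.unique(labels))}
    return np.asarray([remap[l] for l in labels], dtype=int), log


def de_test_lrt(
    counts: CountMatrix | sp.spmatrix | np.ndarray,
    groups: Sequence,
    covariates: Optional[pd.DataFrame] = None,
    min_cells_detected: int = 3,
    features: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Per-feature NB-GLM LRT of (group + covariates) vs (covariates).

    Features detected in fewer than ``min_cells_detected`` cells are excluded
    and reported with NaN statistics. Returns a table with lrt_stat, p, q
    (BH over tested features), fold change between the first- and
    second-ranked groups (on group TPM) and TPM in the first-ranked group.
    """
    if isinstance(counts, CountMatrix):
        feats = list(counts.features)
        mat = counts.counts
    else:
        mat = sp.csr_matrix(counts)
        feats = list(features) if features is not None else list(range(mat.shape[1]))
    mat = sp.csr_matrix(mat)
    groups = pd.Series(list(groups)).astype(str)
    if groups.nunique() < 2:
        raise ValueError("need at least two groups")

    lib = np.asarray(mat.sum(axis=1)).ravel().astype(float)
    ok_cells = lib > 0
    mat = mat[ok_cells]
    groups = groups[ok_cells.nonzero()[0]].reset_index(drop=True)
    lib = lib[ok_cells]
    offset = np.log(lib)

    gdum = pd.get_dummies(groups, drop_first=True, dtype=float)
    X_red = np.ones((mat.shape[0], 1))
    if covariates is not None:
        cov = pd.get_dummies(covariates.loc[ok_cells].reset_index(drop=True), drop_first=True, dtype=float)
        X_red = np.hstack([X_red, cov.to_numpy()])
    X_full = np.hstack([X_red, gdum.to_numpy()])

    tpm = tpm_aggregate(mat, groups.tolist(), feats)
    dense = np.asarray(mat.todense())
    detected = (dense > 0).sum(axis=0)

    rows = []
    for j, feat in enumerate(feats):
        tvals = tpm[feat].sort_values(ascending=False)
        first, second = tvals.iloc[0], (tvals.iloc[1] if len(tvals) > 1 else 0.0)
        fc = first / second if second > 0 else np.inf
        if detected[j] < min_cells_detected:
            rows.append({"feature": feat, "group": tvals.index[0], "lrt_stat": np.nan,
                         "p": np.nan, "tested": False,
                         "fc_first_vs_second": fc, "tpm_first": first})
            continue
        res = nb_lrt(dense[:, j], X_full, X_red, offset)
        rows.append({"feature": feat, "group": tvals.index[0], "lrt_stat": res.lrt_stat,
                     "p": res.p, "tested": res.converged,
                     "fc_first_vs_second": fc, "tpm_first": first})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def select_markers(de: pd.DataFrame, config: PipelineConfig, mode: str = "mouse_marker") -> pd.DataFrame:
    """Filter a DE table down to markers under the mode's cutoffs."""
    if mode == "mouse_marker":
        fc_min = config.marker_fc_min
    elif mode == "human_de":
        fc_min = config.human_de_fc_min
    else:
        raise ValueError(f"unknown mode {mode!r}")
    keep = (
        (de["q"] < config.de_fdr)
        & (de["fc_first_vs_second"] > fc_min)
        & (de["tpm_first"] > config.marker_tpm_min)
    )
    return de[keep.fillna(False)].reset_index(drop=True)
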