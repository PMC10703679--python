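"""Spatial mapping of cell types by non-negative least squares.

Cell-type signatures are aggregated UMI counts per type, library-size
normalized, scaled by 1e5 and log1p-transformed; spot profiles get the same
normalization. Each spot's profile is then decomposed as a non-negative
combination of the signatures (Lawson-Hanson active-set NNLS), and the
returned solution is verified against the KKT conditions: non-negativity,
non-negative gradient on the zero coordinates, and complementary slackness.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import nnls

from .config import PipelineConfig
from .matrix import CountMatrix, normalize_log


@dataclass
class SignatureMatrix:
    values: pd.DataFrame  # features x cell types, normalized
    n_cells: pd.Series  # cells aggregated per type

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ValueError("signatures must be non-negative")


def build_signature_matrix(
    counts: CountMatrix | sp.spmatrix | np.ndarray,
    labels: Sequence,
    config: PipelineConfig,
    features: Optional[Sequence] = None,
) -> SignatureMatrix:
    """Aggregate per-type UMI counts and normalize (libsize, x1e5, log1p)."""
    if isinstance(counts, CountMatrix):
        feats = list(counts.features)
        mat = counts.counts
    else:
        mat = sp.csr_matrix(counts)
        feats = list(features) if features is not None else list(range(mat.shape[1]))
    mat = sp.csr_matrix(mat)
    labels = pd.Series(list(labels))
    cols, ncells = {}, {}
    for lab in sorted(labels.unique()):
        idx = np.where(labels.values == lab)[0]
        agg = np.asarray(mat[idx].sum(axis=0)).ravel()
        if agg.sum() == 0:
            continue  # empty type dropped
        norm, _ = normalize_log(agg, config.norm_scale)
        cols[lab] = norm.ravel()
        ncells[lab] = len(idx)
    return SignatureMatrix(pd.DataFrame(cols, index=feats), pd.Series(ncells))


@dataclass
class SpotDeconvolution:
    weights: pd.DataFrame  # spots x cell types
    residuals: pd.Series
    kkt_max_violation: float

    @property
    def proportions(self) -> pd.DataFrame:
        totals = self.weights.sum(axis=1)
        out = self.weights.div(totals.where(totals > 0, 1.0), axis=0)
        out[totals == 0] = 0.0
        return out


def nnls_deconvolve(
    spots: pd.DataFrame, signatures: SignatureMatrix
) -> SpotDeconvolution:
    """Per-spot NNLS of the normalized spot profile onto the signatures.

    ``spots`` is spots x features (already normalized the same way as the
    signatures). Feature sets must match exactly.
    """
    sig_feats = list(signatures.values.index)
    spot_feats = list(spots.columns)
    if set(sig_feats) != set(spot_feats):
        diff = set(sig_feats) ^ set(spot_feats)
        raise ValueError(f"feature mismatch between spots and signatures: {sorted(diff)[:10]}")
    S = signatures.values.to_numpy(dtype=float)  # features x types
    types = list(signatures.values.columns)
    W = np.zeros((len(spots), len(types)))
    resid = np.zeros(len(spots))
    kkt = 0.0
    for i, (_, row) in enumerate(zip(spots.index, spots.loc[:, sig_feats].to_numpy(dtype=float))):
        w, r = nnls(S, row)
        W[i] = w
        resid[i] = r
        grad = S.T @ (S @ w - row)
        kkt = max(
            kkt,
            float(np.max(-grad[w <= 1e-12], initial=0.0)),  # gradient >= 0 where w = 0
            float(np.max(np.abs(grad[w > 1e-12]) , initial=0.0)),  # slackness on support
        )
    return SpotDeconvolution(
        pd.DataFrame(W, index=spots.index, columns=types),
        pd.Series(resid, index=spots.index),
        kkt,
    )


def normalize_spots(raw: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Apply the signature normalization (libsize, x1e5, log1p) to raw spot
    counts; zero-library spots are left all-zero and reported via a flag
    column is avoided — callers can detect them by a zero row sum."""
    norm, _ = normalize_log(raw.to_numpy(dtype=float), config.norm_scale)
    return pd.DataFrame(norm, index=raw.index, columns=raw.columns)
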