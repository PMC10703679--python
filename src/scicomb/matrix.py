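"""Sparse cells x features count matrices and their normalizations.

``CountMatrix`` is a thin container around a ``scipy.sparse`` matrix of UMI
counts plus per-cell assignment statistics. Matrices persist as MatrixMarket
bundles (``matrix.mtx`` + ``barcodes.tsv`` + ``features.tsv`` and, when
present, ``cell_stats.tsv``), the exchange format single-cell tools share.

Two normalizations recur downstream and are defined once here:

* ``normalize_log`` — per-cell library-size normalization scaled by 1e5 and
  log1p-transformed: ``x' = log(1 + 1e5 * x / libsize)``.
* ``tpm_aggregate`` — counts-per-million within a cell group. For UMI data
  there is no transcript-length term, so "TPM" here is simply a per-group
  count fraction on a 1e6 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

STAT_COLUMNS = ["total_reads", "assigned", "ambiguous", "discarded", "duplicates", "unassigned_frac"]


@dataclass
class CountMatrix:
    cells: list
    features: list
    counts: sp.csr_matrix  # cells x features, integer
    per_cell_stats: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.cells), len(self.features)):
            raise ValueError(
                f"counts shape {self.counts.shape} != "
                f"({len(self.cells)}, {len(self.features)})"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("negative counts")
        if self.per_cell_stats is not None:
            self.per_cell_stats.index.name = "cell"
            self.validate_stats()

    def validate_stats(self) -> None:
        st = self.per_cell_stats
        missing = [c for c in STAT_COLUMNS if c not in st.columns]
        if missing:
            raise ValueError(f"per_cell_stats missing columns {missing}")
        lhs = st["assigned"] + st["ambiguous"] + st["discarded"] + st["duplicates"]
        if not (lhs == st["total_reads"]).all():
            bad = st.index[lhs != st["total_reads"]].tolist()
            raise ValueError(f"read-conservation violated for cells {bad[:5]}")

    @property
    def shape(self):
        return self.counts.shape

    def library_sizes(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel()

    def genes_detected(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def subset_cells(self, keep: Sequence[int]) -> "CountMatrix":
        keep = list(keep)
        stats = None
        if self.per_cell_stats is not None:
            stats = self.per_cell_stats.iloc[keep].copy()
        return CountMatrix(
            [self.cells[i] for i in keep], list(self.features), self.counts[keep], stats
        )

    # -- persistence ---------------------------------------------------------

    def write_mtx(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(self.counts), field="integer")
        (outdir / "barcodes.tsv").write_text("\n".join(map(str, self.cells)) + "\n" if self.cells else "")
        (outdir / "features.tsv").write_text("\n".join(map(str, self.features)) + "\n" if self.features else "")
        if self.per_cell_stats is not None:
            self.per_cell_stats.to_csv(outdir / "cell_stats.tsv", sep="\t", index_label="cell")

    @classmethod
    def read_mtx(cls, indir: str | Path) -> "CountMatrix":
        indir = Path(indir)
        counts = sp.csr_matrix(mmread(str(indir / "matrix.mtx")))
        cells = (indir / "barcodes.tsv").read_text().splitlines()
        features = (indir / "features.tsv").read_text().splitlines()
        stats = None
        stats_path = indir / "cell_stats.tsv"
        if stats_path.exists():
            stats = pd.read_csv(stats_path, sep="\t", index_col="cell")
        return cls(cells, features, counts, stats)


def normalize_log(counts: sp.spmatrix | np.ndarray, scale: float = 1e5) -> tuple[np.ndarray, np.ndarray]:
    """Library-size normalize, scale, log1p.

    Returns ``(normalized, ok)`` where ``ok`` flags cells with non-zero
    library size; rows of zero-library cells are excluded from normalization
    (left all-zero) rather than silently divided.
    """
    dense = np.asarray(counts.todense() if sp.issparse(counts) else counts, dtype=float)
    if dense.ndim == 1:
        dense = dense[None, :]
    lib = dense.sum(axis=1)
    ok = lib > 0
    out = np.zeros_like(dense)
    out[ok] = np.log1p(scale * dense[ok] / lib[ok, None])
    return out, ok


def tpm_aggregate(counts: sp.spmatrix | np.ndarray, labels: Sequence, features: Optional[Sequence] = None) -> pd.DataFrame:
    """Aggregate counts by cell label and convert to counts-per-million.

    Rows are groups, columns features; each row sums to 1e6. Groups whose
    total count is zero are excluded.
    """
    labels = pd.Series(list(labels))
    if labels.isna().any():
        bad = labels.index[labels.isna()].tolist()
        raise ValueError(f"cells without a label at positions {bad[:5]}")
    mat = sp.csr_matrix(counts)
    if len(labels) != mat.shape[0]:
        raise ValueError("one label per cell required")
    groups = sorted(labels.unique())
    agg = np.zeros((len(groups), mat.shape[1]))
    for i, g in enumerate(groups):
        idx = np.where(labels.values == g)[0]
        agg[i] = np.asarray(mat[idx].sum(axis=0)).ravel()
    totals = agg.sum(axis=1)
    keep = totals > 0
    tpm = 1e6 * agg[keep] / totals[keep, None]
    cols = list(features) if features is not None else list(range(mat.shape[1]))
    return pd.DataFrame(tpm, index=[g for g, k in zip(groups, keep) if k], columns=cols)
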