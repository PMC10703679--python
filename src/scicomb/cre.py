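"""Chromatin-accessibility computations: peak filtering and merging,
binary peak counting, differential-peak filters, peak-gene linkage with a
permutation FDR, and TF motif-expression correlation.

Peak-gene linkage works on pseudo-cells (one aggregated profile per
subcluster, TPM-normalized and log1p-transformed in both modalities). For
every gene passing a TPM > 10 maximum filter, candidate peaks are the
accessible sites whose center falls within +/-500 kb of the gene's TSS.
The observed Pearson correlation of each candidate pair is compared against
a null built by permuting the subcluster identities of the ATAC matrix; the
retention threshold is the smallest correlation t at which the estimated
false-discovery proportion (#null >= t) / (#observed >= t) drops below 0.01,
computed on the positive tail since only positive links are kept. Each peak
then keeps only its best-correlated gene, and distal peaks sitting on
another gene's promoter (TSS +/- 2 kb) are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import GenomeAnnotation
from .config import PipelineConfig


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    score: float = 0.0  # -log10 q from the caller
    summit: Optional[int] = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("peak end must exceed start")
        if self.score < 0:
            raise ValueError("peak score must be >= 0")

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def read_narrowpeak(path) -> List[Peak]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            chrom, start, end = f[0], int(f[1]), int(f[2])
            score = float(f[8]) if len(f) > 8 else float(f[4]) if len(f) > 4 else 0.0
            summit = start + int(f[9]) if len(f) > 9 and int(f[9]) >= 0 else None
            peaks.append(Peak(chrom, start, end, max(score, 0.0), summit))
    return peaks


def write_bed(peaks: Sequence[Peak], path) -> None:
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t{p.score:.4f}\t.\n")


def score_per_million_filter(peaks: Sequence[Peak], cutoff: float) -> List[Peak]:
    """Normalize peak scores to 'score per million' and keep spm >= cutoff."""
    total = sum(p.score for p in peaks)
    if total == 0:
        raise ValueError("all peak scores are zero; cannot compute score per million")
    return [p for p in peaks if 1e6 * p.score / total >= cutoff]


def merge_summit_peaks(peaks: Sequence[Peak], pad: int = 250) -> List[Peak]:
    """Extend summits by ``pad`` bp each side and merge overlapping
    intervals (half-open). Peaks without a summit contribute their interval
    unchanged (they are already regions, not points), which makes the merge
    idempotent."""
    ivs = []
    for p in peaks:
        if p.summit is not None:
            ivs.append((p.chrom, max(0, p.summit - pad), p.summit + pad, p.score))
        else:
            ivs.append((p.chrom, p.start, p.end, p.score))
    ivs.sort()
    merged: List[Peak] = []
    for chrom, start, end, score in ivs:
        if merged and merged[-1].chrom == chrom and start <= merged[-1].end:
            last = merged.pop()
            merged.append(Peak(chrom, last.start, max(last.end, end), max(last.score, score)))
        else:
            merged.append(Peak(chrom, start, end, score))
    return merged


def count_peak_accessibility(
    fragments: pd.DataFrame, peaks: Sequence[Peak]
) -> pd.DataFrame:
    """Binary cell x peak matrix: 1 iff any fragment of the cell overlaps
    the peak. ``fragments`` columns: cell, chrom, start, end."""
    cells = sorted(fragments["cell"].unique())
    cell_idx = {c: i for i, c in enumerate(cells)}
    mat = np.zeros((len(cells), len(peaks)), dtype=np.int8)
    by_chrom: Dict[str, List[Tuple[int, Peak, int]]] = {}
    for j, p in enumerate(peaks):
        by_chrom.setdefault(p.chrom, []).append((p.start, p, j))
    for chrom, plist in by_chrom.items():
        plist.sort()
    for row in fragments.itertuples(index=False):
        for _, p, j in by_chrom.get(row.chrom, ()):
            if row.start < p.end and p.start < row.end:
                mat[cell_idx[row.cell], j] = 1
    return pd.DataFrame(mat, index=cells, columns=[p.name for p in peaks])


def differential_peak_filter(
    de: pd.DataFrame, config: PipelineConfig
) -> pd.DataFrame:
    """Keep peaks differentially accessible at 5% FDR with TPM > 20 in the
    target cell type. ``de`` is the LRT table (q, tpm_first columns)."""
    keep = (de["q"] < config.de_fdr) & (de["tpm_first"] > config.atac_diff_tpm_min)
    return de[keep.fillna(False)].reset_index(drop=True)


# -- peak-gene linkage -------------------------------------------------------


@dataclass
class PeakGeneLink:
    peak: str
    gene: str
    pcc: float
    q: float
    distance_to_tss: int


def _tpm_log(mat: pd.DataFrame) -> pd.DataFrame:
    totals = mat.sum(axis=0)
    return np.log1p(1e6 * mat / totals.where(totals > 0, 1.0))


def link_peaks_to_genes(
    rna: pd.DataFrame,  # genes x pseudo-cells, raw aggregated counts
    atac: pd.DataFrame,  # peaks x pseudo-cells, raw aggregated counts
    peak_pos: Dict[str, Tuple[str, int]],  # peak -> (chrom, center)
    ann: GenomeAnnotation,
    config: PipelineConfig,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlation linkage of peaks to genes with permutation FDR control.

    Returns the retained links as a DataFrame (peak, gene, pcc, q,
    distance_to_tss) sorted by decreasing correlation. Pairs with a constant
    gene or peak vector are skipped.
    """
    if list(rna.columns) != list(atac.columns):
        raise ValueError("RNA and ATAC pseudo-cell columns must match")
    rna_n = _tpm_log(rna)
    atac_n = _tpm_log(atac)
    # TPM>10 max filters on the TPM scale (before log)
    rna_tpm_max = (1e6 * rna / rna.sum(axis=0).where(rna.sum(axis=0) > 0, 1.0)).max(axis=1)
    atac_tpm_max = (1e6 * atac / atac.sum(axis=0).where(atac.sum(axis=0) > 0, 1.0)).max(axis=1)
    genes = [g for g in rna.index if g in ann.genes and rna_tpm_max[g] > config.cre_tpm_min]
    peaks = [p for p in atac.index if atac_tpm_max[p] > config.cre_tpm_min]

    candidates = []  # (gene, peak, distance)
    for g in genes:
        tss = ann.genes[g].tss
        chrom = ann.genes[g].chrom
        for p in peaks:
            pc, center = peak_pos[p]
            if pc == chrom and abs(center - tss) <= config.cre_window_bp:
                candidates.append((g, p, center - tss))
    if not candidates:
        return pd.DataFrame(columns=["peak", "gene", "pcc", "q", "distance_to_tss"])

    def corr_batch(atac_mat: pd.DataFrame) -> np.ndarray:
        out = np.full(len(candidates), np.nan)
        for i, (g, p, _) in enumerate(candidates):
            x = rna_n.loc[g].to_numpy(dtype=float)
            y = atac_mat.loc[p].to_numpy(dtype=float)
            if x.std() == 0 or y.std() == 0:
                continue
            out[i] = float(np.corrcoef(x, y)[0, 1])
        return out

    obs = corr_batch(atac_n)
    rng = np.random.default_rng(seed)
    null = []
    for _ in range(max(1, config.cre_n_permutations)):
        perm = rng.permutation(atac_n.shape[1])
        null.append(corr_batch(atac_n.iloc[:, perm]))
    null = np.concatenate(null)
    null = null[~np.isnan(null)]
    obs_ok = obs[~np.isnan(obs)]

    # smallest positive threshold with estimated FDR <= cre_fdr
    grid = np.sort(obs_ok[obs_ok > 0])
    threshold = None
    n_rounds = max(1, config.cre_n_permutations)
    for t in grid:
        n_obs = float((obs_ok >= t).sum())
        n_null = float((null >= t).sum()) / n_rounds
        if n_obs > 0 and n_null / n_obs <= config.cre_fdr:
            threshold = t
            break
    if threshold is None:
        return pd.DataFrame(columns=["peak", "gene", "pcc", "q", "distance_to_tss"])

    links = []
    for (g, p, dist), r in zip(candidates, obs):
        if np.isnan(r) or r < threshold:
            continue
        n_null = float((null >= r).sum()) / n_rounds
        n_obs = float((obs_ok >= r).sum())
        links.append({"peak": p, "gene": g, "pcc": r,
                      "q": min(1.0, n_null / n_obs), "distance_to_tss": int(dist)})
    if not links:
        return pd.DataFrame(columns=["peak", "gene", "pcc", "q", "distance_to_tss"])
    df = pd.DataFrame(links)
    # one gene per peak: the best-correlated
    df = df.sort_values(["pcc", "gene"], ascending=[False, True]).drop_duplicates("peak")
    # drop distal peaks overlapping another gene's promoter
    keep_rows = []
    for row in df.itertuples(index=False):
        chrom, center = peak_pos[row.peak]
        drop = False
        if abs(row.distance_to_tss) > config.cre_promoter_bp:  # distal to its own gene
            for g, gene in ann.genes.items():
                if g == row.gene or gene.chrom != chrom:
                    continue
                if abs(center - gene.tss) <= config.cre_promoter_bp:
                    drop = True
                    break
        if not drop:
            keep_rows.append(row._asdict())
    out = pd.DataFrame(keep_rows, columns=["peak", "gene", "pcc", "q", "distance_to_tss"])
    return out.sort_values("pcc", ascending=False).reset_index(drop=True)


def correlate_tf_activity(
    deviations: pd.DataFrame,  # cells x motifs
    expression: pd.DataFrame,  # cells x genes
    labels: Sequence,
    tf_to_motif: Dict[str, str],
    rescale_range: Tuple[float, float] = (0.0, 10.0),
) -> pd.DataFrame:
    """Correlate TF motif accessibility with TF expression across groups.

    Per cell, motif deviations are min-max rescaled to ``rescale_range``;
    both matrices are aggregated by label (mean), z-scaled across labels, and
    a Pearson correlation is computed per TF. TFs without a motif mapping or
    with a constant aggregated vector are skipped and listed.
    """
    lo, hi = rescale_range
    dev = deviations.to_numpy(dtype=float)
    dmin, dmax = dev.min(axis=1, keepdims=True), dev.max(axis=1, keepdims=True)
    span = np.where(dmax > dmin, dmax - dmin, 1.0)
    dev_scaled = pd.DataFrame(lo + (hi - lo) * (dev - dmin) / span,
                              index=deviations.index, columns=deviations.columns)
    labels = pd.Series(list(labels), index=deviations.index)
    agg_dev = dev_scaled.groupby(labels).mean()
    agg_expr = expression.groupby(labels).mean()

    def zscale(df: pd.DataFrame) -> pd.DataFrame:
        sd = df.std(axis=0, ddof=0)
        return (df - df.mean(axis=0)) / sd.where(sd > 0, 1.0)

    zd, ze = zscale(agg_dev), zscale(agg_expr)
    rows, skipped = [], []
    for tf, motif in tf_to_motif.items():
        if tf not in ze.columns or motif not in zd.columns:
            skipped.append(tf)
            continue
        x, y = ze[tf].to_numpy(), zd[motif].to_numpy()
        if x.std() == 0 or y.std() == 0:
            skipped.append(tf)
            continue
        rows.append({"tf": tf, "motif": motif, "pcc": float(np.corrcoef(x, y)[0, 1])})
    out = pd.DataFrame(rows, columns=["tf", "motif", "pcc"])
    out.attrs["skipped"] = skipped
    return out
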