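"""Cell-level quality control.

The two RT primer classes (oligo-dT and random hexamer) of one nucleus are
counted as independent pseudo-cells upstream. QC first keeps only physical
cells seen by BOTH primer classes, sums their columns, and then filters the
merged cells on three criteria (all strict inequalities):

* unassigned read fraction > 30%
* UMIs > 20,000
* detected genes < 200

Doublet scores are computed externally; applying a score threshold is in
scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .config import PipelineConfig
from .matrix import STAT_COLUMNS, CountMatrix


def _split_cell_id(cell_id: str) -> Tuple[str, str]:
    """-> (physical_cell_id, primer_class)."""
    phys, _, primer = cell_id.rpartition(".")
    if primer not in ("dT", "randomN") or not phys:
        raise ValueError(f"cell id {cell_id!r} does not end in a primer class")
    return phys, primer


def merge_primer_cells(
    gene: CountMatrix, exon: Optional[CountMatrix] = None
) -> Tuple[CountMatrix, Optional[CountMatrix], pd.Series]:
    """Merge dT/randomN pseudo-cell columns into physical cells.

    Cells lacking either primer class are dropped (and counted in the
    returned report). Counts and per-cell statistics are summed; the merged
    unassigned fraction is recomputed from the pooled counters.
    """
    groups: Dict[str, Dict[str, int]] = {}
    for i, cid in enumerate(gene.cells):
        phys, primer = _split_cell_id(cid)
        slot = groups.setdefault(phys, {})
        if primer in slot:
            raise ValueError(f"duplicate pseudo-cell for {phys} / {primer}")
        slot[primer] = i

    kept = sorted(p for p, slot in groups.items() if {"dT", "randomN"} <= set(slot))
    dropped = len(groups) - len(kept)

    def merge(mat: CountMatrix) -> CountMatrix:
        rows = []
        for phys in kept:
            slot = groups[phys]
            rows.append(mat.counts[slot["dT"]] + mat.counts[slot["randomN"]])
        counts = sp.vstack(rows).tocsr() if rows else sp.csr_matrix((0, len(mat.features)))
        stats = None
        if mat.per_cell_stats is not None:
            st = mat.per_cell_stats
            recs = []
            for phys in kept:
                slot = groups[phys]
                pooled = st.iloc[[slot["dT"], slot["randomN"]]][STAT_COLUMNS[:-1]].sum()
                total = pooled["total_reads"]
                unass = (pooled["ambiguous"] + pooled["discarded"]) / total if total else 0.0
                recs.append({"cell": phys, **pooled.to_dict(), "unassigned_frac": unass})
            stats = pd.DataFrame(recs).set_index("cell") if recs else None
        return CountMatrix(list(kept), list(mat.features), counts, stats)

    merged_gene = merge(gene)
    merged_exon = None
    if exon is not None:
        if list(exon.cells) != list(gene.cells):
            raise ValueError("gene and exon matrices must share cell columns")
        merged_exon = merge(exon)
    report = pd.Series({"physical_cells": len(groups), "kept": len(kept), "dropped_single_primer": dropped})
    return merged_gene, merged_exon, report


@dataclass
class CellQCRecord:
    cell_id: str
    umis: int
    genes_detected: int
    unassigned_frac: float
    has_dT: bool = True
    has_randomN: bool = True
    doublet_score: Optional[float] = None
    fail_reasons: List[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.fail_reasons


def qc_filter(
    merged: CountMatrix, config: PipelineConfig
) -> Tuple[CountMatrix, pd.DataFrame]:
    """Apply the three QC criteria; returns the filtered matrix and a
    per-cell report with every failure reason recorded."""
    if merged.per_cell_stats is None:
        raise ValueError("per_cell_stats required for QC")
    umis = merged.library_sizes()
    genes = merged.genes_detected()
    unass = merged.per_cell_stats["unassigned_frac"].to_numpy()
    records = []
    keep_idx = []
    for i, cell in enumerate(merged.cells):
        reasons = []
        if unass[i] > config.qc_max_unassigned_frac:
            reasons.append("unassigned")
        if umis[i] > config.qc_max_umis:
            reasons.append("umis")
        if genes[i] < config.qc_min_genes:
            reasons.append("genes")
        if not reasons:
            keep_idx.append(i)
        records.append(
            {
                "cell": cell,
                "umis": int(umis[i]),
                "genes_detected": int(genes[i]),
                "unassigned_frac": float(unass[i]),
                "pass": not reasons,
                "fail_reasons": ",".join(reasons),
            }
        )
    report = pd.DataFrame(records).set_index("cell")
    return merged.subset_cells(keep_idx), report


def apply_doublet_scores(
    matrix: CountMatrix, scores: pd.Series, threshold: float
) -> Tuple[CountMatrix, List[str]]:
    """Remove cells whose externally computed doublet score exceeds
    ``threshold`` (strict). Every cell must have a score."""
    missing = [c for c in matrix.cells if c not in scores.index]
    if missing:
        raise KeyError(f"no doublet score for cells: {missing[:5]}")
    removed = [c for c in matrix.cells if scores[c] > threshold]
    keep_idx = [i for i, c in enumerate(matrix.cells) if scores[c] <= threshold]
    return matrix.subset_cells(keep_idx), removed
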