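"""Read-to-feature assignment and UMI counting.

Aligned reads (SAM, names carrying ``cell|umi|readid`` from demultiplexing)
are deduplicated per cell on the (UMI, chrom, fragment start, strand) key and
then assigned to genes with a priority cascade reflecting 3'-biased
oligo-dT chemistry:

1. genes overlapping the read on the same strand — a unique hit counts
   directly; for multi-hits an oligo-dT read goes to the gene with the
   closest annotated 3' end, while a random-hexamer multi-hit is ambiguous;
2. failing that, a gene whose 3' terminus lies within a rescue window
   (default 1,000 bp) upstream of the read on the same strand;
3. failing that, a unique gene overlapping on the opposite strand;
4. otherwise the read is discarded.

Exon assignment runs within the already-assigned gene: a unique overlapping
exon, else the exon with maximal overlap (ties -> none), else none
(intronic; the gene count still increments).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
import pysam
import scipy.sparse as sp

from .annotation import Gene, GenomeAnnotation
from .config import PipelineConfig
from .matrix import STAT_COLUMNS, CountMatrix

ASSIGNED_CATEGORIES = ("gene_unique", "gene_3prime_tiebreak", "upstream_rescue", "antisense_rescue")
ALL_CATEGORIES = ASSIGNED_CATEGORIES + ("ambiguous", "discarded", "duplicate")


@dataclass(frozen=True)
class AlignedRead:
    cell_id: str
    umi: str
    chrom: str
    start: int  # 0-based half-open fragment interval
    end: int
    strand: str
    primer_class: str  # "dT" | "randomN"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end - 1) / 2.0


@dataclass
class Assignment:
    category: str
    gene_id: Optional[str] = None
    exon_id: Optional[str] = None

    def __post_init__(self):
        assigned = self.category in ASSIGNED_CATEGORIES
        if assigned != (self.gene_id is not None):
            raise ValueError(f"gene_id presence inconsistent with category {self.category}")
        if self.exon_id is not None and self.gene_id is None:
            raise ValueError("exon_id without gene_id")


def dedup_umis(reads: Iterable[AlignedRead]) -> Tuple[List[AlignedRead], int]:
    """Collapse PCR duplicates within one cell.

    A duplicate shares (cell, UMI, chrom, fragment start, strand) with an
    earlier read; the first occurrence is kept. The fragment end is excluded
    from the key because it varies with trimming.
    """
    seen = set()
    kept, dups = [], 0
    for r in reads:
        key = (r.cell_id, r.umi, r.chrom, r.start, r.strand)
        if key in seen:
            dups += 1
        else:
            seen.add(key)
            kept.append(r)
    return kept, dups


def _closest_3prime(read: AlignedRead, genes: List[Gene]) -> Gene:
    mid = read.midpoint
    return min(genes, key=lambda g: (abs(mid - g.three_prime_end), g.gene_id))


def assign_read_to_gene(read: AlignedRead, ann: GenomeAnnotation, config: PipelineConfig) -> Assignment:
    if not ann.has_chrom(read.chrom):
        return Assignment("discarded")
    sense = ann.overlapping_genes(read.chrom, read.start, read.end, read.strand)
    if len(sense) == 1:
        return Assignment("gene_unique", sense[0].gene_id)
    if len(sense) > 1:
        if read.primer_class == "dT":
            return Assignment("gene_3prime_tiebreak", _closest_3prime(read, sense).gene_id)
        return Assignment("ambiguous")
    upstream = ann.upstream_genes(read.chrom, read.start, read.end, read.strand, config.upstream_rescue_bp)
    if len(upstream) == 1:
        return Assignment("upstream_rescue", upstream[0].gene_id)
    if len(upstream) > 1:
        if read.primer_class == "dT":
            return Assignment("upstream_rescue", _closest_3prime(read, upstream).gene_id)
        return Assignment("ambiguous")
    anti_strand = "-" if read.strand == "+" else "+"
    antisense = ann.overlapping_genes(read.chrom, read.start, read.end, anti_strand)
    if len(antisense) == 1:
        return Assignment("antisense_rescue", antisense[0].gene_id)
    if len(antisense) > 1:
        return Assignment("ambiguous")
    return Assignment("discarded")


def assign_read_to_exon(read: AlignedRead, gene_id: str, ann: GenomeAnnotation) -> Optional[str]:
    exons = ann.overlapping_exons(gene_id, read.start, read.end)
    if not exons:
        return None
    if len(exons) == 1:
        return exons[0].exon_id
    overlaps = [
        (min(read.end, e.end) - max(read.start, e.start), e.exon_id) for e in exons
    ]
    overlaps.sort(key=lambda t: (-t[0], t[1]))
    if overlaps[0][0] == overlaps[1][0]:
        return None  # ambiguous between exons
    return overlaps[0][1]


# -- SAM ingest --------------------------------------------------------------


def _parse_name(name: str) -> Tuple[str, str, str]:
    parts = name.split("|")
    if len(parts) != 3:
        raise ValueError(f"malformed read name (expected cell|umi|readid): {name!r}")
    return parts[0], parts[1], parts[2]


def read_sam(path: str | Path) -> List[AlignedRead]:
    """Read a SAM/BAM file into fragments.

    Mates sharing a query name are merged into one fragment spanning the
    union of their intervals; the strand is taken from the first mate seen.
    Unmapped and non-primary records are skipped.
    """
    frags: Dict[str, dict] = {}
    order: List[str] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            name = rec.query_name
            entry = frags.get(name)
            if entry is None:
                order.append(name)
                frags[name] = {
                    "chrom": rec.reference_name,
                    "start": rec.reference_start,
                    "end": rec.reference_end,
                    "strand": "-" if rec.is_reverse else "+",
                }
            else:
                if entry["chrom"] == rec.reference_name:
                    entry["start"] = min(entry["start"], rec.reference_start)
                    entry["end"] = max(entry["end"], rec.reference_end)
    out = []
    for name in order:
        cell_id, umi, _ = _parse_name(name)
        primer = cell_id.rsplit(".", 1)[-1]
        f = frags[name]
        out.append(
            AlignedRead(cell_id, umi, f["chrom"], f["start"], f["end"], f["strand"], primer)
        )
    return out


def count_features(
    reads_or_sam,
    ann: GenomeAnnotation,
    config: PipelineConfig,
) -> Tuple[CountMatrix, CountMatrix]:
    """Build gene and exon UMI count matrices from aligned reads.

    Accepts a SAM/BAM path or an iterable of ``AlignedRead``. Per-cell
    statistics satisfy assigned + ambiguous + discarded + duplicates =
    total_reads exactly.
    """
    if isinstance(reads_or_sam, (str, Path)):
        reads = read_sam(reads_or_sam)
    else:
        reads = list(reads_or_sam)

    by_cell: Dict[str, List[AlignedRead]] = defaultdict(list)
    for r in reads:
        by_cell[r.cell_id].append(r)

    cells = sorted(by_cell)
    gene_ids = sorted(ann.genes)
    exon_ids = sorted(ann.exons)
    gene_idx = {g: i for i, g in enumerate(gene_ids)}
    exon_idx = {e: i for i, e in enumerate(exon_ids)}

    gene_counts = sp.lil_matrix((len(cells), len(gene_ids)), dtype=np.int64)
    exon_counts = sp.lil_matrix((len(cells), len(exon_ids)), dtype=np.int64)
    stats = []
    for ci, cell in enumerate(cells):
        total = len(by_cell[cell])
        kept, dups = dedup_umis(by_cell[cell])
        tallies = {c: 0 for c in ALL_CATEGORIES}
        tallies["duplicate"] = dups
        for r in kept:
            a = assign_read_to_gene(r, ann, config)
            tallies[a.category] += 1
            if a.gene_id is not None:
                gene_counts[ci, gene_idx[a.gene_id]] += 1
                exon = assign_read_to_exon(r, a.gene_id, ann)
                if exon is not None:
                    exon_counts[ci, exon_idx[exon]] += 1
        assigned = sum(tallies[c] for c in ASSIGNED_CATEGORIES)
        unass = tallies["ambiguous"] + tallies["discarded"]
        stats.append(
            {
                "cell": cell,
                "total_reads": total,
                "assigned": assigned,
                "ambiguous": tallies["ambiguous"],
                "discarded": tallies["discarded"],
                "duplicates": tallies["duplicate"],
                "unassigned_frac": unass / total if total else 0.0,
            }
        )
    stats_df = pd.DataFrame(stats).set_index("cell") if stats else pd.DataFrame(columns=STAT_COLUMNS)
    gm = CountMatrix(cells, gene_ids, gene_counts.tocsr(), stats_df.copy() if stats else None)
    em = CountMatrix(cells, exon_ids, exon_counts.tocsr(), None)
    return gm, em
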