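"""Strand-aware gene/exon annotation index.

All internal coordinates are 0-based half-open. GTF (1-based inclusive) is
converted on ingest and on write. For each gene the transcription start site
(TSS) and the 3' terminus are precomputed: on '+' the TSS is ``start`` and the
3' end is ``end - 1``; on '-' the TSS is ``end - 1`` and the 3' end is
``start``. These anchor the 3'-proximity tie-break and the upstream-rescue
rule during read assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

from intervaltree import IntervalTree


@dataclass(frozen=True)
class Gene:
    gene_id: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"gene {self.gene_id}: end <= start")
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime_end(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class Exon:
    exon_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


class GenomeAnnotation:
    """Interval index over genes and exons supporting the assignment queries."""

    def __init__(self, genes: List[Gene], exons: List[Exon]):
        self.genes: Dict[str, Gene] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self.exons_by_gene: Dict[str, List[Exon]] = {g.gene_id: [] for g in genes}
        self.exons: Dict[str, Exon] = {}
        for e in exons:
            g = self.genes.get(e.gene_id)
            if g is None:
                raise ValueError(f"exon {e.exon_id}: unknown gene {e.gene_id}")
            if not (g.start <= e.start < e.end <= g.end):
                raise ValueError(f"exon {e.exon_id} not contained in gene {e.gene_id}")
            self.exons_by_gene[e.gene_id].append(e)
            self.exons[e.exon_id] = e
        # per (chrom, strand) gene interval trees
        self._trees: Dict[Tuple[str, str], IntervalTree] = {}
        for g in self.genes.values():
            key = (g.chrom, g.strand)
            self._trees.setdefault(key, IntervalTree())
            self._trees[key].addi(g.start, g.end, g.gene_id)
        self.chroms = sorted({g.chrom for g in self.genes.values()})

    # -- queries -------------------------------------------------------------

    def has_chrom(self, chrom: str) -> bool:
        return any(c == chrom for c, _ in self._trees)

    def overlapping_genes(self, chrom: str, start: int, end: int, strand: str) -> List[Gene]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        hits = [self.genes[iv.data] for iv in tree.overlap(start, end)]
        return sorted(hits, key=lambda g: g.gene_id)

    def upstream_genes(self, chrom: str, start: int, end: int, strand: str, window: int) -> List[Gene]:
        """Genes on ``strand`` whose 3' terminus lies within ``window`` bp
        upstream of the read (strand-relative: a '+' read looks at lower
        coordinates)."""
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        out = []
        for iv in tree.overlap(start - window, end + window):
            g = self.genes[iv.data]
            tp = g.three_prime_end
            if strand == "+":
                ok = start - window <= tp < start
            else:
                ok = end <= tp < end + window
            if ok:
                out.append(g)
        return sorted(out, key=lambda g: g.gene_id)

    def overlapping_exons(self, gene_id: str, start: int, end: int) -> List[Exon]:
        if gene_id not in self.genes:
            raise KeyError(f"unknown gene {gene_id}")
        return [
            e
            for e in self.exons_by_gene[gene_id]
            if e.start < end and start < e.end
        ]

    # -- GTF I/O -------------------------------------------------------------

    def to_gtf(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for g in sorted(self.genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id)):
                fh.write(
                    f"{g.chrom}\tscicomb\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
                    f'gene_id "{g.gene_id}";\n'
                )
                for e in sorted(self.exons_by_gene[g.gene_id], key=lambda e: e.start):
                    fh.write(
                        f"{e.chrom}\tscicomb\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                        f'gene_id "{g.gene_id}"; exon_id "{e.exon_id}";\n'
                    )

    @classmethod
    def from_gtf(cls, path: str | Path) -> "GenomeAnnotation":
        import pyranges as pr

        df = pr.read_gtf(str(path)).df  # pyranges converts to 0-based half-open
        genes, exons = [], []
        for row in df.itertuples(index=False):
            if row.Feature == "gene":
                genes.append(
                    Gene(row.gene_id, str(row.Chromosome), int(row.Start), int(row.End), str(row.Strand))
                )
            elif row.Feature == "exon":
                exons.append(
                    Exon(row.exon_id, row.gene_id, str(row.Chromosome), int(row.Start), int(row.End), str(row.Strand))
                )
        return cls(genes, exons)
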