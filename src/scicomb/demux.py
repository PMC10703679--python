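"""Combinatorial-barcode demultiplexing.

Read 1 carries the ligation index, UMI and RT index (layout in
``ReadLayout``); read 2 is cDNA. Each index is matched against its whitelist
tolerating at most one mismatched base (Hamming distance, since indices are
fixed-position); an observed sequence equidistant from two whitelist entries
is rejected as ambiguous rather than guessed. The RT index encodes the sample
and the primer class (oligo-dT vs random hexamer); reads from the two primer
classes of one physical cell are kept as independent pseudo-cells until the
QC merge step.

After barcode extraction the cDNA is trimmed: a terminal poly(A) run (>= 10
A's, tolerating one non-A per ten) and trailing low-quality bases (Phred
< 20) are removed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Iterator, Optional, Tuple

import pandas as pd

from .config import PipelineConfig, ReadLayout

REJECTION_REASONS = ("no_match", "ambiguous", "truncated")


@dataclass(frozen=True)
class CellBarcode:
    sample_id: str
    rt_well: str
    primer_class: str  # "dT" | "randomN"
    ligation_index: str
    pcr_index: str
    umi: str

    def __post_init__(self):
        if self.primer_class not in ("dT", "randomN"):
            raise ValueError(f"bad primer class {self.primer_class!r}")

    @property
    def cell_id(self) -> str:
        """Unique per (physical cell x primer class)."""
        return f"{self.sample_id}.{self.rt_well}.{self.ligation_index}.{self.primer_class}"

    @property
    def physical_cell_id(self) -> str:
        """Shared by the dT and randomN pseudo-cells of one nucleus."""
        return f"{self.sample_id}.{self.rt_well}.{self.ligation_index}"


class Whitelist:
    """Fixed-length barcode whitelist with per-entry annotations."""

    def __init__(self, name: str, entries: Dict[str, dict]):
        lengths = {len(e) for e in entries}
        if len(lengths) > 1:
            raise ValueError(f"whitelist {name}: mixed entry lengths {lengths}")
        self.name = name
        self.entries = dict(entries)
        self.length = lengths.pop() if lengths else 0

    def __contains__(self, seq: str) -> bool:
        return seq in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for seq, ann in self.entries.items():
            rows.append({"sequence": seq, **ann})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, name: Optional[str] = None) -> "Whitelist":
        df = pd.read_csv(path, sep="\t", dtype=str)
        entries = {
            row.pop("sequence"): row for row in df.to_dict("records")
        }
        return cls(name or Path(path).stem, entries)


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def match_barcode(observed: str, wl: Whitelist, max_mismatch: int = 1):
    """Return ``(entry, distance)`` for the unique whitelist entry within
    ``max_mismatch``, or ``(None, reason)`` with reason in {no_match,
    ambiguous}. A length mismatch is a malformed read structure and raises."""
    if len(observed) != wl.length:
        raise ValueError(
            f"observed barcode length {len(observed)} != whitelist {wl.name} length {wl.length}"
        )
    if observed in wl:
        return observed, 0
    best, best_d, tied = None, max_mismatch + 1, False
    for entry in wl.entries:
        d = hamming(observed, entry)
        if d < best_d:
            best, best_d, tied = entry, d, False
        elif d == best_d:
            tied = True
    if best_d > max_mismatch:
        return None, "no_match"
    if tied:
        return None, "ambiguous"
    return best, best_d


def trim_tail(seq: str, qual: str, min_polya: int = 10, min_qual: int = 20) -> Tuple[str, str]:
    """Trim trailing low-quality bases, then a terminal poly(A) run.

    The poly(A) run must be >= ``min_polya`` long, allowing at most one non-A
    base per ten positions of the run. Never lengthens the read.
    """
    if len(seq) != len(qual):
        raise ValueError("seq and qual lengths differ")
    end = len(seq)
    while end > 0 and ord(qual[end - 1]) - 33 < min_qual:
        end -= 1
    # longest suffix that qualifies as a poly(A) run
    best_cut = end
    non_a = 0
    for i in range(end - 1, -1, -1):
        if seq[i] != "A":
            non_a += 1
        run = end - i
        # a qualifying run begins on an A; mismatches sit inside the run
        if seq[i] == "A" and run >= min_polya and non_a <= run // 10:
            best_cut = i
    return seq[:best_cut], qual[:best_cut]


@dataclass
class DemuxedRead:
    barcode: CellBarcode
    cdna_seq: str
    cdna_qual: str
    read_id: str

    @property
    def name(self) -> str:
        """FASTQ/SAM name encoding the cell and UMI for round-tripping."""
        return f"{self.barcode.cell_id}|{self.barcode.umi}|{self.read_id}"


def demultiplex_pair(
    read1: Tuple[str, str, str],
    read2: Tuple[str, str, str],
    rt_whitelist: Whitelist,
    lig_whitelist: Whitelist,
    layout: ReadLayout,
    config: PipelineConfig,
    pcr_index: str = "P01",
):
    """Demultiplex one read pair -> ``DemuxedRead`` or ``(None, reason)``.

    Reads are ``(id, seq, qual)`` triples. The RT whitelist annotation must
    carry ``sample_id``, ``rt_well`` and ``primer_class`` columns.
    """
    rid1, seq1, _ = read1
    rid2, seq2, qual2 = read2
    if len(seq1) < layout.min_read1_len:
        return None, "truncated"
    lig_obs = seq1[layout.lig_start : layout.lig_start + layout.lig_len]
    umi = seq1[layout.umi_start : layout.umi_start + layout.umi_len]
    rt_obs = seq1[layout.rt_start : layout.rt_start + layout.rt_len]

    rt_hit, rt_info = match_barcode(rt_obs, rt_whitelist, config.max_barcode_mismatch)
    if rt_hit is None:
        return None, rt_info
    lig_hit, lig_info = match_barcode(lig_obs, lig_whitelist, config.max_barcode_mismatch)
    if lig_hit is None:
        return None, lig_info

    ann = rt_whitelist.entries[rt_hit]
    bc = CellBarcode(
        sample_id=ann["sample_id"],
        rt_well=ann["rt_well"],
        primer_class=ann["primer_class"],
        ligation_index=lig_hit,
        pcr_index=pcr_index,
        umi=umi,
    )
    tseq, tqual = trim_tail(seq2, qual2)
    return DemuxedRead(bc, tseq, tqual, rid2 or rid1), None


def read_fastq(path: str | Path) -> Iterator[Tuple[str, str, str]]:
    with open(path) as fh:
        while True:
            header = fh.readline().rstrip("\n")
            if not header:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()
            qual = fh.readline().rstrip("\n")
            yield header[1:].split()[0], seq, qual


def demultiplex_fastq(
    fastq1: str | Path,
    fastq2: str | Path,
    rt_whitelist: Whitelist,
    lig_whitelist: Whitelist,
    layout: ReadLayout,
    config: PipelineConfig,
    pcr_index: str = "P01",
    out_fastq: Optional[str | Path] = None,
):
    """Demultiplex paired FASTQ files.

    Returns ``(demuxed_reads, report)`` where the report counts assigned
    pairs and every rejection reason; assigned + rejected equals input pairs.
    """
    counts = {"input_pairs": 0, "assigned": 0}
    counts.update({r: 0 for r in REJECTION_REASONS})
    out = []
    sink = open(out_fastq, "w") if out_fastq else None
    try:
        for r1, r2 in zip(read_fastq(fastq1), read_fastq(fastq2)):
            counts["input_pairs"] += 1
            res, reason = demultiplex_pair(
                r1, r2, rt_whitelist, lig_whitelist, layout, config, pcr_index
            )
            if res is None:
                counts[reason] += 1
                continue
            counts["assigned"] += 1
            out.append(res)
            if sink is not None:
                sink.write(f"@{res.name}\n{res.cdna_seq}\n+\n{res.cdna_qual}\n")
    finally:
        if sink is not None:
            sink.close()
    report = pd.Series(counts, name="count")
    return out, report
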