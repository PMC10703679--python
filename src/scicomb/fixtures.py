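"""Synthetic fixtures: every input the pipeline consumes, generated with
planted ground truth.

The generators emulate the data *structure* of a combinatorial-indexing
dual-primer RNA-seq experiment — barcode layout, read chemistry, a toy
genome with overlapping genes, and count matrices with planted cluster /
module / abundance / peak-link / age signal — not the error profile of any
particular sequencer. Count noise is negative-binomial, matching the
overdispersion the downstream GLM tests assume. All outputs are
deterministic given the seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pysam
import scipy.sparse as sp

from .annotation import Exon, Gene, GenomeAnnotation
from .config import PipelineConfig, ReadLayout
from .counting import AlignedRead
from .demux import Whitelist, hamming
from .matrix import CountMatrix, normalize_log

BASES = "ACGT"


@dataclass
class FixtureSpec:
    n_samples: int = 2
    wells_per_sample: int = 2
    n_cells: int = 8
    n_genes: int = 12
    n_exons_per_gene: int = 3
    reads_per_pseudocell: int = 40
    fraction_randomN_reads: float = 0.5
    barcode_error1_frac: float = 0.0
    barcode_error2_frac: float = 0.0
    nb_dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self):
        for name in ("fraction_randomN_reads", "barcode_error1_frac", "barcode_error2_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.barcode_error1_frac + self.barcode_error2_frac > 1.0:
            raise ValueError("error fractions exceed 1")
        if self.n_genes < 8:
            raise ValueError("genome fixture needs >= 8 genes for its mandatory motifs")


def _nb_sample(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return rng.negative_binomial(r, p)


# -- genome ------------------------------------------------------------------

GENE_LEN = 2000
EXON_LEN = 200
EXON_SPACING = 300
SPACED_GAP = 2000  # > the 1 kb upstream-rescue window


def make_genome_fixture(spec: FixtureSpec, outdir: Optional[str | Path] = None):
    """Toy genome + annotation containing, by construction: a same-strand
    overlapping gene pair (g000/g001, to exercise the 3' tie-break), an
    opposite-strand overlapping pair (g002/g003), and intergenic gaps larger
    than the upstream-rescue window. Returns ``(annotation, chrom_lengths,
    sequences)`` and optionally writes FASTA + GTF."""
    rng = np.random.default_rng(spec.seed)
    genes: List[Gene] = []
    chrom = "chr1"

    def add(gid, start, strand):
        genes.append(Gene(gid, chrom, start, start + GENE_LEN, strand))

    add("g000", 1000, "+")
    add("g001", 2500, "+")  # overlaps g000 on the same strand
    add("g002", 6000, "-")
    add("g003", 7000, "+")  # overlaps g002 on the opposite strand
    pos = 11000
    for i in range(4, spec.n_genes):
        add(f"g{i:03d}", pos, "+" if i % 2 == 0 else "-")
        pos += GENE_LEN + SPACED_GAP
    empty_zone = pos + 5000  # no gene within the rescue window of this point

    exons = []
    for g in genes:
        for e in range(spec.n_exons_per_gene):
            es = g.start + e * (EXON_LEN + EXON_SPACING)
            if es + EXON_LEN > g.end:
                break
            exons.append(Exon(f"{g.gene_id}.e{e}", g.gene_id, chrom, es, es + EXON_LEN, g.strand))
    ann = GenomeAnnotation(genes, exons)

    length = empty_zone + 10000
    seq = "".join(rng.choice(list(BASES), size=length))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "genome.fa", "w") as fh:
            fh.write(f">{chrom}\n")
            for i in range(0, length, 70):
                fh.write(seq[i : i + 70] + "\n")
        ann.to_gtf(outdir / "annotation.gtf")
    return ann, {chrom: length}, {chrom: seq}, empty_zone


# -- whitelists and cells ----------------------------------------------------


def make_whitelist_sequences(n: int, length: int, rng, min_dist: int = 3) -> List[str]:
    """Random barcodes with pairwise Hamming distance >= min_dist, so that
    1-mismatch correction is provably unambiguous."""
    out: List[str] = []
    attempts = 0
    while len(out) < n:
        cand = "".join(rng.choice(list(BASES), size=length))
        if all(hamming(cand, e) >= min_dist for e in out):
            out.append(cand)
        attempts += 1
        if attempts > 200000:
            raise RuntimeError("could not synthesize whitelist at requested distance")
    return out


def make_whitelists(spec: FixtureSpec, rng) -> Tuple[Whitelist, Whitelist]:
    n_rt = spec.n_samples * spec.wells_per_sample * 2  # x2: dT and randomN
    rt_seqs = make_whitelist_sequences(n_rt, 10, rng)
    entries = {}
    i = 0
    for s in range(spec.n_samples):
        for w in range(spec.wells_per_sample):
            for primer in ("dT", "randomN"):
                entries[rt_seqs[i]] = {
                    "sample_id": f"S{s}",
                    "rt_well": f"W{w:02d}",
                    "primer_class": primer,
                }
                i += 1
    lig_seqs = make_whitelist_sequences(max(spec.n_cells, 4), 10, rng)
    lig = Whitelist("ligation", {s: {} for s in lig_seqs})
    return Whitelist("rt", entries), lig


@dataclass(frozen=True)
class FixtureCell:
    sample_id: str
    rt_well: str
    ligation_index: str
    rt_seq_dT: str
    rt_seq_randomN: str

    def cell_id(self, primer: str) -> str:
        return f"{self.sample_id}.{self.rt_well}.{self.ligation_index}.{primer}"


def make_cells(spec: FixtureSpec, rt_wl: Whitelist, lig_wl: Whitelist) -> List[FixtureCell]:
    by_well: Dict[Tuple[str, str], Dict[str, str]] = {}
    for seq, ann in rt_wl.entries.items():
        key = (ann["sample_id"], ann["rt_well"])
        by_well.setdefault(key, {})[ann["primer_class"]] = seq
    wells = sorted(by_well)
    lig_seqs = sorted(lig_wl.entries)
    cells = []
    for i in range(spec.n_cells):
        sample, well = wells[i % len(wells)]
        cells.append(
            FixtureCell(sample, well, lig_seqs[i], by_well[(sample, well)]["dT"],
                        by_well[(sample, well)]["randomN"])
        )
    return cells


# -- reads -------------------------------------------------------------------

READ_LEN = 100
CATEGORY_WEIGHTS = {
    "gene_unique": 0.50,
    "gene_3prime_tiebreak": 0.10,
    "ambiguous": 0.08,
    "upstream_rescue": 0.08,
    "antisense_rescue": 0.08,
    "discarded": 0.08,
    "duplicate": 0.08,
}


def _plant_read(category: str, primer: str, ann: GenomeAnnotation, empty_zone: int, rng):
    """Choose a genomic placement realizing ``category``; returns
    (chrom, start, strand, gene_truth, exon_truth, category_truth)."""
    genes = ann.genes
    spaced_plus = sorted(g for g in genes if int(g[1:]) >= 4 and genes[g].strand == "+")
    spaced_minus = sorted(g for g in genes if int(g[1:]) >= 4 and genes[g].strand == "-")
    chrom = "chr1"
    if category == "gene_unique":
        gid = str(rng.choice(spaced_plus + spaced_minus))
        g = genes[gid]
        if rng.random() < 0.6:  # exonic: fully inside exon 0
            e = ann.exons_by_gene[gid][0]
            start = e.start + int(rng.integers(0, e.end - e.start - READ_LEN))
            return chrom, start, g.strand, gid, e.exon_id, category
        # intronic: between exon 0 and exon 1
        e0, e1 = ann.exons_by_gene[gid][0], ann.exons_by_gene[gid][1]
        start = e0.end + int(rng.integers(0, e1.start - e0.end - READ_LEN))
        return chrom, start, g.strand, gid, None, category
    if category in ("gene_3prime_tiebreak", "ambiguous"):
        # overlap of g000 and g001 on '+': [2500, 3000)
        start = 2500 + int(rng.integers(0, 500 - READ_LEN))
        if primer == "dT":
            mid = start + (READ_LEN - 1) / 2
            winner = min(("g000", "g001"),
                         key=lambda g: (abs(mid - genes[g].three_prime_end), g))
            return chrom, start, "+", winner, None, "gene_3prime_tiebreak"
        return chrom, start, "+", None, None, "ambiguous"
    if category == "upstream_rescue":
        gid = str(rng.choice(spaced_plus))
        g = genes[gid]
        start = g.end + int(rng.integers(50, 1000 - READ_LEN - 50))
        return chrom, start, "+", gid, None, category
    if category == "antisense_rescue":
        gid = str(rng.choice(spaced_minus))
        g = genes[gid]
        e0, e1 = ann.exons_by_gene[gid][0], ann.exons_by_gene[gid][1]
        start = e0.end + int(rng.integers(0, e1.start - e0.end - READ_LEN))
        return chrom, start, "+", gid, None, category
    if category == "discarded":
        start = empty_zone + int(rng.integers(0, 4000))
        return chrom, start, "+", None, None, category
    raise ValueError(category)


def _mutate(seq: str, n_errors: int, rng, forbidden: Sequence[str] = (), min_dist: int = 2) -> str:
    """Introduce exactly n_errors substitutions; resample until the mutant
    keeps Hamming distance >= min_dist from every forbidden entry, so that a
    2-error barcode can never be mis-corrected to a different entry."""
    for _ in range(1000):
        pos = rng.choice(len(seq), size=n_errors, replace=False)
        out = list(seq)
        for p in pos:
            out[p] = str(rng.choice([b for b in BASES if b != seq[p]]))
        cand = "".join(out)
        if n_errors < 2 or all(hamming(cand, e) >= min_dist for e in forbidden):
            return cand
    raise RuntimeError("could not plant the requested barcode errors")


def make_read_fixture(spec: FixtureSpec, outdir: str | Path):
    """Paired FASTQ + truth table + SAM for the demux/counting stages.

    The truth table records, per read pair: cell, primer class, UMI, the
    intended assignment category, truth gene/exon, the number of planted
    barcode errors and duplicate status. The SAM contains the reads a
    correct demultiplexer would pass through (<= 1 barcode error), placed at
    their true loci and named ``cell|umi|readid``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ann, chrom_lengths, seqs, empty_zone = make_genome_fixture(spec, outdir)
    rt_wl, lig_wl = make_whitelists(spec, rng)
    rt_wl.to_tsv(outdir / "rt_whitelist.tsv")
    lig_wl.to_tsv(outdir / "lig_whitelist.tsv")
    cells = make_cells(spec, rt_wl, lig_wl)
    layout = ReadLayout()

    cats = list(CATEGORY_WEIGHTS)
    probs = np.array([CATEGORY_WEIGHTS[c] for c in cats])
    probs = probs / probs.sum()

    truth_rows = []
    fq1, fq2, sam_records = [], [], []
    read_no = 0
    for cell in cells:
        for primer in ("dT", "randomN"):
            n_reads = spec.reads_per_pseudocell
            prev_uniques: List[dict] = []
            for _ in range(n_reads):
                cat = str(rng.choice(cats, p=probs))
                if cat == "duplicate" and not prev_uniques:
                    cat = "gene_unique"
                if cat == "duplicate":
                    src = prev_uniques[int(rng.integers(0, len(prev_uniques)))]
                    chrom, start, strand = src["chrom"], src["start"], src["strand"]
                    gene_t, exon_t = src["gene_truth"], src["exon_truth"]
                    umi = src["umi"]
                    truth_cat = "duplicate"
                else:
                    chrom, start, strand, gene_t, exon_t, truth_cat = _plant_read(
                        cat, primer, ann, empty_zone, rng
                    )
                    umi = "".join(rng.choice(list(BASES), size=layout.umi_len))
                rid = f"r{read_no:06d}"
                read_no += 1

                # barcode errors
                u = rng.random()
                rt_seq = cell.rt_seq_dT if primer == "dT" else cell.rt_seq_randomN
                lig_seq = cell.ligation_index
                n_err = 0
                if u < spec.barcode_error2_frac:
                    n_err = 2
                elif u < spec.barcode_error2_frac + spec.barcode_error1_frac:
                    n_err = 1
                if n_err:
                    target = "rt" if rng.random() < 0.5 else "lig"
                    wl = rt_wl if target == "rt" else lig_wl
                    if target == "rt":
                        rt_seq = _mutate(rt_seq, n_err, rng, list(wl.entries))
                    else:
                        lig_seq = _mutate(lig_seq, n_err, rng, list(wl.entries))

                r1 = lig_seq + umi + rt_seq
                cdna = seqs[chrom][start : start + READ_LEN]
                fq1.append((f"{rid}/1", r1, "I" * len(r1)))
                fq2.append((f"{rid}/2", cdna, "I" * len(cdna)))
                # only reads surviving demux can anchor a planted duplicate,
                # otherwise dedup would keep the copy as the first occurrence
                if truth_cat == "gene_unique" and n_err <= 1:
                    prev_uniques.append(
                        {"chrom": chrom, "start": start, "strand": strand,
                         "gene_truth": gene_t, "exon_truth": exon_t, "umi": umi}
                    )
                truth_rows.append(
                    {"read_id": rid, "cell_id": cell.cell_id(primer),
                     "physical_cell": f"{cell.sample_id}.{cell.rt_well}.{cell.ligation_index}",
                     "primer_class": primer, "umi": umi, "chrom": chrom,
                     "start": start, "strand": strand, "category": truth_cat,
                     "gene": gene_t if gene_t else "", "exon": exon_t if exon_t else "",
                     "n_barcode_errors": n_err}
                )
                if n_err <= 1:
                    sam_records.append(
                        (f"{cell.cell_id(primer)}|{umi}|{rid}", chrom, start, strand, cdna)
                    )

    for name, reads in (("reads_R1.fastq", fq1), ("reads_R2.fastq", fq2)):
        with open(outdir / name, "w") as fh:
            for rid, s, q in reads:
                fh.write(f"@{rid}\n{s}\n+\n{q}\n")

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": l} for c, l in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(outdir / "reads.sam"), "w", header=header) as sam:
        for name, chrom, start, strand, cdna in sam_records:
            a = pysam.AlignedSegment(sam.header)
            a.query_name = name
            a.query_sequence = cdna
            a.flag = 16 if strand == "-" else 0
            a.reference_id = sam.header.get_tid(chrom)
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = [(0, len(cdna))]
            a.query_qualities = pysam.qualitystring_to_array("I" * len(cdna))
            sam.write(a)

    truth = pd.DataFrame(truth_rows)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return ann, truth, rt_wl, lig_wl, layout


def make_random_reads(
    ann: GenomeAnnotation, chrom_length: int, n: int, seed: int = 0
) -> List[AlignedRead]:
    """Randomized fragments over the toy genome for oracle-equivalence
    testing. Positions are mostly uniform, with a fraction concentrated on
    the same-strand overlap region and on 3'-flanking windows so every
    assignment category is exercised; ~5% of reads duplicate an earlier
    (UMI, position) pair."""
    rng = np.random.default_rng(seed)
    gene_ends = [g.end for g in ann.genes.values()]
    out: List[AlignedRead] = []
    for i in range(n):
        u = rng.random()
        if out and u < 0.05:  # planted duplicate
            src = out[int(rng.integers(0, len(out)))]
            out.append(AlignedRead(src.cell_id, src.umi, src.chrom, src.start,
                                   src.end, src.strand, src.primer_class))
            continue
        if u < 0.15:  # same-strand overlap region (tie-break / ambiguous)
            start = int(rng.integers(2400, 3000))
        elif u < 0.25:  # 3'-flanking windows (upstream rescue)
            e = gene_ends[int(rng.integers(0, len(gene_ends)))]
            start = int(rng.integers(e, e + 1200))
        else:
            start = int(rng.integers(0, chrom_length - READ_LEN))
        strand = "+" if rng.random() < 0.5 else "-"
        primer = "dT" if rng.random() < 0.5 else "randomN"
        out.append(
            AlignedRead(f"cell0.{primer}", f"U{i:06d}", "chr1", start, start + READ_LEN, strand, primer)
        )
    return out


# -- count-matrix fixtures ---------------------------------------------------


def make_cluster_matrix(
    cluster_sizes: Sequence[int] = (60, 60, 60),
    n_genes: int = 100,
    n_exons_per_gene: int = 2,
    exon_only_pair: Optional[Tuple[int, int]] = (0, 1),
    base_mean: float = 2.0,
    signal_fold: float = 8.0,
    dispersion: float = 0.1,
    seed: int = 0,
):
    """Cells x genes and cells x exons count matrices with planted clusters.

    The two clusters in ``exon_only_pair`` share identical gene-level mean
    profiles and differ only in exon usage (one concentrates every gene's
    counts on the first exon, the other on the second); remaining clusters
    carry distinct gene-level signatures. With ``exon_only_pair=None`` every
    cluster gets its own gene signature (e.g. for deconvolution references).
    Returns (gene CountMatrix, exon CountMatrix, truth labels).
    """
    rng = np.random.default_rng(seed)
    k = len(cluster_sizes)
    gene_ids = [f"g{j:04d}" for j in range(n_genes)]
    exon_ids = [f"g{j:04d}.e{e}" for j in range(n_genes) for e in range(n_exons_per_gene)]

    means = np.full((k, n_genes), base_mean)
    sig_genes = max(5, n_genes // (k * 2))
    block = 0
    for c in range(k):
        if exon_only_pair is not None and c == exon_only_pair[1]:
            continue  # shares gene means with exon_only_pair[0]
        means[c, block : block + sig_genes] *= signal_fold
        block += sig_genes

    usage = np.full((k, n_genes, n_exons_per_gene), 1.0 / n_exons_per_gene)
    if exon_only_pair is not None:
        means[exon_only_pair[1]] = means[exon_only_pair[0]]
        # the pair splits on exon identity only
        usage[exon_only_pair[0], :, :] = 0.0
        usage[exon_only_pair[0], :, 0] = 1.0
        usage[exon_only_pair[1], :, :] = 0.0
        usage[exon_only_pair[1], :, min(1, n_exons_per_gene - 1)] = 1.0

    gene_rows, exon_rows, labels = [], [], []
    for c, size in enumerate(cluster_sizes):
        for _ in range(size):
            g = _nb_sample(rng, means[c], dispersion)
            e = np.zeros(n_genes * n_exons_per_gene, dtype=np.int64)
            for j in range(n_genes):
                if g[j] > 0:
                    e[j * n_exons_per_gene : (j + 1) * n_exons_per_gene] = rng.multinomial(
                        g[j], usage[c, j]
                    )
            gene_rows.append(g)
            exon_rows.append(e)
            labels.append(c)
    cells = [f"cell{i:04d}" for i in range(len(labels))]
    gm = CountMatrix(cells, gene_ids, sp.csr_matrix(np.array(gene_rows)))
    em = CountMatrix(cells, exon_ids, sp.csr_matrix(np.array(exon_rows)))
    return gm, em, np.array(labels)


def make_abundance_cells(
    n_subclusters: int = 10,
    effects: Optional[Dict[int, float]] = None,
    n_animals_per_condition: int = 2,
    wells_per_animal: int = 2,
    cells_per_well: int = 600,
    conditions: Tuple[str, str] = ("case", "control"),
    seed: int = 0,
) -> pd.DataFrame:
    """Cell metadata with planted composition effects.

    ``effects`` maps subcluster index -> fold change of its population
    fraction in the case condition. Each animal contributes
    ``wells_per_animal`` replicate wells; sexes alternate across animals.
    """
    rng = np.random.default_rng(seed)
    effects = effects or {}
    base = np.ones(n_subclusters) / n_subclusters
    rows = []
    for cond in conditions:
        props = base.copy()
        if cond == conditions[0]:
            for scid, fc in effects.items():
                props[scid] *= fc
        props = props / props.sum()
        for a in range(n_animals_per_condition):
            animal = f"{cond}_m{a}"
            sex = "M" if a % 2 == 0 else "F"
            for w in range(wells_per_animal):
                rep = f"{animal}_w{w}"
                counts = rng.multinomial(cells_per_well, props)
                for scid, n in enumerate(counts):
                    for _ in range(n):
                        rows.append(
                            {"subcluster": f"sc{scid:02d}", "replicate": rep,
                             "animal": animal, "condition": cond, "sex": sex}
                        )
    df = pd.DataFrame(rows)
    df.index = [f"c{i:06d}" for i in range(len(df))]
    return df


def make_module_pseudobulk(
    n_modules: int = 4,
    genes_per_module: int = 50,
    n_subclusters: int = 40,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.Series]:
    """Subcluster x gene normalized pseudobulk with planted gene modules.

    Each module is active (expression ~5) in its own disjoint quarter of the
    subclusters and near zero elsewhere, so every planted gene passes the
    expression (max >= 1) and variance (max/median >= 5) filters.
    """
    rng = np.random.default_rng(seed)
    per = n_subclusters // n_modules
    cols, truth = {}, {}
    for m in range(n_modules):
        active = np.zeros(n_subclusters)
        active[m * per : (m + 1) * per] = 5.0
        for g in range(genes_per_module):
            name = f"mod{m}_g{g:03d}"
            vals = active * (1 + 0.1 * rng.standard_normal(n_subclusters)) \
                + np.abs(noise_sd * rng.standard_normal(n_subclusters))
            cols[name] = np.maximum(vals, 0.0)
            truth[name] = m
    pseudobulk = pd.DataFrame(cols, index=[f"sc{i:02d}" for i in range(n_subclusters)])
    return pseudobulk, pd.Series(truth, name="module")


def make_link_fixture(
    n_linked: int = 50,
    n_genes: int = 60,
    n_peaks: int = 100,
    n_pseudocells: int = 50,
    link_strength: float = 0.92,
    seed: int = 0,
):
    """RNA and ATAC pseudo-cell matrices with planted peak-gene links.

    The first ``n_linked`` peaks are tied to the first ``n_linked`` genes
    through a shared latent factor (target correlation ``link_strength`` on
    the normalized scale); all other peaks are independent decoys. Genes sit
    20 kb apart on one chromosome, each planted peak 5 kb from its gene's
    TSS, decoy peaks away from every promoter. Returns (rna, atac,
    peak_pos, annotation, truth) where truth maps peak -> (gene, true_pcc).
    """
    if n_linked > min(n_genes, n_peaks):
        raise ValueError("n_linked exceeds available genes/peaks")
    rng = np.random.default_rng(seed)
    genes = []
    for j in range(n_genes):
        start = 10_000 + j * 20_000
        genes.append(Gene(f"lg{j:03d}", "chr1", start, start + 1_000, "+"))
    ann = GenomeAnnotation(genes, [])

    cols = [f"pc{i:02d}" for i in range(n_pseudocells)]
    rna = {}
    atac = {}
    peak_pos = {}
    truth = {}
    mix = link_strength
    for j in range(n_genes):
        z = rng.standard_normal(n_pseudocells)
        expr = np.exp(1.5 + 1.2 * z)
        rna[f"lg{j:03d}"] = np.round(50 * expr).astype(int)
        if j < n_linked:
            w = mix * z + np.sqrt(1 - mix**2) * rng.standard_normal(n_pseudocells)
            acc = np.exp(1.0 + 1.2 * w)
            pname = f"peak{j:03d}"
            atac[pname] = np.round(40 * acc).astype(int)
            peak_pos[pname] = ("chr1", genes[j].tss + 5_000)
            truth[pname] = genes[j].gene_id
    for d in range(n_peaks - n_linked):
        pname = f"decoy{d:03d}"
        acc = np.exp(1.0 + 1.2 * rng.standard_normal(n_pseudocells))
        atac[pname] = np.round(40 * acc).astype(int)
        # centered mid-way between promoters
        j = d % n_genes
        peak_pos[pname] = ("chr1", genes[j].start + 9_000)
    rna_df = pd.DataFrame(rna, index=cols).T
    atac_df = pd.DataFrame(atac, index=cols).T
    return rna_df, atac_df, peak_pos, ann, truth


def make_clock_cells(
    ages_months: Sequence[float] = (3.0, 6.0, 21.0),
    n_animals_per_age: int = 4,
    cells_per_animal: int = 60,
    n_signal_genes: int = 50,
    n_noise_genes: int = 50,
    noise: str = "nb",
    dispersion: float = 0.1,
    seed: int = 0,
):
    """Cells x genes expression with a planted ln(age) slope.

    ``noise='none'`` yields expression exactly affine in ln(age) (for
    closed-form checks); ``noise='nb'`` draws NB counts around the age-
    dependent mean and returns log-normalized values. Returns (expr,
    cell_meta, animal_meta, slopes).
    """
    rng = np.random.default_rng(seed)
    n_genes = n_signal_genes + n_noise_genes
    gene_ids = [f"g{j:03d}" for j in range(n_genes)]
    slopes = np.zeros(n_genes)
    slopes[:n_signal_genes] = rng.uniform(-1.0, 1.0, n_signal_genes)
    baseline = rng.uniform(1.0, 3.0, n_genes)

    rows, meta = [], []
    animals = {}
    i = 0
    for age in ages_months:
        for a in range(n_animals_per_age):
            animal = f"a{age:g}_{a}"
            animals[animal] = age
            mu = baseline + slopes * np.log(age)
            for _ in range(cells_per_animal):
                if noise == "none":
                    rows.append(mu.copy())
                else:
                    counts = _nb_sample(rng, np.exp(mu), dispersion)
                    normed, _ = normalize_log(counts.astype(float))
                    rows.append(normed.ravel())
                meta.append({"cell": f"c{i:05d}", "animal": animal, "cell_type": "T0"})
                i += 1
    expr = pd.DataFrame(rows, index=[m["cell"] for m in meta], columns=gene_ids)
    cell_meta = pd.DataFrame(meta).set_index("cell")
    animal_meta = pd.DataFrame({"age_months": pd.Series(animals)})
    return expr, cell_meta, animal_meta, pd.Series(slopes, index=gene_ids)
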