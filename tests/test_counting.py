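"""Read assignment rules, deduplication and matrix construction.

The gene-assignment oracle below is a literal, index-free restatement of the
priority cascade: it scans every annotation row and applies the rules one by
one. The implementation must agree with it on every read.
"""

import numpy as np
import pytest

from scicomb.annotation import Gene, GenomeAnnotation
from scicomb.counting import (ASSIGNED_CATEGORIES, AlignedRead, Assignment,
                              assign_read_to_exon, assign_read_to_gene,
                              count_features, dedup_umis, read_sam)
from scicomb.fixtures import make_random_reads


def oracle_assign(read, ann, config):
    """Brute-force scan over all genes applying the cascade literally."""
    genes = list(ann.genes.values())
    if read.chrom not in {g.chrom for g in genes}:
        return ("discarded", None)
    mid = (read.start + read.end - 1) / 2.0

    def closest(cands):
        return min(cands, key=lambda g: (abs(mid - g.three_prime_end), g.gene_id)).gene_id

    sense = [g for g in genes
             if g.chrom == read.chrom and g.strand == read.strand
             and g.start < read.end and read.start < g.end]
    if len(sense) == 1:
        return ("gene_unique", sense[0].gene_id)
    if len(sense) > 1:
        if read.primer_class == "dT":
            return ("gene_3prime_tiebreak", closest(sense))
        return ("ambiguous", None)
    upstream = []
    for g in genes:
        if g.chrom != read.chrom or g.strand != read.strand:
            continue
        tp = g.three_prime_end
        if read.strand == "+" and read.start - config.upstream_rescue_bp <= tp < read.start:
            upstream.append(g)
        elif read.strand == "-" and read.end <= tp < read.end + config.upstream_rescue_bp:
            upstream.append(g)
    if len(upstream) == 1:
        return ("upstream_rescue", upstream[0].gene_id)
    if len(upstream) > 1:
        if read.primer_class == "dT":
            return ("upstream_rescue", closest(upstream))
        return ("ambiguous", None)
    anti = [g for g in genes
            if g.chrom == read.chrom and g.strand != read.strand
            and g.start < read.end and read.start < g.end]
    if len(anti) == 1:
        return ("antisense_rescue", anti[0].gene_id)
    if len(anti) > 1:
        return ("ambiguous", None)
    return ("discarded", None)


class TestAssignGene:
    def test_oracle_equivalence_on_randomized_reads(self, genome, config):
        """100% agreement with the brute-force oracle across >= 1,000 reads
        hitting every assignment category."""
        ann, lengths, _, _ = genome
        reads = make_random_reads(ann, lengths["chr1"], 1500, seed=3)
        kept, dups = dedup_umis(reads)
        assert dups > 0
        seen = set()
        for r in kept:
            a = assign_read_to_gene(r, ann, config)
            cat, gid = oracle_assign(r, ann, config)
            assert (a.category, a.gene_id) == (cat, gid), r
            seen.add(a.category)
        assert seen == {"gene_unique", "gene_3prime_tiebreak", "upstream_rescue",
                        "antisense_rescue", "ambiguous", "discarded"}

    def test_dt_tiebreak_picks_closest_three_prime(self, config):
        # A ends 200 bp from the read midpoint, B 1,500 bp away
        a = Gene("A", "chr1", 0, 5050, "+")
        b = Gene("B", "chr1", 4000, 6350, "+")
        ann = GenomeAnnotation([a, b], [])
        read = AlignedRead("c.dT", "u", "chr1", 4800, 4900, "+", "dT")
        got = assign_read_to_gene(read, ann, config)
        assert got.category == "gene_3prime_tiebreak" and got.gene_id == "A"

    def test_randomn_multioverlap_is_ambiguous(self, config):
        a = Gene("A", "chr1", 0, 5050, "+")
        b = Gene("B", "chr1", 4000, 6350, "+")
        ann = GenomeAnnotation([a, b], [])
        read = AlignedRead("c.randomN", "u", "chr1", 4800, 4900, "+", "randomN")
        assert assign_read_to_gene(read, ann, config).category == "ambiguous"

    def test_upstream_rescue_window(self, config):
        # gene A (+) ends at 4600; read at [5000, 5100) has no overlap anywhere
        a = Gene("A", "chr1", 3000, 4600, "+")
        ann = GenomeAnnotation([a], [])
        read = AlignedRead("c.dT", "u", "chr1", 5000, 5100, "+", "dT")
        got = assign_read_to_gene(read, ann, config)
        assert (got.category, got.gene_id) == ("upstream_rescue", "A")
        # beyond the 1 kb window the read is discarded
        far = AlignedRead("c.dT", "u", "chr1", 5700, 5800, "+", "dT")
        assert assign_read_to_gene(far, ann, config).category == "discarded"

    def test_missing_chrom_discarded(self, genome, config):
        ann = genome[0]
        read = AlignedRead("c.dT", "u", "chrZ", 0, 100, "+", "dT")
        assert assign_read_to_gene(read, ann, config).category == "discarded"


class TestAssignExon:
    def test_junction_read_goes_to_larger_overlap(self, config):
        from scicomb.annotation import Exon

        g = Gene("A", "chr1", 0, 1000, "+")
        e1 = Exon("A.e1", "A", "chr1", 100, 200, "+")
        e2 = Exon("A.e2", "A", "chr1", 200, 300, "+")
        ann = GenomeAnnotation([g], [e1, e2])
        # 60 bp in e1, 15 bp in e2
        read = AlignedRead("c.dT", "u", "chr1", 140, 215, "+", "dT")
        assert assign_read_to_exon(read, "A", ann) == "A.e1"
        # exact tie -> ambiguous -> none
        tie = AlignedRead("c.dT", "u", "chr1", 150, 250, "+", "dT")
        assert assign_read_to_exon(tie, "A", ann) is None
        # intronic -> none
        intron = AlignedRead("c.dT", "u", "chr1", 400, 500, "+", "dT")
        assert assign_read_to_exon(intron, "A", ann) is None


class TestDedup:
    def test_identical_key_collapsed(self):
        r = AlignedRead("c.dT", "u1", "chr1", 10, 110, "+", "dT")
        kept, dups = dedup_umis([r, r])
        assert len(kept) == 1 and dups == 1

    def test_same_umi_different_position_kept(self):
        r1 = AlignedRead("c.dT", "u1", "chr1", 10, 110, "+", "dT")
        r2 = AlignedRead("c.dT", "u1", "chr2", 10, 110, "+", "dT")
        kept, dups = dedup_umis([r1, r2])
        assert len(kept) == 2 and dups == 0


class TestCountFeatures:
    def _truth_tables(self, read_fixture):
        truth = read_fixture["truth"]
        t = truth[truth["n_barcode_errors"] <= 1]
        assigned = t[t["category"].isin(ASSIGNED_CATEGORIES)]
        return t, assigned

    def test_matrix_matches_planted_truth(self, read_fixture, config):
        t, assigned = self._truth_tables(read_fixture)
        gm, em = count_features(read_fixture["dir"] / "reads.sam", read_fixture["ann"], config)
        for (cell, gene), n in assigned.groupby(["cell_id", "gene"]).size().items():
            assert gm.counts[gm.cells.index(cell), gm.features.index(gene)] == n
        assert gm.counts.sum() == len(assigned)
        exonic = assigned[assigned["exon"] != ""]
        for (cell, exon), n in exonic.groupby(["cell_id", "exon"]).size().items():
            assert em.counts[em.cells.index(cell), em.features.index(exon)] == n
        assert em.counts.sum() == len(exonic)
        assert em.counts.sum() <= gm.counts.sum()

    def test_per_cell_conservation_and_duplicates(self, read_fixture, config):
        t, _ = self._truth_tables(read_fixture)
        gm, _ = count_features(read_fixture["dir"] / "reads.sam", read_fixture["ann"], config)
        gm.validate_stats()  # assigned + ambiguous + discarded + duplicates == total
        dup_truth = t[t["category"] == "duplicate"].groupby("cell_id").size()
        for cell, n in dup_truth.items():
            assert gm.per_cell_stats.loc[cell, "duplicates"] == n

    def test_record_order_invariance(self, read_fixture, config):
        reads = read_sam(read_fixture["dir"] / "reads.sam")
        gm1, em1 = count_features(reads, read_fixture["ann"], config)
        rng = np.random.default_rng(0)
        shuffled = [reads[i] for i in rng.permutation(len(reads))]
        gm2, em2 = count_features(shuffled, read_fixture["ann"], config)
        assert (gm1.counts != gm2.counts).nnz == 0
        assert (em1.counts != em2.counts).nnz == 0

    def test_empty_input(self, genome, config):
        gm, em = count_features([], genome[0], config)
        assert gm.shape[0] == 0 and em.shape[0] == 0

    def test_malformed_read_name_is_hard_error(self, read_fixture, tmp_path, config):
        bad = tmp_path / "bad.sam"
        bad.write_text(
            "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n"
            "noname\t0\tchr1\t1\t60\t10M\t*\t0\t0\tACGTACGTAC\tIIIIIIIIII\n"
        )
        with pytest.raises(ValueError, match="noname"):
            count_features(bad, read_fixture["ann"], config)
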