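"""Peak filtering/merging, binary accessibility counting, peak-gene linkage
with permutation FDR, and TF motif-expression correlation."""

import numpy as np
import pandas as pd
import pytest

from scicomb.config import PipelineConfig
from scicomb.cre import (Peak, correlate_tf_activity, count_peak_accessibility,
                         differential_peak_filter, link_peaks_to_genes,
                         merge_summit_peaks, read_narrowpeak,
                         score_per_million_filter, _tpm_log)
from scicomb.fixtures import make_link_fixture


class TestScorePerMillion:
    def test_single_peak_kept(self):
        out = score_per_million_filter([Peak("chr1", 0, 100, 5.0)], 1.3)
        assert len(out) == 1

    def test_arithmetic(self):
        peaks = [Peak("chr1", 0, 100, 1.0), Peak("chr1", 200, 300, 3.0)]
        # spm = [250000, 750000], both above 1.3
        assert len(score_per_million_filter(peaks, 1.3)) == 2
        # raise the cutoff between the two
        assert score_per_million_filter(peaks, 500000.0)[0].score == 3.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            score_per_million_filter([Peak("chr1", 0, 100, 0.0)], 1.3)


class TestMergeSummits:
    def test_close_summits_merge(self):
        peaks = [Peak("chr1", 900, 1100, 1.0, summit=1000),
                 Peak("chr1", 1300, 1500, 1.0, summit=1400)]
        merged = merge_summit_peaks(peaks, pad=250)
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (750, 1650)

    def test_distant_summits_stay(self):
        peaks = [Peak("chr1", 900, 1100, 1.0, summit=1000),
                 Peak("chr1", 1900, 2100, 1.0, summit=2000)]
        assert len(merge_summit_peaks(peaks, pad=250)) == 2

    def test_idempotent(self):
        peaks = [Peak("chr1", 900, 1100, 1.0, summit=1000),
                 Peak("chr1", 1300, 1500, 1.0, summit=1400),
                 Peak("chr1", 5000, 5200, 1.0, summit=5100)]
        once = merge_summit_peaks(peaks, pad=250)
        twice = merge_summit_peaks(once, pad=250)  # merged peaks carry no summit
        assert [(p.start, p.end) for p in twice] == [(p.start, p.end) for p in once]

    def test_narrowpeak_round_trip(self, tmp_path):
        path = tmp_path / "p.narrowPeak"
        path.write_text("chr1\t100\t300\tpk1\t100\t.\t5.1\t6.2\t7.3\t50\n")
        peaks = read_narrowpeak(path)
        assert peaks[0].score == 7.3 and peaks[0].summit == 150


class TestPeakCounting:
    def test_binary_and_matches_brute_force(self):
        rng = np.random.default_rng(0)
        peaks = [Peak("chr1", s, s + 200, 1.0) for s in range(0, 5000, 500)]
        frags = pd.DataFrame(
            {"cell": rng.choice(["a", "b", "c"], 200),
             "chrom": "chr1",
             "start": rng.integers(0, 5000, 200)}
        )
        frags["end"] = frags["start"] + 80
        mat = count_peak_accessibility(frags, peaks)
        assert set(np.unique(mat.to_numpy())) <= {0, 1}
        for cell in ["a", "b", "c"]:
            sub = frags[frags["cell"] == cell]
            for p in peaks:
                hit = any((r.start < p.end) and (p.start < r.end) for r in sub.itertuples())
                assert mat.loc[cell, p.name] == int(hit)


class TestDifferentialPeaks:
    @pytest.mark.parametrize("q,tpm,kept", [(0.01, 25.0, True), (0.01, 15.0, False), (0.2, 100.0, False)])
    def test_fdr_and_tpm_filters(self, config, q, tpm, kept):
        de = pd.DataFrame({"feature": ["p1"], "q": [q], "tpm_first": [tpm]})
        assert (len(differential_peak_filter(de, config)) == 1) is kept


@pytest.fixture(scope="module")
def fixture():
    return make_link_fixture(seed=11)


class TestLinkage:

    def test_planted_links_recovered_with_fdr_control(self, fixture, config):
        rna, atac, pos, ann, truth = fixture
        links = link_peaks_to_genes(rna, atac, pos, ann, config, seed=0)
        assert len(links) >= 45
        retained_true = sum(truth.get(r.peak) == r.gene for r in links.itertuples())
        fdr = 1 - retained_true / len(links)
        assert fdr <= 0.02
        rn, an = _tpm_log(rna), _tpm_log(atac)
        strong = [p for p, g in truth.items()
                  if np.corrcoef(rn.loc[g], an.loc[p])[0, 1] >= 0.8]
        got = set(links["peak"])
        assert sum(p in got for p in strong) / len(strong) >= 0.9
        assert (links["pcc"] > 0).all()
        assert (links["distance_to_tss"].abs() <= config.cre_window_bp).all()

    def test_fully_permuted_data_yields_almost_no_links(self, fixture, config):
        """Exchangeable null: running linkage on RNA with shuffled pseudo-cell
        identities retains at most a couple of links."""
        rna, atac, pos, ann, _ = fixture
        rng = np.random.default_rng(5)
        rna_perm = rna.iloc[:, rng.permutation(rna.shape[1])]
        rna_perm.columns = rna.columns
        links = link_peaks_to_genes(rna_perm, atac, pos, ann, config, seed=1)
        assert len(links) <= 2

    def test_anticorrelated_pair_excluded(self, fixture, config):
        """Reversing one planted peak's accessibility across pseudo-cells
        flips its correlation negative; the link must disappear."""
        rna, atac, pos, ann, truth = fixture
        atac_mod = atac.copy()
        atac_mod.loc["peak000"] = atac.loc["peak000"].to_numpy()[::-1]
        links = link_peaks_to_genes(rna, atac_mod, pos, ann, config, seed=0)
        linked = links.set_index("peak")["gene"].to_dict()
        assert linked.get("peak000") != truth["peak000"]


class TestTFCorrelation:
    def test_proportional_activity_gives_unit_correlation(self):
        cells = [f"c{i}" for i in range(30)]
        labels = np.repeat(list("abcde"), 6)
        rng = np.random.default_rng(0)
        signal = rng.uniform(1, 5, 5)
        per_cell = np.repeat(signal, 6)
        # anchor motifs pin each cell's min/max so the per-cell (0,10)
        # rescale is the same affine map for every cell
        dev = pd.DataFrame({"M1": per_cell, "lo": np.zeros(30), "hi": np.full(30, 20.0)},
                           index=cells)
        expr = pd.DataFrame({"TF1": per_cell + 0.0, "other": rng.uniform(size=30)}, index=cells)
        out = correlate_tf_activity(dev, expr, labels, {"TF1": "M1"})
        assert out.loc[0, "pcc"] == pytest.approx(1.0)

    def test_constant_deviation_skipped(self):
        cells = [f"c{i}" for i in range(10)]
        labels = np.repeat(["a", "b"], 5)
        dev = pd.DataFrame({"M1": np.ones(10)}, index=cells)
        expr = pd.DataFrame({"TF1": np.arange(10.0)}, index=cells)
        out = correlate_tf_activity(dev, expr, labels, {"TF1": "M1"})
        assert len(out) == 0 and out.attrs["skipped"] == ["TF1"]

    def test_missing_motif_listed(self):
        cells = ["c0", "c1", "c2", "c3"]
        dev = pd.DataFrame({"M1": [1.0, 2, 3, 4]}, index=cells)
        expr = pd.DataFrame({"TF1": [1.0, 2, 3, 4]}, index=cells)
        out = correlate_tf_activity(dev, expr, ["a", "a", "b", "b"], {"TFX": "MX"})
        assert out.attrs["skipped"] == ["TFX"]
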