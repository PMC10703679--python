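# Methods

This note documents the models and procedures implemented in `scicomb`, the
assumptions behind them, the parameters that matter, what the synthetic
fixtures do and do not emulate, and the numerical choices that had to be
pinned down where the underlying protocol leaves room.

## Barcode model and demultiplexing

A nucleus is identified by the combination of an RT index (which also
encodes the sample and the primer class), a ligation index and a PCR index;
a UMI tags the molecule. Read 1 carries `[ligation 10 bp | UMI 8 bp |
RT 10 bp]` (offsets are configuration, `ReadLayout`, not code); read 2 is
cDNA; the PCR index is a per-file parameter because sequencers demultiplex
it upstream.

Index matching tolerates at most one mismatched base (`max_barcode_mismatch
= 1`). Distance is Hamming, not Levenshtein, because the indices sit at
fixed offsets; an observed index equidistant from two whitelist entries is
rejected as `ambiguous` rather than assigned at random, which trades a
small loss of reads for zero cross-cell contamination. Rejections are
counted by reason, and `assigned + rejected = input pairs` always.

Tail trimming removes (1) trailing bases below Phred 20 and then (2) the
longest terminal poly(A) run of length ≥ 10 that starts on an A and
contains at most one non-A per ten bases. The run must start on an A so
that a single template base immediately preceding the tail is never eaten.
UMIs are compared exactly; no 1-mismatch UMI collapsing is done (the
alternative is noted as future work — at 8 bp and per-cell read depths in
the hundreds, UMI collisions dominate sequencing errors anyway).

## Read-to-gene assignment

Internally all coordinates are 0-based half-open; GTF (1-based inclusive)
and SAM are converted on ingest. Per gene, TSS = `start` on `+` / `end−1`
on `−`, and the 3′ terminus is the opposite end.

Assignment is a strict priority cascade, reflecting 3′-biased oligo-dT
chemistry:

1. **Sense overlap.** A unique same-strand overlapping gene wins. If
   several overlap, a dT read goes to the gene with the smallest
   `|read midpoint − gene 3′ end|` (ties broken lexicographically by gene
   id so the result is deterministic); a random-hexamer read has no 3′
   anchor and is `ambiguous`.
2. **Upstream rescue.** With no sense overlap, a gene whose 3′ terminus
   lies within 1,000 bp upstream of the read *on the read's strand* is a
   rescue candidate — strand-relative, because dT reads fall just past
   annotated 3′ ends. Multiple candidates are resolved like the tie-break
   (nearest 3′ for dT, ambiguous for randomN); the protocol text does not
   address the multi-candidate case and this mirror of rule 1 is the
   package's choice.
3. **Antisense rescue.** A unique opposite-strand overlapping gene;
   multiple → ambiguous.
4. Otherwise `discarded` (including reads on contigs absent from the
   annotation).

Mates sharing a query name are merged to one fragment (interval union);
duplicates are keyed on (cell, UMI, chrom, fragment start, strand) — the
end is excluded because trimming perturbs it. Exon assignment runs inside
the assigned gene only: unique overlap → that exon; several → maximal
overlap, exact ties → none; none → none (intronic; the gene still counts).
Consequently `Σ exon counts ≤ Σ gene counts` holds structurally.

## QC

The dT and randomN pseudo-cells of one nucleus are merged by summation
after dropping nuclei seen by only one primer class (requiring both is an
effective noise filter: ambient molecules rarely recruit two independent
RT events). Filters are strict inequalities on the merged cell: unassigned
fraction > 0.30, UMIs > 20,000, genes < 200; equality passes. The
unassigned fraction is recomputed from pooled counters, not averaged.
Doublet scoring itself is external; the package applies a strict `score >
threshold` cut.

## Subclustering on gene + exon principal components

Both matrices are normalized `log(1 + 1e5·x/libsize)` per cell. The
embedding concatenates 30 gene-matrix PCs with 10 exon-matrix PCs (block
order fixed, gene first); if a block has lower rank, only the achievable
components are kept and recorded. Clustering is Louvain on a symmetrized
kNN graph (default k = 15, resolution 1.0 — the source protocol does not
print these, so they are explicit configuration). Subclusters whose 2D
centroid distance falls below `min_sep ×` the median within-cluster radius
are merged iteratively, closest pair first; this makes the manual "not
readily distinguishable in UMAP space" step deterministic and testable.

## Differential expression and abundance

Both use the same test: a negative-binomial GLM with log link, a log
offset, dispersion estimated once by moments from the full-model Poisson
fit (`α̂ = Σ[(y−μ)² − μ]/Σμ²`, clipped to [0, 10]; below 1e-8 the model is
Poisson), and a χ² likelihood-ratio test of the full (group + covariates)
against the reduced (covariates) design. This is a re-implementation of
the contract of the commonly cited single-cell LRT; degenerate fits are
flagged, not raised. BH correction is applied over tested features.

For DE the offset is log library size and sex enters as a covariate. For
abundance, the unit is the RT well (a replicate nested in one animal): the
response is cells per subcluster per well, the offset log total cells per
well, so the test is on fractions; sex is a covariate by default
(config-switchable — the protocol states it only for DE). Fold change is
computed on pooled condition fractions with a 1e-5 pseudocount, making
FC(a,b)·FC(b,a) = 1 and 0/0 = 1 exactly. Calls: `up` iff FC > 2 ∧
q < 0.05, `down` for the reciprocal, and subclusters with < 20 cells in
either sex are `excluded` before interpretation.

## NNLS spatial mapping

Signatures are per-type aggregated UMI counts under the same ×1e5 log1p
normalization; spots are normalized identically (the protocol implies but
does not state the identical scale; using one scale is the only choice
that makes a mixture model meaningful). Each spot is decomposed by
Lawson–Hanson active-set NNLS; the package verifies the KKT conditions
(w ≥ 0, gradient ≥ 0 on the zero set, |gradient| ≈ 0 on the support) and
reports the largest violation. Weights are reported raw and as per-spot
proportions; the feature space should be restricted to marker genes for
sharper signatures when used on real data.

## Gene modules

Input is subcluster-level pseudobulk, libsize-normalized and
log-transformed. Genes are kept when the normalized maximum ≥ 1 and
max/median ≥ 5; a zero median is replaced by the smallest positive value
in the matrix, so zero-median genes pass whenever they pass the expression
floor (the filter's intent is variance-driven retention). Retained genes
are embedded with UMAP (cosine, min_dist 0.01, n_neighbors 30) and grouped
by density-peak clustering on the 2D coordinates: Gaussian local density ρ
with bandwidth dc fixed at the 2nd percentile of pairwise distances (the
cited clustering package's default, made explicit for determinism), δ =
distance to the nearest denser point (global peak: maximum distance),
centers at ρ > 1 ∧ δ > 1, remaining points assigned down the
denser-neighbor chain. Thresholds are read on the raw density scale.

## ATAC-side computations

Peak caller scores (−log10 q) are normalized to score-per-million
(`1e6·s/Σs`) and filtered at 1.3; summits are padded ±250 bp and merged
with half-open semantics (already-merged, summitless peaks contribute
their interval unchanged, keeping the merge idempotent). Accessibility is
binary: a cell is accessible at a peak iff any fragment overlaps it.
Differential peaks keep q < 0.05 ∧ TPM > 20 in the target type.

**Peak–gene linkage** works on subcluster pseudo-cells, TPM-normalized and
log1p-transformed in both modalities, with genes and peaks kept when their
maximum TPM exceeds 10. Candidates are (gene, peak) pairs with the peak
*center* within ±500 kb of the TSS (the window anchor on the peak side is
a convention the protocol leaves open). The null distribution comes from
permuting the pseudo-cell identities of the ATAC matrix (one round by
default, per the protocol's singular wording; more rounds can be pooled);
the retention threshold is the smallest positive correlation t with
`#null ≥ t / #observed ≥ t ≤ 0.01`, estimated on the positive tail only
since only positive links are biologically retained. Each peak keeps its
best-correlated gene, and distal peaks (beyond ±2 kb of their own TSS)
whose center falls within ±2 kb of another gene's TSS are dropped.

**TF activity.** Motif deviation scores (computed externally) are min-max
rescaled to (0, 10) per cell, aggregated by group, z-scaled across groups
and correlated with the equally aggregated, z-scaled TF expression; TFs
without a motif mapping or with constant vectors are skipped and listed.

## Aging clock

Within each (animal, cell type), cells are randomly binned into groups of
~15 and averaged on the normalized scale; bins never span animals, so no
pseudobulk mixes ages. One ridge model per cell type predicts ln(age in
months) from standardized features, trained on 80% of pseudobulk cells
with the split stratified *by animal* within each age — unstratified
splitting would leak animal identity between train and test and is
deliberately not the default. The penalty is chosen by 5-fold
cross-validation over `10^(-4..4)` unless fixed by the caller (the
protocol states no penalty). Age acceleration is predicted minus
chronological ln(age).

## Synthetic fixtures: what they emulate, and what they don't

The generators reproduce the *structure* of the data: the barcode layout
and whitelists (synthesized with pairwise Hamming distance ≥ 3, which makes
1-mismatch correction provably unambiguous and 2-error rejection exact —
planted 2-error barcodes are additionally resampled to stay ≥ 2 mismatches
from every whitelist entry); a toy genome containing, by construction, a
same-strand overlapping gene pair, an opposite-strand pair and intergenic
gaps wider than the rescue window; reads planted per assignment category
with known truth; and count matrices with planted clusters (including a
pair differing *only* in exon usage), abundance effects, gene modules,
peak–gene links and ln(age) slopes. Count noise is negative-binomial
(Poisson at dispersion → 0), matching the overdispersion the GLMs assume.

They do **not** emulate sequencer-specific error profiles, ambient RNA,
barcode hopping, chimeric reads, ATAC fragment-size periodicity, or
realistic transcriptome-wide mean-variance relationships. Passing tests
therefore demonstrate that the algorithms are implemented correctly and
behave as specified under their own assumptions — not that those
assumptions hold on any particular real dataset.

## Simulation sizes and numerical choices

Defaults used by the test suite and `scripts/acceptance.py`, chosen as
small as possible while keeping every check statistically meaningful:

- read fixture: 8 nuclei × 2 primer classes × 40–50 reads; oracle
  equivalence on 1,500 randomized reads (≥ 1,000 after deduplication);
- clustering fixture: 3 × 60 cells × 100 genes × 2 exons/gene;
- abundance: 200 null simulations and 25 power simulations of 10
  subclusters, 2 animals × 2 wells × 600 cells per condition;
- NNLS: 4 types × 40 cells, 30 spots, 5% multiplicative noise;
- modules: 4 modules × 50 genes over 40 subclusters;
- linkage: 50 planted links, 100 peaks × 60 genes over 50 pseudo-cells
  (≈ 5,000 candidate pairs);
- clock: 3 ages × 4 animals × 60 cells, 50 signal + 50 noise genes;
- LRT calibration: 2,000 Poisson features at 300 cells (150 per group) —
  at this depth the χ² approximation is accurate enough that a KS test at
  2,000 samples does not detect discreteness artifacts.

Other numerical choices: PCA uses the exact (full SVD) solver, capped at
the matrix rank; UMAP runs with a fixed `random_state` (single-threaded by
construction then); igraph's RNG is seeded before Louvain; NNLS tolerances
are scipy's defaults with KKT violation reported; all thresholds live in
`PipelineConfig` and nowhere else.

## Known limitations

- The NB moment dispersion estimator is noisy for very shallow cells; a
  shrinkage estimator would be better for real data at < 100 cells/group.
- Abundance testing treats wells as independent replicates; a mixed model
  with an animal random effect (or CLR-based compositional analysis) is
  noted as future work.
- Multi-mapping reads are ignored (primary alignments only), and
  transcript-isoform quantification beyond exon counts is out of scope.
- The density-peak dc choice (2nd distance percentile) matters for very
  small gene sets; below ~50 points the module structure should be read
  with care.
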