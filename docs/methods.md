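# Methods

`oligochip` re-implements the computational path of a custom
long-oligonucleotide two-color expression microarray: building a
non-redundant unigene set from EST-like reads, designing one probe per
unigene, screening probes for cross-hybridization, and analyzing the
resulting two-color hybridizations (QC, normalization, differential
expression, replicate power, qPCR cross-validation, and downstream set
analysis). This note records the models, parameter choices and
numerical conventions, and what the synthetic fixtures do and do not
establish.

## EST pre-clustering

Reads are grouped by single-linkage over pairwise local alignments: an
edge joins two reads when the best-scoring local alignment reaches
**90% identity over at least 30 aligned columns** (both thresholds
configurable). Identity is counted over aligned columns including
internal gaps; both strands are compared and the better taken, since
ESTs are unoriented. Cluster ids are the lexicographically smallest
member, so results are independent of input order.

Alignment uses `Bio.Align.PairwiseAligner` in local mode with linear
gap scoring (match +1, mismatch −1.03, gap −2.11). The penalties are
deliberately slightly non-commensurate: no combination of matches,
mismatches and gaps sums to zero, so the optimal alignment's column
composition is generically unique and "identity of the best local
alignment" is well-defined. With round numbers (−1/−2), score-neutral
gap extensions create co-optimal alignments whose identities straddle
the 90% threshold, which makes the clustering rule ambiguous exactly
where it matters.

The 90%/30 bp rule is applied to the single best local alignment, not
to cumulative coverage across multiple alignments; this is a
convention, and the alternative reading would merge slightly more
aggressively.

Low-complexity masking is windowed Shannon entropy (window 16 nt,
threshold 1.2 bits): every position covered by a window below threshold
is masked (replaced by N for alignment, never altered in the output).
The optional dinucleotide-aware mode scores the first-order conditional
entropy H(next base | current base) = H(2-mers) − H(bases), which is ~0
for any short-period repeat — including (ACGT)n, whose plain
mononucleotide entropy is maximal — so a single threshold serves both
modes. Adaptor trimming removes exact terminal matches against a
user-supplied adaptor list only; vendor vector databases are out of
scope.

## Probe design

For each unigene, all windows with length 65 ± 5 nt whose 3′-most base
lies within 1000 nt of the unigene 3′ end are enumerated and annotated
with GC%, nearest-neighbor Tm, and two secondary-structure scores.
Feasible windows satisfy every hard constraint (Tm 67 ± 3 °C,
GC 43 ± 5%, hairpin stem ≤ 8 bp, self-dimer ≤ 12 bp); among them the
probe minimizes

    rank = 1·|Tm − 67| + 1·|GC − 43| + 1·stem + 1·selfdimer + 0.001·dist3′

with a deterministic (dist3′, start) tie-break. Unigenes with no
feasible window are reported as missing genes with a reason
(`too_short` or `no_window_meets_constraints`), and designed + missing
always partitions the input.

**Tm model.** Unified nearest-neighbor thermodynamics
(`Bio.SeqUtils.MeltingTemp.Tm_NN`, table `DNA_NN3`) with the entropic
monovalent-salt correction 0.368·(N−1)·ln[Na⁺] and oligo concentration
50 nM. The default ionic strength is **25 mM Na⁺**. This value was
chosen to make the design target triple self-consistent: under this
model a 43%-GC 65-mer melts at 67.0 ± 2.9 °C, so the Tm window and the
GC window select overlapping probe sets. At physiological or
print-buffer ionic strength (150 mM) the same oligo melts near 76 °C
and the joint constraints (Tm 67 ± 3 **and** GC 43 ± 5) are essentially
infeasible — any vendor model quoting 67 °C for such probes must have
used a lower effective salt (or an equivalent rescaling), and the
parameter is exposed in the config for users who want a different
convention.

**Secondary structure.** Full free-energy folding is out of scope; the
scores are maximal complementary run lengths, computed from a run-length
matrix R[i,j] (longest complementary run whose innermost pair is (i,j))
shared across all windows of a unigene. The hairpin stem score requires
at least `min_loop` = 3 unpaired bases between the arms; the self-dimer
score is the same maximum without the loop constraint (two molecules).
Both are exact (verified against O(n³) enumeration) and invariant under
reverse complement.

## Cross-hybridization screen

A designed probe is flagged against a non-source unigene when **both**
hold strictly: overall identity > 70% and a contiguous exact match
> 20 nt, on either target strand. Overall identity is expressed over
the probe length (matching columns of the best local alignment divided
by probe length), so unaligned probe bases count as mismatches; the
denominator convention is a config switch. The longest common substring
is computed by a vectorized diagonal-run scan. At the package's fixture
scale every probe × unigene pair is evaluated exhaustively; no k-mer
prefilter is needed.

## Two-color QC

Spot tables are a strict subset mapping of GenePix-results conventions
(columns Slide, Block, Row, Column, ID, ControlClass, F_red, B_red,
F_green, B_green, Flag). Manually flagged spots are excluded from every
statistic. Local background (median of the available 1–4 surrounding
regions) is reported but never subtracted.

Background noise is estimated per channel from unflagged
negative-control (NC) spots: a gene is **expressed** when its
foreground strictly exceeds median(NC) + 2·SD(NC) (sample SD, n−1).
Spot **filtering** before normalization uses the stricter threshold
90th-percentile(empty+NC) + 2·SD(empty+NC), which a spot must exceed in
both channels; the percentile and multiplier are config keys. A gene is
"present" across a comparison when at least 5 of its 6 hybridizations
call it expressed. Whether expression calls combine channels by union
or intersection is exposed as an option (per-channel is the default).

## Normalization and differential expression

Spots are mapped to M = log2(R/G), A = ½·log2(R·G). Per slide,
intensity-dependent dye bias is removed by subtracting a lowess fit of
M on A (tricube local linear regression, span 0.4, 2 robustness
iterations, control spots excluded); normalization changes M only,
never A. The statsmodels lowess at zero robustness iterations is
identical (to ~1e-15) to a direct tricube weighted-least-squares
implementation, which the tests exploit.

The dye-swap design makes differential expression a one-sample problem
on dye-corrected ratios (swapped hybridizations enter with sign −1).
Two tests are run:

* **Per-gene linear model** — ordinary one-sample t of the mean
  corrected ratio against 0, BH-adjusted across testable genes. Genes
  with < 2 observations are untestable; a zero SD with nonzero mean
  yields an infinite-t sentinel excluded from the BH pool (its evidence
  comes from the permutation test only). Empirical-Bayes variance
  moderation is deliberately not implemented; the linear-model column
  approximates a moderated fit without shrinkage.
* **SAM-style permutation test** — d = mean/(s + s0) with s the
  per-gene sample SD and s0 the 5th percentile of the s distribution (a
  percentile rule replaces the full s0 search; both the percentile and
  an explicit s0 are config keys). The null distribution flips the
  signs of whole hybridizations (the natural self-self null for a
  dye-swap design; 200 sign-flip draws by default, seeded). The
  per-gene FDR is the median permuted count of |d*| ≥ |d| divided by
  the observed count, capped at 1, then monotonized q-value-style
  (suffix minimum over the |d| ranking) so FDR is non-decreasing as the
  threshold loosens.

Consensus lists are the intersection of the two methods' calls with
per-method provenance retained.

## Replicate power

Per-feature variability is the CV (100·SD/mean) of raw signal across
the six hybridizations of a comparison; CVs are also reported on a
100-based rank scale (ties share mean ranks), with P90 = the CV at rank
90. Power planning uses a two-sided two-sample t test under two noise
models:

* **lognormal** (default, because ratios are analyzed in log space):
  a raw-scale CV maps to log-scale SD σ = √ln(1+cv²); power is the
  noncentral-t tail with df = 2n−2 and ncp = ln(fold)/(σ√(2/n)).
* **additive_cv**: raw-scale group SDs cv·mean (means 1 and fold) with
  Welch–Satterthwaite df.

Inverse planning (minimum detectable fold; maximum tolerable CV) is by
bisection to relative tolerance 1e-4, and the analytic power is
cross-checked by a seeded Monte-Carlo simulation of 1e5 t tests (the
two agree within 0.01). With n = 6 per group and two-sided α = 0.10,
a CV of 35% yields power ≈ 0.95 for a 2-fold change, and a 1.5-fold
change remains detectable at power 0.90 up to CV ≈ 22.6%. The α = 0.01
parameterization is available in the config.

## qPCR quantification

Relative expression of a target X against a panel of ≥ 2 reference
genes is 2^(−(Ct(X) − mean Ct(refs))), the Ct-scale equivalent of
normalizing to the reference geometric mean; one extra cycle halves the
value. Some write-ups print the exponent with a positive sign, which
inverts the Ct-expression relationship; that form is selectable
(`as_printed_positive_exponent`) but the standard negative exponent is
the default. Amplification efficiency is a configurable base (default
2.0). Technical replicates are averaged before normalization.

Reference stability follows the geNorm M statistic: for each candidate,
the mean over other candidates of the SD across samples of their
pairwise Ct difference (= pairwise log2 expression ratio); lower M is
more stable. The default is a single-pass ranking (the top 3 form the
panel); geNorm's iterative worst-candidate elimination is available as
an option. Platform agreement between microarray and qPCR log2 ratios
is the Pearson r plus a separate sign-concordance percentage.

## Downstream set analysis

A gene is tissue-specific when it is up-regulated in that tissue in
both pairwise comparisons involving it. Venn partitioning of three gene
sets produces the 7 disjoint regions (conservation asserted). Term
enrichment is a two-sided Fisher exact test per term on the 2×2 table
(k, n−k, K−k, N−n−K+k) against the array background, BH-adjusted across
terms; two-sided p sums all tables at most as probable as the observed
one, and genes absent from the annotation map count toward n and N but
hit no term. Each gene-term pair counts once (a gene with several terms
contributes to each).

Hybridization profiles are clustered by agglomerative average linkage
on Euclidean distances, implemented directly (O(n³), n ≤ dozens of
hybridizations) so the tie-break — lexicographically smallest cluster
pair — is deterministic; scipy's linkage is used as an independent
cross-check on tie-free instances. Dendrograms export to newick with
ultrametric branch lengths (leaf depth = merge height / 2).

## Synthetic fixtures

All test inputs are generated, seeded, and returned with ground-truth
sidecars sufficient to score every downstream module:

* **Unigenes** — i.i.d. sequences at 43% GC (matching the probe-design
  target composition), lengths 200–400 nt by default; homologous blocks
  are *constructed*: the requested identity over the requested block
  length is realized exactly by placing the exact number of
  substitutions, and a spec that is not exactly realizable raises.
* **Two-color slides** — 6 hybridizations (3 biological replicates × 2
  dyes, alternating dye swaps). Per-gene baseline intensity A ~ U(8,14)
  log2 units; negative-control and empty spots from N(100, 15²)
  truncated at 0; per-observation log2-ratio noise SD 0.3 (the
  calibration condition used throughout); planted log2 folds (default
  ±1, alternating sign) recorded in a truth table; optional smooth dye
  bias as a quadratic in A scaled by an amplitude in log2 units —
  nontrivial for loess yet recoverable.
* **Ct tables** — reference genes with constant expected Ct (offsets
  averaging exactly zero around 20 cycles), targets encoding planted
  folds at 2-fold per cycle, 3 technical replicates, noise SD 0.2
  cycles.
* **Term maps** — independent gene-term draws at density 0.15 over 8
  terms.

The fixtures deliberately omit print-tip/spatial effects, scanner
saturation, heavy-tailed backgrounds and sequence-composition structure
of real transcriptomes. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated generative
model, not robustness to artifacts the model does not contain.

## Problem sizes used by the test suite

Oracle-equivalence tests run at sizes where brute force is exact:
pre-clustering 30 sequences × 100 trials against a full
Smith-Waterman union-find oracle; cross-hybridization 50 unigenes × 50
trials against a double brute-force oracle; Fisher p-values enumerated
for every 2×2 table with N ≤ 60 (using the n↔K symmetry of the
hypergeometric); average linkage ≤ 10 leaves against an O(n³) oracle.
Calibration runs use 1000 genes × 6 hybridizations (20 replicates for
the SAM null). These sizes are the package's validation conditions;
the algorithms themselves have no such limits.

## Known limitations

* The alignment-based rules depend on the scoring convention; the
  shipped scores are a documented choice, not a reconstruction of any
  particular similarity-search tool.
* The SAM s0 percentile rule is a simplification of the original
  s0-search; at desk scale it is deterministic and calibrates well
  (null false-positive proportion ≤ 0.08 at nominal 0.05 in the test
  conditions), but it is not numerically identical to the original.
* Thermodynamic cross-hybridization (duplex ΔG with mismatches), GO
  graph propagation, and consensus assembly of pre-clusters are out of
  scope.
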