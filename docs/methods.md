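# Methods

This note documents the models implemented in `refrank`, the conventions and
defaults chosen where the field's software packages disagree or are silent,
and what the synthetic-data tests do and do not demonstrate.

## Data model and preprocessing

A study is a matrix of cycle-threshold (Ct) values, genes × samples, with
per-sample annotations (group/tissue, treatment, biological and technical
replicate).  Ct is the PCR cycle at which fluorescence crosses threshold;
one cycle ≈ one doubling of template, so Ct lives on a log2 expression
scale.  Missing measurements are NaN throughout — an unparseable cell is
flagged missing on read, never coerced to zero.  Values outside the advisory
10–40 cycle window warn but do not fail (real instruments rarely report
outside it, but truncation would be worse than a warning).

Technical replicates (same cDNA, repeated wells) are collapsed by arithmetic
mean of the non-missing Cts, the universal treatment of within-run
triplicates.  Biological replicates are never averaged — they carry the
variance the stability algorithms measure.

Amplification efficiency `E` per gene comes from a 10-fold dilution standard
curve: `E = 10^(−1/slope) − 1`, slope in Ct per log10 dilution (necessarily
negative; `slope = −1/log10 2 ≈ −3.32` means perfect doubling, `E = 1`).
Relative quantities are `q(g, s) = (1 + E_g)^(Ct_min(g) − Ct(g, s))`.

Conventions chosen here (the originating study reports none):

* **Calibrator** — the per-gene minimum Ct (the most-expressed sample), so
  quantities are scale-free and ≤ 1.  Any other calibrator multiplies a
  gene's quantities by a constant, which every downstream statistic is
  invariant to (tested).
* **Default efficiency** — `E = 1` (classic `2^−ΔCt`) when no standard curve
  is supplied; recorded in output metadata.
* **Missing data** — genes with any missing collapsed Ct are excluded from a
  group's analysis with a warning.  All four algorithms assume complete
  matrices; imputation is out of scope.

## Stability algorithms

All sample standard deviations use the unbiased n−1 denominator.

**geNorm.**  Pairwise variation `V(j, k) = SD_s( log2 q_j(s)/q_k(s) )`;
`M_j = mean_{k≠j} V(j, k)`.  The gene with the largest M is removed and M
recomputed on the survivors until two remain.  The final pair is genuinely
inseparable under this model (their M values are identical — the SD of their
mutual log ratio), so it is reported as a tied pair, ordered
lexicographically and flagged; the tie propagates into consensus aggregation
(below).  Ratios use log base 2; M is invariant to scaling any gene by a
positive constant.  The pairwise-variation curve uses normalization factors
`NF_n` (geometric mean of the top-n genes' quantities):
`V(n, n+1) = SD_s( log2 NF_n/NF_{n+1} )`, with the canonical 0.15 cutoff
recommending the smallest sufficient n (configurable; when no V clears the
cutoff the n minimizing the accumulated SD of `log2 NF_n` is reported
instead).

**NormFinder.**  On natural-log quantities, within each group g the model is
`y_ij = a_i + b_j + e_ij` (gene effect, sample effect, gene-specific error).
Each sample is centered across genes; two-way residuals give per-gene mean
squares `ms_i`, bias-corrected to `s2_i = (ms_i − mean(ms)/(k−1)) · k/(k−2)`
and floored at 0 (an estimated variance below the shared-noise floor is
indistinguishable from zero — visible for designed near-zero-variance genes
in tests).  With G ≥ 2 groups, the per-gene group deviation `d_ig` (from
sample-centered group means, centered across groups) estimates inter-group
bias; it is shrunk toward zero by its sampling variance `c_ig = s2_ig/n_g`
relative to the between-gene spread of deviations, and
`stability_i = mean_g( |d̃_ig| + sqrt(c_ig) )`.  With one group the value
reduces to the estimated intra-group SD.  Centering across genes means a
bias direction shared by most of the panel moves the frame rather than the
biased genes — the standard, documented behaviour of this model family, and
the reason the simulation tests use mixed-sign group effects.

**BestKeeper.**  Works on the raw Ct scale: per gene the SD and
`CV = 100·SD/mean` of Ct; the BestKeeper index is the per-sample geometric
mean of Ct over genes with SD ≤ 1 cycle (exclusion affects index
construction only, not ranking eligibility; if every gene exceeds the cutoff
the index is built over all genes with a warning); each gene is correlated
against the index (Pearson r, two-sided p).  The primary ranking score is
the SD, ascending — matching how the method's output is used as a ranking
input in comparative studies.

**Expression CV.**  Quantities are divided by the all-gene normalization
factor per sample; the score is the CV (percent) of the normalized values.
A gene exactly proportional to the factor scores 0.  Note that for k = 2
the two normalized vectors are elementwise reciprocals, so the "more stable
gene has lower CV" intuition can invert on the raw scale; with k ≥ 3 genes
the measure behaves as intended (tests use k ≥ 3).

Rankings are ordered by score ascending with lexicographic tie-break; tie
groups are recorded explicitly.

## Consensus by Spearman-footrule aggregation

Given m full rankings of k genes with weights `w_l` (default 1,
unweighted), the consensus minimizes
`F(c) = Σ_l w_l Σ_g |pos_c(g) − pos_l(g)|` with 1-based positions.  The
footrule is a metric on permutations with maximum `⌊k²/2⌋` at the reversal.

* **Exhaustive** (k ≤ 10): all k! orderings are streamed in lexicographic
  order and scored in vectorized chunks, so the first optimum found is the
  lexicographically smallest co-optimum (a deterministic, documented
  choice); the co-optimum count is reported.  k = 9 takes ~0.5 s.
* **Assignment**: the objective decomposes over (gene, position) pairs, so
  minimizing a k×k cost matrix `cost(g, p) = Σ_l w_l |rank_l(g) − p|` with
  the Hungarian algorithm yields a global optimum in milliseconds.  Among
  co-optima its choice is solver-dependent; the objective always equals the
  exhaustive optimum (a randomized equivalence suite enforces this).
* **Cross-Entropy Monte Carlo** (any k): orderings are sampled from a k×k
  position-probability matrix (uniform start), the elite fraction refits the
  matrix with multiplicative smoothing, and the search stops after a
  convergence window without improvement.  Defaults: sample size
  `max(100, 10k²)`, elite quantile 0.1, smoothing 0.25, window 7, ≤ 1000
  iterations — standard Cross-Entropy settings scaled to permutation size.
  Seeded and bit-reproducible; results are flagged non-guaranteed-optimal.
  On the embedded 9-gene benchmark tables it attains the exhaustive optimum
  in ≥ 19/20 seeds.

**Ties.**  When an input list declares interchangeable positions (geNorm's
final pair always does), every within-group permutation of the affected
lists is concretized (Cartesian product, bounded by a 64-variant budget) and
aggregated; the lowest-objective variant wins, with equal objectives broken
toward the lexicographically smallest ordering and all co-optimal variants
reported.  Tie groups larger than 3 genes (degenerate inputs) are recorded
but not expanded — the ranking's deterministic lexicographic order stands.

A Kendall-tau distance is exposed as an alternative objective for
exploration but no consensus path uses it.

## Pipeline

Per group (tissue), and once with all groups pooled: collapse → quantities →
enabled methods → rank matrix → tie-aware aggregation → report (one column
per method + Consensus).  Within a tissue the model-based algorithm can use
the treatment arms as its subgroups (default) or treat the tissue as one
group; the pooled analysis always uses tissue as the subgroup variable while
geNorm/BestKeeper/CV pool all samples.  The pipeline runs each algorithm
once — four lists, not six: published six-column tables arise from running
two of the algorithms twice in different software wrappers.  An opt-in flag
emulates that structure by re-running geNorm/NormFinder on a second
preprocessing path (efficiency-uncorrected quantities, E = 1); when no
gene-specific efficiencies are supplied the duplicated columns coincide with
the originals by construction.  A failed group is logged machine-readably
and does not abort the others.  All randomness flows from the config seed;
re-running a config writes bit-identical outputs.

## Synthetic data

The simulator emulates the motivating design — 9 genes × 4 tissues × 2
treatments × 3 biological × 3 technical replicates — with Gaussian noise on
the Ct scale (log-scale expression noise, the conventional qPCR error
model):

    Ct = baseline_g + tissueShift_g(tissue) + treatEffect_g·1[treated]
         + bioNoise(residual_sd_g) + techNoise(technical_sd)

The default parameters are derived from the embedded benchmark mean-Ct
table: baselines are the per-gene grand means (≈ 23–31 cycles), tissue-shift
SDs the spread of each gene's four tissue means (≈ 0.7–2.4 cycles),
treatment effects the mean chromium-minus-control shifts, and biological
residual SDs `√3 ×` the mean printed SEMs (triplicate SEM back-converted to
per-replicate SD, ≈ 0.05–0.5 cycles); technical scatter is 0.15 cycles, a
typical within-run triplicate value.  The ground-truth record keeps every
drawn effect and the implied total SD per gene
(`√(tissue² + p(1−p)·effect² + residual² + technical²/n_tech)`), hence the
designed stability order.

**The recovery benchmark** (`designed_best_gene_spec`) gives one gene a 10×
smaller noise SD than the rest and places the separation entirely in the
independent per-sample residual component (1.0 vs 0.1 cycles; tissue and
treatment effects zero).  Two deliberate reasons: per-gene tissue shifts
drawn from only four tissues have 3 degrees of freedom, so the *realized*
stability order would frequently contradict the designed one (a broken
benchmark, not a harder one); and a deterministic treatment response shared
by the unstable genes would make them co-regulated, which pairwise-ratio
methods cancel by construction — the well-known co-regulation blind spot.
Under this design the designed gene reaches consensus rank 1 in ≥ 95% of
100 seeded study-sized runs, and rank 1 per method for NormFinder,
BestKeeper and expression CV; for geNorm the meaningful event is membership
in the tied final pair, since the pairwise model cannot separate its last
two genes.

What the synthetic tests do **not** show: real Ct data have non-Gaussian
tails, plate/batch effects, efficiency miscalibration, and co-regulated
panels — none of which the simulator emulates.  Passing recovery tests
demonstrates algorithmic correctness under the stated error model, not
field performance on any particular tissue panel.

## Numerical choices and degenerate inputs

* Sample SD: n−1 denominator everywhere; log base 2 for geNorm ratios and
  natural log inside NormFinder (results are base-invariant within a method
  up to constant factors).
* All-constant (zero-variance) matrices: every score 0, ranking =
  lexicographic order, a warning, no crash.
* Variance floor: NormFinder's bias-corrected per-gene variance is floored
  at 0; near-zero true variances therefore report as 0.
* Floating-point objective comparisons use a 1e-9 absolute tolerance
  (objectives are sums of small integers times weights).
* Consensus co-optima: deterministic lexicographic selection, count
  reported.  Positions are 1-based everywhere.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run exhaustive 9! aggregation on
the five embedded benchmark tables, a 200-instance randomized
brute-vs-assignment equivalence suite (k ≤ 8, m ≤ 10), 20-seed Cross-Entropy
cross-checks at k = 9, 100-seed recovery simulations at the study's own
replication (9 × 72 wells), and a 10⁴-replicate variance-calibration check
of the simulator — sizes chosen so every check completes in seconds while
keeping the estimates' sampling error well below the asserted margins.

## Known limitations

* Partial (top-j) lists are not aggregated; every input must rank the full
  panel.
* NormFinder scores are this package's implementation of the published
  model; other implementations differ in small estimator details, so scores
  should be compared within a run, not across programs.
* BestKeeper's descriptive statistics are computed on Ct directly; genes
  with constant Ct have undefined correlation to the index (reported NaN).
* The expression-CV measure is scale-dependent (raw quantities); it is kept
  because it mirrors the qBase-style quality measure, not because it is the
  best-behaved statistic of the four.
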