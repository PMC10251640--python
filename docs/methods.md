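# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `drsdecay`. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## 1. The degradation model

A molecule of length `L` (nt) exposed for `t` hours to a homogeneous
cleavage hazard `λ` (per nt per hour) accumulates `N ~ Poisson(λtL)` cuts
at independent uniform positions. Each cut independently destroys the 3′
adaptability (poly(A) loss) with probability `p`; a molecule that loses
its 3′ end is unsequenceable. Otherwise the sequenceable fragment is the
suffix from the 3′-most cut to the 3′ terminus (the whole molecule when
`N = 0`), discarded when shorter than `min_read_len`. This is the minimal
generative model that reproduces the three signatures of degradation in
DRS libraries: a length-dependent decline of full-length reads
(`P(full) = e^{−λtL}`), a 3′-biased gene-body profile, and a detection
deficit confined to long features. The vectorized sampler draws the
3′-most cut directly as `L·U^{1/N}` (the maximum of `N` uniforms); the
test suite checks that this matches the scalar per-cut routine in
distribution and that both reproduce the closed forms
`P(full) = e^{−μ}` and `E[suffix] = L(1−e^{−μ})/μ`, `μ = λtL`.

Degradation from the 5′ side or internal-only nicking without 3′ loss is
not modelled separately: any cut pattern collapses to (suffix survives /
molecule lost), which is all that matters for what DRS can sequence.

## 2. Simulator defaults (the study conditions)

| parameter | default | meaning / rationale |
|---|---|---|
| `times_h` | 0, 0.5, 1, 4, 6, 8 | six time points of a freeze–thaw series (the merged 3–4 h point is placed at 4 h) |
| `replicates_per_time` | 3,2,2,3,3,2 | 15 samples, ≥2 per time point, from 3 replicate series (= batches) |
| `lambda_cleave` | 2×10⁻⁴ /nt/h | sets μ ≈ 2 for a median-length (~1.3 kb) transcript at 8 h, giving relative coverage-fraction declines of the magnitude seen in real degradation series; the absolute scale of λ is not identifiable from published summary tables, so this calibration is heuristic |
| `p_polya_loss_per_cut` | 0.2 | each cleavage has a 20% chance of rendering the molecule unsequenceable; drives the library-complexity loss for long features |
| `min_read_len` | 100 nt | ONT cannot usefully basecall shorter fragments; prevents a spurious ultra-short read mode |
| `spike_frac` | 0.10 | spike-ins at 10% of reads, Mix A in 0 h samples, Mix B elsewhere, never degraded (added after the time series) |
| `batch_sd` | 0.1 | lognormal per-(batch, feature) expression multiplier, fixed across the series — the replicate signature seen on a PCA's second component |
| `batch_deg_sd` | 0.2 | lognormal per-batch degradation-severity multiplier: replicate series degrade at different rates |
| `sample_deg_sd` | 0.25 | lognormal per-sample severity multiplier: individual samples at the same nominal time differ in realized degradation. This is what makes measured RIN informative beyond the categorical time factor; without it pseudo-RIN is an exact function of time × batch and the RIN-corrected design is numerically singular |
| `rin_noise_sd` | 0.02 | instrument repeatability of the RIN reading |
| `gc_fragility` | 1.5 | per-transcript hazard multiplier `exp(−1.5(GC − mean GC))`: low-GC transcripts degrade faster, planting the architecture association the decay analysis is meant to detect (length dependence needs no planting — it is intrinsic to 3′-anchored cleavage) |
| `p_secondary` | 0.15 | fraction of reads from multi-isoform genes emitting one secondary alignment to a sibling isoform at 0.90–1.00× the primary score, exercising the NanoCount-style filter and the EM |
| `n_reads_per_sample` | 50 000 | desk-scale library size; all acceptance checks pass at this depth, and individual analyses raise it where precision requires (200k for hazard recovery, 250k for the 5000-feature DE comparison) |

The pseudo-RIN map is `RIN = 2 + 7.8·e^{−c·λt}` with `c` calibrated so an
intact sample reads 9.8 and the configured final time ≈ 7.25, emulating
the 9.8 → 7.25 decline of the reference series; it is strictly decreasing
with asymptote 2.

**Spike-in truth.** Mixes A and B swap concentrations within spike pairs
(one member `+l`, its partner `−l` log2 units, magnitudes 0.5/1/2/3), so
the two mix totals balance exactly and the nominal fold changes are
realized without a global renormalization offset; one third of spikes are
nulls shared by both mixes.

**What the simulator does not emulate** — and hence what passing tests do
*not* establish about real data: basecalling error and alignment noise
(scores are idealized suffix lengths), poly(A)-tail variation,
pore-blocking throughput effects, 5′-degraded-but-3′-intact partial reads
from internal priming, library-prep truncation of intact samples (a real
0 h DRS library has median coverage ≈ 0.7, the simulator's exactly 1.0),
and transcription during the time series (the simulated "up" cluster is
only relative enrichment of stable features).

## 3. Integrity metrics conventions

- Aligned length is the reference span (`target_end − target_start`) of a
  read's best alignment (highest score; ties → longer span → smaller
  transcript id), compared against the annotated isoform length and
  clipped to ≤ 1.
- The 95% full-length boundary is inclusive and evaluated in integer
  arithmetic (`span·100 ≥ 95·L`), so no platform-dependent float drift at
  the boundary; end windows are inclusive too (≤ 25 nt 5′, ≤ 50 nt 3′).
- Medians use the even-count midpoint convention.
- All per-sample metrics are computed over pass reads (mean Q ≥ 7 where
  the source provides it; the simulator emits all-pass) using each read's
  best primary alignment.
- N50 is read-length based (the common sequencing-summary convention);
  whether published tables used aligned length instead is not always
  stated.
- Features-per-1M uses a single seeded subsample of 10⁶ best alignments
  (all reads, flagged, when fewer are available) rather than a
  rarefaction curve: reproducible and cheap.
- Gene-body coverage rescales each transcript's per-base coverage onto
  100 positional bins (5′ = bin 0), averages across transcripts with ≥ 1
  read, and normalizes the peak bin to 1.
- Reverse-strand transcriptome hits are dropped at parse time (DRS is
  strand-of-origin) and reads assigned to unannotated references are
  excluded from metrics but counted.

## 4. Quantification

The NanoCount-style filter drops alignments ending > 50 nt from the
annotated 3′ end, then, per read, alignments scoring < 95% of the read's
best surviving score; reads with no survivors leave quantification. The
EM then assigns each multi-aligned read across its surviving targets in
proportion to current abundance estimates (uniform start, convergence
when the largest abundance change < 10⁻⁶, cap 100 rounds). Expected
counts per sample sum to the number of quantified reads; TPM uses the
annotated length as effective length (DRS reads are whole molecules, not
fragments). Gene counts are isoform sums, or plain primary-alignment
tallies in simple mode — the latter is used for the large DE simulations
where isoform ambiguity is switched off.

Note that cross-sample *concordance* of a quantifier is not the same as
its *accuracy*: a naive best-hit counter resolves ambiguity identically
in every sample and can look more self-consistent between time points
than the EM, precisely because the EM adapts to sample-specific (and
degradation-shifted) abundance estimates. The test suite demonstrates
this inversion under high ambiguity.

## 5. Differential expression

Per feature: `K ~ NB(mu, alpha)`, `log mu = log s + Xβ`, size factors by
median-of-ratios (geometric-mean-1 rescaling; positive-count fallback
with a warning when no feature is everywhere-positive). The design is
intercept + time (categorical, 0 h reference) + batch (categorical), and
optionally RIN as a centred numeric covariate (centring reduces
collinearity with the intercept; time and RIN remain strongly correlated
by design, which is exactly why the RIN model absorbs degradation
signal). Features enter testing when they have ≥ 10 normalized counts in
≥ 5 samples.

Fitting is a batched IRLS across features (one shared design matrix;
per-feature 9×9 normal equations solved in a single stacked
`np.linalg.solve`), initialized from a log-linear least-squares fit, with
the linear predictor clipped to ±30. Dispersion: a Poisson-level fit
gives working means; method-of-moments dispersions fit a log-linear trend
against the mean; the per-feature profile MLE (log-grid search with two
refinement rounds, floor 10⁻⁸, ceiling 50) is shrunk toward the trend
with weight `n/(n+4)` on the log scale. This moderation is a lightweight
stand-in for the shrinkage machinery of dedicated DE packages — an
approximation, not an equivalence; the test suite cross-checks
coefficients against per-feature statsmodels NB-GLM fits and the full
pipeline against pyDESeq2 on a small run (log2FC correlation > 0.98).

Wald tests use the normal reference. No separate scale parameter is
estimated out of the statistic, so no Student-t correction applies; on
intact-series null simulations the raw p < 0.05 fraction is within three
binomial standard errors of 0.05 (an early experiment with a t(n−p)
reference was conservative by nearly a factor of three and was dropped).
p-values are BH-adjusted per contrast over tested, converged features;
non-convergent features are flagged and excluded from the BH denominator.
Fold changes are reported in log2. Contrasts whose MLE diverges (a time
level with zero counts) are excluded from the clustering input — those
features belong to the undetectable-feature analysis.

Spike-in validation regresses observed on known log2 fold changes. The
default observed value is the *pooled* contrast — the average of all
non-reference time coefficients — because the mix switch is shared by
every non-reference sample, making this the efficient estimate of the mix
effect; per-time validation is available and used for the per-time-point
slope checks. Significance tallies used to quantify degradation-induced
false DE exclude the spike-ins, which carry true mix fold changes by
construction.

## 6. Decay analysis

Clustering runs K-means with k = 4, 25 seeded restarts, ≤ 100 iterations,
keeping the lowest within-cluster sum of squares. Clusters are named from
their centroids: "stable" has the smallest mean |log2FC| (a rule that
replaces any run-specific cluster numbering); among the rest, "up" has
the largest and "fast" the smallest final-time value, "slow" is the
remainder. Normalized trajectories subtract the stable centroid, which
cancels any common compositional drift `c(t)`; the invariance is tested
for drifts small enough not to change which cluster is stable.

Undetectable features require (i) ≥ 5 normalized counts in ≥ 4 of the
first five samples — the samples at the two earliest time points, or the
earliest five by time when the design does not give exactly five; (ii)
zero normalized counts in every final-time sample; (iii) a nonlinear
least-squares exponential fit `y0·e^{−kt}` (initialized from a log-linear
regression on positive counts, `k ≥ 0` enforced by bounds) whose
observed-vs-fitted Pearson r ≥ 0.5. The correlation convention is
ambiguous in common usage, so counts-vs-time is available behind
`r_mode="time"`; observed-vs-fitted is the default. Fit non-convergence
fails criterion (iii).

Architecture association: one-way ANOVA of GC fraction and UTR5/UTR3/CDS/
total lengths across the four clusters, outliers included; η² =
SS_between/SS_total (decomposition verified to 10⁻⁹ against brute force);
Tukey HSD for all six pairs, with pairs involving a cluster of < 2
members flagged. Gene-level architecture uses each gene's longest
isoform; GC is skipped with a warning when no FASTA was available.

## 7. Problem sizes

Test-suite and acceptance-script runs use desk-scale sizes chosen once:
closed forms at 10⁵ molecules; hazard recovery at 2×10⁵ reads (relative
error ≲ 2%, bound 10%); the degradation-signature checks on the default
15-sample series at 50k reads/sample; the DE comparison at 5 000
single-isoform features × 15 samples at 250k reads/sample (batched GLM
fits take seconds); null calibration at 2 000 features. Published
dataset-level numbers (absolute N50s, DE counts, cluster sizes) derive
from ~15 full DRS flow cells and are not reproducible at these scales;
the package instead reproduces the arithmetic identities of those tables
exactly and the qualitative phenomena as ordered inequalities.

## 8. Known limitations

- λ's absolute scale is a heuristic calibration to a plausible RIN
  decline; only the shape of the length dependence is identified.
- The dispersion moderation is intentionally simple; extremely low
  replicate numbers per level (n = 2) leave per-contrast power limited,
  and the RIN-corrected model trades power for bias removal (more false
  negatives among weak spike-in fold changes — visible in the worked
  example).
- Pseudo-RIN is a monotone transform of the true per-sample hazard plus
  small noise; real RIN is an electrophoretic summary whose relation to
  sequenceability is messier.
- The single-isoform re-analysis is supported by filtering annotation and
  alignments to single-isoform genes; genome-space BED intersection
  semantics (reads merely overlapping vs contained) are not reproduced —
  assignment is by transcript id.
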