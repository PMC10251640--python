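# drsdecay

Degradation-aware analysis of Oxford Nanopore **direct RNA sequencing
(DRS)**: integrity metrics, filtered isoform quantification, RIN-corrected
differential expression, and degradation-trajectory clustering — driven
end-to-end by a 3′-anchored degradation simulator, so every stage can be
exercised and validated without external data.

## Why

DRS sequences native RNA molecules 3′→5′ and requires an adaptable
(poly(A)) 3′ end, so only fragments that retain the annotated 3′ terminus
are sequenceable. Partial RNA degradation — ubiquitous in post-mortem,
clinical and field samples — therefore truncates reads from the 5′ side,
depletes long transcripts, biases libraries toward short genes and
isoforms, and masquerades as differential expression (DE) in time-course
or case/control comparisons. This package is for transcriptomics analysts
who need to (a) quantify how degraded a DRS library is from its
transcriptome alignments alone, and (b) remove the degradation signal from
a DE analysis by conditioning on the RNA integrity number (RIN).

## The model

**Degradation.** A transcript of length `L` exposed to cumulative
per-nucleotide cleavage hazard `λt` receives `N ~ Poisson(λtL)` cuts at
uniform positions; each cut destroys 3′ adaptability with probability `p`;
a surviving molecule yields a suffix read from the 3′-most cut to the 3′
terminus. Two closed forms anchor the simulator and the hazard estimator:

```
P(full-length read) = exp(−λtL)
E[suffix length]    = L · (1 − e^{−μ}) / μ,   μ = λtL
```

so `−log(full-length fraction)` is linear in `L` with slope `λt`, which
`estimate_lambda_t` exploits to recover the hazard from alignments.

**Integrity metrics.** Per read: coverage fraction = best-alignment span /
annotated isoform length; full-length if ≥ 95% coverage (or within 25 nt
of the 5′ and 50 nt of the 3′ end). Per sample: N50, median aligned
length, full-length percentages, median read/isoform coverage fractions,
features detected per million reads, meta-transcript gene-body coverage.

**Quantification.** NanoCount-style filtering (drop alignments ending
> 50 nt from the 3′ end, then alignments scoring < 95% of the read's best)
followed by EM assignment of multi-mapping reads in proportion to current
abundance estimates.

**Differential expression.** Per feature `i`, sample `j`:

```
K_ij ~ NB(mu_ij, alpha_i),   log mu_ij = log s_j + x_j' beta_i
```

with median-of-ratios size factors `s_j` as offset and design
`~ time + batch` or `~ RIN + batch + time` (time categorical vs 0 h, RIN a
centred numeric covariate). Dispersions are profile-ML estimates moderated
toward a mean-dispersion trend; Wald tests per time contrast,
BH-adjusted. Two-mix spike-in controls with known concentration ratios
validate that RIN correction removes degradation-induced DE without
destroying true fold changes.

**Decay analysis.** K-means (k=4) on per-time log2 fold-change
trajectories gives up/stable/slow/fast classes; trajectories are
normalized by subtracting the stable-cluster centroid (removing
compositional drift); features absent at the final time point are called
undetectable when they were present early, are zero in all terminal
samples, and follow an exponential decay `y0·e^{−kt}` with observed-vs-
fitted Pearson r ≥ 0.5; cluster membership is tested against gene/isoform
architecture (GC, UTR/CDS/total lengths) by one-way ANOVA with Tukey HSD
and eta-squared effect sizes.

## Worked example

Simulate a 15-sample degradation series (six time points over 8 h,
spike-ins at 10% of reads), count reads per gene, and fit DE with and
without RIN:

```python
import drsdecay as dd
from drsdecay.quantify import build_count_matrix, primary_gene_counts
from drsdecay.de import DegradationDEModel, spikein_validate

txome = dd.simulate_transcriptome(n_genes=1000, seed=0)
run = dd.simulate_experiment(dd.SimConfig(n_reads_per_sample=50_000, seed=0), txome)

counts = build_count_matrix({
    s.sample_id: primary_gene_counts(run.alignments[s.sample_id],
                                     run.transcriptome.transcripts)
    for s in run.samples
})
for rin in (False, True):
    results = DegradationDEModel(counts, run.samples, include_rin=rin).fit()
    print(results.summary())
    sv = spikein_validate(results, run.truth.spike_truth)
    print(f"  spike-ins: slope={sv.slope:.2f}  rho={sv.spearman_rho:.2f}  "
          f"true DE found={sv.n_true_de_detected}  false positives={sv.n_false_positive}")
```

Output:

```
Degradation differential expression (NB GLM, Wald)
  design: ~ time + batch   (reference time 0 h)
  samples: 15   features tested: 816 / 1060
      contrast   n signif (padj<0.05)
         0.5 h                     38
           1 h                     35
           4 h                    149
           6 h                    227
           8 h                    215
  spike-ins: slope=1.01  rho=0.98  true DE found=35  false positives=11

Degradation differential expression (NB GLM, Wald)
  design: ~ time + batch + rin   (reference time 0 h)
  samples: 15   features tested: 816 / 1060
      contrast   n signif (padj<0.05)
         0.5 h                     35
           1 h                     34
           4 h                     26
           6 h                     24
           8 h                     21
  spike-ins: slope=1.04  rho=0.95  true DE found=26  false positives=0
```

No biological expression change was simulated, so every significant
endogenous gene in the uncorrected model is a degradation artifact (169 of
the 215 calls at 8 h; the rest are spike-ins, which carry real mix fold
changes). Adding RIN to the design removes all 169 endogenous artifacts —
the 21 remaining calls at 8 h are exclusively spike-ins — while the known
spike-in fold changes are still recovered with slope ≈ 1 and Spearman
ρ ≥ 0.95 and zero spike-in false positives.

A shell-level pipeline is available as `drsdecay simulate / metrics /
quantify / de / decay`; see `drsdecay --help`.

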