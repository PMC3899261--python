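# Methods

## Data model

Well-level threshold cycles are held in long format as
(sample, gene region, replicate well, Ct), with per-sample metadata (group,
reverse-transcription primer). A well that never crossed threshold within
the cycling protocol (default 40 cycles) is an explicit *undetermined*
sentinel, distinct from an absent row; replicate collapsing excludes
undetermined wells from the aggregate and yields undetermined only when all
wells are. Replicates collapse by the arithmetic mean of Ct (median
available for robustness); a finite-well spread above `max_spread`
(default 1 cycle) sets a QC flag but never drops data — QC issues are
flags, not failures. Two independent instrument runs are merged by
averaging the collapsed Cts cell-wise.

A *mask* is a set of (group, region) pairs excluded from stability ranking
while remaining available to quantification. Its motivating use is
RT-chemistry incompatibility: cDNA primed with oligo-dT under-represents
template far from the poly-A tail, so CDS-region measurements in an
oligo-dT-primed group are not comparable with the rest of the panel and
must not feed the stability statistics. Masking is flag-only; stored Ct
values never change.

## Quantification

Standard curves are ordinary least squares of Ct on log10(quantity) over a
dilution series (default five decade steps, 100…0.01; at least 3 points;
no weighting). Efficiency is E = 10^(−1/slope) − 1; a non-negative slope is
rejected as physically impossible. Unknowns invert the line,
Q = 10^((Ct − intercept)/slope); the inverse round-trips to < 1e−9.
A region lacking a curve may use an assumed efficiency E, with
Q = (1+E)^(meanCt − Ct) anchored at the region's mean Ct; the anchor is
arbitrary and irrelevant because every downstream statistic is invariant to
a per-region scale factor. Provenance (`from_standard_curve` vs
`assumed_efficiency`) is recorded per region.

The CDS/3′-UTR template ratio uses the exponential-amplification inversion
Q0 = T/(1+E)^Ct with T the fluorescence threshold (default 0.3). T cancels
when shared between the two amplicons but is carried explicitly. Group
summaries (mean, SD with n−1) cover unmasked samples only.

## Stability statistics

All three statistics see only differences of log-scale expression between
genes, so a global per-sample factor (cDNA input, pipetting) cancels
exactly — this is asserted in the test suite, not just assumed.

**geNorm.** V_jk is the n−1 standard deviation across samples of
log2(Q_j/Q_k), computed pairwise-complete (only samples where both regions
are usable; minimum 2). M_j averages V_jk over the other active regions
(active set ≥ 3). Stepwise ranking removes the largest-M region and
recomputes until three remain; M ties within 1e−12 (the numerical noise
floor of the optimized covariance-based implementation) break by removing
the lexicographically last name, logged in the trace. The retained trio is
reported as a set with one M — the mean of the three members' final M
values — mirroring the one-number-per-trio presentation of published
rankings. NF_n is the per-sample geometric mean of the n best regions;
V_{n/n+1} is the n−1 SD of log2(NF_n/NF_{n+1}) for n = 2…k−1, and the
smallest n with V below the cutoff (default 0.15) is reported as
sufficient; when V_3/4 is below the cutoff the verdict string is
"3 genes sufficient".

**NormFinder.** Within each group, log2 quantities follow an additive
two-way layout y_ij = gene_i + sample_j + e_ij with gene-specific
Var(e_ij) = σ²_i. With k genes and n samples, the per-gene mean square v_i
of the two-way residuals satisfies E[v_i] = (1 − 2/k)σ²_i + σ̄²/k, giving
the unbiased method-of-moments estimator
σ̂²_i = k/(k−2)·(v_i − v̄/(k−1)), truncated at 0 for reporting (k ≥ 3
required). The inter-group deviation d_ig subtracts the group's gene-mean
(so Σ_i d_ig = 0 within every group) and then each gene's across-group mean
(equal group weights). The variance γ² of the true deviations is estimated
by moments (Σd̂²/((G−1)(k−1)) minus the mean squared standard error,
truncated at 0) and d̂ is shrunk by γ²/(γ² + σ̂²_ig/n_g). The per-group
stability is |d̃_ig| + sqrt(σ̂²_ig/n_g) — systematic-bias magnitude plus
intra-group standard error — averaged over groups; we use the standard
error rather than the posterior SD of the shrinkage model because the
latter collapses to 0 whenever γ̂² truncates at 0 (the no-group-effect
case), which would erase the intra-group component exactly where it is the
only signal. Single-group mode sets all d to 0 and ranks by the
(untruncated) corrected residual variance, which is an increasing affine
map of the raw residual variance. Pair stability treats the average of two
genes as a pseudo-gene: d_pair = (d_a+d_b)/2 (opposite deviations cancel),
σ²_pair = (σ²_a+σ²_b)/4 under independent errors, same shrinkage and
formula; for i.i.d. equal-variance genes this sits at 1/√2 of the single
stability. NormFinder needs complete matrices; regions with missing or
masked cells in the analyzed samples are dropped with a warning (consequence:
with the FB CDS mask active, CDS regions leave the overall NormFinder
ranking — a documented trade-off of masking within a complete-data model).
Log base 2 is used throughout; any fixed base gives identical rankings.

**ΔCt.** Pair SD is the n−1 SD of Ct_j − Ct_k over shared finite,
unmasked samples; a gene's score averages over partners; ranking is
ascending with lexicographic tie-break. Pairs with < 2 shared samples are
omitted and flagged; a gene with no valid pair is dropped with a warning.
Efficiency differences between amplicons are *not* corrected — the method's
known limitation, accepted in exchange for needing no standard curves. With
quantities defined as 2^(−Ct), geNorm's V_jk equals the ΔCt pair SD
exactly; the suite asserts this bridge to 1e−12. An optional pre-filter
keeps one amplicon per gene symbol (smallest Ct interquartile range) to
avoid inflating apparent stability with trivially correlated homologues.

## Workflow

The screening pipeline runs: (1) ΔCt on the whole panel (no curves) and
keeps the best `keep` regions (default 6; `keep=None` bypasses the screen);
(2) standard-curve quantification of the kept panel; (3) geNorm and
NormFinder overall and per group — per-group analyses subset samples but
reuse the global curves (a curve is a property of the primer pair, not of
the group), and per-group NormFinder runs in single-group (intra-group)
mode; (4) NF_n from the geNorm top-n (default 3) and the V_{n/n+1}
sufficiency verdict. Reports are one machine-readable JSON plus a Markdown
summary and ranking CSVs, written without timestamps so identical inputs
and seed reproduce byte-identical files.

Target normalization divides the target's quantity by the reference NF
(missing components propagate; the target may not be in the reference
set). The robustness comparison normalizes the same target by a best and a
worst reference set and reports the per-sample ratio (its median = the
systematic fold offset, max/min = its spread) and the within-group Pearson
correlation of the two log profiles: scale shift with preserved profile is
the expected signature when swapping references that differ in level and
noise but not in sample-rank behaviour. The post-normalization CV of a
reference is SD/mean across samples of Q_region/NF(full set); the CV
definition is deliberately self-referential (each reference divided by its
own set's NF) because that directly measures the residual variation
normalization leaves behind.

## Synthetic data

The generator is additive on the Ct scale — equivalently multiplicative,
log-normal, on quantities, matching the error structure the statistics
assume: Ct = base + group shift + optional per-sample profile + loading
(per-sample global, N(0, loading_sd)) + gene noise (per sample×region) +
well noise, plus a fixed RT-bias offset on CDS regions of oligo-dT-primed
groups. Dilution series derive from each region's true efficiency with well
noise only. All draws come from one seed; identical specs give identical
tables.

The study-like preset has 4 groups of 4/6/4/2 samples (16 total) and 17
regions over 8 genes, with base Cts spanning ~21 (HIS_cds) to ~29
(bTUB_utr2) so median Cts span ≥ 6 cycles; per-gene amplification
efficiencies drawn uniformly in [0.91, 1.12]; gene noise 0.15–0.6 cycles
encoding a stable core (HIS_cds, SAND_utr, TIP_utr, EF1a) and an unstable
tail (bTUB_utr2/3, ACT_utr2) with tissue-dependent shifts; loading SD 0.3;
well SD 0.15; and +1 cycle RT bias on CDS amplicons in FB, depressing the
apparent CDS template to roughly half. Efficiencies are shared within a
gene (overlapping amplicons of one transcript) so the CDS/UTR template
ratio isolates the RT-bias effect instead of conflating it with
primer-efficiency differences; the ANX pair, whose two amplicons have
matched baseline abundance, is the designated readout for that effect.
The ground truth records the injected instability (gene noise plus
size-weighted group-shift dispersion, including RT bias on CDS regions),
true efficiencies and latent loading effects for parameter-recovery tests.
A benchmark variant zeroes all shifts and sets uniform low noise except one
noisy region, making the least stable region known by construction. A
targets variant adds two cold-inducible genes (CBF2/CBF4-like) sharing a
seasonal per-sample profile peaking in the December flower-bud sample.

What the generator does *not* emulate: PCR inhibition and efficiency drift
between runs, melting-curve artefacts, inter-run batch effects beyond the
single loading term, non-Gaussian outlier wells, and correlated expression
between genes beyond the shared loading and group structure. Passing tests
therefore demonstrate correctness of the statistics and the pipeline's
behaviour under the assumed error model, not robustness to every instrument
pathology.

## Numerical choices and problem sizes

SDs use the n−1 denominator everywhere. geNorm's fast path computes all
pairwise variances from one covariance matrix (Var(x_j−x_k) =
S_jj+S_kk−2S_jk) when data are complete, falling back to a
pairwise-complete loop otherwise; tests verify both against independent
double-loop oracles to 1e−12 (geNorm) and 1e−10 (NormFinder ANOVA
decomposition). Negative variance estimates truncate at 0. Repeated-
simulation checks use 100 seeds for recovery and robustness properties and
20–50 seeds for secondary properties, with the 16×17×3 study-scale design
throughout; these sizes give stable pass/fail margins while the full suite
runs in well under a minute.

## Known limitations

- NormFinder drops incomplete regions instead of modelling missingness.
- The assumed-efficiency quantification path anchors at the region's mean
  Ct; absolute quantities from that path are not comparable across regions
  (ratios within a region are).
- ΔCt inherits no efficiency correction by design.
- The generator's RT bias is a fixed cycle offset, not a transcript-length
  model.
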