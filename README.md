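# qpcrnorm

Reference-gene stability evaluation and normalization for RT-qPCR.

Relative quantification by real-time PCR stands or falls with the choice of
reference ("housekeeping") genes: a target's transcript level is reported
relative to a normalization factor built from genes assumed stable across
the samples, and an unstable reference silently distorts every downstream
fold change. `qpcrnorm` implements the full validation workflow a lab runs
on a candidate panel — here modelled on a woody-plant study design with 16
tissue samples in four groups (flower bud FB, flower organs FO, fruit flesh
FF, fruit skin FS) and 17 candidate amplicons from 8 genes — together with a
synthetic Ct generator with known ground truth, so the whole pipeline is
testable without instrument data.

## What it computes

**Standard-curve quantification.** A decade dilution series (relative
quantities 100, 10, 1, 0.1, 0.01) gives the calibration
Ct = intercept + slope·log10(Q); amplification efficiency is
E = 10^(−1/slope) − 1 (E = 1 ⇔ perfect doubling, slope −3.32), and unknown
Cts invert the line: Q = 10^((Ct − intercept)/slope).

**Three stability statistics**, each invariant to per-sample loading:

- *geNorm*: V_jk = SD over samples of log2(Q_j/Q_k); M_j = mean V_jk over
  partners; stepwise elimination of the highest-M region down to a trio.
  V_{n/n+1} = SD of log2(NF_n/NF_{n+1}) decides how many references are
  enough (cutoff 0.15), where NF_n is the per-sample geometric mean of the
  n best references.
- *NormFinder*: a two-way model on log quantities per sample group
  (gene level + sample effect + noise) yields a bias-corrected intra-group
  variance σ²_ig and an inter-group deviation d_ig per gene; the stability
  value combines |shrunken d| with the intra-group standard error, and the
  best *pair* of genes can beat any single gene when their group deviations
  cancel.
- *ΔCt*: SD of pairwise Ct differences, averaged over partners — no curves
  needed, which makes it the recommended first-pass screen before geNorm /
  NormFinder on the survivors.

**Template-amount ratio.** Q0 = T/(1+E)^Ct (T = fluorescence threshold,
default 0.3) compares CDS- vs 3′-UTR-region template of the same gene and
exposes reverse-transcription bias: oligo-dT-primed cDNA under-represents
primer sites far from the poly-A tail, which is why CDS measurements in the
oligo-dT group are masked out of stability ranking.

## Worked example

```python
from qpcrnorm import (StudyConfig, preset_paper_like, run_screening_pipeline, simulate)

spec = preset_paper_like(seed=1)          # 4 groups (4/6/4/2 samples) x 17 regions
sim = simulate(spec)                      # well-level Cts + dilution series + truth
config = StudyConfig(mask=sorted(spec.cds_mask_pairs()), seed=1)
report = run_screening_pipeline(sim.table, sim.dilution_series, config)
print(sorted(report.genorm_overall.final_trio), round(report.genorm_overall.final_trio_m, 3))
print(round(report.v_3_4, 3), report.verdict)
```

prints

```
['EF1a_cds', 'HIS_cds', 'TIP_utr'] 0.218
0.059 3 genes sufficient
```

i.e. the stepwise geNorm elimination retains the trio with average stability
M = 0.218 (well under the ~0.5 practitioners treat as "stable"), and the
pairwise variation between NF_3 and NF_4 is 0.059 < 0.15, so three
references suffice for this dataset.

The same analysis as a narrative lives in `analysis/01_simulate_study.py`
… `analysis/04_normalize_targets.py` (simulation → standard curves and
CDS/UTR ratios → stability rankings → target normalization with a
best-vs-worst reference robustness check), each writing its tables under
`results/`. A `qpcrnorm` CLI exposes the same steps
(`simulate`, `quantify`, `rank`, `screen`, `normalize`, `compare-refs`).

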