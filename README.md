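# credmet

Credentialing, quality control, annotation and statistics for untargeted
LC-MS metabolomics of **low-volume biofluids** — the setting where a few
microliters of fluid (embryonic cerebrospinal fluid, small serum draws)
are profiled by HILIC LC-MS and the dominant analytical problem is
telling true biological signals from shared background.

The package is aimed at metabolomics analysts who start from an aligned
feature table (feature id, m/z, retention time, polarity, per-sample
peak areas) and want a scripted, reproducible version of the workflow
that vendor tools perform interactively.

## What it does

**Credentialing.** Two independent strategies decide which detected
features are biology rather than background:

* *Mock filtering*: each feature's mean area in biological samples is
  compared with empty-tube mock extractions processed identically;
  features with `bio/mock > 3` (strict) and above a minimum credible
  intensity (10,000 area units) are retained.
* *IROA isotope pairing*: samples are mixed with a ~95 % ¹³C-labeled
  reference metabolome, so every true metabolite with *n* carbons
  appears as a light/heavy peak pair separated by exactly
  `n × 1.0033548 Da` at the same retention time. Features without a
  co-eluting heavy partner (5 ppm, 40 s tolerances) are rejected.

**QC normalization.** A reimplementation of the consolidation script
used for targeted data: per-sample normalization to mean-centered
spiked internal standards; removal of metabolites whose 1×/3×/10×
dilution series is non-linear (R² ≤ 0.95) or whose pooled-QC CV ≥ 30 %;
a per-sample biological-material "scaling factor" from high-confidence
metabolites; LoD imputation (one fifth of each variable's minimum
positive value); log transform + Pareto scaling
(`(x − x̄)/√s` per variable) for multivariate statistics; and a
glucose-6-phosphate blood-contamination check.

**Annotation.** Exact-mass (5 ppm) and retention-time (40 s) matching
against MS¹ compound libraries, greedy √-intensity-weighted cosine
matching against MS² spectral libraries (MSP/MGF), community confidence
Levels 1–4, compound-database construction with S/N gating and
duplicate-name demotion, and iterative Top-8 DDA inclusion/exclusion
list generation (6 s dynamic exclusion).

**Statistics.** IQR pre-filter, volcano statistics (Welch or pooled t,
two-tailed; log2 fold-changes from untransformed normalized areas),
top-25 selection, two-component PLS-DA (NIPALS) with VIP scores
(`VIP_j = √(p·Σ_a w²_ja·SSY_a / Σ_a SSY_a)`, so mean VIP² = 1), and
one-way ANOVA with Šídák adjustment `1 − (1 − p)^m`.

**Kinetics.** Clearance/utilization dynamics as log-linear
(geometric-decay) fits `ln C = ln C₀ − k·t` with OLS slopes ± SE, and a
compartment comparison via the interaction term of
`ln C ~ t + compartment + t×compartment`.

**Synthetic data.** A fully seeded generator emulating the sample
design — biological + mock + pooled-QC + dilution-QC samples, 37 spiked
internal standards, two-group treatment effects, below-LoD censoring,
¹³C reference mixes (95:5 / 5:95 designs) and decay time courses — with
ground-truth labels for every feature, so every stage is testable
without any instrument data.

## Worked example

```python
import credmet as cm

cfg = cm.Config()
table, truth = cm.generate_experiment(cm.SimConfig(rng_seed=1))

reports = cm.mock_filter(table, cfg)
kept = [r.feature_id for r in reports if r.decision == "retained"]
print(f"mock filtering retained {len(kept)} of {table.n_features} features")

norm, rep = cm.normalize_pipeline(table, truth.ids("internal_standard"),
                                  truth.ids("true_metabolite"), cfg)
print(f"QC filters left {norm.n_features} features; IS factors span "
      f"{rep.is_factor.min():.2f}-{rep.is_factor.max():.2f}")

cred = norm.subset_features([f for f in kept if f in norm.features.index])
anns = cm.annotate_table(cred, cm.mini_library(), cfg)
print(f"annotated {len(anns)} credentialed features "
      f"({sum(a.level == 1 for a in anns)} at Level 1)")

series = cm.generate_decay_series(["eCSF", "mSer"], [0.05, 0.05],
                                  [15, 30, 60, 90], n_rep=4,
                                  noise_cv=0.15, seed=2)
print(cm.fit_decay_table(series)[0].summary())
print(cm.compare_decay(series, ("mSer", "eCSF")).summary())
```

prints

```
mock filtering retained 100 of 237 features
QC filters left 200 features; IS factors span 0.77-1.42
annotated 100 credentialed features (100 at Level 1)
kynurenine in eCSF: slope -0.0515/min (SE 0.0012, 95% CI [-0.0541, -0.0488]), R²=0.992, n=16
eCSF vs mSer: Δslope -0.0017/min (SE 0.0019), p = 0.3715
```

All 100 planted true metabolites pass the mock filter while all 100
contaminants are rejected (the generator labels every feature); the QC
stage drops the internal standards and borderline analytes; every
credentialed metabolite annotates at Level 1 against the bundled
mini-library. The decay fit recovers the simulated 0.05/min clearance
rate (−0.0515 ± 0.0012), and the interaction test correctly finds no
rate difference between compartments simulated with equal kinetics
(p = 0.37).

A command-line interface wraps the same stages:

```sh
credmet simulate --seed 1 --out-table t.csv --out-meta m.csv --out-truth g.csv
credmet credential mock --table t.csv --meta m.csv --out report.csv
credmet run-db --seed 1 --out-dir db_out
credmet run-contrast --seed 1 --out-dir contrast_out
credmet kinetics --series series.csv --out fits.csv --compare eCSF:mSer
```

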