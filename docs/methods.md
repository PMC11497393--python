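# Methods

This note documents the models and procedures implemented in credmet,
the parameter choices that matter, what the synthetic-data generator
does and does not emulate, and the numerical decisions taken where the
underlying workflow left them open.

## Feature credentialing

### Mock filtering

A feature is credentialed when its mean peak area over biological
samples exceeds the mean over mock (empty-tube) extractions by strictly
more than `mock_fold_threshold` (default 3) **and** the biological mean
is at least `min_intensity` (default 10,000 area units). Missing cells
enter the means as a noise floor ε = (smallest positive area in the
table) × `lod_fraction`, rather than as infinite ratios; a feature
absent from every mock is retained on the intensity gate alone, with
its own report reason. An optional Welch-t significance gate
(`welch_gate_p`) can be added to the fold gate; the fold rule alone is
the default because fold-change is the primary published criterion and
the significance wording varies between descriptions of the same
filter. Because the decision is a ratio of means, it is invariant to
any global rescaling of the table; the intensity gate is the only
scale-dependent element.

### Isotope-pair (IROA) credentialing

With a ~95 % ¹³C-labeled reference metabolome mixed into the sample, a
true metabolite with *n* carbons appears as two co-eluting features
separated by `n × Δ`, Δ = 1.0033548378 Da (the ¹³C–¹²C mass
difference). The pairing rule: for each candidate light feature, search
features with retention time within `rt_tol` (40 s) and m/z equal to
`light + n·Δ` within `ppm_tol` (5 ppm, computed on the heavier m/z,
matching how instrument mass accuracy scales) for integer
`n ∈ [1, 60]`; both partners must exceed `min_intensity`. Among
multiple candidates the smallest |ppm error| wins, ties broken by
smallest |ΔRT|. Features are processed in ascending m/z, and a feature
consumed as a heavy partner is not itself credentialed — the light
(¹²C) member is the biological signal. The heavy/light intensity ratio
is reported (≈1 for the 1:1 "LTRS" mix of the 95:5 and 5:95 pools, ≈19
for the 5:95 internal-standard design) but is not used as a gate: no
numeric acceptance band for it is established, so it remains
diagnostic.

## QC normalization

The normalization stage runs in a fixed order; each step's output is a
valid feature table.

1. **Internal-standard factor.** Each spiked standard's areas are
   divided by that standard's cross-sample mean; a sample's factor is
   the mean of these centered ratios over all standards measured in it,
   and the table is divided through per sample. "Mean-centering" is
   implemented as division rather than subtraction: subtraction could
   yield negative factors, which is incompatible with the factor
   semantics of a per-sample divisor. The factor estimator recovers the
   generator's per-sample technical factors at r > 0.95 under default
   conditions (12 samples, 20 % CV).
2. **Dilution linearity.** Per feature, ordinary least squares of peak
   area on dilution factor across the 1×/3×/10× dilution-QC
   injections (with intercept, standard R²); features with
   R² ≤ `rsq_min` (0.95) are removed. Constant (saturated) series get
   R² = 0. At the generator's default reinjection precision (5 % CV)
   an occasional honest analyte lands just below the gate; the filter
   reports the offending statistic so such removals are auditable.
3. **Pooled-QC CV.** Per feature, CV = sd/mean over pooled-QC
   reinjections (missing excluded); features with CV ≥ `cv_max` (0.30)
   or undefined CV are removed. The default sd convention is the
   population sd (`cv_ddof = 0`); the sample-sd convention is one
   config switch away.
4. **Biological-material factor.** The per-sample "scaling factor" is
   the mean of mean-centered areas over a high-confidence metabolite
   set. The mean (rather than the raw sum) is used so that a baseline
   sample has factor ≈ 1 and a sample with twice the material has
   factor ≈ 2; the two differ only by a global constant that cancels on
   normalization. Under default synthetic conditions the factors differ
   by less than 2-fold within a sample type.

**Imputation and transform** are applied only on the way into
multivariate statistics: missing cells become (minimum positive value
of the variable) × 1/5; then natural log (base configurable) and Pareto
scaling — per variable, subtract the mean and divide by √sd, using the
sample sd (ddof = 1). Observed values are never altered by imputation;
per-metabolite plots should instead omit missing values. Constant rows
scale to zero rather than propagating NaN.

**Blood contamination** is screened by comparing each sample's
glucose-6-phosphate level with its median in a plasma-like reference
table; G6P is abundant in lysis-prone red blood cells and essentially
absent from clean CSF, so a ratio above 0.1 (configurable) flags the
sample.

## Annotation

MS¹ matching accepts a library candidate when the observed m/z is
within 5 ppm of the adduct m/z ([M−H]⁻ = M − 1.007276;
[M+H]⁺ = M + 1.007276; the water-loss adduct [M−H₂O−H]⁻ is available
but off by default) and, when the entry carries a retention time, ΔRT
is within 40 s — the tolerance above which isomer confusions (e.g.
betaine vs valine) appear in HILIC libraries. MS² similarity is a
greedy cosine on √-intensity-weighted peaks matched within 0.01 Da;
peaks are paired in order of increasing m/z difference, each used at
most once. The score threshold for treating an MS² match as
identification evidence defaults to 0.7 — a declared default, since the
reference workflow curated spectra manually and states no numeric
criterion.

Confidence levels follow the community tiers, first rule wins:
Level 1 = in-house candidate with RT match (exact mass and/or in-house
MS² ≥ threshold); Level 2 = exact mass plus external-library MS² match
with no RT available (external MS¹-only matches do not reach Level 2);
Level 3 = formula plus a name from an external compound list (top
listed hit); Level 4 = formula only, displayed as `MW<mz>_RT<rt>`.
Features with no formula are excluded. Formula assignment itself is
upstream (vendor isotope-pattern deconvolution); the package accepts a
per-feature formula column.

Compound-database construction drops MS² spectra whose base-peak to
median-peak ratio falls below 3 (single-peak spectra pass trivially),
and resolves duplicate display names by giving the name to the
candidate nearest the library RT, demoting the rest to `MW_RT` labels
at Level 4. Negative- and positive-mode tables are concatenated, never
merged by name; negative-mode display names receive a `_[M-H]` suffix
so both ions of one compound stay visible.

DDA planning emits inclusion lists (credentialed features without a
collected spectrum, as m/z with RT ± 40 s windows) and exclusion lists
(mock-derived features already fragmented); iterating acquisition
rounds (Top-8, 6 s dynamic exclusion) strictly shrinks the inclusion
list.

## Statistics

The contrast path is: IQR pre-filter (drop the ⌊5 %⌋ of features with
the smallest interquartile range) → LoD imputation → log/Pareto →
tests. Volcano statistics use a two-tailed t-test (Welch–Satterthwaite
df by default; the pooled-variance variant is available, as both appear
in practice) on transformed values, with log2 fold-changes computed
from the untransformed normalized group means. Raw p-values are the
headline selection criterion (a Benjamini–Hochberg column is emitted
but not used for selection); the "significantly changed" call combines
p < 0.05 with a 2-fold change gate, the standard volcano highlight.
Constant rows return p = 1 with a flag instead of NaN.

PLS-DA uses the NIPALS implementation of scikit-learn on
column-centered data with a centered one-hot class response and 2
components by default. VIP is computed from the x-weights and the
per-component Y sums of squares as
`VIP_j = √(p·Σ_a w²_ja·SSY_a / Σ_a SSY_a)`; the mean of VIP² over
variables is exactly 1, which the tests assert as an algebraic
identity. ANOVA post-hoc pairs use the pooled-variance two-sample t
over the pair itself, Šídák-adjusted as `1 − (1 − p)^m` over the m
requested comparisons; the family-wise error of this procedure is
verified by null simulation.

## Kinetics

"Geometric" (constant fractional rate) clearance linearizes under the
log transform, so rates are estimated by OLS of ln(value) on time;
replicates at a time point are independent observations (independent
animals). A raw-scale linear fit is available as an alternative mode.
Two compartments are compared by the joint regression
`ln C ~ t + compartment + t×compartment`; the interaction coefficient
equals the difference of the separately fitted slopes exactly, and its
t-test is the declared comparison — the underlying analysis names no
specific test, so this is this package's choice. Calibration under the
generator (rates 0.05–0.15/min, 15 % CV, 4 replicates × 4 times): 95 %
CI coverage ≈ 95 %, null rejection ≈ 5 %, and power ≈ 1 for a 3-fold
rate difference, as measured by the test suite and acceptance script.

## The synthetic-data generator

The generator emulates the study's sample design: n biological samples
in two treatment groups, mock extractions, pooled-QC reinjections, a
1×/3×/10× dilution series (two injections per level), and 37 spiked
internal standards. Per-metabolite abundances are log-normal around a
base of 10⁶ area units (σ = 1 on the log scale); every sample carries
one multiplicative technical factor applied to all its features —
log-normal with 20 % CV for independently prepared samples and 5 % CV
for reinjections of the shared QC pool, reflecting that reinjection
precision is much tighter than preparation-to-preparation variation.
True metabolites take their m/z, retention time and formula from a
bundled mini-library of ~60 real polar compounds (amino acids,
kynurenine-pathway intermediates, corticosteroids, central-carbon
metabolites), so annotation against the same library is meaningful.
Contaminant m/z are rejection-sampled to lie > 10 ppm from every
library adduct mass, and contaminants have equal expected abundance in
mock and biological samples by construction. Mocks receive true
metabolites only as a 1 % noise floor of the median true abundance, so
sample/mock ratios are finite without pseudocounts. Censoring replaces
all areas below the 2 % quantile of positive areas with missing,
emulating below-LoD dropout. Isotope-mix tables place each labeled
metabolite's heavy partner exactly at `light + n·Δ`; isotopic envelopes
are collapsed to single light/heavy sticks (a ±1-carbon satellite for
95 % labeling purity is available but off by default, as no envelope
detail is established). Decay series are `C₀·e^(−kt)` times log-normal
replicate noise.

What the generator does **not** emulate — and hence what passing tests
do not establish about instrument data: chromatographic peak shapes and
integration error, retention-time drift and batch effects beyond
per-sample scale factors, correlated (pathway-structured) biological
variation, heteroscedastic detector noise, in-source fragmentation, and
real isotopic envelopes. Results on real data additionally depend on
upstream peak picking and alignment, which are outside this package.

## Problem sizes and determinism

All randomness flows through `numpy.random.default_rng` seeded from one
integer; identical seeds give byte-identical tables, reports and
manifests. The test suite and the acceptance script use deliberately
modest problem sizes — hundreds of features, tens of samples, and
simulation calibrations of 200–1000 replicates (500 for the kinetics
coverage/power estimates) — chosen so the whole battery reruns quickly
on a single CPU while keeping Monte-Carlo error comfortably inside the
asserted margins.

## Known limitations

* The pipeline starts at aligned feature tables; no raw-file or mzML
  processing, peak picking, or RT alignment.
* No de-novo formula inference from isotope patterns; formula-absent
  features are excluded from annotation rather than guessed.
* External spectral databases are modeled as local library files; no
  online retrieval.
* Batch correction beyond per-sample factors is out of scope (separate
  batches should be curated independently).
* Pathway enrichment and figure rendering are out of scope; outputs are
  tabular.
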