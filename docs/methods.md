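# Methods

## Marker-selection model

The selection cascade operates on a probe × sample matrix of Infinium-style
β values (fraction of methylated alleles at one CpG, unitless, in [0, 1])
with a matched matrix of detection p-values. Stages, in order:

1. **Detection QC** — a probe is removed if its detection p-value exceeds
   α (default 0.05) in *any* sample, tumors and PBL replicates alike,
   evaluated before replicate averaging. Survivors are therefore complete;
   a missing β later in the cascade is treated as a bug, not imputed.
2. **Annotation exclusion** — probes flagged as SNP-containing or
   repeat-derived are removed. Flags are consumed as explicit booleans from
   the annotation table; a probe without a record is an error rather than a
   silent keep, because absence of evidence is not evidence of a clean probe.
3. **Replicate averaging** — PBL technical replicates collapse to one column
   per subject: arithmetic mean for β, maximum for detection p (a probe is
   trusted only if every replicate passed). Whether the original protocol
   used min, max or per-replicate p here is not documented anywhere we know
   of; max is the conservative choice.
4. **Leukocyte-methylation filter** — probes with averaged PBL β ≥ t
   (default 0.2) in any PBL subject are removed. The boundary is inclusive:
   descriptions of this protocol disagree between "≥ 0.2" and "> 0.2", and
   we follow the operative ≥ form; the threshold is a parameter, so either
   convention is one argument away.
5. **Separation ranking** — per probe, T_L = min β over tumors,
   PBL_H = max β over (averaged) PBL subjects, d = T_L − PBL_H. Probes with
   d ≤ 0 are dropped; d = 0 counts as failure. Survivors are sorted by d
   descending; ties break by probe id ascending purely for determinism.
   Requiring the *least* methylated tumor to exceed the *most* methylated
   leukocyte sample encodes the sensitivity-by-consistency idea: a marker
   passing is methylated in every tumor and in no blood control.
6. **Top-k selection** — first k (default 15) records; with
   `unique_genes=True` the best-ranked probe per gene is kept before
   truncation (the collapse rule used originally is unrecorded; best-rank
   is the natural deterministic choice).

All tumors are pooled regardless of histological subtype — the design
maximizes sensitivity across subtypes — with the histology label carried
but unused; subtype-stratified ranking would be a caller-side filter.

The cascade is also exposed as `MarkerSelector`, a scikit-learn compatible
supervised feature selector (fit on a samples × probes frame plus group
labels; transform subsets columns), so it composes with sklearn pipelines.
The per-stage functions remain the primitive API.

## MethyLight screens

Verification is an ordered, short-circuiting cascade per marker: design →
M.SssI control → PBL Ct counter-screen → control-plasma PMR → tumor PMR.
A marker failing a stage has no results for later stages, matching how a
wet-lab funnel actually proceeds (and sparing reagents).

* ALU DNA-quality gate: Ct < 21, strict (Ct = 21 fails). Undetected ALU
  means unusable DNA, returned as a failed gate, not an exception.
* PBL counter-screen: pass iff **every** PBL sample shows Ct > 35 or no
  amplification. One sample at Ct ≤ 35 fails the marker.
* PMR = 100·2^−ΔΔCt against an ALU repeat-content control, scaled to an
  enzymatically fully methylated (M.SssI) reference. The formula is
  shift-invariant: adding a constant to all four Cts leaves PMR unchanged.
  An undetected target with valid ALU yields PMR 0 (no methylation
  detected) rather than missing; an undetected ALU raises, since
  normalization is impossible.
* PMR bins: < 10 low, [10, 50] mid (closed interval), > 50 high. The
  interval-closure convention at exactly 10 and 50 is a documented choice;
  both cutpoints are parameters.
* Control plasma: pass iff every control plasma PMR < 5 (strict).
* Tumor panel: positivity fraction = share of tumors with PMR > 20
  (strict); the screen requires fraction 1.0.

Undetected reactions are encoded as `ct=None` in memory and the literal
`ND` on disk — never as a large cycle number — so they cannot silently
enter arithmetic. The PCR cycle ceiling defining "undetected" is taken as
50 cycles.

## Digital-PCR quantification

With molecules distributed over N wells at limiting dilution, the count of
occupied wells k underestimates the molecule number once double occupancy
becomes likely. The most-probable-number estimate λ̂ = −N·ln(1 − k/N) is
the maximum-likelihood inversion of P(well positive) = 1 − e^(−λ/N); it is
applied **per plate** before summation across a sample's plates, because
each plate is its own dilution. A fully positive plate (k = N) carries no
upper information and raises a saturation error under the Poisson method.
Concentration scales the summed estimate by 1000/volume_assayed_µl to
molecules per ml serum (the assay bookkeeping makes 1 µl of diluted
template represent 1 µl of serum; one analysis uses 100 µl). Plates with
more than 15 hits per 96 wells are flagged saturated (threshold scaling
proportionally with plate size); the flag mirrors the reporting caveat of
the original assay while the Poisson estimate corrects it. Simulation
shows the corrected estimator unbiased within Monte-Carlo error up to 80%
well occupancy, where the naive count is already ~2× low.

## Longitudinal statistics

Per patient, Pearson's r between serum marker concentration (molecules/ml)
and CA-125 (U/ml) across serial draws; significance by the exact t
transform t = r·√((n−2)/(1−r²)) against a two-sided t(n−2) null at
p < 0.05. Two-sidedness is our choice (the protocol states only the null
and cutoff); correlations are computed on raw values, untransformed. Pairs
with a missing value in either channel drop pairwise; fewer than three
complete pairs or a zero-variance channel makes a patient *untestable*,
reported as such rather than silently excluded. Post-resection drop is a
strict decrease from the first (baseline) draw to the first draw after the
surgery week, evaluated independently per channel; baselines may be pre-
or post-surgery and carry a flag saying which.

Case/control discrimination uses the midrank ROC AUC (ties get half
credit; equals Mann–Whitney U/(n₁n₂)) with a stratified percentile
bootstrap CI: cases and controls resampled within group, 2000 resamples by
default, fully deterministic under the seed. With perfectly separated
groups the CI collapses to [1, 1]; degenerate (all-equal) groups log a
warning.

## Synthetic-data generators

The generators produce data with the statistical structure the analysis
assumes, sized to the study design they emulate; every generator is
bit-reproducible under its seed.

**Infinium cohort** (defaults: 2000 probes, 41 tumors, 2 PBL subjects ×
2 technical replicates, 40 planted markers). Beta distributions are
specified as (mean, precision) with a = mean·precision,
b = (1−mean)·precision. Planted markers draw tumor β from (0.60, 30) and
PBL β from (0.02, 50) — chosen so that min-over-41-tumors exceeds
max-over-PBL with probability ≳ 0.99 per probe, i.e. planted markers are
genuinely "methylated in all tumors, absent in blood". A fraction (0.20)
of the remaining probes is leukocyte-methylated, drawn from (0.70, 20) in
all samples, and must die at the PBL filter; the rest share a background
(0.10, 8) across groups, so their tumor-vs-PBL separation is pure chance
and almost never positive with 41 tumors against 2 subjects. Detection
failures (0.5% of cells, p uniform on (0.05, 1]) and SNP (10%) / repeat
(5%) flags land only on non-planted probes, emulating candidate markers
with robust assay chemistry; this is what makes "recall of planted markers
= 1.0" a meaningful specification of the cascade rather than a coin flip.
The probe-to-gene map assigns ~1.9 probes per gene.

**Patient trajectories.** A latent burden (arbitrary units, default 10 at
baseline) is constant until surgery (week 0), decays exponentially at 0.4
/week afterwards (≈1.7-week half-life, matching the rapid post-resection
clearance of circulating markers) down to a minimal-residual-disease floor
of 0.05, and regrows at 0.12/week from the relapse week (default 40).
CA-125 = 30·burden + 10 U/ml floor (non-tumor production), with
multiplicative lognormal noise (CV 0.2) since CA-125 spans orders of
magnitude; the marker count in the assayed volume (100 µl) is
Poisson(20·burden·vol_ml), recorded as count/vol_ml. Draws default to
16 visits at 6-week spacing over 90 weeks, the cadence of the monitoring
design being emulated (~15 samples over ~92 weeks). Under these defaults
both channels drop after surgery and correlate significantly in ≈100% of
simulated patients — the shared-latent condition.

**Digital plates.** Molecules reaching a plate ~ Poisson(conc·vol·eff),
scattered uniformly over wells; a well is positive iff it received ≥ 1
molecule. Detection efficiency defaults to 1.0 but is exposed because real
bisulfite conversion and recovery are lossy.

**Screen panels.** Marker fates are engineered (3 design failures, 1
M.SssI failure, 3 PBL-methylated, 7 plasma-positive, 1 clean survivor per
15 candidates — the verification funnel being emulated) and shuffled by
seed; Ct values are drawn in ranges that realize each fate, with plasma
and tumor target Cts produced by inverting the PMR formula at a chosen
PMR. The screen cascade must recover exactly the engineered survivor.

**Synthetic serial table.** `synthetic_concordance_cohort` builds a cohort
whose per-patient marker-vs-CA-125 sample correlation equals a requested
value *exactly*, by Gram–Schmidt: noise is orthogonalized against the
centered CA-125 vector and mixed as r·x̂ + √(1−r²)·ẑ, then mapped affinely
onto a non-negative molecules/ml scale (affine maps preserve sample
correlation). This is a labelled synthetic fixture — it lets the
concordance machinery be validated against planted coefficients (six
concordant patients at r ∈ {0.97, 0.81, 0.70, 0.97, 0.95, 0.74}, three
discordant at r = 0.15, 15 draws each) without any measured patient data.

### What the generators do not emulate

Real β distributions are bimodal with probe-type-specific dynamic range
and spatial correlation along the genome; real detection failures cluster
by sample quality, not uniformly; tumor purity, subtype heterogeneity and
copy-number effects on β are absent; CA-125 kinetics include
surgery-induced spikes and assay drift; serum cfDNA yields vary by
extraction. Passing tests therefore demonstrate the *algorithms* are
correct under their stated assumptions, not that the thresholds would
reproduce any particular probe count on a real array cohort — the original
stage counts additionally depend on the specific array annotation and
dbSNP/RepeatMasker versions, which this package deliberately consumes as
input rather than recomputing.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng`; multi-stage
  seeds derive via `SeedSequence.spawn`, so stages are independently and
  jointly reproducible.
* Ranking ties break by probe id; bootstrap CI bounds clamp to bracket the
  point estimate; percentile CI uses linear interpolation (numpy default).
* Pearson r/p delegate to `scipy.stats.pearsonr` and AUC to
  `sklearn.metrics.roc_auc_score`; the test suite cross-checks both
  against independent longhand implementations (product-moment formula;
  all-pairs counting) to 1e−12.
* Problem sizes in the test and acceptance runs — 2000-probe cohorts, 500
  simulated plates, 2000 bootstrap resamples, 20 pipeline seeds — are the
  package's chosen defaults for simulation studies; they give Monte-Carlo
  error well inside every asserted tolerance.

## Known limitations

* The MethyLight reference ratio (Ct_target − Ct_ALU of the M.SssI
  reference) must be supplied; the package defaults are plausible assay
  constants, not calibrated ones.
* The Poisson correction assumes equal well volumes and perfect
  partitioning; droplet-style volume variation is not modeled.
* `post_resection_drop` compares single draws (baseline vs first
  post-surgery); it does not smooth over assay noise.
* No survival, lead-time or relapse-prediction analysis: the longitudinal
  module quantifies concordance with an established burden marker only.
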