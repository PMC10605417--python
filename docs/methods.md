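# Methods

This note documents the statistical model behind `episig`, the synthetic
cohort its validation rests on, and the design choices made where the
procedure was genuinely open.

## Scales and the dual-threshold convention

Methylation arrives as beta values β ∈ [0, 1] (methylated fraction).
Hypothesis tests run on M-values, `M = log2((β+ε)/(1−β+ε))` with offset
ε = 0.01 (`m_offset`), which stabilizes variance near the boundaries and
bounds |M| ≈ 6.7 at β ∈ {0, 1}; effect sizes are reported on the beta
scale as the difference of group means (Δβ), where the biological
threshold of 5% is meaningful. A CpG is called significant only when both
the BH q-value (< 0.05, `q_threshold`) and |Δβ| (> 0.05,
`delta_beta_threshold`) clear their cuts; a relaxed q < 0.1 is exposed
(`q_threshold_relaxed`) but used only where an analysis asks for it.

## QC and preprocessing

Individual calls are masked when detection p > 0.05 (strictly greater) or
bead support < 3 (strictly fewer); the masking is idempotent.
Mitochondrial probes (chrM/MT, case-insensitive) are removed; X/Y are kept
because the cohort is all male. Probes missing in more than 50% of
samples (`max_probe_missing`) are dropped so per-probe complete-case fits
retain a floor of observations — the paper trail of removals is returned
in a `QcReport`. Sample outliers are flagged in a single pass as samples
whose Euclidean distance to the mean M-value profile (over fully observed
probes) exceeds 2× the median distance (`outlier_multiplier`); with the
generator's defaults and no planted outliers this removes nothing in
≥ 9/10 seeds, by construction of the threshold.

## Surrogate variables

Blood methylation carries latent cell-composition structure. The number
of surrogate variables k is estimated by parallel analysis on the
residual matrix (design projected out per probe): each probe's residual
row is independently permuted, the permuted matrix is re-projected onto
the design's residual space, and the observed variance fractions of the
leading components are compared with the 95th percentile (upper order
statistic, conservative for the default 20 permutations,
`sva_permutations`) of the permuted fractions, stopping at the first
failure. Re-projection matters: without it the observed leading fraction
is inflated relative to the permutation null by the design-rank deficit
and pure-noise data yields spurious k > 0.

The SVs themselves use the two-step construction: right singular vectors
of the residual matrix identify eigengenes; each SV is then rebuilt as
the matching right singular vector of the *raw* (row-centered) data of
the probes associated with that eigengene (BH q < 0.1 on the per-probe
correlation, falling back to the 100 strongest). The rebuild is the
crucial step — a bare residual eigenvector is orthogonal to the design by
construction, so the share of a latent factor collinear with the main
effect would stay aliased with it and confound the fit. The collected
vectors are Gram–Schmidt orthonormalized with a deterministic sign
(largest-magnitude entry positive). SVs are re-estimated for every
analysis subset (per LOO fold, for the mutant-only treatment contrast).

## Moderated modeling

Per probe, OLS on complete cases against (intercept, main effect, day,
SV1..k). Empirical-Bayes moderation follows the standard method of
moments on z = log s²: with `e = z − ψ(d/2) + log(d/2)`, the prior df d0
solves `ψ′(d0/2) = mean[(e − ē)²·n/(n−1) − ψ′(d/2)]` via a Newton
iteration on the trigamma inverse, and `s0² = exp(ē + ψ(d0/2) −
log(d0/2))`. When the excess spread is nonpositive the prior is
degenerate (d0 = ∞) and the common variance is the geometric mean of the
s², so the moderated t reduces exactly to the classical t. Posterior
variances are `s̃² = (d0·s0² + d·s²)/(d0 + d)` (probes with s² = 0 are
handled by the same formula), moderated `t = b/(s̃√v)` with d0 + d df,
two-sided p. The implementation was cross-checked against the
Bioconductor reference implementation on a frozen fixture (agreement to
1e-14 in t and hyperparameters; see `tests/test_modeling.py`).

BH-FDR is the step-up `q(i) = min_{j≥i} m·p(j)/j` over non-missing
p-values, verified against a brute-force transcription of the definition.

## Cross-validation

For each vehicle-treated sample: hold it out, re-derive SVs and the
signature on the remaining samples, build group mean beta profiles at the
fold's signature CpGs, and classify by the larger Pearson correlation.
Exact ties (within 1e-12) or zero-variance vectors yield an explicit
"unclassifiable". Sensitivity/specificity count unclassifiable folds as
errors. The held-out sample enters nothing on the training side; a
dedicated test corrupts a held-out sample and verifies its fold's
signature is unchanged.

## DMR detection

Raw probewise p-values become z = Φ⁻¹(1 − p). The autocorrelation of z
is estimated in distance bins of 310 bp up to a 1000 bp window
(`acf_bin_bp`, `dmr_max_gap_bp`; bins with < 10 pairs inherit the
previous bin, with the zero-distance limit fixed at 1). Each probe's
neighborhood is combined with Stouffer–Liptak–Kechris,
`z_comb = Σz / √(ΣΣσ)` with σ from the ACF (independence fallback if the
correlation mass is nonpositive); runs of adjusted p < 0.01
(`dmr_seed_p`) with gaps ≤ 1000 bp become candidate regions. Regions are
scored by the SLK combination of their members' raw p-values and
Sidak-corrected, `1 − (1 − p)^(span_tested/span_region)`, where the
tested span sums per-chromosome probe extents. Final filters: Sidak
p < 0.005 (`dmr_sidak_max`), ≥ 3 members with the same Δβ sign, ≥ 1
member in the signature. Window, seed and bin defaults follow the
documented defaults of the established comb-p-style tooling; all are in
`AnalysisConfig`.

## Treatment rescue

The threshold-free statistic flags a signature CpG as rescued when
|mean(KS1-treated) − mean(WT-vehicle)| < |mean(KS1-vehicle) −
mean(WT-vehicle)| strictly (ties, within float tolerance, are not
rescued); fractions are reported overall and by original direction. Its
50% noise baseline is a first-class property: with no treatment effect
either arm lands closer half the time, so only the excess over one half
carries evidence. The per-probe contrast is the moderated fit of
vehicle vs treated within mutants only, SVs re-estimated on that subset,
with FDR computed over the signature probes — the multiplicity universe
of the restricted scan.

## Volume association

The per-structure tables fit `volume ~ genotype * treatment` (absolute
and percent-of-total volumes) with BH across structures and a body-weight
pseudo-row. The methylation scan restricts to signature CpGs on
vehicle-treated samples, with centered total brain volume as main effect,
day as covariate and no SVs. Genotype is additionally adjusted for
(`adjust_genotype=True`): in this cohort volume is strongly collinear
with genotype (the mutant brains are ~10% smaller), so an unadjusted scan
would attribute every genotype-differential CpG's group shift to volume;
the adjusted scan isolates within-genotype coupling, which is the
biomarker-relevant quantity. The unadjusted variant remains one flag
away. The continuous analogue of Δβ is the beta-scale slope times the
observed volume range, thresholded at 5%. PC1 of the selected CpGs
(centered, unscaled betas — the probes share a scale) is regressed on
volume within each genotype, reporting slope, F(1, n−2) and p, with PC1's
sign fixed by its pooled correlation with volume.

## The synthetic cohort

The generator emulates the study's structure with known truth; its
defaults are the study conditions. Groups of 13/10/8/9 (WT-vehicle,
KS1-vehicle, WT-treated, KS1-treated), 20,000 probes as a scaled-down
array, baseline means from a bimodal mixture (45% near 0.1, 45% near 0.9,
10% intermediate). Planted effects are computed on the beta scale and
carried through the logit so means stay in (0, 1); per-sample noise is
Beta(μc, (1−μ)c) with concentration c = 625, giving within-group SD
≈ 0.02 at mid-range means — array-like replicate noise; the source study
reports no within-group variance, so this is an exposed stand-in
(`precision`).

* **Signature**: 500 CpGs, 48% hypermethylated, |Δβ| uniform on
  [0.05, 0.20], planted exactly as group-mean differences (signature
  baselines drawn mid-range so the shift fits). A 5-probe hypermethylated
  cluster at 80–100 bp spacing (Δβ = 0.15) is always planted for DMR
  recovery, plus an optional hypomethylated twin; all other probes sit
  ≥ 2 kb apart on 19 autosomes + X.
* **Confounders**: two standard-normal per-sample factors loading on
  disjoint 1000-probe subsets (loadings N(0, 0.2) on the logit scale) —
  strong enough to dominate the residual spectrum, weak enough that clean
  cohorts pass outlier screening.
* **Batch**: a +0.02 beta shift on 2000 probes for day-2 animals.
* **Rescue**: the configured `rescue_fraction` is the *expected observed*
  mean-closeness fraction. Because an unrescued probe is counted rescued
  with probability 1/2 by symmetry, the truly shrunk subset has size
  `round(n_signature · max(0, 2f − 1))`; shrunk probes keep
  `(1 − rescue_shrinkage)` of their effect in the treated-mutant arm.
  Values below 0.5 plant nothing (the observable floor is the noise
  baseline). This calibration is what makes "69% rescued" recoverable as
  69% rather than 84%.
* **Volume**: per-genotype triangular distributions matched to the
  study's printed (min, median, max) — WT (402.7, 425.4, 442.5), KS1
  (327.5, 388.7, 417.9) mm³ — the only summaries reported. Coupling is
  planted in mutants only, at 27 signature CpGs, slope 0.0015 β/mm³
  anti-aligned with each probe's disease direction (the most severely
  affected animals show both the smallest brains and the most extreme
  methylation), which keeps the volume axis aligned with PC1 as described
  for the real cohort.
* **QC layers**: detection p-values log-uniform in [1e-6, 1e-2] and bead
  counts ≥ 3 for clean calls; a `missing_rate` (default 1%) of cells is
  planted as failures, split between high detection p and low beads.

What the generator does **not** emulate: probe-type chemistry and dye
bias, genetic variation (the cohort is isogenic), spatially realistic CpG
density (outside the planted clusters probes are far apart), litter
structure, and any real cell-type reference. Passing tests therefore
demonstrate that the pipeline recovers the planted statistical structure
at the study's scale and noise level — not that it would reproduce the
original study's exact counts on the unavailable raw data.

## Numerical choices and degenerate inputs

p-values are clipped to [1e-15, 1 − 1e-15] before Φ⁻¹; SLK underflow is
reported as the smallest positive normal with a flag; Sidak uses
expm1/log1p. The variance scan defaults to mean-centered Levene — the
median-centered Brown–Forsythe variant (selectable, `center="median"`)
is conservative at the cohort's group sizes (empirical level ≈ 0.03 at
nominal 0.05 vs ≈ 0.06 mean-centered); both match the scipy reference
implementation exactly. Gene-level signature comparison aggregates
multi-site genes by majority direction; exact ties are labeled "mixed"
and never count as direction agreement. Probes with insufficient
complete cases, undefined correlations, zero-spread Levene groups and
empty fold signatures all surface as missing values or explicit labels,
never silent zeros.

## Problem sizes

Validation runs use the study-scale cohort (20,000 probes × 40 samples,
ten seeds) for cross-validation, signature calibration, surrogate
recovery, DMR cluster recovery, rescue calibration and the volume trend;
null-calibration checks (global-null DMRs, noise-baseline rescue,
Levene level) use 2,000–4,000-probe cohorts, which are ample for
frequency estimates at the tested tolerances.

## Known limitations

The surrogate estimator assumes latent factors are strong relative to
noise; weak factors (loadings comparable to residual SD) are
under-counted by design (the conservative order-statistic cut). The
mean-closeness rescue statistic cannot distinguish partial rescue from
regression-to-baseline without the planted truth; only its excess over
50% is interpretable. The Sidak span normalization is self-referential
(tested-probe extents), so DMR p-values are comparable within a run, not
across cohorts with different probe grids. The volume scan's genotype
adjustment absorbs any true volume effect that is perfectly collinear
with genotype; with n = 23 this is the price of a controlled null.
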