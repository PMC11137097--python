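# Methods

This note documents the models, conventions and design choices behind
`glymph`, what the synthetic-data layer does and does not emulate, and
the numerical decisions a maintainer would need to know.

## Coordinate and unit conventions

Volumes are reoriented to canonical RAS axes on load, so image axes mean
x = left–right, y = anterior–posterior, z = inferior–superior. This is
load-bearing: the ALPS index is defined on diffusivities along these
fixed anatomical axes, so `axis_diffusivities` returns the tensor's
*diagonal* entries in the image frame and deliberately never
eigen-decomposes. Diffusivities are in mm²/s, b-values in s/mm², PET
activity in kBq/mL, dose in MBq, weight in kg. Voxel indices are
0-based. NIfTI-1 stores the affine in float32; round trips preserve
voxel data bit-exactly and geometry to float32 precision.

Gradient frames are assigned to a shell when |b − shell| ≤ 50 s/mm²
(scanner-reported b-values jitter). Each shell is fitted separately,
sharing the b = 0 frame(s): the default protocol is 1 b0 + 30
near-uniform directions (spherical Fibonacci lattice) per shell at
b = 1000 and 2000.

## Tensor fit

Per voxel, the monoexponential model `S_i = S0 exp(−b_i gᵢᵀ D gᵢ)` is
linearised to `log S = X β` with β = (ln S0, Dxx, Dyy, Dzz, Dxy, Dxz,
Dyz), solved by ordinary least squares and then one iteratively
reweighted pass with weights equal to the squared predicted signal — the
standard variance-stabilising weighting for log-transformed magnitude
data. The method is deterministic (no iteration-count ambiguity) and
exact on noiseless data with ≥ 7 independent frames; the tests verify
recovery of random SPD tensors to < 1e-10 relative error and the
acceptance script reports < 1e-8 on 50 tensors.

Numerical guards: signals are floored at 1e-6 of the estimated S0 before
the log (avoids −∞ in noisy background); voxels with non-finite or
non-positive b0 signal are flagged invalid rather than aborting; negative
diagonal estimates are clamped to 0 and flagged (diffusivities are
physical). Flagged voxels propagate as NaN into the diffusivity maps and
are excluded from ROI means; an ROI left empty after exclusion is an
error.

## ALPS computation

ROI-mean Dxx/Dyy/Dzz are extracted for projection, association and
subcortical areas per hemisphere (the subcortical triple is reported but
never enters the index: those fibres run parallel to the perivascular
spaces, so their Dxx mixes fibre and perivascular diffusion). The
hemispheric index `mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)`
is computed first; the subject index is the arithmetic mean of the two
hemispheric indexes (averaging indexes, not pooling ROIs, matches the
stated per-participant averaging). Per-shell indexes are labelled b1000
and b2000 and never mixed. ROIs come either from a label volume (the
phantom path) or from JSON sphere specs (default 5-mm radius at
user-chosen voxel coordinates); no automated placement is attempted
because no reproducible placement rule exists.

## PET quantification

SUV divides activity by injected dose per body weight; decay correction,
the 50–70-min frame averaging and reconstruction are assumed done
upstream, so the module consumes a single static volume. SUVR divides by
the cerebellar-mean SUV (the output's cerebellar mean is exactly 1 by
construction). The centiloid transform is the standard linear level-2
form; its anchors are *calibration inputs*, shipped with conventional
PiB whole-cerebellum defaults (SUVR_yc = 1.009, SUVR_ad100 = 2.076) and
overridable in every API and the CLI. The scale is open-ended: values
outside [0, 100] pass through unchanged.

## Synthetic imaging data

The phantom reproduces the geometric logic of the ALPS ROI scheme, not
anatomy: per hemisphere, three axis-aligned bands — projection
(Dzz-dominant), association (Dyy-dominant), subcortical (Dxx-dominant) —
at a "ventricle-body" slab, plus isotropic background, a cerebellum block
and a cortex band for PET. Default zone diffusivities are
proj (0.90, 0.70, 1.70)·10⁻³, assoc (0.90, 1.70, 0.70)·10⁻³,
subc (1.70, 0.70, 0.70)·10⁻³ mm²/s with isotropic 0.80·10⁻³ elsewhere —
tissue-typical values chosen so the default perivascular gain
g = 0.08·10⁻³ mm²/s (added to Dxx in the projection and association
bands) gives an analytic ALPS of (0.90+0.08)/0.70 = 1.4, a cognitively
normal level. g is the phantom's single disease knob; zone dominance is
validated (ties allowed, so an isotropic phantom with g = 0 is a legal
degenerate case with ALPS exactly 1). The grid defaults to 48×48×14 at
the study resolution 1.9×1.9×3.0 mm.

DWI noise is single-coil Rician — the magnitude of the noiseless signal
plus complex Gaussian noise — with σ defined as mean(S0)/SNR on the
unweighted signal; `snr=None` bypasses the noise path exactly, making
noiseless pipeline-vs-analytic agreement a machine-precision test. The
sampled b0 mean is verified against `scipy.stats.rice`. Not modelled:
multi-coil noise statistics, partial-volume/CSF contamination, motion and
eddy distortions, PET point-spread blurring, real anatomy. Passing tests
therefore validate the estimators and their noise robustness under the
stated model, not robustness to acquisition artefacts in clinical data.

The synthetic SUVR map sets the cerebellum to 1 and the cortex band to
the SUVR that the inverse centiloid transform demands, so
simulate → quantify round-trips to the requested centiloid at 1e-9.

## Synthetic cohorts

Centiloid is the exogenous stage axis: per group (defaults 27 CN with
mean 0.4 ± 6.7, 56 AD with 78.5 ± 33.4) it is drawn normally; ALPS at
each shell follows `ALPS = intercept + slope·CL + ε` (defaults b1000:
1.436 − 0.0018·CL, pooled r 0.65; b2000: 1.386 − 0.0014·CL, r 0.47) with
σ_res = |slope|·SD(pooled CL)·√(1/r² − 1), the unique residual scale
consistent with the requested pooled correlation. MMSE is generated by
inverting its ALPS-response link (slope 0.017, intercept 0.902, r 0.55):
with implied SD σ_M = r·σ_ALPS/slope, `MMSE = μ_M + (r²/slope)(ALPS −
μ_ALPS) + N(0, σ_M√(1−r²))`, which reproduces both the response-oriented
slope and r on re-analysis; it is then clipped to [0, 30] and rounded
(real MMSE is a bounded integer score — the defaults clip ~15–20% of
draws at the ceiling, mildly attenuating the recovered MMSE links; a
warning reports clipping above 25%). The VSRAD link (−2.65·ALPS + 5.16,
r 0.40) is oriented with VSRAD as the response because only that
orientation is dimensionally consistent with the biomarker SDs (the
reverse orientation would imply a slope near −0.06). Residual-variance
detail beyond r is not specified anywhere upstream; this construction is
one consistent choice and is the documented generative contract.

Design note: the configured group marginals put VSRAD slightly *higher*
in AD than CN through the negative ALPS link, whereas the nominal group
table lists the reverse ordering; the generator follows the regression
links, since the correlation structure is what the analyses must recover,
and the two stated parameter sets cannot both hold simultaneously.

Analytic expectations for every generated column (including the
censored-normal MMSE mean) are exposed via
`CohortSpec.expected_group_mean` and used as the oracle in recovery
tests. All generators take explicit seeds; there is no global random
state.

## Statistics

Pearson regression uses OLS with r and the two-sided p from
t = r√((n−2)/(1−r²)); pointwise 95% confidence bands for the mean
response use the standard hat-matrix form. One-way ANOVA is computed
from the between/within sum-of-squares decomposition (verified against
the squared pooled two-sample t for k = 2); identical groups yield
F = 0, p = 1 by convention. Fisher's LSD is pairwise t-tests on the
pooled ANOVA mean square with *no* multiplicity adjustment — that is
what LSD is. The sex ratio uses a chi-square contingency test. The
significance threshold is 0.05 throughout and all p-values are
two-sided.

nVSRAD uses denominator VSRAD_MAX as printed in the source formulation
(it reaches 100 at the maximum only when VSRAD_MIN = 0); the
conventional range denominator is available via
`vsrad_range_denominator=True` / `--nvsrad-range-denominator`.
Normalization constants are always computed over all subjects of the
analysed table and reported alongside results. Because the
normalizations are affine, they preserve correlation magnitudes and
rescale slopes by known factors (tested).

## Known limitation: group-separation power at extreme alpha

With the default group moments, the noncentral-F power of the two-group
ANOVA on ALPS(b1000) at α = 1e-5 is ≈ 0.78 (λ ≈ 31, F_crit ≈ 22.2 on
1/81 df), and the simulated rejection rate matches it. A ≥ 95% rejection
rate at that α is therefore analytically unattainable under these
conditions — it would need roughly 1.3× the present effect size — and
the acceptance test asserting that target fails by design; the companion
test verifying empirical-rate-vs-oracle agreement is the meaningful
check.

## Problem sizes

Monte-Carlo tests use 20 noise seeds for phantom pipelines (24×24×8 grid
for repeated runs, the full 48×48×14 grid for the headline accuracy
check), 200 cohorts for parameter recovery and 300–500 for rejection
rates — sizes at which Monte-Carlo standard errors are comfortably below
the asserted tolerances.

## Pipeline determinism

`run_pipeline` derives one independent substream per stage from the
master seed via `SeedSequence.spawn`, writes uncompressed NIfTI (gzip
containers can embed metadata that breaks byte-identity), and records
SHA-256 hashes of every output in `manifest.json`; identical config and
seed reproduce identical hashes, and every file written is declared in
the manifest.
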