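# glymph

Imaging biomarkers of glymphatic function for dementia research: the
DTI-ALPS perivascular diffusivity index from multi-shell diffusion MRI,
amyloid-PET quantification on the centiloid scale, atrophy Z-scores, and
the cohort statistics that relate them — together with a synthetic-data
layer (tensor phantoms, Rician-noise DWI, SUVR maps, CN/AD cohort tables)
so the entire analysis chain can be exercised and validated without
patient data.

## The science

The glymphatic system drains interstitial waste — including β-amyloid —
through perivascular spaces. At the level of the lateral-ventricle bodies
the perivascular spaces of the medullary veins run left–right (x), while
projection fibres run head–foot (z) and association fibres
front–back (y). Water diffusivity along x in the projection and
association areas is therefore perpendicular to the local fibres and
reads out perivascular flow. The **ALPS index** is

```
ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)
```

computed from the *diagonal* elements of the diffusion tensor in the
scanner axis frame (never eigenvalues), per hemisphere, then averaged per
subject. An index near 1 means minimal perivascular diffusion; it falls
toward 1 as glymphatic function declines.

Amyloid burden is quantified from static PET as
`SUV = activity / (dose / weight)`, normalised to the cerebellar mean
(SUVR), and mapped to the **centiloid** scale
`CL = 100 (SUVR − SUVR_yc) / (SUVR_ad100 − SUVR_yc)` where the anchors
are calibration inputs. Atrophy uses the VSRAD-style Z-score
`Z = (control mean − individual) / control SD`. For stage comparison the
biomarkers are put on a common 0–100 severity scale:

```
nDTI-ALPS = (ALPS_MAX − ALPS) / (ALPS_MAX − 1) × 100
nMMSE     = (30 − MMSE) / 30 × 100
nVSRAD    = (VSRAD − VSRAD_MIN) / VSRAD_MAX × 100
```

and regressed against centiloid; group differences use one-way ANOVA with
post-hoc Fisher LSD, associations use Pearson regression.

## Worked example

```python
from glymph import PhantomSpec, make_tensor_phantom, simulate_cohort, CohortModel
from glymph.phantom import fit_phantom_alps

# three-zone white-matter phantom at the study resolution, SNR 30
spec = PhantomSpec(snr=30.0)
print(make_tensor_phantom(spec).analytic_alps)   # 1.4  (ground truth)
print(fit_phantom_alps(spec, rng=0))             # {1000.0: 1.3985, 2000.0: 1.3877}

# synthetic 27 CN + 56 AD cohort and the full statistics battery
results = CohortModel(simulate_cohort(rng=42)).fit()
print(results.summary())
```

The phantom run simulates the 61-frame DWI protocol (1 b=0 + 30
directions at b=1000 and b=2000 s/mm²), fits per-shell tensors by
log-linear weighted least squares and recovers the ground-truth index
within ~1% at SNR 30. The cohort summary prints the group table (e.g.
ALPS b=1000: CN 1.417 ± 0.105 vs AD 1.296 ± 0.125, ANOVA p = 4.2e-05),
the Pearson regressions (ALPS vs centiloid slope −0.00185, r = −0.64),
and the normalized slopes against centiloid, where nDTI-ALPS is the
steepest (0.27 here) — the signature that perivascular dysfunction tracks
amyloid accumulation more closely than atrophy or cognition.

A command-line interface covers the same ground on files:

```sh
glymph run-all scenario.yaml        # simulate -> fit -> ALPS -> PET -> stats
glymph fit-dti dwi.nii dwi.bval dwi.bvec
glymph alps maps_prefix rois.nii rois.json --bvalue 1000
glymph pet-quant activity.nii meta.json rois.nii rois.json
glymph stats cohort.tsv
```

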