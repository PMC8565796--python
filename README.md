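# petnorm

Histogram-mode intensity normalization and voxel-wise statistics for
[18F]-FDG brain PET.

## The problem

Brain FDG-PET uptake varies between subjects for reasons that have nothing
to do with local metabolism: blood glucose, stress, injected dose, scanner
calibration. Before scans can be compared voxel by voxel — to build a
normal-brain atlas, or to ask where a patient's metabolism deviates from
it — each image must be rescaled by a single subject-specific factor.
How that factor is chosen matters: the common *global mean scaling*
(divide by the mean in-brain uptake) is biased whenever a lesion or
extracerebral spill-in shifts the mean, and *no* normalization leaves the
full inter-subject spread in place.

`petnorm` implements the data-driven *histogram-mode* alternative. Each
coregistered image *I* is divided voxel-wise by a population template *T*;
the in-brain ratios r_i = I_i / T_i are histogrammed (bin width 0.01) and
a Gaussian is fitted around the raw mode; the fitted peak — the most
prevalent ratio in the brain — is the normalization factor. Because the
mode of the ratio distribution ignores tail values, focal uptake changes
leave the factor untouched.

On top of the normalizers the package provides:

- **SUV conversion and preprocessing** — SUV = C · W / D (C voxel
  concentration in kBq/cc, D decay-corrected injected dose in kBq, W
  weight in g), cropping to a brain field of view, Gaussian smoothing
  (FWHM in mm), and integer-voxel center-of-mass alignment. Inputs are
  assumed coregistered on one grid.
- **Normal atlas construction** — initial template by voxel-wise
  averaging, brain mask as voxels above 50% of the template maximum,
  per-subject normalization, then voxel-wise mean μ_i and SD σ_i of the
  normalized stack. Per-voxel coefficient of variation CoV_i = 100 σ_i/μ_i
  (%) summarizes the residual between-subject variability per method.
- **Group analysis** — voxel-wise two-sample t (pooled variance) of a
  patient group against the normal subjects, Benjamini–Hochberg FDR across
  in-brain voxels (q = 0.05), split into increase/decrease maps.
- **Individual analysis** — Z-score maps z_i = (x_i − μ_i)/σ_i against the
  atlas, thresholded at the empirical 95% interval of each map's own
  in-brain values (the retained voxels are the 2.5% lowest and highest).
- **Digital phantoms** — populations of coregistered rat-brain-like
  volumes with known ground truth (log-normal global scales, voxel-wise
  multiplicative noise, optional spill-in heterogeneity and focal
  lesions), so every claim above is testable against generating
  parameters.

The normalizers and the atlas builder are scikit-learn style estimators
(`fit`/`transform`, fitted attributes with a trailing underscore) and
compose with sklearn tooling; plain functions wrap them for one-off use.

## Worked example

The `demo` subcommand runs the whole study design on synthetic data:
28 normal subjects build the atlas, then a 9-subject group with a focal
30% uptake drop and a 9-subject control group are compared against it.

```bash
petnorm demo --out demo/ --seed 7
```

prints (abridged):

```json
{
  "cov_by_method": {
    "histogram":   {"mean_cov_pct": 6.58,  "sd_cov_pct": 3.80},
    "global_mean": {"mean_cov_pct": 6.75,  "sd_cov_pct": 2.83},
    "none":        {"mean_cov_pct": 34.62, "sd_cov_pct": 1.34}
  },
  "group_stats": {
    "lesion":  {"fdr_t_threshold": 3.62, "n_sig_increase": 14, "n_sig_decrease": 910},
    "control": {"fdr_t_threshold": null, "n_sig_increase": 0,  "n_sig_decrease": 0}
  },
  "lesion_decrease_overlap": 1.0
}
```

Reading this: after histogram-mode normalization the mean in-brain CoV
across the 28 normals is 6.6%, versus 6.8% for global-mean scaling and
34.6% with no normalization — the factor removed essentially all of the
between-subject scale spread, leaving little more than the 5% voxel
noise. The lesioned group shows an FDR-significant decrease cluster
covering 100% of the true lesion (the handful of "increase" voxels is
within the 5% false-discovery budget that comes with ~900 discoveries),
while the control group shows nothing. `demo/` also contains the atlas
bundle (`atlas_mean/sd/mask.nii.gz` + metadata), per-subject factors
(`factors.csv`), t maps, significance masks, a thresholded Z map and a
run manifest with hashes of every output.

Library use mirrors the CLI:

```python
from petnorm import (PhantomSpec, make_template_phantom, sample_population,
                     NormalAtlas, HistogramNormalizer, group_ttest)

spec = PhantomSpec()                       # 80^3 grid, 0.4 mm voxels
template = make_template_phantom(spec)
normals = sample_population(template, 28, spec, seed=7)
atlas = NormalAtlas(method="histogram").fit([img for img, _ in normals])
print(atlas.factors_)                      # per-subject normalization factors
```

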