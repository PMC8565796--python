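# Methods

## Intensity normalization model

All methods in this package assume that between-subject variability in
brain FDG-PET is, to first order, a single multiplicative factor per
subject: subject *j*'s image is s_j · P(x) · ε(x), where P is a shared
uptake pattern, s_j a global scale (dose, glucose state, calibration) and
ε voxel noise. A scalar intensity normalization can remove exactly s_j,
nothing more; regional physiology that genuinely differs between subjects
stays in the data whatever factor is used.

Three estimators of s_j are implemented, all operating over the same
brain region (voxels strictly above 50% of the template maximum — the
mask is always derived from the *template*, never from the individual
image, so diseased scans are normalized over the same anatomy as the
normals):

- **Histogram mode.** Divide the image voxel-wise by the template,
  histogram the in-mask ratios in fixed 0.01-wide bins spanning (0, 3]
  (extended upward if larger ratios occur, so every in-mask ratio is
  counted), locate the raw mode (ties broken toward the lowest bin), and
  least-squares fit a Gaussian A·exp(−(r−c)²/2σ²) to the counts within
  ±0.15 ratio units of the mode. The factor is the fitted center c; if
  the fit fails (fewer than four occupied bins in the window,
  non-convergence, or a center outside the histogram) the raw mode bin
  center is used and the fallback is reported. The mode ignores ratio
  tails, so focal lesions and spill-in leave the factor unchanged.
- **Global mean.** The mean in-mask uptake. This is the least-squares
  optimal scalar for the image itself, which is precisely its weakness:
  any focal deviation moves it.
- **None.** Factor 1; SUV values pass through.

Whether the "maximum of the histogram" should be the raw mode or the
fitted peak is a genuinely open choice; the fitted center is used because
it is sub-bin accurate and deterministic, with the raw mode as an honest
fallback, and both are exposed in reports.

## Atlas construction

The atlas pipeline is: voxel-wise mean of the coregistered inputs
(initial template) → 50% mask → per-subject factor by the chosen method →
divide → voxel-wise mean and SD of the normalized stack. The SD uses the
sample (n−1) denominator, since the atlas estimates population
variability for Z-scoring new subjects. The per-voxel coefficient of
variation is CoV_i = 100 σ_i/μ_i (%), and the per-method summary is the
mean (± SD) of CoV over the same 50% mask from the initial template.

Because the initial template is built from *unnormalized* images, factors
estimated against it are identified only up to the population's mean
scale (a common constant). This does not affect CoV or any downstream
statistic, which are invariant to a common rescaling; parameter-recovery
tests therefore compare factors after dividing out the geometric mean of
each side. An optional `iterations > 1` replaces the template with the
normalized mean and repeats the loop, removing the (small) bias; the
default is the single pass of the standard workflow.

## Voxel-wise statistics

**Group level.** Two-sample t per in-mask voxel (pooled variance,
df = n₁+n₂−2, the SPM-style default; Welch available), two-sided p,
Benjamini–Hochberg step-up across all in-mask voxels at q = 0.05, with
the significant set split post hoc by the sign of t. Note what FDR does
and does not promise: with a strong one-sided signal (hundreds of true
lesion voxels), the BH threshold relaxes and admits ≈ q·(number
significant) false discoveries, roughly half of them on the wrong side.
A handful of spurious "increase" voxels alongside a large decrease
cluster is therefore expected behaviour, not an error; tests bound the
increases by the FDR budget rather than demanding an empty mask.

**Individual level.** z_i = (x_i − μ_i)/σ_i against the atlas; voxels
with σ_i = 0 are excluded and counted. The map is thresholded at the
empirical 2.5th/97.5th percentiles of its *own* in-mask values (linear
interpolation between order statistics), so by construction the
significant voxels are the 2.5% lowest and 2.5% highest values of that
image — a per-image descriptive threshold, not ±1.96. The 5% retention is
exact up to one-voxel rounding for continuous maps and degenerates to
empty masks when all values tie.

## The phantom generator

The generator emulates what the method assumes and what challenges it:

- geometry: an 80×80×80 grid of 0.4 mm voxels (a 32 mm field of view
  cropped around the brain); three concentric ellipsoidal compartments
  (relative uptake 1.0 / 1.4 / 0.8, semi-axes 12×9×8 mm) on a 10%
  background, blurred by a 1 mm FWHM system kernel;
- per-subject global scale, log-normal with σ_log = 0.3 (the spread a
  mixed dose/physiology population plausibly shows; it puts unnormalized
  CoV near 30%);
- voxel-wise multiplicative log-normal noise with unit mean and CV 5%
  (post-smoothing count noise at typical rodent FDG statistics);
- optional *spill-in heterogeneity*: a fixed anterior-ventral cap of the
  outer low-uptake shell (~14% of brain voxels) multiplied per subject by
  1 + U(0.2, 1.0), emulating variable spill-in from extracerebral hot
  structures such as the Harderian glands;
- optional focal lesions: a sphere intersected with the brain, multiplied
  by a factor < 1 (hypometabolism) identically across a diseased group.

Noise is applied after lesion insertion and nothing is blurred
afterwards, so the per-voxel ratio of a subject to the noiseless template
is exactly scale × noise (× focal factor inside its mask) — ground truth
stays exact.

The spill-in design deserves a note, because it is the feature that makes
the three methods rank the way they do on real data. For *mean-preserving
symmetric* heterogeneity inside the mask, global-mean scaling always
yields a lower across-subject CoV than mode scaling (the mean is the
least-squares scalar, and within a 50%-of-max mask a coherent region's
uptake share can never exceed twice its voxel share, the flip condition).
What ranks the mean below the mode in practice is *asymmetric hot
contamination*: strong positive focal deviations drag the uptake-weighted
mean image-by-image while the mode — and the template maximum — stay
put. The generator therefore models spill-in as hot, anatomically fixed
and variable in magnitude. With it enabled, mean in-mask CoV orders
histogram < global mean < none replicate after replicate, which is the
ordering property the package tests; the *absolute* CoV of the
global-mean method depends strongly on how much contamination one
simulates, so only the ordering (not the printed gap between histogram
and global-mean scaling on real animals) should be read into phantom
numbers.

What the phantom does **not** model: PET physics (attenuation, scatter,
reconstruction artifacts), anatomical variability requiring non-linear
registration, spatially correlated noise, partial-volume effects, or
additive offsets. Passing tests show the estimators do what they claim
under the multiplicative model; they do not certify performance under
registration error or reconstruction bias.

## Numerical choices and degenerate inputs

- All computation in float64; files written as float32 NIfTI-1.
- Smoothing uses reflective boundaries (avoids rim darkening in a cropped
  brain FOV); σ_vox = FWHM / (2√(2 ln 2)) / voxel size per axis.
- Center-of-mass alignment restricts the CoM to voxels above 25% of each
  volume's maximum — a raw intensity CoM is biased by background that
  does not move with the brain — and rounds to integer voxels,
  zero-filling vacated space. It is a convenience for roughly aligned
  inputs, not a registration method; the package's precondition is
  coregistered volumes.
- The 50% brain mask uses strict inequality ("larger than"). A constant
  positive template therefore yields a *full* mask (every value exceeds
  half of itself); the empty-mask error path exists but is unreachable
  for threshold fractions below 1.
- Ratio histograms require ≥100 in-mask voxels; Z-map thresholding
  requires ≥100 finite Z values.
- `bh_fdr` delegates to the standard step-up implementation and is
  checked against a brute-force enumeration in the tests.

## Problem sizes in tests

Single-run tests and the acceptance script use the full 80³ geometry with
n = 28 normals and 9-subject groups. Replicate-heavy checks (the 20-fold
CoV-ordering and clean-null loops) run on a geometrically scaled 48³ grid
(brain semi-axes 7.2×5.4×4.8 mm), and unit tests on a 32³ grid — chosen
as the smallest sizes at which masks still contain thousands of voxels
and the statistics are stable.

## Known limitations

- Inputs must already be coregistered on a common grid; no affine or
  diffeomorphic registration is provided.
- The histogram factor is bin-quantized when the Gaussian fit falls back
  to the raw mode (noise-free degenerate inputs); expect up to half a bin
  (0.005 ratio units) of quantization there.
- Reference-region normalization (cerebellum, pons) is out of scope.
- Decay correction is assumed done upstream; `to_suv` takes the
  decay-corrected dose as given.
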