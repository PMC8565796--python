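"""Digital rat-brain phantoms with known ground truth.

The generator emulates the statistical structure that histogram-mode
normalization assumes about a population of coregistered FDG brain
volumes: a shared uptake pattern (a compartmentalized ellipsoidal "brain"
on low background, blurred to system resolution), a per-subject
multiplicative global scale drawn log-normally, optional focal regional
perturbations, optional focal hypometabolic lesions, and voxel-wise
multiplicative log-normal noise of known coefficient of variation.

Subject variability is purely multiplicative — a single scalar per
subject — because that is exactly the degree of freedom a scalar
intensity normalization can remove.  Additive offsets are not modeled.
Noise is applied after lesion insertion; no further blur follows, so the
per-voxel ratio of a subject to the noiseless template is exactly
``global_scale`` times the noise (times any focal factor inside its mask).

Default geometry is an 80x80x80 grid of 0.4 mm voxels (a 32 mm
field of view cropped around the brain).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import ConfigurationError, DimensionError
from .image import VoxelImage, gaussian_smooth, write_volume


@dataclasses.dataclass
class PhantomSpec:
    """Geometry and noise model of a phantom population.

    ``compartment_levels`` are the relative uptake levels of concentric
    ellipsoidal compartments, listed from the innermost outward; their
    number defines the number of compartments.  ``background_uptake`` is a
    fraction of the mean in-brain level.  ``noise_cv`` is the coefficient
    of variation of the voxel-wise multiplicative noise.
    """

    grid_shape: tuple[int, int, int] = (80, 80, 80)
    voxel_size_mm: float = 0.4
    brain_center: Optional[tuple[int, int, int]] = None
    brain_semi_axes_mm: tuple[float, float, float] = (12.0, 9.0, 8.0)
    compartment_levels: tuple[float, ...] = (1.0, 1.4, 0.8)
    background_uptake: float = 0.1
    noise_cv: float = 0.05
    smoothing_fwhm_mm: float = 1.0
    seed: int = 0

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.brain_center is None:
            self.brain_center = tuple(s // 2 for s in self.grid_shape)
        self.brain_center = tuple(int(c) for c in self.brain_center)
        self.compartment_levels = tuple(float(v) for v in self.compartment_levels)
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 2 for s in self.grid_shape):
            raise ConfigurationError(f"invalid grid shape {self.grid_shape}")
        if self.voxel_size_mm <= 0:
            raise ConfigurationError("voxel_size_mm must be positive")
        if len(self.compartment_levels) < 1 or any(
            v <= 0 for v in self.compartment_levels
        ):
            raise ConfigurationError("compartment levels must be strictly positive")
        if self.background_uptake < 0 or self.noise_cv < 0 or self.smoothing_fwhm_mm < 0:
            raise ConfigurationError("background, noise CV and FWHM must be >= 0")
        for c, a, n in zip(self.brain_center, self.brain_semi_axes_mm, self.grid_shape):
            r_vox = a / self.voxel_size_mm
            if a <= 0:
                raise ConfigurationError("brain semi-axes must be positive")
            if c - r_vox < 0 or c + r_vox > n - 1:
                raise ConfigurationError(
                    f"brain ellipsoid (semi-axis {a} mm) does not fit inside the "
                    f"{n}-voxel grid at center {c}"
                )

    def normalized_radius(self) -> np.ndarray:
        """Per-voxel ellipsoidal radius rho; the brain is ``rho <= 1``."""
        grids = np.ogrid[tuple(slice(0, s) for s in self.grid_shape)]
        rho2 = np.zeros(self.grid_shape)
        for g, c, a in zip(grids, self.brain_center, self.brain_semi_axes_mm):
            rho2 = rho2 + ((g - c) * self.voxel_size_mm / a) ** 2
        return np.sqrt(rho2)

    def brain_mask(self) -> np.ndarray:
        return self.normalized_radius() <= 1.0


@dataclasses.dataclass
class SubjectGroundTruth:
    """Known generating parameters of one synthetic subject."""

    global_scale: float
    regional_perturbations: list[tuple[np.ndarray, float]] = dataclasses.field(
        default_factory=list
    )
    lesion_mask: Optional[np.ndarray] = None
    lesion_factor: float = 1.0

    def __post_init__(self):
        if self.global_scale <= 0:
            raise ConfigurationError("global_scale must be positive")


def make_template_phantom(spec: PhantomSpec) -> VoxelImage:
    """Noiseless reference uptake map (deterministic; no RNG).

    Concentric ellipsoidal compartments at ``spec.compartment_levels`` on a
    background of ``background_uptake`` times the mean in-brain level, then
    blurred by ``smoothing_fwhm_mm``.
    """
    rho = spec.normalized_radius()
    brain = rho <= 1.0
    k = len(spec.compartment_levels)
    # compartment index: rho in ((i-1)/k, i/k] -> level i-1
    idx = np.clip(np.ceil(rho * k).astype(int), 1, k) - 1
    data = np.where(brain, np.take(spec.compartment_levels, idx), 0.0)
    mean_brain = float(data[brain].mean())
    data = np.where(brain, data, spec.background_uptake * mean_brain)
    img = VoxelImage(data, spec.voxel_size_mm, unit="SUV")
    if spec.smoothing_fwhm_mm > 0:
        img = gaussian_smooth(img, spec.smoothing_fwhm_mm)
    return img


def sample_subject(
    template: VoxelImage,
    truth: SubjectGroundTruth,
    spec: PhantomSpec,
    rng_seed: int,
) -> VoxelImage:
    """One subject: template x scale, focal factors, then multiplicative noise.

    Noise is log-normal with unit mean and coefficient of variation
    ``spec.noise_cv``, so images stay positive and the voxel-wise CV across
    subjects (after dividing out true scales) converges to ``noise_cv``.
    """
    data = template.data * truth.global_scale
    for mask, factor in truth.regional_perturbations:
        if mask.shape != data.shape:
            raise DimensionError(
                f"perturbation mask shape {mask.shape} != image shape {data.shape}"
            )
        data = np.where(mask, data * factor, data)
    if truth.lesion_mask is not None:
        if truth.lesion_mask.shape != data.shape:
            raise DimensionError(
                f"lesion mask shape {truth.lesion_mask.shape} != image shape {data.shape}"
            )
        data = np.where(truth.lesion_mask, data * truth.lesion_factor, data)
    if spec.noise_cv > 0:
        rng = np.random.default_rng(rng_seed)
        sigma = np.sqrt(np.log1p(spec.noise_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=data.shape)
        data = data * noise
    return template.with_data(data)


def spherical_lesion_mask(
    spec: PhantomSpec,
    center: Sequence[int] | None = None,
    radius_mm: float = 2.4,
) -> np.ndarray:
    """Spherical focal region, intersected with the brain so it stays a
    connected subset of brain voxels.  Default center sits inside the brain
    off-axis (a striatum-like site)."""
    if center is None:
        center = tuple(
            int(c + 0.4 * a / spec.voxel_size_mm)
            for c, a in zip(spec.brain_center, spec.brain_semi_axes_mm)
        )
    grids = np.ogrid[tuple(slice(0, s) for s in spec.grid_shape)]
    d2 = sum(((g - c) * spec.voxel_size_mm) ** 2 for g, c in zip(grids, center))
    return (d2 <= radius_mm**2) & spec.brain_mask()


def perturbation_region(spec: PhantomSpec, fraction: float = 0.14) -> np.ndarray:
    """Fixed anterior-ventral boundary region covering ~``fraction`` of the brain.

    Emulates spill-in from extracerebral hot structures (Harderian glands
    and the like) whose apparent uptake varies strongly between subjects:
    the anatomy is fixed, only the magnitude varies.  The region is a cap
    of the outermost ellipsoidal shell (radius fraction > 0.72) facing a
    fixed anterior-ventral direction, so it stays within the low-uptake
    peripheral compartment and leaves the template maximum in clean
    central tissue.
    """
    rho = spec.normalized_radius()
    brain = rho <= 1.0
    shell = (rho > 0.72) & brain
    # normalized direction coordinates for the cap orientation
    grids = np.ogrid[tuple(slice(0, s) for s in spec.grid_shape)]
    direction = np.array([0.55, -0.6, -0.35])
    direction /= np.linalg.norm(direction)
    proj = np.zeros(spec.grid_shape)
    for g, c, a, d in zip(grids, spec.brain_center, spec.brain_semi_axes_mm, direction):
        proj = proj + (g - c) * spec.voxel_size_mm / a * d
    n_target = int(fraction * brain.sum())
    if n_target >= shell.sum():
        return shell
    cutoff = np.quantile(proj[shell], 1.0 - n_target / shell.sum())
    return shell & (proj >= cutoff)


def sample_population(
    template: VoxelImage,
    n_subjects: int,
    spec: PhantomSpec,
    seed: int | None = None,
    scale_median: float = 1.0,
    scale_sigma_log: float = 0.3,
    regional_perturbations: bool = False,
    perturbation_fraction: float = 0.14,
    perturbation_magnitude_range: tuple[float, float] = (0.2, 1.0),
    lesion_mask: Optional[np.ndarray] = None,
    lesion_factor: float = 1.0,
) -> list[tuple[VoxelImage, SubjectGroundTruth]]:
    """A population of subjects with independently drawn global scales.

    Scales are log-normal: ``scale = scale_median * exp(N(0, scale_sigma_log))``.
    With ``regional_perturbations`` every subject carries a hot focal region
    at a fixed anatomical site (default ~14% of brain voxels; see
    :func:`perturbation_region`) whose multiplicative factor 1 + u, u uniform
    in ``perturbation_magnitude_range``, varies per subject — emulating
    variable spill-in from extracerebral structures.  Such asymmetric hot
    contamination drags the uptake-weighted in-brain mean without moving the
    histogram mode, which is what separates global-mean from histogram-mode
    scaling.  ``lesion_mask``/``lesion_factor``, when given, are
    applied identically to every subject (a diseased group).
    """
    if n_subjects < 2:
        raise ConfigurationError(f"need at least 2 subjects, got {n_subjects}")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    pert_region = (
        perturbation_region(spec, perturbation_fraction)
        if regional_perturbations
        else None
    )
    population = []
    for _ in range(n_subjects):
        scale = scale_median * np.exp(rng.normal(0.0, scale_sigma_log))
        perturbations = []
        if regional_perturbations:
            factor = 1.0 + rng.uniform(*perturbation_magnitude_range)
            perturbations.append((pert_region, factor))
        truth = SubjectGroundTruth(
            global_scale=float(scale),
            regional_perturbations=perturbations,
            lesion_mask=lesion_mask,
            lesion_factor=lesion_factor,
        )
        subject_seed = int(rng.integers(2**31))
        population.append((sample_subject(template, truth, spec, subject_seed), truth))
    return population


def write_population(
    population: list[tuple[VoxelImage, SubjectGroundTruth]],
    out_dir: str | Path,
    spec: PhantomSpec,
    seed: int | None = None,
) -> Path:
    """Write subjects as NIfTI plus a JSON ground-truth manifest.

    Returns the manifest path.  The manifest records per-subject true scale
    and lesion bounding box, plus the generating seed and geometry.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, (img, truth) in enumerate(population):
        name = f"subject_{i:03d}.nii.gz"
        write_volume(img, out_dir / name)
        bbox = None
        if truth.lesion_mask is not None and truth.lesion_mask.any():
            idx = np.argwhere(truth.lesion_mask)
            bbox = [idx.min(axis=0).tolist(), idx.max(axis=0).tolist()]
        records.append(
            {
                "file": name,
                "global_scale": truth.global_scale,
                "lesion_factor": truth.lesion_factor,
                "lesion_bbox": bbox,
            }
        )
    manifest = {
        "seed": spec.seed if seed is None else seed,
        "grid_shape": list(spec.grid_shape),
        "voxel_size_mm": spec.voxel_size_mm,
        "noise_cv": spec.noise_cv,
        "subjects": records,
    }
    manifest_path = out_dir / "ground_truth.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path
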