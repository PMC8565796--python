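"""Normal-brain atlas construction and coefficient-of-variation maps.

The atlas workflow: average the coregistered population into an initial
template, derive the brain mask (voxels above 50% of the template
maximum), compute a per-subject normalization factor with the chosen
method, divide each image by its factor, and take the voxel-wise mean and
standard deviation of the normalized stack.  The per-voxel coefficient of
variation, CoV_i = 100 * sigma_i / mu_i (%), measures the residual
between-subject variability each normalization method leaves behind; its
in-mask mean is the headline summary for comparing methods.

The population SD uses the sample (n-1) denominator, since the atlas is
an estimate of population variability used for Z-scoring new subjects.
An optional second iteration replaces the template with the normalized
mean and repeats the normalize/average loop, removing the small bias of
building the initial template from unnormalized images; the default is a
single pass.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, DimensionError, NumericalDomainError, ValidationError
from .image import VoxelImage, read_volume, write_volume
from .normalize import BrainMask, brain_mask_from_template, make_normalizer


@dataclasses.dataclass
class AtlasTemplate:
    """Voxel-wise mean/SD over a normalized normal population."""

    mean_img: VoxelImage
    sd_img: VoxelImage
    n_subjects: int
    mask: BrainMask
    method: str = "histogram"

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ConfigurationError("an atlas needs at least 2 subjects")
        shapes = {self.mean_img.shape, self.sd_img.shape, self.mask.mask.shape}
        if len(shapes) != 1:
            raise DimensionError(f"incongruent atlas grids: {shapes}")
        if np.any(self.sd_img.data < 0):
            raise ValidationError("sd_img must be nonnegative")


def build_initial_template(images: Sequence[VoxelImage]) -> VoxelImage:
    """Voxel-wise arithmetic mean of two or more congruent images."""
    if len(images) < 2:
        raise ConfigurationError(f"need at least 2 images, got {len(images)}")
    shape = images[0].shape
    for img in images[1:]:
        if img.shape != shape:
            raise DimensionError(f"shape mismatch: {img.shape} vs {shape}")
    stack = np.stack([img.data for img in images])
    return images[0].with_data(stack.mean(axis=0))


class NormalAtlas(BaseEstimator):
    """Build a normal atlas from a population of coregistered images.

    Parameters
    ----------
    method : {"histogram", "global_mean", "none"}, default "histogram"
        Per-subject normalization applied before averaging.
    threshold_fraction : float, default 0.5
        Brain-mask threshold as a fraction of the template maximum.
    bin_width, r_max, fit_halfwidth : float
        Ratio-histogram parameters (histogram method only).
    iterations : int, default 1
        Number of normalize/average passes; the template of pass k+1 is the
        mean image of pass k.
    ddof : int, default 1
        Delta degrees of freedom of the voxel-wise SD (1 = sample SD).

    Attributes
    ----------
    initial_template_ : VoxelImage
        Mean of the raw input images.
    mask_ : BrainMask
        Brain region from the initial template (also used for CoV summaries).
    mean_img_, sd_img_ : VoxelImage
        Voxel-wise mean and SD of the normalized stack.
    factors_ : ndarray of shape (n_subjects,)
        Normalization factor per subject (last iteration).
    fit_converged_ : list of bool
        Gaussian-fit convergence per subject (histogram method; else all True).
    normalized_images_ : list of VoxelImage
        The normalized subjects the atlas was averaged from.
    """

    def __init__(
        self,
        method: str = "histogram",
        threshold_fraction: float = 0.5,
        bin_width: float = 0.01,
        r_max: float = 3.0,
        fit_halfwidth: float = 0.15,
        iterations: int = 1,
        ddof: int = 1,
    ):
        self.method = method
        self.threshold_fraction = threshold_fraction
        self.bin_width = bin_width
        self.r_max = r_max
        self.fit_halfwidth = fit_halfwidth
        self.iterations = iterations
        self.ddof = ddof

    def _make_normalizer(self):
        if self.method == "histogram":
            return make_normalizer(
                "histogram",
                threshold_fraction=self.threshold_fraction,
                bin_width=self.bin_width,
                r_max=self.r_max,
                fit_halfwidth=self.fit_halfwidth,
            )
        return make_normalizer(self.method, threshold_fraction=self.threshold_fraction)

    def fit(self, images: Sequence[VoxelImage], y=None):
        """Run the template -> mask -> normalize -> average pipeline."""
        if self.iterations < 1:
            raise ConfigurationError("iterations must be >= 1")
        template = build_initial_template(images)
        self.initial_template_ = template
        self.mask_ = brain_mask_from_template(template, self.threshold_fraction)
        for _ in range(self.iterations):
            normalizer = self._make_normalizer().fit(template)
            results = [normalizer.normalize(img) for img in images]
            stack = np.stack([r.normalized_image.data for r in results])
            template = images[0].with_data(stack.mean(axis=0), unit="normalized")
        self.factors_ = np.array([r.factor for r in results])
        self.fit_converged_ = [
            r.histogram.fit_converged if r.histogram is not None else True
            for r in results
        ]
        self.normalized_images_ = [r.normalized_image for r in results]
        self.mean_img_ = template
        self.sd_img_ = images[0].with_data(
            stack.std(axis=0, ddof=self.ddof), unit="normalized"
        )
        self.n_subjects_ = len(images)
        return self

    def as_template(self) -> AtlasTemplate:
        return AtlasTemplate(
            self.mean_img_, self.sd_img_, self.n_subjects_, self.mask_, self.method
        )

    def save(self, out_dir: str | Path) -> None:
        """Write the atlas bundle: mean, SD, mask volumes and metadata JSON."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_volume(self.mean_img_, out_dir / "atlas_mean.nii.gz")
        write_volume(self.sd_img_, out_dir / "atlas_sd.nii.gz")
        mask_img = self.mean_img_.with_data(
            self.mask_.mask.astype(float), unit="statistic"
        )
        write_volume(mask_img, out_dir / "atlas_mask.nii.gz")
        meta = {
            "n_subjects": self.n_subjects_,
            "method": self.method,
            "threshold_fraction": self.threshold_fraction,
            "bin_width": self.bin_width,
            "iterations": self.iterations,
            "ddof": self.ddof,
            "factors": self.factors_.tolist(),
            "fit_converged": self.fit_converged_,
        }
        (out_dir / "atlas_meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, in_dir: str | Path) -> "NormalAtlas":
        """Reload a saved atlas bundle (without the per-subject images)."""
        in_dir = Path(in_dir)
        meta = json.loads((in_dir / "atlas_meta.json").read_text())
        atlas = cls(
            method=meta["method"],
            threshold_fraction=meta["threshold_fraction"],
            bin_width=meta["bin_width"],
            iterations=meta["iterations"],
            ddof=meta["ddof"],
        )
        atlas.mean_img_ = read_volume(in_dir / "atlas_mean.nii.gz", unit="normalized")
        atlas.sd_img_ = read_volume(in_dir / "atlas_sd.nii.gz", unit="normalized")
        mask_img = read_volume(in_dir / "atlas_mask.nii.gz", unit="statistic")
        atlas.mask_ = BrainMask(mask_img.data > 0.5, threshold_fraction=meta["threshold_fraction"])
        atlas.factors_ = np.array(meta["factors"])
        atlas.fit_converged_ = meta["fit_converged"]
        atlas.n_subjects_ = meta["n_subjects"]
        return atlas


def build_atlas(
    images: Sequence[VoxelImage],
    method: str = "histogram",
    threshold_fraction: float = 0.5,
    iterations: int = 1,
    **params,
) -> AtlasTemplate:
    """Functional wrapper: fit a :class:`NormalAtlas` and return the template."""
    atlas = NormalAtlas(
        method=method,
        threshold_fraction=threshold_fraction,
        iterations=iterations,
        **params,
    ).fit(images)
    return atlas.as_template()


def cov_map(atlas: AtlasTemplate) -> VoxelImage:
    """Per-voxel coefficient of variation, 100 * sigma_i / mu_i (%), in-mask.

    Out-of-mask voxels are NaN.  A nonpositive mean inside the mask is a
    :class:`~petnorm.errors.NumericalDomainError`.
    """
    m = atlas.mask.mask
    mu = atlas.mean_img.data
    if np.any(mu[m] <= 0):
        voxel = tuple(int(i) for i in np.argwhere(m & (mu <= 0))[0])
        raise NumericalDomainError(
            f"atlas mean is nonpositive inside the mask, e.g. at voxel {voxel}"
        )
    out = np.full(mu.shape, np.nan)
    out[m] = 100.0 * atlas.sd_img.data[m] / mu[m]
    return atlas.mean_img.with_data(out, unit="statistic")


def relative_reduction(value: float, baseline: float) -> float:
    """Percent reduction of ``value`` relative to ``baseline``.

    Used to compare mean-CoV summaries between normalization methods:
    ``relative_reduction(6.0, 30.0) == 80.0`` means 80% lower variability.
    """
    if baseline <= 0:
        raise ValidationError(f"baseline must be positive, got {baseline}")
    return 100.0 * (baseline - value) / baseline


def mean_cov(cov_img: VoxelImage, mask: BrainMask) -> tuple[float, float]:
    """Mean and SD of in-mask CoV values (the per-method summary statistic)."""
    values = cov_img.data[mask.mask]
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValidationError("no finite CoV values inside the mask")
    return float(values.mean()), float(values.std(ddof=1)) if values.size > 1 else 0.0
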