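"""Intensity normalization: histogram-mode, global-mean, and none.

The histogram-mode (data-driven) method divides an image voxel-wise by a
population template, histograms the ratios inside the brain region, and
takes the most prevalent ratio — the histogram peak — as the scalar
normalization factor.  Because the mode of the ratio distribution ignores
tail values, the factor is robust to focal lesions that would drag the
in-brain mean.  Global-mean scaling uses that mean instead and is biased
by exactly such lesions; "none" passes SUV images through unchanged.

The brain region is always derived from the template (voxels above 50% of
the template maximum), never from the individual image, so that diseased
scans are normalized over the same anatomy as the normals.

Estimators follow the scikit-learn convention: construct with
hyper-parameters, ``fit`` on the template, then ``transform`` individual
images (or call ``normalize`` for the full result including the fitted
ratio histogram and the factor).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import DimensionError, NumericalDomainError, ValidationError
from .image import VoxelImage

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class BrainMask:
    """Boolean brain region derived from a template by intensity threshold."""

    mask: np.ndarray
    source_template_id: str = ""
    threshold_fraction: float = 0.5

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise DimensionError("mask must be 3D")
        if not self.mask.any():
            raise ValidationError("brain mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclasses.dataclass
class RatioHistogram:
    """Histogram of subject/template ratios with a Gaussian peak fit."""

    bin_edges: np.ndarray
    counts: np.ndarray
    raw_mode_bin_center: float
    gauss_amplitude: float = np.nan
    gauss_center: float = np.nan
    gauss_sigma: float = np.nan
    fit_converged: bool = False

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def peak(self) -> float:
        """The most prevalent ratio: Gaussian center if the fit converged,
        else the raw mode bin center."""
        return self.gauss_center if self.fit_converged else self.raw_mode_bin_center


@dataclasses.dataclass
class NormalizationResult:
    """Outcome of normalizing one image: the factor and the scaled image."""

    method: str
    factor: float
    normalized_image: VoxelImage
    histogram: Optional[RatioHistogram] = None


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------

def brain_mask_from_template(
    template: VoxelImage, threshold_fraction: float = 0.5
) -> BrainMask:
    """Voxels strictly above ``threshold_fraction`` of the template maximum.

    The inequality is strict, so a constant template yields an empty mask,
    which is an error.
    """
    if not 0 < threshold_fraction < 1:
        raise ValidationError(f"threshold_fraction must be in (0,1), got {threshold_fraction}")
    vmax = float(np.max(template.data))
    if vmax <= 0:
        raise ValidationError("template has no positive values")
    mask = template.data > threshold_fraction * vmax
    if not mask.any():
        raise ValidationError(
            "brain mask is empty (no voxel strictly exceeds the threshold)"
        )
    return BrainMask(mask, threshold_fraction=threshold_fraction)


def ratio_image(img: VoxelImage, template: VoxelImage, mask: BrainMask) -> VoxelImage:
    """Voxel-wise img/template inside the mask; NaN outside (excluded downstream)."""
    if img.shape != template.shape or img.shape != mask.mask.shape:
        raise DimensionError(
            f"incongruent grids: image {img.shape}, template {template.shape}, "
            f"mask {mask.mask.shape}"
        )
    m = mask.mask
    zero = m & (template.data == 0)
    if zero.any():
        voxel = tuple(int(i) for i in np.argwhere(zero)[0])
        raise NumericalDomainError(
            f"template is zero inside the mask, e.g. at voxel {voxel}"
        )
    out = np.full(img.shape, np.nan)
    out[m] = img.data[m] / template.data[m]
    return img.with_data(out, unit="ratio")


def _gaussian(x, amplitude, center, sigma):
    return amplitude * np.exp(-0.5 * ((x - center) / sigma) ** 2)


def ratio_histogram(
    ratio_img: VoxelImage,
    mask: BrainMask,
    bin_width: float = 0.01,
    r_max: float = 3.0,
    fit_halfwidth: float = 0.15,
    min_voxels: int = 100,
) -> RatioHistogram:
    """Fixed-width histogram of in-mask ratios with a Gaussian fit at the peak.

    Bins of ``bin_width`` span from 0 up to at least ``r_max`` (extended to
    cover the largest observed ratio, so every in-mask finite ratio is
    counted).  The raw mode is the argmax bin (ties broken toward the lowest
    ratio).  A Gaussian is least-squares fitted to the counts within
    ``fit_halfwidth`` ratio units of the raw mode; convergence is reported
    honestly and the raw mode remains available as a fallback.
    """
    values = ratio_img.data[mask.mask]
    values = values[np.isfinite(values)]
    if values.size < min_voxels:
        raise ValidationError(
            f"only {values.size} in-mask ratios; need at least {min_voxels}"
        )
    top = max(r_max, float(values.max()) + bin_width)
    n_bins = int(np.ceil(top / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(values, bins=edges)
    mode_bin = int(np.argmax(counts))
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode_center = float(centers[mode_bin])

    hist = RatioHistogram(edges, counts, mode_center)
    window = np.abs(centers - mode_center) <= fit_halfwidth
    x, y = centers[window], counts[window].astype(float)
    if np.count_nonzero(y) >= 4:
        p0 = (float(counts[mode_bin]), mode_center, max(5 * bin_width, 0.02))
        try:
            popt, _ = curve_fit(_gaussian, x, y, p0=p0, maxfev=5000)
            amplitude, center, sigma = popt
            sigma = abs(float(sigma))
            if (
                np.isfinite([amplitude, center, sigma]).all()
                and amplitude > 0
                and sigma > 0
                and edges[0] < center < edges[-1]
            ):
                hist.gauss_amplitude = float(amplitude)
                hist.gauss_center = float(center)
                hist.gauss_sigma = sigma
                hist.fit_converged = True
        except RuntimeError:
            pass
    if not hist.fit_converged:
        logger.warning(
            "Gaussian peak fit did not converge; falling back to raw mode bin "
            "center %.4f", mode_center,
        )
    return hist


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class _TemplateNormalizer(BaseEstimator, TransformerMixin):
    """Shared fit/transform plumbing for template-based normalizers."""

    method: str = ""

    def fit(self, template: VoxelImage, y=None):
        """Derive the brain mask from the template and store both."""
        self.template_ = template
        self.mask_ = brain_mask_from_template(template, self.threshold_fraction)
        return self

    def _check_fitted(self):
        if not hasattr(self, "mask_"):
            raise ValidationError(f"{type(self).__name__} is not fitted")

    def factor(self, img: VoxelImage) -> float:
        return self.normalize(img).factor

    def transform(self, img: VoxelImage) -> VoxelImage:
        return self.normalize(img).normalized_image

    def normalize(self, img: VoxelImage) -> NormalizationResult:  # pragma: no cover
        raise NotImplementedError


class HistogramNormalizer(_TemplateNormalizer):
    """Histogram-mode normalization against a template.

    Parameters
    ----------
    threshold_fraction : float, default 0.5
        Brain region = template voxels strictly above this fraction of the
        template maximum.
    bin_width : float, default 0.01
        Ratio-histogram bin width (ratio units).
    r_max : float, default 3.0
        Minimum upper edge of the histogram range.
    fit_halfwidth : float, default 0.15
        Half-width (ratio units) of the Gaussian fit window around the raw
        mode.

    Attributes
    ----------
    template_ : VoxelImage
        The template fitted against.
    mask_ : BrainMask
        Brain region derived from the template.
    """

    method = "histogram"

    def __init__(
        self,
        threshold_fraction: float = 0.5,
        bin_width: float = 0.01,
        r_max: float = 3.0,
        fit_halfwidth: float = 0.15,
    ):
        self.threshold_fraction = threshold_fraction
        self.bin_width = bin_width
        self.r_max = r_max
        self.fit_halfwidth = fit_halfwidth

    def normalize(self, img: VoxelImage) -> NormalizationResult:
        self._check_fitted()
        ratios = ratio_image(img, self.template_, self.mask_)
        hist = ratio_histogram(
            ratios,
            self.mask_,
            bin_width=self.bin_width,
            r_max=self.r_max,
            fit_halfwidth=self.fit_halfwidth,
        )
        factor = hist.peak
        normalized = img.with_data(img.data / factor, unit="normalized")
        return NormalizationResult("histogram", factor, normalized, hist)


class GlobalMeanNormalizer(_TemplateNormalizer):
    """Whole-brain (global mean) scaling: factor = mean in-brain uptake."""

    method = "global_mean"

    def __init__(self, threshold_fraction: float = 0.5):
        self.threshold_fraction = threshold_fraction

    def normalize(self, img: VoxelImage) -> NormalizationResult:
        self._check_fitted()
        if img.shape != self.mask_.mask.shape:
            raise DimensionError(
                f"image shape {img.shape} != mask shape {self.mask_.mask.shape}"
            )
        factor = float(img.data[self.mask_.mask].mean())
        if factor == 0:
            raise NumericalDomainError("in-mask mean is zero")
        normalized = img.with_data(img.data / factor, unit="normalized")
        return NormalizationResult("global_mean", factor, normalized)


class NoNormalizer(_TemplateNormalizer):
    """Pass-through: factor 1, image and unit unchanged (SUV analysis)."""

    method = "none"

    def __init__(self, threshold_fraction: float = 0.5):
        self.threshold_fraction = threshold_fraction

    def normalize(self, img: VoxelImage) -> NormalizationResult:
        return NormalizationResult("none", 1.0, img.copy())


NORMALIZERS = {
    "histogram": HistogramNormalizer,
    "global_mean": GlobalMeanNormalizer,
    "none": NoNormalizer,
}


def make_normalizer(method: str, **params) -> _TemplateNormalizer:
    """Instantiate a normalizer by method name."""
    try:
        cls = NORMALIZERS[method]
    except KeyError:
        raise ValidationError(
            f"unknown method {method!r}; expected one of {sorted(NORMALIZERS)}"
        ) from None
    return cls(**params)


# ---------------------------------------------------------------------------
# Functional wrappers
# ---------------------------------------------------------------------------

def normalization_factor_histogram(
    img: VoxelImage, template: VoxelImage, mask: BrainMask | None = None, **params
) -> NormalizationResult:
    """Histogram-mode normalization of one image against a template."""
    norm = HistogramNormalizer(**params)
    norm.template_ = template
    norm.mask_ = mask or brain_mask_from_template(template, norm.threshold_fraction)
    return norm.normalize(img)


def normalization_factor_global_mean(
    img: VoxelImage, mask: BrainMask
) -> NormalizationResult:
    """Global-mean scaling of one image over a given brain mask."""
    norm = GlobalMeanNormalizer()
    norm.mask_ = mask
    return norm.normalize(img)


def normalize_none(img: VoxelImage) -> NormalizationResult:
    """No normalization: factor 1, values passed through as SUVs."""
    return NoNormalizer().normalize(img)
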