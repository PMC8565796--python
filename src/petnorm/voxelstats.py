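"""Voxel-wise statistics against the normal atlas.

Two analysis levels:

* **Group**: per-voxel two-sample t-test (pooled variance by default, as
  in SPM-style group comparisons; Welch optional) between a patient group
  and the normal subjects, with Benjamini-Hochberg FDR correction across
  all in-mask voxels and the significant set split by the sign of t.

* **Individual**: a Z-score map z_i = (x_i - mu_i) / sigma_i against the
  atlas mean and SD, thresholded at the empirical 95% interval of the
  map's own in-brain Z values — the retained voxels are by construction
  the 2.5% lowest and 2.5% highest values of that image.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import AtlasTemplate
from .errors import ConfigurationError, DimensionError, ValidationError
from .image import VoxelImage
from .normalize import BrainMask

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class StatMap:
    """A 3D statistic map (t or Z) with optional two-sided thresholds."""

    values: np.ndarray
    kind: str
    mask: BrainMask
    threshold_low: Optional[float] = None
    threshold_high: Optional[float] = None
    sig_mask_low: Optional[np.ndarray] = None
    sig_mask_high: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.kind not in ("t", "z"):
            raise ValidationError(f"kind must be 't' or 'z', got {self.kind!r}")
        if self.values.shape != self.mask.mask.shape:
            raise DimensionError("statistic grid incongruent with mask")
        for sig in (self.sig_mask_low, self.sig_mask_high):
            if sig is not None and np.any(sig & ~self.mask.mask):
                raise ValidationError("significance mask extends outside the brain mask")
        if self.sig_mask_low is not None and self.sig_mask_high is not None:
            if np.any(self.sig_mask_low & self.sig_mask_high):
                raise ValidationError("low/high significance masks overlap")

    def in_mask_values(self) -> np.ndarray:
        v = self.values[self.mask.mask]
        return v[np.isfinite(v)]


@dataclasses.dataclass
class GroupTestResult:
    """Voxel-wise group comparison with FDR-corrected significance."""

    t_map: StatMap
    p_map: np.ndarray
    q_threshold: float
    fdr_t_threshold: float
    n_group: int
    n_atlas: int
    sig_increase: np.ndarray
    sig_decrease: np.ndarray


def zscore_map(subject: VoxelImage, atlas: AtlasTemplate) -> StatMap:
    """Per-voxel z = (x_i - mu_i) / sigma_i inside the atlas brain mask.

    Voxels with sigma_i = 0 are excluded (NaN) and their count logged.
    """
    if subject.shape != atlas.mean_img.shape:
        raise DimensionError(
            f"subject shape {subject.shape} != atlas shape {atlas.mean_img.shape}"
        )
    m = atlas.mask.mask
    sd = atlas.sd_img.data
    degenerate = m & (sd == 0)
    if degenerate.any():
        logger.warning(
            "%d in-mask voxels have zero atlas SD and are excluded from the Z map",
            int(degenerate.sum()),
        )
    out = np.full(subject.shape, np.nan)
    valid = m & (sd > 0)
    out[valid] = (subject.data[valid] - atlas.mean_img.data[valid]) / sd[valid]
    return StatMap(out, "z", atlas.mask)


def threshold_zmap_95(zmap: StatMap, min_voxels: int = 100) -> StatMap:
    """Threshold a Z map at the empirical 95% interval of its own values.

    The thresholds are the 2.5th and 97.5th percentiles (linear
    interpolation between order statistics) of the in-mask Z values of this
    map; the significant voxels are those strictly outside, i.e. the 2.5%
    lowest and 2.5% highest values.  If all values are tied the percentiles
    coincide and both significance masks are empty.
    """
    values = zmap.in_mask_values()
    if values.size < min_voxels:
        raise ValidationError(
            f"only {values.size} in-mask Z values; need at least {min_voxels}"
        )
    low, high = np.percentile(values, [2.5, 97.5])
    finite = np.isfinite(zmap.values)
    sig_low = zmap.mask.mask & finite & (zmap.values < low)
    sig_high = zmap.mask.mask & finite & (zmap.values > high)
    return StatMap(
        zmap.values, zmap.kind, zmap.mask,
        threshold_low=float(low), threshold_high=float(high),
        sig_mask_low=sig_low, sig_mask_high=sig_high,
    )


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up across a p-value vector.

    Returns the boolean significance vector and the largest significant
    p-value (0.0 when nothing is significant).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    p_threshold = float(p[reject].max()) if reject.any() else 0.0
    return reject, p_threshold


def group_ttest(
    group: Sequence[VoxelImage],
    atlas_subjects: Sequence[VoxelImage],
    mask: BrainMask,
    q: float = 0.05,
    equal_var: bool = True,
) -> GroupTestResult:
    """Voxel-wise two-sample t-test of a group against the normal subjects.

    Pooled-variance t (df = n1 + n2 - 2) by default, two-sided p, BH-FDR
    across all in-mask voxels at level ``q``.  ``fdr_t_threshold`` is the
    smallest |t| among significant voxels (NaN when nothing is
    significant); the significant set is split by the sign of t into
    increase (group > normals) and decrease masks.
    """
    if len(group) < 2 or len(atlas_subjects) < 2:
        raise ConfigurationError(
            f"both groups need >= 2 subjects, got {len(group)} and {len(atlas_subjects)}"
        )
    shape = mask.mask.shape
    for img in list(group) + list(atlas_subjects):
        if img.shape != shape:
            raise DimensionError(f"image shape {img.shape} != mask shape {shape}")
    m = mask.mask
    a = np.stack([img.data[m] for img in group])
    b = np.stack([img.data[m] for img in atlas_subjects])
    t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    significant, _ = bh_fdr(p, q)

    t_grid = np.full(shape, np.nan)
    p_grid = np.full(shape, np.nan)
    t_grid[m] = t
    p_grid[m] = p
    sig_grid = np.zeros(shape, dtype=bool)
    sig_grid[m] = significant
    sig_increase = sig_grid & (t_grid > 0)
    sig_decrease = sig_grid & (t_grid < 0)
    fdr_t = float(np.abs(t[significant]).min()) if significant.any() else float("nan")
    t_map = StatMap(t_grid, "t", mask)
    return GroupTestResult(
        t_map=t_map,
        p_map=p_grid,
        q_threshold=q,
        fdr_t_threshold=fdr_t,
        n_group=len(group),
        n_atlas=len(atlas_subjects),
        sig_increase=sig_increase,
        sig_decrease=sig_decrease,
    )
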