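"""End-to-end study pipeline: phantom -> atlas -> group and individual stats.

Mirrors the full study design on synthetic data: a cohort of normal
subjects builds the atlas; a lesioned group and a control group are then
normalized against it and compared voxel-wise.  A single
:class:`RunConfig` drives all stages and every stochastic step derives
from one seed, so a run is reproducible end to end; the manifest records
parameters, per-subject factors, thresholds and output hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas import NormalAtlas, cov_map, mean_cov
from .errors import ConfigurationError
from .image import write_volume
from .normalize import HistogramNormalizer
from .phantom import (
    PhantomSpec,
    make_template_phantom,
    sample_population,
    spherical_lesion_mask,
)
from .voxelstats import group_ttest, threshold_zmap_95, zscore_map


@dataclasses.dataclass
class RunConfig:
    """Parameters of a full demo run; round-trips losslessly through YAML."""

    n_normal: int = 28
    n_lesion: int = 9
    n_control: int = 9
    grid: int = 80
    voxel_size_mm: float = 0.4
    noise_cv: float = 0.05
    scale_sigma_log: float = 0.3
    lesion_factor: float = 0.7
    lesion_radius_mm: float = 2.4
    method: str = "histogram"
    threshold_fraction: float = 0.5
    bin_width: float = 0.01
    fwhm_mm: float = 1.0
    q: float = 0.05
    iterations: int = 1
    seed: int = 7

    def __post_init__(self):
        if self.n_normal < 2 or self.n_lesion < 2 or self.n_control < 2:
            raise ConfigurationError("all cohorts need at least 2 subjects")
        if not 0 < self.q < 1:
            raise ConfigurationError(f"q must be in (0,1), got {self.q}")
        if not 0 < self.threshold_fraction < 1:
            raise ConfigurationError("threshold_fraction must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def phantom_spec(self, seed_offset: int = 0) -> PhantomSpec:
        # semi-axes at 60/45/40% of the half-FOV keep the brain inside any grid
        half_fov = self.grid * self.voxel_size_mm / 2.0
        return PhantomSpec(
            grid_shape=(self.grid,) * 3,
            voxel_size_mm=self.voxel_size_mm,
            brain_semi_axes_mm=(0.75 * half_fov, 0.56 * half_fov, 0.5 * half_fov),
            noise_cv=self.noise_cv,
            smoothing_fwhm_mm=self.fwhm_mm,
            seed=self.seed + seed_offset,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 write_images: bool = True) -> dict:
    """Execute the full synthetic study; returns (and writes) the manifest.

    Stages: phantom generation (normals with regional heterogeneity,
    lesioned group with a shared focal hypometabolic lesion, controls),
    atlas construction for all three normalization methods with in-mask
    CoV summaries, group t-tests of each group against the normals, and a
    thresholded Z map for the first lesioned subject.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = config.phantom_spec()
    template = make_template_phantom(spec)
    rng = np.random.default_rng(config.seed)
    seeds = rng.integers(2**31, size=4)

    normals = sample_population(
        template, config.n_normal, spec, seed=int(seeds[0]),
        scale_sigma_log=config.scale_sigma_log, regional_perturbations=True,
    )
    # patient cohorts follow the same population model as the normals
    # (including spill-in heterogeneity); the lesion is the only difference
    lesion = spherical_lesion_mask(spec, radius_mm=config.lesion_radius_mm)
    lesioned = sample_population(
        template, config.n_lesion, spec, seed=int(seeds[1]),
        scale_sigma_log=config.scale_sigma_log, regional_perturbations=True,
        lesion_mask=lesion, lesion_factor=config.lesion_factor,
    )
    controls = sample_population(
        template, config.n_control, spec, seed=int(seeds[2]),
        scale_sigma_log=config.scale_sigma_log, regional_perturbations=True,
    )

    # atlases for every method, for the CoV comparison table
    cov_table = {}
    atlases = {}
    for method in ("histogram", "global_mean", "none"):
        atlas = NormalAtlas(
            method=method,
            threshold_fraction=config.threshold_fraction,
            bin_width=config.bin_width,
            iterations=config.iterations,
        ).fit([img for img, _ in normals])
        atlases[method] = atlas
        cmean, csd = mean_cov(cov_map(atlas.as_template()), atlas.mask_)
        cov_table[method] = {"mean_cov_pct": cmean, "sd_cov_pct": csd}

    atlas = atlases[config.method]
    normalizer = HistogramNormalizer(
        threshold_fraction=config.threshold_fraction, bin_width=config.bin_width
    )
    # patients are normalized against the final atlas mean, as in the workflow
    normalizer.fit(atlas.mean_img_)

    factor_rows = []
    for sid, factor, conv in zip(
        range(config.n_normal), atlas.factors_, atlas.fit_converged_
    ):
        factor_rows.append(("normal", sid, float(factor), bool(conv)))

    def _normalize_group(name, population):
        out = []
        for sid, (img, _) in enumerate(population):
            res = normalizer.normalize(img)
            conv = res.histogram.fit_converged if res.histogram else True
            factor_rows.append((name, sid, float(res.factor), bool(conv)))
            out.append(res.normalized_image)
        return out

    lesioned_norm = _normalize_group("lesion", lesioned)
    controls_norm = _normalize_group("control", controls)

    group_results = {}
    for name, imgs in (("lesion", lesioned_norm), ("control", controls_norm)):
        res = group_ttest(imgs, atlas.normalized_images_, atlas.mask_, q=config.q)
        group_results[name] = res

    zmap = threshold_zmap_95(zscore_map(lesioned_norm[0], atlas.as_template()))

    factors = pd.DataFrame(
        factor_rows, columns=["group", "subject_id", "factor", "fit_converged"]
    )
    factors["method"] = config.method
    outputs = {}
    if write_images:
        atlas.save(out_dir / "atlas")
        factors.to_csv(out_dir / "factors.csv", index=False)
        for name, res in group_results.items():
            tgrid = atlas.mean_img_.with_data(
                np.nan_to_num(res.t_map.values), unit="statistic"
            )
            write_volume(tgrid, out_dir / f"t_map_{name}.nii.gz")
            write_volume(
                atlas.mean_img_.with_data(
                    res.sig_decrease.astype(float), unit="statistic"
                ),
                out_dir / f"sig_decrease_{name}.nii.gz",
            )
        write_volume(
            atlas.mean_img_.with_data(np.nan_to_num(zmap.values), unit="statistic"),
            out_dir / "z_map_lesion_subject0.nii.gz",
        )
        for p in sorted(out_dir.rglob("*")):
            if p.is_file():
                outputs[str(p.relative_to(out_dir))] = _sha256(p)

    overlap = float(
        (group_results["lesion"].sig_decrease & lesion).sum() / lesion.sum()
    )
    manifest = {
        "petnorm_version": __version__,
        "config": dataclasses.asdict(config),
        "cov_by_method": cov_table,
        "group_stats": {
            name: {
                "fdr_t_threshold": (
                    res.fdr_t_threshold if np.isfinite(res.fdr_t_threshold) else None
                ),
                "n_sig_increase": int(res.sig_increase.sum()),
                "n_sig_decrease": int(res.sig_decrease.sum()),
            }
            for name, res in group_results.items()
        },
        "lesion_decrease_overlap": overlap,
        "zmap_thresholds": [zmap.threshold_low, zmap.threshold_high],
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
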