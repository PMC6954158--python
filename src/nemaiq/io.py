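"""Volume and configuration I/O.

Volumes travel as NIfTI-1 with the voxel spacing in the affine and the
physical units (kBq/ml) recorded in a JSON sidecar.  Experiment
descriptions are YAML files; ``write_default_config`` emits the
canonical default study so a user can edit from a working template.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .geometry import F18_HALF_LIFE_MIN
from .presets import default_presets
from .simulate import GridSpec, ImageVolume, ReconPreset
from .study import SBR_LEVELS, StudyDesign

__all__ = [
    "save_volume",
    "load_volume",
    "default_config",
    "write_default_config",
    "load_config",
    "design_from_config",
]


def save_volume(image: ImageVolume, path, units: str = "kBq/ml") -> None:
    """Write a volume as NIfTI-1 plus a JSON sidecar with units/origin."""
    path = Path(path)
    affine = np.diag(list(image.grid.spacing) + [1.0])
    affine[:3, 3] = image.grid.origin
    nib.save(nib.Nifti1Image(image.values.astype(np.float32), affine), str(path))
    sidecar = {
        "units": units,
        "shape": list(image.grid.shape),
        "spacing_mm": list(image.grid.spacing),
        "origin_mm": list(image.grid.origin),
    }
    side_path = path.with_suffix("").with_suffix("")  # strip .nii[.gz]
    Path(str(side_path) + ".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_volume(path) -> ImageVolume:
    img = nib.load(str(path))
    affine = img.affine
    spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
    origin = tuple(float(x) for x in affine[:3, 3])
    values = np.asanyarray(img.dataobj, dtype=float)
    grid = GridSpec(shape=tuple(values.shape), spacing=spacing, origin=origin)
    return ImageVolume(values=values, grid=grid)


def default_config() -> dict:
    """The canonical default study as a plain dictionary."""
    return {
        "grid": {"shape": [128, 128, 64], "spacing_mm": [2.73, 2.73, 2.78]},
        "phantom": {
            "ring_radius_mm": 57.2,
            "wall_range_mm": [0.9, 1.3],
            "body": {"radius_mm": 140.0, "length_mm": 160.0},
            "background_voi": {"axial_offset_mm": 40.0, "volume_ml": 30.0},
        },
        "half_life_min": F18_HALF_LIFE_MIN,
        "sbr_levels": {
            level: {"sphere_kbq_ml": s, "background_kbq_ml": b}
            for level, (s, b) in SBR_LEVELS.items()
        },
        "scans": {"count": 5, "interval_min": 30.0},
        "supersample": 4,
        "fit_spheres": ["37", "28", "22"],
        "presets": [
            {
                "name": p.name,
                "blur_fwhm_mm": p.blur_fwhm,
                "overshoot_amplitude": p.overshoot_amplitude,
                "noise_cv": p.noise_cv,
                "noise_corr_fwhm_mm": p.noise_corr_fwhm,
                "metadata": p.metadata,
            }
            for p in default_presets().values()
        ],
    }


def write_default_config(path) -> None:
    Path(path).write_text(yaml.safe_dump(default_config(), sort_keys=False))


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def design_from_config(cfg: dict) -> StudyDesign:
    """Build a StudyDesign from a configuration dictionary."""
    grid_cfg = cfg.get("grid", {})
    grid = GridSpec.centered(
        grid_cfg.get("shape", [128, 128, 64]),
        grid_cfg.get("spacing_mm", [2.73, 2.73, 2.78]),
    )
    presets = [
        ReconPreset(
            name=p["name"],
            blur_fwhm=float(p["blur_fwhm_mm"]),
            overshoot_amplitude=float(p.get("overshoot_amplitude", 0.0)),
            noise_cv=float(p.get("noise_cv", 0.0)),
            noise_corr_fwhm=float(p.get("noise_corr_fwhm_mm", 4.0)),
            metadata=str(p.get("metadata", "")),
        )
        for p in cfg.get("presets", [])
    ] or list(default_presets().values())
    sbr_levels = {
        level: (float(v["sphere_kbq_ml"]), float(v["background_kbq_ml"]))
        for level, v in cfg.get(
            "sbr_levels",
            {k: {"sphere_kbq_ml": s, "background_kbq_ml": b} for k, (s, b) in SBR_LEVELS.items()},
        ).items()
    }
    scans = cfg.get("scans", {})
    return StudyDesign(
        presets=presets,
        sbr_levels=sbr_levels,
        grid=grid,
        n_scans=int(scans.get("count", 5)),
        interval_min=float(scans.get("interval_min", 30.0)),
        supersample=int(cfg.get("supersample", 4)),
        fit_spheres=tuple(str(s) for s in cfg.get("fit_spheres", ["37", "28", "22"])),
    )
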