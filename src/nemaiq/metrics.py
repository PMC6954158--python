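"""Contrast recovery and background SNR.

Definitions (all on activity-concentration volumes, kBq/ml):

* CRmax  = (maximum voxel AC within a small search margin around the
  sphere) / (true decay-corrected sphere AC).
* CRpeak = (mean AC of a 1.2-cm-diameter spherical VOI placed to
  maximize that mean, constrained to the sphere) / (true AC) -- the
  peak-VOI construction familiar from SUVpeak.
* SNR    = background mean AC / background AC standard deviation in a
  30-ml spherical background VOI.

The peak-VOI search runs over candidate centers on the subvoxel
lattice (voxel spacing / 3, about 0.9 mm at the default grid) within
the sphere's outer radius; partial-volume membership of each voxel in
the VOI is estimated by 3x3x3 subdivision.  On that subdivided grid
the weighted VOI mean is an exact ball-kernel correlation, evaluated
by FFT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from .geometry import SphereSpec, radius_from_volume
from .simulate import ImageVolume, ball_mask

__all__ = [
    "METRICS_COLUMNS",
    "PeakResult",
    "SnrResult",
    "cr_max",
    "peak_voi_mean",
    "cr_peak",
    "background_snr",
]

#: Tidy per-row schema of a metrics table as produced by the study driver.
METRICS_COLUMNS = (
    "scan",
    "preset",
    "sbr",
    "sphere",
    "crmax",
    "crpeak",
    "peak_x",
    "peak_y",
    "peak_z",
    "snr",
    "bg_mean",
    "bg_sd",
    "true_ac",
)


@dataclass(frozen=True)
class PeakResult:
    mean: float
    center: tuple[float, float, float]


@dataclass(frozen=True)
class SnrResult:
    snr: float
    mean: float
    sd: float
    n_voxels: int
    degenerate: bool = False


def _check_ball_inside(image: ImageVolume, center, radius: float, what: str) -> None:
    lo, hi = image.grid.bounds()
    center = np.asarray(center, dtype=float)
    if np.any(center - radius < lo) or np.any(center + radius > hi):
        raise ValueError(f"{what} ball of radius {radius:.1f} mm extends outside the image")


def cr_max(
    image: ImageVolume,
    sphere: SphereSpec,
    true_ac: float,
    search_margin: float = 2.0,
    center=None,
) -> float:
    """Maximum voxel AC within R_outer + margin of the sphere, over true AC."""
    if true_ac <= 0:
        raise ValueError("true_ac must be positive")
    c = np.asarray(center if center is not None else sphere.center, dtype=float)
    radius = sphere.outer_radius + search_margin
    _check_ball_inside(image, c, radius, "CRmax search")
    mask = ball_mask(image.grid, c, radius)
    return float(image.values[mask].max()) / true_ac


def peak_voi_mean(
    image: ImageVolume,
    sphere: SphereSpec,
    voi_diameter: float = 12.0,
    subdivision: int = 3,
    center=None,
) -> PeakResult:
    """Highest mean of a spherical VOI positioned for this sphere.

    Candidate centers lie on the subdivided voxel lattice within
    ``R_outer`` of the sphere center, which keeps the whole VOI within
    ``R_outer + voi_radius`` and hence guarantees CRmax >= CRpeak up
    to the search-margin convention.  Ties (uniform images) resolve to
    the candidate closest to the nominal center.
    """
    if subdivision < 1:
        raise ValueError("subdivision must be >= 1")
    grid = image.grid
    c = np.asarray(center if center is not None else sphere.center, dtype=float)
    voi_r = voi_diameter / 2.0
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    patch_r = sphere.outer_radius + voi_r + float(spacing.max())
    _check_ball_inside(image, c, patch_r, "peak VOI search")

    lo_idx = np.floor((c - patch_r - origin) / spacing).astype(int)
    hi_idx = np.ceil((c + patch_r - origin) / spacing).astype(int) + 1
    lo_idx = np.maximum(lo_idx, 0)
    hi_idx = np.minimum(hi_idx, np.asarray(grid.shape))
    patch = image.values[tuple(slice(lo_idx[i], hi_idx[i]) for i in range(3))]

    s = subdivision
    fine_sp = spacing / s
    # subdivided values: each voxel split into s^3 cells of equal value
    fine = patch.repeat(s, axis=0).repeat(s, axis=1).repeat(s, axis=2)
    fine_axes = []
    for i in range(3):
        vox_coords = origin[i] + spacing[i] * np.arange(lo_idx[i], hi_idx[i])
        offs = ((np.arange(s) + 0.5) / s - 0.5) * spacing[i]
        fine_axes.append((vox_coords[:, None] + offs[None, :]).ravel())

    # ball kernel on the fine lattice
    n_k = [int(math.floor(voi_r / fine_sp[i])) for i in range(3)]
    kx = np.arange(-n_k[0], n_k[0] + 1) * fine_sp[0]
    ky = np.arange(-n_k[1], n_k[1] + 1) * fine_sp[1]
    kz = np.arange(-n_k[2], n_k[2] + 1) * fine_sp[2]
    kernel = (
        kx[:, None, None] ** 2 + ky[None, :, None] ** 2 + kz[None, None, :] ** 2
    ) <= voi_r**2
    n_in_kernel = int(kernel.sum())

    sums = fftconvolve(fine, kernel.astype(float), mode="same")
    means = sums / n_in_kernel

    FX, FY, FZ = np.meshgrid(*fine_axes, indexing="ij", sparse=True)
    d2 = (FX - c[0]) ** 2 + (FY - c[1]) ** 2 + (FZ - c[2]) ** 2
    cand = d2 <= sphere.outer_radius**2
    # require full kernel support inside the patch (met by construction
    # except for numerically degenerate patch clipping)
    for i, nk in enumerate(n_k):
        idx = np.arange(fine.shape[i])
        ok = (idx >= nk) & (idx <= fine.shape[i] - 1 - nk)
        cand &= ok.reshape([-1 if j == i else 1 for j in range(3)])
    if not np.any(cand):
        raise ValueError("peak VOI search has no candidate centers")

    cand_means = np.where(cand, means, -np.inf)
    vmax = float(cand_means.max())
    tol = 1e-9 * max(abs(vmax), 1e-30)
    ties = cand & (means >= vmax - tol)
    tie_idx = np.argwhere(ties)
    tie_pts = np.stack(
        [fine_axes[i][tie_idx[:, i]] for i in range(3)], axis=1
    )
    best = tie_idx[np.argmin(np.sum((tie_pts - c) ** 2, axis=1))]
    best_pt = tuple(float(fine_axes[i][best[i]]) for i in range(3))
    return PeakResult(mean=float(means[tuple(best)]), center=best_pt)


def cr_peak(
    image: ImageVolume,
    sphere: SphereSpec,
    true_ac: float,
    voi_diameter: float = 12.0,
    subdivision: int = 3,
    center=None,
) -> float:
    """Peak contrast recovery: best 1.2-cm VOI mean over true AC."""
    if true_ac <= 0:
        raise ValueError("true_ac must be positive")
    peak = peak_voi_mean(image, sphere, voi_diameter=voi_diameter,
                         subdivision=subdivision, center=center)
    return peak.mean / true_ac


def background_snr(
    image: ImageVolume, voi_center, voi_volume_ml: float = 30.0
) -> SnrResult:
    """Mean / SD over voxel centers inside the spherical background VOI.

    A zero SD (constant background) yields an infinite SNR flagged as
    degenerate rather than an exception.
    """
    radius = radius_from_volume(voi_volume_ml)
    _check_ball_inside(image, voi_center, radius, "background VOI")
    mask = ball_mask(image.grid, voi_center, radius)
    vals = image.values[mask]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    if sd <= 1e-12 * max(abs(mean), 1e-300):
        return SnrResult(snr=math.inf, mean=mean, sd=0.0, n_voxels=int(vals.size),
                         degenerate=True)
    return SnrResult(snr=mean / sd, mean=mean, sd=sd, n_voxels=int(vals.size))
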