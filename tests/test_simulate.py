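import math

import numpy as np
import pytest

from nemaiq.geometry import ActivityConfig, CylinderBody, PhantomDefinition, SphereSpec
from nemaiq.simulate import (
    GridSpec,
    ImageVolume,
    ReconPreset,
    add_noise,
    apply_recon_signature,
    ball_mask,
    rasterize_truth,
    simulate_series,
)
from conftest import make_single_sphere_phantom


def test_grid_spec_validation_and_centering():
    g = GridSpec.centered((4, 4, 2), (2.0, 2.0, 3.0))
    assert g.origin == (-3.0, -3.0, -1.5)
    lo, hi = g.bounds()
    assert np.allclose(lo, [-4.0, -4.0, -3.0]) and np.allclose(hi, [4.0, 4.0, 3.0])
    with pytest.raises(ValueError):
        GridSpec(shape=(0, 4, 4), spacing=(1, 1, 1), origin=(0, 0, 0))
    with pytest.raises(ValueError):
        GridSpec(shape=(4, 4, 4), spacing=(0.0, 1, 1), origin=(0, 0, 0))


def test_recon_preset_validation():
    with pytest.raises(ValueError):
        ReconPreset(name="x", blur_fwhm=0.0)
    with pytest.raises(ValueError):
        ReconPreset(name="x", blur_fwhm=4.0, noise_cv=-0.1)


def test_rasterize_uniform_background_exact(small_grid):
    ph = PhantomDefinition(
        spheres=[],
        body=CylinderBody(radius=40.0, length=120.0),
        activity=ActivityConfig(sphere_ac=6.2, background_ac=3.1),
    )
    vol = rasterize_truth(ph, small_grid, supersample=4)
    hd = small_grid.half_diagonal
    interior = ball_mask(small_grid, (0, 0, 0), 40.0 - hd - 0.1)
    assert np.all(vol.values[interior] == 3.1)
    assert vol.values.min() >= 0.0


def test_rasterize_mass_balance_isolated_sphere(sphere17_phantom, sphere17_truth, small_grid):
    s = sphere17_phantom.spheres[0]
    act = sphere17_phantom.activity
    # box fully inside the body, enclosing the sphere
    box = ball_mask(small_grid, s.center, 25.0)
    excess = (sphere17_truth.values[box] - act.background_ac).sum() * small_grid.voxel_volume_ml
    v_in = 4.0 / 3.0 * math.pi * s.inner_radius**3 / 1000.0
    v_out = 4.0 / 3.0 * math.pi * s.outer_radius**3 / 1000.0
    expected = act.sphere_ac * v_in - act.background_ac * v_out
    assert excess == pytest.approx(expected, rel=5e-3)


def test_voxel_fully_inside_wall_is_cold():
    grid = GridSpec.centered((33, 33, 33), (2.73, 2.73, 2.78))
    ph = make_single_sphere_phantom(inner_radius=7.0, wall=3.0, voi_center=None,
                                    body_radius=30.0, body_length=80.0)
    vol = rasterize_truth(ph, grid, supersample=4)
    # voxel centered at (3*2.73, 0, 0): radius 8.19, all subsamples within the wall shell
    idx = (16 + 3, 16, 16)
    assert vol.values[idx] == 0.0


def test_phantom_must_fit_grid():
    grid = GridSpec.centered((16, 16, 16), (2.73, 2.73, 2.78))
    ph = make_single_sphere_phantom(voi_center=None)
    with pytest.raises(ValueError, match="fit"):
        rasterize_truth(ph, grid)


def test_tiny_blur_is_identity(sphere17_truth):
    out = apply_recon_signature(sphere17_truth, ReconPreset(name="id", blur_fwhm=0.1))
    assert np.max(np.abs(out.values - sphere17_truth.values)) <= 1e-6


def test_blur_conserves_total_activity(small_grid):
    # phantom far enough from every edge for the kernel support
    ph = make_single_sphere_phantom(body_radius=28.0, body_length=56.0, voi_center=None)
    truth = rasterize_truth(ph, small_grid, supersample=2)
    for blur in (4.2, 8.2):
        out = apply_recon_signature(truth, ReconPreset(name="b", blur_fwhm=blur))
        assert out.values.sum() == pytest.approx(truth.values.sum(), rel=1e-6)


def test_overshoot_elevates_sphere_boundary(truth8, nema8):
    base = apply_recon_signature(truth8, ReconPreset(name="p", blur_fwhm=4.2))
    ring = apply_recon_signature(
        truth8, ReconPreset(name="p", blur_fwhm=4.2, overshoot_amplitude=0.5)
    )
    s = nema8.sphere("37")
    near = ball_mask(truth8.grid, s.center, s.outer_radius + 4.0)
    assert ring.values[near].max() > nema8.activity.sphere_ac  # CR > 1 overshoot
    assert base.values[near].max() <= nema8.activity.sphere_ac * 1.01


def test_radial_profile_close_to_closed_form(blurred8, nema8):
    """Noiseless blurred volume matches the analytic walled-sphere model:
    tightly at the sphere center, and within the cubic-voxel-kernel
    residual overall (which also bounds the angular spread)."""
    from nemaiq.geometry import FWHM_PER_SIGMA
    from nemaiq.profile import extract_radial_samples, model_profile

    img = blurred8[4.2]
    s = nema8.sphere("37")
    S, B = nema8.activity.sphere_ac, nema8.activity.background_ac
    prof = extract_radial_samples(img, s.center, s.outer_radius + 12.0)
    pred = model_profile(prof.radii, S, B, s, 4.2 / FWHM_PER_SIGMA)
    resid = prof.values - pred
    central = prof.radii < 5.0
    assert np.max(np.abs(resid[central])) / S < 1e-3
    assert np.max(np.abs(resid)) / S < 0.04


def test_angular_symmetry_of_blurred_volume(blurred8, nema8):
    """Detrended thin-shell spread stays below 1.5% of the sphere AC."""
    from nemaiq.profile import extract_radial_samples

    s = nema8.sphere("37")
    S = nema8.activity.sphere_ac
    for blur in (3.7, 5.2):
        prof = extract_radial_samples(blurred8[blur], s.center, s.outer_radius + 10.0)
        r, v = prof.radii, prof.values
        worst = 0.0
        for lo in np.arange(0.0, r.max() - 0.5, 0.5):
            m = (r >= lo) & (r < lo + 0.5)
            if m.sum() < 10:
                continue
            design = np.vstack([np.ones(m.sum()), r[m] - lo]).T
            coef, *_ = np.linalg.lstsq(design, v[m], rcond=None)
            worst = max(worst, float(np.std(v[m] - design @ coef)))
        assert worst / S < 0.015


def test_noise_zero_is_identity_and_seed_determinism(sphere17_blurred, sphere17_phantom):
    voi = sphere17_phantom.background_voi_center
    same = add_noise(sphere17_blurred, 0.0, 4.0, seed=3, voi_center=voi)
    assert np.array_equal(same.values, sphere17_blurred.values)
    a = add_noise(sphere17_blurred, 0.15, 4.0, seed=7, voi_center=voi)
    b = add_noise(sphere17_blurred, 0.15, 4.0, seed=7, voi_center=voi)
    c = add_noise(sphere17_blurred, 0.15, 4.0, seed=8, voi_center=voi)
    assert np.array_equal(a.values, b.values)
    assert not np.array_equal(a.values, c.values)


def test_noise_magnitude_matches_requested_cv(sphere17_blurred, sphere17_phantom):
    from nemaiq.geometry import radius_from_volume

    voi = sphere17_phantom.background_voi_center
    mask = ball_mask(sphere17_blurred.grid, voi, radius_from_volume(30.0))
    cvs = []
    for seed in range(10):
        noisy = add_noise(sphere17_blurred, 0.2, 4.0, seed=seed, voi_center=voi)
        vals = noisy.values[mask]
        cvs.append(vals.std(ddof=1) / vals.mean())
    assert np.mean(cvs) == pytest.approx(0.2, rel=0.10)


def test_series_decay_and_single_scan_equivalence(sphere17_phantom, small_grid):
    preset = ReconPreset(name="p", blur_fwhm=4.2, noise_cv=0.0)
    series = simulate_series(sphere17_phantom, small_grid, preset, n_scans=5,
                             interval_min=30.0, seed=0, supersample=2)
    mask = ball_mask(small_grid, sphere17_phantom.background_voi_center, 15.0)
    ratio = series[4].values[mask].mean() / series[0].values[mask].mean()
    assert ratio == pytest.approx(2.0 ** (-120.0 / 109.77), rel=1e-2)
    single = simulate_series(sphere17_phantom, small_grid, preset, n_scans=1,
                             interval_min=99.0, seed=0, supersample=2)
    assert np.array_equal(single[0].values, series[0].values)
    # contrast ratio is decay-invariant scan to scan (noiseless)
    s = sphere17_phantom.spheres[0]
    core = ball_mask(small_grid, s.center, 3.0)
    sbrs = [vol.values[core].mean() / vol.values[mask].mean() for vol in series]
    assert np.allclose(sbrs, sbrs[0], rtol=1e-9)


def test_image_volume_flags_negative_values(small_grid):
    vals = np.zeros(small_grid.shape)
    vol = ImageVolume(values=vals, grid=small_grid)
    assert not vol.has_negative
    vals[0, 0, 0] = -1.0
    assert ImageVolume(values=vals, grid=small_grid).has_negative
    with pytest.raises(ValueError):
        ImageVolume(values=np.full(small_grid.shape, np.nan), grid=small_grid)
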