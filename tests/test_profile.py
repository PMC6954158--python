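import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.integrate import quad

from nemaiq.geometry import FWHM_PER_SIGMA, SphereSpec
from nemaiq.profile import (
    extract_radial_samples,
    fit_profile,
    fit_sphere_fwhm,
    model_profile,
    refine_center,
    sphere_gauss_profile,
    SphereProfile,
)
from nemaiq.simulate import ReconPreset, add_noise, apply_recon_signature, rasterize_truth


def test_step_function_limit():
    R = 8.5
    sigma = 1e-6 * R
    assert sphere_gauss_profile(R / 2, R, sigma) == pytest.approx(1.0, abs=1e-6)
    assert sphere_gauss_profile(2 * R, R, sigma) == pytest.approx(0.0, abs=1e-6)
    assert sphere_gauss_profile(R, R, sigma) == pytest.approx(0.5, abs=1e-6)


def test_center_value_matches_radial_quadrature():
    R, sigma = 8.5, 2.0
    norm = (2 * math.pi * sigma**2) ** 1.5
    integrand = lambda s: 4 * math.pi * s * s * math.exp(-s * s / (2 * sigma**2)) / norm
    expected, _ = quad(integrand, 0.0, R)
    assert sphere_gauss_profile(0.0, R, sigma) == pytest.approx(expected, abs=1e-6)


@pytest.mark.parametrize("R", [8.5, 18.3])
@pytest.mark.parametrize("sigma", [1.0, 3.0])
def test_profile_mass_conservation(R, sigma):
    mass, _ = quad(lambda r: 4 * math.pi * r * r * sphere_gauss_profile(r, R, sigma),
                   0.0, R + 12 * sigma, limit=200)
    assert mass == pytest.approx(4.0 / 3.0 * math.pi * R**3, rel=1e-4)


def test_profile_domain_errors():
    with pytest.raises(ValueError):
        sphere_gauss_profile(1.0, -1.0, 1.0)
    with pytest.raises(ValueError):
        sphere_gauss_profile(1.0, 1.0, 0.0)
    with pytest.raises(ValueError):
        sphere_gauss_profile(-0.5, 1.0, 1.0)


@given(
    st.floats(min_value=2.0, max_value=20.0),
    st.floats(min_value=0.5, max_value=8.0),
)
def test_profile_monotone_nonincreasing(R, sigma):
    r = np.linspace(0.0, R + 6 * sigma, 400)
    f = sphere_gauss_profile(r, R, sigma)
    assert np.all(np.diff(f) <= 1e-10)
    assert np.all((f >= 0.0) & (f <= 1.0))


def test_closed_form_against_discrete_convolution():
    """One dense-grid 3D convolution cross-check (more combinations run
    in the acceptance suite)."""
    from oracles import discrete_convolution_oracle

    R, sigma = 8.5, 2.0
    rng = np.random.default_rng(7)
    radii = rng.uniform(0.2, R + 2 * sigma, size=50)
    oracle = discrete_convolution_oracle(R, sigma, radii)
    closed = sphere_gauss_profile(radii, R, sigma)
    assert np.max(np.abs(closed - oracle)) <= 1e-3


def test_model_profile_reductions():
    sphere = SphereSpec(label="17", inner_radius=8.5, wall_thickness=1.0)
    r = np.linspace(0, 20, 50)
    np.testing.assert_allclose(
        model_profile(r, 24.4, 0.0, sphere, 2.0),
        24.4 * sphere_gauss_profile(r, 8.5, 2.0),
    )
    thin = SphereSpec(label="t", inner_radius=8.5, wall_thickness=1e-9)
    const = model_profile(r, 5.0, 5.0, thin, 2.0)
    np.testing.assert_allclose(const, 5.0, atol=1e-7)
    # at the inner radius the walled model sits between B and S
    sphere37 = SphereSpec(label="37", inner_radius=18.3, wall_thickness=1.3)
    v = model_profile(np.array([18.3]), 24.4, 3.1, sphere37, 2.0)[0]
    assert 3.1 < v < (24.4 + 3.1) / 2 + 0.05 * 24.4


def test_fit_recovers_exact_model_samples(rng):
    sphere = SphereSpec(label="17", inner_radius=8.5, wall_thickness=1.0)
    sigma_true = 5.0 / FWHM_PER_SIGMA
    r = rng.uniform(0.0, sphere.outer_radius + 14.0, size=4000)
    v = model_profile(r, 24.4, 3.1, sphere, sigma_true)
    prof = SphereProfile(radii=r, values=v, r_max=sphere.outer_radius + 14.0,
                         center_used=(0, 0, 0))
    fit = fit_profile(prof, sphere)
    assert fit.converged
    assert fit.fwhm == pytest.approx(5.0, abs=1e-3)
    assert fit.signal == pytest.approx(24.4, rel=1e-4)
    assert fit.background == pytest.approx(3.1, rel=1e-4)


def test_fit_on_generated_volume_recovers_blur(blurred8, nema8):
    fit, est = fit_sphere_fwhm(blurred8[4.2], nema8.sphere("37"))
    assert est.converged and fit.converged
    assert fit.fwhm == pytest.approx(4.2, abs=0.15)


def test_recovered_fwhm_monotone_in_applied_blur(blurred8, nema8):
    fwhms = []
    for blur in (3.7, 5.2, 8.2):
        per_sphere = [
            fit_sphere_fwhm(blurred8[blur], nema8.sphere(lab))[0].fwhm
            for lab in ("37", "28", "22")
        ]
        fwhms.append(np.mean(per_sphere))
    assert fwhms[0] < fwhms[1] < fwhms[2]


def test_fit_noise_grows_as_contrast_drops(small_grid):
    """At fixed blur and fixed absolute noise, the scatter of the
    recovered FWHM grows when the sphere-to-background contrast
    drops."""
    from conftest import make_single_sphere_phantom

    spreads = {}
    for sbr in (8.0, 2.0):
        ph = make_single_sphere_phantom(inner_radius=10.9, wall=1.14,
                                        sphere_ac=3.1 * sbr, background_ac=3.1)
        truth = rasterize_truth(ph, small_grid, supersample=2)
        img = apply_recon_signature(truth, ReconPreset(name="b", blur_fwhm=4.2))
        fwhms = []
        for seed in range(8):
            noisy = add_noise(img, 0.15, 4.0, seed=seed,
                              voi_center=ph.background_voi_center)
            # same absolute noise in both cases: cv is relative to the
            # common background level
            fit, _ = fit_sphere_fwhm(noisy, ph.spheres[0])
            fwhms.append(fit.fwhm)
        spreads[sbr] = np.std(fwhms)
    assert spreads[2.0] > spreads[8.0]


def test_refine_center_recovers_offset(sphere17_blurred, sphere17_phantom):
    s = sphere17_phantom.spheres[0]
    est = refine_center(sphere17_blurred, np.array(s.center) + [3.0, 0.0, 0.0],
                        window_radius=s.outer_radius)
    assert est.converged and not est.degenerate
    assert np.linalg.norm(est.center_mm - s.center_mm) < 0.05


def test_refine_center_uniform_image_degenerate(small_grid):
    from nemaiq.simulate import ImageVolume

    vol = ImageVolume(values=np.full(small_grid.shape, 3.1), grid=small_grid)
    est = refine_center(vol, (1.0, 2.0, 3.0), window_radius=10.0)
    assert est.degenerate
    assert tuple(est.center) == (1.0, 2.0, 3.0)


def test_refine_center_noisy_within_half_voxel(sphere17_blurred, sphere17_phantom):
    s = sphere17_phantom.spheres[0]
    half_voxel = min(sphere17_blurred.grid.spacing) / 2.0
    for seed in range(10):
        noisy = add_noise(sphere17_blurred, 0.1, 4.0, seed=seed,
                          voi_center=sphere17_phantom.background_voi_center)
        est = refine_center(noisy, np.array(s.center) + [2.0, -1.0, 1.0],
                            window_radius=s.outer_radius)
        assert np.linalg.norm(est.center_mm - s.center_mm) < half_voxel


def test_extract_radial_samples_count_and_uniformity(sphere17_blurred, small_grid):
    R = 10.0
    prof = extract_radial_samples(sphere17_blurred, (0.0, 0.0, 0.0), R)
    voxel_volume = float(np.prod(small_grid.spacing))
    expected = 4.0 / 3.0 * math.pi * R**3 / voxel_volume
    surface = 4.0 * math.pi * R**2 * max(small_grid.spacing) / voxel_volume
    assert abs(prof.n_samples - expected) <= surface
    assert np.all(prof.radii <= R + 1e-9)

    from nemaiq.simulate import ImageVolume

    uniform = ImageVolume(values=np.full(small_grid.shape, 7.3), grid=small_grid)
    prof_u = extract_radial_samples(uniform, (0.0, 0.0, 0.0), 12.0)
    assert np.all(prof_u.values == 7.3)


def test_extract_radial_samples_degenerate_rmax(sphere17_blurred):
    prof = extract_radial_samples(sphere17_blurred, (0.3, 0.2, 0.1), 0.5)
    assert prof.n_samples >= 1


def test_extract_radial_samples_clipped_ball_errors(sphere17_blurred):
    with pytest.raises(ValueError, match="high x"):
        extract_radial_samples(sphere17_blurred, (60.0, 0.0, 0.0), 12.0)
    with pytest.raises(ValueError, match="low z"):
        extract_radial_samples(sphere17_blurred, (0.0, 0.0, -60.0), 12.0)


def test_fit_requires_background_coverage(sphere17_blurred, sphere17_phantom):
    s = sphere17_phantom.spheres[0]
    prof = extract_radial_samples(sphere17_blurred, s.center, s.outer_radius + 2.0)
    with pytest.raises(ValueError, match="R_outer"):
        fit_profile(prof, s)
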