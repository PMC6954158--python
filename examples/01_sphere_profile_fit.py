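"""Estimate reconstructed spatial resolution from one synthetic phantom.

Builds the six-sphere phantom at 8:1 contrast, simulates a noisy
reconstruction with 4.2-mm resolution, and fits the walled-sphere /
Gaussian profile model to the 37-mm sphere.
"""

from nemaiq import (
    ActivityConfig,
    DEFAULT_GRID,
    ReconPreset,
    add_noise,
    apply_recon_signature,
    fit_sphere_fwhm,
    nema_iec_phantom,
    rasterize_truth,
)

phantom = nema_iec_phantom(ActivityConfig(sphere_ac=24.4, background_ac=3.1))
truth = rasterize_truth(phantom, DEFAULT_GRID, supersample=4)
clean = apply_recon_signature(truth, ReconPreset(name="demo", blur_fwhm=4.2))
noisy = add_noise(clean, 0.15, 4.0, seed=1,
                  voi_center=phantom.background_voi_center)

for label in ("37", "28", "22"):
    fit, center = fit_sphere_fwhm(noisy, phantom.sphere(label))
    print(f"{label} mm sphere: FWHM = {fit.fwhm:.2f} mm "
          f"(signal {fit.signal:.1f}, background {fit.background:.2f} kBq/ml, "
          f"converged={fit.converged})")

print()
print("The fitted FWHM is the effective Gaussian point-spread width of the")
print("simulated reconstruction; the generator applied 4.2 mm, so recovered")
print("values near 4.2 mm show the profile fit is unbiased at 15% noise.")
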