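"""Contrast recovery and background SNR for one simulated scan.

CRmax is the hottest voxel of a sphere over its true activity
concentration; CRpeak averages a 1.2-cm spherical VOI placed to
maximize its mean; SNR is background mean over background SD in a
30-ml VOI.
"""

from nemaiq import (
    ActivityConfig,
    DEFAULT_GRID,
    background_snr,
    cr_max,
    cr_peak,
    default_presets,
    nema_iec_phantom,
    rasterize_truth,
    simulate_series,
)

phantom = nema_iec_phantom(ActivityConfig(sphere_ac=24.4, background_ac=3.1))
preset = default_presets()["Q.Clear_300"]
scan = simulate_series(phantom, DEFAULT_GRID, preset, n_scans=1, seed=7)[0]

true_ac = phantom.activity.sphere_ac
print(f"preset {preset.name}: resolution {preset.blur_fwhm} mm, "
      f"noise CV {preset.noise_cv}")
print(f"{'sphere':>8} {'CRmax':>7} {'CRpeak':>7}")
for label in ("37", "28", "22", "17", "13", "10"):
    sphere = phantom.sphere(label)
    print(f"{label + ' mm':>8} {cr_max(scan, sphere, true_ac):7.3f} "
          f"{cr_peak(scan, sphere, true_ac):7.3f}")

snr = background_snr(scan, phantom.background_voi_center)
print(f"\nbackground SNR = {snr.snr:.2f} "
      f"(mean {snr.mean:.2f} kBq/ml, SD {snr.sd:.3f}, {snr.n_voxels} voxels)")
print()
print("CRpeak falls with sphere size because the fixed 1.2-cm VOI averages")
print("in more background around small spheres (partial-volume effect);")
print("CRmax can exceed 1 through edge artifacts and noise spikes.")
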