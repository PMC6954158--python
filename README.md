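# nemaiq

Image-quality analysis for reconstructed PET volumes of the NEMA IEC
body phantom — for physicists and developers who need to compare
reconstruction settings (penalized-likelihood, OSEM, TOF, PSF,
post-filters) on quantitative grounds rather than by visual
impression.

The package computes, per sphere and per scan:

* **Reconstructed spatial resolution** — the FWHM of the effective
  Gaussian point spread function, estimated by fitting the analytic
  radial profile of a walled homogeneous sphere convolved with a 3D
  Gaussian,

      f(r;R,σ) = ½[erf((R−r)/(σ√2)) + erf((R+r)/(σ√2))]
                 − σ/(r√(2π))·[e^(−(r−R)²/2σ²) − e^(−(r+R)²/2σ²)]
      model(r) = S·f(r;R,σ) + B·(1 − f(r;R+d,σ)),

  to the unbinned 3D vicinity of each sphere (radius R and wall d
  fixed; signal S, background B and σ fitted; FWHM = σ·2√(2 ln 2)).
  This works at finite background and for extended objects, so the
  size and contrast dependence of the resolution can be studied.
* **Contrast recovery** — CRmax (hottest voxel / true activity
  concentration) and CRpeak (mean of a 1.2-cm spherical VOI positioned
  to maximize its mean / true AC).
* **Background SNR** — mean/SD in a 30-ml spherical background VOI.
* **Study statistics** — Wilcoxon / Mann–Whitney / Kruskal–Wallis
  comparisons, and a CRpeak-vs-SNR tradeoff matrix for pairs of
  reconstruction settings.

Because those metrics live in the image domain, `nemaiq` also ships a
synthetic phantom generator (rasterized six-sphere phantom,
controllable Gaussian resolution, edge-artifact overshoot, correlated
background noise, multi-scan decay series) so the whole pipeline runs
and is tested without scanner data. See `docs/methods.md` for the
model details and their limits.

## Worked example

```python
from nemaiq import (ActivityConfig, DEFAULT_GRID, ReconPreset, add_noise,
                    apply_recon_signature, fit_sphere_fwhm, nema_iec_phantom,
                    rasterize_truth)

phantom = nema_iec_phantom(ActivityConfig(sphere_ac=24.4, background_ac=3.1))
truth = rasterize_truth(phantom, DEFAULT_GRID, supersample=4)
clean = apply_recon_signature(truth, ReconPreset(name="demo", blur_fwhm=4.2))
noisy = add_noise(clean, 0.15, 4.0, seed=1, voi_center=phantom.background_voi_center)
for label in ("37", "28", "22"):
    fit, _ = fit_sphere_fwhm(noisy, phantom.sphere(label))
    print(label, round(fit.fwhm, 2))
```

prints (seed 1):

```
37 4.23
28 4.17
22 4.21
```

— the fit recovers the 4.2-mm resolution the generator applied, to a
few hundredths of a millimetre, at 15% background noise. The
`examples/` directory has one short script per capability:

* `01_sphere_profile_fit.py` — resolution estimation on a noisy volume,
* `02_recovery_metrics.py` — CRmax/CRpeak/SNR for one simulated scan
  (CRpeak falls from ≈1.02 for the 37-mm sphere to ≈0.56 for the 10-mm
  sphere: the partial-volume effect of the fixed 1.2-cm VOI),
* `03_study_tradeoff.py` — a reduced study and the tradeoff verdicts
  between settings.

A thin CLI covers the file-based workflow:

```bash
nemaiq init-config study.yaml
nemaiq simulate --config study.yaml --out vols/ --seed 1
nemaiq analyze  --image vols/<scan>.nii.gz --config study.yaml --out analysis/
nemaiq compare  --config study.yaml --out reports/ --seed 1
```

Volumes travel as NIfTI-1 (kBq/ml, spacing in the header, units in a
JSON sidecar); tables as CSV; figures as PNG.

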