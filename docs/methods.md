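# Methods

`nemaiq` analyzes reconstructed PET volumes of the NEMA IEC body
phantom: six hollow spheres (nominal diameters 10–37 mm) filled with a
hot F-18 solution sitting in a warm background tank. Three quantities
characterize a reconstruction setting: the reconstructed spatial
resolution (FWHM of the effective point spread function), contrast
recovery of each sphere (CRmax, CRpeak), and background signal-to-noise
ratio (SNR). Because the interesting failure modes live in the *image*
domain, the package also ships a synthetic generator that emulates a
reconstructed acquisition without performing tomographic
reconstruction; every analysis stage is exercised end to end on those
volumes.

## Phantom model

Sphere geometry uses the measured inner volumes
(25.6, 10.7, 5.4, 2.6, 1.2, 0.58 ml), converted to inner radii via
r = (3V/4π)^(1/3) (18.3, 13.7, 10.9, 8.5, 6.6, 5.2 mm). Wall
thicknesses are known only as a 0.9–1.3 mm range; the default assigns
them by linear interpolation from the smallest (0.9 mm) to the largest
sphere (1.3 mm), configurable per sphere. Spheres sit on a 57.2-mm ring
in the central transaxial plane at 60° spacing — the standard IEC
layout. The body is a cylinder of radius 140 mm and length 160 mm:
generous enough that no VOI or fit window approaches the boundary, so
the true torso cross-section is irrelevant to every metric in scope
(the length is chosen so the phantom also fits the default grid with
margin). The lung insert is omitted; no metric touches it. The 30-ml
spherical background VOI sits azimuthally midway between two adjacent
spheres at a 40-mm axial offset; phantom validation rejects sphere
overlaps and any VOI placement that clips a sphere or the body.

Activities follow the three filling schemes (sphere:background
24.4:3.1, 12.5:3.1, 7.5:3.9 kBq/ml ≈ 8:1, 4:1, 2:1) and decay with the
F-18 half-life (109.77 min, configurable). Decay cancels in the
sphere-to-background ratio, and both rasterization and the
reconstruction signature are linear in the compartment activities, so a
five-scan series is simulated as one noiseless volume scaled per scan,
plus per-scan noise.

## Synthetic volumes

The default grid is 128×128×64 voxels at 2.73×2.73×2.78 mm³ — the
scanner voxel size on a cropped matrix; the full 256×256 field of view
is available through configuration but adds nothing to the phantom.

**Rasterization** assigns each voxel the volume-weighted mixture of
compartment activity concentrations (hot interior, cold wall, warm
background, zero outside the body), refining only interface voxels with
`supersample³` subsamples (default 4³); interior voxels are exact.

**Resolution.** A preset's `blur_fwhm` is the *net* resolution of the
sampled volume. Rasterization already convolves the truth with the
voxel box (variance `spacing²/12` per axis), so the applied Gaussian
carries per-axis variance `max(σ_target² − spacing²/12, 0)` and is
applied through its exact Fourier transfer function. Two numerical
consequences, both deliberate: (i) profile fits recover `blur_fwhm`
itself (≤0.04 mm bias at 3.7–8.2 mm) rather than `blur_fwhm` plus a
sampling broadening of 0.2–0.45 mm; (ii) because the target resolution
is close to the voxel size, the band-limited kernel leaves a Gibbs
ripple of up to ~0.8% near sharp edges — noiseless CR values can
exceed 1.0 by ≤10⁻³, and the angular spread of the blurred profile
(the voxel box is cubic, not spherical) reaches ~1.4% of the sphere AC
at the sharpest blur. A non-negative spatial kernel would remove the
ripple but cannot reach sub-voxel widths without a large positive
excess kurtosis that biases fitted FWHM by up to −0.2 mm; the ripple is
the cheaper artifact. The FFT is periodic, which conserves total
activity exactly; wrap-around carries only the ripple tail and is
negligible for phantoms kept several FWHM from the grid edge.

**Edge artifacts.** Resolution-modelling reconstruction overshoots at
hot-object boundaries. The generator emulates this with one parameter:
an unsharp-mask ringing term, `amplitude × (blurred − reblur(blurred,
1.5×FWHM))` — a zero-sum band-pass image that elevates values just
inside the boundary and depresses them outside. This reproduces the
phenomenology (overshoot grows with sharper reconstruction, CR can
exceed 1) without claiming to model the true Gibbs behavior of
penalized-likelihood or PSF reconstruction.

**Noise** is additive, zero-mean, spatially correlated Gaussian: white
noise filtered with a Gaussian of FWHM `noise_corr_fwhm` (default
4 mm), normalized by its whole-grid sample SD, and scaled to
`noise_cv × background mean`. Filtering is periodic — reflect-mode
filtering inflates edge variance and was measured to bias the SNR
normalization by ~3% on small grids. The realized VOI SD therefore
fluctuates around its target (a few percent over seeds), which is what
makes the SNR-recovery checks meaningful. Poisson sinogram noise and
per-algorithm noise texture are out of scope: downstream metrics need
only a controllable background mean, SD and correlation length. Across
a scan series the coefficient of variation is inflated by
`2^(elapsed/(2·half_life))` to emulate count loss.

**Presets.** Nine named presets (three penalization factors of a
Bayesian penalized-likelihood reconstruction, plus OSEM+TOF with and
without PSF at three iteration/subset/filter combinations) are shipped
as *fixtures*: resolutions are scanner-informed high-contrast FWHM
magnitudes, noise CVs the reciprocal of typical background SNR, and
overshoot amplitudes phenomenological (growing with lower penalization,
zero without PSF modelling). They give the simulated study realistic
relative behavior; they are not measurements, and the package makes no
claim of reproducing measured scanner values, which would require the
real acquisition data.

## Resolution estimation

For a homogeneous sphere of radius R convolved with an isotropic 3D
Gaussian of width σ, the radial profile has the closed form

    f(r;R,σ) = ½[erf((R−r)/(σ√2)) + erf((R+r)/(σ√2))]
               − σ/(r√(2π))·[e^(−(r−R)²/2σ²) − e^(−(r+R)²/2σ²)],

with f ∈ [0,1]; below r < 10⁻⁶R the removable singularity is replaced
by the analytic limit erf(R/(σ√2)) − √(2/π)(R/σ)e^(−R²/2σ²) (the
profile is even in r, so the neglected correction is O(r²)). The
closed form is verified in the test suite against dense-grid 3D
convolution (0.25-mm grid, ≤10⁻³) and against mass conservation
(≤10⁻⁴ relative). A walled phantom sphere is

    model(r) = S·f(r;R,σ) + B·(1 − f(r;R+d,σ)),

hot interior S, cold wall of thickness d, warm exterior B.

Fitting proceeds per sphere: (1) the center is refined by an iterated
background-subtracted centroid (background = shell median; stop when
the move is <0.01 mm or after 50 iterations; a uniform window returns
the initial center flagged degenerate); (2) every voxel within
r_max = R_outer + max(12 mm, 2.5×FWHM guess) is transformed to its
radial distance — unbinned, no angular averaging; (3) (S, B, σ) are
estimated by unweighted trust-region least squares with R and d fixed
to their known values. Initialization: B₀ = median beyond
R_outer + 6 mm, S₀ from the sphere core (profile maximum for inner
radii <7 mm), σ₀ = 2 mm; bounds S ∈ (0, 10S₀], B ∈ [0, 10B₀],
σ ∈ [0.3, 15] mm, with fits ending on the σ bounds flagged
not-converged. Weighting is uniform because voxel noise is
approximately homoscedastic in the background-dominated shells. The
fit function deliberately keeps the pure Gaussian-PSF assumption — the
edge-artifact term is *not* modelled — so overshoot shows up as a
smaller fitted FWHM and a larger residual sum of squares, which is
reported as the quality diagnostic. FWHM = σ·2√(2 ln 2). Study tables
pool the three largest spheres (22/28/37 mm), where the profile
constrains σ well.

Parameter recovery under the default study conditions: noiseless
|ΔFWHM| ≤ 0.04 mm, and ≤0.04 mm in the 10-seed mean at 15% background
noise, for blurs 3.7–8.2 mm (asserted at the looser 0.15/0.3 mm in the
tests). Recovery degrades as contrast drops; the scatter of repeated
fits grows from 8:1 to 2:1, which the suite checks as a property.

## Contrast recovery and SNR

* `cr_max` — hottest voxel within R_outer + 2 mm (margin configurable)
  over the true decay-corrected sphere AC of that scan.
* `cr_peak` — mean of a 1.2-cm-diameter spherical VOI positioned to
  maximize its mean, over the true AC. Candidate centers lie on the
  subvoxel lattice (spacing/3 ≈ 0.9 mm) within R_outer of the sphere
  center, which keeps the whole VOI within R_outer + 6 mm ("of this
  sphere") and guarantees CRmax ≥ CRpeak up to the margin convention.
  Voxel membership uses 3×3×3 partial-volume subdivision; on the
  subdivided lattice the weighted mean is an exact ball-kernel
  correlation evaluated by FFT. Against an 11× subdivided (~0.25 mm)
  brute-force search the combined search + weighting error is <1%.
  Ties (uniform images) resolve to the candidate nearest the nominal
  center.
* `background_snr` — mean/SD over voxel centers in the 30-ml VOI
  (~1440 voxels at the default grid, so partial weights are
  unnecessary); SD ≈ 0 yields an infinite SNR flagged degenerate. The
  estimator is unbiased within sampling error (checked over 50 seeds
  against 1/noise_cv).

## Statistics and reports

Paired comparisons between settings use the Wilcoxon signed-rank test
(zeros dropped, mid-ranks; exact null for n ≤ 25 without ties,
tie-corrected normal approximation otherwise); between contrast levels,
Mann–Whitney U (exact for pooled n ≤ 12 without ties) and
Kruskal–Wallis (exact enumeration of all group assignments for pooled
n ≤ 12 — enumerated in-package since SciPy has no exact path — else
the χ² approximation). Exact paths are verified against full
enumeration oracles in the tests. Significance is p < 0.05 with no
multiple-testing correction. Relative differences are
100·(a−b)/b with the conventional method as comparator b; the
definition is intentionally not antisymmetric.

The tradeoff classifier labels a pair of settings per axis: CRpeak is
"higher" if A exceeds 1.1×B for at least one small sphere
(10/13/17 mm) of the pooled per-sphere means, "lower" by the mirrored
rule (B > 1.1×A), else "equal" — the mirrored form makes the verdict
exactly covariant under swapping A and B, which a single-denominator
±10% rule is not. The SNR verdict uses the paired Wilcoxon over the
15 (contrast level, scan) cells with the sign of the median
difference. FWHM comparisons pair by (scan, sphere) over the three
largest spheres (n = 15); the pairing convention is recorded in the
report metadata. Report builders require a complete
preset × contrast × scan grid, emit deterministic CSV (same input →
byte-identical output), and draw CR-versus-diameter curves and the
pairwise tradeoff matrix.

## Reproducibility and problem sizes

All randomness flows from integer seeds: `add_noise` is bit-identical
for a given seed, a series derives scan seeds as `seed + k`, and the
study driver gives each (level, preset, scan) cell the seed
`seed + 10000·i_level + 1000·i_preset + k` (mod 2³¹). The default
study grid — nine presets × three contrast levels × five scans on the
128×128×64 grid, metrics on all six spheres and fits on the three
largest — runs in well under a minute on one core;
`scripts/acceptance.py` executes exactly that and writes the headline
quantities as JSON. Test simulations use the same voxel size on
smaller grids (48³, 36³) with single-sphere phantoms where the full
ring adds nothing.

## Known limitations

* No tomographic reconstruction, attenuation, scatter or randoms: the
  generator reproduces image-domain signatures only, so passing tests
  demonstrate correctness of the *analysis* on controlled inputs, not
  the behavior of any particular scanner or algorithm.
* The edge-artifact model is a one-parameter band-pass term; it does
  not reproduce algorithm-specific ringing shapes, and the preset
  amplitudes are fixtures.
* Noise is Gaussian with a single correlation scale; real
  reconstructed noise is non-stationary and algorithm-dependent.
* The Gaussian-PSF profile model is never exact for iterative
  reconstruction; with strong edge artifacts the fitted FWHM
  underestimates the blur kernel width (visible in the residuals).
* Sub-voxel Gibbs ripple (≤0.8%) from the band-limited blur slightly
  exceeds 1.0 in noiseless CR of large spheres.
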