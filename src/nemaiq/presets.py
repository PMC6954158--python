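"""Named reconstruction-setting presets for the synthetic generator.

Nine presets emulate a typical digital-PET protocol comparison:
Bayesian penalized likelihood ("Q.Clear") at three penalization
factors, and OSEM with time-of-flight, with and without PSF modelling,
at three iteration/subset/filter combinations.

The numbers are *fixtures*: resolution defaults are scanner-informed
reconstructed-FWHM magnitudes at high sphere contrast, noise defaults
are the reciprocal of typical background SNR for each setting, and the
overshoot amplitudes are phenomenological (edge elevations grow with
decreasing penalization and vanish without PSF modelling).  They give
the simulated study realistic relative behavior; they are not
measurements, and reproducing measured values requires real scanner
data which this package does not claim to replace.
"""

from __future__ import annotations

from .simulate import ReconPreset

__all__ = ["default_presets", "PRESET_NAMES"]

# name, blur_fwhm [mm], noise_cv (=1/SNR), overshoot amplitude, metadata
_PRESET_TABLE = (
    ("Q.Clear_150", 3.7, 0.238, 0.60, "BPL, beta=150"),
    ("Q.Clear_300", 4.3, 0.143, 0.40, "BPL, beta=300"),
    ("Q.Clear_450", 4.7, 0.108, 0.30, "BPL, beta=450"),
    ("PSF+TOF_4/16", 4.2, 0.227, 0.50, "4 it, 16 ss, 2.0 mm in-plane filter"),
    ("PSF+TOF_2/17", 5.1, 0.143, 0.35, "2 it, 17 ss, 2.0 mm in-plane filter"),
    ("PSF+TOF_4/8", 7.0, 0.078, 0.20, "4 it, 8 ss, 6.4 mm in-plane filter"),
    ("OSEM+TOF_4/16", 4.8, 0.400, 0.0, "4 it, 16 ss, 2.0 mm in-plane filter"),
    ("OSEM+TOF_2/17", 5.2, 0.256, 0.0, "2 it, 17 ss, 2.0 mm in-plane filter"),
    ("OSEM+TOF_2/8", 8.2, 0.060, 0.0, "2 it, 8 ss, 6.4 mm in-plane filter"),
)

PRESET_NAMES = tuple(row[0] for row in _PRESET_TABLE)


def default_presets(noise_corr_fwhm: float = 4.0) -> dict[str, ReconPreset]:
    """The nine named presets, keyed by name."""
    return {
        name: ReconPreset(
            name=name,
            blur_fwhm=blur,
            noise_cv=cv,
            overshoot_amplitude=over,
            noise_corr_fwhm=noise_corr_fwhm,
            metadata=meta,
        )
        for name, blur, cv, over, meta in _PRESET_TABLE
    }
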