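"""First-order derivative spectral features.

The derivative spectrum is the plain difference between neighbouring
retained bands, ``out[i] = in[i+1] - in[i]`` (no wavelength-spacing
division), emphasising spectral shape such as the haemoglobin alpha/beta
absorption features. An ablation switch allows running the pipeline on
normalised spectra directly.
"""

from __future__ import annotations

import numpy as np

from .hsi_data import PixelSet


def first_derivative(pixels: PixelSet) -> PixelSet:
    """Difference of neighbouring bands; feature count drops by one.

    Derivatives are taken across the retained-band sequence, including
    across any band-removal gaps; supply a gapless removal spec upstream
    if that matters for your data.
    """
    if pixels.n_features < 2:
        raise ValueError("need at least 2 bands to differentiate")
    deriv = np.diff(pixels.spectra, axis=1)
    wl = None
    if pixels.wavelengths is not None:
        # midpoint convention for the derivative feature's nominal wavelength
        wl = 0.5 * (pixels.wavelengths[:-1] + pixels.wavelengths[1:])
    return pixels.with_spectra(deriv, wl)


def extract(pixels: PixelSet, enabled: bool = True) -> PixelSet:
    """Apply derivative extraction, or pass through when disabled."""
    return first_derivative(pixels) if enabled else pixels
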