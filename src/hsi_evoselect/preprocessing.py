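"""Three-step preprocessing chain for reflectance cubes.

The chain, applied in order: (1) per-band spatial median smoothing,
(2) per-pixel median normalisation (cancels multiplicative illumination),
(3) removal of designated noisy band ranges. The default removal
specification drops the noisy sensor ranges {0-4, 47-49, 121-127}
(0-based, inclusive), reducing a 128-band cube to 113 bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .hsi_data import HyperCube, PixelSet


@dataclass(frozen=True)
class BandRemovalSpec:
    """Inclusive 0-based index intervals to drop from the spectral axis."""

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        norm = sorted((int(lo), int(hi)) for lo, hi in self.ranges)
        for lo, hi in norm:
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid band interval ({lo}, {hi})")
        for (_, hi), (lo2, _) in zip(norm, norm[1:]):
            if lo2 <= hi:
                raise ValueError("band intervals overlap")
        object.__setattr__(self, "ranges", tuple(norm))

    def mask(self, n_bands: int) -> np.ndarray:
        """Boolean keep-mask of length ``n_bands``."""
        keep = np.ones(n_bands, dtype=bool)
        for lo, hi in self.ranges:
            if hi >= n_bands:
                raise IndexError(f"interval ({lo}, {hi}) out of range for {n_bands} bands")
            keep[lo : hi + 1] = False
        return keep

    @property
    def n_removed(self) -> int:
        return sum(hi - lo + 1 for lo, hi in self.ranges)


#: Default noisy ranges for the 128-band sensor; leaves 113 bands.
DEFAULT_REMOVAL = BandRemovalSpec(ranges=((0, 4), (47, 49), (121, 127)))


def spatial_median_filter(cube: HyperCube, radius: int = 1, mode: str = "reflect") -> HyperCube:
    """Smooth each band with a (2r+1) x (2r+1) spatial median window.

    ``radius=0`` is the identity. Borders are handled by ``mode``
    ({"reflect", "nearest"}).
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if mode not in ("reflect", "nearest"):
        raise ValueError("mode must be 'reflect' or 'nearest'")
    if radius == 0:
        return cube
    size = 2 * radius + 1
    out = ndimage.median_filter(cube.values, size=(size, size, 1), mode=mode)
    return cube.with_values(out)


def _normalize_matrix(x: np.ndarray, what: str) -> np.ndarray:
    med = np.median(x, axis=1)
    bad = ~np.isfinite(med) | (med == 0)
    if np.any(bad):
        idx = int(np.argmax(bad))
        raise ValueError(f"{what} {idx} has zero or non-finite median; cannot normalise")
    return x / med[:, None]


def median_normalize(data: HyperCube | PixelSet) -> HyperCube | PixelSet:
    """Divide every spectrum by its own median (result has median 1)."""
    if isinstance(data, HyperCube):
        h, w, b = data.shape
        flat = _normalize_matrix(data.values.reshape(-1, b), "pixel")
        return data.with_values(flat.reshape(h, w, b))
    return data.with_spectra(_normalize_matrix(data.spectra, "row"))


def remove_bands(
    data: HyperCube | PixelSet, spec: BandRemovalSpec = DEFAULT_REMOVAL
) -> HyperCube | PixelSet:
    """Drop the bands listed in ``spec``; wavelengths dropped in lockstep."""
    if isinstance(data, HyperCube):
        keep = spec.mask(data.n_bands)
        if not keep.any():
            raise ValueError("removal spec covers every band; empty spectra forbidden")
        return data.with_values(data.values[:, :, keep], data.wavelengths[keep])
    keep = spec.mask(data.n_features)
    if not keep.any():
        raise ValueError("removal spec covers every band; empty spectra forbidden")
    wl = data.wavelengths[keep] if data.wavelengths is not None else None
    return data.with_spectra(data.spectra[:, keep], wl)


def preprocess_cube(
    cube: HyperCube,
    median_radius: int = 1,
    normalize: bool = True,
    removal: BandRemovalSpec | None = DEFAULT_REMOVAL,
    border_mode: str = "reflect",
) -> HyperCube:
    """Full chain: median filter -> median normalise -> band removal."""
    out = spatial_median_filter(cube, median_radius, mode=border_mode)
    if normalize:
        out = median_normalize(out)
    if removal is not None:
        out = remove_bands(out, removal)
    return out
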