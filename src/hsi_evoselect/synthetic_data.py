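"""Synthetic annotated hyperspectral scenes.

Emulates the statistical structure of a forensic blood-substance
dataset: 6 annotated classes over 7 images of two scene types, 128
bands spanning 377-1046 nm, a blood class carrying the haemoglobin
alpha/beta absorption features near 542 and 576 nm, per-image
illumination scaling, designated noisy band ranges and day-indexed
spectral drift (oxidation-like attenuation of the haemoglobin dips plus
a global tilt).

Scene types:

* ``frame_like`` ("F") — uniform bright background, pure class
  signatures, low inter-image variation.
* ``comparison_like`` ("E") — mixed backgrounds; each class blob's
  spectra are convex mixtures of the class signature with a random
  smooth background spectrum (weight ~ U(0.1, 0.4)), and illumination
  varies more between images. This is the domain gap that makes
  cross-scene (inductive) classification harder than within-scene
  (transductive) classification.

Class signatures are Gaussian mixtures in wavelength, not measured
spectra; the 542/576 nm dips are the only biologically anchored
features. With ``informative_bands`` set, classes share one base curve
and differ only on that band subset, which is the ground truth used by
band-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hsi_data import HyperCube, LabelMap, PixelSet, default_wavelengths

BLOOD_CLASS = 1
#: alpha/beta haemoglobin absorption band centres (nm)
HB_ALPHA_NM = 576.0
HB_BETA_NM = 542.0

#: the seven-image study roster: (scene_kind, scene_id, day)
STUDY_ROSTER = (
    ("frame_like", "F", "1"),
    ("frame_like", "F", "1a"),
    ("frame_like", "F", "7"),
    ("frame_like", "F", "21"),
    ("comparison_like", "E", "1"),
    ("comparison_like", "E", "7"),
    ("comparison_like", "E", "21"),
)

DEFAULT_NOISY_RANGES = ((0, 4), (47, 49), (121, 127))


def day_number(day: str) -> float:
    """Numeric acquisition time for a day tag; "1a" is the afternoon
    of day 1 and maps to 1.5."""
    if day.endswith("a"):
        return float(day[:-1]) + 0.5
    return float(day)


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene / study.

    ``day_drift`` scales the per-day signature change (dip attenuation
    and tilt); ``illumination_scale`` is the scene's multiplicative
    brightness factor; bands inside ``noisy_band_ranges`` receive 10x
    the base noise. ``informative_bands`` switches to the
    known-informative-subset mode used by band-recovery tests.
    """

    n_classes: int = 6
    bands: int = 128
    height: int = 64
    width: int = 64
    scene_kind: str = "frame_like"
    pixels_per_class: int = 1000
    day_drift: float = 0.02
    illumination_scale: float = 1.0
    noise_sigma: float = 0.01
    noisy_band_ranges: tuple[tuple[int, int], ...] = DEFAULT_NOISY_RANGES
    informative_bands: tuple[int, ...] | None = None
    class_ids: tuple[int, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pixels_per_class < 1:
            raise ValueError("pixels_per_class must be >= 1")
        if self.class_ids is None:
            # six-class label set of the study (class 4 absent by design)
            base = (1, 2, 3, 5, 6, 7)
            self.class_ids = base[: self.n_classes] if self.n_classes <= 6 else tuple(
                range(1, self.n_classes + 1)
            )
        if len(self.class_ids) != self.n_classes:
            raise ValueError("class_ids length must equal n_classes")
        if self.informative_bands is not None:
            if any(not 0 <= b < self.bands for b in self.informative_bands):
                raise ValueError("informative bands out of range")

    @property
    def wavelengths(self) -> np.ndarray:
        return default_wavelengths(self.bands)


def _gauss(wl: np.ndarray, centre: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - centre) / width) ** 2)


def _base_curve(wl: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Smooth positive reflectance curve: offset + a few broad Gaussians."""
    curve = np.full(wl.shape, rng.uniform(0.25, 0.45))
    for _ in range(rng.integers(2, 5)):
        curve += rng.uniform(0.05, 0.25) * _gauss(
            wl, rng.uniform(wl[0], wl[-1]), rng.uniform(60, 220)
        )
    return curve


def class_signature(class_id: int, spec: SceneSpec, day: str = "1") -> np.ndarray:
    """Deterministic reflectance signature of a class on a given day.

    The blood class carries two absorption dips centred at 542 and
    576 nm whose depth decays with acquisition day (haemoglobin
    oxidation); every class receives a small day-indexed global tilt
    proportional to ``spec.day_drift``.
    """
    if class_id not in spec.class_ids:
        raise ValueError(f"class id {class_id} not in scene spec")
    wl = spec.wavelengths
    t = day_number(day)
    if spec.informative_bands is not None:
        # shared base; class identity lives only on the informative subset
        rng = np.random.default_rng(977)
        sig = _base_curve(wl, rng)
        crng = np.random.default_rng(4000 + class_id)
        bump = np.zeros_like(sig)
        bump[list(spec.informative_bands)] = crng.uniform(
            0.15, 0.4, size=len(spec.informative_bands)
        ) * crng.choice([-1.0, 1.0], size=len(spec.informative_bands))
        sig = sig + bump
    else:
        rng = np.random.default_rng(1000 + class_id)
        sig = _base_curve(wl, rng)
        if class_id == BLOOD_CLASS:
            depth = 0.22 * np.exp(-0.12 * spec.day_drift / 0.02 * (t - 1.0))
            sig -= depth * _gauss(wl, HB_BETA_NM, 9.0)
            sig -= depth * _gauss(wl, HB_ALPHA_NM, 9.0)
    # global day tilt
    tilt = spec.day_drift * (t - 1.0) / 20.0
    sig = sig * (1.0 + tilt * (wl - wl.mean()) / (wl[-1] - wl[0]))
    return np.clip(sig, 0.02, None)


def _blob_layout(spec: SceneSpec) -> tuple[np.ndarray, list[np.ndarray]]:
    """Assign exact per-class pixel counts in horizontal strips.

    Returns the label image and the flat pixel indices of each class
    blob (strips give the spatial median filter structure to act on).
    """
    h, w = spec.height, spec.width
    need = spec.n_classes * spec.pixels_per_class
    if need > h * w:
        raise ValueError(
            f"grid {h}x{w} too small for {spec.n_classes} x {spec.pixels_per_class} pixels"
        )
    labels = np.zeros(h * w, dtype=np.int64)
    blobs = []
    pos = 0
    for cid in spec.class_ids:
        idx = np.arange(pos, pos + spec.pixels_per_class)
        labels[idx] = cid
        blobs.append(idx)
        pos += spec.pixels_per_class
    return labels.reshape(h, w), blobs


def generate_scene(spec: SceneSpec, seed: int, day: str | None = None,
                   scene_id: str | None = None) -> tuple[HyperCube, LabelMap]:
    """Generate one annotated scene; bit-deterministic under ``seed``.

    Pixel spectrum = illumination x (signature, optionally mixed with a
    blob background) + Gaussian noise, with 10x noise inside the
    designated noisy band ranges; exact per-class pixel counts.
    """
    rng = np.random.default_rng(seed)
    if day is None:
        day = "1"
    if scene_id is None:
        scene_id = "F" if spec.scene_kind == "frame_like" else "E"
    wl = spec.wavelengths
    h, w, b = spec.height, spec.width, spec.bands
    labels, blobs = _blob_layout(spec)

    cube = np.empty((h * w, b))
    if spec.scene_kind == "frame_like":
        background = np.full(b, 0.9)
    else:
        background = _base_curve(wl, rng) + rng.uniform(0.0, 0.3)
    cube[:] = background

    for cid, idx in zip(spec.class_ids, blobs):
        sig = class_signature(cid, spec, day)
        if spec.scene_kind == "comparison_like":
            blob_bg = _base_curve(wl, rng)
            mix = rng.uniform(0.1, 0.4)
            sig = (1.0 - mix) * sig + mix * blob_bg
        cube[idx] = sig

    cube *= spec.illumination_scale
    sigma = np.full(b, spec.noise_sigma)
    for lo, hi in spec.noisy_band_ranges:
        sigma[lo : hi + 1] *= 10.0
    cube += rng.normal(0.0, 1.0, size=cube.shape) * sigma
    np.clip(cube, 0.0, None, out=cube)

    hyper = HyperCube(cube.reshape(h, w, b), wl, scene_id=scene_id, day=day)
    return hyper, LabelMap(labels)


def generate_study(spec: SceneSpec, seed: int) -> list[tuple[HyperCube, LabelMap]]:
    """Generate the 7-image study: frame scenes on days {1, 1a, 7, 21}
    and comparison scenes on days {1, 7, 21}.

    Comparison images carry the domain gap: background mixing plus
    stronger per-image illumination variation.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i, (kind, scene_id, day) in enumerate(STUDY_ROSTER):
        s = SceneSpec(**{**spec.__dict__, "scene_kind": kind})
        if kind == "frame_like":
            s.illumination_scale = spec.illumination_scale * rng.uniform(0.95, 1.05)
        else:
            s.illumination_scale = spec.illumination_scale * rng.uniform(0.7, 1.3)
        out.append(generate_scene(s, seed=int(rng.integers(2**31 - 1)),
                                  day=day, scene_id=scene_id))
    return out


def make_pixel_set(
    n_classes: int,
    n_per_class: int,
    n_bands: int,
    seed: int,
    informative_bands: tuple[int, ...] | None = None,
    noise_sigma: float = 0.05,
    class_gap: float = 0.5,
) -> PixelSet:
    """Small labelled pixel set for optimiser tests, bypassing scenes.

    Class means are random smooth-ish vectors separated by ``class_gap``;
    with ``informative_bands`` set, classes share one mean and differ
    only on that subset, so only those bands carry signal.
    """
    rng = np.random.default_rng(seed)
    wl = np.linspace(377.0, 1046.0, n_bands)
    means = np.empty((n_classes, n_bands))
    if informative_bands is not None:
        base = _base_curve(wl, rng)
        for k in range(n_classes):
            means[k] = base
            means[k, list(informative_bands)] += class_gap * rng.choice(
                [-1.0, 1.0], size=len(informative_bands)
            ) * rng.uniform(0.5, 1.0, size=len(informative_bands))
    else:
        for k in range(n_classes):
            means[k] = _base_curve(wl, rng) + class_gap * rng.normal(size=n_bands) * 0.2
    spectra = np.vstack([
        means[k] + rng.normal(0.0, noise_sigma, size=(n_per_class, n_bands))
        for k in range(n_classes)
    ])
    labels = np.repeat(np.arange(1, n_classes + 1), n_per_class)
    src = np.empty((spectra.shape[0], 2), dtype=object)
    src[:, 0] = "S"
    src[:, 1] = "1"
    return PixelSet(spectra, labels, src, wl)
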