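"""Data model and I/O for annotated hyperspectral cubes.

A scene is a reflectance cube of shape ``H x W x B`` together with a
band-to-wavelength mapping and a per-pixel integer label map (0 means
unannotated background). Cubes can be read from ENVI header/binary pairs
or round-tripped through a portable compressed fixture container
(NumPy ``.npz`` with named arrays plus JSON metadata).

Band indexing is 0-based everywhere in this package.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

#: Spectral span of the target sensor (SOC710-like): 128 bands, 377-1046 nm.
WAVELENGTH_MIN_NM = 377.0
WAVELENGTH_MAX_NM = 1046.0
DEFAULT_N_BANDS = 128

FIXTURE_SCHEMA_VERSION = 1


def default_wavelengths(n_bands: int = DEFAULT_N_BANDS) -> np.ndarray:
    """Linear wavelength grid from 377 to 1046 nm inclusive."""
    return np.linspace(WAVELENGTH_MIN_NM, WAVELENGTH_MAX_NM, n_bands)


@dataclass
class HyperCube:
    """H x W x B reflectance cube with wavelength calibration.

    Parameters
    ----------
    values : ndarray, shape (H, W, B)
        Non-negative, finite reflectance values (unitless).
    wavelengths : ndarray, shape (B,)
        Strictly increasing band centres in nanometres.
    scene_id : str
        Scene tag, e.g. ``"F"`` (frame) or ``"E"`` (comparison).
    day : str
        Acquisition-day tag; a plain string key (``"1"``, ``"1a"``, ...).
    wavelengths_synthesised : bool
        True when the source file carried no wavelength block and a linear
        377-1046 nm grid was substituted.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    scene_id: str = ""
    day: str = ""
    wavelengths_synthesised: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"cube must be H x W x B, got shape {self.values.shape}")
        if self.n_bands < 2:
            raise ValueError("cube needs at least 2 bands")
        if self.wavelengths.shape != (self.n_bands,):
            raise ValueError(
                f"wavelengths length {self.wavelengths.size} != band count {self.n_bands}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("reflectance values must be finite and >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def with_values(self, values: np.ndarray, wavelengths: np.ndarray | None = None) -> "HyperCube":
        wl = self.wavelengths if wavelengths is None else wavelengths
        return replace(self, values=values, wavelengths=wl)


@dataclass
class LabelMap:
    """Per-pixel integer annotation; 0 = background, positive = class id."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D (H x W)")
        if np.any(self.labels < 0):
            raise ValueError("labels must be >= 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class PixelSet:
    """Flattened labelled pixels: spectra ``(n, d)``, labels ``(n,)``.

    ``source`` records the originating ``(scene_id, day)`` pair per row so
    evaluation can be reported per acquisition day.
    """

    spectra: np.ndarray
    labels: np.ndarray
    source: np.ndarray  # (n, 2) object/str array of (scene_id, day)
    wavelengths: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.source = np.asarray(self.source)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be 2-D (n x d)")
        n = self.spectra.shape[0]
        if self.labels.shape != (n,):
            raise ValueError("labels length must match number of spectra rows")
        if self.source.shape[:1] != (n,):
            raise ValueError("source length must match number of spectra rows")
        if self.wavelengths is not None:
            self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def n_features(self) -> int:
        return self.spectra.shape[1]

    def take(self, idx: np.ndarray) -> "PixelSet":
        return PixelSet(self.spectra[idx], self.labels[idx], self.source[idx], self.wavelengths)

    def with_spectra(self, spectra: np.ndarray, wavelengths: np.ndarray | None = None) -> "PixelSet":
        return PixelSet(spectra, self.labels, self.source, wavelengths)

    def day_keys(self) -> np.ndarray:
        """Unique ``"<scene>(<day>)"`` keys present, e.g. ``"E(7)"``."""
        keys = np.array([f"{s}({d})" for s, d in self.source])
        return np.unique(keys)


def concat_pixel_sets(parts: list[PixelSet]) -> PixelSet:
    if not parts:
        raise ValueError("nothing to concatenate")
    wl = parts[0].wavelengths
    return PixelSet(
        np.concatenate([p.spectra for p in parts]),
        np.concatenate([p.labels for p in parts]),
        np.concatenate([p.source for p in parts]),
        wl,
    )


def flatten_annotated(
    cube: HyperCube,
    labels: LabelMap,
    drop_classes: set[int] = frozenset(),
) -> PixelSet:
    """Flatten annotated pixels to a labelled pixel set.

    Background (label 0) pixels and pixels whose class is in
    ``drop_classes`` are excluded. Row order is the deterministic
    row-major scan of the image so sampling is reproducible.
    """
    if labels.shape != cube.shape[:2]:
        raise ValueError("label map shape does not match cube")
    lab = labels.labels.ravel()
    keep = lab > 0
    for c in drop_classes:
        keep &= lab != c
    flat = cube.values.reshape(-1, cube.n_bands)[keep]
    src = np.empty((flat.shape[0], 2), dtype=object)
    src[:, 0] = cube.scene_id
    src[:, 1] = cube.day
    return PixelSet(flat, lab[keep], src, cube.wavelengths)


# ---------------------------------------------------------------------------
# ENVI header / band-sequential binary reader
# ---------------------------------------------------------------------------

_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
    5: np.float64, 12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}


def _parse_envi_header(text: str) -> dict:
    """Parse the key = value / key = { ... } fields of an ENVI .hdr file."""
    if not text.lstrip().upper().startswith("ENVI"):
        raise ValueError("not an ENVI header (missing ENVI magic)")
    fields: dict[str, str] = {}
    # join brace-blocks onto one logical line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    for line in text.splitlines()[1:]:
        if "=" not in line:
            continue
        key, _, val = line.partition("=")
        fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(header_path: str | Path, scene_id: str = "", day: str = "") -> HyperCube:
    """Read an ENVI header/binary pair into a :class:`HyperCube`.

    If the header carries no ``wavelength`` block, a linear 377-1046 nm
    grid is synthesised and ``wavelengths_synthesised`` is set.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(header_path)
    fields = _parse_envi_header(header_path.read_text())
    try:
        h = int(fields["lines"])
        w = int(fields["samples"])
        b = int(fields["bands"])
        dtype = _ENVI_DTYPES[int(fields["data type"])]
    except KeyError as e:
        raise ValueError(f"ENVI header missing required field: {e}") from e
    interleave = fields.get("interleave", "bsq").lower()

    bin_path = header_path.with_suffix("")
    if not bin_path.exists():
        for ext in (".dat", ".img", ".raw", ".bsq"):
            cand = header_path.with_suffix(ext)
            if cand.exists():
                bin_path = cand
                break
    if not bin_path.exists():
        raise FileNotFoundError(f"no binary companion for {header_path}")

    raw = np.fromfile(bin_path, dtype=dtype)
    if raw.size != h * w * b:
        raise ValueError(
            f"binary has {raw.size} samples, header declares {h}x{w}x{b}={h * w * b}"
        )
    if interleave == "bsq":
        cube = raw.reshape(b, h, w).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(h, b, w).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(h, w, b)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")

    synthesised = False
    if "wavelength" in fields:
        wl_text = fields["wavelength"].strip().lstrip("{").rstrip("}")
        wavelengths = np.array([float(x) for x in wl_text.split(",") if x.strip()])
        if wavelengths.size != b:
            raise ValueError("wavelength block length does not match band count")
    else:
        wavelengths = default_wavelengths(b)
        synthesised = True
    return HyperCube(cube.astype(np.float64), wavelengths, scene_id=scene_id, day=day,
                     wavelengths_synthesised=synthesised)


def write_envi(cube: HyperCube, header_path: str | Path) -> Path:
    """Write a cube as ENVI .hdr + band-sequential float64 binary."""
    header_path = Path(header_path)
    h, w, b = cube.shape
    wl = ", ".join(f"{x:.4f}" for x in cube.wavelengths)
    header_path.write_text(
        "ENVI\n"
        f"samples = {w}\nlines = {h}\nbands = {b}\n"
        "data type = 5\ninterleave = bsq\nbyte order = 0\n"
        f"wavelength = {{ {wl} }}\n"
    )
    cube.values.transpose(2, 0, 1).astype(np.float64).tofile(header_path.with_suffix(""))
    return header_path


# ---------------------------------------------------------------------------
# Portable fixture container (.npz)
# ---------------------------------------------------------------------------

def write_fixture(cube: HyperCube, labels: LabelMap, path: str | Path) -> Path:
    """Losslessly serialise a (cube, labels) pair to a compressed container."""
    if labels.shape != cube.shape[:2]:
        raise ValueError("label map shape does not match cube")
    path = Path(path)
    meta = json.dumps(
        {"scene_id": cube.scene_id, "day": cube.day, "schema_version": FIXTURE_SCHEMA_VERSION}
    )
    np.savez_compressed(
        path,
        values=cube.values,
        wavelengths=cube.wavelengths,
        labels=labels.labels,
        meta=np.array(meta),
    )
    # np.savez appends .npz when absent
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def read_fixture(path: str | Path) -> tuple[HyperCube, LabelMap]:
    with np.load(path, allow_pickle=False) as z:
        for name in ("values", "wavelengths", "labels", "meta"):
            if name not in z:
                raise ValueError(f"fixture container missing array {name!r}")
        meta = json.loads(str(z["meta"]))
        if meta.get("schema_version") != FIXTURE_SCHEMA_VERSION:
            raise ValueError(
                f"fixture schema version {meta.get('schema_version')} != {FIXTURE_SCHEMA_VERSION}"
            )
        cube = HyperCube(z["values"], z["wavelengths"],
                         scene_id=meta["scene_id"], day=meta["day"])
        labels = LabelMap(z["labels"])
    return cube, labels
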