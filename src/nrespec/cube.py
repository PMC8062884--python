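"""Hyperspectral cube handling: reflectance calibration and ROI reduction.

A :class:`SpectralCube` stores a rows x cols x bands array together with its
wavelength grid (nm).  Raw digital numbers are converted to reflectance by
two-point calibration against a grey reference panel of known reflectance,
optionally with a dark-current frame::

    R = (raw - dark) / (white - dark) * panel_reflectance

with the white and dark references spatially averaged to a per-band vector
before the ratio, which suppresses reference noise.  Sample spectra are then
reduced from the image by averaging over a region-of-interest mask.

Cubes round-trip through two containers: an ENVI-style text header plus flat
binary file (``.hdr``/``.raw``), and a NumPy ``.npz`` named-array archive.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    DegenerateReferenceError,
    EmptyRoiError,
    GridMismatchError,
    NrespecError,
)

__all__ = [
    "SpectralCube",
    "RoiMask",
    "calibrate_reflectance",
    "extract_roi_mean",
    "save_cube_npz",
    "load_cube_npz",
    "save_cube_envi",
    "load_cube_envi",
    "save_mask_indices",
    "load_mask_indices",
]


@dataclass
class SpectralCube:
    """A rows x cols x bands image cube with its wavelength grid.

    Parameters
    ----------
    values
        3-D float array, raw digital numbers or reflectance (unitless).
    wavelengths
        Strictly increasing band-center wavelengths in nm; length must equal
        the band dimension.
    is_reflectance
        True once the cube has been calibrated to reflectance.
    """

    values: np.ndarray
    wavelengths: np.ndarray
    is_reflectance: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.values.ndim != 3:
            raise NrespecError(f"cube must be 3-D (rows, cols, bands), got shape {self.values.shape}")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise GridMismatchError(
                f"wavelength vector length {self.wavelengths.size} does not match "
                f"band dimension {self.values.shape[2]}"
            )
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise NrespecError("wavelengths must be strictly increasing")
        if self.is_reflectance and not np.all(np.isfinite(self.values)):
            raise NrespecError("reflectance cube contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]


@dataclass
class RoiMask:
    """Boolean region-of-interest mask over the cube's spatial grid."""

    mask: np.ndarray
    sample_id: str = field(default="sample")

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise NrespecError("ROI mask must be 2-D")
        if not self.mask.any():
            raise EmptyRoiError(f"ROI mask for {self.sample_id!r} selects no pixels")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def _check_same_grid(a: SpectralCube, b: SpectralCube, what: str) -> None:
    if a.values.shape != b.values.shape:
        raise GridMismatchError(f"{what}: shape {b.values.shape} does not match {a.values.shape}")
    if not np.array_equal(a.wavelengths, b.wavelengths):
        raise GridMismatchError(f"{what}: wavelength grids differ")


def calibrate_reflectance(
    raw: SpectralCube,
    white: SpectralCube,
    dark: SpectralCube | None = None,
    panel_reflectance: float | np.ndarray = 1.0,
    clip_max: float = 1.5,
) -> SpectralCube:
    """Two-point calibration of a raw cube against a reference panel.

    The white (and optional dark) cubes are spatially averaged to per-band
    vectors; each pixel/band is then ``(raw - dark) / (white - dark)`` scaled
    by the panel's known reflectance.  Output is clipped to ``[0, clip_max]``
    — the default ceiling of 1.5 tolerates specular glint above the panel
    reflectance instead of silently biasing it to 1.

    Parameters
    ----------
    raw
        Uncalibrated cube.
    white
        Image of the reference panel, same shape and grid as ``raw``.
    dark
        Optional dark-current cube; defaults to all zeros.
    panel_reflectance
        Known panel reflectance, scalar or per-band vector, each in (0, 1].

    Raises
    ------
    GridMismatchError
        If shapes or wavelength grids differ between the inputs.
    DegenerateReferenceError
        If any band's averaged white signal does not exceed the dark signal.
    """
    _check_same_grid(raw, white, "white reference")
    if dark is not None:
        _check_same_grid(raw, dark, "dark reference")
        dark_band = dark.values.mean(axis=(0, 1))
    else:
        dark_band = np.zeros(raw.n_bands)
    white_band = white.values.mean(axis=(0, 1))

    panel = np.asarray(panel_reflectance, dtype=float)
    if panel.ndim == 0:
        panel = np.full(raw.n_bands, float(panel))
    elif panel.shape != (raw.n_bands,):
        raise GridMismatchError(
            f"panel reflectance length {panel.size} does not match {raw.n_bands} bands"
        )
    if np.any(panel <= 0) or np.any(panel > 1):
        raise NrespecError("panel reflectance must lie in (0, 1]")

    denom = white_band - dark_band
    bad = np.flatnonzero(denom <= 0)
    if bad.size:
        wl = raw.wavelengths[bad[0]]
        raise DegenerateReferenceError(
            f"white <= dark in band {bad[0]} ({wl:g} nm); reference is degenerate"
        )

    refl = (raw.values - dark_band) / denom * panel
    refl = np.clip(refl, 0.0, clip_max)
    return SpectralCube(refl, raw.wavelengths.copy(), is_reflectance=True)


def extract_roi_mean(cube: SpectralCube, roi: RoiMask) -> tuple[np.ndarray, int]:
    """Mean spectrum over the masked pixels.

    Returns the per-band arithmetic mean over the ROI's true pixels and the
    pixel count used.  The cube must already be in reflectance.
    """
    if not cube.is_reflectance:
        raise NrespecError("ROI extraction expects a calibrated reflectance cube")
    if roi.mask.shape != cube.values.shape[:2]:
        raise GridMismatchError(
            f"mask shape {roi.mask.shape} does not match cube spatial shape {cube.values.shape[:2]}"
        )
    pixels = cube.values[roi.mask]  # (n_pixels, bands)
    return pixels.mean(axis=0), pixels.shape[0]


# ---------------------------------------------------------------------------
# containers


def save_cube_npz(path: str | Path, cube: SpectralCube) -> None:
    """Write a cube to a named-array ``.npz`` archive."""
    np.savez(
        path,
        values=cube.values,
        wavelengths=cube.wavelengths,
        is_reflectance=np.array(cube.is_reflectance),
    )


def load_cube_npz(path: str | Path) -> SpectralCube:
    with np.load(path) as z:
        return SpectralCube(z["values"], z["wavelengths"], bool(z["is_reflectance"]))


_ENVI_DTYPES = {4: "<f4", 5: "<f8"}


def save_cube_envi(path_stem: str | Path, cube: SpectralCube) -> tuple[Path, Path]:
    """Write an ENVI-style text header (``.hdr``) and flat binary (``.raw``).

    Band-sequential (BSQ) float32 layout; only the header fields the reader
    needs are emitted.
    """
    stem = Path(path_stem)
    hdr_path = stem.with_suffix(".hdr")
    raw_path = stem.with_suffix(".raw")
    rows, cols, bands = cube.shape
    wl = ", ".join(f"{w:g}" for w in cube.wavelengths)
    hdr = (
        "ENVI\n"
        f"samples = {cols}\n"
        f"lines = {rows}\n"
        f"bands = {bands}\n"
        "header offset = 0\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        f"reflectance = {int(cube.is_reflectance)}\n"
        f"wavelength = {{ {wl} }}\n"
    )
    hdr_path.write_text(hdr)
    # BSQ: band-major
    np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype="<f4").tofile(raw_path)
    return hdr_path, raw_path


def load_cube_envi(path_stem: str | Path) -> SpectralCube:
    """Read a cube written by :func:`save_cube_envi` (or a compatible pair)."""
    stem = Path(path_stem)
    hdr_path = stem if stem.suffix == ".hdr" else stem.with_suffix(".hdr")
    text = hdr_path.read_text()

    def _field(name: str) -> str:
        m = re.search(rf"^{name}\s*=\s*(.+)$", text, flags=re.MULTILINE)
        if m is None:
            raise NrespecError(f"ENVI header missing field {name!r}")
        return m.group(1).strip()

    cols = int(_field("samples"))
    rows = int(_field("lines"))
    bands = int(_field("bands"))
    dtype = _ENVI_DTYPES.get(int(_field("data type")))
    if dtype is None:
        raise NrespecError("unsupported ENVI data type (only float32/float64 handled)")
    interleave = _field("interleave").lower()
    if interleave != "bsq":
        raise NrespecError(f"unsupported interleave {interleave!r} (only bsq)")
    m = re.search(r"wavelength\s*=\s*\{([^}]*)\}", text, flags=re.DOTALL)
    if m is None:
        raise NrespecError("ENVI header missing wavelength block")
    wavelengths = np.array([float(t) for t in m.group(1).replace("\n", " ").split(",") if t.strip()])
    is_refl = False
    refl_match = re.search(r"^reflectance\s*=\s*(\d+)", text, flags=re.MULTILINE)
    if refl_match:
        is_refl = bool(int(refl_match.group(1)))

    raw = np.fromfile(hdr_path.with_suffix(".raw"), dtype=dtype)
    if raw.size != rows * cols * bands:
        raise NrespecError("ENVI binary size does not match header dimensions")
    values = np.moveaxis(raw.reshape(bands, rows, cols), 0, 2).astype(float)
    return SpectralCube(values, wavelengths, is_refl)


def save_mask_indices(path: str | Path, roi: RoiMask) -> None:
    """Write a mask as a plain-text index list: header line ``rows cols``,
    then one ``row col`` pair per true pixel."""
    rows, cols = roi.mask.shape
    rr, cc = np.nonzero(roi.mask)
    lines = [f"{rows} {cols} {roi.sample_id}"]
    lines += [f"{r} {c}" for r, c in zip(rr, cc)]
    Path(path).write_text("\n".join(lines) + "\n")


def load_mask_indices(path: str | Path) -> RoiMask:
    lines = Path(path).read_text().strip().splitlines()
    head = lines[0].split()
    rows, cols = int(head[0]), int(head[1])
    sample_id = head[2] if len(head) > 2 else "sample"
    mask = np.zeros((rows, cols), dtype=bool)
    for line in lines[1:]:
        r, c = line.split()
        mask[int(r), int(c)] = True
    return RoiMask(mask, sample_id)
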