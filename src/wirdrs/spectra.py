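"""Shared data model and the image -> spectrum preprocessing chain.

A diffuse reflectance "spectrum" acquired by the smartphone spectrometer is an
8-bit RGB image in which pixel *columns* map linearly to wavelength.  The
preprocessing chain turns such an image into calibrated per-channel spectra:

    threshold -> exposure normalisation -> column collapse -> smoothing
              -> reflectance-standard calibration

Each step is exposed as a standalone function; :func:`preprocess_image` runs
the full chain in this fixed order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "SpectralImage",
    "RGBSpectrumSet",
    "ReflectanceStandard",
    "ProbeGeometry",
    "default_grid",
    "threshold_image",
    "normalize_exposure",
    "collapse_to_spectra",
    "smooth",
    "apply_standard",
    "preprocess_image",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_image_with_sidecar",
]

BAND_NM = (450.0, 630.0)
DEFAULT_N_COLUMNS = 585

Channel = Literal["R", "G", "B", "gray"]


class CalibrationError(ValueError):
    """Missing or invalid acquisition metadata (exposure time, ISO speed)."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform pixel-column -> wavelength map over the working band.

    Column ``j`` (0-based) maps to ``lambda_min + j * spacing``; the default
    585-column grid spans 450-630 nm at ~0.308 nm per pixel.
    """

    wavelengths_nm: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.wavelengths_nm, dtype=float)
        if w.ndim != 1 or w.size < 2:
            raise ValueError("grid needs at least two wavelengths")
        d = np.diff(w)
        if not np.all(d > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.ptp(d) > 1e-9:
            raise ValueError("wavelength spacing must be uniform")
        if w[0] < BAND_NM[0] - 1e-9 or w[-1] > BAND_NM[1] + 1e-9:
            raise ValueError(f"grid must lie within {BAND_NM} nm")
        object.__setattr__(self, "wavelengths_nm", w)

    @property
    def n_columns(self) -> int:
        return int(self.wavelengths_nm.size)

    @property
    def spacing_nm(self) -> float:
        return float(self.wavelengths_nm[1] - self.wavelengths_nm[0])

    @property
    def span_nm(self) -> float:
        return float(self.wavelengths_nm[-1] - self.wavelengths_nm[0])


def default_grid(n_columns: int = DEFAULT_N_COLUMNS) -> WavelengthGrid:
    """The full working band, 450-630 nm, sampled at ``n_columns`` pixels."""
    return WavelengthGrid(np.linspace(BAND_NM[0], BAND_NM[1], n_columns))


@dataclass(frozen=True)
class Spectrum:
    """A single 1-D spectrum on a wavelength grid (intensity in counts)."""

    grid: WavelengthGrid
    intensity: np.ndarray
    channel: Channel = "gray"

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.shape != (self.grid.n_columns,):
            raise ValueError(
                f"intensity length {y.shape} != grid columns {self.grid.n_columns}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "intensity", y)

    def with_intensity(self, intensity: np.ndarray) -> "Spectrum":
        return replace(self, intensity=np.asarray(intensity, dtype=float))


@dataclass(frozen=True)
class SpectralImage:
    """Raw 8-bit RGB spectral image plus acquisition metadata.

    ``pixels`` is an (M, N, 3) integer array; exposure time (s) and ISO speed
    come from the sidecar metadata record, probe_id identifies the fiber
    probe used (1 or 2).
    """

    pixels: np.ndarray
    exposure_time_s: float
    iso_speed: float
    probe_id: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if not np.issubdtype(px.dtype, np.integer):
            raise TypeError("pixels must be an integer array (8-bit image)")
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("pixels must have shape (M, N, 3) with M, N >= 1")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("pixel values must lie in [0, 255]")
        if not (self.exposure_time_s > 0):
            raise CalibrationError("exposure_time_s must be > 0")
        if not (self.iso_speed > 0):
            raise CalibrationError("iso_speed must be > 0")
        if self.probe_id not in (1, 2):
            raise ValueError("probe_id must be 1 or 2")
        object.__setattr__(self, "pixels", px)

    @property
    def n_rows(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def n_columns(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class RGBSpectrumSet:
    """Aligned red/green/blue/gray spectra; gray is the elementwise channel sum."""

    red: Spectrum
    green: Spectrum
    blue: Spectrum
    gray: Spectrum

    def __post_init__(self) -> None:
        g = self.gray.grid
        for s in (self.red, self.green, self.blue):
            if s.grid.n_columns != g.n_columns or not np.allclose(
                s.grid.wavelengths_nm, g.wavelengths_nm
            ):
                raise ValueError("all channels must share one grid")
        total = self.red.intensity + self.green.intensity + self.blue.intensity
        scale = max(float(np.abs(self.gray.intensity).max()), 1.0)
        if not np.allclose(self.gray.intensity, total, rtol=1e-9, atol=1e-9 * scale):
            raise ValueError("gray must equal red+green+blue elementwise")

    @property
    def grid(self) -> WavelengthGrid:
        return self.gray.grid

    @classmethod
    def from_channels(
        cls, grid: WavelengthGrid, red: np.ndarray, green: np.ndarray, blue: np.ndarray
    ) -> "RGBSpectrumSet":
        red = np.asarray(red, float)
        green = np.asarray(green, float)
        blue = np.asarray(blue, float)
        return cls(
            red=Spectrum(grid, red, "R"),
            green=Spectrum(grid, green, "G"),
            blue=Spectrum(grid, blue, "B"),
            gray=Spectrum(grid, red + green + blue, "gray"),
        )


@dataclass(frozen=True)
class ReflectanceStandard:
    """Spectrum of a diffuse reflectance standard (captures source/detector response)."""

    spectrum: Spectrum

    def __post_init__(self) -> None:
        if self.spectrum.intensity.min() <= 0:
            raise ValueError("reflectance standard must be strictly positive")


@dataclass(frozen=True)
class ProbeGeometry:
    """Fiber probe geometry; source-detector separation selects probing depth."""

    probe_id: int
    sds_um: float = field(init=False)
    fiber_diameter_um: float = 200.0

    _SDS = {1: 750.0, 2: 650.0}

    def __post_init__(self) -> None:
        if self.probe_id not in self._SDS:
            raise ValueError("probe_id must be 1 or 2")
        object.__setattr__(self, "sds_um", self._SDS[self.probe_id])

    @property
    def sds_cm(self) -> float:
        return self.sds_um * 1e-4


# ---------------------------------------------------------------------------
# preprocessing chain
# ---------------------------------------------------------------------------


def threshold_image(img: SpectralImage, cutoff: int = 10) -> SpectralImage:
    """Zero out background pixels: per channel, values strictly below ``cutoff``.

    E.g. an input pixel (0, 20, 9) becomes (0, 20, 0) at the default cutoff.
    Idempotent; shape and metadata are preserved.
    """
    px = img.pixels.copy()
    px[px < cutoff] = 0
    return replace(img, pixels=px)


def normalize_exposure(img: SpectralImage) -> np.ndarray:
    """Normalise pixel counts for camera settings: I_norm = I_raw / (Ti * ISO).

    Makes images comparable across exposure time / ISO speed combinations;
    the output is a real-valued (M, N, 3) array.
    """
    return img.pixels.astype(float) / (img.exposure_time_s * img.iso_speed)


def collapse_to_spectra(norm_img: np.ndarray, grid: WavelengthGrid) -> RGBSpectrumSet:
    """Sum each channel over the M pixel rows to get one intensity per column."""
    arr = np.asarray(norm_img, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("normalised image must have shape (M, N, 3)")
    if arr.shape[1] != grid.n_columns:
        raise ValueError(
            f"image has {arr.shape[1]} columns but grid has {grid.n_columns}"
        )
    r, g, b = (arr[:, :, k].sum(axis=0) for k in range(3))
    return RGBSpectrumSet.from_channels(grid, r, g, b)


def smooth(spec: Spectrum, window: int = 6) -> Spectrum:
    """Centred moving average with reflected edges (length preserved).

    An even window is centred by taking ``window // 2`` columns to the left
    and the remainder to the right of each index (6 -> 3 left / 2 right).
    """
    n = spec.grid.n_columns
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds spectrum length {n}")
    return spec.with_intensity(
        uniform_filter1d(spec.intensity, size=window, mode="reflect")
    )


def smooth_array(y: np.ndarray, window: int = 6) -> np.ndarray:
    """Row-wise version of :func:`smooth` for stacked (n, N) intensity arrays."""
    return uniform_filter1d(np.asarray(y, float), size=window, mode="reflect", axis=-1)


def apply_standard(
    spec: Spectrum,
    std: ReflectanceStandard,
    mode: Literal["multiply", "divide"] = "divide",
) -> Spectrum:
    """Calibrate against a reflectance standard, column by column.

    ``multiply`` imprints the source/detector response onto a model spectrum
    (the simulated-data path); ``divide`` removes it from a measured spectrum.
    """
    if std.spectrum.grid.n_columns != spec.grid.n_columns or not np.allclose(
        std.spectrum.grid.wavelengths_nm, spec.grid.wavelengths_nm
    ):
        raise ValueError("spectrum and standard must share one grid")
    if mode == "multiply":
        return spec.with_intensity(spec.intensity * std.spectrum.intensity)
    if mode == "divide":
        return spec.with_intensity(spec.intensity / std.spectrum.intensity)
    raise ValueError(f"unknown mode {mode!r}")


def preprocess_image(
    img: SpectralImage,
    grid: WavelengthGrid | None = None,
    standard: ReflectanceStandard | None = None,
    standard_mode: Literal["multiply", "divide"] = "divide",
    cutoff: int = 10,
    window: int = 6,
) -> RGBSpectrumSet:
    """Full chain: threshold -> exposure normalise -> collapse -> smooth -> standard.

    Deterministic: identical image + metadata give a bit-identical result.
    """
    if grid is None:
        grid = default_grid(img.n_columns)
    norm = normalize_exposure(threshold_image(img, cutoff=cutoff))
    spectra = collapse_to_spectra(norm, grid)
    chans = {
        "R": smooth(spectra.red, window),
        "G": smooth(spectra.green, window),
        "B": smooth(spectra.blue, window),
    }
    if standard is not None:
        chans = {
            k: apply_standard(s, standard, standard_mode) for k, s in chans.items()
        }
    return RGBSpectrumSet.from_channels(
        grid, chans["R"].intensity, chans["G"].intensity, chans["B"].intensity
    )


# ---------------------------------------------------------------------------
# I/O: CSV spectra, PNG images with sidecar metadata
# ---------------------------------------------------------------------------


def write_spectra_csv(path: str | Path, spectra: RGBSpectrumSet | Spectrum) -> None:
    """Write spectra as a long CSV (wavelength_nm, intensity, channel)."""
    if isinstance(spectra, Spectrum):
        items = [spectra]
    else:
        items = [spectra.red, spectra.green, spectra.blue, spectra.gray]
    frames = [
        pd.DataFrame(
            {
                "wavelength_nm": s.grid.wavelengths_nm,
                "intensity": s.intensity,
                "channel": s.channel,
            }
        )
        for s in items
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spectra_csv(path: str | Path) -> dict[str, Spectrum]:
    """Read a long-format spectra CSV back into per-channel ``Spectrum`` objects."""
    df = pd.read_csv(path)
    out: dict[str, Spectrum] = {}
    for channel, sub in df.groupby("channel", sort=False):
        sub = sub.sort_values("wavelength_nm")
        grid = WavelengthGrid(sub["wavelength_nm"].to_numpy())
        out[str(channel)] = Spectrum(grid, sub["intensity"].to_numpy(), channel)
    return out


def read_image_with_sidecar(image_path: str | Path, meta_path: str | Path) -> SpectralImage:
    """Load an 8-bit RGB PNG plus its sidecar JSON metadata record."""
    import imageio.v3 as iio

    px = iio.imread(image_path)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha if present
        px = px[:, :, :3]
    meta = json.loads(Path(meta_path).read_text())
    try:
        return SpectralImage(
            pixels=px.astype(np.int64),
            exposure_time_s=float(meta["exposure_time_s"]),
            iso_speed=float(meta["iso_speed"]),
            probe_id=int(meta["probe_id"]),
        )
    except KeyError as exc:  # pragma: no cover - error path
        raise CalibrationError(f"sidecar record missing field {exc}") from exc
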