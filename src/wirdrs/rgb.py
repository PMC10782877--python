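"""Wavelength -> RGB decomposition of grayscale spectra.

The forward model produces a single ("grayscale") reflectance spectrum, but the
camera records three colour channels.  To emulate that, each pixel column's
grayscale intensity is split into R, G and B parts in proportion to the RGB
colour of its wavelength.  The colour map is a piecewise-linear approximation
of the visible spectrum with the band-edge intensity falloff disabled, so the
channel fractions are defined at every wavelength of the working band.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import RGBSpectrumSet, Spectrum, WavelengthGrid

__all__ = [
    "ChannelFractions",
    "wavelength_to_rgb",
    "to_fractions",
    "channel_fraction_map",
    "split_to_channels",
    "write_fraction_map_csv",
]

VISIBLE_NM = (380.0, 780.0)


@dataclass(frozen=True)
class ChannelFractions:
    """Per-channel share of the total signal at one wavelength (sums to 1)."""

    f_red: float
    f_green: float
    f_blue: float

    def __post_init__(self) -> None:
        total = self.f_red + self.f_green + self.f_blue
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total}")

    def as_array(self) -> np.ndarray:
        return np.array([self.f_red, self.f_green, self.f_blue])


def _rgb_unit(lam: np.ndarray) -> np.ndarray:
    """Piecewise-linear RGB response in [0, 1] per channel.

    Breakpoints: 440 (blue->cyan), 490 (cyan->green), 510 (green->yellow ramp),
    580 (yellow->red ramp), 620 (pure red).  Below 440 the violet mix applies.
    """
    lam = np.asarray(lam, dtype=float)
    r = np.zeros_like(lam)
    g = np.zeros_like(lam)
    b = np.zeros_like(lam)

    m = lam < 440
    r[m] = (440 - lam[m]) / (440 - 380)
    b[m] = 1.0

    m = (lam >= 440) & (lam < 490)
    g[m] = (lam[m] - 440) / (490 - 440)
    b[m] = 1.0

    m = (lam >= 490) & (lam < 510)
    g[m] = 1.0
    b[m] = (510 - lam[m]) / (510 - 490)

    m = (lam >= 510) & (lam < 580)
    r[m] = (lam[m] - 510) / (580 - 510)
    g[m] = 1.0

    m = (lam >= 580) & (lam < 620)
    r[m] = 1.0
    g[m] = (620 - lam[m]) / (620 - 580)

    m = lam >= 620
    r[m] = 1.0
    return np.stack([r, g, b], axis=-1)


def wavelength_to_rgb(wavelength_nm: float) -> tuple[int, int, int]:
    """8-bit RGB triple for a visible wavelength (deterministic, no falloff)."""
    if not (VISIBLE_NM[0] <= wavelength_nm <= VISIBLE_NM[1]):
        raise ValueError(
            f"wavelength {wavelength_nm} nm outside visible range {VISIBLE_NM}"
        )
    rgb = np.rint(_rgb_unit(np.array([wavelength_nm]))[0] * 255).astype(int)
    return int(rgb[0]), int(rgb[1]), int(rgb[2])


def to_fractions(triple: tuple[int, int, int]) -> ChannelFractions:
    """Convert an RGB triple to channel fractions of the overall signal.

    Example: (0, 255, 146) -> (0, 0.64, 0.36) after rounding to two decimals.
    """
    arr = np.asarray(triple, dtype=float)
    total = arr.sum()
    if total <= 0:
        raise ValueError("cannot form fractions of an all-zero RGB triple")
    f = arr / total
    return ChannelFractions(float(f[0]), float(f[1]), float(f[2]))


_FRACTION_CACHE: dict[tuple[float, ...], np.ndarray] = {}


def channel_fraction_map(grid: WavelengthGrid) -> np.ndarray:
    """(N, 3) array of channel fractions for every column of ``grid`` (cached)."""
    key = (grid.wavelengths_nm[0], grid.wavelengths_nm[-1], grid.n_columns)
    cached = _FRACTION_CACHE.get(key)
    if cached is not None:
        return cached
    rgb = _rgb_unit(grid.wavelengths_nm)
    totals = rgb.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError("RGB map is all-zero somewhere on the grid")
    fractions = rgb / totals[:, None]
    _FRACTION_CACHE[key] = fractions
    return fractions


def split_to_channels(gray: Spectrum) -> RGBSpectrumSet:
    """Split a grayscale spectrum into R/G/B by per-column channel fractions.

    Conserves intensity exactly: the three outputs sum back to the input at
    every column, and the operation is linear in the input.
    """
    fractions = channel_fraction_map(gray.grid)
    parts = gray.intensity[:, None] * fractions
    return RGBSpectrumSet.from_channels(gray.grid, parts[:, 0], parts[:, 1], parts[:, 2])


def write_fraction_map_csv(path: str | Path, grid: WavelengthGrid) -> None:
    fractions = channel_fraction_map(grid)
    pd.DataFrame(
        {
            "wavelength_nm": grid.wavelengths_nm,
            "f_red": fractions[:, 0],
            "f_green": fractions[:, 1],
            "f_blue": fractions[:, 2],
        }
    ).to_csv(path, index=False)
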