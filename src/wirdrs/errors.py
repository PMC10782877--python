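"""Use-error corruptions and the training-augmentation suite.

Six corruption types emulate device mishandling artefacts in diffuse
reflectance spectra:

* Gaussian noise at a target linear RMS signal-to-noise ratio (35:1 for
  single-error datasets, 45:1 when all errors are compounded),
* leftward wavelength miscalibration (shift by 4.8 nm),
* spectral compression (content moved inwards by 1 nm at each tail),
* tail rotation (linear intensity ramp, up to +/-5% at the tails),
* systematic intensity scaling (one factor per spectrum, up to +/-5%),
* all of the above compounded.

Fourteen checked combinations of these corruptions form the training
augmentation suite: applied to a 1520-spectrum base dataset they yield the
21,280-record augmented training set.  When several corruptions are
compounded they are applied in the fixed order scale -> rotate -> shift ->
compress -> noise (detection noise enters after the optical/calibration
distortions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .forward import LabeledDataset
from .rgb import channel_fraction_map
from .spectra import Spectrum

__all__ = [
    "ErrorConfig",
    "AUGMENTATION_ROWS",
    "CONDITIONS",
    "add_gaussian_noise",
    "shift_wavelength",
    "compress_spectrum",
    "rotate_spectrum",
    "scale_spectrum",
    "apply_error_row",
    "build_augmented_training_set",
    "make_condition_dataset",
]


@dataclass(frozen=True)
class ErrorConfig:
    """Magnitudes of the corruption suite (defaults are the study conditions)."""

    snr_linear: float | None = 35.0
    snr_linear_all_errors: float | None = 45.0
    shift_nm: float = -4.8  # negative = leftward
    compress_nm_per_tail: float = 1.0
    rotate_max_frac: float = 0.05
    scale_max_frac: float = 0.05
    seed: int = 0


#: Corruption combinations of the augmentation suite: row -> applied errors.
AUGMENTATION_ROWS: dict[int, tuple[str, ...]] = {
    1: (),
    2: ("noise",),
    3: ("shift",),
    4: ("scale",),
    5: ("compress",),
    6: ("rotate",),
    7: ("noise", "compress"),
    8: ("noise", "shift"),
    9: ("noise", "scale", "shift"),
    10: ("noise", "scale", "shift", "compress"),
    11: ("noise", "scale", "shift", "compress", "rotate"),
    12: ("scale", "compress"),
    13: ("scale", "shift"),
    14: ("shift", "compress"),
}

#: The seven evaluation conditions: name -> applied errors.
CONDITIONS: dict[str, tuple[str, ...]] = {
    "perfect": (),
    "noise": ("noise",),
    "shifted": ("shift",),
    "scaled": ("scale",),
    "compressed": ("compress",),
    "rotated": ("rotate",),
    "all": ("scale", "rotate", "shift", "compress", "noise"),
}

_APPLY_ORDER = ("scale", "rotate", "shift", "compress", "noise")


# ---------------------------------------------------------------------------
# resampling helpers (shared by the single-spectrum and dataset paths)
# ---------------------------------------------------------------------------


def _resample(y: np.ndarray, frac_idx: np.ndarray, fill: float | None) -> np.ndarray:
    """Linear interpolation of row(s) of ``y`` at fractional column indices.

    ``fill`` replaces out-of-range samples; ``None`` holds the edge value.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    n = y.shape[1]
    idx = np.asarray(frac_idx, dtype=float)
    lo = np.clip(np.floor(idx).astype(int), 0, n - 2)
    w = idx - lo
    out = y[:, lo] * (1.0 - w) + y[:, lo + 1] * w
    if fill is not None:
        out[:, (idx < 0) | (idx > n - 1)] = fill
    else:
        out[:, idx < 0] = y[:, [0]]
        out[:, idx > n - 1] = y[:, [-1]]
    return out


def _shift_indices(spec_grid, delta_nm: float) -> np.ndarray:
    span = spec_grid.span_nm
    if abs(delta_nm) >= span:
        raise ValueError("shift magnitude must be smaller than the band span")
    # content moves by delta; output column samples the source at lambda - delta
    return np.arange(spec_grid.n_columns) - delta_nm / spec_grid.spacing_nm


def _compress_indices(spec_grid, nm_per_tail: float) -> np.ndarray:
    span = spec_grid.span_nm
    if nm_per_tail < 0 or 2 * nm_per_tail >= span:
        raise ValueError("compression must satisfy 0 <= 2*t < span")
    if nm_per_tail == 0:
        return np.arange(spec_grid.n_columns, dtype=float)
    lam = spec_grid.wavelengths_nm
    lo = lam[0] + nm_per_tail
    hi = lam[-1] - nm_per_tail
    # affine map sending [lo, hi] back onto the full band; margins hold edges
    src = lam[0] + (lam - lo) * span / (hi - lo)
    src = np.clip(src, lam[0], lam[-1])
    return (src - lam[0]) / spec_grid.spacing_nm


def _rotation_ramp(spec_grid, amount: float) -> np.ndarray:
    lam = spec_grid.wavelengths_nm
    rel = (lam - lam[0]) / spec_grid.span_nm  # 0 at left tail, 1 at right
    return 1.0 + amount * (1.0 - 2.0 * rel)


# ---------------------------------------------------------------------------
# single-spectrum operations
# ---------------------------------------------------------------------------


def add_gaussian_noise(
    spec: Spectrum, snr_linear: float | None, seed: int | np.random.Generator = 0
) -> Spectrum:
    """Add zero-mean Gaussian noise at a linear RMS signal-to-noise ratio.

    The noise standard deviation is RMS(signal) / snr, so the realised
    RMS(signal)/RMS(noise) equals ``snr_linear`` in expectation.  ``None``
    disables the corruption.
    """
    if snr_linear is None:
        return spec
    if snr_linear <= 0:
        raise ValueError("snr_linear must be positive")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.mean(spec.intensity**2))) / snr_linear
    return spec.with_intensity(spec.intensity + rng.normal(0.0, sigma, spec.intensity.shape))


def shift_wavelength(spec: Spectrum, delta_nm: float) -> Spectrum:
    """Shift spectral content along the wavelength axis (negative = leftward).

    The grid labels stay unchanged — the miscalibration is silent, as on a
    real device; columns with no source data are set to 0.
    """
    if delta_nm == 0:
        return spec
    idx = _shift_indices(spec.grid, delta_nm)
    return spec.with_intensity(_resample(spec.intensity, idx, fill=0.0)[0])


def compress_spectrum(spec: Spectrum, nm_per_tail: float = 1.0) -> Spectrum:
    """Squeeze content inwards by ``nm_per_tail`` at each band edge.

    The affine map sends [lmin, lmax] onto [lmin+t, lmax-t]; the t-wide
    margins hold the edge values.
    """
    idx = _compress_indices(spec.grid, nm_per_tail)
    return spec.with_intensity(_resample(spec.intensity, idx, fill=None)[0])


def rotate_spectrum(
    spec: Spectrum,
    max_frac: float = 0.05,
    seed: int | np.random.Generator = 0,
    amount: float | None = None,
) -> Spectrum:
    """Tilt the spectrum: linear ramp from (1+a) at the left tail to (1-a) right.

    ``a`` is drawn uniformly from [-max_frac, +max_frac] unless ``amount``
    forces a value; the band midpoint is unchanged and the ramp has mean 1.
    """
    if not (0 <= max_frac < 1):
        raise ValueError("max_frac must be in [0, 1)")
    if amount is None:
        rng = np.random.default_rng(seed)
        amount = float(rng.uniform(-max_frac, max_frac))
    return spec.with_intensity(spec.intensity * _rotation_ramp(spec.grid, amount))


def scale_spectrum(
    spec: Spectrum,
    max_frac: float = 0.05,
    seed: int | np.random.Generator = 0,
    factor: float | None = None,
) -> Spectrum:
    """Systematic intensity fluctuation: one multiplicative factor per spectrum."""
    if not (0 <= max_frac < 1):
        raise ValueError("max_frac must be in [0, 1)")
    if factor is None:
        rng = np.random.default_rng(seed)
        factor = float(rng.uniform(1.0 - max_frac, 1.0 + max_frac))
    return spec.with_intensity(spec.intensity * factor)


# ---------------------------------------------------------------------------
# dataset-level application
# ---------------------------------------------------------------------------


def _apply_errors_arrays(
    ds: LabeledDataset,
    which: tuple[str, ...],
    config: ErrorConfig,
    rng: np.random.Generator,
    snr: float | None,
) -> LabeledDataset:
    """Apply corruptions to every record, channel-consistently.

    Deterministic distortions (scale, rotate, shift, compress) are applied
    identically to R, G and B with one parameter draw per record; Gaussian
    noise is drawn at the gray level and distributed to the channels by the
    column RGB fractions.  Either way gray == R+G+B holds exactly and labels,
    groups and the grid are untouched.
    """
    out = ds.copy()
    n = len(out)
    chans = [out.red, out.green, out.blue]

    for err in _APPLY_ORDER:
        if err not in which:
            continue
        if err == "scale":
            f = rng.uniform(1 - config.scale_max_frac, 1 + config.scale_max_frac, n)
            chans = [c * f[:, None] for c in chans]
        elif err == "rotate":
            a = rng.uniform(-config.rotate_max_frac, config.rotate_max_frac, n)
            lam = out.grid.wavelengths_nm
            rel = (lam - lam[0]) / out.grid.span_nm
            ramp = 1.0 + a[:, None] * (1.0 - 2.0 * rel)
            chans = [c * ramp for c in chans]
        elif err == "shift":
            idx = _shift_indices(out.grid, config.shift_nm)
            chans = [_resample(c, idx, fill=0.0) for c in chans]
        elif err == "compress":
            idx = _compress_indices(out.grid, config.compress_nm_per_tail)
            chans = [_resample(c, idx, fill=None) for c in chans]
        elif err == "noise" and snr is not None:
            gray = chans[0] + chans[1] + chans[2]
            sigma = np.sqrt(np.mean(gray**2, axis=1)) / snr
            noise = rng.normal(0.0, 1.0, gray.shape) * sigma[:, None]
            fractions = channel_fraction_map(out.grid)
            chans = [c + noise * fractions[:, k] for k, c in enumerate(chans)]

    out.red, out.green, out.blue = chans
    out.gray = chans[0] + chans[1] + chans[2]
    return out


def apply_error_row(
    dataset: LabeledDataset,
    row: int,
    config: ErrorConfig | None = None,
    seed: int | None = None,
) -> LabeledDataset:
    """Apply one augmentation-suite row (1-14) of compounded corruptions."""
    if row not in AUGMENTATION_ROWS:
        raise ValueError(f"unknown augmentation row {row}; expected 1..14")
    config = config or ErrorConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = _apply_errors_arrays(dataset, AUGMENTATION_ROWS[row], config, rng, config.snr_linear)
    out.error_tag = np.array([f"row{row}"] * len(out), dtype=object)
    return out


def build_augmented_training_set(
    base: LabeledDataset, config: ErrorConfig | None = None, seed: int | None = None
) -> LabeledDataset:
    """Concatenate all 14 corruption rows applied to ``base``.

    With the canonical 1520-spectrum base this yields the 21,280-record
    augmented training set; other base sizes proceed with a warning.
    """
    if len(base) != 1520:
        warnings.warn(
            f"base dataset has {len(base)} records (canonical size is 1520); "
            "proceeding with 14x that",
            RuntimeWarning,
            stacklevel=2,
        )
    config = config or ErrorConfig()
    master = np.random.SeedSequence(config.seed if seed is None else seed)
    children = master.spawn(len(AUGMENTATION_ROWS))
    parts = [
        apply_error_row(base, row, config, seed=children[i])
        for i, row in enumerate(sorted(AUGMENTATION_ROWS))
    ]
    return LabeledDataset.concatenate(parts)


def make_condition_dataset(
    base: LabeledDataset,
    condition: str,
    config: ErrorConfig | None = None,
    seed: int | None = None,
) -> LabeledDataset:
    """One of the seven evaluation conditions applied to a perfect base set.

    The all-compounded condition uses the higher SNR (45:1 by default); the
    single-error conditions use 35:1.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    config = config or ErrorConfig()
    snr = config.snr_linear_all_errors if condition == "all" else config.snr_linear
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = _apply_errors_arrays(base, CONDITIONS[condition], config, rng, snr)
    out.error_tag = np.array([condition] * len(out), dtype=object)
    return out
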