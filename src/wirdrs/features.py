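"""Wavelength-independent spectral features.

The regressor never sees wavelengths: every predictor is a whole-spectrum
summary (extremes, moments, slope statistics, peak geometry in pixel units)
that survives a miscalibrated wavelength axis.  The frozen 35-entry layout:

* max / mean / std of intensity for R, G, B, gray            (12)
* max / min / mean / std of the first-difference slope series (16)
* spectrum length 1: columns above quarter-max (gray)          (1)
* spectrum length 2: pixel distance between the two highest
  local maxima of the smoothed gray spectrum                   (1)
* skewness of R, G, B, gray                                    (4)
* probe id (categorical)                                       (1)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .forward import LabeledDataset
from .spectra import ProbeGeometry, RGBSpectrumSet, Spectrum, smooth_array

__all__ = [
    "FEATURE_NAMES",
    "FeatureVector",
    "slope_series",
    "spectrum_length_1",
    "spectrum_length_2",
    "skewness",
    "extract_features",
    "extract_feature_table",
    "FeatureExtractor",
]

_CHANNELS = ("R", "G", "B", "gray")

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"max_{c}" for c in _CHANNELS]
    + [f"mean_{c}" for c in _CHANNELS]
    + [f"std_{c}" for c in _CHANNELS]
    + [f"slope_max_{c}" for c in _CHANNELS]
    + [f"slope_min_{c}" for c in _CHANNELS]
    + [f"slope_mean_{c}" for c in _CHANNELS]
    + [f"slope_std_{c}" for c in _CHANNELS]
    + ["spectrum_length_1", "spectrum_length_2"]
    + [f"skew_{c}" for c in _CHANNELS]
    + ["probe_id"]
)
assert len(FEATURE_NAMES) == 35


@dataclass(frozen=True)
class FeatureVector:
    """One 35-entry predictor vector in the frozen feature order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(FEATURE_NAMES),):
            raise ValueError(f"feature vector must have {len(FEATURE_NAMES)} entries")
        if not np.all(np.isfinite(v)):
            raise ValueError("feature values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def names(self) -> tuple[str, ...]:
        return FEATURE_NAMES

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(FEATURE_NAMES))


def slope_series(spec: Spectrum) -> np.ndarray:
    """First differences of intensity per pixel column (length N-1)."""
    if spec.grid.n_columns < 2:
        raise ValueError("need at least two columns for slopes")
    return np.diff(spec.intensity)


def spectrum_length_1(spec: Spectrum) -> int:
    """Number of columns with intensity strictly above quarter-maximum."""
    return int(_length1(spec.intensity[None, :])[0])


def spectrum_length_2(spec: Spectrum, window: int = 6) -> int:
    """Pixel distance between the two highest local maxima of the smoothed spectrum.

    Local maxima are interior columns strictly above their left neighbour and
    at least their right neighbour (so a plateau-topped peak counts once, at
    its leftmost sample); the distance runs from the absolute maximum to the
    highest *other* local maximum (leftmost on ties), and is 0 when no second
    local maximum exists.
    """
    return int(_length2(smooth_array(spec.intensity[None, :], window))[0])


def skewness(spec: Spectrum) -> float:
    """Sample skewness m3 / m2^1.5 of the intensities treated as a sample."""
    return float(_skew(spec.intensity[None, :])[0])


# ---------------------------------------------------------------------------
# vectorised kernels on stacked (n, N) intensity arrays
# ---------------------------------------------------------------------------


def _skew(y: np.ndarray) -> np.ndarray:
    centred = y - y.mean(axis=1, keepdims=True)
    m2 = np.mean(centred**2, axis=1)
    m3 = np.mean(centred**3, axis=1)
    out = np.zeros(y.shape[0])
    ok = m2 > 0
    out[ok] = m3[ok] / m2[ok] ** 1.5
    if not ok.all():
        warnings.warn("zero-variance spectrum: skewness set to 0", RuntimeWarning)
    return out


def _length1(y: np.ndarray) -> np.ndarray:
    peak = y.max(axis=1, keepdims=True)
    return (y > 0.25 * peak).sum(axis=1).astype(float)


def _length2(smoothed: np.ndarray) -> np.ndarray:
    interior = smoothed[:, 1:-1]
    # a plateau-topped peak counts once, at its leftmost sample (even-window
    # smoothing of a symmetric peak yields exact two-sample plateaus)
    is_peak = (interior > smoothed[:, :-2]) & (interior >= smoothed[:, 2:])
    out = np.zeros(smoothed.shape[0])
    argmax = smoothed.argmax(axis=1)
    for i in range(smoothed.shape[0]):
        pos = np.flatnonzero(is_peak[i]) + 1
        pos = pos[pos != argmax[i]]
        if pos.size == 0:
            continue
        best = pos[np.argmax(smoothed[i, pos])]  # argmax returns leftmost tie
        out[i] = abs(int(argmax[i]) - int(best))
    return out


def _channel_blocks(stacks: dict[str, np.ndarray], probe_id: int) -> np.ndarray:
    """(n, 35) feature matrix from per-channel (n, N) intensity stacks."""
    order = [stacks[c] for c in _CHANNELS]
    degenerate = np.any([np.ptp(y, axis=1) == 0 for y in order], axis=0)
    if degenerate.any():
        warnings.warn(
            "degenerate constant channel encountered; its statistics are "
            "reported as-is and skewness as 0",
            RuntimeWarning,
        )
    cols: list[np.ndarray] = []
    cols += [y.max(axis=1) for y in order]
    cols += [y.mean(axis=1) for y in order]
    cols += [y.std(axis=1) for y in order]
    slopes = [np.diff(y, axis=1) for y in order]
    cols += [s.max(axis=1) for s in slopes]
    cols += [s.min(axis=1) for s in slopes]
    cols += [s.mean(axis=1) for s in slopes]
    cols += [s.std(axis=1) for s in slopes]
    gray = stacks["gray"]
    cols.append(_length1(gray))
    cols.append(_length2(smooth_array(gray)))
    cols += [_skew(y) for y in order]
    cols.append(np.full(gray.shape[0], float(probe_id)))
    return np.column_stack(cols)


def extract_features(
    spec_set: RGBSpectrumSet, probe: ProbeGeometry | int = 1
) -> FeatureVector:
    """Extract the 35 wavelength-independent predictors from one spectrum set."""
    probe_id = probe.probe_id if isinstance(probe, ProbeGeometry) else int(probe)
    stacks = {
        "R": spec_set.red.intensity[None, :],
        "G": spec_set.green.intensity[None, :],
        "B": spec_set.blue.intensity[None, :],
        "gray": spec_set.gray.intensity[None, :],
    }
    return FeatureVector(_channel_blocks(stacks, probe_id)[0])


def extract_feature_table(dataset: LabeledDataset) -> pd.DataFrame:
    """Feature table for a whole dataset, plus label/group/tag columns."""
    stacks = {
        "R": dataset.red,
        "G": dataset.green,
        "B": dataset.blue,
        "gray": dataset.gray,
    }
    df = pd.DataFrame(
        _channel_blocks(stacks, dataset.probe_id), columns=list(FEATURE_NAMES)
    )
    df["mu_a"] = dataset.mu_a
    df["mu_s_prime"] = dataset.mu_s_prime
    df["group_id"] = dataset.group_id
    df["error_tag"] = dataset.error_tag
    return df


class FeatureExtractor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: LabeledDataset -> (n, 35) feature frame.

    Lets the feature step compose with sklearn pipelines; ``fit`` only
    records the frozen feature names.
    """

    def fit(self, X: LabeledDataset, y=None) -> "FeatureExtractor":
        self.feature_names_out_ = list(FEATURE_NAMES)
        return self

    def transform(self, X: LabeledDataset) -> pd.DataFrame:
        return extract_feature_table(X)[list(FEATURE_NAMES)]

    def get_feature_names_out(self, input_features=None):
        return np.asarray(FEATURE_NAMES, dtype=object)
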