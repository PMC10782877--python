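"""Closed-form forward reflectance model and labelled-dataset generation.

The forward model maps a pair of tissue optical properties — absorption
coefficient ``mu_a`` and reduced scattering coefficient ``mu_s'`` (both in
cm^-1) — to a diffuse reflectance spectrum at the probe's source-detector
separation.  It is the steady-state diffusion approximation for a
semi-infinite homogeneous medium with an extrapolated boundary (Farrell-type
two-dipole solution), evaluated wavelength by wavelength with

    mu_a(lambda)  = mu_a  * absorption_shape(lambda)
    mu_s'(lambda) = mu_s' * scattering_shape(lambda)

where both spectral shapes are normalised to band-mean 1, so the scalar labels
are exactly the band-average optical properties.  The absorption shape mimics
oxyhemoglobin in the visible (Q-bands near 542/577 nm plus a blue rise); the
scattering shape is the Mie-like power law ``(lambda/ref)^-b``.

A labelled dataset is a Cartesian grid of (mu_a, mu_s') pairs; each grayscale
spectrum is imprinted with the reflectance-standard (source/detector) response
and split into R/G/B channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .rgb import channel_fraction_map
from .spectra import (
    ProbeGeometry,
    ReflectanceStandard,
    RGBSpectrumSet,
    SpectralImage,
    Spectrum,
    WavelengthGrid,
    default_grid,
)

__all__ = [
    "OpticalProperties",
    "ChromophoreModel",
    "LabeledDataset",
    "default_chromophore",
    "default_standard",
    "diffusion_reflectance",
    "simulate_reflectance",
    "forward_closure",
    "generate_grid_dataset",
    "render_image",
    "MU_A_RANGE",
    "MU_S_RANGE",
]

# default label ranges of the simulated study conditions (cm^-1)
MU_A_RANGE = (0.44, 2.45)
MU_S_RANGE = (6.53, 9.58)

# refractive index mismatch assumed for the boundary condition (tissue-like)
_N_REL = 1.4


@dataclass(frozen=True)
class OpticalProperties:
    """Scalar band-average optical properties (cm^-1)."""

    mu_a: float
    mu_s_prime: float

    def __post_init__(self) -> None:
        if not (self.mu_a > 0 and self.mu_s_prime > 0):
            raise ValueError("optical properties must be positive")


@dataclass(frozen=True)
class ChromophoreModel:
    """Spectral shapes that the scalar labels scale.

    ``absorption_shape`` is a strictly positive unitless curve on the grid
    with band mean 1; ``scattering_exponent`` is the Mie-like power-law slope.
    """

    grid: WavelengthGrid
    absorption_shape: np.ndarray
    scattering_exponent: float = 0.37
    reference_wavelength_nm: float = 540.0

    def __post_init__(self) -> None:
        shape = np.asarray(self.absorption_shape, dtype=float)
        if shape.shape != (self.grid.n_columns,):
            raise ValueError("absorption_shape must match the grid")
        if shape.min() <= 0:
            raise ValueError("absorption_shape must be strictly positive")
        if abs(shape.mean() - 1.0) > 1e-9:
            raise ValueError("absorption_shape must have band mean 1")
        object.__setattr__(self, "absorption_shape", shape)

    @property
    def scattering_shape(self) -> np.ndarray:
        """Band-mean-normalised power-law scattering shape on the grid."""
        lam = self.grid.wavelengths_nm
        s = (lam / self.reference_wavelength_nm) ** (-self.scattering_exponent)
        return s / s.mean()


# oxyhemoglobin relative molar extinction in the visible (unitless, scaled to
# the 450 nm value): Soret tail falling through the blue, the 540/577 nm
# Q-bands, and the steep cliff past 585 nm into a nearly transparent red.
_HB_POINTS_NM = (450, 460, 470, 480, 490, 500, 510, 520, 530, 540, 545, 550,
                 560, 570, 577, 585, 590, 600, 610, 620, 630)
_HB_POINTS_REL = (1.0, 0.72, 0.53, 0.42, 0.37, 0.33, 0.32, 0.39, 0.63, 0.90,
                  0.92, 0.71, 0.53, 0.72, 0.96, 0.52, 0.22, 0.051, 0.026,
                  0.016, 0.013)


def default_chromophore(grid: WavelengthGrid | None = None) -> ChromophoreModel:
    """Oxyhemoglobin-like absorber + polystyrene-sphere-like scatterer.

    The absorption curve interpolates tabulated relative oxyhemoglobin
    extinction values over the visible band (monotone piecewise cubic),
    normalised to band mean 1 on the grid.
    """
    from scipy.interpolate import PchipInterpolator

    if grid is None:
        grid = default_grid()
    shape = PchipInterpolator(_HB_POINTS_NM, _HB_POINTS_REL)(grid.wavelengths_nm)
    return ChromophoreModel(grid=grid, absorption_shape=shape / shape.mean())


def default_standard(grid: WavelengthGrid | None = None) -> ReflectanceStandard:
    """White-LED-like source x detector spectral response, strictly positive.

    Broad phosphor lobe peaking near 565 nm with a blue shoulder, rolled off
    towards the blue band edge by the grating/camera response (logistic edge
    at 470 nm) and retaining moderate sensitivity at the red edge — the
    peaked, tailed morphology of grating-dispersed camera spectra.
    """
    if grid is None:
        grid = default_grid()
    lam = grid.wavelengths_nm
    lobe = (
        0.015
        + 1.00 * np.exp(-(((lam - 565.0) / 50.0) ** 2))
        + 0.30 * np.exp(-(((lam - 480.0) / 30.0) ** 2))
    )
    rolloff = 1.0 / (1.0 + np.exp(-(lam - 470.0) / 8.0))
    return ReflectanceStandard(Spectrum(grid, lobe * rolloff, "gray"))


def diffusion_reflectance(
    mu_a: np.ndarray, mu_s_prime: np.ndarray, sds_cm: float
) -> np.ndarray:
    """Extrapolated-boundary diffusion reflectance at radial distance ``sds_cm``.

    Two-dipole solution for a pencil source in a semi-infinite medium:
    an isotropic source at depth z0 = 1/mu_t' and its image above the
    extrapolated boundary at z0 + 2*zb, with zb = 2*A*D.  Arrays broadcast.
    """
    mu_a = np.asarray(mu_a, dtype=float)
    mu_s_prime = np.asarray(mu_s_prime, dtype=float)
    mu_t = mu_a + mu_s_prime
    albedo = mu_s_prime / mu_t
    z0 = 1.0 / mu_t
    diff_const = 1.0 / (3.0 * mu_t)
    mu_eff = np.sqrt(3.0 * mu_a * mu_t)
    # effective internal reflection (Groenhuis polynomial in relative index)
    r_eff = -1.440 / _N_REL**2 + 0.710 / _N_REL + 0.668 + 0.0636 * _N_REL
    boundary_a = (1.0 + r_eff) / (1.0 - r_eff)
    zb = 2.0 * boundary_a * diff_const
    r1 = np.sqrt(z0**2 + sds_cm**2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + sds_cm**2)
    return (albedo / (4.0 * np.pi)) * (
        z0 * (mu_eff + 1.0 / r1) * np.exp(-mu_eff * r1) / r1**2
        + (z0 + 2.0 * zb) * (mu_eff + 1.0 / r2) * np.exp(-mu_eff * r2) / r2**2
    )


def _spectral_coefficients(
    mu_a: np.ndarray, mu_s_prime: np.ndarray, chromo: ChromophoreModel
) -> tuple[np.ndarray, np.ndarray]:
    """Broadcast scalar labels over the grid via the chromophore shapes."""
    mu_a = np.atleast_1d(np.asarray(mu_a, dtype=float))[..., None]
    mu_s_prime = np.atleast_1d(np.asarray(mu_s_prime, dtype=float))[..., None]
    return mu_a * chromo.absorption_shape, mu_s_prime * chromo.scattering_shape


def simulate_reflectance(
    props: OpticalProperties,
    probe: ProbeGeometry,
    chromo: ChromophoreModel | None = None,
    grid: WavelengthGrid | None = None,
) -> Spectrum:
    """Grayscale reflectance spectrum for one (mu_a, mu_s') pair (deterministic)."""
    if grid is None:
        grid = default_grid()
    if chromo is None:
        chromo = default_chromophore(grid)
    mua_l, musp_l = _spectral_coefficients(props.mu_a, props.mu_s_prime, chromo)
    if np.any(mua_l >= musp_l):
        warnings.warn(
            "diffusion validity violated (mu_a >= mu_s' at some wavelength); "
            "proceeding with the closed-form evaluation",
            RuntimeWarning,
            stacklevel=2,
        )
    refl = diffusion_reflectance(mua_l, musp_l, probe.sds_cm)[0]
    return Spectrum(grid, refl, "gray")


def forward_closure(
    probe: ProbeGeometry,
    chromo: ChromophoreModel,
    standard: ReflectanceStandard | None = None,
):
    """Vectorised forward map ``f(mu_a, mu_s') -> gray intensity array``.

    Accepts scalars or 1-D label arrays; returns (..., N) intensities with the
    reflectance-standard response imprinted when a standard is given.  This is
    the closure the spectral-matching inversion searches over.
    """
    std = None if standard is None else standard.spectrum.intensity

    def forward(mu_a, mu_s_prime) -> np.ndarray:
        mua_l, musp_l = _spectral_coefficients(mu_a, mu_s_prime, chromo)
        refl = diffusion_reflectance(mua_l, musp_l, probe.sds_cm)
        if std is not None:
            refl = refl * std
        return refl if np.ndim(mu_a) else refl[0]

    return forward


# ---------------------------------------------------------------------------
# labelled datasets
# ---------------------------------------------------------------------------


@dataclass
class LabeledDataset:
    """Array-backed collection of labelled RGB spectrum sets.

    All records share one grid.  ``red/green/blue/gray`` are (n, N) intensity
    arrays with ``gray == red + green + blue``; labels are band-average
    optical properties; ``group_id`` marks the synthetic titration group and
    ``error_tag`` the corruption condition applied.
    """

    grid: WavelengthGrid
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    gray: np.ndarray
    mu_a: np.ndarray
    mu_s_prime: np.ndarray
    group_id: np.ndarray
    error_tag: np.ndarray
    probe_id: int = 1

    def __post_init__(self) -> None:
        n = self.gray.shape[0]
        for name in ("red", "green", "blue", "gray"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, self.grid.n_columns):
                raise ValueError(f"{name} must have shape (n, N)")
            setattr(self, name, arr)
        for name in ("mu_a", "mu_s_prime"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have shape (n,)")
            setattr(self, name, arr)
        self.group_id = np.asarray(self.group_id, dtype=object)
        self.error_tag = np.asarray(self.error_tag, dtype=object)
        if any(not g for g in self.group_id):
            raise ValueError("group ids must be non-empty")

    def __len__(self) -> int:
        return int(self.gray.shape[0])

    @property
    def labels(self) -> np.ndarray:
        """(n, 2) array of (mu_a, mu_s') labels."""
        return np.column_stack([self.mu_a, self.mu_s_prime])

    def record(self, i: int) -> tuple[RGBSpectrumSet, OpticalProperties, str, str]:
        spectra = RGBSpectrumSet.from_channels(
            self.grid, self.red[i], self.green[i], self.blue[i]
        )
        props = OpticalProperties(float(self.mu_a[i]), float(self.mu_s_prime[i]))
        return spectra, props, str(self.group_id[i]), str(self.error_tag[i])

    def copy(self) -> "LabeledDataset":
        return replace(
            self,
            red=self.red.copy(),
            green=self.green.copy(),
            blue=self.blue.copy(),
            gray=self.gray.copy(),
            mu_a=self.mu_a.copy(),
            mu_s_prime=self.mu_s_prime.copy(),
            group_id=self.group_id.copy(),
            error_tag=self.error_tag.copy(),
        )

    @classmethod
    def concatenate(cls, parts: list["LabeledDataset"]) -> "LabeledDataset":
        first = parts[0]
        return cls(
            grid=first.grid,
            red=np.concatenate([p.red for p in parts]),
            green=np.concatenate([p.green for p in parts]),
            blue=np.concatenate([p.blue for p in parts]),
            gray=np.concatenate([p.gray for p in parts]),
            mu_a=np.concatenate([p.mu_a for p in parts]),
            mu_s_prime=np.concatenate([p.mu_s_prime for p in parts]),
            group_id=np.concatenate([p.group_id for p in parts]),
            error_tag=np.concatenate([p.error_tag for p in parts]),
            probe_id=first.probe_id,
        )


def generate_grid_dataset(
    n_mu_a: int = 40,
    n_mu_s: int = 38,
    ranges: tuple[tuple[float, float], tuple[float, float]] = (MU_A_RANGE, MU_S_RANGE),
    probe: ProbeGeometry | None = None,
    chromo: ChromophoreModel | None = None,
    standard: ReflectanceStandard | None = None,
    grid: WavelengthGrid | None = None,
) -> LabeledDataset:
    """Cartesian label grid -> standard-imprinted, channel-split dataset.

    The default 40 x 38 grid gives the study's 1520 spectra per condition,
    with labels equally spaced over mu_a 0.44-2.45 and mu_s' 6.53-9.58 cm^-1
    (range endpoints included exactly).  Records sharing a mu_a level share a
    ``group_id`` (a synthetic "titration").
    """
    if n_mu_a < 1 or n_mu_s < 1:
        raise ValueError("grid sizes must be >= 1")
    (a_lo, a_hi), (s_lo, s_hi) = ranges
    if not (0 < a_lo <= a_hi and 0 < s_lo <= s_hi):
        raise ValueError("invalid label ranges")
    if grid is None:
        grid = default_grid()
    if probe is None:
        probe = ProbeGeometry(1)
    if chromo is None:
        chromo = default_chromophore(grid)
    if standard is None:
        standard = default_standard(grid)

    mu_a_levels = np.linspace(a_lo, a_hi, n_mu_a)
    mu_s_levels = np.linspace(s_lo, s_hi, n_mu_s)
    mu_a, mu_s = (arr.ravel() for arr in np.meshgrid(mu_a_levels, mu_s_levels, indexing="ij"))

    forward = forward_closure(probe, chromo, standard)
    gray = forward(mu_a, mu_s)

    fractions = channel_fraction_map(grid)
    red = gray * fractions[:, 0]
    green = gray * fractions[:, 1]
    blue = gray * fractions[:, 2]

    groups = np.repeat([f"titration{i:02d}" for i in range(n_mu_a)], n_mu_s)
    return LabeledDataset(
        grid=grid,
        red=red,
        green=green,
        blue=blue,
        gray=red + green + blue,
        mu_a=mu_a,
        mu_s_prime=mu_s,
        group_id=groups.astype(object),
        error_tag=np.array(["perfect"] * len(mu_a), dtype=object),
        probe_id=probe.probe_id,
    )


def render_image(
    spec_set: RGBSpectrumSet,
    m_rows: int = 8,
    exposure_time_s: float = 1.0,
    iso_speed: float = 100.0,
    probe_id: int = 1,
    peak_dn: int = 240,
) -> SpectralImage:
    """Render spectra to a synthetic 8-bit RGB image (fixture generator).

    Each channel is spread uniformly over ``m_rows`` identical rows and
    scaled jointly so the brightest pixel equals ``peak_dn``, then quantised
    to 8 bits.  Values that would exceed 255 are clipped with a warning.
    """
    if not (0 < peak_dn <= 255):
        raise ValueError("peak_dn must be in (0, 255]")
    channels = np.stack(
        [spec_set.red.intensity, spec_set.green.intensity, spec_set.blue.intensity],
        axis=-1,
    )
    peak = channels.max()
    if peak <= 0:
        raise ValueError("cannot render an all-zero spectrum set")
    scaled = channels / peak * peak_dn
    if scaled.max() > 255:  # pragma: no cover - unreachable with peak_dn <= 255
        warnings.warn("rendered intensities clipped to 8-bit range", RuntimeWarning)
    px = np.clip(np.rint(scaled), 0, 255).astype(np.int64)
    pixels = np.repeat(px[None, :, :], m_rows, axis=0)
    return SpectralImage(
        pixels=pixels,
        exposure_time_s=exposure_time_s,
        iso_speed=iso_speed,
        probe_id=probe_id,
    )
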