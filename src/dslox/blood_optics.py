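"""Whole-blood optical properties and the Beer's-law forward spectral model.

Visible-light OCT oximetry rests on the oxygenation dependence of the
whole-blood attenuation spectrum in the 520--630 nm band.  The detected
intensity at the bottom of a vessel, after light has traversed the lumen,
is modelled as

    I(sO2 | lambda, z) = I0(lambda) * sqrt(R0 * r(lambda)) * exp(-mu * z)

with r(lambda) = A * lambda**-alpha the vessel-wall reflectance (power law
under the first Born approximation) and

    mu = sO2 * (mu_a,HbO2 + W * mu_s,HbO2)
       + (1 - sO2) * (mu_a,Hb + W * mu_s,Hb)

the whole-blood attenuation coefficient, W in [0, 1] scaling the
contribution of scattering.  ``z`` is the effective one-way-equivalent
light-penetration path; double-pass geometry is expressed by the caller's
choice of ``z``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Union

import numpy as np

__all__ = [
    "BloodOpticalCoefficients",
    "ForwardModelParams",
    "CoverageError",
    "load_blood_coefficients",
    "attenuation_coefficient",
    "forward_spectrum",
]


class CoverageError(ValueError):
    """Raised when a wavelength query falls outside the tabulated grid."""


@dataclass(frozen=True)
class BloodOpticalCoefficients:
    """Tabulated absorption/scattering coefficients of whole blood.

    Parameters
    ----------
    wavelengths : ndarray
        Strictly increasing wavelength grid, nm.
    mu_a_hb, mu_s_hb : ndarray
        Absorption / scattering coefficients of deoxygenated whole blood,
        1/mm, on the wavelength grid.
    mu_a_hbo2, mu_s_hbo2 : ndarray
        Same for fully oxygenated whole blood.
    """

    wavelengths: np.ndarray
    mu_a_hb: np.ndarray
    mu_s_hb: np.ndarray
    mu_a_hbo2: np.ndarray
    mu_s_hbo2: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", lam)
        if lam.ndim != 1 or lam.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 points")
        if not np.all(np.diff(lam) > 0):
            raise ValueError("wavelength grid must be strictly increasing")
        for name in ("mu_a_hb", "mu_s_hb", "mu_a_hbo2", "mu_s_hbo2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.shape != lam.shape:
                raise ValueError(f"{name} must match the wavelength grid shape")
            if np.any(arr < 0) or not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite and non-negative")

    @property
    def lam_min(self) -> float:
        return float(self.wavelengths[0])

    @property
    def lam_max(self) -> float:
        return float(self.wavelengths[-1])

    def _interp(self, table: np.ndarray, lam) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        if np.any(lam < self.lam_min) or np.any(lam > self.lam_max):
            raise CoverageError(
                f"wavelength query outside tabulated range "
                f"[{self.lam_min:g}, {self.lam_max:g}] nm"
            )
        return np.interp(lam, self.wavelengths, table)

    def mu_a(self, lam, oxygenated: bool) -> np.ndarray:
        """Linear-interpolated absorption coefficient, 1/mm."""
        return self._interp(self.mu_a_hbo2 if oxygenated else self.mu_a_hb, lam)

    def mu_s(self, lam, oxygenated: bool) -> np.ndarray:
        """Linear-interpolated scattering coefficient, 1/mm."""
        return self._interp(self.mu_s_hbo2 if oxygenated else self.mu_s_hb, lam)

    def require_coverage(self, lam_lo: float, lam_hi: float) -> None:
        if lam_lo < self.lam_min or lam_hi > self.lam_max:
            raise CoverageError(
                f"table covers [{self.lam_min:g}, {self.lam_max:g}] nm; "
                f"requested [{lam_lo:g}, {lam_hi:g}] nm"
            )


SourceSpectrum = Union[float, Callable[[np.ndarray], np.ndarray]]


@dataclass
class ForwardModelParams:
    """Parameters of the single-scattering spectral forward model.

    Attributes
    ----------
    i0 : float or callable
        Source spectrum I0(lambda), arbitrary units.  A scalar means a
        spectrally flat source; a callable is evaluated on the working
        wavelength grid (nm).
    r0 : float
        Reference-arm reflectance (dimensionless constant).
    amplitude : float
        Dimensionless vessel-wall scattering amplitude ``A``.
    alpha : float
        Power-law exponent of the wall reflectance r = A * lambda**-alpha.
    w : float
        Scattering scaling factor W in [0, 1].
    z : float
        Effective one-way-equivalent light-penetration path, mm.
    """

    i0: SourceSpectrum = 1.0
    r0: float = 1.0
    amplitude: float = 1.0
    alpha: float = 0.0
    w: float = 0.0
    z: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("W must lie in [0, 1]")
        if self.z <= 0:
            raise ValueError("penetration path z must be positive")
        if self.r0 <= 0 or self.amplitude <= 0:
            raise ValueError("R0 and A must be positive")

    def source(self, lam: np.ndarray) -> np.ndarray:
        lam = np.asarray(lam, dtype=float)
        i0 = self.i0(lam) if callable(self.i0) else np.full_like(lam, float(self.i0))
        if np.any(i0 <= 0):
            raise ValueError("I0 must be positive on the working grid")
        return i0

    def wall_reflectance(self, lam: np.ndarray) -> np.ndarray:
        """r(lambda) = A * lambda**-alpha (lambda in nm)."""
        return self.amplitude * np.asarray(lam, dtype=float) ** (-self.alpha)


# Named bundled tables -> file names under dslox/data
_BUNDLED = {"whole-blood": "hemoglobin_synthetic.csv"}


def load_blood_coefficients(
    table_source: Union[str, Path] = "whole-blood",
    *,
    lam_lo: float = 520.0,
    lam_hi: float = 630.0,
) -> BloodOpticalCoefficients:
    """Load and validate a whole-blood coefficient table.

    Parameters
    ----------
    table_source : str or path
        Name of a bundled table (``"whole-blood"``) or path to a CSV with
        columns ``wavelength_nm, mu_a_hb, mu_s_hb, mu_a_hbo2, mu_s_hbo2``
        (``#`` comment header allowed).
    lam_lo, lam_hi : float
        Required wavelength coverage, nm.  Tables not spanning this range
        raise :class:`CoverageError`.
    """
    if isinstance(table_source, str) and table_source in _BUNDLED:
        ref = resources.files("dslox").joinpath("data", _BUNDLED[table_source])
        with resources.as_file(ref) as path:
            raw = np.loadtxt(path, delimiter=",", comments="#", skiprows=0)
    else:
        path = Path(table_source)
        if not path.exists():
            raise FileNotFoundError(
                f"unknown bundled table or missing file: {table_source!r}"
            )
        raw = np.loadtxt(path, delimiter=",", comments="#")
    if raw.ndim != 2 or raw.shape[1] != 5:
        raise ValueError("coefficient table must have 5 columns")
    coeffs = BloodOpticalCoefficients(
        wavelengths=raw[:, 0],
        mu_a_hb=raw[:, 1],
        mu_s_hb=raw[:, 2],
        mu_a_hbo2=raw[:, 3],
        mu_s_hbo2=raw[:, 4],
    )
    coeffs.require_coverage(lam_lo, lam_hi)
    return coeffs


def attenuation_coefficient(
    so2,
    lam,
    w: float,
    coeffs: BloodOpticalCoefficients,
) -> np.ndarray:
    """Whole-blood attenuation mu = mu_a + W*mu_s, mixed linearly in sO2.

    Returns ``so2*(mu_a_HbO2 + W*mu_s_HbO2) + (1-so2)*(mu_a_Hb + W*mu_s_Hb)``
    at wavelength(s) ``lam`` (nm), in 1/mm.  ``so2`` is a fraction in [0, 1]
    and broadcasts against ``lam``.
    """
    so2 = np.asarray(so2, dtype=float)
    if np.any(so2 < 0) or np.any(so2 > 1):
        raise ValueError("sO2 must lie in [0, 1]")
    mu_ox = coeffs.mu_a(lam, oxygenated=True) + w * coeffs.mu_s(lam, oxygenated=True)
    mu_de = coeffs.mu_a(lam, oxygenated=False) + w * coeffs.mu_s(lam, oxygenated=False)
    return so2 * mu_ox + (1.0 - so2) * mu_de


def forward_spectrum(
    params: ForwardModelParams,
    so2: float,
    lam_grid,
    coeffs: BloodOpticalCoefficients,
) -> np.ndarray:
    """Model intensity spectrum at the configured penetration path.

    I(lambda) = I0(lambda) * sqrt(R0 * A * lambda**-alpha)
                * exp(-mu(lambda, sO2, W) * z), elementwise positive.
    """
    lam = np.asarray(lam_grid, dtype=float)
    mu = attenuation_coefficient(so2, lam, params.w, coeffs)
    i0 = params.source(lam)
    return i0 * np.sqrt(params.r0 * params.wall_reflectance(lam)) * np.exp(-mu * params.z)
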