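"""Spectral extraction chain for spectroscopic vis-OCT.

Turns raw interferograms / per-band volumes into the 28-element normalized
spectral input vectors consumed by both the least-squares inversion and the
spectral regressors:

1.  short-time Fourier transform of the interferogram along wavenumber
    ``k = 2*pi/lambda`` with a bank of Gaussian windows (default 14 windows
    equally spaced in k between 523.4 and 604.5 nm, FWHM 0.32 1/um);
2.  threshold segmentation of vessels on the en face projection;
3.  axial alignment of in-vessel A-lines to the retinal surface and a
    seeded random shuffle;
4.  rolling average over blocks of shuffled A-lines (window 100 / step 50
    or window 250 / step 125 depending on acquisition protocol);
5.  depth-window averaging around the bottom vessel wall (+/-16.6 um) and
    at the vessel centre / top (25 and 41.6 um above the wall, half-width
    8.31 um) to give three 14-band spectra;
6.  concatenation of bottom + centre spectra and normalization by the mean
    of the combined bottom+centre+top signal -> a 1x28 vector.

Depth is measured in um from the aligned retinal surface, increasing
downward; depth-averaging windows are closed intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "WindowBank",
    "DepthSpectra",
    "SpectralSample",
    "PartialWindowError",
    "build_window_bank",
    "stft_bands",
    "segment_vessels",
    "align_and_shuffle",
    "rolling_average",
    "extract_depth_spectra",
    "normalize_and_concat",
]

TWO_PI = 2.0 * np.pi

# default depth-averaging geometry, um
BOTTOM_HALF_WIDTH_UM = 16.6
CENTRE_OFFSET_UM = 25.0
TOP_OFFSET_UM = 41.6
CENTRE_HALF_WIDTH_UM = 8.31


class PartialWindowError(ValueError):
    """A depth-averaging window would be clipped by the volume edge."""


@dataclass(frozen=True)
class WindowBank:
    """Bank of Gaussian spectral windows equally spaced in k-space.

    ``lam_min``/``lam_max`` are the first/last window centres in nm;
    ``fwhm_k`` is the window FWHM in 1/um.
    """

    n_windows: int = 14
    lam_min: float = 523.4
    lam_max: float = 604.5
    fwhm_k: float = 0.32

    def __post_init__(self) -> None:
        if self.n_windows < 2:
            raise ValueError("need at least 2 windows")
        if not self.lam_min < self.lam_max:
            raise ValueError("lam_min must be < lam_max")
        if self.fwhm_k <= 0:
            raise ValueError("fwhm_k must be positive")

    @property
    def k_centres(self) -> np.ndarray:
        """Window centres in k = 2*pi/lambda, 1/um, decreasing with lambda."""
        k_hi = TWO_PI / (self.lam_min * 1e-3)  # nm -> um
        k_lo = TWO_PI / (self.lam_max * 1e-3)
        return np.linspace(k_lo, k_hi, self.n_windows)

    @property
    def centres_nm(self) -> np.ndarray:
        """Window centre wavelengths in nm, strictly increasing."""
        return np.sort(TWO_PI / self.k_centres) * 1e3

    def bandwidth_nm(self, lam_nm) -> np.ndarray:
        """Wavelength bandwidth of a window centred at ``lam_nm``.

        Delta_lambda = lambda**2 * Delta_k / (2*pi); with lambda in nm and
        Delta_k in 1/um this evaluates to ~17 nm at 585 nm for the default
        0.32 1/um FWHM.
        """
        lam_um = np.asarray(lam_nm, dtype=float) * 1e-3
        return lam_um**2 * self.fwhm_k / TWO_PI * 1e3

    def window(self, k_axis: np.ndarray, i: int) -> np.ndarray:
        """Gaussian window i evaluated on a k axis (1/um)."""
        sigma = self.fwhm_k / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        return np.exp(-0.5 * ((k_axis - self.k_centres[i]) / sigma) ** 2)


def build_window_bank(
    n: int = 14,
    lam_min: float = 523.4,
    lam_max: float = 604.5,
    fwhm_k: float = 0.32,
) -> WindowBank:
    """Construct a :class:`WindowBank` (see class docstring for units)."""
    return WindowBank(n_windows=n, lam_min=lam_min, lam_max=lam_max, fwhm_k=fwhm_k)


def stft_bands(
    interferogram: np.ndarray,
    k_axis: np.ndarray,
    bank: WindowBank,
    *,
    power: bool = False,
) -> Tuple[np.ndarray, np.ndarray]:
    """Short-time Fourier transform along k with the Gaussian window bank.

    Parameters
    ----------
    interferogram : ndarray, shape (n_k,)
        Intensity samples on a uniform k grid.
    k_axis : ndarray, shape (n_k,)
        Uniformly spaced wavenumber samples, 1/um, covering all window
        supports (centre +/- FWHM).
    bank : WindowBank
    power : bool
        If True return squared magnitude instead of magnitude.  The
        magnitude convention is the default used throughout the package.

    Returns
    -------
    bands : ndarray, shape (n_windows, n_depth)
        Depth profile of the windowed-FFT magnitude per spectral band
        (positive-frequency half).
    depth_axis : ndarray, shape (n_depth,)
        Optical-path depth per FFT bin, um: a reflector producing fringes
        cos(2*k*z0) peaks at depth ~z0.
    """
    s = np.asarray(interferogram, dtype=float)
    k = np.asarray(k_axis, dtype=float)
    if s.shape != k.shape or s.ndim != 1:
        raise ValueError("interferogram and k_axis must be matching 1-D arrays")
    dk = np.diff(k)
    if not np.allclose(dk, dk[0], rtol=1e-6):
        raise ValueError("k_axis must be uniformly spaced")
    lo, hi = bank.k_centres[0] - bank.fwhm_k, bank.k_centres[-1] + bank.fwhm_k
    if k[0] > lo or k[-1] < hi:
        raise ValueError(
            f"k sampling [{k[0]:g}, {k[-1]:g}] does not cover the window "
            f"supports [{lo:g}, {hi:g}] 1/um"
        )
    n = s.size
    n_half = n // 2 + 1
    bands = np.empty((bank.n_windows, n_half))
    for i in range(bank.n_windows):
        spec = np.abs(np.fft.rfft(s * bank.window(k, i)))
        bands[i] = spec**2 if power else spec
    # fringe cos(2 k z0) has frequency z0/pi cycles per unit k
    freqs = np.fft.rfftfreq(n, d=dk[0])
    depth_axis = freqs * np.pi
    return bands, depth_axis


def segment_vessels(
    enface_projection: np.ndarray,
    threshold: Union[float, Tuple[str, float]] = ("quantile", 0.9),
    *,
    min_size: int = 0,
) -> np.ndarray:
    """Threshold-based vessel segmentation of an en face projection.

    ``threshold`` is either an absolute intensity or ``("quantile", q)``.
    Pixels >= threshold are vessel.  ``min_size`` removes smaller connected
    components.  An empty mask warns rather than raising.
    """
    img = np.asarray(enface_projection, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("en face projection must be finite")
    if isinstance(threshold, tuple):
        kind, q = threshold
        if kind != "quantile":
            raise ValueError(f"unknown threshold spec {threshold!r}")
        thr = float(np.quantile(img, q))
    else:
        thr = float(threshold)
    mask = img >= thr
    if min_size > 0 and mask.any():
        from skimage.morphology import remove_small_objects

        mask = remove_small_objects(mask, min_size=min_size)
    if not mask.any():
        warnings.warn("vessel segmentation produced an empty mask", stacklevel=2)
    return mask


def align_and_shuffle(
    alines: np.ndarray,
    surface_depths: np.ndarray,
    seed: int,
    *,
    fill: float = 0.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axially align A-lines to a common retinal surface, then shuffle.

    Parameters
    ----------
    alines : ndarray, shape (n_alines, n_depth, n_bands)
        Per-band depth profiles of the in-vessel A-lines.
    surface_depths : ndarray, shape (n_alines,)
        Retinal surface position (depth-axis index) per A-line.
    seed : int
        Seeds the shuffling permutation.
    fill : float
        Value filled in at the depths vacated by the shift.

    Returns
    -------
    shuffled : ndarray, same shape as ``alines``
        Aligned (surface moved to the minimum surface depth) and permuted.
    permutation : ndarray
        Applied order (``shuffled[i] = aligned[permutation[i]]``).
    shifts : ndarray
        Integer upward shift applied per (original-order) A-line.
    """
    x = np.asarray(alines, dtype=float)
    surf = np.asarray(surface_depths)
    if x.ndim != 3 or surf.shape != (x.shape[0],):
        raise ValueError("alines must be (n, depth, bands) with one surface per A-line")
    ref = int(np.min(surf))
    shifts = np.asarray(surf - ref, dtype=int)
    aligned = np.full_like(x, fill)
    for i, sh in enumerate(shifts):
        if sh == 0:
            aligned[i] = x[i]
        else:
            aligned[i, : x.shape[1] - sh] = x[i, sh:]
    rng = np.random.default_rng(seed)
    permutation = rng.permutation(x.shape[0])
    return aligned[permutation], permutation, shifts


def rolling_average(alines: np.ndarray, window: int, step: int) -> np.ndarray:
    """Block rolling average over the leading (A-line) axis.

    Output ``j`` is the mean of A-lines ``[j*step, j*step + window)``;
    the number of outputs is ``floor((N - window)/step) + 1``.
    """
    x = np.asarray(alines, dtype=float)
    n = x.shape[0]
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    if window > n:
        raise ValueError(f"rolling window {window} exceeds {n} A-lines")
    count = (n - window) // step + 1
    out = np.empty((count,) + x.shape[1:])
    for j in range(count):
        out[j] = x[j * step : j * step + window].mean(axis=0)
    return out


@dataclass(frozen=True)
class DepthSpectra:
    """Bottom / centre / top band spectra extracted from one averaged A-line."""

    bottom: np.ndarray
    centre: np.ndarray
    top: np.ndarray
    bottom_wall_depth_um: float = float("nan")

    def __post_init__(self) -> None:
        b, c, t = (np.asarray(a, dtype=float) for a in (self.bottom, self.centre, self.top))
        object.__setattr__(self, "bottom", b)
        object.__setattr__(self, "centre", c)
        object.__setattr__(self, "top", t)
        if not (b.shape == c.shape == t.shape) or b.ndim != 1:
            raise ValueError("bottom/centre/top must be 1-D spectra on a shared band grid")
        if np.any(b < 0) or np.any(c < 0) or np.any(t < 0):
            raise ValueError("spectral intensities must be non-negative")


def _window_mean(
    profile: np.ndarray, depth_axis_um: np.ndarray, centre: float, half_width: float
) -> np.ndarray:
    lo, hi = centre - half_width, centre + half_width
    if lo < depth_axis_um[0] - 1e-9 or hi > depth_axis_um[-1] + 1e-9:
        raise PartialWindowError(
            f"averaging window [{lo:.1f}, {hi:.1f}] um clipped by depth axis "
            f"[{depth_axis_um[0]:.1f}, {depth_axis_um[-1]:.1f}] um"
        )
    sel = (depth_axis_um >= lo - 1e-9) & (depth_axis_um <= hi + 1e-9)
    return profile[sel].mean(axis=0)


def extract_depth_spectra(
    aline_bands: np.ndarray,
    depth_axis_um: np.ndarray,
    bottom_wall_depth_um: float,
    *,
    bottom_half_width_um: float = BOTTOM_HALF_WIDTH_UM,
    centre_offset_um: float = CENTRE_OFFSET_UM,
    top_offset_um: float = TOP_OFFSET_UM,
    offset_half_width_um: float = CENTRE_HALF_WIDTH_UM,
) -> DepthSpectra:
    """Average one A-line's band profiles in three depth windows.

    ``bottom`` averages the closed interval wall +/- 16.6 um; ``centre``
    and ``top`` average 16.6 um-wide windows centred 25 and 41.6 um above
    the bottom wall (depth increases downward, so "above" is toward
    smaller depth).  Windows clipped by the depth axis raise
    :class:`PartialWindowError` rather than silently truncating.
    """
    x = np.asarray(aline_bands, dtype=float)
    depth = np.asarray(depth_axis_um, dtype=float)
    if x.ndim != 2 or x.shape[0] != depth.size:
        raise ValueError("aline_bands must be (n_depth, n_bands) matching depth axis")
    bottom = _window_mean(x, depth, bottom_wall_depth_um, bottom_half_width_um)
    centre = _window_mean(x, depth, bottom_wall_depth_um - centre_offset_um, offset_half_width_um)
    top = _window_mean(x, depth, bottom_wall_depth_um - top_offset_um, offset_half_width_um)
    return DepthSpectra(bottom, centre, top, bottom_wall_depth_um=bottom_wall_depth_um)


@dataclass(frozen=True)
class SpectralSample:
    """One normalized 28-element input vector with provenance metadata."""

    values: np.ndarray
    label: Optional[float] = None  # ground-truth spO2 fraction, if known
    rat: Optional[int] = None
    setup: Optional[int] = None
    state: Optional[str] = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (28,):
            raise ValueError("spectral input vector must have length 28")
        if self.label is not None and not 0.0 <= self.label <= 1.0:
            raise ValueError("spO2 label must be a fraction in [0, 1]")


def normalize_and_concat(ds: DepthSpectra) -> SpectralSample:
    """Concatenate bottom + centre spectra, normalized by the combined mean.

    output = (bottom ++ centre) / mean(bottom ++ centre ++ top); the result
    is invariant under global intensity rescaling of all three spectra.
    """
    combined_mean = np.concatenate([ds.bottom, ds.centre, ds.top]).mean()
    if combined_mean <= 0:
        raise ValueError("combined spectral mean is non-positive; cannot normalize")
    vec = np.concatenate([ds.bottom, ds.centre]) / combined_mean
    return SpectralSample(values=vec)


def normalize_batch(bottom: np.ndarray, centre: np.ndarray, top: np.ndarray) -> np.ndarray:
    """Vectorized :func:`normalize_and_concat` over rows of spectra.

    ``bottom``/``centre``/``top`` are (n, n_bands); returns (n, 2*n_bands).
    """
    combined = np.concatenate([bottom, centre, top], axis=1)
    means = combined.mean(axis=1, keepdims=True)
    if np.any(means <= 0):
        raise ValueError("combined spectral mean is non-positive; cannot normalize")
    return np.concatenate([bottom, centre], axis=1) / means
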