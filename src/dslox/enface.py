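"""Pixel-wise en face sO2 / uncertainty map reconstruction and rendering.

Each in-vessel pixel's depth spectra are averaged with its k Euclidean
nearest in-vessel neighbours (the pixel itself included), normalized into
the 28-element input vector, and passed through a trained regressor; the
predicted mean and sigma fill the sO2 and uncertainty maps on the vessel
mask (background undefined).  Rendering follows an HSV scheme: the map
value sets the hue along a configured arc, the co-registered intensity
image sets saturation and value, so background pixels come out grey.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from matplotlib.colors import hsv_to_rgb
from sklearn.neighbors import NearestNeighbors

from .preprocessing import (
    BOTTOM_HALF_WIDTH_UM,
    CENTRE_HALF_WIDTH_UM,
    CENTRE_OFFSET_UM,
    TOP_OFFSET_UM,
    DepthSpectra,
    normalize_batch,
)
from .synthetic import SyntheticVolume

__all__ = ["EnfaceMaps", "knn_spectral_average", "predict_map", "render_hsv"]


@dataclass(frozen=True)
class EnfaceMaps:
    """Per-pixel predicted sO2 and uncertainty on a vessel mask."""

    so2: np.ndarray  # (ny, nx), nan outside mask / at failed pixels
    sigma: np.ndarray
    intensity: np.ndarray  # en face intensity (angiography analogue)
    mask: np.ndarray

    def defined(self) -> np.ndarray:
        return np.isfinite(self.so2)


def knn_spectral_average(
    pixel: Tuple[int, int],
    coords: np.ndarray,
    spectra: np.ndarray,
    k: int,
) -> np.ndarray:
    """Mean spectra of the k Euclidean-nearest in-vessel pixels.

    ``coords`` is (n, 2) pixel coordinates of in-vessel pixels, ``spectra``
    the matching (n, ...) per-pixel spectra; the query pixel participates
    in its own neighbourhood.  If fewer than k pixels exist, all are used
    with a warning.
    """
    coords = np.asarray(coords, dtype=float)
    if k > coords.shape[0]:
        warnings.warn(
            f"requested k={k} neighbours but only {coords.shape[0]} in-vessel "
            f"pixels; using all of them", stacklevel=2,
        )
        k = coords.shape[0]
    nn = NearestNeighbors(n_neighbors=k).fit(coords)
    _, idx = nn.kneighbors(np.asarray(pixel, dtype=float)[None, :])
    return spectra[idx[0]].mean(axis=0)


def _per_pixel_depth_spectra(volume: SyntheticVolume) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bottom/centre/top band spectra for every mask pixel of a volume."""
    ys, xs = np.where(volume.mask)
    depth = volume.depth_axis_um
    n = ys.size
    nb = volume.lam_grid.size
    bottom = np.empty((n, nb))
    centre = np.empty((n, nb))
    top = np.empty((n, nb))
    for i, (y, x) in enumerate(zip(ys, xs)):
        wall = volume.bottom_wall_depth_um[y, x]
        prof = volume.bands[y, x]
        for out, c0, hw in (
            (bottom, wall, BOTTOM_HALF_WIDTH_UM),
            (centre, wall - CENTRE_OFFSET_UM, CENTRE_HALF_WIDTH_UM),
            (top, wall - TOP_OFFSET_UM, CENTRE_HALF_WIDTH_UM),
        ):
            sel = (depth >= c0 - hw - 1e-9) & (depth <= c0 + hw + 1e-9)
            out[i] = prof[sel].mean(axis=0)
    return bottom, centre, top


def predict_map(
    volume: SyntheticVolume,
    model,
    k: int = 100,
    mask: Optional[np.ndarray] = None,
) -> EnfaceMaps:
    """Reconstruct en face sO2/uncertainty maps from a per-band volume.

    ``model`` is anything with a ``predict(x) -> Prediction`` method (a
    trained :class:`~dslox.dsl.SpectralRegressionResults` or a stub).
    Pixels whose kNN-averaged spectra cannot be normalized are flagged
    undefined and processing continues.
    """
    mask = volume.mask if mask is None else np.asarray(mask, dtype=bool)
    ny, nx = mask.shape
    so2 = np.full((ny, nx), np.nan)
    sigma = np.full((ny, nx), np.nan)
    intensity = volume.enface_projection()
    ys, xs = np.where(mask)
    if ys.size == 0:
        return EnfaceMaps(so2, sigma, intensity, mask)

    bottom, centre, top = _per_pixel_depth_spectra(volume)
    # background (noise-floor) subtraction: estimate the per-band floor
    # from out-of-vessel voxels, as raw depth averages sit on top of it
    if (~mask).any():
        floor = np.median(volume.bands[~mask], axis=(0, 1))
        bottom = np.clip(bottom - floor, 1e-9, None)
        centre = np.clip(centre - floor, 1e-9, None)
        top = np.clip(top - floor, 1e-9, None)
    coords = np.column_stack([ys, xs]).astype(float)
    k_eff = min(k, coords.shape[0])
    if k_eff < k:
        warnings.warn(
            f"requested k={k} neighbours but only {coords.shape[0]} in-vessel "
            f"pixels; using k={k_eff}", stacklevel=2,
        )
    nn = NearestNeighbors(n_neighbors=k_eff).fit(coords)
    _, idx = nn.kneighbors(coords)
    b_avg = bottom[idx].mean(axis=1)
    c_avg = centre[idx].mean(axis=1)
    t_avg = top[idx].mean(axis=1)

    ok = np.concatenate([b_avg, c_avg, t_avg], axis=1).mean(axis=1) > 0
    if ok.any():
        x28 = normalize_batch(b_avg[ok], c_avg[ok], t_avg[ok])
        pred = model.predict(x28)
        so2[ys[ok], xs[ok]] = pred.mean
        sigma[ys[ok], xs[ok]] = pred.sigma
    return EnfaceMaps(so2, sigma, intensity, mask)


def render_hsv(
    value_map: np.ndarray,
    intensity: np.ndarray,
    value_range: Tuple[float, float] = (0.0, 1.0),
    hue_arc: Tuple[float, float] = (0.0, 1.0 / 6.0),  # red -> yellow
) -> np.ndarray:
    """Render a map as RGB with hue from the map, S/V from intensity.

    Map values are affinely sent from ``value_range`` onto ``hue_arc``;
    pixels where the map is undefined (NaN) keep zero saturation, so the
    background renders as grey intensity.
    """
    vmap = np.asarray(value_map, dtype=float)
    inten = np.asarray(intensity, dtype=float)
    if vmap.shape != inten.shape:
        raise ValueError("map and intensity image must be co-registered")
    lo, hi = value_range
    norm_i = inten / inten.max() if inten.max() > 0 else np.zeros_like(inten)
    defined = np.isfinite(vmap)
    frac = np.clip((np.where(defined, vmap, lo) - lo) / (hi - lo if hi != lo else 1.0), 0, 1)
    hue = hue_arc[0] + frac * (hue_arc[1] - hue_arc[0])
    hsv = np.stack(
        [np.mod(hue, 1.0), np.where(defined, norm_i, 0.0), norm_i], axis=-1
    )
    return hsv_to_rgb(hsv)
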