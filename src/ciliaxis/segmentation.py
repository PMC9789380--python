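"""Foreground segmentation and 2D orientation analysis.

Nuclei, cilia and axon channels are thresholded with Otsu's method, joined
with morphological closing, and size-filtered. The pyramidal cell layer is
the largest connected component of the dilated nucleus mask; nucleus centers
are recovered by erosion + distance-transform splitting of touching nuclei.
Cilia trajectory analysis works on maximum-intensity projections via the
2D structure tensor (Gaussian-gradient derivatives smoothed with a Gaussian
analysis window) and a single-Gaussian fit of the energy-weighted
orientation histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .volumes import VoxelVolume

logger = logging.getLogger(__name__)

__all__ = [
    "BinaryMask",
    "OrientationResult",
    "otsu_threshold",
    "otsu_mask",
    "close_and_filter",
    "select_layer",
    "nucleus_centers",
    "mip_z",
    "orientation_histogram",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class BinaryMask:
    """3D boolean field on the same grid contract as :class:`VoxelVolume`."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 3:
            raise ValueError("mask must be 3D (z, y, x)")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing components must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class OrientationResult:
    """Energy-weighted orientation histogram and its Gaussian fit.

    ``angles`` are bin centers in degrees within (-90, 90]; ``fit`` holds
    (center_deg, width_deg, amplitude, offset). ``low_confidence`` is set
    when the histogram carries no clear directional peak (amplitude
    comparable to the offset), e.g. for isotropic images.
    """

    angles: np.ndarray
    weights: np.ndarray
    fit: dict[str, float]
    low_confidence: bool = False


def _ball(radius_um: float, spacing) -> np.ndarray:
    """Euclidean-ball structuring element specified in um on a voxel grid."""
    r = np.maximum(np.round(radius_um / np.asarray(spacing)).astype(int), 0)
    if np.all(r == 0):
        return np.ones((1, 1, 1), dtype=bool)
    grids = np.ogrid[tuple(slice(-int(n), int(n) + 1) for n in r)]
    dist2 = sum((g * s) ** 2 for g, s in zip(grids, spacing))
    return dist2 <= radius_um**2 + 1e-9


def otsu_threshold(
    values: np.ndarray,
    nbins: int = 256,
    cap_percentile: float | None = None,
) -> float:
    """Otsu's threshold: maximize between-class variance.

    When ``cap_percentile`` is given, only values at or below that percentile
    enter the histogram (the threshold is still meant to be applied to the
    full data). Data with at most ``nbins`` distinct values are handled
    exactly (candidate thresholds are the distinct values themselves);
    continuous data use an ``nbins``-bin histogram over the observed range.

    Returns the smallest value t such that the foreground is ``values >= t``.
    """
    x = np.asarray(values, dtype=float).ravel()
    if cap_percentile is not None:
        if not 0 < cap_percentile <= 100:
            raise ValueError("cap_percentile must lie in (0, 100]")
        x = x[x <= np.percentile(x, cap_percentile)]
    levels, counts = np.unique(x, return_counts=True)
    if levels.size < 2:
        raise ValueError("constant volume: no Otsu threshold exists")
    if levels.size > nbins:
        counts, edges = np.histogram(x, bins=nbins)
        levels = 0.5 * (edges[:-1] + edges[1:])

    w = counts / counts.sum()
    mu = levels * w
    # threshold candidate k: background = bins < k, foreground = bins >= k
    w_bg = np.cumsum(w)[:-1]
    mu_bg = np.cumsum(mu)[:-1]
    mu_tot = mu.sum()
    w_fg = 1.0 - w_bg
    valid = (w_bg > 0) & (w_fg > 0)
    sigma_b = np.full(levels.size - 1, -np.inf)
    sigma_b[valid] = (mu_tot * w_bg[valid] - mu_bg[valid]) ** 2 / (
        w_bg[valid] * w_fg[valid]
    )
    k = int(np.argmax(sigma_b))
    return float(levels[k + 1])


def otsu_mask(vol: VoxelVolume, cap_percentile: float | None = None) -> BinaryMask:
    """Threshold a volume with (optionally percentile-restricted) Otsu.

    The mask is ``values >= threshold`` over the full volume even when the
    threshold was computed from the capped distribution.
    """
    t = otsu_threshold(vol.values, cap_percentile=cap_percentile)
    return BinaryMask(np.asarray(vol.values) >= t, vol.spacing)


def close_and_filter(mask: BinaryMask, close_radius: float, min_size: float) -> BinaryMask:
    """Morphological closing then removal of small connected components.

    ``close_radius`` is the ball radius in um used to join fragmented
    structures; components smaller than ``min_size`` um^3 are discarded.
    """
    if close_radius < 0 or min_size < 0:
        raise ValueError("close_radius and min_size must be >= 0")
    out = mask.values
    if close_radius > 0:
        ball = _ball(close_radius, mask.spacing)
        pad = [(n // 2,) * 2 for n in ball.shape]
        padded = np.pad(out, pad)
        closed = ndimage.binary_closing(padded, structure=ball)
        out = closed[tuple(slice(p0, s - p1) for (p0, p1), s in zip(pad, closed.shape))]
    if min_size > 0 and out.any():
        labels, n = ndimage.label(out, structure=_CONN26)
        min_vox = min_size / mask.voxel_volume
        sizes = np.bincount(labels.ravel())
        keep = sizes >= min_vox
        keep[0] = False
        out = keep[labels]
    return BinaryMask(out, mask.spacing)


def select_layer(nuclei: BinaryMask, dilate_radius: float) -> BinaryMask:
    """Largest connected component of the dilated nucleus mask.

    Dilating the dense collection of nuclei merges the cell-body band into
    one object; scattered nuclei outside the band stay separate and are
    dropped. Equal-size ties break deterministically toward the lowest label
    (logged).
    """
    if not nuclei.values.any():
        raise ValueError("empty nucleus mask")
    dil = ndimage.binary_dilation(nuclei.values, structure=_ball(dilate_radius, nuclei.spacing))
    labels, n = ndimage.label(dil, structure=_CONN26)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = int(np.argmax(sizes))  # argmax returns the first (lowest) maximizer
    if (sizes == sizes[best]).sum() > 1:
        logger.info("select_layer: %d equal-size components; keeping lowest label %d",
                    int((sizes == sizes[best]).sum()), best)
    return BinaryMask(labels == best, nuclei.spacing)


def nucleus_centers(
    nuclei: BinaryMask,
    erode_radius: float = 0.5,
    split_fraction: float = 0.5,
) -> np.ndarray:
    """Centroids of individual nuclei in physical um coordinates.

    The mask is eroded, the Euclidean distance transform computed, and each
    connected component thresholded at ``split_fraction`` of its own maximum
    distance to split touching nuclei; centroids of the resulting discrete
    cores are returned as an (n, 3) array in (z, y, x) um.
    """
    if erode_radius < 0:
        raise ValueError("erode_radius must be >= 0")
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must lie in (0, 1)")
    core = nuclei.values
    if erode_radius > 0:
        core = ndimage.binary_erosion(core, structure=_ball(erode_radius, nuclei.spacing))
    if not core.any():
        logger.warning("nucleus_centers: mask empty after erosion")
        return np.empty((0, 3))
    edt = ndimage.distance_transform_edt(core, sampling=nuclei.spacing)
    labels, n = ndimage.label(core, structure=_CONN26)
    maxima = ndimage.maximum(edt, labels, index=np.arange(1, n + 1))
    thresholds = split_fraction * np.asarray(maxima)
    seeds = edt >= thresholds[labels - 1]
    seeds &= core
    seed_labels, m = ndimage.label(seeds, structure=_CONN26)
    coms = ndimage.center_of_mass(seeds, seed_labels, index=np.arange(1, m + 1))
    return np.asarray(coms, dtype=float) * np.asarray(nuclei.spacing)


def mip_z(vol: VoxelVolume) -> np.ndarray:
    """Maximum-intensity projection along z, the input to trajectory analysis."""
    return np.asarray(vol.values).max(axis=0)


def _gaussian(x, center, width, amplitude, offset):
    return offset + amplitude * np.exp(-0.5 * ((x - center) / width) ** 2)


def orientation_histogram(
    img: np.ndarray,
    grad_sigma: float = 2.0,
    window_sigma: float = 20.0,
    nbins: int = 180,
    weighting: str = "energy",
) -> OrientationResult:
    """Structure-tensor orientation histogram with a Gaussian fit.

    The structure tensor is built from Gaussian-gradient derivatives at
    ``grad_sigma`` px, smoothed with a Gaussian analysis window of
    ``window_sigma`` px. Per-pixel orientation is
    ``0.5 * atan2(2 Jxy, Jyy - Jxx)`` (degrees, (-90, 90]); the histogram is
    weighted by tensor energy (trace) or coherence. A single Gaussian
    (center, width, amplitude, offset) is fitted to the histogram after
    circularly centering it on the dominant direction.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2 or min(img.shape) < 3:
        raise ValueError("expected a 2D image of at least 3x3 pixels")
    if grad_sigma <= 0 or window_sigma <= 0:
        raise ValueError("grad_sigma and window_sigma must be > 0")
    if img.max() == img.min():
        raise ValueError("constant image carries no orientation signal")

    gy = ndimage.gaussian_filter(img, grad_sigma, order=(1, 0))
    gx = ndimage.gaussian_filter(img, grad_sigma, order=(0, 1))
    jxx = ndimage.gaussian_filter(gx * gx, window_sigma)
    jyy = ndimage.gaussian_filter(gy * gy, window_sigma)
    jxy = ndimage.gaussian_filter(gx * gy, window_sigma)

    theta = np.degrees(0.5 * np.arctan2(2 * jxy, jyy - jxx))
    energy = jxx + jyy
    if weighting == "energy":
        w = energy
    elif weighting == "coherence":
        lam = np.sqrt((jyy - jxx) ** 2 + 4 * jxy**2)
        with np.errstate(invalid="ignore", divide="ignore"):
            w = np.where(energy > 0, lam / energy, 0.0)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")

    hist, edges = np.histogram(theta.ravel(), bins=nbins, range=(-90.0, 90.0),
                               weights=w.ravel())
    centers = 0.5 * (edges[:-1] + edges[1:])

    # unwrap bins (period 180 deg) around the dominant direction so the peak
    # is not split at the +/-90 seam
    ang = np.radians(centers * 2)
    resultant = np.sum(hist * np.exp(1j * ang))
    concentration = float(np.abs(resultant) / max(hist.sum(), 1e-300))
    mean_dir = np.degrees(np.angle(resultant)) / 2.0
    x = mean_dir + ((centers - mean_dir + 90.0) % 180.0) - 90.0
    order = np.argsort(x)
    x_fit, h_fit = x[order], hist[order]

    # moment-based start: circular SD sets the width scale
    circ_sd = np.degrees(np.sqrt(max(-2.0 * np.log(max(concentration, 1e-12)), 0.0))) / 2.0
    amp0 = max(h_fit.max() - h_fit.min(), 1e-12)
    best = None
    for width0 in dict.fromkeys((float(np.clip(circ_sd, 0.5, 45.0)), 2.0, 10.0, 30.0)):
        try:
            popt, _ = optimize.curve_fit(
                _gaussian, x_fit, h_fit,
                p0=(mean_dir, width0, amp0, h_fit.min()), maxfev=5000,
            )
        except RuntimeError:
            continue
        rss = float(np.sum((h_fit - _gaussian(x_fit, *popt)) ** 2))
        if best is None or rss < best[0]:
            best = (rss, popt)
    low_confidence = False
    if best is not None:
        center, width, amplitude, offset = best[1]
        width = abs(width)
    else:
        # needle-like histograms (all weight in ~one bin) defeat the
        # least-squares fit; fall back to circular moments
        center, width = mean_dir, max(circ_sd, 1e-3)
        amplitude, offset = float(h_fit.max() - h_fit.min()), float(h_fit.min())
    if concentration < 0.3:
        # weak directional coherence: histogram is near-flat at this window
        low_confidence = True
    # wrap fitted center into (-90, 90]
    center = ((center + 90.0) % 180.0) - 90.0
    if center == -90.0:
        center = 90.0
    if not np.isfinite(amplitude) or amplitude <= 0.5 * abs(offset):
        low_confidence = True
    if not np.isfinite(width) or width > 60.0:
        # a near-flat histogram is fitted by an arbitrarily wide Gaussian
        low_confidence = True

    return OrientationResult(
        angles=centers,
        weights=hist,
        fit={"center": float(center), "width": float(width),
             "amplitude": float(amplitude), "offset": float(offset)},
        low_confidence=bool(low_confidence),
    )
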