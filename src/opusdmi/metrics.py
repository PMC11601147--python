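"""Image-quality metrics: resolution, signal-to-clutter, grating-lobe levels.

Resolution is measured as the full width at half maximum (the −6 dB width)
of the envelope amplitude profile through the image peak, with linear
sub-pixel interpolation of the half-maximum crossings; the −20 dB width is
reported alongside by :func:`fwhm_profile_widths` for transparency, since
display conventions differ between groups.  The signal-to-clutter ratio is
``20 log10(peak amplitude in a signal window / RMS amplitude over the
clutter region)``, where the clutter region is the image minus an exclusion
box around the signal.  All metrics are invariant to global positive
scaling of the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.signal

from .config import ImageGrid


class MetricError(ValueError):
    pass


def axial_envelope(image: np.ndarray) -> np.ndarray:
    """Envelope via the axial (column-wise) analytic signal magnitude."""
    return np.abs(scipy.signal.hilbert(np.asarray(image, float), axis=0))


def to_db(image: np.ndarray, dynamic_range: float = 30.0) -> np.ndarray:
    """20 log10(|image| / max), floored at -dynamic_range dB."""
    mag = np.abs(np.asarray(image, float))
    peak = mag.max()
    if peak == 0:
        warnings.warn("all-zero image; returning the dB floor everywhere")
        return np.full(mag.shape, -float(dynamic_range))
    with np.errstate(divide="ignore"):
        db = 20 * np.log10(mag / peak)
    return np.maximum(db, -float(dynamic_range))


# --------------------------------------------------------------------------
# resolution
# --------------------------------------------------------------------------

def _crossing_width(coords, profile, level):
    """Width between the outermost linear-interpolated crossings of level
    on either side of the profile maximum."""
    ipk = int(np.argmax(profile))
    left = None
    for i in range(ipk, 0, -1):
        if profile[i - 1] < level <= profile[i]:
            f = (level - profile[i - 1]) / (profile[i] - profile[i - 1])
            left = coords[i - 1] + f * (coords[i] - coords[i - 1])
            break
    right = None
    for i in range(ipk, len(profile) - 1):
        if profile[i + 1] < level <= profile[i]:
            f = (profile[i] - level) / (profile[i] - profile[i + 1])
            right = coords[i] + f * (coords[i + 1] - coords[i])
            break
    if left is None or right is None:
        raise MetricError("profile does not fall below the requested level "
                          "on both sides of the peak (truncated lobe)")
    return right - left


def fwhm(image: np.ndarray, grid: ImageGrid, axis: str,
         peak: tuple[int, int] | None = None,
         fraction: float = 0.5) -> float:
    """FWHM (µm) of the amplitude profile through the peak along an axis.

    ``image`` must be a non-negative envelope image [n_z, n_x]; ``peak``
    is an (iz, ix) pixel index or None for the global argmax; ``fraction``
    is the profile level defining the width (0.5 = −6 dB).
    """
    img = np.asarray(image, float)
    if np.any(img < 0):
        raise MetricError("fwhm expects a non-negative envelope image")
    if peak is None:
        iz, ix = np.unravel_index(np.argmax(img), img.shape)
    else:
        iz, ix = peak
    if not (0 < iz < grid.n_z - 1 and 0 < ix < grid.n_x - 1):
        raise MetricError("peak lies on the grid boundary")
    if axis == "lateral":
        coords, profile = grid.x_coords, img[iz, :]
    elif axis == "axial":
        coords, profile = grid.z_coords, img[:, ix]
    else:
        raise MetricError(f"unknown axis {axis!r}")
    width = _crossing_width(coords, profile, fraction * profile.max())
    return float(width) * 1e6


def fwhm_profile_widths(image, grid, axis, peak=None) -> dict:
    """−6 dB and −20 dB widths (µm) of the peak profile, for transparency."""
    return {"fwhm_um": fwhm(image, grid, axis, peak, fraction=0.5),
            "width_m20db_um": fwhm(image, grid, axis, peak, fraction=0.1)}


# --------------------------------------------------------------------------
# signal-to-clutter
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RoiSpec:
    """Signal window and clutter-exclusion rectangle, in metres.

    Rectangles are (x_min, x_max, z_min, z_max); the clutter region is the
    whole image minus the exclusion rectangle, which must contain the
    signal window (so signal and clutter are disjoint).
    """

    signal_window: tuple[float, float, float, float]
    exclusion_window: tuple[float, float, float, float]

    def __post_init__(self):
        sx0, sx1, sz0, sz1 = self.signal_window
        ex0, ex1, ez0, ez1 = self.exclusion_window
        if sx0 >= sx1 or sz0 >= sz1 or ex0 >= ex1 or ez0 >= ez1:
            raise MetricError("ROI rectangles must have positive extent")
        if not (ex0 <= sx0 and sx1 <= ex1 and ez0 <= sz0 and sz1 <= ez1):
            raise MetricError("exclusion window must contain the signal "
                              "window (signal and clutter must be disjoint)")


def default_point_rois(grid: ImageGrid, peak_xz: tuple[float, float],
                       signal_size: float = 0.5e-3,
                       exclusion_size: float = 1.5e-3) -> RoiSpec:
    """Default ROIs for a point-target scene: a 0.5×0.5 mm signal box and a
    1.5×1.5 mm clutter-exclusion box, both centred on the peak."""
    x, z = peak_xz
    s, e = signal_size / 2, exclusion_size / 2
    return RoiSpec(signal_window=(x - s, x + s, z - s, z + s),
                   exclusion_window=(x - e, x + e, z - e, z + e))


def _rect_mask(grid, rect):
    x0, x1, z0, z1 = rect
    mx = (grid.x_coords >= x0) & (grid.x_coords <= x1)
    mz = (grid.z_coords >= z0) & (grid.z_coords <= z1)
    return mz[:, None] & mx[None, :]


def signal_to_clutter(image: np.ndarray, grid: ImageGrid,
                      roi: RoiSpec) -> float:
    """SCR in dB: peak amplitude in the signal window over RMS clutter."""
    img = np.abs(np.asarray(image, float))
    if img.shape != (grid.n_z, grid.n_x):
        raise MetricError("image shape disagrees with the grid")
    sig = _rect_mask(grid, roi.signal_window)
    excl = _rect_mask(grid, roi.exclusion_window)
    clutter = ~excl
    if not np.any(sig):
        raise MetricError("signal window contains no pixels")
    if not np.any(clutter):
        raise MetricError("clutter region is empty")
    peak = img[sig].max()
    rms = np.sqrt(np.mean(img[clutter] ** 2))
    if rms == 0:
        return float("inf")
    return float(20 * np.log10(peak / rms))


# --------------------------------------------------------------------------
# grating lobes
# --------------------------------------------------------------------------

def lateral_band_region(grid: ImageGrid, min_abs_x: float) -> np.ndarray:
    """Mask of the lobe region flanking the main lobe: |x| >= min_abs_x."""
    mx = np.abs(grid.x_coords) >= min_abs_x
    return np.repeat(mx[None, :], grid.n_z, axis=0)


def grating_lobe_reduction(image_a: np.ndarray, image_b: np.ndarray,
                           grid: ImageGrid,
                           lobe_region: np.ndarray) -> float:
    """Difference (a − b) of peak lobe levels in dB re each image's max.

    A positive value means image ``b`` suppresses the grating lobes by that
    many dB relative to image ``a``.
    """
    lobe_region = np.asarray(lobe_region, bool)
    if lobe_region.shape != (grid.n_z, grid.n_x):
        raise MetricError("lobe region mask disagrees with the grid")
    if not np.any(lobe_region):
        raise MetricError("lobe region is empty")
    levels = []
    for img in (image_a, image_b):
        mag = np.abs(np.asarray(img, float))
        peak = mag.max()
        if peak == 0:
            raise MetricError("all-zero image has no lobe level")
        levels.append(20 * np.log10(max(mag[lobe_region].max(),
                                        1e-300) / peak))
    return float(levels[0] - levels[1])
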