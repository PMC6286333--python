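"""Back-surface boundary detection on the pose-normalized cloud.

The cloud is projected to a binary occupancy image on the x-y plane; the
width of the silhouette along y, as a function of the craniocaudal coordinate
x, is fitted with a 10th-order polynomial whose interior local minima mark
the neck and breech constrictions.  Cropping between them leaves the
back-only cloud used for the symmetry analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import Polynomial

from .geometry import PointCloud

__all__ = [
    "BinaryProjectionImage",
    "WidthProfile",
    "BackCrop",
    "project_to_binary",
    "width_function",
    "fit_width_polynomial",
    "find_back_boundaries",
    "crop_back",
]

log = logging.getLogger(__name__)

#: Fraction of the x-range, from the cranial end, searched for the neck minimum.
NECK_SEARCH_FRACTION = 0.40
#: Fraction of the x-range, from the caudal end, searched for the breech minimum.
BREECH_SEARCH_FRACTION = 0.30


@dataclass
class BinaryProjectionImage:
    """Binary occupancy image of a cloud projected to the x-y plane.

    Pixel ``(i, j)`` is black (1) iff at least one point projects into the
    half-open bin ``[x_min + i*dx, x_min + (i+1)*dx) x [y_min + j*dy, ...)``.
    """

    pixels: np.ndarray  # (i_max+1, j_max+1) uint8, axis 0 = x, axis 1 = y
    dx: float
    dy: float
    x_min: float
    y_min: float

    @property
    def i_max(self) -> int:
        return self.pixels.shape[0] - 1

    @property
    def j_max(self) -> int:
        return self.pixels.shape[1] - 1

    def column_x(self) -> np.ndarray:
        """Column-centre x coordinates (mm)."""
        return self.x_min + (np.arange(self.pixels.shape[0]) + 0.5) * self.dx

    def to_pgm(self, path) -> None:
        """Debug dump as a plain PGM (black pixels dark)."""
        img = (1 - self.pixels.T[::-1]) * 255  # y up, image row 0 at top
        with open(path, "w") as fh:
            fh.write(f"P2\n{img.shape[1]} {img.shape[0]}\n255\n")
            np.savetxt(fh, img, fmt="%d")


def project_to_binary(cloud: PointCloud, dx: float = 3.0, dy: float = 3.0) -> BinaryProjectionImage:
    """Project a pose-normalized cloud onto the x-y plane as a binary image."""
    pts = cloud.points
    if len(np.unique(pts[:, 0])) < 2 or len(np.unique(pts[:, 1])) < 2:
        raise ValueError("need at least 2 distinct x and y values to project")
    x_min, y_min = pts[:, 0].min(), pts[:, 1].min()
    i = np.floor((pts[:, 0] - x_min) / dx).astype(np.intp)
    j = np.floor((pts[:, 1] - y_min) / dy).astype(np.intp)
    pixels = np.zeros((i.max() + 1, j.max() + 1), dtype=np.uint8)
    pixels[i, j] = 1
    return BinaryProjectionImage(pixels=pixels, dx=float(dx), dy=float(dy),
                                 x_min=float(x_min), y_min=float(y_min))


@dataclass
class WidthProfile:
    """Silhouette width vs x: discrete widths and an optional polynomial fit."""

    x: np.ndarray          # column centres, mm
    widths: np.ndarray     # w_d(x) = black pixels per column * dy, mm
    dx: float
    poly: Polynomial | None = None

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        if self.poly is None:
            raise ValueError("polynomial not fitted")
        return self.poly(np.asarray(x, dtype=float))


def width_function(img: BinaryProjectionImage) -> WidthProfile:
    """Discrete width function: black-pixel count per column times dy."""
    counts = img.pixels.sum(axis=1)
    return WidthProfile(x=img.column_x(), widths=counts * img.dy, dx=img.dx)


def fit_width_polynomial(profile: WidthProfile, order: int = 10) -> WidthProfile:
    """Least-squares polynomial fit of the width function.

    The fit is performed on an abscissa mapped to [-1, 1] (handled by
    ``numpy.polynomial.Polynomial.fit``), which keeps a 10th-order fit on a
    millimetre axis numerically well conditioned.
    """
    mask = np.isfinite(profile.widths)
    if mask.sum() < order + 1:
        raise ValueError(f"need at least {order + 1} columns to fit order {order}")
    poly = Polynomial.fit(profile.x[mask], profile.widths[mask], deg=order)
    return WidthProfile(x=profile.x, widths=profile.widths, dx=profile.dx, poly=poly)


def _interior_minima(profile: WidthProfile) -> np.ndarray:
    """x locations of interior local minima of the fitted polynomial."""
    deriv = profile.poly.deriv()
    roots = deriv.roots()
    lo, hi = profile.x.min(), profile.x.max()
    real = roots[np.abs(roots.imag) < 1e-8].real
    real = real[(real > lo) & (real < hi)]
    second = profile.poly.deriv(2)(real)
    return np.sort(real[second > 0])


def find_back_boundaries(profile: WidthProfile) -> tuple[float, float]:
    """Neck and breech x positions from local minima of the fitted width.

    The neck is the deepest local minimum in the cranial 40% (high-x end) of
    the fitted domain; the breech the deepest in the caudal 30% (low-x end).
    A missing minimum falls back to the corresponding domain end.
    """
    if profile.poly is None:
        raise ValueError("polynomial not fitted")
    lo, hi = float(profile.x.min()), float(profile.x.max())
    span = hi - lo
    minima = _interior_minima(profile)

    neck_zone = minima[minima >= hi - NECK_SEARCH_FRACTION * span]
    breech_zone = minima[minima <= lo + BREECH_SEARCH_FRACTION * span]
    if len(neck_zone):
        x_neck = float(neck_zone[np.argmin(profile.evaluate(neck_zone))])
    else:
        log.warning("no neck minimum found; falling back to cranial domain end")
        x_neck = hi
    if len(breech_zone):
        x_breech = float(breech_zone[np.argmin(profile.evaluate(breech_zone))])
    else:
        log.warning("no breech minimum found; falling back to caudal domain end")
        x_breech = lo
    return x_neck, x_breech


@dataclass
class BackCrop:
    """Back-only cloud between the breech and neck boundary planes."""

    x_neck: float
    x_breech: float
    cropped: PointCloud


def crop_back(cloud: PointCloud, x_neck: float, x_breech: float) -> BackCrop:
    """Keep points with ``x_breech <= x <= x_neck`` (full y range)."""
    if not x_breech < x_neck:
        raise ValueError("x_breech must be below x_neck")
    mask = (cloud.points[:, 0] >= x_breech) & (cloud.points[:, 0] <= x_neck)
    if not mask.any():
        raise ValueError("degenerate crop: no points in range")
    return BackCrop(x_neck=float(x_neck), x_breech=float(x_breech),
                    cropped=cloud.select(np.flatnonzero(mask), stage_tag="P4"))
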