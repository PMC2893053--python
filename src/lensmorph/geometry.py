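"""Axis location, boundary extraction, half splitting, and unit conversion.

The measurement frame is the optical axis (the anterior-posterior axis of
rotational symmetry, assumed vertical in an oriented section) and the
equatorial plane (the horizontal line through the widest part of the
section). The outer boundary of the cleaned mask is split along the axis
into two half-profiles; each is reduced to a single-valued radius
function y(x) in millimetres for the solid-of-revolution integral.

Coordinate conventions: row 0 is the anterior side; the axial coordinate
x = (row - equator_row) / pixels_per_mm is negative anterior of the
equator and positive posterior of it; the radial coordinate y >= 0 is the
perpendicular distance from the axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import DegenerateMaskError, InsufficientProfileError, ValidationError
from .image_io import Calibration, LensMask, clean_mask

__all__ = [
    "AxisFrame",
    "HalfProfile",
    "find_axes",
    "align_vertical",
    "extract_edges",
    "split_halves",
    "resample_profile",
]

_FULL_3X3 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class AxisFrame:
    """Optical axis column and equatorial row, in pixel coordinates.

    Both may be fractional: the axis column is the foreground centroid
    column, and the equatorial row is the midpoint when several rows tie
    for maximal width.
    """

    axis_column: float
    equator_row: float

    @property
    def origin(self) -> tuple[float, float]:
        """(axis_column, equator_row) — the axis/equator intersection."""
        return (self.axis_column, self.equator_row)


@dataclass
class HalfProfile:
    """Ordered physical-unit edge coordinates for one half of a section.

    ``x`` runs along the optical axis (mm, anterior negative), ``y`` is
    the perpendicular distance from the axis (mm, >= 0). After
    :func:`resample_profile`, x is strictly increasing (one point per
    pixel row, the outermost edge pixel) and y refers to the outer
    boundary of that pixel.
    """

    x: np.ndarray
    y: np.ndarray
    side: str
    px_size_mm: float | None = None
    resampled: bool = False

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValidationError("x and y must be 1-D arrays of equal length")
        if self.y.size and self.y.min() < 0:
            raise ValidationError("y must be non-negative")

    @property
    def n(self) -> int:
        return int(self.x.size)


def _bbox_extent(m: np.ndarray) -> tuple[int, int]:
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    return rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1


def align_vertical(mask: LensMask) -> LensMask:
    """Rotate a mask so its principal optical axis is vertical.

    The optical axis is taken as the principal direction of *smaller*
    extent (second-order central moments): a normal lens is wider across
    the equator than along the optical axis. The rotated mask is
    re-cleaned because nearest-neighbour rotation can fragment single
    pixels at the boundary.
    """
    coords = np.argwhere(mask.mask).astype(float)
    if coords.shape[0] < 3:
        raise DegenerateMaskError("mask too small for principal-axis alignment")
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / coords.shape[0]
    _, vecs = np.linalg.eigh(cov)  # eigenvalues ascending
    axis_vec = vecs[:, 0]  # smaller-extent direction = optical axis, (drow, dcol)
    if axis_vec[0] < 0:
        axis_vec = -axis_vec
    # angle of the optical axis away from the vertical (row) direction
    phi_deg = float(np.degrees(np.arctan2(axis_vec[1], axis_vec[0])))
    rotated = ndimage.rotate(
        mask.mask.astype(np.uint8), -phi_deg, reshape=True, order=0
    ).astype(bool)
    out = LensMask(rotated, mask.calibration, flags=list(mask.flags))
    return clean_mask(out)


def find_axes(mask: LensMask, mode: str = "vertical") -> tuple[AxisFrame, LensMask]:
    """Locate the optical axis column and the equatorial row.

    In ``"vertical"`` mode the section is trusted to be oriented with the
    optical axis vertical: the axis is the area-centroid column and the
    equator is the row of maximal foreground width (ties broken at the
    midpoint of the tying rows). In ``"auto"`` mode the mask is first
    rotated via :func:`align_vertical`.

    Returns
    -------
    (AxisFrame, LensMask)
        The frame and the mask it refers to (the input mask in
        ``"vertical"`` mode, the rotated mask in ``"auto"`` mode).
    """
    if mode not in ("vertical", "auto"):
        raise ValidationError(f"mode must be 'vertical' or 'auto', got {mode!r}")
    if mode == "auto":
        mask = align_vertical(mask)
    m = mask.mask
    if not m.any():
        raise DegenerateMaskError("empty mask")
    if min(_bbox_extent(m)) < 3:
        raise DegenerateMaskError("mask thinner than 3 px; cannot place axes")
    rows, cols = np.nonzero(m)
    axis_column = float(cols.mean())
    widths = m.sum(axis=1)
    tying = np.flatnonzero(widths == widths.max())
    equator_row = float(tying[0] + tying[-1]) / 2.0
    return AxisFrame(axis_column, equator_row), mask


def extract_edges(mask: LensMask) -> np.ndarray:
    """Boundary pixels of a clean mask as an (N, 2) array of (row, col).

    A foreground pixel is a boundary pixel iff at least one of its 8
    neighbours (or the image border) is background. On a binary mask this
    morphological inner boundary coincides with the nonzero set of a
    Canny edge filter, and is threshold-free.
    """
    m = mask.mask
    if not m.any():
        raise DegenerateMaskError("empty mask")
    interior = ndimage.binary_erosion(m, structure=_FULL_3X3, border_value=0)
    return np.argwhere(m & ~interior)


def split_halves(
    edges: np.ndarray, frame: AxisFrame, calibration: Calibration
) -> tuple[HalfProfile, HalfProfile]:
    """Split boundary pixels along the optical axis into two half-profiles.

    Pixels left of the axis form the "left" half, pixels right of it the
    "right" half; a pixel exactly on the axis column belongs to both, so
    each half-profile closes at the poles. Coordinates are converted to
    millimetres: x = (row - equator_row)/ppm (anterior negative),
    y = |col - axis_column|/ppm.
    """
    edges = np.asarray(edges)
    if edges.size == 0:
        raise DegenerateMaskError("empty edge set")
    ppm = calibration.pixels_per_mm
    rows = edges[:, 0].astype(float)
    cols = edges[:, 1].astype(float)
    x = (rows - frame.equator_row) / ppm
    lateral = (cols - frame.axis_column) / ppm
    halves = []
    for side, sel in (("left", cols <= frame.axis_column), ("right", cols >= frame.axis_column)):
        order = np.argsort(x[sel], kind="stable")
        halves.append(
            HalfProfile(
                x[sel][order],
                np.abs(lateral[sel])[order],
                side=side,
                px_size_mm=1.0 / ppm,
            )
        )
    return halves[0], halves[1]


def resample_profile(half: HalfProfile) -> HalfProfile:
    """Reduce a half-profile to one point per pixel row, outermost wins.

    The solid-of-revolution integrand needs a single-valued y(x); where a
    row contributes several edge pixels (vertical runs near the poles)
    the outermost pixel is kept, consistent with the capsule-as-boundary
    convention. The kept radius is measured to the *outer* boundary of
    that pixel (centre distance + half a pixel), which removes the
    half-pixel under-measurement bias of raw centre coordinates; the
    x spacing is untouched. Idempotent.
    """
    if half.resampled:
        return half
    if half.n < 2:
        raise InsufficientProfileError(
            f"{half.side} half has {half.n} edge point(s); need >= 2"
        )
    order = np.argsort(half.x, kind="stable")
    xs = half.x[order]
    ys = half.y[order]
    xu, start = np.unique(xs, return_index=True)
    y_out = np.maximum.reduceat(ys, start)
    if half.px_size_mm is not None:
        y_out = y_out + 0.5 * half.px_size_mm
    return replace(half, x=xu, y=y_out, resampled=True)
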