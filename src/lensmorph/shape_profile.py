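"""Radial shape profiles: mean boundary radius per angular sector.

The lens outline is described in polar coordinates about the intersection
of the optical axis with the equatorial plane. The angle is measured from
the anterior pole (0 deg) through the equator (90 deg) to the posterior
pole (180 deg); the full circle is divided into 360 one-degree sectors
and the mean distance from the origin to the edge pixels falling in each
sector is recorded. Because the lens is treated as rotationally
symmetric, the two lateral halves are also folded onto 0-180 deg and
averaged, giving the presentation-ready 181-point profile. Profiles of
lenses of similar age and genotype are averaged sector-wise into group
profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateMaskError, ValidationError
from .geometry import AxisFrame, extract_edges, find_axes
from .image_io import Calibration, LensMask

__all__ = [
    "RadialProfile",
    "radial_profile",
    "folded_profile",
    "fold_profile",
    "average_profiles",
    "profile_mask",
]

RAW_SECTORS = 360
FOLDED_POINTS = 181


@dataclass
class RadialProfile:
    """Per-sector mean boundary radius.

    ``mean_radius_mm`` is NaN for sectors with no edge pixels (possible
    near the poles at coarse resolution); absent sectors are skipped, not
    zero-filled, when averaging. ``n_lenses`` counts contributing lenses
    per sector for group averages (1 for a single-lens profile).
    """

    sector_centers_deg: np.ndarray
    mean_radius_mm: np.ndarray
    counts: np.ndarray
    n_lenses: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sector_centers_deg = np.asarray(self.sector_centers_deg, dtype=float)
        self.mean_radius_mm = np.asarray(self.mean_radius_mm, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if not (
            self.sector_centers_deg.shape
            == self.mean_radius_mm.shape
            == self.counts.shape
        ):
            raise ValidationError("profile arrays must have matching shapes")
        if self.n_lenses is None:
            self.n_lenses = (self.counts > 0).astype(int)

    @property
    def present(self) -> np.ndarray:
        return self.counts > 0


def _polar(edges: np.ndarray, frame: AxisFrame, calibration: Calibration):
    edges = np.asarray(edges)
    if edges.size == 0:
        raise DegenerateMaskError("empty edge set")
    dr = edges[:, 0].astype(float) - frame.equator_row
    dc = edges[:, 1].astype(float) - frame.axis_column
    # outer-boundary (pixel-area) convention: the capsule passes along the
    # outer side of the boundary pixel, half a pixel beyond its centre
    radius_mm = (np.hypot(dr, dc) + 0.5) / calibration.pixels_per_mm
    # 0 deg points to the anterior pole (-row direction), increasing
    # toward the equator on the right-hand side of the axis
    theta = np.degrees(np.arctan2(dc, -dr)) % 360.0
    return theta, radius_mm


def _sector_means(idx: np.ndarray, radius: np.ndarray, n_bins: int):
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=radius, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return means, counts


def radial_profile(
    edges: np.ndarray, frame: AxisFrame, calibration: Calibration
) -> RadialProfile:
    """Raw 360-sector radial profile (sector centres 0.5, 1.5, ... 359.5 deg)."""
    theta, radius = _polar(edges, frame, calibration)
    idx = np.floor(theta).astype(int) % RAW_SECTORS
    means, counts = _sector_means(idx, radius, RAW_SECTORS)
    return RadialProfile(np.arange(RAW_SECTORS) + 0.5, means, counts)


def folded_profile(
    edges: np.ndarray, frame: AxisFrame, calibration: Calibration
) -> RadialProfile:
    """Folded 181-point profile on 0..180 deg (anterior -> posterior).

    The two lateral halves are mirrored onto 0-180 deg and averaged,
    exploiting the rotational-symmetry assumption. Bins are centred on
    integer degrees (the 0 and 180 deg bins are half-width).
    """
    theta, radius = _polar(edges, frame, calibration)
    phi = np.where(theta > 180.0, 360.0 - theta, theta)
    idx = np.clip(np.rint(phi).astype(int), 0, FOLDED_POINTS - 1)
    means, counts = _sector_means(idx, radius, FOLDED_POINTS)
    return RadialProfile(np.arange(FOLDED_POINTS, dtype=float), means, counts)


def fold_profile(profile: RadialProfile) -> RadialProfile:
    """Fold a raw 360-sector profile onto 0-180 deg by mirror averaging.

    Sector k (centre k+0.5 deg) pairs with sector 359-k; the folded bins
    therefore sit at 0.5 ... 179.5 deg. Prefer :func:`folded_profile`
    when the edge pixels are available (integer-degree bins).
    """
    if profile.sector_centers_deg.size != RAW_SECTORS:
        raise ValidationError("fold_profile expects a 360-sector profile")
    half = RAW_SECTORS // 2
    r = profile.mean_radius_mm
    c = profile.counts
    r_a, r_b = r[:half], r[::-1][:half]
    c_a, c_b = c[:half], c[::-1][:half]
    present_a, present_b = c_a > 0, c_b > 0
    num = np.where(present_a, np.nan_to_num(r_a), 0) + np.where(
        present_b, np.nan_to_num(r_b), 0
    )
    den = present_a.astype(int) + present_b.astype(int)
    with np.errstate(invalid="ignore"):
        means = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return RadialProfile(profile.sector_centers_deg[:half], means, c_a + c_b)


def average_profiles(profiles: list[RadialProfile]) -> RadialProfile:
    """Sector-wise mean of profiles from lenses of similar age/genotype.

    Each lens contributes its sector mean with equal weight; sectors
    absent in a lens are skipped for that lens. Pixel counts are summed.
    """
    if not profiles:
        raise ValidationError("average_profiles needs at least one profile")
    centers = profiles[0].sector_centers_deg
    for p in profiles[1:]:
        if not np.array_equal(p.sector_centers_deg, centers):
            raise ValidationError("profiles have mismatched sector grids")
    radii = np.stack([p.mean_radius_mm for p in profiles])
    present = np.stack([p.present for p in profiles])
    counts = np.stack([p.counts for p in profiles]).sum(axis=0)
    num = np.where(present, np.nan_to_num(radii), 0.0).sum(axis=0)
    den = present.sum(axis=0)
    with np.errstate(invalid="ignore"):
        means = np.where(den > 0, num / np.maximum(den, 1), np.nan)
    return RadialProfile(centers.copy(), means, counts, n_lenses=den)


def profile_mask(
    mask: LensMask, axis_mode: str = "vertical"
) -> tuple[RadialProfile, RadialProfile]:
    """Convenience wrapper: (raw 360-sector, folded 181-point) profiles."""
    frame, oriented = find_axes(mask, mode=axis_mode)
    edges = extract_edges(oriented)
    cal = mask.calibration
    return radial_profile(edges, frame, cal), folded_profile(edges, frame, cal)
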