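"""Micrograph loading, binarization, mask cleanup, and scale calibration.

A section image enters the pipeline either pre-binarized (foreground =
tissue, the workflow used for manually extracted lenses) or as a grey /
RGB micrograph that is thresholded here. Every image carries a physical
scale calibration in pixels per millimetre, determined by the microscope
magnification at acquisition time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image, UnidentifiedImageError
from scipy import ndimage
from skimage import filters, measure

from .errors import DegenerateMaskError, InputError, ValidationError

__all__ = [
    "Calibration",
    "CalibratedImage",
    "LensMask",
    "load_image",
    "binarize",
    "clean_mask",
]


@dataclass(frozen=True)
class Calibration:
    """Physical scale of an image.

    Parameters
    ----------
    pixels_per_mm : float
        Pixels per millimetre at the acquisition magnification. Must be
        positive.
    magnification_label : str, optional
        Free-text magnification annotation (e.g. ``"10x"``).
    """

    pixels_per_mm: float
    magnification_label: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.pixels_per_mm) or self.pixels_per_mm <= 0:
            raise ValidationError(
                f"pixels_per_mm must be positive, got {self.pixels_per_mm!r}"
            )

    @property
    def mm_per_px(self) -> float:
        return 1.0 / self.pixels_per_mm


@dataclass
class CalibratedImage:
    """A 2-D intensity raster with an attached physical scale.

    ``anterior_at_top`` records the section orientation convention: row 0
    is the anterior pole side. Images loaded with ``anterior_at_top=False``
    are flipped vertically at load time so that downstream geometry can
    always assume anterior-up.
    """

    raster: np.ndarray
    calibration: Calibration
    anterior_at_top: bool = True

    def __post_init__(self) -> None:
        self.raster = np.asarray(self.raster)
        if self.raster.ndim != 2 or min(self.raster.shape) < 2:
            raise ValidationError(
                f"raster must be 2-D with at least 2 rows and 2 columns, "
                f"got shape {self.raster.shape}"
            )


@dataclass
class LensMask:
    """Binary foreground mask of the lens section.

    After :func:`clean_mask` the mask satisfies the measurement
    invariants: exactly one 8-connected foreground component and no
    interior holes (every background pixel is 4-connected to the image
    border).
    """

    mask: np.ndarray
    calibration: Calibration
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValidationError("mask must be 2-D")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def load_image(path, calibration: Calibration, anterior_at_top: bool = True) -> CalibratedImage:
    """Load a PNG/TIFF/BMP micrograph and attach its calibration.

    RGB(A) images are collapsed to luminance; 8- and 16-bit grey images
    are passed through. Raises :class:`InputError` if the file cannot be
    decoded.
    """
    if not isinstance(calibration, Calibration):
        calibration = Calibration(float(calibration))
    try:
        with Image.open(path) as im:
            if im.mode in ("RGB", "RGBA", "P", "LA", "CMYK"):
                im = im.convert("L")
            arr = np.asarray(im)
    except (OSError, UnidentifiedImageError, SyntaxError, ValueError) as exc:
        raise InputError(f"cannot read image {path!s}: {exc}") from exc
    if arr.ndim == 3:  # odd multi-channel layouts PIL leaves untouched
        arr = arr.mean(axis=2)
    if not anterior_at_top:
        arr = arr[::-1]
    return CalibratedImage(arr, calibration, anterior_at_top=True)


def binarize(image: CalibratedImage, threshold="otsu", foreground: str = "dark") -> LensMask:
    """Threshold a calibrated image into a raw (uncleaned) lens mask.

    Parameters
    ----------
    threshold : float or "otsu"
        Intensity cut. ``"otsu"`` picks the threshold automatically.
    foreground : {"dark", "light"}
        ``"dark"`` marks pixels with intensity <= threshold as lens
        (matches sections binarized as black-on-white); ``"light"`` marks
        pixels >= threshold.

    Raises
    ------
    DegenerateMaskError
        If the result is all-foreground or all-background.
    """
    if foreground not in ("dark", "light"):
        raise ValidationError(f"foreground must be 'dark' or 'light', got {foreground!r}")
    raster = np.asarray(image.raster, dtype=float)
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValidationError(f"unknown threshold {threshold!r}")
        if raster.min() == raster.max():
            raise DegenerateMaskError("constant raster: Otsu threshold undefined")
        t = float(filters.threshold_otsu(raster))
    else:
        t = float(threshold)
    fg = raster <= t if foreground == "dark" else raster >= t
    if fg.all() or not fg.any():
        raise DegenerateMaskError(
            "thresholding produced an all-foreground or all-background mask"
        )
    return LensMask(fg, image.calibration)


def clean_mask(mask: LensMask) -> LensMask:
    """Keep the largest 8-connected component and fill interior holes.

    Holes are filled so that the edge filter later sees only the outer
    (capsule) boundary; interior processing voids do not contribute to
    the measured profile. Idempotent.
    """
    m = mask.mask
    if not m.any():
        raise DegenerateMaskError("empty mask")
    labels = measure.label(m, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(counts.argmax())
    comp = labels == keep
    # default 4-connected structuring element for the background flood,
    # the dual of 8-connected foreground
    filled = ndimage.binary_fill_holes(comp)
    return LensMask(filled, mask.calibration, flags=list(mask.flags))
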