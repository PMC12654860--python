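"""Geometry measurement from micrographs of a plate-compressed cell.

Extracts the cell width Lt (plate inner-edge separation along the
compression axis) and the contact length Dt (transverse extent of the cell
mask immediately adjacent to each plate) from bright-field-like frames, and
converts Dt to the circular contact area St = π·Dt²/4.

Conventions: 0-based pixel indices, intensities sampled at pixel centres
(centre of pixel i at (i + 0.5)·pixel_size µm), compression axis horizontal
by default. All measurements are invariant to affine intensity rescaling
(edges come from gradient argmax, segmentation from Otsu's threshold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label

__all__ = [
    "Micrograph",
    "GeometryMeasurement",
    "PlateDetectionError",
    "SegmentationError",
    "locate_plates",
    "measure_width",
    "measure_contact_length",
    "measure_frame",
    "contact_area",
]


class PlateDetectionError(RuntimeError):
    """Raised when two plate inner edges cannot be located."""


class SegmentationError(RuntimeError):
    """Raised when no cell mask can be segmented between the plates."""


@dataclass
class Micrograph:
    """A single frame with its spatial calibration."""

    intensities: np.ndarray
    pixel_size: float  # µm per pixel
    compression_axis: str = "horizontal"

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2 or self.intensities.size == 0:
            raise ValueError("intensities must be a non-empty 2-D array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.compression_axis not in ("horizontal", "vertical"):
            raise ValueError("compression_axis must be horizontal or vertical")

    def _axis_aligned(self) -> np.ndarray:
        """Image with the compression axis along columns (horizontal)."""
        img = self.intensities
        return img if self.compression_axis == "horizontal" else img.T


@dataclass
class GeometryMeasurement:
    """Per-frame geometry: contact length and cell width, µm."""

    Dt: float
    Lt: float
    frame_index: int = 0
    contact: bool = True

    def __post_init__(self):
        if self.Dt < 0:
            raise ValueError("Dt must be >= 0")
        if self.Lt <= 0:
            raise ValueError("Lt must be > 0")


def locate_plates(image: Micrograph) -> tuple[float, float]:
    """Locate the two plate inner edges along the compression axis, in µm.

    The intensity profile averaged across the transverse direction shows two
    dark bands at the margins; the inner edges are the strongest rising
    (left) and falling (right) gradients of that profile. Returned ordered
    (left_um, right_um), positions at pixel boundaries.
    """
    img = image._axis_aligned()
    profile = img.mean(axis=0)
    rng = profile.max() - profile.min()
    if rng <= 0 or not np.isfinite(rng):
        raise PlateDetectionError("no intensity structure: cannot locate plates")
    grad = np.diff(profile)
    gmax, gmin = grad.max(), grad.min()
    # both a dark→bright and a bright→dark transition must be present
    if gmax < 0.25 * rng / 2 or -gmin < 0.25 * rng / 2:
        raise PlateDetectionError("fewer than two plate edges found")
    i_left = int(np.argmax(grad))
    i_right = int(np.argmin(grad))
    if i_right <= i_left:
        raise PlateDetectionError("plate edges out of order")
    px = image.pixel_size
    # transition between pixels i and i+1 sits at boundary (i+1)·px
    return ((i_left + 1) * px, (i_right + 1) * px)


def _segment_cell(image: Micrograph, plates: tuple[float, float]) -> np.ndarray:
    """Binary mask of the largest dark object strictly between the plates."""
    img = image._axis_aligned()
    px = image.pixel_size
    left, right = plates
    x_centres = (np.arange(img.shape[1]) + 0.5) * px
    inter = (x_centres > left + px) & (x_centres < right - px)
    if not np.any(inter):
        raise SegmentationError("no inter-plate region")
    region = img[:, inter]
    vals = region.ravel()
    if np.ptp(vals) <= 0:
        raise SegmentationError("empty cell mask: uniform inter-plate region")
    thr = threshold_otsu(vals)
    mask = np.zeros(img.shape, dtype=bool)
    mask[:, inter] = region < thr
    if not mask.any():
        raise SegmentationError("empty cell mask")
    lab = label(mask)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return lab == largest


def _mask_contact(mask: np.ndarray, plates, px: float, band_px: float) -> tuple[bool, bool]:
    x_centres = (np.arange(mask.shape[1]) + 0.5) * px
    left, right = plates
    at_left = mask[:, (x_centres > left) & (x_centres <= left + band_px * px)].any()
    at_right = mask[:, (x_centres < right) & (x_centres >= right - band_px * px)].any()
    return bool(at_left), bool(at_right)


def measure_width(
    image: Micrograph, plates: tuple[float, float] | None = None
) -> float:
    """Cell width Lt along the compression axis, µm.

    Under compression (cell touching both plates) Lt is the plate inner-edge
    separation; before contact it is the axial extent of the segmented cell
    mask.
    """
    if plates is None:
        plates = locate_plates(image)
    mask = _segment_cell(image, plates)
    px = image.pixel_size
    at_left, at_right = _mask_contact(mask, plates, px, band_px=2.0)
    if at_left and at_right:
        return plates[1] - plates[0]
    cols = np.flatnonzero(mask.any(axis=0))
    if cols.size == 0:
        raise SegmentationError("empty cell mask")
    return (cols[-1] - cols[0] + 1) * px


def measure_contact_length(
    image: Micrograph,
    plates: tuple[float, float] | None = None,
    band_px: float = 2.0,
) -> float:
    """Contact length Dt: transverse cell extent adjacent to the plates, µm.

    The cell mask is intersected with a tolerance band (default 2 px) inside
    each plate inner edge; Dt is the transverse extent of the mask in that
    band, averaged over the plates where contact exists. Returns 0.0 when
    the mask does not reach either band (no contact).
    """
    if plates is None:
        plates = locate_plates(image)
    mask = _segment_cell(image, plates)
    px = image.pixel_size
    left, right = plates
    x_centres = (np.arange(mask.shape[1]) + 0.5) * px

    extents = []
    for sel in (
        (x_centres > left) & (x_centres <= left + band_px * px),
        (x_centres < right) & (x_centres >= right - band_px * px),
    ):
        band = mask[:, sel]
        rows = np.flatnonzero(band.any(axis=1))
        if rows.size:
            extents.append((rows[-1] - rows[0] + 1) * px)
    if not extents:
        return 0.0
    return float(np.mean(extents))


def measure_frame(
    image: Micrograph,
    frame_index: int = 0,
    band_px: float = 2.0,
) -> GeometryMeasurement:
    """Measure Lt and Dt of one frame; flags whether plate contact exists."""
    plates = locate_plates(image)
    Dt = measure_contact_length(image, plates, band_px=band_px)
    Lt = measure_width(image, plates)
    return GeometryMeasurement(Dt=Dt, Lt=Lt, frame_index=frame_index, contact=Dt > 0)


def contact_area(Dt: float) -> float:
    """Circular contact-patch area St = π·Dt²/4, µm²."""
    arr = np.asarray(Dt, dtype=float)
    if np.any(arr < 0):
        raise ValueError("Dt must be >= 0")
    area = np.pi * arr**2 / 4.0
    return area.item() if area.ndim == 0 else area
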