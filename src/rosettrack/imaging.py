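"""Image and mask handling plus per-segment measurements.

A daily top-view rosette image is held as a :class:`PlantImage`; the plant
mask is extracted as the largest connected foreground component (inputs are
assumed background-removed, so any non-zero pixel is foreground by default).
Each candidate leaf segment is summarised by three quantities measured from
the plant mass center C: the direction of its extremity (the segment pixel
farthest from C), the distance to that extremity, and its area in cm^2
obtained from the pixel count through the platform calibration constant
(28,900 px per cm^2 by default).

Coordinates are 0-based (row, col) internally; CSV outputs are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .geometry import angle_from_displacement

#: Platform calibration: pixels per cm^2 of ground truth area.
DEFAULT_PIXELS_PER_CM2 = 28_900.0

__all__ = [
    "DEFAULT_PIXELS_PER_CM2",
    "PlantImage",
    "Segment",
    "LeafObservation",
    "read_image",
    "extract_plant_mask",
    "mass_center",
    "measure_segment",
    "segments_from_labels",
    "labels_from_segments",
    "write_label_mask",
    "segment_table",
]


@dataclass
class PlantImage:
    """A background-removed RGB top-view image for one day.

    Parameters
    ----------
    pixels
        ``(m, n, 3)`` uint8 array (rows, cols, RGB).
    day_index
        1-based position of the image within its series.
    pixels_per_cm2
        Calibration constant converting pixel counts to cm^2.
    """

    pixels: np.ndarray
    day_index: int = 1
    pixels_per_cm2: float = DEFAULT_PIXELS_PER_CM2

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim == 2:
            self.pixels = np.stack([self.pixels] * 3, axis=-1)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] < 3:
            raise ValueError("expected an (m, n, 3) RGB array")
        if self.pixels_per_cm2 <= 0:
            raise ValueError("calibration must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def luminance(self) -> np.ndarray:
        """Rec. 601 luma in [0, 1], used by the edge detector."""
        rgb = self.pixels[..., :3].astype(float) / 255.0
        return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


@dataclass
class Segment:
    """A connected set of foreground pixels on one day.

    ``rows``/``cols`` are parallel 0-based coordinate arrays. ``is_leaf``
    is set by the segmentation refinement: True once the segment passed the
    convexity test, False for flagged residuals.
    """

    rows: np.ndarray
    cols: np.ndarray
    day: int = 1
    index: int = 0
    is_leaf: bool | None = None

    def __post_init__(self):
        self.rows = np.asarray(self.rows, dtype=np.int64).ravel()
        self.cols = np.asarray(self.cols, dtype=np.int64).ravel()
        if self.rows.size == 0:
            raise ValueError("a segment must contain at least one pixel")
        if self.rows.shape != self.cols.shape:
            raise ValueError("rows and cols must have the same length")

    @property
    def n_pixels(self) -> int:
        return int(self.rows.size)

    def bbox(self) -> tuple[int, int, int, int]:
        """(rmin, rmax, cmin, cmax), inclusive."""
        return (
            int(self.rows.min()),
            int(self.rows.max()),
            int(self.cols.min()),
            int(self.cols.max()),
        )

    def to_mask(self, shape: tuple[int, int]) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        mask[self.rows, self.cols] = True
        return mask

    def crop_mask(self, pad: int = 1) -> tuple[np.ndarray, tuple[int, int]]:
        """Boolean mask on the segment's padded bounding box and its offset."""
        rmin, rmax, cmin, cmax = self.bbox()
        rmin = max(rmin - pad, 0)
        cmin = max(cmin - pad, 0)
        mask = np.zeros((rmax - rmin + 1 + pad, cmax - cmin + 1 + pad), dtype=bool)
        mask[self.rows - rmin, self.cols - cmin] = True
        return mask, (rmin, cmin)


@dataclass(frozen=True)
class LeafObservation:
    """Measured descriptors of one segment on one day."""

    day: int
    angle_deg: float
    extremity_px: float
    extremity_cm: float
    area_cm2: float
    n_pixels: int
    extremity_row: int
    extremity_col: int
    segment_index: int = 0


def read_image(path: str | Path, day_index: int = 1,
               pixels_per_cm2: float = DEFAULT_PIXELS_PER_CM2) -> PlantImage:
    """Read an 8-bit RGB PNG/TIFF into a :class:`PlantImage`."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    return PlantImage(arr, day_index=day_index, pixels_per_cm2=pixels_per_cm2)


def extract_plant_mask(image: PlantImage | np.ndarray,
                       threshold: float = 0.0) -> np.ndarray:
    """Largest connected foreground component of a pre-masked image.

    Foreground is any pixel with some channel strictly above ``threshold``
    (0 by default: inputs are background-removed, background is black).
    Small disconnected artifacts left over by the background removal are
    discarded; 8-connectivity is used so thin petioles do not fragment.

    Raises
    ------
    ValueError
        If the image contains no foreground pixel.
    """
    if isinstance(image, PlantImage):
        arr = image.pixels
    else:
        arr = np.asarray(image)
    if arr.ndim == 3:
        fg = (arr > threshold).any(axis=-1)
    else:
        fg = arr > threshold
    if not fg.any():
        raise ValueError("empty plant: image contains no foreground pixel")
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
    if n == 1:
        return fg
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == int(np.argmax(counts))


def mass_center(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the foreground pixels."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mass_center of an empty mask")
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def measure_segment(segment: Segment, center: tuple[float, float],
                    pixels_per_cm2: float = DEFAULT_PIXELS_PER_CM2,
                    norm: str = "euclidean") -> LeafObservation:
    """Measure angle, extremity distance and area of a segment.

    The extremity E is the segment pixel at maximal Euclidean distance from
    the plant mass center C (ties broken by smallest (row, col)); the
    reported distance is the Euclidean length of C->E (``norm="l1"``
    switches the reported length, not the argmax, to the L1 norm). The
    angle is the direction of C->E in the y-up frame, degrees in [0, 360).
    """
    cr, cc = float(center[0]), float(center[1])
    if not (np.isfinite(cr) and np.isfinite(cc)):
        raise ValueError("mass center must be finite")
    dr = segment.rows - cr
    dc = segment.cols - cc
    d2 = dr * dr + dc * dc
    best = np.flatnonzero(d2 == d2.max())
    if best.size > 1:
        order = np.lexsort((segment.cols[best], segment.rows[best]))
        best = best[[order[0]]]
    k = int(best[0])
    erow, ecol = int(segment.rows[k]), int(segment.cols[k])
    if norm == "l1":
        dist = abs(erow - cr) + abs(ecol - cc)
    else:
        dist = float(np.sqrt(d2[k]))
    angle = angle_from_displacement(erow - cr, ecol - cc)
    area = segment.n_pixels / pixels_per_cm2
    return LeafObservation(
        day=segment.day,
        angle_deg=angle,
        extremity_px=float(dist),
        extremity_cm=float(dist) / np.sqrt(pixels_per_cm2),
        area_cm2=float(area),
        n_pixels=segment.n_pixels,
        extremity_row=erow,
        extremity_col=ecol,
        segment_index=segment.index,
    )


def segments_from_labels(labels: np.ndarray, day: int = 1) -> list[Segment]:
    """Turn a label image (0 = background) into Segment objects."""
    labels = np.asarray(labels)
    out = []
    for i, lab in enumerate(np.unique(labels)):
        if lab == 0:
            continue
        rows, cols = np.nonzero(labels == lab)
        out.append(Segment(rows, cols, day=day, index=i))
    return out


def labels_from_segments(segments: Sequence[Segment],
                         shape: tuple[int, int]) -> np.ndarray:
    """Render segments as a uint16 label image (k = 1-based segment id)."""
    labels = np.zeros(shape, dtype=np.uint16)
    for k, seg in enumerate(segments, start=1):
        labels[seg.rows, seg.cols] = k
    return labels


def write_label_mask(path: str | Path, labels: np.ndarray) -> None:
    """Write a 16-bit single-channel PNG label mask."""
    iio.imwrite(Path(path), np.asarray(labels, dtype=np.uint16))


def segment_table(segments: Iterable[Segment], center: tuple[float, float],
                  pixels_per_cm2: float = DEFAULT_PIXELS_PER_CM2) -> pd.DataFrame:
    """Per-day segment measurement table (1-based pixel coordinates)."""
    rows = []
    for k, seg in enumerate(segments, start=1):
        obs = measure_segment(seg, center, pixels_per_cm2)
        rows.append({
            "day": seg.day,
            "segment_id": k,
            "angle_deg": obs.angle_deg,
            "extremity_cm": obs.extremity_cm,
            "area_cm2": obs.area_cm2,
            "n_pixels": obs.n_pixels,
            "extremity_row": obs.extremity_row + 1,
            "extremity_col": obs.extremity_col + 1,
            "is_leaf": seg.is_leaf if seg.is_leaf is not None else True,
        })
    return pd.DataFrame(
        rows,
        columns=["day", "segment_id", "angle_deg", "extremity_cm",
                 "area_cm2", "n_pixels", "extremity_row", "extremity_col",
                 "is_leaf"],
    )
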