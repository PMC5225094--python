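"""Two-step leaf segmentation of a rosette plant mask.

Step one partitions the plant mask with a marker-based watershed: Canny
edge pixels (which trace the boundaries between strongly overlapping
leaves) are removed from the mask, the Euclidean distance transform (EDT)
of the remainder is computed, its local maxima — points farthest from the
background, hence likely leaf centers — become markers, and the watershed
of the inverted EDT grows them back over the full mask.

Step two filters the resulting segments with a convexity (solidity) test:
a segment is a single leaf if area / convex-hull-area exceeds a threshold
i0 (0.9 by default). A failing segment is assumed to be two merged leaves
and is split by intersecting it with an ellipse fitted around the larger
of the two dominant EDT maxima; the two parts are re-tested recursively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.feature import canny, peak_local_max
from skimage.morphology import convex_hull_image
from skimage.segmentation import watershed

from .imaging import PlantImage, Segment

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationConfig",
    "watershed_segments",
    "convexity_ratio",
    "is_single_leaf",
    "split_segment",
    "UnsplittableSegment",
    "refine_segments",
    "segment_image",
]


@dataclass
class SegmentationConfig:
    """Tunable knobs of the two-step segmentation.

    convexity_threshold
        Solidity i0 above which (strictly) a segment counts as one leaf.
    ellipse_inflation
        Factor phi >= 1 inflating the split ellipse semi-axes so the
        ellipse embraces the whole leaf despite pixelation.
    canny_sigma / canny_low / canny_high
        Edge detector scale and hysteresis thresholds; ``None`` thresholds
        fall back to scikit-image's Otsu-based automatic choice.
    min_peak_separation
        Minimum distance (px) between EDT maxima used as markers.
    edt_smoothing_sigma
        Gaussian smoothing of the distance map before peak detection;
        suppresses the spurious ridge maxima that integer-valued EDTs
        produce along elongated blades.
    min_segment_size
        Watershed regions below this pixel count are merged into their
        largest neighbor.
    max_split_depth
        Recursion bound for the refinement step.
    """

    convexity_threshold: float = 0.9
    ellipse_inflation: float = 1.05
    canny_sigma: float = 2.0
    canny_low: float | None = None
    canny_high: float | None = None
    min_peak_separation: int = 10
    edt_smoothing_sigma: float = 2.0
    min_segment_size: int = 50
    max_split_depth: int = 5

    def __post_init__(self):
        if not 0.0 < self.convexity_threshold < 1.0:
            raise ValueError("convexity threshold must lie in (0, 1)")
        if self.ellipse_inflation < 1.0:
            raise ValueError("ellipse inflation must be >= 1")
        if self.max_split_depth < 1:
            raise ValueError("max split depth must be >= 1")


def _edt_markers(mask: np.ndarray, min_distance: int,
                 smoothing_sigma: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """EDT of ``mask`` and a marker label image at its local maxima.

    Peaks must be strict maxima within a ``min_distance`` neighborhood;
    plateaus contribute a single peak (the lexicographically smallest
    pixel, which is what ``peak_local_max`` returns first). With
    ``smoothing_sigma > 0`` the peak search runs on a Gaussian-smoothed
    copy of the transform.
    """
    edt = ndimage.distance_transform_edt(mask)
    search = edt
    if smoothing_sigma > 0:
        search = ndimage.gaussian_filter(edt, smoothing_sigma)
        search[~mask] = 0.0
    peaks = peak_local_max(
        search, min_distance=min_distance, exclude_border=False, labels=mask
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    return edt, markers


def _merge_small(labels: np.ndarray, min_size: int) -> np.ndarray:
    """Merge labeled regions below ``min_size`` px into their largest neighbor."""
    labels = labels.copy()
    while True:
        ids, counts = np.unique(labels[labels > 0], return_counts=True)
        small = ids[counts < min_size]
        if small.size == 0 or ids.size <= 1:
            return labels
        merged_any = False
        for lab in small:
            region = labels == lab
            ring = ndimage.binary_dilation(region, structure=np.ones((3, 3))) & ~region
            neigh = labels[ring]
            neigh = neigh[neigh > 0]
            if neigh.size == 0:
                continue
            nid, ncnt = np.unique(neigh, return_counts=True)
            labels[region] = nid[np.argmax(ncnt)]
            merged_any = True
        if not merged_any:
            return labels


def watershed_segments(mask: np.ndarray, config: SegmentationConfig | None = None,
                       image: PlantImage | None = None, day: int = 1) -> list[Segment]:
    """Partition the plant mask into candidate leaf segments.

    If the RGB ``image`` is supplied, Canny edges of its luminance are cut
    out of the mask before the distance transform so that the contact
    lines between overlapping leaves become EDT valleys separating the
    markers; the watershed itself still floods the complete mask, so every
    foreground pixel ends up in exactly one segment.
    """
    config = config or SegmentationConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return []

    work = mask
    if image is not None:
        edges = canny(
            image.luminance(), sigma=config.canny_sigma,
            low_threshold=config.canny_low, high_threshold=config.canny_high,
        )
        cut = mask & ~edges
        if cut.any():
            work = cut

    edt, markers = _edt_markers(work, config.min_peak_separation,
                                config.edt_smoothing_sigma)
    if markers.max() == 0:  # plant smaller than the peak neighborhood
        rows, cols = np.nonzero(mask)
        return [Segment(rows, cols, day=day, index=0)]

    labels = watershed(-edt, markers=markers, mask=mask)
    # Edge pixels removed before the EDT may sit outside every basin; give
    # them to the nearest labeled region.
    orphan = mask & (labels == 0)
    if orphan.any():
        _, (ir, ic) = ndimage.distance_transform_edt(
            labels == 0, return_indices=True
        )
        labels[orphan] = labels[ir[orphan], ic[orphan]]
    labels = _merge_small(labels, config.min_segment_size)

    segments = []
    for idx, lab in enumerate(np.unique(labels[labels > 0])):
        rows, cols = np.nonzero(labels == lab)
        segments.append(Segment(rows, cols, day=day, index=idx))
    logger.debug("watershed: %d segments on day %d", len(segments), day)
    return segments


def convexity_ratio(segment: Segment) -> float:
    """Solidity of a segment: pixel count / convex-hull pixel count."""
    mask, _ = segment.crop_mask()
    hull = convex_hull_image(mask)
    return float(mask.sum() / hull.sum())


def is_single_leaf(segment: Segment, config: SegmentationConfig | None = None) -> bool:
    """True iff the solidity strictly exceeds the threshold i0."""
    config = config or SegmentationConfig()
    return convexity_ratio(segment) > config.convexity_threshold


class UnsplittableSegment(Exception):
    """The segment has fewer than two usable EDT maxima."""


def _ray_exit_distance(mask: np.ndarray, start: tuple[float, float],
                       direction: tuple[float, float], step: float = 0.5) -> float:
    """Distance from ``start`` to the first non-segment sample along +-direction.

    Marches at sub-pixel steps in both directions and returns the smaller
    of the two exit distances.
    """
    m, n = mask.shape
    dr, dc = direction
    nrm = np.hypot(dr, dc)
    dr, dc = dr / nrm, dc / nrm
    dists = []
    for sign in (1.0, -1.0):
        t = 0.0
        while True:
            t += step
            r = start[0] + sign * t * dr
            c = start[1] + sign * t * dc
            ri, ci = int(round(r)), int(round(c))
            if ri < 0 or ri >= m or ci < 0 or ci >= n or not mask[ri, ci]:
                dists.append(t)
                break
    return min(dists)


def split_segment(segment: Segment, center: tuple[float, float],
                  config: SegmentationConfig | None = None) -> tuple[Segment, Segment]:
    """Split a merged segment with an ellipse around its dominant EDT maximum.

    The two largest EDT maxima P1 >= P2 are located (ties resolved by the
    larger surrounding watershed basin, then lexicographically). An
    ellipse is placed at P1 with one semi-axis along the line through the
    plant center C and P1 and the other perpendicular to it; each
    semi-axis is the inflated distance from P1 to the nearest non-segment
    sample along its direction. The returned pair is (segment ∩ ellipse,
    remainder); together they partition the input.

    Raises
    ------
    UnsplittableSegment
        If fewer than two separated EDT maxima exist.
    """
    config = config or SegmentationConfig()
    mask, (roff, coff) = segment.crop_mask()
    edt = ndimage.distance_transform_edt(mask)
    peaks = peak_local_max(
        edt, min_distance=config.min_peak_separation,
        exclude_border=False, labels=mask,
    )
    if len(peaks) < 2:
        raise UnsplittableSegment(
            f"segment {segment.index} on day {segment.day} has "
            f"{len(peaks)} EDT maximum/maxima"
        )

    values = edt[peaks[:, 0], peaks[:, 1]]
    # Rank peaks: EDT value, then basin size, then lexicographic position.
    markers = np.zeros(mask.shape, dtype=np.int32)
    for k, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = k
    basins = watershed(-edt, markers=markers, mask=mask)
    sizes = np.bincount(basins.ravel(), minlength=len(peaks) + 1)[1:]
    order = np.lexsort((peaks[:, 1], peaks[:, 0], -sizes, -values))
    p1 = peaks[order[0]].astype(float)
    p2 = peaks[order[1]].astype(float)

    c_local = (center[0] - roff, center[1] - coff)
    axis = (p1[0] - c_local[0], p1[1] - c_local[1])
    if np.hypot(*axis) < 1e-9:
        axis = (p1[0] - p2[0], p1[1] - p2[1])
    perp = (-axis[1], axis[0])
    phi = config.ellipse_inflation
    a1 = phi * _ray_exit_distance(mask, tuple(p1), axis)
    b1 = phi * _ray_exit_distance(mask, tuple(p1), perp)

    # Membership test of the rotated ellipse at P1 for all segment pixels.
    ur = np.array(axis) / np.hypot(*axis)
    vr = np.array(perp) / np.hypot(*perp)
    rel = np.stack([segment.rows - roff - p1[0], segment.cols - coff - p1[1]], axis=1)
    xa = rel @ ur
    xb = rel @ vr
    inside = (xa / a1) ** 2 + (xb / b1) ** 2 <= 1.0
    if inside.all() or not inside.any():
        raise UnsplittableSegment("split ellipse does not separate the segment")

    first = Segment(segment.rows[inside], segment.cols[inside],
                    day=segment.day, index=segment.index)
    rest = Segment(segment.rows[~inside], segment.cols[~inside],
                   day=segment.day, index=segment.index)
    return first, rest


def _connected_parts(segment: Segment) -> list[Segment]:
    mask, (roff, coff) = segment.crop_mask()
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    if n <= 1:
        return [segment]
    parts = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labels == lab)
        parts.append(Segment(rows + roff, cols + coff,
                             day=segment.day, index=segment.index))
    return parts


def refine_segments(segments: list[Segment], center: tuple[float, float],
                    config: SegmentationConfig | None = None) -> list[Segment]:
    """Apply the convexity test and recursive ellipse splitting.

    Returns accepted leaf segments (``is_leaf=True``) plus residual
    segments that could not be split further (``is_leaf=False``). The
    output pixels are exactly the input pixels, re-partitioned. Split
    outputs are broken into connected components before re-testing; parts
    below the minimum segment size are kept as residuals rather than
    recursed on.
    """
    config = config or SegmentationConfig()
    out: list[Segment] = []
    queue: list[tuple[Segment, int]] = [(s, 0) for s in segments]
    while queue:
        seg, depth = queue.pop()
        if seg.n_pixels < config.min_segment_size:
            seg.is_leaf = False
            out.append(seg)
            continue
        if is_single_leaf(seg, config):
            seg.is_leaf = True
            out.append(seg)
            continue
        if depth >= config.max_split_depth:
            seg.is_leaf = False
            out.append(seg)
            continue
        try:
            first, rest = split_segment(seg, center, config)
        except UnsplittableSegment:
            seg.is_leaf = False
            out.append(seg)
            continue
        logger.debug("split day %d segment %d (%d px) into %d + %d px",
                     seg.day, seg.index, seg.n_pixels,
                     first.n_pixels, rest.n_pixels)
        for part in (first, rest):
            for comp in _connected_parts(part):
                queue.append((comp, depth + 1))
    for i, seg in enumerate(out):
        seg.index = i
    return out


def segment_image(image: PlantImage, config: SegmentationConfig | None = None
                  ) -> tuple[list[Segment], tuple[float, float]]:
    """Full per-image pipeline: mask -> center -> watershed -> refinement.

    Returns the refined segments and the plant mass center.
    """
    from .imaging import extract_plant_mask, mass_center

    config = config or SegmentationConfig()
    mask = extract_plant_mask(image)
    center = mass_center(mask)
    segments = watershed_segments(mask, config, image=image, day=image.day_index)
    return refine_segments(segments, center, config), center
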