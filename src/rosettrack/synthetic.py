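"""Ground-truthed synthetic rosettes and leaf-area datasets.

The renderer emulates what the phenotyping platform delivers after
background removal: one top-view RGB image per day of a rosette whose
leaves are filled ellipses placed around the plant center. Cotyledons
grow in opposite directions, the first true-leaf pair opposite each
other and roughly perpendicular to the cotyledons, and every leaf from
rank 5 on sits one golden angle (137.5 deg) beyond its predecessor,
clockwise or counter-clockwise. Per-leaf areas follow logistic curves in
time (later leaves larger and steeper), per-leaf emergence jitter
perturbs the phyllotaxy, and a daily global rotation emulates the small
pot displacements between imaging sessions. Every image comes with an
exact per-leaf label mask and per-leaf truth records, so segmentation
and tracking can be scored by IoU against known leaves.

A second generator produces noisy per-leaf area trajectory tables from
the source-sink growth model (multiplicative Gaussian noise, optional
missingness) for calibration studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import circular_distance, wrap_deg
from .growth import Environment, GrowthParams, simulate
from .calibration import ObservationSet
from .imaging import (DEFAULT_PIXELS_PER_CM2, LeafObservation, PlantImage,
                      Segment, mass_center, measure_segment)
from .tracking import GOLDEN_ANGLE_DEG, LeafTrack, TrackingResult

STEM_LABEL = 255

__all__ = [
    "GenotypeSpec",
    "SceneTruth",
    "TrackingMetrics",
    "render_sequence",
    "truth_observations",
    "measure_day",
    "generate_area_dataset",
    "evaluate_tracking",
]


@dataclass
class GenotypeSpec:
    """Geometry, growth and noise settings of one synthetic plant."""

    seed: int
    n_days: int = 21
    canvas: tuple[int, int] = (1232, 1624)          # (rows, cols)
    pixels_per_cm2: float = DEFAULT_PIXELS_PER_CM2
    orientation: str = "counter_clockwise"          # phyllotaxy handedness
    phyllotaxy_jitter_sd_deg: float = 5.0           # per-leaf placement jitter
    rotation_jitter_sd_deg: float = 3.0             # daily pot rotation
    rotation_jitter_max_deg: float | None = None    # hard per-day bound (truncation)
    base_angle_deg: float = 15.0                    # cotyledon direction
    aspect_ratio: float = 0.6                       # ellipse minor/major
    petiole_fraction: float = 0.3                   # petiole length / blade length
    stem_radius_px: int = 4
    # emergence schedule (days, 1-based)
    emergence_day_leaves34: int = 3
    emergence_day_leaf5: int = 5
    emergence_interval_days: float = 1.5            # ranks >= 6
    max_leaves: int = 20
    # logistic area trajectories (cm^2, per day)
    cotyledon_area_cm2: float = 0.35
    true_leaf_area_cm2: float = 0.8
    spiral_area_cm2: float = 0.9
    spiral_area_increment_cm2: float = 0.1
    growth_rate_per_day: float = 0.55
    growth_rate_increment: float = 0.04
    half_time_days: float = 5.0
    area_scale: float = 1.0
    render_rgb: bool = True

    def __post_init__(self):
        if self.orientation not in ("clockwise", "counter_clockwise"):
            raise ValueError("orientation must be clockwise or counter_clockwise")
        if self.phyllotaxy_jitter_sd_deg < 0 or self.rotation_jitter_sd_deg < 0:
            raise ValueError("jitter standard deviations must be >= 0")

    @property
    def orientation_sign(self) -> int:
        return 1 if self.orientation == "counter_clockwise" else -1

    def emergence_days(self) -> list[float]:
        days = [1.0, 1.0, float(self.emergence_day_leaves34),
                float(self.emergence_day_leaves34)]
        t = float(self.emergence_day_leaf5)
        while t <= self.n_days and len(days) < self.max_leaves:
            days.append(t)
            t += self.emergence_interval_days
        return days

    def leaf_area_cm2(self, rank: int, day: float, emerged: float) -> float:
        """Logistic blade area of leaf ``rank`` on ``day`` (0 before emergence)."""
        if day < emerged:
            return 0.0
        if rank <= 2:
            amax, k = self.cotyledon_area_cm2, self.growth_rate_per_day
        elif rank <= 4:
            amax, k = self.true_leaf_area_cm2, self.growth_rate_per_day
        else:
            j = rank - 5
            amax = self.spiral_area_cm2 + j * self.spiral_area_increment_cm2
            k = self.growth_rate_per_day + j * self.growth_rate_increment
        x = (day - emerged) - self.half_time_days
        return self.area_scale * amax / (1.0 + math.exp(-k * x))


@dataclass
class SceneTruth:
    """Exact per-day leaf geometry of a rendered sequence.

    ``labels[day]`` is a uint8 image: 0 background, v = rank of the leaf
    owning the pixel, 255 the central stem disk. ``records`` holds one
    row per (day, rank) with the placement angle (exact), the measured
    angle/extremity from the rendered mask, and the pixel-exact area.
    """

    days: list[int]
    labels: dict[int, np.ndarray]
    records: pd.DataFrame
    centers: dict[int, tuple[float, float]]
    overlap_px: dict[int, int]
    orientation_sign: int
    pixels_per_cm2: float

    def leaf_mask(self, day: int, rank: int) -> np.ndarray:
        return self.labels[day] == rank

    def ranks_on(self, day: int) -> list[int]:
        sub = self.records[self.records["day"] == day]
        return sorted(sub["rank"].tolist())

    def nonoverlapping_days(self) -> list[int]:
        return [d for d in self.days if self.overlap_px[d] == 0]


@dataclass(frozen=True)
class TrackingMetrics:
    """Agreement between reconstructed tracks and scene truth."""

    rank_accuracy: float
    detection_rate: float
    area_mare: float          # mean absolute relative area error on matches
    false_tracks: int
    n_matched: int
    n_assigned: int


def _ellipse_pixels(center_rc: tuple[float, float], angle_deg: float,
                    a: float, b: float, shape: tuple[int, int]
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Pixels of a filled ellipse with semi-axis ``a`` along ``angle_deg``."""
    theta = math.radians(angle_deg)
    u = np.array([-math.sin(theta), math.cos(theta)])   # along-axis, y-up
    v = np.array([-u[1], u[0]])
    pad = int(math.ceil(max(a, b))) + 2
    r0 = int(round(center_rc[0]))
    c0 = int(round(center_rc[1]))
    rmin, rmax = max(r0 - pad, 0), min(r0 + pad, shape[0] - 1)
    cmin, cmax = max(c0 - pad, 0), min(c0 + pad, shape[1] - 1)
    rr, cc = np.mgrid[rmin:rmax + 1, cmin:cmax + 1]
    dr = rr - center_rc[0]
    dc = cc - center_rc[1]
    xa = dr * u[0] + dc * u[1]
    xb = dr * v[0] + dc * v[1]
    inside = (xa / a) ** 2 + (xb / b) ** 2 <= 1.0
    return rr[inside], cc[inside]


def _disk_pixels(center_rc, radius, shape):
    return _ellipse_pixels(center_rc, 0.0, radius, radius, shape)


def render_sequence(spec: GenotypeSpec
                    ) -> tuple[dict[int, PlantImage | None], SceneTruth]:
    """Render the image series and its truth, deterministically per seed."""
    rng = np.random.default_rng(spec.seed)
    emergence = spec.emergence_days()
    n_leaves = len(emergence)
    sign = spec.orientation_sign

    # Placement directions at emergence, before daily rotation. Ranks
    # follow the field convention: leaves 1 and 3 are the members of their
    # pairs whose direction is closest to leaf 5's.
    base = [spec.base_angle_deg, spec.base_angle_deg + 180.0,
            spec.base_angle_deg + 90.0, spec.base_angle_deg + 270.0]
    d5_ideal = base[3] + sign * GOLDEN_ANGLE_DEG
    if circular_distance(d5_ideal, base[0]) > circular_distance(d5_ideal, base[1]):
        base[0], base[1] = base[1], base[0]
    # leaf 3 (at d4 + 180) is automatically the pair member closest to
    # leaf 5 (42.5 vs 137.5 deg), so no swap is needed for the 3/4 pair.
    jitters = rng.normal(0.0, spec.phyllotaxy_jitter_sd_deg, n_leaves)
    directions = []
    for v in range(1, n_leaves + 1):
        if v <= 4:
            ang = base[v - 1]
        elif v == 5:
            ang = d5_ideal
        else:
            ang = directions[-1] + sign * GOLDEN_ANGLE_DEG
        directions.append(ang + jitters[v - 1])

    rotations = rng.normal(0.0, spec.rotation_jitter_sd_deg, spec.n_days)
    if spec.rotation_jitter_max_deg is not None:
        bound = spec.rotation_jitter_max_deg
        rotations = np.clip(rotations, -bound, bound)
    rotations[0] = 0.0
    cum_rot = np.cumsum(rotations)

    m, n = spec.canvas
    center = (m / 2.0, n / 2.0)
    px_per_cm = math.sqrt(spec.pixels_per_cm2)
    shades = rng.integers(-25, 26, n_leaves)

    images: dict[int, PlantImage | None] = {}
    labels: dict[int, np.ndarray] = {}
    centers: dict[int, tuple[float, float]] = {}
    overlap: dict[int, int] = {}
    rows = []
    days = list(range(1, spec.n_days + 1))
    for day in days:
        lab = np.zeros((m, n), dtype=np.uint8)
        srow, scol = _disk_pixels(center, spec.stem_radius_px, (m, n))
        lab[srow, scol] = STEM_LABEL
        overlap_px = 0
        placements = {}
        for v in range(1, n_leaves + 1):
            area = spec.leaf_area_cm2(v, day, emergence[v - 1])
            if area <= 0:
                continue
            area_px = area * spec.pixels_per_cm2
            a = math.sqrt(area_px / (math.pi * spec.aspect_ratio))
            b = spec.aspect_ratio * a
            ang = directions[v - 1] + cum_rot[day - 1]
            # the blade sits beyond a petiole; its inner tip starts where
            # the petiole ends, so blades of different leaves meet only
            # when they genuinely overlap
            petiole_len = spec.petiole_fraction * 2.0 * a
            dist = spec.stem_radius_px + petiole_len + a - 2.0
            theta = math.radians(ang)
            crc = (center[0] - dist * math.sin(theta),
                   center[1] + dist * math.cos(theta))
            rr, cc = _ellipse_pixels(crc, ang, a, b, (m, n))
            if petiole_len > 0:
                # thin petiole from the stem edge to the blade's inner tip
                half = (petiole_len + 4.0) / 2.0
                mid_dist = spec.stem_radius_px - 1.0 + half
                mid = (center[0] - mid_dist * math.sin(theta),
                       center[1] + mid_dist * math.cos(theta))
                prr, pcc = _ellipse_pixels(mid, ang, half,
                                           max(2.0, 0.08 * b), (m, n))
                rr = np.concatenate([rr, prr])
                cc = np.concatenate([cc, pcc])
            taken = lab[rr, cc]
            # overlap = occlusion between leaves away from the insertion
            # zone (all petioles converge at the stem by construction)
            central = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= \
                (spec.stem_radius_px + 3.0) ** 2
            overlap_px += int(((taken > 0) & (taken != STEM_LABEL)
                               & ~central).sum())
            lab[rr, cc] = v          # younger leaves drawn on top
            placements[v] = ang % 360.0
        labels[day] = lab
        overlap[day] = overlap_px
        fg = lab > 0
        ctr = mass_center(fg)
        centers[day] = ctr
        for v, ang in placements.items():
            rr, cc = np.nonzero(lab == v)
            if rr.size == 0:
                continue
            seg = Segment(rr, cc, day=day, index=v)
            obs = measure_segment(seg, ctr, spec.pixels_per_cm2)
            rows.append({
                "day": day, "rank": v,
                "placement_angle_deg": ang,
                "angle_deg": obs.angle_deg,
                "extremity_px": obs.extremity_px,
                "area_cm2": obs.area_cm2,
                "n_pixels": obs.n_pixels,
            })
        if spec.render_rgb:
            rgb = np.zeros((m, n, 3), dtype=np.uint8)
            stem = lab == STEM_LABEL
            rgb[stem] = (30, 90, 40)
            for v in placements:
                where = lab == v
                g = np.clip(150 + shades[v - 1], 60, 230)
                rgb[where] = (45, g, 70)
            images[day] = PlantImage(rgb, day_index=day,
                                     pixels_per_cm2=spec.pixels_per_cm2)
        else:
            images[day] = None

    truth = SceneTruth(
        days=days, labels=labels,
        records=pd.DataFrame(rows), centers=centers, overlap_px=overlap,
        orientation_sign=sign, pixels_per_cm2=spec.pixels_per_cm2,
    )
    return images, truth


def truth_observations(truth: SceneTruth, day: int
                       ) -> tuple[list[LeafObservation], list[int]]:
    """Per-day observations built directly from the truth masks.

    Returns the observation list (segment_index = position) and the
    parallel list of true ranks; lets the tracker be exercised without
    running the segmentation.
    """
    obs_list, ranks = [], []
    ctr = truth.centers[day]
    for i, rank in enumerate(truth.ranks_on(day)):
        rr, cc = np.nonzero(truth.labels[day] == rank)
        seg = Segment(rr, cc, day=day, index=i)
        obs_list.append(measure_segment(seg, ctr, truth.pixels_per_cm2))
        ranks.append(rank)
    return obs_list, ranks


def measure_day(segments: Sequence[Segment], center: tuple[float, float],
                pixels_per_cm2: float = DEFAULT_PIXELS_PER_CM2
                ) -> list[LeafObservation]:
    """Measure a day's segments with positional segment indices."""
    out = []
    for i, seg in enumerate(segments):
        seg.index = i
        out.append(measure_segment(seg, center, pixels_per_cm2))
    return out


def generate_area_dataset(params: GrowthParams, env: Environment,
                          noise_cv: float = 0.02, missing_rate: float = 0.0,
                          seed: int = 0, sample_every_h: int = 24,
                          horizon_h: int | None = None, genotype: str = ""
                          ) -> tuple[ObservationSet, pd.DataFrame]:
    """Noisy daily leaf-area table from the growth model, plus its truth.

    Simulated areas are sampled every ``sample_every_h`` hours, multiplied
    by (1 + eps) with eps ~ N(0, noise_cv^2), and dropped independently
    at ``missing_rate``; all randomness flows from ``seed``.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    horizon = int(horizon_h if horizon_h is not None else env.n_hours)
    sim = simulate(params, env, horizon)
    hours = np.arange(sample_every_h, horizon + 1, sample_every_h)

    recs = []
    for t in hours:
        for v in range(1, sim.n_leaves + 1):
            if sim.appearance_h[v - 1] <= t and sim.areas[v - 1, t] > 0:
                recs.append((int(t), v, float(sim.areas[v - 1, t])))
    frame = pd.DataFrame(recs, columns=["hour", "rank", "area_true_cm2"])
    eps = rng.normal(0.0, noise_cv, len(frame)) if noise_cv > 0 else np.zeros(len(frame))
    frame["area_cm2"] = frame["area_true_cm2"] * (1.0 + eps)
    if missing_rate > 0:
        keep = rng.random(len(frame)) >= missing_rate
        frame = frame[keep].reset_index(drop=True)
    frame = frame[frame["area_cm2"] > 0].reset_index(drop=True)
    obs = ObservationSet(frame["hour"].to_numpy(), frame["rank"].to_numpy(),
                         frame["area_cm2"].to_numpy(), genotype=genotype)
    return obs, frame


def evaluate_tracking(result: TrackingResult | Sequence[LeafTrack],
                      truth: SceneTruth,
                      daily_segments: Mapping[int, Sequence[Segment]],
                      iou_threshold: float = 0.5) -> TrackingMetrics:
    """Score reconstructed tracks against the scene truth by mask IoU.

    Each accepted (day, segment) assignment is matched to the truth leaf
    with maximal IoU on that day, provided the IoU reaches the
    threshold. Rank accuracy is the fraction of matched assignments
    whose track rank equals the truth rank; the detection rate is the
    fraction of (day, truth leaf) instances covered by a matched
    assignment; the area error is the mean absolute relative error over
    matches; a track is counted false when fewer than half of its
    assignments match any truth leaf.
    """
    tracks = list(result)
    n_assigned = n_matched = rank_ok = 0
    area_errs = []
    covered: set[tuple[int, int]] = set()
    false_tracks = 0
    for tr in tracks:
        matched_here = 0
        for day, obs in tr.entries:
            n_assigned += 1
            segs = daily_segments[day]
            seg = segs[obs.segment_index]
            lab = truth.labels[day]
            vals = lab[seg.rows, seg.cols]
            best_rank, best_iou = 0, 0.0
            for rank in truth.ranks_on(day):
                inter = int((vals == rank).sum())
                if inter == 0:
                    continue
                union = seg.n_pixels + int((lab == rank).sum()) - inter
                iou = inter / union
                if iou > best_iou:
                    best_rank, best_iou = rank, iou
            if best_iou >= iou_threshold:
                n_matched += 1
                matched_here += 1
                covered.add((day, best_rank))
                if best_rank == tr.rank:
                    rank_ok += 1
                true_area = float(
                    truth.records.query("day == @day and rank == @best_rank")
                    ["area_cm2"].iloc[0]
                )
                area_errs.append(abs(obs.area_cm2 - true_area) / true_area)
        if tr.entries and matched_here < 0.5 * len(tr.entries):
            false_tracks += 1

    n_truth = len(truth.records)
    return TrackingMetrics(
        rank_accuracy=rank_ok / n_matched if n_matched else 0.0,
        detection_rate=len(covered) / n_truth if n_truth else 0.0,
        area_mare=float(np.mean(area_errs)) if area_errs else 0.0,
        false_tracks=false_tracks,
        n_matched=n_matched,
        n_assigned=n_assigned,
    )
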