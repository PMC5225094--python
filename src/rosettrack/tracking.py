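"""Reconstruct per-rank leaf histories from daily segment measurements.

Each tracked leaf keeps its history of (day, observation) pairs, possibly
with gaps. On every new day each track scores every candidate segment

    s = gamma_d * s_d + gamma_e * s_e + gamma_a * s_a

where s_d is 1 when the candidate direction lies within a tolerance
delta_d of the leaf's last direction and 0 otherwise, and s_e, s_a are
sup-normalised Gaussian scores of the candidate extremity distance and
area against expectations extrapolated from the track (a 4-parameter
sigmoid through the last four observations when available, otherwise
fixed multiplicative fallbacks). A candidate is only accepted when its
score strictly exceeds a safety score s0; with the default weights
(10, 1, 1) and s0 = 11 a candidate must match the direction window and be
reasonably close in extremity and area.

First occurrences follow the rosette's phyllotaxy: the two cotyledons
(opposite directions) are given on day 1, the first true-leaf pair
appears perpendicular to them and mutually opposite, leaf 5 opens the
spiral, and every later leaf is expected one golden angle (137.5 deg)
beyond its predecessor, clockwise or counter-clockwise depending on the
plant.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .geometry import circular_distance, circular_mean, wrap_deg
from .imaging import LeafObservation

logger = logging.getLogger(__name__)

GOLDEN_ANGLE_DEG = 137.5

__all__ = [
    "GOLDEN_ANGLE_DEG",
    "TrackingConfig",
    "LeafTrack",
    "SigmoidFit",
    "Expectations",
    "ScoreBreakdown",
    "TrackingResult",
    "direction_score",
    "gaussian_score",
    "fit_sigmoid",
    "predict_expectations",
    "score_candidate",
    "assign_next_day",
    "detect_new_leaf",
    "track_series",
    "tracks_to_frame",
]


@dataclass
class TrackingConfig:
    """Score weights, windows and fallback rules for the tracker."""

    gamma_d: float = 10.0
    gamma_e: float = 1.0
    gamma_a: float = 1.0
    safety_score: float = 11.0
    direction_tolerance_deg: float = 30.0
    phyllotaxy_angle_deg: float = GOLDEN_ANGLE_DEG
    #: |d3 - d1| and |d3 - d2| must exceed this when first finding leaf 3.
    leaf34_separation_deg: float = 60.0
    #: fallback means when fewer than 4 observations exist
    fallback_extremity_factor: float = 1.2
    fallback_area_factor: float = 2.0
    #: spreads, always taken from the last observed values
    sigma_extremity_factor: float = 0.5
    sigma_area_factor: float = 2.0

    def __post_init__(self):
        if min(self.gamma_d, self.gamma_e, self.gamma_a) <= 0:
            raise ValueError("score weights must be positive")
        if not 0 < self.direction_tolerance_deg < 180:
            raise ValueError("direction tolerance must lie in (0, 180)")
        if self.safety_score >= self.gamma_d + self.gamma_e + self.gamma_a:
            raise ValueError(
                "safety score must be below the maximum achievable score"
            )


@dataclass
class LeafTrack:
    """History of one leaf: ordered (day, observation) pairs with gaps."""

    rank: int
    entries: list[tuple[int, LeafObservation]] = field(default_factory=list)
    scores: dict[int, "ScoreBreakdown"] = field(default_factory=dict)

    def add(self, day: int, obs: LeafObservation,
            score: "ScoreBreakdown | None" = None) -> None:
        if self.entries and day <= self.entries[-1][0]:
            raise ValueError("days must be strictly increasing within a track")
        self.entries.append((day, obs))
        if score is not None:
            self.scores[day] = score

    @property
    def days(self) -> list[int]:
        return [d for d, _ in self.entries]

    @property
    def first_day(self) -> int:
        return self.entries[0][0]

    @property
    def last_observation(self) -> LeafObservation:
        return self.entries[-1][1]

    @property
    def last_angle(self) -> float:
        return self.entries[-1][1].angle_deg

    @property
    def first_angle(self) -> float:
        return self.entries[0][1].angle_deg

    def mean_angle(self) -> float:
        return circular_mean([o.angle_deg for _, o in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class SigmoidFit:
    """4-parameter logistic s(x) = y0 + y1 / (1 + exp(-k (x - x0)))."""

    k: float
    x0: float
    y0: float
    y1: float
    residual_norm: float

    def __call__(self, x):
        z = np.clip(-self.k * (np.asarray(x, dtype=float) - self.x0), -500, 500)
        val = self.y0 + self.y1 / (1.0 + np.exp(z))
        if np.ndim(x) == 0:
            return float(val)
        return val


@dataclass(frozen=True)
class Expectations:
    """Predicted mean/spread of extremity (px) and area (cm^2)."""

    mu_e: float
    sigma_e: float
    mu_a: float
    sigma_a: float

    def __post_init__(self):
        if min(self.mu_e, self.sigma_e, self.mu_a, self.sigma_a) <= 0:
            raise ValueError("expectations must be positive")


@dataclass(frozen=True)
class ScoreBreakdown:
    s_d: float
    s_e: float
    s_a: float
    total: float
    candidate_index: int = -1


def direction_score(candidate_angle: float, last_angle: float,
                    tolerance_deg: float) -> float:
    """Normalised uniform-window score: 1 inside +-tolerance, else 0.

    This is the uniform density on [last - tol, last + tol] times its
    window width; the window is inclusive at both endpoints and the
    difference is evaluated circularly.
    """
    return 1.0 if circular_distance(candidate_angle, last_angle) <= tolerance_deg else 0.0


def gaussian_score(x: float, mu: float, sigma: float) -> float:
    """Normal density at x divided by its supremum: exp(-(x-mu)^2/(2 sigma^2))."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-((x - mu) ** 2) / (2.0 * sigma ** 2)))


def fit_sigmoid(times: Sequence[float], values: Sequence[float]) -> SigmoidFit:
    """Least-squares logistic through the last four (time, value) pairs.

    Requires at least four pairs and uses exactly the last four.
    Initialisation is deterministic (y0 = min, y1 = range, x0 = median
    time, k = 1); k, y0, y1 are bounded below by 0 so extrapolation stays
    finite and non-decreasing.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 4:
        raise ValueError("sigmoid fit needs at least 4 observations")
    t = times[-4:]
    v = values[-4:]

    span = float(v.max() - v.min())
    x0_init = float(np.median(t))
    p0 = np.array([1.0, x0_init, float(v.min()), max(span, 1e-8)])
    lo = np.array([0.0, t.min() - 50.0, 0.0, 0.0])
    hi = np.array([10.0, t.max() + 50.0, max(v.max(), 1e-8) * 2.0 + 1e-8, np.inf])

    def resid(p):
        k, x0, y0, y1 = p
        z = np.clip(-k * (t - x0), -500, 500)
        return y0 + y1 / (1.0 + np.exp(z)) - v

    sol = least_squares(resid, np.clip(p0, lo, hi), bounds=(lo, hi), method="trf")
    k, x0, y0, y1 = sol.x
    return SigmoidFit(float(k), float(x0), float(y0), float(y1),
                      float(np.linalg.norm(sol.fun)))


def predict_expectations(track: LeafTrack, next_day: int,
                         config: TrackingConfig | None = None) -> Expectations:
    """Expected extremity/area of a track on ``next_day``.

    With four or more observations the means come from sigmoid fits
    through the last four (using their actual, possibly non-consecutive,
    days); otherwise mu_e = 1.2 e and mu_a = 2 a from the last observed
    values. The spreads always use the last observed values:
    sigma_e = e / 2 and sigma_a = 2 a. A degenerate or non-positive
    sigmoid extrapolation falls back to the multiplicative rule.
    """
    config = config or TrackingConfig()
    if len(track) == 0:
        raise ValueError("cannot predict from an empty track")
    last = track.last_observation
    e_last, a_last = last.extremity_px, last.area_cm2

    mu_e = config.fallback_extremity_factor * e_last
    mu_a = config.fallback_area_factor * a_last
    if len(track) >= 4:
        days = np.array(track.days, dtype=float)
        es = np.array([o.extremity_px for _, o in track.entries])
        aa = np.array([o.area_cm2 for _, o in track.entries])
        pe = fit_sigmoid(days, es)(next_day)
        pa = fit_sigmoid(days, aa)(next_day)
        if np.isfinite(pe) and pe > 0:
            mu_e = float(pe)
        if np.isfinite(pa) and pa > 0:
            mu_a = float(pa)
    return Expectations(
        mu_e=mu_e,
        sigma_e=config.sigma_extremity_factor * e_last,
        mu_a=mu_a,
        sigma_a=config.sigma_area_factor * a_last,
    )


def score_candidate(candidate: LeafObservation, track: LeafTrack,
                    expectations: Expectations,
                    config: TrackingConfig | None = None) -> ScoreBreakdown:
    """Weighted direction + extremity + area score of a candidate segment."""
    config = config or TrackingConfig()
    s_d = direction_score(candidate.angle_deg, track.last_angle,
                          config.direction_tolerance_deg)
    s_e = gaussian_score(candidate.extremity_px, expectations.mu_e,
                         expectations.sigma_e)
    s_a = gaussian_score(candidate.area_cm2, expectations.mu_a,
                         expectations.sigma_a)
    total = config.gamma_d * s_d + config.gamma_e * s_e + config.gamma_a * s_a
    return ScoreBreakdown(s_d, s_e, s_a, total, candidate.segment_index)


def assign_next_day(tracks: Sequence[LeafTrack],
                    day_observations: Sequence[LeafObservation], day: int,
                    config: TrackingConfig | None = None
                    ) -> list[LeafObservation]:
    """Assign the day's segments to existing tracks; return the leftovers.

    Every (track, candidate) pair is scored; pairs are accepted in order
    of descending score, skipping tracks and segments already taken, and
    only while the score strictly exceeds the safety score. A track with
    no admissible candidate records a gap (simply no entry for the day).
    """
    config = config or TrackingConfig()
    live = [tr for tr in tracks if len(tr) > 0 and tr.first_day < day]
    if not live or not day_observations:
        return list(day_observations)

    scored = []
    for ti, tr in enumerate(live):
        exp = predict_expectations(tr, day, config)
        for ci, cand in enumerate(day_observations):
            br = score_candidate(cand, tr, exp, config)
            scored.append((br.total, ti, ci, br))
    scored.sort(key=lambda x: -x[0])

    taken_tracks: set[int] = set()
    taken_cands: set[int] = set()
    for total, ti, ci, br in scored:
        if total <= config.safety_score:
            break
        if ti in taken_tracks or ci in taken_cands:
            continue
        live[ti].add(day, day_observations[ci], br)
        taken_tracks.add(ti)
        taken_cands.add(ci)
    return [c for i, c in enumerate(day_observations) if i not in taken_cands]


def detect_new_leaf(unassigned: Sequence[LeafObservation],
                    expected_direction: float,
                    config: TrackingConfig | None = None,
                    max_area_cm2: float | None = None
                    ) -> LeafObservation | None:
    """First occurrence of a new leaf near an expected direction.

    Among unassigned segments whose angle lies within the direction
    tolerance of ``expected_direction``, the one closest to the plant
    center (smallest extremity) is returned — young leaves emerge near
    the rosette center. ``max_area_cm2`` additionally rejects segments
    larger than the previously emerged leaf: a first occurrence is always
    the youngest, hence smallest, leaf of the rosette, and without the
    bound an old leaf whose own track missed a day could masquerade as a
    new one. ``None`` if no segment qualifies.
    """
    config = config or TrackingConfig()
    cands = [
        o for o in unassigned
        if circular_distance(o.angle_deg, expected_direction)
        <= config.direction_tolerance_deg
        and (max_area_cm2 is None or o.area_cm2 < max_area_cm2)
    ]
    if not cands:
        return None
    return min(cands, key=lambda o: o.extremity_px)


@dataclass
class TrackingResult:
    """Tracks ordered by rank plus the inferred phyllotaxy orientation.

    ``orientation_sign`` is +1 for counter-clockwise spirals (angles
    increase by the golden angle from leaf to leaf) and -1 for clockwise;
    0 if leaf 5 was never found.
    """

    tracks: list[LeafTrack]
    orientation_sign: int = 0

    @property
    def orientation(self) -> str:
        return {1: "counter_clockwise", -1: "clockwise", 0: "unknown"}[
            self.orientation_sign
        ]

    def by_rank(self, rank: int) -> LeafTrack:
        for tr in self.tracks:
            if tr.rank == rank:
                return tr
        raise KeyError(f"no track with rank {rank}")

    def __iter__(self):
        return iter(self.tracks)

    def __len__(self):
        return len(self.tracks)

    def __getitem__(self, i):
        return self.tracks[i]


def _pick_leaf3(unassigned, t1, t2, config):
    sep = config.leaf34_separation_deg
    cands = [
        o for o in unassigned
        if circular_distance(o.angle_deg, t1.last_angle) > sep
        and circular_distance(o.angle_deg, t2.last_angle) > sep
    ]
    if not cands:
        return None
    return min(cands, key=lambda o: o.extremity_px)


def track_series(daily_observations: Mapping[int, Sequence[LeafObservation]],
                 config: TrackingConfig | None = None,
                 strict_day1: bool = True) -> TrackingResult:
    """Run the full multi-day tracking strategy.

    ``daily_observations`` maps day index to the measured segments of that
    day. Day 1 must contain exactly two segments (the opened cotyledons);
    with ``strict_day1=False`` a different count is tolerated and the two
    segments closest to the center seed the cotyledon tracks.

    The strategy: leaf 1 is an arbitrary day-1 segment and leaf 2 the one
    opposite it; leaf 3 first appears at least ``leaf34_separation_deg``
    away from both cotyledons and leaf 4 opposite leaf 3; leaf 5 is the
    next new leaf regardless of direction. Once leaf 5 exists, cotyledons
    and first true leaves are relabelled so that leaves 1 and 3 are the
    ones with mean direction closest to leaf 5's, the spiral orientation
    is the sign of the wrapped angle from leaf 4 to leaf 5, and leaf 5+j
    is expected one golden angle per rank beyond leaf 5's latest
    direction. All tracks, gapped or not, compete for segments every day.
    """
    config = config or TrackingConfig()
    days = sorted(daily_observations)
    if not days:
        return TrackingResult([], 0)
    day1 = days[0]
    first = list(daily_observations[day1])
    if len(first) != 2:
        if strict_day1:
            raise ValueError(
                f"day {day1} must contain exactly 2 segments (cotyledons), "
                f"got {len(first)}"
            )
        first = sorted(first, key=lambda o: o.extremity_px)[:2]
        if len(first) < 2:
            raise ValueError("cannot seed cotyledon tracks")

    t1 = LeafTrack(rank=1)
    t1.add(day1, first[0])
    # leaf 2: the segment opposite leaf 1
    other = detect_new_leaf(first[1:], t1.last_angle + 180.0, config)
    if other is None:
        logger.warning("second day-1 segment is not opposite the first; "
                       "seeding leaf 2 with it anyway")
        other = first[1]
    t2 = LeafTrack(rank=2)
    t2.add(day1, other)

    tracks: list[LeafTrack] = [t1, t2]
    t3 = t4 = t5 = None
    orientation_sign = 0
    next_spiral_rank = 6

    for day in days[1:]:
        unassigned = assign_next_day(tracks, daily_observations[day], day, config)
        while unassigned:
            cand = None
            if t3 is None:
                cand = _pick_leaf3(unassigned, t1, t2, config)
                if cand is not None:
                    t3 = LeafTrack(rank=3)
                    t3.add(day, cand)
                    tracks.append(t3)
            elif t4 is None:
                cand = detect_new_leaf(unassigned, t3.last_angle + 180.0, config)
                if cand is not None:
                    t4 = LeafTrack(rank=4)
                    t4.add(day, cand)
                    tracks.append(t4)
            elif t5 is None:
                if day <= t4.first_day:
                    break  # leaf 5 emerges after the first true-leaf pair
                # a first occurrence is the youngest leaf: smaller than
                # the true-leaf pair it follows
                limit = min(t3.last_observation.area_cm2,
                            t4.last_observation.area_cm2)
                small = [o for o in unassigned if o.area_cm2 < limit]
                if not small:
                    break
                cand = min(small, key=lambda o: o.extremity_px)
                t5 = LeafTrack(rank=5)
                t5.add(day, cand)
                tracks.append(t5)
                # Relabel cotyledons and first true leaves relative to leaf 5
                # (labels only; the physical histories are untouched).
                d5 = t5.mean_angle()
                if circular_distance(d5, t1.mean_angle()) > circular_distance(
                        d5, t2.mean_angle()):
                    t1.rank, t2.rank = 2, 1
                    t1, t2 = t2, t1
                if circular_distance(d5, t3.mean_angle()) > circular_distance(
                        d5, t4.mean_angle()):
                    t3.rank, t4.rank = 4, 3
                    t3, t4 = t4, t3
                orientation_sign = 1 if wrap_deg(
                    t5.first_angle - t4.last_angle) > 0 else -1
            else:
                j = next_spiral_rank - 5
                expected = t5.last_angle + j * orientation_sign * \
                    config.phyllotaxy_angle_deg
                prev = next(tr for tr in tracks
                            if tr.rank == next_spiral_rank - 1)
                cand = detect_new_leaf(unassigned, expected, config,
                                       max_area_cm2=prev.last_observation.area_cm2)
                if cand is not None:
                    tr = LeafTrack(rank=next_spiral_rank)
                    tr.add(day, cand)
                    tracks.append(tr)
                    next_spiral_rank += 1
            if cand is None:
                break
            unassigned = [o for o in unassigned if o is not cand]

    tracks.sort(key=lambda tr: tr.rank)
    return TrackingResult(tracks, orientation_sign)


def tracks_to_frame(result: TrackingResult | Sequence[LeafTrack],
                    days: Sequence[int] | None = None) -> pd.DataFrame:
    """Tidy per-day track table; gap days appear with empty segment_id."""
    tracks = list(result)
    if days is None:
        all_days = sorted({d for tr in tracks for d in tr.days})
    else:
        all_days = sorted(days)
    rows = []
    for tr in tracks:
        by_day = dict(tr.entries)
        for day in all_days:
            if day < tr.first_day:
                continue
            obs = by_day.get(day)
            score = tr.scores.get(day)
            rows.append({
                "day": day,
                "rank": tr.rank,
                "segment_id": (obs.segment_index + 1) if obs else pd.NA,
                "angle_deg": obs.angle_deg if obs else np.nan,
                "extremity_cm": obs.extremity_cm if obs else np.nan,
                "area_cm2": obs.area_cm2 if obs else np.nan,
                "score_total": score.total if score else np.nan,
                "score_d": score.s_d if score else np.nan,
                "score_e": score.s_e if score else np.nan,
                "score_a": score.s_a if score else np.nan,
                "accepted": obs is not None,
            })
    return pd.DataFrame(rows)
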