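"""Organ-scale source-sink model of rosette growth.

The rosette is the only compartment: leaves appear on a fixed schedule
(the two cotyledon and first-true-leaf pairs at known times, later leaves
every phyllochron), the whole plant produces biomass hourly from
intercepted radiation through a Beer-Lambert saturation of the leaf-area
index,

    q(t) = r(t) * mu * s * (1 - exp(-(k / (e * s)) * sum_v Q_v(t-1))),

and the produced pool is shared among leaves proportionally to their sink
demands — sup-normalised lognormal functions of thermal age, with one
(mu1, sigma1) law for the four preformed leaves and a second (mu2,
sigma2) law scaled by an intensity ratio rho for all later leaves.
Cumulative leaf biomass divided by the leaf mass per area e gives each
leaf's area. There is no senescence: biomasses and areas only grow.

Units: hours for time, degC*h for thermal time, grams for biomass,
cm^2 for areas, MJ cm^-2 h^-1 for radiation, g MJ^-1 for the radiation
use efficiency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Energy content of photosynthetically active photons (J per umol),
#: used to convert the platform's umol m^-2 s^-1 set point.
JOULE_PER_UMOL = 0.2188

__all__ = [
    "Environment",
    "GrowthParams",
    "SimulationResult",
    "thermal_time",
    "leaf_schedule",
    "production",
    "demands",
    "allocate",
    "simulate",
]


@dataclass
class Environment:
    """Hourly radiation and temperature series.

    ``radiation`` is in MJ per cm^2 of ground per hour, ``temperature``
    in degC; index 0 is hour 1. ``base_temperature`` enters the thermal
    time as sum of max(0, T - base).
    """

    radiation: np.ndarray
    temperature: np.ndarray
    base_temperature: float = 0.0

    def __post_init__(self):
        self.radiation = np.asarray(self.radiation, dtype=float).ravel()
        self.temperature = np.asarray(self.temperature, dtype=float).ravel()
        if self.radiation.shape != self.temperature.shape:
            raise ValueError("radiation and temperature must be equally long")
        if (self.radiation < 0).any():
            raise ValueError("radiation must be non-negative")

    @property
    def n_hours(self) -> int:
        return int(self.radiation.size)

    @classmethod
    def constant_photoperiod(cls, n_hours: int, photoperiod_h: float = 8.0,
                             day_radiation_umol: float = 350.0,
                             day_temp_c: float = 21.0,
                             night_temp_c: float = 18.0,
                             base_temperature: float = 0.0,
                             joule_per_umol: float = JOULE_PER_UMOL
                             ) -> "Environment":
        """Growth-chamber style environment: fixed photoperiod, two set points.

        The light-phase radiation set point (umol m^-2 s^-1 of PAR) is
        converted to MJ cm^-2 h^-1 via the energy-per-photon factor.
        """
        hour_of_day = np.arange(n_hours) % 24
        light = hour_of_day < photoperiod_h
        # umol m^-2 s^-1 -> MJ cm^-2 h^-1: * 3600 s/h * J/umol * 1e-6 MJ/J * 1e-4 m^2/cm^2
        r_light = day_radiation_umol * 3600.0 * joule_per_umol * 1e-10
        radiation = np.where(light, r_light, 0.0)
        temperature = np.where(light, day_temp_c, night_temp_c)
        return cls(radiation, temperature, base_temperature)

    def thermal_time_series(self) -> np.ndarray:
        """Cumulative thermal time tau(t) for t = 1..n_hours (degC*h)."""
        cached = getattr(self, "_tau_cache", None)
        if cached is None:
            cached = np.cumsum(
                np.maximum(self.temperature - self.base_temperature, 0.0))
            object.__setattr__(self, "_tau_cache", cached)
        return cached

    def thermal_time_at(self, t: float) -> float:
        """tau at a possibly fractional hour t >= 0 (linear within the hour)."""
        if t <= 0:
            return 0.0
        tau = self.thermal_time_series()
        i = int(math.floor(t))
        i = min(i, self.n_hours)
        base = tau[i - 1] if i >= 1 else 0.0
        frac = t - i
        if frac > 0 and i < self.n_hours:
            base += frac * max(self.temperature[i] - self.base_temperature, 0.0)
        return float(base)


@dataclass
class GrowthParams:
    """Parameters of the source-sink model.

    The estimable subset is (phyllochron_h, leaf_mass_per_area,
    mu1, sigma1, mu2, sigma2, rho, seed_biomass); radiation use
    efficiency, ground area and the Beer-Lambert coefficient are treated
    as fixed inputs, as are the appearance times of the four preformed
    leaves and of leaf 5.
    """

    phyllochron_h: float = 40.0
    leaf_mass_per_area: float = 0.002     # g cm^-2
    mu1: float = 8.0                      # lognormal log-mean, preformed leaves
    sigma1: float = 0.6
    mu2: float = 8.5                      # lognormal log-mean, later leaves
    sigma2: float = 0.8
    rho: float = 1.2                      # sink intensity of later leaves
    seed_biomass: float = 2e-5            # g
    rue: float = 3.5                      # g MJ^-1
    ground_area_cm2: float = 50.0
    beer_lambert_k: float = 0.9
    appearance_h_leaves12: float = 0.0
    appearance_h_leaves34: float = 48.0
    appearance_h_leaf5: float = 96.0
    #: if True, q0 goes entirely to the cotyledons in proportion to their
    #: demands at first light rather than as an equal split at hour 0.
    q0_to_cotyledons: bool = False

    ESTIMABLE = ("phyllochron_h", "leaf_mass_per_area", "mu1", "sigma1",
                 "mu2", "sigma2", "rho", "seed_biomass")

    def __post_init__(self):
        for name in ("phyllochron_h", "leaf_mass_per_area", "sigma1",
                     "sigma2", "rho", "seed_biomass", "rue",
                     "ground_area_cm2", "beer_lambert_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def theta(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in self.ESTIMABLE], dtype=float)

    def with_theta(self, theta) -> "GrowthParams":
        return replace(self, **dict(zip(self.ESTIMABLE, map(float, theta))))

    def appearance_times(self, horizon_h: float) -> np.ndarray:
        """Appearance hour of every leaf appearing within the horizon."""
        times = [self.appearance_h_leaves12, self.appearance_h_leaves12,
                 self.appearance_h_leaves34, self.appearance_h_leaves34]
        t = self.appearance_h_leaf5
        while t <= horizon_h:
            times.append(t)
            t += self.phyllochron_h
        return np.asarray(times, dtype=float)


def thermal_time(env: Environment, t: int) -> float:
    """Accumulated growing degree hours up to hour t."""
    if t <= 0:
        return 0.0
    return float(env.thermal_time_series()[min(t, env.n_hours) - 1])


def leaf_schedule(params: GrowthParams, env: Environment, t: float
                  ) -> tuple[int, np.ndarray]:
    """Leaf count n(t) and emergence thermal times of the appeared leaves.

    A leaf is counted from its appearance hour inclusive. Leaves 1-4
    appear in pairs at their given times; leaf 5 + j appears at the
    leaf-5 time plus j phyllochrons.
    """
    times = params.appearance_times(max(t, params.appearance_h_leaf5))
    appeared = times <= t
    tau_v = np.array([env.thermal_time_at(x) for x in times[appeared]])
    return int(appeared.sum()), tau_v


def production(total_biomass: float, radiation: float,
               params: GrowthParams) -> float:
    """Hourly biomass production from the previous hour's total biomass.

    Beer-Lambert interception on the leaf-area index: the plant's leaf
    area is total biomass / e spread over the ground area s.
    """
    lai_term = params.beer_lambert_k / (
        params.leaf_mass_per_area * params.ground_area_cm2
    ) * total_biomass
    return radiation * params.rue * params.ground_area_cm2 * (
        1.0 - math.exp(-lai_term)
    )


def _lognormal_relative(x: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Lognormal pdf at x divided by its supremum; zero for x <= 0.

    The pdf peaks at the mode exp(mu - sigma^2), so the ratio lies in
    [0, 1] with 1 attained exactly at the mode.
    """
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    if pos.any():
        xp = x[pos]
        log_pdf = -np.log(xp) - (np.log(xp) - mu) ** 2 / (2.0 * sigma ** 2)
        mode = math.exp(mu - sigma ** 2)
        log_pdf_max = -math.log(mode) - (math.log(mode) - mu) ** 2 / (2.0 * sigma ** 2)
        out[pos] = np.exp(log_pdf - log_pdf_max)
    return out


def demands(thermal_ages: np.ndarray, params: GrowthParams) -> np.ndarray:
    """Sink demands of the appeared leaves from their thermal ages.

    Leaf ranks are positional: the first four entries use the preformed
    law (mu1, sigma1), the rest the later-leaf law (mu2, sigma2) scaled
    by rho.
    """
    ages = np.asarray(thermal_ages, dtype=float)
    d = np.empty_like(ages)
    n_pre = min(4, ages.size)
    d[:n_pre] = _lognormal_relative(ages[:n_pre], params.mu1, params.sigma1)
    if ages.size > 4:
        d[4:] = params.rho * _lognormal_relative(ages[4:], params.mu2, params.sigma2)
    return d


def allocate(q: float, demand: np.ndarray) -> np.ndarray:
    """Share the produced biomass proportionally to demands.

    All-zero demands leave everything unallocated (zero shares); the sum
    of shares equals q exactly otherwise.
    """
    demand = np.asarray(demand, dtype=float)
    if (demand < 0).any():
        raise ValueError("demands must be non-negative")
    if q < 0:
        raise ValueError("cannot allocate negative biomass")
    total = demand.sum()
    if total == 0.0:
        if q > 0:
            logger.debug("all demands zero: %.3g g left unallocated", q)
        return np.zeros_like(demand)
    return demand / total * q


@dataclass
class SimulationResult:
    """Hourly per-leaf biomass and area trajectories.

    ``biomass[v, t]`` is Q_{v+1} after hour ``t`` (column 0 = initial
    state at hour 0), ``areas = biomass / e``. ``produced[t-1]`` is
    q(t); ``unallocated`` accumulates production lost to all-zero demand
    hours (zero in normal runs).
    """

    hours: np.ndarray
    appearance_h: np.ndarray
    biomass: np.ndarray
    areas: np.ndarray
    produced: np.ndarray
    unallocated: float

    @property
    def n_leaves(self) -> int:
        return int(self.biomass.shape[0])

    def leaf_count(self, t: int) -> int:
        return int((self.appearance_h <= t).sum())

    def area_at(self, rank: int, t: int) -> float:
        return float(self.areas[rank - 1, t])

    def to_frame(self, stride: int = 1) -> pd.DataFrame:
        """Tidy (hour, rank, biomass_g, area_cm2) table for appeared leaves."""
        rows = []
        for t in self.hours[::stride]:
            for v in range(self.n_leaves):
                if self.appearance_h[v] <= t:
                    rows.append((int(t), v + 1, self.biomass[v, t],
                                 self.areas[v, t]))
        return pd.DataFrame(rows, columns=["hour", "rank", "biomass_g",
                                           "area_cm2"])


def simulate(params: GrowthParams, env: Environment,
             horizon_h: int | None = None) -> SimulationResult:
    """Run the hourly source-sink loop over the horizon.

    Each hour: update the leaf schedule, produce biomass from the
    previous hour's total via Beer-Lambert interception, evaluate the
    lognormal demands at the leaves' thermal ages, allocate
    proportionally and accumulate. The seed biomass q0 is the initial
    pool at hour 0, split equally between the initially present leaves
    (demands are all exactly zero at zero thermal age).
    """
    horizon = int(horizon_h if horizon_h is not None else env.n_hours)
    if horizon < 1:
        raise ValueError("horizon must be at least one hour")
    if horizon > env.n_hours:
        raise ValueError("environment series shorter than the horizon")

    appear = params.appearance_times(horizon)
    n_max = appear.size
    tau = env.thermal_time_series()
    tau_v = np.array([env.thermal_time_at(x) for x in appear])

    initial = appear <= 0
    Q0 = np.zeros(n_max)
    if not params.q0_to_cotyledons and initial.any():
        Q0[initial] = params.seed_biomass / initial.sum()
    seed_pool = params.seed_biomass if params.q0_to_cotyledons else 0.0

    # Demand matrix: leaf v's demand at hour t depends only on thermal age.
    ages = tau[None, :horizon] - tau_v[:, None]
    D = np.empty_like(ages)
    D[:4] = _lognormal_relative(ages[:4], params.mu1, params.sigma1)
    if n_max > 4:
        D[4:] = params.rho * _lognormal_relative(ages[4:], params.mu2,
                                                 params.sigma2)
    appeared = appear[:, None] <= np.arange(1, horizon + 1)[None, :]
    D = np.where(appeared, D, 0.0)
    demand_sum = D.sum(axis=0)

    # The recursion couples hours only through the total biomass, so run
    # a scalar loop for the totals and distribute per leaf afterwards.
    coef = params.beer_lambert_k / (params.leaf_mass_per_area *
                                    params.ground_area_cm2)
    gain = params.rue * params.ground_area_cm2
    radiation = env.radiation
    produced = np.zeros(horizon)
    allocated = np.zeros(horizon)
    unallocated = 0.0
    total = float(Q0.sum())
    exp = math.exp
    for t in range(horizon):
        q = radiation[t] * gain * (1.0 - exp(-coef * total)) if total > 0 \
            else 0.0
        produced[t] = q
        pool = q + seed_pool
        if demand_sum[t] > 0.0:
            allocated[t] = pool
            total += pool
            seed_pool = 0.0
        else:
            unallocated += q  # seed pool is retained, production is lost

    # normalise demands first (entrywise ratios are <= 1 even when the
    # column sum is denormally small), then scale by the allocated pool
    safe_sum = np.where(demand_sum > 0.0, demand_sum, 1.0)
    shares = (D / safe_sum) * np.where(demand_sum > 0.0, allocated, 0.0)
    Q = np.empty((n_max, horizon + 1))
    Q[:, 0] = Q0
    np.cumsum(shares, axis=1, out=Q[:, 1:])
    Q[:, 1:] += Q0[:, None]

    if unallocated > 0.0:
        logger.warning("%.3g g of production fell on all-zero demands and "
                       "was left unallocated", unallocated)
    areas = Q / params.leaf_mass_per_area
    return SimulationResult(
        hours=np.arange(horizon + 1),
        appearance_h=appear,
        biomass=Q,
        areas=areas,
        produced=produced,
        unallocated=unallocated,
    )
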