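"""Parameter estimation for the source-sink model by generalized least squares.

Observed per-leaf area trajectories (possibly with missing entries) are
flattened into a single vector y and matched against the model
prediction f(theta) under a multiplicative error model
y_i = f_i(theta) (1 + eps_i). The estimator alternates two steps until
the parameters settle: (i) freeze weights w_i = 1 / f_i(theta_prev)^2,
(ii) solve the weighted nonlinear least-squares problem
min_theta sum_i w_i (y_i - f_i(theta))^2 with a bounded trust-region
solver, positive parameters living in log space. Standard errors come
from the Gauss-Newton approximation (J' W J)^{-1} sigma_hat^2.

Fit quality is summarised by the modeling efficiency eps = 1 - SSE/SST,
the accuracy alpha = mean |y_tilde / y| and the NRMSE (RMSE divided by
the observation mean); a matrix of cross-genotype NRMSEs is used to
check that each genotype's own parameter set describes it best.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .growth import Environment, GrowthParams, simulate

logger = logging.getLogger(__name__)

__all__ = [
    "ObservationSet",
    "FitConfig",
    "FitResult",
    "efficiency",
    "accuracy",
    "nrmse",
    "predict_observations",
    "fit_parameters",
    "genotype_confusion",
]


@dataclass
class ObservationSet:
    """Observed leaf areas: records of (hour, leaf rank, area in cm^2).

    Missing (hour, rank) combinations are simply absent; the flattening
    into the fit vector is row-major by (rank, hour).
    """

    hours: np.ndarray
    ranks: np.ndarray
    areas: np.ndarray
    genotype: str = ""

    def __post_init__(self):
        self.hours = np.asarray(self.hours, dtype=int).ravel()
        self.ranks = np.asarray(self.ranks, dtype=int).ravel()
        self.areas = np.asarray(self.areas, dtype=float).ravel()
        if not (self.hours.size == self.ranks.size == self.areas.size):
            raise ValueError("hours, ranks and areas must be equally long")
        if self.hours.size == 0:
            raise ValueError("empty observation set")
        if (self.areas <= 0).any():
            raise ValueError("areas must be strictly positive")
        pairs = set(zip(self.hours.tolist(), self.ranks.tolist()))
        if len(pairs) != self.hours.size:
            raise ValueError("(hour, rank) pairs must be unique")
        order = np.lexsort((self.hours, self.ranks))
        self.hours = self.hours[order]
        self.ranks = self.ranks[order]
        self.areas = self.areas[order]

    @property
    def n(self) -> int:
        return int(self.areas.size)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, genotype: str = "",
                   hour_col: str = "hour", rank_col: str = "rank",
                   area_col: str = "area_cm2") -> "ObservationSet":
        return cls(frame[hour_col].to_numpy(), frame[rank_col].to_numpy(),
                   frame[area_col].to_numpy(), genotype=genotype)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"hour": self.hours, "rank": self.ranks,
                             "area_cm2": self.areas})


def efficiency(y, y_tilde) -> float:
    """Modeling efficiency 1 - SSE/SST (1 for a perfect fit)."""
    y = np.asarray(y, dtype=float)
    y_tilde = np.asarray(y_tilde, dtype=float)
    if y.size < 2:
        raise ValueError("efficiency needs at least two observations")
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise ValueError("efficiency undefined for constant observations")
    sse = float(((y - y_tilde) ** 2).sum())
    return 1.0 - sse / sst


def accuracy(y, y_tilde) -> float:
    """Mean absolute prediction/observation ratio (1 when unbiased)."""
    y = np.asarray(y, dtype=float)
    y_tilde = np.asarray(y_tilde, dtype=float)
    if (y == 0).any():
        raise ValueError("accuracy undefined when an observation is zero")
    return float(np.abs(y_tilde / y).mean())


def nrmse(y, y_tilde) -> float:
    """Root mean square error normalised by the observation mean."""
    y = np.asarray(y, dtype=float)
    y_tilde = np.asarray(y_tilde, dtype=float)
    ybar = float(y.mean())
    if ybar == 0.0:
        raise ValueError("NRMSE undefined for zero-mean observations")
    return float(np.sqrt(((y - y_tilde) ** 2).mean()) / ybar)


def predict_observations(params: GrowthParams, env: Environment,
                         obs: ObservationSet) -> np.ndarray:
    """Model areas f(theta) aligned with the observation vector.

    Observations of leaves the parameter set never produces (rank beyond
    the schedule) or before their appearance predict a tiny positive
    area rather than zero, keeping the multiplicative weights finite.
    """
    horizon = int(obs.hours.max())
    sim = simulate(params, env, horizon)
    pred = np.full(obs.n, 1e-12)
    valid = obs.ranks <= sim.n_leaves
    pred[valid] = sim.areas[obs.ranks[valid] - 1, obs.hours[valid]]
    return np.maximum(pred, 1e-12)


@dataclass
class FitConfig:
    """Controls of the alternating GLS estimator."""

    max_outer_iterations: int = 50
    outer_tolerance: float = 1e-6
    n_starts: int = 5
    start_spread: float = 0.3    # lognormal sd of the multi-start jitter
    seed: int = 0
    #: bounds in natural space for each estimable component
    bounds: dict = field(default_factory=lambda: {
        "phyllochron_h": (4.0, 400.0),
        "leaf_mass_per_area": (1e-4, 0.1),
        "mu1": (3.0, 12.0),
        "sigma1": (0.01, 5.0),
        "mu2": (3.0, 12.0),
        "sigma2": (0.01, 5.0),
        "rho": (0.1, 10.0),
        "seed_biomass": (1e-7, 1e-2),
    })


@dataclass
class FitResult:
    """Estimated parameter set with uncertainty and diagnostics."""

    params: GrowthParams
    estimates: dict
    standard_errors: dict
    relative_errors: dict
    converged: bool
    iterations: int
    objective: float
    predicted: np.ndarray
    observations: ObservationSet
    efficiency: float
    accuracy: float
    nrmse: float
    seed: int = 0

    def summary(self) -> pd.DataFrame:
        rows = []
        for name in GrowthParams.ESTIMABLE:
            rows.append({
                "parameter": name,
                "estimate": self.estimates[name],
                "standard_error": self.standard_errors.get(name, np.nan),
                "relative_error": self.relative_errors.get(name, np.nan),
            })
        return pd.DataFrame(rows)


# log-reparameterised components (strictly positive); mu1/mu2 stay linear
_LOG_SCALE = {"phyllochron_h", "leaf_mass_per_area", "sigma1", "sigma2",
              "rho", "seed_biomass"}


def _to_internal(theta: np.ndarray) -> np.ndarray:
    out = theta.copy()
    for i, name in enumerate(GrowthParams.ESTIMABLE):
        if name in _LOG_SCALE:
            out[i] = np.log(theta[i])
    return out


def _from_internal(z: np.ndarray) -> np.ndarray:
    out = z.copy()
    for i, name in enumerate(GrowthParams.ESTIMABLE):
        if name in _LOG_SCALE:
            out[i] = np.exp(z[i])
    return out


def _gls_single_start(theta0: np.ndarray, template: GrowthParams,
                      env: Environment, obs: ObservationSet,
                      config: FitConfig) -> tuple[np.ndarray, float, int, bool]:
    """Alternating weighted least squares from one starting point."""
    lo = np.array([config.bounds[n][0] for n in GrowthParams.ESTIMABLE])
    hi = np.array([config.bounds[n][1] for n in GrowthParams.ESTIMABLE])
    theta = np.clip(theta0, lo, hi)
    y = obs.areas

    z_lo, z_hi = _to_internal(lo), _to_internal(hi)
    converged = False
    it = 0
    weights = None
    for it in range(1, config.max_outer_iterations + 1):
        pred_prev = predict_observations(template.with_theta(theta), env, obs)
        weights = 1.0 / np.maximum(pred_prev, 1e-12)

        def resid(z):
            th = _from_internal(z)
            f = predict_observations(template.with_theta(th), env, obs)
            return (y - f) * weights

        sol = least_squares(resid, _to_internal(theta), bounds=(z_lo, z_hi),
                            method="trf", xtol=1e-10, ftol=1e-10)
        new_theta = _from_internal(sol.x)
        change = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), 1e-12))
        theta = new_theta
        if change < config.outer_tolerance:
            converged = True
            break
    objective = float((resid(_to_internal(theta)) ** 2).sum())
    return theta, objective, it, converged


def _standard_errors(theta: np.ndarray, template: GrowthParams,
                     env: Environment, obs: ObservationSet) -> np.ndarray:
    """Gauss-Newton standard errors in natural parameter space."""
    f0 = predict_observations(template.with_theta(theta), env, obs)
    w = 1.0 / np.maximum(f0, 1e-12) ** 2
    n, p = obs.n, theta.size
    J = np.empty((n, p))
    for i in range(p):
        h = max(1e-6 * abs(theta[i]), 1e-10)
        tp = theta.copy()
        tp[i] += h
        J[:, i] = (predict_observations(template.with_theta(tp), env, obs) - f0) / h
    info = J.T @ (w[:, None] * J)
    resid = obs.areas - f0
    dof = max(n - p, 1)
    sigma2 = float((w * resid ** 2).sum()) / dof
    try:
        cov = np.linalg.inv(info) * sigma2
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        logger.warning("singular information matrix: standard errors unavailable")
        se = np.full(p, np.nan)
    return se


def fit_parameters(obs: ObservationSet, env: Environment,
                   template: GrowthParams | None = None,
                   init: GrowthParams | np.ndarray | None = None,
                   config: FitConfig | None = None,
                   n_starts: int | None = None) -> FitResult:
    """Estimate the eight-component parameter subset from leaf areas.

    ``template`` supplies the fixed quantities (radiation use efficiency,
    ground area, light-extinction coefficient, appearance times);
    ``init`` the starting values of the estimable components (defaults
    to the template's own values). ``n_starts`` overrides the multistart
    count; starts beyond the first jitter the init multiplicatively with
    a seeded generator, and the best final objective wins.
    """
    config = config or FitConfig()
    template = template or GrowthParams()
    if init is None:
        theta_init = template.theta()
    elif isinstance(init, GrowthParams):
        theta_init = init.theta()
    else:
        theta_init = np.asarray(init, dtype=float)
    starts = config.n_starts if n_starts is None else n_starts

    rng = np.random.default_rng(config.seed)
    best = None
    for s in range(max(starts, 1)):
        theta0 = theta_init.copy()
        if s > 0:
            jitter = rng.lognormal(0.0, config.start_spread, theta0.size)
            theta0 = theta0 * jitter
        theta, objective, iters, converged = _gls_single_start(
            theta0, template, env, obs, config
        )
        if best is None or objective < best[1]:
            best = (theta, objective, iters, converged)
    theta, objective, iters, converged = best
    if not converged:
        logger.warning("GLS did not converge in %d outer iterations", iters)

    fitted = template.with_theta(theta)
    pred = predict_observations(fitted, env, obs)
    se = _standard_errors(theta, template, env, obs)
    names = GrowthParams.ESTIMABLE
    estimates = dict(zip(names, theta))
    standard_errors = dict(zip(names, se))
    relative_errors = {
        n: (se_i / abs(est) if np.isfinite(se_i) and est != 0 else np.nan)
        for n, se_i, est in zip(names, se, theta)
    }
    return FitResult(
        params=fitted,
        estimates=estimates,
        standard_errors=standard_errors,
        relative_errors=relative_errors,
        converged=converged,
        iterations=iters,
        objective=objective,
        predicted=pred,
        observations=obs,
        efficiency=efficiency(obs.areas, pred),
        accuracy=accuracy(obs.areas, pred),
        nrmse=nrmse(obs.areas, pred),
        seed=config.seed,
    )


def genotype_confusion(fits: list[FitResult], datasets: list[ObservationSet],
                       env: Environment) -> tuple[np.ndarray, bool]:
    """Cross-genotype NRMSE matrix and the diagonal-dominance flag.

    Entry (i, j) is the NRMSE between the simulation under genotype i's
    estimated parameters and genotype j's observations, both restricted
    to the (hour, rank) index common to all datasets. The boolean is
    True when every row attains its minimum on the diagonal, i.e., each
    parameter set describes its own genotype best.
    """
    if len(fits) != len(datasets):
        raise ValueError("need one fit per dataset")
    common = set(zip(datasets[0].hours.tolist(), datasets[0].ranks.tolist()))
    for ds in datasets[1:]:
        common &= set(zip(ds.hours.tolist(), ds.ranks.tolist()))
    if not common:
        raise ValueError("datasets share no (hour, rank) observation")
    # same (rank, hour) ordering that ObservationSet normalises to, so the
    # probe predictions align with the restricted observation vectors
    idx = sorted(common, key=lambda hr: (hr[1], hr[0]))
    hours = np.array([h for h, _ in idx])
    ranks = np.array([r for _, r in idx])

    def restrict(ds: ObservationSet) -> np.ndarray:
        lut = {(h, r): a for h, r, a in zip(ds.hours, ds.ranks, ds.areas)}
        return np.array([lut[(h, r)] for h, r in idx])

    n = len(fits)
    matrix = np.empty((n, n))
    probe = ObservationSet(hours, ranks, np.ones(len(idx)))
    for i, fit in enumerate(fits):
        sim_i = predict_observations(fit.params, env, probe)
        for j, ds in enumerate(datasets):
            matrix[i, j] = nrmse(restrict(ds), sim_i)
    diagonal_best = bool(all(matrix[i, :].argmin() == i for i in range(n)))
    return matrix, diagonal_best
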