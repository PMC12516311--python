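"""Simulated-annealing fitting of the forward model to an expression profile.

One SA run perturbs the free parameters inside a box (:class:`SearchRange`),
accepts moves by the Metropolis rule under a geometric cooling schedule with
an adaptive move scale, and optionally polishes the best point with a
bounded derivative-free local search.  Ensembles are collections of
independent seeded runs; the quartile-based Tukey rule shrinks the search
box between rounds from the parameters of biologically compatible fits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize

from .io_formats import ExpressionProfile
from .thermo_model import ParameterSet

__all__ = [
    "SearchRange",
    "FitResult",
    "AnnealingConfig",
    "rms_cost",
    "anneal",
    "run_ensemble",
    "refine_search_ranges",
]

logger = logging.getLogger(__name__)

DEFAULT_NU_WINDOW = (35.5, 92.5)


@dataclass(frozen=True)
class SearchRange:
    """Per-parameter (lo, hi) optimization bounds."""

    bounds: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        clean = {}
        for name, (lo, hi) in self.bounds.items():
            lo, hi = float(lo), float(hi)
            if not lo < hi:
                raise ValueError(f"{name}: lo {lo} must be < hi {hi}")
            clean[name] = (lo, hi)
        object.__setattr__(self, "bounds", clean)

    @property
    def names(self) -> list[str]:
        return list(self.bounds)

    def arrays(self, names: Sequence[str] | None = None):
        names = list(names) if names is not None else self.names
        lo = np.array([self.bounds[n][0] for n in names])
        hi = np.array([self.bounds[n][1] for n in names])
        return lo, hi

    def contains(self, params: Mapping[str, float], tol: float = 1e-12) -> bool:
        return all(
            self.bounds[n][0] - tol <= params[n] <= self.bounds[n][1] + tol
            for n in self.bounds
        )

    def sample(self, rng: np.random.Generator) -> ParameterSet:
        lo, hi = self.arrays()
        return ParameterSet.from_vector(self.names, rng.uniform(lo, hi))


@dataclass
class FitResult:
    """One SA solution with its prediction and filter verdicts."""

    params: ParameterSet
    rms: float
    predicted: ExpressionProfile
    seed: int
    round_id: int = 1
    filter1_pass: bool | None = None
    filter2_pass: bool | None = None
    active_sites: object | None = None

    @property
    def compatible(self) -> bool:
        return bool(self.filter1_pass) and bool(self.filter2_pass)


@dataclass(frozen=True)
class AnnealingConfig:
    """SA schedule settings.

    Geometric cooling ``T <- cooling * T`` with ``moves_per_temp``
    Metropolis proposals per temperature; the per-parameter move scale
    adapts toward ``target_acceptance``.  ``polish_maxfev > 0`` appends a
    bounded local refinement of the best-seen point: ``polish_rounds``
    alternating passes of Powell and L-BFGS-B sharing the evaluation
    budget (the combination escapes the axis-aligned stalls either method
    hits alone).
    """

    t_initial: float = 10.0
    t_final: float = 1e-3
    cooling: float = 0.9
    moves_per_temp: int = 40
    max_evaluations: int = 20000
    target_acceptance: float = 0.4
    polish_maxfev: int = 0
    polish_rounds: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cooling < 1:
            raise ValueError("cooling must be in (0, 1)")
        if self.t_final <= 0 or self.t_initial <= self.t_final:
            raise ValueError("need t_initial > t_final > 0")
        if self.max_evaluations <= 0:
            raise ValueError("max_evaluations must be positive and finite")


def rms_cost(observed: ExpressionProfile, predicted: ExpressionProfile,
             nu_window: tuple[float, float] | None = DEFAULT_NU_WINDOW,
             raw_sum: bool = False) -> float:
    """Root-mean-square mismatch between observed and model profiles.

    Restricted to the configured %EL window (default 35.5–92.5).  With
    ``raw_sum=True`` returns the plain sum of squared differences instead.
    """
    if observed.nu_grid.shape != predicted.nu_grid.shape or np.any(
        observed.nu_grid != predicted.nu_grid
    ):
        raise ValueError("observed and predicted profiles are on different grids")
    if nu_window is not None:
        observed = observed.window(*nu_window)
        predicted = predicted.window(*nu_window)
    sq = (observed.values - predicted.values) ** 2
    if raw_sum:
        return float(sq.sum())
    return float(np.sqrt(sq.mean()))


def anneal(objective: Callable[[np.ndarray], float], search: SearchRange,
           config: AnnealingConfig) -> tuple[ParameterSet, float, int]:
    """Minimize ``objective`` over the box by simulated annealing.

    ``objective`` maps a parameter vector (in ``search.names`` order) to a
    finite cost.  Returns (best parameters, best cost, evaluations used);
    fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    names = search.names
    lo, hi = search.arrays()
    span = hi - lo
    x = rng.uniform(lo, hi)
    cost = float(objective(x))
    if not np.isfinite(cost):
        raise ValueError("objective is non-finite at the initial point")
    best_x, best_cost = x.copy(), cost
    n_eval = 1
    scale = 0.25  # move scale as a fraction of each parameter's span
    t = config.t_initial
    while t > config.t_final and n_eval < config.max_evaluations:
        accepted = 0
        proposed = 0
        for _ in range(config.moves_per_temp):
            if n_eval >= config.max_evaluations:
                break
            idx = rng.integers(len(x))
            x_new = x.copy()
            x_new[idx] += rng.normal(0.0, scale * span[idx])
            x_new[idx] = min(max(x_new[idx], lo[idx]), hi[idx])
            c_new = float(objective(x_new))
            n_eval += 1
            proposed += 1
            delta = c_new - cost
            if delta <= 0 or rng.random() < np.exp(-delta / t):
                x, cost = x_new, c_new
                accepted += 1
                if cost < best_cost:
                    best_x, best_cost = x.copy(), cost
        if proposed:
            rate = accepted / proposed
            # nudge the move scale toward the target acceptance rate
            if rate > config.target_acceptance:
                scale = min(scale * 1.25, 1.0)
            else:
                scale = max(scale * 0.8, 1e-4)
        t *= config.cooling
    if config.polish_maxfev > 0:
        bounds = list(zip(lo, hi))
        clipped = lambda v: float(objective(np.clip(v, lo, hi)))  # noqa: E731
        per_stage = max(50, config.polish_maxfev // max(1, 2 * config.polish_rounds))
        cand = best_x.copy()
        for _ in range(max(1, config.polish_rounds)):
            res = optimize.minimize(
                clipped, cand, method="Powell", bounds=bounds,
                options={"maxfev": per_stage, "xtol": 1e-10, "ftol": 1e-12},
            )
            n_eval += res.nfev
            cand = np.clip(res.x, lo, hi)
            res = optimize.minimize(
                clipped, cand, method="L-BFGS-B", bounds=bounds,
                options={"maxfun": per_stage},
            )
            n_eval += res.nfev
            cand = np.clip(res.x, lo, hi)
        c_cand = float(objective(cand))
        n_eval += 1
        if c_cand < best_cost:
            best_x, best_cost = cand, c_cand
    return ParameterSet.from_vector(names, best_x), best_cost, n_eval


def fit_once(model_objective, search: SearchRange, config: AnnealingConfig,
             predict: Callable[[ParameterSet], ExpressionProfile],
             observed: ExpressionProfile, seed: int, round_id: int = 1,
             nu_window=DEFAULT_NU_WINDOW) -> FitResult:
    """One seeded SA fit packaged as a :class:`FitResult`."""
    cfg = replace(config, seed=seed)
    params, cost, _ = anneal(model_objective, search, cfg)
    predicted = predict(params)
    rms = rms_cost(observed, predicted, nu_window)
    return FitResult(params=params, rms=rms, predicted=predicted,
                     seed=seed, round_id=round_id)


def run_ensemble(n: int, search: SearchRange, config: AnnealingConfig,
                 objective_factory, observed: ExpressionProfile,
                 predict: Callable[[ParameterSet], ExpressionProfile],
                 seed_base: int = 0, round_id: int = 1,
                 nu_window=DEFAULT_NU_WINDOW) -> list[FitResult]:
    """``n`` independent fits with seeds ``seed_base .. seed_base + n - 1``.

    ``objective_factory`` maps a parameter-name list to the vector
    objective (so each fit can close over a private model handle); output
    order is deterministic regardless of scheduling.
    """
    fits = []
    for k in range(n):
        seed = seed_base + k
        obj = objective_factory(search.names)
        fits.append(
            fit_once(obj, search, config, predict, observed, seed,
                     round_id=round_id, nu_window=nu_window)
        )
    return fits


class ExpressionFitter:
    """Bundles a model engine with observed data for ensemble fitting."""

    def __init__(self, model, profiles, observed: ExpressionProfile,
                 nu_window: tuple[float, float] | None = DEFAULT_NU_WINDOW):
        self.model = model
        self.profiles = profiles
        self.observed = observed
        self.nu_window = nu_window

    def predict(self, params: ParameterSet) -> ExpressionProfile:
        return self.model.predict(params, self.profiles)

    def cost(self, params: ParameterSet) -> float:
        return rms_cost(self.observed, self.predict(params), self.nu_window)

    def objective(self, names: Sequence[str]):
        def _obj(vec: np.ndarray) -> float:
            c = self.cost(ParameterSet.from_vector(names, vec))
            return c if np.isfinite(c) else 1e12
        return _obj

    def fit(self, search: SearchRange, config: AnnealingConfig, seed: int,
            round_id: int = 1) -> FitResult:
        return fit_once(self.objective(search.names), search, config,
                        self.predict, self.observed, seed, round_id,
                        self.nu_window)

    def ensemble(self, n: int, search: SearchRange, config: AnnealingConfig,
                 seed_base: int = 0, round_id: int = 1) -> list[FitResult]:
        return [self.fit(search, config, seed_base + k, round_id)
                for k in range(n)]


def refine_search_ranges(compatible_fits: Sequence[FitResult],
                         old: SearchRange, eps: float = 1e-9) -> SearchRange:
    """Shrink the search box from the compatible fits by the Tukey rule.

    Per parameter, with Q1/Q3 the linearly interpolated quartiles and
    IQ = Q3 - Q1: values falling outside [Q1 - 1.5 IQ, Q3 + 1.5 IQ] mark the
    parameter as outlier-bearing (category a) and the new bounds are the old
    ones clipped to that band; parameters without outliers (category b) get
    the observed min/max.  Degenerate bounds are widened by ``eps``.
    """
    if len(compatible_fits) < 4:
        raise ValueError(
            f"need at least 4 compatible fits, got {len(compatible_fits)}"
        )
    new_bounds: dict[str, tuple[float, float]] = {}
    for name, (old_lo, old_hi) in old.bounds.items():
        vals = np.array([fit.params[name] for fit in compatible_fits])
        q1, q3 = np.percentile(vals, [25, 75])
        iq = q3 - q1
        tmin, tmax = q1 - 1.5 * iq, q3 + 1.5 * iq
        has_outliers = bool(np.any((vals < tmin) | (vals > tmax)))
        if has_outliers:  # category (a): clip the old box to the Tukey band
            lo = max(old_lo, tmin)
            hi = min(old_hi, tmax)
        else:  # category (b): observed extremes
            lo = float(vals.min())
            hi = float(vals.max())
        if not lo < hi:
            mid = 0.5 * (lo + hi)
            half = max(eps, abs(mid) * eps)
            lo, hi = mid - half, mid + half
        new_bounds[name] = (lo, hi)
    return SearchRange(new_bounds)
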