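"""Minibatch water-wave swarm search for the shrinkage parameters (D, alpha).

Each particle is a candidate position in parameter space carrying a
wavelength that scales its propagation step.  One iteration applies the
water-wave operator triple, hybridized with a PSO-style linearly decaying
inertia weight:

propagation   position += inertia(t) * wavelength * uniform(-1, 1) per
              dimension, clipped to bounds; improvements are kept.
wavelength    fitter-than-median particles shorten their wavelength
              (exploitation), poorer ones grow it back (exploration).
breaking      a burst of probes around the global best; the probe radius
              shrinks whenever a burst fails to improve, giving a
              progressively finer local search.
refraction    particles stagnant for several iterations are re-drawn
              between their position and the global best.

Fitness is evaluated on a random minibatch of image tiles, shared by all
particles within an iteration so comparisons are fair.  With elitism the
best-ever solution is never lost, so the best-fitness trace is monotone.

The full-reference objective scores a candidate's shrink-and-reconstruct
output by ``w * PSNR/PSNR_norm + (1 - w) * MSSIM`` against the clean
reference (maximized); the no-reference objective is the ``ABG + DEI``
composite of the (noisy, filtered) pair (minimized).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import NRConfig, SSIMConfig, mssim, mse_rmse_psnr, nr_suite
from .phantom import exp_transform, log_transform
from .shrinkage import ThresholdParams, shrink_pyramid
from .swt import forward_isfwt, inverse_isfwt

__all__ = [
    "OptimizerConfig",
    "Particle",
    "Swarm",
    "initialize_swarm",
    "wave_update",
    "minimize_function",
    "ObjectiveEvaluator",
    "minibatch_fitness",
    "default_bounds",
    "optimize",
]

Bounds = list[tuple[float, float]]


@dataclass(frozen=True)
class OptimizerConfig:
    swarm_size: int = 20
    iterations: int = 50
    minibatch_fraction: float = 0.5
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    seed: int = 0
    objective_mode: str = "full_reference"
    elitism: bool = True
    # water-wave operator constants
    wavelength_decay: float = 0.95
    wavelength_growth: float = 1.05
    n_break: int = 3
    break_init: float = 0.25
    break_shrink: float = 0.7
    stall_limit: int = 6
    # objective composition
    fr_weight: float = 0.5
    psnr_norm: float = 50.0
    tile_size: int = 64

    def __post_init__(self) -> None:
        if self.swarm_size < 1:
            raise ValueError("swarm_size must be at least 1")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        if not 0.0 < self.minibatch_fraction <= 1.0:
            raise ValueError("minibatch_fraction must lie in (0, 1]")
        if self.objective_mode not in ("full_reference", "no_reference"):
            raise ValueError("objective_mode must be full_reference or no_reference")


@dataclass
class Particle:
    position: np.ndarray
    wavelength: np.ndarray  # per-dimension step scale, > 0
    cost: float = np.inf  # internal cost (minimized)
    best_position: np.ndarray = field(default_factory=lambda: np.empty(0))
    best_cost: float = np.inf
    stall: int = 0


@dataclass
class Swarm:
    particles: list[Particle]
    lower: np.ndarray
    upper: np.ndarray
    rng: np.random.Generator
    best_position: np.ndarray
    best_cost: float = np.inf
    break_radius: float = 0.25


def _check_bounds(bounds: Bounds) -> tuple[np.ndarray, np.ndarray]:
    if not bounds:
        raise ValueError("bounds must not be empty")
    lower = np.array([b[0] for b in bounds], dtype=np.float64)
    upper = np.array([b[1] for b in bounds], dtype=np.float64)
    if not (np.all(np.isfinite(lower)) and np.all(np.isfinite(upper))):
        raise ValueError("bounds must be finite")
    if np.any(lower >= upper):
        raise ValueError("each lower bound must be strictly below its upper bound")
    return lower, upper


def initialize_swarm(bounds: Bounds, config: OptimizerConfig) -> Swarm:
    """Uniformly sampled swarm; wavelengths start at half the bound span."""
    lower, upper = _check_bounds(bounds)
    rng = np.random.default_rng(config.seed)
    particles = []
    for _ in range(config.swarm_size):
        pos = rng.uniform(lower, upper)
        particles.append(
            Particle(
                position=pos,
                wavelength=0.5 * (upper - lower),
                best_position=pos.copy(),
            )
        )
    return Swarm(
        particles=particles,
        lower=lower,
        upper=upper,
        rng=rng,
        best_position=particles[0].position.copy(),
        break_radius=config.break_init,
    )


def _safe_cost(objective, position: np.ndarray) -> float:
    value = float(objective(position))
    return value if np.isfinite(value) else np.inf


def _evaluate_all(swarm: Swarm, objective) -> None:
    for p in swarm.particles:
        p.cost = _safe_cost(objective, p.position)
        if p.cost < p.best_cost:
            p.best_cost, p.best_position = p.cost, p.position.copy()
        if p.cost < swarm.best_cost:
            swarm.best_cost, swarm.best_position = p.cost, p.position.copy()


def wave_update(
    swarm: Swarm, iteration: int, config: OptimizerConfig, objective
) -> Swarm:
    """One optimizer iteration (propagation, wavelength, breaking,
    refraction) against the supplied cost function (lower is better)."""
    span = swarm.upper - swarm.lower
    denom = max(config.iterations - 1, 1)
    inertia = config.inertia_start + (config.inertia_end - config.inertia_start) * min(
        iteration / denom, 1.0
    )
    rng = swarm.rng
    max_wavelength = 0.5 * span

    costs = np.array([p.cost for p in swarm.particles])
    median_cost = float(np.median(costs[np.isfinite(costs)])) if np.any(
        np.isfinite(costs)
    ) else np.inf

    for p in swarm.particles:
        step = inertia * p.wavelength * rng.uniform(-1.0, 1.0, size=len(span))
        candidate = np.clip(p.position + step, swarm.lower, swarm.upper)
        cost = _safe_cost(objective, candidate)
        if cost < p.cost:
            p.position, p.cost, p.stall = candidate, cost, 0
        else:
            p.stall += 1
        if p.cost <= median_cost:
            p.wavelength = p.wavelength * config.wavelength_decay
        else:
            p.wavelength = np.minimum(
                p.wavelength * config.wavelength_growth, max_wavelength
            )
        if p.cost < p.best_cost:
            p.best_cost, p.best_position = p.cost, p.position.copy()
        if p.cost < swarm.best_cost:
            swarm.best_cost, swarm.best_position = p.cost, p.position.copy()

    # breaking: refine around the global best, shrinking on failure
    improved = False
    for _ in range(config.n_break):
        probe = np.clip(
            swarm.best_position + swarm.break_radius * span * rng.normal(size=len(span)),
            swarm.lower,
            swarm.upper,
        )
        cost = _safe_cost(objective, probe)
        if cost < swarm.best_cost:
            swarm.best_cost, swarm.best_position, improved = cost, probe, True
    if not improved:
        swarm.break_radius = max(swarm.break_radius * config.break_shrink, 1e-9)

    # refraction: pull stagnant particles toward the best
    for p in swarm.particles:
        if p.stall >= config.stall_limit:
            mu = 0.5 * (swarm.best_position + p.position)
            sd = 0.5 * np.abs(swarm.best_position - p.position) + 1e-12
            p.position = np.clip(rng.normal(mu, sd), swarm.lower, swarm.upper)
            p.cost = _safe_cost(objective, p.position)
            p.stall = 0
            min_wavelength = min(np.min(q.wavelength / span) for q in swarm.particles)
            p.wavelength = np.maximum(0.5 * min_wavelength * span, 1e-9 * span)
            if p.cost < p.best_cost:
                p.best_cost, p.best_position = p.cost, p.position.copy()
            if p.cost < swarm.best_cost:
                swarm.best_cost, swarm.best_position = p.cost, p.position.copy()
    return swarm


def minimize_function(
    objective,
    bounds: Bounds,
    config: OptimizerConfig,
    *,
    make_objective=None,
    include_points: list[np.ndarray] | None = None,
) -> tuple[np.ndarray, float, list[float]]:
    """Run the full swarm loop against a cost function (minimized).

    ``make_objective(iteration, rng)``, when given, supplies a fresh
    (e.g. minibatch-bound) cost function per iteration; iteration 0 is the
    initial evaluation.  ``include_points`` replaces the first sampled
    positions, which lets callers seed known candidates (the identity
    parameters, say) into the swarm.  Returns the best position, its cost,
    and the per-iteration best-cost trace of length ``iterations + 1``.
    """
    swarm = initialize_swarm(bounds, config)
    if include_points:
        for k, point in enumerate(include_points[: len(swarm.particles)]):
            pos = np.clip(
                np.asarray(point, dtype=np.float64), swarm.lower, swarm.upper
            )
            swarm.particles[k].position = pos
            swarm.particles[k].best_position = pos.copy()
    batch_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    current = objective if make_objective is None else make_objective(0, batch_rng)
    _evaluate_all(swarm, current)
    trace = [swarm.best_cost]
    for t in range(config.iterations):
        if make_objective is not None:
            current = make_objective(t + 1, batch_rng)
        wave_update(swarm, t, config, current)
        if not config.elitism:
            live = min(p.cost for p in swarm.particles)
            trace.append(live)
        else:
            trace.append(swarm.best_cost)
    return swarm.best_position.copy(), swarm.best_cost, trace


class ObjectiveEvaluator:
    """Tile-based despeckling objective for candidate (D, alpha) pairs.

    The noisy image is covered by ``tile_size`` tiles (edge tiles are
    shifted inward so all tiles are full-size); the wavelet pyramid of each
    log-transformed tile is computed once, so evaluating a candidate only
    costs a threshold pass and an inverse transform per tile.  Positions
    are ``[D, alpha]``.
    """

    def __init__(
        self,
        noisy: np.ndarray,
        reference: np.ndarray | None,
        config: OptimizerConfig,
        *,
        wavelet_name: str = "sym4",
        levels: int = 3,
        log_offset: float = 0.05,
        dynamic_range: float = 1.0,
        threshold_mode: str = "exponential",
    ) -> None:
        if config.objective_mode == "full_reference" and reference is None:
            raise ValueError("full-reference objective requires a reference image")
        self.config = config
        self.mode = config.objective_mode
        self.log_offset = log_offset
        self.dynamic_range = dynamic_range
        self.threshold_mode = threshold_mode
        noisy = np.asarray(noisy, dtype=np.float64)
        clipped = np.clip(noisy, 0.0, None)
        origins = self._tile_origins(noisy.shape, config.tile_size)
        self.tiles = []
        for r0, c0, th, tw in origins:
            sl = (slice(r0, r0 + th), slice(c0, c0 + tw))
            noisy_tile = noisy[sl]
            log_tile = log_transform(clipped[sl], log_offset)
            pyr = forward_isfwt(log_tile, wavelet_name, levels)
            ref_tile = None if reference is None else np.asarray(reference)[sl]
            self.tiles.append((noisy_tile, ref_tile, pyr))
        self._nr_cfg = NRConfig()
        self._ssim_cfg = SSIMConfig()

    @staticmethod
    def _tile_origins(shape: tuple[int, int], tile: int):
        h, w = shape
        th, tw = min(tile, h), min(tile, w)
        rows = sorted({*range(0, h - th + 1, th), h - th})
        cols = sorted({*range(0, w - tw + 1, tw), w - tw})
        return [(r, c, th, tw) for r in rows for c in cols]

    @property
    def n_tiles(self) -> int:
        return len(self.tiles)

    def draw_batch(self, rng: np.random.Generator) -> np.ndarray:
        k = max(1, int(round(self.config.minibatch_fraction * self.n_tiles)))
        return rng.choice(self.n_tiles, size=k, replace=False)

    def _tile_fitness(self, index: int, params: ThresholdParams) -> float:
        noisy_tile, ref_tile, pyr = self.tiles[index]
        shrunk = shrink_pyramid(pyr, params, self.threshold_mode)
        rec = exp_transform(inverse_isfwt(shrunk), self.log_offset)
        out = np.clip(rec, 0.0, self.dynamic_range)
        cfg = self.config
        if self.mode == "full_reference":
            _, _, psnr = mse_rmse_psnr(out, ref_tile, self.dynamic_range)
            psnr_term = min(psnr, cfg.psnr_norm) / cfg.psnr_norm
            ssim_term = mssim(out, ref_tile, self.dynamic_range, self._ssim_cfg)
            return cfg.fr_weight * psnr_term + (1.0 - cfg.fr_weight) * ssim_term
        nr = nr_suite(noisy_tile, out, self._nr_cfg)
        return nr["ABG"] + nr["DEI"]

    def fitness(self, position: np.ndarray, tile_indices=None) -> float:
        """Natural-sign fitness (FR: larger is better; NR: smaller)."""
        params = ThresholdParams(D=float(position[0]), alpha=float(position[1]))
        indices = range(self.n_tiles) if tile_indices is None else tile_indices
        values = [self._tile_fitness(i, params) for i in indices]
        return float(np.mean(values))

    def cost(self, position: np.ndarray, tile_indices=None) -> float:
        """Internal minimized cost: negated fitness in FR mode."""
        value = self.fitness(position, tile_indices)
        return -value if self.mode == "full_reference" else value


def minibatch_fitness(
    position,
    noisy: np.ndarray,
    reference: np.ndarray | None,
    batch_rng: np.random.Generator,
    config: OptimizerConfig,
    evaluator: ObjectiveEvaluator | None = None,
    **evaluator_kwargs,
) -> float:
    """Fitness of one candidate on a random minibatch of tiles.

    With ``minibatch_fraction = 1`` this equals the full-image objective
    (the mean over all tiles) exactly.  Pass a prebuilt ``evaluator`` to
    amortize the per-tile wavelet transforms across calls.
    """
    if evaluator is None:
        evaluator = ObjectiveEvaluator(noisy, reference, config, **evaluator_kwargs)
    batch = evaluator.draw_batch(batch_rng)
    return evaluator.fitness(np.asarray(position, dtype=np.float64), batch)


def default_bounds(
    noisy: np.ndarray,
    *,
    wavelet_name: str = "sym4",
    levels: int = 3,
    log_offset: float = 0.05,
    alpha_max: float = 10.0,
    d_scale: float = 3.0,
) -> Bounds:
    """Search box for (D, alpha).

    The D range is scaled from the universal threshold
    ``sigma_hat * sqrt(2 ln N)`` with ``sigma_hat`` the robust (median
    absolute deviation / 0.6745) noise scale of the finest diagonal detail
    band of the log-domain pyramid.
    """
    clipped = np.clip(np.asarray(noisy, dtype=np.float64), 0.0, None)
    pyr = forward_isfwt(log_transform(clipped, log_offset), wavelet_name, levels)
    finest_diag = pyr.details[0][2]
    sigma = float(np.median(np.abs(finest_diag - np.median(finest_diag))) / 0.6745)
    n_coeff = finest_diag.size
    d_max = max(d_scale * sigma * np.sqrt(2.0 * np.log(n_coeff)), 1e-3)
    return [(0.0, d_max), (0.0, alpha_max)]


def optimize(
    noisy: np.ndarray,
    reference: np.ndarray | None,
    bounds: Bounds | None,
    config: OptimizerConfig,
    **evaluator_kwargs,
) -> tuple[ThresholdParams, list[float]]:
    """Search (D, alpha) for one image; returns the winner and the trace.

    The identity candidate (D = 0: no shrinkage) is seeded into the swarm,
    so with elitism the result can never score worse than leaving the
    image untouched under the same objective.  The trace carries the
    best fitness per iteration in the objective's natural orientation
    (non-decreasing for full-reference, non-increasing for no-reference).
    Fully reproducible from ``config.seed``.
    """
    evaluator = ObjectiveEvaluator(noisy, reference, config, **evaluator_kwargs)
    if bounds is None:
        bounds = default_bounds(
            noisy,
            wavelet_name=evaluator_kwargs.get("wavelet_name", "sym4"),
            levels=evaluator_kwargs.get("levels", 3),
            log_offset=evaluator_kwargs.get("log_offset", 0.05),
        )

    def make_objective(iteration: int, batch_rng: np.random.Generator):
        batch = evaluator.draw_batch(batch_rng)
        return lambda position: evaluator.cost(position, batch)

    identity = np.zeros(len(bounds))
    best_position, _, trace = minimize_function(
        None,
        bounds,
        config,
        make_objective=make_objective,
        include_points=[identity],
    )
    if config.objective_mode == "full_reference":
        trace = [-value for value in trace]
    params = ThresholdParams(D=float(best_position[0]), alpha=float(best_position[1]))
    return params, trace
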