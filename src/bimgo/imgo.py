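"""Improved mountain gazelle optimizer (IMGO).

Four additions on top of the baseline herd dynamics:

1. **ICMIC initialization** - the initial herd is laid out by the iterative
   chaotic map with infinite collapses, ``x -> sin(0.7*pi / x)`` on
   [-1,0) u (0,1], whose ergodic orbit spreads the population over the box far
   more evenly than a single uniform draw. One chaotic value is drawn per
   gazelle and broadcast across its coordinates, so the initial herd lies on
   the main diagonal of the box with chaotically spaced offsets.
2. **Nonlinear control factor** - ``a = -2 + log2(1 + (1 - t/T)^2)`` replaces
   the linear schedule, decaying fast early (wide exploration) and slowly late
   (tight exploitation).
3. **Spiral perturbation** - each gazelle is additionally moved along a
   logarithmic spiral around the incumbent best (the whale-style encircling
   move) and the better of old/new positions is kept.
4. **Neighborhood search** - once per iteration one candidate is drawn
   uniformly from the box spanned between the best and second-best members and
   greedily accepted into the incumbent best.

Per iteration the loop consumes exactly 4N (mechanisms) + N (spiral) + 1
(neighborhood) objective evaluations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .mgo import (
    OptimizerConfig,
    OptResult,
    Population,
    bmh,
    coef_BH,
    coef_matrix,
    mh,
    msf,
    tsm,
    weight_F,
    _pick_row,
    _spawn_streams,
)
from .problems import ProblemSpec

__all__ = [
    "ChaoticState",
    "icmic_next",
    "init_population_icmic",
    "control_factor_nonlinear",
    "spiral_perturb",
    "neighborhood_search",
    "imgo_minimize",
]

_EPSILON = 0.7 * math.pi


@dataclass(frozen=True)
class ChaoticState:
    """State of the ICMIC chaotic chain; omega stays in [-1,0) u (0,1]."""

    omega: float
    alpha: float = 0.7
    epsilon: float = _EPSILON
    multiplicative: bool = False

    def __post_init__(self) -> None:
        if self.omega == 0.0:
            raise ValueError("ICMIC state must not be zero")


def icmic_next(state: ChaoticState) -> ChaoticState:
    """One step of the map: sin(0.7*pi / omega) (or sin(0.7*pi * omega) if the
    multiplicative reading is requested). A result that underflows to exactly 0
    is nudged by machine epsilon so the chain never dies."""
    if state.multiplicative:
        nxt = math.sin(state.epsilon * state.omega)
    else:
        nxt = math.sin(state.epsilon / state.omega)
    if nxt == 0.0:
        nxt = np.finfo(float).eps
    return replace(state, omega=nxt)


def init_population_icmic(
    spec: ProblemSpec,
    cfg: OptimizerConfig,
    rng: np.random.Generator,
    evaluate=None,
) -> Population:
    """Seed the herd from one ICMIC orbit, one chaotic value per gazelle.

    Gazelle i takes the i-th orbit value omega_i in [-1,1] and maps it
    affinely onto every coordinate via ``x = lb + (omega + 1)/2 * (ub - lb)``,
    placing the initial herd on the main diagonal of the box with chaotically
    spaced offsets (the per-dimension bounds may differ, so "diagonal" is in
    normalized coordinates). The population is evaluated and returned sorted
    ascending.
    """
    omega0 = float(rng.uniform(-1.0, 1.0))
    if omega0 == 0.0:
        omega0 = np.finfo(float).eps
    state = ChaoticState(omega=omega0, multiplicative=cfg.icmic_multiplicative)
    n, d = cfg.pop_size, spec.dim
    omegas = np.empty(n)
    for k in range(n):
        state = icmic_next(state)
        omegas[k] = state.omega
    positions = spec.lower + (omegas[:, None] + 1.0) / 2.0 * (spec.upper - spec.lower)
    if evaluate is None:
        evaluate = spec.evaluate
    values = np.array([evaluate(x) for x in positions])
    pop = Population(positions, values)
    pop.sort()
    return pop


def control_factor_nonlinear(iter: int, max_iter: int) -> float:
    """a = -2 + log2(1 + (1 - t/T)^2): -1 at t=0, -2 at t=T, steepest early."""
    return -2.0 + math.log2(1.0 + (1.0 - iter / max_iter) ** 2)


def spiral_perturb(
    x: np.ndarray,
    best: np.ndarray,
    c: float,
    rng: np.random.Generator,
    lower: Optional[np.ndarray] = None,
    upper: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Logarithmic-spiral move: best + e^(c*l) * cos(2*pi*l) * |best - x|.

    ``l`` is one scalar U[-1,1] draw shared across dimensions; the result is
    clipped to the box when bounds are given.
    """
    l = rng.uniform(-1.0, 1.0)
    out = best + math.exp(c * l) * math.cos(2.0 * math.pi * l) * np.abs(best - x)
    if lower is not None:
        out = np.clip(out, lower, upper)
    return out


def neighborhood_search(
    best: np.ndarray,
    second_best: np.ndarray,
    spec: ProblemSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Uniform draw from [best - |best - sbest|, best + |best - sbest|] per
    dimension, clipped to the problem box."""
    half = np.abs(best - second_best)
    y = rng.uniform(best - half, best + half)
    return spec.clip(y)


_STREAMS_IMGO = ("init", "mech", "spiral", "neighborhood", "noise")


def imgo_minimize(spec: ProblemSpec, cfg: OptimizerConfig) -> OptResult:
    """Run the full IMGO loop.

    Per iteration: compute the nonlinear control factor; for each gazelle spawn
    the four mechanism offspring into the habitat, then spiral-perturb the
    gazelle itself with greedy acceptance (the running best is updated on the
    spot, so later gazelles spiral around the newest incumbent); sort the
    pooled habitat, draw one neighborhood candidate between best and
    second-best with greedy acceptance into the best slot; retain the N best.
    """
    streams = _spawn_streams(cfg.seed, _STREAMS_IMGO)
    rng_noise = streams["noise"]
    n_evals = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        v = spec.evaluate(x, rng_noise)
        if not math.isfinite(v):
            raise FloatingPointError(f"objective returned non-finite value at {x!r}")
        return v

    pop = init_population_icmic(spec, cfg, streams["init"], evaluate=evaluate)

    rng = streams["mech"]
    rng_spiral = streams["spiral"]
    rng_nb = streams["neighborhood"]
    trace = np.empty(cfg.max_iter)
    n, d = cfg.pop_size, spec.dim

    for t in range(1, cfg.max_iter + 1):
        a = control_factor_nonlinear(t, cfg.max_iter)
        children = np.empty((4 * n, d))
        child_values = np.empty(4 * n)
        # running habitat-wide incumbent used by TSM/MH/BMH and the spiral,
        # refreshed after every evaluation within the sweep
        best = pop.positions[0].copy()
        best_val = float(pop.values[0])
        for i in range(n):
            bh = coef_BH(pop, rng)
            cof = coef_matrix(a, d, rng)
            f = weight_F(d, t, cfg.max_iter, rng)
            block = children[4 * i : 4 * i + 4]
            block[0] = tsm(pop, i, f, bh, _pick_row(cof, rng), rng, best=best)
            block[1] = mh(pop, i, bh, a, rng, best=best, cof=cof)
            block[2] = bmh(pop, i, bh, _pick_row(cof, rng), rng, best=best)
            block[3] = msf(spec, rng)
            np.clip(block, spec.lower, spec.upper, out=block)
            for j in range(4):
                v = evaluate(block[j])
                child_values[4 * i + j] = v
                if v < best_val:
                    best_val = v
                    best = block[j].copy()
            # spiral perturbation of the current gazelle, greedy acceptance;
            # the young-male stratum keeps the ordering fixed at the start of
            # the sweep (the habitat is re-sorted only after the loop)
            cand = spiral_perturb(
                pop.positions[i],
                best,
                cfg.spiral_constant,
                rng_spiral,
                spec.lower,
                spec.upper,
            )
            cand_val = evaluate(cand)
            if cand_val < pop.values[i]:
                pop.positions[i] = cand
                pop.values[i] = cand_val
                if cand_val < best_val:
                    best_val = cand_val
                    best = cand.copy()

        pool_pos = np.vstack([pop.positions, children])
        pool_val = np.concatenate([pop.values, child_values])
        order = np.argsort(pool_val, kind="stable")
        pool_pos = pool_pos[order]
        pool_val = pool_val[order]

        # neighborhood search around the (sorted) best and second-best
        y = neighborhood_search(pool_pos[0], pool_pos[1], spec, rng_nb)
        y_val = evaluate(y)
        if y_val < pool_val[0]:
            pool_pos[0] = y
            pool_val[0] = y_val

        pop = Population(pool_pos[:n].copy(), pool_val[:n].copy(), sorted_flag=True)
        trace[t - 1] = pop.best_value

    return OptResult(
        best_position=pop.best_position.copy(),
        best_value=pop.best_value,
        trace=trace,
        n_evals=n_evals,
        seed=cfg.seed,
    )
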