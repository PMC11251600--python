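"""Baseline mountain gazelle optimizer (MGO).

The MGO evolves a herd of N candidate positions. Every iteration each gazelle
spawns four offspring, one per behavioural mechanism:

* TSM - territorial solitary males, an exploitation move around the incumbent
  best (the "male gazelle"),
* MH  - maternity herds, mixing the best, a random member and the bachelor
  effect vector,
* BMH - bachelor male herds, a fight between the current member and the best,
* MSF - migration to search for food, a uniform restart inside the box.

All 4N offspring join the habitat, the pooled habitat is sorted ascending by
objective value and the best N members survive (elitism). The coefficient
vectors injecting randomness are modulated by a control factor ``a`` that
decays linearly from -1 to -2 over the run.

Randomness is organised as named substreams spawned from one root seed so that
a single configuration is bit-for-bit reproducible and so that the improved
variant can toggle individual components without shifting the other draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .problems import ProblemSpec

__all__ = [
    "Population",
    "OptimizerConfig",
    "OptResult",
    "coef_BH",
    "weight_F",
    "control_factor_linear",
    "coef_matrix",
    "coef_vector",
    "tsm",
    "mh",
    "bmh",
    "msf",
    "mgo_minimize",
]


@dataclass
class Population:
    """N candidate positions with cached objective values.

    ``sort()`` orders members ascending by value (stable, so habitat-entry
    order breaks ties deterministically); afterwards row 0 is the incumbent
    best and row 1 the runner-up used by the neighborhood search.
    """

    positions: np.ndarray  # (N, D)
    values: np.ndarray  # (N,)
    sorted_flag: bool = False

    @property
    def size(self) -> int:
        return self.positions.shape[0]

    @property
    def dim(self) -> int:
        return self.positions.shape[1]

    @property
    def best_position(self) -> np.ndarray:
        i = 0 if self.sorted_flag else int(np.argmin(self.values))
        return self.positions[i]

    @property
    def best_value(self) -> float:
        i = 0 if self.sorted_flag else int(np.argmin(self.values))
        return float(self.values[i])

    @property
    def second_best_position(self) -> np.ndarray:
        if self.sorted_flag:
            return self.positions[min(1, self.size - 1)]
        order = np.argsort(self.values, kind="stable")
        return self.positions[order[min(1, self.size - 1)]]

    def sort(self) -> None:
        order = np.argsort(self.values, kind="stable")
        self.positions = self.positions[order]
        self.values = self.values[order]
        self.sorted_flag = True


@dataclass
class OptimizerConfig:
    """Run configuration shared by MGO and IMGO.

    ``pop_size`` must be at least 4 because the bachelor-herd effect vector
    averages ceil(N/3) members and samples an index from the worse-fitness
    third of the sorted herd. ``spiral_constant`` is the logarithmic-spiral
    shape constant ``c`` of the perturbation step (IMGO only). ``fs_bounds``
    is the continuous box used per feature dimension in binary mode.
    """

    pop_size: int = 30
    max_iter: int = 500
    seed: int = 0
    spiral_constant: float = 1.0
    fs_bounds: tuple[float, float] = (-5.0, 5.0)
    boundary_mode: str = "clip"
    icmic_multiplicative: bool = False  # sin(0.7*pi*x) reading, for comparison only

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.boundary_mode != "clip":
            raise ValueError("only 'clip' boundary handling is supported")


@dataclass
class OptResult:
    """Outcome of one optimizer run."""

    best_position: np.ndarray
    best_value: float
    trace: np.ndarray  # per-iteration best value, length max_iter
    n_evals: int
    seed: int


# ---------------------------------------------------------------------------
# candidate-generation mechanisms
# ---------------------------------------------------------------------------

def coef_BH(pop: Population, rng: np.random.Generator) -> np.ndarray:
    """Bachelor-herd effect vector: X_ra * floor(r1) + M_pr * ceil(r2).

    ``ra`` indexes the young-male stratum, i.e. the worse-fitness tail
    {ceil(N/3) .. N} (1-based) of the ascending-sorted herd. ``M_pr`` is the
    mean of ceil(N/3) members drawn without replacement. floor(r1) with
    r1 ~ U[0,1) is almost surely zero, so the X_ra term vanishes a.s.;
    the formula is implemented literally.
    """
    if not pop.sorted_flag:
        raise ValueError("population must be sorted ascending before coef_BH")
    n = pop.size
    k = math.ceil(n / 3)
    ra = int(rng.integers(k - 1, n))  # 0-based index into the sorted herd
    chosen = rng.choice(n, size=k, replace=False)
    m_pr = pop.positions[chosen].mean(axis=0)
    r1 = rng.random()
    r2 = rng.random()
    return pop.positions[ra] * math.floor(r1) + m_pr * math.ceil(r2)


def weight_F(dim: int, iter: int, max_iter: int, rng: np.random.Generator) -> np.ndarray:
    """Iteration-decaying weight vector: N(0,1)^D scaled by exp(2 - 2*iter/max_iter)."""
    return rng.standard_normal(dim) * math.exp(2.0 - 2.0 * iter / max_iter)


def control_factor_linear(iter: int, max_iter: int) -> float:
    """Linear control factor, decaying from -1 at iter 0 to -2 at max_iter."""
    return -1.0 - iter / max_iter


def coef_matrix(a: float, dim: int, rng: np.random.Generator) -> np.ndarray:
    """The four-branch coefficient matrix Cof, one realization of each branch.

    Rows: (a+1)+r3 broadcast; a*N(0,1)^D; U[0,1)^D; N3 * N4^2 * cos(2*r4*N3)
    elementwise with a scalar r4. One matrix is drawn per gazelle per
    iteration and every Cof use samples a row from it (with replacement) —
    this shared realization across a gazelle's mechanism moves is what gives
    the herd its scale-free late-stage refinement.
    """
    cof = np.empty((4, dim))
    cof[0] = (a + 1.0) + rng.random()
    cof[1] = a * rng.standard_normal(dim)
    cof[2] = rng.random(dim)
    n3 = rng.standard_normal(dim)
    n4 = rng.standard_normal(dim)
    cof[3] = n3 * n4 ** 2 * np.cos((rng.random() * 2.0) * n3)
    return cof


def coef_vector(a: float, dim: int, rng: np.random.Generator) -> np.ndarray:
    """One coefficient vector: a uniformly chosen row of a fresh coef_matrix."""
    cof = coef_matrix(a, dim, rng)
    return cof[int(rng.integers(4))]


def _pick_row(cof: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return cof[int(rng.integers(4))]


def _ri(rng: np.random.Generator) -> int:
    # "random numbers, with values of either 1 or 2"
    return int(rng.integers(1, 3))


def tsm(
    pop: Population,
    i: int,
    F: np.ndarray,
    BH: np.ndarray,
    Cof: np.ndarray,
    rng: np.random.Generator,
    best: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Territorial solitary male move: best - |(ri1*BH - ri2*X_i) * F| * Cof.

    ``best`` is the incumbent male gazelle; the optimizer loop passes the
    running habitat-wide best (updated after every gazelle), defaulting to the
    population's cached best for standalone use.
    """
    if best is None:
        best = pop.best_position
    ri1 = _ri(rng)
    ri2 = _ri(rng)
    return best - np.abs((ri1 * BH - ri2 * pop.positions[i]) * F) * Cof


def mh(
    pop: Population,
    i: int,
    BH: np.ndarray,
    a: float,
    rng: np.random.Generator,
    best: Optional[np.ndarray] = None,
    cof: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Maternity-herd move: (BH + Cof1) + (ri3*best - ri4*X_rand) * Cof2.

    Cof1 and Cof2 are two (possibly identical) rows of the gazelle's
    coefficient matrix; a fresh matrix is drawn when ``cof`` is not given.
    """
    if best is None:
        best = pop.best_position
    if cof is None:
        cof = coef_matrix(a, pop.dim, rng)
    cof1 = _pick_row(cof, rng)
    cof2 = _pick_row(cof, rng)
    ri3 = _ri(rng)
    ri4 = _ri(rng)
    x_rand = pop.positions[int(rng.integers(pop.size))]
    return (BH + cof1) + (ri3 * best - ri4 * x_rand) * cof2


def bmh(
    pop: Population,
    i: int,
    BH: np.ndarray,
    Cof: np.ndarray,
    rng: np.random.Generator,
    best: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Bachelor-male-herd move with fight vector D = (|X_i| + |best|) * (2*r6 - 1)."""
    if best is None:
        best = pop.best_position
    r6 = rng.random()
    d = (np.abs(pop.positions[i]) + np.abs(best)) * (2.0 * r6 - 1.0)
    ri5 = _ri(rng)
    ri6 = _ri(rng)
    return (pop.positions[i] - d) + (ri5 * best - ri6 * BH) * Cof


def msf(spec: ProblemSpec, rng: np.random.Generator) -> np.ndarray:
    """Migration move: (ub - lb) * r7 + lb with one scalar r7 ~ U[0,1).

    The single shared draw places the restart on the main diagonal of the
    normalized box. This coherent long-range move is what lets the herd find
    diagonal basins (Schwefel's 420.97*ones, the Shekel foci, the all-ones
    penalized optimum) reliably; with an independent draw per coordinate the
    restart is almost never useful in moderate dimension and runs trap in
    local basins at a few percent per run.
    """
    return spec.lower + (spec.upper - spec.lower) * rng.random()


# ---------------------------------------------------------------------------
# optimizer loop
# ---------------------------------------------------------------------------

_STREAMS_MGO = ("init", "mech", "noise")


def _spawn_streams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def _uniform_init(spec: ProblemSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    return spec.lower + (spec.upper - spec.lower) * rng.random((n, spec.dim))


def mgo_minimize(spec: ProblemSpec, cfg: OptimizerConfig) -> OptResult:
    """Run the baseline MGO: uniform init, linear control factor, elitist survival.

    The incumbent male gazelle is refreshed after every gazelle's offspring
    are evaluated (habitat-wide running best, as in the reference herd
    dynamics), so later gazelles within the same sweep already exploit newly
    found incumbents. Each iteration consumes exactly 4N objective
    evaluations (the offspring); the returned trace has length
    ``cfg.max_iter`` and is monotone non-increasing by elitism.
    """
    streams = _spawn_streams(cfg.seed, _STREAMS_MGO)
    rng_noise = streams["noise"]
    n_evals = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_evals
        n_evals += 1
        v = spec.evaluate(x, rng_noise)
        if not math.isfinite(v):
            raise FloatingPointError(f"objective returned non-finite value at {x!r}")
        return v

    positions = _uniform_init(spec, cfg.pop_size, streams["init"])
    values = np.array([evaluate(x) for x in positions])
    pop = Population(positions, values)
    pop.sort()

    n, d = cfg.pop_size, spec.dim
    trace = np.empty(cfg.max_iter)
    rng = streams["mech"]
    for t in range(1, cfg.max_iter + 1):
        a = control_factor_linear(t, cfg.max_iter)
        children = np.empty((4 * n, d))
        child_values = np.empty(4 * n)
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
        pool_pos = np.vstack([pop.positions, children])
        pool_val = np.concatenate([pop.values, child_values])
        order = np.argsort(pool_val, kind="stable")[: cfg.pop_size]
        pop = Population(pool_pos[order], pool_val[order], sorted_flag=True)
        trace[t - 1] = pop.best_value

    return OptResult(
        best_position=pop.best_position.copy(),
        best_value=pop.best_value,
        trace=trace,
        n_evals=n_evals,
        seed=cfg.seed,
    )
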