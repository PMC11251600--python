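"""Registry of the 23 classical benchmark functions used to evaluate the optimizer.

The suite splits into three families:

* ``f1``-``f7``   unimodal functions (dimension-generic, default dim 30),
* ``f8``-``f13``  multimodal functions (dimension-generic, default dim 30),
* ``f14``-``f23`` fixed-dimension multimodal functions (foxholes, Kowalik,
  six-hump camel, Branin, Goldstein-Price, Hartmann 3/6, Shekel m=5/7/10).

Each entry carries its box bounds and the documented global optimum so the
test-suite and experiment runner can measure convergence against ground truth.
``f7`` is the only stochastic objective: it adds a single ``U[0,1)`` noise term
per full-vector evaluation and therefore takes an explicit random generator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "ProblemSpec",
    "get_problem",
    "reference_optimum",
    "list_problems",
    "multistart_minimum",
]


@dataclass(frozen=True)
class ProblemSpec:
    """A continuous box-constrained minimization task."""

    name: str
    dim: int
    lower: np.ndarray
    upper: np.ndarray
    objective: Callable[..., float]
    known_optimum: Optional[float] = None
    stochastic: bool = False
    fixed_dim: bool = False

    def __post_init__(self) -> None:
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if lower.shape != (self.dim,) or upper.shape != (self.dim,):
            raise ValueError("bounds must match the problem dimension")
        if not np.all(lower < upper):
            raise ValueError("lower bounds must be elementwise below upper bounds")
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)

    def evaluate(self, x: np.ndarray, rng: Optional[np.random.Generator] = None) -> float:
        """Evaluate the objective; ``rng`` feeds the noise term of stochastic objectives."""
        x = np.asarray(x, dtype=float)
        if self.stochastic:
            return float(self.objective(x, rng))
        return float(self.objective(x))

    def clip(self, x: np.ndarray) -> np.ndarray:
        return np.clip(x, self.lower, self.upper)


# ---------------------------------------------------------------------------
# objective definitions
# ---------------------------------------------------------------------------

def _sphere(x):
    return float(np.dot(x, x))


def _schwefel_2_22(x):
    a = np.abs(x)
    return float(np.sum(a) + np.prod(a))


def _schwefel_1_2(x):
    return float(np.sum(np.cumsum(x) ** 2))


def _schwefel_2_21(x):
    return float(np.max(np.abs(x)))


def _rosenbrock(x):
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (x[:-1] - 1.0) ** 2))


def _step(x):
    return float(np.sum(np.floor(x + 0.5) ** 2))


def _quartic_noise(x, rng=None):
    base = float(np.sum(np.arange(1, x.size + 1) * x ** 4))
    if rng is not None:
        base += float(rng.random())
    return base


def _schwefel(x):
    return float(-np.sum(x * np.sin(np.sqrt(np.abs(x)))))


def _rastrigin(x):
    return float(np.sum(x * x - 10.0 * np.cos(2.0 * np.pi * x) + 10.0))


def _ackley(x):
    d = x.size
    return float(
        -20.0 * np.exp(-0.2 * np.sqrt(np.sum(x * x) / d))
        - np.exp(np.sum(np.cos(2.0 * np.pi * x)) / d)
        + 20.0
        + np.e
    )


def _griewank(x):
    i = np.arange(1, x.size + 1, dtype=float)
    return float(np.sum(x * x) / 4000.0 - np.prod(np.cos(x / np.sqrt(i))) + 1.0)


def _penalty_u(x, a, k, m):
    # middle branch is zero on [-a, a] inclusive (ties go to the zero branch)
    out = np.zeros_like(x)
    hi = x > a
    lo = x < -a
    out[hi] = k * (x[hi] - a) ** m
    out[lo] = k * (-x[lo] - a) ** m
    return out


def _penalized_1(x):
    n = x.size
    y = 1.0 + (x + 1.0) / 4.0
    core = (
        10.0 * math.sin(math.pi * y[0]) ** 2
        + np.sum((y[:-1] - 1.0) ** 2 * (1.0 + 10.0 * np.sin(math.pi * y[1:]) ** 2))
        + (y[-1] - 1.0) ** 2
    )
    return float(math.pi / n * core + np.sum(_penalty_u(x, 5.0, 100.0, 4.0)))


def _penalized_2(x):
    core = (
        math.sin(3.0 * math.pi * x[0]) ** 2
        + np.sum((x[:-1] - 1.0) ** 2 * (1.0 + np.sin(3.0 * math.pi * x[1:]) ** 2))
        + (x[-1] - 1.0) ** 2 * (1.0 + math.sin(2.0 * math.pi * x[-1]) ** 2)
    )
    return float(0.1 * core + np.sum(_penalty_u(x, 5.0, 100.0, 4.0)))


# --- fixed-dimension functions ---------------------------------------------

_FOXHOLES_A = np.array(
    [
        [-32, -16, 0, 16, 32] * 5,
        [-32] * 5 + [-16] * 5 + [0] * 5 + [16] * 5 + [32] * 5,
    ],
    dtype=float,
)


def _foxholes(x):
    j = np.arange(1, 26, dtype=float)
    denom = j + np.sum((x[:, None] - _FOXHOLES_A) ** 6, axis=0)
    return float(1.0 / (1.0 / 500.0 + np.sum(1.0 / denom)))


_KOWALIK_A = np.array(
    [0.1957, 0.1947, 0.1735, 0.16, 0.0844, 0.0627, 0.0456, 0.0342, 0.0323, 0.0235, 0.0246]
)
_KOWALIK_B = 1.0 / np.array([0.25, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0])


def _kowalik(x):
    b = _KOWALIK_B
    model = x[0] * (b * b + b * x[1]) / (b * b + b * x[2] + x[3])
    return float(np.sum((_KOWALIK_A - model) ** 2))


def _six_hump_camel(x):
    x1, x2 = x
    return float(
        4.0 * x1 ** 2 - 2.1 * x1 ** 4 + x1 ** 6 / 3.0 + x1 * x2 - 4.0 * x2 ** 2 + 4.0 * x2 ** 4
    )


def _branin(x):
    x1, x2 = x
    return float(
        (x2 - 5.1 / (4.0 * math.pi ** 2) * x1 ** 2 + 5.0 / math.pi * x1 - 6.0) ** 2
        + 10.0 * (1.0 - 1.0 / (8.0 * math.pi)) * math.cos(x1)
        + 10.0
    )


def _goldstein_price(x):
    x1, x2 = x
    a = 1.0 + (x1 + x2 + 1.0) ** 2 * (
        19.0 - 14.0 * x1 + 3.0 * x1 ** 2 - 14.0 * x2 + 6.0 * x1 * x2 + 3.0 * x2 ** 2
    )
    b = 30.0 + (2.0 * x1 - 3.0 * x2) ** 2 * (
        18.0 - 32.0 * x1 + 12.0 * x1 ** 2 + 48.0 * x2 - 36.0 * x1 * x2 + 27.0 * x2 ** 2
    )
    return float(a * b)


_HARTMANN3_A = np.array(
    [[3.0, 10.0, 30.0], [0.1, 10.0, 35.0], [3.0, 10.0, 30.0], [0.1, 10.0, 35.0]]
)
_HARTMANN3_C = np.array([1.0, 1.2, 3.0, 3.2])
_HARTMANN3_P = np.array(
    [
        [0.3689, 0.1170, 0.2673],
        [0.4699, 0.4387, 0.7470],
        [0.1091, 0.8732, 0.5547],
        [0.03815, 0.5743, 0.8828],
    ]
)

_HARTMANN6_A = np.array(
    [
        [10.0, 3.0, 17.0, 3.5, 1.7, 8.0],
        [0.05, 10.0, 17.0, 0.1, 8.0, 14.0],
        [3.0, 3.5, 1.7, 10.0, 17.0, 8.0],
        [17.0, 8.0, 0.05, 10.0, 0.1, 14.0],
    ]
)
_HARTMANN6_C = np.array([1.0, 1.2, 3.0, 3.2])
_HARTMANN6_P = np.array(
    [
        [0.1312, 0.1696, 0.5569, 0.0124, 0.8283, 0.5886],
        [0.2329, 0.4135, 0.8307, 0.3736, 0.1004, 0.9991],
        [0.2348, 0.1451, 0.3522, 0.2883, 0.3047, 0.6650],
        [0.4047, 0.8828, 0.8732, 0.5743, 0.1091, 0.0381],
    ]
)


def _hartmann(x, a, c, p):
    return float(-np.sum(c * np.exp(-np.sum(a * (x[None, :] - p) ** 2, axis=1))))


def _hartmann3(x):
    return _hartmann(x, _HARTMANN3_A, _HARTMANN3_C, _HARTMANN3_P)


def _hartmann6(x):
    return _hartmann(x, _HARTMANN6_A, _HARTMANN6_C, _HARTMANN6_P)


_SHEKEL_A = np.array(
    [
        [4.0, 4.0, 4.0, 4.0],
        [1.0, 1.0, 1.0, 1.0],
        [8.0, 8.0, 8.0, 8.0],
        [6.0, 6.0, 6.0, 6.0],
        [3.0, 7.0, 3.0, 7.0],
        [2.0, 9.0, 2.0, 9.0],
        [5.0, 5.0, 3.0, 3.0],
        [8.0, 1.0, 8.0, 1.0],
        [6.0, 2.0, 6.0, 2.0],
        [7.0, 3.6, 7.0, 3.6],
    ]
)
_SHEKEL_C = np.array([0.1, 0.2, 0.2, 0.4, 0.4, 0.6, 0.3, 0.7, 0.5, 0.5])


def _shekel(x, m):
    diff = x[None, :] - _SHEKEL_A[:m]
    return float(-np.sum(1.0 / (np.sum(diff * diff, axis=1) + _SHEKEL_C[:m])))


def _shekel5(x):
    return _shekel(x, 5)


def _shekel7(x):
    return _shekel(x, 7)


def _shekel10(x):
    return _shekel(x, 10)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

# name -> (objective, default dim, (lo, hi), known optimum, fixed_dim, stochastic)
_REGISTRY: dict[str, tuple] = {
    "f1": (_sphere, 30, (-100.0, 100.0), 0.0, False, False),
    "f2": (_schwefel_2_22, 30, (-10.0, 10.0), 0.0, False, False),
    "f3": (_schwefel_1_2, 30, (-100.0, 100.0), 0.0, False, False),
    "f4": (_schwefel_2_21, 30, (-100.0, 100.0), 0.0, False, False),
    "f5": (_rosenbrock, 30, (-30.0, 30.0), 0.0, False, False),
    "f6": (_step, 30, (-100.0, 100.0), 0.0, False, False),
    "f7": (_quartic_noise, 30, (-1.28, 1.28), 0.0, False, True),
    "f8": (_schwefel, 30, (-500.0, 500.0), None, False, False),  # -418.9829 * dim
    "f9": (_rastrigin, 30, (-5.12, 5.12), 0.0, False, False),
    "f10": (_ackley, 30, (-32.0, 32.0), 0.0, False, False),
    "f11": (_griewank, 30, (-600.0, 600.0), 0.0, False, False),
    "f12": (_penalized_1, 30, (-50.0, 50.0), 0.0, False, False),
    "f13": (_penalized_2, 30, (-50.0, 50.0), 0.0, False, False),
    "f14": (_foxholes, 2, (-65.0, 65.0), 0.9980038377944498, True, False),
    "f15": (_kowalik, 4, (-5.0, 5.0), 3.0748598778245e-4, True, False),
    "f16": (_six_hump_camel, 2, (-5.0, 5.0), -1.0316284534898774, True, False),
    "f17": (_branin, 2, (-5.0, 5.0), 0.39788735772973816, True, False),
    "f18": (_goldstein_price, 2, (-2.0, 2.0), 3.0, True, False),
    # Hartmann-3 lives on the unit cube; the optimum -3.8628 is only attainable there.
    "f19": (_hartmann3, 3, (0.0, 1.0), -3.862782147820756, True, False),
    "f20": (_hartmann6, 6, (0.0, 1.0), -3.3223680114155156, True, False),
    "f21": (_shekel5, 4, (0.0, 10.0), -10.153199679058231, True, False),
    "f22": (_shekel7, 4, (0.0, 10.0), -10.402940566818663, True, False),
    "f23": (_shekel10, 4, (0.0, 10.0), -10.536409816692046, True, False),
}

_SCHWEFEL_OPT_PER_DIM = -418.9829


def list_problems() -> list[str]:
    return list(_REGISTRY)


def get_problem(name: str, dim: Optional[int] = None) -> ProblemSpec:
    """Look up a benchmark by name, optionally overriding the dimension.

    Dimension overrides are only legal for the dimension-generic functions
    f1-f13; the fixed-dimension functions f14-f23 reject them.
    """
    if name not in _REGISTRY:
        raise KeyError(f"unknown benchmark function: {name!r}")
    obj, default_dim, (lo, hi), opt, fixed, stochastic = _REGISTRY[name]
    if fixed and dim is not None and dim != default_dim:
        raise ValueError(f"{name} has fixed dimension {default_dim}")
    d = default_dim if dim is None else int(dim)
    if d < 1:
        raise ValueError("dimension must be positive")
    if name == "f8":
        opt = _SCHWEFEL_OPT_PER_DIM * d
    return ProblemSpec(
        name=name,
        dim=d,
        lower=np.full(d, lo),
        upper=np.full(d, hi),
        objective=obj,
        known_optimum=opt,
        stochastic=stochastic,
        fixed_dim=fixed,
    )


def reference_optimum(name: str, dim: Optional[int] = None) -> float:
    """The documented optimum of a benchmark (for f8, -418.9829 x dim)."""
    spec = get_problem(name, dim)
    return float(spec.known_optimum)


# Shekel foci double as good multistart seeds for f21-f23.
def _default_starts(spec: ProblemSpec) -> np.ndarray:
    if spec.name in ("f21", "f22", "f23"):
        m = {"f21": 5, "f22": 7, "f23": 10}[spec.name]
        return _SHEKEL_A[:m].copy()
    return np.empty((0, spec.dim))


def multistart_minimum(
    spec: ProblemSpec,
    grid: int = 5,
    n_refine: int = 20,
    extra_starts: Optional[Sequence[np.ndarray]] = None,
) -> float:
    """Global minimum of a deterministic benchmark by dense-grid multistart descent.

    Evaluates the objective on a ``grid``-per-axis lattice over the box, keeps
    the ``n_refine`` best lattice points, and polishes each (plus any
    ``extra_starts``; for the Shekel functions the classical foci are added
    automatically) with bounded L-BFGS-B. Deterministic; used as the
    independent oracle for the registry's documented optima.
    """
    if spec.stochastic:
        raise ValueError("multistart oracle only applies to deterministic objectives")
    axes = [np.linspace(lo, hi, grid) for lo, hi in zip(spec.lower, spec.upper)]
    mesh = np.meshgrid(*axes, indexing="ij")
    points = np.stack([m.ravel() for m in mesh], axis=1)
    values = np.array([spec.objective(p) for p in points])
    order = np.argsort(values, kind="stable")[:n_refine]
    starts = [points[i] for i in order]
    starts.extend(np.asarray(s, dtype=float) for s in _default_starts(spec))
    if extra_starts is not None:
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
    bounds = list(zip(spec.lower, spec.upper))
    best = math.inf
    for s in starts:
        res = minimize(spec.objective, s, method="L-BFGS-B", bounds=bounds)
        if res.fun < best:
            best = float(res.fun)
    return best
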