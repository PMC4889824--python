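"""Cuckoo Search over a mixed integer/real search space.

The optimizer maintains a fixed population of "nests" (candidate solutions).
Each iteration, every nest proposes a new solution by a Lévy flight biased
toward the current best; the proposal is compared against a randomly chosen
nest and replaces it if better.  A fraction ``pa`` of the non-elite nests is
then abandoned and rebuilt by a biased random walk, and the best nest is
carried over unchanged (elitism), so the best fitness trace is monotone.

Fitness is a pair: a primary score to maximise (here, a cross-validated
classification rate in percent) and a secondary cost to minimise on exact
primary ties (here, the support-vector count).  Integer dimensions (kernel
family index, polynomial degree) live on the real line internally and are
rounded on decoding; log-scaled real dimensions (C, gamma) are searched in
log10 space.

Lévy steps use Mantegna's algorithm: step = u / |v|^(1/alpha) with
u ~ N(0, sigma_u^2), v ~ N(0, 1) and

    sigma_u = [Gamma(1+a) sin(pi a/2) / (Gamma((1+a)/2) a 2^((a-1)/2))]^(1/a).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.special import gamma as _gamma_fn

from .exceptions import StateError, ValidationError

FitnessFn = Callable[[dict], tuple[float, float]]


@dataclass(frozen=True)
class SearchSpace:
    """Bounded mixed integer/real search space.

    integer_dims: (name, low, high) inclusive integer ranges.
    real_dims: (name, low, high, scale) with scale "linear" or "log10"
    (log dims require low > 0 and are searched uniformly in log space).
    Integer dims come first in the internal continuous representation.
    """

    integer_dims: tuple[tuple[str, int, int], ...] = ()
    real_dims: tuple[tuple[str, float, float, str], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "integer_dims", tuple(tuple(d) for d in self.integer_dims))
        object.__setattr__(self, "real_dims", tuple(tuple(d) for d in self.real_dims))
        for name, low, high in self.integer_dims:
            if low >= high:
                raise ValidationError(f"integer dim {name!r}: low {low} >= high {high}")
        for name, low, high, scale in self.real_dims:
            if low >= high:
                raise ValidationError(f"real dim {name!r}: low {low} >= high {high}")
            if scale not in ("linear", "log10"):
                raise ValidationError(f"real dim {name!r}: unknown scale {scale!r}")
            if scale == "log10" and low <= 0:
                raise ValidationError(f"log-scaled dim {name!r} needs low > 0; got {low}")

    @property
    def names(self) -> list[str]:
        return [d[0] for d in self.integer_dims] + [d[0] for d in self.real_dims]

    @property
    def dim(self) -> int:
        return len(self.integer_dims) + len(self.real_dims)

    def internal_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) of the internal continuous representation."""
        lows, highs = [], []
        for _, lo, hi in self.integer_dims:
            lows.append(float(lo))
            highs.append(float(hi))
        for _, lo, hi, scale in self.real_dims:
            if scale == "log10":
                lows.append(math.log10(lo))
                highs.append(math.log10(hi))
            else:
                lows.append(float(lo))
                highs.append(float(hi))
        return np.array(lows), np.array(highs)

    def clip(self, position: np.ndarray) -> np.ndarray:
        lo, hi = self.internal_bounds()
        return np.clip(position, lo, hi)

    def sample_uniform(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.internal_bounds()
        return rng.uniform(lo, hi)


def decode(position: np.ndarray, space: SearchSpace) -> dict:
    """Map an internal position to named parameter values.

    Integer dims round to the nearest in-range integer; log dims exponentiate.
    """
    position = np.asarray(position, dtype=float)
    out: dict = {}
    i = 0
    for name, lo, hi in space.integer_dims:
        out[name] = int(min(max(round(position[i]), lo), hi))
        i += 1
    for name, lo, hi, scale in space.real_dims:
        v = position[i]
        x = float(10.0 ** v) if scale == "log10" else float(v)
        out[name] = min(max(x, lo), hi)  # guard float drift at the bounds
        i += 1
    return out


def encode(params: dict, space: SearchSpace) -> np.ndarray:
    """Inverse of :func:`decode` on representable points."""
    vals = []
    for name, _, _ in space.integer_dims:
        vals.append(float(params[name]))
    for name, _, _, scale in space.real_dims:
        v = float(params[name])
        vals.append(math.log10(v) if scale == "log10" else v)
    return np.array(vals)


def mantegna_sigma_u(alpha: float) -> float:
    """Scale of the numerator Gaussian in Mantegna's Lévy-step algorithm."""
    if not (1.0 < alpha <= 2.0):
        raise ValidationError(f"levy alpha must be in (1, 2]; got {alpha}")
    num = _gamma_fn(1.0 + alpha) * math.sin(math.pi * alpha / 2.0)
    den = _gamma_fn((1.0 + alpha) / 2.0) * alpha * 2.0 ** ((alpha - 1.0) / 2.0)
    return float((num / den) ** (1.0 / alpha))


def levy_step(alpha: float, dim: int, rng: np.random.Generator) -> np.ndarray:
    """A heavy-tailed step vector (Mantegna's algorithm), one draw per dimension."""
    sigma_u = mantegna_sigma_u(alpha)
    u = rng.normal(0.0, sigma_u, size=dim)
    v = rng.normal(0.0, 1.0, size=dim)
    return u / np.abs(v) ** (1.0 / alpha)


@dataclass
class Nest:
    """A candidate solution with its fitness pair once evaluated."""

    position: np.ndarray
    fitness_primary: float | None = None
    fitness_secondary: float | None = None

    @property
    def evaluated(self) -> bool:
        return self.fitness_primary is not None


@dataclass(frozen=True)
class CsConfig:
    """Cuckoo Search hyperparameters.

    step_scale is a fraction of each dimension's internal range; abandonment
    applies independently per non-elite nest with probability pa_abandon.
    """

    n_nests: int = 25
    pa_abandon: float = 0.25
    max_iterations: int = 50
    levy_alpha: float = 1.5
    step_scale: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nests < 2:
            raise ValidationError("n_nests must be >= 2")
        if not (0.0 < self.pa_abandon < 1.0) and self.pa_abandon not in (0.0, 1.0):
            raise ValidationError("pa_abandon must be in [0, 1]")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if not (1.0 < self.levy_alpha <= 2.0):
            raise ValidationError("levy_alpha must be in (1, 2]")
        if self.step_scale < 0:
            raise ValidationError("step_scale must be >= 0")


def compare_fitness(a: Nest, b: Nest) -> Nest:
    """Return the better nest: higher primary; exact primary tie broken by
    lower secondary (fewer support vectors); full tie keeps the incumbent a."""
    if not (a.evaluated and b.evaluated):
        raise StateError("both nests must be evaluated before comparison")
    if b.fitness_primary > a.fitness_primary:
        return b
    if b.fitness_primary == a.fitness_primary and b.fitness_secondary < a.fitness_secondary:
        return b
    return a


def propose_cuckoo(
    nest: Nest,
    best: Nest,
    cfg: CsConfig,
    space: SearchSpace,
    rng: np.random.Generator,
) -> np.ndarray:
    """Lévy-flight proposal biased toward the current best, clipped to bounds."""
    lo, hi = space.internal_bounds()
    scale = cfg.step_scale * (hi - lo)
    step = scale * levy_step(cfg.levy_alpha, space.dim, rng) * (nest.position - best.position)
    return space.clip(nest.position + step)


def abandon_and_rebuild(
    population: list[Nest],
    pa: float,
    space: SearchSpace,
    rng: np.random.Generator,
) -> list[Nest]:
    """Replace each non-elite nest with probability pa by a biased random walk.

    The rebuild step is position + U(0,1) * (perm1 - perm2) over two random
    permutations of the population, clipped to bounds; rebuilt nests come back
    unevaluated.  The elite (best) nest is never abandoned.
    """
    n = len(population)
    elite_idx = 0
    for i in range(1, n):
        if compare_fitness(population[elite_idx], population[i]) is population[i]:
            elite_idx = i
    perm1 = rng.permutation(n)
    perm2 = rng.permutation(n)
    replace_mask = rng.random(n) < pa
    out: list[Nest] = []
    for i, nest in enumerate(population):
        if i == elite_idx or not replace_mask[i]:
            out.append(nest)
            continue
        walk = rng.random(space.dim) * (
            population[perm1[i]].position - population[perm2[i]].position
        )
        out.append(Nest(position=space.clip(nest.position + walk)))
    return out


@dataclass
class OptResult:
    """Outcome of a CS run: winner, decoded parameters, and per-iteration trace."""

    best_position: np.ndarray
    best_params: dict
    best_primary: float
    best_secondary: float
    trace: list[tuple[int, float, float]]  # (iteration, best primary, best secondary)
    n_evaluations: int
    eval_log: list[tuple[dict, float, float]] = field(default_factory=list)


def cs_optimize(
    fitness_fn: FitnessFn,
    space: SearchSpace,
    cfg: CsConfig,
    record_evals: bool = False,
) -> OptResult:
    """Run Cuckoo Search; fully reproducible from ``cfg.rng_seed``.

    ``fitness_fn`` maps a decoded parameter dict to (primary, secondary);
    primary is maximised, secondary breaks exact primary ties (minimised).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    eval_log: list[tuple[dict, float, float]] = []
    n_evals = 0

    def evaluate(position: np.ndarray) -> Nest:
        nonlocal n_evals
        params = decode(position, space)
        primary, secondary = fitness_fn(params)
        n_evals += 1
        if record_evals:
            eval_log.append((params, float(primary), float(secondary)))
        return Nest(position=position, fitness_primary=float(primary),
                    fitness_secondary=float(secondary))

    population = [evaluate(space.sample_uniform(rng)) for _ in range(cfg.n_nests)]
    best = population[0]
    for nest in population[1:]:
        best = compare_fitness(best, nest)

    trace: list[tuple[int, float, float]] = [(0, best.fitness_primary, best.fitness_secondary)]
    for it in range(1, cfg.max_iterations + 1):
        # one egg per cuckoo: every nest emits a Lévy proposal, dropped into
        # a randomly chosen nest if better.  A zero-displacement proposal
        # (a nest sitting exactly at the best) is a no-op: re-evaluating an
        # unchanged position would only seed the population with exact
        # duplicates of the elite and stall the walk.
        for i in range(cfg.n_nests):
            pos_new = propose_cuckoo(population[i], best, cfg, space, rng)
            if np.array_equal(pos_new, population[i].position):
                continue
            candidate = evaluate(pos_new)
            j = int(rng.integers(cfg.n_nests))
            population[j] = compare_fitness(population[j], candidate)
            best = compare_fitness(best, candidate)

        population = abandon_and_rebuild(population, cfg.pa_abandon, space, rng)
        for i, nest in enumerate(population):
            if not nest.evaluated:
                population[i] = evaluate(nest.position)
                best = compare_fitness(best, population[i])
        trace.append((it, best.fitness_primary, best.fitness_secondary))

    return OptResult(
        best_position=best.position.copy(),
        best_params=decode(best.position, space),
        best_primary=best.fitness_primary,
        best_secondary=best.fitness_secondary,
        trace=trace,
        n_evaluations=n_evals,
        eval_log=eval_log,
    )


def default_svm_search_space() -> SearchSpace:
    """The kernel-selection space: family index and degree as integers; C and
    gamma log-scaled; coef0 linear."""
    return SearchSpace(
        integer_dims=(("kernel", 0, 2), ("degree", 2, 5)),
        real_dims=(
            ("c_soft_margin", 2.0 ** -5, 2.0 ** 15, "log10"),
            ("gamma", 2.0 ** -15, 2.0 ** 3, "log10"),
            ("coef0", 0.0, 10.0, "linear"),
        ),
    )
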