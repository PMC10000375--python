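"""Harris hawks optimization (HHO).

A population metaheuristic that mimics the cooperative hunting of Harris
hawks.  A flock of candidate solutions ("hawks") circles the best solution
found so far (the "prey").  A prey-energy parameter decays over iterations
and switches the flock from global exploration to one of four exploitation
("besiege") strategies, two of which take heavy-tailed Levy-flight dives.

The engine is generic: it minimizes any callable ``objective(x) -> float``
over a box.  Callers that want to maximize (e.g. contrast enhancement)
negate their fitness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gamma as _gamma

__all__ = [
    "HHOConfig",
    "HawkState",
    "HHOResult",
    "prey_energy",
    "jump_strength",
    "levy_step",
    "hawk_update",
    "optimize",
]

_LEVY_BETA = 1.5
# Mantegna scale for beta = 1.5, precomputed once.
_LEVY_SIGMA = (
    _gamma(1 + _LEVY_BETA)
    * np.sin(np.pi * _LEVY_BETA / 2)
    / (_gamma((1 + _LEVY_BETA) / 2) * _LEVY_BETA * 2 ** ((_LEVY_BETA - 1) / 2))
) ** (1 / _LEVY_BETA)


@dataclass
class HHOConfig:
    """Run configuration: population size, iteration budget and search box."""

    ps: int
    tm: int
    lb: np.ndarray
    ub: np.ndarray
    dim: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.lb = np.atleast_1d(np.asarray(self.lb, dtype=float))
        self.ub = np.atleast_1d(np.asarray(self.ub, dtype=float))
        if self.dim is None:
            self.dim = max(self.lb.size, self.ub.size)
        self.lb = np.broadcast_to(self.lb, (self.dim,)).copy()
        self.ub = np.broadcast_to(self.ub, (self.dim,)).copy()
        if self.ps < 2:
            raise ValueError(f"population size must be >= 2, got {self.ps}")
        if self.tm < 1:
            raise ValueError(f"iteration budget must be >= 1, got {self.tm}")
        if not np.all(self.lb < self.ub):
            raise ValueError("lower bounds must be elementwise below upper bounds")


@dataclass
class HawkState:
    """Position and fitness of one hawk."""

    x: np.ndarray
    fitness: float


@dataclass
class HHOResult:
    """Best solution plus the per-iteration best-so-far fitness trace."""

    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray = field(default_factory=lambda: np.empty(0))


def prey_energy(e0: float, iteration: int, tm: int) -> float:
    """Escaping energy ``Ep = 2*E0*(1 - iteration/tm)`` of the prey.

    ``e0`` is the initial energy in [-1, 1]; the linear decay drives the
    exploration/exploitation switch.
    """
    if not 0 <= iteration <= tm:
        raise ValueError(f"iteration must lie in [0, {tm}], got {iteration}")
    return 2.0 * e0 * (1.0 - iteration / tm)


def jump_strength(r5: float) -> float:
    """Prey jump intensity ``F = 2*(1 - r5)`` for ``r5`` uniform in [0, 1]."""
    if not 0.0 <= r5 <= 1.0:
        raise ValueError(f"r5 must lie in [0, 1], got {r5}")
    return 2.0 * (1.0 - r5)


def levy_step(d: int, rng: np.random.Generator | int) -> np.ndarray:
    """Heavy-tailed Levy-flight step (Mantegna construction, beta=1.5).

    ``rng`` may be a Generator or an integer seed; the draw is deterministic
    given the seed.
    """
    if d < 1:
        raise ValueError(f"dimension must be >= 1, got {d}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    u = rng.normal(0.0, _LEVY_SIGMA, size=d)
    v = rng.normal(0.0, 1.0, size=d)
    return 0.01 * u / np.abs(v) ** (1.0 / _LEVY_BETA)


def _clip(x: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> np.ndarray:
    return np.clip(x, lb, ub)


def hawk_update(
    hawk: HawkState,
    prey: HawkState,
    mean_pos: np.ndarray,
    ep: float,
    lb: np.ndarray,
    ub: np.ndarray,
    objective,
    rng: np.random.Generator,
    rand_pos: np.ndarray | None = None,
) -> np.ndarray:
    """One position update for a single hawk; result clipped to the box.

    Branch selection:

    * ``|Ep| >= 1`` — exploration: perch on a random hawk or relative to the
      prey and the flock mean (q sub-branch).
    * ``r >= 0.5 and |Ep| >= 0.5`` — soft besiege.
    * ``r >= 0.5 and |Ep| < 0.5`` — hard besiege.
    * ``r < 0.5 and |Ep| >= 0.5`` — soft besiege with progressive rapid
      dives (Levy flight); a dive is accepted only if fitter.
    * ``r < 0.5 and |Ep| < 0.5`` — hard besiege with rapid dives, with the
      first dive aimed relative to the flock mean.
    """
    x = hawk.x
    xp = prey.x
    d = x.size
    r = rng.random()
    f = jump_strength(rng.random())

    if abs(ep) >= 1.0:
        q = rng.random()
        if q >= 0.5:
            xr = rand_pos if rand_pos is not None else x
            r1, r2 = rng.random(), rng.random()
            new = xr - r1 * np.abs(xr - 2.0 * r2 * x)
        else:
            r3, r4 = rng.random(), rng.random()
            new = (xp - mean_pos) - r3 * (lb + r4 * (ub - lb))
        return _clip(new, lb, ub)

    if r >= 0.5 and abs(ep) >= 0.5:  # soft besiege
        dx = xp - x
        return _clip(dx - ep * np.abs(f * xp - x), lb, ub)

    if r >= 0.5:  # hard besiege
        dx = xp - x
        return _clip(xp - ep * dx, lb, ub)

    # rapid-dive branches: accept Y or Z only when strictly fitter
    if abs(ep) >= 0.5:
        y = xp - ep * np.abs(f * xp - x)
    else:
        y = xp - ep * np.abs(f * xp - mean_pos)
    y = _clip(y, lb, ub)
    z = _clip(y + rng.random(d) * levy_step(d, rng), lb, ub)
    fy = float(objective(y))
    if fy < hawk.fitness:
        return y
    fz = float(objective(z))
    if fz < hawk.fitness:
        return z
    return x.copy()


def optimize(objective, config: HHOConfig) -> HHOResult:
    """Run HHO for ``config.tm`` iterations and return the best solution.

    The prey is the best-so-far hawk (elitist), so the fitness history is
    non-increasing.  Raises if the objective returns a non-finite value,
    naming the offending position.
    """
    rng = np.random.default_rng(config.seed)
    lb, ub, d = config.lb, config.ub, config.dim
    pos = lb + rng.random((config.ps, d)) * (ub - lb)

    def _eval(x: np.ndarray) -> float:
        v = float(objective(x))
        if not np.isfinite(v):
            raise ValueError(f"objective returned non-finite value {v!r} at position {x}")
        return v

    best_x: np.ndarray | None = None
    best_f = np.inf
    history = np.empty(config.tm)

    for t in range(config.tm):
        fits = np.array([_eval(pos[i]) for i in range(config.ps)])
        i_best = int(np.argmin(fits))
        if fits[i_best] < best_f:
            best_f = float(fits[i_best])
            best_x = pos[i_best].copy()
        history[t] = best_f
        if t == config.tm - 1:
            break
        prey = HawkState(best_x, best_f)
        mean_pos = pos.mean(axis=0)
        new_pos = np.empty_like(pos)
        for i in range(config.ps):
            e0 = rng.uniform(-1.0, 1.0)
            ep = prey_energy(e0, t, config.tm)
            rand_pos = pos[rng.integers(config.ps)].copy()
            new_pos[i] = hawk_update(
                HawkState(pos[i], float(fits[i])),
                prey,
                mean_pos,
                ep,
                lb,
                ub,
                _eval,
                rng,
                rand_pos=rand_pos,
            )
        pos = new_pos

    assert best_x is not None
    return HHOResult(best_position=best_x, best_fitness=best_f, history=history)
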