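"""Replicator dynamics of the tripartite game.

The state ``(x, y, z)`` collects the probabilities that the GNPO allocates
on demand, the hospital accepts, and the government supervises strictly.
Each coordinate follows a replicator equation: its rate of change is the
coordinate times the gap between the payoff of its pure strategy and the
player's mixture average, which factors as ``x(1-x) * bracket`` with an
affine-in-state bracket.  The unit cube is forward invariant and its eight
corners are rest points.

Two evaluations of the vector field are provided: the closed-form brackets
(used everywhere) and a direct construction from the payoff table (used as
an independent oracle in tests).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Union

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .params import ParameterSet
from .payoff import expected_payoffs

__all__ = [
    "as_state",
    "brackets",
    "replicator_field",
    "replicator_field_oracle",
    "Singular",
    "ThresholdSurfaces",
    "thresholds",
    "Trajectory",
    "integrate",
    "IntegrationError",
    "DEFAULT_START",
    "interior_lattice",
]

#: Symmetric-ignorance default initial state.
DEFAULT_START = (0.5, 0.5, 0.5)


def as_state(state: Iterable[float], *, tol: float = 1e-9) -> np.ndarray:
    """Coerce to a float triple and require it to lie in the unit cube."""
    s = np.asarray(tuple(state), dtype=float)
    if s.shape != (3,):
        raise ValueError("state must have exactly three coordinates (x, y, z)")
    if np.any(s < -tol) or np.any(s > 1.0 + tol):
        raise ValueError(f"state {s.tolist()} outside the unit cube")
    return np.clip(s, 0.0, 1.0)


def brackets(p: ParameterSet, state: Iterable[float]) -> np.ndarray:
    """The three affine replicator brackets at ``(x, y, z)``.

    ``bracket[i]`` is the payoff advantage of player ``i``'s first pure
    strategy over its mixture average, divided by the logistic factor; the
    full field is ``coord * (1 - coord) * bracket``.
    """
    x, y, z = np.asarray(tuple(state), dtype=float)
    a = p.alpha
    bx = y * (a * p.V1 - a * p.V2) + a * p.V2 - a * p.V1 + z * p.K2 - p.A
    by = (
        z * (x * a * p.P1 - x * a * p.P2 - x * p.B + p.B + a * p.P2)
        + x * (a * p.W2 - a * p.W1)
        + a * p.H2
        - a * p.W2
    )
    bz = (
        p.R2 + p.K1 + p.K2 - p.H4 + p.H5 + p.T + a * p.P2
        + x * (a * p.P1 - a * p.P2 - p.K2)
        + y * (-p.B - a * p.P2 - p.K1 - p.T)
        + x * y * (p.B - a * p.P1 + a * p.P2)
    )
    return np.array([bx, by, bz])


def replicator_field(p: ParameterSet, state: Iterable[float]) -> np.ndarray:
    """Closed-form replicator vector field ``(dx/dt, dy/dt, dz/dt)``."""
    s = as_state(state)
    return s * (1.0 - s) * brackets(p, s)


def replicator_field_oracle(p: ParameterSet, state: Iterable[float]) -> np.ndarray:
    """Vector field built directly from the payoff table.

    Returns ``(x (E11 - E1), y (E21 - E2), z (E31 - E3))``.  Kept separate
    from :func:`replicator_field` as an independent cross-check of the
    closed-form brackets against the payoff matrix.
    """
    s = as_state(state)
    e = expected_payoffs(p, s)
    return np.array(
        [
            s[0] * (e.E11 - e.E1),
            s[1] * (e.E21 - e.E2),
            s[2] * (e.E31 - e.E3),
        ]
    )


@dataclass(frozen=True)
class Singular:
    """Tagged singular value returned where a threshold denominator vanishes."""

    surface: str
    argument: float

    def __bool__(self) -> bool:  # a singular value is not a usable number
        return False


ThresholdValue = Union[float, Singular]


@dataclass(frozen=True)
class ThresholdSurfaces:
    """The three indifference surfaces of the game.

    ``y_star(z)`` makes the GNPO indifferent (its bracket vanish): below it
    the GNPO drifts to on-demand allocation, above it away.  ``x_star(z)``
    plays the same role for the hospital (below: refuse; above: accept) and
    ``y_double_star(x)`` for the government (below: strict; above: loose).
    Values are returned unclipped and may leave ``[0, 1]``; where a
    denominator vanishes a :class:`Singular` tag is returned instead of
    raising, so batch evaluation can proceed.
    """

    p: ParameterSet

    def y_star(self, z: float) -> ThresholdValue:
        p = self.p
        den = p.alpha * (p.V1 - p.V2)
        if den == 0.0:
            return Singular("y*", float(z))
        return (p.alpha * p.V1 - p.alpha * p.V2 - z * p.K2 + p.A) / den

    def x_star(self, z: float) -> ThresholdValue:
        p, a = self.p, self.p.alpha
        den = z * (a * p.P2 - a * p.P1 + p.B) + a * p.W1 - a * p.W2
        if den == 0.0:
            return Singular("x*", float(z))
        return (z * (p.B + a * p.P2) - a * p.W2 + a * p.H2) / den

    def y_double_star(self, x: float) -> ThresholdValue:
        p, a = self.p, self.p.alpha
        den = x * (p.B + a * p.P2 - a * p.P1) - p.B - a * p.P2 - p.K1 - p.T
        if den == 0.0:
            return Singular("y**", float(x))
        num = (
            p.H4 - p.R2 - p.K1 - p.K2 - p.H5 - p.T - a * p.P2
            - x * (a * p.P1 - a * p.P2 - p.K2)
        )
        return num / den

    def _values(self, fn: Callable[[float], ThresholdValue], args: np.ndarray) -> np.ndarray:
        out = np.empty(len(args))
        for i, v in enumerate(args):
            r = fn(float(v))
            out[i] = np.nan if isinstance(r, Singular) else r
        return out

    def y_star_values(self, z: np.ndarray) -> np.ndarray:
        """Vectorized ``y_star`` with NaN at singular arguments."""
        return self._values(self.y_star, np.asarray(z, dtype=float))

    def x_star_values(self, z: np.ndarray) -> np.ndarray:
        return self._values(self.x_star, np.asarray(z, dtype=float))

    def y_double_star_values(self, x: np.ndarray) -> np.ndarray:
        return self._values(self.y_double_star, np.asarray(x, dtype=float))


def thresholds(p: ParameterSet) -> ThresholdSurfaces:
    """Threshold surfaces and indifference loci for a parameter set."""
    return ThresholdSurfaces(p)


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails; carries the last valid state."""

    def __init__(self, message: str, last_state: np.ndarray | None = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class Trajectory:
    """A solved replicator trajectory on the unit cube."""

    t: np.ndarray
    states: np.ndarray  # shape (len(t), 3), clipped to [0, 1]
    converged: bool
    terminal_field_norm: float
    max_excursion: float = 0.0  # worst raw overshoot outside [0, 1]

    @property
    def terminal(self) -> np.ndarray:
        return self.states[-1]

    def terminal_corner(self, tol: float = 1e-3) -> tuple[float, float, float] | None:
        """Nearest cube corner if the endpoint is within ``tol`` of one."""
        corner = np.round(self.terminal)
        if np.max(np.abs(self.terminal - corner)) <= tol:
            return tuple(float(c) for c in corner)
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.states[:, 0],
                "y": self.states[:, 1],
                "z": self.states[:, 2],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def integrate(
    p: ParameterSet,
    s0: Iterable[float] = DEFAULT_START,
    horizon: float = 50.0,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    field_tol: float = 1e-8,
    t_eval: np.ndarray | None = None,
) -> Trajectory:
    """Integrate the replicator dynamics from ``s0`` for ``horizon`` time units.

    Uses adaptive Runge–Kutta (RK45).  The run stops early once the field
    norm falls below ``field_tol`` (the convergence flag records whether the
    terminal norm meets the tolerance).  States are evaluated on a clipped
    copy inside the right-hand side, so tiny overshoots outside the cube do
    not feed back into the dynamics; the worst raw overshoot is reported as
    ``max_excursion``.
    """
    s0 = as_state(s0)
    excursion = [0.0]

    def rhs(_t: float, s: np.ndarray) -> np.ndarray:
        excursion[0] = max(
            excursion[0], float(np.max(np.maximum(-s, s - 1.0), initial=0.0))
        )
        sc = np.clip(s, 0.0, 1.0)
        return sc * (1.0 - sc) * brackets(p, sc)

    def settled(_t: float, s: np.ndarray) -> float:
        sc = np.clip(s, 0.0, 1.0)
        return float(np.linalg.norm(sc * (1.0 - sc) * brackets(p, sc))) - field_tol

    settled.terminal = True
    settled.direction = -1.0

    sol = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        s0,
        method="RK45",
        rtol=rtol,
        atol=atol,
        events=settled,
        t_eval=t_eval,
        dense_output=False,
    )
    if not sol.success and sol.status != 1:
        last = np.clip(sol.y[:, -1], 0.0, 1.0) if sol.y.size else None
        raise IntegrationError(f"ODE solver failed: {sol.message}", last)
    t = sol.t
    states = np.clip(sol.y.T, 0.0, 1.0)
    if t.size == 0:  # event fired before the first requested sample
        t = np.array([0.0])
        states = s0[None, :]
    norm = float(np.linalg.norm(replicator_field(p, states[-1])))
    # status == 1: the settling event fired (field norm crossed field_tol)
    converged = sol.status == 1 or norm < field_tol
    return Trajectory(
        t=t,
        states=states,
        converged=converged,
        terminal_field_norm=norm,
        max_excursion=excursion[0],
    )


def interior_lattice(levels: Iterable[float] = (0.25, 0.5, 0.75)) -> list[tuple[float, float, float]]:
    """A small interior lattice of start states for basin exploration."""
    levels = tuple(levels)
    return [(x, y, z) for x in levels for y in levels for z in levels]
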