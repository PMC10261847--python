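"""Parameter sets for the tripartite medical-supply allocation game.

The game has three boundedly rational players: a government-owned nonprofit
organization (GNPO) that allocates donated medical supplies, a hospital that
receives them, and a government that supervises the process.  Twenty-one
non-negative payoff parameters (in a common abstract payoff unit) describe
penalties, rewards, reputation losses, coordination costs and supervision
costs.  This module defines the parameter container, its validity
constraints, a literature-calibrated baseline, JSON (de)serialization, and a
seeded random scenario generator used throughout the test suite.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PARAM_NAMES",
    "ParameterSet",
    "Constraint",
    "ConstraintReport",
    "ScenarioBatch",
    "GenerationError",
    "validate",
    "baseline",
    "load_config",
    "save_config",
    "default_ranges",
    "sample_scenarios",
]

#: Canonical parameter order, also the key order of the JSON configuration.
PARAM_NAMES = (
    "K1", "K2", "V1", "V2", "A", "H1", "D", "E", "alpha", "W1", "W2",
    "B", "P1", "P2", "H2", "R1", "H3", "H4", "H5", "R2", "T",
)


@dataclass(frozen=True)
class ParameterSet:
    """The 21 payoff parameters of the tripartite game.

    Attributes
    ----------
    K1, K2
        Government penalties on the GNPO (for hospital fighting under strict
        supervision, and for not allocating on demand, respectively).
    V1, V2
        GNPO reputation losses caused by hospital fighting when allocating
        on demand / not on demand (``V2 > V1``).
    A
        GNPO's opportunistic extra gain from not allocating on demand.
    H1
        GNPO coordination cost incurred by hospital fighting.
    D, E
        Hospital losses: extra loss from an unmet allocation, and baseline
        early-epidemic loss (``D > E``).
    alpha
        Degree of hospital fighting, dimensionless in ``[0, 1]``.
    W1, W2
        Supply compensation paid by the GNPO to a fighting hospital
        (``W2 > W1``).
    B
        Government reward to a hospital that accepts an unmet allocation
        under strict supervision.
    P1, P2
        Government penalties on a fighting hospital (``P1 > P2``).
    H2
        Hospital coordination cost of fighting.
    R1, R2
        Government social benefits from on-demand allocation and from strict
        supervision.
    H3
        Government epidemic-control effort cost after a failed allocation.
    H4, H5
        Costs of strict / loose supervision (``H4 > H5``).
    T
        Loss from higher-authority accountability under loose supervision
        (``T > H4``).
    """

    K1: float
    K2: float
    V1: float
    V2: float
    A: float
    H1: float
    D: float
    E: float
    alpha: float
    W1: float
    W2: float
    B: float
    P1: float
    P2: float
    H2: float
    R1: float
    H3: float
    H4: float
    H5: float
    R2: float
    T: float

    def replace(self, **changes: float) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in PARAM_NAMES], dtype=float)


@dataclass(frozen=True)
class Constraint:
    name: str
    satisfied: bool
    lhs: float
    rhs: float


@dataclass(frozen=True)
class ConstraintReport:
    """Outcome of checking every model inequality on a parameter set."""

    constraints: tuple[Constraint, ...]

    @property
    def valid(self) -> bool:
        return all(c.satisfied for c in self.constraints)

    def violated(self) -> tuple[Constraint, ...]:
        return tuple(c for c in self.constraints if not c.satisfied)


# (name, larger field, smaller field) — strict order constraints of the model.
_ORDER_CONSTRAINTS = (
    ("V2 > V1", "V2", "V1"),
    ("W2 > W1", "W2", "W1"),
    ("P1 > P2", "P1", "P2"),
    ("D > E", "D", "E"),
    ("H4 > H5", "H4", "H5"),
    ("T > H4", "T", "H4"),
)


def validate(p: ParameterSet, *, allow_ties: bool = False) -> ConstraintReport:
    """Check the model's parameter constraints.

    Strict order constraints (``V2 > V1`` etc.) are checked with zero
    tolerance; ``allow_ties=True`` relaxes them to weak inequalities, which
    keeps the dynamics well defined on constraint boundaries (used by the
    sensitivity sweeps, whose printed grids touch the ``T = H4`` boundary).

    Raises
    ------
    ValueError
        If any field is missing or non-finite; the message names the field.
    """
    for name in PARAM_NAMES:
        value = getattr(p, name, None)
        if value is None:
            raise ValueError(f"missing parameter field: {name}")
        if not math.isfinite(float(value)):
            raise ValueError(f"non-finite parameter field: {name}")

    checks: list[Constraint] = []
    for label, hi, lo in _ORDER_CONSTRAINTS:
        lhs, rhs = float(getattr(p, hi)), float(getattr(p, lo))
        ok = lhs >= rhs if allow_ties else lhs > rhs
        checks.append(Constraint(label, ok, lhs, rhs))
    checks.append(Constraint("0 <= alpha", 0.0 <= p.alpha, float(p.alpha), 0.0))
    checks.append(Constraint("alpha <= 1", p.alpha <= 1.0, float(p.alpha), 1.0))
    for name in PARAM_NAMES:
        if name == "alpha":
            continue
        value = float(getattr(p, name))
        checks.append(Constraint(f"{name} >= 0", value >= 0.0, value, 0.0))
    return ConstraintReport(tuple(checks))


def baseline() -> ParameterSet:
    """The calibrated baseline scenario (Wuhan-style emergency).

    The values are the literature-calibrated starting point used by all
    sensitivity sweeps; they satisfy every model constraint and both
    stability condition sets, so the system is bistable between
    (not-on-demand, accept, loose) and (on-demand, accept, strict).
    """
    return ParameterSet(
        K1=80, K2=60, V1=100, V2=150, A=25, H1=80, D=300, E=200, alpha=0.6,
        W1=80, W2=100, B=80, P1=160, P2=80, H2=110, R1=170, H3=160,
        H4=100, H5=50, R2=60, T=150,
    )


def save_config(p: ParameterSet, path: str | Path) -> None:
    """Write a parameter set as a flat JSON object keyed by symbol names."""
    Path(path).write_text(json.dumps(p.as_dict(), indent=2) + "\n")


def load_config(path: str | Path) -> ParameterSet:
    """Load and validate a flat JSON parameter configuration.

    Raises
    ------
    ValueError
        On malformed JSON, a missing key, an unknown key, or a non-numeric
        value; the message names the offending key.
    """
    try:
        raw = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed parameter file {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ValueError(f"parameter file {path} must hold a JSON object")
    unknown = set(raw) - set(PARAM_NAMES)
    if unknown:
        raise ValueError(f"unknown parameter key: {sorted(unknown)[0]}")
    missing = set(PARAM_NAMES) - set(raw)
    if missing:
        raise ValueError(f"missing parameter key: {sorted(missing)[0]}")
    for key, value in raw.items():
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValueError(f"non-numeric value for parameter key: {key}")
    p = ParameterSet(**{k: float(v) for k, v in raw.items()})
    validate(p)  # raises on non-finite values
    return p


class GenerationError(RuntimeError):
    """Raised when rejection sampling cannot reach the requested batch size."""


@dataclass(frozen=True)
class ScenarioBatch:
    """A seeded batch of random parameter sets, all passing :func:`validate`."""

    scenarios: tuple[ParameterSet, ...]
    seed: int
    ranges: dict[str, tuple[float, float]]
    enforce: str
    acceptance_rate: float

    def __len__(self) -> int:
        return len(self.scenarios)

    def __iter__(self):
        return iter(self.scenarios)

    def __getitem__(self, i):
        return self.scenarios[i]


def default_ranges(
    base: ParameterSet | None = None, spread: float = 0.5
) -> dict[str, tuple[float, float]]:
    """Uniform sampling intervals: ±``spread`` around the baseline.

    ``alpha`` is clipped to its admissible range ``[0, 1]``.
    """
    base = base or baseline()
    ranges: dict[str, tuple[float, float]] = {}
    for name in PARAM_NAMES:
        v = float(getattr(base, name))
        lo, hi = v * (1.0 - spread), v * (1.0 + spread)
        if name == "alpha":
            lo, hi = max(lo, 0.0), min(hi, 1.0)
        ranges[name] = (lo, hi)
    return ranges


_ENFORCE_CHOICES = ("none", "condition1", "condition2", "both")


def sample_scenarios(
    n: int,
    seed: int,
    ranges: Mapping[str, Sequence[float]] | None = None,
    enforce: str = "none",
    *,
    min_acceptance: float = 1e-4,
    batch: int = 4096,
) -> ScenarioBatch:
    """Draw ``n`` random valid parameter sets by rejection sampling.

    Parameters are sampled independently and uniformly on their ranges (the
    model treats them as independent), then whole vectors are rejected until
    they satisfy every model inequality and, optionally, the stability
    condition set named by ``enforce`` (``"condition1"``, ``"condition2"``
    or ``"both"``).

    Raises
    ------
    GenerationError
        If fewer than ``n`` vectors are accepted after
        ``max(n / min_acceptance, 10**4)`` draws.
    ValueError
        On invalid arguments (``n < 1``, bad ranges, unknown condition set).
    """
    from . import stability  # local import: stability depends on params

    if n < 1:
        raise ValueError("n must be >= 1")
    if enforce not in _ENFORCE_CHOICES:
        raise ValueError(f"enforce must be one of {_ENFORCE_CHOICES}")
    rng = np.random.default_rng(seed)
    ranges_in = dict(ranges) if ranges is not None else default_ranges()
    resolved: dict[str, tuple[float, float]] = {}
    for name in PARAM_NAMES:
        if name not in ranges_in:
            raise ValueError(f"missing range for parameter: {name}")
        lo, hi = (float(v) for v in ranges_in[name])
        if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi or lo < 0:
            raise ValueError(f"invalid range for parameter: {name}")
        if name == "alpha" and hi > 1.0:
            raise ValueError("alpha range must lie within [0, 1]")
        resolved[name] = (lo, hi)

    max_draws = max(int(math.ceil(n / min_acceptance)), 10_000)
    accepted: list[ParameterSet] = []
    drawn = 0
    while len(accepted) < n and drawn < max_draws:
        k = min(batch, max_draws - drawn)
        drawn += k
        lows = np.array([resolved[name][0] for name in PARAM_NAMES])
        highs = np.array([resolved[name][1] for name in PARAM_NAMES])
        draws = rng.uniform(lows, highs, size=(k, len(PARAM_NAMES)))
        for row in draws:
            p = ParameterSet(**dict(zip(PARAM_NAMES, map(float, row))))
            if not validate(p).valid:
                continue
            if enforce != "none":
                cc = stability.check_conditions(p)
                if enforce in ("condition1", "both") and not cc.condition1:
                    continue
                if enforce in ("condition2", "both") and not cc.condition2:
                    continue
            accepted.append(p)
            if len(accepted) == n:
                break
    if len(accepted) < n:
        raise GenerationError(
            f"accepted {len(accepted)}/{n} scenarios after {drawn} draws; "
            "the constraints may be infeasible on the given ranges"
        )
    rate = len(accepted) / drawn
    return ScenarioBatch(tuple(accepted), int(seed), resolved, enforce, rate)
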