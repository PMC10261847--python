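"""Payoff matrix of the tripartite game and expected payoffs under mixing.

Each of the three players has two pure strategies, so the stage game has
eight pure strategy profiles.  The payoff table is the single source of
truth for the dynamics: the replicator field and its closed-form brackets
are validated against expectations computed from this table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .params import ParameterSet, validate

__all__ = [
    "GNPO_STRATEGIES",
    "HOSPITAL_STRATEGIES",
    "GOVERNMENT_STRATEGIES",
    "StrategyProfile",
    "PROFILES",
    "PayoffTable",
    "ExpectedPayoffs",
    "build_payoff_table",
    "expected_payoffs",
]

GNPO_STRATEGIES = ("able", "unable")          # allocate on demand / not
HOSPITAL_STRATEGIES = ("accept", "refuse")    # accept plan / refuse and fight
GOVERNMENT_STRATEGIES = ("strict", "loose")   # strict / loose supervision


class StrategyProfile(NamedTuple):
    gnpo: str
    hospital: str
    government: str


#: Fixed enumeration order (gnpo, hospital, government), so serialized
#: tables are bit-stable across runs.
PROFILES: tuple[StrategyProfile, ...] = tuple(
    StrategyProfile(g, h, s)
    for g in GNPO_STRATEGIES
    for h in HOSPITAL_STRATEGIES
    for s in GOVERNMENT_STRATEGIES
)


def _cells(p: ParameterSet) -> dict[StrategyProfile, tuple[float, float, float]]:
    a = p.alpha
    return {
        StrategyProfile("able", "accept", "strict"): (
            0.0,
            -p.E,
            p.R1 + p.R2 - p.H4,
        ),
        StrategyProfile("able", "accept", "loose"): (
            0.0,
            -p.E,
            p.R1 - p.H5,
        ),
        StrategyProfile("able", "refuse", "strict"): (
            -p.K1 - a * p.V1 - a * p.H1,
            a * p.W1 - p.E - a * p.P1 - a * p.H2,
            p.R1 + p.R2 + p.K1 + a * p.P1 - p.H4,
        ),
        StrategyProfile("able", "refuse", "loose"): (
            -a * p.V1 - a * p.H1,
            a * p.W1 - p.E - a * p.H2,
            p.R1 - p.H5 - p.T,
        ),
        StrategyProfile("unable", "accept", "strict"): (
            p.A - p.K2,
            p.B - p.D,
            p.R2 + p.K2 - p.B - p.H3 - p.H4,
        ),
        StrategyProfile("unable", "accept", "loose"): (
            p.A,
            -p.D,
            -p.H3 - p.H5,
        ),
        StrategyProfile("unable", "refuse", "strict"): (
            p.A - a * p.V2 - a * p.H1 - p.K1 - p.K2,
            a * p.W2 - p.D - a * p.P2 - a * p.H2,
            p.R2 + p.K1 + p.K2 + a * p.P2 - p.H3 - p.H4,
        ),
        StrategyProfile("unable", "refuse", "loose"): (
            p.A - a * p.V2 - a * p.H1,
            a * p.W2 - p.D - a * p.H2,
            -p.H3 - p.H5 - p.T,
        ),
    }


@dataclass(frozen=True)
class PayoffTable:
    """Per-player payoffs for the eight pure strategy profiles."""

    payoffs: dict[StrategyProfile, tuple[float, float, float]]

    def __getitem__(self, profile: StrategyProfile) -> tuple[float, float, float]:
        return self.payoffs[profile]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "profile": "/".join(prof),
                "u_gnpo": self.payoffs[prof][0],
                "u_hospital": self.payoffs[prof][1],
                "u_government": self.payoffs[prof][2],
            }
            for prof in PROFILES
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_payoff_table(p: ParameterSet, *, check: bool = True) -> PayoffTable:
    """Evaluate the eight payoff cells at a parameter set.

    ``check=False`` skips the validity check; the cell expressions are affine
    in the parameters and remain well defined for degenerate inputs (e.g.
    the all-zero parameter set, where every payoff is zero).
    """
    if check:
        report = validate(p)
        if not report.valid:
            names = ", ".join(c.name for c in report.violated())
            raise ValueError(f"invalid parameter set: violated {names}")
    return PayoffTable(_cells(p))


@dataclass(frozen=True)
class ExpectedPayoffs:
    """Pure-strategy and mixed expected payoffs for the three players.

    ``E11``/``E12`` are the GNPO's expected payoffs for playing on-demand /
    not-on-demand against the opponents' mixture, and ``E1`` their mixture
    average; similarly (``E21``, ``E22``, ``E2``) for the hospital and
    (``E31``, ``E32``, ``E3``) for the government.
    """

    E11: float
    E12: float
    E1: float
    E21: float
    E22: float
    E2: float
    E31: float
    E32: float
    E3: float


def _check_state(state: Iterable[float]) -> tuple[float, float, float]:
    x, y, z = (float(v) for v in state)
    for name, v in (("x", x), ("y", y), ("z", z)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"state coordinate {name}={v} outside [0, 1]")
    return x, y, z


def expected_payoffs(
    p: ParameterSet, state: Iterable[float], *, check: bool = True
) -> ExpectedPayoffs:
    """Expected payoffs at mixed state ``(x, y, z)``.

    ``x``, ``y``, ``z`` are the probabilities of on-demand allocation,
    acceptance, and strict supervision.  All nine quantities are
    probability-weighted sums over the payoff table.
    """
    x, y, z = _check_state(state)
    table = build_payoff_table(p, check=check).payoffs

    def mix(player: int, own: str) -> float:
        total = 0.0
        if player == 0:  # GNPO mixes over hospital x government
            for h, wh in (("accept", y), ("refuse", 1 - y)):
                for s, ws in (("strict", z), ("loose", 1 - z)):
                    total += wh * ws * table[StrategyProfile(own, h, s)][0]
        elif player == 1:  # hospital mixes over GNPO x government
            for g, wg in (("able", x), ("unable", 1 - x)):
                for s, ws in (("strict", z), ("loose", 1 - z)):
                    total += wg * ws * table[StrategyProfile(g, own, s)][1]
        else:  # government mixes over GNPO x hospital
            for g, wg in (("able", x), ("unable", 1 - x)):
                for h, wh in (("accept", y), ("refuse", 1 - y)):
                    total += wg * wh * table[StrategyProfile(g, h, own)][2]
        return total

    e11, e12 = mix(0, "able"), mix(0, "unable")
    e21, e22 = mix(1, "accept"), mix(1, "refuse")
    e31, e32 = mix(2, "strict"), mix(2, "loose")
    return ExpectedPayoffs(
        E11=e11, E12=e12, E1=x * e11 + (1 - x) * e12,
        E21=e21, E22=e22, E2=y * e21 + (1 - y) * e22,
        E31=e31, E32=e32, E3=z * e31 + (1 - z) * e32,
    )
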