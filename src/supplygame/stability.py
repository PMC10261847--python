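"""Equilibrium enumeration and Lyapunov stability classification.

In an asymmetric evolutionary game only strict Nash equilibria — pure
strategy profiles, i.e. the corners of the unit cube — can be evolutionarily
stable, so classification is confined to the eight corners.  At each corner
the Jacobian of the replicator field is diagonal; its eigenvalues have exact
closed forms in the parameters, which are used as the primary output with a
numeric eigendecomposition of the analytic Jacobian as cross-check.  The
Lyapunov indirect method then classifies the corner: all eigenvalue real
parts negative → asymptotically stable (ESS); any positive → unstable;
otherwise the test is inconclusive and the corner is reported as critical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import root

from .dynamics import brackets, interior_lattice, replicator_field
from .params import ParameterSet

__all__ = [
    "CORNER_LABELS",
    "enumerate_pure_equilibria",
    "jacobian",
    "corner_eigenvalues",
    "EquilibriumReport",
    "classify_equilibria",
    "ConditionCheck",
    "check_conditions",
    "find_interior_equilibria",
    "stability_report",
]

#: The eight pure-strategy rest points in their conventional order E1..E8.
_CORNERS: tuple[tuple[float, float, float], ...] = (
    (0.0, 0.0, 0.0),
    (1.0, 0.0, 0.0),
    (0.0, 1.0, 0.0),
    (0.0, 0.0, 1.0),
    (1.0, 1.0, 0.0),
    (1.0, 0.0, 1.0),
    (0.0, 1.0, 1.0),
    (1.0, 1.0, 1.0),
)

CORNER_LABELS = tuple(f"E{i}" for i in range(1, 9))


def enumerate_pure_equilibria() -> list[tuple[float, float, float]]:
    """The eight pure-strategy Nash equilibrium points, ordered E1..E8."""
    return list(_CORNERS)


def jacobian(p: ParameterSet, state: Iterable[float]) -> np.ndarray:
    """Analytic 3x3 Jacobian of the replicator field at a state.

    Diagonal entries are ``(1 - 2u) * bracket_u``; off-diagonals carry the
    logistic factor ``u(1-u)`` times the partial derivative of the bracket,
    so they vanish on the faces of the cube.
    """
    s = np.asarray(tuple(state), dtype=float)
    if s.shape != (3,):
        raise ValueError("state must have exactly three coordinates")
    if np.any(s < 0.0) or np.any(s > 1.0):
        raise ValueError(f"state {s.tolist()} outside the unit cube")
    x, y, z = s
    a = p.alpha
    bx, by, bz = brackets(p, s)

    dbx_dy = a * p.V1 - a * p.V2
    dbx_dz = p.K2
    dby_dx = z * (a * p.P1 - a * p.P2 - p.B) + a * p.W2 - a * p.W1
    dby_dz = x * a * p.P1 - x * a * p.P2 - x * p.B + p.B + a * p.P2
    dbz_dx = a * p.P1 - a * p.P2 - p.K2 + y * (p.B - a * p.P1 + a * p.P2)
    dbz_dy = -p.B - a * p.P2 - p.K1 - p.T + x * (p.B - a * p.P1 + a * p.P2)

    lx, ly, lz = x * (1 - x), y * (1 - y), z * (1 - z)
    return np.array(
        [
            [(1 - 2 * x) * bx, lx * dbx_dy, lx * dbx_dz],
            [ly * dby_dx, (1 - 2 * y) * by, ly * dby_dz],
            [lz * dbz_dx, lz * dbz_dy, (1 - 2 * z) * bz],
        ]
    )


def _corner_key(point: Iterable[float]) -> tuple[float, float, float]:
    pt = tuple(float(v) for v in point)
    if pt not in _CORNERS:
        raise ValueError(f"{pt} is not a corner of the unit cube")
    return pt


def corner_eigenvalues(p: ParameterSet, point: Iterable[float]) -> tuple[float, float, float]:
    """Closed-form Jacobian eigenvalues at a corner, in the conventional order.

    The Jacobian is diagonal at corners, so the eigenvalues are exact affine
    expressions in the parameters.  The returned order follows the
    conventional per-corner listing (which interleaves player axes), the
    same order used in the published stability table of this model family.
    """
    pt = _corner_key(point)
    a = p.alpha
    table = {
        (0.0, 0.0, 0.0): (
            a * p.V2 - a * p.V1 - p.A,
            a * p.H2 - a * p.W2,
            p.H5 - p.H4 + p.K1 + p.K2 + p.R2 + p.T + a * p.P2,
        ),
        (1.0, 0.0, 0.0): (
            a * p.H2 - a * p.W1,
            p.A + a * p.V1 - a * p.V2,
            p.H5 - p.H4 + p.K1 + p.R2 + p.T + a * p.P1,
        ),
        (0.0, 1.0, 0.0): (
            a * p.W2 - a * p.H2,
            -p.A,
            p.H5 - p.H4 - p.B + p.K2 + p.R2,
        ),
        (0.0, 0.0, 1.0): (
            p.K2 - p.A - a * p.V1 + a * p.V2,
            p.B + a * p.H2 + a * p.P2 - a * p.W2,
            p.H4 - p.H5 - p.K1 - p.K2 - p.R2 - p.T - a * p.P2,
        ),
        (1.0, 1.0, 0.0): (
            p.A,
            a * p.W1 - a * p.H2,
            p.H5 - p.H4 + p.R2,
        ),
        (1.0, 0.0, 1.0): (
            a * p.H2 + a * p.P1 - a * p.W1,
            p.A - p.K2 + a * p.V1 - a * p.V2,
            p.H4 - p.H5 - p.K1 - p.R2 - p.T - a * p.P1,
        ),
        (0.0, 1.0, 1.0): (
            p.K2 - p.A,
            a * p.W2 - a * p.H2 - a * p.P2 - p.B,
            p.B + p.H4 - p.H5 - p.K2 - p.R2,
        ),
        (1.0, 1.0, 1.0): (
            p.A - p.K2,
            p.H4 - p.H5 - p.R2,
            a * p.W1 - a * p.P1 - a * p.H2,
        ),
    }
    return tuple(float(v) for v in table[pt])


@dataclass(frozen=True)
class EquilibriumReport:
    """A corner rest point with its eigenvalues and Lyapunov class."""

    label: str
    point: tuple[float, float, float]
    eigenvalues: tuple[float, float, float]
    sign_pattern: tuple[str, str, str]
    classification: str  # "ESS" | "unstable" | "critical"

    def as_dict(self) -> dict:
        return {
            "label": self.label,
            "point": list(self.point),
            "eigenvalues": list(self.eigenvalues),
            "sign_pattern": list(self.sign_pattern),
            "classification": self.classification,
        }


def _sign(v: float, eps: float) -> str:
    if v < -eps:
        return "-"
    if v > eps:
        return "+"
    return "0"


def classify_equilibria(p: ParameterSet, eps: float = 1e-9) -> list[EquilibriumReport]:
    """Classify the eight corners by the Lyapunov indirect method.

    ``eps`` is the half-width of the zero band: an eigenvalue within
    ``[-eps, +eps]`` counts as zero, and a corner with such an eigenvalue
    (and none positive) is reported as "critical" rather than guessed.
    """
    reports = []
    for label, pt in zip(CORNER_LABELS, _CORNERS):
        eigs = corner_eigenvalues(p, pt)
        signs = tuple(_sign(v, eps) for v in eigs)
        if all(s == "-" for s in signs):
            cls = "ESS"
        elif any(s == "+" for s in signs):
            cls = "unstable"
        else:
            cls = "critical"
        reports.append(EquilibriumReport(label, pt, eigs, signs, cls))
    return reports


@dataclass(frozen=True)
class ConditionCheck:
    """The two stability condition sets for the bistable regime.

    Condition set 1 makes (not-on-demand, accept, loose) = E3 stable;
    condition set 2 makes (on-demand, accept, strict) = E8 stable.  Each
    entry is ``(name, value, satisfied)`` with "satisfied" meaning value < 0.
    """

    condition1_checks: tuple[tuple[str, float, bool], ...]
    condition2_checks: tuple[tuple[str, float, bool], ...]

    @property
    def condition1(self) -> bool:
        return all(ok for _, _, ok in self.condition1_checks)

    @property
    def condition2(self) -> bool:
        return all(ok for _, _, ok in self.condition2_checks)

    @property
    def both(self) -> bool:
        return self.condition1 and self.condition2

    def as_dict(self) -> dict:
        return {
            "condition1": {
                "satisfied": self.condition1,
                "checks": [
                    {"name": n, "value": v, "satisfied": ok}
                    for n, v, ok in self.condition1_checks
                ],
            },
            "condition2": {
                "satisfied": self.condition2,
                "checks": [
                    {"name": n, "value": v, "satisfied": ok}
                    for n, v, ok in self.condition2_checks
                ],
            },
        }


def check_conditions(p: ParameterSet) -> ConditionCheck:
    """Evaluate the five inequalities of the two stability condition sets."""
    a = p.alpha
    c1 = (
        ("alpha*W2 - alpha*H2 < 0", a * p.W2 - a * p.H2),
        ("H5 - H4 - B + K2 + R2 < 0", p.H5 - p.H4 - p.B + p.K2 + p.R2),
    )
    c2 = (
        ("A - K2 < 0", p.A - p.K2),
        ("H4 - H5 - R2 < 0", p.H4 - p.H5 - p.R2),
        ("alpha*W1 - alpha*P1 - alpha*H2 < 0", a * p.W1 - a * p.P1 - a * p.H2),
    )
    return ConditionCheck(
        tuple((n, float(v), v < 0.0) for n, v in c1),
        tuple((n, float(v), v < 0.0) for n, v in c2),
    )


def find_interior_equilibria(
    p: ParameterSet,
    starts: Sequence[tuple[float, float, float]] | None = None,
    *,
    tol: float = 1e-10,
    margin: float = 1e-6,
) -> list[tuple[float, float, float]]:
    """Locate mixed-strategy rest points strictly inside the cube.

    Solves the three replicator brackets for simultaneous zeros from a small
    lattice of interior starts and deduplicates the roots.  Interior rest
    points are reported for completeness only — in this asymmetric game they
    are never evolutionarily stable, so they are not classified.
    """
    starts = starts or interior_lattice()
    found: list[np.ndarray] = []
    for s0 in starts:
        sol = root(lambda s: brackets(p, s), np.asarray(s0, dtype=float), tol=tol)
        if not sol.success:
            continue
        s = sol.x
        if np.any(s <= margin) or np.any(s >= 1.0 - margin):
            continue
        if np.linalg.norm(brackets(p, s)) > 1e-8:
            continue
        if not any(np.allclose(s, prev, atol=1e-6) for prev in found):
            found.append(s)
    return [tuple(float(v) for v in s) for s in found]


def stability_report(p: ParameterSet, eps: float = 1e-9) -> dict:
    """JSON-ready stability report: per-corner records plus condition checks."""
    reports = classify_equilibria(p, eps=eps)
    interior = find_interior_equilibria(p)
    return {
        "equilibria": [r.as_dict() for r in reports],
        "ess": [r.label for r in reports if r.classification == "ESS"],
        "conditions": check_conditions(p).as_dict(),
        "interior_rest_points": [list(pt) for pt in interior],
    }
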