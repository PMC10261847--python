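"""Strategy-preference volumes of the phase diagram.

Each player's indifference surface cuts the strategy cube into two regions;
the volume of a region is read as the probability that evolution favours the
corresponding pure strategy.  For the GNPO the volume of the region pulled
toward on-demand allocation (``V_G1``) has an exact closed form; the hospital
(``V_Q1``, pulled toward refuse-and-fight) and government (``V_N1``, pulled
toward strict supervision) volumes are defined by integrals of rational
threshold surfaces.

The raw integrands are unbounded wherever their denominators vanish (at the
calibrated baseline the hospital surface has a pole inside the cube), so the
geometric volumes clip the surface into ``[0, 1]`` before integrating — the
only convention under which the volumes are probabilities of regions of the
unit cube.  For the GNPO volume both the as-printed (unclipped) value and the
clipped geometric value are reported; they differ whenever the surface exits
the cube.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "v_g1_closed",
    "v_g1_integral",
    "v_clipped",
    "v_q1",
    "v_n1",
    "VolumeReport",
    "volume_report",
    "SignRow",
    "SignTable",
    "inference_signs",
]

_REGIONS = ("G", "Q", "N")


def _num_den(p: ParameterSet, which: str, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized numerator/denominator of a threshold surface.

    ``t`` is the free axis: z for the G and Q surfaces, x for the N surface.
    """
    a = p.alpha
    t = np.asarray(t, dtype=float)
    if which == "G":
        num = a * p.V1 - a * p.V2 - t * p.K2 + p.A
        den = np.full_like(t, a * (p.V1 - p.V2))
    elif which == "Q":
        num = t * (p.B + a * p.P2) - a * p.W2 + a * p.H2
        den = t * (a * p.P2 - a * p.P1 + p.B) + a * p.W1 - a * p.W2
    elif which == "N":
        num = (
            p.H4 - p.R2 - p.K1 - p.K2 - p.H5 - p.T - a * p.P2
            - t * (a * p.P1 - a * p.P2 - p.K2)
        )
        den = t * (p.B + a * p.P2 - a * p.P1) - p.B - a * p.P2 - p.K1 - p.T
    else:
        raise ValueError(f"unknown region {which!r}; expected one of {_REGIONS}")
    return num, den


def _surface(p: ParameterSet, which: str, t: np.ndarray) -> np.ndarray:
    """Unclipped surface values with NaN at singular points."""
    num, den = _num_den(p, which, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den != 0.0, num / np.where(den != 0.0, den, 1.0), np.nan)
    return r


def v_g1_closed(p: ParameterSet) -> float:
    """Closed-form GNPO on-demand preference volume.

    ``(A - K2)(A - K2 + 2 alpha V1 - 2 alpha V2) / (2 alpha K2 (V2 - V1))``.
    Exact antiderivative of the unclipped threshold integral; may exceed 1
    when the surface leaves the cube (see :func:`v_clipped`).
    """
    den = 2.0 * p.alpha * p.K2 * (p.V2 - p.V1)
    if den == 0.0:
        raise ZeroDivisionError(
            "closed-form volume undefined: alpha, K2 and V2 - V1 must be nonzero"
        )
    return float((p.A - p.K2) * (p.A - p.K2 + 2 * p.alpha * p.V1 - 2 * p.alpha * p.V2) / den)


def v_g1_integral(p: ParameterSet, n: int = 2001) -> float:
    """Midpoint quadrature of the unclipped GNPO volume integral.

    Integrates the GNPO threshold surface over ``z`` from ``A/K2`` to 1
    (signed if ``A/K2 > 1``); serves as the independent numerical check of
    :func:`v_g1_closed`.
    """
    if p.K2 == 0.0:
        raise ZeroDivisionError("integral undefined for K2 = 0")
    lo = p.A / p.K2
    width = 1.0 - lo
    mids = lo + (np.arange(n) + 0.5) / n * width
    vals = _surface(p, "G", mids)
    return float(np.nanmean(vals) * width)


def v_clipped(p: ParameterSet, which: str, n: int = 2001) -> float:
    """Geometric preference volume with the surface clipped into [0, 1].

    Returns the volume of the region of the unit cube on the attracting side
    of the ``which`` surface ("G": GNPO to on-demand, "Q": hospital to
    refuse-and-fight, "N": government to strict supervision).  The surface
    depends on a single coordinate, so the volume reduces to a 1-D midpoint
    quadrature of the clipped surface on ``n`` cells (the two remaining axes
    integrate to 1); singular cells contribute their clip-range midpoint.
    """
    if n < 1000:
        raise ValueError("grid must have at least 1000 cells per axis")
    mids = (np.arange(n) + 0.5) / n
    vals = _surface(p, which, mids)
    clipped = np.clip(vals, 0.0, 1.0)
    clipped = np.where(np.isnan(clipped), 0.5, clipped)
    return float(np.mean(clipped))


def _singular_points(p: ParameterSet, which: str, n: int = 2001) -> list[float]:
    """Roots of the surface denominator inside [0, 1] (sign changes on the grid)."""
    grid = np.linspace(0.0, 1.0, n)
    _, den = _num_den(p, which, grid)
    roots = [float(g) for g, d in zip(grid, den) if d == 0.0]
    flips = np.nonzero(np.sign(den[:-1]) * np.sign(den[1:]) < 0)[0]
    for i in flips:
        # linear interpolation of the affine denominator between grid nodes
        g0, g1, d0, d1 = grid[i], grid[i + 1], den[i], den[i + 1]
        roots.append(float(g0 - d0 * (g1 - g0) / (d1 - d0)))
    return sorted(set(round(r, 12) for r in roots))


def v_q1(p: ParameterSet, n: int = 2001) -> tuple[float, list[float]]:
    """Clipped hospital refuse-and-fight volume and its singular z set."""
    return v_clipped(p, "Q", n), _singular_points(p, "Q")


def v_n1(p: ParameterSet, n: int = 2001) -> tuple[float, list[float]]:
    """Clipped government strict-supervision volume and its singular x set."""
    return v_clipped(p, "N", n), _singular_points(p, "N")


@dataclass(frozen=True)
class VolumeReport:
    """All six preference volumes plus quadrature metadata."""

    v_g1_closed: float
    v_g1_integral: float
    v_g1_clipped: float
    v_g2_clipped: float
    v_q1: float
    v_q2: float
    v_n1: float
    v_n2: float
    grid: int
    singular: dict[str, list[float]]

    def as_dict(self) -> dict:
        return {
            "V_G1_closed_form": self.v_g1_closed,
            "V_G1_integral": self.v_g1_integral,
            "V_G1_clipped": self.v_g1_clipped,
            "V_G2_clipped": self.v_g2_clipped,
            "V_Q1": self.v_q1,
            "V_Q2": self.v_q2,
            "V_N1": self.v_n1,
            "V_N2": self.v_n2,
            "grid": self.grid,
            "singular_points": self.singular,
        }


def volume_report(p: ParameterSet, n: int = 2001) -> VolumeReport:
    """Compute every preference volume at a parameter set."""
    g_clip = v_clipped(p, "G", n)
    q1, q_sing = v_q1(p, n)
    n1, n_sing = v_n1(p, n)
    return VolumeReport(
        v_g1_closed=v_g1_closed(p),
        v_g1_integral=v_g1_integral(p, n),
        v_g1_clipped=g_clip,
        v_g2_clipped=1.0 - g_clip,
        v_q1=q1,
        v_q2=1.0 - q1,
        v_n1=n1,
        v_n2=1.0 - n1,
        grid=n,
        singular={"G": _singular_points(p, "G"), "Q": q_sing, "N": n_sing},
    )


# (volume, region, parameter, sign claimed by the monotonicity inferences)
_SIGN_ROWS = (
    ("V_G1", "G", "alpha", "+"),
    ("V_G1", "G", "K2", "+"),
    ("V_G1", "G", "A", "-"),
    ("V_Q1", "Q", "B", "-"),
    ("V_Q1", "Q", "P1", "-"),
    ("V_Q1", "Q", "P2", "-"),
    ("V_N1", "N", "K2", "+"),
    ("V_N1", "N", "T", "+"),
    ("V_N1", "N", "P2", "+"),
    ("V_N1", "N", "B", "-"),
)


@dataclass(frozen=True)
class SignRow:
    volume: str
    parameter: str
    derivative: float          # central difference of the clipped volume
    sign: str                  # "+", "-", "0" or "indeterminate"
    integrand_sign: str        # pointwise sign of d(surface)/d(parameter)
    claimed_sign: str          # sign asserted by the model's inferences

    def as_dict(self) -> dict:
        return {
            "volume": self.volume,
            "parameter": self.parameter,
            "derivative": self.derivative,
            "sign": self.sign,
            "integrand_sign": self.integrand_sign,
            "claimed_sign": self.claimed_sign,
        }


@dataclass(frozen=True)
class SignTable:
    rows: tuple[SignRow, ...]

    def row(self, volume: str, parameter: str) -> SignRow:
        for r in self.rows:
            if r.volume == volume and r.parameter == parameter:
                return r
        raise KeyError((volume, parameter))

    def as_dict(self) -> dict:
        return {"rows": [r.as_dict() for r in self.rows]}


def _integrand_sign(p: ParameterSet, which: str, parameter: str, h: float) -> str:
    """Uniform pointwise sign of the surface's partial derivative.

    Samples the surface over the relevant integration domain (the as-printed
    ``[A/K2, 1]`` for G, ``[0, 1]`` otherwise), skipping near-singular
    points, and central-differences it in the parameter.  Returns "+", "-",
    "0" or "mixed".
    """
    if which == "G" and p.K2 != 0.0:
        lo = min(max(p.A / p.K2, 0.0), 1.0)
    else:
        lo = 0.0
    t = np.linspace(lo, 1.0, 201)
    base = float(getattr(p, parameter))
    p_hi = p.replace(**{parameter: base + h})
    p_lo = p.replace(**{parameter: max(base - h, 0.0)})
    num, den = _num_den(p, which, t)
    scale = max(float(np.max(np.abs(den))), 1.0)
    mask = np.abs(den) > 1e-6 * scale
    hi = _surface(p_hi, which, t)[mask]
    lo_v = _surface(p_lo, which, t)[mask]
    diff = hi - lo_v
    diff = diff[np.isfinite(diff)]
    if diff.size == 0:
        return "0"
    tol = 1e-12 * max(float(np.max(np.abs(diff))), 1.0)
    pos, neg = np.any(diff > tol), np.any(diff < -tol)
    if pos and neg:
        return "mixed"
    if pos:
        return "+"
    if neg:
        return "-"
    return "0"


def inference_signs(
    p: ParameterSet, delta: float = 2e-3, n: int = 20001
) -> SignTable:
    """Numeric monotonicity table for the three preference volumes.

    For each (volume, parameter) pair of the model's monotonicity claims the
    table reports a central-difference derivative of the clipped geometric
    volume (step ``delta`` relative, quadrature grid ``n``) and, separately,
    the uniform pointwise sign of the unclipped integrand's partial
    derivative.  The two can disagree when the surface is clipped at the
    cube boundary; both are reported and neither is guessed: a clipped
    derivative smaller than ten times the quadrature self-convergence error
    is reported as "indeterminate".
    """
    rows = []
    n_alt = max(((2 * n) // 3) | 1, 1001)
    for volume, which, parameter, claimed in _SIGN_ROWS:
        base = float(getattr(p, parameter))
        h = delta * max(abs(base), 1.0)
        lo = max(base - h, 0.0)
        hi = base + h
        if parameter == "alpha":
            hi = min(hi, 1.0)
        step = hi - lo
        v_hi = v_clipped(p.replace(**{parameter: hi}), which, n)
        v_lo = v_clipped(p.replace(**{parameter: lo}), which, n)
        noise = abs(v_clipped(p, which, n) - v_clipped(p, which, n_alt)) + 1e-12
        diff = v_hi - v_lo
        deriv = diff / step if step > 0 else 0.0
        if abs(diff) < 10.0 * noise:
            sign = "indeterminate"
        elif diff > 0:
            sign = "+"
        else:
            sign = "-"
        rows.append(
            SignRow(
                volume=volume,
                parameter=parameter,
                derivative=float(deriv),
                sign=sign,
                integrand_sign=_integrand_sign(p, which, parameter, h),
                claimed_sign=claimed,
            )
        )
    return SignTable(tuple(rows))
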