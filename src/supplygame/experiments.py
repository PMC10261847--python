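"""Parameter-sensitivity sweeps of the replicator dynamics.

Each sweep varies a single payoff parameter over a printed grid around the
calibrated baseline, integrates the replicator dynamics from a common
interior start, and summarises where each run settles.  The sweeps are
deterministic (ODE runs involve no randomness), so re-running a spec
reproduces its outputs byte for byte.

The grids reproduce the model's published sensitivity experiments: the
fighting degree alpha, the hospital coordination cost H2, the supervision
costs H4/H5, the accountability loss T, the penalties K1 and P1, the reward
B, and the opportunistic gain A.  The original experiments do not state the
initial state or horizon, so results here are read qualitatively (orderings
across grid values at the default symmetric start), not as pointwise curve
reproductions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import DEFAULT_START, Trajectory, IntegrationError, integrate
from .params import ParameterSet, baseline, validate

__all__ = [
    "SweepSpec",
    "SweepRecord",
    "SweepResult",
    "preset_sweeps",
    "run_sweep",
    "detect_direction_flip",
    "report",
]

#: Printed sensitivity grids, one per published sweep.
_PRESET_GRIDS: tuple[tuple[str, tuple[float, ...]], ...] = (
    ("alpha", tuple(round(0.1 * k, 1) for k in range(1, 10))),
    ("H2", (80, 95, 110, 125, 140)),
    ("H4", (70, 85, 100, 115, 130)),
    ("H5", (30, 40, 50, 60, 70)),
    ("T", (100, 125, 150, 175, 200)),
    ("K1", (40, 60, 80, 100, 120)),
    ("B", (40, 60, 80, 100, 120)),
    ("P1", (120, 140, 160, 180, 200)),
    ("A", (10, 15, 20, 25, 30, 35, 40)),
)


@dataclass(frozen=True)
class SweepSpec:
    """One sensitivity sweep: a parameter, its grid, and solver settings.

    Every grid value must yield a valid parameter set; ``allow_ties`` relaxes
    the strict order constraints to weak ones, needed because the printed
    accountability grid touches the ``T = H4`` boundary (the dynamics remain
    well defined there).
    """

    parameter: str
    values: tuple[float, ...]
    base: ParameterSet = field(default_factory=baseline)
    start: tuple[float, float, float] = DEFAULT_START
    horizon: float = 50.0
    rtol: float = 1e-8
    field_tol: float = 1e-8
    allow_ties: bool = False

    def __post_init__(self):
        if not self.values:
            raise ValueError("sweep needs at least one value")
        for v in self.values:
            report = validate(self.member(v), allow_ties=self.allow_ties)
            if not report.valid:
                names = ", ".join(c.name for c in report.violated())
                raise ValueError(
                    f"sweep value {self.parameter}={v} violates: {names}"
                )

    def member(self, value: float) -> ParameterSet:
        return self.base.replace(**{self.parameter: float(value)})

    def as_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "values": list(self.values),
            "base": self.base.as_dict(),
            "start": list(self.start),
            "horizon": self.horizon,
            "rtol": self.rtol,
            "field_tol": self.field_tol,
        }


def preset_sweeps(base: ParameterSet | None = None) -> list[SweepSpec]:
    """The nine published sensitivity sweeps over the baseline."""
    base = base or baseline()
    specs = []
    for name, grid in _PRESET_GRIDS:
        specs.append(
            SweepSpec(
                parameter=name,
                values=tuple(float(v) for v in grid),
                base=base,
                allow_ties=(name == "T"),  # printed grid touches T = H4
            )
        )
    return specs


@dataclass(frozen=True)
class SweepRecord:
    """Outcome of one grid value: trajectory and terminal diagnostics."""

    value: float
    trajectory: Trajectory | None
    converged: bool
    terminal: tuple[float, float, float] | None
    terminal_corner: tuple[float, float, float] | None
    terminal_class: str | None  # stability class of the terminal corner
    time_average: tuple[float, float, float] | None
    error: str | None = None


@dataclass(frozen=True)
class SweepResult:
    spec: SweepSpec
    records: tuple[SweepRecord, ...]

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "value": r.value,
                    "converged": r.converged,
                    "terminal_x": r.terminal[0] if r.terminal else np.nan,
                    "terminal_y": r.terminal[1] if r.terminal else np.nan,
                    "terminal_z": r.terminal[2] if r.terminal else np.nan,
                    "corner": "" if r.terminal_corner is None
                    else str(tuple(int(c) for c in r.terminal_corner)),
                    "corner_class": r.terminal_class or "",
                    "mean_x": r.time_average[0] if r.time_average else np.nan,
                    "mean_y": r.time_average[1] if r.time_average else np.nan,
                    "mean_z": r.time_average[2] if r.time_average else np.nan,
                    "error": r.error or "",
                }
            )
        return pd.DataFrame(rows)


def _time_average(traj: Trajectory) -> tuple[float, float, float]:
    if traj.t.size < 2:
        return tuple(float(v) for v in traj.terminal)
    span = traj.t[-1] - traj.t[0]
    if span <= 0:
        return tuple(float(v) for v in traj.terminal)
    avg = np.trapezoid(traj.states, traj.t, axis=0) / span
    return tuple(float(v) for v in avg)


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Integrate every grid value of a sweep; failures never abort the batch."""
    from .stability import classify_equilibria  # local import avoids a cycle

    records: list[SweepRecord] = []
    for value in spec.values:
        p = spec.member(value)
        try:
            traj = integrate(
                p,
                spec.start,
                horizon=spec.horizon,
                rtol=spec.rtol,
                field_tol=spec.field_tol,
            )
        except IntegrationError as exc:
            records.append(
                SweepRecord(
                    value=value, trajectory=None, converged=False,
                    terminal=None, terminal_corner=None, terminal_class=None,
                    time_average=None, error=str(exc),
                )
            )
            continue
        corner = traj.terminal_corner()
        corner_class = None
        if corner is not None:
            for rep in classify_equilibria(p):
                if rep.point == corner:
                    corner_class = rep.classification
                    break
        records.append(
            SweepRecord(
                value=float(value),
                trajectory=traj,
                converged=traj.converged,
                terminal=tuple(float(v) for v in traj.terminal),
                terminal_corner=corner,
                terminal_class=corner_class,
                time_average=_time_average(traj),
            )
        )
    return SweepResult(spec=spec, records=tuple(records))


def detect_direction_flip(result: SweepResult, coordinate: str = "z") -> float | None:
    """Grid value at which the terminal coordinate reverses direction.

    Exploratory diagnostic for sweeps whose published effect changes
    direction mid-grid (the opportunistic-gain sweep); the detected flip is
    start-state dependent and is reported, never asserted.
    """
    idx = "xyz".index(coordinate)
    vals = [r.terminal[idx] for r in result.records if r.terminal is not None]
    grid = [r.value for r in result.records if r.terminal is not None]
    if len(vals) < 3:
        return None
    diffs = np.diff(vals)
    signs = np.sign(diffs)
    nonzero = signs[signs != 0]
    if nonzero.size < 2:
        return None
    flips = np.nonzero(nonzero[:-1] * nonzero[1:] < 0)[0]
    if flips.size == 0:
        return None
    # map back to the grid position of the first reversal
    k = np.nonzero(signs != 0)[0][flips[0] + 1]
    return float(grid[k])


def report(
    results: Iterable[SweepResult],
    out_dir: str | Path,
    *,
    plots: bool = False,
) -> dict:
    """Write per-sweep trajectory CSVs and a JSON summary; deterministic.

    Returns the summary dictionary.  With ``plots=True`` a PNG of the three
    coordinates over time is written per sweep (requires matplotlib).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"sweeps": []}
    for res in results:
        name = res.spec.parameter
        frames = []
        for rec in res.records:
            if rec.trajectory is None:
                continue
            df = rec.trajectory.to_frame()
            df.insert(0, "value", rec.value)
            frames.append(df)
        csv_path = out / f"sweep_{name}.csv"
        if frames:
            pd.concat(frames, ignore_index=True).to_csv(
                csv_path, index=False, float_format="%.12g"
            )
        else:
            pd.DataFrame(columns=["value", "t", "x", "y", "z"]).to_csv(
                csv_path, index=False
            )
        entry = {
            "parameter": name,
            "spec": res.spec.as_dict(),
            "csv": csv_path.name,
            "records": [
                {
                    "value": rec.value,
                    "converged": rec.converged,
                    "terminal": list(rec.terminal) if rec.terminal else None,
                    "terminal_corner": (
                        list(rec.terminal_corner) if rec.terminal_corner else None
                    ),
                    "terminal_class": rec.terminal_class,
                    "time_average": (
                        list(rec.time_average) if rec.time_average else None
                    ),
                    "error": rec.error,
                }
                for rec in res.records
            ],
        }
        if name == "A":
            entry["direction_flip"] = {
                axis: detect_direction_flip(res, axis) for axis in "xz"
            }
        summary["sweeps"].append(entry)
        if plots:
            _plot_sweep(res, out / f"sweep_{name}.png")
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def _plot_sweep(res: SweepResult, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2), sharey=True)
    labels = ("x (on-demand)", "y (accept)", "z (strict)")
    for rec in res.records:
        if rec.trajectory is None:
            continue
        for ax, i in zip(axes, range(3)):
            ax.plot(
                rec.trajectory.t,
                rec.trajectory.states[:, i],
                label=f"{res.spec.parameter}={rec.value:g}",
                lw=1.2,
            )
    for ax, lab in zip(axes, labels):
        ax.set_xlabel("t")
        ax.set_title(lab)
        ax.set_ylim(-0.02, 1.02)
    axes[0].set_ylabel("probability")
    axes[-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
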