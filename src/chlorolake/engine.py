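"""Time stepping, event application, trajectory recording and trajectory I/O.

The model advances by explicit Euler with a default step of one day, matching
the daily bookkeeping of the governing difference equations.  Chlorine doses
are resolved on an hourly grid by :mod:`chlorolake.chlorine` and enter the
daily state update as daily-mean concentrations; exogenous phosphorus pulses
add to water TP at the start of their day, before the derivative evaluation.
States are clamped at zero after each step; the number of clamping
interventions is recorded as a model-health signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chlorine import AttenuationModel, ChlorineSeries, DoseEvent, chlorine_series
from .params import ParameterSet
from .processes import ForcingSample, LakeState, state_derivative


class TrajectoryIOError(ValueError):
    """Raised for malformed trajectory files."""


@dataclass
class Scenario:
    """A complete simulation setup.

    ``forcing`` is a daily DataFrame with columns ``day``, ``temperature``,
    ``solar_radiance`` and optionally ``external_tp_load``, covering every day
    in [t0, t1).  ``tp_pulses`` is a list of (day, added pw in mg/L).
    """

    t0: int
    t1: int
    initial_state: LakeState
    forcing: pd.DataFrame
    dose_schedule: list[DoseEvent] = field(default_factory=list)
    tp_pulses: list[tuple[int, float]] = field(default_factory=list)
    attenuation: AttenuationModel = field(default_factory=AttenuationModel)
    dt: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be > 0, got {self.dt}")
        if self.t1 <= self.t0:
            raise ValueError("t1 must be > t0")
        days = set(self.forcing["day"].astype(int))
        missing = [d for d in range(self.t0, self.t1) if d not in days]
        if missing:
            raise ValueError(f"forcing does not cover days {missing[:5]}...")
        for e in self.dose_schedule:
            if not self.t0 <= e.day < self.t1:
                raise ValueError(f"dose event on day {e.day} outside [{self.t0}, {self.t1})")
        for day, _ in self.tp_pulses:
            if not self.t0 <= day < self.t1:
                raise ValueError(f"TP pulse on day {day} outside [{self.t0}, {self.t1})")


@dataclass
class Trajectory:
    """Time-indexed record of simulated states.

    ``data`` holds one row per recorded time with a ``day`` column, one column
    per species id, and ``det``, ``pw``, ``ps``, ``cc`` columns.
    """

    data: pd.DataFrame
    clamp_count: int = 0
    chlorine: ChlorineSeries | None = None

    @property
    def time(self) -> np.ndarray:
        return self.data["day"].to_numpy()

    def series(self, column: str) -> np.ndarray:
        return self.data[column].to_numpy()

    def state_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != "day"]


def simulate(
    scenario: Scenario,
    ps_set: ParameterSet,
    dt: float | None = None,
    strict_as_printed: bool = False,
) -> Trajectory:
    """Integrate the model over the scenario horizon.

    Explicit Euler with step ``dt`` (days; defaults to the scenario's dt).
    Forcing is interpolated linearly for sub-daily steps, with the daily-mean
    chlorine concentration held constant within each day.  Raises
    :class:`FloatingPointError` with step context if the state leaves the
    finite range.
    """
    dt = scenario.dt if dt is None else dt
    if dt <= 0:
        raise ValueError(f"dt must be > 0, got {dt}")
    t0, t1 = scenario.t0, scenario.t1
    horizon = t1 - t0

    chl = chlorine_series(
        [DoseEvent(e.day - t0, e.mass, e.available_fraction, e.resulting_c0)
         for e in scenario.dose_schedule],
        scenario.attenuation, horizon, ps_set.lake.reference_volume,
    )

    f = scenario.forcing.sort_values("day")
    f_day = f["day"].to_numpy(dtype=float)
    f_T = f["temperature"].to_numpy(dtype=float)
    f_sr = f["solar_radiance"].to_numpy(dtype=float)
    f_load = (f["external_tp_load"].to_numpy(dtype=float)
              if "external_tp_load" in f.columns else np.zeros_like(f_day))

    n_steps = int(round(horizon / dt))
    if abs(n_steps * dt - horizon) > 1e-9:
        raise ValueError(f"dt={dt} does not divide the horizon of {horizon} days")

    pulses = sorted(scenario.tp_pulses)
    next_pulse = 0
    state = scenario.initial_state.copy()
    ids = ps_set.species_ids
    columns = ["day"] + ids + ["det", "pw", "ps", "cc"]
    records = np.empty((n_steps + 1, len(columns)))
    clamp_count = 0

    for step in range(n_steps + 1):
        t = t0 + step * dt
        day = min(int(math.floor(t + 1e-9)), t1 - 1)
        cc = float(chl.daily_mean[day - t0])

        while next_pulse < len(pulses) and pulses[next_pulse][0] <= t + 1e-9:
            state.pw += pulses[next_pulse][1]
            next_pulse += 1

        state.cc = cc
        records[step] = [t, *state.biom, state.det, state.pw, state.ps, cc]
        if step == n_steps:
            break

        forcing = ForcingSample(
            temperature=float(np.interp(t, f_day, f_T)),
            solar_radiance=float(np.interp(t, f_day, f_sr)),
            cc=cc,
            external_tp_load=float(np.interp(t, f_day, f_load)),
        )
        try:
            deriv = state_derivative(state, forcing, ps_set, strict_as_printed)
        except FloatingPointError as exc:
            raise FloatingPointError(f"at step {step} (day {t}): {exc}") from exc
        vec = state.as_vector() + dt * deriv.as_vector()
        if not np.isfinite(vec).all():
            bad = np.flatnonzero(~np.isfinite(vec))
            raise FloatingPointError(
                f"non-finite state at step {step} (day {t}), components {bad.tolist()}")
        clamp_count += int(np.count_nonzero(vec < 0))
        np.maximum(vec, 0.0, out=vec)
        state = LakeState.from_vector(vec, cc=cc)

    data = pd.DataFrame(records, columns=columns)
    return Trajectory(data=data, clamp_count=clamp_count, chlorine=chl)


def refine_check(
    scenario: Scenario,
    ps_set: ParameterSet,
    dt_list: Sequence[float],
    strict_as_printed: bool = False,
) -> pd.DataFrame:
    """Step-size refinement report.

    Simulates at each dt and reports the max-norm difference between
    consecutive step sizes over the shared daily time points.  Requires at
    least two step sizes.
    """
    if len(dt_list) < 2:
        raise ValueError("need at least two step sizes to compare")
    trajs = {}
    for dt in dt_list:
        traj = simulate(scenario, ps_set, dt=dt, strict_as_printed=strict_as_printed)
        df = traj.data
        daily = df[np.isclose(df["day"] % 1.0, 0.0)].reset_index(drop=True)
        trajs[dt] = daily
    rows = []
    dts = list(dt_list)
    for a, b in zip(dts[:-1], dts[1:]):
        cols = [c for c in trajs[a].columns if c != "day"]
        diff = np.abs(trajs[a][cols].to_numpy() - trajs[b][cols].to_numpy())
        rows.append({"dt_coarse": a, "dt_fine": b, "max_abs_diff": float(diff.max())})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a wide CSV, one row per recorded time."""
    traj.data.to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path: str | Path) -> Trajectory:
    """Read a trajectory CSV, validating shape and state non-negativity.

    Raises :class:`TrajectoryIOError` naming the first offending row for
    missing values (truncation) or negative state entries.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TrajectoryIOError(f"{path}: cannot parse trajectory: {exc}") from exc
    if "day" not in df.columns:
        raise TrajectoryIOError(f"{path}: missing 'day' column")
    if df.isna().any(axis=None):
        bad = int(df[df.isna().any(axis=1)].index[0])
        raise TrajectoryIOError(
            f"{path}: missing values at data row {bad} "
            f"(last good row {bad - 1}); file may be truncated")
    state_cols = [c for c in df.columns if c != "day"]
    neg = df[state_cols].lt(0).any(axis=1)
    if neg.any():
        bad = int(df[neg].index[0])
        raise TrajectoryIOError(f"{path}: negative state value at data row {bad}")
    t = df["day"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise TrajectoryIOError(f"{path}: time grid is not strictly increasing")
    return Trajectory(data=df)
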