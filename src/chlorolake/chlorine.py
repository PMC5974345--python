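"""Chlorine dose accounting, first-order attenuation, and daily averaging.

A dose of calcium hypochlorite (mass in grams, with a stated available
chlorine fraction) dissolved in the lake's reference volume yields an initial
concentration C0 (mg/L).  Chlorine then decays first order,
C(t) = C0 * exp(-k * (t - t0)), with the attenuation rate k (per hour) taken
from a laboratory-fitted lookup table over C0 = 100..300 mg/L.  Lake-scale
doses are far below that range, so by default the low-end rate (k = 2.041 1/h
at C0 = 100 mg/L) applies via clamping; a fixed override is available.

The ecosystem model consumes chlorine as a daily mean: the average of the 24
hourly concentrations following the start of each day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Laboratory attenuation table: (C0 in mg/L, k in 1/h).
DEFAULT_ATTENUATION_TABLE: tuple[tuple[float, float], ...] = (
    (100.0, 2.041),
    (150.0, 0.9161),
    (200.0, 1.168),
    (250.0, 0.5452),
    (300.0, 0.09466),
)


@dataclass
class DoseEvent:
    """One chlorine application: day index, product mass (g), available fraction."""

    day: int
    mass: float                     # g of product
    available_fraction: float = 0.30
    resulting_c0: float | None = None   # mg/L; filled in when a volume is known

    def __post_init__(self) -> None:
        if self.mass < 0:
            raise ValueError(f"dose mass must be >= 0, got {self.mass}")
        if not 0.0 <= self.available_fraction <= 1.0:
            raise ValueError(
                f"available_fraction must be in [0, 1], got {self.available_fraction}")


@dataclass
class AttenuationModel:
    """Attenuation-rate lookup: k(C0) from the laboratory table.

    Modes: ``nearest`` picks the k of the closest tabulated C0;
    ``linear_interpolation`` interpolates k against C0 and clamps outside the
    tabulated range; ``fixed_k`` always returns ``fixed_k``.
    """

    table: tuple[tuple[float, float], ...] = DEFAULT_ATTENUATION_TABLE
    mode: str = "linear_interpolation"
    fixed_k: float = 2.041

    def __post_init__(self) -> None:
        if self.mode not in ("nearest", "linear_interpolation", "fixed_k"):
            raise ValueError(f"unknown attenuation mode {self.mode!r}")
        c0s = [c for c, _ in self.table]
        if any(k <= 0 for _, k in self.table):
            raise ValueError("all attenuation rates must be > 0")
        if list(c0s) != sorted(set(c0s)):
            raise ValueError("C0 values must be strictly increasing")


@dataclass
class ChlorineSeries:
    """Hourly chlorine concentrations and per-day means over a horizon."""

    hourly: np.ndarray          # mg/L at hours 0 .. horizon*24
    daily_mean: np.ndarray      # mg/L, one value per day
    events: list[DoseEvent] = field(default_factory=list)

    @property
    def horizon(self) -> int:
        return len(self.daily_mean)


def dose_to_concentration(mass: float, available_fraction: float, volume: float) -> float:
    """Initial chlorine concentration (mg/L) of a dose dissolved in ``volume`` litres."""
    if volume <= 0:
        raise ValueError(f"volume must be > 0, got {volume}")
    return mass * available_fraction / volume * 1e3   # g/L -> mg/L


def attenuation_rate_for(c0: float, model: AttenuationModel) -> float:
    """Attenuation rate k (1/h) for an initial concentration ``c0`` (mg/L)."""
    if c0 < 0:
        raise ValueError(f"c0 must be >= 0, got {c0}")
    if model.mode == "fixed_k":
        return model.fixed_k
    if not model.table:
        raise ValueError("attenuation table is empty")
    c0s = np.array([c for c, _ in model.table])
    ks = np.array([k for _, k in model.table])
    if model.mode == "nearest":
        return float(ks[int(np.argmin(np.abs(c0s - c0)))])
    # linear interpolation, clamped at the table ends
    return float(np.interp(c0, c0s, ks))


def concentration_at(c0: float, k: float, t: float) -> float:
    """C(t) = c0 * exp(-k*t) for t hours after a dose; decay sign always applied."""
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return c0 * float(np.exp(-k * t))


def daily_mean_concentration(c0: float, k: float) -> float:
    """Mean of the 24 hourly values c0*exp(-k*i), i = 1..24."""
    hours = np.arange(1, 25, dtype=float)
    return float(np.mean(c0 * np.exp(-k * hours)))


def chlorine_series(
    schedule: Sequence[DoseEvent],
    model: AttenuationModel,
    horizon: int,
    volume: float = 8.0e6,
) -> ChlorineSeries:
    """Hourly chlorine concentration and daily means for a dose schedule.

    At each dose the residual concentration is incremented by the dose's
    initial concentration, and the attenuation rate is re-selected from the
    post-dose total.  Doses apply at hour 0 of their day; the daily mean of
    day d averages the 24 hourly values after the start of day d.
    """
    events = sorted(schedule, key=lambda e: e.day)
    for e in events:
        if not 0 <= e.day < horizon:
            raise ValueError(f"dose event on day {e.day} outside horizon [0, {horizon})")
    n_hours = horizon * 24
    hourly = np.zeros(n_hours + 1)
    dose_at_hour = {}
    out_events = []
    for e in events:
        c0 = e.resulting_c0
        if c0 is None:
            c0 = dose_to_concentration(e.mass, e.available_fraction, volume)
        out_events.append(DoseEvent(e.day, e.mass, e.available_fraction, c0))
        dose_at_hour[e.day * 24] = dose_at_hour.get(e.day * 24, 0.0) + c0

    pre_dose = np.zeros(n_hours + 1)    # residual before any dose at that hour
    c = 0.0
    k = model.fixed_k if model.mode == "fixed_k" else attenuation_rate_for(0.0, model)
    for h in range(n_hours + 1):
        pre_dose[h] = c
        if h in dose_at_hour:
            c += dose_at_hour[h]
            k = attenuation_rate_for(c, model)
        hourly[h] = c
        c *= float(np.exp(-k))
    # Day d averages the 24 hourly values after the start of day d; the
    # endpoint at the next midnight uses the pre-dose residual so a dose on
    # day d+1 does not leak into day d's mean.
    daily = np.array([
        (hourly[d * 24 + 1: d * 24 + 24].sum() + pre_dose[d * 24 + 24]) / 24.0
        for d in range(horizon)
    ])
    return ChlorineSeries(hourly=hourly, daily_mean=daily, events=out_events)


def fit_attenuation(times: Sequence[float], concentrations: Sequence[float]) -> tuple[float, float]:
    """Least-squares first-order decay fit: ln C regressed on t.

    Returns ``(k, r)`` with k the decay rate (1/h, positive for decaying
    series) and r the magnitude of the correlation coefficient of the linear
    fit.  Requires at least three strictly positive concentrations.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.shape != c.shape or t.size < 3:
        raise ValueError("need >= 3 matched (time, concentration) samples")
    if np.any(c <= 0):
        raise ValueError("all concentrations must be > 0 for a log-linear fit")
    lnc = np.log(c)
    slope, _ = np.polyfit(t, lnc, 1)
    r = float(abs(np.corrcoef(t, lnc)[0, 1]))
    return -float(slope), r
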