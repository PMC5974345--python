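"""Model-evaluation metrics, one-at-a-time MRE sensitivity, and grid calibration.

Metrics on paired observed/simulated series:

* Pearson correlation coefficient R;
* RSR — root mean square error divided by the standard deviation of the
  observations, with the customary performance bands (< 0.5 very good,
  0.5-0.6 good, 0.6-0.7 satisfactory, >= 0.7 unsatisfactory);
* IOA — Willmott's index of agreement d, bounded in [0, 1].

Sensitivity of a model output to one parameter is quantified by the mean
relative error between two runs holding everything else at defaults:
MRE = mean_t |(Pmax(t) - Pmin(t)) / Pmax(t)|, where Pmax/Pmin are the target
species' trajectories with the parameter at its range maximum and minimum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import Scenario, Trajectory, simulate
from .params import ParameterSet, set_parameter


def _paired(y, y_sim) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    y_sim = np.asarray(y_sim, dtype=float)
    if y.shape != y_sim.shape or y.ndim != 1 or y.size < 2:
        raise ValueError("paired series must be equal-length 1-d arrays of size >= 2")
    if not (np.isfinite(y).all() and np.isfinite(y_sim).all()):
        raise ValueError("paired series must be finite")
    return y, y_sim


def pearson_r(y, y_sim) -> float:
    """Product-moment correlation between observed and simulated series."""
    y, y_sim = _paired(y, y_sim)
    dy = y - y.mean()
    dys = y_sim - y_sim.mean()
    denom = np.sqrt((dys ** 2).sum() * (dy ** 2).sum())
    if denom == 0:
        raise ValueError("zero-variance series: correlation undefined")
    return float((dy * dys).sum() / denom)


def rsr(y, y_sim) -> float:
    """RMSE-to-observation-standard-deviation ratio."""
    y, y_sim = _paired(y, y_sim)
    denom = np.sqrt(((y - y.mean()) ** 2).sum())
    if denom == 0:
        raise ValueError("constant observations: RSR undefined")
    return float(np.sqrt(((y - y_sim) ** 2).sum()) / denom)


#: RSR performance bands, (upper bound, label), evaluated in order.
RSR_BANDS = (
    (0.5, "very good"),
    (0.6, "good"),
    (0.7, "satisfactory"),
    (np.inf, "unsatisfactory"),
)


def rsr_band(value: float) -> str:
    """Performance classification of an RSR value."""
    if value < 0:
        raise ValueError("RSR is non-negative")
    for bound, label in RSR_BANDS:
        if value < bound:
            return label
    raise AssertionError("unreachable")


def ioa(y, y_sim) -> float:
    """Willmott's index of agreement d, in [0, 1]."""
    y, y_sim = _paired(y, y_sim)
    ybar = y.mean()
    denom = ((np.abs(y_sim - ybar) + np.abs(y - ybar)) ** 2).sum()
    if denom == 0:
        raise ValueError("degenerate series: IOA denominator is zero")
    return float(1.0 - ((y - y_sim) ** 2).sum() / denom)


def evaluate_components(traj: Trajectory, observations: pd.DataFrame) -> pd.DataFrame:
    """Per-component R / RSR (+band) / IOA between a trajectory and observations.

    ``observations`` is a long DataFrame (day, component, value); observed
    days must be present in the trajectory's time grid.  Returns one metric
    row per component; no cross-component aggregation is performed.
    """
    df = traj.data.set_index("day")
    rows = []
    for comp, grp in observations.groupby("component", sort=True):
        days = grp["day"].to_numpy(dtype=float)
        missing = [d for d in days if d not in df.index]
        if missing:
            raise ValueError(f"observation days {missing[:3]} not in trajectory for {comp!r}")
        if comp not in df.columns:
            raise ValueError(f"unknown component {comp!r}")
        y = grp["value"].to_numpy(dtype=float)
        y_sim = df.loc[days, comp].to_numpy(dtype=float)
        row = {"component": comp, "n": len(y)}
        try:
            row["R"] = pearson_r(y, y_sim)
        except ValueError:
            row["R"] = np.nan
        try:
            v = rsr(y, y_sim)
            row["RSR"] = v
            row["RSR_band"] = rsr_band(v)
        except ValueError:
            row["RSR"], row["RSR_band"] = np.nan, ""
        try:
            row["IOA"] = ioa(y, y_sim)
        except ValueError:
            row["IOA"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# One-at-a-time MRE sensitivity
# ---------------------------------------------------------------------------

@dataclass
class SensitivityResult:
    parameter: str
    p_min: float
    p_max: float
    mre: float
    rank: int | None = None


def mre_from_runs(p_min_run, p_max_run, denominator: str = "max_run") -> float:
    """MRE between the min-parameter and max-parameter output series.

    ``denominator='max_run'`` divides each pointwise difference by the
    max-parameter run's value (0 contributions where it is 0);
    ``denominator='larger'`` divides by the pointwise larger magnitude of the
    two runs, which makes the measure symmetric in the endpoint labels.
    """
    lo = np.asarray(p_min_run, dtype=float)
    hi = np.asarray(p_max_run, dtype=float)
    if lo.shape != hi.shape or lo.size == 0:
        raise ValueError("runs must be equal-length non-empty series")
    if denominator == "max_run":
        denom = hi
    elif denominator == "larger":
        denom = np.maximum(np.abs(lo), np.abs(hi))
    else:
        raise ValueError(f"unknown denominator convention {denominator!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.abs((hi - lo) / denom)
    ratio[~np.isfinite(ratio)] = 0.0     # 0/0 and x/0 conventions
    return float(ratio.mean())


def mre_sensitivity(
    scenario: Scenario,
    ps_set: ParameterSet,
    parameter: str,
    bounds: tuple[float, float],
    target_species: str,
    denominator: str = "max_run",
    simulate_fn=None,
) -> SensitivityResult:
    """One-at-a-time sensitivity of a species trajectory to one parameter.

    Runs the scenario with ``parameter`` (``"<species>.<field>"`` or
    ``"lake.<field>"``) at its range minimum and maximum, all other
    parameters at defaults, and averages the pointwise relative spread of the
    target species' trajectory.  ``simulate_fn(scenario, ps)`` may replace the
    engine (e.g. for toy models); it must return an object whose
    ``series(column)`` yields the trajectory of a column.
    """
    lo, hi = bounds
    if lo > hi:
        raise ValueError(f"range minimum {lo} exceeds maximum {hi}")
    run = simulate_fn if simulate_fn is not None else simulate
    try:
        traj_lo = run(scenario, set_parameter(ps_set, parameter, lo))
        traj_hi = run(scenario, set_parameter(ps_set, parameter, hi))
    except Exception as exc:
        raise RuntimeError(f"simulation failed for parameter {parameter!r}: {exc}") from exc
    p_min = np.asarray(traj_lo.series(target_species), dtype=float)
    p_max = np.asarray(traj_hi.series(target_species), dtype=float)
    return SensitivityResult(
        parameter=parameter, p_min=lo, p_max=hi,
        mre=mre_from_runs(p_min, p_max, denominator=denominator),
    )


def rank_sensitivities(results: list[SensitivityResult]) -> list[SensitivityResult]:
    """Order sensitivity results by descending MRE; ties break lexicographically."""
    if not results:
        raise ValueError("no sensitivity results to rank")
    ordered = sorted(results, key=lambda r: (-r.mre, r.parameter))
    return [SensitivityResult(r.parameter, r.p_min, r.p_max, r.mre, rank=i + 1)
            for i, r in enumerate(ordered)]


# ---------------------------------------------------------------------------
# Grid calibration
# ---------------------------------------------------------------------------

def grid_calibrate(
    scenario: Scenario,
    ps_set: ParameterSet,
    observations: pd.DataFrame,
    free_parameters: dict[str, list[float]],
    metric: str = "rsr",
    target: str | None = None,
    simulate_fn=None,
) -> tuple[ParameterSet, dict[str, float], pd.DataFrame]:
    """Exhaustive grid search over up to four free parameters.

    Minimises RSR (``metric='rsr'``) or maximises IOA (``metric='ioa'``) of
    the target component's series against the observations; with no explicit
    target, the mean metric over all observed components is used.  Returns
    (best parameter set, best point as {parameter: value}, search record).
    """
    if metric not in ("rsr", "ioa"):
        raise ValueError(f"unknown metric {metric!r} (expected 'rsr' or 'ioa')")
    if not free_parameters or any(len(g) == 0 for g in free_parameters.values()):
        raise ValueError("every free parameter needs a non-empty grid")
    if len(free_parameters) > 4:
        raise ValueError("grid calibration supports at most 4 free parameters")
    run = simulate_fn if simulate_fn is not None else simulate
    if target is not None:
        observations = observations[observations["component"] == target]
        if observations.empty:
            raise ValueError(f"no observations for target {target!r}")

    names = list(free_parameters)
    best_score = None
    best_point = None
    best_ps = None
    records = []
    sign = 1.0 if metric == "rsr" else -1.0   # minimise rsr, maximise ioa
    for values in itertools.product(*(free_parameters[n] for n in names)):
        candidate = ps_set
        for n, v in zip(names, values):
            candidate = set_parameter(candidate, n, v)
        traj = run(scenario, candidate)
        report = evaluate_components(traj, observations)
        col = "RSR" if metric == "rsr" else "IOA"
        score = float(report[col].mean())
        records.append({**dict(zip(names, values)), metric: score})
        if best_score is None or sign * score < sign * best_score:
            best_score = score
            best_point = dict(zip(names, values))
            best_ps = candidate
    record = pd.DataFrame(records)
    return best_ps, best_point, record
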