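"""Scenario config files: a YAML manifest referencing forcing/schedule CSVs.

A scenario directory contains::

    scenario.yaml     time range, dt, seed, initial state, pulses, attenuation
    forcing.csv       day, temperature, solar_radiance [, external_tp_load]
    doses.csv         day, mass_g, available_fraction
    parameters.yaml   full parameter set (params.save_parameters format)

Paths inside scenario.yaml are resolved relative to the YAML file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chlorine import AttenuationModel, DoseEvent
from .engine import Scenario
from .params import ParameterSet, load_parameters, save_parameters
from .processes import LakeState


class ConfigError(ValueError):
    """Raised for malformed scenario configs."""


def save_scenario(scenario: Scenario, ps_set: ParameterSet, outdir: str | Path) -> Path:
    """Write a scenario directory; returns the path of scenario.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scenario.forcing.to_csv(outdir / "forcing.csv", index=False, float_format="%.17g")
    doses = pd.DataFrame(
        [{"day": e.day, "mass_g": e.mass, "available_fraction": e.available_fraction}
         for e in scenario.dose_schedule])
    if doses.empty:
        doses = pd.DataFrame(columns=["day", "mass_g", "available_fraction"])
    doses.to_csv(outdir / "doses.csv", index=False, float_format="%.17g")
    save_parameters(ps_set, outdir / "parameters.yaml")
    init = scenario.initial_state
    doc = {
        "t0": scenario.t0,
        "t1": scenario.t1,
        "dt": scenario.dt,
        "seed": scenario.seed,
        "forcing": "forcing.csv",
        "doses": "doses.csv",
        "parameters": "parameters.yaml",
        "tp_pulses": [[int(d), float(v)] for d, v in scenario.tp_pulses],
        "initial_state": {
            "biom": {sid: float(b) for sid, b in zip(ps_set.species_ids, init.biom)},
            "det": float(init.det), "pw": float(init.pw), "ps": float(init.ps),
        },
        "attenuation": {"mode": scenario.attenuation.mode,
                        "fixed_k": scenario.attenuation.fixed_k},
    }
    path = outdir / "scenario.yaml"
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def load_scenario(path: str | Path) -> tuple[Scenario, ParameterSet]:
    """Load a scenario written by :func:`save_scenario`."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: cannot read scenario config: {exc}") from exc
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: not a scenario config")
    base = path.parent
    for key in ("t0", "t1", "forcing", "parameters", "initial_state"):
        if key not in doc:
            raise ConfigError(f"{path}: missing required key {key!r}")

    ps_set = load_parameters(base / doc["parameters"])
    forcing = pd.read_csv(base / doc["forcing"])
    doses = []
    if "doses" in doc:
        ddf = pd.read_csv(base / doc["doses"])
        for _, row in ddf.iterrows():
            doses.append(DoseEvent(int(row["day"]), float(row["mass_g"]),
                                   float(row["available_fraction"])))
    init_doc = doc["initial_state"]
    biom = np.array([float(init_doc["biom"][sid]) for sid in ps_set.species_ids])
    init = LakeState(biom=biom, det=float(init_doc.get("det", 0.0)),
                     pw=float(init_doc.get("pw", 0.0)), ps=float(init_doc.get("ps", 0.0)))
    att_doc = doc.get("attenuation", {}) or {}
    attenuation = AttenuationModel(mode=att_doc.get("mode", "linear_interpolation"),
                                   fixed_k=float(att_doc.get("fixed_k", 2.041)))
    scenario = Scenario(
        t0=int(doc["t0"]), t1=int(doc["t1"]), initial_state=init, forcing=forcing,
        dose_schedule=doses,
        tp_pulses=[(int(d), float(v)) for d, v in doc.get("tp_pulses", [])],
        attenuation=attenuation, dt=float(doc.get("dt", 1.0)),
        seed=int(doc.get("seed", 0)),
    )
    return scenario, ps_set
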