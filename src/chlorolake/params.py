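"""Parameter data model, default species table, validation, and persistence.

The model tracks 14 species in five guilds.  Each species carries a bundle of
rate constants (maximum growth/mortality/respiration, half-saturation constants
for phosphorus and light, temperature and crowding coefficients, and a
chlorine-sensitivity coefficient ``kcc``), plus guild-specific fields:
assimilation efficiency and ingestion rate for consumers, grazing half
saturation and respiratory grazing cost for zooplankton, and a settling rate
for phytoplankton.

Default values are the calibrated Lotus Lake set.  Where the source table
prints a range with a bracketed validation value, the bracketed value is the
default and the range is retained in ``SpeciesSpec.ranges`` for sensitivity
analysis and calibration.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import yaml

GUILD_SUBMERGED_MACROPHYTE = "submerged_macrophyte"
GUILD_PHYTOPLANKTON = "phytoplankton"
GUILD_PERIPHYTON = "periphyton"
GUILD_ZOOPLANKTON = "zooplankton"
GUILD_BENTHOS = "benthos"

GUILDS = (
    GUILD_SUBMERGED_MACROPHYTE,
    GUILD_PHYTOPLANKTON,
    GUILD_PERIPHYTON,
    GUILD_ZOOPLANKTON,
    GUILD_BENTHOS,
)
PRODUCER_GUILDS = frozenset(
    {GUILD_SUBMERGED_MACROPHYTE, GUILD_PHYTOPLANKTON, GUILD_PERIPHYTON}
)
CONSUMER_GUILDS = frozenset({GUILD_ZOOPLANKTON, GUILD_BENTHOS})


class ParameterError(ValueError):
    """Raised for malformed parameter files or inconsistent parameter sets."""


@dataclass
class SpeciesSpec:
    """Parameter bundle for one species.

    Rates are per day.  ``ip`` is the half-saturation constant for phosphorus
    uptake (mg m^-3 day^-1 as tabulated), ``ik`` the half-saturation constant
    for solar radiance (MJ m^-2 day^-1), ``tk`` the dimensionless temperature
    effect constant (theta in theta^(T-20)), ``sk`` the self-density crowding
    coefficient, ``smk`` the shading/allelopathy coefficient due to the
    submerged macrophyte, and ``kcc`` the chlorine sensitivity coefficient.

    ``chlorine_multiplier`` is the dimensionless scale M inside the mortality
    factor exp(kcc * cc * M): 1000 for producers and zooplankton, 100 for
    benthos.
    """

    species_id: str
    name: str
    guild: str
    maxg: float = 0.0
    maxm: float = 0.0
    maxr: float = 0.0
    ip: float = 0.0
    ik: float = 0.0
    tk: float = 1.0
    sk: float = 0.0
    smk: float = 0.0
    kcc: float = 0.0
    ae: float | None = None
    ib: float | None = None
    rf: float | None = None
    kpz: float | None = None
    ser: float | None = None
    chlorine_multiplier: float = 1000.0
    #: calibration ranges, field name -> (min, max); metadata only
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)


@dataclass
class LakeConfig:
    """Physical lake configuration and pool-level rate constants.

    ``reference_volume`` (L) converts a chlorine dose in grams to an initial
    concentration in mg/L.  The default 8.0e6 L (8000 m^2 x 1.0 m) is the
    volume that reproduces the published dose concentrations 0.188 and
    0.045 mg/L exactly; note this is not area x mean depth (0.8 m).

    ``p_content_settled`` and ``p_content_benthos`` are the phosphorus
    fractions applied to settled biomass/detritus and to benthos mortality in
    the sediment phosphorus balance.
    """

    depth: float = 0.8                      # m
    active_sediment_layer: float = 0.05     # m
    detritus_decomposition_rate: float = 0.01   # day^-1
    phosphorus_diffusion_rate: float = 0.07     # day^-1
    detritus_settling_rate: float = 0.019       # day^-1
    phosphorus_settling_rate: float = 0.01      # day^-1
    tkp: float = 1.1                        # producer temperature constant
    tk_decomposition: float = 1.05          # decomposer temperature constant
    surface_area: float = 8000.0            # m^2
    reference_volume: float = 8.0e6         # L
    p_content_settled: float = 0.002
    p_content_benthos: float = 0.0001


@dataclass
class ParameterSet:
    """Full model parameterisation: species table, lake, and diet matrix.

    ``diet_matrix`` maps each zooplankton species id to a prey-weight mapping
    over phytoplankton species ids; each row sums to 1.
    """

    species: list[SpeciesSpec]
    lake: LakeConfig
    diet_matrix: dict[str, dict[str, float]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [s.species_id for s in self.species]
        if len(ids) != len(set(ids)):
            raise ParameterError("duplicate species ids: %r" % ids)

    @property
    def species_ids(self) -> list[str]:
        return [s.species_id for s in self.species]

    def get(self, species_id: str) -> SpeciesSpec:
        for s in self.species:
            if s.species_id == species_id:
                return s
        raise KeyError(species_id)

    def index(self, species_id: str) -> int:
        return self.species_ids.index(species_id)

    def by_guild(self, guild: str) -> list[SpeciesSpec]:
        return [s for s in self.species if s.guild == guild]


class Violation(NamedTuple):
    species_id: str     # "" for set-level violations
    field: str
    message: str


# ---------------------------------------------------------------------------
# Default Lotus Lake species table.
#
# Species codes a-n: a Vallisneria natans; b Microcystis aeruginosa;
# c Aphanizomenon flos-aquae; d Euglena gracilis; e Melosira granulata;
# f Ulothrix tenerrima; g Oscillatoria chlorina; h Synedra acus;
# i Brachionus plicatilis; j Diaphanosoma brachyurum; k Mesocyclops leuckarti;
# l Chironomid larvae; m Pomacea canaliculata; n Gyraulus compressus.
# ---------------------------------------------------------------------------

_DEFAULT_SPECIES: list[dict] = [
    dict(species_id="a", name="Vallisneria natans", guild=GUILD_SUBMERGED_MACROPHYTE,
         maxg=0.1, maxm=0.03, maxr=0.022, ip=34230.3, ik=2.2464, tk=1.1,
         sk=0.0001, smk=0.0, kcc=0.14,
         ranges={"sk": (0.0, 0.00023), "kcc": (0.11, 0.17)}),
    dict(species_id="b", name="Microcystis aeruginosa", guild=GUILD_PHYTOPLANKTON,
         maxg=1.3, maxm=0.007, maxr=0.0005, ip=42.13, ik=2.0, tk=1.1,
         sk=0.06, smk=0.0038, kcc=0.001, ser=0.019,
         ranges={"sk": (0.0, 0.1)}),
    dict(species_id="c", name="Aphanizomenon flos-aquae", guild=GUILD_PHYTOPLANKTON,
         maxg=1.2, maxm=0.007, maxr=0.0005, ip=0.52, ik=2.0, tk=1.1,
         sk=0.2, smk=0.0038, kcc=0.1, ser=0.019,
         ranges={"sk": (0.03, 0.4), "kcc": (0.085, 0.14)}),
    dict(species_id="d", name="Euglena gracilis", guild=GUILD_PHYTOPLANKTON,
         maxg=1.1, maxm=0.007, maxr=0.0005, ip=2.01, ik=2.0, tk=1.1,
         sk=0.4, smk=0.003, kcc=0.001, ser=0.019,
         ranges={"sk": (0.35, 0.55)}),
    dict(species_id="e", name="Melosira granulata", guild=GUILD_PHYTOPLANKTON,
         maxg=0.65, maxm=0.007, maxr=0.0005, ip=6.16, ik=2.0, tk=1.1,
         sk=0.3, smk=0.003, kcc=0.096, ser=0.019,
         ranges={"maxg": (0.5, 0.8), "sk": (0.2, 0.4)}),
    dict(species_id="f", name="Ulothrix tenerrima", guild=GUILD_PERIPHYTON,
         maxg=0.065, maxm=0.005, maxr=0.02, ip=2.05, ik=0.09, tk=1.1,
         sk=0.001, smk=0.00001, kcc=0.08,
         ranges={"kcc": (0.06, 0.1)}),
    dict(species_id="g", name="Oscillatoria chlorina", guild=GUILD_PERIPHYTON,
         maxg=0.065, maxm=0.005, maxr=0.02, ip=17.11, ik=0.09, tk=1.1,
         sk=0.0255, smk=0.00001, kcc=0.1,
         ranges={"sk": (0.001, 0.05)}),
    dict(species_id="h", name="Synedra acus", guild=GUILD_PERIPHYTON,
         maxg=0.065, maxm=0.005, maxr=0.02, ip=0.000717, ik=0.09, tk=1.1,
         sk=0.0315, smk=0.00001, kcc=0.3,
         ranges={"sk": (0.003, 0.06)}),
    dict(species_id="i", name="Brachionus plicatilis", guild=GUILD_ZOOPLANKTON,
         maxm=0.14, maxr=0.01, tk=1.05, sk=0.0001, kcc=0.3,
         ae=0.3, ib=1.45, rf=0.07, kpz=1.0, ip=0.046159,
         ranges={"kcc": (0.05, 0.54)}),
    dict(species_id="j", name="Diaphanosoma brachyurum", guild=GUILD_ZOOPLANKTON,
         maxm=0.14, maxr=0.01, tk=1.05, sk=0.0001, kcc=0.3,
         ae=0.3, ib=1.45, rf=0.07, kpz=1.0, ip=0.25448,
         ranges={"kcc": (0.15, 0.76)}),
    dict(species_id="k", name="Mesocyclops leuckarti", guild=GUILD_ZOOPLANKTON,
         maxm=0.14, maxr=0.01, tk=1.05, sk=0.0001, kcc=0.6,
         ae=0.3, ib=1.45, rf=0.07, kpz=1.0, ip=4.14254,
         ranges={"kcc": (0.3, 0.81)}),
    dict(species_id="l", name="Chironomid larvae", guild=GUILD_BENTHOS,
         maxm=0.0001, maxr=0.026, tk=1.05, kcc=0.0,
         ae=0.023, ib=0.001, ip=6.34301, chlorine_multiplier=100.0),
    dict(species_id="m", name="Pomacea canaliculata", guild=GUILD_BENTHOS,
         maxm=0.0001, maxr=0.026, tk=1.05, kcc=0.0,
         ae=0.023, ib=0.001, ip=1.5858, chlorine_multiplier=100.0),
    dict(species_id="n", name="Gyraulus compressus", guild=GUILD_BENTHOS,
         maxm=0.0001, maxr=0.026, tk=1.05, kcc=0.0,
         ae=0.023, ib=0.001, chlorine_multiplier=100.0),
]

#: Provenance notes for symbol-mapping choices in the default table.  The
#: source table prints rows "Iv", "Sr" and "Pk" whose symbols are not defined
#: in the symbol glossary; they are mapped to ip (phosphorus half-saturation),
#: ser (settling rate) and kpz (zooplankton grazing half-saturation).
SYMBOL_MAPPING_NOTES = {
    "Iv": "mapped to ip (half-saturation for phosphorus uptake)",
    "Sr": "mapped to ser (phytoplankton settling rate)",
    "Pk": "mapped to kpz for zooplankton; producer-column Pk values kept as "
          "metadata (a: 0.03, b-e: 1.0, f-h: 0.045)",
}

_PK_PRODUCER_VALUES = {"a": 0.03, "b": 1.0, "c": 1.0, "d": 1.0, "e": 1.0,
                       "f": 0.045, "g": 0.045, "h": 0.045}


def default_lotus_parameters() -> ParameterSet:
    """Return the calibrated 14-species Lotus Lake parameter set.

    Where the calibration table prints a range, the bracketed validation value
    is used as the point default and the range appears in ``ranges``.  Each
    zooplankton species grazes uniformly over the four phytoplankton species.
    """
    species = [SpeciesSpec(**{k: v for k, v in row.items()}) for row in _DEFAULT_SPECIES]
    phyto = [r["species_id"] for r in _DEFAULT_SPECIES if r["guild"] == GUILD_PHYTOPLANKTON]
    diet = {
        r["species_id"]: {p: 1.0 / len(phyto) for p in phyto}
        for r in _DEFAULT_SPECIES
        if r["guild"] == GUILD_ZOOPLANKTON
    }
    return ParameterSet(
        species=species,
        lake=LakeConfig(),
        diet_matrix=diet,
        metadata={"symbol_mapping": dict(SYMBOL_MAPPING_NOTES),
                  "pk_producer_values": dict(_PK_PRODUCER_VALUES)},
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_RATE_FIELDS = ("maxg", "maxm", "maxr", "ip", "ik", "sk", "smk", "kcc")


def validate_parameters(ps: ParameterSet) -> list[Violation]:
    """Check a parameter set and return a list of violations (empty = valid)."""
    out: list[Violation] = []
    ids = set()
    for s in ps.species:
        if s.species_id in ids:
            out.append(Violation(s.species_id, "species_id", "duplicate species id"))
        ids.add(s.species_id)
        if s.guild not in GUILDS:
            out.append(Violation(s.species_id, "guild", f"unknown guild {s.guild!r}"))
            continue
        for f in _RATE_FIELDS:
            v = getattr(s, f)
            if v < 0:
                out.append(Violation(s.species_id, f, f"negative value {v}"))
        if s.tk <= 0:
            out.append(Violation(s.species_id, "tk", f"tk must be > 0, got {s.tk}"))
        if s.guild in CONSUMER_GUILDS:
            for f in ("ae", "ib"):
                if getattr(s, f) is None:
                    out.append(Violation(s.species_id, f, "required for consumers"))
        if s.guild == GUILD_ZOOPLANKTON:
            for f in ("rf", "kpz"):
                if getattr(s, f) is None:
                    out.append(Violation(s.species_id, f, "required for zooplankton"))
        if s.guild == GUILD_PHYTOPLANKTON and s.ser is None:
            out.append(Violation(s.species_id, "ser", "required for phytoplankton"))
        for f in ("ae", "ib", "rf", "kpz", "ser"):
            v = getattr(s, f)
            if v is not None and v < 0:
                out.append(Violation(s.species_id, f, f"negative value {v}"))

    lake = ps.lake
    if lake.depth <= 0:
        out.append(Violation("", "lake.depth", "depth must be > 0"))
    if lake.active_sediment_layer <= 0:
        out.append(Violation("", "lake.active_sediment_layer", "must be > 0"))
    if lake.reference_volume <= 0:
        out.append(Violation("", "lake.reference_volume", "must be > 0"))
    for f in ("detritus_decomposition_rate", "phosphorus_diffusion_rate",
              "detritus_settling_rate", "phosphorus_settling_rate",
              "p_content_settled", "p_content_benthos"):
        if getattr(lake, f) < 0:
            out.append(Violation("", f"lake.{f}", "negative rate"))

    for zoo_id, row in ps.diet_matrix.items():
        if zoo_id not in ids:
            out.append(Violation(zoo_id, "diet_matrix", "grazer id not in species"))
            continue
        total = sum(row.values())
        if abs(total - 1.0) > 1e-9:
            out.append(Violation(zoo_id, "diet_matrix", f"row sums to {total}, not 1"))
        for prey in row:
            if prey not in ids:
                out.append(Violation(zoo_id, "diet_matrix", f"unknown prey {prey!r}"))
    return out


# ---------------------------------------------------------------------------
# Persistence (YAML config + CSV species table export)
# ---------------------------------------------------------------------------

_OPTIONAL_FIELDS = ("ae", "ib", "rf", "kpz", "ser")


def save_parameters(ps: ParameterSet, path: str | Path) -> None:
    """Write a parameter set to a YAML config file (round-trip exact)."""
    doc: dict = {"lake": dict(vars(ps.lake)), "species": [], "diet_matrix": ps.diet_matrix,
                 "metadata": ps.metadata}
    for s in ps.species:
        row: dict = {"id": s.species_id, "name": s.name, "guild": s.guild}
        for f in ("maxg", "maxm", "maxr", "ip", "ik", "tk", "sk", "smk", "kcc",
                  "chlorine_multiplier"):
            row[f] = getattr(s, f)
        for f in _OPTIONAL_FIELDS:
            v = getattr(s, f)
            if v is not None:
                row[f] = v
        if s.ranges:
            row["ranges"] = {k: list(v) for k, v in s.ranges.items()}
        doc["species"].append(row)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_parameters(path: str | Path) -> ParameterSet:
    """Load a parameter set written by :func:`save_parameters`.

    Omitted optional numeric fields default to 0 for ``smk``/``sk``/``kcc`` and
    to ``None`` for guild-specific fields.  Unknown guild names, duplicate
    species ids and malformed YAML raise :class:`ParameterError` with file
    context.
    """
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParameterError(f"{path}: cannot parse config: {exc}") from exc
    if not isinstance(doc, dict) or "species" not in doc:
        raise ParameterError(f"{path}: not a parameter config (missing 'species')")

    species: list[SpeciesSpec] = []
    seen: set[str] = set()
    for i, row in enumerate(doc["species"]):
        sid = row.get("id")
        if sid is None:
            raise ParameterError(f"{path}: species block #{i} has no 'id'")
        if sid in seen:
            raise ParameterError(f"{path}: duplicate species id {sid!r}")
        seen.add(sid)
        guild = row.get("guild")
        if guild not in GUILDS:
            raise ParameterError(
                f"{path}: species {sid!r} has unknown guild {guild!r} "
                f"(expected one of {', '.join(GUILDS)})")
        kwargs: dict = {"species_id": sid, "name": row.get("name", sid), "guild": guild}
        for f in ("maxg", "maxm", "maxr", "ip", "ik", "tk", "sk", "smk", "kcc",
                  "chlorine_multiplier"):
            if f in row:
                kwargs[f] = float(row[f])
        for f in _OPTIONAL_FIELDS:
            if f in row:
                kwargs[f] = float(row[f])
        if "ranges" in row:
            kwargs["ranges"] = {k: tuple(v) for k, v in row["ranges"].items()}
        species.append(SpeciesSpec(**kwargs))

    lake = LakeConfig(**doc.get("lake", {}))
    diet = {z: dict(r) for z, r in doc.get("diet_matrix", {}).items()}
    return ParameterSet(species=species, lake=lake, diet_matrix=diet,
                        metadata=doc.get("metadata", {}) or {})


_CSV_COLUMNS = [
    ("Ae", "ae"), ("Ib", "ib"), ("Ik", "ik"), ("Ip", "ip"), ("Tk", "tk"),
    ("Maxg", "maxg"), ("Maxm", "maxm"), ("Maxr", "maxr"), ("Rf", "rf"),
    ("Sk", "sk"), ("Smk", "smk"), ("Kcc", "kcc"), ("Kpz", "kpz"), ("Ser", "ser"),
    ("M", "chlorine_multiplier"),
]


def export_species_csv(ps: ParameterSet, path: str | Path) -> None:
    """Write the species table as CSV, one row per species, symbol columns."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["species", "name", "guild"] + [c for c, _ in _CSV_COLUMNS])
        for s in ps.species:
            row = [s.species_id, s.name, s.guild]
            for _, f in _CSV_COLUMNS:
                v = getattr(s, f)
                row.append("" if v is None else repr(float(v)))
            w.writerow(row)


def set_parameter(ps: ParameterSet, param_id: str, value: float) -> ParameterSet:
    """Return a copy of ``ps`` with one parameter replaced.

    ``param_id`` is ``"<species_id>.<field>"`` (e.g. ``"e.maxg"``) or
    ``"lake.<field>"``.
    """
    scope, _, fname = param_id.partition(".")
    if not fname:
        raise ParameterError(f"malformed parameter id {param_id!r}; expected scope.field")
    if scope == "lake":
        if not hasattr(ps.lake, fname):
            raise ParameterError(f"unknown lake field {fname!r}")
        lake = replace(ps.lake, **{fname: value})
        return ParameterSet([replace(s) for s in ps.species], lake,
                            {z: dict(r) for z, r in ps.diet_matrix.items()},
                            dict(ps.metadata))
    species = []
    found = False
    for s in ps.species:
        if s.species_id == scope:
            if not hasattr(s, fname):
                raise ParameterError(f"unknown species field {fname!r}")
            s = replace(s, **{fname: value})
            found = True
        else:
            s = replace(s)
        species.append(s)
    if not found:
        raise ParameterError(f"unknown species id {scope!r}")
    return ParameterSet(species, replace(ps.lake),
                        {z: dict(r) for z, r in ps.diet_matrix.items()},
                        dict(ps.metadata))
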