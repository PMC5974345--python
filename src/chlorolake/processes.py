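"""Process rates of the lake food web and its phosphorus cycle.

State variables: biomass density of each of the 14 species (guild-scoped
units: the macrophyte and benthos in g m^-2, plankton and periphyton in
mg L^-1-scale densities), a detritus pool, total phosphorus in water (pw,
mg/L) and in sediment (ps, mg/g), and the ambient daily-mean chlorine
concentration cc (mg/L, supplied as forcing).

Producers (macrophyte, phytoplankton, periphyton) grow under Monod phosphorus
and light limitation with theta^(T-20) temperature scaling and exponential
self-crowding; phytoplankton and periphyton growth is additionally suppressed
by the macrophyte canopy, exp(-smk * Biomsvm).  All species die at
temperature-scaled rates amplified by chlorine, exp(kcc * cc * M), and respire
at temperature-scaled rates.  Zooplankton graze phytoplankton with a prey
refuge below density 0.5; benthos graze detritus linearly.  Detritus collects
mortality of the non-benthos guilds and loses settling, benthos grazing and
decomposition.  Water-column phosphorus exchanges with the sediment pool by
diffusion and settling.

Cross-guild couplings use the state values numerically, without unit
re-scaling, exactly as the governing difference equations are written; the
explicit phosphorus-content constants (0.002 per settled biomass/detritus,
0.0001 per benthos mortality) are the only cross-unit conversions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import (
    GUILD_BENTHOS,
    GUILD_PERIPHYTON,
    GUILD_PHYTOPLANKTON,
    GUILD_SUBMERGED_MACROPHYTE,
    GUILD_ZOOPLANKTON,
    LakeConfig,
    ParameterSet,
    SpeciesSpec,
)


@dataclass
class LakeState:
    """Full model state: per-species biomass, detritus, phosphorus, chlorine."""

    biom: np.ndarray            # per-species biomass density
    det: float = 0.0            # detritus biomass density
    pw: float = 0.0             # TP in water, mg/L
    ps: float = 0.0             # TP in sediment, mg/g
    cc: float = 0.0             # chlorine, mg/L (carried for record-keeping)

    def __post_init__(self) -> None:
        self.biom = np.asarray(self.biom, dtype=float)

    def copy(self) -> "LakeState":
        return LakeState(self.biom.copy(), self.det, self.pw, self.ps, self.cc)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.biom, [self.det, self.pw, self.ps]])

    @classmethod
    def from_vector(cls, v: np.ndarray, cc: float = 0.0) -> "LakeState":
        v = np.asarray(v, dtype=float)
        return cls(biom=v[:-3].copy(), det=float(v[-3]), pw=float(v[-2]),
                   ps=float(v[-1]), cc=cc)


@dataclass
class ForcingSample:
    """Environmental drivers on one day."""

    temperature: float          # degC
    solar_radiance: float       # MJ m^-2 day^-1
    cc: float = 0.0             # daily-mean chlorine, mg/L
    external_tp_load: float = 0.0   # mg/L/day added to pw


@dataclass
class ProcessRates:
    """Per-species and pool-level process rates for one state evaluation."""

    growth: np.ndarray
    mortality: np.ndarray
    respiration: np.ndarray
    grazing: np.ndarray         # consumer gain (assimilated)
    settling: np.ndarray        # phytoplankton settling (settling1 components)
    prey_loss: np.ndarray       # phytoplankton biomass removed by zooplankton
    dec: float = 0.0
    diff: float = 0.0
    settling2: float = 0.0      # detritus settling
    settling3: float = 0.0      # water-TP settling
    det_grazed: float = 0.0     # detritus removed by benthos


# ---------------------------------------------------------------------------
# Elementary process functions
# ---------------------------------------------------------------------------

def _saturation(x: float, half: float) -> float:
    """Monod factor x/(x+half) with the 0/0 -> 0 convention."""
    denom = x + half
    return x / denom if denom > 0 else 0.0


def producer_growth(
    spec: SpeciesSpec,
    biom: float,
    pw: float,
    temperature: float,
    sr: float,
    biomsvm: float,
    lake: LakeConfig,
) -> float:
    """Growth of a primary producer.

    Maxg * Biom * [pw/(pw+ip)] * theta^(T-20) * [sr/(sr+ik)] * exp(-sk*Biom),
    with an extra canopy-suppression factor exp(-smk*Biomsvm) for
    phytoplankton and periphyton (the macrophyte does not shade itself).
    theta is the species temperature constant tk.
    """
    rate = (
        spec.maxg * biom
        * _saturation(pw, spec.ip)
        * spec.tk ** (temperature - 20.0)
        * _saturation(sr, spec.ik)
        * np.exp(-spec.sk * biom)
    )
    if spec.guild != GUILD_SUBMERGED_MACROPHYTE:
        rate *= np.exp(-spec.smk * biomsvm)
    return float(rate)


def mortality(spec: SpeciesSpec, biom: float, temperature: float, cc: float) -> float:
    """Biom * Maxm * tk^(T-20) * exp(kcc * cc * M)."""
    return float(
        biom * spec.maxm * spec.tk ** (temperature - 20.0)
        * np.exp(spec.kcc * cc * spec.chlorine_multiplier)
    )


def respiration(spec: SpeciesSpec, biom: float, temperature: float) -> float:
    """Biom * Maxr * tk^(T-20)."""
    return float(biom * spec.maxr * spec.tk ** (temperature - 20.0))


def zooplankton_grazing(
    zoo: SpeciesSpec, biomzoo: float, biomphy_weighted: float, temperature: float
) -> float:
    """Assimilated grazing of one zooplankton species on its weighted prey field.

    Biomzoo * ae * ib * tk^(T-20) * (1-rf) * (Biomphy-0.5)/(Biomphy+kpz)
    * exp(-sk*Biomzoo); the prey factor is floored at 0 (prey refuge below a
    density of 0.5).
    """
    prey = (biomphy_weighted - 0.5) / (biomphy_weighted + zoo.kpz)
    prey = max(prey, 0.0)
    return float(
        biomzoo * zoo.ae * zoo.ib * zoo.tk ** (temperature - 20.0)
        * (1.0 - zoo.rf) * prey * np.exp(-zoo.sk * biomzoo)
    )


def benthos_grazing(ben: SpeciesSpec, biom: float, det: float, temperature: float) -> float:
    """ae * ib * tk^(T-20) * Biom * det — linear in the detritus pool."""
    return float(ben.ae * ben.ib * ben.tk ** (temperature - 20.0) * biom * det)


def phytoplankton_settling(
    spec: SpeciesSpec, biom: float, temperature: float, lake: LakeConfig
) -> float:
    """(ser/d) * (T/20) * Biom."""
    return float(spec.ser / lake.depth * (temperature / 20.0) * biom)


def detritus_settling(det: float, temperature: float, lake: LakeConfig) -> float:
    """(serd/d) * (T/20) * det."""
    return float(lake.detritus_settling_rate / lake.depth * (temperature / 20.0) * det)


def detritus_decomposition(det: float, temperature: float, lake: LakeConfig) -> float:
    """dr * det * tk^(T-20) with the decomposer temperature constant."""
    return float(lake.detritus_decomposition_rate * det
                 * lake.tk_decomposition ** (temperature - 20.0))


def phosphorus_diffusion(pw: float, ps: float, lake: LakeConfig) -> float:
    """drr * (ps - pw) * (as/d); positive when the sediment is richer."""
    return float(lake.phosphorus_diffusion_rate * (ps - pw)
                 * lake.active_sediment_layer / lake.depth)


def phosphorus_settling(pw: float, lake: LakeConfig) -> float:
    """(serp/d) * pw."""
    return float(lake.phosphorus_settling_rate / lake.depth * pw)


# ---------------------------------------------------------------------------
# Full-state derivative assembly
# ---------------------------------------------------------------------------

def compute_rates(
    state: LakeState,
    forcing: ForcingSample,
    ps_set: ParameterSet,
    strict_as_printed: bool = False,
) -> ProcessRates:
    """Evaluate every process rate at one state.

    In the default mass-flow bookkeeping, prey lose *ingested* biomass
    (assimilated grazing divided by ae and, for zooplankton, by (1-rf)) while
    grazers gain assimilated biomass.  With ``strict_as_printed=True`` the
    prey/detritus debit equals the grazer credit exactly as the equations are
    written.
    """
    species = ps_set.species
    lake = ps_set.lake
    n = len(species)
    T = forcing.temperature
    sr = forcing.solar_radiance
    cc = forcing.cc
    biom = state.biom
    if biom.shape != (n,):
        raise ValueError(f"state has {biom.shape[0]} species, parameter set has {n}")
    idx = {s.species_id: i for i, s in enumerate(species)}

    biomsvm = sum(
        biom[i] for i, s in enumerate(species)
        if s.guild == GUILD_SUBMERGED_MACROPHYTE
    )

    r = ProcessRates(
        growth=np.zeros(n), mortality=np.zeros(n), respiration=np.zeros(n),
        grazing=np.zeros(n), settling=np.zeros(n), prey_loss=np.zeros(n),
    )

    for i, s in enumerate(species):
        r.mortality[i] = mortality(s, biom[i], T, cc)
        r.respiration[i] = respiration(s, biom[i], T)
        if s.guild in (GUILD_SUBMERGED_MACROPHYTE, GUILD_PHYTOPLANKTON, GUILD_PERIPHYTON):
            r.growth[i] = producer_growth(s, biom[i], state.pw, T, sr, biomsvm, lake)
            if s.guild == GUILD_PHYTOPLANKTON:
                r.settling[i] = phytoplankton_settling(s, biom[i], T, lake)
        elif s.guild == GUILD_ZOOPLANKTON:
            weights = ps_set.diet_matrix.get(s.species_id, {})
            prey_field = sum(w * biom[idx[p]] for p, w in weights.items())
            gain = zooplankton_grazing(s, biom[i], prey_field, T)
            r.grazing[i] = gain
            if gain > 0.0:
                debit = gain if strict_as_printed else gain / (s.ae * (1.0 - s.rf))
                avail = {p: w * biom[idx[p]] for p, w in weights.items()}
                total = sum(avail.values())
                if total > 0:
                    for p, a in avail.items():
                        r.prey_loss[idx[p]] += debit * a / total
        elif s.guild == GUILD_BENTHOS:
            gain = benthos_grazing(s, biom[i], state.det, T)
            r.grazing[i] = gain
            r.det_grazed += gain if strict_as_printed else gain / s.ae

    r.settling2 = detritus_settling(state.det, T, lake)
    r.dec = detritus_decomposition(state.det, T, lake)
    r.diff = phosphorus_diffusion(state.pw, state.ps, lake)
    r.settling3 = phosphorus_settling(state.pw, lake)
    return r


def detritus_balance(state: LakeState, rates: ProcessRates, ps_set: ParameterSet) -> float:
    """d(det)/dt: mortality of macrophyte+phytoplankton+periphyton+zooplankton,
    minus detritus settling, benthos grazing and decomposition."""
    gain = sum(
        rates.mortality[i] for i, s in enumerate(ps_set.species)
        if s.guild != GUILD_BENTHOS
    )
    return float(gain - rates.settling2 - rates.det_grazed - rates.dec)


def phosphorus_balance(
    state: LakeState,
    rates: ProcessRates,
    ps_set: ParameterSet,
    strict_as_printed: bool = False,
) -> tuple[float, float]:
    """d(pw)/dt and d(ps)/dt.

    Water TP gains sediment diffusion and decomposed detritus and loses
    producer uptake and settling.  By default decomposition and uptake are
    converted to phosphorus units via the settled-biomass P content; with
    ``strict_as_printed=True`` the raw biomass rates enter the balance as the
    equations are written.  Sediment TP gains settled phytoplankton and
    detritus (x 0.002), settled water TP, and benthos mortality (x 0.0001),
    and loses diffusion.
    """
    lake = ps_set.lake
    f = 1.0 if strict_as_printed else lake.p_content_settled
    growth_producers = sum(
        rates.growth[i] for i, s in enumerate(ps_set.species)
        if s.guild in (GUILD_SUBMERGED_MACROPHYTE, GUILD_PHYTOPLANKTON, GUILD_PERIPHYTON)
    )
    dpw = rates.diff + rates.dec * f - growth_producers * f - rates.settling3
    mortality5 = sum(
        rates.mortality[i] for i, s in enumerate(ps_set.species)
        if s.guild == GUILD_BENTHOS
    )
    dps = (
        rates.settling.sum() * lake.p_content_settled
        + rates.settling2 * lake.p_content_settled
        + rates.settling3
        + mortality5 * lake.p_content_benthos
        - rates.diff
    )
    return float(dpw), float(dps)


def state_derivative(
    state: LakeState,
    forcing: ForcingSample,
    ps_set: ParameterSet,
    strict_as_printed: bool = False,
    return_rates: bool = False,
):
    """Assemble the full rate-of-change vector for one state.

    Producer balances: growth - mortality - respiration, with phytoplankton
    additionally losing settling and zooplankton grazing.  Consumer balances:
    grazing - mortality - respiration.  Returns a LakeState-shaped derivative
    (cc carries no dynamics; the external TP load enters d(pw)/dt).
    """
    rates = compute_rates(state, forcing, ps_set, strict_as_printed)
    dbiom = np.zeros_like(state.biom)
    for i, s in enumerate(ps_set.species):
        if s.guild in (GUILD_SUBMERGED_MACROPHYTE, GUILD_PERIPHYTON):
            dbiom[i] = rates.growth[i] - rates.mortality[i] - rates.respiration[i]
        elif s.guild == GUILD_PHYTOPLANKTON:
            dbiom[i] = (rates.growth[i] - rates.mortality[i] - rates.respiration[i]
                        - rates.settling[i] - rates.prey_loss[i])
        else:  # zooplankton, benthos
            dbiom[i] = rates.grazing[i] - rates.mortality[i] - rates.respiration[i]
    ddet = detritus_balance(state, rates, ps_set)
    dpw, dps = phosphorus_balance(state, rates, ps_set, strict_as_printed)
    dpw += forcing.external_tp_load
    deriv = LakeState(biom=dbiom, det=ddet, pw=dpw, ps=dps, cc=0.0)
    if not np.isfinite(deriv.as_vector()).all():
        raise FloatingPointError("non-finite derivative encountered")
    if return_rates:
        return deriv, rates
    return deriv
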