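"""Independent straight-line transcription of the governing equations.

Used as an oracle against the package's vectorised assembly: every balance is
written out term by term with plain Python floats and explicit loops, reading
parameters from plain dicts rather than the package's dataclasses.  It shares
the package's documented bookkeeping conventions (mass-flow grazing debits,
phosphorus-content conversion of decomposition/uptake) but none of its code
paths.
"""

import math


def reference_derivative(biom, det, pw, ps, cc, T, sr, species, lake, diet):
    """Return (dbiom: dict, ddet, dpw, dps).

    ``biom`` and ``species`` are dicts keyed by species id; ``species[sid]``
    is a plain dict of parameter values including 'guild'; ``lake`` a plain
    dict; ``diet`` maps zooplankton id -> {phyto id: weight}.
    """
    biomsvm = sum(biom[sid] for sid, s in species.items()
                  if s["guild"] == "submerged_macrophyte")

    growth, mort, resp, settl = {}, {}, {}, {}
    for sid, s in species.items():
        g = s["guild"]
        b = biom[sid]
        # mortality: Biom * Maxm * Tk^(T-20) * exp(kcc * cc * M)
        mort[sid] = b * s["maxm"] * s["tk"] ** (T - 20.0) * math.exp(
            s["kcc"] * cc * s["M"])
        # respiration: Tk^(T-20) * Maxr * Biom
        resp[sid] = s["tk"] ** (T - 20.0) * s["maxr"] * b
        growth[sid] = 0.0
        settl[sid] = 0.0
        if g in ("submerged_macrophyte", "phytoplankton", "periphyton"):
            pfac = pw / (pw + s["ip"]) if (pw + s["ip"]) > 0 else 0.0
            lfac = sr / (sr + s["ik"]) if (sr + s["ik"]) > 0 else 0.0
            v = (s["maxg"] * b * pfac * s["tk"] ** (T - 20.0) * lfac
                 * math.exp(-s["sk"] * b))
            if g != "submerged_macrophyte":
                v *= math.exp(-s["smk"] * biomsvm)
            growth[sid] = v
        if g == "phytoplankton":
            settl[sid] = s["ser"] / lake["d"] * (T / 20.0) * b

    graz = {sid: 0.0 for sid in species}
    prey_loss = {sid: 0.0 for sid in species}
    det_grazed = 0.0
    for sid, s in species.items():
        if s["guild"] == "zooplankton":
            field = sum(w * biom[p] for p, w in diet[sid].items())
            prey_fac = (field - 0.5) / (field + s["kpz"])
            if prey_fac < 0.0:
                prey_fac = 0.0
            g7 = (biom[sid] * s["ae"] * s["ib"] * s["tk"] ** (T - 20.0)
                  * (1.0 - s["rf"]) * prey_fac * math.exp(-s["sk"] * biom[sid]))
            graz[sid] = g7
            if g7 > 0.0:
                debit = g7 / (s["ae"] * (1.0 - s["rf"]))
                avail = {p: w * biom[p] for p, w in diet[sid].items()}
                tot = sum(avail.values())
                if tot > 0.0:
                    for p, a in avail.items():
                        prey_loss[p] += debit * a / tot
        elif s["guild"] == "benthos":
            g10 = s["ae"] * s["ib"] * s["tk"] ** (T - 20.0) * biom[sid] * det
            graz[sid] = g10
            det_grazed += g10 / s["ae"]

    dbiom = {}
    for sid, s in species.items():
        g = s["guild"]
        if g in ("submerged_macrophyte", "periphyton"):
            dbiom[sid] = growth[sid] - mort[sid] - resp[sid]
        elif g == "phytoplankton":
            dbiom[sid] = (growth[sid] - mort[sid] - resp[sid]
                          - settl[sid] - prey_loss[sid])
        else:
            dbiom[sid] = graz[sid] - mort[sid] - resp[sid]

    settling2 = lake["serd"] / lake["d"] * (T / 20.0) * det
    dec = lake["dr"] * det * lake["tk_dec"] ** (T - 20.0)
    mort_no_benthos = sum(mort[sid] for sid, s in species.items()
                          if s["guild"] != "benthos")
    ddet = mort_no_benthos - settling2 - det_grazed - dec

    diff = lake["drr"] * (ps - pw) * lake["as"] / lake["d"]
    settling3 = lake["serp"] / lake["d"] * pw
    growth_prod = sum(growth[sid] for sid, s in species.items()
                      if s["guild"] in ("submerged_macrophyte", "phytoplankton",
                                        "periphyton"))
    dpw = diff + dec * lake["p2"] - growth_prod * lake["p2"] - settling3
    mort5 = sum(mort[sid] for sid, s in species.items() if s["guild"] == "benthos")
    settling1 = sum(settl.values())
    dps = (settling1 * lake["p2"] + settling2 * lake["p2"] + settling3
           + mort5 * lake["p5"] - diff)
    return dbiom, ddet, dpw, dps


def params_as_dicts(ps_set):
    """Flatten a ParameterSet into the plain dicts the reference model uses."""
    species = {}
    for s in ps_set.species:
        species[s.species_id] = {
            "guild": s.guild, "maxg": s.maxg, "maxm": s.maxm, "maxr": s.maxr,
            "ip": s.ip, "ik": s.ik, "tk": s.tk, "sk": s.sk, "smk": s.smk,
            "kcc": s.kcc, "M": s.chlorine_multiplier, "ae": s.ae, "ib": s.ib,
            "rf": s.rf, "kpz": s.kpz, "ser": s.ser,
        }
    lake = {
        "d": ps_set.lake.depth, "as": ps_set.lake.active_sediment_layer,
        "dr": ps_set.lake.detritus_decomposition_rate,
        "drr": ps_set.lake.phosphorus_diffusion_rate,
        "serd": ps_set.lake.detritus_settling_rate,
        "serp": ps_set.lake.phosphorus_settling_rate,
        "tk_dec": ps_set.lake.tk_decomposition,
        "p2": ps_set.lake.p_content_settled,
        "p5": ps_set.lake.p_content_benthos,
    }
    return species, lake, ps_set.diet_matrix
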