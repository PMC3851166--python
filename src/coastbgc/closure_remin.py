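"""Implicit zooplankton closure, remineralization, nitrification, oxygen.

Zooplankton (and higher trophic levels) are not state variables: grazing
is an explicit loss applied to phytoplankton and bacteria, modulated by a
temperature limitation so grazing pressure is weak in winter and strong
in summer, and every grazed mole of N and P (and the non-respired share
of C) is returned to the particulate, dissolved-organic or inorganic
pools.  This module also assembles the full source-minus-sink vector from
the process modules as an explicit ledger of pool-to-pool transfers, which
makes element conservation structural rather than incidental.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_state import (
    DegenerateStateError,
    ModelVersion,
    ParameterSet,
    Quotas,
    StateVector,
    TendencyVector,
    VARIABLES_P,
    compute_quotas,
    neutral_quotas,
    variables_for,
)
from . import phytoplankton as phy
from . import bacteria as bac

__all__ = [
    "GrazingFluxes",
    "FluxLedger",
    "EXT",
    "grazing_temperature_limitation",
    "grazing_fluxes",
    "closure_redistribution",
    "remineralization",
    "nitrification",
    "compute_fluxes",
    "total_sms",
]

#: Index of every variable in the shared ordering (noP uses the first 12).
_IX = {name: i for i, name in enumerate(VARIABLES_P)}

#: Sentinel index for fluxes entering or leaving the modelled pools
#: (carbon fixation from / respiration to the untracked DIC pool, pigment
#: destruction, air-sea oxygen terms are not modelled).
EXT = -1


def grazing_temperature_limitation(T: float, params: ParameterSet) -> float:
    """Grazing temperature limitation f(T) ∈ [0, 1].

    A Q10 exponential normalized to 1 at the reference temperature and
    capped at 1: grazing pressure falls with temperature below T_ref, so
    winter grazing is weak and summer grazing strong over the regional
    10–26 °C range.
    """
    if not (-2.0 <= T <= 40.0):
        raise ValueError(f"temperature {T} degC outside plausible range "
                         "[-2, 40]")
    c = params.closure
    return min(1.0, c.Q10 ** ((T - c.T_ref) / 10.0))


@dataclass(frozen=True)
class GrazingFluxes:
    """Grazing losses per prey and element (µmol L⁻¹ d⁻¹; Chla µg L⁻¹ d⁻¹).

    Each prey loses every constituent at the same specific rate, so the
    element fluxes follow prey stoichiometry exactly (grazed N equals
    grazed C times the prey N:C quota) and chlorophyll is removed in
    proportion to phytoplankton carbon.
    """

    phy: dict[str, float]
    bac: dict[str, float]


def grazing_fluxes(state: StateVector, T: float, params: ParameterSet,
                   version: ModelVersion) -> GrazingFluxes:
    """Temperature-limited grazing on phytoplankton and bacteria.

    The specific rate is ``g · f(T)``, optionally saturating in prey
    carbon (Holling II) when ``closure.holling_K > 0``; linear otherwise.
    """
    c = params.closure
    ft = grazing_temperature_limitation(T, params)
    is_p = version is ModelVersion.P

    def prey(g_max: float, c_pool: float) -> float:
        rate = g_max * ft
        if c.holling_K > 0.0:
            rate *= c_pool / (c_pool + c.holling_K)
        return rate

    gp = prey(c.g_phy, state.Cb)
    gb = prey(c.g_bac, state.Cba)
    phy_fluxes = {
        "C": gp * state.Cb,
        "N": gp * state.Nb,
        "P": gp * state.Pb if is_p else 0.0,
        "Chla": gp * state.Chla,
    }
    bac_fluxes = {
        "C": gb * state.Cba,
        "N": gb * state.Nba,
        "P": gb * state.Pba if is_p else 0.0,
    }
    return GrazingFluxes(phy=phy_fluxes, bac=bac_fluxes)


def closure_redistribution(g: GrazingFluxes, params: ParameterSet,
                           version: ModelVersion) -> TendencyVector:
    """Return of grazed matter to the POM/DOM/DIM pools.

    For every element the returned fluxes sum exactly to the grazed flux:
    the POM fraction is egested to detritus, the DOM fraction leaks as
    sloppy feeding, and the DIM fraction is excreted (N to NH4, P to PO4)
    or, for carbon, respired by the implicit consumers — which consumes
    oxygen stoichiometrically.  Grazed chlorophyll is destroyed.
    """
    c = params.closure
    fsum = c.frac_pom + c.frac_dom + c.frac_dim
    if abs(fsum - 1.0) > 1e-12:
        raise ValueError(f"redistribution fractions sum to {fsum}, not 1")
    names = variables_for(version)
    vals = np.zeros(len(names))
    gC = g.phy["C"] + g.bac["C"]
    gN = g.phy["N"] + g.bac["N"]
    vals[_IX["DPOC"]] += c.frac_pom * gC
    vals[_IX["LDOC"]] += c.frac_dom * gC
    vals[_IX["DPON"]] += c.frac_pom * gN
    vals[_IX["LDON"]] += c.frac_dom * gN
    vals[_IX["NH4"]] += c.frac_dim * gN
    zoo_resp = c.frac_dim * gC
    vals[_IX["O"]] -= params.oxygen.gamma_OC * zoo_resp
    if version is ModelVersion.P:
        gP = g.phy["P"] + g.bac["P"]
        vals[_IX["DPOP"]] += c.frac_pom * gP
        vals[_IX["LDOP"]] += c.frac_dom * gP
        vals[_IX["PO4"]] += c.frac_dim * gP
    return TendencyVector(version, vals)


def _remin_factor(T: float, params: ParameterSet) -> float:
    r = params.remin
    return 1.0 if r.Q10 == 1.0 else r.Q10 ** ((T - r.T_ref) / 10.0)


def remineralization(state: StateVector, T: float, params: ParameterSet,
                     version: ModelVersion) -> TendencyVector:
    """First-order POM→DOM hydrolysis and DOM→DIM remineralization.

    Element-parallel chains: DPOC→LDOC→(CO2, untracked), DPON→LDON→NH4
    and, in the P version, DPOP→LDOP→PO4.  Oxygen is consumed for each
    mole of dissolved organic carbon oxidized.  Rates are optionally
    temperature-scaled (Q10; off by default).
    """
    r = params.remin
    k = _remin_factor(T, params)
    names = variables_for(version)
    vals = np.zeros(len(names))
    hC = k * r.hydrolysis_C * state.DPOC
    hN = k * r.hydrolysis_N * state.DPON
    mC = k * r.remin_DOC * state.LDOC
    mN = k * r.remin_DON * state.LDON
    vals[_IX["DPOC"]] -= hC
    vals[_IX["LDOC"]] += hC - mC
    vals[_IX["DPON"]] -= hN
    vals[_IX["LDON"]] += hN - mN
    vals[_IX["NH4"]] += mN
    vals[_IX["O"]] -= params.oxygen.gamma_OC * mC
    if version is ModelVersion.P:
        hP = k * r.hydrolysis_P * state.DPOP
        mP = k * r.remin_DOP * state.LDOP
        vals[_IX["DPOP"]] -= hP
        vals[_IX["LDOP"]] += hP - mP
        vals[_IX["PO4"]] += mP
    return TendencyVector(version, vals)


def nitrification(state: StateVector, params: ParameterSet) -> TendencyVector:
    """NH4 → NO3 oxidation at a first-order rate, consuming oxygen.

    Total nitrogen is unchanged: NO3 gains exactly what NH4 loses.
    """
    flux = params.remin.nitrif * max(0.0, state.NH4)
    names = state.variables
    vals = np.zeros(len(names))
    vals[_IX["NH4"]] -= flux
    vals[_IX["NO3"]] += flux
    vals[_IX["O"]] -= params.oxygen.gamma_ON * flux
    return TendencyVector(state.version, vals)


# --------------------------------------------------------------------------
# Full SMS assembly as a transfer ledger


@dataclass
class FluxLedger:
    """All process fluxes of one SMS evaluation.

    ``transfers`` lists (source index, destination index, rate) with
    :data:`EXT` for the untracked exterior; summing them reproduces the
    full tendency vector (oxygen included, as stoichiometric EXT
    transfers).  ``named`` records the process totals used for budget
    accounting and diagnostics.
    """

    version: ModelVersion
    transfers: list[tuple[int, int, float]] = field(default_factory=list)
    named: dict[str, float] = field(default_factory=dict)
    quotas: Quotas | None = None

    def tendency(self) -> TendencyVector:
        vals = np.zeros(len(variables_for(self.version)))
        for src, dst, rate in self.transfers:
            if src >= 0:
                vals[src] -= rate
            if dst >= 0:
                vals[dst] += rate
        return TendencyVector(self.version, vals)


def compute_fluxes(state: StateVector, T: float, E: float,
                   params: ParameterSet, version: ModelVersion,
                   fallback_quotas: Quotas | None = None) -> FluxLedger:
    """Evaluate every process flux for one state and forcing sample.

    If a biomass pool is below the configured floor, the quota set
    ``fallback_quotas`` (the integrator's last valid quotas) is used so a
    collapsing bloom does not divide by zero; with no fallback available
    (biomass never present) the inert mid-range quota set is used.
    """
    try:
        q = compute_quotas(state, params)
    except DegenerateStateError:
        q = fallback_quotas if fallback_quotas is not None \
            else neutral_quotas(params)

    p = params.phyto
    b = params.bacteria
    c = params.closure
    ox = params.oxygen
    is_p = version is ModelVersion.P
    led = FluxLedger(version=version, quotas=q)
    t = led.transfers
    ix = _IX

    # -- phytoplankton
    lim = phy.nutrient_limitation(q, params, version)
    gpp = state.Cb * phy._gpp_specific(q.theta, lim.Qstar, E, params)
    upt = phy.nutrient_uptake(state, q, params, version)
    chl_syn = phy.chlorophyll_synthesis(state, q, E, params, version)
    phy_resp = p.resp * state.Cb
    t.append((EXT, ix["Cb"], gpp))
    t.append((ix["Cb"], EXT, phy_resp))
    t.append((ix["Cb"], ix["LDOC"], p.exud * state.Cb))
    t.append((ix["Cb"], ix["DPOC"], p.mort * state.Cb))
    t.append((ix["Nb"], ix["DPON"], p.mort * state.Nb))
    t.append((ix["NO3"], ix["Nb"], upt["NO3"]))
    t.append((ix["NH4"], ix["Nb"], upt["NH4"]))
    t.append((EXT, ix["Chla"], chl_syn))
    t.append((ix["Chla"], EXT, (p.resp + p.exud + p.mort) * state.Chla))
    if is_p:
        t.append((ix["Pb"], ix["DPOP"], p.mort * state.Pb))
        t.append((ix["PO4"], ix["Pb"], upt["PO4"]))

    # -- bacteria
    blim = bac.bacterial_limitation(q, params, version)
    bp = bac.bacterial_production(state, blim, params)
    bupt = bac.bacterial_uptake(state, q, params, version)
    over = bac.quota_overflow(state, q, params, version)
    bac_resp = (b.resp_basal * state.Cba + bp * (1.0 - b.GE) / b.GE
                + over["resp_C"])
    t.append((ix["LDOC"], ix["Cba"], bupt["LDOC"]))
    t.append((ix["DPOC"], ix["Cba"], bupt["DPOC"]))
    t.append((ix["LDON"], ix["Nba"], bupt["LDON"]))
    t.append((ix["DPON"], ix["Nba"], bupt["DPON"]))
    t.append((ix["NH4"], ix["Nba"], bupt["NH4"]))
    t.append((ix["Cba"], EXT, bac_resp))
    t.append((ix["Cba"], ix["DPOC"], b.mort * state.Cba))
    t.append((ix["Nba"], ix["DPON"], b.mort * state.Nba))
    t.append((ix["Nba"], ix["NH4"], over["NH4"]))
    if is_p:
        t.append((ix["LDOP"], ix["Pba"], bupt["LDOP"]))
        t.append((ix["DPOP"], ix["Pba"], bupt["DPOP"]))
        t.append((ix["PO4"], ix["Pba"], bupt["PO4"]))
        t.append((ix["Pba"], ix["DPOP"], b.mort * state.Pba))
        t.append((ix["Pba"], ix["PO4"], over["PO4"]))

    # -- closure (grazing + redistribution)
    gr = grazing_fluxes(state, T, params, version)
    zoo_resp = c.frac_dim * (gr.phy["C"] + gr.bac["C"])
    for prey_ix, fluxes in ((("Cb", "Nb", "Pb"), gr.phy),
                            (("Cba", "Nba", "Pba"), gr.bac)):
        cn, nn, pn = prey_ix
        t.append((ix[cn], ix["DPOC"], c.frac_pom * fluxes["C"]))
        t.append((ix[cn], ix["LDOC"], c.frac_dom * fluxes["C"]))
        t.append((ix[cn], EXT, c.frac_dim * fluxes["C"]))
        t.append((ix[nn], ix["DPON"], c.frac_pom * fluxes["N"]))
        t.append((ix[nn], ix["LDON"], c.frac_dom * fluxes["N"]))
        t.append((ix[nn], ix["NH4"], c.frac_dim * fluxes["N"]))
        if is_p:
            t.append((ix[pn], ix["DPOP"], c.frac_pom * fluxes["P"]))
            t.append((ix[pn], ix["LDOP"], c.frac_dom * fluxes["P"]))
            t.append((ix[pn], ix["PO4"], c.frac_dim * fluxes["P"]))
    t.append((ix["Chla"], EXT, gr.phy["Chla"]))

    # -- remineralization chains and nitrification
    k = _remin_factor(T, params)
    r = params.remin
    remin_doc = k * r.remin_DOC * state.LDOC
    t.append((ix["DPOC"], ix["LDOC"], k * r.hydrolysis_C * state.DPOC))
    t.append((ix["DPON"], ix["LDON"], k * r.hydrolysis_N * state.DPON))
    t.append((ix["LDOC"], EXT, remin_doc))
    t.append((ix["LDON"], ix["NH4"], k * r.remin_DON * state.LDON))
    if is_p:
        t.append((ix["DPOP"], ix["LDOP"], k * r.hydrolysis_P * state.DPOP))
        t.append((ix["LDOP"], ix["PO4"], k * r.remin_DOP * state.LDOP))
    nit = r.nitrif * max(0.0, state.NH4)
    t.append((ix["NH4"], ix["NO3"], nit))

    # -- oxygen stoichiometry
    resp_total = phy_resp + bac_resp + zoo_resp + remin_doc
    o2_source = ox.gamma_OC * gpp
    o2_sink = ox.gamma_OC * resp_total + ox.gamma_ON * nit
    t.append((EXT, ix["O"], o2_source))
    t.append((ix["O"], EXT, o2_sink))

    led.named.update(
        GPP=gpp, BP=bp, chl_synthesis=chl_syn,
        uptake_NO3=upt["NO3"], uptake_NH4=upt["NH4"],
        uptake_PO4=upt.get("PO4", 0.0),
        phy_resp=phy_resp, bac_resp=bac_resp, zoo_resp=zoo_resp,
        remin_DOC=remin_doc, resp_total=resp_total,
        grazing_C=gr.phy["C"] + gr.bac["C"],
        grazing_N=gr.phy["N"] + gr.bac["N"],
        grazing_P=gr.phy["P"] + gr.bac["P"],
        nitrification=nit,
        o2_source=o2_source, o2_sink=o2_sink,
        f_T=grazing_temperature_limitation(T, params),
        Qstar=lim.Qstar, f_bac=blim.f,
        limN=lim.limN, limP=lim.limP,
    )
    return led


def total_sms(state: StateVector, forcing, params: ParameterSet,
              version: ModelVersion,
              fallback_quotas: Quotas | None = None) -> TendencyVector:
    """Full source-minus-sink vector (Eq.-of-motion tendency, no transport).

    Deterministic sum of the phytoplankton, bacteria, closure,
    remineralization, nitrification and oxygen terms.  In a closed box the
    total N (and P) tendency is zero to rounding, and the summed carbon
    tendency equals GPP minus total respiration: every internal flux is a
    pool-to-pool transfer.
    """
    return compute_fluxes(state, forcing.T, forcing.E, params, version,
                          fallback_quotas=fallback_quotas).tendency()
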