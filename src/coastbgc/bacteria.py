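"""Heterotrophic bacteria dynamics with C/N/P cell-quota co-limitation.

Bacteria take up labile dissolved and detrital organic substrates plus
ammonium (and phosphate in the P version), each flux saturating in the
substrate and down-regulated by the satiation of the corresponding
elemental quota.  Bacterial production is capped by a Liebig co-limitation
term built from the stress ratios (min Q):Q — the scarcer an element is
inside the cell, the closer its ratio is to one and the stronger the
limitation.  Element quotas above their maximum are vented back to the
inorganic pools (bacterial remineralization); excess carbon is respired.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .core_state import (
    ModelVersion,
    ParameterSet,
    Quotas,
    StateVector,
    TendencyVector,
    compute_quotas,
    variables_for,
)

__all__ = [
    "BacterialLimitation",
    "bacterial_limitation",
    "bacterial_production",
    "bacterial_uptake",
    "bacteria_sms",
]


class BacterialElement(enum.Enum):
    C = "C"
    N = "N"
    P = "P"


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


@dataclass(frozen=True)
class BacterialLimitation:
    """Liebig co-limitation of bacterial production.

    ``r_X = Qmin_X / Q_X`` is the stress ratio of element X (1 when fully
    starved, ``Qmin/Qmax`` when replete); ``f`` is the production
    limitation in [0, 1]; the limiting element is the argmax of the
    ratios, ties resolved in the fixed order C → N → P.
    """

    f: float
    r_C: float
    r_N: float
    r_P: float
    limiting_element: BacterialElement


def bacterial_limitation(q: Quotas, params: ParameterSet,
                         version: ModelVersion) -> BacterialLimitation:
    """Co-limitation term f and per-element stress ratios.

    Each element contributes ``clamp((1 - r_X)/(1 - r_X_sat))`` where
    ``r_X_sat = Qmin_X/Qmax_X`` is the replete-cell ratio; f is the
    minimum over elements (Liebig), so f=1 for a replete cell and f=0
    when any quota sits at its minimum.  P is excluded under noP.
    """
    b = params.bacteria
    ratios: dict[BacterialElement, float] = {
        BacterialElement.C: b.QC_min / q.QC_BA,
        BacterialElement.N: b.QN_min / q.QN_BA,
    }
    sat = {
        BacterialElement.C: b.QC_min / b.QC_max,
        BacterialElement.N: b.QN_min / b.QN_max,
    }
    if version is ModelVersion.P:
        ratios[BacterialElement.P] = b.QP_min / q.QP_BA
        sat[BacterialElement.P] = b.QP_min / b.QP_max
    f = min(_clamp01((1.0 - r) / (1.0 - sat[el]))
            for el, r in ratios.items())
    # argmax of the stress ratio; dict order gives the C -> N -> P tie-break
    limiting = max(ratios, key=lambda el: ratios[el])
    return BacterialLimitation(
        f=f,
        r_C=ratios[BacterialElement.C],
        r_N=ratios[BacterialElement.N],
        r_P=ratios.get(BacterialElement.P, float("nan")),
        limiting_element=limiting,
    )


def bacterial_production(state: StateVector, lim: BacterialLimitation,
                         params: ParameterSet) -> float:
    """BP = Cba · µ_max · f (µmol C L⁻¹ d⁻¹); hard-capped by Cba·µ_max."""
    return state.Cba * params.bacteria.mu_max * lim.f


def bacterial_uptake(state: StateVector, q: Quotas, params: ParameterSet,
                     version: ModelVersion) -> dict[str, float]:
    """Per-substrate uptake fluxes (µmol L⁻¹ d⁻¹), keyed by source pool.

    ``Cba·Vmax·S/(S+K)`` scaled by the satiation of the quota of the
    substrate's element, so inorganic nutrients are only drawn to correct
    a stoichiometric deficit.  Detrital matter is consumed through a
    single effective hydrolysis-plus-uptake rate.
    """
    b = params.bacteria
    cba = state.Cba
    hC = _clamp01((b.QC_max - q.QC_BA) / (b.QC_max - b.QC_min))
    hN = _clamp01((b.QN_max - q.QN_BA) / (b.QN_max - b.QN_min))

    def mm(s: float, vmax: float, k: float, h: float) -> float:
        return cba * vmax * s / (s + k) * h if s > 0.0 else 0.0

    out = {
        "LDOC": mm(state.LDOC, b.Vmax_LDOC, b.K_LDOC, hC),
        "DPOC": mm(state.DPOC, b.Vmax_DPOC, b.K_DPOC, hC),
        "LDON": mm(state.LDON, b.Vmax_LDON, b.K_LDON, hN),
        "DPON": mm(state.DPON, b.Vmax_DPON, b.K_DPON, hN),
        "NH4": mm(state.NH4, b.Vmax_NH4, b.K_NH4, hN),
    }
    if version is ModelVersion.P:
        hP = _clamp01((b.QP_max - q.QP_BA) / (b.QP_max - b.QP_min))
        out["LDOP"] = mm(state.LDOP, b.Vmax_LDOP, b.K_LDOP, hP)
        out["DPOP"] = mm(state.DPOP, b.Vmax_DPOP, b.K_DPOP, hP)
        out["PO4"] = mm(state.PO4, b.Vmax_PO4, b.K_PO4, hP)
    return out


def quota_overflow(state: StateVector, q: Quotas, params: ParameterSet,
                   version: ModelVersion) -> dict[str, float]:
    """Release/respiration fluxes venting quotas above their maxima.

    Nitrogen above ``QN_max`` is excreted to NH4, phosphorus above
    ``QP_max`` to PO4; carbon above ``QC_max`` (relative to nitrogen) is
    respired.  Rates relax the quota at ``adj_rate``.
    """
    b = params.bacteria
    out = {
        "NH4": b.adj_rate * state.Cba * max(0.0, q.QN_BA - b.QN_max),
        "resp_C": b.adj_rate * state.Nba * max(0.0, q.QC_BA - b.QC_max),
    }
    if version is ModelVersion.P:
        out["PO4"] = b.adj_rate * state.Cba * max(0.0, q.QP_BA - b.QP_max)
    return out


def bacteria_sms(state: StateVector, forcing, params: ParameterSet,
                 version: ModelVersion) -> TendencyVector:
    """Source-minus-sink contributions of the bacterial pools.

    Non-zero entries only for {Cba, Nba[, Pba]}: substrate uptake minus
    respiration (basal, growth-linked at ``(1-GE)/GE`` per unit of
    production, and carbon-overflow), mortality to detritus, grazing and
    excess-quota release.  ``forcing`` supplies the temperature used by
    the grazing closure.
    """
    from .closure_remin import grazing_fluxes  # local import avoids a cycle

    b = params.bacteria
    q = compute_quotas(state, params)
    lim = bacterial_limitation(q, params, version)
    bp = bacterial_production(state, lim, params)
    upt = bacterial_uptake(state, q, params, version)
    over = quota_overflow(state, q, params, version)
    gr = grazing_fluxes(state, forcing.T, params, version)

    resp = b.resp_basal * state.Cba + bp * (1.0 - b.GE) / b.GE \
        + over["resp_C"]
    names = variables_for(version)
    vals = np.zeros(len(names))
    vals[names.index("Cba")] = (upt["LDOC"] + upt["DPOC"] - resp
                                - b.mort * state.Cba - gr.bac["C"])
    vals[names.index("Nba")] = (upt["LDON"] + upt["DPON"] + upt["NH4"]
                                - b.mort * state.Nba - gr.bac["N"]
                                - over["NH4"])
    if version is ModelVersion.P:
        vals[names.index("Pba")] = (upt["LDOP"] + upt["DPOP"] + upt["PO4"]
                                    - b.mort * state.Pba - gr.bac["P"]
                                    - over["PO4"])
    return TendencyVector(version, vals)
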