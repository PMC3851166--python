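"""Phytoplankton source-minus-sink terms.

Growth follows cell-quota (Droop-type) theory: carbon fixation is limited
by the most depleted normalized internal nutrient ratio (Liebig's law of
the minimum over N and P), and by light through a saturating
photosynthesis–irradiance curve whose initial slope scales with the
chlorophyll-to-carbon ratio θ (Geider-type photoacclimation).  Chlorophyll
is carried prognostically; its synthesis is regulated so that θ falls when
light is plentiful or when nutrient limitation (Q*) tightens, which also
propagates phosphorus limitation into the chlorophyll signal.
"""

from __future__ import annotations

import enum
import math
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
    "LimitingElement",
    "LimitationResult",
    "nutrient_limitation",
    "gross_primary_production",
    "nutrient_uptake",
    "chlorophyll_synthesis",
    "chlorophyll_tendency",
    "phyto_sms",
]


class LimitingElement(enum.Enum):
    N = "N"
    P = "P"
    none = "none"


@dataclass(frozen=True)
class LimitationResult:
    """Normalized quota limitations and their Liebig minimum Q*."""

    limN: float
    limP: float
    Qstar: float
    limiting_element: LimitingElement


def _clamp01(x: float) -> float:
    return 0.0 if x < 0.0 else (1.0 if x > 1.0 else x)


def nutrient_limitation(q: Quotas, params: ParameterSet,
                        version: ModelVersion) -> LimitationResult:
    """Normalized-quota limitation terms and the most limiting ratio Q*.

    Each element's limitation is ``(Q - Qmin)/(Qmax - Qmin)`` clamped to
    [0, 1]; Q* is their minimum.  Under the noP version P never limits.
    Ties are reported as N so the output is deterministic.
    """
    p = params.phyto
    limN = _clamp01((q.QN - p.QN_min) / (p.QN_max - p.QN_min))
    if version is ModelVersion.P:
        limP = _clamp01((q.QP - p.QP_min) / (p.QP_max - p.QP_min))
    else:
        limP = 1.0
    qstar = min(limN, limP)
    if qstar >= 1.0:
        which = LimitingElement.none
    elif limN <= limP:
        which = LimitingElement.N
    else:
        which = LimitingElement.P
    return LimitationResult(limN=limN, limP=limP, Qstar=qstar,
                            limiting_element=which)


def _gpp_specific(theta: float, qstar: float, E: float,
                  params: ParameterSet) -> float:
    """C-specific photosynthesis rate (d⁻¹) at irradiance E.

    ``PCm·Q*·(1 - exp(-α·θ·E / (PCm·Q*)))``; the Q*→0 limit is 0 and is
    taken explicitly rather than evaluated as 0/0.
    """
    p = params.phyto
    if qstar <= 0.0 or E <= 0.0:
        return 0.0
    pmax = p.PCm * qstar
    return pmax * -math.expm1(-p.alpha_chl * theta * E / pmax)


def gross_primary_production(state: StateVector, q: Quotas, E: float,
                             params: ParameterSet,
                             version: ModelVersion) -> float:
    """Gross carbon fixation flux (µmol C L⁻¹ d⁻¹); 0 in the dark."""
    if E < 0:
        raise ValueError(f"negative irradiance E={E}")
    lim = nutrient_limitation(q, params, version)
    return state.Cb * _gpp_specific(q.theta, lim.Qstar, E, params)


def nutrient_uptake(state: StateVector, q: Quotas, params: ParameterSet,
                    version: ModelVersion) -> dict[str, float]:
    """Saturating uptake of NO3, NH4 (and PO4 under the P version).

    Each flux is ``Cb·Vmax·S/(S+K)·(Qmax-Q)/(Qmax-Qmin)`` clamped at zero:
    a full quota shuts uptake down (satiation).  NO3 uptake can optionally
    be inhibited by ammonium (off by default).
    """
    p = params.phyto
    cb = state.Cb
    hN = _clamp01((p.QN_max - q.QN) / (p.QN_max - p.QN_min))
    no3, nh4 = state.NO3, state.NH4
    inhib = 1.0 / (1.0 + p.nh4_inhibition * nh4)
    out = {
        "NO3": cb * p.Vmax_NO3 * no3 / (no3 + p.K_NO3) * hN * inhib,
        "NH4": cb * p.Vmax_NH4 * nh4 / (nh4 + p.K_NH4) * hN,
    }
    if version is ModelVersion.P:
        hP = _clamp01((p.QP_max - q.QP) / (p.QP_max - p.QP_min))
        po4 = state.PO4
        out["PO4"] = cb * p.Vmax_PO4 * po4 / (po4 + p.K_PO4) * hP
    return out


def chlorophyll_synthesis(state: StateVector, q: Quotas, E: float,
                          params: ParameterSet,
                          version: ModelVersion) -> float:
    """Gross chlorophyll synthesis flux (µg L⁻¹ d⁻¹).

    The photoacclimation regulation ratio
    ``ρ_chl = θ_N_max · P^C / (α·θ·E)`` (capped at θ_N_max, the dark
    limit) is applied to nitrogen assimilation and scaled by Q* so that
    phosphorus starvation also caps pigment synthesis.
    """
    if E < 0:
        raise ValueError(f"negative irradiance E={E}")
    p = params.phyto
    lim = nutrient_limitation(q, params, version)
    if lim.Qstar <= 0.0:
        return 0.0
    pc = _gpp_specific(q.theta, lim.Qstar, E, params)
    denom = p.alpha_chl * q.theta * E
    rho = p.theta_N_max if denom <= 0.0 else min(
        p.theta_N_max, p.theta_N_max * pc / denom)
    upt = nutrient_uptake(state, q, params, version)
    return lim.Qstar * rho * (upt["NO3"] + upt["NH4"])


def chlorophyll_tendency(state: StateVector, q: Quotas, E: float,
                         params: ParameterSet,
                         version: ModelVersion) -> float:
    """Chlorophyll net tendency (µg L⁻¹ d⁻¹), grazing excluded.

    Synthesis per :func:`chlorophyll_synthesis`; losses mirror the linear
    carbon losses (respiration, exudation, mortality) at the same
    specific rate, so they do not by themselves change θ.
    """
    p = params.phyto
    synth = chlorophyll_synthesis(state, q, E, params, version)
    losses = (p.resp + p.exud + p.mort) * state.Chla
    return synth - losses


def phyto_sms(state: StateVector, forcing, params: ParameterSet,
              version: ModelVersion) -> TendencyVector:
    """Source-minus-sink contributions of phytoplankton processes.

    Returns a tendency vector whose only non-zero entries are the
    phytoplankton pools {Cb, Nb, Chla[, Pb]}: gross production minus
    respiration, exudation, mortality and grazing for carbon; uptake minus
    grazing and mortality for N (and P); the photoacclimation tendency
    minus grazing for chlorophyll.  ``forcing`` supplies ``T`` and ``E``.
    """
    from .closure_remin import grazing_fluxes  # local import avoids a cycle

    q = compute_quotas(state, params)
    p = params.phyto
    upt = nutrient_uptake(state, q, params, version)
    gpp = gross_primary_production(state, q, forcing.E, params, version)
    gr = grazing_fluxes(state, forcing.T, params, version)

    names = variables_for(version)
    vals = np.zeros(len(names))
    lin_loss = p.resp + p.exud + p.mort
    vals[names.index("Cb")] = gpp - lin_loss * state.Cb - gr.phy["C"]
    vals[names.index("Nb")] = (upt["NO3"] + upt["NH4"]
                               - p.mort * state.Nb - gr.phy["N"])
    vals[names.index("Chla")] = (
        chlorophyll_tendency(state, q, forcing.E, params, version)
        - gr.phy["Chla"])
    if version is ModelVersion.P:
        vals[names.index("Pb")] = (upt["PO4"] - p.mort * state.Pb
                                   - gr.phy["P"])
    return TendencyVector(version, vals)
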