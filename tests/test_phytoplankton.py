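"""Quota limitation, photosynthesis, uptake and photoacclimation."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from coastbgc import (ModelVersion, ParameterSet, compute_quotas,
                      gross_primary_production, nutrient_limitation,
                      nutrient_uptake, chlorophyll_tendency, phyto_sms)
from coastbgc.core_state import Quotas, VersionError
from coastbgc.forcing import ForcingSample
from coastbgc.phytoplankton import LimitingElement, chlorophyll_synthesis

from conftest import rel_diff


def quotas(QN=0.15, QP=0.008, theta=0.4, QC_BA=6.0, QN_BA=0.2,
           QP_BA=0.012) -> Quotas:
    return Quotas(QN=QN, QP=QP, theta=theta, QC_BA=QC_BA, QN_BA=QN_BA,
                  QP_BA=QP_BA)


class TestNutrientLimitation:
    def test_saturated_quotas_unlimited(self, params):
        q = quotas(QN=params.phyto.QN_max, QP=params.phyto.QP_max)
        lim = nutrient_limitation(q, params, ModelVersion.P)
        assert lim.Qstar == 1.0
        assert lim.limiting_element is LimitingElement.none

    def test_liebig_minimum_dominates(self, params):
        q = quotas(QN=params.phyto.QN_min, QP=params.phyto.QP_max)
        lim = nutrient_limitation(q, params, ModelVersion.P)
        assert lim.limN == 0.0 and lim.Qstar == 0.0
        assert lim.limiting_element is LimitingElement.N

    def test_normalized_quota_hand_value(self):
        """QN halfway between bounds gives limN=0.5; with P normalized
        at 0.9 the Liebig minimum is N."""
        params = ParameterSet()
        params.phyto.QN_min, params.phyto.QN_max = 0.05, 0.2
        qp = params.phyto.QP_min + 0.9 * (params.phyto.QP_max
                                          - params.phyto.QP_min)
        lim = nutrient_limitation(quotas(QN=0.125, QP=qp), params,
                                  ModelVersion.P)
        assert lim.limN == pytest.approx(0.5)
        assert lim.limP == pytest.approx(0.9)
        assert lim.Qstar == pytest.approx(0.5)
        assert lim.limiting_element is LimitingElement.N

    def test_nop_ignores_phosphorus(self, params):
        q = quotas(QN=0.15, QP=params.phyto.QP_min)
        lim = nutrient_limitation(q, params, ModelVersion.noP)
        assert lim.limP == 1.0
        assert lim.Qstar == lim.limN

    @given(q1=st.floats(0.05, 0.2), q2=st.floats(0.05, 0.2))
    def test_monotone_in_quota(self, q1, q2):
        """Q* is non-decreasing in each quota (Liebig property)."""
        params = ParameterSet()
        lo, hi = sorted((q1, q2))
        s_lo = nutrient_limitation(quotas(QN=lo), params,
                                   ModelVersion.P).Qstar
        s_hi = nutrient_limitation(quotas(QN=hi), params,
                                   ModelVersion.P).Qstar
        assert s_hi >= s_lo


class TestGrossPrimaryProduction:
    def test_dark_is_zero(self, state_p, params):
        q = compute_quotas(state_p, params)
        assert gross_primary_production(state_p, q, 0.0, params,
                                        ModelVersion.P) == 0.0

    def test_light_saturated_limit(self, state_p, params):
        state_p["Nb"] = params.phyto.QN_max * state_p["Cb"]
        state_p["Pb"] = params.phyto.QP_max * state_p["Cb"]
        q = compute_quotas(state_p, params)
        flux = gross_primary_production(state_p, q, 1e7, params,
                                        ModelVersion.P)
        assert flux == pytest.approx(state_p["Cb"] * params.phyto.PCm,
                                     rel=1e-9)

    def test_closed_form_value(self):
        """Cb=1, PCm=2, Q*=0.5, alpha*theta*E=1 -> 2*0.5*(1-e^-1)=0.632."""
        params = ParameterSet()
        params.phyto.PCm = 2.0
        params.phyto.alpha_chl = 1.0
        from coastbgc import StateVector, make_initial_state
        s = make_initial_state(ModelVersion.P, "oligotrophic-summer")
        s["Cb"] = 1.0
        s["Chla"] = 0.5              # theta = 0.5
        s["Nb"] = 0.125              # limN = 0.5
        s["Pb"] = params.phyto.QP_max
        q = compute_quotas(s, params)
        flux = gross_primary_production(s, q, 2.0, params, ModelVersion.P)
        assert flux == pytest.approx(1.0 * (1.0 - math.exp(-1.0)),
                                     rel=1e-12)

    def test_continuous_at_zero_qstar(self, state_p, params):
        state_p["Nb"] = params.phyto.QN_min * state_p["Cb"]
        q = compute_quotas(state_p, params)
        assert gross_primary_production(state_p, q, 100.0, params,
                                        ModelVersion.P) == 0.0
        # slightly above the minimum quota the flux is tiny but positive
        state_p["Nb"] = (params.phyto.QN_min + 1e-9) * state_p["Cb"]
        q = compute_quotas(state_p, params)
        flux = gross_primary_production(state_p, q, 100.0, params,
                                        ModelVersion.P)
        assert 0.0 < flux < 1e-6

    def test_negative_irradiance_rejected(self, state_p, params):
        q = compute_quotas(state_p, params)
        with pytest.raises(ValueError):
            gross_primary_production(state_p, q, -1.0, params,
                                     ModelVersion.P)

    @given(e1=st.floats(0, 500), e2=st.floats(0, 500))
    def test_monotone_in_irradiance(self, e1, e2):
        from coastbgc import make_initial_state
        params = ParameterSet()
        s = make_initial_state(ModelVersion.P, "oligotrophic-summer")
        q = compute_quotas(s, params)
        lo, hi = sorted((e1, e2))
        assert gross_primary_production(s, q, hi, params,
                                        ModelVersion.P) >= \
            gross_primary_production(s, q, lo, params, ModelVersion.P)


class TestNutrientUptake:
    def test_exhausted_pool_no_uptake(self, state_p, params):
        state_p["PO4"] = 0.0
        q = compute_quotas(state_p, params)
        assert nutrient_uptake(state_p, q, params,
                               ModelVersion.P)["PO4"] == 0.0

    def test_satiated_quota_no_uptake(self, state_p, params):
        state_p["Pb"] = params.phyto.QP_max * state_p["Cb"]
        q = compute_quotas(state_p, params)
        assert nutrient_uptake(state_p, q, params,
                               ModelVersion.P)["PO4"] == 0.0

    def test_michaelis_menten_hand_value(self):
        """Vmax=1, K=0.5, S=0.5, quota factor 0.5, Cb=1 -> 0.25."""
        params = ParameterSet()
        params.phyto.Vmax_NO3 = 1.0
        params.phyto.K_NO3 = 0.5
        from coastbgc import make_initial_state
        s = make_initial_state(ModelVersion.P, "oligotrophic-summer")
        s["Cb"] = 1.0
        s["NO3"] = 0.5
        s["Nb"] = 0.125   # (Qmax-Q)/(Qmax-Qmin) = 0.5
        q = compute_quotas(s, params)
        assert nutrient_uptake(s, q, params, ModelVersion.P)["NO3"] == \
            pytest.approx(0.25, rel=1e-12)

    def test_nop_has_no_phosphate_flux(self, state_nop, params):
        q = compute_quotas(state_nop, params)
        assert "PO4" not in nutrient_uptake(state_nop, q, params,
                                            ModelVersion.noP)


class TestChlorophyll:
    def test_no_synthesis_when_fully_limited(self, state_p, params):
        state_p["Nb"] = params.phyto.QN_min * state_p["Cb"]
        q = compute_quotas(state_p, params)
        assert chlorophyll_synthesis(state_p, q, 100.0, params,
                                     ModelVersion.P) == 0.0

    def test_balanced_growth_theta_stationary(self, params):
        """Integrating the coupled Cb/Chla pair at constant light and
        replete nutrients reaches a fixed point where theta changes by
        <1e-6 (relative) per step."""
        from coastbgc import make_initial_state
        s = make_initial_state(ModelVersion.P, "oligotrophic-summer")
        dt = 1.0 / 72.0
        for _ in range(72 * 60):   # 60 days to equilibrate
            s["Nb"] = 0.15 * s["Cb"]           # hold quotas fixed
            s["Pb"] = 0.008 * s["Cb"]
            q = compute_quotas(s, params)
            from coastbgc.phytoplankton import (_gpp_specific,
                                                nutrient_limitation)
            lim = nutrient_limitation(q, params, ModelVersion.P)
            pc = _gpp_specific(q.theta, lim.Qstar, 80.0, params)
            loss = (params.phyto.resp + params.phyto.exud
                    + params.phyto.mort)
            dchl = chlorophyll_tendency(s, q, 80.0, params, ModelVersion.P)
            s["Cb"] = s["Cb"] * (1.0 + dt * (pc - loss))
            s["Chla"] = s["Chla"] + dt * dchl
        theta0 = s["Chla"] / s["Cb"]
        # one more step
        s["Nb"] = 0.15 * s["Cb"]
        s["Pb"] = 0.008 * s["Cb"]
        q = compute_quotas(s, params)
        from coastbgc.phytoplankton import _gpp_specific
        lim = nutrient_limitation(q, params, ModelVersion.P)
        pc = _gpp_specific(q.theta, lim.Qstar, 80.0, params)
        loss = params.phyto.resp + params.phyto.exud + params.phyto.mort
        dchl = chlorophyll_tendency(s, q, 80.0, params, ModelVersion.P)
        cb1 = s["Cb"] * (1.0 + dt * (pc - loss))
        chl1 = s["Chla"] + dt * dchl
        assert abs(chl1 / cb1 - theta0) / theta0 < 1e-6

    def test_lower_qstar_gives_lower_theta(self, params):
        """Two 5-day integrations identical except for the imposed Q*
        (varied through the P quota at a fixed N quota, so nitrogen
        assimilation is equal): the more P-limited run ends with lower
        Chl:C — phosphorus limitation caps pigment synthesis."""
        from coastbgc import make_initial_state
        from coastbgc.phytoplankton import (_gpp_specific,
                                            nutrient_limitation)

        def run(qp):
            s = make_initial_state(ModelVersion.P, "oligotrophic-summer")
            dt = 1.0 / 72.0
            for _ in range(72 * 5):
                s["Nb"] = 0.125 * s["Cb"]       # limN = 0.5, fixed
                s["Pb"] = qp * s["Cb"]
                q = compute_quotas(s, params)
                dchl = chlorophyll_tendency(s, q, 80.0, params,
                                            ModelVersion.P)
                lim = nutrient_limitation(q, params, ModelVersion.P)
                pc = _gpp_specific(q.theta, lim.Qstar, 80.0, params)
                loss = (params.phyto.resp + params.phyto.exud
                        + params.phyto.mort)
                s["Cb"] = s["Cb"] * (1.0 + dt * (pc - loss))
                s["Chla"] = max(1e-12, s["Chla"] + dt * dchl)
            return s["Chla"] / s["Cb"]

        theta_p_replete = run(params.phyto.QP_max)       # Qstar = limN
        qp_low = params.phyto.QP_min + 0.3 * (params.phyto.QP_max
                                              - params.phyto.QP_min)
        theta_p_limited = run(qp_low)                    # Qstar = 0.3
        assert theta_p_limited < theta_p_replete


class TestPhytoSMS:
    def test_dark_starved_is_loss_only(self, state_p, params):
        for v in ("NO3", "NH4", "PO4"):
            state_p[v] = 0.0
        params.closure.g_phy = 0.0
        params.closure.g_bac = 0.0
        sms = phyto_sms(state_p, ForcingSample(T=15.0, E=0.0), params,
                        ModelVersion.P)
        for v in ("Cb", "Nb", "Pb", "Chla"):
            assert sms[v] <= 0.0

    def test_net_growth_when_replete_and_ungrazed(self, state_p, params):
        params.closure.g_phy = 0.0
        state_p["NO3"] = 10.0
        state_p["PO4"] = 2.0
        sms = phyto_sms(state_p, ForcingSample(T=15.0, E=200.0), params,
                        ModelVersion.P)
        assert sms["Cb"] > 0.0

    def test_nop_tendency_has_no_phosphorus_entry(self, state_nop, params):
        sms = phyto_sms(state_nop, ForcingSample(T=15.0, E=50.0), params,
                        ModelVersion.noP)
        with pytest.raises(VersionError):
            sms["Pb"]

    def test_p_saturation_matches_nop(self, p_saturated_pair, params):
        """With phosphorus pinned saturating, the P version's Cb/Nb/Chla
        tendencies equal the C/N-only version's to 1e-10 relative — the
        structural consistency behind the two-version comparison."""
        sp, sn = p_saturated_pair
        f = ForcingSample(T=18.0, E=60.0)
        tp = phyto_sms(sp, f, params, ModelVersion.P)
        tn = phyto_sms(sn, f, params, ModelVersion.noP)
        for v in ("Cb", "Nb", "Chla"):
            assert rel_diff(tp[v], tn[v]) < 1e-10
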