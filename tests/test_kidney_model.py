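"""Mechanistic kidney model: pH partition, segment cascade, CKD scaling."""

import numpy as np
import pytest

import renal_mps_pbpk as r
from renal_mps_pbpk import parameters as P
from renal_mps_pbpk.ivive import SecretionClearance
from renal_mps_pbpk.kidney_model import (NephronSegment,
                                         segment_mass_balance_residuals)


def make_drug(papp=26.3, pka=7.9, fu=0.64, bp=1.08, sec_total=39.3, n=3):
    return r.RenalDrugParams(
        fu_p=fu, blood_plasma_ratio=bp, pka_base=pka, papp_1e6_cm_s=papp,
        secretion=SecretionClearance(total=sec_total, n_subsegments=n))


class TestFractionUnionized:
    @pytest.mark.parametrize("ph,pka,expected", [
        (7.4, 7.9, 0.2403),
        (7.9, 7.9, 0.5),
        (6.3, 9.12, 1.511e-3),
    ])
    def test_henderson_hasselbalch(self, ph, pka, expected):
        assert r.fraction_unionized(ph, pka) == pytest.approx(expected, rel=1e-3)

    def test_bounded_in_unit_interval(self):
        for ph in np.linspace(4.5, 8.0, 20):
            assert 0 < r.fraction_unionized(ph, 9.12) < 1


class TestRenalClearance:
    def test_filtration_only_closed_form(self, kidney):
        """No permeability, no secretion: CL_r = fu_p * GFR exactly."""
        drug = make_drug(papp=0.0, sec_total=0.0)
        clr = r.simulate_renal_clearance(drug, kidney, method="algebraic")
        assert clr == pytest.approx(0.64 * 7.2, rel=1e-12)
        clr_ode = r.simulate_renal_clearance(drug, kidney, method="ode")
        assert clr_ode == pytest.approx(0.64 * 7.2, rel=1e-6)

    def test_zero_permeability_secretion_bound(self, kidney):
        """papp = 0: CL_r = fu_p*GFR + secreted flux / C_plasma exactly."""
        drug = make_drug(papp=0.0, sec_total=39.3)
        clr, cf, cb = r.simulate_renal_clearance(
            drug, kidney, method="algebraic", return_state=True)
        sec_each = drug.secretion.total / 3
        secreted = sum(sec_each * drug.fu_b * cb[i] for i in range(3))
        assert clr == pytest.approx(0.64 * 7.2 + secreted, rel=1e-12)

    def test_ode_matches_algebraic(self, kidney, morphine_renal, m6g_renal):
        for drug in (morphine_renal, m6g_renal):
            a = r.simulate_renal_clearance(drug, kidney, method="algebraic")
            o = r.simulate_renal_clearance(drug, kidney, method="ode")
            assert o == pytest.approx(a, rel=1e-6)

    def test_one_segment_closed_form_oracle(self):
        """ODE steady state matches an independently written single-
        compartment algebraic solution."""
        seg = NephronSegment(name="S1", flow_in=120.0, flow_out=1.2, ph=6.5,
                             exchange_area_cm2=5.0e4, secreting=True)
        phys = r.KidneyPhysiology(gfr_ml_min=120.0, q_kidney_L_h=74.1,
                                  segments=[seg])
        drug = make_drug(sec_total=20.0, n=1)
        clr = r.simulate_renal_clearance(drug, phys, method="ode")

        # independent closed form, written from the mass balances directly
        f74 = 1 / (1 + 10 ** (drug.pka_base - 7.4))
        fseg = 1 / (1 + 10 ** (drug.pka_base - 6.5))
        pa = drug.papp_1e6_cm_s / f74 * 1e-6 * 5.0e4 * 3.6
        fub = drug.fu_p / drug.blood_plasma_ratio
        qb, gfr, qout = 74.1, 7.2, 0.072
        cb0 = drug.blood_plasma_ratio * (1 - gfr * fub / qb)
        up = (20.0 + pa * f74) * fub
        # [qout+pa*fseg, -up; -pa*fseg, qb+up] [cf, cb] = [gfr*fu, qb*cb0]
        a11, a12, b1 = qout + pa * fseg, -up, gfr * drug.fu_p
        a21, a22, b2 = -pa * fseg, qb + up, qb * cb0
        cf = (b1 * a22 - a12 * b2) / (a11 * a22 - a12 * a21)
        assert clr == pytest.approx(qout * cf, rel=1e-6)

    def test_segment_mass_balance(self, kidney, morphine_renal, m6g_renal):
        for drug in (morphine_renal, m6g_renal):
            res = segment_mass_balance_residuals(drug, kidney)
            assert np.max(np.abs(res)) < 1e-6

    def test_monotone_in_secretion_and_fu(self, kidney):
        base = r.simulate_renal_clearance(make_drug(), kidney, "algebraic")
        more_sec = r.simulate_renal_clearance(
            make_drug(sec_total=60.0), kidney, "algebraic")
        more_fu = r.simulate_renal_clearance(
            make_drug(fu=0.9), kidney, "algebraic")
        assert more_sec > base
        assert more_fu > base

    def test_reabsorption_lowers_clearance(self, kidney):
        """Permeability opens the reabsorption pathway: CL_r must drop."""
        tight = r.simulate_renal_clearance(make_drug(papp=0.0), kidney,
                                           "algebraic")
        leaky = r.simulate_renal_clearance(make_drug(papp=26.3), kidney,
                                           "algebraic")
        assert leaky < tight

    def test_invalid_plasma_conc(self, kidney, morphine_renal):
        with pytest.raises(ValueError):
            r.simulate_renal_clearance(morphine_renal, kidney, c_plasma=0.0)


class TestCkdScaling:
    def test_identity_at_baseline(self, kidney, morphine_renal):
        p2, d2 = r.apply_ckd(kidney, morphine_renal, 120.0)
        assert p2.gfr_ml_min == pytest.approx(120.0)
        assert d2.secretion.total == pytest.approx(
            morphine_renal.secretion.total)
        assert r.simulate_renal_clearance(d2, p2, "algebraic") == pytest.approx(
            r.simulate_renal_clearance(morphine_renal, kidney, "algebraic"))

    def test_half_gfr_halves_flows_and_secretion(self, kidney, morphine_renal):
        p2, d2 = r.apply_ckd(kidney, morphine_renal, 60.0)
        assert p2.gfr_ml_min == pytest.approx(60.0)
        assert p2.q_urine_ml_min == pytest.approx(0.6)
        assert p2.segments[0].flow_out == pytest.approx(93.3 / 2)
        assert d2.secretion.total == pytest.approx(39.3 / 2)

    def test_severe_disease_scaling(self, kidney, morphine_renal):
        p2, d2 = r.apply_ckd(kidney, morphine_renal, 3.0)
        assert d2.secretion.total == pytest.approx(39.3 * 0.025)
        assert (r.simulate_renal_clearance(d2, p2, "algebraic")
                < r.simulate_renal_clearance(morphine_renal, kidney,
                                             "algebraic"))

    def test_invalid_targets(self, kidney, morphine_renal):
        with pytest.raises(ValueError):
            r.apply_ckd(kidney, morphine_renal, 0.0)
        with pytest.raises(ValueError):
            r.apply_ckd(kidney, morphine_renal, 150.0)

    def test_profile_monotone_and_matches_direct_call(self, kidney,
                                                      morphine_renal):
        grid = [3.0, 30.0, 60.0, 90.0, 120.0]
        df = r.clr_vs_gfr_profile([morphine_renal], kidney, grid)
        clr = df["clr_L_per_h"].to_numpy()
        assert np.all(np.diff(clr) > 0)
        p2, d2 = r.apply_ckd(kidney, morphine_renal, 30.0)
        assert clr[1] == pytest.approx(
            r.simulate_renal_clearance(d2, p2, "algebraic"))

    def test_filtration_only_drug_traces_fu_gfr_line(self, kidney):
        drug = make_drug(papp=0.0, sec_total=0.0)
        grid = [12.0, 60.0, 120.0]
        df = r.clr_vs_gfr_profile([drug], kidney, grid)
        expected = 0.64 * np.asarray(grid) * 0.06
        np.testing.assert_allclose(df["clr_L_per_h"], expected, rtol=1e-10)


class TestCalibration:
    def test_recovers_frozen_area_scale(self, morphine_renal):
        scale = r.calibrate_exchange_areas(morphine_renal, 8.24)
        assert scale == pytest.approx(P.KIDNEY_PHYSIOLOGY["area_scale_cm2"],
                                      rel=1e-5)

    def test_clearance_decreases_with_area(self, morphine_renal):
        lo = r.simulate_renal_clearance(
            morphine_renal, r.default_kidney_physiology(area_scale_cm2=1e3),
            "algebraic")
        hi = r.simulate_renal_clearance(
            morphine_renal, r.default_kidney_physiology(area_scale_cm2=1e5),
            "algebraic")
        assert hi < lo

    def test_unreachable_target_rejected(self, morphine_renal):
        with pytest.raises(ValueError):
            r.calibrate_exchange_areas(morphine_renal, 1000.0)
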