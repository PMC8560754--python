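"""Whole-body PBPK: distribution volume, well-stirred liver, coupled ODEs."""

import numpy as np
import pytest

import renal_mps_pbpk as r
from renal_mps_pbpk import parameters as P


@pytest.fixture(scope="module")
def infusion():
    return r.DoseRegimen(route="iv_infusion", amount_mg=10.0, duration_h=0.25)


class TestVss:
    def test_morphine_optimized_kp(self, morphine_model, body):
        assert r.compute_vss(morphine_model, body) == pytest.approx(141.0,
                                                                    rel=0.05)

    def test_m6g_extracellular_kp(self, m6g_model, body):
        assert r.compute_vss(m6g_model, body) == pytest.approx(21.0, rel=0.05)

    def test_vanishing_kp_leaves_plasma_volume(self, body, m6g_model):
        from dataclasses import replace
        drug = replace(m6g_model, kp={t: 1e-12 for t in m6g_model.kp})
        # M6G has no erythrocyte partitioning (B/P < 1 - Hct)
        assert r.compute_vss(drug, body) == pytest.approx(
            body.volume_plasma_L, rel=1e-6)

    def test_missing_tissue_rejected(self, morphine_model, body):
        from dataclasses import replace
        kp = dict(morphine_model.kp)
        kp.pop("muscle")
        with pytest.raises(ValueError, match="muscle"):
            r.compute_vss(replace(morphine_model, kp=kp), body)


class TestHepaticClearance:
    def test_subtraction(self):
        assert r.hepatic_clearance_from_total(83.5, 8.24) == pytest.approx(
            75.3, abs=0.05)
        assert r.hepatic_clearance_from_total(5.0, 5.0) == 0.0
        assert r.hepatic_clearance_from_total(83.5, 0.0) == 83.5

    def test_renal_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            r.hepatic_clearance_from_total(8.0, 9.0)

    def test_backcalc_reference_values(self):
        cl_int = r.backcalc_intrinsic_hepatic(75.3, 0.64, 1.08, 99.7)
        assert cl_int == pytest.approx(520.0, rel=0.005)
        assert r.backcalc_intrinsic_hepatic(0.0, 0.64, 1.08, 99.7) == 0.0

    @pytest.mark.parametrize("frac", [0.1, 0.5, 0.9])
    def test_well_stirred_round_trip(self, frac):
        q_h = 99.7
        cl_h = frac * q_h
        cl_int = r.backcalc_intrinsic_hepatic(cl_h, 0.64, 1.08, q_h)
        assert r.well_stirred_hepatic(cl_int, 0.64, 1.08, q_h) == pytest.approx(
            cl_h, rel=1e-12)

    def test_extraction_above_unity_rejected(self):
        with pytest.raises(ValueError):
            r.backcalc_intrinsic_hepatic(100.0, 0.64, 1.08, 99.7)


class TestBodyPhysiology:
    def test_flows_sum_to_cardiac_output(self, body):
        non_lung = sum(row["flow"] for t, row in body.tissues.items()
                       if t != "lung")
        assert body.cardiac_output == pytest.approx(non_lung)

    def test_hepatic_flow_composition(self, body):
        assert body.q_hepatic == pytest.approx(99.7)


class TestSimulation:
    def test_no_formation_means_no_metabolite(self, body, morphine_model,
                                              m6g_model, infusion):
        from dataclasses import replace
        parent = replace(morphine_model, fm_m6g=0.0)
        _, met, _ = r.simulate_parent_metabolite(parent, m6g_model, infusion,
                                                 phys=body, horizon_h=12.0)
        assert np.all(met.conc == 0.0)

    def test_mass_balance_within_half_percent(self, body, morphine_model,
                                              m6g_model, infusion):
        _, _, diag = r.simulate_parent_metabolite(
            morphine_model, m6g_model, infusion, phys=body, horizon_h=24.0)
        assert diag["mass_balance_rel_error"] < 0.005
        assert diag["metabolite_mass_balance_rel_error"] < 0.005

    def test_dose_auc_matches_total_clearance(self, body, morphine_model,
                                              infusion):
        """Non-compartmental Dose/AUC within 2% of CL_h + CL_r."""
        prof, _, _ = r.simulate_parent_metabolite(
            morphine_model, None, infusion, phys=body, horizon_h=36.0,
            n_points=1441)
        res = r.nca(prof, infusion)
        expected = morphine_model.cl_h + morphine_model.cl_r
        assert res["cl"] == pytest.approx(expected, rel=0.02)

    def test_moment_analysis_vss(self, body, m6g_model):
        """Direct metabolite dosing: CL*MRT within 5% of the Kp-sum Vss."""
        dose = r.DoseRegimen(route="iv_infusion", amount_mg=5.0,
                             duration_h=0.25)
        prof, _, _ = r.simulate_parent_metabolite(
            m6g_model, None, dose, phys=body, horizon_h=24.0, n_points=1441,
            site="central_venous")
        res = r.nca(prof, dose)
        assert res["vss"] == pytest.approx(r.compute_vss(m6g_model, body),
                                           rel=0.05)

    def test_dose_superposition(self, body, morphine_model, m6g_model):
        """Linear model: doubling dose doubles every concentration."""
        d1 = r.DoseRegimen(route="iv_infusion", amount_mg=5.0, duration_h=0.5)
        d2 = r.DoseRegimen(route="iv_infusion", amount_mg=10.0, duration_h=0.5)
        p1, m1, _ = r.simulate_parent_metabolite(morphine_model, m6g_model,
                                                 d1, phys=body, horizon_h=12.0)
        p2, m2, _ = r.simulate_parent_metabolite(morphine_model, m6g_model,
                                                 d2, phys=body, horizon_h=12.0)
        np.testing.assert_allclose(p2.conc, 2 * p1.conc, rtol=1e-6)
        np.testing.assert_allclose(m2.conc, 2 * m1.conc, rtol=1e-6)

    def test_metabolite_auc_linear_in_fm(self, body, morphine_model,
                                         m6g_model, infusion):
        from dataclasses import replace
        aucs = []
        for fm in (0.05, 0.1):
            parent = replace(morphine_model, fm_m6g=fm)
            _, met, _ = r.simulate_parent_metabolite(
                parent, m6g_model, infusion, phys=body, horizon_h=24.0)
            aucs.append(np.trapezoid(met.conc, met.times))
        assert aucs[1] == pytest.approx(2 * aucs[0], rel=1e-6)

    def test_terminal_slope_stable_to_tolerance(self, body, morphine_model,
                                                infusion):
        """Halving solver tolerances leaves the terminal slope unchanged."""
        slopes = []
        for rtol in (1e-8, 5e-9):
            prof, _, _ = r.simulate_parent_metabolite(
                morphine_model, None, infusion, phys=body, horizon_h=24.0,
                rtol=rtol)
            tail = prof.times > 12
            k = np.polyfit(prof.times[tail], np.log(prof.conc[tail]), 1)[0]
            slopes.append(k)
        assert slopes[0] == pytest.approx(slopes[1], rel=1e-4)

    def test_bolus_route_supported(self, body, m6g_model):
        dose = r.DoseRegimen(route="iv_bolus", amount_mg=5.0)
        prof, _, diag = r.simulate_parent_metabolite(
            m6g_model, None, dose, phys=body, horizon_h=12.0)
        assert diag["mass_balance_rel_error"] < 0.005
        assert prof.conc.max() > 0

    def test_per_kg_dosing(self):
        d = r.DoseRegimen(route="iv_bolus", amount_mg=0.1, subject_mass_kg=70)
        assert d.total_mg() == pytest.approx(7.0)

    def test_invalid_doses_rejected(self):
        with pytest.raises(ValueError):
            r.DoseRegimen(route="iv_bolus", amount_mg=0.0)
        with pytest.raises(ValueError):
            r.DoseRegimen(route="iv_infusion", amount_mg=1.0, duration_h=0.0)
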