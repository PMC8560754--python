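"""Clearance reduction: steady-state estimators, intrinsicization, permeability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import renal_mps_pbpk as r


def series(times, conc, channel="tubular", condition="control", flow=60.0,
           censored=None, nominal=1000.0):
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if censored is None:
        censored = np.zeros(times.shape, dtype=bool)
    return r.EffluentSeries(donor="d1", compound="morphine",
                            condition=condition, channel=channel,
                            times=times, conc=conc, censored=censored,
                            flow_out=flow, nominal_inflow_conc=nominal)


class TestSteadyStateEfflux:
    def test_plateau_rate_is_conc_times_flow(self):
        s = series([6, 8, 10, 12], [50, 50, 50, 50])
        rate, vconc = r.steady_state_efflux(s, window_start=6.0)
        assert rate == pytest.approx(3000.0)     # nM * µL/h
        assert vconc == pytest.approx(1000.0)

    def test_zero_concentration_gives_zero_rate(self):
        s = series([6, 8, 10], [0, 0, 0])
        rate, _ = r.steady_state_efflux(s)
        assert rate == 0.0

    def test_window_without_samples_errors(self):
        s = series([2, 4], [10, 20])
        with pytest.raises(ValueError):
            r.steady_state_efflux(s, window_start=6.0)

    def test_all_censored_window_errors(self):
        s = series([6, 8, 10], [1, 1, 1], censored=[True, True, True])
        with pytest.raises(ValueError, match="censored"):
            r.steady_state_efflux(s)

    def test_nominal_reference_default_measured_on_request(self):
        tub = series([6, 8], [50, 50])
        vas = series([6, 8], [940, 960], channel="vascular")
        _, vconc = r.steady_state_efflux(tub, vascular=vas)
        assert vconc == pytest.approx(1000.0)
        _, vconc = r.steady_state_efflux(tub, vascular=vas,
                                         vascular_ref="measured")
        assert vconc == pytest.approx(950.0)

    def test_censored_samples_excluded_from_mean(self):
        s = series([6, 8, 10], [50, 1, 50], censored=[False, True, False])
        rate, _ = r.steady_state_efflux(s)
        assert rate == pytest.approx(3000.0)


class TestApparentClearance:
    @pytest.mark.parametrize("rate,vconc,expected", [
        (50 * 60.0, 1000.0, 3.0),
        (0.0, 1000.0, 0.0),
        (60 * 1000.0, 1000.0, 60.0),   # complete equilibration: CL_app = flow
    ])
    def test_examples(self, rate, vconc, expected):
        assert r.apparent_clearance(rate, vconc) == pytest.approx(expected)

    def test_nonpositive_vascular_conc_rejected(self):
        with pytest.raises(ValueError):
            r.apparent_clearance(100.0, 0.0)


class TestActiveFromApparent:
    def test_difference(self):
        assert r.active_from_apparent(3.0, 1.0) == pytest.approx(2.0)
        assert r.active_from_apparent(1.0, 1.0) == 0.0

    def test_negative_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            assert r.active_from_apparent(0.8, 1.0) == 0.0


class TestIntrinsicize:
    def test_hand_arithmetic(self):
        assert r.intrinsicize(3.0, 60.0) == pytest.approx(3.1578947, rel=1e-6)
        assert r.intrinsicize(0.0, 60.0) == 0.0
        assert r.intrinsicize(30.0, 60.0) == pytest.approx(60.0)

    def test_flow_limited_regime_rejected(self):
        with pytest.raises(ValueError, match="flow-limited"):
            r.intrinsicize(60.0, 60.0)

    @given(st.floats(0.0, 59.0))
    @settings(max_examples=50, deadline=None)
    def test_inverse_identity_and_ordering(self, cl_app):
        """apparentize(intrinsicize(x)) = x; CL_int >= CL_app always."""
        cl_int = r.intrinsicize(cl_app, 60.0)
        assert cl_int >= cl_app
        assert r.apparentize(cl_int, 60.0) == pytest.approx(cl_app, abs=1e-9)

    def test_divergence_near_flow_limit(self):
        """CL_int grows without bound as CL_app approaches channel flow."""
        assert r.intrinsicize(59.999, 60.0) > 1e6


class TestPermeability:
    def test_unit_conversion(self, geometry):
        g = r.DeviceGeometry(surface_area_cm2=0.0493)
        assert r.papp_from_intrinsic(4.93, g) == pytest.approx(27.78, rel=1e-3)
        assert r.papp_from_intrinsic(0.0, g) == 0.0

    def test_inverse_proportional_to_area(self):
        g1 = r.DeviceGeometry(surface_area_cm2=0.05)
        g2 = r.DeviceGeometry(surface_area_cm2=0.10)
        assert r.papp_from_intrinsic(5.0, g1) == pytest.approx(
            2 * r.papp_from_intrinsic(5.0, g2))

    def test_default_geometry_is_cylinder_surface(self):
        g = r.DeviceGeometry()
        assert g.surface_area_cm2 == pytest.approx(
            np.pi * 120e-4 * 1.31, rel=1e-9)


class TestReduceDonor:
    def _table_like_truth(self, geometry):
        """Donor with intrinsic active clearance 14.1 µL/h and permeability
        27.8e-6 cm/s, expressed as generating apparent clearances."""
        cl_int_p = 27.8e-6 * geometry.surface_area_cm2 * 3600 * 1e3
        cl_int_t = cl_int_p + 14.1
        return r.MpsGroundTruth(
            cl_app_transport=r.apparentize(cl_int_t, 60.0),
            cl_app_passive=r.apparentize(cl_int_p, 60.0),
            noise_cv=0.0, seed=2)

    def test_donor_level_round_trip(self, geometry):
        truth = self._table_like_truth(geometry)
        control, inhibitor = r.generate_effluent_series(truth)
        cs = r.reduce_donor(control, inhibitor, geometry, window_start=14.0)
        assert cs.cl_int_active == pytest.approx(14.1, rel=1e-3)
        assert cs.papp_1e6_cm_s == pytest.approx(27.8, rel=1e-3)

    def test_fully_effective_inhibitor_means_no_active(self, geometry):
        truth = r.MpsGroundTruth(cl_app_transport=2.0, cl_app_passive=2.0,
                                 noise_cv=0.0, seed=3)
        control, inhibitor = r.generate_effluent_series(truth)
        cs = r.reduce_donor(control, inhibitor, geometry, window_start=14.0)
        assert cs.cl_int_active == pytest.approx(0.0, abs=1e-9)

    def test_percent_inhibition_recovers_generating_fraction(self, geometry):
        """cl_int_active / cl_int_transport matches the generating split."""
        cl_int_p, cl_int_a = 2.0, 6.0
        truth = r.MpsGroundTruth(
            cl_app_transport=r.apparentize(cl_int_p + cl_int_a, 60.0),
            cl_app_passive=r.apparentize(cl_int_p, 60.0),
            noise_cv=0.0, seed=4)
        control, inhibitor = r.generate_effluent_series(truth)
        cs = r.reduce_donor(control, inhibitor, geometry, window_start=14.0)
        assert cs.cl_int_active / cs.cl_int_transport == pytest.approx(
            0.75, rel=5e-3)

    def test_mismatched_donor_rejected(self, geometry):
        a = series([6, 8], [50, 50])
        b = series([6, 8], [20, 20], condition="inhibitor")
        b.donor = "other"
        with pytest.raises(ValueError, match="single donor"):
            r.reduce_donor([a], [b], geometry)


class TestInhibitorEffect:
    def test_hand_computed_pooled_t(self):
        t, p = r.inhibitor_effect_test([10, 11, 9], [5, 6, 4])
        assert t == pytest.approx(6.1237, rel=1e-4)
        assert p < 0.05

    def test_identical_arms_not_significant(self):
        t, p = r.inhibitor_effect_test([10, 11, 9], [10, 11, 9])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_variance_equal_means(self):
        t, p = r.inhibitor_effect_test([5, 5, 5], [5, 5, 5])
        assert (t, p) == (0.0, 1.0)

    def test_insufficient_samples(self):
        with pytest.raises(ValueError):
            r.inhibitor_effect_test([1.0], [2.0, 3.0])
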