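"""Transport of the drug solution along the infusion line."""

import numpy as np
import pytest

from chronopk.pump import (
    DEFAULT_TUBE,
    InfusionSegment,
    PumpProgram,
    TubeSpec,
    TubeNeverFilledError,
    build_trial_schedule,
    fill_delay,
    flush_spike_fraction,
    peak_rate_from_dose,
    solve_transport_characteristics,
    solve_transport_fd,
)
from conftest import DRUGS, random_program


class TestTrialSchedule:
    def test_cpt11_segment_matches_published_settings(self):
        program = build_trial_schedule("CPT11", reference_bsa=1.84)
        drug_seg = program.segments[0]
        assert drug_seg.shape == "half_sin_squared"
        assert drug_seg.duration_h == 6.0
        assert drug_seg.stock_mg_ml == 3.33
        assert drug_seg.peak_rate_ml_h == pytest.approx(18.02 * 1.84)
        # glucose rinse starts 7 h 45 after the 02:00 drug start (09:45)
        assert program.segments[1].start_h == pytest.approx(7.75)

    def test_sin2_segment_volume_is_half_peak_times_duration(self):
        # analytic integral of peak*sin^2 over one arch
        program = build_trial_schedule("LOHP", reference_bsa=1.84)
        seg = program.segments[0]
        assert seg.total_volume_ml == pytest.approx(1.63 / 2 * 11.5 * 1.84, rel=1e-12)

    def test_rates_scale_linearly_with_bsa(self):
        p1 = build_trial_schedule("FU5", reference_bsa=1.0)
        p2 = build_trial_schedule("FU5", reference_bsa=1.84)
        for s1, s2 in zip(p1.segments, p2.segments):
            assert s2.peak_rate_ml_h == pytest.approx(1.84 * s1.peak_rate_ml_h)

    def test_unknown_drug_rejected(self):
        with pytest.raises(KeyError):
            build_trial_schedule("5FU-bogus")

    def test_peak_rate_from_dose_reproduces_printed_value(self):
        assert peak_rate_from_dose(180.0, 3.33, 6.0) == pytest.approx(18.02, abs=0.01)


class TestCharacteristics:
    def test_constant_rate_plug_flow_delay(self):
        seg = InfusionSegment(0.0, 4.0, "constant", 3.68, "drug", stock_mg_ml=10.0)
        flush = InfusionSegment(4.0, 1.0, "constant", 3.68, "glucose")
        program = PumpProgram((seg, flush), tube=DEFAULT_TUBE)
        profile = solve_transport_characteristics(program)
        assert profile.onset_h == pytest.approx(0.5, abs=1e-9)
        # after the delay the outlet equals the inlet mass rate
        mid = profile.rate_at(2.0)
        assert mid == pytest.approx(3.68 * 10.0, rel=1e-12)

    @pytest.mark.parametrize("drug,minutes", [("CPT11", 51), ("FU5", 140), ("LOHP", 183)])
    def test_trial_fill_delays(self, trial_deliveries, drug, minutes):
        assert fill_delay(trial_deliveries[drug]) == minutes

    def test_mass_conservation_on_random_programs(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            program = random_program(rng)
            profile = solve_transport_characteristics(program)
            inlet = program.total_pumped_mass_mg
            assert abs(profile.total_mass_mg - inlet) / inlet < 1e-6

    def test_outlet_depends_only_on_tube_volume(self):
        fat = TubeSpec(volume_ml=1.84, length_mm=800.0)
        for drug in DRUGS:
            a = solve_transport_characteristics(build_trial_schedule(drug))
            b = solve_transport_characteristics(build_trial_schedule(drug, tube=fat))
            np.testing.assert_allclose(a.rate_mg_h, b.rate_mg_h, rtol=0, atol=1e-12)

    def test_delivery_proportional_to_flow_once_tube_full(self, trial_programs):
        program = trial_programs["LOHP"]
        profile = solve_transport_characteristics(program)
        seg = program.segments[0]
        # window where both outlet parcel and current flow are in the drug arch
        window = (profile.times_h > profile.onset_h + 0.1) & (profile.times_h < seg.end_h - 0.1)
        q = program.rate_ml_h(profile.times_h[window])
        ratio = profile.rate_mg_h[window] / q
        np.testing.assert_allclose(ratio, seg.stock_mg_ml, rtol=1e-12)

    def test_cumulative_is_nondecreasing(self, trial_deliveries):
        for profile in trial_deliveries.values():
            assert np.all(np.diff(profile.cumulative_mg) >= -1e-12)


class TestFillDelay:
    def test_constant_rate_closed_form(self):
        seg = InfusionSegment(0.0, 3.0, "constant", 1.84, "drug", stock_mg_ml=5.0)
        program = PumpProgram((seg,), tube=DEFAULT_TUBE)
        assert fill_delay(solve_transport_characteristics(program)) == 60

    def test_doubling_tube_volume_doubles_delay(self):
        seg = InfusionSegment(0.0, 5.0, "constant", 1.84, "drug", stock_mg_ml=5.0)
        small = PumpProgram((seg,), tube=TubeSpec(volume_ml=1.84))
        big = PumpProgram((seg,), tube=TubeSpec(volume_ml=3.68))
        d1 = fill_delay(solve_transport_characteristics(small))
        d2 = fill_delay(solve_transport_characteristics(big))
        assert d2 == 2 * d1

    def test_never_filled_flagged(self):
        seg = InfusionSegment(0.0, 0.5, "constant", 1.0, "drug", stock_mg_ml=5.0)
        program = PumpProgram((seg,), tube=DEFAULT_TUBE)  # pumps 0.5 ml < 1.84 ml
        profile = solve_transport_characteristics(program)
        with pytest.raises(TubeNeverFilledError):
            fill_delay(profile)


class TestFlushSpike:
    @pytest.mark.parametrize("drug,pct", [("LOHP", 10.71), ("CPT11", 1.85), ("FU5", 5.36)])
    def test_trial_spike_fractions(self, trial_programs, drug, pct):
        assert flush_spike_fraction(trial_programs[drug]) == pytest.approx(pct, abs=0.05)

    def test_closed_form_tube_content_over_dose(self, trial_programs):
        program = trial_programs["LOHP"]
        expected = 100.0 * DEFAULT_TUBE.volume_ml * 3.0 / (28.0 * 1.84)
        assert flush_spike_fraction(program) == pytest.approx(expected, rel=1e-9)

    def test_zero_stock_gives_zero_spike(self):
        seg = InfusionSegment(0.0, 2.0, "constant", 5.0, "drug", stock_mg_ml=0.0)
        flush = InfusionSegment(2.0, 1.0, "constant", 5.0, "glucose")
        program = PumpProgram((seg, flush), nominal_dose_mg=100.0)
        assert flush_spike_fraction(program) == 0.0

    def test_partial_flush_warns(self):
        seg = InfusionSegment(0.0, 2.0, "constant", 5.0, "drug", stock_mg_ml=10.0)
        flush = InfusionSegment(2.0, 0.1, "constant", 5.0, "glucose")  # 0.5 ml < tube
        program = PumpProgram((seg, flush))
        with pytest.warns(UserWarning, match="partial"):
            flush_spike_fraction(program)


class TestFiniteDifference:
    def test_plug_flow_matches_characteristics(self):
        seg = InfusionSegment(0.0, 3.0, "constant", 7.36, "drug", stock_mg_ml=10.0)
        flush = InfusionSegment(3.0, 1.0, "constant", 7.36, "glucose")
        program = PumpProgram((seg, flush))
        _, fd = solve_transport_fd(program, dx_mm=DEFAULT_TUBE.length_mm / 400)
        ch = solve_transport_characteristics(program)
        err = np.trapezoid(np.abs(fd.rate_mg_h - ch.rate_at(fd.times_h)), fd.times_h)
        assert err / program.total_pumped_mass_mg < 0.02

    def test_fd_mass_conservation(self):
        program = build_trial_schedule("LOHP")
        _, fd = solve_transport_fd(program, dx_mm=DEFAULT_TUBE.length_mm / 2000)
        inlet = program.total_pumped_mass_mg
        assert abs(fd.total_mass_mg - inlet) / inlet < 1e-3

    def test_error_shrinks_under_refinement_on_random_programs(self):
        rng = np.random.default_rng(7)
        improved = 0
        for _ in range(20):
            program = random_program(rng)
            ch = solve_transport_characteristics(program)
            errs = []
            for nx in (100, 400):
                _, fd = solve_transport_fd(program, dx_mm=program.tube.length_mm / nx)
                errs.append(np.trapezoid(np.abs(fd.rate_mg_h - ch.rate_at(fd.times_h)), fd.times_h))
            improved += errs[1] < errs[0]
        assert improved >= 18  # first-order scheme: refinement reduces L1 error

    def test_cfl_violation_rejected(self):
        program = build_trial_schedule("CPT11")
        with pytest.raises(ValueError, match="CFL"):
            solve_transport_fd(program, dx_mm=2.34, dt_h=1.0)

    def test_field_nonnegative_and_initially_empty(self):
        program = build_trial_schedule("LOHP")
        state, _ = solve_transport_fd(program, dx_mm=DEFAULT_TUBE.length_mm / 200)
        assert state.u.min() >= -1e-12
        np.testing.assert_array_equal(state.u[0][1:], 0.0)


class TestValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            InfusionSegment(0.0, 1.0, "constant", -1.0, "drug", stock_mg_ml=1.0)

    def test_overlapping_segments_rejected(self):
        a = InfusionSegment(0.0, 2.0, "constant", 1.0, "drug", stock_mg_ml=1.0)
        b = InfusionSegment(1.0, 2.0, "constant", 1.0, "glucose")
        with pytest.raises(ValueError, match="overlap"):
            PumpProgram((a, b))

    def test_tube_geometry_consistency(self):
        t = TubeSpec.from_geometry(radius_mm=0.5, length_mm=2340.0)
        assert t.volume_ml == pytest.approx(1.838, abs=0.002)
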