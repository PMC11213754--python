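import numpy as np
import pytest

from biodeg.gas import (
    AMBIENT_O2_FRACTION,
    R_GAS,
    BottleSpec,
    FlushEvent,
    GasAccountingError,
    GasCurve,
    GasReading,
    aggregate_replicates,
    blank_correct,
    cumulative_methane,
    cumulative_o2_consumed,
    headspace_moles,
    o2_grams_to_liters,
    o2_liters_to_grams,
)


class TestBottleSpec:
    def test_headspace_volume(self, anaerobic_spec):
        assert anaerobic_spec.headspace_volume_ml == 75.0

    def test_liquid_exceeding_total_rejected(self):
        with pytest.raises(GasAccountingError):
            BottleSpec(120, 130, 55, 1.7e5)

    def test_composition_must_sum_to_one(self):
        with pytest.raises(GasAccountingError, match="sum"):
            BottleSpec(120, 45, 55, 1.7e5, {"N2": 0.8, "CO2": 0.3})

    def test_unknown_gas_rejected(self):
        with pytest.raises(GasAccountingError, match="unknown"):
            BottleSpec(120, 45, 55, 1.7e5, {"He": 1.0})


class TestHeadspaceMoles:
    def test_zero_fraction(self, anaerobic_spec):
        assert headspace_moles(anaerobic_spec, 0.0, 1.7e5) == 0.0

    def test_hand_ideal_gas_value(self, anaerobic_spec):
        # independent arithmetic: 0.20 * 1.7e5 Pa * 75e-6 m3 / (R * 328.15 K)
        expected = 0.20 * 1.7e5 * 75e-6 / (8.314 * 328.15)
        got = headspace_moles(anaerobic_spec, 0.20, 1.7e5)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(9.35e-4, rel=1e-3)

    def test_pressure_linearity(self, anaerobic_spec):
        one = headspace_moles(anaerobic_spec, 0.1, 1.0e5)
        two = headspace_moles(anaerobic_spec, 0.1, 2.0e5)
        assert two == pytest.approx(2 * one, rel=1e-12)

    def test_unit_round_trip(self, anaerobic_spec):
        mol = headspace_moles(anaerobic_spec, 0.37, 1.3e5)
        liters = mol * 22.4
        assert liters / 22.4 == pytest.approx(mol, rel=1e-12)

    def test_grams_liters_round_trip(self):
        assert o2_liters_to_grams(o2_grams_to_liters(0.1319)) == pytest.approx(
            0.1319, rel=1e-12
        )


class TestCumulativeMethane:
    def test_all_zero_fractions_flat_curve(self, anaerobic_spec):
        readings = [GasReading(t, 0.0) for t in (0, 7, 14)]
        curve = cumulative_methane(anaerobic_spec, readings)
        assert np.allclose(curve.cumulative, 0.0)
        assert curve.times[0] == 0 and curve.cumulative[0] == 0

    def test_single_reading_derived_value(self, anaerobic_spec):
        # fraction 0.20 at constant 1.7e5 Pa puts ~9.346e-4 mol CH4 above the
        # (zero) initial amount -> 9.346e-4 * 22.4 L STP
        curve = cumulative_methane(anaerobic_spec, [GasReading(7.0, 0.20)])
        expected_mol = 0.20 * 1.7e5 * 75e-6 / (R_GAS * 328.15)
        assert curve.cumulative[-1] == pytest.approx(expected_mol * 22.4, rel=1e-9)
        assert curve.cumulative[-1] == pytest.approx(0.0209, abs=5e-4)
        # time-0 anchor prepended
        assert curve.times[0] == 0.0 and curve.cumulative[0] == 0.0

    def test_initial_ch4_subtracted(self):
        spec = BottleSpec(120, 45, 55, 1.7e5, {"N2": 0.7, "CO2": 0.2, "CH4": 0.1})
        curve = cumulative_methane(spec, [GasReading(0.0, 0.1), GasReading(7.0, 0.1)])
        assert np.allclose(curve.cumulative, 0.0, atol=1e-15)

    def test_unsorted_readings_rejected(self, anaerobic_spec):
        with pytest.raises(GasAccountingError, match="increasing"):
            cumulative_methane(
                anaerobic_spec, [GasReading(7.0, 0.1), GasReading(3.0, 0.05)]
            )

    def test_missing_pressure_without_constant_mode(self, anaerobic_spec):
        with pytest.raises(GasAccountingError, match="pressure"):
            cumulative_methane(
                anaerobic_spec,
                [GasReading(0.0, 0.0)],
                assume_constant_pressure=False,
            )

    def test_monotonicity_violation_flagged(self, anaerobic_spec):
        readings = [GasReading(0, 0.0), GasReading(7, 0.2), GasReading(14, 0.1)]
        curve = cumulative_methane(anaerobic_spec, readings)
        assert any("non_monotonic" in fl for fl in curve.flags)


def _o2_fraction_after(spec, consumed_mol, pressure):
    n_total = pressure * spec.headspace_volume_ml * 1e-6 / (R_GAS * spec.temperature_k)
    return (AMBIENT_O2_FRACTION * n_total - consumed_mol) / n_total


class TestCumulativeO2:
    def test_constant_fraction_no_flush_zero(self, aerobic_spec):
        readings = [GasReading(t, 0.2095) for t in (0, 7, 14)]
        curve = cumulative_o2_consumed(aerobic_spec, readings, [])
        assert np.allclose(curve.cumulative, 0.0, atol=1e-15)

    def test_two_segments_hand_value(self):
        # each segment consumes exactly 1e-3 mol -> total 2e-3 mol = 0.0640 g
        # (3e5 Pa so a single headspace fill holds more than 1e-3 mol of O2)
        spec = BottleSpec(120, 50, 37, 3e5, {"N2": 0.7905, "O2": 0.2095})
        f1 = _o2_fraction_after(spec, 1e-3, 3e5)
        readings = [GasReading(0, 0.2095), GasReading(5, f1), GasReading(10, f1)]
        flushes = [FlushEvent(5, AMBIENT_O2_FRACTION, 3e5)]
        curve = cumulative_o2_consumed(spec, readings, flushes)
        assert curve.cumulative[-1] == pytest.approx(2e-3 * 22.4, rel=1e-9)
        assert curve.grams()[-1] == pytest.approx(2e-3 * 31.9988, rel=1e-9)
        assert round(float(curve.grams()[-1]), 4) == 0.0640

    def test_flush_restoring_prior_state_is_invisible(self, aerobic_spec):
        f1 = _o2_fraction_after(aerobic_spec, 5e-4, 1.7e5)
        readings = [GasReading(0, 0.2095), GasReading(5, f1), GasReading(10, f1)]
        base = cumulative_o2_consumed(aerobic_spec, readings, [])
        with_null_flush = cumulative_o2_consumed(
            aerobic_spec, readings, [FlushEvent(5, f1, 1.7e5)]
        )
        assert np.allclose(base.cumulative, with_null_flush.cumulative, atol=1e-15)

    def test_segment_additivity(self, aerobic_spec):
        # consumption over [0, 10] equals [0, 5] + [5, 10] when split at a reading
        f1 = _o2_fraction_after(aerobic_spec, 4e-4, 1.7e5)
        f2 = _o2_fraction_after(aerobic_spec, 9e-4, 1.7e5)
        readings = [GasReading(0, 0.2095), GasReading(5, f1), GasReading(10, f2)]
        curve = cumulative_o2_consumed(aerobic_spec, readings, [])
        whole = curve.cumulative[-1]
        first = curve.cumulative[1]
        second = whole - first
        assert whole == pytest.approx(first + second, rel=1e-12)
        assert first == pytest.approx(4e-4 * 22.4, rel=1e-9)
        assert second == pytest.approx(5e-4 * 22.4, rel=1e-9)

    def test_replenished_o2_never_counted(self, aerobic_spec):
        # consumption, then flush back to ambient, then no further change
        f1 = _o2_fraction_after(aerobic_spec, 5e-4, 1.7e5)
        readings = [
            GasReading(0, 0.2095),
            GasReading(5, f1),
            GasReading(10, AMBIENT_O2_FRACTION),
        ]
        flushes = [FlushEvent(5, AMBIENT_O2_FRACTION, 1.7e5)]
        curve = cumulative_o2_consumed(aerobic_spec, readings, flushes)
        assert curve.cumulative[-1] == pytest.approx(5e-4 * 22.4, rel=1e-9)

    def test_flush_without_segment_reading_rejected(self, aerobic_spec):
        readings = [GasReading(0, 0.2095), GasReading(10, 0.2)]
        flushes = [FlushEvent(3, 0.2095, 1.7e5), FlushEvent(5, 0.2095, 1.7e5)]
        with pytest.raises(GasAccountingError, match="no reading"):
            cumulative_o2_consumed(aerobic_spec, readings, flushes)


def _curve(times, values, mode="methane_production"):
    return GasCurve(np.asarray(times, float), np.asarray(values, float), mode)


class TestBlankCorrect:
    def test_identical_sample_and_blank_zero(self):
        c = _curve([0, 10, 20], [0, 1, 2])
        corrected = blank_correct(c, [c, c])
        assert np.allclose(corrected.cumulative, 0.0)

    def test_constant_offset_preserved(self):
        blank = _curve([0, 10, 20], [0, 1, 2])
        sample = _curve([0, 10, 20], [0.05, 1.05, 2.05])
        corrected = blank_correct(sample, [blank])
        assert np.allclose(corrected.cumulative, 0.05)

    def test_linear_interpolation_of_blank_mean(self):
        blanks = [_curve([0, 10, 20], [0, 1, 2]), _curve([0, 10, 20], [0, 3, 4])]
        sample = _curve([0, 5, 15], [0, 1.5, 2.8])
        corrected = blank_correct(sample, blanks)
        # blank mean: 0 at 0, 2 at 10, 3 at 20 -> interp 1.0 at 5, 2.5 at 15
        assert corrected.cumulative == pytest.approx([0.0, 0.5, 0.3])

    def test_negative_values_kept_and_flagged(self):
        blank = _curve([0, 10], [0, 1])
        sample = _curve([0, 10], [0, 0.5])
        corrected = blank_correct(sample, [blank])
        assert corrected.cumulative[-1] == pytest.approx(-0.5)
        assert "negative_after_blank_correction" in corrected.flags

    def test_coverage_error_and_end_hold(self):
        blank = _curve([0, 10], [0, 1])
        sample = _curve([0, 10, 30], [0, 1, 1])
        with pytest.raises(GasAccountingError, match="cover"):
            blank_correct(sample, [blank])
        held = blank_correct(sample, [blank], end_hold=True)
        assert held.cumulative[-1] == pytest.approx(0.0)  # blank held at 1

    def test_no_blanks_rejected(self):
        with pytest.raises(GasAccountingError):
            blank_correct(_curve([0, 1], [0, 1]), [])

    def test_blank_linearity_property(self, rng):
        blanks = [
            _curve([0, 10, 20], np.cumsum(rng.uniform(0, 0.2, 3))) for _ in range(3)
        ]
        sample = _curve([0, 10, 20], [0, 0.4, 0.9])
        k = 0.37
        shifted = _curve(sample.times, sample.cumulative + k)
        a = blank_correct(shifted, blanks).cumulative
        b = blank_correct(sample, blanks).cumulative + k
        assert np.allclose(a, b, atol=1e-12)


class TestAggregateReplicates:
    def test_identical_curves(self):
        c = _curve([0, 10, 20], [0, 1, 2])
        agg = aggregate_replicates([c, c, c])
        assert np.allclose(agg.mean, c.cumulative)
        assert np.allclose(agg.sd, 0.0)

    def test_textbook_sd(self):
        curves = [_curve([0.0, 1.0], [0.0, v]) for v in (1.0, 2.0, 3.0)]
        agg = aggregate_replicates(curves)
        assert agg.mean[-1] == pytest.approx(2.0)
        assert agg.sd[-1] == pytest.approx(1.0)  # n-1 denominator

    def test_single_curve_sd_absent(self):
        agg = aggregate_replicates([_curve([0, 1], [0, 1])])
        assert agg.sd is None
        assert any("SD undefined" in fl for fl in agg.flags)

    def test_resampling_onto_first_grid(self):
        a = _curve([0, 10, 20], [0, 1, 2])
        b = _curve([0, 5, 20], [0, 0.5, 2])  # linear, same line as a
        agg = aggregate_replicates([a, b])
        assert np.allclose(agg.mean, a.cumulative)

    def test_mixed_modes_rejected(self):
        a = _curve([0, 1], [0, 1])
        b = _curve([0, 1], [0, 1], mode="oxygen_consumption")
        with pytest.raises(GasAccountingError):
            aggregate_replicates([a, b])
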