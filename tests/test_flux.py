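"""Metabolic flux: probe calibrations, cumulative fluxes, forward model."""

import numpy as np
import pytest

from acidhif.flux import (
    CalibrationParams,
    FluorTimeCourse,
    O2ProbeCalibration,
    PhProbeCalibration,
    ProbeSaturationWarning,
    calibrate_timecourse,
    cumulative_acid,
    cumulative_o2,
    intensity_to_po2,
    lactate_slope,
    ph_to_ratio,
    po2_to_intensity,
    ratio_to_ph,
)
from acidhif.simulate import FluxSimSpec, integrate_forward, make_flux_timecourse
from acidhif.simulate.flux import FluxParameterError


class TestPhProbe:
    def test_midpoint_ratio_gives_pka(self):
        cal = PhProbeCalibration(pka=7.3, ratio_min=0.2, ratio_max=5.0)
        assert ratio_to_ph((0.2 + 5.0) / 2, cal) == pytest.approx(7.3)

    def test_round_trip_identity(self):
        cal = PhProbeCalibration()
        ph = np.linspace(5.5, 8.5, 101)
        assert np.allclose(ratio_to_ph(ph_to_ratio(ph, cal), cal), ph, atol=1e-9)

    def test_monotone_in_ratio(self):
        cal = PhProbeCalibration()
        r = np.linspace(cal.ratio_min + 0.01, cal.ratio_max - 0.01, 500)
        assert np.all(np.diff(ratio_to_ph(r, cal)) > 0)

    def test_saturated_ratio_clipped_with_warning(self):
        cal = PhProbeCalibration()
        with pytest.warns(ProbeSaturationWarning):
            out = ratio_to_ph(cal.ratio_max + 1.0, cal)
        assert np.isfinite(out)


class TestO2Probe:
    def test_zero_o2_at_full_intensity(self):
        cal = O2ProbeCalibration()
        assert intensity_to_po2(cal.intensity_at_zero_o2, cal) == pytest.approx(0.0)

    def test_algebraic_inversion_at_160(self):
        cal = O2ProbeCalibration(intensity_at_zero_o2=1000.0, stern_volmer_constant=0.004)
        i = 1000.0 / (1.0 + 0.004 * 160.0)
        assert intensity_to_po2(i, cal) == pytest.approx(160.0)

    def test_monotone_decreasing_in_intensity(self):
        cal = O2ProbeCalibration()
        i = np.linspace(10.0, cal.intensity_at_zero_o2, 300)
        assert np.all(np.diff(intensity_to_po2(i, cal)) <= 0)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            intensity_to_po2(0.0, O2ProbeCalibration())


class TestCumulativeFluxes:
    CAL = CalibrationParams()

    def test_constant_ph_gives_zero_series(self):
        assert np.allclose(cumulative_acid(np.full(10, 7.4), self.CAL), 0.0)

    def test_hand_arithmetic_40_nmol(self):
        # dpH = 0.1 at beta = 2 mmol/L/pH in 200 uL -> 40 nmol
        out = cumulative_acid(np.array([7.4, 7.3]), self.CAL)
        assert out[-1] == pytest.approx(40e-9, rel=1e-9)

    def test_o2_hand_arithmetic(self):
        # dpO2 = 20 mmHg at alpha = 1.3 umol/L/mmHg in 200 uL -> 5.2 nmol
        out = cumulative_o2(np.array([160.0, 140.0]), self.CAL)
        assert out[-1] == pytest.approx(1.3e-6 * 200e-6 * 20.0, rel=1e-9)

    def test_ingress_correction_raises_estimate_below_atmosphere(self):
        cal = CalibrationParams(oil_ingress_rate=0.05)
        t = np.linspace(0, 10, 50)
        po2 = 160.0 - 8.0 * t  # below atmosphere throughout
        naive = cumulative_o2(po2, CalibrationParams(), time=t)
        corrected = cumulative_o2(po2, cal, time=t)
        assert np.all(corrected[1:] > naive[1:])

    def test_outputs_scale_with_volume_and_buffering(self):
        ph = np.array([7.4, 7.2, 7.0])
        base = cumulative_acid(ph, CalibrationParams())
        double_v = cumulative_acid(ph, CalibrationParams(volume=400e-6))
        double_b = cumulative_acid(ph, CalibrationParams(buffering_capacity=4e-3))
        assert np.allclose(double_v, 2 * base) and np.allclose(double_b, 2 * base)

    def test_normalization_to_live_cell_signal(self):
        ph = np.array([7.4, 7.3])
        assert cumulative_acid(ph, self.CAL, live_cell_signal=2.0)[-1] == pytest.approx(20e-9)


class TestForwardModel:
    def test_no_metabolism_constant_state(self):
        spec = FluxSimSpec(fermentative_rate=0.0, respiratory_rate=0.0, noise_sd=0.0)
        _, truth = make_flux_timecourse(spec)
        assert np.allclose(truth.flux.ph, spec.ph0)
        assert np.allclose(truth.flux.po2, spec.po2_0)

    def test_constant_fermentation_matches_closed_form(self):
        spec = FluxSimSpec(respiratory_rate=0.0, noise_sd=0.0)
        _, truth = make_flux_timecourse(spec)
        pred = spec.ph0 - spec.fermentative_rate * truth.flux.time / (
            spec.buffering_capacity * spec.volume
        )
        assert np.allclose(truth.flux.ph, pred, atol=1e-12)

    def test_concurrent_fluxes_monotone_non_increasing(self):
        _, truth = make_flux_timecourse(FluxSimSpec(noise_sd=0.0))
        assert np.all(np.diff(truth.flux.ph) <= 0)
        assert np.all(np.diff(truth.flux.po2) <= 0)

    def test_step_halving_changes_nothing_beyond_point1_percent(self):
        spec = FluxSimSpec(glycolysis_ph_block=(6.6, 2.0), oil_ingress_rate=0.02)
        t1 = integrate_forward(spec, substeps=1)
        t2 = integrate_forward(spec, substeps=2)
        assert np.allclose(t1.flux.ph, t2.flux.ph, rtol=1e-3, atol=1e-6)
        assert np.allclose(t1.flux.cumulative_acid, t2.flux.cumulative_acid, rtol=1e-3)

    def test_zero_buffering_with_acid_rejected(self):
        with pytest.raises(FluxParameterError):
            FluxSimSpec(buffering_capacity=0.0)

    def test_lactate_equals_acid_without_volatile_fraction(self):
        _, truth = make_flux_timecourse(FluxSimSpec(co2_acid_fraction=0.0, noise_sd=0.0))
        assert np.allclose(truth.cumulative_lactate, truth.flux.cumulative_acid)

    def test_glycolysis_block_attenuates_acidification(self):
        free = integrate_forward(FluxSimSpec())
        blocked = integrate_forward(FluxSimSpec(glycolysis_ph_block=(7.2, 2.0)))
        assert blocked.flux.cumulative_acid[-1] < free.flux.cumulative_acid[-1]

    def test_seed_determinism(self):
        r1, _ = make_flux_timecourse(FluxSimSpec(seed=4))
        r2, _ = make_flux_timecourse(FluxSimSpec(seed=4))
        assert np.array_equal(r1.ph_probe_ratio, r2.ph_probe_ratio)
        assert np.array_equal(r1.o2_probe_intensity, r2.o2_probe_intensity)


class TestRecoveryFromGenerator:
    def test_noise_free_round_trip_recovers_truth_fluxes(self):
        spec = FluxSimSpec(noise_sd=0.0, oil_ingress_rate=0.02)
        raw, truth = make_flux_timecourse(spec)
        flux = calibrate_timecourse(raw, spec.calibration())
        assert np.allclose(flux.ph, truth.flux.ph, atol=1e-9)
        assert np.allclose(flux.cumulative_acid, truth.flux.cumulative_acid, rtol=1e-6, atol=1e-12)
        # ingress-corrected O2 consumption matches the integrated respiratory truth
        assert np.allclose(flux.cumulative_o2, truth.flux.cumulative_o2, rtol=2e-3, atol=1e-12)

    def test_noisy_recovery_within_tolerance(self):
        spec = FluxSimSpec(seed=2)
        raw, truth = make_flux_timecourse(spec)
        flux = calibrate_timecourse(raw, spec.calibration())
        final_truth = truth.flux.cumulative_acid[-1]
        assert flux.cumulative_acid[-1] == pytest.approx(final_truth, rel=0.05)


class TestLactateSlope:
    def test_identity_pairs_give_unit_slope(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = lactate_slope(x, x)
        assert res.slope_through_origin == pytest.approx(1.0)
        assert res.pearson_r == pytest.approx(1.0)

    def test_volatile_acid_fraction_halves_slope(self):
        xs, ys = [], []
        for seed in range(1, 7):
            spec = FluxSimSpec(co2_acid_fraction=0.5, seed=seed)
            raw, truth = make_flux_timecourse(spec)
            flux = calibrate_timecourse(raw, spec.calibration())
            for t in (8.0, 17.0):
                idx = int(np.argmin(np.abs(flux.time - t)))
                xs.append(flux.cumulative_acid[idx])
                ys.append(truth.lactate_at(t))
        res = lactate_slope(np.array(xs), np.array(ys))
        assert res.slope_through_origin == pytest.approx(0.5, abs=0.05)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            lactate_slope(np.ones(4), np.array([1.0, 2.0, 3.0, 4.0]))
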