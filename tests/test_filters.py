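"""Filter design, discretization, response evaluation, fitting, application."""

import numpy as np
import pytest

from actcounts.filters import (
    AnalogBandpass,
    DigitalBandpass,
    HALF_POWER_DB,
    apply_filter,
    default_fixed_filter,
    design_butterworth_bandpass,
    discretize,
    filter_from_json,
    filter_to_json,
    fit_bandpass_to_reference,
    frequency_response,
    half_power_points,
    packaged_reference_response,
)


def analog_mag_db_oracle(filt, f_hz):
    """Brute-force |H(j2πf)| by direct polynomial evaluation."""
    out = []
    for f in np.atleast_1d(f_hz):
        s = 1j * 2 * np.pi * f
        num = sum(c * s**k for k, c in enumerate(reversed(filt.num)))
        den = sum(c * s**k for k, c in enumerate(reversed(filt.den)))
        out.append(20 * np.log10(abs(num / den)))
    return np.array(out)


def digital_mag_db_oracle(filt, f_hz):
    """Brute-force unit-circle evaluation of the discrete transfer function."""
    out = []
    for f in np.atleast_1d(f_hz):
        z = np.exp(-1j * 2 * np.pi * f / filt.fs)
        num = sum(c * z**k for k, c in enumerate(filt.b))
        den = sum(c * z**k for k, c in enumerate(filt.a))
        out.append(20 * np.log10(abs(num / den)))
    return np.array(out)


class TestButterworthDesign:
    def test_half_power_at_band_edges(self, modifiable_analog):
        mags = frequency_response(modifiable_analog, [0.305, 1.615]).magnitude_db
        assert np.allclose(mags, HALF_POWER_DB, atol=0.01)

    def test_peak_at_geometric_center(self):
        filt = design_butterworth_bandpass(1.0, 2.0, 2)
        mag = frequency_response(filt, [np.sqrt(2.0)]).magnitude_db[0]
        assert abs(mag) < 0.01

    def test_half_power_points_locator(self, modifiable_analog):
        lo, hi = half_power_points(modifiable_analog)
        assert lo == pytest.approx(0.305, rel=1e-6)
        assert hi == pytest.approx(1.615, rel=1e-6)

    @pytest.mark.parametrize(
        "low,high,order",
        [(0.0, 1.0, 4), (-0.1, 1.0, 4), (2.0, 1.0, 4), (0.3, 1.6, 3), (0.3, 1.6, 0)],
    )
    def test_invalid_arguments(self, low, high, order):
        with pytest.raises(ValueError):
            design_butterworth_bandpass(low, high, order)

    @pytest.mark.parametrize("order", [2, 4, 8])
    def test_stability_and_bandpass_shape(self, order):
        filt = design_butterworth_bandpass(0.305, 1.615, order)
        assert np.all(np.roots(filt.den).real < 0)
        # band-pass shape: gain vanishes toward DC and toward high frequency
        mags = frequency_response(filt, [1e-4, 1e4]).magnitude_db
        assert np.all(mags < -40)

    def test_decade_above_matches_polynomial_oracle(self):
        filt = design_butterworth_bandpass(0.305, 1.615, 4)
        got = frequency_response(filt, [16.15]).magnitude_db
        assert got == pytest.approx(analog_mag_db_oracle(filt, [16.15]), abs=1e-9)


class TestFrequencyResponse:
    def test_analog_grid_matches_oracle(self, modifiable_analog):
        grid = np.geomspace(0.01, 10, 1000)
        got = frequency_response(modifiable_analog, grid).magnitude_db
        assert np.allclose(got, analog_mag_db_oracle(modifiable_analog, grid), atol=1e-8)

    def test_digital_grid_matches_unit_circle_oracle(self, modifiable_100):
        grid = np.geomspace(0.05, 5, 200)
        got = frequency_response(modifiable_100, grid).magnitude_db
        assert np.allclose(got, digital_mag_db_oracle(modifiable_100, grid), atol=1e-8)

    def test_rejects_nyquist_and_bad_grids(self, modifiable_30):
        with pytest.raises(ValueError):
            frequency_response(modifiable_30, [1.0, 15.0])
        with pytest.raises(ValueError):
            frequency_response(modifiable_30, [2.0, 1.0])
        with pytest.raises(ValueError):
            frequency_response(modifiable_30, [-1.0])


class TestDiscretize:
    def test_dc_gain_is_zero(self, modifiable_30):
        dc = abs(np.sum(modifiable_30.b) / np.sum(modifiable_30.a))
        assert dc < 1e-9

    @pytest.mark.parametrize("fs", [30.0, 100.0])
    def test_preserves_half_power_edges(self, modifiable_analog, fs):
        dig = discretize(modifiable_analog, fs)
        from scipy.optimize import brentq

        def mag(f):
            return frequency_response(dig, [f]).magnitude_db[0] - HALF_POWER_DB

        lo = brentq(mag, 0.1, 0.7)
        hi = brentq(mag, 0.8, 3.0)
        assert lo == pytest.approx(0.305, rel=0.01)
        assert hi == pytest.approx(1.615, rel=0.01)

    @pytest.mark.parametrize("fs", [30.0, 50.0, 100.0])
    def test_analog_digital_agreement_over_passband(self, modifiable_analog, fs):
        dig = discretize(modifiable_analog, fs)
        grid = np.geomspace(0.305, 1.615, 300)
        a = frequency_response(modifiable_analog, grid).magnitude_db
        d = frequency_response(dig, grid).magnitude_db
        assert np.max(np.abs(a - d)) < 0.1

    def test_analog_digital_agreement_wideband_at_100hz(self, modifiable_analog):
        # bilinear warping on the skirts shrinks with fs; at 100 Hz the
        # agreement extends across 0.05-3 Hz
        dig = discretize(modifiable_analog, 100.0)
        grid = np.geomspace(0.05, 3.0, 300)
        a = frequency_response(modifiable_analog, grid).magnitude_db
        d = frequency_response(dig, grid).magnitude_db
        assert np.max(np.abs(a - d)) < 0.1

    def test_rejects_low_sampling_rate(self, modifiable_analog):
        with pytest.raises(ValueError, match="too low"):
            discretize(modifiable_analog, 10.0)

    def test_digital_poles_inside_unit_circle(self, modifiable_30):
        assert np.all(np.abs(np.roots(modifiable_30.a)) < 1.0)


class TestApplyFilter:
    def test_zero_in_zero_out(self, modifiable_100):
        y = apply_filter(np.zeros(500), modifiable_100)
        assert y.shape == (500,)
        assert np.all(y == 0)

    def test_dc_rejection_settles(self, modifiable_30):
        x = np.ones(int(120 * 30))
        y = apply_filter(x, modifiable_30)
        assert np.max(np.abs(y[int(60 * 30):])) < 1e-6

    def test_steady_state_sinusoid_gain(self, modifiable_100):
        fs, f0 = 100.0, 1.0
        t = np.arange(int(120 * fs)) / fs
        y = apply_filter(np.sin(2 * np.pi * f0 * t), modifiable_100)
        amp = np.max(np.abs(y[int(60 * fs):]))
        expect = 10 ** (frequency_response(modifiable_100, [f0]).magnitude_db[0] / 20)
        assert amp == pytest.approx(expect, rel=0.005)

    def test_sampling_rate_mismatch(self, modifiable_100):
        with pytest.raises(ValueError, match="Hz"):
            apply_filter(np.zeros(10), modifiable_100, fs=30.0)


class TestFit:
    def test_self_recovery_of_modifiable_filter(self, modifiable_reference):
        res = fit_bandpass_to_reference(modifiable_reference, order=4, seed=11)
        assert res.objective < 0.01
        lo, hi = half_power_points(res.filter)
        assert lo == pytest.approx(0.305, rel=0.01)
        assert hi == pytest.approx(1.615, rel=0.01)

    def test_deterministic_for_fixed_seed(self, modifiable_reference):
        r1 = fit_bandpass_to_reference(modifiable_reference, order=4, seed=3)
        r2 = fit_bandpass_to_reference(modifiable_reference, order=4, seed=3)
        assert np.array_equal(r1.filter.num, r2.filter.num)
        assert np.array_equal(r1.filter.den, r2.filter.den)
        assert r1.objective == r2.objective

    def test_order8_target_recovered_through_discretization(self, log_grid):
        # the fit target is tabulated as a 30 Hz discrete response (the form a
        # measured count-filter characterization takes); the fitted analog
        # filter's own 30 Hz discretization must reproduce it
        target = discretize(default_fixed_filter(), 30.0)
        ref = frequency_response(target, log_grid)
        res = fit_bandpass_to_reference(ref, order=8, seed=5)
        dig = frequency_response(discretize(res.filter, 30.0), log_grid)
        band = (log_grid >= 0.25) & (log_grid <= 2.5)
        assert np.max(np.abs(dig.magnitude_db[band] - ref.magnitude_db[band])) < 0.5

    def test_rejects_sparse_or_narrow_reference(self, modifiable_analog):
        from actcounts.filters import FrequencyResponse

        f = np.geomspace(0.2, 5, 100)  # does not reach down to 0.1 Hz
        ref = frequency_response(modifiable_analog, f)
        with pytest.raises(ValueError, match="0.1, 5"):
            fit_bandpass_to_reference(ref, order=4, seed=0)
        f = np.geomspace(0.05, 6, 20)  # too few points
        ref = frequency_response(modifiable_analog, f)
        with pytest.raises(ValueError):
            fit_bandpass_to_reference(ref, order=4, seed=0)


class TestPackagedDefaults:
    def test_fixed_filter_is_stable_order8_bandpass(self):
        filt = default_fixed_filter()
        assert filt.order == 8
        assert np.all(np.roots(filt.den).real < 0)
        mags = frequency_response(filt, [1e-4, 1e4]).magnitude_db
        assert np.all(mags < -40)

    def test_fixed_filter_matches_packaged_reference(self):
        ref = packaged_reference_response()
        filt = default_fixed_filter()
        band = (ref.freqs_hz >= 0.25) & (ref.freqs_hz <= 2.5)
        got = frequency_response(filt, ref.freqs_hz[band]).magnitude_db
        assert np.max(np.abs(got - ref.magnitude_db[band])) < 0.5

    def test_reference_table_covers_fit_domain(self):
        ref = packaged_reference_response()
        assert len(ref) >= 50
        assert ref.freqs_hz[0] <= 0.1 and ref.freqs_hz[-1] >= 5.0


class TestJsonInterchange:
    def test_analog_roundtrip(self, modifiable_analog):
        doc = filter_to_json(modifiable_analog)
        assert doc["kind"] == "analog" and doc["fs"] is None
        back = filter_from_json(doc)
        assert np.allclose(back.num, modifiable_analog.num)
        assert np.allclose(back.den, modifiable_analog.den)
        assert back.nominal_band == modifiable_analog.nominal_band

    def test_digital_roundtrip(self, modifiable_30):
        back = filter_from_json(filter_to_json(modifiable_30))
        assert isinstance(back, DigitalBandpass)
        assert back.fs == 30.0
        assert np.allclose(back.b, modifiable_30.b)
        assert np.allclose(back.a, modifiable_30.a)


class TestStructuralValidation:
    def test_rejects_unstable_analog(self):
        with pytest.raises(ValueError, match="unstable"):
            AnalogBandpass([1.0, 0.0], [1.0, -1.0, 1.0])  # pole in RHP

    def test_rejects_nonzero_dc_gain(self):
        with pytest.raises(ValueError, match="DC"):
            AnalogBandpass([1.0, 1.0], [1.0, 1.0, 1.0])

    def test_rejects_odd_order(self):
        with pytest.raises(ValueError, match="even"):
            AnalogBandpass([1.0, 0.0], [1.0, 2.0, 2.0, 1.0])

    def test_rejects_unstable_digital(self):
        with pytest.raises(ValueError, match="unstable"):
            DigitalBandpass([1.0, 0.0], [1.0, -1.5], fs=30.0)
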