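"""Monoexponential fitting, cDWI synthesis and network-input scaling."""

import numpy as np
import pytest

from spinenorm.dwi_model import (
    ADC_SCALE, compute_cdwi, fit_monoexponential, fit_study,
    scale_network_input, study_log_s0_max,
)
from spinenorm.types import ParametricMaps, StationVolume


def station_from_signal(signal, b_values, spacing=(5.0, 1.6, 1.6)):
    signal = np.asarray(signal, dtype=float)
    return StationVolume(signal=signal, b_values=b_values, spacing=spacing,
                         slice_positions=5.0 * np.arange(signal.shape[1]))


def make_station(s0, adc, b_values=(50.0, 600.0, 900.0)):
    """Noiseless station from given (slice,row,col) S0/ADC maps."""
    b = np.asarray(b_values)
    signal = s0[None] * np.exp(-b[:, None, None, None] * adc[None])
    return station_from_signal(signal, tuple(b_values))


class TestFitMonoexponential:
    def test_flat_signal_gives_zero_adc(self):
        c = 123.0
        st = station_from_signal(np.full((3, 2, 4, 4), c), (50.0, 600.0, 900.0))
        maps = fit_monoexponential(st)
        assert np.allclose(maps.adc, 0.0, atol=1e-15)
        assert np.allclose(maps.s0, c)

    def test_exact_recovery_in_model_class(self):
        s0 = np.full((2, 4, 4), 500.0)
        adc = np.full((2, 4, 4), 1.2e-3)
        maps = fit_monoexponential(make_station(s0, adc))
        assert np.allclose(maps.adc, 1.2e-3, rtol=1e-12)
        assert np.allclose(maps.s0, 500.0, rtol=1e-12)

    def test_two_point_closed_form_matches_grid_search_oracle(self):
        # S(50)=900, S(900)=380: the OLS solution on two points equals the
        # exact interpolant; cross-check by a dense grid search over ADC
        # minimising the squared log-residual.
        s1, s2, b1, b2 = 900.0, 380.0, 50.0, 900.0
        signal = np.zeros((2, 2, 1, 1))
        signal[0], signal[1] = s1, s2
        maps = fit_monoexponential(station_from_signal(signal, (b1, b2)))

        adc_grid = np.linspace(-1e-3, 4e-3, 400001)
        # for fixed ADC the optimal log-S0 is the mean of ln S + b*ADC
        ln_s = np.log([s1, s2])
        b = np.array([b1, b2])
        ln_s0 = (ln_s + b * adc_grid[:, None]).mean(axis=1)
        resid = ((ln_s - (ln_s0[:, None] - b * adc_grid[:, None])) ** 2).sum(axis=1)
        adc_best = adc_grid[np.argmin(resid)]

        expected = np.log(s1 / s2) / (b2 - b1)
        assert maps.adc[0, 0, 0] == pytest.approx(expected, rel=1e-12)
        assert maps.adc[0, 0, 0] == pytest.approx(adc_best, abs=2e-8)
        assert maps.s0[0, 0, 0] == pytest.approx(s1 * np.exp(b1 * expected), rel=1e-12)

    def test_negative_adc_retained(self):
        signal = np.zeros((2, 2, 1, 1))
        signal[0], signal[1] = 100.0, 150.0   # rising signal -> negative ADC
        maps = fit_monoexponential(station_from_signal(signal, (50.0, 900.0)))
        assert maps.adc[0, 0, 0] < 0

    def test_single_b_value_rejected(self):
        st = station_from_signal(np.full((2, 2, 2, 2), 10.0), (900.0, 900.0))
        with pytest.raises(ValueError, match="distinct b-values"):
            fit_monoexponential(st)

    def test_all_zero_voxel_floored(self):
        signal = np.full((2, 2, 2, 2), 100.0)
        signal[:, 0, 0, 0] = 0.0
        maps = fit_monoexponential(station_from_signal(signal, (50.0, 900.0)))
        assert maps.adc[0, 0, 0] == 0.0
        assert maps.s0[0, 0, 0] > 0

    def test_scale_equivariance(self, rng):
        s0 = rng.uniform(100, 1000, (2, 3, 3))
        adc = rng.uniform(0.2e-3, 3e-3, (2, 3, 3))
        st = make_station(s0, adc)
        st2 = station_from_signal(st.signal * 7.5, st.b_values)
        m1, m2 = fit_monoexponential(st), fit_monoexponential(st2)
        assert np.allclose(m2.adc, m1.adc, atol=1e-12)
        assert np.allclose(m2.s0, 7.5 * m1.s0, rtol=1e-10)


class TestComputeCdwi:
    def test_b_zero_identity(self, rng):
        maps = ParametricMaps(adc=rng.normal(1e-3, 5e-4, (2, 3, 3)),
                              s0=rng.uniform(1, 100, (2, 3, 3)),
                              spacing=(5, 1.6, 1.6), slice_positions=np.arange(2.0))
        assert np.array_equal(compute_cdwi(maps, 0.0), maps.s0)

    def test_exponential_value(self):
        maps = ParametricMaps(adc=np.full((1, 1, 1), 1.0e-3),
                              s0=np.full((1, 1, 1), 1000.0),
                              spacing=(5, 1.6, 1.6), slice_positions=np.zeros(1))
        out = compute_cdwi(maps, 900.0)
        assert out[0, 0, 0] == pytest.approx(1000.0 * np.exp(-0.9), rel=1e-12)

    def test_negative_adc_clamped(self):
        maps = ParametricMaps(adc=np.full((1, 1, 1), -0.5e-3),
                              s0=np.full((1, 1, 1), 200.0),
                              spacing=(5, 1.6, 1.6), slice_positions=np.zeros(1))
        # oracle: max(ADC, 0) then the exponential
        assert compute_cdwi(maps, 900.0)[0, 0, 0] == pytest.approx(200.0)

    def test_monotone_decreasing_in_b(self, rng):
        maps = ParametricMaps(adc=rng.uniform(1e-4, 3e-3, (1, 4, 4)),
                              s0=rng.uniform(10, 100, (1, 4, 4)),
                              spacing=(5, 1.6, 1.6), slice_positions=np.zeros(1))
        vols = [compute_cdwi(maps, b) for b in (0, 300, 600, 900)]
        for lo, hi in zip(vols, vols[1:]):
            assert np.all(hi < lo)

    def test_output_bounded_by_s0(self, rng):
        maps = ParametricMaps(adc=rng.normal(1e-3, 1e-3, (2, 4, 4)),
                              s0=rng.uniform(1, 100, (2, 4, 4)),
                              spacing=(5, 1.6, 1.6), slice_positions=np.arange(2.0))
        out = compute_cdwi(maps, 900.0)
        assert np.all(out >= 0) and np.all(out <= maps.s0 + 1e-12)

    def test_roundtrip_reproduces_phantom_signal(self, noiseless_phantom):
        # exact round trip wherever the signal sits above the log floor
        study, _ = noiseless_phantom
        for st in study.stations:
            maps = fit_monoexponential(st)
            above_floor = np.all(st.signal > 1e-3, axis=0)
            for i, b in enumerate(st.b_values):
                rel = (np.abs(compute_cdwi(maps, b) - st.signal[i])
                       / (st.signal[i] + 1e-12))[above_floor]
                assert rel.max() < 1e-6


class TestScaleNetworkInput:
    def _maps(self, adc_val, s0_val, shape=(2, 8, 8)):
        return ParametricMaps(adc=np.full(shape, adc_val), s0=np.full(shape, s0_val),
                              spacing=(5, 1.6, 1.6),
                              slice_positions=5.0 * np.arange(shape[0]))

    @pytest.mark.parametrize("adc,expected", [
        (3.5e-3, 1.0),
        (0.0, 0.0),
        (-0.5e-3, -0.5e-3 / 3.5e-3),   # -0.142857...
    ])
    def test_adc_channel_is_fixed_division(self, adc, expected):
        ni = scale_network_input(self._maps(adc, 50.0), out_matrix=8, out_mm=1.6)
        assert ni.scaled_adc[0, 4, 4] == pytest.approx(expected, rel=1e-12)

    def test_constant_s0_channel_all_ones(self):
        ni = scale_network_input(self._maps(1e-3, 42.0), out_matrix=8, out_mm=1.6)
        assert np.allclose(ni.scaled_s0, 1.0)

    def test_s0_max_is_one_over_scope(self, rng):
        maps = ParametricMaps(adc=np.full((2, 8, 8), 1e-3),
                              s0=rng.uniform(5, 500, (2, 8, 8)),
                              spacing=(5, 1.6, 1.6), slice_positions=np.arange(2.0))
        ni = scale_network_input(maps, out_matrix=8, out_mm=1.6)
        assert ni.scaled_s0.max() == pytest.approx(1.0)

    def test_degenerate_s0_gives_zero_channel(self, caplog):
        ni = scale_network_input(self._maps(1e-3, 0.5), out_matrix=8, out_mm=1.6)
        assert np.all(ni.scaled_s0 == 0.0)

    def test_resample_doubles_matrix_at_half_resolution(self):
        maps = self._maps(1e-3, 50.0, shape=(1, 8, 8))
        ni = scale_network_input(maps, out_matrix=10, out_mm=0.8)
        assert ni.scaled_s0.shape == (1, 10, 10)
        # centre retains the constant value, border is zero padding
        assert ni.scaled_s0[0, 5, 5] == pytest.approx(1.0)

    def test_pooled_study_max(self, noiseless_phantom):
        study, _ = noiseless_phantom
        maps = fit_study(study)
        mx = study_log_s0_max(maps)
        scaled = [scale_network_input(m, out_matrix=32, out_mm=1.6, log_s0_max=mx)
                  for m in maps]
        assert max(ni.scaled_s0.max() for ni in scaled) == pytest.approx(1.0)
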