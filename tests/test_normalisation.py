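"""Station composition, CDF-matched harmonisation and canal standardisation."""

import numpy as np
import pytest

from spinenorm.dwi_model import compute_cdwi, fit_study
from spinenorm.normalisation import (
    compose_stations, harmonise_stations, mip, normalise_to_canal,
    station_scale_factor,
)
from spinenorm.phantom import PhantomSpec, generate_phantom
from spinenorm.types import DWIStudy, StationVolume


def two_station_study(rng, n_slices=6, m=8):
    def station(z0):
        sig = rng.uniform(1, 100, (2, n_slices, m, m))
        return StationVolume(signal=sig, b_values=(50.0, 900.0),
                             spacing=(5.0, 1.6, 1.6),
                             slice_positions=z0 + 5.0 * np.arange(n_slices))
    return DWIStudy(stations=[station(0.0), station(5.0 * n_slices)])


class TestComposeStations:
    def test_concatenation_with_boundary(self, rng):
        study = two_station_study(rng)
        vols = [rng.uniform(0, 1, (6, 8, 8)) for _ in range(2)]
        composed, boundaries, positions = compose_stations(study, vols)
        assert composed.shape == (12, 8, 8)
        assert boundaries == [6]
        assert np.array_equal(composed[:6], vols[0])
        assert np.all(np.diff(positions) > 0)

    def test_single_station_no_boundaries(self, rng):
        study = DWIStudy(stations=[two_station_study(rng).stations[0]])
        vols = [rng.uniform(0, 1, (6, 8, 8))]
        _, boundaries, _ = compose_stations(study, vols)
        assert boundaries == []

    def test_overlap_taken_from_superior_station(self, rng):
        st1 = StationVolume(signal=rng.uniform(1, 2, (2, 4, 8, 8)),
                            b_values=(50.0, 900.0), spacing=(5.0, 1.6, 1.6),
                            slice_positions=np.array([0.0, 5.0, 10.0, 15.0]))
        st2 = StationVolume(signal=rng.uniform(1, 2, (2, 4, 8, 8)),
                            b_values=(50.0, 900.0), spacing=(5.0, 1.6, 1.6),
                            slice_positions=np.array([15.0, 20.0, 25.0, 30.0]))
        study = DWIStudy(stations=[st1, st2])
        v1 = np.full((4, 8, 8), 1.0)
        v2 = np.full((4, 8, 8), 2.0)
        composed, boundaries, positions = compose_stations(study, [v1, v2])
        assert composed.shape[0] == 7           # shared slice merged once
        assert composed[3, 0, 0] == 1.0          # superior station wins at 15mm

    def test_inconsistent_geometry_rejected(self, rng):
        study = two_station_study(rng)
        with pytest.raises(ValueError, match="geometry"):
            compose_stations(study, [np.zeros((6, 8, 8)), np.zeros((6, 4, 4))])


class TestStationScaleFactor:
    def test_identical_distributions_give_unity(self, rng):
        s = rng.uniform(10, 100, (3, 16, 16))
        assert station_scale_factor(s, s.copy()) == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("gain", [1.3, 0.5])
    def test_recovers_inverse_gain(self, rng, gain):
        upper = rng.uniform(10, 100, (3, 16, 16))
        lower = upper * gain
        # dense grid-search oracle over s
        def objective(s):
            u = np.sort(upper[upper > 0].ravel())
            l = np.sort((lower * s)[(lower * s) > 0].ravel())
            grid = np.linspace(min(u[0], l[0]), max(u[-1], l[-1]), 256)
            Fu = np.searchsorted(u, grid, side="right") / u.size
            Fl = np.searchsorted(l, grid, side="right") / l.size
            return np.sum((Fu - Fl) ** 2)
        ss = np.linspace(0.5 / gain, 1.5 / gain, 2001)
        oracle = ss[np.argmin([objective(s) for s in ss])]
        got = station_scale_factor(upper, lower)
        assert got == pytest.approx(1.0 / gain, rel=0.02)
        assert got == pytest.approx(oracle, rel=0.02)

    def test_all_zero_side_returns_unity(self, rng):
        upper = np.zeros((3, 8, 8))
        lower = rng.uniform(1, 2, (3, 8, 8))
        assert station_scale_factor(upper, lower) == 1.0


class TestHarmoniseStations:
    def test_unity_factors_leave_volume_unchanged(self, rng):
        # identical slice repeated: both boundary sides share one distribution
        vol = np.repeat(rng.uniform(10, 100, (1, 8, 8)), 12, axis=0)
        out, factors = harmonise_stations(vol, [4, 8])
        assert np.allclose(out, vol, rtol=1e-3)
        assert factors[0] == 1.0
        assert all(f == pytest.approx(1.0, abs=1e-3) for f in factors)

    def test_two_stations_lower_scaled_by_factor(self, rng):
        base = np.repeat(rng.uniform(10, 100, (1, 8, 8)), 4, axis=0)
        vol = np.concatenate([base, base * 1.3])
        out, factors = harmonise_stations(vol, [4])
        assert len(factors) == 2
        assert np.allclose(out[4:], vol[4:] * factors[1], rtol=1e-12)
        assert factors[1] == pytest.approx(1 / 1.3, rel=0.005)

    def test_gain_recovery_on_phantom(self, gained_phantom):
        study, truth = gained_phantom
        maps = fit_study(study)
        cdwi = [compute_cdwi(m, 900.0) for m in maps]
        composed, boundaries, _ = compose_stations(study, cdwi)
        out, factors = harmonise_stations(composed, boundaries)
        for f, g in zip(factors, truth.gains):
            assert abs(f * g - 1.0) < 0.02
        # harmonised station medians agree with the gain-free truth within 2%
        spec_free = np.stack([compute_cdwi(m, 900.0) / g
                              for m, g in zip(maps, truth.gains)])
        for k, b in enumerate([0] + boundaries):
            hi = boundaries[k] if k < len(boundaries) else composed.shape[0]
            sl = out[b:hi]
            ref = spec_free[k]
            assert np.median(sl[sl > 1]) == pytest.approx(
                np.median(ref[ref > 1]), rel=0.02)

    def test_idempotent_second_pass(self, gained_phantom):
        study, _ = gained_phantom
        maps = fit_study(study)
        cdwi = [compute_cdwi(m, 900.0) for m in maps]
        composed, boundaries, _ = compose_stations(study, cdwi)
        once, _ = harmonise_stations(composed, boundaries)
        _, second = harmonise_stations(once, boundaries)
        assert all(abs(f - 1.0) < 1e-3 for f in second)

    def test_within_station_contrast_preserved(self, gained_phantom):
        study, _ = gained_phantom
        maps = fit_study(study)
        cdwi = [compute_cdwi(m, 900.0) for m in maps]
        composed, boundaries, _ = compose_stations(study, cdwi)
        out, _ = harmonise_stations(composed, boundaries)
        sl = composed[2]
        ratio_before = sl[10, 10] / sl[16, 16]
        ratio_after = out[2][10, 10] / out[2][16, 16]
        assert ratio_after == pytest.approx(ratio_before, rel=1e-9)


class TestNormaliseToCanal:
    def test_constant_canal_maps_to_one(self):
        vol = np.full((4, 6, 6), 7.0)
        mask = np.zeros_like(vol, dtype=bool)
        mask[1:3, 2:4, 2:4] = True
        res = normalise_to_canal(vol, mask)
        assert np.allclose(res.normalised[mask], 1.0)

    def test_percentile_matches_sorting_oracle(self):
        vol = np.arange(1.0, 101.0).reshape(4, 5, 5)
        mask = np.ones_like(vol, dtype=bool)
        res = normalise_to_canal(vol, mask)
        assert res.canal_reference == pytest.approx(90.1)   # linear interpolation
        assert res.normalised.flat[89] * res.canal_reference == pytest.approx(90.0)

    def test_ninetieth_percentile_contract(self, rng):
        vol = rng.uniform(0, 50, (6, 8, 8))
        mask = rng.random((6, 8, 8)) < 0.3
        res = normalise_to_canal(vol, mask)
        assert np.percentile(res.normalised[mask], 90) == pytest.approx(1.0, abs=1e-6)

    def test_global_scale_invariance(self, rng):
        vol = rng.uniform(0, 50, (6, 8, 8))
        mask = rng.random((6, 8, 8)) < 0.3
        a = normalise_to_canal(vol, mask)
        b = normalise_to_canal(vol * 2.0, mask)
        assert np.allclose(a.normalised, b.normalised)

    def test_empty_canal_rejected(self):
        with pytest.raises(ValueError, match="empty canal"):
            normalise_to_canal(np.ones((2, 2, 2)), np.zeros((2, 2, 2), dtype=bool))


class TestMip:
    def test_all_zero(self):
        assert np.all(mip(np.zeros((3, 4, 5)), "coronal") == 0)

    def test_single_bright_voxel(self):
        vol = np.zeros((3, 4, 5))
        vol[1, 2, 3] = 9.0
        cor = mip(vol, "coronal")
        sag = mip(vol, "sagittal")
        assert cor.shape == (3, 5) and cor[1, 3] == 9.0
        assert sag.shape == (3, 4) and sag[1, 2] == 9.0

    def test_max_distributivity(self, rng):
        a = rng.random((3, 4, 5))
        b = rng.random((3, 4, 5))
        for axis in ("coronal", "sagittal"):
            assert np.array_equal(mip(np.maximum(a, b), axis),
                                  np.maximum(mip(a, axis), mip(b, axis)))
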