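"""Registration, baseline subtraction and concentration conversion."""

import numpy as np
import pytest
from scipy import ndimage

from issmri import (
    AcquisitionParams,
    ImageSeries,
    VoxelGrid,
    concentration_to_signal,
    make_signal_law,
    register_series,
    signal_to_concentration,
    simulate_concentration_field,
    subtract_baseline,
)
from issmri.preprocess import _shift_int

from conftest import SHAM


@pytest.fixture(scope="module")
def structured_series():
    """Series with a textured baseline (so NCC has something to lock onto)
    and frames = baseline + a tracer-like blob."""
    rng = np.random.default_rng(5)
    grid = VoxelGrid.centered((24, 24, 24))
    tex = ndimage.gaussian_filter(rng.normal(0, 1, grid.shape), 2.0)
    base = 500.0 + 50.0 * tex / tex.std()
    r = grid.distance_map((0.0, 0.0, 0.0))
    blob = 40.0 * np.exp(-(r**2) / 8.0)
    frames = np.stack([base + blob * f for f in (1.0, 0.7, 0.4)])
    return ImageSeries(
        grid=grid, baseline=base, frames=frames, times=np.array([0.5, 1.0, 2.0])
    )


class TestRegistration:
    def test_aligned_series_gets_zero_shifts(self, structured_series):
        reg = register_series(structured_series, max_shift=2)
        assert reg.shifts == [(0, 0, 0)] * 3
        np.testing.assert_array_equal(reg.series.frames, structured_series.frames)

    def test_recovers_injected_integer_shift(self, structured_series):
        s = structured_series
        applied = (2, -1, 0)
        moved = np.stack([_shift_int(f, applied) for f in s.frames])
        series = ImageSeries(grid=s.grid, baseline=s.baseline, frames=moved, times=s.times)
        reg = register_series(series, max_shift=2)
        # the reported shift is the correction that undoes the motion
        assert reg.shifts == [tuple(-v for v in applied)] * 3
        # interior voxels are restored exactly (edges were zero-filled)
        core = (slice(3, -3),) * 3
        for orig, fixed in zip(s.frames, reg.series.frames):
            np.testing.assert_array_equal(fixed[core], orig[core])

    def test_max_shift_zero_is_identity(self, structured_series):
        reg = register_series(structured_series, max_shift=0)
        assert reg.shifts == [(0, 0, 0)] * 3
        np.testing.assert_array_equal(reg.series.frames, structured_series.frames)

    def test_constant_frame_warns_and_keeps_zero_shift(self):
        grid = VoxelGrid.centered((8, 8, 8))
        series = ImageSeries(
            grid=grid,
            baseline=np.full(grid.shape, 100.0),
            frames=np.full((2,) + grid.shape, 100.0),
            times=np.array([0.5, 1.0]),
        )
        with pytest.warns(UserWarning, match="registration skipped"):
            reg = register_series(series, max_shift=1)
        assert reg.shifts == [(0, 0, 0)] * 2


class TestSubtraction:
    def test_identical_frame_gives_zero_increment(self):
        grid = VoxelGrid.centered((12, 12, 12))
        base = np.random.default_rng(0).normal(300, 10, grid.shape)
        series = ImageSeries(
            grid=grid, baseline=base, frames=base[None].copy(), times=np.array([1.0])
        )
        inc = subtract_baseline(series)
        np.testing.assert_array_equal(inc.values, 0.0)
        assert inc.noise_sigma_est == 0.0

    def test_noiseless_phantom_increment_matches_forward_model(self, acq, sham_conc):
        img = concentration_to_signal(sham_conc, acq)
        inc = subtract_baseline(img)
        sl = make_signal_law(acq, alpha=0.2)
        expected = sl.signal(sham_conc.values) - sl.baseline_signal()
        np.testing.assert_allclose(inc.values, expected, atol=1e-9)

    def test_linear_in_overall_scaling(self, acq, sham_conc):
        img = concentration_to_signal(sham_conc, acq)
        inc1 = subtract_baseline(img)
        scaled = ImageSeries(
            grid=img.grid,
            baseline=3.0 * img.baseline,
            frames=3.0 * img.frames,
            times=img.times,
        )
        inc3 = subtract_baseline(scaled)
        np.testing.assert_allclose(inc3.values, 3.0 * inc1.values, rtol=1e-9, atol=1e-9)

    def test_noise_estimate_matches_injected_noise(self, acq):
        """Pure-noise increments: corner-block sigma ~ sqrt(2)*sigma_img and
        the mean increment sits within 3 SEM of zero (high-SNR Rician)."""
        from issmri import add_noise

        grid = VoxelGrid.centered((24, 24, 24))
        sigma = 4.0
        rng = np.random.default_rng(9)
        base = add_noise(np.full(grid.shape, 800.0), sigma, rng)
        frames = np.stack(
            [add_noise(np.full(grid.shape, 800.0), sigma, rng) for _ in range(4)]
        )
        series = ImageSeries(grid=grid, baseline=base, frames=frames, times=np.arange(1.0, 5.0))
        inc = subtract_baseline(series)
        assert inc.noise_sigma_est == pytest.approx(np.sqrt(2) * sigma, rel=0.1)
        sem = np.sqrt(2) * sigma / np.sqrt(inc.values.size)
        assert abs(inc.values.mean()) < 3 * sem


class TestConversion:
    def test_zero_increment_gives_zero_concentration(self, acq):
        grid = VoxelGrid.centered((8, 8, 8))
        from issmri import IncrementSeries

        inc = IncrementSeries(
            grid=grid,
            times=np.array([1.0]),
            values=np.zeros((1,) + grid.shape),
            noise_sigma_est=1.0,
        )
        conc = signal_to_concentration(inc, acq)
        np.testing.assert_array_equal(conc.values, 0.0)

    @pytest.mark.parametrize("law", ["saturation", "inversion"])
    def test_round_trip_on_noiseless_phantom(self, acq, sham_conc, law):
        """concentration -> signal -> increment -> concentration is the
        identity to 0.1% wherever the signal is not saturation-clipped."""
        img = concentration_to_signal(sham_conc, acq, law=law)
        inc = subtract_baseline(img)
        back = signal_to_concentration(inc, acq, law=law)
        # compare where neither clipped nor below signal float precision
        ok = ~back.meta["clipped"] & (sham_conc.values > 1e-6)
        np.testing.assert_allclose(back.values[ok], sham_conc.values[ok], rtol=1e-3)

    def test_negative_increments_map_to_zero_but_survive_in_signed(self, acq):
        from issmri import IncrementSeries

        grid = VoxelGrid.centered((8, 8, 8))
        values = np.full((1,) + grid.shape, -5.0)
        inc = IncrementSeries(grid=grid, times=np.array([1.0]), values=values, noise_sigma_est=1.0)
        conc = signal_to_concentration(inc, acq)
        np.testing.assert_array_equal(conc.values, 0.0)
        assert np.all(conc.meta["signed_values"] < 0)
        assert conc.meta["neg_fraction"] == 1.0

    def test_saturated_increment_clipped_and_flagged(self, acq):
        from issmri import IncrementSeries

        sl = make_signal_law(acq, alpha=0.2)
        grid = VoxelGrid.centered((8, 8, 8))
        values = np.full((1,) + grid.shape, 0.99 * sl.increment_sup())
        inc = IncrementSeries(grid=grid, times=np.array([1.0]), values=values, noise_sigma_est=1.0)
        conc = signal_to_concentration(inc, acq, saturation_fraction=0.9)
        assert conc.meta["clip_fraction"] == 1.0
        np.testing.assert_allclose(conc.values, conc.meta["clip_value_conc"])

    def test_small_increment_linear_regime(self, acq):
        """Small increments divided by the law's slope at zero approximate
        the concentration to 5%."""
        from issmri import IncrementSeries

        sl = make_signal_law(acq, alpha=0.2)
        c_true = 0.02
        grid = VoxelGrid.centered((4, 4, 4))
        values = np.full((1,) + grid.shape, float(sl.increment(c_true)))
        inc = IncrementSeries(grid=grid, times=np.array([1.0]), values=values, noise_sigma_est=0.1)
        conc = signal_to_concentration(inc, acq)
        approx = values[0, 0, 0, 0] / sl.slope_at_zero()
        assert approx == pytest.approx(c_true, rel=0.05)
        assert conc.values[0, 0, 0, 0] == pytest.approx(c_true, rel=1e-3)
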