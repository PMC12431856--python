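"""FRAP measurement, double normalization and recovery fitting."""

import numpy as np
import pytest

from condquant import frap as fr
from condquant.io_images import ImageStack
from condquant.synthetic_data import SyntheticFrapParams, generate_frap


def _render_movie(params: SyntheticFrapParams, shape=(64, 64), roi=(32, 32)):
    """Render a generated trace into a flat 2D movie: ROI disc carries the
    ROI signal, the rest of the nucleus the whole-nucleus signal, and a
    corner box the background."""
    trace, truth = generate_frap(params)
    nt = len(trace.time)
    ny, nx = shape
    movie = np.zeros((nt, ny, nx))
    yy, xx = np.ogrid[:ny, :nx]
    # pixel size 0.11 um -> 1 um radius is ~9.1 px
    disc = ((yy - roi[0]) ** 2 + (xx - roi[1]) ** 2) <= (1.0 / 0.11) ** 2
    nucleus = ((yy - roi[0]) ** 2 + (xx - roi[1]) ** 2) <= 28.0**2
    for t in range(nt):
        movie[t][nucleus] = trace.nucleus_mean[t]
        movie[t][disc] = trace.roi_mean[t]
        movie[t][:8, :8] = trace.background_mean[t]
    stack = ImageStack(movie, (1.0, 0.11, 0.11), layout="tyx")
    return stack, nucleus & ~disc, trace, truth


class TestMeasureFrap:
    def test_measured_roi_matches_generator_series(self):
        params = SyntheticFrapParams(noise_sd=0.0, n_post=30)
        stack, nucleus_only, trace, _ = _render_movie(params)
        measured = fr.measure_frap(
            stack, (32, 32), 1.0, nucleus_only | True, (0, 8, 0, 8),
            bleach_index=params.n_pre,
        )
        np.testing.assert_allclose(measured.roi_mean, trace.roi_mean, rtol=1e-12)
        np.testing.assert_allclose(measured.background_mean, trace.background_mean)

    def test_bleach_frame_detected_from_drop(self):
        params = SyntheticFrapParams(noise_sd=0.0, n_pre=7, n_post=30)
        stack, _, _, _ = _render_movie(params)
        nucleus = np.ones(stack.data.shape[1:], dtype=bool)
        measured = fr.measure_frap(stack, (32, 32), 1.0, nucleus, (0, 8, 0, 8))
        assert measured.bleach_index == 7

    def test_constant_movie_has_no_bleach(self):
        movie = np.full((20, 64, 64), 500.0)
        stack = ImageStack(movie, (1.0, 0.11, 0.11), layout="tyx")
        nucleus = np.ones((64, 64), dtype=bool)
        with pytest.raises(ValueError, match="no bleach found"):
            fr.measure_frap(stack, (32, 32), 1.0, nucleus, (0, 8, 0, 8))

    def test_zero_background_region_measures_zero(self):
        movie = np.zeros((12, 64, 64))
        movie[:, 20:50, 20:50] = 100.0
        movie[6:, 20:50, 20:50] = 60.0  # a clear drop everywhere
        stack = ImageStack(movie, (1.0, 0.11, 0.11), layout="tyx")
        nucleus = np.zeros((64, 64), dtype=bool)
        nucleus[20:50, 20:50] = True
        t = fr.measure_frap(stack, (32, 32), 1.0, nucleus, (0, 8, 0, 8))
        assert (t.background_mean == 0).all()

    def test_roi_outside_image_rejected(self):
        stack = ImageStack(np.zeros((5, 32, 32)), (1.0, 0.11, 0.11), layout="tyx")
        with pytest.raises(ValueError, match="outside"):
            fr.measure_frap(stack, (2, 2), 1.0, np.ones((32, 32), dtype=bool),
                            (0, 4, 0, 4), bleach_index=1)


class TestNormalizeFrap:
    def test_whole_field_photobleaching_cancels(self):
        params = SyntheticFrapParams(bleach_depth=0.0, photobleach_rate=0.08,
                                     noise_sd=0.0)
        trace, _ = generate_frap(params)
        v = fr.normalize_frap(trace)
        np.testing.assert_allclose(v.value, 1.0, atol=1e-9)

    def test_plateau_closed_form(self):
        params = SyntheticFrapParams(bleach_depth=0.8, mobile_fraction=0.5,
                                     noise_sd=0.0, n_post=600, recovery_rate=0.3)
        trace, _ = generate_frap(params)
        v = fr.normalize_frap(trace)
        assert v.value[-1] == pytest.approx(0.6, abs=1e-9)

    def test_prebleach_only_is_exactly_one(self):
        trace = fr.FrapTrace(
            time=np.arange(5.0),
            roi_mean=np.full(5, 80.0),
            nucleus_mean=np.full(5, 160.0),
            background_mean=np.full(5, 10.0),
            bleach_index=4,
        )
        v = fr.normalize_frap(trace)
        np.testing.assert_allclose(v.value, 1.0)
        assert v.value[: trace.bleach_index].mean() == pytest.approx(1.0)

    def test_invariant_under_shared_gain(self):
        params = SyntheticFrapParams(noise_sd=0.0)
        trace, _ = generate_frap(params)
        scaled = fr.FrapTrace(
            time=trace.time, roi_mean=trace.roi_mean * 3.7,
            nucleus_mean=trace.nucleus_mean * 3.7,
            background_mean=trace.background_mean * 3.7,
            bleach_index=trace.bleach_index,
        )
        np.testing.assert_allclose(
            fr.normalize_frap(trace).value, fr.normalize_frap(scaled).value,
            rtol=1e-12,
        )

    def test_nonpositive_nucleus_signal_names_the_frame(self):
        trace = fr.FrapTrace(
            time=np.arange(4.0),
            roi_mean=np.full(4, 50.0),
            nucleus_mean=np.array([100.0, 100.0, 5.0, 100.0]),
            background_mean=np.full(4, 10.0),
            bleach_index=1,
        )
        trace.nucleus_mean[2] = 5.0
        trace.background_mean[2] = 20.0
        with pytest.raises(ValueError, match="frame 2"):
            fr.normalize_frap(trace)


class TestAggregateAndFit:
    def test_identical_traces_have_zero_sd(self):
        trace, _ = generate_frap(SyntheticFrapParams(noise_sd=0.0))
        v = fr.normalize_frap(trace)
        ens = fr.aggregate_frap([v, v, v])
        np.testing.assert_allclose(ens.sd_curve, 0.0, atol=1e-12)
        np.testing.assert_allclose(ens.mean_curve, v.value)

    def test_smooth_curve_near_one_before_bleach(self):
        traces = [
            fr.normalize_frap(generate_frap(
                SyntheticFrapParams(noise_sd=1.0, seed=i, n_pre=10)
            )[0])
            for i in range(6)
        ]
        ens = fr.aggregate_frap(traces)
        assert abs(ens.smooth_curve[:5] - 1.0).max() < 0.15

    def test_ensemble_plateau_recovers_truth_within_two_se(self):
        n_cells, mf = 19, 0.7
        traces = [
            fr.normalize_frap(generate_frap(SyntheticFrapParams(
                mobile_fraction=mf, bleach_depth=0.8, recovery_rate=0.2,
                noise_sd=2.0, n_post=60, seed=100 + i,
            ))[0])
            for i in range(n_cells)
        ]
        ens = fr.aggregate_frap(traces)
        tail = slice(-10, None)
        plateau_est = ens.mean_curve[tail].mean()
        se = ens.sd_curve[tail].mean() / np.sqrt(n_cells)
        truth_plateau = 0.2 + 0.8 * mf  # not yet fully recovered at t=60 s
        # allow the residual exponential term at the measured tail times
        t_tail = ens.time[tail] - ens.time[ens.bleach_index]
        residual = 0.8 * mf * np.exp(-0.2 * t_tail).mean()
        assert abs(plateau_est - (truth_plateau - residual)) < 2 * se

    def test_noiseless_fit_recovers_parameters(self):
        traces = [
            fr.normalize_frap(generate_frap(SyntheticFrapParams(
                mobile_fraction=0.7, recovery_rate=0.2, bleach_depth=0.8,
                noise_sd=0.0, n_post=120,
            ))[0])
        ] * 2
        fit = fr.fit_recovery(fr.aggregate_frap(traces))
        assert fit["mobile_fraction"] == pytest.approx(0.7, abs=1e-6)
        assert fit["rate"] == pytest.approx(0.2, abs=1e-6)
        assert fit["halftime_s"] == pytest.approx(np.log(2) / 0.2, abs=1e-5)

    def test_immobile_pool_fits_to_zero(self):
        traces = [
            fr.normalize_frap(generate_frap(SyntheticFrapParams(
                mobile_fraction=0.0, noise_sd=0.0, n_post=40,
            ))[0])
        ] * 2
        fit = fr.fit_recovery(fr.aggregate_frap(traces))
        assert abs(fit["mobile_fraction"]) < 1e-6

    def test_noisy_ensemble_recovery_within_ten_percent(self):
        traces = [
            fr.normalize_frap(generate_frap(SyntheticFrapParams(
                mobile_fraction=0.7, recovery_rate=0.2, bleach_depth=0.8,
                noise_sd=2.0, n_post=120, seed=200 + i,
            ))[0])
            for i in range(19)
        ]
        fit = fr.fit_recovery(fr.aggregate_frap(traces))
        assert fit["mobile_fraction"] == pytest.approx(0.7, rel=0.10)
        assert fit["rate"] == pytest.approx(0.2, rel=0.10)

    def test_mismatched_grids_rejected(self):
        a, _ = generate_frap(SyntheticFrapParams(n_post=20))
        b, _ = generate_frap(SyntheticFrapParams(n_post=30))
        with pytest.raises(ValueError, match="grid"):
            fr.aggregate_frap([fr.normalize_frap(a), fr.normalize_frap(b)])
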