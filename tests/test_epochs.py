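"""Epoch extraction, baselining, rejection, averaging and peak features."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bipr.epochs import (
    EPOCH_GRID_S,
    BiprEpoch,
    BiprWaveform,
    EpochRejected,
    average_epochs,
    baseline_epoch,
    extract_epochs,
    extract_features,
    outlier_mask,
    reject_epoch,
    run_bipr,
)
from bipr.preprocess import preprocess_trace
from bipr.simulate import SimRunConfig, generate_pupil_run, kernel_peaks
from bipr.trace import BlinkEvent, PupilTrace


def _epoch(values, missing=None):
    values = np.asarray(values, dtype=float)
    if missing is None:
        missing = np.zeros(501, dtype=bool)
    return BiprEpoch(values=values, missing_mask=np.asarray(missing, dtype=bool))


def _trace100(values):
    values = np.asarray(values, dtype=float)
    t = np.arange(values.size) * 10.0
    return PupilTrace(t_ms=t, pupil=values, sampling_rate=100.0,
                      missing=np.zeros(values.size, dtype=bool))


class TestExtraction:
    def test_edge_blink_dropped(self):
        tr = _trace100(np.ones(30_000))  # 300 s
        eps, dropped = extract_epochs(tr, [BlinkEvent(onset_ms=1000.0, offset_ms=1100.0)])
        assert eps == [] and dropped == 1

    def test_window_maps_to_absolute_time(self):
        vals = np.arange(30_000, dtype=float) + 1.0
        tr = _trace100(vals)
        eps, _ = extract_epochs(tr, [BlinkEvent(onset_ms=10_000.0, offset_ms=10_100.0)])
        # rel -2 s .. +3 s -> absolute 8 s .. 13 s -> indices 800..1300
        assert np.array_equal(eps[0].values, vals[800:1301])

    def test_rapid_blink_train_epochs_kept(self):
        tr = _trace100(np.ones(30_000))
        blinks = [BlinkEvent(onset_ms=10_000.0, offset_ms=10_100.0),
                  BlinkEvent(onset_ms=11_000.0, offset_ms=11_100.0)]
        eps, dropped = extract_epochs(tr, blinks)
        assert len(eps) == 2 and dropped == 0


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        out = baseline_epoch(_epoch(np.full(501, 7.0)))
        assert np.allclose(out.values, 0.0)

    def test_identity_ramp_arithmetic(self):
        # epoch equal to its own time grid: baseline mean over the 20
        # samples in [-0.200, -0.01] is -0.105, so t=0.5 maps to 0.605
        out = baseline_epoch(_epoch(EPOCH_GRID_S.copy()))
        i = np.argwhere(np.isclose(EPOCH_GRID_S, 0.5))[0, 0]
        assert out.values[i] == pytest.approx(0.605, abs=1e-12)

    def test_all_missing_baseline_rejected(self):
        missing = np.zeros(501, dtype=bool)
        missing[180:200] = True
        with pytest.raises(EpochRejected, match="no baseline"):
            baseline_epoch(_epoch(np.ones(501), missing))

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        e = _epoch(rng.normal(size=501))
        once = baseline_epoch(e)
        twice = baseline_epoch(once)
        assert np.allclose(once.values, twice.values, atol=1e-12)

    def test_baseline_window_mean_is_zero(self):
        rng = np.random.default_rng(1)
        out = baseline_epoch(_epoch(rng.normal(size=501)))
        assert abs(out.values[180:200].mean()) < 1e-9


class TestRejection:
    @pytest.mark.parametrize("n_missing,keep", [(120, True), (123, False), (0, True)])
    def test_strict_threshold(self, n_missing, keep):
        # (0, 3] s window holds 300 samples; 120 missing = exactly 40%
        missing = np.zeros(501, dtype=bool)
        missing[201 : 201 + n_missing] = True
        got, _ = reject_epoch(_epoch(np.ones(501), missing))
        assert got is keep

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 300), st.integers(0, 50))
    def test_monotone_in_missingness(self, n0, extra):
        missing = np.zeros(501, dtype=bool)
        missing[201 : 201 + n0] = True
        keep0, _ = reject_epoch(_epoch(np.ones(501), missing))
        missing2 = missing.copy()
        missing2[201 : 201 + min(n0 + extra, 300)] = True
        keep1, _ = reject_epoch(_epoch(np.ones(501), missing2))
        assert keep0 or not keep1  # adding missingness never resurrects


class TestAveraging:
    def test_single_epoch_identity(self):
        e = _epoch(np.sin(EPOCH_GRID_S))
        w = average_epochs([e])
        assert np.allclose(w.mean_values, e.values)
        assert w.n_epochs_used == 1

    def test_opposite_epochs_cancel(self):
        v = np.sin(EPOCH_GRID_S)
        w = average_epochs([_epoch(v), _epoch(-v)])
        assert np.allclose(w.mean_values, 0.0)

    def test_disjoint_masks_vs_explicit_loop(self):
        rng = np.random.default_rng(3)
        vals = [rng.normal(size=501) for _ in range(3)]
        masks = [np.zeros(501, dtype=bool) for _ in range(3)]
        masks[0][:100] = True
        masks[1][100:200] = True
        masks[2][450:501] = True
        w = average_epochs([_epoch(v, m) for v, m in zip(vals, masks)])
        # independent per-point oracle
        for j in range(501):
            avail = [vals[i][j] for i in range(3) if not masks[i][j]]
            assert w.mean_values[j] == pytest.approx(np.mean(avail), abs=1e-12)


class TestFeatures:
    def test_quarter_sine_argmax_at_window_edge(self):
        y = np.sin(2 * np.pi * EPOCH_GRID_S / 4.0)
        f = extract_features(BiprWaveform(mean_values=y, n_epochs_used=1))
        assert f.d_time_s == pytest.approx(0.90)
        assert f.c_time_s == pytest.approx(2.5)  # quarter wave still positive; min at window end

    def test_flat_zero_flagged_atypical(self):
        f = extract_features(BiprWaveform(mean_values=np.zeros(501), n_epochs_used=1))
        assert f.d_amp_au == 0.0 and f.atypical

    def test_invariants_on_two_lobe_shape(self):
        t = EPOCH_GRID_S
        y = 30 * np.exp(-0.5 * ((t - 0.5) / 0.15) ** 2) - 20 * np.exp(-0.5 * ((t - 1.0) / 0.25) ** 2)
        f = extract_features(BiprWaveform(mean_values=y, n_epochs_used=1))
        assert f.c_time_s > f.d_time_s
        assert f.dc_time_diff_s == pytest.approx(f.c_time_s - f.d_time_s)
        assert f.dc_peakdrop_au == pytest.approx(f.d_amp_au - f.c_amp_au)
        assert not f.atypical

    def test_constant_offset_equivariance(self):
        # adding a constant to the raw trace changes no feature: the
        # baseline window absorbs it
        cfg = SimRunConfig(duration_s=120, noise_sd=0.5, seed=31)
        trace, _ = generate_pupil_run(cfg)
        out, blinks, *_ = preprocess_trace(trace)
        _, f0 = run_bipr(out, blinks)
        shifted = out.copy(pupil=out.pupil + 123.0)
        _, f1 = run_bipr(shifted, blinks)
        assert f1.d_time_s == f0.d_time_s and f1.c_time_s == f0.c_time_s
        assert f1.d_amp_au == pytest.approx(f0.d_amp_au, abs=1e-9)
        assert f1.c_amp_au == pytest.approx(f0.c_amp_au, abs=1e-9)
        assert f1.dc_peakdrop_au == pytest.approx(f0.dc_peakdrop_au, abs=1e-9)

    def test_pipeline_recovers_kernel_peaks(self):
        # low-noise recovery across latency settings: peak times within
        # one 100 Hz sample, amplitudes within 5%
        for dl, cl in [(0.3, 0.9), (0.5, 1.2), (0.7, 0.9)]:
            cfg = SimRunConfig(duration_s=300, seed=11, noise_sd=0.2,
                               blink_rate_per_min=6.0, d_latency_s=dl, c_latency_s=cl)
            trace, _ = generate_pupil_run(cfg)
            out, blinks, *_ = preprocess_trace(trace)
            _, f = run_bipr(out, blinks)
            dt, da, ct, ca = kernel_peaks(cfg)
            assert abs(f.d_time_s - dt) <= 0.01 + 1e-9
            assert abs(f.c_time_s - ct) <= 0.01 + 1e-9
            assert abs(f.d_amp_au - da) <= 0.05 * abs(da)
            assert abs(f.c_amp_au - ca) <= 0.05 * abs(ca)

    def test_kernel_free_runs_average_flat(self):
        cfg = SimRunConfig(duration_s=300, noise_sd=2.0, d_amp=0.0, c_amp=-0.0, seed=5)
        trace, _ = generate_pupil_run(cfg)
        out, blinks, *_ = preprocess_trace(trace)
        wave, _ = run_bipr(out, blinks)
        post = wave.mean_values[201:]
        assert abs(np.nanmean(post)) < 3 * cfg.noise_sd / np.sqrt(wave.n_epochs_used)


class TestOutlierMask:
    def test_textbook_example(self):
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], dtype=float)
        keep = outlier_mask(vals)
        # Q1=3.25, Q3=7.75, IQR=4.5 -> fences [-5.75, 16.75]
        assert not keep[-1]
        assert keep[:-1].all()

    def test_all_equal_nothing_excluded(self):
        assert outlier_mask(np.full(10, 3.3)).all()

    def test_symmetric_under_sign_flip(self):
        rng = np.random.default_rng(9)
        v = np.concatenate([rng.normal(size=50), [8.0, -8.0]])
        assert np.array_equal(outlier_mask(v), outlier_mask(-v))

    def test_too_few_values_warns_and_keeps(self):
        with pytest.warns(UserWarning):
            keep = outlier_mask(np.array([1.0, 2.0, 3.0]))
        assert keep.all()

    def test_nan_never_kept(self):
        keep = outlier_mask(np.array([1, 2, 3, 4, 5, np.nan]))
        assert not keep[-1]
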