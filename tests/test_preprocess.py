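"""Run preparation: normalization, confounds, scrubbing, HRF, deconvolution."""

import numpy as np
import pandas as pd
import pytest

import mindyx as mx
from mindyx.preprocess import labels_from_events, run_stats


def _run(data, tr=0.72, **kw):
    return mx.BoldRun(data=np.asarray(data, float), tr=tr, **kw)


class TestNormalize:
    def test_own_stats_standardize(self):
        rng = np.random.default_rng(0)
        run = _run(rng.normal(2.0, 3.0, (4, 200)))
        out = mx.normalize_run(run)
        assert np.allclose(out.data.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(out.data.std(axis=1), 1, atol=1e-12)

    def test_constant_series_rejected(self):
        run = _run(np.ones((2, 50)))
        with pytest.raises(ValueError):
            mx.normalize_run(run)

    def test_interval_reference_stats(self):
        # task run standardized by interval statistics: interval volumes end
        # up zero-mean unit-sd, block volumes keep their offset
        rng = np.random.default_rng(1)
        labels = np.array(["interval"] * 50 + ["cond_1"] * 50, dtype=object)
        data = rng.normal(0, 1, (2, 100))
        data[:, 50:] += 5.0
        run = _run(data, condition=labels)
        m, s = run_stats(run, volumes=(run.condition == "interval"))
        out = mx.normalize_run(run, ref_mean=m, ref_sd=s, detrend=False)
        iv = out.data[:, :50]
        blk = out.data[:, 50:]
        assert np.allclose(iv.mean(axis=1), 0, atol=1e-12)
        assert np.allclose(iv.std(axis=1), 1, atol=1e-12)
        assert np.all(blk.mean(axis=1) > 2)

    def test_detrend_removes_linear_drift(self):
        t = np.arange(300, dtype=float)
        run = _run(np.vstack([0.5 * t + np.sin(t)]))
        out = mx.normalize_run(run)
        # residual correlation with time is (numerically) zero after detrend
        assert abs(np.corrcoef(out.data[0], t)[0, 1]) < 1e-8


class TestConfoundRegression:
    def test_matches_hand_ols(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=50)
        y = 2.0 + 1.5 * c + rng.normal(0, 0.1, 50)
        run = _run(y[None, :])
        out = mx.regress_confounds(run, c[:, None])
        X = np.column_stack([np.ones(50), c])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(out.data[0], y - X @ beta, atol=1e-10)

    def test_confound_itself_removed(self):
        c = np.sin(np.arange(80) / 5.0)
        run = _run(c[None, :])
        out = mx.regress_confounds(run, c[:, None])
        assert np.allclose(out.data, 0, atol=1e-10)

    def test_orthogonal_series_unchanged(self):
        t = np.arange(100)
        y = np.cos(2 * np.pi * t / 10)      # orthogonal to the slow confound
        c = np.ones(100) * 3.0
        run = _run(y[None, :])
        with pytest.warns(RuntimeWarning):  # constant confound + intercept
            out = mx.regress_confounds(run, c[:, None])
        assert np.allclose(out.data[0], y - y.mean(), atol=1e-10)


class TestScrub:
    def test_identity_when_clean(self):
        rng = np.random.default_rng(3)
        run = _run(rng.normal(size=(3, 40)))
        out, frac = mx.scrub_interpolate(run, np.zeros(40), 0.2)
        assert frac == 0.0
        assert np.array_equal(out.data, run.data)

    def test_interior_volume_is_neighbor_mean(self):
        run = _run(np.arange(10, dtype=float)[None, :] ** 2)
        fd = np.zeros(10)
        fd[4] = 1.0
        out, frac = mx.scrub_interpolate(run, fd, 0.2)
        assert out.data[0, 4] == pytest.approx((run.data[0, 3] + run.data[0, 5]) / 2)
        assert frac == pytest.approx(0.1)

    def test_boundary_copies_nearest_good(self):
        run = _run(np.arange(8, dtype=float)[None, :])
        fd = np.zeros(8)
        fd[[0, 7]] = 9.0
        out, _ = mx.scrub_interpolate(run, fd, 0.2)
        assert out.data[0, 0] == run.data[0, 1]
        assert out.data[0, 7] == run.data[0, 6]

    def test_matches_explicit_loop_oracle(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(2, 30))
        fd = rng.uniform(0, 0.4, 30)
        run = _run(data)
        out, _ = mx.scrub_interpolate(run, fd, 0.2)
        good = np.flatnonzero(fd <= 0.2)
        for i in range(2):
            for t in np.flatnonzero(fd > 0.2):
                left = good[good < t]
                right = good[good > t]
                if left.size == 0:
                    exp = data[i, right[0]]
                elif right.size == 0:
                    exp = data[i, left[-1]]
                else:
                    l, r = left[-1], right[0]
                    exp = data[i, l] + (data[i, r] - data[i, l]) * (t - l) / (r - l)
                assert out.data[i, t] == pytest.approx(exp)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        run = _run(rng.normal(size=(2, 30)))
        fd = np.zeros(30)
        fd[[3, 17]] = 1.0
        once, _ = mx.scrub_interpolate(run, fd, 0.2)
        twice, _ = mx.scrub_interpolate(once, fd, 0.2)
        assert np.allclose(once.data, twice.data)

    def test_all_flagged_rejected(self):
        run = _run(np.ones((1, 5)) * np.arange(5))
        with pytest.raises(ValueError):
            mx.scrub_interpolate(run, np.full(5, 2.0), 0.2)


class TestCanonicalHrf:
    def test_shape_and_origin(self):
        hrf = mx.canonical_hrf(0.72)
        assert hrf.h[0] == pytest.approx(0.0, abs=1e-12)
        assert np.max(hrf.h) == pytest.approx(1.0)

    def test_peak_near_five_seconds(self):
        hrf = mx.canonical_hrf(0.72)
        t_peak = np.argmax(hrf.h) * 0.72
        assert 4.0 < t_peak < 6.0

    def test_single_sign_change(self):
        hrf = mx.canonical_hrf(0.72)
        signs = np.sign(hrf.h[np.abs(hrf.h) > 1e-12])
        assert np.sum(np.diff(signs) != 0) == 1  # one positive lobe, one undershoot

    def test_matches_nilearn_spm_hrf(self):
        # oracle: nilearn's SPM kernel on a fine grid, interpolated to our
        # sample times (its oversampling=1 grid is offset by one sample)
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        fine = nilearn_hrf.spm_hrf(0.72, oversampling=100)
        t_fine = np.linspace(0, 32, fine.size)
        ours = mx.canonical_hrf(0.72).h
        ref = np.interp(np.arange(ours.size) * 0.72, t_fine, fine)
        ref = ref / np.max(np.abs(ref))
        assert np.corrcoef(ours, ref)[0, 1] > 0.999
        assert np.max(np.abs(ours - ref)) < 0.01


class TestWienerDeconvolution:
    def test_unit_impulse_kernel_scales_by_snr_factor(self):
        rng = np.random.default_rng(6)
        run = _run(rng.normal(size=(3, 64)))
        h = np.zeros(8)
        h[0] = 1.0
        out = mx.wiener_deconvolve(run, mx.HRFKernel(h, 0.72), snr=50)
        assert np.allclose(out.data, run.data * 50 / 51, atol=1e-12)

    def test_linearity(self):
        rng = np.random.default_rng(7)
        run = _run(rng.normal(size=(2, 128)))
        hrf = mx.canonical_hrf(0.72)
        a = 3.7
        out1 = mx.wiener_deconvolve(run.with_data(a * run.data), hrf)
        out2 = mx.wiener_deconvolve(run, hrf)
        assert np.allclose(out1.data, a * out2.data, atol=1e-10)

    def test_round_trip_in_passband(self):
        # band-limited signal within the HRF passband survives the
        # convolve -> deconvolve round trip with small relative error
        tr = 0.72
        t = np.arange(600) * tr
        x = np.vstack([np.sin(2 * np.pi * 0.03 * t) + 0.5 * np.sin(2 * np.pi * 0.06 * t)])
        hrf = mx.canonical_hrf(tr)
        y = np.apply_along_axis(lambda s: np.convolve(s, hrf.h)[:600], 1, x)
        rec = mx.wiener_deconvolve(_run(y, tr), hrf, snr=50).data
        core = slice(60, 540)  # away from run edges
        rel_rmse = (np.sqrt(np.mean((rec[0, core] - x[0, core]) ** 2))
                    / np.sqrt(np.mean(x[0, core] ** 2)))
        assert rel_rmse < 0.05

    def test_high_snr_approaches_inverse_filter(self):
        # taper the signal to zero at both ends so truncating the linear
        # convolution loses nothing; then snr -> inf must invert exactly
        tr = 1.0
        t = np.arange(256) * tr
        x = np.vstack([np.sin(2 * np.pi * 0.05 * t) * np.hanning(256)])
        h = np.array([1.0, 0.5])  # invertible minimum-phase kernel
        y = np.apply_along_axis(lambda s: np.convolve(s, h)[:256], 1, x)
        rec = mx.wiener_deconvolve(_run(y, tr), mx.HRFKernel(h, tr), snr=1e12).data
        assert np.allclose(rec, x, atol=1e-4)

    def test_shape_and_labels_preserved(self):
        rng = np.random.default_rng(8)
        labels = np.array(["rest"] * 64, dtype=object)
        run = _run(rng.normal(size=(3, 64)), condition=labels)
        out = mx.wiener_deconvolve(mx.normalize_run(run), mx.canonical_hrf(0.72))
        assert out.data.shape == run.data.shape
        assert np.array_equal(out.condition, labels)
        assert out.kind == "neural"

    def test_bad_snr_rejected(self):
        run = _run(np.random.default_rng(9).normal(size=(1, 64)))
        with pytest.raises(ValueError):
            mx.wiener_deconvolve(run, mx.canonical_hrf(0.72), snr=0.0)


class TestDesign:
    def test_one_hot_boxcars(self):
        labels = np.array(["rest", "interval", "cond_1", "cond_2", "cond_1"],
                          dtype=object)
        d = mx.build_design(labels, ("cond_1", "cond_2"))
        expected = np.array([[0, 0, 1, 0, 1],
                             [0, 0, 0, 1, 0]], dtype=float)
        assert np.array_equal(d.u, expected)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            mx.build_design(np.array(["cond_9"], dtype=object), ("cond_1",))

    def test_labels_from_events(self):
        ev = pd.DataFrame({"onset": [2.0, 6.0], "duration": [2.0, 2.0],
                           "trial_type": ["cond_1", "cond_2"]})
        labels = labels_from_events(ev, tr=1.0, n_volumes=10)
        assert list(labels) == ["interval", "interval", "cond_1", "cond_1",
                                "interval", "interval", "cond_2", "cond_2",
                                "interval", "interval"]
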