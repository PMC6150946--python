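import numpy as np
import pytest
from scipy import signal

import opmlat as o
from opmlat._exceptions import ConditioningError, ConfigurationError, DegenerateError

from _oracles import brute_force_scan


class TestBandFilter:
    def test_passband_center_preserved(self, array):
        fs, n = 200.0, 2000
        t = np.arange(n) / fs
        data = np.tile(np.sin(2 * np.pi * 20.0 * t), (1, array.n_channels, 1)) * 1e-12
        ds = o.TrialDataset(data=data, sampling_rate=fs, times=t - 2.0,
                            events=np.array([[0.0, 3.0]]), array=array)
        out = o.band_filter(ds, (15.0, 30.0))
        mid = slice(n // 4, 3 * n // 4)
        ratio = np.sqrt(np.mean(out.data[0, 0, mid] ** 2) / np.mean(data[0, 0, mid] ** 2))
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_stopband_attenuated_30db(self, array):
        fs, n = 200.0, 2000
        t = np.arange(n) / fs
        data = np.tile(np.sin(2 * np.pi * 5.0 * t), (1, array.n_channels, 1)) * 1e-12
        ds = o.TrialDataset(data=data, sampling_rate=fs, times=t - 2.0,
                            events=np.array([[0.0, 3.0]]), array=array)
        out = o.band_filter(ds, (15.0, 30.0))
        mid = slice(n // 4, 3 * n // 4)
        att = np.sqrt(np.mean(out.data[0, 0, mid] ** 2) / np.mean(data[0, 0, mid] ** 2))
        assert 20 * np.log10(1 / max(att, 1e-300)) >= 30.0

    def test_zero_in_zero_out(self, array):
        ds = o.TrialDataset(data=np.zeros((1, array.n_channels, 500)), sampling_rate=200.0,
                            times=np.arange(500) / 200.0 - 1.0,
                            events=np.array([[0.0, 1.0]]), array=array)
        out = o.band_filter(ds)
        np.testing.assert_array_equal(out.data, 0.0)

    def test_band_above_nyquist_rejected(self, small_clean):
        with pytest.raises(ConfigurationError):
            o.band_filter(small_clean, (15.0, 150.0))


class TestLcmvWeights:
    def test_unit_gain_everywhere(self, small_filtered, leadfields):
        w = o.lcmv_weights(small_filtered, leadfields)
        for p in range(0, leadfields.grid.n_points, 97):
            gain = w.weights[p] @ (leadfields.fields[:, p, :] @ w.orientations[p])
            assert gain == pytest.approx(1.0, abs=1e-8)

    def test_orientations_unit_norm(self, small_filtered, leadfields):
        w = o.lcmv_weights(small_filtered, leadfields)
        np.testing.assert_allclose(np.linalg.norm(w.orientations, axis=1), 1.0, atol=1e-9)

    def test_sign_convention(self, small_filtered, leadfields):
        w = o.lcmv_weights(small_filtered, leadfields)
        for p in range(0, leadfields.grid.n_points, 211):
            ww = w.weights[p]
            lead = ww[np.argmax(np.abs(ww) > 1e-3 * np.abs(ww).max())]
            assert lead > 0

    def test_orientation_flip_leaves_power_invariant(self, small_filtered, leadfields):
        cov = o.trial_covariances(small_filtered).mean(axis=0)
        creg = cov + 0.05 * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
        cinv = np.linalg.inv(creg)
        L = leadfields.fields[:, 10, :]
        w = o.lcmv_weights(small_filtered, leadfields)
        theta = w.orientations[10]
        m = L.T @ cinv @ L
        assert theta @ m @ theta == pytest.approx((-theta) @ m @ (-theta), rel=1e-12)

    def test_singular_covariance_needs_regularization(self, array, leadfields):
        rng = np.random.default_rng(0)
        rank1 = np.outer(rng.standard_normal(array.n_channels), rng.standard_normal(300))
        ds = o.TrialDataset(data=rank1[None] * 1e-12, sampling_rate=200.0,
                            times=np.arange(300) / 200.0 - 1.0,
                            events=np.array([[0.0, 0.5]]), array=array)
        with pytest.raises(ConditioningError, match="regularization"):
            o.lcmv_weights(ds, leadfields, regularization=0.0)

    def test_peak_matches_brute_force_oracle(self, coarse_leadfields, simulate_factory):
        # [DERIVED] exhaustive scan over grid points x dense orientation fan,
        # same output-power definition: 1 / (theta^T L^T Creg^-1 L theta)
        for seed in (1, 2, 3):
            ds = simulate_factory(n_trials=15, seed=seed, amplitude_nam=40.0)
            ds, _ = o.synthetic_gradiometry(o.downsample_and_filter(ds))
            dsf = o.band_filter(ds)
            cov = o.trial_covariances(dsf).mean(axis=0)
            oracle_peak, oracle_power = brute_force_scan(cov, coarse_leadfields.fields, 0.05)
            w = o.lcmv_weights(dsf, coarse_leadfields, regularization=0.05)
            creg = cov + 0.05 * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
            cinv = np.linalg.inv(creg)
            m = np.einsum("cpa,cd,dpb->pab", coarse_leadfields.fields, cinv,
                          coarse_leadfields.fields)
            power = 1.0 / np.einsum("pa,pab,pb->p", w.orientations, m, w.orientations)
            assert int(np.argmax(power)) == oracle_peak
            # the eigen solution can only beat the finite fan
            assert power[oracle_peak] >= oracle_power[oracle_peak] * (1 - 1e-9)
            assert power[oracle_peak] <= oracle_power[oracle_peak] * (1 + 1e-3)


class TestFMap:
    def test_identical_windows_give_f_one(self, small_filtered, leadfields):
        w = o.lcmv_weights(small_filtered, leadfields)
        sm = o.f_map(small_filtered, w, baseline_window=(-1.0, 0.0), active_window=(-1.0, 0.0))
        np.testing.assert_allclose(sm.F, 1.0, atol=1e-12)

    def test_statmap_invariants(self, small_filtered, leadfields):
        w = o.lcmv_weights(small_filtered, leadfields)
        sm = o.f_map(small_filtered, w)
        assert np.all(sm.F >= 0)
        assert np.all((sm.p > 0) & (sm.p <= 1))
        assert np.all(sm.magnitude >= 1.0)
        # BH pass set is a p-sorted prefix
        order = np.argsort(sm.p)
        passed = sm.fdr_pass[order]
        if passed.any():
            last = np.max(np.flatnonzero(passed))
            assert passed[: last + 1].all()

    def test_unequal_windows_rejected(self, small_filtered, leadfields):
        w = o.lcmv_weights(small_filtered, leadfields)
        with pytest.raises(ConfigurationError, match="equal length"):
            o.f_map(small_filtered, w, baseline_window=(-1.0, 0.0), active_window=(0.0, 2.0))

    def test_desync_produces_sub_unity_f_at_peak(self, small_filtered, leadfields):
        w = o.lcmv_weights(small_filtered, leadfields)
        sm = o.f_map(small_filtered, w)
        peak = int(np.argmax(np.abs(np.log(sm.F))))
        assert sm.F[peak] < 1.0

    def test_zero_baseline_variance_degenerate(self, array, leadfields):
        n = 400
        data = np.zeros((2, array.n_channels, n))
        rng = np.random.default_rng(1)
        times = np.arange(n) / 200.0 - 1.0
        data[:, :, times >= 0] = rng.standard_normal((2, array.n_channels, int((times >= 0).sum()))) * 1e-12
        ds = o.TrialDataset(data=data, sampling_rate=200.0, times=times,
                            events=np.tile([0.0, 1.0], (2, 1)), array=array)
        w = o.lcmv_weights(ds, leadfields, regularization=0.05)
        with pytest.raises(DegenerateError):
            o.f_map(ds, w, baseline_window=(-1.0, 0.0), active_window=(0.0, 1.0))

    def test_empirical_dof_mode_runs(self, small_filtered, leadfields):
        w = o.lcmv_weights(small_filtered, leadfields)
        sm = o.f_map(small_filtered, w, dof_mode="empirical")
        assert np.all(np.isfinite(sm.p))

    def test_rotation_covariance(self, sphere, grid, simulate_factory, leadfields):
        # rotating sensors, sources and orientations together leaves the
        # channel-space data, and hence the F map, unchanged
        from scipy.spatial.transform import Rotation

        ds = simulate_factory(n_trials=6, seed=31)
        dsf = o.band_filter(o.synthetic_gradiometry(o.downsample_and_filter(ds))[0])
        w = o.lcmv_weights(dsf, leadfields)
        sm = o.f_map(dsf, w)

        rot = Rotation.from_euler("xyz", [10, -20, 30], degrees=True).as_matrix()
        arr = dsf.array
        rarray = o.SensorArray(
            labels=list(arr.labels),
            positions=(arr.positions - sphere.center) @ rot.T + sphere.center,
            orientations=arr.orientations @ rot.T,
            roles=list(arr.roles), sampling_rate=arr.sampling_rate,
        )
        rsphere = o.ConductorSphere(sphere.center, sphere.radius)
        rgrid = o.SourceGrid(points=(grid.points - sphere.center) @ rot.T + sphere.center,
                             spacing=grid.spacing, hemispheres=grid.hemispheres,
                             sphere=rsphere)
        rlf = o.compute_leadfields(rarray, rgrid, rsphere)
        rds = o.TrialDataset(data=dsf.data, sampling_rate=dsf.sampling_rate, times=dsf.times,
                             events=dsf.events, array=rarray)
        rw = o.lcmv_weights(rds, rlf)
        rsm = o.f_map(rds, rw)
        np.testing.assert_allclose(rsm.F, sm.F, rtol=1e-8)

    def test_regularization_smooths_null_map(self, simulate_factory, leadfields):
        ds = simulate_factory(n_trials=12, seed=17, desync_depth=0.0, amplitude_nam=0.0)
        dsf = o.band_filter(o.synthetic_gradiometry(o.downsample_and_filter(ds))[0])
        spreads = []
        for reg in (0.01, 0.05, 0.5):
            w = o.lcmv_weights(dsf, leadfields, regularization=reg)
            sm = o.f_map(dsf, w)
            spreads.append(np.var(np.log(sm.F)))
        assert spreads[0] >= spreads[1] * 0.9
        assert spreads[1] >= spreads[2] * 0.9

    def test_tsv_export(self, small_filtered, leadfields, tmp_path):
        import pandas as pd

        w = o.lcmv_weights(small_filtered, leadfields)
        sm = o.f_map(small_filtered, w)
        path = tmp_path / "statmap.tsv"
        o.beamformer.statmap_to_tsv(sm, path)
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["x_mm", "y_mm", "z_mm", "F", "p", "fdr_pass"]
        assert len(df) == leadfields.grid.n_points

    def test_nifti_export(self, small_filtered, leadfields, tmp_path):
        nib = pytest.importorskip("nibabel")
        w = o.lcmv_weights(small_filtered, leadfields)
        sm = o.f_map(small_filtered, w)
        path = tmp_path / "statmap.nii"
        o.beamformer.statmap_to_nifti(sm, path)
        img = nib.load(str(path))
        vals = img.get_fdata()
        assert np.nansum(vals > 0) == leadfields.grid.n_points


class TestConfidenceVolume:
    def test_determinism(self, small_filtered, leadfields, grid):
        a = o.confidence_volume(small_filtered, leadfields, grid.mask_for("IFG_left"),
                                n_boot=10, seed=3)
        b = o.confidence_volume(small_filtered, leadfields, grid.mask_for("IFG_left"),
                                n_boot=10, seed=3)
        np.testing.assert_array_equal(a.peaks, b.peaks)
        np.testing.assert_array_equal(a.extents, b.extents)

    def test_extents_nonnegative_and_recorded(self, small_filtered, leadfields, grid):
        cv = o.confidence_volume(small_filtered, leadfields, grid.mask_for("IFG_left"),
                                 n_boot=8, seed=1)
        assert np.all(cv.extents >= 0)
        assert cv.n_boot == 8

    def test_stable_single_source_concentrates_peaks(self, simulate_factory, leadfields, grid):
        # strong stable source: every bootstrap resample peaks at the same
        # grid point, so extents collapse to zero.  (A literally noise-free
        # rank-1 dataset is degenerate: its F map is constant over points.)
        ori = o.optimal_tangential_orientation(
            leadfields.array, leadfields.sphere, o.DEFAULT_SOURCE_MM
        )
        ds = simulate_factory(n_trials=30, seed=41, amplitude_nam=60.0, desync_depth=0.9,
                              source_orientations=ori[None], interference_amplitude_t=0.0)
        dsf = o.band_filter(o.synthetic_gradiometry(o.downsample_and_filter(ds))[0])
        cv = o.confidence_volume(dsf, leadfields, grid.mask_for("IFG_left"),
                                 active_window=(0.5, 1.5), n_boot=12, seed=2,
                                 regularization=0.5)
        np.testing.assert_allclose(cv.extents, 0.0, atol=1e-9)

    def test_empty_roi_rejected(self, small_filtered, leadfields, grid):
        with pytest.raises(ConfigurationError, match="empty"):
            o.confidence_volume(small_filtered, leadfields,
                                np.zeros(grid.n_points, bool), n_boot=4, seed=0)

    def test_nboot_validation(self, small_filtered, leadfields, grid):
        with pytest.raises(ConfigurationError):
            o.confidence_volume(small_filtered, leadfields, grid.mask_for("IFG_left"),
                                n_boot=1, seed=0)


class TestSourceTimecourse:
    def test_virtual_channel_shape_and_weights(self, small_clean, small_filtered, leadfields):
        w = o.lcmv_weights(small_filtered, leadfields)
        sm = o.f_map(small_filtered, w)
        peak = int(np.argmax(np.abs(np.log(sm.F))))
        vc = o.source_timecourse(small_clean, w, peak)
        assert vc.data.shape == (small_clean.n_trials, 1, small_clean.n_samples)
        expected = w.weights[peak] @ small_clean.scalp_data()[0]
        np.testing.assert_allclose(vc.data[0, 0], expected)

    def test_percent_change_invariant_to_weight_scale(self, small_clean, small_filtered, leadfields):
        w = o.lcmv_weights(small_filtered, leadfields)
        peak = 50
        vc1 = o.source_timecourse(small_clean, w, peak)
        w_scaled = o.BeamformerWeights(
            weights=w.weights * 7.0, orientations=w.orientations,
            regularization=w.regularization, conditioning=w.conditioning, grid=w.grid,
        )
        vc7 = o.source_timecourse(small_clean, w_scaled, peak)
        c1 = o.percent_change(o.multitaper_tf(vc1, 10, 35))
        c7 = o.percent_change(o.multitaper_tf(vc7, 10, 35))
        np.testing.assert_allclose(c1.values, c7.values, atol=1e-9)

    def test_task_window_change_negative(self, small_clean, small_filtered, leadfields, grid):
        w = o.lcmv_weights(small_filtered, leadfields)
        sm = o.f_map(small_filtered, w)
        roi = grid.mask_for("IFG_left")
        peak = np.flatnonzero(roi)[int(np.argmax(np.abs(np.log(sm.F[roi]))))]
        vc = o.source_timecourse(small_clean, w, int(peak))
        course = o.percent_change(o.multitaper_tf(vc, 10, 35))
        task_bins = (course.times >= 0.5) & (course.times < 2.5)
        assert course.values[0, task_bins].mean() < 0

    def test_envelope_correlation(self, simulate_factory, leadfields, grid):
        # [DERIVED] virtual channel beta power tracks the stored source envelope
        ds, comp = simulate_factory(return_components=True, n_trials=20, seed=51,
                                    amplitude_nam=40.0)
        clean, _ = o.synthetic_gradiometry(o.downsample_and_filter(ds))
        dsf = o.band_filter(clean)
        w = o.lcmv_weights(dsf, leadfields)
        sm = o.f_map(dsf, w)
        peak = int(np.argmax(np.abs(np.log(sm.F))))
        vc = o.source_timecourse(clean, w, peak)
        spec = o.multitaper_tf(vc, 10, 35)
        power = o.band_power(spec, (15.0, 30.0)).mean(axis=0)[0]  # (times,)
        env2 = comp["envelope"] ** 2  # (trials, samples) at 1000 Hz
        idx = np.clip(((spec.times + 2.0) * 1000).astype(int), 0, env2.shape[1] - 1)
        target = env2.mean(axis=0)[idx]
        r = np.corrcoef(power, target)[0, 1]
        assert r >= 0.8
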