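import numpy as np
import pytest

from diametric.exceptions import ValidationError
from diametric.falff import FrequencyBand
from diametric.io import BoldRun, VolumeMask
from diametric.preprocess import (
    ConfoundMatrix,
    OutlierConfig,
    acompcor_components,
    build_confounds,
    denoise,
    detect_outliers,
    erode_mask,
    global_signal,
    smooth,
)


class TestDetectOutliers:
    def test_constant_motion_and_signal_flag_nothing(self):
        flags = detect_outliers(np.ones((50, 6)), np.ones(50))
        assert flags.sum() == 0

    def test_displacement_step_flags_exactly_that_volume(self):
        motion = np.zeros((50, 6))
        motion[10:, 0] = 0.6  # x jumps 0.6 mm between t=9 and t=10
        flags = detect_outliers(motion, np.zeros(50), OutlierConfig(0.5, 3.0))
        assert flags[10]
        assert flags.sum() == 1

    def test_volume_zero_never_flagged_by_displacement(self):
        motion = np.zeros((20, 6))
        motion[0, 1] = 5.0  # large absolute position, no step after t=0
        motion[1:, 1] = 5.0
        flags = detect_outliers(motion, np.zeros(20))
        assert not flags.any()

    def test_intensity_rule_matches_direct_recomputation(self, rng):
        """Flag iff |g - mean| > 3 * sd with sd over the entire series."""
        g = rng.standard_normal(100)
        g[40] += 6.0
        flags = detect_outliers(np.zeros((100, 6)), g, OutlierConfig(0.5, 3.0))
        expected = np.abs(g - g.mean()) > 3.0 * g.std()
        assert np.array_equal(flags, expected)
        assert flags[40]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            detect_outliers(np.zeros((10, 6)), np.zeros(9))


class TestErodeMask:
    def test_solid_3cube_erodes_to_center(self, grid8, cube_mask):
        eroded = erode_mask(cube_mask((2, 2, 2), (4, 4, 4)))
        assert eroded.n_voxels == 1
        assert eroded.voxels[3, 3, 3]

    def test_single_voxel_erodes_to_empty_with_warning(self, grid8):
        vox = np.zeros(grid8.shape, bool)
        vox[4, 4, 4] = True
        with pytest.warns(UserWarning, match="empty"):
            eroded = erode_mask(VolumeMask(grid8, vox))
        assert eroded.n_voxels == 0

    def test_5cube_matches_brute_force_neighborhood_rule(self, cube_mask):
        mask = cube_mask((1, 1, 1), (5, 5, 5))
        eroded = erode_mask(mask)
        # brute force: survive iff self and all 6 face neighbors inside
        vox = mask.voxels
        expect = np.zeros_like(vox)
        for i in range(1, 7):
            for j in range(1, 7):
                for k in range(1, 7):
                    if vox[i, j, k] and all(
                        vox[i + di, j + dj, k + dk]
                        for di, dj, dk in (
                            (1, 0, 0), (-1, 0, 0), (0, 1, 0),
                            (0, -1, 0), (0, 0, 1), (0, 0, -1),
                        )
                    ):
                        expect[i, j, k] = True
        assert np.array_equal(eroded.voxels, expect)
        assert eroded.n_voxels == 27


class TestACompCor:
    def test_common_source_recovered_as_first_component(self, grid8, cube_mask):
        g = np.random.default_rng(2)
        source = g.standard_normal(80)
        data = np.zeros(grid8.shape + (80,))
        mask = cube_mask((1, 1, 1), (3, 3, 3))
        data[mask.voxels] = source + 0.01 * g.standard_normal(
            (mask.n_voxels, 80)
        )
        run = BoldRun(grid8, data + 1.0, 2.0)
        comps = acompcor_components(run, mask, 3)
        r = np.corrcoef(comps[:, 0], source)[0, 1]
        assert abs(r) > 0.99

    def test_components_orthonormal(self, make_run, cube_mask):
        comps = acompcor_components(make_run(seed=4), cube_mask(), 5)
        gram = comps.T @ comps
        assert np.allclose(gram, np.eye(5), atol=1e-8)

    def test_component_count_reduced_with_warning(self, grid8):
        g = np.random.default_rng(3)
        vox = np.zeros(grid8.shape, bool)
        vox[0, 0, :3] = True
        data = g.standard_normal(grid8.shape + (40,))
        with pytest.warns(UserWarning, match="available"):
            comps = acompcor_components(
                BoldRun(grid8, data, 2.0), VolumeMask(grid8, vox), 5
            )
        assert comps.shape[1] == 3

    def test_white_noise_components_share_variance(self, grid8, cube_mask):
        """No dominant direction in a pure-noise mask: top components carry
        comparable (Marchenko-Pastur bounded) variance shares."""
        g = np.random.default_rng(5)
        run = BoldRun(grid8, g.standard_normal(grid8.shape + (120,)), 2.0)
        mask = cube_mask((0, 0, 0), (5, 5, 5))  # 216 voxels
        X = run.data[mask.voxels]
        Xn = (X - X.mean(1, keepdims=True)) / X.std(1, keepdims=True)
        s = np.linalg.svd(Xn.T, compute_uv=False)
        shares = s**2 / (s**2).sum()
        # loose Marchenko-Pastur-style bounds: the top share stays near the
        # bulk-edge prediction and the leading components are comparable
        v_over_t = mask.n_voxels / 120
        edge_share = (1 + np.sqrt(v_over_t)) ** 2 / (120 * v_over_t)
        assert shares[0] < 2.0 * edge_share
        assert shares[0] / shares[4] < 1.5


class TestBuildConfounds:
    def _setup(self, make_run, cube_mask, n_outliers=0):
        run = make_run(n_volumes=60, seed=6)
        wm = cube_mask((1, 1, 1), (3, 3, 3))
        csf = cube_mask((5, 5, 5), (7, 7, 7))
        g = np.random.default_rng(7)
        motion = np.cumsum(g.normal(0, 0.02, (60, 6)), axis=0)
        flags = np.zeros(60, bool)
        flags[:n_outliers] = True
        return run, wm, csf, motion, flags

    def test_column_arithmetic_without_outliers(self, make_run, cube_mask):
        run, wm, csf, motion, flags = self._setup(make_run, cube_mask)
        cm = build_confounds(run, wm, csf, motion, flags, 5)
        assert cm.values.shape[1] == 5 + 5 + 6 + 6 + 1  # 23
        assert cm.labels[-1] == "trend"

    def test_column_arithmetic_with_outliers(self, make_run, cube_mask):
        run, wm, csf, motion, flags = self._setup(make_run, cube_mask, 3)
        cm = build_confounds(run, wm, csf, motion, flags, 5)
        assert cm.values.shape[1] == 26
        assert sum(lbl.startswith("outlier_") for lbl in cm.labels) == 3

    def test_constant_motion_derivatives_dropped(self, make_run, cube_mask):
        run, wm, csf, motion, flags = self._setup(make_run, cube_mask)
        motion = np.ones((60, 6))
        with pytest.warns(UserWarning, match="all-zero"):
            cm = build_confounds(run, wm, csf, motion, flags, 2)
        assert not any(lbl.startswith("dmotion") for lbl in cm.labels)

    def test_fully_flagged_run_rejected(self, make_run, cube_mask):
        run, wm, csf, motion, _ = self._setup(make_run, cube_mask)
        with pytest.raises(ValidationError, match="no usable volumes"):
            build_confounds(run, wm, csf, motion, np.ones(60, bool), 5)


class TestDenoise:
    def test_voxel_equal_to_confound_fully_removed(self, grid8):
        g = np.random.default_rng(8)
        conf = g.standard_normal(64)
        data = np.tile(conf, grid8.shape + (1,))
        run = BoldRun(grid8, data, 2.0)
        cm = ConfoundMatrix(conf[:, None], ["c1"])
        out = denoise(run, cm, band=None)
        assert np.abs(out.data).max() < 1e-8 * np.abs(data).max()

    def test_out_of_band_sinusoid_suppressed(self, grid8):
        t = np.arange(64) * 2.0
        sig = np.sin(2 * np.pi * 0.15 * t)
        run = BoldRun(grid8, np.tile(sig, grid8.shape + (1,)), 2.0)
        out = denoise(run, None, FrequencyBand(0.008, 0.09))
        rms_in = np.sqrt((sig**2).mean())
        rms_out = np.sqrt((out.data[0, 0, 0] ** 2).mean())
        assert rms_out < 0.05 * rms_in

    def test_empty_confounds_equals_bandpassed_input(self, make_run):
        from diametric._filters import bandpass_ideal

        run = make_run(n_volumes=64, seed=9)
        out = denoise(run, None, FrequencyBand())
        expect = bandpass_ideal(run.data, 2.0, 0.008, 0.09, axis=-1)
        assert np.allclose(out.data, expect)

    def test_residuals_orthogonal_to_filtered_confounds(self, make_run):
        from diametric._filters import bandpass_ideal

        run = make_run(n_volumes=64, seed=10)
        g = np.random.default_rng(11)
        cm = ConfoundMatrix(g.standard_normal((64, 4)), list("abcd"))
        band = FrequencyBand()
        out = denoise(run, cm, band)
        Xf = bandpass_ideal(cm.values, 2.0, band.low_hz, band.high_hz, axis=0)
        Y = out.data.reshape(-1, 64).T
        corr = Xf.T @ Y / 64
        assert np.abs(corr).max() < 1e-6

    def test_outlier_indicators_zero_flagged_volumes(self, make_run):
        """Scrubbing by regression: with indicator columns (and no temporal
        filter) the flagged volumes' residuals vanish exactly."""
        run = make_run(n_volumes=64, seed=12)
        ind = np.zeros((64, 2))
        ind[10, 0] = 1.0
        ind[30, 1] = 1.0
        cm = ConfoundMatrix(ind, ["outlier_10", "outlier_30"])
        out = denoise(run, cm, band=None)
        assert np.abs(out.data[..., 10]).max() < 1e-8
        assert np.abs(out.data[..., 30]).max() < 1e-8

    def test_denoising_is_linear(self, make_run):
        run = make_run(n_volumes=64, seed=13)
        g = np.random.default_rng(14)
        cm = ConfoundMatrix(g.standard_normal((64, 3)), list("abc"))
        band = FrequencyBand()
        once = denoise(run, cm, band).data
        scaled = denoise(run.with_data(3.0 * run.data), cm, band).data
        assert np.allclose(scaled, 3.0 * once, atol=1e-10)

    def test_rank_deficient_confounds_warn_but_project(self, make_run):
        run = make_run(n_volumes=64, seed=15)
        g = np.random.default_rng(16)
        col = g.standard_normal(64)
        cm = ConfoundMatrix(np.column_stack([col, col]), ["a", "b"])
        with pytest.warns(UserWarning, match="rank deficient"):
            out = denoise(run, cm, band=None)
        resid = out.data.reshape(-1, 64) @ (col - col.mean())
        assert np.abs(resid).max() < 1e-6 * np.abs(run.data).max() * 64


class TestSmooth:
    def test_constant_volume_preserved(self, grid8):
        run = BoldRun(grid8, np.full(grid8.shape + (10,), 3.5), 2.0)
        out = smooth(run, 8.0)
        assert np.allclose(out.data, 3.5)

    def test_noise_variance_reduced(self, make_run):
        run = make_run(n_volumes=10, seed=17)
        out = smooth(run, 8.0)
        assert out.data.var() < 0.5 * run.data.var()
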