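import numpy as np
import pytest
import sympy

import enameloct as e
from enameloct.simulation import (
    cosine_amplitude_for_curvature,
    db_from_linear,
)


class TestMaLine:
    def test_signal_vanishes_at_zero_depth(self):
        params = e.SimulationParams(depth_grid=np.array([0.0, 4.4, 8.8]),
                                    z1=0.0, z2=8.8)
        linear, db = e.ma_line(params)
        assert linear[0] == 0.0
        assert db[0] == 0.0  # background marker, not -inf

    def test_unit_magnification_doubles_band(self):
        params = e.SimulationParams(m=1.0)
        linear, _ = e.ma_line(params)
        base = e.ma_line(e.SimulationParams(m=1.0, z1=0.0, z2=4.4))
        z = params.depth_grid
        in_band = (z >= params.z1) & (z <= params.z2)
        i1 = (params.a * z * np.exp(-2 * params.mu_t1 * z * params.s)
              + params.b * z * np.exp(-2 * params.mu_t2 * z * params.s))
        np.testing.assert_allclose(linear[in_band], 2 * i1[in_band])
        np.testing.assert_allclose(linear[~in_band], i1[~in_band])

    def test_matches_symbolic_evaluation(self):
        """Cross-check against an independent sympy rendering of the model."""
        a, b, mu1, mu2, s, m = 1.3, 900.0, 0.03, 0.18, 0.125, 2.5
        z1, z2 = 120.0, 280.0
        grid = np.linspace(4.4, 430.0, 10)
        params = e.SimulationParams(a=a, b=b, mu_t1=mu1, mu_t2=mu2, s=s,
                                    m=m, z1=z1, z2=z2, depth_grid=grid)
        linear, _ = e.ma_line(params)
        zs = sympy.symbols("z")
        i1 = (a * zs * sympy.exp(-2 * mu1 * zs * s)
              + b * zs * sympy.exp(-2 * mu2 * zs * s))
        for zk, got in zip(grid, linear):
            expected = i1.subs(zs, zk)
            if z1 <= zk <= z2:
                expected = expected * (1 + m)
            assert got == pytest.approx(float(expected), rel=1e-12)

    def test_band_ratio_property(self):
        params = e.SimulationParams(m=3.0)
        linear, _ = e.ma_line(params)
        z = params.depth_grid
        i1 = (params.a * z * np.exp(-2 * params.mu_t1 * z * params.s)
              + params.b * z * np.exp(-2 * params.mu_t2 * z * params.s))
        ratio = linear / i1
        in_band = (z >= params.z1) & (z <= params.z2)
        np.testing.assert_allclose(ratio[in_band], 4.0)
        np.testing.assert_allclose(ratio[~in_band], 1.0)

    def test_larger_scale_shortens_threshold_depth(self):
        """Increasing S strictly shortens the depth at which the profile
        falls below any fixed dB level."""
        def depth_below(s_value, level_db=16.0):
            # negligible magnification isolates the base profile I1
            _, db = e.ma_line(e.SimulationParams(s=s_value, m=1e-9))
            above = np.flatnonzero(db >= level_db)
            return above.max()

        assert depth_below(0.15) < depth_below(0.125) < depth_below(0.10)

    def test_degenerate_amplitudes_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            e.ma_line(e.SimulationParams(a=0.0, b=0.0))


class TestLsLine:
    def test_low_degree_polynomial_reproduced(self):
        x = np.arange(40, dtype=float)
        y = 2 + 0.5 * x - 0.02 * x ** 2 + 1e-4 * x ** 5
        np.testing.assert_allclose(e.ls_line(y, degree=5), y, rtol=1e-9)

    def test_constant_input_reproduced(self):
        np.testing.assert_allclose(e.ls_line(np.full(30, 7.0), degree=20),
                                   np.full(30, 7.0), atol=1e-8)

    def test_fits_mathematical_aline_closely(self):
        linear, _ = e.ma_line(e.SimulationParams())
        fitted = e.ls_line(linear, degree=20)
        rms = np.sqrt(np.mean((fitted - linear) ** 2))
        assert rms < 0.05 * linear.max()

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            e.ls_line(np.arange(10.0), degree=20)


class TestRaLine:
    def test_single_column_roi_returns_that_aline(self, flat_sim):
        profile = e.ra_line([flat_sim.bscan], roi_cols=slice(0, 1))
        col = flat_sim.bscan.intensity_db[:, 0]
        tissue = col != 0
        np.testing.assert_allclose(profile[tissue], col[tissue])

    def test_duplicate_frames_change_nothing(self, flat_sim):
        one = e.ra_line([flat_sim.bscan])
        two = e.ra_line([flat_sim.bscan, flat_sim.bscan])
        np.testing.assert_allclose(one, two)

    def test_average_converges_to_noiseless_profile(self, cmap):
        """With additive zero-mean linear noise the batch average approaches
        the noiseless A-scan."""
        rng = np.random.default_rng(19)
        params = e.SimulationParams()
        linear, db = e.ma_line(params)
        surface = e.make_surface("F_sur", 40, row=3)
        frames = []
        for _ in range(100):
            noisy_linear = linear * rng.uniform(0.7, 1.3, linear.size)
            sim = e.build_bscan(db_from_linear(noisy_linear), surface,
                                cmap=cmap, params=params)
            frames.append(sim.bscan)
        avg = e.ra_line(frames)
        tissue_rows = slice(3, 3 + linear.size)
        got = 10 ** (avg[tissue_rows] / 10)
        # one shared noise draw per frame: standard error ~ sd/sqrt(100)
        np.testing.assert_allclose(got, linear, rtol=0.06)

    def test_empty_frame_list_rejected(self):
        with pytest.raises(ValueError):
            e.ra_line([])


class TestMakeSurface:
    def test_flat_surface_has_unit_curvature(self):
        surf = e.make_surface("F_sur", 60, row=5)
        geom = e.surface_geometry(surf, 4.4, 19.5)
        assert geom.curvature_index == 1.0

    def test_zero_amplitude_cosine_is_flat(self):
        cos0 = e.make_surface("M_sur", 60, offset_row=5, amplitude_px=0,
                              period_cols=60)
        flat = e.make_surface("F_sur", 60, row=5)
        np.testing.assert_array_equal(cos0.surface_row, flat.surface_row)

    def test_amplitude_solved_for_target_curvature_band(self):
        """Root-finding reproduces the reported 1.07-1.09 sample curvature."""
        width, ps_a, ps_l = 225, 4.4, 19.5
        amp_um = cosine_amplitude_for_curvature(1.08, width * ps_l)
        surf = e.make_surface("M_sur", width, offset_row=amp_um / ps_a + 2,
                              amplitude_px=amp_um / ps_a, period_cols=width)
        geom = e.surface_geometry(surf, ps_a, ps_l)
        assert 1.07 <= geom.curvature_index <= 1.09

    def test_non_monotone_control_points_rejected(self):
        with pytest.raises(ValueError):
            e.make_surface("D_sur", 30,
                           control_points=[(0, 5), (20, 8), (10, 6)])

    def test_supplied_profile_roundtrip(self):
        rows = np.arange(2, 32)
        surf = e.make_surface("S_sur", 30, profile=rows)
        np.testing.assert_array_equal(surf.surface_row, rows)


class TestBuildBScan:
    def test_flat_surface_columns_identical(self, flat_sim):
        cols = flat_sim.bscan.intensity_db
        np.testing.assert_array_equal(cols, cols[:, :1].repeat(cols.shape[1],
                                                               axis=1))

    def test_truth_limits_match_segmentation_of_noiseless_frame(
            self, cmap, clean_batch):
        for sim in clean_batch:
            _, _, _, limits = e.segment_frame(sim.bscan, cmap)
            np.testing.assert_array_equal(limits.delta_ia,
                                          sim.truth_limits.delta_ia)
            np.testing.assert_array_equal(limits.delta_ie,
                                          sim.truth_limits.delta_ie)

    def test_truth_invariant_to_surface_kind(self, cmap):
        params = e.SimulationParams()
        _, db = e.ma_line(params)
        flat = e.build_bscan(db, e.make_surface("F_sur", 50, row=2),
                             cmap=cmap)
        curved = e.build_bscan(
            db, e.make_surface("M_sur", 50, offset_row=12, amplitude_px=10,
                               period_cols=50), cmap=cmap)
        assert flat.true_depths() == curved.true_depths()

    def test_overflow_truncated_with_warning(self, cmap, caplog):
        _, db = e.ma_line(e.SimulationParams())
        surf = e.make_surface("F_sur", 10, row=5)
        sim = e.build_bscan(db, surf, cmap=cmap, height=50)
        assert sim.bscan.shape[0] == 50


class TestExtractSpeckle:
    def test_constant_frame_has_zero_noise(self):
        frame = e.BScan(np.full((10, 10), 20.0))
        for method in ("median3", "wiener5"):
            assert not e.extract_speckle(frame, method).intensity_db.any()

    @pytest.mark.parametrize("method,size", [("median3", 3), ("wiener5", 5)])
    def test_reconstruction_identity(self, method, size, speckled_batch):
        from scipy import ndimage, signal

        frame = speckled_batch[0].bscan
        noise = e.extract_speckle(frame, method)
        # recompute the smoothed frame independently; the residual is the
        # frame-minus-filtered difference bit-exactly
        if method == "median3":
            filtered = ndimage.median_filter(frame.intensity_db, size=size)
        else:
            pad = size // 2
            padded = np.pad(frame.intensity_db, pad, mode="edge")
            filtered = signal.wiener(padded, mysize=size)[pad:-pad, pad:-pad]
        np.testing.assert_array_equal(noise.intensity_db,
                                      frame.intensity_db - filtered)
        np.testing.assert_allclose(filtered + noise.intensity_db,
                                   frame.intensity_db, rtol=0, atol=1e-12)

    def test_median_noise_concentrated_at_impulse(self):
        values = np.full((11, 11), 10.0)
        values[5, 5] = 30.0
        noise = e.extract_speckle(e.BScan(values), "median3").intensity_db
        assert noise[5, 5] == 20.0
        outside = np.ones((11, 11), bool)
        outside[4:7, 4:7] = False
        assert not noise[outside].any()

    def test_small_frame_rejected(self):
        with pytest.raises(ValueError):
            e.extract_speckle(e.BScan(np.zeros((3, 3))), "wiener5")


class TestSimulateDataset:
    def test_same_seed_bit_identical(self):
        a = e.simulate_dataset(4, seed=21, width=60)
        b = e.simulate_dataset(4, seed=21, width=60)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.bscan.intensity_db,
                                          s2.bscan.intensity_db)

    def test_23_frames_span_all_surface_kinds(self):
        sims = e.simulate_dataset(23, seed=2, speckle_sigma_db=0.0, width=60)
        assert len(sims) == 23
        assert {s.surface_kind for s in sims} == set(
            ("F_sur", "S_sur", "M_sur", "D_sur"))

    def test_true_die_increases_with_z2(self, cmap):
        depths = []
        for z2 in (240.0, 280.0, 320.0, 360.0):
            params = e.SimulationParams(z2=z2)
            _, db = e.ma_line(params)
            sim = e.build_bscan(db, e.make_surface("F_sur", 20, row=2),
                                cmap=cmap, params=params)
            depths.append(sim.true_depths()[1])
        assert np.all(np.diff(depths) > 0)

    def test_empty_parameter_range_rejected(self):
        with pytest.raises(ValueError):
            e.simulate_dataset(2, seed=0, param_ranges={"m": (3.0, 2.0)})
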