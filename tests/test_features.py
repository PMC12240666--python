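"""Measure computation: nuisance regression, spectra, GS, GSCORR, SFI."""

import numpy as np
import pytest

from gstopo.io import BoldImage, Parcellation
from gstopo.features import (
    aggregate_levels,
    build_nuisance_design,
    compute_alff_falff,
    compute_gscorr,
    compute_sfi,
    extract_gs,
    regress_nuisance,
    roi_gmv,
    smooth_map,
    z_standardize,
)


def _bold(data, tr=2.0):
    return BoldImage(data=np.asarray(data, float), tr_seconds=tr, affine=np.eye(4))


class TestNuisanceRegression:
    def _setup(self, rng, t=80, shape=(6, 6, 4)):
        data = rng.normal(size=shape + (t,))
        wm = np.zeros(shape, bool); wm[0, :, :] = True
        csf = np.zeros(shape, bool); csf[1, :, :] = True
        motion = rng.normal(scale=0.05, size=(t, 6))
        return data, wm, csf, motion

    def test_design_has_expected_columns(self, rng):
        data, wm, csf, motion = self._setup(rng)
        d = build_nuisance_design(motion, data[wm].mean(0), data[csf].mean(0))
        # 24 motion + wm + csf + intercept + trend
        assert d.matrix.shape[1] == 28
        assert not d.dropped

    def test_voxel_in_design_span_has_null_residual(self, rng):
        data, wm, csf, motion = self._setup(rng)
        wm_mean = data[wm].mean(axis=0)
        data[3, 3, 2] = wm_mean  # voxel equal to the WM regressor
        resid = regress_nuisance(_bold(data), motion, wm, csf)
        np.testing.assert_allclose(resid.data[3, 3, 2], 0.0, atol=1e-10)

    def test_constant_motion_collinear_columns_dropped(self, rng):
        data, wm, csf, _ = self._setup(rng)
        motion = np.ones((80, 6)) * 0.3
        d = build_nuisance_design(motion, data[wm].mean(0), data[csf].mean(0))
        assert len(d.dropped) >= 20  # all but one constant-ish motion column
        resid = regress_nuisance(_bold(data), motion, wm, csf)
        assert np.isfinite(resid.data).all()

    def test_residuals_match_normal_equations_oracle(self, rng):
        data, wm, csf, motion = self._setup(rng)
        resid = regress_nuisance(_bold(data), motion, wm, csf)
        d = build_nuisance_design(motion, data[wm].mean(0), data[csf].mean(0))
        x = d.matrix
        beta_or = np.linalg.solve(x.T @ x, x.T @ data[3, 2, 1])
        np.testing.assert_allclose(resid.data[3, 2, 1], data[3, 2, 1] - x @ beta_or,
                                   atol=1e-10)

    def test_residuals_orthogonal_to_every_regressor(self, rng):
        data, wm, csf, motion = self._setup(rng)
        resid = regress_nuisance(_bold(data), motion, wm, csf)
        d = build_nuisance_design(motion, data[wm].mean(0), data[csf].mean(0))
        r = resid.data[4, 4, 2]
        for j in range(d.matrix.shape[1]):
            col = d.matrix[:, j]
            assert abs(r @ col) < 1e-8 * max(np.linalg.norm(r) * np.linalg.norm(col), 1.0)

    def test_short_series_rejected_with_advice(self, rng):
        data, wm, csf, motion = self._setup(rng, t=20)
        with pytest.raises(ValueError, match="longer"):
            regress_nuisance(_bold(data[..., :20]), motion[:20], wm, csf)


class TestAlffFalff:
    def test_pure_sinusoid_concentrates_power_in_band(self):
        t = np.arange(200) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)
        data = np.broadcast_to(x, (2, 2, 2, 200)).copy()
        mask = np.ones((2, 2, 2), bool)
        amp = compute_alff_falff(_bold(data), mask)
        assert amp.falff[0, 0, 0] >= 0.95

    def test_matches_periodogram_oracle(self, rng):
        data = rng.normal(size=(3, 3, 2, 200))
        mask = np.ones((3, 3, 2), bool)
        amp = compute_alff_falff(_bold(data), mask)
        x = data[1, 2, 1]
        a = np.abs(np.fft.rfft(x)) / 200
        freqs = np.fft.rfftfreq(200, d=2.0)
        band = (freqs >= 0.01) & (freqs <= 0.1) & (freqs > 0)
        assert amp.alff[1, 2, 1] == pytest.approx(a[band].mean(), abs=1e-10)
        assert amp.falff[1, 2, 1] == pytest.approx(a[band].sum() / a[freqs > 0].sum(),
                                                   abs=1e-10)

    def test_constant_series_flagged_with_zero_falff(self):
        data = np.ones((2, 2, 1, 50))
        mask = np.ones((2, 2, 1), bool)
        amp = compute_alff_falff(_bold(data), mask)
        assert amp.alff[0, 0, 0] == 0.0
        assert amp.falff[0, 0, 0] == 0.0
        assert amp.n_flagged == 4

    def test_alff_scales_linearly_with_amplitude(self, rng):
        data = rng.normal(size=(2, 2, 1, 120))
        mask = np.ones((2, 2, 1), bool)
        a1 = compute_alff_falff(_bold(data), mask)
        a3 = compute_alff_falff(_bold(3.0 * data), mask)
        np.testing.assert_allclose(a3.alff[mask], 3.0 * a1.alff[mask], atol=1e-10)
        np.testing.assert_allclose(a3.falff[mask], a1.falff[mask], atol=1e-10)

    def test_falff_bounded_in_unit_interval(self, rng):
        data = rng.normal(size=(4, 4, 2, 64))
        mask = np.ones((4, 4, 2), bool)
        amp = compute_alff_falff(_bold(data, tr=1.7), mask)
        assert ((amp.falff >= 0) & (amp.falff <= 1)).all()

    def test_white_noise_falff_matches_bin_counting_expectation(self):
        rng = np.random.default_rng(5)
        freqs = np.fft.rfftfreq(200, d=2.0)
        expect = ((freqs >= 0.01) & (freqs <= 0.1) & (freqs > 0)).sum() / (freqs > 0).sum()
        vals = []
        for _ in range(100):
            data = rng.normal(size=(1, 1, 1, 200))
            amp = compute_alff_falff(_bold(data), np.ones((1, 1, 1), bool))
            vals.append(amp.falff[0, 0, 0])
        se = np.std(vals, ddof=1) / 10
        assert abs(np.mean(vals) - expect) < 3 * se + 0.01

    def test_band_outside_nyquist_rejected(self, rng):
        data = rng.normal(size=(2, 2, 1, 50))
        with pytest.raises(ValueError, match="Nyquist"):
            compute_alff_falff(_bold(data, tr=10.0), np.ones((2, 2, 1), bool))


class TestZStandardizeAndSmooth:
    def test_standardized_map_is_fixed_point(self, rng):
        mask = np.ones((6, 6, 4), bool)
        m = rng.normal(size=(6, 6, 4))
        z = z_standardize(m, mask)
        np.testing.assert_allclose(z_standardize(z, mask), z, atol=1e-12)

    def test_affine_invariance(self, rng):
        mask = np.ones((6, 6, 4), bool)
        m = rng.normal(size=(6, 6, 4))
        np.testing.assert_allclose(z_standardize(3.2 * m - 7.0, mask),
                                   z_standardize(m, mask), atol=1e-10)

    def test_matches_mu_sigma_oracle_and_unit_moments(self, rng):
        mask = rng.uniform(size=(6, 6, 4)) < 0.7
        m = rng.normal(size=(6, 6, 4))
        z = z_standardize(m, mask)
        np.testing.assert_allclose(z[mask], (m[mask] - m[mask].mean()) / m[mask].std())
        assert abs(z[mask].mean()) < 1e-9 and abs(z[mask].std() - 1) < 1e-9
        assert (z[~mask] == 0).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            z_standardize(np.ones((3, 3, 3)), np.ones((3, 3, 3), bool))

    def test_zero_fwhm_is_identity(self, rng):
        m = rng.normal(size=(5, 5, 5))
        np.testing.assert_array_equal(smooth_map(m, 0.0, 1.0), m)

    def test_constant_map_invariant_under_smoothing(self):
        m = np.full((8, 8, 8), 2.5)
        np.testing.assert_allclose(smooth_map(m, 6.0, 2.0), m, atol=1e-9)

    def test_impulse_center_matches_analytic_gaussian(self):
        # sigma = 2 mm at 1 mm voxels: center of the smoothed impulse equals
        # the 3D Gaussian normalization 1/(2 pi sigma^2)^{3/2}
        sigma = 2.0
        fwhm = sigma * 2 * np.sqrt(2 * np.log(2))
        m = np.zeros((31, 31, 31))
        m[15, 15, 15] = 1.0
        sm = smooth_map(m, fwhm, 1.0)
        assert sm[15, 15, 15] == pytest.approx((2 * np.pi * sigma**2) ** -1.5, abs=1e-6)


class TestGsAndGscorr:
    def test_uniform_gm_series_recovered_exactly(self, rng):
        x = rng.normal(size=40)
        data = np.zeros((4, 4, 2, 40))
        gm = np.zeros((4, 4, 2), bool)
        gm[1:3, 1:3, :] = True
        data[gm] = x
        # identical voxel series: recovery exact up to summation order (1 ulp)
        np.testing.assert_allclose(extract_gs(_bold(data), gm), x, rtol=1e-15, atol=0)

    def test_two_voxel_average(self, rng):
        a, b = rng.normal(size=(2, 30))
        data = np.zeros((2, 1, 1, 30))
        data[0, 0, 0], data[1, 0, 0] = a, b
        gm = np.ones((2, 1, 1), bool)
        np.testing.assert_allclose(extract_gs(_bold(data), gm), (a + b) / 2)

    def test_matches_mask_loop_oracle(self, rng):
        data = rng.normal(size=(5, 5, 4, 30))
        gm = rng.uniform(size=(5, 5, 4)) < 0.5
        gs = extract_gs(_bold(data), gm)
        oracle = np.mean([data[i, j, k] for i, j, k in np.argwhere(gm)], axis=0)
        np.testing.assert_allclose(gs, oracle, atol=1e-12)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            extract_gs(_bold(rng.normal(size=(2, 2, 2, 10))), np.zeros((2, 2, 2), bool))

    def _parc(self, shape, n_rois, rng):
        labels = rng.integers(1, n_rois + 1, size=shape)
        nets = ["CON", "FPN", "DMN", "SEN", "ON", "CEN"]
        return Parcellation(labels=labels,
                            network_of={r: nets[(r - 1) % 6] for r in range(1, n_rois + 1)})

    def test_roi_identical_to_gs_clips_at_documented_bound(self, rng, caplog):
        shape = (4, 4, 2)
        labels = np.ones(shape, int)
        parc = Parcellation(labels=labels, network_of={1: "DMN"})
        x = rng.normal(size=50)
        data = np.broadcast_to(x, shape + (50,)).copy()
        z = compute_gscorr(_bold(data), x, parc)
        assert z[0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_orthogonal_sinusoids_give_near_zero_z(self):
        t = np.arange(100)
        sin = np.sin(2 * np.pi * 5 * t / 100)
        cos = np.cos(2 * np.pi * 5 * t / 100)
        shape = (2, 2, 1)
        parc = Parcellation(labels=np.ones(shape, int), network_of={1: "DMN"})
        data = np.broadcast_to(sin, shape + (100,)).copy()
        z = compute_gscorr(_bold(data), cos, parc)
        assert abs(z[0]) < 1e-10

    def test_matches_per_roi_loop_oracle(self, rng):
        shape = (6, 6, 4)
        parc = self._parc(shape, 12, rng)
        data = rng.normal(size=shape + (60,))
        gs = rng.normal(size=60)
        z = compute_gscorr(_bold(data), gs, parc)
        for i, roi in enumerate(parc.roi_ids):
            series = data[parc.labels == roi].mean(axis=0)
            r = np.corrcoef(series, gs)[0, 1]
            assert z[i] == pytest.approx(np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7)),
                                         abs=1e-10)

    def test_invariant_to_affine_rescaling_of_inputs(self, rng):
        shape = (6, 6, 4)
        parc = self._parc(shape, 6, rng)
        data = rng.normal(size=shape + (60,))
        gs = rng.normal(size=60)
        z1 = compute_gscorr(_bold(data), gs, parc)
        z2 = compute_gscorr(_bold(2.5 * data + 1.0), 0.3 * gs - 2.0, parc)
        np.testing.assert_allclose(z1, z2, atol=1e-10)

    def test_zero_variance_roi_names_roi(self, rng):
        shape = (4, 4, 2)
        labels = np.ones(shape, int); labels[0, 0, 0] = 2
        parc = Parcellation(labels=labels, network_of={1: "DMN", 2: "SEN"})
        data = rng.normal(size=shape + (30,))
        data[0, 0, 0] = 5.0
        with pytest.raises(ValueError, match="2"):
            compute_gscorr(_bold(data), rng.normal(size=30), parc)


class TestGmvSfiAggregation:
    def _parc(self):
        labels = np.zeros((4, 4, 2), int)
        labels[0, 0, 0] = 1; labels[0, 1, 0] = 1
        labels[1, 0, 0] = 2
        labels[2:, :, :] = 3
        nets = {1: "CON", 2: "SEN", 3: "DMN"}
        return Parcellation(labels=labels, network_of=nets)

    def test_constant_and_two_voxel_means(self):
        parc = self._parc()
        gmv = np.zeros((4, 4, 2))
        gmv[0, 0, 0], gmv[0, 1, 0] = 0.2, 0.4
        gmv[1, 0, 0] = 0.5
        gmv[2:, :, :] = 0.7
        vals, total = roi_gmv(gmv, parc)
        np.testing.assert_allclose(vals, [0.3, 0.5, 0.7])
        assert total == pytest.approx(gmv[parc.brain_mask].sum())

    def test_matches_loop_oracle_and_sum_mode(self, rng):
        parc = self._parc()
        gmv = np.abs(rng.normal(size=(4, 4, 2)))
        mean_vals, _ = roi_gmv(gmv, parc, agg="mean")
        sum_vals, _ = roi_gmv(gmv, parc, agg="sum")
        for i, roi in enumerate(parc.roi_ids):
            assert mean_vals[i] == pytest.approx(gmv[parc.labels == roi].mean())
            assert sum_vals[i] == pytest.approx(gmv[parc.labels == roi].sum())

    def test_negative_gmv_rejected(self):
        parc = self._parc()
        gmv = np.full((4, 4, 2), -0.1)
        with pytest.raises(ValueError, match="negative"):
            roi_gmv(gmv, parc)

    def test_sfi_examples_and_zero_annihilation(self, rng):
        np.testing.assert_allclose(compute_sfi(np.array([0.5]), np.array([0.4])), [0.2])
        z = rng.normal(size=10); z[3] = 0.0
        g = np.abs(rng.normal(size=10))
        sfi = compute_sfi(z, g)
        assert sfi[3] == 0.0
        np.testing.assert_array_equal(sfi, z * g)
        with pytest.raises(ValueError, match="mismatch"):
            compute_sfi(np.zeros(3), np.zeros(4))

    def test_sfi_permutation_equivariance(self, rng):
        z = rng.normal(size=8); g = np.abs(rng.normal(size=8))
        perm = rng.permutation(8)
        np.testing.assert_array_equal(compute_sfi(z, g)[perm],
                                      compute_sfi(z[perm], g[perm]))

    def test_aggregate_constant_input(self):
        parc = self._parc()
        agg = aggregate_levels(np.full(3, 1.7), parc)
        assert agg["whole_brain"] == pytest.approx(1.7)
        for net in ("CON", "SEN", "DMN"):
            assert agg[f"net_{net}"] == pytest.approx(1.7)

    def test_single_roi_network_passthrough_and_grouped_mean_oracle(self, rng):
        parc = self._parc()
        vals = rng.normal(size=3)
        agg = aggregate_levels(vals, parc)
        assert agg["net_SEN"] == pytest.approx(vals[1])  # ROI 2 is SEN's only member
        assert agg["whole_brain"] == pytest.approx(vals.mean(), abs=1e-12)
        assert agg["net_CON"] == pytest.approx(vals[0], abs=1e-12)
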