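"""Synthetic cohort generator: geometry, planted effects, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats

from gstopo.io import NETWORKS
from gstopo.synthetic import (
    GROUPS,
    SimulationConfig,
    generate_cohort,
    generate_measure_cohort,
    generate_parcellation,
    generate_subject,
    network_assignment,
    tissue_masks,
)


class TestParcellation:
    def test_minimal_six_roi_case_covers_mask(self):
        config = SimulationConfig(n_rois=6, grid_shape=(12, 12, 12),
                                  effect_rois=(1,), gmv_effect_rois=(2,),
                                  clinical_link_rois=(3,))
        parc = generate_parcellation(config)
        gm = tissue_masks(config)["gm"]
        assert sorted(np.unique(parc.labels)) == [0, 1, 2, 3, 4, 5, 6]
        np.testing.assert_array_equal(parc.labels > 0, gm)
        assert set(parc.network_of.values()) == set(NETWORKS)

    def test_full_scale_160_rois_nonempty_and_exhaustive(self):
        config = SimulationConfig(n_rois=160, effect_rois=(1,), gmv_effect_rois=(2,),
                                  clinical_link_rois=(3,))
        parc = generate_parcellation(config)
        sizes = np.bincount(parc.labels.ravel())[1:]
        assert len(sizes) == 160 and (sizes > 0).all()
        np.testing.assert_array_equal(parc.labels > 0, tissue_masks(config)["gm"])

    def test_every_parcel_is_contiguous(self, small_config, small_parcellation):
        for roi in small_parcellation.roi_ids:
            _, n_comp = ndimage.label(small_parcellation.labels == roi)
            assert n_comp == 1, f"ROI {roi} split into {n_comp} components"

    def test_deterministic_given_seed(self, small_config):
        a = generate_parcellation(small_config)
        b = generate_parcellation(small_config)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_grid_too_small_raises_sizing_error(self):
        with pytest.raises(ValueError, match="[Pp]arcel|voxel"):
            config = SimulationConfig(n_rois=500, grid_shape=(6, 6, 6),
                                      effect_rois=(1,), gmv_effect_rois=(2,),
                                      clinical_link_rois=(3,))
            generate_parcellation(config)

    def test_network_assignment_is_total_and_balanced(self):
        nets = network_assignment(40)
        assert len(nets) == 40
        counts = pd.Series(list(nets.values())).value_counts()
        assert set(counts.index) == set(NETWORKS)
        assert counts.max() - counts.min() <= 1


class TestGenerateSubject:
    def test_unknown_group_rejected(self, small_config):
        with pytest.raises(ValueError, match="unknown group"):
            generate_subject(small_config, site=0, group="CONTROL", index=0)

    def test_anxious_hama_exceeds_cutoff(self, small_config, small_parcellation):
        for index in range(6):
            *_, truth = generate_subject(small_config, 0, "MDD_anx", index,
                                         parcellation=small_parcellation)
            assert 14 < truth.hama <= 56

    def test_nonanxious_hama_at_or_below_cutoff(self, small_config, small_parcellation):
        for index in range(6):
            *_, truth = generate_subject(small_config, 0, "MDD_nonanx", index,
                                         parcellation=small_parcellation)
            assert 0 <= truth.hama <= 14

    def test_noiseless_unit_coupling_roi_means_equal_latent_signal(self):
        config = SimulationConfig(
            n_sites=1, subjects_per_site_per_group=1, grid_shape=(14, 14, 10),
            n_rois=8, n_timepoints=60, n_discard=2, noise_sd=0.0,
            local_signal_sd=0.0, wm_leak=0.0, csf_leak=0.0, motion_leak=0.0,
            coupling_base=1.0, coupling_roi_sd=0.0, coupling_sd=0.0,
            subject_global_sd=0.0, site_intercept_sd=0.0, site_slope_sd=0.0,
            covariate_effects={}, effect_size=0.0, gmv_effect_size=0.0,
            effect_rois=(1,), gmv_effect_rois=(2,), clinical_link_rois=(3,), seed=3,
        )
        parc = generate_parcellation(config)
        bold, _, _, _, truth = generate_subject(config, 0, "HC", 0, parcellation=parc)
        retained = bold.data[..., config.n_discard:]
        for roi in parc.roi_ids:
            roi_mean = retained[parc.labels == roi].mean(axis=0)
            np.testing.assert_allclose(roi_mean, truth.gs_trace, atol=1e-12)

    def test_reproducible_from_config_and_indices(self, small_config, small_parcellation):
        a = generate_subject(small_config, 1, "HC", 1, parcellation=small_parcellation)
        b = generate_subject(small_config, 1, "HC", 1, parcellation=small_parcellation)
        np.testing.assert_array_equal(a[0].data, b[0].data)
        np.testing.assert_array_equal(a[2], b[2])
        np.testing.assert_array_equal(a[4].true_coupling, b[4].true_coupling)

    def test_gmv_map_constant_within_each_roi(self, small_subject, small_parcellation):
        *_, gmv_map, truth = small_subject
        for roi in small_parcellation.roi_ids:
            vals = gmv_map[small_parcellation.labels == roi]
            np.testing.assert_allclose(vals, truth.true_gmv[roi - 1])

    def test_motion_is_bounded(self, small_subject):
        motion = small_subject[2]
        assert np.abs(motion[:, :3]).max() <= 1.0 + 1e-12
        assert np.abs(motion[:, 3:]).max() <= 0.02 + 1e-12

    def test_null_effect_couplings_exchangeable_across_groups(self):
        """With effect_size=0, a permutation test on group mean coupling
        difference should not reject beyond its nominal level."""
        config = SimulationConfig(
            n_sites=1, subjects_per_site_per_group=40, n_rois=6,
            effect_size=0.0, site_intercept_sd=0.0, site_slope_sd=0.0,
            covariate_effects={}, effect_rois=(1,), gmv_effect_rois=(2,),
            clinical_link_rois=(3,), seed=9,
        )
        _, measures = generate_measure_cohort(config)
        df = measures["GSCORR"].values
        groups = np.array([sid.split("_")[1] for sid in df.index])
        x = df["roi_1"].to_numpy()
        obs = x[groups == "MDD"].mean() - x[groups == "HC"].mean()
        rng = np.random.default_rng(0)
        null = []
        for _ in range(200):
            perm = rng.permutation(groups)
            null.append(x[perm == "MDD"].mean() - x[perm == "HC"].mean())
        p = (np.sum(np.abs(null) >= abs(obs)) + 1) / 201
        assert p > 0.05


class TestGenerateCohort:
    def test_manifest_arithmetic_and_site_count(self, tmp_path):
        config = SimulationConfig(n_sites=4, subjects_per_site_per_group=5,
                                  grid_shape=(12, 12, 10), n_rois=8, n_timepoints=40,
                                  n_discard=2, effect_rois=(1,), gmv_effect_rois=(2,),
                                  clinical_link_rois=(3,), seed=21)
        manifest = generate_cohort(config, tmp_path / "c")
        assert len(manifest) == 4 * 3 * 5
        assert manifest["site_id"].nunique() == 4

    def test_same_seed_gives_byte_identical_manifests(self, tmp_path):
        config = SimulationConfig(n_sites=2, subjects_per_site_per_group=2,
                                  grid_shape=(12, 12, 10), n_rois=8, n_timepoints=40,
                                  n_discard=2, effect_rois=(1,), gmv_effect_rois=(2,),
                                  clinical_link_rois=(3,), seed=22)
        generate_cohort(config, tmp_path / "a")
        generate_cohort(config, tmp_path / "b")
        assert (tmp_path / "a" / "manifest.tsv").read_bytes() == \
            (tmp_path / "b" / "manifest.tsv").read_bytes()
        assert (tmp_path / "a" / "ground_truth.tsv").read_bytes() == \
            (tmp_path / "b" / "ground_truth.tsv").read_bytes()

    def test_refuses_nonempty_directory_without_overwrite(self, tmp_path):
        config = SimulationConfig(n_sites=1, subjects_per_site_per_group=1,
                                  grid_shape=(12, 12, 10), n_rois=8, n_timepoints=40,
                                  n_discard=2, effect_rois=(1,), gmv_effect_rois=(2,),
                                  clinical_link_rois=(3,), seed=23)
        target = tmp_path / "c"
        target.mkdir()
        (target / "existing.txt").write_text("keep me\n")
        with pytest.raises(FileExistsError):
            generate_cohort(config, target)

    def test_positive_clinical_link_yields_positive_hama_coupling_correlation(self):
        """The generative slope should survive score truncation: the sample
        correlation between link-ROI coupling and HAMA is positive at n=300."""
        config = SimulationConfig(n_sites=2, subjects_per_site_per_group=50, n_rois=10,
                                  effect_rois=(1,), gmv_effect_rois=(2,),
                                  clinical_link_rois=(5,), seed=31)
        manifest, measures = generate_measure_cohort(config)
        anx = manifest[manifest["diagnosis"] == "MDD_anx"]
        coupling = measures["GSCORR"].values.loc[anx["subject_id"], "roi_5"]
        r, p = stats.pearsonr(coupling, anx["hama"])
        assert r > 0 and p < 0.01


class TestMeasureCohort:
    def test_planted_effect_shifts_only_affected_group_and_rois(self):
        config = SimulationConfig(n_sites=2, subjects_per_site_per_group=200, n_rois=8,
                                  effect_rois=(2,), effect_size=-0.08,
                                  gmv_effect_rois=(3,), clinical_link_rois=(4,),
                                  site_intercept_sd=0.0, site_slope_sd=0.0,
                                  covariate_effects={}, seed=41)
        manifest, measures = generate_measure_cohort(config)
        z = measures["GSCORR"].values.join(manifest.set_index("subject_id")["diagnosis"])
        anx = z[z["diagnosis"] == "MDD_anx"]
        hc = z[z["diagnosis"] == "HC"]
        shift_planted = anx["roi_2"].mean() - hc["roi_2"].mean()
        shift_null = anx["roi_7"].mean() - hc["roi_7"].mean()
        assert shift_planted == pytest.approx(-0.08, abs=0.02)
        assert shift_null == pytest.approx(0.0, abs=0.02)

    def test_sfi_is_product_of_gscorr_and_gmv(self):
        config = SimulationConfig(n_sites=1, subjects_per_site_per_group=3, n_rois=8,
                                  effect_rois=(1,), gmv_effect_rois=(2,),
                                  clinical_link_rois=(3,), seed=42)
        _, measures = generate_measure_cohort(config)
        for r in range(1, 9):
            np.testing.assert_allclose(
                measures["SFI"].values[f"roi_{r}"],
                measures["GSCORR"].values[f"roi_{r}"] * measures["GMV"].values[f"roi_{r}"],
            )

    def test_group_cells_complete(self):
        config = SimulationConfig(n_sites=3, subjects_per_site_per_group=4, n_rois=6,
                                  effect_rois=(1,), gmv_effect_rois=(2,),
                                  clinical_link_rois=(3,), seed=43)
        manifest, _ = generate_measure_cohort(config)
        cells = manifest.groupby(["site_id", "diagnosis"]).size()
        assert len(cells) == 9 and (cells == 4).all()
        assert set(manifest["diagnosis"]) == set(GROUPS)
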