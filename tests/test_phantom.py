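"""Phantom simulator: prevalence control, rendering fidelity,
confounder locality, cohort determinism and contour sampling."""

import dataclasses

import numpy as np
import pytest

from vascmap import phantom, volio
from vascmap.classes import ARTERY, BRAIN, CSF, EV, EXCLUDED, TISSUE_CLASSES, VEIN


class TestBuildLabelVolume:
    def test_prevalence_recovery_at_training_fractions(self, small_config, small_labels):
        # the default targets are the reported clinical training fractions
        prev = small_labels.prevalences()
        for cls, target in small_config.target_prevalence.items():
            if target >= 0.005:
                assert abs(prev[cls] - target) / target <= 0.30, (
                    f"class {cls}: achieved {prev[cls]:.4f} vs target {target}"
                )
        assert (small_labels.data == EV).sum() > 0  # EV target > 0 -> nonempty

    def test_ev_absent_when_target_zero(self, small_config):
        targets = dict(small_config.target_prevalence)
        targets[EV] = 0.0
        cfg = dataclasses.replace(small_config, target_prevalence=targets)
        labels = phantom.build_label_volume(cfg)
        assert (labels.data == EV).sum() == 0

    def test_degenerate_geometry_brain_and_csf_only(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            n_vessel_trees=(0, 0),
            nidus=phantom.NidusConfig(
                radius=4.0, artery_fraction=0, vein_fraction=0, ev_fraction=0
            ),
            target_prevalence={ARTERY: 0.0, VEIN: 0.0, BRAIN: 0.88, CSF: 0.12, EV: 0.0},
        )
        labels = phantom.build_label_volume(cfg)
        assert set(np.unique(labels.data)) <= {EXCLUDED, BRAIN, CSF}

    def test_determinism_same_seed(self, small_config, small_labels):
        again = phantom.build_label_volume(small_config)
        np.testing.assert_array_equal(small_labels.data, again.data)

    def test_mask_is_ellipsoidal_interior(self, small_labels):
        # excluded exactly outside the mask, tissue inside
        assert (small_labels.data[~small_labels.mask] == EXCLUDED).all()
        assert (small_labels.data[small_labels.mask] != EXCLUDED).all()

    def test_nidus_exceeding_mask_fails(self, small_config):
        cfg = dataclasses.replace(
            small_config, nidus=phantom.NidusConfig(radius=100.0)
        )
        with pytest.raises(phantom.PhantomGeometryError, match="nidus"):
            phantom.build_label_volume(cfg)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            phantom.PhantomConfig(grid_shape=(8, 32, 32))
        with pytest.raises(ValueError):
            phantom.PhantomConfig(vessel_radius_range=(0.5, 2.0))
        with pytest.raises(ValueError):
            phantom.PhantomConfig(
                target_prevalence={ARTERY: 0.8, VEIN: 0.8, BRAIN: 0.1, CSF: 0.1, EV: 0.0}
            )


class TestRenderModalities:
    def test_noise_free_render_is_exact(self, small_labels, clean_config, clean_images):
        model = phantom.default_intensity_model()
        for contrast in ("tof", "t1c", "t2"):
            img = clean_images.channel(contrast)
            for cls in TISSUE_CLASSES:
                vox = img[small_labels.data == cls]
                expected = model.mean_intensity[contrast][cls]
                assert np.all(vox == np.float32(expected))
            assert np.all(img[small_labels.data == EXCLUDED] <= 0.1)

    def test_tof_artery_brighter_than_brain(self, small_labels, small_images):
        art = small_images.tof[small_labels.data == ARTERY].mean()
        brain = small_images.tof[small_labels.data == BRAIN].mean()
        assert art > brain

    def test_noise_sd_matches_sigma(self, small_config, small_labels, clean_images):
        cfg = dataclasses.replace(small_config, noise_sigma=0.05, bias_field_amplitude=0.0)
        noisy = phantom.render_modalities(
            small_labels, phantom.default_intensity_model(), cfg
        )
        # brain voxels sit mid-range, so clipping never bites
        sel = small_labels.data == BRAIN
        diff = noisy.tof[sel] - clean_images.tof[sel]
        assert abs(diff.std() - 0.05) <= 0.005

    def test_missing_class_in_model_fails(self, small_labels, small_config):
        model = phantom.default_intensity_model()
        del model.mean_intensity["t2"][CSF]
        with pytest.raises(ValueError, match="csf"):
            phantom.render_modalities(small_labels, model, small_config)

    def test_ordering_validation_rejects_bad_model(self):
        model = phantom.default_intensity_model()
        model.mean_intensity["tof"][ARTERY] = 0.0  # arteries must be TOF-bright
        with pytest.raises(ValueError, match="ordering"):
            model.validate()


class TestConfounders:
    def test_empty_set_is_identity(self, small_config, small_labels, small_images):
        labels, images, affected = phantom.inject_confounders(
            small_labels, small_images, small_config
        )
        assert affected == {}
        np.testing.assert_array_equal(images.tof, small_images.tof)
        np.testing.assert_array_equal(images.t1c, small_images.t1c)

    def test_poorly_enhancing_vein_locality(self, small_config, small_labels, small_images):
        cfg = dataclasses.replace(
            small_config, confounders=frozenset({"poorly_enhancing_vein"})
        )
        model = phantom.default_intensity_model()
        labels, images, affected = phantom.inject_confounders(
            small_labels, small_images, cfg, model
        )
        seg = affected["poorly_enhancing_vein"]
        assert seg.shape[0] > 0
        k, i, j = seg[:, 0], seg[:, 1], seg[:, 2]
        # affected voxels keep their vein label but render at brain T1+c
        assert (labels.data[k, i, j] == VEIN).all()
        assert np.all(images.t1c[k, i, j] == np.float32(model.mean_intensity["t1c"][BRAIN]))
        # nothing else changed, on any channel
        touched = np.zeros(labels.data.shape, dtype=bool)
        touched[k, i, j] = True
        np.testing.assert_array_equal(images.t1c[~touched], small_images.t1c[~touched])
        np.testing.assert_array_equal(images.tof, small_images.tof)
        np.testing.assert_array_equal(images.t2, small_images.t2)

    def test_tof_slab_full_extent_is_identity(self, small_config, small_labels, small_images):
        cfg = dataclasses.replace(
            small_config, confounders=frozenset({"tof_partial_slab"})
        )
        _, images, affected = phantom.inject_confounders(
            small_labels, small_images, cfg, slab=(0, small_labels.data.shape[0])
        )
        assert affected["tof_partial_slab"].shape[0] == 0
        np.testing.assert_array_equal(images.tof, small_images.tof)

    def test_tof_partial_slab_zeroes_outside(self, small_config, small_labels, small_images):
        cfg = dataclasses.replace(
            small_config, confounders=frozenset({"tof_partial_slab"})
        )
        _, images, affected = phantom.inject_confounders(
            small_labels, small_images, cfg
        )
        seg = affected["tof_partial_slab"]
        assert np.all(images.tof[seg[:, 0], seg[:, 1], seg[:, 2]] == 0.0)

    def test_confounder_without_vein_fails(self, small_config):
        cfg = dataclasses.replace(
            small_config,
            n_vessel_trees=(0, 0),
            nidus=phantom.NidusConfig(
                radius=4.0, artery_fraction=0, vein_fraction=0, ev_fraction=0
            ),
            target_prevalence={BRAIN: 0.9, CSF: 0.1},
            confounders=frozenset({"poorly_enhancing_vein"}),
        )
        labels = phantom.build_label_volume(cfg)
        images = phantom.render_modalities(
            labels, phantom.default_intensity_model(), cfg
        )
        with pytest.raises(phantom.ConfounderError):
            phantom.inject_confounders(labels, images, cfg)


class TestCohort:
    def test_cohort_size_and_manifest(self, tmp_path):
        cfg = phantom.PhantomConfig(
            grid_shape=(16, 32, 32),
            nidus=phantom.NidusConfig(radius=2.5),
            vessel_radius_range=(1.0, 1.5),
            seed=0,
        )
        manifest = phantom.make_cohort(23, cfg, seed=5, out_dir=tmp_path / "cohort")
        assert len(manifest) == 23
        assert sum(1 for p in (tmp_path / "cohort").iterdir() if p.is_dir()) == 23
        prev_cols = [c for c in manifest.columns if c.startswith("prev_")]
        sums = manifest[prev_cols].sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-6)

    def test_cohort_files_byte_identical_across_runs(self, tmp_path):
        cfg = phantom.PhantomConfig(
            grid_shape=(16, 32, 32), nidus=phantom.NidusConfig(radius=2.5), seed=0
        )
        phantom.make_cohort(1, cfg, seed=11, out_dir=tmp_path / "a")
        phantom.make_cohort(1, cfg, seed=11, out_dir=tmp_path / "b")
        fa = (tmp_path / "a" / "sub-00" / "labels.nii.gz").read_bytes()
        fb = (tmp_path / "b" / "sub-00" / "labels.nii.gz").read_bytes()
        assert fa == fb

    def test_manifest_prevalence_matches_recount(self, tmp_path):
        cfg = phantom.PhantomConfig(
            grid_shape=(16, 32, 32), nidus=phantom.NidusConfig(radius=2.5), seed=0
        )
        manifest = phantom.make_cohort(1, cfg, seed=3, out_dir=tmp_path / "c")
        labels = volio.read_volume(tmp_path / "c" / "sub-00" / "labels.nii.gz")
        mask = labels.data != EXCLUDED
        brain_frac = (labels.data == BRAIN).sum() / mask.sum()
        assert abs(manifest["prev_brain"].iloc[0] - brain_frac) < 1e-9


class TestSampleContours:
    def test_full_fraction_partitions_intracranial(self, small_labels):
        contours = phantom.sample_contours(small_labels, 1.0, seed=0)
        total = sum(v.shape[0] for v in contours.values())
        assert total == int(small_labels.mask.sum())
        for cls, idx in contours.items():
            assert (small_labels.data[idx[:, 0], idx[:, 1], idx[:, 2]] == cls).all()

    def test_absent_class_absent_from_contours(self, small_config):
        targets = dict(small_config.target_prevalence)
        targets[EV] = 0.0
        cfg = dataclasses.replace(small_config, target_prevalence=targets)
        labels = phantom.build_label_volume(cfg)
        contours = phantom.sample_contours(labels, 0.05, seed=0)
        assert EV not in contours

    def test_fraction_count_bounds(self, small_labels):
        contours = phantom.sample_contours(small_labels, 0.01, seed=0)
        n_brain = int((small_labels.data == BRAIN).sum())
        got = contours[BRAIN].shape[0]
        assert 0.5 * 0.01 * n_brain <= got <= 2.0 * 0.01 * n_brain
        # small classes fall back to the 10-voxel floor
        for cls, idx in contours.items():
            n_cls = int((small_labels.data == cls).sum())
            assert idx.shape[0] >= min(10, n_cls)

    def test_disjoint_and_within_class(self, small_labels):
        contours = phantom.sample_contours(small_labels, 0.05, seed=2)
        seen = set()
        for cls, idx in contours.items():
            keys = {tuple(v) for v in idx}
            assert not (keys & seen)
            seen |= keys

    def test_invalid_fraction_rejected(self, small_labels):
        for frac in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                phantom.sample_contours(small_labels, frac, seed=0)

    def test_determinism(self, small_labels):
        a = phantom.sample_contours(small_labels, 0.03, seed=9)
        b = phantom.sample_contours(small_labels, 0.03, seed=9)
        for cls in a:
            np.testing.assert_array_equal(a[cls], b[cls])
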