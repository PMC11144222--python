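"""Condition grid combinatorics, tooth cropping and orientation augmentation."""

import numpy as np
import pytest

from dentalcbct.dataset_factory import (
    ConditionGrid,
    ToothSample,
    apply_orientation,
    augment_orientations,
    count_samples,
    crop_tooth,
    default_condition_grid,
    enumerate_conditions,
    orientation_group,
)
from dentalcbct.phantom import VoxelPhantom
from dentalcbct.recon import ReconVolume


class TestConditionGrid:
    def test_default_grid_shape(self):
        grid = default_condition_grid()
        assert grid.counts == (7, 2, 3, 3, 1)
        assert grid.n_conditions == 126

    def test_enumeration_length_is_product(self, mini_grid):
        conditions = enumerate_conditions(mini_grid)
        assert len(conditions) == mini_grid.n_conditions == 4

    def test_single_cell_grid(self):
        grid = ConditionGrid(
            phantoms=((),), density_sets=({},), spectra=("mono-60",),
            noise_levels=(None,), cutoffs=(None,),
        )
        assert enumerate_conditions(grid) == [(0, 0, "mono-60", None, None)]

    def test_enumeration_order_documented(self):
        grid = ConditionGrid(
            phantoms=((), ()), density_sets=({},), spectra=("a",),
            noise_levels=(None, 1e4), cutoffs=(0.004, 0.016),
        )
        conditions = enumerate_conditions(grid)
        assert len(conditions) == 8
        # cutoff fastest, phantom slowest
        assert conditions[0] == (0, 0, "a", None, 0.004)
        assert conditions[1] == (0, 0, "a", None, 0.016)
        assert conditions[-1] == (1, 0, "a", 1e4, 0.016)

    def test_empty_axis_rejected(self):
        with pytest.raises(ValueError, match="spectra"):
            ConditionGrid(
                phantoms=((),), density_sets=({},), spectra=(),
                noise_levels=(None,), cutoffs=(None,),
            )


class TestCountSamples:
    def test_published_total_factorization_a(self):
        grid = default_condition_grid(n_augmentations=50)
        assert count_samples(grid, teeth_per_phantom=27) == 170_100

    def test_published_total_factorization_b(self):
        grid = ConditionGrid(
            phantoms=tuple(() for _ in range(7)),
            density_sets=({}, {}),
            spectra=("soft-90kVp", "hard-90kVp", "100kVp"),
            noise_levels=(None, 1e4, 1e5),
            cutoffs=(0.004, 0.016),
            n_augmentations=25,
        )
        assert count_samples(grid, teeth_per_phantom=27) == 170_100

    def test_all_ones(self):
        grid = ConditionGrid(
            phantoms=((),), density_sets=({},), spectra=("mono-60",),
            noise_levels=(None,), cutoffs=(None,), n_augmentations=1,
        )
        assert count_samples(grid, 1) == 1

    def test_small_product(self):
        grid = ConditionGrid(
            phantoms=((), ()), density_sets=({},), spectra=("a",),
            noise_levels=(None, 1e4), cutoffs=(0.004, 0.016), n_augmentations=3,
        )
        assert count_samples(grid, 2) == 2 * 1 * 1 * 2 * 2 * 2 * 3


def _synthetic_volume_and_phantom(materials, n=48, cube=(10, 18)):
    """A ReconVolume that simply encodes the label map, plus its phantom."""
    labels = np.full((n, n, n), 8, dtype=np.int16)
    instances = np.zeros_like(labels)
    sl = slice(*cube)
    labels[sl, sl, sl] = 10
    instances[sl, sl, sl] = 101
    ph = VoxelPhantom(labels, instances, (0.2,) * 3, materials)
    vol = ReconVolume((labels == 10).astype(float), (0.2,) * 3, {})
    return vol, ph


class TestCropTooth:
    def test_output_shape_is_requested_cube(self, materials):
        vol, ph = _synthetic_volume_and_phantom(materials)
        sample = crop_tooth(vol, ph, 101, out_size=128, seed=0)
        assert sample.image.shape == (128, 128, 128)
        assert sample.mask.shape == (128, 128, 128)
        assert sample.mask.any()

    def test_zero_margin_mask_spans_cube(self, materials):
        vol, ph = _synthetic_volume_and_phantom(materials)
        sample = crop_tooth(vol, ph, 101, margin_range=(0, 0), out_size=32, seed=0)
        # with no margin the crop box is exactly the tooth's bounding box,
        # so the resampled mask touches every face of the output cube
        nz = np.nonzero(sample.mask)
        for axis in range(3):
            assert nz[axis].min() == 0
            assert nz[axis].max() == 31

    def test_same_seed_same_offsets(self, materials):
        vol, ph = _synthetic_volume_and_phantom(materials)
        a = crop_tooth(vol, ph, 101, out_size=32, seed=9)
        b = crop_tooth(vol, ph, 101, out_size=32, seed=9)
        assert a.meta["crop_lo"] == b.meta["crop_lo"]
        np.testing.assert_array_equal(a.image, b.image)
        c = crop_tooth(vol, ph, 101, out_size=32, seed=10)
        assert a.meta["margins"] != c.meta["margins"]

    def test_mask_excludes_other_teeth(self, jaw_phantom):
        vol = ReconVolume(np.zeros(jaw_phantom.shape), jaw_phantom.voxel_pitch, {})
        sample = crop_tooth(vol, jaw_phantom, 101, margin_range=(8, 12), out_size=32, seed=0)
        # the crop may overlap neighbouring teeth but the mask must not
        assert sample.meta["tooth_id"] == 101
        assert sample.mask.sum() > 0

    def test_absent_tooth_raises(self, materials):
        vol, ph = _synthetic_volume_and_phantom(materials)
        with pytest.raises(KeyError, match="104"):
            crop_tooth(vol, ph, 104)

    def test_frame_mismatch_rejected(self, materials):
        vol, ph = _synthetic_volume_and_phantom(materials)
        bad = ReconVolume(vol.values[:-2], vol.voxel_pitch, {})
        with pytest.raises(ValueError, match="frame"):
            crop_tooth(bad, ph, 101)


@pytest.fixture
def asymmetric_sample():
    rng = np.random.default_rng(0)
    image = rng.random((8, 8, 8)).astype(np.float32)
    mask = np.zeros((8, 8, 8), dtype=bool)
    mask[1:3, 2:6, 4:5] = True
    return ToothSample(image=image, mask=mask, meta={"tooth_id": 101, "orientation": None})


class TestAugmentOrientations:
    def test_group_has_48_elements_identity_first(self):
        group = orientation_group()
        assert len(group) == 48
        assert group[0] == ((0, 1, 2), (False, False, False))
        assert len(set(group)) == 48

    def test_n1_returns_original(self, asymmetric_sample):
        out = augment_orientations(asymmetric_sample, 1, seed=3)
        np.testing.assert_array_equal(out[0].image, asymmetric_sample.image)
        np.testing.assert_array_equal(out[0].mask, asymmetric_sample.mask)

    def test_flip_twice_is_identity(self, asymmetric_sample):
        flipped = apply_orientation(asymmetric_sample.image, (0, 1, 2), (True, False, True))
        back = apply_orientation(flipped, (0, 1, 2), (True, False, True))
        np.testing.assert_array_equal(back, asymmetric_sample.image)

    def test_all_48_transforms_distinct_on_asymmetric_grid(self, asymmetric_sample):
        out = augment_orientations(asymmetric_sample, 48, seed=0)
        fingerprints = {s.image.tobytes() for s in out}
        assert len(fingerprints) == 48

    def test_voxel_multiset_preserved(self, asymmetric_sample):
        for s in augment_orientations(asymmetric_sample, 8, seed=1):
            np.testing.assert_array_equal(
                np.sort(s.image.ravel()), np.sort(asymmetric_sample.image.ravel())
            )
            assert s.mask.sum() == asymmetric_sample.mask.sum()

    def test_more_than_48_rejected(self, asymmetric_sample):
        with pytest.raises(ValueError, match="48"):
            augment_orientations(asymmetric_sample, 49)

    def test_image_and_mask_transform_together(self, asymmetric_sample):
        marked = asymmetric_sample.image.copy()
        marked[asymmetric_sample.mask] = 99.0
        sample = ToothSample(image=marked, mask=asymmetric_sample.mask, meta={"orientation": None})
        for s in augment_orientations(sample, 12, seed=2):
            np.testing.assert_array_equal(s.image == 99.0, s.mask)


class TestGenerateDataset:
    def test_manifest_matches_count_and_resumes(
        self, fixture_corpus, mini_grid, corpus_phantom, corpus_geometry
    ):
        from dentalcbct.dataset_factory import generate_dataset

        out, manifest = fixture_corpus
        expected = count_samples(mini_grid, len(corpus_phantom.tooth_ids()))
        assert len(manifest) == expected
        assert (manifest["status"] == "ok").all()
        # re-run resumes from complete shards and changes nothing
        again = generate_dataset(
            mini_grid, corpus_phantom, corpus_geometry, out, seed=7,
            crop_size=32, margin_range=(2, 5),
        )
        assert again.equals(manifest)

    def test_every_sample_has_nonempty_matching_mask(self, fixture_corpus):
        import h5py

        out, manifest = fixture_corpus
        for file_name in manifest["file"].unique():
            with h5py.File(out / file_name, "r") as fh:
                images, masks = fh["image"][...], fh["mask"][...]
            assert images.shape == masks.shape
            assert (masks.reshape(masks.shape[0], -1).sum(axis=1) > 0).all()

    def test_samples_regenerable_from_manifest(
        self, fixture_corpus, mini_grid, corpus_phantom, corpus_geometry, tmp_path
    ):
        """Bit-exact regeneration from the global seed (full provenance)."""
        import h5py

        from dentalcbct.dataset_factory import generate_dataset

        out, manifest = fixture_corpus
        regen = generate_dataset(
            mini_grid, corpus_phantom, corpus_geometry, tmp_path / "regen", seed=7,
            crop_size=32, margin_range=(2, 5),
        )
        assert regen.equals(manifest)
        name = manifest["file"].iloc[0]
        with h5py.File(out / name, "r") as a, h5py.File(tmp_path / "regen" / name, "r") as b:
            np.testing.assert_array_equal(a["image"][...], b["image"][...])
            np.testing.assert_array_equal(a["mask"][...], b["mask"][...])
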