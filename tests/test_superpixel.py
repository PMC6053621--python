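import numpy as np
import pytest
from skimage import measure

from earcount.superpixel import (
    LabeledPatchSet,
    SlicConfig,
    extract_patches,
    label_patches,
    slic_segment,
)
from earcount.synthetic_data import SceneConfig, generate_scene


def two_region_image(h=40, w=40):
    img = np.zeros((h, w, 3), dtype=np.uint8)
    img[:, : w // 2] = (200, 30, 30)
    img[:, w // 2 :] = (30, 30, 200)
    ref = (np.arange(w)[None, :] >= w // 2).astype(int) * np.ones((h, 1), dtype=int)
    return img, ref


class TestSlicSegment:
    def test_constant_image_k4_gives_four_equal_quadrants(self):
        img = np.full((40, 40, 3), 100, dtype=np.uint8)
        spmap = slic_segment(img, SlicConfig(n_superpixels=4))
        assert spmap.K == 4
        assert sorted(np.bincount(spmap.labels.ravel()).tolist()) == [400] * 4

    def test_k1_single_superpixel(self):
        img = np.full((40, 50, 3), 77, dtype=np.uint8)
        spmap = slic_segment(img, SlicConfig(n_superpixels=1))
        assert spmap.K == 1
        assert (spmap.labels == 0).all()

    def test_two_region_image_recovered(self):
        img, ref = two_region_image()
        spmap = slic_segment(img, SlicConfig(n_superpixels=2))
        assert spmap.K == 2
        agreement = max((spmap.labels == ref).mean(), (spmap.labels == 1 - ref).mean())
        assert agreement >= 0.99

    def test_two_region_image_agrees_with_global_kmeans_oracle(self):
        # brute-force Lloyd iterations in (lab, xy) with the same distance,
        # but with a global (unwindowed) assignment step
        from skimage.color import rgb2lab

        from earcount.superpixel import _perturb_seeds, _seed_grid

        img, ref = two_region_image()
        lab = rgb2lab(img)
        h, w = lab.shape[:2]
        s = np.sqrt(h * w / 2)
        m = 10.0
        seeds = _perturb_seeds(_seed_grid(h, w, 2), lab)
        centers_xy = seeds.astype(float)
        centers_lab = lab[seeds[:, 0].astype(int), seeds[:, 1].astype(int)]
        yy, xx = np.mgrid[0:h, 0:w]
        for _ in range(10):
            dists = np.stack([
                ((lab - centers_lab[c]) ** 2).sum(axis=2)
                + ((yy - centers_xy[c, 0]) ** 2 + (xx - centers_xy[c, 1]) ** 2)
                / s**2 * m**2
                for c in range(2)
            ])
            assign = np.argmin(dists, axis=0)
            for c in range(2):
                sel = assign == c
                if sel.any():
                    centers_lab[c] = lab[sel].mean(axis=0)
                    centers_xy[c] = (yy[sel].mean(), xx[sel].mean())
        ours = slic_segment(img, SlicConfig(n_superpixels=2)).labels
        agreement = max((ours == assign).mean(), (ours == 1 - assign).mean())
        assert agreement >= 0.99

    def test_partition_and_connectivity_on_scene(self):
        scene = generate_scene(SceneConfig(height=180, width=280, ear_count=6,
                                           min_separation=55, seed=21))
        spmap = slic_segment(scene.image)
        labels = spmap.labels
        assert labels.min() == 0 and labels.max() == spmap.K - 1
        assert np.bincount(labels.ravel()).sum() == labels.size
        comp = measure.label(labels, background=-7, connectivity=1)
        assert comp.max() == spmap.K  # each label is one 4-connected region

    def test_superpixel_count_within_20_percent_of_request(self):
        scene = generate_scene(SceneConfig(seed=13))
        k = round(scene.image.shape[0] * scene.image.shape[1] / 400)
        spmap = slic_segment(scene.image)
        assert abs(spmap.K - k) <= 0.2 * k

    def test_deterministic(self):
        scene = generate_scene(SceneConfig(height=120, width=160, ear_count=3,
                                           min_separation=45, seed=2))
        a = slic_segment(scene.image)
        b = slic_segment(scene.image)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.centers, b.centers)

    def test_k_exceeding_pixel_count_rejected(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        with pytest.raises(ValueError):
            slic_segment(img, SlicConfig(n_superpixels=101))


class TestExtractPatches:
    def test_one_patch_per_superpixel_all_20x20(self, small_scenes):
        scene = small_scenes[0]
        spmap = slic_segment(scene.image)
        patches = extract_patches(scene.image, spmap)
        assert len(patches) == spmap.K
        assert patches.patches.shape[1:] == (20, 20, 3)

    def test_centered_window_at_image_center(self):
        img = np.arange(40 * 40 * 3, dtype=np.uint8).reshape(40, 40, 3)
        spmap = slic_segment(img, SlicConfig(n_superpixels=1))
        patches = extract_patches(img, spmap)
        r, c = patches.centers[0]
        assert np.array_equal(patches.patches[0], img[r - 10 : r + 10, c - 10 : c + 10])

    def test_boundary_window_clamped_not_padded(self):
        # single superpixel in a thin image: centroid 3 px from the left edge
        img = np.zeros((30, 60, 3), dtype=np.uint8)
        spmap = slic_segment(img, SlicConfig(n_superpixels=1))
        spmap.centers[0] = (15.0, 3.0)
        patches = extract_patches(img, spmap)
        assert patches.patches[0].shape == (20, 20, 3)
        assert np.array_equal(patches.patches[0], img[5:25, 0:20])

    def test_patch_larger_than_image_rejected(self):
        img = np.zeros((15, 15, 3), dtype=np.uint8)
        spmap = slic_segment(img, SlicConfig(n_superpixels=1))
        with pytest.raises(ValueError):
            extract_patches(img, spmap, patch_size=20)


class TestLabelPatches:
    def test_zero_ratio_rule(self, small_scenes):
        scene = small_scenes[1]
        spmap = slic_segment(scene.image)
        patches = extract_patches(scene.image, spmap)
        labeled = label_patches(patches, spmap, scene.mask)
        ear_per_sp = np.bincount(spmap.labels.ravel(),
                                 weights=scene.mask.ravel().astype(float),
                                 minlength=spmap.K)
        expected = (ear_per_sp > 0).astype(int)
        assert np.array_equal(labeled.labels, expected)

    def test_single_ear_pixel_labels_foreground(self):
        img = np.full((40, 40, 3), 90, dtype=np.uint8)
        spmap = slic_segment(img, SlicConfig(n_superpixels=4))
        patches = extract_patches(img, spmap)
        mask = np.zeros((40, 40), dtype=bool)
        mask[5, 5] = True  # exactly one ear pixel
        labeled = label_patches(patches, spmap, mask)
        assert labeled.labels[spmap.labels[5, 5]] == 1
        assert labeled.labels.sum() == 1

    def test_all_ear_mask_labels_everything(self):
        img = np.full((40, 40, 3), 90, dtype=np.uint8)
        spmap = slic_segment(img, SlicConfig(n_superpixels=4))
        patches = extract_patches(img, spmap)
        labeled = label_patches(patches, spmap, np.ones((40, 40), dtype=bool))
        assert (labeled.labels == 1).all()

    def test_mask_shape_mismatch_rejected(self):
        img = np.zeros((40, 40, 3), dtype=np.uint8)
        spmap = slic_segment(img, SlicConfig(n_superpixels=1))
        patches = extract_patches(img, spmap)
        with pytest.raises(ValueError, match="does not match"):
            label_patches(patches, spmap, np.zeros((30, 30), dtype=bool))


class TestExports:
    def test_label_png_round_trip_and_patch_manifest(self, tmp_path):
        from PIL import Image

        from earcount.superpixel import save_labels_png, save_patch_dataset

        img = np.random.default_rng(3).integers(0, 256, (40, 40, 3), np.uint8)
        spmap = slic_segment(img, SlicConfig(n_superpixels=4))
        save_labels_png(spmap, tmp_path / "labels.png")
        back = np.asarray(Image.open(tmp_path / "labels.png"))
        assert back.dtype == np.uint16
        assert np.array_equal(back, spmap.labels)

        patches = label_patches(extract_patches(img, spmap), spmap,
                                np.zeros((40, 40), bool))
        save_patch_dataset(patches, tmp_path / "patches")
        manifest = (tmp_path / "patches" / "manifest.csv").read_text().splitlines()
        assert manifest[0] == "id,row,col,superpixel_id,label"
        assert len(manifest) == spmap.K + 1
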