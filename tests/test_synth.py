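"""Synthetic scene generator: determinism, stratified splits, augmentations,
class separability by construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from PIL import Image
from skimage.color import rgb2hsv
from skimage.measure import label

from cnatnet.synth import (DatasetConfig, DatasetManifest, SceneSpec,
                           ValidationError, affine, allocate_splits, augment,
                           brightness, default_appearance, generate_dataset,
                           hflip, largest_remainder, render_scene, rotate)


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def test_same_spec_and_seed_render_identical_pixels():
    spec = SceneSpec(grade="premium", level="cluster", n_filaments=12,
                     background="cluttered", seed=99)
    assert np.array_equal(render_scene(spec), render_scene(spec))


def test_monomer_scene_draws_one_connected_stroke():
    spec = SceneSpec(grade="premium", level="monomer", n_filaments=1, seed=3)
    img = render_scene(spec, size=128)
    hsv = rgb2hsv(img)
    mask = (hsv[..., 1] > 0.28) & (hsv[..., 2] > 0.32)
    components = label(mask, connectivity=2)
    sizes = np.bincount(components.ravel())[1:]
    assert (sizes > 30).sum() == 1


@pytest.mark.parametrize("kwargs", [
    dict(grade="premium", level="monomer", n_filaments=2),
    dict(grade="normal", level="cluster", n_filaments=3),
    dict(grade="deluxe", level="monomer", n_filaments=1),
    dict(grade="normal", level="monomer", n_filaments=1, lighting="candle"),
])
def test_invalid_scene_specs_rejected(kwargs):
    with pytest.raises(ValidationError):
        SceneSpec(**kwargs)


def test_undersized_canvas_rejected():
    spec = SceneSpec(grade="normal", level="monomer", n_filaments=1)
    with pytest.raises(ValidationError):
        render_scene(spec, size=32)


def test_grades_differ_in_masked_hue_and_saturation():
    """Across 50 seed-paired scenes the premium/normal hue gap exceeds the
    gap between the configured hue ranges (and similarly for saturation)."""
    hue_gap = (38.0 - 22.0) / 360.0       # normal low edge - premium high edge
    sat_gap = 0.72 - 0.60                 # premium low edge - normal high edge
    diffs_h, diffs_s = [], []
    for seed in range(50):
        stats = {}
        for grade in ("premium", "normal"):
            spec = SceneSpec(grade=grade, level="monomer", n_filaments=1,
                             seed=1000 + seed)
            hsv = rgb2hsv(render_scene(spec, size=96))
            mask = (hsv[..., 1] > 0.28) & (hsv[..., 2] > 0.32)
            stats[grade] = (hsv[..., 0][mask].mean(), hsv[..., 1][mask].mean())
        diffs_h.append(stats["normal"][0] - stats["premium"][0])
        diffs_s.append(stats["premium"][1] - stats["normal"][1])
    assert np.mean(diffs_h) >= hue_gap
    assert np.mean(diffs_s) >= sat_gap


# ---------------------------------------------------------------------------
# split apportionment
# ---------------------------------------------------------------------------

def test_thousand_images_split_700_200_100():
    assert largest_remainder(1000, (7, 2, 1)) == [700, 200, 100]


@given(total=st.integers(1, 5000),
       ratio=st.tuples(st.integers(1, 9), st.integers(1, 9),
                       st.integers(1, 9)))
def test_largest_remainder_is_exact(total, ratio):
    parts = largest_remainder(total, ratio)
    assert sum(parts) == total
    assert all(p >= 0 for p in parts)


@given(sizes=st.lists(st.integers(10, 200), min_size=1, max_size=6))
def test_split_allocation_exact_and_covering(sizes):
    cells = {f"cell{i}": n for i, n in enumerate(sizes)}
    alloc = allocate_splits(cells, (7, 2, 1))
    total = sum(sizes)
    global_target = largest_remainder(total, (7, 2, 1))
    for j in range(3):
        assert sum(alloc[c][j] for c in cells) == global_target[j]
    for c, n in cells.items():
        assert sum(alloc[c]) == n
        assert all(a >= 1 for a in alloc[c])


def test_too_small_cells_raise():
    with pytest.raises(ValidationError, match="cannot cover"):
        allocate_splits({"a": 2, "b": 100}, (7, 2, 1))


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def test_manifest_integrity(ds_small):
    frame = ds_small.frame
    assert len(frame) == 60
    assert frame["path"].is_unique
    counts = frame["split"].value_counts()
    assert counts["train"] == 42 and counts["val"] == 12 and counts["test"] == 6
    # splits disjoint by path
    by_split = [set(frame[frame["split"] == s]["path"]) for s in
                ("train", "val", "test")]
    assert not (by_split[0] & by_split[1] | by_split[0] & by_split[2]
                | by_split[1] & by_split[2])
    # every grade x level cell in every split
    table = frame.groupby(["grade", "level", "split"]).size()
    assert len(table) == 12 and (table > 0).all()
    # every image exists and loads at the configured size
    for path in frame["path"]:
        img = Image.open(ds_small.root / path)
        assert img.size == (96, 96)


def test_generation_is_bit_deterministic(tmp_path):
    cfg_a = DatasetConfig(out_dir=tmp_path / "a", n_images=40,
                          image_size=64, seed=5)
    cfg_b = DatasetConfig(out_dir=tmp_path / "b", n_images=40,
                          image_size=64, seed=5)
    man_a, man_b = generate_dataset(cfg_a), generate_dataset(cfg_b)
    pd.testing.assert_frame_equal(man_a.frame, man_b.frame)
    for path in man_a.frame["path"]:
        assert (man_a.root / path).read_bytes() == \
            (man_b.root / path).read_bytes()


def test_manifest_round_trip(ds_small):
    loaded = DatasetManifest.load(ds_small.root / "manifest.csv")
    pd.testing.assert_frame_equal(loaded.frame, ds_small.frame)
    assert len(loaded.records("val")) == 12


def test_dataset_config_validation(tmp_path):
    with pytest.raises(ValidationError):
        DatasetConfig(out_dir=tmp_path, n_images=5)
    with pytest.raises(ValidationError):
        DatasetConfig(out_dir=tmp_path, split_ratio=(7, 2))
    with pytest.raises(ValidationError):
        default_appearance("premium", cue="telepathic")


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

def _test_image():
    rng = np.random.default_rng(0)
    return rng.integers(0, 256, size=(64, 64, 3), dtype=np.uint8)


def test_hflip_is_an_involution():
    img = _test_image()
    assert np.array_equal(hflip(hflip(img)), img)


def test_identity_parameters_leave_image_unchanged():
    img = _test_image()
    assert np.array_equal(rotate(img, 0.0), img)
    assert np.array_equal(brightness(img, 1.0), img)
    assert np.array_equal(affine(img), img)


def test_quarter_turn_matches_explicit_index_remap():
    """A 90-degree rotation equals the coordinate permutation
    out[i, j] = in[j, W-1-i] (counter-clockwise), checked on an
    asymmetric 8x8 pattern."""
    img = (np.arange(8 * 8 * 3, dtype=np.uint8).reshape(8, 8, 3) * 7) % 251
    got = rotate(img, 90)
    h, w = img.shape[:2]
    want = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            want[i, j] = img[j, w - 1 - i]
    assert np.array_equal(got, want)


def test_augment_preserves_dimensions_and_is_seeded():
    img = _test_image()
    ops = ("rotate", "hflip", "brightness", "affine")
    out1 = augment(img, ops, seed=4)
    out2 = augment(img, ops, seed=4)
    assert out1.shape == img.shape
    assert np.array_equal(out1, out2)
    assert not np.array_equal(augment(img, ops, seed=5), out1)


def test_unknown_augmentation_rejected():
    with pytest.raises(ValidationError, match="sharpen"):
        augment(_test_image(), ["sharpen"])
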