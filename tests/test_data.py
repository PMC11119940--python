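"""Data pipeline: resize/crop arithmetic, split partitioning, and the
synthetic long-tailed generator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from PIL import Image

from pestnet.data import (DatasetManifest, SplitSpec, SyntheticSpec, crop,
                          generate_synthetic, load_manifest,
                          resize_short_side, save_dataset, split)


def blank(h, w):
    return np.zeros((h, w, 3), dtype=np.uint8)


# -- resize -------------------------------------------------------------------

@pytest.mark.parametrize("in_hw,out_hw", [
    ((512, 1024), (256, 512)),
    ((256, 256), (256, 256)),
    ((300, 200), (384, 256)),   # 200 -> 256 is scale 1.28, so 300 -> 384
])
def test_resize_short_side_arithmetic(in_hw, out_hw):
    out = resize_short_side(blank(*in_hw), 256)
    assert out.shape[:2] == out_hw


def test_resize_preserves_aspect_ratio_within_one_pixel(rng):
    for h, w in [(260, 900), (701, 333), (257, 258)]:
        out = resize_short_side(blank(h, w), 256)
        oh, ow = out.shape[:2]
        assert min(oh, ow) == 256
        assert abs(oh / ow - h / w) * max(oh, ow) < 1.0


def test_resize_accepts_pil_roundtrip():
    img = Image.fromarray(blank(300, 200))
    out = resize_short_side(img, 256)
    assert out.size == (256, 384)  # PIL reports (width, height)


# -- crop ---------------------------------------------------------------------

def test_center_crop_identity_and_offsets():
    img = np.arange(256 * 512 * 3, dtype=np.uint8).reshape(256, 512, 3)
    assert np.array_equal(crop(img[:, :256], "center"), img[:, :256])
    out = crop(img, "center")
    assert np.array_equal(out, img[:, 128:384])  # columns 128..383


def test_random_crop_seeded_determinism(rng):
    img = rng.integers(0, 255, size=(300, 400, 3), dtype=np.uint8)
    a = crop(img, "random", seed=11)
    b = crop(img, "random", seed=11)
    c = crop(img, "random", seed=12)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_small_image_reflection_padded(rng):
    img = rng.integers(0, 255, size=(100, 300, 3), dtype=np.uint8)
    out = crop(img, "center", size=256)
    assert out.shape == (256, 256, 3)


def test_preprocess_idempotent_on_conforming_images(rng):
    """resize-to-256-short-side followed by center crop is idempotent."""
    img = rng.integers(0, 255, size=(256, 300, 3), dtype=np.uint8)
    once = crop(resize_short_side(img, 256), "center")
    twice = crop(resize_short_side(once, 256), "center")
    assert np.array_equal(once, twice)


def test_unknown_crop_mode_rejected():
    with pytest.raises(ValueError):
        crop(blank(256, 256), "corner")


# -- split --------------------------------------------------------------------

def make_manifest(n):
    return DatasetManifest([(blank(8, 8), i % 3) for i in range(n)],
                           ["a", "b", "c"])


def test_split_reproduces_reference_counts():
    """4508 records under the default 70 / (30 -> 30/70) scheme give exactly
    3155 / 406 / 947."""
    tr, va, te = split(make_manifest(4508), SplitSpec(seed=1))
    assert (len(tr), len(va), len(te)) == (3155, 406, 947)


def test_split_ten_records():
    tr, va, te = split(make_manifest(10), SplitSpec(seed=5))
    assert (len(tr), len(va), len(te)) == (7, 1, 2)


@given(st.integers(4, 600), st.integers(0, 2 ** 31 - 1))
def test_split_partitions_exactly(n, seed):
    m = make_manifest(n)
    # tag records so identity is traceable through the shuffle
    for i, (img, lab) in enumerate(m.records):
        m.records[i] = (i, lab)
    tr, va, te = split(m, SplitSpec(seed=seed))
    ids = [r[0] for part in (tr, va, te) for r in part.records]
    assert sorted(ids) == list(range(n))
    assert len(tr) + len(va) + len(te) == n
    assert min(len(tr), len(va), len(te)) >= 1


def test_split_empty_subset_rejected():
    with pytest.raises(ValueError):
        split(make_manifest(3))  # validation block would be empty


def test_split_seed_determinism():
    m = make_manifest(50)
    a = split(m, SplitSpec(seed=3))
    b = split(m, SplitSpec(seed=3))
    assert all(x.labels.tolist() == y.labels.tolist() for x, y in zip(a, b))


# -- synthetic generator ------------------------------------------------------

def test_power_law_counts_exact():
    spec = SyntheticSpec(num_classes=10, images_per_class_max=100,
                         imbalance_exponent=1.0)
    assert spec.class_counts().tolist() == [100, 50, 33, 25, 20, 17, 14, 13, 11, 10]


def test_zero_exponent_gives_uniform_counts():
    spec = SyntheticSpec(num_classes=6, images_per_class_max=20,
                         imbalance_exponent=0.0)
    assert spec.class_counts().tolist() == [20] * 6


def test_generator_histogram_matches_law():
    spec = SyntheticSpec(num_classes=4, images_per_class_max=12, seed=3)
    man = generate_synthetic(spec)
    assert man.class_counts().tolist() == spec.class_counts().tolist()


def test_generator_byte_identical_from_seed():
    spec = SyntheticSpec(num_classes=3, images_per_class_max=4, seed=9)
    a = generate_synthetic(spec)
    b = generate_synthetic(spec)
    assert len(a) == len(b)
    for i in range(len(a)):
        assert np.array_equal(a.image(i), b.image(i))
    c = generate_synthetic(SyntheticSpec(num_classes=3, images_per_class_max=4,
                                         seed=10))
    assert any(not np.array_equal(a.image(i), c.image(i)) for i in range(len(a)))


def test_generator_rejects_degenerate_spec():
    with pytest.raises(ValueError):
        generate_synthetic(SyntheticSpec(num_classes=0))


def test_classes_are_visually_distinct(tiny_dataset):
    """Mean color per class should separate — the class signal the tests
    rely on actually exists in pixel space."""
    means = []
    labels = tiny_dataset.labels
    for c in range(tiny_dataset.num_classes):
        idx = np.where(labels == c)[0][:5]
        means.append(np.mean([tiny_dataset.image(i).mean(axis=(0, 1))
                              for i in idx], axis=0))
    means = np.array(means)
    dists = np.linalg.norm(means[:, None] - means[None], axis=-1)
    np.fill_diagonal(dists, np.inf)
    assert dists.min() > 2.0  # every class pair differs in mean color


# -- on-disk round trip -------------------------------------------------------

def test_save_and_load_dataset(tmp_path):
    spec = SyntheticSpec(num_classes=3, images_per_class_max=3, seed=1)
    man = generate_synthetic(spec)
    tsv = save_dataset(man, str(tmp_path / "ds"))
    from_tsv = load_manifest(tsv)
    from_tree = load_manifest(str(tmp_path / "ds"))
    assert len(from_tsv) == len(man) == len(from_tree)
    assert sorted(from_tree.labels.tolist()) == sorted(man.labels.tolist())
    # pixel fidelity through the PNG round trip
    img = from_tsv.image(0)
    assert img.dtype == np.uint8 and img.shape == (64, 64, 3)


def test_unreadable_image_raises_with_path(tmp_path):
    bad = tmp_path / "broken.png"
    bad.write_text("not an image")
    man = DatasetManifest([(str(bad), 0), (str(bad), 1)])
    with pytest.raises(OSError, match="broken.png"):
        man.image(0)
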