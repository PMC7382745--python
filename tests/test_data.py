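"""Case I/O, resizing, fold splitting and online augmentation."""

import numpy as np
import pytest

from mdunet.data import (
    AugmentConfig,
    CaseFileError,
    CaseRecord,
    epoch_stream,
    fourfold_split,
    load_case,
    read_fold_manifest,
    resize_case,
    save_case,
    write_fold_manifests,
)


def _write(tmp_path, case, cid="case_0000"):
    save_case(tmp_path, cid, case.image, case.clavicle_mask,
              case.anterior_mask, case.posterior_mask)
    return cid


def _record(phantom, cid="r0"):
    return CaseRecord(id=cid, image=phantom.image, clavicle_mask=phantom.clavicle_mask,
                      anterior_mask=phantom.anterior_mask,
                      posterior_mask=phantom.posterior_mask,
                      native_size=phantom.image.shape)


def test_write_load_roundtrip(tmp_path, small_phantom):
    cid = _write(tmp_path, small_phantom)
    rec = load_case(tmp_path, cid)
    np.testing.assert_array_equal(rec.clavicle_mask, small_phantom.clavicle_mask)
    np.testing.assert_array_equal(rec.anterior_mask, small_phantom.anterior_mask)
    np.testing.assert_array_equal(rec.posterior_mask, small_phantom.posterior_mask)
    assert np.abs(rec.image - small_phantom.image).max() <= 1.0 / 255.0 + 1e-9


def test_missing_file_error_names_path(tmp_path, small_phantom):
    cid = _write(tmp_path, small_phantom)
    (tmp_path / f"{cid}_anterior.png").unlink()
    with pytest.raises(CaseFileError, match="anterior"):
        load_case(tmp_path, cid)


def test_mask_binarized_above_127(tmp_path, small_phantom):
    import imageio.v3 as iio

    cid = _write(tmp_path, small_phantom)
    m = np.zeros_like(small_phantom.clavicle_mask, dtype=np.uint8)
    m[1, 1] = 200
    m[2, 2] = 100
    iio.imwrite(tmp_path / f"{cid}_clavicle.png", m)
    rec = load_case(tmp_path, cid)
    assert rec.clavicle_mask[1, 1] == 1
    assert rec.clavicle_mask[2, 2] == 0


def test_resize_halves_shapes_and_keeps_masks_binary(small_phantom):
    rec = _record(small_phantom)
    out = resize_case(rec, 32)
    assert out.image.shape == (32, 32)
    for m in (out.clavicle_mask, out.anterior_mask, out.posterior_mask):
        assert m.shape == (32, 32)
        assert set(np.unique(m)) <= {0, 1}
    assert out.native_size == rec.image.shape


def test_resize_to_native_size_is_identity(small_phantom):
    rec = _record(small_phantom)
    out = resize_case(rec, rec.image.shape[0])
    np.testing.assert_array_equal(out.image, rec.image)
    np.testing.assert_array_equal(out.anterior_mask, rec.anterior_mask)


def test_resize_rejects_tiny_target(small_phantom):
    with pytest.raises(ValueError, match=">= 8"):
        resize_case(_record(small_phantom), 4)


# ---------------------------------------------------------------------------
# Fold splitting
# ---------------------------------------------------------------------------

def test_fourfold_88_gives_22_10_56():
    ids = [f"c{i}" for i in range(88)]
    folds = fourfold_split(ids, seed=0)
    assert len(folds) == 4
    for f in folds:
        assert (len(f.test_ids), len(f.val_ids), len(f.train_ids)) == (22, 10, 56)


def test_fourfold_test_sets_partition_ids():
    ids = [f"c{i}" for i in range(88)]
    folds = fourfold_split(ids, seed=3)
    pooled = [cid for f in folds for cid in f.test_ids]
    assert sorted(pooled) == sorted(ids)
    for f in folds:
        assert not (set(f.test_ids) & set(f.val_ids))
        assert not (set(f.test_ids) & set(f.train_ids))
        assert not (set(f.val_ids) & set(f.train_ids))
        assert set(f.test_ids) | set(f.val_ids) | set(f.train_ids) == set(ids)


def test_fourfold_is_deterministic():
    ids = [f"c{i}" for i in range(16)]
    a = fourfold_split(ids, seed=5)
    b = fourfold_split(ids, seed=5)
    assert a == b
    c = fourfold_split(ids, seed=6)
    assert a != c


def test_fourfold_12_ids_proportional_rule():
    folds = fourfold_split([f"c{i}" for i in range(12)], seed=1)
    for f in folds:
        assert len(f.test_ids) == 3
        assert len(f.val_ids) == max(1, round(10 / 66 * 9))
        assert len(f.train_ids) == 9 - len(f.val_ids)


def test_fourfold_rejects_small_or_ragged():
    with pytest.raises(ValueError, match="at least 8"):
        fourfold_split(["a"] * 4, seed=0)
    with pytest.raises(ValueError, match="divisible"):
        fourfold_split([f"c{i}" for i in range(10)], seed=0)


def test_manifest_roundtrip(tmp_path):
    folds = fourfold_split([f"c{i}" for i in range(12)], seed=2)
    paths = write_fold_manifests(folds, tmp_path)
    for fold, p in zip(folds, paths):
        assert read_fold_manifest(p) == fold


# ---------------------------------------------------------------------------
# Online augmentation
# ---------------------------------------------------------------------------

def test_epoch_stream_expansion_count(small_phantom):
    recs = [_record(small_phantom, f"r{i}") for i in range(5)]
    aug = AugmentConfig(expansion_factor=3, seed=0)
    samples = list(epoch_stream(recs, aug, epoch_index=1))
    assert len(samples) == 15


def test_identity_augmentation_returns_sources_exactly(small_phantom):
    recs = [_record(small_phantom)]
    aug = AugmentConfig(rotation_range=0, shift_range=0, shear_range=0,
                        zoom_range=0, horizontal_flip=False, expansion_factor=4, seed=0)
    for s in epoch_stream(recs, aug, epoch_index=0):
        np.testing.assert_array_equal(s.image, np.clip(recs[0].image, 0, 1))
        np.testing.assert_array_equal(s.anterior_mask, recs[0].anterior_mask)


def test_flip_only_augmentation_mirrors_masks(small_phantom):
    recs = [_record(small_phantom)]
    aug = AugmentConfig(rotation_range=0, shift_range=0, shear_range=0,
                        zoom_range=0, horizontal_flip=True, expansion_factor=20, seed=1)
    flipped = unflipped = 0
    src = recs[0].anterior_mask
    for s in epoch_stream(recs, aug, epoch_index=0):
        if np.array_equal(s.anterior_mask, src):
            unflipped += 1
        elif np.array_equal(s.anterior_mask, src[:, ::-1]):
            flipped += 1
        else:  # pragma: no cover
            raise AssertionError("flip-only sample is neither source nor its mirror")
    assert flipped > 0 and unflipped > 0


def test_augmented_masks_stay_binary(small_phantom):
    recs = [_record(small_phantom)]
    aug = AugmentConfig(seed=9)
    for s in epoch_stream(recs, aug, epoch_index=2):
        for m in (s.clavicle_mask, s.anterior_mask, s.posterior_mask):
            assert set(np.unique(m)) <= {0, 1}


def test_image_and_mask_share_the_geometric_transform():
    # a single landmark pixel must land on the same spot in image and mask
    h = w = 48
    image = np.zeros((h, w), dtype=np.float32)
    mask = np.zeros((h, w), dtype=np.uint8)
    image[30, 12] = 1.0
    mask[30, 12] = 1
    rec = CaseRecord(id="lm", image=image, clavicle_mask=mask,
                     anterior_mask=mask.copy(), posterior_mask=mask.copy(),
                     native_size=(h, w))
    aug = AugmentConfig(rotation_range=15, shift_range=0.1, shear_range=8,
                        zoom_range=0.15, horizontal_flip=True,
                        expansion_factor=10, seed=4)
    checked = 0
    for s in epoch_stream([rec], aug, epoch_index=0):
        if s.clavicle_mask.sum() == 0:
            continue  # landmark warped out of frame
        my, mx = np.argwhere(s.clavicle_mask).mean(axis=0)
        iy, ix = np.unravel_index(np.argmax(s.image), s.image.shape)
        assert abs(my - iy) <= 1.0 and abs(mx - ix) <= 1.0
        checked += 1
    assert checked > 0


def test_epoch_stream_reproducible_and_epoch_dependent(small_phantom):
    recs = [_record(small_phantom)]
    aug = AugmentConfig(seed=5, expansion_factor=3)
    a = [s.image for s in epoch_stream(recs, aug, epoch_index=1)]
    b = [s.image for s in epoch_stream(recs, aug, epoch_index=1)]
    c = [s.image for s in epoch_stream(recs, aug, epoch_index=2)]
    for x, y in zip(a, b):
        np.testing.assert_array_equal(x, y)
    assert any(not np.array_equal(x, y) for x, y in zip(a, c))


def test_epoch_stream_requires_cases():
    with pytest.raises(ValueError, match="non-empty"):
        list(epoch_stream([], AugmentConfig(), 0))
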