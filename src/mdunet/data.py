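"""Case file I/O, resizing, cross-validation splits and online augmentation.

On-disk layout: one 8-bit grayscale PNG per image and per structure mask,
named ``<case>_image.png``, ``<case>_clavicle.png``, ``<case>_anterior.png``,
``<case>_posterior.png``; mask files hold {0, 255} and are binarized at >127
on load.

The cross-validation protocol shuffles the case ids once, uses the four equal
consecutive blocks as test sets, and inside each fold takes validation cases
from the head of the remaining shuffled order at the 10-of-66 proportion.
Online augmentation expands the training set by a fixed factor per epoch
(56 cases -> 560 samples at the default factor 10), applying one random
affine transform — rotation, shift, shear, zoom, horizontal flip — jointly to
the image (bilinear) and its masks (nearest neighbour, so masks stay binary).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.transform import AffineTransform, resize, warp

from .phantom import derive_case_seed

__all__ = [
    "CaseRecord", "FoldSplit", "AugmentConfig",
    "save_case", "load_case", "resize_case",
    "fourfold_split", "write_fold_manifests", "read_fold_manifest",
    "epoch_stream",
]

_SUFFIXES = ("image", "clavicle", "anterior", "posterior")


class CaseFileError(IOError):
    pass


@dataclass
class CaseRecord:
    """One case in memory: intensity image plus three binary structure masks."""

    id: str
    image: np.ndarray
    clavicle_mask: np.ndarray
    anterior_mask: np.ndarray
    posterior_mask: np.ndarray
    native_size: tuple[int, int]

    def masks(self):
        return {
            "clavicle": self.clavicle_mask,
            "anterior": self.anterior_mask,
            "posterior": self.posterior_mask,
        }


def _case_paths(directory, case_id):
    return {s: os.path.join(directory, f"{case_id}_{s}.png") for s in _SUFFIXES}


def save_case(directory, case_id, image, clavicle_mask, anterior_mask, posterior_mask):
    """Write a case as four lossless 8-bit grayscale PNG files."""
    os.makedirs(directory, exist_ok=True)
    paths = _case_paths(directory, case_id)
    img8 = np.clip(np.rint(np.asarray(image, dtype=np.float64) * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(paths["image"], img8)
    for name, mask in (("clavicle", clavicle_mask), ("anterior", anterior_mask),
                       ("posterior", posterior_mask)):
        iio.imwrite(paths[name], (np.asarray(mask, dtype=np.uint8) * 255))
    return paths


def load_case(directory, case_id) -> CaseRecord:
    """Load a case; image scaled to [0, 1], masks binarized at value > 127."""
    paths = _case_paths(directory, case_id)
    for name, p in paths.items():
        if not os.path.exists(p):
            raise CaseFileError(f"missing {name} file for case '{case_id}': {p}")
    image = np.asarray(iio.imread(paths["image"]), dtype=np.float32) / 255.0
    masks = {}
    for name in _SUFFIXES[1:]:
        m = np.asarray(iio.imread(paths[name]))
        masks[name] = (m > 127).astype(np.uint8)
        if masks[name].shape != image.shape:
            raise CaseFileError(
                f"shape mismatch in case '{case_id}': {name} mask {masks[name].shape} "
                f"vs image {image.shape}")
    return CaseRecord(
        id=case_id, image=image,
        clavicle_mask=masks["clavicle"], anterior_mask=masks["anterior"],
        posterior_mask=masks["posterior"], native_size=image.shape,
    )


def resize_case(rec: CaseRecord, size: int) -> CaseRecord:
    """Resize to size x size: bilinear for the image, nearest for the masks."""
    if size < 8:
        raise ValueError(f"size must be >= 8, got {size}")
    if rec.image.shape == (size, size):
        return rec
    image = resize(rec.image, (size, size), order=1, anti_aliasing=True,
                   preserve_range=True).astype(np.float32)
    masks = {}
    for name, m in rec.masks().items():
        masks[name] = resize(m, (size, size), order=0, anti_aliasing=False,
                             preserve_range=True).astype(np.uint8)
    return CaseRecord(id=rec.id, image=image,
                      clavicle_mask=masks["clavicle"], anterior_mask=masks["anterior"],
                      posterior_mask=masks["posterior"], native_size=rec.native_size)


# ---------------------------------------------------------------------------
# Cross-validation splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    test_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    train_ids: tuple[str, ...]

    def __post_init__(self):
        groups = (set(self.test_ids), set(self.val_ids), set(self.train_ids))
        for i in range(3):
            for j in range(i + 1, 3):
                if groups[i] & groups[j]:
                    raise ValueError(f"fold {self.fold_index}: overlapping id groups")


def fourfold_split(ids, seed: int) -> list[FoldSplit]:
    """Shuffle once, block the ids into 4 test sets, split the rest 10/66-wise.

    With 88 ids each fold is 22 test / 10 validation / 56 training; other
    sizes divisible by 4 use validation = round(10/66 * remaining).
    """
    ids = list(ids)
    n = len(ids)
    if n < 8:
        raise ValueError(f"need at least 8 ids for fourfold cross-validation, got {n}")
    if n % 4:
        raise ValueError(f"number of ids must be divisible by 4, got {n}")
    rng = np.random.default_rng(np.random.PCG64(seed))
    shuffled = [ids[i] for i in rng.permutation(n)]
    block = n // 4
    folds = []
    for f in range(4):
        test = shuffled[f * block : (f + 1) * block]
        rest = shuffled[: f * block] + shuffled[(f + 1) * block :]
        n_val = max(1, int(round(10.0 / 66.0 * len(rest))))
        folds.append(FoldSplit(
            fold_index=f + 1,
            test_ids=tuple(test),
            val_ids=tuple(rest[:n_val]),
            train_ids=tuple(rest[n_val:]),
        ))
    return folds


def write_fold_manifests(folds, out_dir) -> list[str]:
    """Export folds as plain-text id lists, one ``fold_<i>.txt`` per fold."""
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for fold in folds:
        p = os.path.join(out_dir, f"fold_{fold.fold_index}.txt")
        with open(p, "w") as fh:
            fh.write(f"# fold {fold.fold_index}\n")
            for section, group in (("test", fold.test_ids), ("val", fold.val_ids),
                                   ("train", fold.train_ids)):
                fh.write(f"[{section}]\n")
                fh.writelines(f"{cid}\n" for cid in group)
        paths.append(p)
    return paths


def read_fold_manifest(path) -> FoldSplit:
    sections = {"test": [], "val": [], "train": []}
    current = None
    fold_index = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("# fold"):
                fold_index = int(line.split()[-1])
            elif line.startswith("[") and line.endswith("]"):
                current = line[1:-1]
                if current not in sections:
                    raise ValueError(f"unknown manifest section '{current}' in {path}")
            elif current is not None:
                sections[current].append(line)
            else:
                raise ValueError(f"id outside any section in {path}: '{line}'")
    return FoldSplit(fold_index=fold_index, test_ids=tuple(sections["test"]),
                     val_ids=tuple(sections["val"]), train_ids=tuple(sections["train"]))


# ---------------------------------------------------------------------------
# Online augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Ranges of the random affine augmentation (all symmetric about zero).

    ``rotation_range`` and ``shear_range`` in degrees, ``shift_range`` as a
    fraction of the image size, ``zoom_range`` as a fractional scale deviation
    (0.1 -> scale drawn in [0.9, 1.1]); horizontal flips with probability 0.5
    when enabled.  ``expansion_factor`` is how many augmented copies of each
    training case one epoch yields.
    """

    rotation_range: float = 10.0
    shift_range: float = 0.05
    shear_range: float = 5.0
    zoom_range: float = 0.10
    horizontal_flip: bool = True
    expansion_factor: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_range", "shift_range", "shear_range", "zoom_range"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.expansion_factor < 1:
            raise ValueError(f"expansion_factor must be >= 1, got {self.expansion_factor}")


@dataclass
class AugmentedSample:
    case_id: str
    image: np.ndarray
    clavicle_mask: np.ndarray
    anterior_mask: np.ndarray
    posterior_mask: np.ndarray


def _draw_transform(aug: AugmentConfig, rng, shape):
    """Sample one affine transform about the image centre; None = identity."""
    h, w = shape
    rot = np.deg2rad(rng.uniform(-aug.rotation_range, aug.rotation_range))
    shear = np.deg2rad(rng.uniform(-aug.shear_range, aug.shear_range))
    zoom = 1.0 + rng.uniform(-aug.zoom_range, aug.zoom_range)
    tx = rng.uniform(-aug.shift_range, aug.shift_range) * w
    ty = rng.uniform(-aug.shift_range, aug.shift_range) * h
    flip = bool(aug.horizontal_flip and rng.random() < 0.5)
    if rot == 0.0 and shear == 0.0 and zoom == 1.0 and tx == 0.0 and ty == 0.0:
        return None, flip
    centre = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    tform = (AffineTransform(translation=-centre)
             + AffineTransform(rotation=rot, shear=shear, scale=(zoom, zoom))
             + AffineTransform(translation=centre + np.array([tx, ty])))
    return tform, flip


def _apply_transform(sample_arrays, tform, flip):
    out = []
    for arr, order in sample_arrays:
        a = arr[:, ::-1] if flip else arr
        if tform is not None:
            a = warp(a.astype(np.float32), tform.inverse, order=order, cval=0.0,
                     preserve_range=True)
        out.append(a)
    return out


def epoch_stream(train, aug: AugmentConfig, epoch_index: int):
    """Yield ``len(train) * expansion_factor`` augmented samples for one epoch.

    Reproducible from ``(aug.seed, epoch_index)``: the stream cycles through
    the training cases ``expansion_factor`` times, drawing an independent
    transform per sample and warping image and masks with the same geometry.
    """
    if not train:
        raise ValueError("epoch_stream requires a non-empty training list")
    rng = np.random.default_rng(np.random.PCG64(derive_case_seed(aug.seed, epoch_index)))
    for _ in range(aug.expansion_factor):
        for rec in train:
            tform, flip = _draw_transform(aug, rng, rec.image.shape)
            image, clav, ant, post = _apply_transform(
                [(rec.image, 1), (rec.clavicle_mask, 0), (rec.anterior_mask, 0),
                 (rec.posterior_mask, 0)], tform, flip)
            yield AugmentedSample(
                case_id=rec.id,
                image=np.clip(image, 0.0, 1.0).astype(np.float32),
                clavicle_mask=clav.astype(np.uint8),
                anterior_mask=ant.astype(np.uint8),
                posterior_mask=post.astype(np.uint8),
            )
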