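"""Mask coding: complementary-plane encoding, argmax decoding, multitask targets.

A binary mask is re-encoded as two complementary planes — plane 0 marks the
foreground ("10"), plane 1 the background ("01") — so the network predicts a
per-pixel probability pair (P1 foreground, P2 background) and decoding is a
threshold-free comparison of the two.  The multilabel problem (a pixel lying
on both an anterior and a posterior rib) becomes four single-label binary
tasks: clavicle, anterior ribs, posterior ribs, and the union of all bones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Fixed task order used everywhere (loss indices, checkpoints, outputs).
TASK_NAMES = ("clavicle", "anterior", "posterior", "all_bones")

PROB_SUM_TOL = 1e-5


class MaskValidationError(ValueError):
    pass


def _check_binary(mask, name="mask"):
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise MaskValidationError(f"{name} must be a rank-2 array, got rank {mask.ndim}")
    if not np.isin(mask, (0, 1)).all():
        raise MaskValidationError(f"{name} must contain only values 0 and 1")
    return mask.astype(np.uint8, copy=False)


def encode_mask(mask: np.ndarray) -> np.ndarray:
    """Binary mask (H, W) -> encoded planes (2, H, W): (mask, 1 - mask)."""
    m = _check_binary(mask)
    return np.stack([m, 1 - m]).astype(np.uint8)


def decode_probability(probs: np.ndarray) -> np.ndarray:
    """Probability planes (2, H, W) -> binary mask by larger probability.

    A pixel is foreground iff P1 > P2; an exact tie decodes to background.
    No threshold parameter exists.
    """
    probs = np.asarray(probs)
    if probs.ndim != 3 or probs.shape[0] != 2:
        raise MaskValidationError(f"expected probability planes of shape (2, H, W), got {probs.shape}")
    sums = probs.sum(axis=0)
    if np.abs(sums - 1.0).max() > PROB_SUM_TOL:
        raise MaskValidationError(
            f"probability planes must sum to 1 per pixel within {PROB_SUM_TOL} "
            f"(max deviation {np.abs(sums - 1.0).max():.3g})")
    return (probs[0] > probs[1]).astype(np.uint8)


def union_mask(clavicle, anterior, posterior) -> np.ndarray:
    """Pixelwise OR of the three structure masks ('all bones')."""
    c = _check_binary(clavicle, "clavicle")
    a = _check_binary(anterior, "anterior")
    p = _check_binary(posterior, "posterior")
    if not (c.shape == a.shape == p.shape):
        raise MaskValidationError(
            f"mask shapes differ: clavicle {c.shape}, anterior {a.shape}, posterior {p.shape}")
    return (c | a | p).astype(np.uint8)


@dataclass(frozen=True)
class MultiTaskTargets:
    """Encoded targets for the four tasks, in :data:`TASK_NAMES` order."""

    clavicle: np.ndarray
    anterior: np.ndarray
    posterior: np.ndarray
    all_bones: np.ndarray

    def as_list(self):
        return [self.clavicle, self.anterior, self.posterior, self.all_bones]


def to_multitask_targets(clavicle, anterior, posterior) -> MultiTaskTargets:
    """Convert three possibly-overlapping structure masks into four encoded tasks.

    Each task is an independent two-plane target, so a pixel in the
    anterior/posterior overlap is foreground ("10") in *both* rib tasks —
    each task image carries exactly one label per pixel.
    """
    union = union_mask(clavicle, anterior, posterior)
    return MultiTaskTargets(
        clavicle=encode_mask(clavicle),
        anterior=encode_mask(anterior),
        posterior=encode_mask(posterior),
        all_bones=encode_mask(union),
    )
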