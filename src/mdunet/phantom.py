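"""Synthetic chest-phantom generator with per-structure ground-truth masks.

The phantom reproduces the statistical structure that makes rib/clavicle
segmentation from frontal chest radiographs hard, without any anatomical
pretension: a smooth background field with a brighter mediastinal column, two
bright elliptical lung fields, two near-horizontal clavicle bands at the top,
and — per side — a family of posterior rib bands (arcs of parabolas opening
downward in image coordinates) crossed by a family of anterior rib bands
(parabolas opening upward).  The two families are laid out so that each
anterior arc is guaranteed to cross its posterior counterpart, producing
pixels that belong to *both* rib structures — the multilabel phenomenon the
multitask conversion exists to solve.  Band intensity is attenuated outside
the lung ellipses (low bone/background contrast outside the lungs) and the
image is blurred and noised (fuzzy rib edges), while the ground-truth masks
record the exact band supports before any corruption.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["PhantomParams", "PhantomCase", "generate_phantom", "generate_dataset"]


class PhantomParameterError(ValueError):
    """A phantom parameter violates its domain; the message names the field."""


@dataclass(frozen=True)
class PhantomParams:
    """Geometry, contrast and corruption parameters of one phantom.

    Sizes are in pixels; contrast/attenuation factors are dimensionless in
    [0, 1]; ``noise_sd`` is the standard deviation of additive Gaussian noise
    on the [0, 1] intensity scale.
    """

    height: int = 256
    width: int = 256
    n_rib_pairs: int = 5
    rib_band_width: int = 7
    clavicle_thickness: int = 8
    lung_contrast: float = 0.7
    outside_lung_attenuation: float = 0.5
    edge_blur_sigma: float = 1.5
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self):
        if self.height < 32:
            raise PhantomParameterError(f"height must be >= 32, got {self.height}")
        if self.width < 32:
            raise PhantomParameterError(f"width must be >= 32, got {self.width}")
        if self.n_rib_pairs < 1:
            raise PhantomParameterError(f"n_rib_pairs must be >= 1, got {self.n_rib_pairs}")
        if self.rib_band_width < 1:
            raise PhantomParameterError(f"rib_band_width must be >= 1, got {self.rib_band_width}")
        if self.clavicle_thickness < 1:
            raise PhantomParameterError(
                f"clavicle_thickness must be >= 1, got {self.clavicle_thickness}")
        if not 0.0 <= self.lung_contrast <= 1.0:
            raise PhantomParameterError(f"lung_contrast must be in [0, 1], got {self.lung_contrast}")
        if not 0.0 <= self.outside_lung_attenuation <= 1.0:
            raise PhantomParameterError(
                f"outside_lung_attenuation must be in [0, 1], got {self.outside_lung_attenuation}")
        if self.edge_blur_sigma < 0:
            raise PhantomParameterError(f"edge_blur_sigma must be >= 0, got {self.edge_blur_sigma}")
        if self.noise_sd < 0:
            raise PhantomParameterError(f"noise_sd must be >= 0, got {self.noise_sd}")


@dataclass(frozen=True)
class PhantomCase:
    """One phantom image plus its three crisp ground-truth structure masks."""

    image: np.ndarray
    clavicle_mask: np.ndarray
    anterior_mask: np.ndarray
    posterior_mask: np.ndarray
    seed: int


# additive band amplitudes on the [0, 1] intensity scale; anterior ribs are
# the faintest structure, matching their poor radiographic conspicuity
_CLAVICLE_AMP = 0.35
_POSTERIOR_AMP = 0.30
_ANTERIOR_AMP = 0.22
_LUNG_AMP = 0.25


def _lung_field(h, w):
    """Union indicator of the two lung ellipses."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    lung = np.zeros((h, w), dtype=bool)
    for cx in (0.32 * w, 0.68 * w):
        d = ((xx - cx) / (0.20 * w)) ** 2 + ((yy - 0.55 * h) / (0.30 * h)) ** 2
        lung |= d <= 1.0
    return lung


def _band_from_curve(h, w, x_lo, x_hi, curve_y, half_width):
    """Support of ``|y - curve_y(x)| <= half_width`` over a column range."""
    mask = np.zeros((h, w), dtype=bool)
    xs = np.arange(int(round(x_lo)), int(round(x_hi)))
    xs = xs[(xs >= 0) & (xs < w)]
    yy = np.arange(h)[:, None].astype(np.float64)
    cy = curve_y(xs.astype(np.float64))[None, :]
    sub = np.abs(yy - cy) <= half_width
    # clip vertically to the thorax region so arcs never run off the frame
    sub &= (yy >= 0.08 * h) & (yy <= 0.94 * h)
    mask[:, xs] = sub
    return mask


def generate_phantom(params: PhantomParams) -> PhantomCase:
    """Deterministically render one phantom from its parameters (seed included)."""
    params.validate()
    h, w = params.height, params.width
    rng = np.random.default_rng(np.random.PCG64(params.seed))

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    # smooth background: gentle vertical gradient plus a bright mediastinal column
    background = 0.22 + 0.08 * (yy / h) + 0.15 * np.exp(-(((xx - 0.5 * w) / (0.10 * w)) ** 2))
    lung = _lung_field(h, w)
    background = background + _LUNG_AMP * params.lung_contrast * lung

    clav = np.zeros((h, w), dtype=bool)
    post = np.zeros((h, w), dtype=bool)
    ant = np.zeros((h, w), dtype=bool)

    half_rib = params.rib_band_width / 2.0
    half_clav = params.clavicle_thickness / 2.0
    n = params.n_rib_pairs
    spacing = 0.58 * h / n

    for sign, xc in ((1, 0.28 * w), (-1, 0.72 * w)):
        x_lo = xc - 0.21 * w
        x_hi = xc + 0.21 * w
        # clavicle: near-horizontal band, slight random tilt
        tilt = rng.uniform(-0.06, 0.06)
        y0 = 0.135 * h + rng.uniform(-0.01, 0.01) * h
        clav |= _band_from_curve(
            h, w, x_lo, x_hi, lambda x: y0 + tilt * sign * (x - xc), half_clav)
        for k in range(n):
            jv = rng.uniform(-0.01, 0.01) * h
            ju = rng.uniform(-0.01, 0.01) * h
            a_post = 0.10 * h / (0.21 * w) ** 2 * rng.uniform(0.85, 1.15)
            a_ant = 0.12 * h / (0.21 * w) ** 2 * rng.uniform(0.85, 1.15)
            v_k = 0.22 * h + k * spacing + jv      # posterior vertex (topmost point)
            u_k = 0.30 * h + k * spacing + ju      # anterior vertex (lowest point)
            post |= _band_from_curve(
                h, w, x_lo, x_hi,
                lambda x, v=v_k, a=a_post: v + a * (x - xc) ** 2, half_rib)
            ant |= _band_from_curve(
                h, w, x_lo, x_hi,
                lambda x, u=u_k, a=a_ant: u - a * (x - xc) ** 2, half_rib)

    # additive band intensities, attenuated outside the lung fields
    additive = (_CLAVICLE_AMP * clav + _POSTERIOR_AMP * post + _ANTERIOR_AMP * ant)
    scale = np.where(lung, 1.0, params.outside_lung_attenuation)
    image = np.clip(background + additive * scale, 0.0, 1.0)

    if params.edge_blur_sigma > 0:
        image = gaussian_filter(image, params.edge_blur_sigma)
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, 1.0)

    return PhantomCase(
        image=image.astype(np.float32),
        clavicle_mask=clav.astype(np.uint8),
        anterior_mask=ant.astype(np.uint8),
        posterior_mask=post.astype(np.uint8),
        seed=params.seed,
    )


def derive_case_seed(root_seed: int, index: int) -> int:
    """Splitmix-style mix of (root_seed, index) into an independent case seed."""
    z = (int(root_seed) * 0x9E3779B97F4A7C15 + int(index) + 1) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & 0xFFFFFFFFFFFFFFFF
    z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & 0xFFFFFFFFFFFFFFFF
    return (z ^ (z >> 31)) & 0x7FFFFFFFFFFFFFFF


def generate_dataset(n_cases: int, params: PhantomParams, root_seed: int, out_dir) -> list[str]:
    """Write ``n_cases`` phantoms to ``out_dir`` in the standard case layout.

    Case ``i`` is rendered with a seed mixed deterministically from
    ``(root_seed, i)``, so reruns with the same root seed are byte-identical.
    Returns the case identifiers in generation order.
    """
    from .data import save_case  # local import: data module owns the file layout

    if n_cases < 1:
        raise PhantomParameterError(f"n_cases must be >= 1, got {n_cases}")
    ids = []
    for i in range(n_cases):
        case_id = f"case_{i:04d}"
        case = generate_phantom(replace(params, seed=derive_case_seed(root_seed, i)))
        save_case(out_dir, case_id, case.image,
                  case.clavicle_mask, case.anterior_mask, case.posterior_mask)
        ids.append(case_id)
    return ids
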