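"""Patch-consistent image augmentation for streamed training.

Every random draw (flips, rotation angle, stain rotation angles, stain
concentration factors) is sampled *once per image* into an
:class:`AugmentationPlan`, so any patch of the image can be augmented
independently and the patches remain mutually consistent: concatenating
augmented patches reproduces the augmented whole image.

Geometric augmentation (flip + rotation about the canvas center, bilinear,
white fill) is made patch-local by inverse-mapping the requested output
rectangle to its source bounding box and resampling only that window.

Color augmentation follows the Beer-Lambert optical-density model of H&E
staining: RGB is converted to optical density, decomposed into hematoxylin
and eosin concentrations through a stain matrix, the concentrations are
scaled, and the pixel is recomposed through a slightly rotated stain matrix.
It is pixel-local, hence trivially patch-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .tiling import Rect, TiledImage, TilingError, fetch_window

# Ruifrok-Johnston style H&E optical-density vectors, unit-normalized.
DEFAULT_STAIN_MATRIX = np.array(
    [
        [0.650, 0.704, 0.286],  # hematoxylin
        [0.072, 0.990, 0.105],  # eosin
    ]
)
DEFAULT_STAIN_MATRIX = DEFAULT_STAIN_MATRIX / np.linalg.norm(
    DEFAULT_STAIN_MATRIX, axis=1, keepdims=True
)


@dataclass(frozen=True)
class AugmentConfig:
    rotation_range: tuple[float, float] = (-180.0, 180.0)
    stain_angle_range: tuple[float, float] = (-10.0, 10.0)
    concentration_range: tuple[float, float] = (0.5, 1.5)


@dataclass(frozen=True)
class AugmentationPlan:
    """All per-image random draws, fixed before any patch is touched."""

    hflip: bool
    vflip: bool
    theta_rot: float  # degrees
    theta_h: float  # stain rotation of hematoxylin vector, degrees
    theta_e: float  # stain rotation of eosin vector, degrees
    f_h: float  # hematoxylin concentration factor
    f_e: float  # eosin concentration factor
    rng_seed: int

    @classmethod
    def identity(cls, seed: int = 0) -> "AugmentationPlan":
        return cls(False, False, 0.0, 0.0, 0.0, 1.0, 1.0, seed)

    @property
    def is_geometric_identity(self) -> bool:
        return not self.hflip and not self.vflip and self.theta_rot == 0.0


def sample_plan(seed: int, config: AugmentConfig = AugmentConfig()) -> AugmentationPlan:
    """Deterministically draw a per-image augmentation plan from ``seed``."""
    rng = np.random.default_rng(seed)
    lo, hi = config.rotation_range
    th_lo, th_hi = config.stain_angle_range
    f_lo, f_hi = config.concentration_range
    return AugmentationPlan(
        hflip=bool(rng.random() < 0.5),
        vflip=bool(rng.random() < 0.5),
        theta_rot=float(rng.uniform(lo, hi)),
        theta_h=float(rng.uniform(th_lo, th_hi)),
        theta_e=float(rng.uniform(th_lo, th_hi)),
        f_h=float(rng.uniform(f_lo, f_hi)),
        f_e=float(rng.uniform(f_lo, f_hi)),
        rng_seed=int(seed),
    )


# ---------------------------------------------------------------------------
# geometric augmentation
# ---------------------------------------------------------------------------


def _source_coords(plan: AugmentationPlan, rect: Rect, canvas: tuple[int, int]):
    """Inverse-map output pixel centers of ``rect`` to source coordinates.

    Forward transform: flips, then rotation by ``theta_rot`` about the canvas
    center.  The inverse therefore rotates by ``-theta`` and then un-flips.
    """
    ch, cw = canvas
    cr, cc = (ch - 1) / 2.0, (cw - 1) / 2.0
    rows = np.arange(rect.r0, rect.r1, dtype=np.float64)
    cols = np.arange(rect.c0, rect.c1, dtype=np.float64)
    rr, cc_grid = np.meshgrid(rows - cr, cols - cc, indexing="ij")
    th = np.deg2rad(plan.theta_rot)
    # rotate output offsets by -theta
    sr = np.cos(th) * rr + np.sin(th) * cc_grid + cr
    sc = -np.sin(th) * rr + np.cos(th) * cc_grid + cc
    if plan.vflip:
        sr = (ch - 1) - sr
    if plan.hflip:
        sc = (cw - 1) - sc
    return sr, sc


def augment_patch_affine(
    image: TiledImage,
    plan: AugmentationPlan,
    out_rect: Rect,
    canvas: tuple[int, int] | None = None,
    dtype=np.uint8,
) -> np.ndarray:
    """The ``out_rect`` window of the full-image flip+rotation transform.

    Only the source bounding box of the patch (plus a 2-pixel interpolation
    margin) is read from the image, so the cost is proportional to the patch,
    not the slide.  Out-of-raster source pixels are white.
    """
    if canvas is None:
        canvas = (image.height, image.width)
    sr, sc = _source_coords(plan, out_rect, canvas)
    if plan.is_geometric_identity:
        block = fetch_window(image, out_rect)
        return block if dtype == np.uint8 else block.astype(dtype)
    r0 = int(np.floor(sr.min())) - 2
    r1 = int(np.ceil(sr.max())) + 3
    c0 = int(np.floor(sc.min())) - 2
    c1 = int(np.ceil(sc.max())) + 3
    src = fetch_window(image, Rect(r0, r1, c0, c1)).astype(np.float64)
    coords = np.stack([sr - r0, sc - c0])
    out = np.empty((out_rect.height, out_rect.width, 3), dtype=np.float64)
    for ch in range(3):
        out[..., ch] = map_coordinates(src[..., ch], coords, order=1, mode="constant", cval=255.0)
    if dtype == np.uint8:
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out.astype(dtype)


# ---------------------------------------------------------------------------
# stain model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StainModel:
    """Two unit-norm H&E stain vectors in 3-D optical-density space."""

    stain_matrix: np.ndarray = None  # (2, 3): rows H, E
    i0: int = 255
    od_base: int = 10

    def __post_init__(self):
        m = self.stain_matrix if self.stain_matrix is not None else DEFAULT_STAIN_MATRIX
        m = np.asarray(m, dtype=np.float64)
        if m.shape != (2, 3):
            raise TilingError("stain matrix must be 2x3 (rows H, E)")
        if np.any(m < 0):
            raise TilingError("stain vectors must be non-negative")
        norms = np.linalg.norm(m, axis=1)
        if np.any(norms == 0):
            raise TilingError("stain vectors must be nonzero")
        object.__setattr__(self, "stain_matrix", m / norms[:, None])


def rgb_to_od(block: np.ndarray) -> np.ndarray:
    """Beer-Lambert optical density: OD = -log10((v + 1) / 256) per channel.

    The +1 guard keeps OD finite at v = 0; OD(255) = 0 exactly.
    """
    v = np.asarray(block, dtype=np.float64)
    return -np.log10((v + 1.0) / 256.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Invert :func:`rgb_to_od`, clip to [0, 255], round to nearest integer."""
    od = np.asarray(od, dtype=np.float64)
    if np.any(od < 0):
        raise TilingError("optical density must be non-negative")
    v = 256.0 * np.power(10.0, -od) - 1.0
    return np.clip(np.rint(v), 0, 255).astype(np.uint8)


def stain_concentrations(od: np.ndarray, stain: StainModel) -> np.ndarray:
    """Per-pixel non-negative least-squares H&E concentrations.

    ``od`` is (..., 3); returns (..., 2).  With only two stains the NNLS
    solution is closed-form: either the unconstrained 2x2 solve (when both
    components are non-negative) or the better of the two single-stain
    projections clipped at zero.
    """
    od = np.asarray(od, dtype=np.float64)
    if not np.all(np.isfinite(od)):
        raise TilingError("optical density must be finite")
    s = stain.stain_matrix
    gram = s @ s.T
    det = gram[0, 0] * gram[1, 1] - gram[0, 1] * gram[1, 0]
    if abs(det) < 1e-12:
        raise TilingError("stain matrix is degenerate (collinear stain vectors)")
    b = od @ s.T  # (..., 2)
    inv = np.array([[gram[1, 1], -gram[0, 1]], [-gram[1, 0], gram[0, 0]]]) / det
    c_free = b @ inv.T
    # boundary candidates: one stain at a time, clipped at zero
    c_h = np.clip(b[..., 0] / gram[0, 0], 0.0, None)
    c_e = np.clip(b[..., 1] / gram[1, 1], 0.0, None)

    def resid(c):
        return np.sum((od - c @ s) ** 2, axis=-1)

    cand_h = np.stack([c_h, np.zeros_like(c_h)], axis=-1)
    cand_e = np.stack([np.zeros_like(c_e), c_e], axis=-1)
    boundary = np.where((resid(cand_h) <= resid(cand_e))[..., None], cand_h, cand_e)
    interior_ok = np.all(c_free >= 0, axis=-1)[..., None]
    return np.where(interior_ok, c_free, boundary)


def perturb_stain(stain: StainModel, plan: AugmentationPlan) -> StainModel:
    """Rotate each stain vector by its sampled angle within span(H, E).

    A positive angle tips the vector toward the other stain; entries are
    clipped at zero and the rows re-normalized to unit norm.
    """
    s = stain.stain_matrix
    h, e = s[0], s[1]
    if abs(abs(h @ e) - 1.0) < 1e-12:
        raise TilingError("collinear stain vectors cannot be rotated in-plane")

    def rotate(v, other, theta_deg):
        u = other - (other @ v) * v
        u = u / np.linalg.norm(u)
        th = np.deg2rad(theta_deg)
        out = np.cos(th) * v + np.sin(th) * u
        out = np.clip(out, 0.0, None)
        return out / np.linalg.norm(out)

    new = np.stack([rotate(h, e, plan.theta_h), rotate(e, h, plan.theta_e)])
    return replace(stain, stain_matrix=new)


def augment_patch_stain(
    block: np.ndarray, stain: StainModel, plan: AugmentationPlan
) -> np.ndarray:
    """Stain-space color augmentation of one patch (pixel-local, patch-exact).

    Decompose to H&E concentrations, scale by (f_h, f_e), recompose through
    the perturbed stain matrix.  Pure white stays pure white (zero OD maps to
    zero concentration and back).
    """
    od = rgb_to_od(block)
    c = stain_concentrations(od, stain)
    c = c * np.array([plan.f_h, plan.f_e])
    new_stain = perturb_stain(stain, plan)
    od_new = c @ new_stain.stain_matrix
    return od_to_rgb(od_new)


def augment_window(
    image: TiledImage,
    plan: AugmentationPlan | None,
    rect: Rect,
    stain: StainModel | None = None,
    canvas: tuple[int, int] | None = None,
) -> np.ndarray:
    """Fully augmented window: affine first, then stain-space color transform."""
    if plan is None:
        return fetch_window(image, rect)
    block = augment_patch_affine(image, plan, rect, canvas=canvas)
    return augment_patch_stain(block, stain if stain is not None else StainModel(), plan)
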