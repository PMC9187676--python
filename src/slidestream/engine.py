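"""Memory-bounded streamed training and inference on tiled images.

The forward pass visits disjoint core tiles in row-major order.  For each
tile it fetches the tile plus its halo margin (optionally augmented), runs
the local layer stack, crops to the tile's output, and folds the result into
per-channel running maxima.  Intermediate feature maps are discarded after
each tile (gradient checkpointing): only the running maxima, argmax
locations and the tile descriptors survive, so peak memory is bounded by one
extended tile regardless of image size.

The backward pass exploits the global-max head: the feature-map gradient is
nonzero only at the argmax location of each channel, so only tiles
containing at least one argmax are re-forwarded and back-propagated.  Tiles
whose (augmented) input window is pure white are skipped outright.

Two orthogonal oracles live here as well: :func:`naive_reference` evaluates
the whole image densely with no patching, and is the ground truth the
streamed path is tested against.
"""

from __future__ import annotations

import queue
import threading
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .augmentation import AugmentationPlan, StainModel, augment_window
from .losses import NoiseTransition, forward_corrected_ce, forward_corrected_ce_grad
from .nn import Layer, StreamableNet
from .tiling import (
    LayerGeometry,
    PatchPlan,
    Rect,
    TiledImage,
    is_contentless,
    plan_patches,
)


class EngineError(RuntimeError):
    pass


class NoContentError(EngineError):
    """Raised when every patch of an image was skipped as contentless."""


# ---------------------------------------------------------------------------
# window interval arithmetic
# ---------------------------------------------------------------------------


def _layer_extents(geoms: list[LayerGeometry], h: int, w: int) -> list[tuple[int, int]]:
    """Input extent (h, w) of each layer plus the final feature extent."""
    extents = [(h, w)]
    for g in geoms:
        h, w = g.output_extent(h), g.output_extent(w)
        extents.append((h, w))
    return extents


def _window_chain(geoms, extents, core_r, core_c):
    """Per-layer (valid interval, pad amounts) needed to produce ``core``.

    Walking top-down, the raw input interval of each layer is the backward
    interval map of the (clipped) interval above; clipping against the
    layer's global input extent yields the part that actually exists, and the
    clipped-off overhang is exactly the global boundary padding the layer
    must materialize itself.
    """
    n = len(geoms)
    valid = [None] * (n + 1)
    pads = [None] * n
    valid[n] = (core_r, core_c)
    vr, vc = core_r, core_c
    for l in range(n - 1, -1, -1):
        g = geoms[l]
        raw_r = g.input_interval(*vr)
        raw_c = g.input_interval(*vc)
        eh, ew = extents[l]
        vr = (max(raw_r[0], 0), min(raw_r[1], eh))
        vc = (max(raw_c[0], 0), min(raw_c[1], ew))
        valid[l] = (vr, vc)
        pads[l] = (vr[0] - raw_r[0], raw_r[1] - vr[1], vc[0] - raw_c[0], raw_c[1] - vc[1])
    return valid, pads


def _forward_window(layers, valid, pads, x, keep_acts=False):
    """Run the stack on one materialized window; returns (core output, acts, peak area)."""
    acts = [] if keep_acts else None
    peak = x.shape[1] * x.shape[2]
    for layer, p in zip(layers, pads):
        if keep_acts:
            acts.append(x)
        x = layer.forward(x, p)
        peak = max(peak, x.shape[1] * x.shape[2])
    return x, acts, peak


def _backward_window(layers, pads, acts, g, grads):
    """Back-propagate ``g`` through one window, accumulating parameter grads."""
    for layer, p, x in zip(reversed(layers), reversed(pads), reversed(acts)):
        g, pg = layer.backward(x, g, p)
        for pname, arr in pg.items():
            grads[f"{layer.name}.{pname}"] += arr


def interior_feature(net: StreamableNet, value: float = 1.0) -> np.ndarray:
    """Per-channel response of the stack to an infinite constant input.

    Computed by materializing the exact receptive field of one interior
    output pixel.  Used to reason about contentless (pure white) patches.
    """
    lo_r, hi_r = 0, 1
    lo_c, hi_c = 0, 1
    for g in reversed(net.geometries()):
        lo_r, hi_r = g.input_interval(lo_r, hi_r)
        lo_c, hi_c = g.input_interval(lo_c, hi_c)
    x = np.full((net.in_channels, hi_r - lo_r, hi_c - lo_c), value, dtype=np.float64)
    for layer in net.layers:
        x = layer.forward(x)
    return x[:, 0, 0]


# ---------------------------------------------------------------------------
# forward
# ---------------------------------------------------------------------------


@dataclass
class ForwardRecord:
    """Everything the backward pass needs besides the image itself."""

    logit: float
    maxima: np.ndarray  # (C,)
    argmax: np.ndarray  # (C, 2) final-feature-map coordinates
    content_flags: list[bool]
    visit_order: list[int]
    n_skipped: int
    white_win_channels: list[int]  # channels a skipped white patch would have won
    peak_activation_area: int
    fingerprint: tuple

    @property
    def n_patches(self) -> int:
        return len(self.content_flags)


def _fingerprint(image, plan, patches, skip_white):
    plan_key = None if plan is None else (
        plan.hflip, plan.vflip, plan.theta_rot, plan.theta_h, plan.theta_e,
        plan.f_h, plan.f_e, plan.rng_seed,
    )
    return (image.height, image.width, patches.tile_size, patches.n_tiles, plan_key, skip_white)


def _fetch_input(image, plan, stain, rect, canvas):
    block = augment_window(image, plan, rect, stain=stain, canvas=canvas)
    return block, np.moveaxis(block, -1, 0).astype(np.float64) / 255.0


def _tile_windows(net, patches, tile):
    """Interval chain for one core tile, in final-feature coordinates."""
    s = patches.stride
    core_r = (tile.r0 // s, tile.r1 // s)
    core_c = (tile.c0 // s, tile.c1 // s)
    extents = _layer_extents(net.geometries(), patches.padded_height, patches.padded_width)
    valid, pads = _window_chain(net.geometries(), extents, core_r, core_c)
    return valid, pads, core_r, core_c


def forward_streamed(
    net: StreamableNet,
    image: TiledImage,
    patches: PatchPlan,
    plan: AugmentationPlan | None = None,
    stain: StainModel | None = None,
    skip_white: bool = False,
    whiteness_delta: int = 0,
    pipeline: bool = False,
) -> ForwardRecord:
    """Patched forward pass with gradient checkpointing and white-patch skipping.

    With ``pipeline=True`` a background thread prefetches and augments the
    next patch while the current one is computed (the scheduling contract:
    results are bit-identical to sequential execution).
    """
    c = net.feature_channels
    maxima = np.full(c, -np.inf)
    argmax = np.full((c, 2), -1, dtype=np.int64)
    content_flags: list[bool] = []
    visit_order: list[int] = []
    skipped_signatures: dict[tuple, tuple] = {}
    peak = 0
    canvas = (patches.padded_height, patches.padded_width)
    geoms = net.geometries()
    extents = _layer_extents(geoms, *canvas)
    s = patches.stride

    def prepare(idx):
        tile = patches.core_tiles[idx]
        core_r = (tile.r0 // s, tile.r1 // s)
        core_c = (tile.c0 // s, tile.c1 // s)
        valid, pads = _window_chain(geoms, extents, core_r, core_c)
        (vr, vc) = valid[0]
        rect = Rect(vr[0], vr[1], vc[0], vc[1])
        block, x = _fetch_input(image, plan, stain, rect, canvas)
        skip = skip_white and is_contentless(block, whiteness_delta)
        return idx, core_r, core_c, valid, pads, x, skip

    if pipeline:
        q: queue.Queue = queue.Queue(maxsize=2)

        def producer():
            for idx in range(patches.n_tiles):
                q.put(prepare(idx))
            q.put(None)

        t = threading.Thread(target=producer, daemon=True)
        t.start()

        def items():
            while True:
                item = q.get()
                if item is None:
                    return
                yield item

        stream = items()
    else:
        stream = (prepare(i) for i in range(patches.n_tiles))

    for idx, core_r, core_c, valid, pads, x, skip in stream:
        visit_order.append(idx)
        if skip:
            content_flags.append(False)
            # all-white windows with identical shapes/pads have identical
            # outputs, so remember one representative per signature
            sig = (
                tuple((vr[1] - vr[0], vc[1] - vc[0]) for (vr, vc) in valid),
                tuple(pads),
            )
            skipped_signatures.setdefault(sig, (valid, pads))
            continue
        content_flags.append(True)
        y, _, p_area = _forward_window(net.layers, valid, pads, x)
        peak = max(peak, p_area)
        flat = y.reshape(c, -1)
        local_idx = np.argmax(flat, axis=1)  # first occurrence, row-major
        local_max = flat[np.arange(c), local_idx]
        rows = core_r[0] + local_idx // y.shape[2]
        cols = core_c[0] + local_idx % y.shape[2]
        better = local_max > maxima
        tie = (local_max == maxima) & (
            (rows < argmax[:, 0]) | ((rows == argmax[:, 0]) & (cols < argmax[:, 1]))
        )
        upd = better | tie
        maxima[upd] = local_max[upd]
        argmax[upd, 0] = rows[upd]
        argmax[upd, 1] = cols[upd]

    if pipeline:
        t.join()

    n_skipped = sum(1 for f in content_flags if not f)
    if n_skipped == patches.n_tiles:
        raise NoContentError("every patch was skipped as contentless")

    # deviation flag: evaluate each distinct skipped-window signature on an
    # all-white input (exact, including global-boundary padding effects) and
    # report channels where a skipped patch would have attained (or tied)
    # the channel maximum
    white_win_mask = np.zeros(c, dtype=bool)
    for valid, pads in skipped_signatures.values():
        (vr, vc) = valid[0]
        x = np.ones((net.in_channels, vr[1] - vr[0], vc[1] - vc[0]), dtype=np.float64)
        y, _, _ = _forward_window(net.layers, valid, pads, x)
        white_win_mask |= y.reshape(c, -1).max(axis=1) >= maxima
    white_win = [int(ch) for ch in np.nonzero(white_win_mask)[0]]

    logit = float(net.head_w @ maxima + net.head_b)
    return ForwardRecord(
        logit=logit,
        maxima=maxima,
        argmax=argmax,
        content_flags=content_flags,
        visit_order=visit_order,
        n_skipped=n_skipped,
        white_win_channels=white_win,
        peak_activation_area=peak,
        fingerprint=_fingerprint(image, plan, patches, skip_white),
    )


# ---------------------------------------------------------------------------
# backward
# ---------------------------------------------------------------------------


@dataclass
class GradientSet:
    """One gradient per trainable parameter, plus a recomputation counter."""

    grads: dict[str, np.ndarray]
    recomputed_patches: int = 0

    def __getitem__(self, key: str) -> np.ndarray:
        return self.grads[key]

    def keys(self):
        return self.grads.keys()

    def max_rel_error(self, other: "GradientSet") -> float:
        """Max relative (scale-normalized) discrepancy against ``other``."""
        err = 0.0
        for k in self.grads:
            a, b = self.grads[k], other.grads[k]
            scale = max(np.max(np.abs(b)), 1e-8)
            err = max(err, float(np.max(np.abs(a - b)) / scale))
        return err


def _tile_index_of(patches: PatchPlan, r: int, c: int) -> int:
    """Index of the core tile containing final-feature position (r, c)."""
    s, t = patches.stride, patches.tile_size
    n_cols = -(-patches.padded_width // t)
    return (r * s) // t * n_cols + (c * s) // t


def backward_streamed(
    net: StreamableNet,
    image: TiledImage,
    patches: PatchPlan,
    record: ForwardRecord,
    dloss_dlogit: float,
    plan: AugmentationPlan | None = None,
    stain: StainModel | None = None,
) -> GradientSet:
    """Checkpointed backward pass: re-forward only argmax-bearing patches."""
    if record.fingerprint != _fingerprint(image, plan, patches, record.fingerprint[5]):
        raise EngineError("forward record does not match the given image/plan/tiling")
    grads = net.zero_gradients()
    if dloss_dlogit == 0.0:
        return GradientSet(grads, 0)

    grads["head.w"] += dloss_dlogit * record.maxima
    grads["head.b"] += np.array([dloss_dlogit])

    by_tile: dict[int, list[int]] = {}
    for ch in range(net.feature_channels):
        r, c = record.argmax[ch]
        by_tile.setdefault(_tile_index_of(patches, int(r), int(c)), []).append(ch)

    canvas = (patches.padded_height, patches.padded_width)
    geoms = net.geometries()
    extents = _layer_extents(geoms, *canvas)
    s = patches.stride
    for tidx in sorted(by_tile):
        tile = patches.core_tiles[tidx]
        core_r = (tile.r0 // s, tile.r1 // s)
        core_c = (tile.c0 // s, tile.c1 // s)
        valid, pads = _window_chain(geoms, extents, core_r, core_c)
        (vr, vc) = valid[0]
        _, x = _fetch_input(image, plan, stain, Rect(vr[0], vr[1], vc[0], vc[1]), canvas)
        y, acts, _ = _forward_window(net.layers, valid, pads, x, keep_acts=True)
        g = np.zeros_like(y)
        for ch in by_tile[tidx]:
            r, c = record.argmax[ch]
            g[ch, int(r) - core_r[0], int(c) - core_c[0]] += dloss_dlogit * net.head_w[ch]
        _backward_window(net.layers, pads, acts, g, grads)

    return GradientSet(grads, recomputed_patches=len(by_tile))


# ---------------------------------------------------------------------------
# CAM
# ---------------------------------------------------------------------------


def cam_streamed(
    net: StreamableNet,
    image: TiledImage,
    patches: PatchPlan,
    plan: AugmentationPlan | None = None,
    stain: StainModel | None = None,
    skip_white: bool = False,
    whiteness_delta: int = 0,
) -> np.ndarray:
    """Class activation map at feature resolution, stitched from patches.

    Per location: ``sigmoid(w . F(x, y) + b)``, values in [0, 1].  Skipped
    white patches (if enabled) are filled with the interior white response.
    """
    canvas_h, canvas_w = patches.padded_height, patches.padded_width
    geoms = net.geometries()
    extents = _layer_extents(geoms, canvas_h, canvas_w)
    hf, wf = extents[-1]
    cam = np.empty((hf, wf), dtype=np.float64)
    white_logit = None
    s = patches.stride
    canvas = (canvas_h, canvas_w)
    for tile in patches.core_tiles:
        core_r = (tile.r0 // s, tile.r1 // s)
        core_c = (tile.c0 // s, tile.c1 // s)
        valid, pads = _window_chain(geoms, extents, core_r, core_c)
        (vr, vc) = valid[0]
        block, x = _fetch_input(image, plan, stain, Rect(vr[0], vr[1], vc[0], vc[1]), canvas)
        view = cam[core_r[0] : core_r[1], core_c[0] : core_c[1]]
        if skip_white and is_contentless(block, whiteness_delta):
            if white_logit is None:
                white_logit = float(net.head_w @ interior_feature(net, 1.0) + net.head_b)
            view[...] = expit(white_logit)
            continue
        y, _, _ = _forward_window(net.layers, valid, pads, x)
        view[...] = expit(np.einsum("cij,c->ij", y, net.head_w) + net.head_b)
    return cam


# ---------------------------------------------------------------------------
# naive full-image oracle
# ---------------------------------------------------------------------------


def naive_reference(
    net: StreamableNet,
    image: TiledImage,
    plan: AugmentationPlan | None = None,
    stain: StainModel | None = None,
    dloss_dlogit: float = 1.0,
    return_features: bool = False,
):
    """Full-image forward/backward with no patching (the equivalence oracle).

    Feasible only for desk-scale images; materializes every feature map.
    """
    s = net.stride
    ph = -(-image.height // s) * s
    pw = -(-image.width // s) * s
    _, x = _fetch_input(image, plan, stain, Rect(0, ph, 0, pw), (ph, pw))
    acts = []
    for layer in net.layers:
        acts.append(x)
        p = layer.geometry.padding
        x = layer.forward(x, (p, p, p, p))
    feats = x
    c = net.feature_channels
    flat = feats.reshape(c, -1)
    idx = np.argmax(flat, axis=1)
    maxima = flat[np.arange(c), idx]
    logit = float(net.head_w @ maxima + net.head_b)

    grads = net.zero_gradients()
    grads["head.w"] += dloss_dlogit * maxima
    grads["head.b"] += np.array([dloss_dlogit])
    g = np.zeros_like(feats)
    rows, cols = idx // feats.shape[2], idx % feats.shape[2]
    g[np.arange(c), rows, cols] = dloss_dlogit * net.head_w
    for layer, a in zip(reversed(net.layers), reversed(acts)):
        p = layer.geometry.padding
        g, pg = layer.backward(a, g, (p, p, p, p))
        for pname, arr in pg.items():
            grads[f"{layer.name}.{pname}"] += arr
    gset = GradientSet(grads, recomputed_patches=-1)
    if return_features:
        return logit, gset, feats
    return logit, gset


def naive_cam(net: StreamableNet, image: TiledImage, plan=None, stain=None) -> np.ndarray:
    _, _, feats = naive_reference(net, image, plan, stain, return_features=True)
    return expit(np.einsum("cij,c->ij", feats, net.head_w) + net.head_b)


# ---------------------------------------------------------------------------
# training / scoring
# ---------------------------------------------------------------------------


@dataclass
class StepResult:
    loss: float
    logit: float
    recomputed_patches: int
    skipped_patches: int


def train_step(
    net: StreamableNet,
    image: TiledImage,
    label: int,
    noise: NoiseTransition | None = None,
    optimizer=None,
    plan: AugmentationPlan | None = None,
    stain: StainModel | None = None,
    tile_size: int = 2048,
    skip_white: bool = True,
    whiteness_delta: int = 0,
) -> StepResult:
    """One streamed optimization step on a single (image, weak label) pair."""
    if label not in (0, 1):
        raise EngineError(f"label must be 0 or 1, got {label}")
    noise = noise or NoiseTransition.identity()
    patches = plan_patches(image, tile_size, net.geometries())
    record = forward_streamed(
        net, image, patches, plan=plan, stain=stain,
        skip_white=skip_white, whiteness_delta=whiteness_delta,
    )
    p = float(np.clip(expit(record.logit), 1e-12, 1 - 1e-12))
    loss = forward_corrected_ce(p, label, noise)
    dlogit = forward_corrected_ce_grad(p, label, noise) * p * (1.0 - p)
    gset = backward_streamed(net, image, patches, record, dlogit, plan=plan, stain=stain)
    if optimizer is not None:
        optimizer(net, gset.grads)
    return StepResult(loss, record.logit, gset.recomputed_patches, record.n_skipped)


def score_image(
    net: StreamableNet,
    image: TiledImage,
    tile_size: int = 2048,
    skip_white: bool = True,
) -> float:
    """Positive-class probability for one image (sigmoid of the streamed logit)."""
    patches = plan_patches(image, tile_size, net.geometries())
    try:
        record = forward_streamed(net, image, patches, skip_white=skip_white)
        logit = record.logit
    except NoContentError:
        logit = float(net.head_w @ interior_feature(net, 1.0) + net.head_b)
    return float(expit(logit))
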