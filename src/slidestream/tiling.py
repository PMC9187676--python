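"""Tile planning and windowed pixel access for arbitrarily large slide images.

A whole-slide scan is treated as a white-padded raster: every pixel outside
the scanned region is pure white ``(255, 255, 255)``.  All spatial reasoning
uses 0-based ``(row, col)`` coordinates and half-open rectangles
``[r0, r1) x [c0, c1)`` so that interval arithmetic composes cleanly through
convolutional layer stacks.

The central quantity is the *halo margin*: the number of extra input pixels a
core tile must be extended by, per side, so that running a stack of local
layers on the extended window and cropping reproduces the global computation
exactly at tile borders.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

WHITE = 255


class TilingError(ValueError):
    pass


@dataclass(frozen=True)
class Rect:
    """Half-open pixel rectangle ``[r0, r1) x [c0, c1)``."""

    r0: int
    r1: int
    c0: int
    c1: int

    def __post_init__(self) -> None:
        if self.r1 <= self.r0 or self.c1 <= self.c0:
            raise TilingError(f"empty rectangle {self!r}")

    @property
    def height(self) -> int:
        return self.r1 - self.r0

    @property
    def width(self) -> int:
        return self.c1 - self.c0

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)


@dataclass(frozen=True)
class LayerGeometry:
    """Spatial geometry ``(kernel, stride, padding)`` of a local layer."""

    kernel: int
    stride: int = 1
    padding: int = 0

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.stride < 1 or self.padding < 0:
            raise TilingError(
                f"invalid layer geometry k={self.kernel} s={self.stride} p={self.padding}"
            )

    def input_interval(self, a: int, b: int) -> tuple[int, int]:
        """Input interval feeding output interval ``[a, b)``.

        For output position ``o`` the layer reads input
        ``[o*s - p, o*s - p + k)``; for ``[a, b)`` this is
        ``[a*s - p, (b-1)*s + k - p)``.
        """
        if b <= a:
            raise TilingError("empty output interval")
        return a * self.stride - self.padding, (b - 1) * self.stride + self.kernel - self.padding

    def output_extent(self, n: int) -> int:
        """Length of the output feature axis given input axis length ``n``."""
        out = (n + 2 * self.padding - self.kernel) // self.stride + 1
        if out < 1:
            raise TilingError(f"layer {self} produces empty output on extent {n}")
        return out


def total_stride(layers: list[LayerGeometry]) -> int:
    s = 1
    for g in layers:
        s *= g.stride
    return s


def halo_margin(layers: list[LayerGeometry]) -> int:
    """Smallest margin M such that per-tile computation matches global.

    Computed by backward interval arithmetic: map one output pixel ``[0, 1)``
    at the final feature scale back through the stack; the overhang of the
    resulting input interval beyond the core input span ``[0, S)`` (S = total
    stride) is the margin required on each side.
    """
    if not layers:
        return 0
    lo, hi = 0, 1
    for g in reversed(layers):
        lo, hi = g.input_interval(lo, hi)
    s = total_stride(layers)
    return max(-lo, hi - s, 0)


@dataclass(frozen=True)
class PatchPlan:
    """Disjoint core tiles covering the white-padded image domain."""

    core_tiles: tuple[Rect, ...]
    halo: int
    stride: int
    tile_size: int
    padded_height: int
    padded_width: int

    @property
    def n_tiles(self) -> int:
        return len(self.core_tiles)


class TiledImage:
    """Lazily windowed 8-bit RGB raster with white out-of-bounds fill.

    ``height``/``width`` describe the declared canvas; the backing pixel array
    may be smaller (placed at ``origin``) in which case everything outside it
    is white.  This lets tests exercise gigapixel-shaped canvases without
    materialising them.
    """

    def __init__(
        self,
        pixels: np.ndarray,
        microns_per_pixel: float | None = None,
        canvas_shape: tuple[int, int] | None = None,
        origin: tuple[int, int] = (0, 0),
    ):
        pixels = np.asarray(pixels)
        if pixels.ndim != 3 or pixels.shape[2] != 3 or pixels.dtype != np.uint8:
            raise TilingError("pixels must be an HxWx3 uint8 array")
        self._pixels = pixels
        self._origin = origin
        h, w = canvas_shape if canvas_shape is not None else pixels.shape[:2]
        if h < 1 or w < 1:
            raise TilingError("canvas must be at least 1x1")
        if origin[0] + pixels.shape[0] > h or origin[1] + pixels.shape[1] > w:
            raise TilingError("backing array exceeds declared canvas")
        self.height = int(h)
        self.width = int(w)
        self.microns_per_pixel = microns_per_pixel

    @classmethod
    def from_file(cls, path: str | Path, microns_per_pixel: float | None = None) -> "TiledImage":
        path = Path(path)
        if path.suffix.lower() in (".tif", ".tiff"):
            import tifffile

            arr = tifffile.imread(path)
        else:
            from PIL import Image

            arr = np.asarray(Image.open(path).convert("RGB"))
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        return cls(arr.astype(np.uint8), microns_per_pixel=microns_per_pixel)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.height, self.width, 3)

    def fetch(self, rect: Rect) -> np.ndarray:
        return fetch_window(self, rect)


def fetch_window(image: TiledImage, rect: Rect) -> np.ndarray:
    """Pixel block of exactly ``rect``'s shape; out-of-raster area is white."""
    block = np.full((rect.height, rect.width, 3), WHITE, dtype=np.uint8)
    arr = image._pixels
    ar0, ac0 = image._origin
    ar1, ac1 = ar0 + arr.shape[0], ac0 + arr.shape[1]
    r0, r1 = max(rect.r0, ar0), min(rect.r1, ar1)
    c0, c1 = max(rect.c0, ac0), min(rect.c1, ac1)
    if r0 < r1 and c0 < c1:
        block[r0 - rect.r0 : r1 - rect.r0, c0 - rect.c0 : c1 - rect.c0] = arr[
            r0 - ar0 : r1 - ar0, c0 - ac0 : c1 - ac0
        ]
    return block


def plan_patches(image: TiledImage, tile_size: int, layers: list[LayerGeometry]) -> PatchPlan:
    """Row-major disjoint core tiles covering the image padded to a stride multiple.

    The image is virtually padded right/bottom with white to the next multiple
    of the stack's total stride S; trailing tiles may be smaller than
    ``tile_size`` but remain multiples of S.
    """
    s = total_stride(layers)
    if tile_size % s != 0:
        raise TilingError(f"tile_size {tile_size} is not a multiple of the total stride {s}")
    if tile_size < 1:
        raise TilingError("tile_size must be positive")
    ph = math.ceil(image.height / s) * s
    pw = math.ceil(image.width / s) * s
    tiles = []
    for r0 in range(0, ph, tile_size):
        r1 = min(r0 + tile_size, ph)
        for c0 in range(0, pw, tile_size):
            c1 = min(c0 + tile_size, pw)
            tiles.append(Rect(r0, r1, c0, c1))
    return PatchPlan(
        core_tiles=tuple(tiles),
        halo=halo_margin(layers),
        stride=s,
        tile_size=tile_size,
        padded_height=ph,
        padded_width=pw,
    )


def is_contentless(block: np.ndarray, whiteness_delta: int = 0) -> bool:
    """True iff every channel of every pixel is within ``whiteness_delta`` of white."""
    block = np.asarray(block)
    return bool(np.all(block >= WHITE - whiteness_delta))
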