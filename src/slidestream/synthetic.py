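"""Synthetic stained-slide fixtures.

Real gastric-node whole-slide scans are private, so every other module is
exercised on generated stand-ins that keep the statistical structure that
matters for the method: a white-padded canvas, elliptical node regions
filled with dense hematoxylin-dominant texture (lymphocyte-like clumps),
and - in positive nodes - a planted eosin-rich focus whose physical
diameter falls in one of the clinically defined size classes
(macrometastasis >= 2 mm, micrometastasis 0.2-2 mm, isolated tumor cells
< 0.2 mm at a stated microns-per-pixel).

Rendering goes through the optical-density stain model (concentration
fields composed through the H&E stain matrix, then ``od_to_rgb``), so the
stain-augmentation math is exercised end-to-end, and the background outside
nodes is exactly pure white.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy.ndimage import gaussian_filter

from .augmentation import StainModel, od_to_rgb
from .tiling import TiledImage

# physical lesion-diameter ranges in millimetres per size class
SIZE_CLASSES_MM = {
    "macro": (2.0, 4.0),
    "micro": (0.2, 2.0),
    "itc": (0.06, 0.2),
}
DEFAULT_MIX = {"none": 0.5, "micro": 0.3, "itc": 0.2}
DEFAULT_MPP = 7.36  # 1.25x scanner scale; keeps all size classes on desk-scale canvases


class SynthesisError(RuntimeError):
    pass


@dataclass
class SyntheticNode:
    mask: np.ndarray  # bool canvas mask of the node
    lesion_mask: np.ndarray  # bool canvas mask of the planted focus (may be empty)
    size_class: str  # none / macro / micro / itc

    @property
    def label(self) -> int:
        return int(self.lesion_mask.any())


@dataclass
class SyntheticSlide:
    image: TiledImage
    nodes: list[SyntheticNode]

    @property
    def label(self) -> int:
        return int(any(n.label for n in self.nodes))


@dataclass
class SyntheticStudy:
    slides: list[SyntheticSlide]
    microns_per_pixel: float
    seed: int
    params: dict

    @property
    def images(self):
        return [s.image for s in self.slides]

    @property
    def slide_labels(self):
        return [s.label for s in self.slides]


def render_concentration_field(
    mask: np.ndarray,
    base_h: float = 0.25,
    base_e: float = 0.10,
    blob_gain: float = 1.6,
    sigma: float = 1.2,
    seed: int = 0,
) -> np.ndarray:
    """Clumpy 2-channel (H, E) concentration raster supported on ``mask``.

    Smoothed Gaussian noise thresholded into blobs emulates densely packed
    lymphocyte nuclei (hematoxylin-dominant) over a weak eosin stroma.
    Deterministic from ``seed``; zero (renders white) outside the mask.
    """
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    out = np.zeros((h, w, 2), dtype=np.float64)
    if not mask.any():
        return out
    rng = np.random.default_rng(seed)
    noise_h = gaussian_filter(rng.standard_normal((h, w)), sigma)
    noise_e = gaussian_filter(rng.standard_normal((h, w)), sigma * 2)
    out[..., 0] = (base_h + blob_gain * np.clip(noise_h - 0.25, 0.0, None)) * mask
    out[..., 1] = (base_e * (1.0 + np.clip(noise_e, 0.0, None))) * mask
    return out


def _ellipse_mask(h, w, cr, cc, ra, rc, angle=0.0):
    rows, cols = np.mgrid[0:h, 0:w]
    dr, dc = rows - cr, cols - cc
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dr + sa * dc
    v = -sa * dr + ca * dc
    return (u / ra) ** 2 + (v / rc) ** 2 <= 1.0


def _place_nodes(rng, canvas, n_nodes):
    """Disjoint node ellipses with a white border margin; retried placement."""
    frac = 0.20 if n_nodes == 1 else max(0.08, 0.20 / np.sqrt(n_nodes))
    placed = []
    for _ in range(n_nodes):
        for _attempt in range(200):
            ra = rng.uniform(0.7, 1.0) * frac * canvas
            rc = rng.uniform(0.7, 1.0) * frac * canvas
            r_out = max(ra, rc)
            cr = rng.uniform(r_out + 2, canvas - r_out - 2)
            cc = rng.uniform(r_out + 2, canvas - r_out - 2)
            if all(
                np.hypot(cr - p[0], cc - p[1]) > r_out + p[2] + 3 for p in placed
            ):
                placed.append((cr, cc, r_out, ra, rc))
                break
        else:
            raise SynthesisError(f"could not place {n_nodes} disjoint nodes on a {canvas} px canvas")
    return placed


def _sample_lesion(rng, size_class, mpp, node_r):
    """Lesion radius in pixels for a size class; resampled to fit the node."""
    lo_mm, hi_mm = SIZE_CLASSES_MM[size_class]
    for _ in range(100):
        d_px = rng.uniform(lo_mm, hi_mm) * 1000.0 / mpp
        if d_px / 2.0 <= 0.8 * node_r:
            return max(d_px / 2.0, 1.5)
    raise SynthesisError(
        f"a '{size_class}' lesion does not fit a node of radius {node_r:.0f} px "
        f"at {mpp} um/pixel after 100 attempts"
    )


def generate_study(
    n_slides: int,
    nodes_per_slide: int = 1,
    lesion_mix: dict[str, float] | None = None,
    microns_per_pixel: float = DEFAULT_MPP,
    canvas: int = 512,
    seed: int = 0,
    difficulty: float = 1.0,
    stain: StainModel | None = None,
) -> SyntheticStudy:
    """Generate a reproducible synthetic study.

    ``lesion_mix`` gives the per-node probability of each size class
    (``none`` plants no lesion).  ``difficulty`` scales the eosin
    concentration gap between lesion and background texture (smaller =
    harder).  Fully reproducible from ``seed``.
    """
    if canvas < 256:
        raise SynthesisError("canvas must be at least 256 px")
    mix = dict(lesion_mix or DEFAULT_MIX)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise SynthesisError(f"lesion mix proportions must sum to 1, got {total}")
    classes = sorted(mix)
    probs = np.array([mix[c] for c in classes])
    stain = stain or StainModel()
    children = np.random.SeedSequence(seed).spawn(n_slides)
    slides = []
    for si in range(n_slides):
        rng = np.random.default_rng(children[si])
        conc = np.zeros((canvas, canvas, 2), dtype=np.float64)
        nodes = []
        for cr, cc, r_out, ra, rc in _place_nodes(rng, canvas, nodes_per_slide):
            angle = rng.uniform(0, np.pi)
            mask = _ellipse_mask(canvas, canvas, cr, cc, ra, rc, angle)
            field = render_concentration_field(mask, seed=int(rng.integers(2**31)))
            size_class = str(rng.choice(classes, p=probs))
            lesion = np.zeros((canvas, canvas), dtype=bool)
            if size_class != "none":
                lr = _sample_lesion(rng, size_class, microns_per_pixel, min(ra, rc))
                # lesion center inside the node, away from its rim
                for _ in range(100):
                    t = rng.uniform(0, 2 * np.pi)
                    rad = rng.uniform(0, 0.6)
                    lcr = cr + rad * (ra - lr) * np.cos(t)
                    lcc = cc + rad * (rc - lr) * np.sin(t)
                    cand = _ellipse_mask(canvas, canvas, lcr, lcc, lr, lr)
                    if (cand & ~mask).sum() == 0 and cand.any():
                        lesion = cand
                        break
                else:
                    raise SynthesisError("could not place lesion inside node")
                tex = gaussian_filter(rng.standard_normal((canvas, canvas)), 1.5)
                field[..., 1] += difficulty * (0.55 + 0.4 * np.clip(tex, 0, None)) * lesion
                field[..., 0] *= np.where(lesion, 0.55, 1.0)
            conc += field
            nodes.append(SyntheticNode(mask=mask, lesion_mask=lesion, size_class=size_class))
        rgb = od_to_rgb(conc @ stain.stain_matrix)
        slides.append(
            SyntheticSlide(image=TiledImage(rgb, microns_per_pixel=microns_per_pixel), nodes=nodes)
        )
    return SyntheticStudy(
        slides=slides,
        microns_per_pixel=microns_per_pixel,
        seed=seed,
        params={
            "n_slides": n_slides,
            "nodes_per_slide": nodes_per_slide,
            "lesion_mix": mix,
            "canvas": canvas,
            "difficulty": difficulty,
        },
    )


# ---------------------------------------------------------------------------
# manifest I/O
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(study: SyntheticStudy, out_dir: str | Path) -> Path:
    """Write images (PNG), masks (PNG), labels (CSV) and parameters (YAML).

    The YAML records the generator seed and per-file SHA-256 checksums so a
    reader can detect tampering and regenerate byte-identically.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    files = []
    for si, slide in enumerate(study.slides):
        img_path = out / "images" / f"slide_{si:03d}.png"
        from .tiling import Rect, fetch_window

        arr = fetch_window(slide.image, Rect(0, slide.image.height, 0, slide.image.width))
        Image.fromarray(arr).save(img_path)
        files.append(img_path)
        for ni, node in enumerate(slide.nodes):
            mask_path = out / "masks" / f"slide_{si:03d}_node_{ni:02d}.png"
            Image.fromarray((node.mask * 255).astype(np.uint8)).save(mask_path)
            files.append(mask_path)
            lesion_path = out / "masks" / f"slide_{si:03d}_node_{ni:02d}_lesion.png"
            Image.fromarray((node.lesion_mask * 255).astype(np.uint8)).save(lesion_path)
            files.append(lesion_path)
            rows.append(
                {
                    "slide": si,
                    "node": ni,
                    "size_class": node.size_class,
                    "node_label": node.label,
                    "slide_label": slide.label,
                }
            )
    labels_path = out / "labels.csv"
    pd.DataFrame(rows).to_csv(labels_path, index=False)
    files.append(labels_path)
    params = {
        "seed": study.seed,
        "microns_per_pixel": study.microns_per_pixel,
        **study.params,
        "checksums": {str(f.relative_to(out)): _sha256(f) for f in files},
    }
    (out / "params.yaml").write_text(yaml.safe_dump(params))
    return out


def read_manifest(in_dir: str | Path, verify: bool = True):
    """Load a written study: (images, labels DataFrame, params dict).

    With ``verify=True`` every recorded checksum is rechecked; a mismatch
    raises :class:`SynthesisError` naming the file.
    """
    root = Path(in_dir)
    params = yaml.safe_load((root / "params.yaml").read_text())
    if verify:
        for rel, digest in params.get("checksums", {}).items():
            p = root / rel
            if not p.exists():
                raise SynthesisError(f"manifest file missing: {rel}")
            if _sha256(p) != digest:
                raise SynthesisError(f"checksum mismatch for {rel}")
    labels = pd.read_csv(root / "labels.csv")
    images = {}
    for si in sorted(labels["slide"].unique()):
        images[int(si)] = TiledImage.from_file(
            root / "images" / f"slide_{si:03d}.png",
            microns_per_pixel=params.get("microns_per_pixel"),
        )
    return images, labels, params
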