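"""End-to-end slide assessment: masks -> node instances -> scores -> counts.

Mirrors the clinical review pipeline: the detector (here: provided masks or
a pluggable segmenter hook) outlines candidate lymph nodes; each node is
cropped with a halo margin and scored by the streamed classifier; scores at
or above the operating threshold (0.4 by default, 0.15 in screening mode)
mark the node positive; per-slide and per-study positive/negative counts
are tallied for the review panel.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .engine import cam_streamed, score_image
from .nn import StreamableNet
from .postprocess import LNInstance, MIN_AREA_DEFAULT, postprocess_mask
from .tiling import Rect, TiledImage, fetch_window, halo_margin, plan_patches

THRESHOLD_DEFAULT = 0.4
THRESHOLD_SCREENING = 0.15


class WorkflowError(RuntimeError):
    pass


@dataclass
class SlideReport:
    slide_id: str
    instances: list[LNInstance]
    threshold: float
    scores: list[float]

    @property
    def positive_count(self) -> int:
        return sum(1 for i in self.instances if i.label == "positive")

    @property
    def negative_count(self) -> int:
        return sum(1 for i in self.instances if i.label == "negative")

    def to_dict(self) -> dict:
        return {
            "slide_id": self.slide_id,
            "threshold": self.threshold,
            "positive_count": self.positive_count,
            "negative_count": self.negative_count,
            "instances": [
                {"area_px": inst.area, "label": inst.label, "score": inst.score}
                for inst in self.instances
            ],
        }


@dataclass
class StudyReport:
    slide_reports: list[SlideReport]

    @property
    def positive_count(self) -> int:
        return sum(r.positive_count for r in self.slide_reports)

    @property
    def negative_count(self) -> int:
        return sum(r.negative_count for r in self.slide_reports)

    def to_dict(self) -> dict:
        return {
            "positive_count": self.positive_count,
            "negative_count": self.negative_count,
            "slides": [r.to_dict() for r in self.slide_reports],
        }


def _combined_mask(masks) -> np.ndarray:
    if callable(masks):
        raise WorkflowError("segmenter hooks must be called by the caller; pass the mask")
    if isinstance(masks, (list, tuple)):
        out = np.zeros_like(np.asarray(masks[0], dtype=bool))
        for m in masks:
            out |= np.asarray(m, dtype=bool)
        return out
    return np.asarray(masks, dtype=bool)


def assess_slide(
    image: TiledImage,
    masks,
    net: StreamableNet,
    threshold: float = THRESHOLD_DEFAULT,
    tile_size: int = 2048,
    min_area: int = MIN_AREA_DEFAULT,
    slide_id: str = "slide",
    out_dir: str | Path | None = None,
) -> SlideReport:
    """Score every LN instance of one slide and tally positive/negative counts.

    ``masks`` is a binary mask (or list of per-node masks, OR-combined) at
    the image's scale; call a segmenter yourself if you have one.  Each
    instance's bounding box plus one halo margin is cropped and scored by
    the streaming engine; a CAM overlay is written for positives when
    ``out_dir`` is given.
    """
    mask = _combined_mask(masks)
    instances = postprocess_mask(mask, min_area=min_area)
    if not instances:
        warnings.warn(f"{slide_id}: no LN instance found in mask")
    margin = halo_margin(net.geometries())
    scores = []
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for k, inst in enumerate(instances):
        r0, r1, c0, c1 = inst.bbox
        rect = Rect(r0 - margin, r1 + margin, c0 - margin, c1 + margin)
        crop = TiledImage(fetch_window(image, rect))
        score = score_image(net, crop, tile_size=tile_size)
        inst.score = score
        inst.label = "positive" if score >= threshold else "negative"
        scores.append(score)
        if out is not None and inst.label == "positive":
            _write_cam_overlay(net, crop, out / f"{slide_id}_ln{k:02d}_cam.png", tile_size)
    return SlideReport(slide_id=slide_id, instances=instances, threshold=threshold, scores=scores)


def _write_cam_overlay(net, crop, path, tile_size):
    patches = plan_patches(crop, tile_size, net.geometries())
    cam = cam_streamed(net, crop, patches, skip_white=True)
    s = patches.stride
    cam_full = np.kron(cam, np.ones((s, s)))[: crop.height, : crop.width]
    rgb = fetch_window(crop, Rect(0, crop.height, 0, crop.width)).astype(np.float64)
    alpha = 0.5 * cam_full[..., None]
    heat = np.zeros_like(rgb)
    heat[..., 0] = 255.0
    over = np.clip((1 - alpha) * rgb + alpha * heat, 0, 255).astype(np.uint8)
    Image.fromarray(over).save(path)


def run_study(
    source,
    net: StreamableNet,
    threshold: float = THRESHOLD_DEFAULT,
    tile_size: int = 2048,
    min_area: int = MIN_AREA_DEFAULT,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Assess every slide of a study (manifest directory or SyntheticStudy).

    For a manifest directory all referenced files are enumerated (and
    checksums verified) before any computation; missing files abort the run
    naming the offending path.
    """
    from .synthetic import SyntheticStudy, read_manifest

    reports = []
    if isinstance(source, SyntheticStudy):
        for si, slide in enumerate(source.slides):
            masks = [n.mask for n in slide.nodes]
            reports.append(
                assess_slide(
                    slide.image, masks, net, threshold=threshold, tile_size=tile_size,
                    min_area=min_area, slide_id=f"slide_{si:03d}", out_dir=out_dir,
                )
            )
    else:
        root = Path(source)
        images, labels, _params = read_manifest(root, verify=True)
        for si, image in images.items():
            node_ids = labels.loc[labels["slide"] == si, "node"]
            masks = []
            for ni in node_ids:
                p = root / "masks" / f"slide_{si:03d}_node_{ni:02d}.png"
                masks.append(np.asarray(Image.open(p)) > 0)
            reports.append(
                assess_slide(
                    image, masks, net, threshold=threshold, tile_size=tile_size,
                    min_area=min_area, slide_id=f"slide_{si:03d}", out_dir=out_dir,
                )
            )
    report = StudyReport(reports)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        (Path(out_dir) / "study_report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report
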