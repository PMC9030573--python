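"""Slide-level inference: tile prediction, thresholding and stitching.

Only tiles flagged as tissue are sent through the network; everything
else is background by construction, which is what makes whole-slide
processing fast. A pixel is called tumor when its tumor-class
probability reaches the decision threshold alpha (default 0.5, boundary
inclusive); per-tile decisions are stitched back into a slide-sized
mask. Detected foci are reported with their physical size class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

from . import nn
from .fcn_model import ModifiedFCN
from .tile_grid import SlideImage, TileGrid, extract_tile, stitch
from .synthetic_wsi import CLASS_BOUNDS_MM


@dataclass
class InferenceConfig:
    tile_size: int = 512
    alpha: float = 0.5
    batch_size: int = 4
    workers: int = 1  # reserved; processing is sequential and deterministic

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.tile_size < 32 or self.batch_size < 1:
            raise ValueError("invalid tile size or batch size")


@dataclass
class SegmentationResult:
    mask: np.ndarray                    # (H, W) uint8 in {0, 1}
    grid: TileGrid
    prob: np.ndarray | None = None      # optional tumor-probability raster
    provenance: dict = field(default_factory=dict)


def predict_slide(
    model: ModifiedFCN,
    slide: SlideImage,
    grid: TileGrid,
    config: InferenceConfig | None = None,
    keep_prob: bool = False,
) -> SegmentationResult:
    """Segment a whole slide with a trained model.

    Every tissue tile is pushed through the network, thresholded at
    alpha, and stitched; non-tissue tiles are background. The result is
    deterministic for fixed weights and independent of tile order.
    """
    config = config or InferenceConfig(tile_size=model.spec.input_size)
    config.validate()
    if config.tile_size != model.spec.input_size:
        raise ValueError("config tile size must equal the model input size")
    if grid.tile_size != config.tile_size:
        raise ValueError("grid tile size does not match the model")
    if (grid.slide_height, grid.slide_width) != (slide.height, slide.width):
        raise ValueError("grid was built for a different slide")

    keys = sorted(grid.tissue_tiles())
    masks, probs = {}, {}
    for start in range(0, len(keys), config.batch_size):
        chunk = keys[start:start + config.batch_size]
        x = np.stack([extract_tile(slide, grid, i, j).pixels
                      for i, j in chunk]).astype(nn.F32)
        logits = model.forward(x.transpose(0, 3, 1, 2), train=False)
        prob = nn.softmax(logits, axis=1)
        tumor = prob[:, 1] if model.spec.n_classes == 2 else \
            prob.argmax(axis=1).astype(nn.F32)
        for key, p in zip(chunk, tumor):
            masks[key] = (p >= config.alpha).astype(np.uint8)
            if keep_prob:
                probs[key] = p.astype(np.float32)

    mask = stitch(grid, masks, fill_value=0, dtype=np.uint8) if masks else \
        np.zeros((grid.slide_height, grid.slide_width), np.uint8)
    prob_map = None
    if keep_prob:
        prob_map = stitch(grid, probs, fill_value=0.0, dtype=np.float32) \
            if probs else np.zeros_like(mask, np.float32)
    return SegmentationResult(
        mask=mask, grid=grid, prob=prob_map,
        provenance={"alpha": config.alpha, "tile_size": config.tile_size})


def classify_focus_size(major_mm: float) -> str:
    """TNM size class from the major-axis physical length (mm)."""
    if major_mm > 2.0:
        return "macro"
    if major_mm > 0.2:
        return "micro"
    return "itc"


def focus_report(result: SegmentationResult | np.ndarray, mpp: float) -> list[dict]:
    """Connected components of the tumor mask with their physical class.

    Each detected focus is reported with its pixel area, ellipse-fit
    major-axis length (px and mm) and TNM class (macro > 2 mm,
    micro 0.2-2 mm, ITC <= 0.2 mm).
    """
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    mask = result.mask if isinstance(result, SegmentationResult) else result
    labeled, n = ndimage.label(mask == 1, structure=np.ones((3, 3)))
    report = []
    for region in measure.regionprops(labeled):
        major_px = float(region.axis_major_length)
        if major_px == 0.0:  # single-pixel component
            major_px = 1.0
        major_mm = major_px * mpp / 1000.0
        cy, cx = region.centroid
        report.append({
            "label": int(region.label),
            "area_px": int(region.area),
            "centroid": (float(cy), float(cx)),
            "major_px": major_px,
            "major_mm": major_mm,
            "cls": classify_focus_size(major_mm),
        })
    assert len(report) == n
    return report
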