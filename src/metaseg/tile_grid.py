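"""Tile-based whole-slide data structure with Otsu background exclusion.

A gigapixel slide is decomposed into a grid of fixed-size square tiles
(default 512 px). Tissue is separated from bright glass background once
per slide, by Otsu-thresholding the grayscale luminance of a downsampled
thumbnail; only tiles whose tissue fraction exceeds a cutoff are flagged
for processing, which is what makes whole-slide inference fast. Per-tile
outputs are reassembled losslessly into slide-level rasters.

Label conventions used across the package: 0 = non-tumor, 1 = tumor,
255 = ignore (pixels excluded from losses and metrics).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

LABEL_BACKGROUND = 0
LABEL_TUMOR = 1
LABEL_IGNORE = 255

#: Rec. 601 luma coefficients for RGB -> grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


class DegenerateInputError(ValueError):
    """Raised when an input admits no meaningful two-class split."""


@dataclass
class SlideImage:
    """An RGB slide raster with its physical scale.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    mpp : microns per pixel (isotropic)
    name : provenance label (file stem or synthetic id)
    """

    pixels: np.ndarray
    mpp: float
    name: str = ""

    def __post_init__(self):
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("slide pixels must be (H, W, 3)")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class TileUnit:
    """One U x U tile; ``valid_region`` is the (h, w) of real content for
    edge tiles (interior tiles have valid_region == (U, U))."""

    i: int
    j: int
    pixels: np.ndarray
    valid_region: tuple[int, int]


@dataclass
class TileGrid:
    slide_width: int
    slide_height: int
    tile_size: int
    rows: int
    cols: int
    tissue: np.ndarray  # (rows, cols) bool
    tissue_threshold: int
    downsample: int = 1
    weights: dict = field(default_factory=dict)  # (i, j) -> boosting weight

    def tissue_tiles(self) -> list[tuple[int, int]]:
        ii, jj = np.nonzero(self.tissue)
        return list(zip(ii.tolist(), jj.tolist()))

    def to_json(self, path: str | Path) -> None:
        doc = {
            "slide_width": self.slide_width,
            "slide_height": self.slide_height,
            "tile_size": self.tile_size,
            "rows": self.rows,
            "cols": self.cols,
            "tissue_threshold": int(self.tissue_threshold),
            "downsample": self.downsample,
            "tissue_indices": [[int(i), int(j)] for i, j in self.tissue_tiles()],
            "weights": {f"{i},{j}": w for (i, j), w in self.weights.items()},
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "TileGrid":
        doc = json.loads(Path(path).read_text())
        tissue = np.zeros((doc["rows"], doc["cols"]), bool)
        for i, j in doc["tissue_indices"]:
            tissue[i, j] = True
        weights = {
            tuple(int(v) for v in k.split(",")): w
            for k, w in doc.get("weights", {}).items()
        }
        return cls(
            slide_width=doc["slide_width"],
            slide_height=doc["slide_height"],
            tile_size=doc["tile_size"],
            rows=doc["rows"],
            cols=doc["cols"],
            tissue=tissue,
            tissue_threshold=doc["tissue_threshold"],
            downsample=doc["downsample"],
            weights=weights,
        )


# ---------------------------------------------------------------- I/O

def read_slide(path: str | Path, mpp: float = 1.0) -> SlideImage:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("RGB"))
    return SlideImage(pixels=np.ascontiguousarray(arr[..., :3]), mpp=mpp,
                      name=path.stem)


def write_slide(slide: SlideImage, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, slide.pixels, compression="lzw")
    else:
        Image.fromarray(slide.pixels).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        return tifffile.imread(path).astype(np.uint8)
    return np.asarray(Image.open(path)).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, mask.astype(np.uint8), compression="lzw")
    else:
        Image.fromarray(mask.astype(np.uint8)).save(path)


# ------------------------------------------------------ Otsu filtering

def otsu_threshold(histogram: np.ndarray) -> int:
    """Gray level maximizing between-class variance for a 256-bin histogram.

    The returned threshold t splits levels into {0..t} (dark class) and
    {t+1..255}; ties are broken toward the lowest qualifying level. A
    histogram whose mass sits in a single level admits no two-class split
    and raises :class:`DegenerateInputError`.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.shape != (256,):
        raise ValueError("histogram must have 256 bins")
    total = hist.sum()
    if total <= 0:
        raise DegenerateInputError("all-zero histogram")
    levels = np.arange(256)
    w0 = np.cumsum(hist)                      # mass of {0..t}
    m0 = np.cumsum(hist * levels)             # first moment of {0..t}
    w1 = total - w0
    mu_total = m0[-1]
    valid = (w0 > 0) & (w1 > 0)
    if not valid.any():
        raise DegenerateInputError("histogram has a single occupied level")
    with np.errstate(divide="ignore", invalid="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mean0 - mean1) ** 2
    sigma_b[~valid] = -np.inf
    return int(np.argmax(sigma_b))            # argmax takes the first maximum


def grayscale(rgb: np.ndarray) -> np.ndarray:
    """Rec. 601 luminance, rounded to uint8."""
    gray = np.tensordot(rgb.astype(np.float64), _LUMA, axes=([-1], [0]))
    return np.clip(np.rint(gray), 0, 255).astype(np.uint8)


def tissue_mask(slide: SlideImage, downsample: int = 32) -> tuple[np.ndarray, int]:
    """Boolean tissue thumbnail + the Otsu threshold used.

    The slide is downsampled by block averaging, converted to grayscale
    luminance, and thresholded once; pixels at or below the threshold
    (darker than the glass background) are tissue.
    """
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    px = slide.pixels.astype(np.float64)
    if downsample > 1:
        h, w = px.shape[:2]
        hc, wc = (h // downsample) * downsample, (w // downsample) * downsample
        if hc == 0 or wc == 0:
            raise ValueError("downsample larger than the slide")
        blocks = px[:hc, :wc].reshape(
            hc // downsample, downsample, wc // downsample, downsample, 3
        )
        px = blocks.mean(axis=(1, 3))
    gray = np.clip(np.rint(np.tensordot(px, _LUMA, axes=([-1], [0]))), 0, 255)
    gray = gray.astype(np.uint8)
    hist = np.bincount(gray.ravel(), minlength=256)
    t = otsu_threshold(hist)
    return gray <= t, t


# ---------------------------------------------------------- tile grid

def build_grid(
    slide: SlideImage,
    tile_size: int = 512,
    tissue: np.ndarray | None = None,
    downsample: int = 32,
    min_tissue_fraction: float = 0.05,
) -> TileGrid:
    """Decompose a slide into ceil(H/U) x ceil(W/U) tiles with tissue flags.

    A tile is flagged tissue iff the tissue fraction of its in-slide
    footprint (measured on the thumbnail) is >= ``min_tissue_fraction``.
    Pass a precomputed ``tissue`` thumbnail (with its ``downsample``) to
    reuse one; otherwise it is computed here.
    """
    u = int(tile_size)
    if u < 32:
        raise ValueError("tile size must be >= 32 px")
    if u > slide.width and u > slide.height:
        raise ValueError("tile size exceeds both slide dimensions")
    threshold = -1
    if tissue is None:
        tissue, threshold = tissue_mask(slide, downsample)
    rows, cols = grid_dims(slide.height, slide.width, u)
    flags = np.zeros((rows, cols), bool)
    th, tw = tissue.shape
    for i in range(rows):
        y0 = (i * u) // downsample
        y1 = max(y0 + 1, min(th, math.ceil(min((i + 1) * u, slide.height) / downsample)))
        y0 = min(y0, th - 1)
        for j in range(cols):
            x0 = (j * u) // downsample
            x1 = max(x0 + 1, min(tw, math.ceil(min((j + 1) * u, slide.width) / downsample)))
            x0 = min(x0, tw - 1)
            window = tissue[y0:y1, x0:x1]
            flags[i, j] = window.mean() >= min_tissue_fraction
    return TileGrid(
        slide_width=slide.width,
        slide_height=slide.height,
        tile_size=u,
        rows=rows,
        cols=cols,
        tissue=flags,
        tissue_threshold=int(threshold),
        downsample=downsample,
    )


def grid_dims(slide_height: int, slide_width: int, tile_size: int) -> tuple[int, int]:
    """(rows, cols) = (ceil(H/U), ceil(W/U)) of the tile decomposition."""
    return math.ceil(slide_height / tile_size), math.ceil(slide_width / tile_size)


def tile_window(grid: TileGrid, i: int, j: int) -> tuple[int, int, int, int]:
    """Half-open slide-pixel window (y0, y1, x0, x1) of tile (i, j);
    edge tiles are clipped to the slide, so (y1-y0, x1-x0) is the tile's
    valid region."""
    if not (0 <= i < grid.rows and 0 <= j < grid.cols):
        raise IndexError(f"tile ({i}, {j}) outside {grid.rows}x{grid.cols} grid")
    u = grid.tile_size
    y0, x0 = i * u, j * u
    y1 = min(y0 + u, grid.slide_height)
    x1 = min(x0 + u, grid.slide_width)
    return y0, y1, x0, x1


def extract_tile(slide: SlideImage, grid: TileGrid, i: int, j: int) -> TileUnit:
    """Extract tile (i, j); edge tiles are reflection-padded to U x U.

    Pixel coordinates are 0-based half-open: tile (i, j) covers rows
    [iU, iU+U) and columns [jU, jU+U) of the slide.
    """
    y0, y1, x0, x1 = tile_window(grid, i, j)
    u = grid.tile_size
    patch = slide.pixels[y0:y1, x0:x1]
    vh, vw = patch.shape[:2]
    if (vh, vw) != (u, u):
        patch = np.pad(patch, ((0, u - vh), (0, u - vw), (0, 0)), mode="symmetric")
    return TileUnit(i=i, j=j, pixels=patch, valid_region=(vh, vw))


def extract_mask_tile(mask: np.ndarray, grid: TileGrid, i: int, j: int,
                      pad_value: int = LABEL_IGNORE) -> np.ndarray:
    """Extract the label-mask tile aligned with ``extract_tile``; the padded
    strip of edge tiles is filled with the ignore label so it never carries
    gradient or metric weight."""
    y0, y1, x0, x1 = tile_window(grid, i, j)
    u = grid.tile_size
    patch = mask[y0:y1, x0:x1]
    vh, vw = patch.shape[:2]
    if (vh, vw) != (u, u):
        patch = np.pad(patch, ((0, u - vh), (0, u - vw)),
                       constant_values=pad_value)
    return patch


def stitch(grid: TileGrid, maps: dict, fill_value=0, dtype=None) -> np.ndarray:
    """Reassemble per-tile U x U maps into a slide-level raster.

    Only the valid region of each tile is written; tiles absent from
    ``maps`` (e.g. background tiles) receive ``fill_value``.
    """
    u = grid.tile_size
    sample = next(iter(maps.values())) if maps else None
    extra = () if sample is None or sample.ndim == 2 else sample.shape[2:]
    if dtype is None:
        dtype = sample.dtype if sample is not None else np.uint8
    out = np.full((grid.slide_height, grid.slide_width, *extra), fill_value,
                  dtype=dtype)
    for (i, j), tile_map in maps.items():
        if tile_map.shape[:2] != (u, u):
            raise ValueError(
                f"map for tile ({i}, {j}) has shape {tile_map.shape[:2]}, "
                f"expected ({u}, {u})")
        y0, y1, x0, x1 = tile_window(grid, i, j)
        out[y0:y1, x0:x1] = tile_map[: y1 - y0, : x1 - x0]
    return out
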