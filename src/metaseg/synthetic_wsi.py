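"""Seeded synthetic H&E-like slides with ground-truth metastasis masks.

Real lymph-node cohorts (paired H&E / immunohistochemistry slides with
pathologist annotation) are access-restricted, so this module fabricates
slides that reproduce the statistical structure the pipeline relies on:

* a bright, near-white glass background and a darker, textured
  pink-purple tissue region, so the grayscale histogram is bimodal and
  Otsu thresholding separates tissue from background;
* elliptical metastatic foci in the three TNM size classes — macro
  (> 2 mm), micro (> 0.2 mm and <= 2 mm) and isolated tumor cells
  (<= 0.2 mm) — measured as physical major-axis length at the
  configured microns-per-pixel scale;
* optional partial labeling (whole connected components dropped from
  the training mask) to exercise the ignore-label focus-sampling path.

Everything is driven by one integer seed; equal seeds give bit-identical
slides, masks and manifests.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .tile_grid import (
    LABEL_BACKGROUND,
    LABEL_IGNORE,
    LABEL_TUMOR,
    SlideImage,
    write_mask,
    write_slide,
)

#: TNM focus size classes as (low, high] bounds on major-axis length, mm.
#: The lower ITC bound and upper macro cap bound the open TNM intervals so
#: that sampled foci are renderable.
CLASS_BOUNDS_MM = {
    "macro": (2.0, 4.0),
    "micro": (0.2, 2.0),
    "itc": (0.02, 0.2),
}

_TISSUE_RGB = np.array([190.0, 130.0, 170.0])
_FOCUS_RGB = np.array([118.0, 62.0, 138.0])
_BACKGROUND_LEVEL = 242.0


class PlacementError(RuntimeError):
    """Foci could not be placed without overlap in the tissue region."""


@dataclass
class SynthConfig:
    """Geometry and content of one synthetic slide."""

    width_px: int = 2048
    height_px: int = 2048
    mpp: float = 1.0
    n_macro: int = 1
    n_micro: int = 2
    n_itc: int = 3
    tissue_fraction: float = 0.6
    partial_label_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.width_px < 64 or self.height_px < 64:
            raise ValueError("slide must be at least one tile (>= 64 px) per side")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")
        if min(self.n_macro, self.n_micro, self.n_itc) < 0:
            raise ValueError("focus counts must be non-negative")
        if not 0 < self.tissue_fraction <= 1:
            raise ValueError("tissue_fraction must be in (0, 1]")
        if not 0 <= self.partial_label_fraction <= 1:
            raise ValueError("partial_label_fraction must be in [0, 1]")


@dataclass
class Focus:
    cls: str
    center_y: float
    center_x: float
    major_px: float
    minor_px: float
    angle_rad: float

    def major_mm(self, mpp: float) -> float:
        """Physical major-axis length at the slide's scale."""
        return self.major_px * mpp / 1000.0


@dataclass
class SlidePair:
    image: SlideImage
    truth: np.ndarray            # complete reference mask {0, 1}
    labels: np.ndarray           # training mask, possibly partially erased
    foci: list = field(default_factory=list)
    tissue: np.ndarray | None = None   # generator's tissue-vs-glass mask


# ------------------------------------------------------------ geometry

def _ellipse_pixels(cy, cx, semi_major, semi_minor, angle, shape):
    """Index arrays of the filled rotated ellipse, or None if it does not
    fit inside ``shape``."""
    c, s = np.cos(angle), np.sin(angle)
    hx = np.sqrt((semi_major * c) ** 2 + (semi_minor * s) ** 2)
    hy = np.sqrt((semi_major * s) ** 2 + (semi_minor * c) ** 2)
    y0, y1 = int(np.floor(cy - hy)), int(np.ceil(cy + hy)) + 1
    x0, x1 = int(np.floor(cx - hx)), int(np.ceil(cx + hx)) + 1
    if y0 < 0 or x0 < 0 or y1 > shape[0] or x1 > shape[1]:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    xr = dx * c + dy * s
    yr = -dx * s + dy * c
    inside = (xr / semi_major) ** 2 + (yr / semi_minor) ** 2 <= 1.0
    return yy[inside], xx[inside]


@dataclass
class TissueGeometry:
    """Core tissue ellipse: center, semi-axes and orientation (px/rad)."""

    center_y: float
    center_x: float
    semi_major: float
    semi_minor: float
    angle_rad: float


def _tissue_region(cfg: SynthConfig, rng) -> tuple[np.ndarray, "TissueGeometry"]:
    """Smooth elongated tissue blob covering ~tissue_fraction of the slide.

    The blob is a centered ellipse whose long axis follows the slide
    diagonal when macro foci must fit (a > 2 mm focus needs the longest
    available span), with an outward-only low-order boundary perturbation
    so the outline is organic rather than geometric.
    """
    h, w = cfg.height_px, cfg.width_px
    if cfg.n_macro > 0:
        phi = np.arctan2(h, w) * rng.choice([1.0, -1.0]) + rng.normal(0, 0.05)
    else:
        phi = rng.uniform(0, np.pi)
    c, s = abs(np.cos(phi)), abs(np.sin(phi))
    span_major = min(w / (2 * c + 1e-9), h / (2 * s + 1e-9))
    span_minor = min(w / (2 * s + 1e-9), h / (2 * c + 1e-9))
    a = 0.95 * span_major
    b = min(cfg.tissue_fraction * w * h / (np.pi * a), 0.95 * span_minor)
    p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float32)
    dy, dx = yy - h / 2.0, xx - w / 2.0
    xr = dx * np.cos(phi) + dy * np.sin(phi)
    yr = -dx * np.sin(phi) + dy * np.cos(phi)
    theta = np.arctan2(yr, xr)
    pert = 0.08 * (0.5 + 0.5 * np.sin(3 * theta + p1) * np.sin(5 * theta + p2))
    r2 = (xr / a) ** 2 + (yr / b) ** 2
    geom = TissueGeometry(center_y=h / 2.0, center_x=w / 2.0,
                          semi_major=float(a), semi_minor=float(b),
                          angle_rad=float(phi))
    return r2 <= (1.0 + pert) ** 2, geom


def place_foci(
    mask: np.ndarray,
    cls: str,
    count: int,
    mpp: float,
    rng,
    tissue: np.ndarray | None = None,
    geometry: TissueGeometry | None = None,
    max_attempts: int = 600,
) -> tuple[np.ndarray, list[Focus]]:
    """Plant ``count`` non-overlapping elliptical foci of one size class.

    Major-axis physical length is sampled within the class bounds and the
    minor/major ratio in [0.4, 1.0]. Small foci are proposed uniformly
    over the tissue with uniform orientation; a class whose lower bound
    is large relative to the tissue core (given via ``geometry``) is
    proposed constructively — aligned with the tissue's long axis, near
    its center, with size and eccentricity capped so the ellipse can fit
    at all. Each focus must lie entirely inside the tissue region and
    must not touch previously planted foci; after ``max_attempts``
    rejected draws per focus a :class:`PlacementError` is raised.
    """
    if cls not in CLASS_BOUNDS_MM:
        raise ValueError(f"unknown focus class {cls!r}")
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    mask = mask.copy()
    lo_mm, hi_mm = CLASS_BOUNDS_MM[cls]
    lo_semi = lo_mm * 500.0 / mpp   # semi-axis bounds in px
    hi_semi = hi_mm * 500.0 / mpp
    placed: list[Focus] = []
    if tissue is not None:
        ty, tx = np.nonzero(tissue)
        if ty.size == 0:
            raise PlacementError("no tissue to place foci in")
    constructive = (geometry is not None
                    and lo_semi > 0.35 * geometry.semi_minor)
    if constructive:
        a_cap = min(hi_semi, 0.92 * geometry.semi_major,
                    0.92 * geometry.semi_minor / 0.4)
        if count > 0 and a_cap <= lo_semi:
            raise PlacementError(
                f"a {cls} focus (major axis > {lo_mm} mm) cannot fit the "
                "tissue region at this slide geometry")
    for _ in range(count):
        for attempt in range(max_attempts):
            if constructive:
                # bias toward the feasible low end so smaller classes
                # still find room afterwards
                a_semi = rng.uniform(lo_semi,
                                     lo_semi + 0.35 * (a_cap - lo_semi))
                ratio_hi = min(1.0, 0.92 * geometry.semi_minor / a_semi)
                b_semi = a_semi * rng.uniform(0.4, max(0.4, ratio_hi))
                angle = geometry.angle_rad + rng.normal(0, 0.02)
                jitter = 0.05 * geometry.semi_minor
                cy = geometry.center_y + rng.normal(0, jitter)
                cx = geometry.center_x + rng.normal(0, jitter)
                major_px, minor_px = 2 * a_semi, 2 * b_semi
            else:
                # within-bounds size draw, shrinking toward the class
                # lower bound as rejections accumulate so crowded tissue
                # still admits the focus
                hi_eff = lo_mm + (hi_mm - lo_mm) * 0.95 ** attempt
                major_px = rng.uniform(lo_mm, hi_eff) * 1000.0 / mpp
                minor_px = major_px * rng.uniform(0.4, 1.0)
                angle = rng.uniform(0, np.pi)
                if tissue is not None:
                    k = rng.integers(ty.size)
                    cy, cx = float(ty[k]), float(tx[k])
                else:
                    cy = rng.uniform(0, mask.shape[0])
                    cx = rng.uniform(0, mask.shape[1])
            pix = _ellipse_pixels(cy, cx, major_px / 2.0, minor_px / 2.0,
                                  angle, mask.shape)
            if pix is None:
                continue
            ys, xs = pix
            if tissue is not None and not tissue[ys, xs].all():
                continue
            if (mask[ys, xs] != LABEL_BACKGROUND).any():
                continue
            mask[ys, xs] = LABEL_TUMOR
            placed.append(Focus(cls, cy, cx, major_px, minor_px, angle))
            break
        else:
            raise PlacementError(
                f"could not place a {cls} focus after {max_attempts} attempts")
    return mask, placed


def corrupt_labels(truth: np.ndarray, fraction: float, mode: str, rng) -> np.ndarray:
    """Erase a fraction of tumor connected components from the mask.

    ``round(fraction * n_components)`` components (chosen at random) are
    relabeled to background (``drop_to_background``, emulating annotation
    gaps) or to the ignore label (``drop_to_ignore``); every other pixel
    is untouched.
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    if mode not in {"drop_to_background", "drop_to_ignore"}:
        raise ValueError(f"unknown corruption mode {mode!r}")
    out = truth.copy()
    comp, n = ndimage.label(truth == LABEL_TUMOR, structure=np.ones((3, 3)))
    k = int(round(fraction * n))
    if k == 0:
        return out
    chosen = rng.permutation(n)[:k] + 1
    target = LABEL_BACKGROUND if mode == "drop_to_background" else LABEL_IGNORE
    out[np.isin(comp, chosen)] = target
    return out


# ------------------------------------------------------------ rendering

def generate_slide(config: SynthConfig) -> SlidePair:
    """Render one synthetic slide with its complete and training masks."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    tissue, geometry = _tissue_region(config, rng)

    truth = np.zeros((h, w), np.uint8)
    foci: list[Focus] = []
    for cls, count in (("macro", config.n_macro), ("micro", config.n_micro),
                       ("itc", config.n_itc)):
        truth, placed = place_foci(truth, cls, count, config.mpp, rng,
                                   tissue=tissue, geometry=geometry)
        foci.extend(placed)

    img = np.empty((h, w, 3), np.float32)
    img[:] = _BACKGROUND_LEVEL
    img += rng.standard_normal((h, w, 3), dtype=np.float32) * 3.0
    low = ndimage.gaussian_filter(
        rng.standard_normal((h, w), dtype=np.float32), sigma=24.0)
    low /= max(float(low.std()), 1e-6)
    fine = rng.standard_normal((h, w, 3), dtype=np.float32) * 6.0
    amp = np.array([14.0, 20.0, 12.0], np.float32)

    in_tissue = tissue & (truth != LABEL_TUMOR)
    img[in_tissue] = (_TISSUE_RGB + low[in_tissue, None] * amp
                      + fine[in_tissue])
    in_focus = truth == LABEL_TUMOR
    img[in_focus] = (_FOCUS_RGB + low[in_focus, None] * (amp * 0.7)
                     + fine[in_focus])
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    if config.partial_label_fraction > 0:
        labels = corrupt_labels(truth, config.partial_label_fraction,
                                "drop_to_background", rng)
    else:
        labels = truth.copy()
    image = SlideImage(pixels=pixels, mpp=config.mpp,
                       name=f"synth-{config.seed}")
    return SlidePair(image=image, truth=truth, labels=labels, foci=foci,
                     tissue=tissue)


# --------------------------------------------------------------- cohort

def _child_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0]
               % (2 ** 31))


def generate_cohort(
    n_train_malignant: int,
    n_train_benign: int,
    n_test_malignant: int,
    n_test_benign: int,
    base_config: SynthConfig,
    out_dir: str | Path,
) -> list[dict]:
    """Write a train/test cohort of slides and masks plus a JSONL manifest.

    Benign slides carry zero foci (all-background truth). Each slide gets
    a deterministic child seed derived from the base config's seed and its
    cohort index, so the whole cohort is reproducible from one integer.
    """
    counts = (n_train_malignant, n_train_benign, n_test_malignant, n_test_benign)
    if min(counts) < 0:
        raise ValueError("cohort counts must be non-negative")
    if sum(counts) == 0:
        raise ValueError("cohort must contain at least one slide")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    index = 0
    for split, malignant, n in (("train", True, n_train_malignant),
                                ("train", False, n_train_benign),
                                ("test", True, n_test_malignant),
                                ("test", False, n_test_benign)):
        for _ in range(n):
            seed = _child_seed(base_config.seed, index)
            cfg = dataclasses.replace(base_config, seed=seed)
            if not malignant:
                cfg = dataclasses.replace(cfg, n_macro=0, n_micro=0, n_itc=0)
            pair = generate_slide(cfg)
            stem = f"slide_{index:03d}"
            img_path = out_dir / f"{stem}.png"
            mask_path = out_dir / f"{stem}_labels.png"
            truth_path = out_dir / f"{stem}_truth.png"
            write_slide(pair.image, img_path)
            write_mask(pair.labels, mask_path)
            write_mask(pair.truth, truth_path)
            manifest.append({
                "path": img_path.name,
                "mask_path": mask_path.name,
                "truth_path": truth_path.name,
                "split": split,
                "malignant": malignant,
                "seed": seed,
                "mpp": base_config.mpp,
            })
            index += 1
    with open(out_dir / "manifest.jsonl", "w") as fh:
        for entry in manifest:
            fh.write(json.dumps(entry) + "\n")
    return manifest


def read_manifest(path: str | Path) -> list[dict]:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.jsonl"
    with open(path) as fh:
        return [json.loads(line) for line in fh if line.strip()]
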