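"""End-to-end synthetic recovery experiment.

Generates a seeded cohort of synthetic slides with planted macro-, micro-
and ITC-scale foci and 20% of label components erased, trains a
width-reduced modified FCN with boosting learning plus focus sampling,
and measures held-out segmentation quality. This is the package's
integration benchmark: the full pipeline (synthesis -> Otsu tiling ->
boosted training -> thresholded inference -> metrics) exercised at a
desk-scale problem size that a single CPU handles in minutes.

The width-reduced spec keeps the architecture topology (5 blocks,
13 convs, 64x64/stride-32 deconv, two dropouts, center crop) and shrinks
only the channel widths, the tile size (128 px) and the pre-pad (32 px).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .evaluation import ConfusionCounts, confusion_counts, slide_metrics
from .fcn_model import ModelSpec, build_modified_fcn
from .inference import InferenceConfig, predict_slide
from .synthetic_wsi import SynthConfig, _child_seed, _ellipse_pixels, generate_slide
from .tile_grid import build_grid, extract_mask_tile, extract_tile
from .training import BoostConfig, TrainConfig, TrainTile, run_boosting

#: channel widths of the width-reduced model (topology unchanged).
REDUCED_BLOCKS = ((2, 8), (2, 16), (3, 32), (3, 32), (3, 32))


def reduced_spec(tile_size: int = 128) -> ModelSpec:
    return ModelSpec(input_size=tile_size, pad=32, blocks=REDUCED_BLOCKS,
                     n_classes=2)


def cohort_configs(seed: int, n_train_malignant: int = 6,
                   n_train_benign: int = 2, n_test_malignant: int = 2,
                   slide_px: int = 2048) -> list[tuple[str, SynthConfig]]:
    """(split, config) pairs for the recovery cohort.

    Malignant slides carry 1 macro, 2 micro and 3 ITC foci at 1 um/px
    with 20% of label components dropped; benign slides have no foci.
    """
    base = SynthConfig(width_px=slide_px, height_px=slide_px, mpp=1.0,
                       n_macro=1, n_micro=2, n_itc=3, tissue_fraction=0.6,
                       partial_label_fraction=0.2, seed=seed)
    out = []
    index = 0
    for split, malignant, n in (("train", True, n_train_malignant),
                                ("train", False, n_train_benign),
                                ("test", True, n_test_malignant)):
        for _ in range(n):
            cfg = dataclasses.replace(base, seed=_child_seed(seed, index))
            if not malignant:
                cfg = dataclasses.replace(cfg, n_macro=0, n_micro=0, n_itc=0)
            out.append((split, cfg))
            index += 1
    return out


def collect_train_tiles(pair, grid, max_positive: int | None = None,
                        rng=None) -> list[TrainTile]:
    """Tissue tiles of one slide as training units.

    A tile is flagged partially labeled when its window contains truth
    tumor pixels that the (corrupted) label mask calls background — the
    generator knows where labels were erased, which is exactly the
    partial-annotation condition focus sampling exists for. Optionally
    caps the number of tumor-bearing tiles per slide.
    """
    erased = (pair.truth == 1) & (pair.labels == 0)
    tiles = []
    for i, j in grid.tissue_tiles():
        unit = extract_tile(pair.image, grid, i, j)
        labels = extract_mask_tile(pair.labels, grid, i, j)
        partial = bool(extract_mask_tile(erased.astype(np.uint8), grid, i, j,
                                         pad_value=0).any())
        tiles.append(TrainTile(key=(pair.image.name, i, j), pixels=unit.pixels,
                               labels=labels, partial=partial))
    if max_positive is not None and rng is not None:
        positive = [t for t in tiles if (t.labels == 1).mean() >= 0.05]
        rest = [t for t in tiles if (t.labels == 1).mean() < 0.05]
        if len(positive) > max_positive:
            keep = rng.permutation(len(positive))[:max_positive]
            positive = [positive[k] for k in sorted(keep)]
        tiles = positive + rest
    return tiles


def synthetic_recovery(
    seed: int,
    n_train_malignant: int = 6,
    n_train_benign: int = 2,
    n_test_malignant: int = 2,
    slide_px: int = 2048,
    tile_size: int = 128,
    rounds: int = 2,
    epochs_per_round: int = 2,
    learning_rate: float = 0.01,
    max_positive_per_slide: int = 60,
) -> dict:
    """Run the full pipeline on a synthetic cohort and score recovery.

    Returns held-out tumor-class IoU (confusions summed over test
    slides), per-slide metrics, focus-level recall for macro foci, and
    whether boosting engaged (some tile's weight grew after round 1).
    """
    rng = np.random.default_rng(seed)
    configs = cohort_configs(seed, n_train_malignant, n_train_benign,
                             n_test_malignant, slide_px)
    downsample = 16

    train_tiles: list[TrainTile] = []
    test_pairs = []
    for split, cfg in configs:
        pair = generate_slide(cfg)
        grid = build_grid(pair.image, tile_size=tile_size,
                          downsample=downsample, min_tissue_fraction=0.05)
        if split == "train":
            train_tiles.extend(collect_train_tiles(
                pair, grid, max_positive=max_positive_per_slide, rng=rng))
        else:
            test_pairs.append((pair, grid))

    model = build_modified_fcn(reduced_spec(tile_size), seed=seed)
    boost = BoostConfig(gamma=0.05, chi=1.0, rounds=rounds, alpha=0.5,
                        negative_quota=0.5)
    train_cfg = TrainConfig(learning_rate=learning_rate, weight_decay=5e-4,
                            momentum=0.9, epochs_per_round=epochs_per_round,
                            batch_size=4, seed=seed, loss_reduction="mean")
    model, history = run_boosting(model, train_tiles, boost, train_cfg)

    infer_cfg = InferenceConfig(tile_size=tile_size, alpha=0.5, batch_size=8)
    total = ConfusionCounts(0, 0, 0, 0)
    per_slide = []
    macro_hits, macro_total = 0, 0
    for pair, grid in test_pairs:
        result = predict_slide(model, pair.image, grid, infer_cfg)
        total = total + confusion_counts(result.mask, pair.truth)
        per_slide.append(slide_metrics(result.mask, pair.truth))
        for focus in pair.foci:
            if focus.cls != "macro":
                continue
            macro_total += 1
            pix = _ellipse_pixels(focus.center_y, focus.center_x,
                                  focus.major_px / 2, focus.minor_px / 2,
                                  focus.angle_rad, result.mask.shape)
            if pix is not None and (result.mask[pix] == 1).any():
                macro_hits += 1

    denom = total.tp + total.fn + total.fp
    iou = total.tp / denom if denom else 1.0
    first = history[0]
    engaged = any(first["weights_out"][k] > first["weights_in"][k]
                  for k in first["weights_in"])
    return {
        "heldout_tumor_iou": float(iou),
        "per_slide_metrics": per_slide,
        "macro_focus_recall": (macro_hits / macro_total) if macro_total else None,
        "macro_foci": macro_total,
        "boosting_engaged": bool(engaged),
        "history": history,
        "n_train_tiles": len(train_tiles),
        "n_positive_tiles": sum(1 for t in train_tiles
                                if (t.labels == 1).mean() >= 0.05),
    }
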