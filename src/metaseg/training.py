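"""Boosting learning: attention-weighted tiles, boosted augmentation,
focus sampling and the SGD recipe that produces the final model.

The scheme trains the modified FCN in H rounds. Every tissue tile e
carries an attention weight le:

* initialization: le = 1 if the tile's annotated-tumor fraction
  (tumor pixels / U^2) reaches gamma (default 0.05), else 0 — so
  training starts from tiles that actually show metastasis;
* after each round, the tile's prediction-error fraction (mismatching
  non-ignore pixels / U^2) is measured; tiles at or above gamma get
  their weight incremented by chi. Weights never decrease, so hard
  tiles (false positives and false negatives alike) accumulate
  attention across rounds.

A tile with weight w contributes round(w) independently augmented
copies to the round's training set (right-angle rotation, mirror flips,
and contrast/saturation/brightness jitter of +-20%/+-20%/+-12.5%);
weight 0 means the tile is not sampled. Focus sampling relabels
unannotated tissue as ignore (255) so partially labeled slides do not
poison the background class: ignore pixels contribute exactly zero loss
and zero gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from . import nn
from .fcn_model import ModifiedFCN
from .tile_grid import LABEL_IGNORE, LABEL_TUMOR


class TrainingSetEmptyError(RuntimeError):
    """No tile carries positive sampling weight."""


class ConsistencyError(RuntimeError):
    """A weighted tile is missing its prediction or truth."""


@dataclass
class BoostConfig:
    gamma: float = 0.05          # attention / error-fraction threshold
    chi: float = 1.0             # weight increment for erroneous tiles
    rounds: int = 3              # H
    alpha: float = 0.5           # probability threshold for tile errors
    negative_quota: float = 0.0  # admitted background tiles per positive tile
    focus_dilation_px: int = 0   # ignore band around annotations (0 = off)

    def validate(self) -> None:
        if not 0 < self.gamma < 1:
            raise ValueError("gamma must be in (0, 1)")
        if self.chi <= 0:
            raise ValueError("chi must be positive")
        if self.rounds < 1:
            raise ValueError("at least one boosting round is required")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-10   # paired with summed pixel loss
    weight_decay: float = 0.0005
    dropout: float = 0.5
    momentum: float = 0.9
    epochs_per_round: int = 1
    batch_size: int = 1
    seed: int = 0
    loss_reduction: str = "sum"    # "sum" (default) or "mean"

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("learning_rate must be > 0, weight_decay >= 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.loss_reduction not in {"sum", "mean"}:
            raise ValueError("loss_reduction must be 'sum' or 'mean'")


@dataclass
class AugmentationSpec:
    right_angle_rotations: tuple = (90, 180, 270)
    jitter_rotation_deg: float = 0.0      # optional +-5 deg refinement
    flips: tuple = ("horizontal", "vertical")
    contrast_range: float = 0.20
    saturation_range: float = 0.20
    brightness_range: float = 0.125
    seed: int = 0

    @classmethod
    def identity(cls) -> "AugmentationSpec":
        return cls(right_angle_rotations=(), jitter_rotation_deg=0.0,
                   flips=(), contrast_range=0.0, saturation_range=0.0,
                   brightness_range=0.0)


@dataclass
class TrainTile:
    """One tissue tile ready for training."""

    key: tuple
    pixels: np.ndarray                 # (U, U, 3) uint8
    labels: np.ndarray                 # (U, U) uint8 in {0, 1, 255}
    tissue: np.ndarray | None = None   # (U, U) bool; None = all tissue
    partial: bool = False              # flagged partially labeled


# ------------------------------------------------------ weight rules

def init_weights(masks: dict, gamma: float, tile_size: int | None = None) -> dict:
    """Initial attention weights from the annotated-tumor fraction.

    ``masks`` maps tile key -> (U, U) label mask. The weight is 1 when
    tumor pixels / U^2 >= gamma, else 0.
    """
    weights = {}
    for key, mask in masks.items():
        if tile_size is not None and mask.shape != (tile_size, tile_size):
            raise ValueError(f"mask for {key} has shape {mask.shape}")
        if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
            raise ValueError(f"mask for {key} must be square 2-D")
        frac = float((mask == LABEL_TUMOR).sum()) / mask.size
        weights[key] = 1.0 if frac >= gamma else 0.0
    return weights


def update_weights(weights: dict, predictions: dict, truths: dict,
                   gamma: float, chi: float) -> dict:
    """One boosting update of the attention weights.

    The tile's error fraction is the count of pixels where prediction and
    truth disagree (truth != ignore) divided by the full tile area U^2;
    tiles with error fraction >= gamma gain chi, all others keep their
    weight. Weights therefore never decrease.
    """
    out = {}
    for key, w in weights.items():
        if key not in predictions or key not in truths:
            raise ConsistencyError(f"missing prediction/truth for tile {key}")
        pred, truth = predictions[key], truths[key]
        if pred.shape != truth.shape:
            raise ValueError(f"shape mismatch for tile {key}")
        errors = int(((pred != truth) & (truth != LABEL_IGNORE)).sum())
        frac = errors / truth.size
        out[key] = w + chi if frac >= gamma else w
    return out


# ------------------------------------------------------- augmentation

def rotate90(arr: np.ndarray, degrees: int) -> np.ndarray:
    """Right-angle rotation (counterclockwise) of an image or mask."""
    if degrees % 90 != 0:
        raise ValueError("rotate90 handles multiples of 90 degrees only")
    return np.rot90(arr, k=(degrees // 90) % 4, axes=(0, 1)).copy()


def photometric_jitter(tile: np.ndarray, contrast: float, saturation: float,
                       brightness: float) -> np.ndarray:
    """Contrast/saturation/brightness adjustment of an RGB tile.

    Each argument is the signed relative change (e.g. contrast=0.2 means
    +20%); zero arguments leave the tile bit-identical.
    """
    x = tile.astype(np.float32)
    if contrast != 0.0:
        pivot = x.mean()
        x = pivot + (1.0 + contrast) * (x - pivot)
    if saturation != 0.0:
        gray = x @ np.array([0.299, 0.587, 0.114], np.float32)
        x = gray[..., None] + (1.0 + saturation) * (x - gray[..., None])
    if brightness != 0.0:
        x = x * (1.0 + brightness)
    if contrast == saturation == brightness == 0.0:
        return tile.copy()
    return np.clip(np.rint(x), 0, 255).astype(tile.dtype)


def draw_jitter(spec: AugmentationSpec, rng) -> tuple[float, float, float]:
    c = rng.uniform(-spec.contrast_range, spec.contrast_range) \
        if spec.contrast_range else 0.0
    s = rng.uniform(-spec.saturation_range, spec.saturation_range) \
        if spec.saturation_range else 0.0
    b = rng.uniform(-spec.brightness_range, spec.brightness_range) \
        if spec.brightness_range else 0.0
    return c, s, b


def boosted_augment(tile: np.ndarray, mask: np.ndarray, weight: float,
                    spec: AugmentationSpec, rng) -> list[tuple[np.ndarray, np.ndarray]]:
    """round(weight) independently augmented copies of a tile and its mask.

    Geometric transforms (rotations, flips) are applied identically to
    tile and mask; photometric jitter touches the tile only. A weight of
    0 excludes the tile entirely.
    """
    if weight < 0:
        raise ValueError("weight must be non-negative")
    n_copies = int(round(weight))
    out = []
    for _ in range(n_copies):
        img, msk = tile, mask
        options = (0,) + tuple(spec.right_angle_rotations)
        deg = int(options[rng.integers(len(options))])
        if deg:
            img, msk = rotate90(img, deg), rotate90(msk, deg)
        if spec.jitter_rotation_deg:
            theta = float(rng.uniform(-spec.jitter_rotation_deg,
                                      spec.jitter_rotation_deg))
            img = ndimage.rotate(img, theta, reshape=False, order=1,
                                 mode="reflect")
            msk = ndimage.rotate(msk, theta, reshape=False, order=0,
                                 mode="nearest")
        if "horizontal" in spec.flips and rng.random() < 0.5:
            img, msk = img[:, ::-1].copy(), msk[:, ::-1].copy()
        if "vertical" in spec.flips and rng.random() < 0.5:
            img, msk = img[::-1].copy(), msk[::-1].copy()
        c, s, b = draw_jitter(spec, rng)
        img = photometric_jitter(img, c, s, b)
        if img is tile:
            img = tile.copy()
        out.append((img, msk))
    return out


# ------------------------------------------------------ focus sampling

def focus_sample(mask: np.ndarray, tissue: np.ndarray,
                 partial_region: np.ndarray | None = None,
                 dilation_px: int = 0) -> np.ndarray:
    """Relabel unannotated tissue as ignore so it carries no gradient.

    Background-labeled tissue pixels are switched to the ignore label when
    they fall inside ``partial_region`` (zones known to be incompletely
    annotated, e.g. tiles flagged partial) or within ``dilation_px`` of an
    annotated tumor region. Annotated pixels are never overwritten; a
    fully annotated mask (no flags, no dilation) passes through unchanged.
    """
    if mask.shape != tissue.shape:
        raise ValueError("mask and tissue mask must share shape")
    out = mask.copy()
    candidates = tissue & (mask == 0)
    selected = np.zeros_like(candidates)
    if partial_region is not None:
        selected |= partial_region.astype(bool)
    if dilation_px > 0:
        annotated = mask == LABEL_TUMOR
        if annotated.any():
            selected |= ndimage.binary_dilation(annotated,
                                                iterations=dilation_px)
    out[candidates & selected] = LABEL_IGNORE
    return out


# --------------------------------------------------------------- loss

def pixel_loss(prob: np.ndarray, truth: np.ndarray,
               reduction: str = "sum") -> float:
    """Cross-entropy of a probability map against a label mask.

    ``prob`` is (H, W, C) per-pixel class probabilities; pixels whose
    truth is the ignore label contribute exactly zero. With every pixel
    ignored the loss is 0 and a warning is emitted.
    """
    if prob.shape[:2] != truth.shape:
        raise ValueError("probability map and truth must share spatial dims")
    if reduction not in {"sum", "mean"}:
        raise ValueError("reduction must be 'sum' or 'mean'")
    valid = truth != LABEL_IGNORE
    n_valid = int(valid.sum())
    if n_valid == 0:
        warnings.warn("all pixels ignored; loss is 0", RuntimeWarning)
        return 0.0
    tgt = np.where(valid, truth, 0).astype(np.int64)
    p = np.take_along_axis(prob, tgt[..., None], axis=2)[..., 0]
    loss = -float(np.log(np.clip(p[valid], 1e-12, None)).sum())
    return loss / n_valid if reduction == "mean" else loss


# ----------------------------------------------------------- boosting

def _predict_class_maps(model: ModifiedFCN, tiles: Sequence[TrainTile],
                        alpha: float, batch_size: int) -> dict:
    """Thresholded (tumor prob >= alpha) class maps for a set of tiles."""
    preds = {}
    order = list(range(len(tiles)))
    for start in range(0, len(order), batch_size):
        chunk = [tiles[k] for k in order[start:start + batch_size]]
        x = np.stack([t.pixels for t in chunk]).astype(nn.F32)
        logits = model.forward(x.transpose(0, 3, 1, 2), train=False)
        prob = nn.softmax(logits, axis=1)
        if model.spec.n_classes == 2:
            cls = (prob[:, 1] >= alpha).astype(np.uint8)
        else:
            cls = prob.argmax(axis=1).astype(np.uint8)
        for t, cmap in zip(chunk, cls):
            preds[t.key] = cmap
    return preds


def run_boosting(
    model: ModifiedFCN,
    tiles: Sequence[TrainTile],
    boost: BoostConfig,
    train: TrainConfig,
    augmentation: AugmentationSpec | None = None,
    on_round_end=None,
) -> tuple[ModifiedFCN, list[dict]]:
    """Train the model for ``boost.rounds`` rounds of boosting learning.

    Each round: focus-sampled masks + current weights define the training
    set (round(weight) augmented copies per tile, plus an optional quota
    of background tiles), SGD runs for ``epochs_per_round`` epochs, then
    every tile is re-predicted and the weights updated from the error
    fractions. Returns the final model and a per-round history with the
    incoming/outgoing weights, mean loss, and tile error fractions. Fully
    reproducible from ``train.seed``.
    """
    boost.validate()
    train.validate()
    augmentation = augmentation or AugmentationSpec()
    rng = np.random.default_rng(train.seed)

    fs_masks = {}
    for t in tiles:
        tissue = t.tissue if t.tissue is not None \
            else np.ones_like(t.labels, bool)
        partial = np.ones_like(t.labels, bool) if t.partial else None
        fs_masks[t.key] = focus_sample(t.labels, tissue,
                                       partial_region=partial,
                                       dilation_px=boost.focus_dilation_px)

    weights = init_weights({t.key: t.labels for t in tiles}, boost.gamma)
    by_key = {t.key: t for t in tiles}
    optimizer = nn.SGD(model.net, lr=train.learning_rate,
                       momentum=train.momentum,
                       weight_decay=train.weight_decay)
    history: list[dict] = []

    for round_idx in range(1, boost.rounds + 1):
        sampling = dict(weights)
        if boost.negative_quota > 0:
            positives = [k for k, w in weights.items() if w > 0]
            negatives = sorted(k for k, w in weights.items() if w == 0)
            n_admit = min(len(negatives),
                          int(round(boost.negative_quota * len(positives))))
            if n_admit:
                for idx in rng.permutation(len(negatives))[:n_admit]:
                    sampling[negatives[idx]] = 1.0

        samples: list[tuple[np.ndarray, np.ndarray]] = []
        for key in sorted(sampling):
            w = sampling[key]
            if w <= 0:
                continue
            t = by_key[key]
            samples.extend(boosted_augment(t.pixels, fs_masks[key], w,
                                           augmentation, rng))
        if not samples:
            raise TrainingSetEmptyError(
                "no tile has positive sampling weight in round "
                f"{round_idx}")

        losses = []
        for _ in range(train.epochs_per_round):
            order = rng.permutation(len(samples))
            for start in range(0, len(order), train.batch_size):
                idx = order[start:start + train.batch_size]
                x = np.stack([samples[k][0] for k in idx]).astype(nn.F32)
                y = np.stack([samples[k][1] for k in idx])
                model.zero_grad()
                logits = model.forward(x.transpose(0, 3, 1, 2), train=True,
                                       rng=rng)
                loss, dlogits, n_valid = nn.cross_entropy_with_logits(
                    logits, y, reduction=train.loss_reduction)
                if n_valid:
                    model.backward(dlogits)
                    optimizer.step()
                losses.append(loss)

        preds = _predict_class_maps(model, tiles, boost.alpha,
                                    max(train.batch_size, 1))
        new_weights = update_weights(weights, preds, fs_masks,
                                     boost.gamma, chi=boost.chi)
        error_fracs = {
            k: float(((preds[k] != fs_masks[k])
                      & (fs_masks[k] != LABEL_IGNORE)).sum()) / fs_masks[k].size
            for k in weights
        }
        record = {
            "round": round_idx,
            "weights_in": dict(weights),
            "weights_out": dict(new_weights),
            "mean_loss": float(np.mean(losses)),
            "error_fractions": error_fracs,
            "n_samples": len(samples),
        }
        history.append(record)
        weights = new_weights
        if on_round_end is not None:
            on_round_end(round_idx, model, record)

    return model, history
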