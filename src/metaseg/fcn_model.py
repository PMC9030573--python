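"""The modified FCN-32s segmentation network and its checkpoint contract.

The network is a VGG16-style fully convolutional encoder — five blocks of
3x3/stride-1 convolutions (2, 2, 3, 3, 3 layers; 13 in total), each conv
followed by ReLU and each block by 2x2/stride-2 max pooling — with the two
fully-connected-derived layers of the original FCN dropped. A zero-padding
layer widens the input before block 1 (512 -> 712 at the defaults), a 1x1
score convolution maps the 512 encoder channels to the class scores, and a
single-stream 64x64/stride-32 transposed convolution upsamples in one shot
("32s"), after which a center crop restores the input size and a softmax
yields per-pixel class probabilities. Two dropout layers sit on the pool5
features ahead of the score convolution.

Shape trace at the defaults: 512 -> pad 712 -> pools 356/178/89/44/22 ->
deconv (22-1)*32+64 = 736 -> center crop offset 112 -> 512.

Transfer learning is a loading contract, not a file: any checkpoint whose
tensor names and shapes match the spec is accepted (e.g. weights from a
tumor-segmentation model of another organ), matched tensors are copied and
mismatches reported (or rejected under ``strict``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn

VGG16_BLOCKS = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))


@dataclass(frozen=True)
class ModelSpec:
    """Layer specification of the modified FCN."""

    input_size: int = 512
    pad: int = 100
    blocks: tuple = VGG16_BLOCKS
    n_classes: int = 2
    dropout_ratio: float = 0.5
    deconv_kernel: int = 64
    deconv_stride: int = 32

    def validate(self) -> None:
        if len(self.blocks) != 5:
            raise ValueError("the modified FCN has exactly 5 conv blocks")
        if sum(n for n, _ in self.blocks) != 13:
            raise ValueError("the 5 blocks must hold 13 convolutional layers")
        tr = trace_shapes(self)
        if tr["pool_sizes"][-1] < 1:
            raise ValueError("input too small: pool5 extent would vanish")
        if tr["deconv_size"] < self.input_size:
            raise ValueError("deconv output smaller than the input size")


def trace_shapes(spec: ModelSpec) -> dict:
    """Closed-form spatial trace (no tensors touched).

    Convolutions are size-preserving (3x3, stride 1, pad 1); each pool
    halves with floor; the transposed conv maps n -> (n-1)*stride + kernel;
    the crop is centered.
    """
    size = spec.input_size + 2 * spec.pad
    pools = []
    s = size
    for _ in spec.blocks:
        s = s // 2
        pools.append(s)
    deconv = (pools[-1] - 1) * spec.deconv_stride + spec.deconv_kernel
    return {
        "padded_size": size,
        "pool_sizes": pools,
        "deconv_size": deconv,
        "crop_offset": (deconv - spec.input_size) // 2,
    }


class ModifiedFCN:
    """The assembled network; thin wrapper over an :class:`nn.Sequential`."""

    def __init__(self, spec: ModelSpec, net: nn.Sequential):
        self.spec = spec
        self.net = net

    #: fixed input standardization (x - 128) / 64 applied before the first
    #: layer, so raw 8-bit RGB enters the encoder well-conditioned.
    INPUT_SHIFT = 128.0
    INPUT_SCALE = 1.0 / 64.0

    def forward(self, x: np.ndarray, train: bool = False, rng=None) -> np.ndarray:
        """Logits (N, n_classes, H, W) for input (N, 3, H, W) in [0, 255]."""
        if x.shape[2] != self.spec.input_size or x.shape[3] != self.spec.input_size:
            raise ValueError(
                f"input spatial dims {x.shape[2:]} != spec input size "
                f"{self.spec.input_size}")
        x = (x.astype(nn.F32) - self.INPUT_SHIFT) * self.INPUT_SCALE
        return self.net.forward(x, train=train, rng=rng)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        return self.net.backward(dlogits)

    def state_dict(self):
        return self.net.state_dict()

    def zero_grad(self):
        self.net.zero_grad()


def build_modified_fcn(spec: ModelSpec | None = None, seed: int = 0) -> ModifiedFCN:
    """Construct the network with fresh initialization.

    Encoder convs are He-initialized, the score conv starts at zero and
    the transposed conv at bilinear interpolation — so an untrained model
    already produces a flat, well-normalized probability field.
    """
    spec = spec or ModelSpec()
    spec.validate()
    rng = np.random.default_rng(seed)
    layers: list[tuple[str, nn.Layer]] = [("pad", nn.ZeroPad2d(spec.pad))]
    in_ch = 3
    for b, (n_convs, out_ch) in enumerate(spec.blocks, start=1):
        for c in range(1, n_convs + 1):
            layers.append((f"conv{b}_{c}",
                           nn.Conv2d(in_ch, out_ch, kernel=3, pad=1, rng=rng)))
            layers.append((f"relu{b}_{c}", nn.ReLU()))
            in_ch = out_ch
        layers.append((f"pool{b}", nn.MaxPool2d()))
    # the two dropout layers regularize the deepest feature maps (the
    # role they played on the fc-derived layers of the original net);
    # dropping score logits themselves would inject label-scale noise
    layers.append(("drop6", nn.Dropout(spec.dropout_ratio)))
    layers.append(("drop7", nn.Dropout(spec.dropout_ratio)))
    layers.append(("score", nn.Conv2d(in_ch, spec.n_classes, kernel=1, pad=0,
                                      init="zero")))
    layers.append(("upscore", nn.ConvTranspose2d(spec.n_classes, spec.n_classes,
                                                 spec.deconv_kernel,
                                                 spec.deconv_stride)))
    layers.append(("crop", nn.CenterCrop(spec.input_size)))
    return ModifiedFCN(spec, nn.Sequential(layers))


def predict_tile(model: ModifiedFCN, tile: np.ndarray) -> np.ndarray:
    """Per-pixel class probabilities (U, U, n_classes) for one RGB tile.

    Inference mode: dropout disabled, deterministic for fixed weights.
    """
    u = model.spec.input_size
    if tile.shape != (u, u, 3):
        raise ValueError(f"tile shape {tile.shape} != ({u}, {u}, 3)")
    x = tile.astype(nn.F32).transpose(2, 0, 1)[None]
    logits = model.forward(x, train=False)
    return nn.softmax(logits, axis=1)[0].transpose(1, 2, 0)


def predict_tiles(model: ModifiedFCN, tiles: np.ndarray) -> np.ndarray:
    """Batched variant: (N, U, U, 3) -> (N, U, U, n_classes)."""
    x = tiles.astype(nn.F32).transpose(0, 3, 1, 2)
    logits = model.forward(x, train=False)
    return nn.softmax(logits, axis=1).transpose(0, 2, 3, 1)


# ---------------------------------------------------------- checkpoints

@dataclass
class Checkpoint:
    tensors: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)


@dataclass
class LoadReport:
    loaded: list[str]
    skipped: list[str]


def save_checkpoint(model: ModifiedFCN, path: str | Path,
                    metadata: dict | None = None) -> None:
    """Write weights as an .npz plus a JSON sidecar of names and shapes."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    state = model.state_dict()
    np.savez(path, **state)
    sidecar = {
        "spec": dataclasses_asdict(model.spec),
        "tensors": {k: list(v.shape) for k, v in state.items()},
        "metadata": metadata or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def dataclasses_asdict(spec: ModelSpec) -> dict:
    return {
        "input_size": spec.input_size,
        "pad": spec.pad,
        "blocks": [list(b) for b in spec.blocks],
        "n_classes": spec.n_classes,
        "dropout_ratio": spec.dropout_ratio,
        "deconv_kernel": spec.deconv_kernel,
        "deconv_stride": spec.deconv_stride,
    }


def spec_from_dict(doc: dict) -> ModelSpec:
    return ModelSpec(
        input_size=doc["input_size"],
        pad=doc["pad"],
        blocks=tuple(tuple(b) for b in doc["blocks"]),
        n_classes=doc["n_classes"],
        dropout_ratio=doc["dropout_ratio"],
        deconv_kernel=doc["deconv_kernel"],
        deconv_stride=doc["deconv_stride"],
    )


def load_checkpoint(path: str | Path) -> Checkpoint:
    path = Path(path)
    with np.load(path) as data:
        tensors = {k: data[k].copy() for k in data.files}
    metadata = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        metadata = json.loads(sidecar.read_text())
    return Checkpoint(tensors=tensors, metadata=metadata)


class CheckpointMismatchError(RuntimeError):
    pass


def load_pretrained(model: ModifiedFCN, checkpoint: Checkpoint,
                    strict: bool = False) -> LoadReport:
    """Copy every name+shape-matched tensor from the checkpoint.

    With ``strict=False`` (transfer-learning mode) mismatched or missing
    tensors are skipped and reported; with ``strict=True`` any mismatch
    raises :class:`CheckpointMismatchError`.
    """
    state = {name: val for name, val, _ in model.net.named_params()}
    loaded, skipped = [], []
    for name, target in state.items():
        src = checkpoint.tensors.get(name)
        if src is not None and src.shape == target.shape:
            target[...] = src
            loaded.append(name)
        else:
            skipped.append(name)
    extra = [k for k in checkpoint.tensors if k not in state]
    if strict and (skipped or extra):
        raise CheckpointMismatchError(
            f"strict load failed: skipped={skipped}, unmatched={extra}")
    return LoadReport(loaded=loaded, skipped=skipped + extra)
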