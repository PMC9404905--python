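"""RDU-Net: residual, dilated U-Net for lung-lobe semantic segmentation.

A U-shaped encoder-decoder whose basic unit is a pre-activation residual
block of two 3x3 convolutions at a per-level dilation rate, with an identity
(or 1x1-projection) shortcut. Pooling is replaced by stride-2 convolutions
on the way down and nearest-neighbour upsampling plus convolution on the way
up, with skip concatenations as in U-Net. The dilation rate cycles
small-large-small over the resolution levels (default 1-2-4-2-1), enlarging
the receptive field without extra downsampling.

Because the residual shortcut is added after the convolutional branch (no
trailing nonlinearity), a block whose convolution weights are zero is
exactly the identity: a badly-learned block cannot degrade the features it
forwards.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .ctslice import CTSlice, LobeMask, as_labels
from .nn import Adam, Conv2d, InstanceNorm2d, Module, Tensor, concat, upsample_nearest2d
from .nn.functional import softmax_cross_entropy
from .score import LOBE_SCHEMES

__all__ = [
    "RDUNetConfig",
    "ResidualDilatedBlock",
    "residual_dilated_block",
    "RDUNet",
    "build_rdunet",
    "train_segmenter",
    "segment_lobes",
    "extract_lobe_images",
    "dice_and_iou",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class RDUNetConfig:
    """Architecture hyperparameters.

    ``dilation_cycle`` holds one rate per resolution level, encoder order;
    the decoder mirrors it. ``n_classes`` counts lobes plus background.
    """

    depth: int = 5
    base_channels: int = 16
    dilation_cycle: tuple[int, ...] = (1, 2, 4, 2, 1)
    n_classes: int = 5
    use_pooling: bool = False
    lobe_scheme: str = "lobes4"

    def __post_init__(self) -> None:
        self.dilation_cycle = tuple(int(r) for r in self.dilation_cycle)
        if len(self.dilation_cycle) != self.depth:
            raise ValueError(
                f"dilation_cycle length {len(self.dilation_cycle)} != depth {self.depth}"
            )
        if any(r < 1 for r in self.dilation_cycle):
            raise ValueError("dilation rates must be >= 1")
        if self.n_classes < 2:
            raise ValueError("need at least background + one lobe class")

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "base_channels": self.base_channels,
            "dilation_cycle": list(self.dilation_cycle),
            "n_classes": self.n_classes,
            "use_pooling": self.use_pooling,
            "lobe_scheme": self.lobe_scheme,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RDUNetConfig":
        d = dict(d)
        d["dilation_cycle"] = tuple(d["dilation_cycle"])
        return cls(**d)


class ResidualDilatedBlock(Module):
    """Two dilated 3x3 convs with norm/ReLU plus a shortcut, added at the end.

    Pre-activation layout (norm -> ReLU -> conv, twice); the shortcut is the
    identity when channel counts match, else a 1x1 projection.
    """

    def __init__(self, channels_in: int, channels_out: int, rate: int,
                 rng: np.random.Generator | None = None):
        if rate < 1:
            raise ValueError("dilation rate must be >= 1")
        self.norm1 = InstanceNorm2d(channels_in)
        self.conv1 = Conv2d(channels_in, channels_out, 3, dilation=rate, rng=rng)
        self.norm2 = InstanceNorm2d(channels_out)
        self.conv2 = Conv2d(channels_out, channels_out, 3, dilation=rate, rng=rng)
        self.project = (
            None if channels_in == channels_out else Conv2d(channels_in, channels_out, 1, rng=rng)
        )
        self.rate = rate

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(self.norm1(x).relu())
        h = self.conv2(self.norm2(h).relu())
        skip = x if self.project is None else self.project(x)
        return skip + h

    def zero_residual(self) -> None:
        """Zero the convolutional branch, making the block the identity."""
        for conv in (self.conv1, self.conv2):
            conv.weight.data[...] = 0.0
            conv.bias.data[...] = 0.0


def residual_dilated_block(channels_in: int, channels_out: int, rate: int,
                           rng: np.random.Generator | None = None) -> ResidualDilatedBlock:
    """Build one residual dilated block (spatial size preserved)."""
    return ResidualDilatedBlock(channels_in, channels_out, rate, rng=rng)


class _MaxPool2(Module):
    """2x2 max pooling, only used when the config asks for classic pooling."""

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2)
        data = r.data.max(axis=(3, 5))
        mask = r.data == data[:, :, :, None, :, None]

        def backward(g):
            r._accumulate(np.broadcast_to(g[:, :, :, None, :, None], r.data.shape) * mask)

        out = Tensor(data)
        if r.requires_grad or r._prev:
            out.requires_grad = True
            out._prev = (r,)
            out._backward = backward
        return out


class RDUNet(Module):
    """The full encoder-decoder model."""

    def __init__(self, config: RDUNetConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        depth, base = config.depth, config.base_channels
        chans = [base * 2**i for i in range(depth)]

        self.enc_blocks: list[ResidualDilatedBlock] = []
        self.down: list[Module] = []
        in_ch = 1
        for i in range(depth):
            self.enc_blocks.append(
                residual_dilated_block(in_ch, chans[i], config.dilation_cycle[i], rng)
            )
            if i < depth - 1:
                if config.use_pooling:
                    self.down.append(_MaxPool2())
                    in_ch = chans[i]
                else:
                    self.down.append(Conv2d(chans[i], chans[i + 1], 3, stride=2, rng=rng))
                    in_ch = chans[i + 1]

        self.up: list[Conv2d] = []
        self.dec_blocks: list[ResidualDilatedBlock] = []
        for i in range(depth - 2, -1, -1):
            self.up.append(Conv2d(chans[i + 1], chans[i], 3, rng=rng))
            self.dec_blocks.append(
                residual_dilated_block(2 * chans[i], chans[i], config.dilation_cycle[i], rng)
            )
        self.head = Conv2d(chans[0], config.n_classes, 1, rng=rng)

    def _check_shape(self, h: int, w: int) -> None:
        factor = 2 ** (self.config.depth - 1)
        if h < factor or w < factor:
            raise ValueError(
                f"input {h}x{w} smaller than the network's minimum {factor}x{factor} "
                f"(depth {self.config.depth})"
            )
        if h % factor or w % factor:
            raise ValueError(
                f"input {h}x{w} must be a multiple of {factor} (depth {self.config.depth})"
            )

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        self._check_shape(h, w)
        skips: list[Tensor] = []
        depth = self.config.depth
        for i in range(depth):
            x = self.enc_blocks[i](x)
            if i < depth - 1:
                skips.append(x)
                x = self.down[i](x)
        for j, i in enumerate(range(depth - 2, -1, -1)):
            x = self.up[j](upsample_nearest2d(x, 2))
            x = concat([skips[i], x], axis=1)
            x = self.dec_blocks[j](x)
        return self.head(x)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def build_rdunet(config: RDUNetConfig, seed: int = 0) -> RDUNet:
    """Construct an RDU-Net with seeded He initialization."""
    return RDUNet(config, seed=seed)


def _prep_image(image: CTSlice | np.ndarray) -> np.ndarray:
    arr = image.pixels if isinstance(image, CTSlice) else np.asarray(image, dtype=np.float64)
    return (arr / 255.0 - 0.5)[None, None]


def train_segmenter(
    model: RDUNet,
    dataset: list[tuple[CTSlice | np.ndarray, LobeMask | np.ndarray]],
    epochs: int = 30,
    lr: float = 3e-3,
    seed: int = 0,
) -> tuple[RDUNet, list[float]]:
    """Train with per-pixel cross-entropy; returns the best-loss snapshot.

    One optimisation step per sample, sample order reshuffled each epoch
    from ``seed``; the recorded trace holds one mean loss per epoch.
    Deterministic for a fixed seed (pure NumPy, no threading nondeterminism).
    """
    if not dataset:
        raise ValueError("empty training dataset")
    rng = np.random.default_rng(seed)
    opt = Adam(model.parameters(), lr=lr)
    losses: list[float] = []
    best = (np.inf, model.state_dict())
    for _epoch in range(epochs):
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        for idx in order:
            image, mask = dataset[idx]
            labels = as_labels(mask)
            x = Tensor(_prep_image(image))
            logits = model(x)
            loss = softmax_cross_entropy(logits, labels[None])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
        epoch_loss /= len(dataset)
        losses.append(epoch_loss)
        if epoch_loss < best[0]:
            best = (epoch_loss, model.state_dict())
    model.load_state_dict(best[1])
    return model, losses


def segment_lobes(model: RDUNet, image: CTSlice | np.ndarray) -> LobeMask:
    """Per-pixel argmax segmentation of one slice."""
    logits = model(Tensor(_prep_image(image)))
    labels = np.argmax(logits.data[0], axis=0).astype(np.int32)
    table = LOBE_SCHEMES.get(model.config.lobe_scheme, {})
    table = {i: name for i, name in table.items() if i < model.config.n_classes}
    return LobeMask(labels=labels, lobe_table=table)


@dataclass
class LobeCrop:
    """Tight crop of one lobe with its origin offset in the parent image."""

    pixels: np.ndarray
    offset: tuple[int, int]  # (row, col) of crop origin


def extract_lobe_images(
    image: CTSlice | np.ndarray, lobe_mask: LobeMask | np.ndarray
) -> dict[int, LobeCrop]:
    """Crop each lobe to its bounding box, zeroing non-lobe pixels.

    Detections found in a crop can be mapped back through ``offset``.
    """
    arr = image.pixels if isinstance(image, CTSlice) else np.asarray(image, dtype=np.float64)
    labels = as_labels(lobe_mask)
    if arr.shape != labels.shape:
        raise ValueError(f"image {arr.shape} and mask {labels.shape} shapes differ")
    crops: dict[int, LobeCrop] = {}
    for lobe_id in np.unique(labels):
        if lobe_id == 0:
            continue
        sel = labels == lobe_id
        ys, xs = np.nonzero(sel)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        crop = np.where(sel[y0:y1, x0:x1], arr[y0:y1, x0:x1], 0.0)
        crops[int(lobe_id)] = LobeCrop(pixels=crop, offset=(int(y0), int(x0)))
    return crops


def dice_and_iou(
    pred: LobeMask | np.ndarray, truth: LobeMask | np.ndarray
) -> dict[int, dict[str, float]]:
    """Per-lobe IOU and Dice between predicted and true label images.

    Background is excluded; every lobe present in either mask is reported.
    """
    p = as_labels(pred)
    t = as_labels(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    scores: dict[int, dict[str, float]] = {}
    for lobe_id in sorted(set(np.unique(p)) | set(np.unique(t))):
        if lobe_id == 0:
            continue
        pm = p == lobe_id
        tm = t == lobe_id
        inter = float(np.sum(pm & tm))
        union = float(np.sum(pm | tm))
        denom = float(pm.sum() + tm.sum())
        scores[int(lobe_id)] = {
            "iou": inter / union if union else 0.0,
            "dice": 2.0 * inter / denom if denom else 0.0,
        }
    return scores


def save_checkpoint(model: RDUNet, path: str | os.PathLike) -> None:
    """Write weights as .npz with a JSON sidecar holding the config."""
    path = os.fspath(path)
    np.savez(path, **model.state_dict())
    sidecar = path + ".json" if not path.endswith(".npz") else path[:-4] + ".json"
    with open(sidecar, "w") as fh:
        json.dump(model.config.to_dict(), fh)


def load_checkpoint(path: str | os.PathLike) -> RDUNet:
    path = os.fspath(path)
    if not path.endswith(".npz"):
        path = path + ".npz"
    sidecar = path[:-4] + ".json"
    with open(sidecar) as fh:
        config = RDUNetConfig.from_dict(json.load(fh))
    model = build_rdunet(config)
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model
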