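"""U-Net style model: configurable encoder presets, skip concatenation, softmax head."""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from ctrkit.segmentation.nn import Adam, Conv2d, Layer, MaxPool2, ReLU, UpsampleNearest2, softmax

_VGG_CHANNELS = (64, 128, 256, 512, 512)
_VGG_CONVS = (2, 2, 3, 3, 3)

#: Class indices of the softmax head.
CLASS_BACKGROUND, CLASS_LUNG, CLASS_HEART = 0, 1, 2


@dataclass(frozen=True)
class UNetConfig:
    input_size: int = 64
    encoder_stages: int = 3
    base_channels: int = 8
    encoder_preset: str = "reduced"  # "reduced" | "vgg16_like"
    classes: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.classes < 2:
            raise ValueError("need at least 2 classes")
        if self.encoder_preset not in ("reduced", "vgg16_like"):
            raise ValueError(f"unknown encoder_preset {self.encoder_preset!r}")
        if self.encoder_stages < 1:
            raise ValueError("need at least one encoder stage")
        if self.encoder_preset == "vgg16_like" and self.encoder_stages > len(_VGG_CHANNELS):
            raise ValueError("vgg16_like supports at most 5 stages")
        if self.input_size % (2**self.encoder_stages) != 0:
            raise ValueError(
                f"input_size {self.input_size} not divisible by 2^{self.encoder_stages}"
            )

    def stage_channels(self) -> list[int]:
        if self.encoder_preset == "vgg16_like":
            return list(_VGG_CHANNELS[: self.encoder_stages])
        return [self.base_channels * 2**s for s in range(self.encoder_stages)]

    def stage_convs(self) -> list[int]:
        if self.encoder_preset == "vgg16_like":
            return list(_VGG_CONVS[: self.encoder_stages])
        return [2] * self.encoder_stages


@dataclass
class SegmentationOutput:
    lung_mask: np.ndarray  # bool (H, W)
    heart_mask: np.ndarray  # bool (H, W)
    scores: np.ndarray  # (classes, H, W) softmax probabilities


def _run(layers: list[Layer], x: np.ndarray) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x)
    return x


def _run_back(layers: list[Layer], d: np.ndarray) -> np.ndarray:
    for layer in reversed(layers):
        d = layer.backward(d)
    return d


class UNet:
    """Contraction path halves spatial dims per stage; expansion path restores
    them with nearest up-sampling, a 2x2 up-convolution, skip concatenation,
    and two 3x3 convolutions per decoder block."""

    def __init__(self, config: UNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        chans = config.stage_channels()
        convs = config.stage_convs()
        bottleneck_ch = min(chans[-1] * 2, 512 if config.encoder_preset == "vgg16_like" else 10**9)

        self.enc_blocks: list[list[Layer]] = []
        self.pools: list[MaxPool2] = []
        in_ch = 1
        for ch, n_conv in zip(chans, convs):
            block: list[Layer] = []
            for _ in range(n_conv):
                block += [Conv2d(in_ch, ch, 3, rng), ReLU()]
                in_ch = ch
            self.enc_blocks.append(block)
            self.pools.append(MaxPool2())

        self.bottleneck: list[Layer] = [
            Conv2d(in_ch, bottleneck_ch, 3, rng), ReLU(),
            Conv2d(bottleneck_ch, bottleneck_ch, 3, rng), ReLU(),
        ]
        in_ch = bottleneck_ch

        self.dec_blocks: list[dict] = []
        for ch in reversed(chans):
            self.dec_blocks.append(
                {
                    "up": UpsampleNearest2(),
                    "upconv": Conv2d(in_ch, ch, 2, rng),
                    "uprelu": ReLU(),
                    "convs": [
                        Conv2d(2 * ch, ch, 3, rng), ReLU(),
                        Conv2d(ch, ch, 3, rng), ReLU(),
                    ],
                    "skip_ch": ch,
                }
            )
            in_ch = ch
        self.head = Conv2d(in_ch, config.classes, 1, rng)

    # -- parameter plumbing -------------------------------------------------

    def _convs(self) -> list[tuple[str, Conv2d]]:
        named = []
        for i, block in enumerate(self.enc_blocks):
            named += [
                (f"enc{i}_conv{j}", l)
                for j, l in enumerate(x for x in block if isinstance(x, Conv2d))
            ]
        named += [
            (f"bottleneck_conv{j}", l)
            for j, l in enumerate(x for x in self.bottleneck if isinstance(x, Conv2d))
        ]
        for i, dec in enumerate(self.dec_blocks):
            named.append((f"dec{i}_upconv", dec["upconv"]))
            named += [
                (f"dec{i}_conv{j}", l)
                for j, l in enumerate(x for x in dec["convs"] if isinstance(x, Conv2d))
            ]
        named.append(("head", self.head))
        return named

    def params(self) -> dict[str, np.ndarray]:
        return {f"{n}.{k}": v for n, c in self._convs() for k, v in c.params().items()}

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{n}.{k}": v for n, c in self._convs() for k, v in c.grads().items()}

    def zero_grads(self) -> None:
        for _, conv in self._convs():
            conv.dw[...] = 0.0
            conv.db[...] = 0.0

    def parameter_count(self) -> int:
        return sum(conv.n_params() for _, conv in self._convs())

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batch of images (N, 1, H, W) -> logits (N, classes, H, W)."""
        if x.ndim != 4 or x.shape[2] != x.shape[3] or x.shape[2] != self.config.input_size:
            raise ValueError(
                f"expected (N, 1, {self.config.input_size}, {self.config.input_size}), "
                f"got {x.shape}"
            )
        skips = []
        for block, pool in zip(self.enc_blocks, self.pools):
            x = _run(block, x)
            skips.append(x)
            x = pool.forward(x)
        x = _run(self.bottleneck, x)
        for dec, skip in zip(self.dec_blocks, reversed(skips)):
            x = dec["up"].forward(x)
            x = dec["uprelu"].forward(dec["upconv"].forward(x))
            x = np.concatenate([skip, x], axis=1)
            x = _run(dec["convs"], x)
        return self.head.forward(x)

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits)
        dskips = []
        for dec in reversed(self.dec_blocks):
            d = _run_back(dec["convs"], d)
            ch = dec["skip_ch"]
            dskip, d = d[:, :ch], d[:, ch:]
            dskips.append(dskip)
            d = dec["upconv"].backward(dec["uprelu"].backward(d))
            d = dec["up"].backward(d)
        d = _run_back(self.bottleneck, d)
        for block, pool, dskip in zip(
            reversed(self.enc_blocks), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d)
            d = _run_back(block, d + dskip)
        # d is now the gradient w.r.t. the input image; discarded

    def make_optimizer(self, lr: float) -> Adam:
        return Adam(self.params(), lr=lr)


def build_model(config: UNetConfig) -> UNet:
    """Construct a seeded, untrained network from its configuration."""
    return UNet(config)


def predict(model: UNet, image: np.ndarray) -> SegmentationOutput:
    """Segment one grayscale image; masks by per-pixel argmax of the scores."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if image.shape != (model.config.input_size, model.config.input_size):
        raise ValueError(
            f"image shape {image.shape} does not match configured input size "
            f"{model.config.input_size}"
        )
    logits = model.forward(image[None, None])
    scores = softmax(logits)[0]
    labels = scores.argmax(axis=0)
    return SegmentationOutput(
        lung_mask=labels == CLASS_LUNG,
        heart_mask=labels == CLASS_HEART,
        scores=scores,
    )


def save_checkpoint(model: UNet, path) -> None:
    """Self-describing checkpoint: config JSON plus all weight tensors."""
    arrays = {f"param/{k}": v for k, v in model.params().items()}
    np.savez(path, config=json.dumps(asdict(model.config)), **arrays)


def load_checkpoint(path) -> UNet:
    with np.load(path, allow_pickle=False) as data:
        config = UNetConfig(**json.loads(str(data["config"])))
        model = UNet(config)
        params = model.params()
        for key in data.files:
            if key.startswith("param/"):
                params[key[len("param/"):]][...] = data[key]
    return model
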