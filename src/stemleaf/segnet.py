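"""Segmentation network assembly and training.

The architecture is a U-shaped encoder/decoder: a VGG16 convolutional
encoder (the 13 conv layers; fully connected layers omitted), an optional
re-tuned ASPP bridge between encoder and decoder, a decoder made of four
up-concatenation stages (x2 bilinear upsample, skip concatenation, two
3x3 convs) and an optional criss-cross attention block after each decoder
stage, followed by a 1x1 conv head and per-pixel softmax.

The "baseline" variant (ASPP and CCA disabled) has exactly 24,891,267
trainable parameters at full width with 3 classes.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from . import losses
from .dilation import validate_rates
from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Module,
    Parameter,
    Tensor,
    as_tensor,
    concatenate,
    relu,
    softmax,
    upsample_bilinear2x,
    maxpool2x2,
)
from .nn.autograd import _criss_cross_core, cca_attention

__all__ = [
    "AttentionCCA",
    "AsppBridge",
    "NetworkConfig",
    "SegmentationModel",
    "build_acunet",
    "build_aspp",
    "build_cca",
    "count_parameters",
    "load_vgg16_weights",
    "predict",
    "train",
]

VGG16_WIDTHS = (64, 64, 128, 128, 256, 256, 256, 512, 512, 512, 512, 512, 512)
VGG16_BLOCKS = ((64, 64), (128, 128), (256, 256, 256), (512, 512, 512), (512, 512, 512))
DECODER_WIDTHS = (512, 256, 128, 64)


@dataclass(frozen=True)
class NetworkConfig:
    """Hyper-structure of the segmentation network.

    ``width_scale`` shrinks every channel width proportionally (toy/CPU
    configs); ``encoder_blocks`` truncates the encoder to its first N
    blocks.  Neither changes the architecture pattern.
    """

    num_classes: int = 3
    input_size: int = 512
    decoder_widths: tuple[int, ...] = DECODER_WIDTHS
    aspp_rates: tuple[int, ...] = (1, 2, 7, 15)
    aspp_width: int = 256
    cca_recurrence: int = 2
    cca_reduction: int = 8
    use_aspp: bool = True
    use_cca: bool = True
    use_pretrained_encoder: bool = False
    width_scale: float = 1.0
    encoder_blocks: int = 5
    feature_norm: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.num_classes < 2:
            raise ValueError("need at least 2 classes")
        down = 2 ** (self.encoder_blocks - 1)
        if self.input_size % down != 0:
            raise ValueError(
                f"input size {self.input_size} not divisible by {down} "
                f"({self.encoder_blocks - 1} downsamplings reach the bridge)"
            )
        if not (1 <= self.encoder_blocks <= 5):
            raise ValueError("encoder_blocks must be in 1..5")
        if self.use_aspp:
            verdict = validate_rates(3, tuple(self.aspp_rates))
            if verdict != "valid":
                raise ValueError(f"ASPP rates {self.aspp_rates} rejected: {verdict}")

    def scaled(self, width: int) -> int:
        return max(8, int(round(width * self.width_scale)))

    def encoder_layout(self) -> tuple[tuple[int, ...], ...]:
        return tuple(
            tuple(self.scaled(w) for w in block)
            for block in VGG16_BLOCKS[: self.encoder_blocks]
        )

    def decoder_layout(self) -> tuple[int, ...]:
        widths = DECODER_WIDTHS[len(DECODER_WIDTHS) - (self.encoder_blocks - 1) :]
        return tuple(self.scaled(w) for w in widths)

    def as_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["decoder_widths"] = list(d["decoder_widths"])
        d["aspp_rates"] = list(d["aspp_rates"])
        return d


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------


class AsppBridge(Module):
    """Parallel multi-rate dilated-conv block with image-level pooling.

    Branches: a 1x1 conv (the rate-1 entry), one same-padded 3x3 dilated
    conv per remaining rate, and global average pooling -> 1x1 conv ->
    broadcast upsample.  Branch outputs are concatenated and projected by
    a 1x1 conv + batch norm to ``width`` channels.
    """

    def __init__(self, in_channels: int, rates, width: int, rng=None):
        super().__init__()
        if in_channels < 1:
            raise ValueError("in_channels must be >= 1")
        rates = tuple(int(r) for r in rates)
        verdict = validate_rates(3, rates)
        if verdict != "valid":
            raise ValueError(f"dilation schedule {rates} rejected: {verdict}")
        self.rates = rates
        self.width = width
        conv_rates = [r for r in rates if r != 1]
        self.point_branch = Conv2d(in_channels, width, kernel_size=1, rng=rng)
        self.point_bn = BatchNorm2d(width)
        self.dilated = [
            Conv2d(in_channels, width, kernel_size=3, dilation=r, rng=rng)
            for r in conv_rates
        ]
        self.dilated_bn = [BatchNorm2d(width) for _ in conv_rates]
        self.pool_conv = Conv2d(in_channels, width, kernel_size=1, rng=rng)
        self.project = Conv2d(width * (len(conv_rates) + 2), width, kernel_size=1, rng=rng)
        self.project_bn = BatchNorm2d(width)

    @property
    def branch_count(self) -> int:
        return len(self.dilated) + 2  # 1x1 + dilated convs + pooling branch

    def forward(self, x):
        b, _, h, w = x.shape
        branches = [relu(self.point_bn(self.point_branch(x)))]
        for conv, bn in zip(self.dilated, self.dilated_bn):
            branches.append(relu(bn(conv(x))))
        pooled = x.mean(axis=(2, 3), keepdims=True)
        pooled = relu(self.pool_conv(pooled))
        branches.append(pooled.broadcast_to((b, self.width, h, w)))
        fused = concatenate(branches, axis=1)
        return relu(self.project_bn(self.project(fused)))


class AttentionCCA(Module):
    """Criss-cross attention: each position attends to the H+W-1 positions
    in its row and column; the pass is repeated ``recurrence`` times with
    shared parameters so information propagates across the full image."""

    def __init__(self, channels: int, recurrence: int = 2, reduction: int = 8, rng=None):
        super().__init__()
        if channels % reduction != 0:
            raise ValueError(
                f"channels ({channels}) must be divisible by reduction ({reduction})"
            )
        self.channels = channels
        self.recurrence = recurrence
        inner = channels // reduction
        self.query = Conv2d(channels, inner, kernel_size=1, bias=False, rng=rng)
        self.key = Conv2d(channels, inner, kernel_size=1, bias=False, rng=rng)
        self.value = Conv2d(channels, channels, kernel_size=1, bias=False, rng=rng)
        self.gamma = Parameter(np.asarray([0.5], dtype=np.float32))

    def attention_weights(self, x) -> np.ndarray:
        """(B, H, W, W+H) attention distribution of one pass (diagnostic).

        The first W entries are the row weights, the last H the column
        weights; each position's distribution sums to 1.
        """
        x = as_tensor(x)
        q, k, v = self.query(x), self.key(x), self.value(x)
        _, ar, ac, _, _ = _criss_cross_core(q.data, k.data, v.data, mask=-30.0)
        return np.concatenate([ar, ac.transpose(0, 2, 1, 3)], axis=3)

    def _pass(self, x):
        q, k, v = self.query(x), self.key(x), self.value(x)
        agg = cca_attention(q, k, v)
        return x + self.gamma.reshape(1, 1, 1, 1) * agg

    def forward(self, x):
        for _ in range(self.recurrence):
            x = self._pass(x)
        return x


def build_aspp(in_channels: int, rates, width: int, rng=None) -> AsppBridge:
    return AsppBridge(in_channels, rates, width, rng=rng)


def build_cca(channels: int, recurrence: int = 2, reduction: int = 8, rng=None) -> AttentionCCA:
    return AttentionCCA(channels, recurrence=recurrence, reduction=reduction, rng=rng)


def _instance_standardize(x):
    """Parameter-free per-sample, per-channel standardization.

    Training-stability aid for from-scratch runs (the published setup
    relies on a pretrained encoder): keeps deep features well-scaled so
    the softmax head cannot saturate to the majority class before the
    colour features form.  Adds no trainable parameters.
    """
    mu = x.mean(axis=(2, 3), keepdims=True)
    var = ((x - mu) ** 2.0).mean(axis=(2, 3), keepdims=True)
    return (x - mu) * ((var + 1e-5) ** -0.5)


class _EncoderBlock(Module):
    def __init__(self, in_channels: int, widths, rng=None, norm: bool = False):
        super().__init__()
        self.norm = norm
        self.convs = []
        for w in widths:
            self.convs.append(Conv2d(in_channels, w, kernel_size=3, rng=rng))
            in_channels = w
        self.out_channels = in_channels

    def forward(self, x):
        for conv in self.convs:
            x = relu(conv(x))
            if self.norm:
                x = _instance_standardize(x)
        return x


class _DecoderStage(Module):
    def __init__(self, in_channels: int, skip_channels: int, width: int, rng=None, norm: bool = False):
        super().__init__()
        self.norm = norm
        self.conv1 = Conv2d(in_channels + skip_channels, width, kernel_size=3, rng=rng)
        self.conv2 = Conv2d(width, width, kernel_size=3, rng=rng)
        self.out_channels = width

    def forward(self, x, skip):
        x = upsample_bilinear2x(x)
        x = concatenate([x, skip], axis=1)
        x = relu(self.conv1(x))
        x = relu(self.conv2(x))
        return _instance_standardize(x) if self.norm else x


class SegmentationModel(Module):
    """Encoder / optional ASPP bridge / decoder with optional CCA, softmax head."""

    def __init__(self, config: NetworkConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        enc_layout = config.encoder_layout()
        self.encoder_blocks = []
        in_ch = 3
        skip_channels = []
        for widths in enc_layout:
            block = _EncoderBlock(in_ch, widths, rng=rng, norm=config.feature_norm)
            self.encoder_blocks.append(block)
            skip_channels.append(block.out_channels)
            in_ch = block.out_channels

        bridge_ch = in_ch
        if config.use_aspp:
            self.aspp = build_aspp(bridge_ch, config.aspp_rates, config.scaled(config.aspp_width), rng=rng)
            # project back to the encoder width so the decoder matches baseline
            self.aspp_out = Conv2d(config.scaled(config.aspp_width), bridge_ch, kernel_size=1, rng=rng)
        else:
            self.aspp = None
            self.aspp_out = None

        self.decoder_stages = []
        self.cca_blocks = []
        dec_widths = config.decoder_layout()
        x_ch = bridge_ch
        for width, skip_ch in zip(dec_widths, reversed(skip_channels[:-1])):
            stage = _DecoderStage(x_ch, skip_ch, width, rng=rng, norm=config.feature_norm)
            self.decoder_stages.append(stage)
            if config.use_cca:
                self.cca_blocks.append(
                    build_cca(width, config.cca_recurrence, config.cca_reduction, rng=rng)
                )
            x_ch = width
        self.head = Conv2d(x_ch, config.num_classes, kernel_size=1, rng=rng)

    def forward(self, x):
        skips = []
        for i, block in enumerate(self.encoder_blocks):
            if i > 0:
                x = maxpool2x2(x)
            x = block(x)
            skips.append(x)
        if self.aspp is not None:
            x = relu(self.aspp_out(self.aspp(x)))
        for i, stage in enumerate(self.decoder_stages):
            x = stage(x, skips[-(i + 2)])
            if self.cca_blocks:
                x = self.cca_blocks[i](x)
        return softmax(self.head(x), axis=1)


def build_acunet(config: NetworkConfig | None = None, **overrides) -> SegmentationModel:
    """Build the full attention/ASPP network (or a variant via config flags)."""
    if config is None:
        config = NetworkConfig(**overrides)
    elif overrides:
        from dataclasses import replace

        config = replace(config, **overrides)
    return SegmentationModel(config)


def count_parameters(model: Module) -> int:
    """Exact number of trainable scalars."""
    return int(sum(p.data.size for p in model.parameters()))


# ---------------------------------------------------------------------------
# VGG16 checkpoint interop
# ---------------------------------------------------------------------------

# conv layer indices inside torchvision's vgg16 "features" Sequential
_VGG16_FEATURE_IDX = (0, 2, 5, 7, 10, 12, 14, 17, 19, 21, 24, 26, 28)


def load_vgg16_weights(model: SegmentationModel, state: dict) -> None:
    """Copy standard VGG16 convolutional weights into the encoder.

    ``state`` maps names like ``features.0.weight`` / ``features.0.bias``
    (torchvision layout) to arrays of shape (Cout, Cin, 3, 3) / (Cout,).
    Requires a full-width, untruncated encoder.
    """
    convs = [c for block in model.encoder_blocks for c in block.convs]
    if len(convs) != len(_VGG16_FEATURE_IDX):
        raise ValueError("encoder is truncated; cannot map a full VGG16 checkpoint")
    for conv, idx in zip(convs, _VGG16_FEATURE_IDX):
        w = np.asarray(state[f"features.{idx}.weight"], dtype=np.float32)
        b = np.asarray(state[f"features.{idx}.bias"], dtype=np.float32)
        if w.shape != conv.weight.data.shape or b.shape != conv.bias.data.shape:
            raise ValueError(
                f"checkpoint tensor features.{idx} has shape {w.shape}, "
                f"expected {conv.weight.data.shape}"
            )
        conv.weight.data = w.copy()
        conv.bias.data = b.copy()


# ---------------------------------------------------------------------------
# inference / training
# ---------------------------------------------------------------------------


def predict(model: SegmentationModel, image: np.ndarray) -> np.ndarray:
    """Forward one H x W x 3 image (uint8 or float [0,1]) -> H x W x C probs."""
    image = np.asarray(image)
    if image.dtype.kind in "iu":
        image = image.astype(np.float32) / 255.0
    x = Tensor(image.astype(np.float32).transpose(2, 0, 1)[None])
    was_training = model.training
    model.eval()
    probs = model(x).data[0].transpose(1, 2, 0)
    model.train(was_training)
    return probs


@dataclass
class TrainResult:
    history: list = field(default_factory=list)

    @property
    def train_losses(self) -> list[float]:
        return [h["train_loss"] for h in self.history]


def train(
    model: SegmentationModel,
    images: np.ndarray,
    masks: np.ndarray,
    epochs: int = 10,
    batch_size: int = 4,
    lr: float = 1e-3,
    loss: str = "dice_boundary",
    boundary_weight: float = 1.0,
    val: tuple[np.ndarray, np.ndarray] | None = None,
    seed: int = 0,
    log=None,
) -> TrainResult:
    """Adam training loop; one epoch = full traversal of the training set.

    ``images``: (N, H, W, 3) float [0,1]; ``masks``: (N, H, W) ints in
    0..C-1.  Records per-epoch mean train loss (and val loss when a
    validation pair is given).
    """
    if len(images) == 0:
        raise ValueError("empty dataset")
    if images.shape[:3] != masks.shape:
        raise ValueError("image/mask shape mismatch")
    if loss not in ("dice", "boundary", "dice_boundary"):
        raise ValueError(f"unknown loss {loss!r}")
    nclasses = model.config.num_classes
    if masks.min() < 0 or masks.max() >= nclasses:
        raise ValueError("mask values out of class range")

    x_all = images.astype(np.float32).transpose(0, 3, 1, 2)
    onehot_all = np.eye(nclasses, dtype=np.float32)[masks].transpose(0, 3, 1, 2)
    need_phi = loss in ("boundary", "dice_boundary")
    phi_all = (
        np.stack([losses.distance_maps(m, nclasses) for m in masks]).astype(np.float32)
        if need_phi
        else None
    )

    optimizer = Adam(model.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    result = TrainResult()
    n = len(images)
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(n)
        epoch_losses = []
        t0 = time.time()
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb = Tensor(x_all[idx])
            probs = model(xb)
            if loss == "dice":
                batch_loss = losses.dice_loss_t(probs, onehot_all[idx])
            elif loss == "boundary":
                batch_loss = losses.boundary_loss_t(probs, phi_all[idx])
            else:
                batch_loss = losses.dice_boundary_loss_t(
                    probs, onehot_all[idx], phi_all[idx], weight=boundary_weight
                )
            optimizer.zero_grad()
            batch_loss.backward()
            optimizer.step()
            epoch_losses.append(batch_loss.item())
        entry = {
            "epoch": epoch + 1,
            "train_loss": float(np.mean(epoch_losses)),
            "median_train_loss": float(np.median(epoch_losses)),
            "seconds": round(time.time() - t0, 3),
        }
        if val is not None:
            entry["val_loss"] = evaluate_loss(
                model, val[0], val[1], loss=loss, boundary_weight=boundary_weight
            )
        result.history.append(entry)
        if log is not None:
            log(
                "epoch=%d train_loss=%.6f%s"
                % (
                    entry["epoch"],
                    entry["train_loss"],
                    f" val_loss={entry['val_loss']:.6f}" if "val_loss" in entry else "",
                )
            )
    return result


def evaluate_loss(
    model: SegmentationModel,
    images: np.ndarray,
    masks: np.ndarray,
    loss: str = "dice_boundary",
    boundary_weight: float = 1.0,
) -> float:
    nclasses = model.config.num_classes
    model.eval()
    total = []
    for img, mask in zip(images, masks):
        probs = Tensor(img.astype(np.float32).transpose(2, 0, 1)[None])
        probs = model(probs)
        onehot = np.eye(nclasses, dtype=np.float32)[mask].transpose(2, 0, 1)[None]
        if loss == "dice":
            value = losses.dice_loss_t(probs, onehot)
        elif loss == "boundary":
            value = losses.boundary_loss_t(
                probs, losses.distance_maps(mask, nclasses)[None].astype(np.float32)
            )
        else:
            value = losses.dice_boundary_loss_t(
                probs,
                onehot,
                losses.distance_maps(mask, nclasses)[None].astype(np.float32),
                weight=boundary_weight,
            )
        total.append(value.item())
    model.train()
    return float(np.mean(total))
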