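"""U-Net left-ventricle segmentation with Dice loss and ROI cropping.

The network has five encoder and five decoder blocks.  Each block is
conv3x3 -> BN -> ReLU -> conv3x3 -> BN -> ReLU -> dropout(0.1); the encoder
downsamples with 2x2 max pooling (stride 2) and doubles the channel count
from 8 up to 128, the decoder upsamples with 2x2 transposed convolutions,
halves the channels back down to 8 and concatenates the mirrored encoder
activation (skip connection).  Kernels are He-Normal initialized.  A final
1x1 convolution produces per-pixel class scores (background / cavity /
myocardium by default) trained with soft multi-class Dice loss under Adam.

The "perfect ROI" protocol crops the input to a margin-padded bounding box
of the reference mask before segmentation — an upper-bound evaluation setup
where localization error is removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cardiopcso._nnops import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2,
    Dropout,
    MaxPool2,
    ReLU,
    conv_output_size,
    softmax_channels,
)
from cardiopcso.synthetic import PhantomPair

__all__ = [
    "UNetSpec",
    "UNet",
    "RoiBox",
    "encoder_channels",
    "build_unet",
    "dice_score",
    "dice_loss",
    "roi_crop",
    "train_unet",
    "predict_mask",
]


@dataclass
class UNetSpec:
    depth: int = 5
    base_channels: int = 8
    max_channels: int = 128
    in_channels: int = 1
    n_classes: int = 3
    kernel: int = 3
    dropout: float = 0.1
    batch_norm: bool = True
    padding: str = "same"
    seed: int = 0

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {self.padding!r}")


def encoder_channels(spec: UNetSpec) -> list[int]:
    """Channel count per encoder level: min(base * 2^level, max)."""
    return [min(spec.base_channels * 2**level, spec.max_channels) for level in range(spec.depth)]


class _Block:
    """conv -> BN -> ReLU -> conv -> BN -> ReLU -> dropout."""

    def __init__(self, c_in, c_out, spec: UNetSpec, rng):
        self.layers = []
        self.conv1 = Conv2d(c_in, c_out, spec.kernel, spec.padding, rng)
        self.conv2 = Conv2d(c_out, c_out, spec.kernel, spec.padding, rng)
        self.bn1 = BatchNorm2d(c_out) if spec.batch_norm else None
        self.bn2 = BatchNorm2d(c_out) if spec.batch_norm else None
        self.relu1, self.relu2 = ReLU(), ReLU()
        self.drop = Dropout(spec.dropout)

    def forward(self, x, train, rng):
        x = self.conv1.forward(x, train)
        if self.bn1 is not None:
            x = self.bn1.forward(x, train)
        x = self.relu1.forward(x, train)
        x = self.conv2.forward(x, train)
        if self.bn2 is not None:
            x = self.bn2.forward(x, train)
        x = self.relu2.forward(x, train)
        return self.drop.forward(x, train, rng)

    def backward(self, d):
        d = self.drop.backward(d)
        d = self.relu2.backward(d)
        if self.bn2 is not None:
            d = self.bn2.backward(d)
        d = self.conv2.backward(d)
        d = self.relu1.backward(d)
        if self.bn1 is not None:
            d = self.bn1.backward(d)
        return self.conv1.backward(d)

    def param_refs(self):
        refs = [(self.conv1, "W"), (self.conv1, "b"), (self.conv2, "W"), (self.conv2, "b")]
        for bn in (self.bn1, self.bn2):
            if bn is not None:
                refs += [(bn, "gamma"), (bn, "beta")]
        return refs


class UNet:
    """Symmetric encoder/decoder with skip concatenation; see module docstring."""

    def __init__(self, spec: UNetSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        chans = encoder_channels(spec)
        self.enc = []
        c_in = spec.in_channels
        for c in chans:
            self.enc.append(_Block(c_in, c, spec, rng))
            c_in = c
        self.pools = [MaxPool2() for _ in range(spec.depth - 1)]
        self.ups = []
        self.dec = []
        for level in range(spec.depth - 2, -1, -1):
            c_up = chans[level]
            self.ups.append(ConvTranspose2(c_in, c_up, rng))
            self.dec.append(_Block(c_up * 2, c_up, spec, rng))
            c_in = c_up
        self.head = Conv2d(c_in, spec.n_classes, k=1, padding="same", rng=rng)

    # -- plumbing ----------------------------------------------------------
    def _check_size(self, H, W):
        div = 2 ** (self.spec.depth - 1)
        if self.spec.padding == "valid":
            # valid padding shrinks each level by (k-1) per conv; the size
            # bookkeeping only works out for specially chosen inputs
            n = H
            for _ in range(self.spec.depth - 1):
                n = conv_output_size(conv_output_size(n, self.spec.kernel, "valid"),
                                     self.spec.kernel, "valid")
                if n < 2 or n % 2:
                    raise ValueError(
                        f"input size {H} is incompatible with valid padding at depth "
                        f"{self.spec.depth}; choose a size whose per-level shrinkage "
                        f"stays even (classic U-Net input arithmetic)"
                    )
                n //= 2
            raise NotImplementedError(
                "valid-padding U-Net requires cropped skip connections; "
                "use padding='same'"
            )
        if H % div or W % div:
            raise ValueError(f"input size {H}x{W} must be divisible by {div}")

    def forward(self, x, train=False, rng=None):
        """x: (N, C, H, W) -> per-pixel class scores (N, n_classes, H, W)."""
        N, C, H, W = x.shape
        self._check_size(H, W)
        skips = []
        h = x
        for level, block in enumerate(self.enc):
            h = block.forward(h, train, rng)
            if level < self.spec.depth - 1:
                skips.append(h)
                h = self.pools[level].forward(h, train)
        self._skip_channels = [s.shape[1] for s in skips]
        for i, (up, block) in enumerate(zip(self.ups, self.dec)):
            h = up.forward(h, train)
            skip = skips[-(i + 1)]
            h = np.concatenate([skip, h], axis=1)
            h = block.forward(h, train, rng)
        return self.head.forward(h, train)

    def backward(self, dscores):
        d = self.head.backward(dscores)
        dskips = []
        for i in range(len(self.dec) - 1, -1, -1):
            d = self.dec[i].backward(d)
            c_skip = self._skip_channels[-(i + 1)]
            dskips.append(d[:, :c_skip])
            d = self.ups[i].backward(d[:, c_skip:])
        # loop ran shallowest-first, so dskips[level] already pairs with enc level
        for level in range(self.spec.depth - 1, -1, -1):
            if level < self.spec.depth - 1:
                d = self.pools[level].backward(d)
                d = d + dskips[level]
            d = self.enc[level].backward(d)
        return d

    def param_refs(self):
        refs = []
        for b in self.enc:
            refs += b.param_refs()
        for up in self.ups:
            refs += [(up, "W"), (up, "b")]
        for b in self.dec:
            refs += b.param_refs()
        refs += [(self.head, "W"), (self.head, "b")]
        return refs

    def n_params(self) -> int:
        return sum(getattr(l, a).size for l, a in self.param_refs())


def build_unet(spec: UNetSpec) -> UNet:
    return UNet(spec)


def dice_score(pred_mask, true_mask, class_id: int = 1) -> float:
    """Hard Dice 2|A n B| / (|A| + |B|); 1.0 when both masks are empty."""
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError("shape mismatch")
    a = pred_mask == class_id
    b = true_mask == class_id
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (a & b).sum() / denom)


def dice_loss(scores: np.ndarray, true_mask: np.ndarray, foreground_only: bool = True):
    """Soft Dice loss and its gradient with respect to the class scores.

    ``scores`` is (N, n_classes, H, W); the loss is 1 minus the soft Dice
    averaged over foreground classes (all classes if ``foreground_only`` is
    False), with per-class Dice computed over the pooled batch pixels.
    Returns ``(loss, dscores)``.
    """
    probs = softmax_channels(scores)
    n_classes = scores.shape[1]
    classes = range(1, n_classes) if foreground_only and n_classes > 1 else range(n_classes)
    classes = list(classes)
    onehot = np.stack([(true_mask == c).astype(float) for c in range(n_classes)], axis=1)
    dprobs = np.zeros_like(probs)
    total = 0.0
    for c in classes:
        p, t = probs[:, c], onehot[:, c]
        inter = (p * t).sum()
        s = p.sum() + t.sum()
        if s == 0:
            total += 1.0
            continue
        total += 2.0 * inter / s
        # d(dice)/dp = (2 t s - 2 inter) / s^2 ; loss is 1 - mean(dice)
        dprobs[:, c] = -(2.0 * t * s - 2.0 * inter) / (s**2) / len(classes)
    loss = 1.0 - total / len(classes)
    # softmax backward
    dot = (dprobs * probs).sum(axis=1, keepdims=True)
    dscores = probs * (dprobs - dot)
    return loss, dscores


@dataclass
class RoiBox:
    """Half-open row/col bounds of a crop window, with paste-back support."""

    r0: int
    r1: int
    c0: int
    c1: int
    margin: int = 0
    full_shape: tuple = field(default=None)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.r1 - self.r0, self.c1 - self.c0)

    def crop(self, arr: np.ndarray) -> np.ndarray:
        return arr[self.r0 : self.r1, self.c0 : self.c1]

    def paste(self, patch: np.ndarray, fill=0) -> np.ndarray:
        if self.full_shape is None:
            raise ValueError("RoiBox has no recorded full shape")
        out = np.full(self.full_shape, fill, dtype=patch.dtype)
        out[self.r0 : self.r1, self.c0 : self.c1] = patch
        return out


def _grow_to_multiple(lo: int, hi: int, limit: int, multiple: int) -> tuple[int, int]:
    length = hi - lo
    target = int(np.ceil(length / multiple)) * multiple
    if target > limit:
        raise ValueError(f"cannot pad crop to a multiple of {multiple} within size {limit}")
    extra = target - length
    lo = max(0, lo - extra // 2)
    hi = min(limit, lo + target)
    lo = hi - target
    return lo, hi


def roi_crop(
    image: np.ndarray,
    reference_mask: np.ndarray,
    margin: int = 8,
    multiple: int | None = None,
) -> tuple[np.ndarray, RoiBox]:
    """Crop to the reference mask's bounding box expanded by ``margin``.

    With ``multiple`` set (e.g. 2**(depth-1)), the box is symmetrically
    grown inside the image until its sides are divisible, so the crop can
    enter the U-Net directly.  Returns the crop and the invertible box.
    """
    image = np.asarray(image)
    mask = np.asarray(reference_mask)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("reference mask is empty")
    r0 = max(0, rows[0] - margin)
    r1 = min(image.shape[0], rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(image.shape[1], cols[-1] + 1 + margin)
    if multiple:
        r0, r1 = _grow_to_multiple(r0, r1, image.shape[0], multiple)
        c0, c1 = _grow_to_multiple(c0, c1, image.shape[1], multiple)
    box = RoiBox(int(r0), int(r1), int(c0), int(c1), margin, image.shape)
    return box.crop(image), box


def _stack(pairs: list[PhantomPair]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([p.image for p in pairs])[:, None, :, :].astype(float)
    Y = np.stack([p.mask for p in pairs])
    return X, Y


def train_unet(
    spec: UNetSpec,
    pairs: list[PhantomPair],
    epochs: int = 20,
    lr: float = 1e-3,
    batch_size: int = 4,
    seed: int = 0,
    val_pairs: list[PhantomPair] | None = None,
) -> tuple[UNet, dict]:
    """Adam training on soft Dice loss; returns the model and a history dict
    with per-epoch mean training loss (and validation Dice when given).
    """
    if len(pairs) < 8:
        raise ValueError("need at least 8 training pairs")
    model = UNet(spec)
    rng = np.random.default_rng(seed)
    opt = Adam(model.param_refs(), lr=lr)
    X, Y = _stack(pairs)
    history = {"loss": [], "val_dice": []}
    for epoch in range(epochs):
        order = rng.permutation(len(X))
        losses = []
        for start in range(0, len(X), batch_size):
            idx = order[start : start + batch_size]
            scores = model.forward(X[idx], train=True, rng=rng)
            loss, dscores = dice_loss(scores, Y[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged (non-finite loss) at epoch {epoch}")
            model.backward(dscores)
            opt.step()
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        if val_pairs:
            dices = [
                np.mean(
                    [
                        dice_score(predict_mask(model, p.image), p.mask, c)
                        for c in range(1, spec.n_classes)
                    ]
                )
                for p in val_pairs
            ]
            history["val_dice"].append(float(np.mean(dices)))
    return model, history


def predict_mask(model: UNet, image: np.ndarray) -> np.ndarray:
    """Per-pixel argmax class prediction for a single 2-D image."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    scores = model.forward(image[None, None], train=False)
    return scores[0].argmax(axis=0)


def evaluate_pairs(model: UNet, pairs: list[PhantomPair], n_classes: int = 3) -> dict:
    """Per-image Dice/IoU for each foreground class plus means."""
    from cardiopcso.metrics import iou as iou_fn

    rows = []
    for p in pairs:
        pred = predict_mask(model, p.image)
        row = {}
        for c in range(1, n_classes):
            row[f"dice_{c}"] = dice_score(pred, p.mask, c)
            row[f"iou_{c}"] = iou_fn(pred, p.mask, c)
        rows.append(row)
    mean = {k: float(np.mean([r[k] for r in rows])) for k in rows[0]} if rows else {}
    mean["mean_dice"] = float(np.mean([v for k, v in mean.items() if k.startswith("dice")]))
    return {"per_image": rows, "mean": mean}
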