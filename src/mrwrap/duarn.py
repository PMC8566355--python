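"""DUARN: Dual U-net Artifact Reduction Network.

Two U-nets run in sequence. Phase 1 (artifact estimation) maps the
artifacted image to a per-pixel probability that the pixel lies in the
wrapped (corrupted) region, trained with binary cross-entropy against the
simulated artifact mask. Phase 2 (deep elimination) takes the artifacted
image concatenated with the phase-1 probability map and outputs the
restored image, trained with the composite loss

    L = a · (masked MSE) + b · BCE,      a + b = 1, defaults a=0.75, b=0.25

where the per-pixel squared error is gated by the binarized phase-1 mask
P1 (so errors outside the artifact area get a small weight) and the BCE
term runs over all pixels to penalize boundary misalignment.

Each U-net has a 3×3 stem, four 2×2 stride-2 encoder stages and four 2×2
transposed-convolution decoder stages (each conv followed by feature
normalization and ReLU), skip connections at matching resolutions merged by
concatenation plus a 3×3 fusing convolution, and a final 1×1 convolution
to a single channel. Full-scale channel widths are (64, 128, 256, 512);
the default here is the scaled-down (8, 16, 32, 64) variant that trains
on a CPU.

The restorer's 1×1 head is zero-initialized and its output is added to
the logit of the input image before the sigmoid, so the untrained network
is exactly the identity map and training only has to learn the correction
inside the artifact region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import rotate as _nd_rotate

from . import nn
from .simulator import SimulationSample

__all__ = [
    "UNetConfig",
    "LossWeights",
    "TrainConfig",
    "MaskEstimate",
    "UNet",
    "TrainedModel",
    "bce_loss",
    "masked_mse_loss",
    "duarn_loss",
    "train_phase1",
    "train_phase2",
    "reduce_artifact",
    "dice_coefficient",
    "mask_iou",
    "save_model",
    "load_model",
]

BCE_EPS = 1e-7

# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class UNetConfig:
    """Architecture of one U-net.

    ``widths`` are the channel counts of the four scales; the full-scale
    network uses (64, 128, 256, 512). Input height and width must be
    divisible by 16 (four halvings).
    """

    in_channels: int = 1
    widths: tuple[int, int, int, int] = (8, 16, 32, 64)
    residual_input: bool = False  # add logit(input ch. 0) before the sigmoid

    def validate(self) -> None:
        if self.in_channels < 1:
            raise ValueError(f"in_channels must be >= 1, got {self.in_channels}")
        if len(self.widths) != 4 or any(w < 1 for w in self.widths):
            raise ValueError(f"widths must be 4 positive ints, got {self.widths}")


@dataclass(frozen=True)
class LossWeights:
    """Weights of the composite loss; a + b = 1.

    Both weights are small positive numbers in normal use (defaults
    a=0.75, b=0.25); the boundary values a=0 / b=0 are permitted so the
    MSE-only and BCE-only ablation variants can be trained and the loss
    reductions verified.
    """

    a: float = 0.75
    b: float = 0.25

    def validate(self) -> None:
        if self.a < 0 or self.b < 0:
            raise ValueError(
                f"loss weights must be nonnegative, got a={self.a}, b={self.b}"
            )
        if abs(self.a + self.b - 1.0) > 1e-9:
            raise ValueError(f"loss weights must sum to 1, got a+b={self.a + self.b}")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol for one phase.

    The published protocol is Adam with learning rate 1e-4 / batch 2 /
    momentum (beta1) 0.8 for phase 1 and 1e-5 / batch 1 / 0.9 for phase 2,
    with early stopping and flip/rotate/brightness augmentation; those are
    the per-phase defaults from :meth:`phase1` and :meth:`phase2`.
    """

    phase: int = 1
    learning_rate: float = 1e-4
    batch_size: int = 2
    momentum: float = 0.8  # Adam beta1
    max_epochs: int = 50
    patience: int = 10
    lr_patience: int = 3  # halve the lr after this many stale epochs
    min_delta: float = 1e-5
    val_fraction: float = 0.1
    augment_flip: bool = True
    augment_rotate: bool = True
    augment_brightness: bool = True
    seed: int = 0
    loss_weights: LossWeights = field(default_factory=LossWeights)
    mask_threshold: float = 0.5

    @classmethod
    def phase1(cls, **kw) -> "TrainConfig":
        return cls(**{"phase": 1, "learning_rate": 1e-4, "batch_size": 2,
                      "momentum": 0.8, **kw})

    @classmethod
    def phase2(cls, **kw) -> "TrainConfig":
        return cls(**{"phase": 2, "learning_rate": 1e-5, "batch_size": 1,
                      "momentum": 0.9, **kw})

    def validate(self) -> None:
        if self.learning_rate < 0:
            raise ValueError(f"learning_rate must be >= 0, got {self.learning_rate}")
        if self.patience < 1:
            raise ValueError(f"patience must be >= 1, got {self.patience}")
        if self.batch_size < 1:
            raise ValueError(f"batch_size must be >= 1, got {self.batch_size}")
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError(f"val_fraction must lie in (0,1), got {self.val_fraction}")


@dataclass(frozen=True)
class MaskEstimate:
    """Phase-1 output: artifact-region probabilities and binarized P1."""

    probabilities: np.ndarray
    binarized: np.ndarray
    threshold: float = 0.5


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def _check_unit_interval(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    if x.size and (x.min() < 0.0 or x.max() > 1.0):
        raise ValueError(f"{name} values must lie in [0, 1]")
    return x


def bce_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean per-pixel binary cross-entropy; pred clamped to [eps, 1-eps]."""
    pred = _check_unit_interval(pred, "pred")
    target = _check_unit_interval(target, "target")
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred, BCE_EPS, 1.0 - BCE_EPS)
    return float(-np.mean(target * np.log(p) + (1.0 - target) * np.log1p(-p)))


def masked_mse_loss(pred: np.ndarray, target: np.ndarray, mask: np.ndarray) -> float:
    """Per-pixel squared error gated by the mask, averaged over all pixels."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if not (pred.shape == target.shape == mask.shape):
        raise ValueError(
            f"shape mismatch: {pred.shape}, {target.shape}, {mask.shape}"
        )
    return float(np.mean(mask * (pred - target) ** 2))


def duarn_loss(
    pred: np.ndarray,
    target: np.ndarray,
    mask: np.ndarray,
    weights: LossWeights = LossWeights(),
) -> float:
    """Composite restoration loss a·maskedMSE + b·BCE (BCE over all pixels)."""
    weights.validate()
    return weights.a * masked_mse_loss(pred, target, mask) + weights.b * bce_loss(
        pred, target
    )


# ---------------------------------------------------------------------------
# the U-net
# ---------------------------------------------------------------------------


class _DownStage:
    def __init__(self, cin, cout, rng):
        self.conv = nn.DownConv2x2(cin, cout, rng)
        self.bn = nn.InstanceNorm2d(cout)
        self.act = nn.ReLU()

    def forward(self, x, train):
        return self.act.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.act.backward(dy)))

    def layers(self):
        return [self.conv, self.bn]


class _UpStage:
    """Transposed-conv upscale + skip concatenation + 3×3 fuse conv."""

    def __init__(self, cin, cskip, cout, rng):
        self.up = nn.UpConv2x2(cin, cskip, rng)
        self.bn1 = nn.InstanceNorm2d(cskip)
        self.act1 = nn.ReLU()
        self.fuse = nn.Conv2d(2 * cskip, cout, 3, rng)
        self.bn2 = nn.InstanceNorm2d(cout)
        self.act2 = nn.ReLU()
        self.cskip = cskip

    def forward(self, x, skip, train):
        u = self.act1.forward(self.bn1.forward(self.up.forward(x, train), train), train)
        h = np.concatenate([u, skip], axis=1)
        return self.act2.forward(self.bn2.forward(self.fuse.forward(h, train), train), train)

    def backward(self, dy):
        dh = self.fuse.backward(self.bn2.backward(self.act2.backward(dy)))
        du, dskip = dh[:, : self.cskip], dh[:, self.cskip :]
        dx = self.up.backward(self.bn1.backward(self.act1.backward(du)))
        return dx, dskip

    def layers(self):
        return [self.up, self.bn1, self.fuse, self.bn2]


class UNet:
    """Encoder–decoder network mapping (B, Cin, H, W) -> (B, 1, H, W) logits."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        config.validate()
        self.config = config
        rng = np.random.default_rng(seed)
        w0, w1, w2, w3 = config.widths
        self.stem = nn.Conv2d(config.in_channels, w0, 3, rng)
        self.stem_act = nn.ReLU()
        self.downs = [
            _DownStage(w0, w1, rng),
            _DownStage(w1, w2, rng),
            _DownStage(w2, w3, rng),
            _DownStage(w3, w3, rng),
        ]
        self.ups = [
            _UpStage(w3, w3, w2, rng),
            _UpStage(w2, w2, w1, rng),
            _UpStage(w1, w1, w0, rng),
            _UpStage(w0, w0, w0, rng),
        ]
        self.head = nn.Conv2d(w0, 1, 1, rng)
        if config.residual_input:
            # start as the identity map: the head contributes nothing
            self.head.w.value[...] = 0.0

    # -- graph ------------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError(f"input height/width must be divisible by 16, got {h}x{w}")
        x = np.ascontiguousarray(x, dtype=nn.DTYPE)
        s = self.stem_act.forward(self.stem.forward(x, train), train)
        skips = [s]
        h = s
        for stage in self.downs:
            h = stage.forward(h, train)
            skips.append(h)
        h = skips.pop()  # bottleneck
        for stage in self.ups:
            h = stage.forward(h, skips.pop(), train)
        z = self.head.forward(h, train)
        if self.config.residual_input:
            z = z + nn.logit(x[:, :1])
        return z

    def backward(self, dz: np.ndarray) -> np.ndarray:
        dz = np.ascontiguousarray(dz, dtype=nn.DTYPE)
        dh = self.head.backward(dz)
        dskips = []  # collected in order [d(s0), d(e1), d(e2), d(e3)]
        for stage in reversed(self.ups):
            dh, dskip = stage.backward(dh)
            dskips.append(dskip)
        d = dh  # gradient wrt the bottleneck e4
        for stage, dskip in zip(reversed(self.downs), reversed(dskips)):
            d = stage.backward(d) + dskip
        return self.stem.backward(self.stem_act.backward(d))

    def layers(self):
        out = [self.stem]
        for s in self.downs:
            out.extend(s.layers())
        for s in self.ups:
            out.extend(s.layers())
        out.append(self.head)
        return out

    def params(self) -> list[nn.Param]:
        ps = []
        for layer in self.layers():
            ps.extend(layer.params())
        return ps

    # -- state ------------------------------------------------------------

    def get_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_state(self, arrs: list[np.ndarray]) -> None:
        ps = self.params()
        if len(arrs) != len(ps):
            raise ValueError(
                f"state has {len(arrs)} arrays but the network has {len(ps)} parameters"
            )
        for p, a in zip(ps, arrs):
            p.value[...] = a

    # -- inference --------------------------------------------------------

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Sigmoid output in eval mode for a (B, Cin, H, W) batch."""
        return nn.sigmoid(self.forward(images, train=False))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    """A trained U-net together with its configs and per-epoch loss log."""

    net: UNet
    net_config: UNetConfig
    train_config: TrainConfig
    history: list[dict]  # {"epoch", "train_loss", "val_loss"}


def _augment(arrays, mask_index, rng, cfg: TrainConfig):
    """Co-transform a tuple of same-shape 2-D arrays.

    ``mask_index`` marks entries that are binary masks (nearest-neighbour
    rotation, excluded from brightness jitter). Horizontal flips mirror
    image, target and mask together so a right-side artifact becomes a
    consistent left-side one; rotations are restricted to ±10 degrees;
    brightness jitter is a ±10% gain applied before re-clipping to [0, 1].
    """
    arrays = list(arrays)
    if cfg.augment_flip and rng.random() < 0.5:
        arrays = [a[:, ::-1].copy() for a in arrays]
    if cfg.augment_rotate and rng.random() < 0.5:
        angle = rng.uniform(-10.0, 10.0)
        for i, a in enumerate(arrays):
            order = 0 if i in mask_index else 1
            arrays[i] = np.clip(
                _nd_rotate(a, angle, reshape=False, order=order, mode="constant"),
                0.0,
                1.0,
            )
    if cfg.augment_brightness and rng.random() < 0.5:
        gain = rng.uniform(0.9, 1.1)
        for i, a in enumerate(arrays):
            if i not in mask_index:
                arrays[i] = np.clip(a * gain, 0.0, 1.0)
    return arrays


def _split_train_val(n: int, val_fraction: float, rng) -> tuple[np.ndarray, np.ndarray]:
    idx = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    if n_val >= n:
        raise ValueError("dataset too small for the requested validation fraction")
    return idx[n_val:], idx[:n_val]


def _check_samples(samples: list[SimulationSample]) -> None:
    if not samples:
        raise ValueError("empty training dataset")
    shape = samples[0].clean.shape
    for s in samples:
        if s.clean.shape != shape or s.artifacted.shape != shape:
            raise ValueError("all samples must share one image shape")
    if shape[0] % 16 or shape[1] % 16:
        raise ValueError(f"sample height/width must be divisible by 16, got {shape}")


def _run_epochs(
    net: UNet,
    cfg: TrainConfig,
    batches_fn,
    val_loss_fn,
    train_idx: np.ndarray,
    rng,
) -> list[dict]:
    """Generic epoch loop with early stopping on the validation loss.

    ``cfg.learning_rate`` is the *initial* rate: it is halved whenever the
    validation loss fails to improve for ``cfg.lr_patience`` consecutive
    epochs, and training stops after ``cfg.patience`` stale epochs. The
    best-validation weights are restored at the end.
    """
    opt = nn.Adam(net.params(), lr=cfg.learning_rate, beta1=cfg.momentum)
    history: list[dict] = []
    best_val = np.inf
    best_state = net.get_state()
    stale = 0
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(train_idx)
        losses = []
        for lo in range(0, len(order), cfg.batch_size):
            batch_idx = order[lo : lo + cfg.batch_size]
            opt.zero_grad()
            loss, dz = batches_fn(batch_idx, rng)
            net.backward(dz)
            opt.step()
            losses.append(loss)
        val_loss = val_loss_fn()
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_loss": val_loss, "lr": opt.lr}
        )
        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            best_state = net.get_state()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
            if cfg.lr_patience and stale % cfg.lr_patience == 0:
                opt.lr *= 0.5
    net.set_state(best_state)
    return history


def train_phase1(
    samples: list[SimulationSample],
    cfg: TrainConfig | None = None,
    net_cfg: UNetConfig | None = None,
) -> TrainedModel:
    """Train the artifact-estimation U-net with BCE against the true mask."""
    cfg = TrainConfig.phase1() if cfg is None else cfg
    cfg.validate()
    net_cfg = UNetConfig(in_channels=1) if net_cfg is None else net_cfg
    if net_cfg.in_channels != 1:
        raise ValueError("phase-1 network takes a single input channel")
    _check_samples(samples)
    xs = np.stack([s.artifacted for s in samples])[:, None]
    ys = np.stack([s.artifact_mask for s in samples]).astype(np.float64)[:, None]

    rng = np.random.default_rng(cfg.seed)
    net = UNet(net_cfg, seed=int(rng.integers(2**31)))
    train_idx, val_idx = _split_train_val(len(samples), cfg.val_fraction, rng)

    def batches_fn(batch_idx, brng):
        xb, yb = [], []
        for i in batch_idx:
            xi, yi = _augment([xs[i, 0], ys[i, 0]], {1}, brng, cfg)
            xb.append(xi)
            yb.append(yi)
        x = np.stack(xb)[:, None]
        y = np.stack(yb)[:, None]
        z = net.forward(x, train=True)
        p = nn.sigmoid(z)
        loss = bce_loss(p, y)
        dz = (p - y) / p[0].size / len(batch_idx)
        return loss, dz

    def val_loss_fn():
        p = net.predict_proba(xs[val_idx])
        return bce_loss(p, ys[val_idx])

    history = _run_epochs(net, cfg, batches_fn, val_loss_fn, train_idx, rng)
    return TrainedModel(net, net_cfg, cfg, history)


def train_phase2(
    samples: list[SimulationSample],
    mask_model: TrainedModel,
    cfg: TrainConfig | None = None,
    net_cfg: UNetConfig | None = None,
) -> TrainedModel:
    """Train the restoration U-net with the composite masked loss.

    Inputs are the artifacted image and the phase-1 probability map
    (2-channel); the MSE term is gated by P1 binarized at
    ``cfg.mask_threshold`` and the target is the clean image.
    """
    cfg = TrainConfig.phase2() if cfg is None else cfg
    cfg.validate()
    net_cfg = (
        UNetConfig(in_channels=2, residual_input=True) if net_cfg is None else net_cfg
    )
    if net_cfg.in_channels != 2:
        raise ValueError("phase-2 network takes 2 input channels (image, P1)")
    _check_samples(samples)
    cfg.loss_weights.validate()
    a, b = cfg.loss_weights.a, cfg.loss_weights.b
    mask_net = mask_model.net

    xs = np.stack([s.artifacted for s in samples])[:, None]
    ys = np.stack([s.clean for s in samples])[:, None]
    p1_all = mask_net.predict_proba(xs)

    rng = np.random.default_rng(cfg.seed)
    net = UNet(net_cfg, seed=int(rng.integers(2**31)))
    train_idx, val_idx = _split_train_val(len(samples), cfg.val_fraction, rng)

    def _loss_and_grad(x2, y, m):
        z = net.forward(x2, train=True)
        p = nn.sigmoid(z)
        loss = a * masked_mse_loss(p, y, m) + b * bce_loss(p, y)
        n = p[0].size * p.shape[0]
        # d/dz of the composite loss through the sigmoid
        dz = (2.0 * a * m * (p - y) * p * (1.0 - p) + b * (p - y)) / n
        return loss, dz

    def batches_fn(batch_idx, brng):
        xb, yb = [], []
        for i in batch_idx:
            xi, yi = _augment([xs[i, 0], ys[i, 0]], set(), brng, cfg)
            xb.append(xi)
            yb.append(yi)
        x = np.stack(xb)[:, None]
        y = np.stack(yb)[:, None]
        p1 = mask_net.predict_proba(x)
        m = (p1 >= cfg.mask_threshold).astype(np.float64)
        return _loss_and_grad(np.concatenate([x, p1], axis=1), y, m)

    def val_loss_fn():
        x, y, p1 = xs[val_idx], ys[val_idx], p1_all[val_idx]
        m = (p1 >= cfg.mask_threshold).astype(np.float64)
        p = net.predict_proba(np.concatenate([x, p1], axis=1))
        return a * masked_mse_loss(p, y, m) + b * bce_loss(p, y)

    history = _run_epochs(net, cfg, batches_fn, val_loss_fn, train_idx, rng)
    return TrainedModel(net, net_cfg, cfg, history)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------


def _pad_to_16(img: np.ndarray) -> tuple[np.ndarray, tuple[int, int]]:
    h, w = img.shape
    ph = (-h) % 16
    pw = (-w) % 16
    if ph or pw:
        img = np.pad(img, ((0, ph), (0, pw)))
    return img, (h, w)


def reduce_artifact(
    img: np.ndarray,
    mask_model: TrainedModel,
    restore_model: TrainedModel,
    threshold: float = 0.5,
) -> tuple[np.ndarray, MaskEstimate]:
    """Run the full two-phase pipeline on one normalized [0, 1] image.

    Images whose sides are not divisible by 16 are zero-padded and the
    output cropped back. Returns the restored image (clipped to [0, 1])
    and the phase-1 mask estimate.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("input image must be normalized to [0, 1]")
    padded, (h, w) = _pad_to_16(img)
    x = padded[None, None]
    p1 = mask_model.net.predict_proba(x)
    restored = restore_model.net.predict_proba(np.concatenate([x, p1], axis=1))
    probs = p1[0, 0, :h, :w]
    est = MaskEstimate(
        probabilities=probs,
        binarized=(probs >= threshold).astype(np.uint8),
        threshold=threshold,
    )
    return np.clip(restored[0, 0, :h, :w], 0.0, 1.0), est


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks (1.0 when both are empty)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection-over-union of two binary masks (1.0 when both empty)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_model(model: TrainedModel, path) -> None:
    """Save a trained U-net (weights + configs + log) to an .npz file."""
    meta = {
        "net_config": asdict(model.net_config),
        "train_config": asdict(model.train_config),
        "history": model.history,
    }
    arrays = {f"arr_{i}": a for i, a in enumerate(model.net.get_state())}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path) -> TrainedModel:
    """Load a trained U-net saved by :func:`save_model`."""
    with np.load(path) as f:
        meta = json.loads(bytes(f["meta"]).decode())
        arrays = [f[f"arr_{i}"] for i in range(len(f.files) - 1)]
    nc = dict(meta["net_config"])
    nc["widths"] = tuple(nc["widths"])
    net_cfg = UNetConfig(**nc)
    tc = dict(meta["train_config"])
    tc["loss_weights"] = LossWeights(**tc["loss_weights"])
    train_cfg = TrainConfig(**tc)
    net = UNet(net_cfg, seed=0)
    net.set_state(arrays)
    return TrainedModel(net, net_cfg, train_cfg, meta["history"])
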