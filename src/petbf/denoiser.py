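"""Residual 3D U-Net denoiser: model, training protocol, CV splits, inference.

The network is an encoder--decoder with skip connections and internal
residual blocks, wrapped in a global residual bypass: the input (already in
[0, 1]) is passed through an inverse sigmoid (logit, after clamping to
[eps, 1-eps]), added to the U-Net body's output, and squashed by a final
sigmoid. A zero body output therefore reproduces the input unchanged, the
output range is constrained to (0, 1), and intensities near 0 and 1 are
hard for the network to move — the behavior wanted when SUV extremes carry
the quantitative signal.

Training minimizes mean absolute error between the network output and the
bilaterally filtered target patch, monitors validation mean squared error,
stops early when the validation metric has not improved for ``patience``
epochs, and returns the parameters of the best-validation epoch. Studies
are assigned to cross-validation folds at the patient level so that no
patient's gate volumes are split across train/validation/test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import nn
from .errors import ConfigurationError, TrainingError, ValidationError
from .preprocess import PatchPair, augment_pair, normalize_volume
from .volume_io import Volume

__all__ = [
    "UNetSpec",
    "TrainConfig",
    "FoldAssignment",
    "UNet",
    "build_model",
    "split_patients",
    "train",
    "denoise_volume",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture knobs: resolution levels, channel widths, bypass clamp.

    The default (depth 3, 16 base channels, growth 2) is a desk-scale
    configuration that trains in minutes on a CPU; larger presets are a
    matter of configuration, not code.
    """

    depth: int = 3
    base_channels: int = 16
    channel_growth: int = 2
    bypass_epsilon: float = 1e-4

    def __post_init__(self) -> None:
        if self.depth < 1 or self.base_channels < 1 or self.channel_growth < 1:
            raise ConfigurationError("depth, base_channels, channel_growth must be >= 1")
        if not 0 < self.bypass_epsilon < 0.5:
            raise ConfigurationError("bypass_epsilon must be in (0, 0.5)")


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol defaults: MAE loss, Adadelta, batch 128, max 400
    epochs, early stopping after 50 epochs without validation-MSE
    improvement. Desk-scale runs override the sizes, not the protocol."""

    max_epochs: int = 400
    batch_size: int = 128
    patience: int = 50
    optimizer_name: str = "adadelta"
    learning_rate: float | None = None
    augment: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not self.patience < self.max_epochs:
            raise ConfigurationError("patience must be < max_epochs")


class _ResBlock:
    """conv-act-conv plus identity (or 1x1-projected) skip, then activation."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.conv1 = nn.Conv3d(cin, cout, 3, rng)
        self.act1 = nn.LeakyReLU()
        self.conv2 = nn.Conv3d(cout, cout, 3, rng)
        self.proj = nn.Conv3d(cin, cout, 1, rng) if cin != cout else None
        self.act2 = nn.LeakyReLU()

    def params(self) -> list[nn.Param]:
        ps = self.conv1.params() + self.conv2.params()
        if self.proj is not None:
            ps += self.proj.params()
        return ps

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.act1.forward(self.conv1.forward(x)))
        s = self.proj.forward(x) if self.proj is not None else x
        return self.act2.forward(h + s)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        d = self.act2.backward(dout)
        dx = self.conv1.backward(self.act1.backward(self.conv2.backward(d)))
        dx += self.proj.backward(d) if self.proj is not None else d
        return dx


class UNet:
    """The residual 3D U-Net with logit/sigmoid bypass.

    Fully convolutional: accepts any channels-last (N, D, H, W, 1) input
    whose spatial dimensions are divisible by 2**(depth-1).
    """

    def __init__(self, spec: UNetSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        ch = [spec.base_channels * spec.channel_growth**i for i in range(spec.depth)]
        self.enc = []
        cin = 1
        for lvl in range(spec.depth - 1):
            self.enc.append(_ResBlock(cin, ch[lvl], rng))
            cin = ch[lvl]
        self.pools = [nn.AvgPool3d() for _ in range(spec.depth - 1)]
        self.bottleneck = _ResBlock(cin, ch[-1], rng)
        self.ups = [nn.Upsample3d() for _ in range(spec.depth - 1)]
        self.dec = []
        cin = ch[-1]
        for lvl in reversed(range(spec.depth - 1)):
            self.dec.append(_ResBlock(cin + ch[lvl], ch[lvl], rng))
            cin = ch[lvl]
        # zero-initialized head: the untrained network is the identity bypass
        self.head = nn.Conv3d(cin, 1, 1, rng, zero_init=True)
        self._cache: dict = {}

    def params(self) -> list[nn.Param]:
        ps: list[nn.Param] = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for blk in self.dec:
            ps += blk.params()
        ps += self.head.params()
        return ps

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p.value[...] = w

    def _check_shape(self, x: np.ndarray) -> None:
        if x.ndim != 5 or x.shape[-1] != 1:
            raise ConfigurationError(f"expected (N, D, H, W, 1) input, got {x.shape}")
        f = 2 ** (self.spec.depth - 1)
        if any(s % f != 0 or s < f for s in x.shape[1:4]):
            raise ConfigurationError(
                f"spatial dims {x.shape[1:4]} must be divisible by {f} for depth {self.spec.depth}"
            )

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Full forward pass; caches intermediates for :meth:`backward`."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        self._check_shape(x)
        eps = self.spec.bypass_epsilon
        xc = np.clip(x, eps, 1.0 - eps)
        bypass = np.log(xc / (1.0 - xc))  # logit
        skips = []
        h = x
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._split = []
        for blk, up, skip in zip(self.dec, self.ups, reversed(skips)):
            h = up.forward(h)
            self._split.append(h.shape[-1])
            h = np.concatenate([h, skip], axis=-1)
            h = blk.forward(h)
        body = self.head.forward(h)
        u = bypass + body
        y = 1.0 / (1.0 + np.exp(-u))
        self._y = y
        return y

    def backward(self, dy: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dOutput."""
        du = dy * self._y * (1.0 - self._y)
        d = self.head.backward(np.ascontiguousarray(du, dtype=np.float32))
        dskips = []
        for blk, up, csplit in zip(reversed(self.dec), reversed(self.ups), reversed(self._split)):
            d = blk.backward(d)
            dup, dskip = d[..., :csplit], d[..., csplit:]
            dskips.append(dskip)
            d = up.backward(dup)
        d = self.bottleneck.backward(d)
        # dskips[i] pairs with enc level i (shallowest first); walk levels deep->shallow
        for blk, pool, dskip in zip(reversed(self.enc), reversed(self.pools), reversed(dskips)):
            d = pool.backward(d)
            d = d + dskip
            d = blk.backward(d)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Forward pass without keeping the output cache."""
        y = self.forward(x)
        self._y = None
        return y


def build_model(spec: UNetSpec | None = None, seed: int = 0) -> UNet:
    """Construct an (untrained) residual U-Net; identity at initialization."""
    return UNet(spec or UNetSpec(), seed=seed)


@dataclass
class FoldAssignment:
    """Patient-level k-fold split: per-fold train/validation/test id lists."""

    folds: list[dict[str, list]]

    def __post_init__(self) -> None:
        test_seen: list = []
        for f in self.folds:
            tr, va, te = set(f["train"]), set(f["validation"]), set(f["test"])
            if tr & va or tr & te or va & te:
                raise ValidationError("train/validation/test overlap within a fold")
            test_seen.extend(f["test"])
        if len(test_seen) != len(set(test_seen)):
            raise ValidationError("a patient appears in more than one test fold")


def split_patients(patient_ids: list, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Shuffle patients into k near-equal test folds; for fold f the test set
    is fold f and the remaining patients are split 4:1 into train and
    validation (64% / 16% / 20% of the cohort for k=5). Validation patients
    are drawn from fold (f+1) mod k so the rotation is deterministic."""
    if len(patient_ids) < k:
        raise ValidationError(f"need >= {k} patients, got {len(patient_ids)}")
    n = len(patient_ids)
    rng = np.random.default_rng(seed)
    order = [patient_ids[i] for i in rng.permutation(n)]
    chunks = [list(c) for c in np.array_split(np.arange(n), k)]
    n_val = max(1, round(n * (1.0 - 1.0 / k) / k))
    folds = []
    for f in range(k):
        test = [order[i] for i in chunks[f]]
        pool = [order[i] for i in chunks[(f + 1) % k]]
        val = pool[:n_val]
        train = pool[n_val:] + [
            order[i] for c in range(k) if c not in (f, (f + 1) % k) for i in chunks[c]
        ]
        folds.append({"train": train, "validation": val, "test": test})
    return FoldAssignment(folds)


def _stack(pairs: list[PatchPair]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([p.input_patch for p in pairs])[..., None].astype(np.float32)
    t = np.stack([p.target_patch for p in pairs])[..., None].astype(np.float32)
    return x, t


def _eval_mse(model: UNet, pairs: list[PatchPair], batch_size: int) -> float:
    se, n = 0.0, 0
    for i in range(0, len(pairs), batch_size):
        x, t = _stack(pairs[i : i + batch_size])
        pred = model.predict(x)
        se += float(((pred - t) ** 2).sum())
        n += pred.size
    return se / n


def train(
    model: UNet,
    train_pairs: list[PatchPair],
    val_pairs: list[PatchPair],
    config: TrainConfig | None = None,
) -> tuple[UNet, dict]:
    """MAE training with validation-MSE early stopping and best-epoch selection.

    Augmentation (flips + shared gamma) is re-drawn per sample per epoch and
    applied to training pairs only. Returns the model carrying the weights
    of the best-validation epoch and a history dict with per-epoch
    ``train_loss`` and ``val_mse`` (index 0 is the untrained model).
    """
    config = config or TrainConfig()
    if not train_pairs or not val_pairs:
        raise ValidationError("train and validation sets must be nonempty")
    rng = np.random.default_rng(config.seed)
    opt = nn.make_optimizer(config.optimizer_name, model.params(), lr=config.learning_rate)
    history: dict = {"train_loss": [], "val_mse": []}
    best_mse = _eval_mse(model, val_pairs, config.batch_size)
    history["val_mse"].append(best_mse)
    history["train_loss"].append(float("nan"))
    best_weights = model.get_weights()
    best_epoch = 0
    # the patience counter baselines at the first trained epoch; the
    # untrained (epoch 0) metric participates in selection only
    stop_best = float("inf")
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(train_pairs))
        epoch_loss, nb = 0.0, 0
        for i in range(0, len(order), config.batch_size):
            batch = [train_pairs[j] for j in order[i : i + config.batch_size]]
            if config.augment:
                batch = [augment_pair(p, rng) for p in batch]
            x, t = _stack(batch)
            pred = model.forward(x)
            loss, dpred = nn.mae_loss(pred, t)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dpred)
            opt.step()
            epoch_loss += loss
            nb += 1
        val_mse = _eval_mse(model, val_pairs, config.batch_size)
        history["train_loss"].append(epoch_loss / max(nb, 1))
        history["val_mse"].append(val_mse)
        if val_mse < best_mse:
            best_mse = val_mse
            best_weights = model.get_weights()
            best_epoch = epoch
        if val_mse < stop_best:
            stop_best = val_mse
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break
    model.set_weights(best_weights)
    history["best_epoch"] = best_epoch
    history["best_val_mse"] = best_mse
    return model, history


def _tile_corners(length: int, tile: int, stride: int) -> list[int]:
    corners = list(range(0, max(length - tile, 0) + 1, stride))
    if corners[-1] != length - tile:
        corners.append(length - tile)
    return corners


def denoise_volume(
    model: UNet,
    vol: Volume,
    tile: int = 64,
    overlap: int = 16,
) -> Volume:
    """Apply the trained network to a whole volume.

    The volume is normalized to [0, 1] by its own range, processed in
    overlapping tiles blended by uniform averaging, and mapped back to SUV.
    Axes shorter than the tile are reflect-padded and cropped afterwards;
    the tile size must be divisible by the network's downsampling factor.
    """
    f = 2 ** (model.spec.depth - 1)
    if tile % f != 0:
        raise ConfigurationError(f"tile size {tile} not divisible by network factor {f}")
    if overlap >= tile:
        raise ConfigurationError("overlap must be smaller than the tile size")
    norm, rec = normalize_volume(vol)
    data = norm.data.astype(np.float32)
    pad = [(0, max(tile - s, 0)) for s in data.shape]
    padded = np.pad(data, pad, mode="reflect") if any(p[1] for p in pad) else data
    acc = np.zeros_like(padded, dtype=np.float64)
    cnt = np.zeros_like(padded, dtype=np.float64)
    stride = tile - overlap
    corners = [_tile_corners(s, tile, stride) for s in padded.shape]
    for i in corners[0]:
        for j in corners[1]:
            for k in corners[2]:
                sl = (slice(i, i + tile), slice(j, j + tile), slice(k, k + tile))
                out = model.predict(padded[sl][None, ..., None])[0, ..., 0]
                acc[sl] += out
                cnt[sl] += 1.0
    blended = (acc / cnt)[tuple(slice(0, s) for s in data.shape)]
    return vol.with_data(rec.invert(blended))


def save_checkpoint(model: UNet, path: str | Path, extra: dict | None = None) -> None:
    """Persist weights + architecture spec (npz with a JSON header entry)."""
    meta = {
        "spec": {
            "depth": model.spec.depth,
            "base_channels": model.spec.base_channels,
            "channel_growth": model.spec.channel_growth,
            "bypass_epsilon": model.spec.bypass_epsilon,
        },
        "extra": extra or {},
    }
    arrays = {f"w{i}": w for i, w in enumerate(model.get_weights())}
    np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path: str | Path) -> tuple[UNet, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["meta"]).decode())
        weights = [npz[f"w{i}"] for i in range(len(npz.files) - 1)]
    model = build_model(UNetSpec(**meta["spec"]))
    model.set_weights(weights)
    return model, meta.get("extra", {})
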