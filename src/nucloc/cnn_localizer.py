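"""Convolutional regression of nuclear localization from cell images.

A compact convolutional network maps a fixed-size single-cell crop
(fluorescence, optionally plus bright-field) to one continuous value:
the predicted nuclear localization on the scale of the ground-truth
statistic l = <I_nuc>/<I_cell>.  The architecture is a stack of 3x3
convolution blocks (channels doubling per block, 2x2 max pooling after
every block except the last), a flatten, and a small fully connected
head ending in a single linear output.  Training minimizes mean squared
error against marker-derived ground-truth localizations with Adam (or
SGD) under a linear learning-rate schedule.

The network, its gradients, and the optimizers are implemented directly
in NumPy (float32, im2col/GEMM convolutions), which keeps the package
dependency-light, fully deterministic on a single CPU thread, and fast
enough for the tens of thousands of 64x64 crops this problem needs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .data_model import CellImage, ClassBands, LocalizationValue

logger = logging.getLogger("nucloc")

_KERNEL = 3  # conv kernel side; 'same' padding
_FC_HIDDEN = 64  # width of hidden fully connected layers
# Per-channel in-mask normalization percentile.  The median (the typical
# cytosolic level) keeps the normalized nuclear amplitude independent of
# the nucleus-to-cell pixel fraction; a high percentile would couple it
# to cell size.
_NORM_PERCENTILE = 50.0


@dataclass
class NetworkSpec:
    """Architecture of the regressor.

    ``base_channels`` feature maps in the first convolution block, the
    number doubling in subsequent blocks.  Every block is conv(s) + ReLU;
    all blocks but the last are followed by 2x2 max pooling.  The head
    has ``n_fc_layers`` linear layers (ReLU between them), the last
    mapping to a scalar.
    """

    in_channels: int = 2
    base_channels: int = 8
    n_conv_layers: int = 3
    convs_per_layer: int = 1
    n_fc_layers: int = 2
    input_size: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 (fluor) or 2 (fluor+bright)")
        if not (4 <= self.base_channels <= 32):
            raise ValueError("base_channels must be in [4, 32]")
        if not (1 <= self.n_conv_layers <= 3):
            raise ValueError("n_conv_layers must be in [1, 3]")
        if not (1 <= self.convs_per_layer <= 3):
            raise ValueError("convs_per_layer must be in [1, 3]")
        if not (1 <= self.n_fc_layers <= 3):
            raise ValueError("n_fc_layers must be in [1, 3]")
        n_pool = self.n_conv_layers - 1
        h, w = self.input_size
        if h % (2**n_pool) or w % (2**n_pool) or h // 2**n_pool < 1:
            raise ValueError("input_size too small for the pooling depth")

    @property
    def channels_per_layer(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.n_conv_layers)]

    @property
    def flat_features(self) -> int:
        h, w = self.input_size
        shrink = 2 ** (self.n_conv_layers - 1)
        return self.channels_per_layer[-1] * (h // shrink) * (w // shrink)


@dataclass
class TrainConfig:
    """Training hyperparameters.

    The learning rate decays linearly from ``lr`` to
    ``scheduler_ratio * lr`` over ``scheduler_epochs`` epochs and stays
    constant afterwards.  ``val_fraction`` of the data is held out for
    per-epoch validation, split randomly with ``seed``.  Labels below
    ``exclude_below`` (the poorly-segmented band) are dropped from
    training unless ``include_low_labels``.
    """

    batch_size: int = 64
    lr: float = 1e-3
    scheduler_ratio: float = 0.5
    scheduler_epochs: int = 50
    n_epochs: int = 50
    optimizer: str = "adam"
    seed: int = 0
    val_fraction: float = 0.10
    exclude_below: float = 1.15
    include_low_labels: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


# ---------------------------------------------------------------------------
# Layers (forward + backward, float32)
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, 9*C) patch matrix for 3x3 'same' convolution.

    Channels-last layout keeps every later reshape a zero-copy view.
    """
    n, h, w, c = x.shape
    pad = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(pad, (_KERNEL, _KERNEL), axis=(1, 2))
    # win: (N, H, W, C, 3, 3)
    return np.ascontiguousarray(win).reshape(n * h * w, c * _KERNEL * _KERNEL)


class _Conv:
    """3x3 'same' convolution via im2col + GEMM (channels-last)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        fan_in = c_in * _KERNEL * _KERNEL
        scale = np.sqrt(2.0 / fan_in)  # He initialization for ReLU stacks
        self.w = rng.normal(0, scale, (fan_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        cols = _im2col(x)
        out = cols @ self.w + self.b
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, h, w, c) = self._cache
        d2 = dout.reshape(-1, self.w.shape[1])
        self.grads[0][...] = cols.T @ d2
        self.grads[1][...] = d2.sum(axis=0)
        dcols = (d2 @ self.w.T).reshape(n, h, w, c, _KERNEL, _KERNEL)
        dxpad = np.zeros((n, h + 2, w + 2, c), dtype=np.float32)
        for i in range(_KERNEL):
            for j in range(_KERNEL):
                dxpad[:, i : i + h, j : j + w, :] += dcols[:, :, :, :, i, j]
        return dxpad[:, 1:-1, 1:-1, :]


class _ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class _MaxPool2:
    """2x2 max pooling (channels-last).

    Backward routes gradient through an equality mask; exact positive
    ties are vanishingly rare and zero ties are blocked by the preceding
    rectifier's gradient mask.
    """

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        self._xv = x.reshape(n, h // 2, 2, w // 2, 2, c)
        out = self._xv.max(axis=(2, 4))
        self._out = out
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, hh, _, wh, _, c = self._xv.shape
        mask = self._xv == self._out[:, :, None, :, None, :]
        dup = mask * dout[:, :, None, :, None, :]
        return dup.reshape(n, hh * 2, wh * 2, c)


class _Flatten:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = rng.normal(0, scale, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.w.T


class ConvNet:
    """The regressor as an explicit layer stack with manual backprop."""

    def __init__(self, spec: NetworkSpec, seed: int = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        layers: list = []
        c_in = spec.in_channels
        for i, c_out in enumerate(spec.channels_per_layer):
            for _ in range(spec.convs_per_layer):
                layers.append(_Conv(c_in, c_out, rng))
                layers.append(_ReLU())
                c_in = c_out
            if i < spec.n_conv_layers - 1:
                layers.append(_MaxPool2())
        layers.append(_Flatten())
        n_in = spec.flat_features
        for j in range(spec.n_fc_layers - 1):
            layers.append(_Linear(n_in, _FC_HIDDEN, rng))
            layers.append(_ReLU())
            n_in = _FC_HIDDEN
        layers.append(_Linear(n_in, 1, rng))
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        # public layout is (N, C, H, W); compute channels-last internally
        out = np.ascontiguousarray(
            np.asarray(x, dtype=np.float32).transpose(0, 2, 3, 1)
        )
        for layer in self.layers:
            out = layer.forward(out)
        return out[:, 0]

    def backward(self, dpred: np.ndarray) -> None:
        dout = dpred[:, None].astype(np.float32)
        for layer in reversed(self.layers):
            dout = layer.backward(dout)

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.parameters]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.parameters, weights, strict=True):
            p[...] = w


def build_network(spec: NetworkSpec, seed: int = 0) -> ConvNet:
    """Instantiate an untrained network with seeded initial weights."""
    return ConvNet(spec, seed=seed)


# ---------------------------------------------------------------------------
# Optimizers and schedule
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params, grads, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


class _SGD:
    def __init__(self, params):
        pass

    def step(self, params, grads, lr: float) -> None:
        for p, g in zip(params, grads):
            p -= lr * g


def scheduled_lr(cfg: TrainConfig, epoch: int) -> float:
    """Linear decay from lr to scheduler_ratio*lr over scheduler_epochs."""
    frac = min(epoch, cfg.scheduler_epochs) / cfg.scheduler_epochs
    return cfg.lr * (1.0 - (1.0 - cfg.scheduler_ratio) * frac)


# ---------------------------------------------------------------------------
# Input preparation
# ---------------------------------------------------------------------------

def prepare_input(img: CellImage, spec: NetworkSpec) -> np.ndarray:
    """Convert a CellImage into the fixed-size network input.

    The cell is cropped to its bounding box, pixels outside the cell mask
    are zeroed, the crop is centred in an ``input_size`` frame (cells
    larger than the frame are down-scaled, with a warning), and each
    channel is divided by its 99th-percentile in-mask intensity so that
    arbitrary fluorescence units cancel.  Deterministic.
    """
    channels = ["fluor"] if spec.in_channels == 1 else ["fluor", "bright"]
    for name in channels:
        if getattr(img, name) is None:
            raise ValueError(f"spec requires channel {name!r}, not present")

    ys, xs = np.nonzero(img.cell_mask)
    y0, y1 = ys.min(), ys.max() + 1
    x0, x1 = xs.min(), xs.max() + 1
    mask = img.cell_mask[y0:y1, x0:x1]

    h, w = spec.input_size
    out = np.zeros((spec.in_channels, h, w), dtype=np.float32)
    for ci, name in enumerate(channels):
        crop = getattr(img, name)[y0:y1, x0:x1] * mask
        norm = np.percentile(getattr(img, name)[img.cell_mask], _NORM_PERCENTILE)
        crop = crop / max(float(norm), 1e-12)
        ch, cw = crop.shape
        if ch > h or cw > w:
            from skimage.transform import resize

            scale = min(h / ch, w / cw)
            crop = resize(
                crop,
                (max(1, int(ch * scale)), max(1, int(cw * scale))),
                anti_aliasing=True,
                preserve_range=True,
            )
            ch, cw = crop.shape
            logger.warning("cell %s larger than input frame; down-scaled", img.cell_id)
        oy, ox = (h - ch) // 2, (w - cw) // 2
        out[ci, oy : oy + ch, ox : ox + cw] = crop
    return out


def prepare_batch(imgs: Sequence[CellImage], spec: NetworkSpec) -> np.ndarray:
    return np.stack([prepare_input(im, spec) for im in imgs])


# ---------------------------------------------------------------------------
# Training and prediction
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted regressor: architecture, weights, and the training record."""

    spec: NetworkSpec
    weights: list = field(repr=False, default_factory=list)
    training_log: list = field(default_factory=list)  # per-epoch dicts
    data_fingerprint: str = ""

    def network(self) -> ConvNet:
        net = ConvNet(self.spec, seed=0)
        net.set_weights(self.weights)
        return net

    def save(self, path) -> None:
        """Serialize weights (npz) with the spec embedded as JSON metadata."""
        meta = json.dumps(asdict(self.spec))
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        np.savez(
            path,
            __spec__=np.frombuffer(meta.encode(), dtype=np.uint8),
            __fingerprint__=np.frombuffer(
                self.data_fingerprint.encode(), dtype=np.uint8
            ),
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__spec__"]).decode())
            meta["input_size"] = tuple(meta["input_size"])
            fp = bytes(data["__fingerprint__"]).decode()
            n = len([k for k in data.files if k.startswith("w")])
            weights = [data[f"w{i}"] for i in range(n)]
        return cls(spec=NetworkSpec(**meta), weights=weights, data_fingerprint=fp)


def _fingerprint(x: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(x).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def _mse_and_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), (2.0 / diff.size) * diff


def train_arrays(
    x: np.ndarray,
    y: np.ndarray,
    spec: NetworkSpec,
    cfg: TrainConfig,
    model: Optional[ConvNet] = None,
) -> TrainedModel:
    """Fit the network on prepared input arrays.

    ``x`` is (N, C, H, W), ``y`` the ground-truth localizations.  Labels
    below ``cfg.exclude_below`` are dropped unless
    ``cfg.include_low_labels`` (the lowest localization mode reflects
    segmentation artefacts, not biology).  Runs ``cfg.n_epochs`` epochs
    of minibatch MSE minimization, logging train and validation loss per
    epoch.  Fully deterministic given ``cfg.seed``.
    """
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if not np.isfinite(y).all():
        raise ValueError("ground-truth labels must be finite")
    if not cfg.include_low_labels:
        keep = y >= cfg.exclude_below
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("excluding %d training labels below %.2f", n_drop, cfg.exclude_below)
        x, y = x[keep], y[keep]
    if len(y) < cfg.batch_size:
        raise ValueError(
            f"need at least batch_size={cfg.batch_size} examples, have {len(y)}"
        )

    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    perm = rng.permutation(n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    xt, yt = x[train_idx], y[train_idx]
    xv, yv = x[val_idx], y[val_idx]

    net = model if model is not None else ConvNet(spec, seed=cfg.seed)
    opt = _Adam(net.parameters) if cfg.optimizer == "adam" else _SGD(net.parameters)

    log = []
    for epoch in range(cfg.n_epochs):
        lr = scheduled_lr(cfg, epoch)
        order = rng.permutation(len(yt))
        losses = []
        for start in range(0, len(yt), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = net.forward(xt[idx])
            loss, dpred = _mse_and_grad(pred, yt[idx])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or check the labels"
                )
            net.backward(dpred)
            opt.step(net.parameters, net.gradients, lr)
            losses.append(loss)
        val_pred = predict_arrays(net, xv)
        val_loss = float(np.mean((val_pred - yv) ** 2))
        log.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
            }
        )
        logger.info(
            "epoch %d lr %.2e train %.4f val %.4f", epoch, lr, log[-1]["train_loss"], val_loss
        )
    return TrainedModel(
        spec=spec,
        weights=net.get_weights(),
        training_log=log,
        data_fingerprint=_fingerprint(x, y),
    )


def train(
    images: Sequence[tuple[CellImage, float]],
    cfg: TrainConfig,
    spec: Optional[NetworkSpec] = None,
) -> TrainedModel:
    """Fit the network on (CellImage, ground-truth localization) pairs."""
    spec = spec or NetworkSpec()
    imgs, labels = zip(*images)
    x = prepare_batch(imgs, spec)
    return train_arrays(x, np.asarray(labels), spec, cfg)


def predict_arrays(net: ConvNet, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    if len(x) == 0:
        return np.empty(0, dtype=np.float32)
    preds = [
        net.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)
    ]
    return np.concatenate(preds)


def predict(model: TrainedModel, imgs: Sequence[CellImage]) -> list[LocalizationValue]:
    """Predict localization for a collection of cells (method tag ``cnn``).

    Deterministic given the model weights; predictions are directly
    interpretable on the ground-truth l scale.
    """
    if not model.weights:
        raise ValueError("model has no trained weights")
    imgs = list(imgs)
    if not imgs:
        return []
    net = model.network()
    x = prepare_batch(imgs, model.spec)
    preds = predict_arrays(net, x)
    return [LocalizationValue(value=float(v), method_tag="cnn") for v in preds]


def accuracy(preds, truths, bands: ClassBands = ClassBands()) -> float:
    """Fraction of cells on the correct side of the nuclear band.

    A cell counts as correctly classified when prediction and truth agree
    on whether localization exceeds ``bands.high``.
    """
    p = np.asarray(
        [v.value if isinstance(v, LocalizationValue) else v for v in preds], dtype=float
    )
    t = np.asarray(truths, dtype=float)
    if p.shape != t.shape:
        raise ValueError("predictions and truths differ in length")
    if p.size == 0:
        raise ValueError("empty inputs")
    return float(np.mean((p > bands.high) == (t > bands.high)))


# ---------------------------------------------------------------------------
# Random hyperparameter search
# ---------------------------------------------------------------------------

#: Search ranges for architecture and training hyperparameters.
SEARCH_SPACE = {
    "batch_size": (16, 256),
    "n_epochs": (20, 200),
    "lr": (1e-5, 1e-1),  # log-uniform
    "scheduler_epochs": (20, 100),
    "optimizer": ("adam", "sgd"),
    "base_channels": (4, 32),
    "n_conv_layers": (1, 3),
    "convs_per_layer": (1, 3),
    "n_fc_layers": (1, 3),
}


def sample_candidate(rng: np.random.Generator, space=None) -> tuple[NetworkSpec, TrainConfig]:
    space = space or SEARCH_SPACE
    lo, hi = space["lr"]
    spec = NetworkSpec(
        base_channels=int(rng.integers(*space["base_channels"], endpoint=True)),
        n_conv_layers=int(rng.integers(*space["n_conv_layers"], endpoint=True)),
        convs_per_layer=int(rng.integers(*space["convs_per_layer"], endpoint=True)),
        n_fc_layers=int(rng.integers(*space["n_fc_layers"], endpoint=True)),
    )
    cfg = TrainConfig(
        batch_size=int(rng.integers(*space["batch_size"], endpoint=True)),
        n_epochs=int(rng.integers(*space["n_epochs"], endpoint=True)),
        lr=float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
        scheduler_epochs=int(rng.integers(*space["scheduler_epochs"], endpoint=True)),
        optimizer=str(rng.choice(list(space["optimizer"]))),
    )
    return spec, cfg


def random_search(
    data: Sequence[tuple[CellImage, float]],
    budget: int,
    seed: int = 0,
    space=None,
    bands: ClassBands = ClassBands(),
    subset_size: Optional[int] = None,
    epoch_cap: Optional[int] = None,
) -> list[tuple[NetworkSpec, TrainConfig, float]]:
    """Random sampling over hyperparameters and architecture.

    Each candidate trains on a random subset of the data (``subset_size``
    examples, default all) and is scored by validation accuracy at the
    nuclear band.  ``epoch_cap`` optionally truncates candidate epoch
    counts so searches stay affordable on a desk CPU.  Returns candidates
    ranked best-first; deterministic given ``seed``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    data = list(data)
    imgs, labels = zip(*data)
    labels = np.asarray(labels, dtype=np.float32)

    results = []
    for i in range(budget):
        spec, cfg = sample_candidate(rng, space)
        cfg.seed = int(rng.integers(0, 2**31))
        if epoch_cap is not None:
            cfg.n_epochs = min(cfg.n_epochs, epoch_cap)
        idx = np.arange(len(data))
        if subset_size is not None and subset_size < len(data):
            idx = rng.choice(len(data), subset_size, replace=False)
        x = prepare_batch([imgs[j] for j in idx], spec)
        y = labels[idx]
        cfg.batch_size = min(cfg.batch_size, max(1, len(y) // 2))
        try:
            model = train_arrays(x, y, spec, cfg)
        except (ValueError, RuntimeError) as exc:
            logger.warning("candidate %d failed: %s", i, exc)
            results.append((spec, cfg, 0.0))
            continue
        # score on the candidate's own validation split
        val_rng = np.random.default_rng(cfg.seed)
        keep = y >= cfg.exclude_below if not cfg.include_low_labels else np.ones(len(y), bool)
        yk, xk = y[keep], x[keep]
        n_val = max(1, int(round(cfg.val_fraction * len(yk))))
        perm = val_rng.permutation(len(yk))
        xv, yv = xk[perm[:n_val]], yk[perm[:n_val]]
        preds = predict_arrays(model.network(), xv)
        acc = accuracy(preds, yv, bands) if len(yv) else 0.0
        results.append((spec, cfg, acc))
    results.sort(key=lambda r: -r[2])
    return results
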