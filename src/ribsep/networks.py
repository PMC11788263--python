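"""Desk-scale training scaffolding for the edge and suppression networks.

A compact dense-block encoder-decoder implemented directly on NumPy
arrays (no deep-learning framework is required at run time), with Adam,
a cosine-annealing warm-restart learning-rate schedule, seeded
determinism, checkpointing with a JSON sidecar, and the 4-channel input
assembly (intensity, Sobel x/y gradients, edge mask) used by the
suppression network.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage


# ---------------------------------------------------------------------------
# config


@dataclass
class TrainConfig:
    image_size: int = 512
    batch_size: int = 6
    epochs: int = 300
    lr0: float = 1e-4
    t0: int = 10  # first restart period, in epochs
    t_mult: int = 2  # period doubling factor
    loss: str = "mse"  # or "bce"
    seed: int = 0
    base_channels: int = 8
    augment_rotate: bool = False  # max 10 degrees
    augment_translate: bool = False  # max 5% of the image side
    augment_flip: bool = False
    normalize: bool = True

    def __post_init__(self) -> None:
        for name in ("image_size", "batch_size", "epochs", "t0", "t_mult", "base_channels"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.loss not in ("mse", "bce"):
            raise ValueError("loss must be 'mse' or 'bce'")


def cosine_warm_restart_lr(epoch: float, lr0: float, t0: int = 10, t_mult: int = 2) -> float:
    """Learning rate at a (fractional) epoch under warm restarts.

    Restart periods are t0, t0*t_mult, t0*t_mult^2, ...; at the start of
    each period the rate returns to ``lr0`` and decays to 0 on a cosine.
    """
    t_i = float(t0)
    t_cur = float(epoch)
    while t_cur >= t_i:
        t_cur -= t_i
        t_i *= t_mult
    return lr0 * 0.5 * (1.0 + np.cos(np.pi * t_cur / t_i))


# ---------------------------------------------------------------------------
# layers (NCHW tensors, manual forward/backward)


class _Conv:
    """Same-padding convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k * k))
        self.w = rng.normal(0.0, scale, size=(c_out, c_in * k * k))
        self.b = np.zeros(c_out)
        self.k = k
        self.c_in = c_in
        self.c_out = c_out
        self._cache = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        out = cols @ self.w.T + self.b
        self._cache = (cols, x.shape)
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray):
        cols, xshape = self._cache
        n, c, h, w = xshape
        k = self.k
        p = k // 2
        g2 = g.transpose(0, 2, 3, 1).reshape(-1, self.c_out)
        gw = g2.T @ cols
        gb = g2.sum(axis=0)
        gcols = (g2 @ self.w).reshape(n, h, w, c, k, k)
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p))
        for di in range(k):
            for dj in range(k):
                gxp[:, :, di : di + h, dj : dj + w] += gcols[:, :, :, :, di, dj].transpose(
                    0, 3, 1, 2
                )
        gx = gxp[:, :, p : p + h, p : p + w] if p else gxp
        return gx, [gw, gb]


class _ReLU:
    def forward(self, x):
        self._m = x > 0
        return x * self._m

    def backward(self, g):
        return g * self._m


def _avgpool2(x):
    n, c, h, w = x.shape
    return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))


def _avgpool2_back(g, shape):
    n, c, h, w = shape
    return np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) / 4.0


def _upsample2(x):
    return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)


def _upsample2_back(g):
    n, c, h, w = g.shape
    return g.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class DenseSuppressionNet:
    """Two-scale encoder-decoder with a dense (concatenating) encoder block.

    Small by construction: meant for 64-128 px inputs and CPU training.
    """

    def __init__(self, in_channels: int, base_channels: int, seed: int):
        rng = np.random.default_rng(seed)
        c = base_channels
        self.in_channels = in_channels
        self.base_channels = c
        self.conv1 = _Conv(in_channels, c, 3, rng)
        self.conv2 = _Conv(c, c, 3, rng)  # dense: output concatenated with conv1
        self.conv3 = _Conv(2 * c, 2 * c, 3, rng)
        self.conv4 = _Conv(2 * c, 2 * c, 3, rng)
        self.conv5 = _Conv(4 * c, c, 3, rng)
        self.conv6 = _Conv(c, 1, 1, rng)
        self.relu = [_ReLU() for _ in range(5)]
        self._layers = [self.conv1, self.conv2, self.conv3, self.conv4, self.conv5, self.conv6]

    @property
    def params(self):
        return [p for layer in self._layers for p in layer.params]

    def set_params(self, values) -> None:
        flat = [p for layer in self._layers for p in layer.params]
        if len(values) != len(flat):
            raise ValueError("parameter count mismatch")
        i = 0
        for layer in self._layers:
            layer.w = values[i].copy()
            layer.b = values[i + 1].copy()
            i += 2

    def forward(self, x: np.ndarray) -> np.ndarray:
        e1 = self.relu[0].forward(self.conv1.forward(x))
        e2 = self.relu[1].forward(self.conv2.forward(e1))
        skip = np.concatenate([e1, e2], axis=1)
        self._skip_shape = skip.shape
        p = _avgpool2(skip)
        m1 = self.relu[2].forward(self.conv3.forward(p))
        m2 = self.relu[3].forward(self.conv4.forward(m1))
        u = _upsample2(m2)
        f = np.concatenate([u, skip], axis=1)
        d = self.relu[4].forward(self.conv5.forward(f))
        return self.conv6.forward(d)

    def backward(self, g: np.ndarray):
        grads: dict[int, list] = {}
        g, grads[5] = self.conv6.backward(g)
        g = self.relu[4].backward(g)
        g, grads[4] = self.conv5.backward(g)
        c2 = 2 * self.base_channels
        gu, gskip1 = g[:, :c2], g[:, c2:]
        g = _upsample2_back(gu)
        g = self.relu[3].backward(g)
        g, grads[3] = self.conv4.backward(g)
        g = self.relu[2].backward(g)
        g, grads[2] = self.conv3.backward(g)
        g = _avgpool2_back(g, self._skip_shape)
        g = g + gskip1
        c = self.base_channels
        ge1a, ge2 = g[:, :c], g[:, c:]
        g = self.relu[1].backward(ge2)
        g, grads[1] = self.conv2.backward(g)
        g = g + ge1a
        g = self.relu[0].backward(g)
        g, grads[0] = self.conv1.backward(g)
        return [gr for i in range(6) for gr in grads[i]]


# ---------------------------------------------------------------------------
# model bundle


@dataclass
class ModelBundle:
    """A trained network plus its provenance and training history."""

    architecture: dict
    weights: list
    history: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def build(self) -> DenseSuppressionNet:
        net = DenseSuppressionNet(
            in_channels=self.architecture["in_channels"],
            base_channels=self.architecture["base_channels"],
            seed=0,
        )
        net.set_params(self.weights)
        return net

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *self.weights)
        meta = {
            "architecture": self.architecture,
            "history": self.history,
            "provenance": self.provenance,
            "n_arrays": len(self.weights),
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        with np.load(path.with_suffix(".npz")) as z:
            weights = [z[f"arr_{i}"] for i in range(meta["n_arrays"])]
        return cls(
            architecture=meta["architecture"],
            weights=weights,
            history=meta["history"],
            provenance=meta["provenance"],
        )


# ---------------------------------------------------------------------------
# input assembly


def assemble_input(image: np.ndarray, edge_mask: np.ndarray) -> np.ndarray:
    """Stack [intensity, Sobel-x, Sobel-y, edge mask] as a (4, H, W) array.

    Gradients are 3x3 Sobel responses of the raw intensity image,
    standardized afterwards to zero mean and unit-ish scale.
    """
    image = np.asarray(image, dtype=float)
    edge_mask = np.asarray(edge_mask, dtype=float)
    if image.shape != edge_mask.shape:
        raise ValueError("image and edge mask shapes differ")
    gx = ndimage.sobel(image, axis=1, mode="reflect")
    gy = ndimage.sobel(image, axis=0, mode="reflect")

    def standardize(a):
        sd = a.std()
        return (a - a.mean()) / sd if sd > 1e-12 else a - a.mean()

    return np.stack([image, standardize(gx), standardize(gy), edge_mask])


# ---------------------------------------------------------------------------
# training


class TrainingDivergedError(RuntimeError):
    pass


def _augment(x: np.ndarray, y: np.ndarray, config: TrainConfig, rng: np.random.Generator):
    """Random rotation/translation/flip applied consistently to x and y."""
    if config.augment_flip and rng.random() < 0.5:
        x = x[..., ::-1].copy()
        y = y[..., ::-1].copy()
    if config.augment_rotate:
        ang = rng.uniform(-10, 10)
        x = np.stack([ndimage.rotate(ch, ang, reshape=False, order=1, mode="nearest") for ch in x])
        y = ndimage.rotate(y, ang, reshape=False, order=1, mode="nearest")
    if config.augment_translate:
        lim = 0.05 * x.shape[-1]
        dr, dc = rng.uniform(-lim, lim, size=2)
        x = np.stack([ndimage.shift(ch, (dr, dc), order=1, mode="nearest") for ch in x])
        y = ndimage.shift(y, (dr, dc), order=1, mode="nearest")
    return x, y


def _loss_and_grad(pred: np.ndarray, target: np.ndarray, kind: str):
    if kind == "mse":
        diff = pred - target
        return float(np.mean(diff**2)), 2.0 * diff / diff.size
    # bce on a sigmoid head
    z = 1.0 / (1.0 + np.exp(-np.clip(pred, -30, 30)))
    eps = 1e-7
    zc = np.clip(z, eps, 1 - eps)
    loss = float(-np.mean(target * np.log(zc) + (1 - target) * np.log(1 - zc)))
    return loss, (z - target) / target.size


class _Adam:
    def __init__(self, params, lr):
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params, grads):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1**self.t)
            vh = self.v[i] / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def _normalize_inputs(x: np.ndarray) -> np.ndarray:
    out = x.copy()
    sd = out[0].std()
    out[0] = (out[0] - out[0].mean()) / sd if sd > 1e-12 else out[0] - out[0].mean()
    return out


def _train(
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    in_channels: int,
    init: ModelBundle | None,
    provenance: dict,
) -> ModelBundle:
    if len(dataset) < 1:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(config.seed)
    if init is not None:
        if init.architecture["in_channels"] != in_channels:
            raise ValueError("channel mismatch between init bundle and dataset")
        net = DenseSuppressionNet(in_channels, init.architecture["base_channels"], config.seed)
        net.set_params(init.weights)
    else:
        net = DenseSuppressionNet(in_channels, config.base_channels, config.seed)

    xs, ys = [], []
    for x, y in dataset:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[0] != in_channels:
            raise ValueError(f"expected {in_channels}-channel inputs, got {x.shape[0]}")
        if config.normalize:
            x = _normalize_inputs(x)
        xs.append(x)
        ys.append(np.asarray(y, dtype=float)[None])

    opt = _Adam(net.params, config.lr0)
    history = []
    n = len(xs)
    order = np.arange(n)
    steps_per_epoch = max(1, int(np.ceil(n / config.batch_size)))
    for epoch in range(config.epochs):
        rng.shuffle(order)
        epoch_loss = 0.0
        for s in range(steps_per_epoch):
            idx = order[s * config.batch_size : (s + 1) * config.batch_size]
            if len(idx) == 0:
                continue
            bx, by = [], []
            for i in idx:
                x, y = xs[i], ys[i][0]
                x, y = _augment(x, y, config, rng)
                bx.append(x)
                by.append(y[None])
            xb = np.stack(bx)
            yb = np.stack(by)
            opt.lr = cosine_warm_restart_lr(
                epoch + s / steps_per_epoch, config.lr0, config.t0, config.t_mult
            )
            pred = net.forward(xb)
            loss, g = _loss_and_grad(pred, yb, config.loss)
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"loss became {loss} at epoch {epoch} step {s}; "
                    f"lr0={config.lr0}, batch={config.batch_size}"
                )
            grads = net.backward(g)
            opt.step(net.params, grads)
            epoch_loss += loss
        history.append(epoch_loss / steps_per_epoch)

    arch = {"in_channels": in_channels, "base_channels": net.base_channels, "loss": config.loss}
    prov = dict(provenance)
    if init is not None:
        prov["pretrained_on"] = init.provenance.get("trained_on", "unknown")
    return ModelBundle(
        architecture=arch,
        weights=[p.copy() for p in net.params],
        history=history,
        provenance=prov,
    )


def train_edge_model(
    dataset: list[tuple[np.ndarray, np.ndarray]], config: TrainConfig
) -> ModelBundle:
    """Train the edge network on (image, target) pairs.

    Targets are distance-transform encodings (``mse`` loss) or binary
    masks (``bce`` segmentation baseline).  Inputs are single-channel.
    One model handles one bone category; train three for the three
    categories.
    """
    if len(dataset) < 1:
        raise ValueError("need at least 1 training sample")
    return _train(dataset, config, in_channels=1, init=None, provenance={"task": "edge", "trained_on": "user-dataset"})


def train_suppressor(
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: TrainConfig,
    init: ModelBundle | None = None,
) -> ModelBundle:
    """Train the bone-prediction network on (4-channel input, bone) pairs.

    ``init`` fine-tunes from a pretrained bundle (transfer learning);
    provenance records the lineage.  Supports the four configurations:
    scratch, +edge channel (encoded in the inputs), +pretrain, and both.
    """
    if len(dataset) < 1:
        raise ValueError("need at least 1 training sample")
    in_ch = np.asarray(dataset[0][0]).shape[0] if np.asarray(dataset[0][0]).ndim == 3 else 1
    return _train(
        dataset,
        config,
        in_channels=in_ch,
        init=init,
        provenance={"task": "suppressor", "trained_on": "user-dataset"},
    )


def predict(model: ModelBundle, x: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Forward one input through a bundle; clips mse outputs to [0, 1]."""
    net = model.build()
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.shape[0] != model.architecture["in_channels"]:
        raise ValueError(
            f"model expects {model.architecture['in_channels']} channels, got {x.shape[0]}"
        )
    if normalize:
        x = _normalize_inputs(x)
    out = net.forward(x[None])[0, 0]
    if model.architecture.get("loss") == "bce":
        return 1.0 / (1.0 + np.exp(-np.clip(out, -30, 30)))
    return np.clip(out, 0.0, 1.0)


def validation_loss(model: ModelBundle, dataset, normalize: bool = True) -> float:
    """Mean loss of a bundle over a dataset, without training."""
    net = model.build()
    total = 0.0
    for x, y in dataset:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if normalize:
            x = _normalize_inputs(x)
        pred = net.forward(x[None])
        loss, _ = _loss_and_grad(pred, np.asarray(y, dtype=float)[None, None], model.architecture.get("loss", "mse"))
        total += loss
    return total / len(dataset)


def predict_decomposition(
    model: ModelBundle, image: np.ndarray, edge_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fully automated suppression: bone = network output (clipped >= 0),
    soft = image - bone."""
    x = assemble_input(image, edge_mask)
    bone = predict(model, x)
    bone = np.maximum(bone, 0.0)
    soft = np.asarray(image, dtype=float) - bone
    return bone, soft
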