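"""A small convolutional network for per-video fish identification.

The classifier maps a 65x65 grayscale head feature map to one of
``num_fish`` identities.  Architecture (all convolutions 3x3, stride 1,
no padding; all max-poolings 2x2, stride 2, floor division on odd
sizes):

    input 65x65x1
    -> conv 30 ch  + maxpool          (63 -> 31)
    -> conv 50 ch  + maxpool          (29 -> 14)
    -> conv 80 ch  + maxpool          (12 -> 6)
    -> conv 70 ch  + maxpool + ReLU   ( 4 -> 2)
    -> dropout(0.2) + fully connected 4*num
    -> fully connected num -> class scores

ReLU appears only after the fourth convolution block; the max-pooling
stages are the only other nonlinearity.  Training is plain stochastic
gradient descent on the softmax cross-entropy at a fixed learning rate
(defaults: 30 epochs, lr 0.005), with dropout active only in training
mode.  Implemented directly on numpy (im2col convolutions), which is
entirely adequate at the few-thousand-image scale of per-video training.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONV_CHANNELS = (30, 50, 80, 70)
KERNEL = 3


@dataclass
class TrainReport:
    epochs_run: int
    train_loss: list[float] = field(default_factory=list)
    test_error: float = float("nan")


def _im2col(x: np.ndarray) -> np.ndarray:
    """(B, C, H, W) -> (B, H-2, W-2, C*9) patch matrix for a 3x3 kernel."""
    sw = np.lib.stride_tricks.sliding_window_view(x, (KERNEL, KERNEL), axis=(2, 3))
    # (B, C, H', W', 3, 3) -> (B, H', W', C, 3, 3)
    sw = sw.transpose(0, 2, 3, 1, 4, 5)
    b, hh, ww = sw.shape[:3]
    return np.ascontiguousarray(sw).reshape(b, hh, ww, -1)


def _clip(g: np.ndarray, max_norm: float = 5.0) -> np.ndarray:
    # per-tensor gradient-norm ceiling: keeps plain SGD at a fixed
    # learning rate stable through the linear convolution stack
    norm = float(np.linalg.norm(g))
    return g * (max_norm / norm) if norm > max_norm else g


class _Conv:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 first: bool = False):
        fan_in = c_in * KERNEL * KERNEL
        fan_out = c_out * KERNEL * KERNEL
        self.w = rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), (c_out, fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, np.float32)
        self.c_in = c_in
        self.first = first  # input layer: no gradient w.r.t. x needed
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        cols = _im2col(x)
        b, hh, ww, k = cols.shape
        out = (cols.reshape(-1, k) @ self.w.T + self.b).reshape(b, hh, ww, -1)
        if keep:
            self._cols, self._xshape = cols, x.shape
        return out.transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray, lr: float) -> np.ndarray | None:
        # dout: (B, C_out, H', W')
        d = np.ascontiguousarray(dout.transpose(0, 2, 3, 1))  # (B, H', W', C_out)
        b, hh, ww, c_out = d.shape
        dflat = d.reshape(-1, c_out)
        cols = self._cols.reshape(-1, self._cols.shape[-1])
        dw = dflat.T @ cols / b
        db = dflat.sum(axis=0) / b
        dx = None
        if not self.first:
            bs, c, h, w = self._xshape
            # accumulate in channels-last layout so the shifted adds are
            # contiguous over the channel axis
            w_kl = self.w.reshape(c_out, c, KERNEL, KERNEL).transpose(0, 2, 3, 1).reshape(c_out, -1)
            dcols = (dflat @ w_kl).reshape(b, hh, ww, KERNEL, KERNEL, c)
            dxl = np.zeros((b, h, w, c), np.float32)
            for di in range(KERNEL):
                for dj in range(KERNEL):
                    dxl[:, di : di + hh, dj : dj + ww, :] += dcols[:, :, :, di, dj, :]
            dx = np.ascontiguousarray(dxl.transpose(0, 3, 1, 2))
        self.w -= lr * _clip(dw)
        self.b -= lr * _clip(db)
        return dx


class _MaxPool:
    """2x2/stride-2 max pooling; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        b, c, h, w = x.shape
        hh, ww = h // 2, w // 2
        xr = x[:, :, : 2 * hh, : 2 * ww].reshape(b, c, hh, 2, ww, 2)
        out = xr.max(axis=(3, 5))
        if keep:
            self._xr, self._out, self._inshape = xr, out, x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        # route the gradient to every element equal to the window max
        # (exact float ties are vanishingly rare after convolution)
        b, c, h, w = self._inshape
        hh, ww = h // 2, w // 2
        mask = self._xr == self._out[:, :, :, None, :, None]
        dxr = mask * dout[:, :, :, None, :, None]
        dx = np.zeros(self._inshape, np.float32)
        dx[:, :, : 2 * hh, : 2 * ww] = dxr.reshape(b, c, 2 * hh, 2 * ww)
        return dx


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / (n_in + n_out)), (n_out, n_in)).astype(np.float32)
        self.b = np.zeros(n_out, np.float32)

    def forward(self, x: np.ndarray, keep: bool) -> np.ndarray:
        if keep:
            self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout: np.ndarray, lr: float) -> np.ndarray:
        b = dout.shape[0]
        dw = dout.T @ self._x / b
        db = dout.sum(axis=0) / b
        dx = dout @ self.w
        self.w -= lr * _clip(dw)
        self.b -= lr * _clip(db)
        return dx


class FishCNN:
    """Per-video appearance classifier (see module docstring)."""

    def __init__(self, num_fish: int, seed: int = 0, *,
                 dropout: float = 0.2, relu_all_convs: bool = False,
                 input_size: int = 65):
        if num_fish < 2:
            raise ValueError("a classifier needs at least 2 identities")
        self.num_fish = num_fish
        self.dropout = dropout
        self.relu_all_convs = relu_all_convs
        self.input_size = input_size
        # input standardisation scalars, fitted on the training set
        self.input_mean = 0.75
        self.input_std = 0.1
        rng = np.random.default_rng(seed)
        self.convs: list[_Conv] = []
        self.pools: list[_MaxPool] = []
        c_in, size = 1, input_size
        self.spatial_sizes = [size]
        for c_out in CONV_CHANNELS:
            self.convs.append(_Conv(c_in, c_out, rng, first=not self.convs))
            self.pools.append(_MaxPool())
            size = size - (KERNEL - 1)
            self.spatial_sizes.append(size)
            size //= 2
            self.spatial_sizes.append(size)
            c_in = c_out
        self.flat_dim = c_in * size * size
        self.fc1 = _Dense(self.flat_dim, 4 * num_fish, rng)
        self.fc2 = _Dense(4 * num_fish, num_fish, rng)

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, *, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Class scores for a batch of maps (B, 65, 65) scaled to [0, 1]."""
        h = x.astype(np.float32)[:, None]
        self._relu_masks: list[np.ndarray | None] = []
        for i, (conv, pool) in enumerate(zip(self.convs, self.pools)):
            h = conv.forward(h, train)
            h = pool.forward(h, train)
            if i == len(self.convs) - 1 or self.relu_all_convs:
                mask = h > 0
                h = h * mask
                self._relu_masks.append(mask if train else None)
            else:
                self._relu_masks.append(None)
        h = h.reshape(h.shape[0], -1)
        if train and self.dropout > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng for dropout")
            keep = (rng.random(h.shape) >= self.dropout).astype(np.float32)
            h = h * keep / (1.0 - self.dropout)
            self._drop_mask = keep
        else:
            self._drop_mask = None
        h = self.fc1.forward(h, train)
        return self.fc2.forward(h, train)

    def _backward(self, dscores: np.ndarray, lr: float) -> None:
        d = self.fc2.backward(dscores, lr)
        d = self.fc1.backward(d, lr)
        if self._drop_mask is not None:
            d = d * self._drop_mask / (1.0 - self.dropout)
        b = d.shape[0]
        size = self.spatial_sizes[-1]
        d = d.reshape(b, CONV_CHANNELS[-1], size, size)
        for i in range(len(self.convs) - 1, -1, -1):
            if self._relu_masks[i] is not None:
                d = d * self._relu_masks[i]
            d = self.pools[i].backward(d)
            d = self.convs[i].backward(d, lr)

    # ------------------------------------------------------------------
    def normalize(self, maps: np.ndarray) -> np.ndarray:
        """0-255 grayscale maps -> standardised network inputs."""
        return (np.asarray(maps, np.float32) / 255.0 - self.input_mean) / self.input_std

    def predict_scores(self, maps: np.ndarray, batch_size: int = 128) -> np.ndarray:
        x = self.normalize(maps)
        out = []
        for i in range(0, len(x), batch_size):
            out.append(self.forward(x[i : i + batch_size]))
        return np.concatenate(out) if out else np.empty((0, self.num_fish))

    def predict(self, maps: np.ndarray) -> np.ndarray:
        return self.predict_scores(maps).argmax(axis=1)


def save_checkpoint(model: FishCNN, path) -> None:
    """Persist weights plus the architecture description (.npz)."""
    arrays = {}
    for i, conv in enumerate(model.convs):
        arrays[f"conv{i}_w"] = conv.w
        arrays[f"conv{i}_b"] = conv.b
    for name, layer in (("fc1", model.fc1), ("fc2", model.fc2)):
        arrays[f"{name}_w"] = layer.w
        arrays[f"{name}_b"] = layer.b
    np.savez(
        path, num_fish=model.num_fish, input_size=model.input_size,
        dropout=model.dropout, relu_all_convs=model.relu_all_convs,
        input_mean=model.input_mean, input_std=model.input_std,
        channels=np.asarray(CONV_CHANNELS), **arrays,
    )


def load_checkpoint(path, num_fish: int | None = None) -> FishCNN:
    """Restore a checkpoint; refuses one trained for a different
    number of fish than the configuration expects."""
    with np.load(path) as z:
        stored = int(z["num_fish"])
        if num_fish is not None and stored != num_fish:
            raise ValueError(
                f"checkpoint was trained for {stored} fish, "
                f"configuration expects {num_fish}"
            )
        model = FishCNN(stored, seed=0,
                        dropout=float(z["dropout"]),
                        relu_all_convs=bool(z["relu_all_convs"]),
                        input_size=int(z["input_size"]))
        model.input_mean = float(z["input_mean"])
        model.input_std = float(z["input_std"])
        for i, conv in enumerate(model.convs):
            conv.w = z[f"conv{i}_w"]
            conv.b = z[f"conv{i}_b"]
        for name, layer in (("fc1", model.fc1), ("fc2", model.fc2)):
            layer.w = z[f"{name}_w"]
            layer.b = z[f"{name}_b"]
    return model


def _softmax_ce(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    z = scores - scores.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = len(labels)
    loss = float(-np.log(p[np.arange(n), labels] + 1e-12).mean())
    dscores = p
    dscores[np.arange(n), labels] -= 1.0
    return loss, dscores


def train_classifier(
    model: FishCNN,
    train_maps: np.ndarray,
    train_labels: np.ndarray,
    test_maps: np.ndarray | None = None,
    test_labels: np.ndarray | None = None,
    *,
    epochs: int = 30,
    lr: float = 0.005,
    batch_size: int = 64,
    seed: int = 0,
) -> TrainReport:
    """Plain SGD on softmax cross-entropy; one epoch = one full pass.

    Raises on divergence (non-finite loss).  Returns per-epoch mean
    training loss and, when a test split is given, the final test error
    rate.
    """
    labels = np.asarray(train_labels)
    if np.asarray(train_maps).size == 0 or np.unique(labels).size < 2:
        raise ValueError("training set must be non-empty with >= 2 labels")
    raw = np.asarray(train_maps, np.float32) / 255.0
    model.input_mean = float(raw.mean())
    model.input_std = float(raw.std()) or 1.0
    maps = model.normalize(train_maps)
    rng = np.random.default_rng(seed)
    report = TrainReport(epochs_run=0)
    for epoch in range(epochs):
        order = rng.permutation(len(maps))
        losses = []
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            scores = model.forward(maps[idx], train=True, rng=rng)
            loss, dscores = _softmax_ce(scores, labels[idx])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            model._backward(dscores, lr)
            losses.append(loss)
        report.train_loss.append(float(np.mean(losses)))
        report.epochs_run = epoch + 1
    if test_maps is not None and len(test_maps):
        pred = model.predict(np.asarray(test_maps, np.float32))
        report.test_error = float(np.mean(pred != np.asarray(test_labels)))
    return report
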