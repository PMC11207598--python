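"""Proof-of-concept markerless head-pose CNN.

A small regression network maps a 4-channel stack of in-bore camera frames
(two views at time t0, the same two views at t1) to the 6-DOF pose *delta*
between the two timepoints -- the quantity MRI motion correction needs.

Architecture: three convolutional blocks of increasing depth (4, 16, 64),
each containing two 3x3 stride-1 pad-1 convolutions with ReLU, a 20%
dropout layer and a 2x2 stride-2 max-pool; then a fully-connected head
(flatten -> 128 ReLU -> 6 linear).  A 180 x 120 input traverses the three
pool stages to 22 x 15 (floor division at odd sizes).  Training uses Adam
(lr 1e-4, weight decay 1e-5), MSE loss on labels min-max scaled to [0, 1]
per DOF, Kaiming initialisation, and no data augmentation (augmentations
that move pixels would corrupt the sub-pixel pose signal).

The network and its backward pass are implemented directly on numpy (im2col
+ GEMM); training the desk-scale dataset takes minutes on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.preprocessing import MinMaxScaler

from .detection import Frame

__all__ = [
    "NetworkConfig",
    "TrainConfig",
    "LabelScaler",
    "PoseRegressionCNN",
    "preprocess_inputs",
    "scale_labels",
    "unscale_predictions",
    "train",
    "evaluate",
]


# ---------------------------------------------------------------------------
# Input preprocessing
# ---------------------------------------------------------------------------

def _resize(img: np.ndarray, out_hw: tuple[int, int]) -> np.ndarray:
    """Area-style resize; exact block mean when the factor is integer."""
    h, w = img.shape
    oh, ow = out_hw
    if h % oh == 0 and w % ow == 0:
        return img.reshape(oh, h // oh, ow, w // ow).mean(axis=(1, 3))
    from skimage.transform import resize as sk_resize
    return sk_resize(img, out_hw, order=1, anti_aliasing=True, preserve_range=True)


def preprocess_inputs(frames, out_hw: tuple[int, int] = (120, 180)) -> np.ndarray:
    """Four frames -> (4, H, W) float32 stack in [0, 1].

    Channel order is fixed: cam1@t0, cam2@t0, cam1@t1, cam2@t1.  Pixel
    values are scaled from [0, 255] to [0, 1] and each frame resized to
    180 x 120 (width x height).
    """
    if len(frames) != 4:
        raise ValueError("expected exactly 4 frames (two views at two timepoints)")
    arrays = [f.pixels if isinstance(f, Frame) else np.asarray(f, dtype=np.float32)
              for f in frames]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all four frames must share one resolution")
    stack = np.stack([_resize(a.astype(np.float32) / 255.0, out_hw) for a in arrays])
    return stack.astype(np.float32)


# ---------------------------------------------------------------------------
# Label scaling
# ---------------------------------------------------------------------------

class LabelScaler:
    """Per-DOF min-max scaling to [0, 1], fit on train+validation labels only.

    The fitted mapping is saved with the model and reused at inference, so
    test labels transformed with it may legitimately fall outside [0, 1].
    """

    def __init__(self) -> None:
        self._scaler = MinMaxScaler()
        self._fitted = False

    def fit(self, labels: np.ndarray) -> "LabelScaler":
        labels = np.asarray(labels, dtype=float)
        if labels.ndim != 2 or labels.shape[1] != 6:
            raise ValueError("labels must be (N, 6)")
        rng = labels.max(axis=0) - labels.min(axis=0)
        if np.any(rng <= 0):
            raise ValueError("degenerate DOF: max equals min in the fitting labels")
        self._scaler.fit(labels)
        self._fitted = True
        return self

    def transform(self, labels: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("scaler not fitted")
        return self._scaler.transform(np.asarray(labels, dtype=float))

    def inverse(self, scaled: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise RuntimeError("scaler not fitted")
        return self._scaler.inverse_transform(np.asarray(scaled, dtype=float))

    @property
    def data_min(self) -> np.ndarray:
        return self._scaler.data_min_

    @property
    def data_max(self) -> np.ndarray:
        return self._scaler.data_max_


def scale_labels(labels: np.ndarray, scaler: LabelScaler) -> np.ndarray:
    return scaler.transform(labels)


def unscale_predictions(outputs: np.ndarray, scaler: LabelScaler) -> np.ndarray:
    return scaler.inverse(outputs)


# ---------------------------------------------------------------------------
# Layers (NHWC activations, float32)
# ---------------------------------------------------------------------------

class _Conv3x3:
    """3x3 stride-1 pad-1 convolution as nine shifted GEMMs (NHWC).

    The shifted-slice formulation keeps every GEMM operand nearly contiguous,
    which is far faster in numpy than an explicit im2col gather.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / (9 * c_in))
        self.W = rng.normal(0.0, std, (3, 3, c_in, c_out)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.c_in, self.c_out = c_in, c_out

    def _slices(self, key, shape):
        # persistent per-layer scratch (avoids large-allocation churn, which
        # costs as much as the GEMMs themselves at these sizes)
        store = getattr(self, "_scratch", None)
        if store is None:
            store = self._scratch = {}
        if key not in store or store[key][0].shape != shape:
            store[key] = [np.empty(shape, dtype=np.float32) for _ in range(9)] \
                if key == "cols" else np.empty(shape, dtype=np.float32)
        return store[key]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        out = self._slices("out", (n * h * w, self.c_out))
        out[:] = self.b
        tmp = self._slices("tmp", (n * h * w, self.c_out))
        cols = self._slices("cols", (n, h, w, c))
        for di in range(3):
            for dj in range(3):
                buf = cols[3 * di + dj]
                np.copyto(buf, xp[:, di:di + h, dj:dj + w, :])
                np.dot(buf.reshape(-1, c), self.W[di, dj], out=tmp)
                out += tmp
        if train:
            self._shape = (n, h, w, c)
        return out.reshape(n, h, w, self.c_out).copy()

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, h, w, c = self._shape
        cols = self._scratch["cols"]
        dflat = np.ascontiguousarray(dout.reshape(-1, self.c_out))
        self.db[...] = dflat.sum(axis=0)
        # dx is itself a 3x3 convolution of dout with the spatially flipped,
        # in/out-transposed kernel -- accumulated contiguously like forward
        dp = np.pad(dout, ((0, 0), (1, 1), (1, 1), (0, 0)))
        dx = np.zeros((n * h * w, c), dtype=np.float32)
        dbuf = self._slices("dbuf", (n, h, w, self.c_out))
        dtmp = self._slices("dtmp", (n * h * w, c))
        for di in range(3):
            for dj in range(3):
                self.dW[di, dj] = cols[3 * di + dj].reshape(-1, c).T @ dflat
                np.copyto(dbuf, dp[:, di:di + h, dj:dj + w, :])
                np.dot(dbuf.reshape(-1, self.c_out), self.W[2 - di, 2 - dj].T, out=dtmp)
                dx += dtmp
        return dx.reshape(n, h, w, c)

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


class _ReLU:
    def forward(self, x, train):
        if train:
            self._mask = x > 0
            return x * self._mask
        return np.maximum(x, 0)

    def backward(self, dout):
        return dout * self._mask

    def params(self):
        return []


class _Dropout:
    def __init__(self, rate: float):
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape, dtype=np.float32) < keep) / np.float32(keep)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask

    def params(self):
        return []


class _MaxPool2:
    def forward(self, x, train):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        win = x[:, :h2 * 2, :w2 * 2].reshape(n, h2, 2, w2, 2, c)
        out = np.maximum(np.maximum(win[:, :, 0, :, 0], win[:, :, 0, :, 1]),
                         np.maximum(win[:, :, 1, :, 0], win[:, :, 1, :, 1]))
        if train:
            self._cache = (win, out, (n, h, w, c))
        return out

    def backward(self, dout):
        win, out, (n, h, w, c) = self._cache
        h2, w2 = out.shape[1], out.shape[2]
        # ties split the gradient equally; all ops on contiguous 4-D arrays
        sels = [[win[:, :, a, :, b] == out for b in (0, 1)] for a in (0, 1)]
        counts = sum(s.astype(np.float32) for row in sels for s in row)
        contrib = dout / counts
        dwin = np.empty((n, h2, 2, w2, 2, c), dtype=dout.dtype)
        for a in (0, 1):
            for b in (0, 1):
                np.multiply(contrib, sels[a][b], out=dwin[:, :, a, :, b])
        dx = np.zeros((n, h, w, c), dtype=dout.dtype)
        dx[:, :h2 * 2, :w2 * 2] = dwin.reshape(n, h2 * 2, w2 * 2, c)
        self._cache = None
        return dx

    def params(self):
        return []


class _Flatten:
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)

    def params(self):
        return []


class _Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / n_in)
        self.W = rng.normal(0.0, std, (n_in, n_out)).astype(np.float32)
        self.b = np.zeros(n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T

    def params(self):
        return [(self.W, self.dW), (self.b, self.db)]


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Fig-style three-block regression CNN configuration."""

    block_depths: tuple[int, ...] = (4, 16, 64)
    in_channels: int = 4
    input_hw: tuple[int, int] = (120, 180)
    fc_hidden: int = 128
    dropout: float = 0.2
    n_outputs: int = 6

    def __post_init__(self) -> None:
        if len(self.block_depths) != 3:
            raise ValueError("the architecture uses exactly three convolutional blocks")
        if self.n_outputs != 6:
            raise ValueError("the regression head outputs the 6 DOF")

    def feature_hw(self) -> tuple[int, int]:
        h, w = self.input_hw
        for _ in self.block_depths:
            h, w = h // 2, w // 2
        return h, w

    def flat_features(self) -> int:
        h, w = self.feature_hw()
        return h * w * self.block_depths[-1]


class PoseRegressionCNN:
    """The three-block convolutional 6-DOF delta-pose regressor."""

    def __init__(self, config: NetworkConfig | None = None, seed: int = 0):
        self.config = config or NetworkConfig()
        rng = np.random.default_rng(seed)
        cfg = self.config
        self.layers = []
        self._dropouts = []
        c_prev = cfg.in_channels
        for depth in cfg.block_depths:
            self.layers += [_Conv3x3(c_prev, depth, rng), _ReLU(),
                            _Conv3x3(depth, depth, rng), _ReLU()]
            drop = _Dropout(cfg.dropout)
            self._dropouts.append(drop)
            self.layers += [drop, _MaxPool2()]
            c_prev = depth
        self.layers.append(_Flatten())
        if cfg.fc_hidden:
            self.layers += [_Linear(cfg.flat_features(), cfg.fc_hidden, rng), _ReLU(),
                            _Linear(cfg.fc_hidden, cfg.n_outputs, rng)]
        else:  # direct linear readout of the flattened features
            self.layers.append(_Linear(cfg.flat_features(), cfg.n_outputs, rng))

    def _seed_dropout(self, rng: np.random.Generator) -> None:
        for d in self._dropouts:
            d.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """x: (N, C, H, W) float32 -> (N, 6)."""
        a = np.ascontiguousarray(np.transpose(x, (0, 2, 3, 1)))
        for layer in self.layers:
            a = layer.forward(a, train)
        return a

    def backward(self, dout: np.ndarray) -> None:
        d = dout
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameters(self):
        out = []
        for layer in self.layers:
            out += layer.params()
        return out

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [self.forward(x[i:i + batch_size].astype(np.float32))
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs, axis=0)


class _Adam:
    """Adam with decoupled-from-nothing L2 weight decay (grad += wd * param)."""

    def __init__(self, params, lr: float, weight_decay: float):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            gw = g + self.wd * p
            m *= self.b1
            m += (1 - self.b1) * gw
            v *= self.b2
            v += (1 - self.b2) * gw * gw
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# ---------------------------------------------------------------------------
# Training and evaluation
# ---------------------------------------------------------------------------

@dataclass
class TrainConfig:
    lr: float = 1e-4
    weight_decay: float = 1e-5
    epochs: int = 100
    batch_size: int = 32
    split: tuple[int, int, int] = (1400, 400, 200)
    seed: int = 0
    shuffle: bool = True   # training (and the train+val pool); never the test set

    def __post_init__(self) -> None:
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if min(self.split) <= 0:
            raise ValueError("all split sizes must be positive")


@dataclass
class TrainedModel:
    model: PoseRegressionCNN
    scaler: LabelScaler
    history: dict

    def predict_unscaled(self, x: np.ndarray) -> np.ndarray:
        return unscale_predictions(self.model.predict(x), self.scaler)


def split_dataset(n: int, split: tuple[int, int, int]):
    """Sequential train/val/test index split (test isolation by position)."""
    n_train, n_val, n_test = split
    if n_train + n_val + n_test != n:
        raise ValueError(f"split {split} does not sum to dataset size {n}")
    idx = np.arange(n)
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


def train(x: np.ndarray, y: np.ndarray, net: NetworkConfig | None = None,
          cfg: TrainConfig | None = None, verbose: bool = False) -> TrainedModel:
    """Train the delta-pose CNN.

    ``x``: (N, C, H, W) float32 input stacks; ``y``: (N, 6) unscaled pose
    deltas.  The label scaler is fit on the train+validation labels only and
    stored with the model; validation loss is computed without gradient
    updates; the test partition is never touched here.
    """
    cfg = cfg or TrainConfig()
    net = net or NetworkConfig()
    tr_idx, va_idx, te_idx = split_dataset(len(x), cfg.split)
    if len(tr_idx) == 0 or len(va_idx) == 0:
        raise ValueError("empty split")
    scaler = LabelScaler().fit(np.asarray(y)[np.concatenate([tr_idx, va_idx])])
    ys = scaler.transform(y).astype(np.float32)

    rng = np.random.default_rng(cfg.seed)
    model = PoseRegressionCNN(net, seed=int(rng.integers(2 ** 31)))
    model._seed_dropout(np.random.default_rng(int(rng.integers(2 ** 31))))
    opt = _Adam(model.parameters(), cfg.lr, cfg.weight_decay)

    history = {"train_loss": [], "val_loss": []}
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx) if cfg.shuffle else tr_idx
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            b = order[i:i + cfg.batch_size]
            xb = x[b].astype(np.float32)
            yb = ys[b]
            out = model.forward(xb, train=True)
            diff = out - yb
            loss = float(np.mean(diff ** 2))
            model.backward((2.0 / diff.size) * diff.astype(np.float32))
            opt.step()
            losses.append(loss)
        val_pred = model.predict(x[va_idx])
        val_loss = float(np.mean((val_pred - ys[va_idx]) ** 2))
        history["train_loss"].append(float(np.mean(losses)))
        history["val_loss"].append(val_loss)
        if verbose:
            print(f"epoch {epoch + 1:3d}  train {history['train_loss'][-1]:.5f}  "
                  f"val {val_loss:.5f}")
    return TrainedModel(model=model, scaler=scaler, history=history)


def render_delta_pose_dataset(trace, params=None, resolution=(180, 120),
                              noise_sigma: float = 0.0, seed: int = 0,
                              out_hw: tuple[int, int] = (120, 180)):
    """Render the two in-bore camera views along a trajectory and assemble
    (stack, delta) training pairs.

    Returns ``(x, y)``: x is (N-1, 4, H, W) float32 4-channel stacks of
    consecutive timepoints, y is (N-1, 6) unscaled pose deltas.  Frames are
    rendered once per timepoint and reused by the two pairs that share them.
    Renders are noiseless by default, matching a synthetic (ray-traced)
    training corpus; sensor noise can be added via ``noise_sigma``.
    """
    from .scene import HeadProxyParams, RenderOptions, inbore_camera, render_head_proxy

    params = params or HeadProxyParams()
    cams = [inbore_camera("left", resolution=resolution),
            inbore_camera("right", resolution=resolution)]
    opts = RenderOptions(noise_sigma=noise_sigma, supersample=2)
    rng = np.random.default_rng(seed)
    poses = trace.poses()
    if any(p is None for p in poses):
        raise ValueError("trajectory contains invalid frames")
    n = len(poses)
    frames = np.empty((n, 2) + (out_hw[0], out_hw[1]), dtype=np.float32)
    for i, p in enumerate(poses):
        for k, cam in enumerate(cams):
            f = render_head_proxy(p, cam, params, opts, rng=rng)
            frames[i, k] = _resize(f.pixels.astype(np.float32) / 255.0, out_hw)
    dof = trace.dof_array
    y = np.diff(dof, axis=0)
    x = np.concatenate([frames[:-1], frames[1:]], axis=1)  # cam1@t0,cam2@t0,cam1@t1,cam2@t1
    return x.astype(np.float32), y


def conv_features(model: PoseRegressionCNN, x: np.ndarray,
                  batch_size: int = 64) -> np.ndarray:
    """Flattened convolutional-stack features (the FC head's input)."""
    out = []
    for i in range(0, len(x), batch_size):
        a = np.ascontiguousarray(
            np.transpose(x[i:i + batch_size].astype(np.float32), (0, 2, 3, 1)))
        for layer in model.layers:
            a = layer.forward(a, False)
            if isinstance(layer, _Flatten):
                break
        out.append(a)
    return np.vstack(out)


def feature_information_baseline(x: np.ndarray, y: np.ndarray,
                                 train_idx, test_idx,
                                 ridge_rel: float = 1e-3, seed: int = 0) -> dict:
    """Per-DOF RMSE of a kernel-ridge readout of the *untrained* conv features.

    A diagnostic upper bound on what any training procedure could extract
    from the architecture's feature map: a closed-form L2-regularised linear
    readout of the randomly initialised convolutional stack.  Used to
    separate "the features do not carry the pose signal" from "the
    optimiser did not find it".
    """
    model = PoseRegressionCNN(NetworkConfig(), seed=seed)
    F = conv_features(model, x[train_idx]).astype(np.float64)
    Ft = conv_features(model, x[test_idx]).astype(np.float64)
    mu = F.mean(axis=0)
    F -= mu
    Ft -= mu
    ybar = np.asarray(y)[train_idx].mean(axis=0)
    K = F @ F.T
    lam = ridge_rel * float(np.mean(np.diag(K)))
    alpha = np.linalg.solve(K + lam * np.eye(len(F)), np.asarray(y)[train_idx] - ybar)
    pred = Ft @ (F.T @ alpha) + ybar
    rmse = np.sqrt(np.mean((pred - np.asarray(y)[test_idx]) ** 2, axis=0))
    names = ["x_mm", "y_mm", "z_mm", "pitch_deg", "yaw_deg", "roll_deg"]
    out = {n: float(r) for n, r in zip(names, rmse)}
    out["average"] = float(np.mean(rmse))
    return out


def evaluate(trained: TrainedModel, x: np.ndarray, y: np.ndarray) -> dict:
    """Per-DOF RMSE (mm / deg, unscaled) plus their unweighted average."""
    if len(x) == 0:
        raise ValueError("empty evaluation set")
    pred = trained.predict_unscaled(x)
    rmse = np.sqrt(np.mean((pred - np.asarray(y)) ** 2, axis=0))
    names = ["x_mm", "y_mm", "z_mm", "pitch_deg", "yaw_deg", "roll_deg"]
    out = {n: float(r) for n, r in zip(names, rmse)}
    out["average"] = float(np.mean(rmse))
    return out
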