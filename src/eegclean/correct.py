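"""Self-supervised gap interpolation ("frame interpolation") for
artifact correction.

A gap of G consecutive frames is removed from an epoch; the h frames
ending at the last clean sample before the gap and the h frames
starting at the first clean sample after it are stacked into a
channels x 2h context array.  One network per missing-frame offset
q in {0..G-1} is trained (on epochs flagged clean) to predict the
channel vector at its offset from that shared context; at the defaults
(h=32, G=40, fs=200 Hz) the training window is 32+40+32 = 104 samples
and the reconstructed segment is 200 ms.

The networks are compact 1-D convolutional encoders over the
channels x time context with a dense head emitting one frame (the
output of each model is a single channels-vector, so the decoder is
dense rather than a mirrored convolution stack).  They are implemented
in numpy with manual backpropagation and Adam, fully deterministic
given a seed, and independently trainable in parallel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .detect import DetectionResult
from .io_epochs import EpochSet

__all__ = [
    "GapSpec",
    "TrainingPair",
    "InterpolatorEnsemble",
    "build_training_pairs",
    "train_ensemble",
    "predict_gap",
    "locate_artifact_segment",
    "correct_epochs",
    "save_ensemble",
    "load_ensemble",
]

_EPS = 1e-12


@dataclass
class GapSpec:
    """A gap between clean samples t_b and t_e (exclusive), length G."""

    t_b: int  # last clean sample before the gap
    t_e: int  # first clean sample after the gap
    h: int

    @property
    def G(self) -> int:
        return self.t_e - self.t_b - 1

    def validate(self, n_samples: int) -> None:
        if self.G < 1:
            raise ValueError("gap must contain at least one sample")
        if self.t_b < self.h - 1 or self.t_e + self.h > n_samples:
            raise ValueError("context windows do not fit inside the epoch")


@dataclass
class TrainingPair:
    context: np.ndarray  # channels x 2h
    target: np.ndarray  # channels x G
    source_epoch: int


# ---------------------------------------------------------------------
# Minimal seeded neural network (conv1d encoder + dense head)
# ---------------------------------------------------------------------

class _Conv1d:
    def __init__(self, c_in: int, c_out: int, k: int, stride: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = rng.normal(0.0, scale, size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.k, self.stride = k, stride

    def out_width(self, w: int) -> int:
        return (w - self.k) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, Cin, W) -> (B, Cout, Wout), via contiguous im2col + matmul
        b = x.shape[0]
        win = sliding_window_view(x, self.k, axis=2)[:, :, :: self.stride, :]
        w_out = win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(b * w_out, -1)
        self._cols, self._wout = cols, w_out
        wmat = self.W.reshape(self.W.shape[0], -1).T  # (Cin*k, Cout)
        y = cols @ wmat + self.b
        return y.reshape(b, w_out, -1).transpose(0, 2, 1)

    def backward(self, x: np.ndarray, dy: np.ndarray) -> np.ndarray:
        b, c_out, w_out = dy.shape
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 1)).reshape(b * w_out, c_out)
        self.dW = (self._cols.T @ dyr).T.reshape(self.W.shape)
        self.db = dyr.sum(axis=0)
        dcols = dyr @ self.W.reshape(c_out, -1)  # (B*Wout, Cin*k)
        dwin = dcols.reshape(b, w_out, x.shape[1], self.k)
        dx = np.zeros_like(x)
        # scatter back through each kernel tap (k is small)
        span = (w_out - 1) * self.stride + 1
        for t in range(self.k):
            dx[:, :, t : t + span : self.stride] += dwin[:, :, :, t].transpose(0, 2, 1)
        return dx

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW = self._x.T @ dy
        self.db = dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.dW, self.db]


class _FrameNet:
    """Conv encoder over channels x 2h context -> one frame (channels,)."""

    def __init__(self, n_channels: int, width: int, hidden: int, seed: int):
        rng = np.random.default_rng(seed)
        self.convs = [
            _Conv1d(n_channels, 16, k=5, stride=2, rng=rng),
            _Conv1d(16, 32, k=5, stride=2, rng=rng),
            _Conv1d(32, 32, k=3, stride=2, rng=rng),
        ]
        w = width
        for c in self.convs:
            w = c.out_width(w)
            if w < 1:
                raise ValueError("context too short for the encoder stack")
        self.flat = 32 * w
        self.fc1 = _Dense(self.flat, hidden, rng)
        self.fc2 = _Dense(hidden, n_channels, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._acts = [x]
        h = x
        for c in self.convs:
            h = c.forward(h)
            self._acts.append(h)
            h = np.maximum(h, 0.0)
            self._acts.append(h)
        self._shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        z = self.fc1.forward(flat)
        self._z = z
        a = np.maximum(z, 0.0)
        return self.fc2.forward(a)

    def backward(self, dy: np.ndarray) -> None:
        da = self.fc2.backward(dy)
        dz = da * (self._z > 0)
        dflat = self.fc1.backward(dz)
        dh = dflat.reshape(self._shape)
        for i in reversed(range(len(self.convs))):
            pre = self._acts[2 * i + 1]
            dh = dh * (pre > 0)
            dh = self.convs[i].backward(self._acts[2 * i], dh)

    @property
    def layers(self):
        return self.convs + [self.fc1, self.fc2]


class _Adam:
    """Adam with decoupled weight decay (AdamW-style)."""

    def __init__(self, params, lr: float, weight_decay: float = 0.0):
        self.lr = lr
        self.wd = weight_decay
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            if self.wd and p.ndim > 1:  # decay weights, not biases
                p *= 1.0 - self.lr * self.wd
            p -= self.lr * (m / (1 - b1**self.t)) / (np.sqrt(v / (1 - b2**self.t)) + eps)


@dataclass
class InterpolatorEnsemble:
    """G trained networks, model q predicting the frame at gap offset q."""

    models: list
    h: int
    G: int
    fs: float
    n_channels: int
    context_mean: float
    context_scale: float
    training_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.models) != self.G:
            raise ValueError("ensemble must hold exactly G models")


# ---------------------------------------------------------------------
# Training-pair construction
# ---------------------------------------------------------------------

def build_training_pairs(
    clean: EpochSet,
    h: int = 32,
    G: int = 40,
    pairs_per_epoch: int = 1,
    seed: int = 0,
) -> list[TrainingPair]:
    """Cut random 2h+G windows from clean epochs into (context, target).

    The first h samples form the left stack, the last h the right stack,
    and the middle G are the prediction target.  Epochs shorter than
    2h+G are skipped (counted in the returned pairs' absence).
    """
    window = 2 * h + G
    rng = np.random.default_rng(seed)
    pairs: list[TrainingPair] = []
    for i in range(clean.n_epochs):
        n = clean.n_samples
        if n < window:
            continue
        for _ in range(pairs_per_epoch):
            start = int(rng.integers(0, n - window + 1))
            seg = clean.data[i, :, start : start + window]
            context = np.concatenate([seg[:, :h], seg[:, h + G :]], axis=1)
            target = seg[:, h : h + G]
            pairs.append(TrainingPair(context.copy(), target.copy(), i))
    return pairs


def train_ensemble(
    pairs: list[TrainingPair],
    h: int = 32,
    G: int = 40,
    fs: float = 200.0,
    hidden: int = 32,
    epochs: int = 30,
    lr: float = 2e-3,
    batch_size: int = 64,
    weight_decay: float = 0.05,
    seed: int = 0,
) -> InterpolatorEnsemble:
    """Train one frame-prediction network per gap offset.

    All G networks see the same channels x 2h contexts; model q is
    fitted (squared error, Adam) to the target column q.  The networks
    are independent, so they can be trained in parallel; training is
    deterministic given ``seed``.
    """
    if not pairs:
        raise ValueError("need at least one training pair")
    if G < 1:
        raise ValueError("G must be >= 1")
    contexts = np.stack([p.context for p in pairs])  # (N, C, 2h)
    targets = np.stack([p.target for p in pairs])  # (N, C, G)
    n, c, width = contexts.shape
    if width != 2 * h or targets.shape[2] != G:
        raise ValueError("pair geometry does not match (h, G)")
    mean = float(contexts.mean())
    scale = float(contexts.std()) or 1.0
    Xn = (contexts - mean) / scale
    bridge = _linear_bridge(contexts, h, G)
    models = []
    log: list[dict] = []
    for q in range(G):
        rng = np.random.default_rng(np.random.SeedSequence((seed, q)))
        net = _FrameNet(c, width, hidden, seed=int(rng.integers(0, 2**31 - 1)))
        opt = _Adam([p for layer in net.layers for p in layer.params], lr, weight_decay)
        # skip connection: the network learns the residual around the
        # linear bridge between the gap's edge samples
        y = (targets[:, :, q] - bridge[:, :, q]) / scale
        final_loss = np.inf
        for ep in range(epochs):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, batch_size):
                bi = order[s : s + batch_size]
                xb, yb = Xn[bi], y[bi]
                pred = net.forward(xb)
                diff = pred - yb
                loss = float(np.mean(diff**2))
                if not np.isfinite(loss):
                    raise FloatingPointError(f"training diverged at offset q={q}")
                losses.append(loss)
                net.backward(2.0 * diff / diff.size)
                opt.step(
                    [p for layer in net.layers for p in layer.params],
                    [g for layer in net.layers for g in layer.grads],
                )
            final_loss = float(np.mean(losses))
        models.append(net)
        log.append({"offset": q, "final_loss": final_loss})
    return InterpolatorEnsemble(
        models=models,
        h=h,
        G=G,
        fs=fs,
        n_channels=c,
        context_mean=mean,
        context_scale=scale,
        training_log=log,
    )


def _linear_bridge(contexts: np.ndarray, h: int, G: int) -> np.ndarray:
    """Linear interpolation between the gap's edge samples, (N, C, G)."""
    left_edge = contexts[:, :, h - 1]
    right_edge = contexts[:, :, h]
    w = (np.arange(1, G + 1) / (G + 1))[None, None, :]
    return left_edge[:, :, None] * (1 - w) + right_edge[:, :, None] * w


def predict_gap(ens: InterpolatorEnsemble, left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Predict the channels x G gap from the two h-frame context stacks.

    Each offset model emits a residual that is added to the linear
    bridge between the last sample before and the first sample after
    the gap.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != (ens.n_channels, ens.h) or right.shape != (ens.n_channels, ens.h):
        raise ValueError(
            f"context must be {ens.n_channels} channels x {ens.h} frames on each side"
        )
    ctx = np.concatenate([left, right], axis=1)[None, :, :]
    bridge = _linear_bridge(ctx, ens.h, ens.G)[0]
    ctx = (ctx - ens.context_mean) / ens.context_scale
    out = np.empty((ens.n_channels, ens.G))
    for q, net in enumerate(ens.models):
        out[:, q] = net.forward(ctx)[0]
    return out * ens.context_scale + bridge


def locate_artifact_segment(epoch_data: np.ndarray, G: int, h: int, fs: float) -> GapSpec:
    """Pick the G-sample window with the largest broadband deviation.

    The statistic is the windowed sum over channels of the absolute
    deviation from each channel's median; the window is clamped so both
    h-sample contexts fit inside the epoch.
    """
    data = np.asarray(epoch_data, dtype=float)
    n = data.shape[1]
    if n < 2 * h + G:
        raise ValueError("epoch too short for the requested gap geometry")
    dev = np.abs(data - np.median(data, axis=1, keepdims=True)).sum(axis=0)
    csum = np.concatenate([[0.0], np.cumsum(dev)])
    starts = np.arange(h, n - G - h + 1)
    window_sums = csum[starts + G] - csum[starts]
    start = int(starts[int(np.argmax(window_sums))])
    return GapSpec(t_b=start - 1, t_e=start + G, h=h)


def correct_epochs(
    es: EpochSet,
    det: DetectionResult,
    ens: InterpolatorEnsemble,
) -> EpochSet:
    """Replace the located artifact segment of every flagged epoch.

    Only the G gap samples change; everything else is bit-identical, and
    unflagged epochs pass through untouched.  Epochs too short for the
    gap geometry are passed through and counted in the metadata.
    """
    if es.n_channels != ens.n_channels:
        raise ValueError("ensemble channel count does not match the epoch set")
    out = es.copy()
    corrected, skipped = [], 0
    for i in np.flatnonzero(np.asarray(det.flags, dtype=bool)):
        if es.n_samples < 2 * ens.h + ens.G:
            skipped += 1
            continue
        spec = locate_artifact_segment(es.data[i], ens.G, ens.h, es.fs)
        spec.validate(es.n_samples)
        start = spec.t_b + 1
        left = es.data[i, :, start - ens.h : start]
        right = es.data[i, :, spec.t_e : spec.t_e + ens.h]
        out.data[i, :, start : spec.t_e] = predict_gap(ens, left, right)
        corrected.append({"epoch_index": int(i), "start": start, "end": int(spec.t_e)})
    out.metadata.setdefault("corrections", []).extend(corrected)
    out.metadata["correction_skipped"] = skipped
    return out


# ---------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------

def save_ensemble(ens: InterpolatorEnsemble, path: str | Path) -> Path:
    """Single-file HDF5 container: geometry, normalisation, all weights."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs.update(
            {
                "h": ens.h,
                "G": ens.G,
                "fs": ens.fs,
                "n_channels": ens.n_channels,
                "context_mean": ens.context_mean,
                "context_scale": ens.context_scale,
            }
        )
        for q, net in enumerate(ens.models):
            grp = f.create_group(f"model_{q}")
            for li, layer in enumerate(net.layers):
                for pi, p in enumerate(layer.params):
                    grp.create_dataset(f"layer{li}_p{pi}", data=p)
    return path


def load_ensemble(path: str | Path) -> InterpolatorEnsemble:
    import h5py

    with h5py.File(path, "r") as f:
        h, G = int(f.attrs["h"]), int(f.attrs["G"])
        fs = float(f.attrs["fs"])
        c = int(f.attrs["n_channels"])
        mean, scale = float(f.attrs["context_mean"]), float(f.attrs["context_scale"])
        models = []
        for q in range(G):
            net = _FrameNet(c, 2 * h, hidden=int(f[f"model_{q}/layer3_p0"].shape[1]), seed=0)
            for li, layer in enumerate(net.layers):
                for pi in range(len(layer.params)):
                    layer.params[pi][...] = f[f"model_{q}/layer{li}_p{pi}"][()]
            models.append(net)
    return InterpolatorEnsemble(models, h, G, fs, c, mean, scale)
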