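"""Synthetic EEG with ground-truth artifact annotations.

Emulates the statistical structure the detection pipeline assumes: clean
epochs are sums of band-limited oscillators (delta through gamma) on a
1/f^alpha noise floor, condition classes differ by a weak alpha-power
modulation, and a configurable minority of epochs carries an additive,
time-localised artifact of a known kind (blink, muscle burst, electrode
pop, slow drift) with an exact interval/channel ground-truth mask.

All randomness derives from one integer seed through counter-based
substreams (``SeedSequence((seed, epoch_index, stream))``), so each
epoch is reproducible independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .io_epochs import Epoch, EpochSet

__all__ = ["SynthConfig", "ArtifactMask", "make_clean_epoch", "inject_artifact", "make_dataset"]

ARTIFACT_KINDS = ("blink", "muscle", "pop", "drift")

# canonical EEG rhythm bands (Hz) and typical resting amplitudes (uV)
_BANDS = {
    "delta": ((0.5, 3.0), 20.0),
    "theta": ((4.0, 7.0), 10.0),
    "alpha": ((8.0, 15.0), 15.0),
    "beta": ((16.0, 31.0), 5.0),
    "gamma": ((32.0, 45.0), 2.0),
}


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the study's data shape."""

    n_epochs: int = 1000
    n_channels: int = 32
    fs: float = 200.0
    epoch_len: float = 1.0
    n_classes: int = 6
    artifact_prevalence: float = 0.172
    artifact_mix: dict = field(
        default_factory=lambda: {"blink": 0.4, "muscle": 0.3, "pop": 0.2, "drift": 0.1}
    )
    artifact_magnitude: float = 8.0
    class_effect: float = 0.2
    noise_exponent: float = 1.0
    n_subjects: int = 1
    subject_artifact_bias: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.artifact_prevalence < 0.5:
            raise ValueError("artifact_prevalence must lie in [0, 0.5): artifacts are outliers")
        if abs(sum(self.artifact_mix.values()) - 1.0) > 1e-9:
            raise ValueError("artifact_mix weights must sum to 1")
        unknown = set(self.artifact_mix) - set(ARTIFACT_KINDS)
        if unknown:
            raise ValueError(f"unknown artifact kinds: {sorted(unknown)}")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels (connectivity features)")

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_len * self.fs))


@dataclass
class ArtifactMask:
    """Ground truth for one injected artifact (half-open sample interval)."""

    epoch_index: int
    kind: str
    start: int
    end: int
    channel: int | None  # None = all/multiple channels; int = single channel (pop)


def _rng(seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(s) for s in stream)))


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, alpha: float) -> np.ndarray:
    """1/f^alpha noise via spectral shaping of white noise, unit RMS per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-alpha / 2.0)
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n_samples, axis=1)
    rms = np.sqrt(np.mean(x**2, axis=1, keepdims=True))
    return x / np.maximum(rms, 1e-12)


def make_clean_epoch(cfg: SynthConfig, class_id: int, seed: int) -> Epoch:
    """One artifact-free epoch of class ``class_id``.

    Alpha-band amplitude is scaled by ``1 + class_effect * class_id`` so a
    downstream classifier has a recoverable (but weak) condition signal.
    """
    if not 0 <= class_id < cfg.n_classes:
        raise ValueError(f"class_id {class_id} out of range")
    rng = _rng(seed, class_id, 1)
    n = cfg.n_samples
    t = np.arange(n) / cfg.fs
    data = np.zeros((cfg.n_channels, n))
    for name, ((f_lo, f_hi), amp) in _BANDS.items():
        f_hi = min(f_hi, cfg.fs / 2 - 1)
        if f_hi <= f_lo:
            continue
        freq = rng.uniform(f_lo, f_hi)
        phases = rng.uniform(0, 2 * np.pi, cfg.n_channels)
        amps = amp * rng.lognormal(0.0, 0.3, cfg.n_channels)
        if name == "alpha":
            amps = amps * (1.0 + cfg.class_effect * class_id)
        data += amps[:, None] * np.sin(2 * np.pi * freq * t[None, :] + phases[:, None])
    data += 10.0 * _pink_noise(rng, cfg.n_channels, n, cfg.noise_exponent)
    return Epoch(data=data, fs=cfg.fs, label=str(class_id))


def inject_artifact(
    ep: Epoch,
    kind: str,
    magnitude: float,
    seed: int,
    channel_weights: np.ndarray | None = None,
) -> tuple[Epoch, ArtifactMask]:
    """Additively inject one artifact; returns the new epoch and its mask.

    ``magnitude`` scales the artifact peak relative to the clean epoch's
    pooled standard deviation.  ``channel_weights`` optionally imposes a
    subject-specific spatial profile (multi-channel kinds only).
    """
    if kind not in ARTIFACT_KINDS:
        raise ValueError(f"unknown artifact kind {kind!r}")
    rng = _rng(seed, 2)
    n_ch, n = ep.data.shape
    sigma = float(np.std(ep.data))
    peak = magnitude * sigma
    fs = ep.fs
    art = np.zeros_like(ep.data)

    if kind == "blink":
        # low-frequency biphasic pulse, 300-500 ms, frontal-dominant
        dur = int(rng.uniform(0.3, 0.5) * fs)
        dur = min(dur, n)
        start = int(rng.integers(0, n - dur + 1))
        tt = np.linspace(0, 1, dur)
        pulse = np.sin(2 * np.pi * tt) * np.hanning(dur)  # biphasic, <4 Hz content
        w = np.zeros(n_ch)
        front = min(4, n_ch)
        w[:front] = np.linspace(1.0, 0.4, front)
        w[front:] = 0.1
        if channel_weights is not None:
            w = w * channel_weights
        art[:, start : start + dur] = peak * np.outer(w, pulse)
        mask_ch = None
    elif kind == "muscle":
        # 20-80 Hz noise burst, 200-600 ms, several channels
        dur = int(rng.uniform(0.2, 0.6) * fs)
        dur = min(dur, n)
        start = int(rng.integers(0, n - dur + 1))
        hi = min(80.0, fs / 2 - 1)
        sos = signal.butter(4, [20.0, hi], btype="bandpass", fs=fs, output="sos")
        burst = signal.sosfiltfilt(sos, rng.standard_normal((n_ch, dur + 40)), axis=1)[:, 20:-20]
        burst /= np.maximum(np.std(burst), 1e-12)
        n_aff = int(rng.integers(max(2, n_ch // 4), n_ch + 1))
        w = np.zeros(n_ch)
        w[rng.choice(n_ch, size=n_aff, replace=False)] = rng.uniform(0.5, 1.0, n_aff)
        if channel_weights is not None:
            w = w * channel_weights
        art[:, start : start + dur] = peak * w[:, None] * burst * np.hanning(dur)[None, :]
        mask_ch = None
    elif kind == "pop":
        # abrupt step + exponential decay on exactly one channel
        dur = int(rng.uniform(0.2, 0.4) * fs)
        dur = min(dur, n)
        start = int(rng.integers(0, n - dur + 1))
        ch = int(rng.integers(0, n_ch))
        tau = max(dur / 4.0, 1.0)
        decay = np.exp(-np.arange(dur) / tau)
        art[ch, start : start + dur] = peak * rng.choice([-1.0, 1.0]) * decay
        mask_ch = ch
    else:  # drift
        # <1 Hz ramp over a long interval, all channels
        dur = int(rng.uniform(0.5, 1.0) * n)
        start = int(rng.integers(0, n - dur + 1))
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(dur) / dur))  # smooth monotone rise
        w = rng.uniform(0.5, 1.0, n_ch)
        if channel_weights is not None:
            w = w * channel_weights
        art[:, start : start + dur] = peak * np.outer(w, ramp)
        mask_ch = None

    out = Epoch(
        data=ep.data + art,
        fs=ep.fs,
        label=ep.label,
        artifact_flag=True,
        subject_id=ep.subject_id,
    )
    mask = ArtifactMask(epoch_index=-1, kind=kind, start=start, end=start + dur, channel=mask_ch)
    return out, mask


def make_dataset(cfg: SynthConfig) -> tuple[EpochSet, np.ndarray, list[ArtifactMask]]:
    """Full labelled data set with ground-truth artifact flags and masks.

    Exactly ``round(prevalence * n_epochs)`` epochs carry one artifact
    each; kinds follow ``artifact_mix``; class labels are balanced;
    everything is reproducible from ``cfg.seed``.
    """
    n = cfg.n_epochs
    master = _rng(cfg.seed, 0)
    n_art = int(round(cfg.artifact_prevalence * n))
    art_idx = set(master.choice(n, size=n_art, replace=False).tolist()) if n_art else set()
    kinds = list(cfg.artifact_mix)
    probs = np.array([cfg.artifact_mix[k] for k in kinds])

    # subject-specific spatial artifact profiles (optional)
    subj_of = np.minimum(np.arange(n) * cfg.n_subjects // n, cfg.n_subjects - 1)
    subj_weights = {}
    for s in range(cfg.n_subjects):
        if cfg.subject_artifact_bias:
            subj_weights[s] = _rng(cfg.seed, 3, s).uniform(0.3, 1.5, cfg.n_channels)
        else:
            subj_weights[s] = None

    data = np.empty((n, cfg.n_channels, cfg.n_samples))
    labels: list[str] = []
    flags = np.zeros(n, dtype=bool)
    masks: list[ArtifactMask] = []
    for i in range(n):
        class_id = i % cfg.n_classes
        ep = make_clean_epoch(cfg, class_id, seed=_epoch_seed(cfg.seed, i))
        ep.subject_id = f"s{subj_of[i]}"
        if i in art_idx:
            kind = kinds[int(_rng(cfg.seed, i, 4).choice(len(kinds), p=probs))]
            ep, mask = inject_artifact(
                ep,
                kind,
                cfg.artifact_magnitude,
                seed=_epoch_seed(cfg.seed, i) + 1,
                channel_weights=subj_weights[int(subj_of[i])],
            )
            mask.epoch_index = i
            masks.append(mask)
            flags[i] = True
        data[i] = ep.data
        labels.append(str(class_id))

    es = EpochSet(
        data,
        cfg.fs,
        [f"ch{c}" for c in range(cfg.n_channels)],
        labels=labels,
        artifact_flags=[bool(f) for f in flags],
        subject_ids=[f"s{s}" for s in subj_of],
        metadata={"generator": "eegclean.synth", "seed": cfg.seed},
    )
    return es, flags, masks


def _epoch_seed(seed: int, epoch_index: int) -> int:
    # stable per-epoch substream key, independent of generation order
    return int(np.random.SeedSequence((seed, epoch_index)).generate_state(1)[0] % (2**31 - 1))


def export_masks(masks: list[ArtifactMask], path) -> None:
    """CSV of (epoch_index, kind, start, end, channel)."""
    import pandas as pd

    pd.DataFrame(
        {
            "epoch_index": [m.epoch_index for m in masks],
            "kind": [m.kind for m in masks],
            "start": [m.start for m in masks],
            "end": [m.end for m in masks],
            "channel": ["" if m.channel is None else m.channel for m in masks],
        }
    ).to_csv(path, index=False)
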