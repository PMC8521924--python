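"""Quantitative-EEG feature bank: 58 features per epoch.

Three families are computed for every epoch, mirroring the clinical
qEEG taxonomy:

* **complexity** (25): Shannon entropy, ten Tsallis entropies, five
  wavelet subband information quantities, two cepstrum coefficients,
  largest Lyapunov exponent, Higuchi fractal dimension, Hjorth mobility
  and complexity, false-nearest-neighbour fraction, two AR coefficients;
* **continuity** (27): median frequency, five band powers, standard
  deviation, alpha/delta ratio, burst-suppression regularity, three
  low-voltage fractions, diffuse slowing, spike counts and the
  delta-burst-after-spike statistic, burst and suppression run
  statistics, five within-burst band powers;
* **connectivity** (6): delta-band coherence, mutual information,
  Granger causality, phase-lag index, and cross-correlation
  magnitude/lag, averaged over channel pairs.

Univariate features are computed per channel and averaged across
channels; the result is one named 58-vector per epoch.  Degenerate
inputs (constant channels) yield documented sentinel values, never NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pywt
from scipy import signal as sps
from scipy.signal import hilbert
from scipy.spatial.distance import cdist
from statsmodels.regression.linear_model import yule_walker

from .io_epochs import EpochSet

__all__ = [
    "FeatureConfig",
    "FeatureMatrix",
    "FEATURE_NAMES",
    "FEATURE_FAMILIES",
    "shannon_entropy",
    "tsallis_entropies",
    "subband_information_quantity",
    "cepstrum_coefficients",
    "hjorth_params",
    "nonlinear_features",
    "arma_coefficients",
    "spectral_features",
    "burst_suppression_features",
    "spike_features",
    "connectivity_features",
    "extract_features",
    "standardize",
]

DEFAULT_Q_ORDERS = (1.1, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 7.0, 10.0)
_SUBBANDS = ("delta", "theta", "alpha", "beta", "gamma")
# band-power integration ranges (Hz); delta-coherence uses 0-4 as printed
BAND_EDGES = {
    "delta": (0.0, 3.0),
    "theta": (4.0, 7.0),
    "alpha": (8.0, 15.0),
    "beta": (16.0, 31.0),
    "gamma": (32.0, np.inf),
}
_EPS = 1e-12


@dataclass
class FeatureConfig:
    """Tunable extraction parameters (defaults are the package standard)."""

    n_bins: int = 64
    q_orders: Sequence[float] = DEFAULT_Q_ORDERS
    sharp_spike_ms: float = 20.0
    spike_ms: float = 70.0
    burst_min_ms: float = 100.0
    suppression_min_ms: float = 500.0
    suppression_uv: float = 10.0
    envelope_ms: float = 100.0
    granger_max_order: int = 10
    mi_bins: int = 16
    permissive: bool = False
    n_jobs: int = 1


def _feature_names(cfg: FeatureConfig | None = None) -> tuple[list[str], dict[str, str]]:
    cfg = cfg or FeatureConfig()
    names: list[str] = []
    fam: dict[str, str] = {}

    def add(family: str, *ns: str) -> None:
        for n in ns:
            names.append(n)
            fam[n] = family

    add("complexity", "shannon_entropy")
    add("complexity", *[f"tsallis_entropy_q{q:g}" for q in cfg.q_orders])
    add("complexity", *[f"subband_iq_{b}" for b in _SUBBANDS])
    add("complexity", "cepstrum_c1", "cepstrum_c2")
    add("complexity", "lyapunov_exponent", "higuchi_fd", "hjorth_mobility", "hjorth_complexity")
    add("complexity", "fnn_fraction", "ar_coef_1", "ar_coef_2")
    add("continuity", "median_frequency")
    add("continuity", *[f"power_{b}" for b in _SUBBANDS])
    add("continuity", "signal_std", "alpha_delta_ratio", "regularity")
    add("continuity", "lv_fraction_5uv", "lv_fraction_10uv", "lv_fraction_20uv")
    add("continuity", "diffuse_slowing", "n_spikes", "delta_burst_after_spike", "n_sharp_spikes")
    add("continuity", "n_bursts", "burst_len_mean", "burst_len_std")
    add("continuity", *[f"burst_power_{b}" for b in _SUBBANDS])
    add("continuity", "n_suppressions", "suppression_len_mean", "suppression_len_std")
    add(
        "connectivity",
        "coherence_delta",
        "mutual_information",
        "granger_causality",
        "phase_lag_index",
        "xcorr_magnitude",
        "xcorr_lag",
    )
    return names, fam


FEATURE_NAMES, FEATURE_FAMILIES = _feature_names()


@dataclass
class FeatureMatrix:
    """(n_epochs x 58) named feature table."""

    values: np.ndarray
    names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))
    standardized: bool = False
    column_means: np.ndarray | None = None
    column_stds: np.ndarray | None = None

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, columns=self.names)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, index_label="epoch_index")
        return path

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col="epoch_index")
        return cls(values=df.to_numpy(dtype=float), names=list(df.columns))


# ---------------------------------------------------------------------
# Complexity features
# ---------------------------------------------------------------------

def _amplitude_probs(x: np.ndarray, n_bins: int) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        return np.array([1.0])
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    return counts[counts > 0] / x.size


def shannon_entropy(x: np.ndarray, n_bins: int = 64) -> float:
    """Shannon entropy (bits) of the equal-width amplitude histogram."""
    p = _amplitude_probs(x, n_bins)
    return float(-np.sum(p * np.log2(p)))


def tsallis_entropies(x: np.ndarray, q_orders: Sequence[float] = DEFAULT_Q_ORDERS, n_bins: int = 64) -> np.ndarray:
    """Tsallis entropies S_q = (1 - sum p^q)/(q - 1); q=1 is the nats limit."""
    p = _amplitude_probs(x, n_bins)
    out = np.empty(len(q_orders))
    for i, q in enumerate(q_orders):
        if abs(q - 1.0) < 1e-12:
            out[i] = float(-np.sum(p * np.log(p)))
        else:
            out[i] = float((1.0 - np.sum(p**q)) / (q - 1.0))
    return out


def _dwt_subbands(x: np.ndarray, fs: float) -> dict[str, np.ndarray]:
    """Daubechies-4 decomposition with subbands mapped onto delta..gamma.

    Level L is chosen so the approximation covers roughly 0-3 Hz at the
    working rate (fs/2^(L+1) ~ 3 Hz).  gamma pools every detail band
    above the beta band; at low rates it falls back to the highest
    available detail band.
    """
    n = len(x)
    want = max(1, int(round(np.log2(max(fs / 6.25, 2.0)))))
    level = min(want, pywt.dwt_max_level(n, pywt.Wavelet("db4").dec_len))
    coeffs = pywt.wavedec(x, "db4", level=level)
    # coeffs = [A_L, D_L, D_{L-1}, ..., D_1]
    def recon(which: int) -> np.ndarray:
        sel = [c if i == which else np.zeros_like(c) for i, c in enumerate(coeffs)]
        return pywt.waverec(sel, "db4")[:n]

    out: dict[str, np.ndarray] = {}
    out["delta"] = recon(0)
    out["theta"] = recon(1) if level >= 1 else recon(0)
    out["alpha"] = recon(2) if level >= 2 else recon(len(coeffs) - 1)
    out["beta"] = recon(3) if level >= 3 else recon(len(coeffs) - 1)
    if level >= 4:
        gamma = np.zeros(n)
        for i in range(4, len(coeffs)):
            gamma += recon(i)
        out["gamma"] = gamma
    else:
        out["gamma"] = recon(len(coeffs) - 1)
    return out


def subband_information_quantity(x: np.ndarray, fs: float, n_bins: int = 64) -> np.ndarray:
    """Shannon entropy of each wavelet-reconstructed subband (delta..gamma)."""
    if np.ptp(x) == 0:
        return np.zeros(5)
    bands = _dwt_subbands(np.asarray(x, dtype=float), fs)
    return np.array([shannon_entropy(bands[b], n_bins) for b in _SUBBANDS])


def cepstrum_coefficients(x: np.ndarray, n_coefs: int = 2) -> np.ndarray:
    """First real-cepstrum coefficients c[1], c[2] (c[0] carries scale only)."""
    x = np.asarray(x, dtype=float)
    mag = np.abs(np.fft.rfft(x))
    c = np.fft.irfft(np.log(mag + _EPS), n=len(x))
    return c[1 : 1 + n_coefs].copy()


def hjorth_params(x: np.ndarray) -> tuple[float, float]:
    """Hjorth mobility and complexity; constant signals give (0, 0)."""
    x = np.asarray(x, dtype=float)
    v0 = np.var(x)
    if v0 <= _EPS:
        return 0.0, 0.0
    d1 = np.diff(x)
    v1 = np.var(d1)
    mobility = float(np.sqrt(v1 / v0))
    if v1 <= _EPS:
        return mobility, 0.0
    v2 = np.var(np.diff(d1))
    mob_d = np.sqrt(v2 / v1)
    return mobility, float(mob_d / mobility)


def _delay_autocorr(x: np.ndarray) -> int:
    """Embedding delay: first zero crossing of the autocorrelation."""
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= _EPS:
        return 1
    n = len(x)
    ac = np.correlate(x, x, mode="full")[n - 1 :] / denom
    below = np.nonzero(ac <= 0)[0]
    return int(below[0]) if below.size else max(1, n // 10)


def _embed(x: np.ndarray, dim: int, tau: int) -> np.ndarray:
    m = len(x) - (dim - 1) * tau
    if m <= 0:
        return np.empty((0, dim))
    return np.stack([x[i * tau : i * tau + m] for i in range(dim)], axis=1)


def _lyapunov_rosenstein(x: np.ndarray, fs: float, dim: int = 5) -> float:
    """Largest Lyapunov exponent (nats/sample), Rosenstein's method."""
    x = np.asarray(x, dtype=float)
    tau = _delay_autocorr(x)
    emb = _embed(x, dim, tau)
    m = emb.shape[0]
    if m < 10 * dim:
        return 0.0
    # Theiler window: mean period from the spectral mean frequency
    freqs = np.fft.rfftfreq(len(x), d=1.0)
    psd = np.abs(np.fft.rfft(x - x.mean())) ** 2
    tot = psd[1:].sum()
    mean_f = float((freqs[1:] * psd[1:]).sum() / tot) if tot > 0 else 0.1
    w = max(1, int(round(1.0 / max(mean_f, 1.0 / len(x)))))
    d = cdist(emb, emb)
    np.fill_diagonal(d, np.inf)
    ii = np.arange(m)
    banned = np.abs(ii[:, None] - ii[None, :]) <= w
    d[banned] = np.inf
    nn = np.argmin(d, axis=1)
    k_max = min(20, m // 10)
    if k_max < 2:
        return 0.0
    logs = np.full((m, k_max), np.nan)
    for k in range(1, k_max + 1):
        valid = (ii + k < m) & (nn + k < m)
        sep = np.abs(
            np.linalg.norm(emb[ii[valid] + k] - emb[nn[valid] + k], axis=1)
        )
        good = sep > _EPS
        rows = ii[valid][good]
        logs[rows, k - 1] = np.log(sep[good])
    counts = np.sum(np.isfinite(logs), axis=0)
    sums = np.nansum(np.where(np.isfinite(logs), logs, 0.0), axis=0)
    y = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    ks = np.arange(1, k_max + 1, dtype=float)
    ok = np.isfinite(y)
    if ok.sum() < 2:
        return 0.0
    slope = np.polyfit(ks[ok], y[ok], 1)[0]
    return float(slope)


def _higuchi_fd(x: np.ndarray, k_max: int = 10) -> float:
    """Higuchi fractal dimension (k_max=10); smooth curves give ~1."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if np.ptp(x) == 0:
        return 1.0
    lk, ks = [], []
    for k in range(1, k_max + 1):
        lengths = []
        for m in range(k):
            idx = np.arange(m, n, k)
            if idx.size < 2:
                continue
            seg = np.abs(np.diff(x[idx])).sum()
            norm = (n - 1) / (idx.size - 1) / k
            lengths.append(seg * norm / k)
        if lengths:
            lk.append(np.log(np.mean(lengths) + _EPS))
            ks.append(np.log(1.0 / k))
    if len(ks) < 2:
        return 1.0
    return float(np.polyfit(ks, lk, 1)[0])


def _fnn_fraction(x: np.ndarray, dim: int = 3, rtol: float = 15.0) -> float:
    """Kennel false-nearest-neighbour fraction at the given dimension."""
    x = np.asarray(x, dtype=float)
    tau = _delay_autocorr(x)
    emb = _embed(x, dim, tau)
    m_next = len(x) - dim * tau
    if m_next < 10:
        return 0.0
    emb = emb[:m_next]
    d = cdist(emb, emb)
    np.fill_diagonal(d, np.inf)
    nn = np.argmin(d, axis=1)
    ii = np.arange(m_next)
    d3 = d[ii, nn]
    extra = np.abs(x[ii + dim * tau] - x[nn + dim * tau])
    ok = d3 > _EPS
    if ok.sum() == 0:
        return 0.0
    return float(np.mean(extra[ok] / d3[ok] > rtol))


def nonlinear_features(x: np.ndarray, fs: float) -> tuple[float, float, float]:
    """(largest Lyapunov exponent, Higuchi FD, FNN fraction)."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return 0.0, 1.0, 0.0
    return _lyapunov_rosenstein(x, fs), _higuchi_fd(x), _fnn_fraction(x)


def arma_coefficients(x: np.ndarray, order: int = 2) -> np.ndarray:
    """AR coefficients by Yule-Walker on the mean-removed signal."""
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return np.zeros(order)
    rho, _ = yule_walker(x - x.mean(), order=order, method="mle")
    return np.asarray(rho, dtype=float)


# ---------------------------------------------------------------------
# Continuity features
# ---------------------------------------------------------------------

def _welch(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    nper = int(min(len(x), round(fs)))
    nper = max(nper, 8)
    return sps.welch(x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2)


def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float) -> float:
    hi = min(hi, freqs[-1]) if np.isfinite(hi) else freqs[-1]
    mask = (freqs >= lo) & (freqs <= hi)
    if mask.sum() < 2:
        return float(psd[mask].sum())
    return float(np.trapezoid(psd[mask], freqs[mask]))


def band_powers(x: np.ndarray, fs: float) -> np.ndarray:
    """Trapezoid-integrated Welch band powers for delta..gamma."""
    freqs, psd = _welch(x, fs)
    return np.array([_band_power(freqs, psd, *BAND_EDGES[b]) for b in _SUBBANDS])


def spectral_features(x: np.ndarray, fs: float) -> dict[str, float]:
    """Median frequency, band powers, alpha/delta ratio, std, diffuse slowing."""
    x = np.asarray(x, dtype=float)
    freqs, psd = _welch(x, fs)
    bp = {b: _band_power(freqs, psd, *BAND_EDGES[b]) for b in _SUBBANDS}
    total = float(np.trapezoid(psd, freqs))
    if total <= _EPS:
        median_freq = 0.0
        slowing = 1.0
    else:
        cum = np.concatenate([[0.0], np.cumsum(np.diff(freqs) * (psd[1:] + psd[:-1]) / 2.0)])
        median_freq = float(np.interp(total / 2.0, cum, freqs))
        slowing = 1.0 if freqs[int(np.argmax(psd))] < 8.0 else 0.0
    out = {"median_frequency": median_freq}
    out.update({f"power_{b}": bp[b] for b in _SUBBANDS})
    out["signal_std"] = float(np.std(x, ddof=1)) if len(x) > 1 else 0.0
    out["alpha_delta_ratio"] = float(bp["alpha"] / (bp["delta"] + _EPS))
    out["diffuse_slowing"] = slowing
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of ``mask`` as half-open (start, end) pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def regularity(x: np.ndarray) -> float:
    """Burst-suppression regularity from sorted squared amplitudes.

    REG = sqrt(3 * sum i^2 u(i) / (N^2 sum u(i))), u = x^2 sorted
    descending, i = 1..N.  1 for a perfectly continuous signal; the
    all-zero signal is defined as 1.
    """
    u = np.sort(np.asarray(x, dtype=float) ** 2)[::-1]
    s = u.sum()
    if s <= _EPS:
        return 1.0
    n = len(u)
    i = np.arange(1, n + 1, dtype=float)
    return float(np.sqrt(3.0 * np.sum(i**2 * u) / (n**2 * s)))


def burst_suppression_features(x: np.ndarray, fs: float, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Burst/suppression run statistics, within-burst band powers,
    low-voltage fractions and regularity.

    Bursts: moving-RMS envelope above its mean + 1 SD for >= 100 ms.
    Suppressions: envelope below 10 uV for >= 500 ms.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    n = len(x)
    w = max(1, int(round(cfg.envelope_ms / 1000.0 * fs)))
    env = np.sqrt(np.convolve(x**2, np.ones(w) / w, mode="same"))
    thr = env.mean() + env.std()
    min_burst = max(1, int(round(cfg.burst_min_ms / 1000.0 * fs)))
    min_supp = max(1, int(round(cfg.suppression_min_ms / 1000.0 * fs)))
    # the centred RMS window smears state transitions by ~w/2 per side:
    # trim high-envelope runs and extend low-envelope runs accordingly
    half = w // 2
    bursts = [
        (a + half, b - half)
        for a, b in _runs(env > thr)
        if (b - half) - (a + half) >= min_burst
    ]
    supps = [
        (max(0, a - half), min(n, b + half))
        for a, b in _runs(env < cfg.suppression_uv)
        if min(n, b + half) - max(0, a - half) >= min_supp
    ]

    def run_stats(runs: list[tuple[int, int]]) -> tuple[float, float]:
        if not runs:
            return 0.0, 0.0
        lens = np.array([(b - a) / fs for a, b in runs])
        return float(lens.mean()), float(lens.std())

    b_mean, b_std = run_stats(bursts)
    s_mean, s_std = run_stats(supps)
    if bursts:
        concat = np.concatenate([x[a:b] for a, b in bursts])
        bbp = band_powers(concat, fs)
    else:
        bbp = np.zeros(5)
    out = {
        "regularity": regularity(x),
        "n_bursts": float(len(bursts)),
        "burst_len_mean": b_mean,
        "burst_len_std": b_std,
        "n_suppressions": float(len(supps)),
        "suppression_len_mean": s_mean,
        "suppression_len_std": s_std,
    }
    out.update({f"burst_power_{b}": float(v) for b, v in zip(_SUBBANDS, bbp)})
    for thr_uv in (5, 10, 20):
        out[f"lv_fraction_{thr_uv}uv"] = float(np.mean(np.abs(x) < thr_uv)) if n else 0.0
    return out


def spike_features(x: np.ndarray, fs: float, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Spike counts and the delta-burst-after-spike statistic.

    A spike is a maximal excursion of |x - mean| beyond 3 SD lasting at
    most 70 ms; a sharp spike lasts under 20 ms (clinical sharp-transient
    convention).
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(x, dtype=float)
    mu, sd = x.mean(), x.std()
    if sd <= _EPS:
        return {"n_spikes": 0.0, "n_sharp_spikes": 0.0, "delta_burst_after_spike": 0.0}
    max_len = int(round(cfg.spike_ms / 1000.0 * fs))
    sharp_len = int(round(cfg.sharp_spike_ms / 1000.0 * fs))
    runs = _runs(np.abs(x - mu) > 3 * sd)
    spikes = [(a, b) for a, b in runs if b - a <= max_len]
    sharp = [r for r in spikes if r[1] - r[0] < sharp_len]
    half_s = int(round(0.5 * fs))
    diffs = []
    for a, b in spikes:
        before = x[max(0, a - half_s) : a]
        after = x[b : b + half_s]
        if len(before) >= 8 and len(after) >= 8:
            diffs.append(band_powers(after, fs)[0] - band_powers(before, fs)[0])
    return {
        "n_spikes": float(len(spikes)),
        "n_sharp_spikes": float(len(sharp)),
        "delta_burst_after_spike": float(np.mean(diffs)) if diffs else 0.0,
    }


# ---------------------------------------------------------------------
# Connectivity features
# ---------------------------------------------------------------------

def mutual_information(x: np.ndarray, y: np.ndarray, bins: int = 16) -> float:
    """Histogram mutual information (bits) on a bins x bins grid."""
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    pxy = joint / joint.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    nz = pxy > 0
    return float(np.sum(pxy[nz] * np.log2(pxy[nz] / (px @ py)[nz])))


def phase_lag_index(x: np.ndarray, y: np.ndarray) -> float:
    """|mean sign of the instantaneous phase difference| (analytic signal)."""
    dphi = np.angle(hilbert(x)) - np.angle(hilbert(y))
    return float(np.abs(np.mean(np.sign(np.sin(dphi)))))


def _rss_fit(X: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of a least-squares fit (singular-safe)."""
    try:
        beta = np.linalg.solve(X.T @ X, X.T @ y)
    except np.linalg.LinAlgError:
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def _granger_f(x: np.ndarray, y: np.ndarray, max_order: int = 10) -> float:
    """Bivariate Granger F-statistic for x -> y (AIC order, max 10).

    The lag order is selected by AIC of the unrestricted model over a
    common sample (rows from max_order onward); the F-test then compares
    the restricted model (own lags of y) against the unrestricted one
    (own + x lags) at that order.  Degenerate (collinear or constant)
    inputs return 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    p_max = min(max_order, (n - 4) // 4)
    if p_max < 1:
        return 0.0
    # lag stacks on the common sample t = p_max .. n-1
    n_eff = n - p_max
    ylags = np.stack([y[p_max - k - 1 : n - k - 1] for k in range(p_max)], axis=1)
    xlags = np.stack([x[p_max - k - 1 : n - k - 1] for k in range(p_max)], axis=1)
    ones = np.ones((n_eff, 1))
    target = y[p_max:]
    best = None
    for p in range(1, p_max + 1):
        X = np.concatenate([ones, ylags[:, :p], xlags[:, :p]], axis=1)
        rss_u = _rss_fit(X, target)
        aic = n_eff * np.log(max(rss_u, _EPS) / n_eff) + 2 * (2 * p + 1)
        if best is None or aic < best[0]:
            best = (aic, p, rss_u)
    _, p, rss_u = best
    Xr = np.concatenate([ones, ylags[:, :p]], axis=1)
    rss_r = _rss_fit(Xr, target)
    df2 = n_eff - (2 * p + 1)
    if rss_u <= _EPS or df2 <= 0:
        return 0.0
    f = ((rss_r - rss_u) / p) / (rss_u / df2)
    return float(max(f, 0.0))


def _segment_ffts(data: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed half-second segment FFTs per channel (for coherence).

    Half-second segments with 50% overlap give >= 3 averaging segments on
    a 1 s epoch, so magnitude-squared coherence is non-trivial.
    """
    c, n = data.shape
    nper = max(8, int(min(n, round(fs / 2))))
    hop = max(1, nper // 2)
    starts = np.arange(0, n - nper + 1, hop)
    win = np.hanning(nper)
    segs = np.stack([data[:, s : s + nper] * win[None, :] for s in starts], axis=1)
    return np.fft.rfft(segs, axis=2), np.fft.rfftfreq(nper, d=1.0 / fs)


def connectivity_features(data: np.ndarray, fs: float, cfg: FeatureConfig | None = None) -> dict[str, float]:
    """Pair-averaged connectivity summary of one epoch (channels x samples).

    Unordered pairs for coherence/MI/PLI/cross-correlation; ordered pairs
    for the Granger statistic.
    """
    cfg = cfg or FeatureConfig()
    data = np.asarray(data, dtype=float)
    c, n = data.shape
    if c < 2:
        raise ValueError("connectivity features need at least 2 channels")
    ffts, freqs = _segment_ffts(data, fs)
    delta_sel = freqs <= 4.0
    psd = np.mean(np.abs(ffts) ** 2, axis=1)  # (c, n_freq)
    phases = np.angle(hilbert(data, axis=1))
    centered = data - data.mean(axis=1, keepdims=True)
    stds = centered.std(axis=1)
    coh, mi, pli, xmag, xlag, granger = [], [], [], [], [], []
    for i in range(c):
        for j in range(i + 1, c):
            pxy = np.mean(ffts[i] * np.conj(ffts[j]), axis=0)
            denom = psd[i] * psd[j]
            cxy = np.abs(pxy) ** 2 / np.where(denom > _EPS, denom, np.inf)
            coh.append(float(np.mean(cxy[delta_sel])) if delta_sel.any() else 0.0)
            mi.append(mutual_information(data[i], data[j], cfg.mi_bins))
            dphi = phases[i] - phases[j]
            pli.append(float(np.abs(np.mean(np.sign(np.sin(dphi))))))
            if stds[i] > _EPS and stds[j] > _EPS:
                cc = sps.correlate(centered[i], centered[j], mode="full") / (n * stds[i] * stds[j])
                k = int(np.argmax(np.abs(cc)))
                xmag.append(float(np.abs(cc[k])))
                xlag.append(abs(k - (n - 1)) / fs * 1000.0)
            else:
                xmag.append(0.0)
                xlag.append(0.0)
            granger.append(_granger_f(data[i], data[j], cfg.granger_max_order))
            granger.append(_granger_f(data[j], data[i], cfg.granger_max_order))
    return {
        "coherence_delta": float(np.mean(coh)),
        "mutual_information": float(np.mean(mi)),
        "granger_causality": float(np.mean(granger)),
        "phase_lag_index": float(np.mean(pli)),
        "xcorr_magnitude": float(np.mean(xmag)),
        "xcorr_lag": float(np.mean(xlag)),
    }


# ---------------------------------------------------------------------
# Whole-epoch extraction
# ---------------------------------------------------------------------

def _univariate_vector(x: np.ndarray, fs: float, cfg: FeatureConfig) -> dict[str, float]:
    out: dict[str, float] = {"shannon_entropy": shannon_entropy(x, cfg.n_bins)}
    for q, v in zip(cfg.q_orders, tsallis_entropies(x, cfg.q_orders, cfg.n_bins)):
        out[f"tsallis_entropy_q{q:g}"] = float(v)
    for b, v in zip(_SUBBANDS, subband_information_quantity(x, fs, cfg.n_bins)):
        out[f"subband_iq_{b}"] = float(v)
    c1, c2 = cepstrum_coefficients(x)
    out["cepstrum_c1"], out["cepstrum_c2"] = float(c1), float(c2)
    lyap, hfd, fnn = nonlinear_features(x, fs)
    out["lyapunov_exponent"], out["higuchi_fd"], out["fnn_fraction"] = lyap, hfd, fnn
    mob, comp = hjorth_params(x)
    out["hjorth_mobility"], out["hjorth_complexity"] = mob, comp
    a = arma_coefficients(x)
    out["ar_coef_1"], out["ar_coef_2"] = float(a[0]), float(a[1])
    out.update(spectral_features(x, fs))
    out.update(burst_suppression_features(x, fs, cfg))
    out.update(spike_features(x, fs, cfg))
    return out


def _epoch_vector(data: np.ndarray, fs: float, cfg: FeatureConfig) -> np.ndarray:
    per_channel = [_univariate_vector(ch, fs, cfg) for ch in data]
    uni = {k: float(np.mean([d[k] for d in per_channel])) for k in per_channel[0]}
    if data.shape[0] >= 2:
        conn = connectivity_features(data, fs, cfg)
    elif cfg.permissive:
        conn = {k: 0.0 for k in (
            "coherence_delta", "mutual_information", "granger_causality",
            "phase_lag_index", "xcorr_magnitude", "xcorr_lag")}
    else:
        raise ValueError("connectivity features need >= 2 channels (set permissive=True to emit 0)")
    uni.update(conn)
    return np.array([uni[name] for name in FEATURE_NAMES])


def extract_features(es: EpochSet, cfg: FeatureConfig | None = None) -> FeatureMatrix:
    """Extract the full 58-feature vector for every epoch.

    Epochs are independent, so extraction parallelises trivially
    (``cfg.n_jobs``); results are bit-identical for any worker count.
    """
    cfg = cfg or FeatureConfig()
    if cfg.n_jobs != 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=cfg.n_jobs)(
            delayed(_epoch_vector)(es.data[i], es.fs, cfg) for i in range(es.n_epochs)
        )
    else:
        rows = [_epoch_vector(es.data[i], es.fs, cfg) for i in range(es.n_epochs)]
    values = np.stack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))
    if not np.all(np.isfinite(values)):
        bad = np.argwhere(~np.isfinite(values))
        raise AssertionError(f"non-finite feature values at (epoch, feature) {bad[:5]}")
    return FeatureMatrix(values=values)


def standardize(fm: FeatureMatrix) -> FeatureMatrix:
    """Column z-scoring; constant columns map to 0; stores the inverse."""
    mu = fm.values.mean(axis=0)
    sd = fm.values.std(axis=0)
    safe = np.where(sd > _EPS, sd, 1.0)
    z = (fm.values - mu) / safe
    z[:, sd <= _EPS] = 0.0
    return FeatureMatrix(
        values=z, names=list(fm.names), standardized=True, column_means=mu, column_stds=sd
    )


def destandardize(fm: FeatureMatrix) -> FeatureMatrix:
    if not fm.standardized or fm.column_means is None:
        raise ValueError("matrix is not standardized")
    sd = np.where(fm.column_stds > _EPS, fm.column_stds, 1.0)
    vals = fm.values * sd + fm.column_means
    vals[:, fm.column_stds <= _EPS] = fm.column_means[fm.column_stds <= _EPS]
    return FeatureMatrix(values=vals, names=list(fm.names), standardized=False)
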