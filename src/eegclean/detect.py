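"""Unsupervised artifact detection on the feature matrix.

Implements the statistical scorers (HBOS, LOF, ABOD, one-class SVM),
the representation-learning scorers (PCA reconstruction, autoencoder,
variational autoencoder), and the locally selective combination (LSCP)
ensemble, plus contamination thresholding, per-subject vs aggregated
fitting, and a random hyper-parameter search.

Every scorer returns one finite real per epoch with a uniform
orientation: **higher = more anomalous**.  Flags are obtained by taking
the top ``ceil(contamination * n)`` scores within each fitting
partition, ties broken toward lower epoch index.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA
from sklearn.neighbors import LocalOutlierFactor, NearestNeighbors
from sklearn.neural_network import MLPRegressor
from sklearn.svm import OneClassSVM

from .evaluate import f_score
from .features import FeatureMatrix
from .io_epochs import EpochSet

__all__ = [
    "DetectorConfig",
    "DetectionResult",
    "hbos_scores",
    "lof_scores",
    "abod_scores",
    "ocsvm_scores",
    "pca_recon_scores",
    "autoencoder_scores",
    "vae_scores",
    "lscp_scores",
    "threshold_by_contamination",
    "run_detection",
    "random_search",
    "default_lscp_base",
]

_EPS = 1e-12
METHODS = ("hbos", "lof", "abod", "ocsvm", "pca", "autoencoder", "vae", "lscp")


@dataclass
class DetectorConfig:
    """One detector: method name + method-specific parameters."""

    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    mode: str = "aggregated"  # or "per_subject"

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown detection method {self.method!r}")
        if self.mode not in ("aggregated", "per_subject"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.method == "lscp" and len(self.params.get("base", [])) < 2:
            if "base" in self.params:
                raise ValueError("lscp requires >= 2 base detector configs")


@dataclass
class DetectionResult:
    """Scores, binary flags, and the configuration that produced them."""

    scores: np.ndarray
    flags: np.ndarray
    contamination: float
    method: DetectorConfig
    subject_partition: dict[str, np.ndarray] | None = None

    def to_csv(self, path, subject_ids: Sequence[str] | None = None):
        import pandas as pd

        n = len(self.scores)
        pd.DataFrame(
            {
                "epoch_index": np.arange(n),
                "subject_id": subject_ids if subject_ids is not None else ["s0"] * n,
                "score": self.scores,
                "flag": self.flags.astype(int),
            }
        ).to_csv(path, index=False)
        return path


def _as_matrix(fm: FeatureMatrix | np.ndarray) -> np.ndarray:
    if isinstance(fm, FeatureMatrix):
        return np.asarray(fm.values, dtype=float)
    return np.asarray(fm, dtype=float)


# ---------------------------------------------------------------------
# Statistical scorers
# ---------------------------------------------------------------------

def hbos_scores(
    fm: FeatureMatrix | np.ndarray,
    n_bins: int = 10,
    tol: float = 0.5,
    dynamic_bins: bool = False,
) -> np.ndarray:
    """Histogram-based outlier score.

    Per feature, a histogram of the training values is built (equal
    width, or equal frequency when ``dynamic_bins``); the score of a row
    is the summed log inverse density of the bins its values fall in.
    Out-of-range values within ``tol`` x bin-width of the edge are
    assigned the edge bin; beyond that they receive the minimum density.
    """
    X = _as_matrix(fm)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    n, d = X.shape
    scores = np.zeros(n)
    for j in range(d):
        col = X[:, j]
        lo, hi = float(col.min()), float(col.max())
        if hi <= lo:
            continue  # constant feature: identical density for all rows
        if dynamic_bins:
            edges = np.unique(np.quantile(col, np.linspace(0, 1, n_bins + 1)))
            if len(edges) < 3:
                edges = np.linspace(lo, hi, n_bins + 1)
        else:
            edges = np.linspace(lo, hi, n_bins + 1)
        counts, _ = np.histogram(col, bins=edges)
        widths = np.diff(edges)
        density = counts / (n * np.maximum(widths, _EPS))
        idx = np.clip(np.searchsorted(edges, col, side="right") - 1, 0, len(counts) - 1)
        dens = density[idx]
        # out-of-range handling (scoring rows may extend past training range)
        below = col < lo
        above = col > hi
        slack_lo = tol * widths[0]
        slack_hi = tol * widths[-1]
        dens[below & (lo - col <= slack_lo)] = density[0]
        dens[below & (lo - col > slack_lo)] = _EPS
        dens[above & (col - hi <= slack_hi)] = density[-1]
        dens[above & (col - hi > slack_hi)] = _EPS
        scores += np.log(1.0 / (dens + _EPS))
    return scores


def lof_scores(fm: FeatureMatrix | np.ndarray, k_neighbors: int = 20) -> np.ndarray:
    """Local outlier factor (reachability-density ratio); ~1 for inliers."""
    X = _as_matrix(fm)
    k = min(k_neighbors, len(X) - 1)
    lof = LocalOutlierFactor(n_neighbors=k)
    lof.fit(X)
    return -lof.negative_outlier_factor_


def abod_scores(fm: FeatureMatrix | np.ndarray, k_neighbors: int = 10) -> np.ndarray:
    """Angle-based outlier score (negated angle-variance, so higher = outlier).

    For each point, over all pairs of its k nearest neighbours, the
    distance-weighted cosine statistic ``<a-p, b-p> / (|a-p|^2 |b-p|^2)``
    is computed; inliers see neighbours at widely varying angles (large
    variance), isolated points see a narrow cone (small variance).
    """
    X = _as_matrix(fm)
    n = len(X)
    k = min(k_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    idx = idx[:, 1:]  # drop each point's self-match
    out = np.empty(n)
    for i in range(n):
        diffs = X[idx[i]] - X[i]
        norms2 = np.einsum("ij,ij->i", diffs, diffs)
        good = norms2 > _EPS
        diffs, norms2 = diffs[good], norms2[good]
        m = len(diffs)
        if m < 2:
            out[i] = 0.0
            continue
        dots = diffs @ diffs.T
        w = dots / np.outer(norms2, norms2)
        iu = np.triu_indices(m, k=1)
        out[i] = float(np.var(w[iu]))
    return -out


def ocsvm_scores(fm: FeatureMatrix | np.ndarray, nu: float = 0.2, kernel: str = "rbf") -> np.ndarray:
    """One-class SVM boundary distance (outside the boundary = larger)."""
    X = _as_matrix(fm)
    model = OneClassSVM(nu=nu, kernel=kernel, gamma="scale")
    model.fit(X)
    return -model.decision_function(X)


# ---------------------------------------------------------------------
# Representation-learning scorers
# ---------------------------------------------------------------------

def pca_recon_scores(fm: FeatureMatrix | np.ndarray, n_components: int = 5) -> np.ndarray:
    """Squared reconstruction error after projecting to the top components."""
    X = _as_matrix(fm)
    k = min(n_components, min(X.shape))
    pca = PCA(n_components=k)
    z = pca.fit_transform(X)
    recon = pca.inverse_transform(z)
    return np.sum((X - recon) ** 2, axis=1)


def autoencoder_scores(
    fm: FeatureMatrix | np.ndarray,
    hidden_sizes: Sequence[int] = (32, 8, 32),
    epochs: int = 300,
    seed: int = 0,
) -> np.ndarray:
    """Autoencoder reconstruction error (bottleneck MLP trained on all rows)."""
    X = _as_matrix(fm)
    model = MLPRegressor(
        hidden_layer_sizes=tuple(hidden_sizes),
        activation="relu",
        solver="adam",
        max_iter=epochs,
        random_state=seed,
        tol=1e-6,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, X)
    recon = model.predict(X)
    return np.sum((X - recon) ** 2, axis=1)


def vae_scores(
    fm: FeatureMatrix | np.ndarray,
    latent_dim: int = 5,
    hidden: int = 32,
    epochs: int = 300,
    lr: float = 1e-3,
    seed: int = 0,
) -> np.ndarray:
    """Variational-autoencoder reconstruction error.

    A small dense VAE (one hidden layer each side) is trained with the
    usual reconstruction + KL objective; the anomaly score is the
    deterministic (mean-encoding) reconstruction error only.
    """
    X = _as_matrix(fm)
    n, d = X.shape
    rng = np.random.default_rng(seed)

    def init(a, b):
        return rng.normal(0, np.sqrt(2.0 / a), size=(a, b))

    W1, b1 = init(d, hidden), np.zeros(hidden)
    Wm, bm = init(hidden, latent_dim), np.zeros(latent_dim)
    Wv, bv = init(hidden, latent_dim), np.zeros(latent_dim)
    W2, b2 = init(latent_dim, hidden), np.zeros(hidden)
    W3, b3 = init(hidden, d), np.zeros(d)
    params = [W1, b1, Wm, bm, Wv, bv, W2, b2, W3, b3]
    adam_m = [np.zeros_like(p) for p in params]
    adam_v = [np.zeros_like(p) for p in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    batch = min(64, n)
    for _ in range(epochs):
        order = rng.permutation(n)
        for s in range(0, n, batch):
            xb = X[order[s : s + batch]]
            m = len(xb)
            h1 = np.maximum(xb @ W1 + b1, 0)
            mu = h1 @ Wm + bm
            logvar = np.clip(h1 @ Wv + bv, -8, 8)
            z = mu + np.exp(0.5 * logvar) * rng.standard_normal(mu.shape)
            h2 = np.maximum(z @ W2 + b2, 0)
            xh = h2 @ W3 + b3
            # backward: d/dxh of mean squared error, plus KL on (mu, logvar)
            dxh = 2.0 * (xh - xb) / m
            dW3, db3 = h2.T @ dxh, dxh.sum(0)
            dh2 = (dxh @ W3.T) * (h2 > 0)
            dW2, db2 = z.T @ dh2, dh2.sum(0)
            dz = dh2 @ W2.T
            dmu = dz + mu / m
            dlogvar = dz * (z - mu) * 0.5 + 0.5 * (np.exp(logvar) - 1.0) / m
            dWm, dbm = h1.T @ dmu, dmu.sum(0)
            dWv, dbv = h1.T @ dlogvar, dlogvar.sum(0)
            dh1 = (dmu @ Wm.T + dlogvar @ Wv.T) * (h1 > 0)
            dW1, db1 = xb.T @ dh1, dh1.sum(0)
            grads = [dW1, db1, dWm, dbm, dWv, dbv, dW2, db2, dW3, db3]
            t += 1
            for p, g, mm, vv in zip(params, grads, adam_m, adam_v):
                mm += (1 - beta1) * (g - mm)
                vv += (1 - beta2) * (g * g - vv)
                p -= lr * (mm / (1 - beta1**t)) / (np.sqrt(vv / (1 - beta2**t)) + eps)
    h1 = np.maximum(X @ W1 + b1, 0)
    mu = h1 @ Wm + bm
    h2 = np.maximum(mu @ W2 + b2, 0)
    xh = h2 @ W3 + b3
    return np.sum((X - xh) ** 2, axis=1)


# ---------------------------------------------------------------------
# LSCP ensemble
# ---------------------------------------------------------------------

def default_lscp_base() -> list[DetectorConfig]:
    """The reported best ensemble: two divergent HBOS scorers + one OCSVM."""
    return [
        DetectorConfig("hbos", {"n_bins": 50, "tol": 0.1}),
        DetectorConfig("hbos", {"n_bins": 10, "tol": 0.5}),
        DetectorConfig("ocsvm", {"nu": 0.2}),
    ]


def _base_scores(X: np.ndarray, cfg: DetectorConfig) -> np.ndarray:
    fn = {
        "hbos": hbos_scores,
        "lof": lof_scores,
        "abod": abod_scores,
        "ocsvm": ocsvm_scores,
        "pca": pca_recon_scores,
        "autoencoder": autoencoder_scores,
        "vae": vae_scores,
    }
    if cfg.method not in fn:
        raise ValueError(f"{cfg.method!r} cannot be an LSCP base detector")
    params = dict(cfg.params)
    if cfg.method in ("autoencoder", "vae"):
        params.setdefault("seed", cfg.seed)
    return fn[cfg.method](X, **params)


def lscp_scores(
    fm: FeatureMatrix | np.ndarray,
    base: Sequence[DetectorConfig] | None = None,
    k_local: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Locally selective combination in parallel (LSCP).

    All base detectors are fitted on the full matrix and their scores
    z-normalised; the per-row mean of the normalised scores is the
    pseudo ground truth.  For each row, the base detector whose scores
    best Pearson-correlate with the pseudo target over the row's
    ``k_local`` nearest neighbours is selected, and its score emitted.
    """
    X = _as_matrix(fm)
    base = list(base) if base is not None else default_lscp_base()
    if len(base) < 2:
        raise ValueError("lscp requires >= 2 base detectors")
    n = len(X)
    if k_local >= n:
        raise ValueError(f"k_local={k_local} must be < n_rows={n}")
    raw = np.stack([_base_scores(X, cfg) for cfg in base], axis=1)  # (n, B)
    mu, sd = raw.mean(axis=0), raw.std(axis=0)
    Z = (raw - mu) / np.where(sd > _EPS, sd, 1.0)
    pseudo = Z.mean(axis=1)
    nn = NearestNeighbors(n_neighbors=k_local).fit(X)
    _, idx = nn.kneighbors(X)
    out = np.empty(n)
    for i in range(n):
        region = idx[i]
        t = pseudo[region]
        tc = t - t.mean()
        tn = np.linalg.norm(tc)
        best_r, best_b = -np.inf, 0
        for b in range(Z.shape[1]):
            s = Z[region, b]
            sc = s - s.mean()
            sn = np.linalg.norm(sc)
            r = float(tc @ sc / (tn * sn)) if tn > _EPS and sn > _EPS else 0.0
            if r > best_r + 1e-15:
                best_r, best_b = r, b
        out[i] = Z[i, best_b]
    return out


# ---------------------------------------------------------------------
# Thresholding, modes, search
# ---------------------------------------------------------------------

def threshold_by_contamination(scores: np.ndarray, contamination: float) -> np.ndarray:
    """Flag the top ``ceil(contamination * n)`` scores.

    Ties at the cut are broken by epoch index (lower index flagged first).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if not 0 <= contamination <= 1:
        raise ValueError("contamination must lie in [0, 1]")
    m = math.ceil(contamination * n)
    flags = np.zeros(n, dtype=bool)
    if m == 0:
        return flags
    order = np.lexsort((np.arange(n), -scores))  # score desc, index asc
    flags[order[:m]] = True
    return flags


def _score_matrix(X: np.ndarray, cfg: DetectorConfig) -> np.ndarray:
    if cfg.method == "lscp":
        params = dict(cfg.params)
        base = params.pop("base", None)
        return lscp_scores(X, base=base, seed=cfg.seed, **params)
    return _base_scores(X, cfg)


def run_detection(
    es: EpochSet | None,
    fm: FeatureMatrix,
    cfg: DetectorConfig,
    contamination: float = 0.172,
) -> DetectionResult:
    """Fit a detector and threshold it, per subject or on all epochs at once.

    ``mode='per_subject'`` fits and thresholds independently within each
    subject's epochs and merges the results; ``'aggregated'`` fits once.
    """
    X = _as_matrix(fm)
    n = len(X)
    if cfg.mode == "per_subject":
        if es is None:
            raise ValueError("per_subject mode needs the EpochSet for subject ids")
        scores = np.empty(n)
        flags = np.zeros(n, dtype=bool)
        partition: dict[str, np.ndarray] = {}
        subjects = np.asarray(es.subject_ids)
        for subj in dict.fromkeys(es.subject_ids):  # stable order
            idx = np.flatnonzero(subjects == subj)
            partition[subj] = idx
            s = _score_matrix(X[idx], cfg)
            scores[idx] = s
            flags[idx] = threshold_by_contamination(s, contamination)
        return DetectionResult(scores, flags, contamination, cfg, partition)
    scores = _score_matrix(X, cfg)
    flags = threshold_by_contamination(scores, contamination)
    return DetectionResult(scores, flags, contamination, cfg)


def random_search(
    fm: FeatureMatrix,
    truth: np.ndarray,
    method: str,
    param_space: dict,
    n_trials: int = 50,
    seed: int = 0,
    contamination: float = 0.172,
    es: EpochSet | None = None,
) -> tuple[DetectorConfig, list[dict]]:
    """Random hyper-parameter search ranked by F-score against annotations.

    ``param_space`` maps parameter name to either a list of choices or a
    ``(low, high)`` tuple sampled uniformly (ints if both ends are ints).
    Returns the best config and the full trial log.
    """
    rng = np.random.default_rng(seed)
    truth = np.asarray(truth, dtype=bool)
    log: list[dict] = []
    best: tuple[float, DetectorConfig] | None = None
    for trial in range(n_trials):
        params = {}
        for key, space in param_space.items():
            if isinstance(space, tuple) and len(space) == 2 and not isinstance(space[0], str):
                lo, hi = space
                if isinstance(lo, int) and isinstance(hi, int):
                    params[key] = int(rng.integers(lo, hi + 1))
                else:
                    params[key] = float(rng.uniform(lo, hi))
            else:
                params[key] = space[int(rng.integers(0, len(space)))]
        cfg = DetectorConfig(method, params, seed=int(rng.integers(0, 2**31 - 1)))
        res = run_detection(es, fm, cfg, contamination)
        f = f_score(res.flags, truth)
        log.append({"trial": trial, "params": dict(params), "f_score": f})
        if best is None or f > best[0]:
            best = (f, cfg)
    assert best is not None
    return best[1], log
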