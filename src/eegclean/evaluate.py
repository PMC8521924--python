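"""Agreement metrics, the size-matched random baseline, and the
downstream classifier probe.

Detection quality is reported as the F-score and Cohen's kappa between
predicted and annotated artifact flags.  The reference point is a
random classifier that knows the exact number of artifacts: it flags
exactly k of n epochs uniformly at random, whose expected F-score has
the closed form k/n (hypergeometric E[TP] = k^2/n).

The downstream probe trains a linear max-margin classifier on
down-sampled flattened epochs under stratified cross-validation with
identical fold assignments across data variants, so accuracy
differences isolate the effect of artifact correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .io_epochs import EpochSet

__all__ = [
    "MetricsReport",
    "confusion_counts",
    "f_score",
    "cohens_kappa",
    "random_baseline",
    "downstream_probe",
]


@dataclass
class MetricsReport:
    f_score: float
    kappa: float
    confusion: dict[str, int]
    per_subject: dict[str, dict[str, float]] = field(default_factory=dict)
    downstream_accuracies: dict[str, tuple[float, float]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(
            json.dumps(
                {
                    "f_score": self.f_score,
                    "kappa": self.kappa,
                    "confusion": self.confusion,
                    "per_subject": self.per_subject,
                    "downstream_accuracies": {
                        k: list(v) for k, v in self.downstream_accuracies.items()
                    },
                },
                indent=2,
            )
        )


def confusion_counts(pred, truth) -> dict[str, int]:
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have identical shape")
    return {
        "tp": int(np.sum(pred & truth)),
        "fp": int(np.sum(pred & ~truth)),
        "fn": int(np.sum(~pred & truth)),
        "tn": int(np.sum(~pred & ~truth)),
    }


def f_score(pred, truth) -> float:
    """F1 = 2TP / (2TP + FP + FN); 0 when the denominator vanishes."""
    c = confusion_counts(pred, truth)
    denom = 2 * c["tp"] + c["fp"] + c["fn"]
    return 0.0 if denom == 0 else 2 * c["tp"] / denom


def cohens_kappa(pred, truth) -> float:
    """Chance-corrected agreement; 0 when expected agreement is 1."""
    c = confusion_counts(pred, truth)
    n = sum(c.values())
    if n == 0:
        return 0.0
    po = (c["tp"] + c["tn"]) / n
    p_pred = (c["tp"] + c["fp"]) / n
    p_truth = (c["tp"] + c["fn"]) / n
    pe = p_pred * p_truth + (1 - p_pred) * (1 - p_truth)
    if pe >= 1.0 - 1e-15:
        return 0.0
    return (po - pe) / (1 - pe)


def metrics_report(pred, truth, subject_ids=None) -> MetricsReport:
    report = MetricsReport(
        f_score=f_score(pred, truth),
        kappa=cohens_kappa(pred, truth),
        confusion=confusion_counts(pred, truth),
    )
    if subject_ids is not None:
        pred = np.asarray(pred, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        subjects = np.asarray(subject_ids)
        for subj in dict.fromkeys(subject_ids):
            idx = subjects == subj
            report.per_subject[str(subj)] = {
                "f_score": f_score(pred[idx], truth[idx]),
                "kappa": cohens_kappa(pred[idx], truth[idx]),
            }
    return report


def random_baseline(n: int, k: int, reps: int = 10_000, seed: int = 0) -> tuple[float, float]:
    """Mean F-score and kappa of a size-matched random detector.

    The truth has k positives of n; each replicate flags exactly k
    epochs uniformly at random without replacement.  The mean F-score
    converges to k/n (since F = TP/k here and E[TP] = k^2/n).
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if k == 0:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    # flagging k of n uniformly: TP is the overlap of a random k-subset
    # with the k true positives
    u = rng.random((reps, n))
    flagged = np.argpartition(u, k - 1, axis=1)[:, :k]
    tp = np.sum(flagged < k, axis=1)  # truth = first k indices, WLOG
    fs = np.where(tp > 0, tp / k, 0.0)
    kappas = np.empty(reps)
    for r in range(reps):
        t = int(tp[r])
        c = {"tp": t, "fp": k - t, "fn": k - t, "tn": n - 2 * k + t}
        po = (c["tp"] + c["tn"]) / n
        pe = (k / n) ** 2 + ((n - k) / n) ** 2
        kappas[r] = 0.0 if pe >= 1 else (po - pe) / (1 - pe)
    return float(fs.mean()), float(kappas.mean())


def _flatten_epochs(es: EpochSet, target_fs: float = 50.0) -> np.ndarray:
    """Down-sample each epoch and flatten channels x samples to one row."""
    if target_fs < es.fs:
        factor = max(1, int(round(es.fs / target_fs)))
        data = sps.decimate(es.data, factor, axis=2, zero_phase=True)
    else:
        data = es.data
    return data.reshape(es.n_epochs, -1)


def _bandpower_rows(es: EpochSet) -> np.ndarray:
    """Per-channel log band powers + log SD, one row per epoch.

    A compact spectral representation sensitive to band-power condition
    effects that a linear classifier cannot recover from raw amplitude
    samples with random oscillator phases.
    """
    from .features import band_powers

    rows = np.empty((es.n_epochs, es.n_channels * 6))
    for i in range(es.n_epochs):
        feats = []
        for ch in range(es.n_channels):
            x = es.data[i, ch]
            feats.extend(np.log(band_powers(x, es.fs) + 1e-12))
            feats.append(np.log(np.std(x) + 1e-12))
        rows[i] = feats
    return rows


def downstream_probe(
    variants: dict[str, EpochSet],
    labels,
    n_folds: int = 5,
    seed: int = 0,
    target_fs: float = 50.0,
    representation: str = "flat",
    eval_mask=None,
    train_mask=None,
) -> dict[str, tuple[float, float]]:
    """Cross-validated linear-SVM condition decoding per data variant.

    All variants share the same fold assignments (stratified on the
    labels), so accuracy differences are attributable to the variant.
    ``representation`` is ``'flat'`` (down-sampled flattened epochs) or
    ``'bandpower'`` (per-channel log band powers).  ``train_mask``
    restricts each training fold to the masked epochs (e.g. the trials
    an artifact detector kept); ``eval_mask`` restricts accuracy
    scoring to the masked test epochs (e.g. artifact-bearing trials).
    Returns ``{variant: (mean, std)}``.
    """
    labels = np.asarray(labels)
    sizes = {es.n_epochs for es in variants.values()}
    if len(sizes) != 1 or sizes.pop() != len(labels):
        raise ValueError("all variants must share epoch count and label order")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < n_folds:
        raise ValueError("every class needs at least n_folds members for stratification")
    if representation not in ("flat", "bandpower"):
        raise ValueError(f"unknown representation {representation!r}")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(labels)), labels))
    if eval_mask is not None:
        eval_mask = np.asarray(eval_mask, dtype=bool)
    if train_mask is not None:
        train_mask = np.asarray(train_mask, dtype=bool)
    out: dict[str, tuple[float, float]] = {}
    for name, es in variants.items():
        if representation == "flat":
            X = _flatten_epochs(es, target_fs)
        else:
            X = _bandpower_rows(es)
        accs = []
        for train_idx, test_idx in folds:
            if train_mask is not None:
                train_idx = train_idx[train_mask[train_idx]]
            if eval_mask is not None:
                test_idx = test_idx[eval_mask[test_idx]]
                if len(test_idx) == 0:
                    continue
            clf = make_pipeline(StandardScaler(), LinearSVC(C=0.01, max_iter=5000))
            clf.fit(X[train_idx], labels[train_idx])
            accs.append(float(np.mean(clf.predict(X[test_idx]) == labels[test_idx])))
        out[name] = (float(np.mean(accs)), float(np.std(accs)))
    return out
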