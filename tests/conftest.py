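"""Shared fixtures: synthetic data sets (cheap and benchmark-scale) and a
minimal EDF writer for input/output round-trip tests."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pytest

from eegclean import features, synth


def write_edf(
    path: Path,
    signals_uv: np.ndarray,
    fs: float,
    ch_names: list[str] | None = None,
    phys_max: float | None = None,
) -> Path:
    """Write a minimal valid EDF file (int16 records, physical unit uV).

    Small test-only writer; ``phys_max`` overrides the symmetric physical
    range to exercise amplitude scaling.
    """
    signals_uv = np.asarray(signals_uv, dtype=float)
    n_ch, n_samp = signals_uv.shape
    ch_names = ch_names or [f"EEG{i}" for i in range(n_ch)]
    rec_dur = 1.0
    spr = int(round(fs * rec_dur))  # samples per record per channel
    n_rec = n_samp // spr
    assert n_rec * spr == n_samp, "fixture length must be a whole number of records"
    pmax = float(phys_max) if phys_max is not None else max(1.0, np.abs(signals_uv).max())
    pmin = -pmax
    dmax, dmin = 32767, -32768

    def pad(s: str, n: int) -> bytes:
        return s.encode("ascii")[:n].ljust(n)

    header = b"".join(
        [
            pad("0", 8),
            pad("test subject", 80),
            pad("test recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * n_ch), 8),
            pad("", 44),
            pad(str(n_rec), 8),
            pad(str(rec_dur), 8),
            pad(str(n_ch), 4),
        ]
    )
    per_sig = b"".join(
        [
            b"".join(pad(nm, 16) for nm in ch_names),
            b"".join(pad("AgAgCl electrode", 80) for _ in ch_names),
            b"".join(pad("uV", 8) for _ in ch_names),
            b"".join(pad(f"{pmin:g}", 8) for _ in ch_names),
            b"".join(pad(f"{pmax:g}", 8) for _ in ch_names),
            b"".join(pad(str(dmin), 8) for _ in ch_names),
            b"".join(pad(str(dmax), 8) for _ in ch_names),
            b"".join(pad("", 80) for _ in ch_names),
            b"".join(pad(str(spr), 8) for _ in ch_names),
            b"".join(pad("", 32) for _ in ch_names),
        ]
    )
    scale = (pmax - pmin) / (dmax - dmin)
    digital = np.round((signals_uv - pmin) / scale + dmin).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        f.write(per_sig)
        for r in range(n_rec):
            for ch in range(n_ch):
                f.write(digital[ch, r * spr : (r + 1) * spr].tobytes())
    return path


def read_edf_amplitudes_direct(path: Path) -> np.ndarray:
    """Independent struct-level EDF parse (scaling oracle for read_edf)."""
    raw = Path(path).read_bytes()
    n_ch = int(raw[252:256].decode().strip())
    n_rec = int(raw[236:244].decode().strip())
    sig = raw[256 : 256 + 256 * n_ch]

    def field(offset, width, i):
        start = offset * n_ch + width * i
        return sig[start : start + width].decode().strip()

    pmin = np.array([float(field(16 + 80 + 8, 8, i)) for i in range(n_ch)])
    pmax = np.array([float(field(16 + 80 + 8 + 8, 8, i)) for i in range(n_ch)])
    dmin = np.array([float(field(16 + 80 + 8 + 16, 8, i)) for i in range(n_ch)])
    dmax = np.array([float(field(16 + 80 + 8 + 24, 8, i)) for i in range(n_ch)])
    spr = np.array([int(field(216, 8, i)) for i in range(n_ch)])  # after prefiltering block
    body = raw[256 + 256 * n_ch :]
    out = [[] for _ in range(n_ch)]
    pos = 0
    for _ in range(n_rec):
        for ch in range(n_ch):
            k = int(spr[ch])
            vals = np.frombuffer(body[pos : pos + 2 * k], dtype="<i2").astype(float)
            out[ch].append((vals - dmin[ch]) * (pmax[ch] - pmin[ch]) / (dmax[ch] - dmin[ch]) + pmin[ch])
            pos += 2 * k
    return np.stack([np.concatenate(c) for c in out])


@pytest.fixture(scope="session")
def small_set():
    """120 epochs x 4 channels with default prevalence/magnitude artifacts."""
    cfg = synth.SynthConfig(n_epochs=120, n_channels=4, seed=1)
    es, truth, masks = synth.make_dataset(cfg)
    return {"cfg": cfg, "es": es, "truth": truth, "masks": masks}


@pytest.fixture(scope="session")
def small_features(small_set):
    fm = features.extract_features(small_set["es"])
    return {"fm": fm, "fz": features.standardize(fm)}


@pytest.fixture(scope="session")
def benchmark():
    """The seeded default synthetic benchmark: n=1000, prevalence 0.172,
    artifact magnitude 8, two subjects with subject-specific artifact
    topographies, 8 channels at 200 Hz."""
    cfg = synth.SynthConfig(
        n_epochs=1000,
        n_channels=8,
        seed=7,
        artifact_magnitude=8.0,
        n_subjects=2,
        subject_artifact_bias=True,
    )
    es, truth, masks = synth.make_dataset(cfg)
    fm = features.extract_features(es)
    return {
        "cfg": cfg,
        "es": es,
        "truth": truth,
        "masks": masks,
        "fm": fm,
        "fz": features.standardize(fm),
    }
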