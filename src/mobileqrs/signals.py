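"""ECG record / annotation I/O and the shared preprocessing primitives.

Signals travel through the pipeline as :class:`ECGRecord` objects (uniformly
sampled single-channel voltage plus sampling rate).  Reference R peaks and QRS
boundaries are carried by :class:`AnnotationTrack` with 0-based sample
indices.  File formats are plain delimited text: one value per line (or a
``time,value`` two-column variant) for signals, and a headered CSV/TSV with
``r_peak`` / ``qrs_on`` / ``qrs_off`` columns for annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps


@dataclass
class ECGRecord:
    """A uniformly sampled single-channel ECG.

    Parameters
    ----------
    samples : ndarray
        Voltage samples (arbitrary units), finite, length >= 2.
    fs : float
        Sampling rate in Hz, > 0.
    role : str
        ``"mobile"`` or ``"chest"``.
    start_time : float
        Offset of sample 0 in seconds.
    subject_id : str
        Opaque subject label.
    session : str
        ``"training"`` or ``"testing"``.
    """

    samples: np.ndarray
    fs: float
    role: str = "mobile"
    start_time: float = 0.0
    subject_id: str = ""
    session: str = "training"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("ECGRecord needs a 1-D signal of length >= 2")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECGRecord samples must all be finite")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.role not in ("mobile", "chest"):
            raise ValueError(f"unknown channel role {self.role!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def time(self, index: np.ndarray | int) -> np.ndarray | float:
        """Absolute time in seconds of a sample index."""
        return self.start_time + np.asarray(index) / self.fs


@dataclass
class AnnotationTrack:
    """Per-beat reference marks: R peaks and optional QRS boundaries.

    All indices are 0-based sample indices into the annotated record.  When
    boundaries are present they satisfy ``qrs_on[j] < r_peaks[j] < qrs_off[j]``
    for every beat ``j``.
    """

    r_peaks: np.ndarray
    qrs_on: np.ndarray | None = None
    qrs_off: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.r_peaks = np.asarray(self.r_peaks, dtype=np.int64)
        if self.r_peaks.size and np.any(np.diff(self.r_peaks) <= 0):
            raise ValueError("r_peaks must be strictly increasing")
        for name in ("qrs_on", "qrs_off"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=np.int64)
                if v.size != self.r_peaks.size:
                    raise ValueError(f"{name} must have one entry per beat")
                setattr(self, name, v)
        if self.qrs_on is not None and np.any(self.qrs_on >= self.r_peaks):
            raise ValueError("qrs_on must precede its R peak")
        if self.qrs_off is not None and np.any(self.qrs_off <= self.r_peaks):
            raise ValueError("qrs_off must follow its R peak")

    def __len__(self) -> int:
        return self.r_peaks.size

    def durations_ms(self, fs: float) -> np.ndarray:
        """Per-beat QRS durations in ms (requires both boundaries)."""
        if self.qrs_on is None or self.qrs_off is None:
            raise ValueError("QRS boundaries are not annotated")
        return (self.qrs_off - self.qrs_on) * 1000.0 / fs


def read_ecg(path: str | Path, fs: float, role: str = "mobile", **kwargs) -> ECGRecord:
    """Read a plain-text ECG file.

    Accepts one numeric value per line, or a two-column delimited
    ``time,value`` layout (the second column is taken as the signal).
    Rows containing NaN/inf are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.atleast_2d(np.loadtxt(path, delimiter=None if path.suffix != ".csv" else ","))
    if arr.ndim == 2 and arr.shape[0] == 1 and arr.shape[1] > 2:
        arr = arr.T
    values = arr[:, -1] if arr.ndim == 2 and arr.shape[1] >= 2 else arr.ravel()
    if values.size < 2:
        raise ValueError(f"{path}: fewer than 2 samples")
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{path}: non-finite sample values")
    return ECGRecord(values, fs=fs, role=role, **kwargs)


def write_ecg(rec: ECGRecord, path: str | Path) -> None:
    """Write one sample value per line at full float precision."""
    np.savetxt(Path(path), rec.samples, fmt="%.17g")


def read_annotations(path: str | Path) -> AnnotationTrack:
    """Read an annotation table (CSV/TSV with an ``r_peak`` column and
    optional ``qrs_on`` / ``qrs_off`` columns of 0-based sample indices)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if "r_peak" not in df.columns:
        raise ValueError(f"{path}: missing required 'r_peak' column")
    kw = {}
    for col in ("qrs_on", "qrs_off"):
        if col in df.columns:
            kw[col] = df[col].to_numpy(dtype=np.int64)
    return AnnotationTrack(df["r_peak"].to_numpy(dtype=np.int64), **kw)


def write_annotations(track: AnnotationTrack, path: str | Path) -> None:
    data = {"r_peak": track.r_peaks}
    if track.qrs_on is not None:
        data["qrs_on"] = track.qrs_on
    if track.qrs_off is not None:
        data["qrs_off"] = track.qrs_off
    pd.DataFrame(data).to_csv(path, index=False)


def butter_bandpass_sos(low: float, high: float, fs: float, order: int = 6):
    """Butterworth bandpass design in second-order sections."""
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band edges ({low}, {high}) Hz violate 0 < low < high < {nyq}")
    return sps.butter(order, [low / nyq, high / nyq], btype="band", output="sos")


def bandpass_filter(rec: ECGRecord, low: float = 2.0, high: float = 30.0,
                    order: int = 6) -> ECGRecord:
    """Zero-phase Butterworth bandpass (default 2-30 Hz, order 6).

    Applied forward-backward (``sosfiltfilt``) so that QRS landmark timing is
    not shifted by filter phase; the magnitude response is therefore the
    square of the single-pass design.  Removes baseline wander (below 2 Hz)
    and power-line interference (above 30 Hz).
    """
    sos = butter_bandpass_sos(low, high, rec.fs, order)
    padlen = 3 * (2 * order + 1)
    if rec.samples.size <= padlen:
        raise ValueError("record shorter than the filter warm-up length")
    filtered = sps.sosfiltfilt(sos, rec.samples)
    return replace(rec, samples=filtered)


def resample_to_length(seq: np.ndarray, target_len: int) -> np.ndarray:
    """Linear-interpolation resampling onto a uniform grid of ``target_len``.

    Endpoints are preserved exactly; ``target_len == len(seq)`` returns a
    copy of the input.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.size < 2:
        raise ValueError("need at least 2 samples to resample")
    if target_len < 2:
        raise ValueError("target_len must be >= 2")
    if target_len == seq.size:
        return seq.copy()
    old = np.linspace(0.0, 1.0, seq.size)
    new = np.linspace(0.0, 1.0, target_len)
    out = np.interp(new, old, seq)
    out[0], out[-1] = seq[0], seq[-1]
    return out


def minmax_scale(seq: np.ndarray) -> tuple[np.ndarray, bool]:
    """Affinely map a sequence onto [0, 1].

    Returns ``(scaled, degenerate)``.  A constant (flat-line) input cannot be
    scaled; it maps to all zeros with ``degenerate=True`` so callers can drop
    it (saturated artifact segments show up this way) instead of erroring.
    """
    seq = np.asarray(seq, dtype=float)
    if seq.size < 2:
        raise ValueError("need at least 2 samples")
    lo, hi = seq.min(), seq.max()
    if hi == lo:
        return np.zeros_like(seq), True
    return (seq - lo) / (hi - lo), False
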