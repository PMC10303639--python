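"""Stage I — heartbeat identification on the filtered mobile ECG.

Spike candidates are picked by an adaptive amplitude threshold (a moving
95th-percentile envelope of the rectified signal), described by a
ten-feature vector mixing amplitude, morphology, timing and local-SNR
proxies, and accepted or rejected by a soft-margin linear SVM trained with
the chest-lead R peaks as ground truth.  Accepted peaks bound the R-to-R
heartbeat segments consumed by the warping stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats
from sklearn.svm import SVC

from .signals import ECGRecord, AnnotationTrack

FEATURE_NAMES = (
    "apex_abs_amplitude",
    "peak_to_peak_60ms",
    "apex_over_local_median",
    "half_max_width_ms",
    "max_abs_slope_60ms",
    "energy_ratio_60_500ms",
    "prev_interval_ms",
    "interval_over_median",
    "corr_with_running_mean",
    "excess_kurtosis_60ms",
)

N_FEATURES = len(FEATURE_NAMES)


@dataclass
class BeatCandidate:
    """A spike candidate: apex sample index plus the half-open feature window."""

    peak_index: int
    window: tuple[int, int]
    truncated: bool = False


@dataclass
class SVMModel:
    """Linear SVM in support-vector form.

    The decision function is ``sign(sum_i alpha_i * y_i * <x, x_i> + b)``
    evaluated on standardized features; ``alpha_i * y_i`` is stored as the
    signed dual coefficient.  ``sign(0)`` is defined as ``+1``.
    """

    support_vectors: np.ndarray          # (V, 10), standardized space
    dual_coef: np.ndarray                # (V,) = alpha_i * y_i
    bias: float
    center: np.ndarray                   # per-feature training mean
    scale: np.ndarray                    # per-feature training std (>= eps)
    kernel: str = "linear"

    @property
    def n_support(self) -> int:
        return self.support_vectors.shape[0]

    def decision_value(self, x: np.ndarray) -> float:
        x = np.asarray(x, dtype=float)
        if x.shape != (self.support_vectors.shape[1],):
            raise ValueError("wrong feature dimension")
        z = (x - self.center) / self.scale
        return float((self.support_vectors @ z) @ self.dual_coef + self.bias)


def _moving_percentile_envelope(x: np.ndarray, fs: float, window_s: float,
                                q: float = 95.0) -> np.ndarray:
    """Moving ``q``-th percentile of ``|x|``, evaluated on half-window hops
    and linearly interpolated back to sample resolution."""
    n = x.size
    win = max(int(round(window_s * fs)), 2)
    hop = max(win // 2, 1)
    centers, values = [], []
    for start in range(0, n, hop):
        seg = x[max(0, start - win // 2): start + win // 2]
        if seg.size == 0:
            continue
        centers.append(min(start, n - 1))
        values.append(np.percentile(seg, q))
    centers, values = np.asarray(centers), np.asarray(values)
    return np.interp(np.arange(n), centers, values)


def detect_spike_candidates(rec: ECGRecord, refractory_ms: float = 250.0,
                            window_s: float = 2.0, frac: float = 0.5) -> list[BeatCandidate]:
    """Adaptive-threshold spike picking on a bandpass-filtered record.

    A sample is a candidate apex when it is a local maximum of the rectified
    signal exceeding ``frac`` times the moving 95th-percentile envelope
    (window ``window_s``), and no larger candidate lies within the refractory
    period.  Returns candidates sorted by index, each with a +-1 s feature
    window clipped to the record.
    """
    x = np.abs(rec.samples)
    if x.size < int(window_s * rec.fs):
        raise ValueError("record shorter than one threshold window")
    thr = frac * _moving_percentile_envelope(x, rec.fs, window_s)
    distance = max(int(round(refractory_ms / 1000.0 * rec.fs)), 1)
    peaks, _ = sps.find_peaks(x, height=thr, distance=distance)
    half = int(round(1.0 * rec.fs))
    out = []
    for p in peaks:
        lo, hi = p - half, p + half
        trunc = lo < 0 or hi > x.size
        out.append(BeatCandidate(int(p), (max(lo, 0), min(hi, x.size)), trunc))
    return out


@dataclass
class _FeatureState:
    """Running state threaded through sequential feature extraction."""

    intervals_ms: list = field(default_factory=list)
    mean_window: np.ndarray | None = None
    n_windows: int = 0

    def update(self, interval_ms: float | None, window: np.ndarray) -> None:
        if interval_ms is not None:
            self.intervals_ms.append(interval_ms)
        if self.mean_window is None or self.mean_window.size != window.size:
            self.mean_window = window.astype(float).copy()
            self.n_windows = 1
        else:
            self.n_windows += 1
            self.mean_window += (window - self.mean_window) / self.n_windows


def _norm_corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else 0.0


def _half_max_width_ms(seg: np.ndarray, apex_local: int, fs: float) -> float:
    """Width (ms) of the spike at half its apex height, by crossing scan."""
    apex = seg[apex_local]
    half = abs(apex) / 2.0
    mag = np.abs(seg)
    left = apex_local
    while left > 0 and mag[left - 1] >= half:
        left -= 1
    right = apex_local
    while right < seg.size - 1 and mag[right + 1] >= half:
        right += 1
    return (right - left + 1) * 1000.0 / fs


def extract_features(rec: ECGRecord, cand: BeatCandidate,
                     prev: BeatCandidate | None = None,
                     state: _FeatureState | None = None) -> np.ndarray:
    """The ten-dimensional candidate description, in fixed order.

    1. apex absolute amplitude
    2. peak-to-peak amplitude within +-60 ms
    3. apex amplitude over the median absolute signal within +-1 s
       (a local signal-to-noise proxy)
    4. width at half the apex amplitude, ms
    5. maximum absolute slope within +-60 ms (units/sample * fs)
    6. signal energy within +-60 ms over energy within +-500 ms
    7. interval to the previous candidate, ms (0 if none)
    8. that interval over the running median interval (1 if undefined)
    9. normalized correlation of the +-60 ms window with the running mean
       of preceding candidate windows (0 if none)
    10. excess kurtosis of the +-60 ms window

    A window truncated by the record edge is computed on the available
    samples and the candidate is flagged ``truncated``.
    """
    x = rec.samples
    fs = rec.fs
    p = cand.peak_index

    def seg(half_ms: float) -> np.ndarray:
        h = int(round(half_ms / 1000.0 * fs))
        if p - h < 0 or p + h + 1 > x.size:
            cand.truncated = True
        return x[max(p - h, 0): min(p + h + 1, x.size)]

    w60 = seg(60.0)
    w500 = seg(500.0)
    w1000 = seg(1000.0)

    apex = abs(x[p])
    f1 = apex
    f2 = float(w60.max() - w60.min())
    med = float(np.median(np.abs(w1000)))
    f3 = apex / med if med > 0 else 0.0
    f4 = _half_max_width_ms(w60, p - max(p - int(round(0.060 * fs)), 0), fs)
    f5 = float(np.max(np.abs(np.diff(w60)))) * fs if w60.size > 1 else 0.0
    e60 = float(np.sum(w60 ** 2))
    e500 = float(np.sum(w500 ** 2))
    f6 = e60 / e500 if e500 > 0 else 0.0

    if prev is not None:
        interval_ms = (p - prev.peak_index) * 1000.0 / fs
    else:
        interval_ms = None
    f7 = interval_ms if interval_ms is not None else 0.0
    if state is not None and state.intervals_ms and interval_ms is not None:
        f8 = interval_ms / float(np.median(state.intervals_ms))
    else:
        f8 = 1.0
    if state is not None and state.mean_window is not None and state.mean_window.size == w60.size:
        f9 = _norm_corr(w60, state.mean_window)
    else:
        f9 = 0.0
    f10 = float(stats.kurtosis(w60, fisher=True, bias=True)) if w60.size > 3 else 0.0

    if state is not None:
        state.update(interval_ms, w60)
    return np.array([f1, f2, f3, f4, f5, f6, f7, f8, f9, f10], dtype=float)


def extract_feature_matrix(rec: ECGRecord, cands: list[BeatCandidate]) -> np.ndarray:
    """Sequential feature extraction over a candidate list (running state
    for intervals and the mean spike window is threaded left to right)."""
    state = _FeatureState()
    rows = []
    prev = None
    for c in cands:
        rows.append(extract_features(rec, c, prev, state))
        prev = c
    X = np.asarray(rows, dtype=float).reshape(len(cands), N_FEATURES)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    return X


def label_candidates(cands: list[BeatCandidate], reference: AnnotationTrack,
                     fs: float, tol_ms: float = 75.0) -> np.ndarray:
    """Supervised labels from time-aligned reference R peaks.

    A candidate is +1 iff its apex lies within ``tol_ms`` of a reference
    R peak not already claimed by a nearer candidate (greedy one-to-one
    matching on increasing |offset|); otherwise -1.
    """
    if len(reference) == 0:
        raise ValueError("empty reference annotation")
    tol = tol_ms / 1000.0 * fs
    labels = np.full(len(cands), -1, dtype=int)
    pairs = []
    refs = reference.r_peaks
    for ci, c in enumerate(cands):
        j = int(np.argmin(np.abs(refs - c.peak_index)))
        lo, hi = max(j - 1, 0), min(j + 2, refs.size)
        for r in range(lo, hi):
            d = abs(refs[r] - c.peak_index)
            if d <= tol:
                pairs.append((d, ci, r))
    claimed_ref: set[int] = set()
    claimed_cand: set[int] = set()
    for d, ci, r in sorted(pairs):
        if ci in claimed_cand or r in claimed_ref:
            continue
        labels[ci] = 1
        claimed_cand.add(ci)
        claimed_ref.add(r)
    return labels


def train_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> SVMModel:
    """Fit the soft-margin linear SVM on standardized features.

    Standardization constants (training mean / std) are stored in the model
    and re-applied at prediction time.  Both classes must be present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size or X.shape[0] < 2:
        raise ValueError("need len(X) == len(y) >= 2")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to train the SVM")
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale < 1e-12] = 1.0
    Z = (X - center) / scale
    clf = SVC(kernel="linear", C=C)
    clf.fit(Z, y)
    # sklearn orders classes ascending: decision > 0 <=> class +1
    return SVMModel(
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        center=center,
        scale=scale,
    )


def svm_predict(model: SVMModel, x: np.ndarray) -> int:
    """Evaluate the support-vector decision function; sign(0) := +1."""
    return 1 if model.decision_value(x) >= 0 else -1


def svm_predict_batch(model: SVMModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    Z = (X - model.center) / model.scale
    dec = Z @ model.support_vectors.T @ model.dual_coef + model.bias
    return np.where(dec >= 0, 1, -1)


def segment_heartbeats(rec: ECGRecord, accepted_peaks: np.ndarray) -> list[tuple[int, int]]:
    """R-to-R segmentation: n accepted peaks yield n-1 half-open segments
    ``[R_j, R_{j+1})``, tiling the span with no gaps or overlaps.  Each
    segment holds the second half of beat j and the first half of beat j+1.
    """
    peaks = np.asarray(accepted_peaks, dtype=np.int64)
    if peaks.size < 2:
        raise ValueError("need at least 2 accepted peaks to segment")
    if np.any(np.diff(peaks) <= 0):
        raise ValueError("peaks must be strictly increasing")
    if peaks[0] < 0 or peaks[-1] >= len(rec):
        raise ValueError("peaks outside the record")
    return [(int(peaks[j]), int(peaks[j + 1])) for j in range(peaks.size - 1)]
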