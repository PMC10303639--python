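"""Stage III — QRS duration assembly, minute averaging, lead-bias
calibration, and agreement metrics.

Because beats are segmented R-to-R, one segment holds the QRS *offset* of
its first beat and the *onset* of the following beat: the duration of the
beat centered on R peak j therefore stitches the onset located in segment
j-1 to the offset located in segment j.  Durations are averaged over
evaluation minutes, shifted by a per-subject additive bias learned on the
training session (mean chest minus mean mobile duration), and compared to
the chest reference with correlation / error / Bland-Altman summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .mvdtw import WarpResult

DEFAULT_MAX_DURATION_MS = 300.0


@dataclass
class CalibrationModel:
    """Additive per-subject lead bias, chest-mean minus mobile-mean (ms),
    learned from the training session only."""

    bias_ms: float


@dataclass
class MetricsReport:
    """Agreement between predicted and reference minute durations.

    ``cr`` Pearson correlation; ``me``/``std`` mean and sample (n-1 denominator)
    standard deviation of the signed error pred - ref (ms); ``mae`` mean
    absolute error; ``rmse`` root mean square error; ``ba_limits`` the
    Bland-Altman mean difference +- 1.96 * std.
    """

    cr: float
    me: float
    std: float
    mae: float
    rmse: float
    ba_limits: tuple[float, float]
    n: int


def segment_boundaries_to_samples(warp: WarpResult, segment: tuple[int, int],
                                  resampled_len: int) -> tuple[int, int]:
    """Map warped boundary indices (resampled-beat coordinates) back to
    absolute sample indices of the original record."""
    start, end = segment
    span = end - start
    ratio = (span - 1) / (resampled_len - 1)
    off = start + int(round(warp.qrs_off * ratio))
    on = start + int(round(warp.qrs_on * ratio))
    return off, on


def beat_qrs_durations(warp_results: list[WarpResult],
                       segments: list[tuple[int, int]],
                       sqi: np.ndarray, fs: float,
                       resampled_len: int,
                       max_duration_ms: float = DEFAULT_MAX_DURATION_MS) -> tuple[np.ndarray, np.ndarray]:
    """Per-beat QRS durations (ms) stitched across adjacent segments.

    Beat j (centered on the peak shared by segments j-1 and j) is valid only
    when both neighboring segments carry SQI = 1; its duration runs from the
    onset located in segment j-1 to the offset located in segment j.
    Durations outside (0, ``max_duration_ms``) are dropped as warp
    pathologies.  Returns ``(durations_ms, r_peak_samples)`` for the valid
    beats; n segments can yield at most n-1 beats.
    """
    if len(warp_results) != len(segments) or len(segments) != len(sqi):
        raise ValueError("warp results, segments and SQI must be aligned")
    if len(segments) < 2:
        raise ValueError("need at least 2 segments to assemble a duration")
    durations, peaks = [], []
    for j in range(1, len(segments)):
        if sqi[j - 1] != 1 or sqi[j] != 1:
            continue
        _, on_abs = segment_boundaries_to_samples(
            warp_results[j - 1], segments[j - 1], resampled_len)
        off_abs, _ = segment_boundaries_to_samples(
            warp_results[j], segments[j], resampled_len)
        dur = (off_abs - on_abs) * 1000.0 / fs
        if 0.0 < dur < max_duration_ms:
            durations.append(dur)
            peaks.append(segments[j][0])
    return np.asarray(durations, dtype=float), np.asarray(peaks, dtype=np.int64)


def minute_average(durations_ms: np.ndarray, times_s: np.ndarray,
                   minute_spans: list[tuple[float, float]]) -> np.ndarray:
    """Mean duration per evaluation window; windows with no valid beat give
    NaN (propagated downstream, never imputed)."""
    durations_ms = np.asarray(durations_ms, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    out = np.full(len(minute_spans), np.nan)
    for i, (t0, t1) in enumerate(minute_spans):
        mask = (times_s >= t0) & (times_s < t1)
        if np.any(mask):
            out[i] = durations_ms[mask].mean()
    return out


def fit_bias(train_mobile: np.ndarray, train_chest: np.ndarray) -> CalibrationModel:
    """Lead bias from paired training minutes: mean(chest) - mean(mobile)
    over minutes where both are available."""
    m = np.asarray(train_mobile, dtype=float)
    c = np.asarray(train_chest, dtype=float)
    if m.shape != c.shape:
        raise ValueError("mobile and chest minute series must be aligned")
    ok = np.isfinite(m) & np.isfinite(c)
    if not np.any(ok):
        raise ValueError("no paired non-missing training minutes")
    return CalibrationModel(bias_ms=float(c[ok].mean() - m[ok].mean()))


def apply_calibration(estimates: np.ndarray, model: CalibrationModel) -> np.ndarray:
    """Shift minute estimates by the learned bias; missing stays missing."""
    return np.asarray(estimates, dtype=float) + model.bias_ms


def evaluate(pred: np.ndarray, ref: np.ndarray) -> MetricsReport:
    """Agreement metrics over paired non-missing minutes.

    CR is the Pearson correlation (NaN when the reference has zero
    variance); errors are pred - ref.  STD uses the sample (n-1)
    convention, so RMSE^2 = ME^2 + STD^2 * (n-1)/n.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    ok = np.isfinite(pred) & np.isfinite(ref)
    if ok.sum() < 2:
        raise ValueError("need at least 2 paired non-missing minutes")
    p, r = pred[ok], ref[ok]
    e = p - r
    me = float(e.mean())
    std = float(e.std(ddof=1))
    mae = float(np.abs(e).mean())
    rmse = float(math.sqrt(np.mean(e ** 2)))
    if r.std() == 0 or p.std() == 0:
        cr = float("nan")
    else:
        cr = float(np.corrcoef(p, r)[0, 1])
    ba = (me - 1.96 * std, me + 1.96 * std)
    return MetricsReport(cr=cr, me=me, std=std, mae=mae, rmse=rmse,
                         ba_limits=ba, n=int(ok.sum()))
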