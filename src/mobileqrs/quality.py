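"""Distortion-based heartbeat purification.

Per-beat warping distortions are normalized by the training-session maximum,
a quality threshold tau is learned once per subject by the histogram
triangle method (the bin with maximum perpendicular distance to the line
from the histogram peak to its rightmost nonempty bin), and each beat gets a
binary signal quality index: 1 iff both its raw and its trailing-moving-
average distortion fall at or below tau.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_NBINS = 50
DEFAULT_SMOOTH_ORDER = 10


@dataclass
class DistortionHistogram:
    """Triangle-method threshold search result."""

    bin_edges: np.ndarray
    counts: np.ndarray
    b_max: int                   # bin of maximum count
    b_right: int                 # rightmost nonempty bin
    distances: np.ndarray        # perpendicular distance per bin in [b_max, b_right]
    tau: float                   # threshold (center of the maximizing bin)


def normalize_distortions(raw_pi: np.ndarray, reference_max: float) -> np.ndarray:
    """Scale raw distortions by the training-session maximum, clipped to [0, 1].

    The anchor is learned on the training session and persisted with the
    subject model so that the threshold tau transfers unchanged to testing
    data; testing distortions beyond the anchor clip to 1.
    """
    if not reference_max > 0:
        raise ValueError("reference_max must be positive")
    raw_pi = np.asarray(raw_pi, dtype=float)
    if np.any(raw_pi < 0):
        raise ValueError("distortions must be nonnegative")
    return np.clip(raw_pi / reference_max, 0.0, 1.0)


def point_line_distance(px: np.ndarray, py: np.ndarray,
                        x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    """Perpendicular distance from points to the line through (x0,y0)-(x1,y1)."""
    dx, dy = x1 - x0, y1 - y0
    norm = np.hypot(dx, dy)
    if norm == 0:
        raise ValueError("degenerate hypotenuse")
    return np.abs(dy * (px - x0) - dx * (py - y0)) / norm


def triangle_threshold(values: np.ndarray, nbins: int = DEFAULT_NBINS) -> DistortionHistogram:
    """Histogram-triangle threshold search on normalized distortions.

    The histogram (``nbins`` equal bins over [0, 1]) of mobile-beat
    distortions is assumed left-skewed: clean beats pile up at low
    distortion while artifact-corrupted beats spread over a long right tail.
    The hypotenuse runs from the peak bin ``(b_max, h(b_max))`` to the
    rightmost nonempty bin ``(b_right, h(b_right))`` in (bin index, count)
    coordinates; tau is the center of the bin between them with maximum
    perpendicular distance to that line.
    """
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=nbins, range=(0.0, 1.0))
    nonempty = np.flatnonzero(counts)
    if nonempty.size < 2:
        raise ValueError("need at least 2 nonempty histogram bins")
    b_max = int(np.argmax(counts))
    b_right = int(nonempty[-1])
    if b_right <= b_max:
        raise ValueError("histogram peak at the right edge; not left-skewed")
    bins = np.arange(b_max, b_right + 1)
    dist = point_line_distance(bins.astype(float), counts[bins].astype(float),
                               float(b_max), float(counts[b_max]),
                               float(b_right), float(counts[b_right]))
    b_star = int(bins[np.argmax(dist)])
    tau = float(0.5 * (edges[b_star] + edges[b_star + 1]))
    return DistortionHistogram(bin_edges=edges, counts=counts, b_max=b_max,
                               b_right=b_right, distances=dist, tau=tau)


def smooth_distortions(pi: np.ndarray, A: int = DEFAULT_SMOOTH_ORDER) -> np.ndarray:
    """Trailing (causal) moving average of order ``A``.

    ``eta[j]`` averages ``pi[j-A+1 .. j]``; during start-up (j < A-1) the
    mean runs over the j+1 values available.
    """
    if A < 1:
        raise ValueError("smoothing order must be >= 1")
    pi = np.asarray(pi, dtype=float)
    csum = np.concatenate(([0.0], np.cumsum(pi)))
    j = np.arange(pi.size)
    lo = np.maximum(j - A + 1, 0)
    return (csum[j + 1] - csum[lo]) / (j + 1 - lo)


def compute_sqi(pi: np.ndarray, eta: np.ndarray, tau: float) -> np.ndarray:
    """Binary signal quality index: 1 iff both the raw and the smoothed
    distortion are at or below the threshold (inclusive)."""
    pi = np.asarray(pi, dtype=float)
    eta = np.asarray(eta, dtype=float)
    if pi.shape != eta.shape:
        raise ValueError("pi and eta must be aligned")
    return ((pi <= tau) & (eta <= tau)).astype(np.int8)


def purify(n_beats: int, sqi: np.ndarray) -> np.ndarray:
    """Indices of beats retained by the quality flags (SQI == 1)."""
    sqi = np.asarray(sqi)
    if sqi.size != n_beats:
        raise ValueError("SQI series not aligned with the beat list")
    return np.flatnonzero(sqi == 1)
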