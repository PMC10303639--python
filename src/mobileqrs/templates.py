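"""Per-subject heartbeat template learning by K-medoid clustering.

Training-session R-to-R beats (min-max scaled, resampled to a common length,
expanded to three views) are clustered with K-means++-seeded partitioning
around medoids (PAM); the medoid of the most-populous cluster becomes the
DTW template, and its QRS boundaries are mapped in from a reference
annotation.  Distances are plain Euclidean on the concatenation of the three
views — the clustering deliberately avoids DTW distances to keep the
learning step cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .signals import AnnotationTrack

DEFAULT_BEAT_LENGTH = 256


@dataclass
class BeatSet:
    """Equal-length scaled beats stacked row-wise.

    ``vectors`` is the (n_beats, D) matrix clustered on; for multiview beats
    D is three times the common resampled length (views concatenated).
    """

    vectors: np.ndarray
    length: int

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("BeatSet expects a 2-D (n_beats, D) array")
        if self.vectors.min() < -1e-9 or self.vectors.max() > 1 + 1e-9:
            raise ValueError("beat values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.vectors.shape[0]


@dataclass
class Clustering:
    """A K-medoid partition: medoid row indices, per-beat assignment, and the
    summed instance-to-medoid dissimilarity objective."""

    medoids: np.ndarray          # (K,) beat indices
    assignment: np.ndarray       # (n,) index into medoids
    objective: float

    def cluster_sizes(self) -> np.ndarray:
        return np.bincount(self.assignment, minlength=self.medoids.size)


@dataclass
class HeartbeatTemplate:
    """The learned representative beat, in all three views, with its QRS
    boundary annotations in template sample coordinates.

    In the R-to-R convention a segment starts at one R peak and ends at the
    next, so the QRS *offset* of the segment's first beat (``qrs_temp_off``,
    near the start) precedes the QRS *onset* of the following beat
    (``qrs_temp_on``, near the end).
    """

    views: np.ndarray            # (3, N)
    qrs_temp_off: int | None = None
    qrs_temp_on: int | None = None

    def __post_init__(self) -> None:
        self.views = np.asarray(self.views, dtype=float)
        if self.views.ndim != 2 or self.views.shape[0] != 3:
            raise ValueError("template must carry exactly 3 views")
        if self.qrs_temp_off is not None and self.qrs_temp_on is not None:
            n = self.views.shape[1]
            if not (0 < self.qrs_temp_off < self.qrs_temp_on < n - 1):
                raise ValueError(
                    "template boundaries must satisfy 0 < off < on < N-1")

    @property
    def length(self) -> int:
        return self.views.shape[1]

    @property
    def annotated(self) -> bool:
        return self.qrs_temp_off is not None and self.qrs_temp_on is not None


def _objective(dist: np.ndarray, medoids: np.ndarray) -> tuple[float, np.ndarray]:
    """Objective and nearest-medoid assignment given a pairwise matrix."""
    sub = dist[:, medoids]
    assign = np.argmin(sub, axis=1)
    xi = float(sub[np.arange(sub.shape[0]), assign].sum())
    return xi, assign


def kmeanspp_seed(beats: BeatSet, K: int = 3, rng: np.random.Generator | None = None) -> np.ndarray:
    """K-means++-style seeding with distance-proportional weights.

    The first seed is uniform over the beats; each subsequent seed is drawn
    with probability proportional to its Euclidean distance to the closest
    already-chosen seed.  A beat identical to a chosen seed therefore has
    selection probability zero.  Returns K distinct beat indices.
    """
    rng = np.random.default_rng(rng)
    n = len(beats)
    if not (1 <= K <= n):
        raise ValueError(f"need 1 <= K={K} <= n_beats={n}")
    X = beats.vectors
    seeds = [int(rng.integers(n))]
    closest = np.linalg.norm(X - X[seeds[0]], axis=1)
    for _ in range(1, K):
        total = closest.sum()
        if total <= 0:
            # all beats coincide with chosen seeds; fall back to unchosen indices
            remaining = np.setdiff1d(np.arange(n), seeds)
            seeds.append(int(rng.choice(remaining)))
        else:
            probs = closest / total
            seeds.append(int(rng.choice(n, p=probs)))
        closest = np.minimum(closest, np.linalg.norm(X - X[seeds[-1]], axis=1))
    return np.asarray(seeds, dtype=np.int64)


def pam_cluster(beats: BeatSet, seeds: np.ndarray,
                dist: np.ndarray | None = None,
                trace: list | None = None) -> Clustering:
    """Partitioning around medoids with best-improvement swaps.

    From the seed configuration, every (medoid, non-medoid) swap is scored
    by the resulting summed dissimilarity; the best strictly improving swap
    is applied, and the loop repeats until no single swap lowers the
    objective.  Deterministic given the seeds (ties broken by lowest swap
    index), so the objective sequence across accepted swaps is strictly
    decreasing.
    """
    n = len(beats)
    medoids = np.array(sorted(set(int(s) for s in seeds)), dtype=np.int64)
    if medoids.size != len(seeds):
        raise ValueError("seed indices must be distinct")
    if np.any(medoids < 0) or np.any(medoids >= n):
        raise ValueError("seed index out of range")
    if dist is None:
        dist = squareform(pdist(beats.vectors))
    xi, assign = _objective(dist, medoids)
    if trace is not None:
        trace.append(xi)
    improved = True
    while improved:
        improved = False
        best_xi, best_swap = xi, None
        others = np.setdiff1d(np.arange(n), medoids)
        if others.size == 0:
            break
        for mi in range(medoids.size):
            keep = np.delete(medoids, mi)
            if keep.size:
                base = dist[:, keep].min(axis=1)
            else:
                base = np.full(n, np.inf)
            # objective after swapping medoid mi for each candidate, vectorized
            cand_xi = np.minimum(base[:, None], dist[:, others]).sum(axis=0)
            k = int(np.argmin(cand_xi))
            if cand_xi[k] < best_xi - 1e-12:
                best_xi, best_swap = float(cand_xi[k]), (mi, int(others[k]))
        if best_swap is not None:
            mi, new = best_swap
            medoids = medoids.copy()
            medoids[mi] = new
            xi = best_xi
            if trace is not None:
                trace.append(xi)
            improved = True
    order = np.argsort(medoids)
    medoids = medoids[order]
    xi, assign = _objective(dist, medoids)
    return Clustering(medoids=medoids, assignment=assign, objective=xi)


def select_medoid_index(clustering: Clustering, beats: BeatSet) -> int:
    """Row index of the medoid of the most-populous cluster.

    Ties on cluster size are broken by the lower within-cluster objective
    contribution, then by the lower medoid index.
    """
    sizes = clustering.cluster_sizes()
    best, best_key = None, None
    for p, m in enumerate(clustering.medoids):
        members = np.flatnonzero(clustering.assignment == p)
        contrib = float(np.linalg.norm(
            beats.vectors[members] - beats.vectors[m], axis=1).sum())
        key = (-sizes[p], contrib, int(m))
        if best_key is None or key < best_key:
            best, best_key = int(m), key
    return best


def select_template(clustering: Clustering, beats: BeatSet,
                    n_views: int = 3) -> HeartbeatTemplate:
    """Medoid of the most-populous cluster, reshaped to its three views."""
    best = select_medoid_index(clustering, beats)
    views = beats.vectors[best].reshape(n_views, -1)
    return HeartbeatTemplate(views=views)


def map_index_through_resampling(index: int, src_len: int, dst_len: int) -> int:
    """Map a sample index through a uniform-grid linear resampling
    (endpoints map to endpoints)."""
    if not (0 <= index < src_len):
        raise ValueError("index outside source segment")
    return int(round(index * (dst_len - 1) / (src_len - 1)))


def annotate_template_boundaries(template: HeartbeatTemplate,
                                 qrs_off_in_segment: int,
                                 qrs_on_in_segment: int,
                                 segment_length: int) -> HeartbeatTemplate:
    """Attach QRS boundaries to the template.

    ``qrs_off_in_segment`` / ``qrs_on_in_segment`` are reference boundary
    indices in the medoid beat's original R-to-R coordinates (offset of the
    segment's first beat, onset of the next beat); they are mapped into
    template coordinates through the resampling ratio.
    """
    n = template.length
    off = map_index_through_resampling(qrs_off_in_segment, segment_length, n)
    on = map_index_through_resampling(qrs_on_in_segment, segment_length, n)
    if not (0 < off < on < n - 1):
        raise ValueError("mapped boundaries violate 0 < off < on < N-1")
    return HeartbeatTemplate(views=template.views, qrs_temp_off=off, qrs_temp_on=on)


def boundaries_from_annotations(segment: tuple[int, int],
                                reference: AnnotationTrack,
                                tol: int) -> tuple[int, int]:
    """Look up the reference QRS offset/onset for one R-to-R segment.

    The segment's start peak is matched to the nearest reference beat (within
    ``tol`` samples) whose ``qrs_off`` gives the in-segment offset; the end
    peak likewise supplies the next beat's ``qrs_on``.  Returned indices are
    relative to the segment start.
    """
    if reference.qrs_on is None or reference.qrs_off is None:
        raise ValueError("reference lacks QRS boundary annotations")
    start, end = segment
    refs = reference.r_peaks
    j0 = int(np.argmin(np.abs(refs - start)))
    j1 = int(np.argmin(np.abs(refs - end)))
    if abs(refs[j0] - start) > tol or abs(refs[j1] - end) > tol:
        raise ValueError("no reference beat matches the segment's peaks")
    off = int(reference.qrs_off[j0]) - start
    on = int(reference.qrs_on[j1]) - start
    return off, on
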