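"""End-to-end orchestration: per-subject training, frozen-model testing,
and the eight-way ablation runner.

Training learns five components from one subject's training session — the
heartbeat-identification SVM, the warping template with its QRS boundary
annotations, the distortion normalization anchor, the quality threshold
tau, and the lead-bias calibration — and bundles them in a
:class:`SubjectModel`.  Testing applies the frozen model with no
re-learning.  The ablation runner crosses {single-view DTW, MV-DTW} x
{with/without SQI purification} x {with/without calibration} on the same
minute pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .signals import ECGRecord, AnnotationTrack, bandpass_filter, minmax_scale, resample_to_length
from . import detect as det
from . import templates as tmpl
from . import mvdtw
from .quality import (normalize_distortions, triangle_threshold,
                     smooth_distortions, compute_sqi)
from . import calibrate as cal
from .simulate import SyntheticSession

logger = logging.getLogger("mobileqrs")

ABLATION_ORDER = [
    ("DTW", False, False),
    ("DTW + SQI", True, False),
    ("DTW + Cal.", False, True),
    ("DTW + SQI + Cal.", True, True),
    ("MV-DTW", False, False),
    ("MV-DTW + SQI", True, False),
    ("MV-DTW + Cal.", False, True),
    ("MV-DTW + SQI + Cal.", True, True),
]


@dataclass
class PipelineConfig:
    """Every tunable of the analysis pipeline, with its default."""

    fs: float = 500.0
    band_low: float = 2.0
    band_high: float = 30.0
    filter_order: int = 6
    refractory_ms: float = 250.0
    threshold_window_s: float = 2.0
    threshold_frac: float = 0.5
    label_tol_ms: float = 75.0
    svm_C: float = 1.0
    beat_length: int = 256
    n_clusters: int = 3
    angle_gap: int = 10
    nbins: int = 50
    smooth_order: int = 10
    max_duration_ms: float = 300.0
    seed: int = 17

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class SubjectModel:
    """All components learned from one subject's training session."""

    svm: det.SVMModel | None
    template: tmpl.HeartbeatTemplate
    reference_max: float
    tau: float
    calibration: cal.CalibrationModel
    config: PipelineConfig
    stage_counts: dict = field(default_factory=dict)


@dataclass
class SegmentedBeats:
    """Aligned per-segment products of stage I: R-to-R segments, their
    three-view resampled beats, and a validity mask (degenerate segments
    stay in place so cross-segment stitching keeps its alignment)."""

    segments: list
    beats: list                      # MultiViewBeat or None per segment
    valid: np.ndarray                # bool per segment


def prepare_beats(filtered: ECGRecord, accepted_peaks: np.ndarray,
                  config: PipelineConfig) -> SegmentedBeats:
    """Segment R-to-R, min-max scale, resample to the common length and
    expand to three views; degenerate or too-short segments hold a ``None``
    placeholder so downstream alignment is preserved."""
    segments = det.segment_heartbeats(filtered, accepted_peaks)
    beats: list = []
    valid = np.zeros(len(segments), dtype=bool)
    min_len = 2 * config.angle_gap + 2
    for j, (a, b) in enumerate(segments):
        seg = filtered.samples[a:b]
        if seg.size < min_len:
            beats.append(None)
            continue
        scaled, degen = minmax_scale(seg)
        if degen:
            beats.append(None)
            continue
        res = resample_to_length(scaled, config.beat_length)
        beats.append(mvdtw.build_views(res, config.angle_gap, beat_index=j))
        valid[j] = True
    return SegmentedBeats(segments=segments, beats=beats, valid=valid)


def detect_and_segment(filtered: ECGRecord, config: PipelineConfig,
                       svm: det.SVMModel | None = None,
                       labels: np.ndarray | None = None) -> tuple[list, np.ndarray, SegmentedBeats]:
    """Candidate detection, SVM screening, and R-to-R beat preparation.

    With a trained ``svm`` the model's predictions screen candidates; with
    ``labels`` (training before the SVM exists) the supervised labels do.
    Returns ``(candidates, accept_flags, SegmentedBeats)``.
    """
    cands = det.detect_spike_candidates(
        filtered, refractory_ms=config.refractory_ms,
        window_s=config.threshold_window_s, frac=config.threshold_frac)
    if len(cands) < 2:
        raise RuntimeError("detect_spike_candidates: fewer than 2 candidates")
    X = det.extract_feature_matrix(filtered, cands)
    if svm is not None:
        preds = det.svm_predict_batch(svm, X)
    elif labels is not None:
        preds = np.asarray(labels)
    else:
        preds = np.ones(len(cands), dtype=int)
    accepted = np.array([c.peak_index for c, p in zip(cands, preds) if p == 1],
                        dtype=np.int64)
    if accepted.size < 2:
        raise RuntimeError("fewer than 2 accepted peaks after screening")
    return cands, preds, prepare_beats(filtered, accepted, config)


def warp_all(seg: SegmentedBeats, template: tmpl.HeartbeatTemplate,
             view_subset: tuple[int, ...] | None = None) -> tuple[list, np.ndarray]:
    """Warp every valid beat against the template.

    Invalid (degenerate/short) segments receive a placeholder result with
    infinite distortion so they are purified away while alignment with the
    segment list is preserved.  Returns ``(warp_results, raw_distortions)``.
    """
    results, raw = [], np.empty(len(seg.segments))
    for j, beat in enumerate(seg.beats):
        if beat is None:
            results.append(mvdtw.WarpResult(qrs_off=0, qrs_on=template.length - 1,
                                            distortion=np.inf, beat_index=j))
            raw[j] = np.inf
        else:
            r = mvdtw.warp_beat(beat, template, view_subset)
            results.append(r)
            raw[j] = r.distortion
    return results, raw


def _minute_estimates(warps: list, seg: SegmentedBeats, sqi: np.ndarray,
                      config: PipelineConfig, minute_spans: list,
                      start_time: float = 0.0) -> np.ndarray:
    durations, peaks = cal.beat_qrs_durations(
        warps, seg.segments, sqi, config.fs, config.beat_length,
        config.max_duration_ms)
    times = start_time + peaks / config.fs
    return cal.minute_average(durations, times, minute_spans)


def reference_minutes(reference: AnnotationTrack, fs: float,
                      minute_spans: list) -> np.ndarray:
    """Chest-lead minute-mean QRS durations from a boundary-annotated track."""
    durs = reference.durations_ms(fs)
    times = reference.r_peaks / fs
    return cal.minute_average(durs, times, minute_spans)


def learn_quality_model(raw_distortions: np.ndarray, config: PipelineConfig
                        ) -> tuple[float, float, np.ndarray]:
    """Normalization anchor, triangle threshold, and training SQIs.

    The triangle search assumes a left-skewed histogram: a dominant
    low-distortion mode plus a long tail of corrupted beats.  When the bulk
    of the normalized distortions sits in the upper half (median > 0.5) the
    training session has no low-distortion mode — max-normalization has only
    stretched quantization-level scatter — so no threshold can separate
    quality classes and purification is disabled (tau = 1).
    """
    finite = raw_distortions[np.isfinite(raw_distortions)]
    if finite.size == 0 or finite.max() <= 0:
        raise RuntimeError("no usable training distortions")
    reference_max = float(finite.max())
    pi = normalize_distortions(np.where(np.isfinite(raw_distortions),
                                            raw_distortions, reference_max),
                                   reference_max)
    if np.median(pi) > 0.5:
        tau = 1.0
    else:
        tau = triangle_threshold(pi, config.nbins).tau
    eta = smooth_distortions(pi, config.smooth_order)
    return reference_max, tau, compute_sqi(pi, eta, tau)


def run_training(mobile: ECGRecord, chest_ref: AnnotationTrack,
                 config: PipelineConfig,
                 minute_spans: list,
                 template_ref: AnnotationTrack | None = None,
                 chest_minutes: np.ndarray | None = None) -> SubjectModel:
    """Learn the full per-subject model from one training session.

    ``chest_ref`` supplies time-aligned reference R peaks for supervised SVM
    labelling (and, when boundary-annotated, the chest minute durations for
    calibration).  ``template_ref`` supplies the QRS boundary annotations
    transferred onto the template medoid; it defaults to ``chest_ref``.
    ``chest_minutes`` overrides the reference minute durations directly.
    """
    counts: dict = {}
    filtered = bandpass_filter(mobile, config.band_low, config.band_high,
                               config.filter_order)
    cands = det.detect_spike_candidates(
        filtered, refractory_ms=config.refractory_ms,
        window_s=config.threshold_window_s, frac=config.threshold_frac)
    counts["candidates"] = len(cands)
    X = det.extract_feature_matrix(filtered, cands)
    try:
        y = det.label_candidates(cands, chest_ref, config.fs, config.label_tol_ms)
    except ValueError as exc:
        raise RuntimeError(f"label_candidates: {exc}") from exc
    if len(np.unique(y)) == 2:
        svm = det.train_svm(X, y, config.svm_C)
        preds = det.svm_predict_batch(svm, X)
    else:
        # every candidate matched a reference beat (e.g. noise-free data):
        # nothing to discriminate, accept all
        svm = None
        preds = y.copy()
    counts["svm_accepted"] = int((preds == 1).sum())
    accepted = np.array([c.peak_index for c, p in zip(cands, preds) if p == 1],
                        dtype=np.int64)
    if accepted.size < 2:
        raise RuntimeError("fewer than 2 accepted peaks after screening")
    seg = prepare_beats(filtered, accepted, config)
    counts["segments"] = len(seg.segments)
    counts["valid_beats"] = int(seg.valid.sum())
    logger.info("training: %s", counts)

    # --- template learning on the valid beats
    valid_idx = np.flatnonzero(seg.valid)
    if valid_idx.size < config.n_clusters:
        raise RuntimeError("pam_cluster: fewer valid beats than clusters")
    vectors = np.stack([seg.beats[j].views.ravel() for j in valid_idx])
    beatset = tmpl.BeatSet(vectors=vectors, length=config.beat_length)
    rng = np.random.default_rng(config.seed)
    seeds = tmpl.kmeanspp_seed(beatset, config.n_clusters, rng)
    clustering = tmpl.pam_cluster(beatset, seeds)
    medoid_row = tmpl.select_medoid_index(clustering, beatset)
    medoid_seg_idx = int(valid_idx[medoid_row])
    template = tmpl.HeartbeatTemplate(
        views=beatset.vectors[medoid_row].reshape(3, -1))
    ref_for_template = template_ref if template_ref is not None else chest_ref
    tol = int(round(config.label_tol_ms / 1000.0 * config.fs))
    try:
        off, on = tmpl.boundaries_from_annotations(
            seg.segments[medoid_seg_idx], ref_for_template, tol)
    except ValueError as exc:
        raise RuntimeError(f"annotate_template_boundaries: {exc}") from exc
    a, b = seg.segments[medoid_seg_idx]
    template = tmpl.annotate_template_boundaries(template, off, on, b - a)

    # --- distortion quality model
    warps, raw = warp_all(seg, template)
    reference_max, tau, sqi = learn_quality_model(raw, config)
    counts["sqi_retained"] = int((sqi == 1).sum())

    # --- calibration
    mobile_minutes = _minute_estimates(warps, seg, sqi, config, minute_spans,
                                       mobile.start_time)
    if chest_minutes is None:
        if chest_ref.qrs_on is None:
            raise RuntimeError("fit_bias: no chest minute durations available")
        chest_minutes = reference_minutes(chest_ref, config.fs, minute_spans)
    calibration = cal.fit_bias(mobile_minutes, chest_minutes)
    counts["duration_valid_minutes"] = int(np.isfinite(mobile_minutes).sum())
    logger.info("training complete: %s, bias=%.2f ms, tau=%.3f",
                counts, calibration.bias_ms, tau)
    return SubjectModel(svm=svm, template=template, reference_max=reference_max,
                        tau=tau, calibration=calibration, config=config,
                        stage_counts=counts)


@dataclass
class TestingResult:
    beat_durations_ms: np.ndarray
    beat_times_s: np.ndarray
    minute_estimates: np.ndarray     # calibrated
    minute_estimates_raw: np.ndarray
    sqi: np.ndarray
    metrics: cal.MetricsReport | None


def run_testing(mobile: ECGRecord, model: SubjectModel, minute_spans: list,
                chest_minutes: np.ndarray | None = None) -> TestingResult:
    """Apply a frozen subject model to a testing session."""
    config = model.config
    if abs(mobile.fs - config.fs) > 1e-9:
        raise RuntimeError(f"record fs {mobile.fs} != model fs {config.fs}")
    filtered = bandpass_filter(mobile, config.band_low, config.band_high,
                               config.filter_order)
    _, _, seg = detect_and_segment(filtered, config, svm=model.svm)
    warps, raw = warp_all(seg, model.template)
    pi = normalize_distortions(np.where(np.isfinite(raw), raw,
                                            model.reference_max),
                                   model.reference_max)
    eta = smooth_distortions(pi, config.smooth_order)
    sqi = compute_sqi(pi, eta, model.tau)
    durations, peaks = cal.beat_qrs_durations(
        warps, seg.segments, sqi, config.fs, config.beat_length,
        config.max_duration_ms)
    times = mobile.start_time + peaks / config.fs
    raw_minutes = cal.minute_average(durations, times, minute_spans)
    minutes = cal.apply_calibration(raw_minutes, model.calibration)
    metrics = None
    if chest_minutes is not None:
        if np.isfinite(minutes).sum() < 2:
            logger.warning("metrics refused: fewer than 2 valid minute estimates")
        else:
            metrics = cal.evaluate(minutes, chest_minutes)
    return TestingResult(beat_durations_ms=durations, beat_times_s=times,
                         minute_estimates=minutes, minute_estimates_raw=raw_minutes,
                         sqi=sqi, metrics=metrics)


def run_ablation(session: SyntheticSession, config: PipelineConfig) -> pd.DataFrame:
    """The eight-configuration comparison on one synthetic subject.

    Rows cross {single-view DTW, MV-DTW} x {-,+SQI} x {-,+Cal}: single-view
    DTW restricts the local distance to the amplitude view; without SQI all
    beats are retained; without calibration the raw mobile minute estimates
    are scored.  The distortion scale, threshold, and bias are re-learned on
    the training session separately for every (view, SQI) combination so
    each row is a self-consistent pipeline.
    """
    cfg = config
    spans = session.config.evaluation_minutes()
    model = run_training(
        session.train_mobile, session.train_chest_truth.annotation_track(),
        cfg, spans, template_ref=session.train_mobile_truth.annotation_track())

    train_filtered = bandpass_filter(session.train_mobile, cfg.band_low,
                                     cfg.band_high, cfg.filter_order)
    test_filtered = bandpass_filter(session.test_mobile, cfg.band_low,
                                    cfg.band_high, cfg.filter_order)
    _, _, train_seg = detect_and_segment(train_filtered, cfg, svm=model.svm)
    _, _, test_seg = detect_and_segment(test_filtered, cfg, svm=model.svm)
    chest_train = cal.minute_average(
        session.train_chest_truth.durations_ms(cfg.fs),
        session.train_chest_truth.r_peaks / cfg.fs, spans)
    chest_test = cal.minute_average(
        session.test_chest_truth.durations_ms(cfg.fs),
        session.test_chest_truth.r_peaks / cfg.fs, spans)

    rows = []
    for view_label, subset in (("DTW", (0,)), ("MV-DTW", None)):
        train_warps, train_raw = warp_all(train_seg, model.template, subset)
        test_warps, test_raw = warp_all(test_seg, model.template, subset)
        ref_max, tau, train_sqi = learn_quality_model(train_raw, cfg)
        pi = normalize_distortions(
            np.where(np.isfinite(test_raw), test_raw, ref_max), ref_max)
        eta = smooth_distortions(pi, cfg.smooth_order)
        test_sqi = compute_sqi(pi, eta, tau)
        for use_sqi in (False, True):
            sq_tr = train_sqi if use_sqi else np.ones(len(train_seg.segments), dtype=np.int8)
            sq_te = test_sqi if use_sqi else np.ones(len(test_seg.segments), dtype=np.int8)
            train_min = _minute_estimates(train_warps, train_seg, sq_tr, cfg, spans)
            test_min = _minute_estimates(test_warps, test_seg, sq_te, cfg, spans)
            bias = cal.fit_bias(train_min, chest_train)
            for use_cal in (False, True):
                pred = cal.apply_calibration(test_min, bias) if use_cal else test_min
                m = cal.evaluate(pred, chest_test)
                label = view_label + (" + SQI" if use_sqi else "") + (" + Cal." if use_cal else "")
                rows.append({"approach": label, "view": view_label,
                             "sqi": use_sqi, "cal": use_cal,
                             "cr": m.cr, "me": m.me, "std": m.std,
                             "mae": m.mae, "rmse": m.rmse, "n": m.n})
    order = [label for label, _, _ in ABLATION_ORDER]
    df = pd.DataFrame(rows).set_index("approach").loc[order].reset_index()
    return df
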