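import numpy as np
import pytest
from scipy import optimize

from mobileqrs.signals import ECGRecord, AnnotationTrack, bandpass_filter
from mobileqrs.detect import (
    BeatCandidate, detect_spike_candidates, extract_features,
    extract_feature_matrix, label_candidates, train_svm, svm_predict,
    svm_predict_batch, segment_heartbeats, N_FEATURES, SVMModel,
)
from mobileqrs.pipeline import detect_and_segment, PipelineConfig

FS = 500.0


def spike_train(peak_times_s, amps=None, dur_s=12.0, width_s=0.015, fs=FS):
    n = int(dur_s * fs)
    x = np.zeros(n)
    t = np.arange(n) / fs
    amps = amps or [1.0] * len(peak_times_s)
    for tc, a in zip(peak_times_s, amps):
        x += a * np.exp(-0.5 * ((t - tc) / width_s) ** 2)
    return ECGRecord(x, fs=fs)


class TestCandidateDetection:
    def test_isolated_spikes_all_found(self):
        times = [1.0 + k for k in range(10)]
        rec = spike_train(times)
        cands = detect_spike_candidates(rec)
        assert len(cands) == 10
        found = np.array([c.peak_index for c in cands]) / FS
        np.testing.assert_allclose(found, times, atol=2 / FS)

    def test_refractory_keeps_larger(self):
        rec = spike_train([5.0, 5.1], amps=[0.6, 1.0])
        cands = detect_spike_candidates(rec, refractory_ms=250)
        near = [c for c in cands if abs(c.peak_index / FS - 5.05) < 0.2]
        assert len(near) == 1
        assert abs(near[0].peak_index / FS - 5.1) < 0.01

    def test_candidates_cover_true_peaks(self, clean_session):
        rec = bandpass_filter(clean_session.train_mobile)
        truth = clean_session.train_mobile_truth
        cands = detect_spike_candidates(rec)
        found = np.array([c.peak_index for c in cands])
        tol = 0.020 * FS
        matched = [np.min(np.abs(found - r)) <= tol for r in truth.r_peaks]
        assert np.mean(matched) == 1.0

    def test_short_record_errors(self):
        with pytest.raises(ValueError):
            detect_spike_candidates(ECGRecord(np.zeros(100), fs=FS))


class TestFeatures:
    def test_triangular_spike(self):
        x = np.zeros(2000)
        apex = 1000
        w = 6  # narrow spike relative to the +-60 ms feature window
        x[apex - w:apex + w + 1] = 1.0 - np.abs(np.arange(-w, w + 1)) / w
        rec = ECGRecord(x, fs=FS)
        c = BeatCandidate(apex, (apex - 500, apex + 500))
        f = extract_features(rec, c)
        assert f[0] == pytest.approx(1.0)
        assert f[9] > 0  # spiky window -> positive excess kurtosis
        assert f.shape == (N_FEATURES,)

    def test_identical_context_identical_features(self):
        rec = spike_train([3.0, 8.0])
        cands = detect_spike_candidates(rec)
        f1 = extract_features(rec, cands[0])
        f2 = extract_features(rec, cands[1])
        np.testing.assert_allclose(f1, f2, atol=1e-12)

    def test_half_max_width_of_rectangle(self):
        # a rectangular pulse of width w ms has half-max width w
        for w_ms in (20, 40, 60):
            x = np.zeros(3000)
            apex = 1500
            half = int(w_ms / 1000 * FS / 2)
            x[apex - half:apex + half] = 1.0
            rec = ECGRecord(x, fs=FS)
            f = extract_features(rec, BeatCandidate(apex, (apex - 500, apex + 500)))
            assert f[3] == pytest.approx(w_ms, abs=2 * 1000 / FS)

    def test_edge_window_flagged_truncated(self):
        rec = spike_train([0.2])
        c = BeatCandidate(int(0.2 * FS), (0, int(0.2 * FS) + 500))
        extract_features(rec, c)
        assert c.truncated


class TestLabelling:
    def test_exact_and_one_to_one(self):
        cands = [BeatCandidate(100, (0, 200)), BeatCandidate(110, (10, 210)),
                 BeatCandidate(500, (400, 600))]
        ref = AnnotationTrack(r_peaks=[100])
        y = label_candidates(cands, ref, FS)
        np.testing.assert_array_equal(y, [1, -1, -1])

    def test_empty_reference_errors(self):
        with pytest.raises(ValueError):
            label_candidates([BeatCandidate(10, (0, 20))],
                             AnnotationTrack(r_peaks=[]), FS)

    def test_generator_truth_table(self, small_session):
        """With injected false spikes, labels agree with the generator's
        registry: candidates at true R peaks are +1, candidates at false
        spikes are -1."""
        rec = bandpass_filter(small_session.train_mobile)
        truth = small_session.train_mobile_truth
        cands = detect_spike_candidates(rec)
        y = label_candidates(cands, AnnotationTrack(r_peaks=truth.r_peaks), FS)
        idx = np.array([c.peak_index for c in cands])
        tol = 0.030 * FS
        for k, spike in enumerate(truth.false_spike_indices):
            near = np.abs(idx - spike) <= tol
            assert not np.any(y[near] == 1)
        # labelled positives sit close to true R peaks
        pos = idx[y == 1]
        dists = np.min(np.abs(pos[:, None] - truth.r_peaks[None, :]), axis=1)
        assert np.all(dists <= 0.075 * FS)


def brute_force_dual_svm(X, y, C=1.0):
    """Tiny-instance linear soft-margin SVM via direct QP on the dual."""
    K = X @ X.T
    n = len(y)

    def neg_dual(a):
        return -(a.sum() - 0.5 * (a * y) @ K @ (a * y))

    cons = [{"type": "eq", "fun": lambda a: a @ y}]
    res = optimize.minimize(neg_dual, np.full(n, 0.1), bounds=[(0, C)] * n,
                            constraints=cons, method="SLSQP",
                            options={"maxiter": 1000, "ftol": 1e-12})
    a = res.x
    w = (a * y) @ X
    sv = (a > 1e-6) & (a < C - 1e-6)
    b = np.mean(y[sv] - X[sv] @ w) if np.any(sv) else 0.0
    return w, b


class TestSVM:
    def test_separable_pair(self):
        X = np.zeros((2, N_FEATURES))
        X[0, 3], X[1, 3] = 1.0, -1.0
        y = np.array([1, -1])
        model = train_svm(X, y)
        assert svm_predict(model, X[0]) == 1
        assert svm_predict(model, X[1]) == -1

    def test_matches_dual_qp_oracle(self):
        rng = np.random.default_rng(3)
        X2 = np.array([[1.0, 1.0], [2.0, 0.5], [1.5, 1.5],
                       [-1.0, -1.0], [-2.0, -0.2], [-1.2, -1.8]])
        y = np.array([1, 1, 1, -1, -1, -1])
        X = np.zeros((6, N_FEATURES))
        X[:, :2] = X2
        model = train_svm(X, y, C=1.0)
        # oracle works in the standardized space the model trains in
        Z = (X - model.center) / model.scale
        w, b = brute_force_dual_svm(Z, y.astype(float), C=1.0)
        dec_model = Z @ model.support_vectors.T @ model.dual_coef + model.bias
        dec_oracle = Z @ w + b
        # SLSQP solves the dual to ~1e-4; both solvers must agree to that level
        np.testing.assert_allclose(dec_model, dec_oracle, atol=1e-3)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, N_FEATURES))
        y = np.where(X[:, 0] + 0.3 * rng.normal(size=40) > 0, 1, -1)
        if len(np.unique(y)) < 2:
            y[0] = -y[0]
        m1 = train_svm(X, y)
        perm = rng.permutation(40)
        m2 = train_svm(X[perm], y[perm])
        Xt = rng.normal(size=(20, N_FEATURES))
        np.testing.assert_array_equal(svm_predict_batch(m1, Xt),
                                      svm_predict_batch(m2, Xt))

    def test_single_class_errors(self):
        X = np.zeros((3, N_FEATURES))
        with pytest.raises(ValueError):
            train_svm(X, np.array([1, 1, 1]))

    def test_predict_direct_sum_oracle(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, N_FEATURES))
        y = np.where(X[:, 1] > 0, 1, -1)
        model = train_svm(X, y)
        for x in rng.normal(size=(10, N_FEATURES)):
            z = (x - model.center) / model.scale
            manual = sum(model.dual_coef[i] * float(model.support_vectors[i] @ z)
                         for i in range(model.n_support)) + model.bias
            assert svm_predict(model, x) == (1 if manual >= 0 else -1)
            assert model.decision_value(x) == pytest.approx(manual, abs=1e-10)

    def test_sign_zero_is_positive(self):
        model = SVMModel(support_vectors=np.zeros((1, N_FEATURES)),
                         dual_coef=np.array([1.0]), bias=0.0,
                         center=np.zeros(N_FEATURES), scale=np.ones(N_FEATURES))
        assert svm_predict(model, np.zeros(N_FEATURES)) == 1

    def test_wrong_dimension_errors(self):
        model = SVMModel(support_vectors=np.zeros((1, N_FEATURES)),
                         dual_coef=np.array([1.0]), bias=0.0,
                         center=np.zeros(N_FEATURES), scale=np.ones(N_FEATURES))
        with pytest.raises(ValueError):
            svm_predict(model, np.zeros(3))


class TestSegmentation:
    def test_direct_construction(self):
        rec = ECGRecord(np.zeros(2000), fs=FS)
        segs = segment_heartbeats(rec, np.array([100, 600, 1100]))
        assert segs == [(100, 600), (600, 1100)]

    def test_single_peak_errors(self):
        rec = ECGRecord(np.zeros(2000), fs=FS)
        with pytest.raises(ValueError):
            segment_heartbeats(rec, np.array([100]))

    def test_tiling_property(self):
        rng = np.random.default_rng(6)
        peaks = np.unique(rng.integers(0, 5000, size=20))
        rec = ECGRecord(np.zeros(5000), fs=FS)
        segs = segment_heartbeats(rec, peaks)
        assert len(segs) == peaks.size - 1
        for (a1, b1), (a2, b2) in zip(segs[:-1], segs[1:]):
            assert b1 == a2
        assert segs[0][0] == peaks[0] and segs[-1][1] == peaks[-1]


class TestDetectionQuality:
    def test_sensitivity_and_ppv_after_svm(self, artifact_free_session):
        """After SVM screening on artifact-free default-noise data,
        essentially every true beat is accepted and essentially every
        accepted candidate is a true beat (raw candidates also include T
        waves, which the classifier must reject)."""
        s = artifact_free_session
        rec = bandpass_filter(s.train_mobile)
        truth = s.train_mobile_truth
        cands = detect_spike_candidates(rec)
        X = extract_feature_matrix(rec, cands)
        y = label_candidates(cands, AnnotationTrack(r_peaks=truth.r_peaks), FS)
        model = train_svm(X, y)
        preds = svm_predict_batch(model, X)
        accepted = np.array([c.peak_index for c, p in zip(cands, preds) if p == 1])
        tol = 0.030 * FS
        sens = np.mean(np.min(np.abs(truth.r_peaks[:, None] - accepted[None, :]),
                              axis=1) <= tol)
        ppv = np.mean(np.min(np.abs(accepted[:, None] - truth.r_peaks[None, :]),
                             axis=1) <= tol)
        assert sens >= 0.99 and ppv >= 0.99
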