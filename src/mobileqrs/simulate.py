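"""Synthetic paired chest/mobile ECG sessions with exact per-beat truth.

Each heartbeat is a sum of five Gaussian wavelets at the P/Q/R/S/T
characteristic points.  The Q and S wavelet centers and widths scale with
the beat's drawn QRS duration, and the ground-truth QRS onset/offset are
defined analytically at two standard deviations outside the Q and S
centers — so the generator knows every boundary exactly, which a recorded
dataset cannot provide.

The mobile channel re-synthesizes the same beat train with QRS durations
widened by a per-subject lead bias, scales the waveform to a few percent of
the chest amplitude, and corrupts it with baseline wander, broadband noise,
twenty-second motion-artifact bursts in the second minute of every trial,
and occasional false spikes — emulating an ear-lead recording during
exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .signals import ECGRecord, AnnotationTrack


@dataclass
class SyntheticConfig:
    """Generator settings; defaults give one 30-minute session of fifteen
    2-minute trials at 500 Hz with moderate noise and an 8 ms lead bias."""

    fs: float = 500.0
    n_trials: int = 15
    trial_minutes: int = 2
    hr_base: float = 70.0            # bpm; per-subject resting rate
    hr_drift_bpm: float = 3.0        # slow sinusoidal drift amplitude
    hr_drift_period_s: float = 300.0
    rr_jitter_ms: float = 20.0       # beat-to-beat RR jitter SD
    qrs_duration_ms: float = 100.0   # mean true chest QRS duration
    qrs_duration_sd_ms: float = 4.0  # beat-to-beat scatter
    qrs_drift_ms: float = 4.0        # slow exercise-induced modulation amplitude
    qrs_drift_period_s: float = 600.0
    mobile_scale: float = 0.03       # ear-lead amplitude relative to chest
    lead_bias_ms: float = 8.0        # mobile-minus-chest QRS duration offset
    chest_noise_sd: float = 0.005    # broadband, chest units (R wave = 1.0)
    mobile_noise_sd: float = 0.004   # broadband, added after amplitude scaling
    baseline_wander_amp: float = 0.01
    baseline_wander_hz: float = 0.33
    artifact_burst_s: float = 20.0   # burst length within each trial's 2nd minute
    artifact_offset_s: float = 20.0  # burst start within the 2nd minute
    artifact_gain: float = 8.0       # burst noise SD multiplier
    false_spike_rate: float = 4.0    # per minute
    seed: int = 0

    @property
    def trial_s(self) -> float:
        return self.trial_minutes * 60.0

    @property
    def duration_s(self) -> float:
        return self.n_trials * self.trial_s

    def evaluation_minutes(self) -> list[tuple[float, float]]:
        """The second minute of each trial (the minute holding the artifact
        burst, matching the evaluation protocol)."""
        return [(t * self.trial_s + 60.0, t * self.trial_s + 120.0)
                for t in range(self.n_trials)]

    def artifact_intervals(self) -> list[tuple[float, float]]:
        out = []
        for t in range(self.n_trials):
            start = t * self.trial_s + 60.0 + self.artifact_offset_s
            out.append((start, start + self.artifact_burst_s))
        return out

    def validate(self) -> None:
        if self.fs <= 0 or self.n_trials < 1 or self.trial_minutes < 1:
            raise ValueError("invalid session layout")
        if not (0.0 < self.mobile_scale < 1.0):
            raise ValueError("mobile_scale must lie in (0, 1)")
        if self.qrs_duration_ms <= 0 or self.qrs_duration_sd_ms < 0:
            raise ValueError("QRS duration parameters must be positive")
        max_qrs = self.qrs_duration_ms + 5 * self.qrs_duration_sd_ms + abs(self.lead_bias_ms)
        min_rr_ms = 60000.0 / (self.hr_base + self.hr_drift_bpm) - 5 * self.rr_jitter_ms
        if max_qrs >= min_rr_ms:
            raise ValueError("QRS duration inconsistent with RR interval")


@dataclass
class GroundTruth:
    """Exact per-beat truth for one channel of one session."""

    r_peaks: np.ndarray              # sample indices
    qrs_on: np.ndarray
    qrs_off: np.ndarray
    beat_is_clean: np.ndarray        # bool, False inside artifact bursts
    artifact_intervals: list
    false_spike_indices: np.ndarray
    true_minute_durations: np.ndarray  # per-minute mean QRS duration, ms

    def annotation_track(self) -> AnnotationTrack:
        return AnnotationTrack(r_peaks=self.r_peaks, qrs_on=self.qrs_on,
                               qrs_off=self.qrs_off)

    def durations_ms(self, fs: float) -> np.ndarray:
        return (self.qrs_off - self.qrs_on) * 1000.0 / fs


@dataclass
class SyntheticSession:
    """A paired training + testing subject: four records and their truths."""

    config: SyntheticConfig
    train_chest: ECGRecord
    train_chest_truth: GroundTruth
    train_mobile: ECGRecord
    train_mobile_truth: GroundTruth
    test_chest: ECGRecord
    test_chest_truth: GroundTruth
    test_mobile: ECGRecord
    test_mobile_truth: GroundTruth


# (center offset, width sigma, amplitude); offsets/widths of Q, R, S scale
# with the beat's QRS duration d, P and T ride at fixed latencies
_P_WAVE = (-0.180, 0.022, 0.10)
_T_WAVE = (0.270, 0.045, 0.28)
_Q_CENTER, _Q_SIGMA, _Q_AMP = -0.25, 0.10, -0.12
_R_SIGMA, _R_AMP = 0.11, 1.00
_S_CENTER, _S_SIGMA, _S_AMP = 0.30, 0.125, -0.18
# onset = Q center - 2 sigma_Q = -0.45 d; offset = S center + 2 sigma_S = +0.55 d


def _beat_schedule(cfg: SyntheticConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """R-peak times (s) and per-beat chest QRS durations (s)."""
    times, t = [], 0.5
    while t < cfg.duration_s - 0.6:
        times.append(t)
        hr = cfg.hr_base + cfg.hr_drift_bpm * np.sin(2 * np.pi * t / cfg.hr_drift_period_s)
        rr = 60.0 / hr + rng.normal(0.0, cfg.rr_jitter_ms / 1000.0)
        t += max(rr, 0.3)
    times = np.asarray(times)
    # slow drift emulates exercise-induced duration modulation across the
    # session; it gives the minute means real between-minute variance
    phase = rng.uniform(0, 2 * np.pi)
    drift = cfg.qrs_drift_ms / 1000.0 * np.sin(
        2 * np.pi * times / cfg.qrs_drift_period_s + phase)
    durs = (cfg.qrs_duration_ms / 1000.0 + drift
            + rng.normal(0.0, cfg.qrs_duration_sd_ms / 1000.0, size=times.size))
    durs = np.clip(durs, 0.04, 0.25)
    return times, durs


def _synthesize(times: np.ndarray, durs: np.ndarray, n: int, fs: float) -> np.ndarray:
    """Render the Gaussian-wavelet beat train onto an n-sample grid."""
    x = np.zeros(n)
    half = 0.5  # wavelet support rendered within +-0.5 s of the R peak
    for t_k, d in zip(times, durs):
        lo = max(int((t_k - half) * fs), 0)
        hi = min(int((t_k + half) * fs) + 1, n)
        tt = np.arange(lo, hi) / fs - t_k
        wavelets = (
            _P_WAVE,
            (_Q_CENTER * d, _Q_SIGMA * d, _Q_AMP),
            (0.0, _R_SIGMA * d, _R_AMP),
            (_S_CENTER * d, _S_SIGMA * d, _S_AMP),
            _T_WAVE,
        )
        for c, s, a in wavelets:
            x[lo:hi] += a * np.exp(-0.5 * ((tt - c) / s) ** 2)
    return x


def _truth_arrays(times: np.ndarray, durs: np.ndarray, cfg: SyntheticConfig,
                  n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    fs = cfg.fs
    r = np.round(times * fs).astype(np.int64)
    on = np.round((times - 0.45 * durs) * fs).astype(np.int64)
    off = np.round((times + 0.55 * durs) * fs).astype(np.int64)
    keep = (on > 0) & (off < n) & (on < r) & (r < off)
    return r[keep], on[keep], off[keep]


def _minute_truth(r: np.ndarray, on: np.ndarray, off: np.ndarray,
                  cfg: SyntheticConfig) -> np.ndarray:
    n_min = int(cfg.duration_s // 60)
    durations = (off - on) * 1000.0 / cfg.fs
    t_beat = r / cfg.fs
    out = np.full(n_min, np.nan)
    for m in range(n_min):
        mask = (t_beat >= 60.0 * m) & (t_beat < 60.0 * (m + 1))
        if np.any(mask):
            out[m] = durations[mask].mean()
    return out


def _clean_flags(r: np.ndarray, intervals: list, fs: float) -> np.ndarray:
    t = r / fs
    clean = np.ones(t.size, dtype=bool)
    for a, b in intervals:
        clean &= ~((t >= a) & (t < b))
    return clean


def generate_chest_ecg(cfg: SyntheticConfig, rng: np.random.Generator,
                       session: str = "training",
                       schedule: tuple[np.ndarray, np.ndarray] | None = None
                       ) -> tuple[ECGRecord, GroundTruth]:
    """The reference chest lead: clean beat train plus mild broadband noise."""
    cfg.validate()
    n = int(round(cfg.duration_s * cfg.fs))
    if schedule is None:
        schedule = _beat_schedule(cfg, rng)
    times, durs = schedule
    x = _synthesize(times, durs, n, cfg.fs)
    if cfg.chest_noise_sd > 0:
        x = x + rng.normal(0.0, cfg.chest_noise_sd, size=n)
    r, on, off = _truth_arrays(times, durs, cfg, n)
    truth = GroundTruth(
        r_peaks=r, qrs_on=on, qrs_off=off,
        beat_is_clean=np.ones(r.size, dtype=bool),
        artifact_intervals=[],
        false_spike_indices=np.empty(0, dtype=np.int64),
        true_minute_durations=_minute_truth(r, on, off, cfg),
    )
    rec = ECGRecord(x, fs=cfg.fs, role="chest", session=session)
    return rec, truth


def derive_mobile_ecg(cfg: SyntheticConfig, rng: np.random.Generator,
                      schedule: tuple[np.ndarray, np.ndarray],
                      session: str = "training") -> tuple[ECGRecord, GroundTruth]:
    """The ear-lead channel sharing the chest beat schedule.

    QRS durations widen by ``lead_bias_ms``; the waveform is scaled to
    ``mobile_scale`` of the chest amplitude and corrupted with baseline
    wander, broadband noise, per-trial artifact bursts and false spikes.
    """
    cfg.validate()
    n = int(round(cfg.duration_s * cfg.fs))
    times, chest_durs = schedule
    durs = np.clip(chest_durs + cfg.lead_bias_ms / 1000.0, 0.04, 0.28)
    x = _synthesize(times, durs, n, cfg.fs) * cfg.mobile_scale

    t = np.arange(n) / cfg.fs
    if cfg.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        x = x + cfg.baseline_wander_amp * np.sin(2 * np.pi * cfg.baseline_wander_hz * t + phase)
    if cfg.mobile_noise_sd > 0:
        x = x + rng.normal(0.0, cfg.mobile_noise_sd, size=n)

    intervals = cfg.artifact_intervals() if (cfg.artifact_burst_s > 0 and cfg.artifact_gain > 0) else []
    for a, b in intervals:
        i0, i1 = int(a * cfg.fs), min(int(b * cfg.fs), n)
        if cfg.mobile_noise_sd > 0:
            burst_sd = cfg.mobile_noise_sd * cfg.artifact_gain
            x[i0:i1] += rng.normal(0.0, burst_sd, size=i1 - i0)
        # low-frequency shake comparable to the signal itself
        f_shake = rng.uniform(1.0, 3.0)
        amp = cfg.mobile_scale * cfg.artifact_gain / 4.0
        x[i0:i1] += amp * np.sin(2 * np.pi * f_shake * t[i0:i1] + rng.uniform(0, 2 * np.pi))

    # false spikes: narrow transients away from true R peaks
    spikes = []
    n_spikes = rng.poisson(cfg.false_spike_rate * cfg.duration_s / 60.0)
    r_times = times
    for _ in range(n_spikes):
        for _attempt in range(20):
            ts = rng.uniform(1.0, cfg.duration_s - 1.0)
            if np.min(np.abs(r_times - ts)) > 0.200:
                break
        else:
            continue
        amp = cfg.mobile_scale * rng.uniform(0.9, 1.6)
        sigma = rng.uniform(0.008, 0.020)
        lo = max(int((ts - 5 * sigma) * cfg.fs), 0)
        hi = min(int((ts + 5 * sigma) * cfg.fs) + 1, n)
        tt = np.arange(lo, hi) / cfg.fs - ts
        x[lo:hi] += amp * np.exp(-0.5 * (tt / sigma) ** 2)
        spikes.append(int(round(ts * cfg.fs)))

    r, on, off = _truth_arrays(times, durs, cfg, n)
    truth = GroundTruth(
        r_peaks=r, qrs_on=on, qrs_off=off,
        beat_is_clean=_clean_flags(r, intervals, cfg.fs),
        artifact_intervals=intervals,
        false_spike_indices=np.asarray(sorted(spikes), dtype=np.int64),
        true_minute_durations=_minute_truth(r, on, off, cfg),
    )
    rec = ECGRecord(x, fs=cfg.fs, role="mobile", session=session)
    return rec, truth


def generate_session(cfg: SyntheticConfig) -> SyntheticSession:
    """A full synthetic subject: independent training and testing sessions
    sharing the subject-level parameters (heart rate, amplitude scale, lead
    bias) but with fresh beat schedules and noise.  Bit-reproducible from
    ``cfg.seed``."""
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]
    out = {}
    for session, (rng_sched, rng_noise) in zip(
            ("training", "testing"), ((rngs[0], rngs[1]), (rngs[2], rngs[3]))):
        schedule = _beat_schedule(cfg, rng_sched)
        chest, chest_truth = generate_chest_ecg(cfg, rng_noise, session, schedule)
        mobile, mobile_truth = derive_mobile_ecg(cfg, rng_noise, schedule, session)
        out[session] = (chest, chest_truth, mobile, mobile_truth)
    return SyntheticSession(
        config=cfg,
        train_chest=out["training"][0], train_chest_truth=out["training"][1],
        train_mobile=out["training"][2], train_mobile_truth=out["training"][3],
        test_chest=out["testing"][0], test_chest_truth=out["testing"][1],
        test_mobile=out["testing"][2], test_mobile_truth=out["testing"][3],
    )
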