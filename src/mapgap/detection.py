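"""MAP detection: filtering, beat segmentation, per-beat assessment, and the
four-consecutive-waveform rule.

A monophasic action potential (MAP) is recognised on a beat when the
band-passed MAP channel shows a deflection whose amplitude exceeds 2 mV
(strictly) and whose duration reaches 100 ms (inclusively). Per-beat
repolarization metrics follow the standard conventions:

AT      activation time — earliest recorded ventricular activation (QRS
        onset on the reference ECG) to local activation (maximum upstroke
        velocity of the MAP);
EOR     earliest ventricular activation to local end of repolarization (the
        first decay past 90% recovery toward baseline, APD90-style);
MAPDUR  local activation to local EOR, i.e. MAPDUR = EOR - AT.

A site counts as MAP-positive only after 4 consecutive beats with similar
waveform characteristics; the contact force credited to the detection is the
force at the LAST beat of that first qualifying run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Optional

import numpy as np
from scipy import signal

from .config import DetectorConfig
from .errors import NoBeatsError, WindowTooShortError
from .trace import Trace

#: minimum credible R-peak amplitude (mV) before an ECG counts as having beats
_ECG_FLOOR_MV = 0.3


# ------------------------------------------------------------------ filtering

#: corner-correction factor for a 2nd-order Butterworth applied forward and
#: backward: corners are pre-warped so the stated band is the -3 dB band of
#: the combined zero-phase response
_DOUBLE_PASS_CORRECTION = (2.0**0.5 - 1.0) ** 0.25


def corrected_band(config: DetectorConfig, sample_rate: float) -> tuple[float, float]:
    """Design corners of the zero-phase band-pass for a given sample rate."""
    nyq = sample_rate / 2.0
    lo = config.band_low * _DOUBLE_PASS_CORRECTION
    hi = min(config.band_high / _DOUBLE_PASS_CORRECTION, 0.995 * nyq)
    return lo, hi


def bandpass_filter(trace: Trace, config: Optional[DetectorConfig] = None) -> Trace:
    """Zero-phase Butterworth band-pass of the MAP and ECG channels.

    A second-order band-pass is applied forward and backward so fiducial
    timing is preserved; the design corners are widened by the standard
    double-pass correction so that ``band_low``–``band_high`` is the -3 dB
    band of the overall response. The channel mean is removed first and the
    forward-backward initial conditions use Gustafsson's method, which stays
    numerically exact for the very low high-pass corner (0.1 Hz) that the
    default pad-based initialisation mishandles. Force/sensor channels are
    untouched.
    """
    cfg = config or DetectorConfig()
    nyq = trace.sample_rate / 2.0
    if cfg.band_high >= nyq:
        raise ValueError(f"band_high {cfg.band_high} Hz >= Nyquist {nyq} Hz")
    lo, hi = corrected_band(cfg, trace.sample_rate)
    b, a = signal.butter(2, [lo, hi], btype="bandpass", fs=trace.sample_rate)
    # the impulse response is dominated by the high-pass pole; 16 time
    # constants bound the truncation error well below the noise floor
    irlen = int(16 * trace.sample_rate / (2 * np.pi * lo))

    def _apply(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        n = len(x)
        return signal.filtfilt(
            b, a, x - x.mean(), method="gust",
            irlen=irlen if irlen < n - 1 else None,
        )

    return replace(trace, map_mv=_apply(trace.map_mv), ecg_mv=_apply(trace.ecg_mv))


# ------------------------------------------------------------- QRS references

def detect_qrs(trace: Trace) -> np.ndarray:
    """R-peak times (s) on the reference ECG.

    Raises :class:`NoBeatsError` on a flat ECG or when fewer than two beats
    are found (a single beat cannot establish a rhythm).
    """
    x = np.asarray(trace.ecg_mv, dtype=float)
    amax = float(np.max(x)) if len(x) else 0.0
    if amax < _ECG_FLOOR_MV:
        raise NoBeatsError("ECG channel is flat — no QRS complexes found")
    peaks, _ = signal.find_peaks(
        x,
        height=max(0.5 * amax, _ECG_FLOOR_MV),
        distance=max(1, int(round(0.25 * trace.sample_rate))),
    )
    if len(peaks) < 2:
        raise NoBeatsError(f"found {len(peaks)} QRS complex(es); need at least 2")
    return trace.time[peaks]


def qrs_onsets(trace: Trace, qrs_times: np.ndarray) -> np.ndarray:
    """Earliest-ventricular-activation fiducial per beat: the QRS onset,
    located as the first sustained crossing of 10% of the R amplitude when
    walking back from the R peak."""
    x = np.asarray(trace.ecg_mv, dtype=float)
    fs = trace.sample_rate
    t0 = trace.time[0]
    onsets = np.empty(len(qrs_times))
    back = int(round(0.15 * fs))
    for k, r in enumerate(qrs_times):
        i = int(round((r - t0) * fs))
        thr = 0.1 * x[i]
        j = i
        while j > max(0, i - back) and x[j] >= thr:
            j -= 1
        onsets[k] = trace.time[min(j + 1, i)]
    return onsets


# --------------------------------------------------------------- segmentation

@dataclass
class BeatWindow:
    """One beat's analysis window: MAP samples (and force, when calibrated)
    from a fixed pre-QRS offset up to the next beat's offset."""

    beat_index: int
    qrs_time: float
    start_time: float  # s, time of first sample
    sample_rate: float
    map_mv: np.ndarray
    force_g: Optional[np.ndarray] = None

    @property
    def duration_ms(self) -> float:
        return len(self.map_mv) / self.sample_rate * 1000.0


def segment_beats(
    trace: Trace, qrs_times: np.ndarray, config: Optional[DetectorConfig] = None
) -> list[BeatWindow]:
    """Partition the trace into per-beat windows.

    Window ``i`` runs from ``qrs_i - pre_qrs_offset`` to
    ``qrs_{i+1} - pre_qrs_offset``; the last window extends by the median RR
    interval. Window cores are non-overlapping and, for interior beats,
    partition the trace exactly.
    """
    cfg = config or DetectorConfig()
    if len(qrs_times) < 2:
        raise NoBeatsError("need at least 2 QRS references to segment beats")
    fs = trace.sample_rate
    t0 = trace.time[0]
    rr = float(np.median(np.diff(qrs_times)))
    bounds_s = np.concatenate(
        [qrs_times - cfg.pre_qrs_offset_s, [qrs_times[-1] - cfg.pre_qrs_offset_s + rr]]
    )
    idx = np.clip(np.round((bounds_s - t0) * fs).astype(int), 0, len(trace))
    windows = []
    for i in range(len(qrs_times)):
        lo, hi = idx[i], idx[i + 1]
        windows.append(
            BeatWindow(
                beat_index=i,
                qrs_time=float(qrs_times[i]),
                start_time=float(t0 + lo / fs),
                sample_rate=fs,
                map_mv=trace.map_mv[lo:hi],
                force_g=None if trace.force_g is None else trace.force_g[lo:hi],
            )
        )
    return windows


# ------------------------------------------------------------ beat assessment

@dataclass
class BeatAssessment:
    """Per-beat MAP detection outcome.

    Timing metrics (AT/EOR/MAPDUR, ms) are populated only when a MAP is
    present; ``amplitude`` always reports the measured deflection so that
    near-misses remain inspectable.
    """

    beat_index: int
    qrs_time: float
    earliest_activation_time: float
    map_present: bool
    amplitude: Optional[float] = None  # mV
    activation_time_at: Optional[float] = None  # ms
    end_of_repolarization_eor: Optional[float] = None  # ms
    map_duration_mapdur: Optional[float] = None  # ms
    cf_at_beat: Optional[float] = None  # grams


def assess_beat(
    window: BeatWindow,
    earliest_activation_time: float,
    config: Optional[DetectorConfig] = None,
) -> BeatAssessment:
    """Decide whether the beat carries a MAP and measure AT/EOR/MAPDUR.

    Local activation is the maximum-upstroke-velocity sample; the amplitude
    baseline is the median of the pre-upstroke segment (robust to residual
    baseline wander); EOR is the first decay past
    ``repolarization_fraction`` recovery of the amplitude, with sub-sample
    linear interpolation at the crossing.
    """
    cfg = config or DetectorConfig()
    sig = np.asarray(window.map_mv, dtype=float)
    fs = window.sample_rate
    if window.duration_ms < cfg.min_duration:
        raise WindowTooShortError(
            f"window of {window.duration_ms:.0f} ms shorter than the "
            f"{cfg.min_duration:.0f} ms MAP criterion"
        )
    cf = None if window.force_g is None else float(np.median(window.force_g))
    ms_per_sample = 1000.0 / fs
    eat_idx = (earliest_activation_time - window.start_time) * fs

    diffs = np.diff(sig)
    act_i = int(np.argmax(diffs)) + 1
    pre_end = act_i - int(round(0.010 * fs))
    if pre_end >= 5:
        baseline = float(np.median(sig[:pre_end]))
    else:
        baseline = float(sig[0])

    peak_i = int(np.argmax(sig[act_i:])) + act_i
    if cfg.amplitude_mode == "peak_to_peak":
        amplitude = float(np.max(sig) - np.min(sig))
    else:
        amplitude = float(sig[peak_i] - baseline)

    # end of repolarization: first crossing of the recovery level after the peak
    level = baseline + (1.0 - cfg.repolarization_fraction) * amplitude
    below = np.nonzero(sig[peak_i:] <= level)[0]
    eor_idx: Optional[float] = None
    if below.size:
        j = peak_i + int(below[0])
        if j == peak_i or sig[j] == level:
            eor_idx = float(j)
        else:
            frac = (sig[j - 1] - level) / (sig[j - 1] - sig[j])
            eor_idx = (j - 1) + float(frac)

    at_ms = (act_i - eat_idx) * ms_per_sample
    mapdur_ms = None if eor_idx is None else (eor_idx - act_i) * ms_per_sample
    present = (
        amplitude > cfg.min_amplitude
        and mapdur_ms is not None
        and mapdur_ms >= cfg.min_duration
    )
    if not present:
        return BeatAssessment(
            beat_index=window.beat_index,
            qrs_time=window.qrs_time,
            earliest_activation_time=earliest_activation_time,
            map_present=False,
            amplitude=amplitude,
            cf_at_beat=cf,
        )
    eor_ms = (eor_idx - eat_idx) * ms_per_sample
    return BeatAssessment(
        beat_index=window.beat_index,
        qrs_time=window.qrs_time,
        earliest_activation_time=earliest_activation_time,
        map_present=True,
        amplitude=amplitude,
        activation_time_at=at_ms,
        end_of_repolarization_eor=eor_ms,
        map_duration_mapdur=eor_ms - at_ms,
        cf_at_beat=cf,
    )


# ----------------------------------------------------- consistent-run search

@dataclass
class DetectionResult:
    """Outcome of one catheter application.

    ``cf_at_detection`` is the contact force at the last beat of the first
    run of ``consistency_run`` consecutive, mutually similar MAPs; it is
    null exactly when no qualifying run exists.
    """

    beats: list[BeatAssessment]
    first_consistent_run_start: Optional[int]
    cf_at_detection: Optional[float]
    max_cf_applied: Optional[float]

    @property
    def map_present(self) -> bool:
        return self.first_consistent_run_start is not None


def _similar(a: BeatAssessment, b: BeatAssessment, tol: float) -> bool:
    for x, y in ((a.amplitude, b.amplitude), (a.map_duration_mapdur, b.map_duration_mapdur)):
        if x is None or y is None:
            return False
        denom = max(abs(x), abs(y))
        if denom == 0:
            continue
        if abs(x - y) / denom > tol:
            return False
    return True


def find_consistent_run(
    beats: list[BeatAssessment], config: Optional[DetectorConfig] = None
) -> DetectionResult:
    """First run of ``consistency_run`` consecutive detected MAPs whose
    waveforms are pairwise similar (relative difference in amplitude and
    MAPDUR within ``similarity_tolerance``). Absence of a run is a null
    result, not an error. Ties cannot arise — the scan returns the lowest
    qualifying start index."""
    cfg = config or DetectorConfig()
    run = cfg.consistency_run
    cfs = [b.cf_at_beat for b in beats if b.cf_at_beat is not None]
    max_cf = max(cfs) if cfs else None
    for start in range(len(beats) - run + 1):
        window = beats[start : start + run]
        if not all(b.map_present for b in window):
            continue
        if all(_similar(a, b, cfg.similarity_tolerance) for a, b in combinations(window, 2)):
            return DetectionResult(
                beats=beats,
                first_consistent_run_start=start,
                cf_at_detection=window[-1].cf_at_beat,
                max_cf_applied=max_cf,
            )
    return DetectionResult(
        beats=beats,
        first_consistent_run_start=None,
        cf_at_detection=None,
        max_cf_applied=max_cf,
    )


# ------------------------------------------------------------------ pipeline

def analyze_trace(trace: Trace, config: Optional[DetectorConfig] = None) -> DetectionResult:
    """Full per-trace analysis: band-pass, QRS references, beat windows,
    per-beat assessment, consistent-run search. The trace should carry a
    calibrated force channel for contact forces to be reported."""
    cfg = config or DetectorConfig()
    filt = bandpass_filter(trace, cfg)
    qrs = detect_qrs(filt)
    onsets = qrs_onsets(filt, qrs)
    windows = segment_beats(filt, qrs, cfg)
    beats = []
    for i, w in enumerate(windows):
        try:
            beats.append(assess_beat(w, float(onsets[i]), cfg))
        except WindowTooShortError:
            beats.append(
                BeatAssessment(
                    beat_index=w.beat_index,
                    qrs_time=w.qrs_time,
                    earliest_activation_time=float(onsets[i]),
                    map_present=False,
                    cf_at_beat=None if w.force_g is None else float(np.median(w.force_g)),
                )
            )
    return find_consistent_run(beats, cfg)
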