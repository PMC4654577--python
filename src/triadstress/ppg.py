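"""Photoplethysmography (PPG) signal analysis.

Extracts per-beat pulse rate and peak-to-peak thumb-blood-volume (TBV)
amplitude from a thumb-sensor waveform, applies artifact rules (noise
excision and multiplicative step correction), and computes interval
means and the two normalisation ratios used to express stress:

* conversation / video mean peak-to-peak (TBV shrinks under stress), and
* speaking-turn / listening-turn means for both TBV and pulse rate.

Raw peak-to-peak values depend on cuff tightness and sensor gain, so only
ratios are interpretable; every statistic produced here is invariant to
multiplying the whole trace by a positive constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from . import intervals as iv

__all__ = [
    "WaveformTrace",
    "SegmentMap",
    "ArtifactAnnotation",
    "BeatSeries",
    "IntervalMetrics",
    "read_waveform",
    "write_waveform",
    "detect_beats",
    "apply_artifacts",
    "interval_means",
    "normalize_session",
]


@dataclass
class WaveformTrace:
    """A uniformly sampled PPG waveform for one subject.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    sampling_rate_hz : float
        Sampling rate; must be >= 20 Hz for usable peak localisation.
    samples : ndarray
        Signal amplitude in arbitrary units.
    t0_s : float
        Time of the first sample on the session clock (seconds).
    """

    subject_id: str
    sampling_rate_hz: float
    samples: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise ValueError("samples must be a 1-d array with >= 2 points")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.samples.size) / self.sampling_rate_hz


@dataclass(frozen=True)
class SegmentMap:
    """Session phases as half-open intervals: relaxation video, then conversation."""

    video: Tuple[float, float]
    conversation: Tuple[float, float]

    def __post_init__(self) -> None:
        for name in ("video", "conversation"):
            s, e = getattr(self, name)
            if e <= s:
                raise ValueError(f"{name} segment must have end > start")
        if self.video[1] > self.conversation[0]:
            raise ValueError("video segment must precede conversation")


@dataclass(frozen=True)
class ArtifactAnnotation:
    """Manual artifact annotation.

    kind="excise": beats inside [start_s, end_s) are removed from all
    statistics. kind="step": a step-like gain change at ``start_s`` is
    corrected by rescaling all later amplitudes by the ratio of mean
    amplitudes in 20 s windows before/after the break.
    """

    kind: str
    start_s: float
    end_s: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("excise", "step"):
            raise ValueError("kind must be 'excise' or 'step'")
        if self.kind == "excise":
            if self.end_s is None or self.end_s <= self.start_s:
                raise ValueError("excise annotation needs end_s > start_s")


@dataclass
class BeatSeries:
    """Per-beat pulse measurements.

    One entry per complete pulse cycle: ``times`` is the waveform-peak
    time of the beat, ``amplitudes`` the peak-to-peak value (top of this
    beat minus the bottom before the next beat, arbitrary units), and
    ``bpm`` the instantaneous rate from the spacing to the next peak.
    ``valid`` flags beats whose rate lies in the configured physiological
    bounds; out-of-range beats are flagged, never silently dropped.
    """

    subject_id: str
    times: np.ndarray
    amplitudes: np.ndarray
    bpm: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.bpm = np.asarray(self.bpm, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.times.size, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = self.times.size
        if not (self.amplitudes.size == self.bpm.size == self.valid.size == n):
            raise ValueError("beat arrays must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("beat times must be strictly increasing")
        if np.any(self.amplitudes <= 0):
            raise ValueError("beat amplitudes must be positive")

    def __len__(self) -> int:
        return int(self.times.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "peak_to_peak": self.amplitudes,
                "bpm": self.bpm,
                "valid": self.valid,
            }
        )


@dataclass
class IntervalMetrics:
    """Per-subject interval means and normalisation ratios.

    Ratios are NaN (flagged missing) when the corresponding interval set
    contains no beats — e.g. a subject who never held a speaking turn.
    """

    subject_id: str
    bpm_video: float
    bpm_conversation: float
    tbv_video: float
    tbv_conversation: float
    tbv_conv_video_ratio: float
    bpm_conv_video_ratio: float
    bpm_speak: float = np.nan
    bpm_listen: float = np.nan
    tbv_speak: float = np.nan
    tbv_listen: float = np.nan
    tbv_speak_listen_ratio: float = np.nan
    bpm_speak_listen_ratio: float = np.nan

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# waveform I/O  (CSV: time_s,signal)
# ---------------------------------------------------------------------------

def write_waveform(trace: WaveformTrace, path) -> None:
    """Write a trace as a two-column CSV (``time_s,signal``)."""
    df = pd.DataFrame({"time_s": trace.times, "signal": trace.samples})
    df.to_csv(path, index=False, float_format="%.6f")


def read_waveform(path, subject_id: Optional[str] = None,
                  sampling_rate_hz: Optional[float] = None) -> WaveformTrace:
    """Read a ``time_s,signal`` CSV into a :class:`WaveformTrace`.

    The time column must be uniformly spaced and strictly increasing;
    the first offending row is named in the error. If
    ``sampling_rate_hz`` is omitted it is inferred from the median time
    step.
    """
    df = pd.read_csv(path)
    if df.shape[0] < 2:
        raise ValueError(f"{path}: waveform file needs >= 2 samples")
    if "time_s" not in df.columns or "signal" not in df.columns:
        raise ValueError(f"{path}: expected columns time_s,signal")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        # offending data row bad[0]+1 (0-based) sits on file line bad[0]+3
        raise ValueError(
            f"{path}: non-monotone time at row {bad[0] + 3} "
            f"(t={float(t[bad[0] + 1])} after t={float(t[bad[0]])})"
        )
    step = np.median(dt)
    off = np.nonzero(np.abs(dt - step) > 1e-4 * step + 1e-9)[0]
    if off.size:
        raise ValueError(f"{path}: non-uniform sampling at row {off[0] + 3}")
    fs = sampling_rate_hz if sampling_rate_hz is not None else 1.0 / step
    if subject_id is None:
        import os

        subject_id = os.path.splitext(os.path.basename(str(path)))[0]
    return WaveformTrace(subject_id, fs, df["signal"].to_numpy(dtype=float), t0_s=t[0])


# ---------------------------------------------------------------------------
# beat detection
# ---------------------------------------------------------------------------

def detect_beats(trace: WaveformTrace, min_bpm: float = 40.0,
                 max_bpm: float = 180.0) -> BeatSeries:
    """Detect pulse beats and per-beat peak-to-peak amplitudes.

    A beat is a local maximum above a rolling baseline, with a
    refractory spacing of ``60 / max_bpm`` seconds. Each complete cycle
    (peak i to peak i+1) yields one beat: amplitude = peak i minus the
    minimum before peak i+1; instantaneous rate = 60 / spacing. Rates
    outside [min_bpm, max_bpm] are flagged in ``valid``.

    The peak-height threshold is quantile-based, so detection — and all
    downstream ratios — are invariant to overall gain.
    """
    if not 0 < min_bpm < max_bpm:
        raise ValueError("need 0 < min_bpm < max_bpm")
    x = trace.samples
    fs = trace.sampling_rate_hz
    if trace.duration_s < 2 * 60.0 / min_bpm:
        raise ValueError("trace too short: need at least two beats at min_bpm")
    # rolling-baseline detrend over ~2 slowest cycles; gain-equivariant
    win = max(3, int(round(fs * 2 * 60.0 / min_bpm)))
    baseline = (
        pd.Series(x).rolling(win, center=True, min_periods=1).median().to_numpy()
    )
    detr = x - baseline
    spread = np.quantile(detr, 0.95) - np.quantile(detr, 0.05)
    if spread <= 0:
        raise ValueError("no beats detectable: flat trace")
    distance = max(1, int(round(fs * 60.0 / max_bpm)))
    peaks, _ = find_peaks(detr, distance=distance, prominence=0.25 * spread)
    if peaks.size < 2:
        raise ValueError("no beats detectable in trace")
    times = trace.t0_s + peaks / fs
    n = peaks.size - 1
    amps = np.empty(n)
    for i in range(n):
        trough = x[peaks[i]: peaks[i + 1] + 1].min()
        amps[i] = x[peaks[i]] - trough
    gaps = np.diff(peaks) / fs
    bpm = 60.0 / gaps
    ok = amps > 0
    if not np.all(ok):  # pathological flat cycle; drop rather than emit <=0
        amps, bpm, t = amps[ok], bpm[ok], times[:-1][ok]
    else:
        t = times[:-1]
    if t.size == 0:
        raise ValueError("no beats detectable in trace")
    valid = (bpm >= min_bpm) & (bpm <= max_bpm)
    return BeatSeries(trace.subject_id, t, amps, bpm, valid)


def brute_force_amplitudes(trace: WaveformTrace, beat_times: Sequence[float]) -> np.ndarray:
    """Reference peak-to-peak scan: for each known beat time, argmax near the
    beat minus the minimum before the next beat. Used as an independent
    oracle against :func:`detect_beats` on noiseless synthetic traces."""
    x, fs = trace.samples, trace.sampling_rate_hz
    bt = np.asarray(beat_times, dtype=float) - trace.t0_s
    idx = np.clip(np.round(bt * fs).astype(int), 0, x.size - 1)
    out = np.empty(idx.size - 1)
    for i in range(idx.size - 1):
        seg = x[idx[i]: idx[i + 1] + 1]
        out[i] = seg.max() - seg.min()
    return out


# ---------------------------------------------------------------------------
# artifact rules
# ---------------------------------------------------------------------------

def apply_artifacts(beats: BeatSeries, annotations: Sequence[ArtifactAnnotation],
                    window_s: float = 20.0) -> BeatSeries:
    """Apply excision and step-gain corrections to a beat series.

    Excisions are applied first; beats whose peak time lies inside an
    excised interval are removed from all statistics. Each step break at
    t0 then rescales all amplitudes at or after t0 by
    ``mean(amp in [t0-window, t0)) / mean(amp in [t0, t0+window))``.
    Beat times are never changed.
    """
    if not annotations:
        return beats
    times = beats.times.copy()
    amps = beats.amplitudes.copy()
    bpm = beats.bpm.copy()
    valid = beats.valid.copy()

    keep = np.ones(times.size, dtype=bool)
    for ann in annotations:
        if ann.kind == "excise":
            keep &= ~((times >= ann.start_s) & (times < ann.end_s))
    times, amps, bpm, valid = times[keep], amps[keep], bpm[keep], valid[keep]

    for ann in annotations:
        if ann.kind != "step":
            continue
        t0 = ann.start_s
        before = (times >= t0 - window_s) & (times < t0)
        after = (times >= t0) & (times < t0 + window_s)
        if (not before.any() or not after.any()
                or t0 - window_s < times[0] or t0 + window_s > times[-1]):
            raise ValueError(
                f"step at t={t0}: the {window_s} s window on one side is "
                "empty or truncated, cannot estimate correction ratio"
            )
        ratio = amps[before].mean() / amps[after].mean()
        amps[times >= t0] *= ratio
    return BeatSeries(beats.subject_id, times, amps, bpm, valid)


# ---------------------------------------------------------------------------
# interval statistics
# ---------------------------------------------------------------------------

def interval_means(beats: BeatSeries, interval_set: Sequence[Tuple[float, float]],
                   valid_only: bool = True) -> Tuple[float, float]:
    """Mean BPM and mean peak-to-peak over beats whose peak time lies in
    the union of half-open intervals. Each beat is one observation."""
    ivs = iv.normalize(interval_set)
    if not ivs:
        raise ValueError("empty interval set")
    mask = np.zeros(beats.times.size, dtype=bool)
    for s, e in ivs:
        mask |= (beats.times >= s) & (beats.times < e)
    if valid_only:
        mask &= beats.valid
    if not mask.any():
        raise ValueError("no beats fall inside the requested intervals")
    return float(beats.bpm[mask].mean()), float(beats.amplitudes[mask].mean())


def normalize_session(beats: BeatSeries, segments: SegmentMap, turns,
                      subject_id: Optional[str] = None) -> IntervalMetrics:
    """Compute the session's normalisation ratios for one subject.

    ``turns`` is a :class:`triadstress.turns.TurnTrack`. Speaking
    intervals are the subject's own turns; listening intervals are the
    other members' turns minus any overlap with the subject's own turns;
    silence belongs to neither. If the subject held no turn, the
    speak/listen ratios are flagged missing (NaN) while the segment
    ratios are still produced.
    """
    from .turns import speaking_listening_sets

    sid = subject_id or beats.subject_id
    bpm_v, tbv_v = interval_means(beats, [segments.video])
    bpm_c, tbv_c = interval_means(beats, [segments.conversation])
    out = IntervalMetrics(
        subject_id=sid,
        bpm_video=bpm_v,
        bpm_conversation=bpm_c,
        tbv_video=tbv_v,
        tbv_conversation=tbv_c,
        tbv_conv_video_ratio=tbv_c / tbv_v,
        bpm_conv_video_ratio=bpm_c / bpm_v,
    )
    speak, listen = speaking_listening_sets(turns, sid)
    speak = iv.intersect(speak, [segments.conversation])
    listen = iv.intersect(listen, [segments.conversation])
    try:
        bpm_s, tbv_s = interval_means(beats, speak) if speak else (np.nan, np.nan)
        bpm_l, tbv_l = interval_means(beats, listen) if listen else (np.nan, np.nan)
    except ValueError:
        return out
    out.bpm_speak, out.tbv_speak = bpm_s, tbv_s
    out.bpm_listen, out.tbv_listen = bpm_l, tbv_l
    if np.isfinite(tbv_s) and np.isfinite(tbv_l):
        out.tbv_speak_listen_ratio = tbv_s / tbv_l
        out.bpm_speak_listen_ratio = bpm_s / bpm_l
    return out


def metrics_frame(metrics: Sequence[IntervalMetrics]) -> pd.DataFrame:
    """Tidy one-row-per-subject frame of interval metrics."""
    return pd.DataFrame([m.to_dict() for m in metrics])
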