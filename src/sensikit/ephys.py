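"""Current-clamp feature battery.

Action potentials are detected with the first-derivative method: an
event begins where dV/dt first reaches the detection threshold
(10 mV/ms by default).  From the sweep families the module measures
resting membrane potential (mean of the 200 ms preceding the stimulus),
rheobase (minimum step current eliciting at least one AP), the waveform
features of the first evoked AP under the held-at--75 mV protocol
(threshold, peak amplitude, time to peak, half-width, fast and medium
afterhyperpolarisation), spontaneous firing from a 2-minute gap-free
segment, the f-I spike counts, and the exclusion rules (no AP up to the
largest step, or RMP above -40 mV).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .recording import SweepProtocol, SweepRecording

__all__ = [
    "APDetectionParams",
    "APEvent",
    "APWaveformFeatures",
    "ExcitabilityProfile",
    "ExclusionDecision",
    "correct_ljp",
    "detect_aps",
    "measure_rmp",
    "measure_rheobase",
    "waveform_features",
    "classify_firing",
    "apply_exclusions",
    "extract_cell_features",
]


@dataclass(frozen=True)
class APDetectionParams:
    dvdt_threshold_mV_per_ms: float = 10.0
    min_interevent_ms: float = 2.0
    smooth_window: int = 0  # odd Savitzky-Golay window; 0 disables smoothing

    def __post_init__(self) -> None:
        if self.dvdt_threshold_mV_per_ms <= 0:
            raise ValueError("dvdt_threshold must be positive")
        if self.min_interevent_ms < 0:
            raise ValueError("min_interevent_ms must be non-negative")


@dataclass(frozen=True)
class APEvent:
    onset_index: int
    peak_index: int
    peak_mV: float


@dataclass
class APWaveformFeatures:
    threshold_mV: float
    peak_amplitude_mV: float
    time_to_peak_ms: float
    half_width_ms: float
    fahp_mV: float
    mahp_mV: float


@dataclass
class ExcitabilityProfile:
    rmp_mV: float
    rheobase_pA: float | None
    spontaneous: bool | None          # None when no gap-free segment
    firing_pattern: str               # single | multiple | none
    fi_counts: list[int]
    max_aps: int


@dataclass(frozen=True)
class ExclusionDecision:
    excluded: bool
    reason: str | None


def correct_ljp(rec: SweepRecording) -> SweepRecording:
    """Apply the liquid junction potential offline (corrected = recorded + LJP,
    default LJP -14 mV).  Raises if the recording was already corrected."""
    if rec.ljp_corrected:
        raise ValueError("recording already LJP-corrected; refusing to correct twice")
    return SweepRecording(
        sweeps=rec.sweeps + rec.ljp_mV,
        sampling_rate_Hz=rec.sampling_rate_Hz,
        protocol=rec.protocol,
        ljp_mV=rec.ljp_mV,
        ljp_corrected=True,
        gapfree=None if rec.gapfree is None else rec.gapfree + rec.ljp_mV,
    )


def _dvdt_mv_per_ms(sweep: np.ndarray, fs_hz: float, params: APDetectionParams) -> np.ndarray:
    v = np.asarray(sweep, dtype=float)
    if params.smooth_window and params.smooth_window >= 5:
        from scipy.signal import savgol_filter
        v = savgol_filter(v, params.smooth_window, polyorder=3)
    return np.diff(v) * (fs_hz / 1000.0)


def detect_aps(
    sweep: np.ndarray,
    fs_hz: float,
    params: APDetectionParams = APDetectionParams(),
) -> list[APEvent]:
    """First-derivative AP detection on one sweep.

    Events start at upward crossings of the dV/dt threshold separated by
    at least ``min_interevent_ms``; each event's peak is the following
    local maximum of Vm.
    """
    v = np.asarray(sweep, dtype=float)
    if v.size < 2:
        raise ValueError("sweep must contain at least two samples")
    dvdt = _dvdt_mv_per_ms(v, fs_hz, params)
    supra = dvdt >= params.dvdt_threshold_mV_per_ms
    # upward crossings; a suprathreshold first sample pair counts as one
    crossing = supra & ~np.concatenate(([False], supra[:-1]))
    idx = np.flatnonzero(crossing)
    min_gap = int(round(params.min_interevent_ms * fs_hz / 1000.0))
    events: list[APEvent] = []
    last = -np.inf
    for i in idx:
        if i - last < min_gap:
            continue
        last = i
        peak = _next_local_max(v, i)
        events.append(APEvent(onset_index=int(i), peak_index=peak, peak_mV=float(v[peak])))
    return events


def _next_local_max(v: np.ndarray, start: int) -> int:
    """First local maximum of v at or after ``start``."""
    i = start
    n = v.size
    while i + 1 < n and v[i + 1] >= v[i]:
        i += 1
    return i


def measure_rmp(sweep: np.ndarray, fs_hz: float, step_start_s: float,
                window_s: float = 0.2) -> float:
    """Mean Vm over the 200 ms immediately preceding the stimulus."""
    i1 = int(round(step_start_s * fs_hz))
    n_win = int(round(window_s * fs_hz))
    if i1 - n_win < 0:
        raise ValueError(
            f"need {window_s * 1000:.0f} ms of pre-stimulus data, have "
            f"{i1 / fs_hz * 1000:.0f} ms"
        )
    return float(np.mean(sweep[i1 - n_win:i1]))


def _step_events(rec: SweepRecording, params: APDetectionParams) -> list[list[APEvent]]:
    i0, i1 = rec.step_window
    out = []
    for sweep in rec.sweeps:
        evs = detect_aps(sweep, rec.sampling_rate_Hz, params)
        out.append([e for e in evs if i0 <= e.onset_index < i1])
    return out


def measure_rheobase(
    rec: SweepRecording,
    params: APDetectionParams = APDetectionParams(),
) -> float | None:
    """Minimum injected current whose step window contains >= 1 AP."""
    for amp, evs in zip(rec.protocol.amplitudes_pA, _step_events(rec, params)):
        if evs:
            return float(amp)
    return None


def waveform_features(
    rec: SweepRecording,
    params: APDetectionParams = APDetectionParams(),
    mahp_window_s: float = 0.2,
) -> APWaveformFeatures:
    """Waveform features of the first AP on the first suprathreshold sweep.

    Intended for the held-at--75 mV protocol; the amplitude reference is
    the sweep's own pre-stimulus holding level, so it coincides with
    -75 mV on an uncorrected held recording and is invariant under LJP
    correction.  Half-width is measured between linearly interpolated
    crossings of the half-amplitude level.
    """
    fs = rec.sampling_rate_Hz
    i0, i1 = rec.step_window
    per_sweep = _step_events(rec, params)
    sweep_idx = next((i for i, evs in enumerate(per_sweep) if evs), None)
    if sweep_idx is None:
        raise ValueError("no action potential on any sweep; waveform features undefined")
    v = rec.sweeps[sweep_idx]
    events = per_sweep[sweep_idx]
    first = events[0]

    reference = measure_rmp(v, fs, rec.protocol.step_start_s)
    threshold = float(v[first.onset_index])
    peak_amplitude = first.peak_mV - reference
    time_to_peak_ms = (first.peak_index - i0) / fs * 1000.0

    half_level = reference + peak_amplitude / 2.0
    half_width_ms = _width_at_level(v, first.peak_index, half_level, fs)

    fahp_end = events[1].onset_index if len(events) > 1 else i1
    fahp = float(np.min(v[first.peak_index:max(fahp_end, first.peak_index + 1)]))
    m_end = min(v.size, i1 + int(round(mahp_window_s * fs)))
    mahp = float(np.min(v[i1:m_end]))
    return APWaveformFeatures(
        threshold_mV=threshold,
        peak_amplitude_mV=float(peak_amplitude),
        time_to_peak_ms=float(time_to_peak_ms),
        half_width_ms=float(half_width_ms),
        fahp_mV=fahp,
        mahp_mV=mahp,
    )


def _width_at_level(v: np.ndarray, peak: int, level: float, fs_hz: float) -> float:
    """Duration (ms) between the interpolated level crossings around ``peak``."""
    # walk left
    i = peak
    while i > 0 and v[i] > level:
        i -= 1
    if v[i] > level:
        raise ValueError("half-amplitude level never crossed on the rising flank")
    frac = (level - v[i]) / (v[i + 1] - v[i]) if v[i + 1] != v[i] else 0.0
    t_left = i + frac
    # walk right
    j = peak
    n = v.size
    while j < n - 1 and v[j] > level:
        j += 1
    if v[j] > level:
        raise ValueError("half-amplitude level never crossed on the falling flank")
    frac = (v[j - 1] - level) / (v[j - 1] - v[j]) if v[j - 1] != v[j] else 0.0
    t_right = (j - 1) + frac
    return (t_right - t_left) / fs_hz * 1000.0


def classify_firing(
    rec: SweepRecording,
    params: APDetectionParams = APDetectionParams(),
) -> dict:
    """Spontaneous-activity flag, firing pattern and f-I counts.

    Spontaneous means at least one AP anywhere in the gap-free segment
    (None when no segment was recorded).  The firing pattern is judged
    across all sweeps: "multiple" if any sweep fires >= 2 APs within the
    step, "single" if the maximum is exactly 1, "none" otherwise.
    """
    fi_counts = [len(evs) for evs in _step_events(rec, params)]
    max_aps = max(fi_counts) if fi_counts else 0
    pattern = "multiple" if max_aps >= 2 else ("single" if max_aps == 1 else "none")
    spontaneous: bool | None = None
    if rec.gapfree is not None:
        spontaneous = len(detect_aps(rec.gapfree, rec.sampling_rate_Hz, params)) >= 1
    return dict(spontaneous=spontaneous, firing_pattern=pattern,
                fi_counts=fi_counts, max_aps=max_aps)


def apply_exclusions(profile: ExcitabilityProfile, rmp_cutoff_mV: float = -40.0
                     ) -> ExclusionDecision:
    """Exclude cells that never fire up to the largest step or whose
    resting membrane potential is above -40 mV."""
    if profile.rheobase_pA is None:
        return ExclusionDecision(True, "non-firing")
    if profile.rmp_mV > rmp_cutoff_mV:
        return ExclusionDecision(True, "depolarised RMP")
    return ExclusionDecision(False, None)


def extract_cell_features(
    resting_rec: SweepRecording,
    held_rec: SweepRecording | None = None,
    params: APDetectionParams = APDetectionParams(),
) -> pd.DataFrame:
    """One-row feature table for a cell: passive/active properties,
    firing classification and the exclusion decision."""
    fs = resting_rec.sampling_rate_Hz
    rmp = measure_rmp(resting_rec.sweeps[0], fs, resting_rec.protocol.step_start_s)
    rheo = measure_rheobase(resting_rec, params)
    firing = classify_firing(resting_rec, params)
    profile = ExcitabilityProfile(
        rmp_mV=rmp, rheobase_pA=rheo,
        spontaneous=firing["spontaneous"],
        firing_pattern=firing["firing_pattern"],
        fi_counts=firing["fi_counts"],
        max_aps=firing["max_aps"],
    )
    decision = apply_exclusions(profile)
    row = dict(
        rmp_mV=rmp, rheobase_pA=rheo,
        spontaneous=firing["spontaneous"],
        firing_pattern=firing["firing_pattern"],
        max_aps=firing["max_aps"],
        excluded=decision.excluded, reason=decision.reason,
        threshold_mV=np.nan, peak_amplitude_mV=np.nan, time_to_peak_ms=np.nan,
        half_width_ms=np.nan, fahp_mV=np.nan, mahp_mV=np.nan,
    )
    if held_rec is not None:
        try:
            wf = waveform_features(held_rec, params)
        except ValueError:
            wf = None
        if wf is not None:
            row.update(
                threshold_mV=wf.threshold_mV,
                peak_amplitude_mV=wf.peak_amplitude_mV,
                time_to_peak_ms=wf.time_to_peak_ms,
                half_width_ms=wf.half_width_ms,
                fahp_mV=wf.fahp_mV,
                mahp_mV=wf.mahp_mV,
            )
    return pd.DataFrame([row])
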