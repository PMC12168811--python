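"""Calcium-imaging responder pipeline.

Takes per-ROI raw fluorescence traces (mean intensity per frame, from a
label mask over a time-lapse movie, or a pre-extracted table), converts
them to dF/F against the pre-compound baseline, gates live cells by their
response to the terminal 50 mM KCl challenge, classifies drug responders
by a three-part criterion (duration, onset latency, amplitude), and
summarises per coverslip.

Criteria
--------
live
    at least ``live_min_frames`` KCl-epoch frames exceed the second
    (wash) baseline mean by ``k_sd`` standard deviations.
responder
    live, AND at least ``responder_min_frames`` drug-epoch frames exceed
    the baseline mean by ``k_sd`` SD (in dF/F space), AND the first
    suprathreshold frame falls within ``onset_window_s`` of compound
    application, AND the response reaches at least ``min_amplitude``
    (default 10% dF/F) above baseline.

The per-cell response magnitude ("max % response") is the mean of the
three largest dF/F values over the response timeframe (onset to end of
the drug epoch).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .timeline import AcquisitionTimeline, FrameWindow

__all__ = [
    "ResponderParams",
    "DeltaFTrace",
    "CellCallResult",
    "CoverslipSummary",
    "extract_roi_traces",
    "compute_dff",
    "call_cell",
    "max_response",
    "characterize_transient",
    "summarize_coverslip",
    "call_cohort",
    "traces_to_table",
    "table_to_traces",
]


@dataclass(frozen=True)
class ResponderParams:
    """Thresholds of the live-cell and responder criteria."""

    k_sd: float = 3.0
    live_min_frames: int = 10
    responder_min_frames: int = 80
    onset_window_s: float = 300.0
    min_amplitude: float = 0.10
    #: which baseline supplies the mean/SD for the responder predicate;
    #: the pre-compound baseline (in dF/F space its mean is exactly 0)
    #: is the default, the wash baseline is available as an alternative.
    responder_baseline: Literal["baseline1", "baseline2"] = "baseline1"

    def __post_init__(self) -> None:
        if self.k_sd <= 0 or self.live_min_frames <= 0 or self.responder_min_frames <= 0:
            raise ValueError("k_sd, live_min_frames, responder_min_frames must be positive")
        if self.onset_window_s <= 0:
            raise ValueError("onset_window_s must be positive")
        if not (0 < self.min_amplitude <= 1):
            raise ValueError("min_amplitude must lie in (0, 1]")


@dataclass
class DeltaFTrace:
    """dF/F trace with both baseline statistics."""

    roi_id: int | str
    dff: np.ndarray
    baseline1_mean: float  # raw-fluorescence units
    baseline1_sd: float    # raw-fluorescence units
    baseline2_mean: float  # dF/F units (wash window)
    baseline2_sd: float    # dF/F units

    @property
    def baseline1_sd_dff(self) -> float:
        """Pre-compound baseline SD expressed in dF/F units."""
        return self.baseline1_sd / self.baseline1_mean


@dataclass
class CellCallResult:
    roi_id: int | str
    live: bool
    responder: bool
    onset_frame: int | None = None
    max_pct_response: float | None = None
    reason: str | None = None  # code for negative calls


@dataclass
class CoverslipSummary:
    n_rois: int
    n_live: int
    n_responders: int
    pct_live: float
    pct_responders: float | None  # of live; None when no live cells
    mean_max_pct_response: float | None
    median_max_pct_response: float | None


def extract_roi_traces(movie: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Mean intensity per label per frame.

    Parameters
    ----------
    movie:
        (T, H, W) stack.
    labels:
        (H, W) integer label mask; 0 is background and is ignored.

    Returns
    -------
    Long-format table with columns ``roi_id``, ``frame``, ``raw_F``.
    """
    movie = np.asarray(movie)
    labels = np.asarray(labels)
    if movie.ndim != 3:
        raise ValueError("movie must be a (T, H, W) stack")
    if labels.shape != movie.shape[1:]:
        raise ValueError(
            f"label mask shape {labels.shape} does not match movie frames {movie.shape[1:]}"
        )
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("label mask contains no ROIs")
    t = movie.shape[0]
    rows = []
    flat = movie.reshape(t, -1).astype(float)
    lab_flat = labels.ravel()
    for roi in ids:
        sel = lab_flat == roi
        trace = flat[:, sel].mean(axis=1)
        rows.append(pd.DataFrame({"roi_id": int(roi), "frame": np.arange(t), "raw_F": trace}))
    return pd.concat(rows, ignore_index=True)


def traces_to_table(traces: dict[int | str, np.ndarray]) -> pd.DataFrame:
    """Dict of per-ROI raw traces -> long-format table."""
    rows = []
    for roi, f in traces.items():
        f = np.asarray(f, dtype=float)
        rows.append(pd.DataFrame({"roi_id": roi, "frame": np.arange(f.size), "raw_F": f}))
    return pd.concat(rows, ignore_index=True)


def table_to_traces(table: pd.DataFrame) -> dict[int | str, np.ndarray]:
    """Long-format table (roi_id, frame, raw_F) -> dict of per-ROI arrays."""
    out: dict[int | str, np.ndarray] = {}
    for roi, grp in table.groupby("roi_id", sort=True):
        out[roi] = grp.sort_values("frame")["raw_F"].to_numpy(dtype=float)
    return out


def compute_dff(
    raw: np.ndarray,
    timeline: AcquisitionTimeline,
    roi_id: int | str = 0,
) -> DeltaFTrace:
    """dF/F against the pre-compound baseline mean.

    ``dff[t] = (F[t] - baseline1_mean) / baseline1_mean``; the second
    baseline's mean/SD are computed on the dF/F trace over the wash
    window just before KCl.
    """
    raw = np.asarray(raw, dtype=float)
    timeline.validate_length(raw.size)
    b0, b1 = timeline.baseline_window
    base = raw[b0:b1]
    m1 = float(base.mean())
    if m1 <= 0:
        raise ValueError(f"degenerate baseline: mean {m1} is not positive")
    s1 = float(base.std(ddof=0))
    dff = (raw - m1) / m1
    w0, w1 = timeline.wash_window
    m2 = float(dff[w0:w1].mean())
    s2 = float(dff[w0:w1].std(ddof=0))
    return DeltaFTrace(
        roi_id=roi_id,
        dff=dff,
        baseline1_mean=m1,
        baseline1_sd=s1,
        baseline2_mean=m2,
        baseline2_sd=s2,
    )


def _responder_threshold(trace: DeltaFTrace, params: ResponderParams) -> float:
    if params.responder_baseline == "baseline1":
        # pre-compound baseline in dF/F space has mean 0 by construction
        return params.k_sd * trace.baseline1_sd_dff
    return trace.baseline2_mean + params.k_sd * trace.baseline2_sd


def call_cell(
    trace: DeltaFTrace,
    timeline: AcquisitionTimeline,
    params: ResponderParams = ResponderParams(),
) -> CellCallResult:
    """Live-cell gate and responder classification for one ROI.

    Never raises on a dead cell: it is returned as a non-responder with
    ``reason="dead"``.
    """
    dff = trace.dff
    timeline.validate_length(dff.size)

    k0, k1 = timeline.kcl_window
    live_thr = trace.baseline2_mean + params.k_sd * trace.baseline2_sd
    n_live_frames = int(np.count_nonzero(dff[k0:k1] >= live_thr))
    live = n_live_frames >= params.live_min_frames
    if not live:
        return CellCallResult(trace.roi_id, live=False, responder=False, reason="dead")

    d0, d1 = timeline.drug_window
    thr = _responder_threshold(trace, params)
    supra = dff[d0:d1] >= thr
    n_supra = int(np.count_nonzero(supra))
    if n_supra < params.responder_min_frames:
        return CellCallResult(trace.roi_id, live=True, responder=False,
                              reason="insufficient-frames")

    onset_rel = int(np.flatnonzero(supra)[0])
    onset_frame = d0 + onset_rel
    onset_s = onset_rel * timeline.frame_period_s
    if onset_s > params.onset_window_s:
        return CellCallResult(trace.roi_id, live=True, responder=False, reason="late-onset")

    response = dff[onset_frame:d1]
    if response.size == 0 or float(response.max()) < params.min_amplitude:
        return CellCallResult(trace.roi_id, live=True, responder=False, reason="sub-amplitude")

    return CellCallResult(
        trace.roi_id,
        live=True,
        responder=True,
        onset_frame=onset_frame,
        max_pct_response=max_response(dff, (onset_frame, d1)),
    )


def max_response(dff: np.ndarray, window: FrameWindow) -> float:
    """Mean of the three largest dF/F values in ``window``.

    Windows shorter than three frames average every frame they have.
    """
    lo, hi = window
    vals = np.asarray(dff, dtype=float)[lo:hi]
    if vals.size == 0:
        raise ValueError(f"empty response window {window}")
    k = min(3, vals.size)
    top = np.partition(vals, vals.size - k)[vals.size - k:]
    return float(top.mean())


@dataclass
class TransientFeatures:
    """Descriptive shape features of a responder's drug transient."""

    peak_count: int
    time_to_peak_s: float
    half_decay_s: float | None
    archetype: str  # slow | intermediate | rapid | oscillatory | unclassified


def characterize_transient(
    trace: DeltaFTrace,
    timeline: AcquisitionTimeline,
    params: ResponderParams = ResponderParams(),
    *,
    slow_cutoff_s: float = 40.0,
    rapid_cutoff_s: float = 10.0,
    oscillatory_min_peaks: int = 3,
) -> TransientFeatures:
    """Shape features of the drug-epoch transient of a responder.

    Purely descriptive: the archetype label (slow / intermediate /
    rapidly-decaying / oscillatory, following the transient shapes seen
    with veratridine) never feeds the responder classification.  The
    cutoffs are heuristics on the post-peak half-decay time and on the
    count of distinct suprathreshold peaks.
    """
    from scipy.signal import find_peaks

    call = call_cell(trace, timeline, params)
    if not call.responder:
        raise ValueError(f"transient features are undefined for non-responders "
                         f"(roi {trace.roi_id}, reason {call.reason})")

    d0, d1 = timeline.drug_window
    seg = trace.dff[d0:d1]
    thr = _responder_threshold(trace, params)
    peak_height = max(thr, params.min_amplitude / 2)
    peaks, _ = find_peaks(seg, height=peak_height, prominence=peak_height / 2)
    peak_count = int(peaks.size)

    ipk = int(np.argmax(seg))
    peak_val = float(seg[ipk])
    time_to_peak_s = ipk * timeline.frame_period_s

    half_decay_s: float | None = None
    below = np.flatnonzero(seg[ipk:] <= peak_val / 2)
    if below.size:
        half_decay_s = float(below[0]) * timeline.frame_period_s

    if peak_count >= oscillatory_min_peaks:
        label = "oscillatory"
    elif half_decay_s is None:
        label = "unclassified"
    elif half_decay_s >= slow_cutoff_s:
        label = "slow"
    elif half_decay_s >= rapid_cutoff_s:
        label = "intermediate"
    else:
        label = "rapid"
    return TransientFeatures(peak_count, time_to_peak_s, half_decay_s, label)


def summarize_coverslip(results: Sequence[CellCallResult]) -> CoverslipSummary:
    """Coverslip-level percentages; each coverslip is one independent unit."""
    if len(results) == 0:
        raise ValueError("cannot summarise an empty coverslip")
    n = len(results)
    live = [r for r in results if r.live]
    resp = [r for r in results if r.responder]
    pct_live = 100.0 * len(live) / n
    pct_resp = 100.0 * len(resp) / len(live) if live else None
    maxes = [r.max_pct_response for r in resp if r.max_pct_response is not None]
    return CoverslipSummary(
        n_rois=n,
        n_live=len(live),
        n_responders=len(resp),
        pct_live=pct_live,
        pct_responders=pct_resp,
        mean_max_pct_response=float(np.mean(maxes)) if maxes else None,
        median_max_pct_response=float(np.median(maxes)) if maxes else None,
    )


def call_cohort(
    table: pd.DataFrame,
    timeline: AcquisitionTimeline,
    params: ResponderParams = ResponderParams(),
) -> pd.DataFrame:
    """Run dF/F conversion and cell calling over a long-format trace table.

    Returns one row per ROI: live/responder flags, onset frame, max %
    response and the negative-call reason code.
    """
    rows = []
    for roi, raw in table_to_traces(table).items():
        trace = compute_dff(raw, timeline, roi_id=roi)
        call = call_cell(trace, timeline, params)
        rows.append(
            dict(
                roi_id=roi,
                live=call.live,
                responder=call.responder,
                onset_frame=call.onset_frame,
                max_pct_response=call.max_pct_response,
                reason=call.reason,
            )
        )
    return pd.DataFrame(rows)
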