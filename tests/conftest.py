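"""Shared fixtures and independent oracle helpers.

The engineered-trace builder constructs raw-fluorescence traces whose
baseline statistics are known exactly (a deterministic +-1 ripple on a
baseline of 100 gives baseline SD exactly 1, i.e. 0.01 in dF/F units),
so classification boundaries can be probed frame by frame.
"""

from __future__ import annotations

import numpy as np
import pytest

from sensikit.calcium import CellCallResult, DeltaFTrace, ResponderParams, compute_dff
from sensikit.timeline import AcquisitionTimeline


@pytest.fixture
def unit_timeline() -> AcquisitionTimeline:
    """1 s/frame layout: baseline 100, drug 400, wash 100, KCl 100 frames."""
    return AcquisitionTimeline(
        frame_period_s=1.0,
        baseline_window=(0, 100),
        compound_frame=100,
        wash_window=(500, 600),
        kcl_window=(600, 700),
    )


def engineered_trace(
    tl: AcquisitionTimeline,
    drug_frames: int = 0,
    drug_onset_s: float = 60.0,
    drug_level: float = 0.12,
    kcl_frames: int = 30,
    kcl_level: float = 0.5,
    baseline_F: float = 100.0,
    ripple: float = 1.0,
) -> np.ndarray:
    """Raw trace with exact counts of suprathreshold frames.

    The +-ripple alternation occupies the baseline and wash windows,
    giving baseline1 SD = ripple exactly and baseline2 SD =
    ripple/baseline_F in dF/F units.  ``drug_frames`` consecutive frames
    at ``drug_level`` dF/F start ``drug_onset_s`` after the compound
    frame; ``kcl_frames`` frames at ``kcl_level`` start at the KCl
    window.
    """
    n = tl.n_frames
    f = np.full(n, baseline_F)
    alt = np.where(np.arange(n) % 2 == 0, ripple, -ripple)
    b0, b1 = tl.baseline_window
    w0, w1 = tl.wash_window
    f[b0:b1] += alt[b0:b1]
    f[w0:w1] += alt[w0:w1]
    if drug_frames:
        start = tl.compound_frame + int(round(drug_onset_s / tl.frame_period_s))
        stop = start + drug_frames
        assert stop <= tl.drug_window[1], "engineered response leaves the drug epoch"
        f[start:stop] = baseline_F * (1 + drug_level)
    if kcl_frames:
        k0 = tl.kcl_window[0]
        f[k0:k0 + kcl_frames] = baseline_F * (1 + kcl_level)
    return f


def naive_call(
    raw: np.ndarray,
    tl: AcquisitionTimeline,
    params: ResponderParams = ResponderParams(),
) -> tuple[bool, bool]:
    """Per-frame predicate-loop oracle for the cell caller.

    Re-derives dF/F, both baselines and every predicate with explicit
    Python loops; returns (live, responder) labels only.
    """
    b0, b1 = tl.baseline_window
    base = [float(x) for x in raw[b0:b1]]
    m1 = sum(base) / len(base)
    s1 = (sum((x - m1) ** 2 for x in base) / len(base)) ** 0.5
    dff = [(x - m1) / m1 for x in raw]

    w0, w1 = tl.wash_window
    wash = dff[w0:w1]
    m2 = sum(wash) / len(wash)
    s2 = (sum((x - m2) ** 2 for x in wash) / len(wash)) ** 0.5

    k0, k1 = tl.kcl_window
    n_kcl = 0
    for t in range(k0, k1):
        if dff[t] >= m2 + params.k_sd * s2:
            n_kcl += 1
    live = n_kcl >= params.live_min_frames
    if not live:
        return False, False

    d0, d1 = tl.drug_window
    if params.responder_baseline == "baseline1":
        thr = params.k_sd * (s1 / m1)
    else:
        thr = m2 + params.k_sd * s2
    supra = [t for t in range(d0, d1) if dff[t] >= thr]
    if len(supra) < params.responder_min_frames:
        return True, False
    onset = supra[0]
    if (onset - d0) * tl.frame_period_s > params.onset_window_s:
        return True, False
    if max(dff[onset:d1]) < params.min_amplitude:
        return True, False
    return True, True


def naive_detect_aps(sweep, fs_hz, thr_mv_per_ms=10.0, min_interevent_ms=2.0):
    """Naive dV/dt crossing-scan oracle: explicit loops, forward difference."""
    v = list(map(float, sweep))
    dvdt = [(v[i + 1] - v[i]) * fs_hz / 1000.0 for i in range(len(v) - 1)]
    min_gap = int(round(min_interevent_ms * fs_hz / 1000.0))
    events = []
    last = None
    for i, d in enumerate(dvdt):
        crossing = d >= thr_mv_per_ms and (i == 0 or dvdt[i - 1] < thr_mv_per_ms)
        if not crossing:
            continue
        if last is not None and i - last < min_gap:
            continue
        last = i
        j = i
        while j + 1 < len(v) and v[j + 1] >= v[j]:
            j += 1
        events.append((i, j, v[j]))
    return events
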