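"""Synthetic calcium-imaging cohorts with machine-readable ground truth.

Each simulated ROI is dead, live-but-non-responding, or a drug
responder.  Live cells carry a large sustained transient during the
terminal KCl epoch; responders additionally carry a drug-epoch response
built from one of four archetype shapes (slow, intermediate or rapidly
decaying single transients, or an oscillatory train) riding on a smooth
pedestal.  The pedestal guarantees, with a configurable safety margin,
that every truth-labelled responder satisfies all three classification
criteria (suprathreshold duration, onset latency, amplitude) and that
no other cell does, so cohorts serve as exact end-to-end oracles for
the responder pipeline.

All drug-epoch signal is tapered to zero before the wash window so the
second (wash) baseline stays uncontaminated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import pandas as pd

from ..calcium import ResponderParams
from ..timeline import AcquisitionTimeline

ARCHETYPES = ("slow", "intermediate", "rapid", "oscillatory")

#: decay time constants (s) of the single-transient archetypes
DECAY_TAU_S = {"slow": 60.0, "intermediate": 20.0, "rapid": 5.0}
#: oscillation period (s) of the oscillatory archetype
OSC_PERIOD_S = 15.0


@dataclass(frozen=True)
class CalciumSimConfig:
    """Cohort-level simulation settings.

    The default frame period of 1.5 s makes 80 frames span ~2 minutes,
    the relation the responder duration criterion is built on.  The
    epoch layout (baseline 120 s, compound 300 s, wash 120 s, KCl 60 s)
    follows the baseline -> drug -> wash -> KCl protocol ordering.
    """

    n_cells: int = 100
    frac_dead: float = 0.1
    frac_responders_among_live: float = 0.4
    archetype_mix: dict[str, float] = field(
        default_factory=lambda: {a: 0.25 for a in ARCHETYPES}
    )
    noise_sd: float = 0.01          # dF/F units
    frame_period_s: float = 1.5
    epoch_durations_s: tuple[float, float, float, float] = (120.0, 300.0, 120.0, 60.0)
    response_margin: float = 1.5    # multiplier on every classification threshold
    baseline_F: float = 100.0       # raw-fluorescence baseline level
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in [("frac_dead", self.frac_dead),
                        ("frac_responders_among_live", self.frac_responders_among_live)]:
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if set(self.archetype_mix) - set(ARCHETYPES):
            raise ValueError(f"unknown archetypes in mix: {set(self.archetype_mix) - set(ARCHETYPES)}")
        if abs(sum(self.archetype_mix.values()) - 1.0) > 1e-9:
            raise ValueError("archetype_mix weights must sum to 1")
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")
        if self.response_margin < 1.0:
            raise ValueError("response_margin must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def timeline(self) -> AcquisitionTimeline:
        return AcquisitionTimeline.from_epoch_durations(
            self.frame_period_s, self.epoch_durations_s
        )


def gen_transient(
    archetype: str,
    amplitude: float,
    onset_frame: int,
    timeline: AcquisitionTimeline,
    *,
    n_frames: int | None = None,
) -> np.ndarray:
    """One archetype-shaped dF/F transient on an otherwise-zero trace.

    Single-transient archetypes rise linearly over two frames to exactly
    ``amplitude`` and then decay exponentially with the archetype's time
    constant.  The oscillatory archetype is a train of four rapid bumps
    spaced one oscillation period apart with gently declining amplitudes,
    the first peaking at exactly ``amplitude``.
    """
    if archetype not in ARCHETYPES:
        raise ValueError(f"unknown archetype {archetype!r}; expected one of {ARCHETYPES}")
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    n = timeline.n_frames if n_frames is None else n_frames
    fp = timeline.frame_period_s
    out = np.zeros(n)

    def bump(start: int, amp: float, tau_s: float, rise_frames: int = 2) -> None:
        peak = start + rise_frames
        if peak >= n:
            return
        for i in range(rise_frames + 1):
            if start + i < n:
                out[start + i] = max(out[start + i], amp * i / rise_frames)
        t = np.arange(1, n - peak) * fp
        out[peak + 1:] = np.maximum(out[peak + 1:], amp * np.exp(-t / tau_s))

    if archetype == "oscillatory":
        period_frames = max(2, int(round(OSC_PERIOD_S / fp)))
        for j in range(4):
            bump(onset_frame + j * period_frames, amplitude * (1.0 - 0.1 * j),
                 tau_s=OSC_PERIOD_S / 5, rise_frames=1)
    else:
        bump(onset_frame, amplitude, DECAY_TAU_S[archetype])
    return out


def _taper_to_zero(signal: np.ndarray, stop: int, taper_frames: int = 5) -> None:
    """Force ``signal`` smoothly to zero at frame ``stop`` (in place)."""
    lo = max(0, stop - taper_frames)
    ramp = np.linspace(1.0, 0.0, stop - lo, endpoint=False)
    signal[lo:stop] *= ramp
    signal[stop:] = 0.0


def gen_calcium_cohort(
    config: CalciumSimConfig,
    params: ResponderParams = ResponderParams(),
) -> tuple[pd.DataFrame, AcquisitionTimeline, pd.DataFrame]:
    """Simulate one cohort of raw-fluorescence traces.

    Returns
    -------
    trace table
        Long format (``roi_id``, ``frame``, ``raw_F``).
    timeline
        The cohort's :class:`AcquisitionTimeline`.
    truth table
        One row per ROI: ``roi_id``, ``true_class`` in
        {dead, non-responder, responder}, and for responders the
        archetype, onset frame and peak amplitude.
    """
    if config.n_cells <= 0:
        raise ValueError("empty cohort: n_cells must be positive")
    rng = np.random.default_rng(config.seed)
    tl = config.timeline()
    fp = tl.frame_period_s
    n_frames = tl.n_frames
    margin = config.response_margin

    n_dead = int(round(config.frac_dead * config.n_cells))
    n_live = config.n_cells - n_dead
    n_resp = int(round(config.frac_responders_among_live * n_live))

    classes = (["responder"] * n_resp
               + ["non-responder"] * (n_live - n_resp)
               + ["dead"] * n_dead)
    rng.shuffle(classes)

    arch_names = list(config.archetype_mix)
    arch_w = np.array([config.archetype_mix[a] for a in arch_names])

    d0, d1 = tl.drug_window
    k0, k1 = tl.kcl_window

    # responder pedestal: tall enough that every pedestal frame clears the
    # k_sd*noise threshold AND the 10% amplitude floor by the margin, long
    # enough that the duration criterion is met by the margin even after
    # noise; taper keeps the wash clean.
    ped_height = margin * (params.k_sd * config.noise_sd + params.min_amplitude)
    ped_frames = int(math.ceil(margin * params.responder_min_frames)) + 6
    drug_len = d1 - d0
    if ped_frames + 8 > drug_len:
        raise ValueError(
            f"drug epoch of {drug_len} frames too short for a margin-{margin} "
            f"responder pedestal of {ped_frames} frames"
        )
    max_onset_by_window = int(params.onset_window_s / (margin * fp))
    max_onset = min(max_onset_by_window, drug_len - ped_frames - 6)
    if max_onset < 2:
        raise ValueError("no feasible responder onset window under this configuration")

    # KCl transient for live cells: sustained plateau covering well more
    # than margin * live_min_frames frames.
    kcl_len = k1 - k0
    kcl_frames_needed = int(math.ceil(margin * params.live_min_frames)) + 2
    if kcl_frames_needed > kcl_len - 2:
        raise ValueError("KCl epoch too short for the requested live-cell margin")

    traces = np.empty((config.n_cells, n_frames))
    truth_rows = []
    for i, cls in enumerate(classes):
        signal = np.zeros(n_frames)
        arch = None
        onset = None
        amp = None
        if cls != "dead":
            kcl_amp = rng.uniform(0.8, 1.5)
            rise = min(2, kcl_len - kcl_frames_needed)
            plateau_start = k0 + rise
            signal[k0:plateau_start] = kcl_amp * np.linspace(0, 1, rise, endpoint=False)
            signal[plateau_start:k1 - 1] = kcl_amp
        if cls == "responder":
            arch = arch_names[rng.choice(len(arch_names), p=arch_w)]
            onset = int(rng.integers(2, max_onset + 1))
            amp = float(rng.uniform(0.3, 0.8))
            drug_sig = np.zeros(n_frames)
            ped = np.zeros(n_frames)
            ramp = min(2, ped_frames)
            ped[d0 + onset: d0 + onset + ramp] = ped_height * np.linspace(0, 1, ramp, endpoint=False)
            ped[d0 + onset + ramp: d0 + onset + ped_frames] = ped_height
            drug_sig += ped
            drug_sig += gen_transient(arch, amp, d0 + onset, tl)
            _taper_to_zero(drug_sig, d1)
            signal += drug_sig
            amp = float(drug_sig.max())
        noise = rng.normal(0.0, config.noise_sd, n_frames)
        traces[i] = config.baseline_F * (1.0 + signal + noise)
        truth_rows.append(dict(roi_id=i, true_class=cls, archetype=arch,
                               onset_frame=None if onset is None else d0 + onset,
                               amplitude=amp))

    table = pd.DataFrame({
        "roi_id": np.repeat(np.arange(config.n_cells), n_frames),
        "frame": np.tile(np.arange(n_frames), config.n_cells),
        "raw_F": traces.ravel(),
    })
    truth = pd.DataFrame(truth_rows)
    return table, tl, truth
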