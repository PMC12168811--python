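"""Current-clamp recording simulator.

An adaptive exponential integrate-and-fire (AdEx) neuron integrated
with fixed-step Euler provides unambiguous ground truth for the
electrophysiology feature extractor: every reset event is a spike by
construction, so rheobase and per-sweep spike counts are known exactly.
The dynamics are deterministic; the configured ``noise_sd_mV`` is added
to the rendered trace as measurement noise afterwards.

Membrane equation (mV, pA, nS, pF, ms)::

    C dV/dt = -gL (V - EL) + gL dT exp((V - VT)/dT) + I - w
    tau_w dw/dt = a (V - EL) - w

with reset V -> V_reset, w -> w + b when V crosses the numerical cutoff
VT + 5 dT.  Because the integrate-and-fire upswing carries no biological
waveform, a stereotyped 2 ms triangular spike to +30 mV is pasted onto
the trace at each reset event; this is a rendering convention that gives
the dV/dt detector realistic work.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ..recording import SweepProtocol, SweepRecording

SPIKE_RENDER_PEAK_MV = 30.0
SPIKE_RENDER_MS = 2.0


class SimulationError(RuntimeError):
    """Integration left the physically plausible voltage range."""


@dataclass(frozen=True)
class NeuronSimConfig:
    leak_reversal_mV: float = -65.0
    leak_conductance_nS: float = 10.0
    capacitance_pF: float = 100.0
    spike_threshold_mV: float = -50.0   # AdEx VT
    slope_factor_mV: float = 2.0        # AdEx dT
    a_nS: float = 2.0
    b_pA: float = 60.0
    tau_w_ms: float = 120.0
    reset_mV: float = -55.0
    noise_sd_mV: float = 0.0
    sampling_rate_Hz: float = 20000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_Hz < 10000:
            raise ValueError("sampling_rate_Hz must be at least 10 kHz")
        if self.capacitance_pF <= 0:
            raise ValueError("capacitance_pF must be positive")
        if self.noise_sd_mV < 0:
            raise ValueError("noise_sd_mV must be non-negative")

    @property
    def cutoff_mV(self) -> float:
        """Numerical spike cutoff: VT + 5 dT."""
        return self.spike_threshold_mV + 5.0 * self.slope_factor_mV

    def holding_current_pA(self, v_hold_mV: float) -> float:
        """Steady-state bias current that holds the neuron at ``v_hold_mV``."""
        gl, el = self.leak_conductance_nS, self.leak_reversal_mV
        dt_mv, vt = self.slope_factor_mV, self.spike_threshold_mV
        return (gl * (v_hold_mV - el)
                - gl * dt_mv * np.exp((v_hold_mV - vt) / dt_mv)
                + self.a_nS * (v_hold_mV - el))


def _integrate(
    config: NeuronSimConfig,
    current_pA: np.ndarray,   # (n_sweeps, n_samples) injected current
    v0_mV: np.ndarray,        # (n_sweeps,) initial voltage
) -> tuple[np.ndarray, list[list[int]]]:
    """Euler-integrate all sweeps in lockstep; returns traces + reset indices."""
    n_sweeps, n_samples = current_pA.shape
    dt = 1000.0 / config.sampling_rate_Hz  # ms
    gl, el = config.leak_conductance_nS, config.leak_reversal_mV
    d_mv, vt = config.slope_factor_mV, config.spike_threshold_mV
    c, a, b, tw = (config.capacitance_pF, config.a_nS, config.b_pA, config.tau_w_ms)
    vcut = config.cutoff_mV

    v = v0_mV.astype(float).copy()
    w = a * (v - el)
    out = np.empty((n_sweeps, n_samples))
    resets: list[list[int]] = [[] for _ in range(n_sweeps)]
    for t in range(n_samples):
        out[:, t] = v
        exp_arg = np.minimum((v - vt) / d_mv, 20.0)  # guard against overflow
        dv = dt / c * (-gl * (v - el) + gl * d_mv * np.exp(exp_arg)
                       + current_pA[:, t] - w)
        dw = dt / tw * (a * (v - el) - w)
        v = v + dv
        w = w + dw
        fired = v >= vcut
        if fired.any():
            for i in np.flatnonzero(fired):
                resets[i].append(t + 1)
            v[fired] = config.reset_mV
            w[fired] += b
        bad = np.abs(v) > 200.0
        if bad.any():
            raise SimulationError(
                f"membrane potential left +/-200 mV at sample {t} "
                f"(sweeps {np.flatnonzero(bad).tolist()})"
            )
    return out, resets


def _render_spikes(trace: np.ndarray, resets: list[int], fs_hz: float) -> None:
    """Paste the stereotyped triangular spike at each reset event (in place)."""
    n_half = max(1, int(round(fs_hz * SPIKE_RENDER_MS / 2 / 1000.0)))
    n = trace.size
    for r in resets:
        start = max(0, r - 1)
        v_base = trace[start]
        stop = min(n - 1, start + 2 * n_half)
        # fall rejoins the post-reset model trace so the paste boundary is
        # continuous and cannot create a spurious dV/dt crossing
        v_end = trace[stop]
        up = np.linspace(v_base, SPIKE_RENDER_PEAK_MV, n_half + 1)
        down = np.linspace(SPIKE_RENDER_PEAK_MV, v_end, n_half + 1)[1:]
        wave = np.concatenate([up, down])
        trace[start:stop + 1] = wave[: stop + 1 - start]


def oracle_spike_counts(
    config: NeuronSimConfig,
    protocol: SweepProtocol,
    *,
    pre_s: float = 0.25,
    post_s: float = 0.25,
) -> list[int]:
    """Brute-force ground truth: noise-free re-simulation, counting reset
    events inside each sweep's step window."""
    cfg = replace(config, noise_sd_mV=0.0)
    _, resets, step0, step1 = _simulate_sweeps(cfg, protocol, pre_s=pre_s, post_s=post_s)
    return [sum(step0 <= r < step1 for r in rs) for rs in resets]


def oracle_rheobase(config: NeuronSimConfig, protocol: SweepProtocol) -> float | None:
    """Smallest protocol amplitude with at least one reset event."""
    counts = oracle_spike_counts(config, protocol)
    for amp, c in zip(protocol.amplitudes_pA, counts):
        if c > 0:
            return float(amp)
    return None


def _simulate_sweeps(config, protocol, *, pre_s, post_s, v_hold_mV=None):
    fs = config.sampling_rate_Hz
    n_pre = int(round(pre_s * fs))
    n_step = int(round(protocol.step_duration_s * fs))
    n_post = int(round(post_s * fs))
    n = n_pre + n_step + n_post
    amps = np.asarray(protocol.amplitudes_pA, dtype=float)
    current = np.zeros((amps.size, n))
    current[:, n_pre:n_pre + n_step] = amps[:, None]
    if v_hold_mV is not None:
        current += config.holding_current_pA(v_hold_mV)
        v0 = np.full(amps.size, float(v_hold_mV))
    else:
        v0 = np.full(amps.size, config.leak_reversal_mV)
    traces, resets = _integrate(config, current, v0)
    return traces, resets, n_pre, n_pre + n_step


def gen_current_clamp(
    config: NeuronSimConfig,
    protocol: SweepProtocol | None = None,
    *,
    pre_s: float = 0.25,
    post_s: float = 0.25,
    gapfree_s: float | None = None,
) -> tuple[SweepRecording, pd.DataFrame]:
    """Simulate one cell's step-protocol recording (plus optional gap-free
    segment) and its ground truth.

    The truth table has one row per sweep (amplitude, oracle spike count)
    and the recording carries resting potential and rheobase truth in its
    metadata; a protocol in ``held_minus75`` mode is simulated with the
    steady-state bias current that holds the model at -75 mV.
    """
    protocol = protocol or SweepProtocol()
    if np.any(np.diff(protocol.amplitudes_pA) <= 0):
        raise ValueError("protocol amplitudes must be strictly ascending")
    v_hold = -75.0 if protocol.holding_mode == "held_minus75" else None
    traces, resets, step0, step1 = _simulate_sweeps(
        config, protocol, pre_s=pre_s, post_s=post_s, v_hold_mV=v_hold
    )
    for tr, rs in zip(traces, resets):
        _render_spikes(tr, rs, config.sampling_rate_Hz)
    rng = np.random.default_rng(config.seed)
    if config.noise_sd_mV > 0:
        traces = traces + rng.normal(0.0, config.noise_sd_mV, traces.shape)

    gapfree = None
    gapfree_spikes = None
    if gapfree_s is not None:
        n = int(round(gapfree_s * config.sampling_rate_Hz))
        current = np.zeros((1, n))
        v0 = np.full(1, config.leak_reversal_mV)
        gtrace, gresets = _integrate(config, current, v0)
        _render_spikes(gtrace[0], gresets[0], config.sampling_rate_Hz)
        if config.noise_sd_mV > 0:
            gtrace = gtrace + rng.normal(0.0, config.noise_sd_mV, gtrace.shape)
        gapfree = gtrace[0]
        gapfree_spikes = len(gresets[0])

    counts = [sum(step0 <= r < step1 for r in rs) for rs in resets]
    rheo = None
    for amp, c in zip(protocol.amplitudes_pA, counts):
        if c > 0:
            rheo = float(amp)
            break
    truth = pd.DataFrame({
        "amplitude_pA": np.asarray(protocol.amplitudes_pA, dtype=float),
        "n_spikes": counts,
    })
    truth.attrs["rmp_mV"] = config.leak_reversal_mV
    truth.attrs["rheobase_pA"] = rheo
    truth.attrs["gapfree_n_spikes"] = gapfree_spikes
    rec = SweepRecording(
        sweeps=traces,
        sampling_rate_Hz=config.sampling_rate_Hz,
        protocol=protocol,
        gapfree=gapfree,
    )
    return rec, truth
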