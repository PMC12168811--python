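"""Tests of the current-clamp feature battery."""

import numpy as np
import pytest

from sensikit.ephys import (
    APDetectionParams,
    ExcitabilityProfile,
    apply_exclusions,
    classify_firing,
    correct_ljp,
    detect_aps,
    extract_cell_features,
    measure_rheobase,
    measure_rmp,
    waveform_features,
)
from sensikit.recording import SweepProtocol, SweepRecording
from sensikit.synthgen import NeuronSimConfig, gen_current_clamp, oracle_spike_counts

from conftest import naive_detect_aps

FS = 20000.0


def small_protocol(**kw):
    kw.setdefault("amplitudes_pA", np.arange(-50.0, 401.0, 50.0))
    return SweepProtocol(**kw)


def make_recording(sweeps, protocol=None, fs=FS, **kw):
    protocol = protocol or SweepProtocol(
        amplitudes_pA=np.arange(0.0, 25.0 * len(sweeps), 25.0) + 25.0)
    return SweepRecording(np.asarray(sweeps, float), fs, protocol, **kw)


def triangular_spike_sweep(
    fs=FS, base=-75.0, peak=25.0, rise_ms=2.0, fall_ms=2.0,
    step_start_s=0.25, total_s=0.7, spike_delay_ms=20.0,
):
    """Piecewise-linear sweep: flat at ``base`` with one triangular AP."""
    n = int(total_s * fs)
    v = np.full(n, base)
    t0 = int((step_start_s + spike_delay_ms / 1000.0) * fs)
    up = int(rise_ms / 1000 * fs)
    down = int(fall_ms / 1000 * fs)
    v[t0:t0 + up + 1] = np.linspace(base, peak, up + 1)
    v[t0 + up:t0 + up + down + 1] = np.linspace(peak, base, down + 1)
    return v


class TestCorrectLjp:
    def test_shift_and_double_correction_guard(self):
        rec = make_recording([np.full(20000, -70.0)],
                             SweepProtocol(amplitudes_pA=np.array([25.0])))
        corr = correct_ljp(rec)
        assert np.allclose(corr.sweeps, -84.0)
        with pytest.raises(ValueError, match="twice"):
            correct_ljp(corr)

    def test_zero_ljp_is_identity(self):
        rec = make_recording([np.full(20000, -70.0)],
                             SweepProtocol(amplitudes_pA=np.array([25.0])),
                             ljp_mV=0.0)
        assert np.allclose(correct_ljp(rec).sweeps, -70.0)


class TestDetectAps:
    def test_flat_sweep_has_no_events(self):
        assert detect_aps(np.full(5000, -70.0), FS) == []

    def test_steady_suprathreshold_ramp_is_one_event(self):
        # slope 20 mV/ms -> single crossing at the first sample pair
        t = np.arange(2000) / FS * 1000.0
        events = detect_aps(-70.0 + 20.0 * t, FS)
        assert len(events) == 1 and events[0].onset_index == 0

    def test_counts_match_rendered_spikes(self):
        cfg = NeuronSimConfig()
        prot = small_protocol()
        rec, truth = gen_current_clamp(cfg, prot)
        i0, i1 = rec.step_window
        for sweep, expected in zip(rec.sweeps, truth["n_spikes"]):
            evs = [e for e in detect_aps(sweep, FS) if i0 <= e.onset_index < i1]
            assert len(evs) == expected

    def test_agrees_with_naive_scan_on_random_sweeps(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            # smooth random walk punctuated by fast jumps
            v = -70.0 + np.cumsum(rng.normal(0, 0.05, 4000))
            for j in rng.integers(100, 3900, size=rng.integers(0, 5)):
                v[j:j + 10] += np.linspace(0, 80, 10)
            mine = detect_aps(v, FS)
            oracle = naive_detect_aps(v, FS)
            assert [(e.onset_index, e.peak_index) for e in mine] == \
                   [(o[0], o[1]) for o in oracle]

    def test_count_non_increasing_in_threshold(self):
        rng = np.random.default_rng(9)
        v = -70.0 + np.cumsum(rng.normal(0, 0.3, 8000))
        counts = [len(detect_aps(v, FS, APDetectionParams(dvdt_threshold_mV_per_ms=thr)))
                  for thr in (5.0, 10.0, 20.0, 40.0)]
        assert all(b <= a for a, b in zip(counts, counts[1:]))


class TestMeasureRmp:
    def test_constant_pre_stimulus(self):
        v = np.full(int(0.7 * FS), -70.0)
        assert measure_rmp(v, FS, 0.25) == pytest.approx(-70.0)

    def test_simulator_leak_equilibrium(self):
        cfg = NeuronSimConfig(leak_reversal_mV=-65.0)
        rec, _ = gen_current_clamp(cfg, small_protocol())
        assert measure_rmp(rec.sweeps[0], FS, 0.25) == pytest.approx(-65.0, abs=0.01)

    def test_insufficient_pre_stimulus_raises(self):
        v = np.full(int(0.3 * FS), -70.0)
        with pytest.raises(ValueError, match="pre-stimulus"):
            measure_rmp(v, FS, 0.1)


class TestRheobase:
    def test_equals_oracle_on_simulated_cell(self):
        cfg = NeuronSimConfig()
        prot = small_protocol()
        rec, truth = gen_current_clamp(cfg, prot)
        assert measure_rheobase(rec) == truth.attrs["rheobase_pA"]

    def test_none_when_no_sweep_fires(self):
        cfg = NeuronSimConfig(spike_threshold_mV=500.0)
        rec, _ = gen_current_clamp(cfg, small_protocol())
        assert measure_rheobase(rec) is None

    def test_exhaustive_min_over_firing_sweeps(self):
        cfg = NeuronSimConfig()
        prot = small_protocol()
        rec, _ = gen_current_clamp(cfg, prot)
        i0, i1 = rec.step_window
        firing = [amp for amp, sweep in zip(prot.amplitudes_pA, rec.sweeps)
                  if any(i0 <= e.onset_index < i1 for e in detect_aps(sweep, FS))]
        assert measure_rheobase(rec) == min(firing)
        below = [amp for amp in prot.amplitudes_pA if amp < min(firing)]
        for amp, sweep in zip(prot.amplitudes_pA, rec.sweeps):
            if amp in below:
                assert not [e for e in detect_aps(sweep, FS)
                            if i0 <= e.onset_index < i1]


class TestWaveformFeatures:
    def test_triangular_spike_geometry(self):
        v = triangular_spike_sweep()
        rec = make_recording([v], SweepProtocol(amplitudes_pA=np.array([100.0])))
        wf = waveform_features(rec)
        assert wf.peak_amplitude_mV == pytest.approx(100.0, abs=0.1)
        assert wf.half_width_ms == pytest.approx(2.0, abs=0.01)
        assert wf.time_to_peak_ms == pytest.approx(22.0, abs=0.1)

    def test_threshold_at_first_dvdt_crossing(self):
        # two-segment rise: 5 mV/ms from -75 to -45, then 50 mV/ms upward;
        # the 10 mV/ms crossing happens where Vm = -45
        fs = FS
        n = int(0.7 * fs)
        v = np.full(n, -75.0)
        t0 = int(0.27 * fs)
        seg1 = int(6.0 / 1000 * fs)  # 30 mV at 5 mV/ms
        seg2 = int(1.4 / 1000 * fs)  # 70 mV at 50 mV/ms
        v[t0:t0 + seg1] = -75.0 + 5.0 * np.arange(seg1) / fs * 1000.0
        v[t0 + seg1:t0 + seg1 + seg2] = -45.0 + 50.0 * np.arange(seg2) / fs * 1000.0
        fall = int(2.0 / 1000 * fs)
        peak = v[t0 + seg1 + seg2 - 1]
        v[t0 + seg1 + seg2:t0 + seg1 + seg2 + fall] = np.linspace(peak, -75.0, fall)
        rec = make_recording([v], SweepProtocol(amplitudes_pA=np.array([100.0])))
        wf = waveform_features(rec)
        assert wf.threshold_mV == pytest.approx(-45.0, abs=0.5)

    def test_fahp_is_window_minimum(self):
        cfg = NeuronSimConfig()
        prot = small_protocol(holding_mode="held_minus75")
        rec, _ = gen_current_clamp(cfg, prot)
        wf = waveform_features(rec)
        i0, i1 = rec.step_window
        per_sweep = []
        for sweep in rec.sweeps:
            evs = [e for e in detect_aps(sweep, FS) if i0 <= e.onset_index < i1]
            per_sweep.append(evs)
        idx = next(i for i, evs in enumerate(per_sweep) if evs)
        evs = per_sweep[idx]
        end = evs[1].onset_index if len(evs) > 1 else i1
        expected = min(rec.sweeps[idx][evs[0].peak_index:end])
        assert wf.fahp_mV == pytest.approx(expected)

    def test_no_ap_raises(self):
        rec = make_recording([np.full(int(0.7 * FS), -75.0)],
                             SweepProtocol(amplitudes_pA=np.array([100.0])))
        with pytest.raises(ValueError, match="no action potential"):
            waveform_features(rec)

    def test_time_dilation_scales_in_ms(self):
        """Resampling 2x leaves half-width and time-to-peak identical in ms."""
        v1 = triangular_spike_sweep(fs=FS)
        v2 = triangular_spike_sweep(fs=2 * FS)
        r1 = make_recording([v1], SweepProtocol(amplitudes_pA=np.array([100.0])), fs=FS)
        r2 = make_recording([v2], SweepProtocol(amplitudes_pA=np.array([100.0])), fs=2 * FS)
        w1, w2 = waveform_features(r1), waveform_features(r2)
        assert w1.half_width_ms == pytest.approx(w2.half_width_ms, abs=0.05)
        assert w1.time_to_peak_ms == pytest.approx(w2.time_to_peak_ms, abs=0.05)

    def test_ljp_shifts_voltages_not_durations(self):
        cfg = NeuronSimConfig()
        prot = small_protocol(holding_mode="held_minus75")
        rec, _ = gen_current_clamp(cfg, prot)
        w0 = waveform_features(rec)
        w1 = waveform_features(correct_ljp(rec))
        assert w1.threshold_mV == pytest.approx(w0.threshold_mV - 14.0, abs=1e-9)
        assert w1.fahp_mV == pytest.approx(w0.fahp_mV - 14.0, abs=1e-9)
        assert w1.mahp_mV == pytest.approx(w0.mahp_mV - 14.0, abs=1e-9)
        assert w1.half_width_ms == pytest.approx(w0.half_width_ms, abs=1e-9)
        assert w1.time_to_peak_ms == pytest.approx(w0.time_to_peak_ms, abs=1e-9)
        assert w1.peak_amplitude_mV == pytest.approx(w0.peak_amplitude_mV, abs=1e-9)


class TestClassifyFiring:
    def test_spontaneous_definition_zero_vs_one_ap(self):
        cfg_quiet = NeuronSimConfig()
        rec, _ = gen_current_clamp(cfg_quiet, small_protocol(), gapfree_s=1.0)
        assert classify_firing(rec)["spontaneous"] is False
        cfg_tonic = NeuronSimConfig(leak_reversal_mV=-45.0)
        rec2, truth2 = gen_current_clamp(cfg_tonic, small_protocol(), gapfree_s=1.0)
        assert truth2.attrs["gapfree_n_spikes"] >= 1
        assert classify_firing(rec2)["spontaneous"] is True

    def test_missing_gapfree_reports_unknown(self):
        rec, _ = gen_current_clamp(NeuronSimConfig(), small_protocol())
        assert classify_firing(rec)["spontaneous"] is None

    def test_single_vs_multiple_pattern(self):
        base = np.full(int(0.7 * FS), -70.0)
        flat = base.copy()
        one = triangular_spike_sweep(base=-70.0)
        prot = SweepProtocol(amplitudes_pA=np.arange(25.0, 25.0 * 6, 25.0))
        rec = make_recording([flat, flat, one, one, one], prot)
        out = classify_firing(rec)
        assert out["firing_pattern"] == "single" and out["max_aps"] == 1
        assert out["fi_counts"] == [0, 0, 1, 1, 1]

    def test_fi_counts_match_simulator_truth(self):
        cfg = NeuronSimConfig()
        prot = small_protocol()
        rec, truth = gen_current_clamp(cfg, prot)
        out = classify_firing(rec)
        assert out["fi_counts"] == truth["n_spikes"].tolist()
        assert out["fi_counts"] == oracle_spike_counts(cfg, prot)


class TestExclusions:
    def _profile(self, rmp, rheo):
        return ExcitabilityProfile(rmp_mV=rmp, rheobase_pA=rheo, spontaneous=False,
                                   firing_pattern="single", fi_counts=[0, 1],
                                   max_aps=1)

    def test_depolarised_rmp_excluded(self):
        d = apply_exclusions(self._profile(-35.0, 150.0))
        assert d.excluded and d.reason == "depolarised RMP"

    def test_non_firing_excluded(self):
        d = apply_exclusions(self._profile(-60.0, None))
        assert d.excluded and d.reason == "non-firing"

    def test_healthy_cell_included(self):
        d = apply_exclusions(self._profile(-60.0, 200.0))
        assert not d.excluded and d.reason is None

    def test_feature_table_flags_non_firing_cell(self):
        cfg = NeuronSimConfig(spike_threshold_mV=500.0)
        rec, _ = gen_current_clamp(cfg, small_protocol())
        row = extract_cell_features(rec).iloc[0]
        assert row["excluded"] and row["reason"] == "non-firing"


class TestParameterRecovery:
    def test_random_configs_recover_rmp_and_rheobase(self):
        """Noise-free simulated cells: RMP within 1 mV of the configured
        leak reversal; measured rheobase equals the re-simulation oracle."""
        rng = np.random.default_rng(17)
        prot = small_protocol()
        for _ in range(8):
            cfg = NeuronSimConfig(
                leak_reversal_mV=float(rng.uniform(-75, -60)),
                leak_conductance_nS=float(rng.uniform(6, 14)),
                capacitance_pF=float(rng.uniform(70, 150)),
                spike_threshold_mV=float(rng.uniform(-52, -44)),
                sampling_rate_Hz=10000.0,
                seed=int(rng.integers(0, 2**31)),
            )
            rec, truth = gen_current_clamp(cfg, prot)
            rmp = measure_rmp(rec.sweeps[0], cfg.sampling_rate_Hz, prot.step_start_s)
            assert rmp == pytest.approx(cfg.leak_reversal_mV, abs=1.0)
            assert measure_rheobase(rec) == truth.attrs["rheobase_pA"]
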