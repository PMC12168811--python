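"""Sweep-family containers for current-clamp recordings."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np


def default_step_amplitudes() -> np.ndarray:
    """-50 pA to 850 pA in 25 pA increments."""
    return np.arange(-50.0, 851.0, 25.0)


@dataclass(frozen=True)
class SweepProtocol:
    """Current-step stimulation protocol.

    Defaults: 200 ms steps from -50 pA to 850 pA in 25 pA increments,
    delivered at 0.5 Hz, either from the cell's resting potential or
    while holding at -75 mV.
    """

    step_start_s: float = 0.25
    step_duration_s: float = 0.2
    amplitudes_pA: np.ndarray = field(default_factory=default_step_amplitudes)
    inter_sweep_rate_Hz: float = 0.5
    holding_mode: Literal["resting", "held_minus75"] = "resting"

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes_pA, dtype=float)
        object.__setattr__(self, "amplitudes_pA", amps)
        if amps.size == 0 or np.any(np.diff(amps) <= 0):
            raise ValueError("amplitudes_pA must be a non-empty strictly ascending list")
        if self.step_start_s < 0 or self.step_duration_s <= 0:
            raise ValueError("step window must be non-degenerate")

    def to_dict(self) -> dict:
        return dict(
            step_start_s=self.step_start_s,
            step_duration_s=self.step_duration_s,
            amplitudes_pA=self.amplitudes_pA.tolist(),
            inter_sweep_rate_Hz=self.inter_sweep_rate_Hz,
            holding_mode=self.holding_mode,
        )

    @classmethod
    def from_dict(cls, d: dict) -> "SweepProtocol":
        return cls(
            step_start_s=d["step_start_s"],
            step_duration_s=d["step_duration_s"],
            amplitudes_pA=np.asarray(d["amplitudes_pA"], dtype=float),
            inter_sweep_rate_Hz=d.get("inter_sweep_rate_Hz", 0.5),
            holding_mode=d.get("holding_mode", "resting"),
        )


@dataclass
class SweepRecording:
    """One cell's membrane-potential sweep family (mV).

    ``ljp_mV`` is the liquid junction potential; ``apply`` via
    :func:`sensikit.ephys.correct_ljp`, which flips ``ljp_corrected`` so
    the offset cannot be applied twice.
    """

    sweeps: np.ndarray                 # (n_sweeps, n_samples)
    sampling_rate_Hz: float
    protocol: SweepProtocol
    ljp_mV: float = -14.0
    ljp_corrected: bool = False
    gapfree: np.ndarray | None = None  # optional spontaneous segment

    def __post_init__(self) -> None:
        self.sweeps = np.asarray(self.sweeps, dtype=float)
        if self.sweeps.ndim != 2:
            raise ValueError("sweeps must be a (n_sweeps, n_samples) array")
        if self.sweeps.shape[0] != self.protocol.amplitudes_pA.size:
            raise ValueError("one sweep per protocol amplitude required")
        if self.sampling_rate_Hz <= 0:
            raise ValueError("sampling_rate_Hz must be positive")

    @property
    def step_window(self) -> tuple[int, int]:
        """Stimulus window as a half-open sample interval."""
        fs = self.sampling_rate_Hz
        i0 = int(round(self.protocol.step_start_s * fs))
        return i0, i0 + int(round(self.protocol.step_duration_s * fs))

    def save(self, path: str | Path) -> None:
        """Write as a compressed numeric archive plus embedded protocol JSON."""
        meta = dict(
            sampling_rate_Hz=self.sampling_rate_Hz,
            ljp_mV=self.ljp_mV,
            ljp_corrected=self.ljp_corrected,
            protocol=self.protocol.to_dict(),
        )
        arrays = dict(sweeps=self.sweeps, meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8))
        if self.gapfree is not None:
            arrays["gapfree"] = self.gapfree
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "SweepRecording":
        with np.load(path) as z:
            meta = json.loads(z["meta"].tobytes().decode())
            return cls(
                sweeps=z["sweeps"],
                sampling_rate_Hz=meta["sampling_rate_Hz"],
                protocol=SweepProtocol.from_dict(meta["protocol"]),
                ljp_mV=meta["ljp_mV"],
                ljp_corrected=meta["ljp_corrected"],
                gapfree=z["gapfree"] if "gapfree" in z.files else None,
            )
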