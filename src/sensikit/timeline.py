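"""Acquisition timeline for a calcium-imaging recording.

A recording is divided into four ordered epochs: a pre-compound baseline,
a drug (compound) epoch, a wash, and a terminal high-KCl depolarisation
used as the live-cell positive control.  All windows are 0-based,
half-open frame intervals ``[start, stop)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

FrameWindow = tuple[int, int]


@dataclass(frozen=True)
class AcquisitionTimeline:
    """Frame layout of one recording.

    Parameters
    ----------
    frame_period_s:
        Seconds between consecutive frames.
    baseline_window:
        Frames used for the first (raw-fluorescence) baseline.
    compound_frame:
        Frame index at which the compound is applied; the drug epoch runs
        from here to the start of the wash window.
    wash_window:
        Frames of the wash period just before KCl; the second baseline
        (in dF/F space) is computed here.
    kcl_window:
        Frames of the 50 mM KCl depolarisation epoch.
    """

    frame_period_s: float
    baseline_window: FrameWindow
    compound_frame: int
    wash_window: FrameWindow
    kcl_window: FrameWindow

    def __post_init__(self) -> None:
        if self.frame_period_s <= 0:
            raise ValueError("frame_period_s must be positive")
        b0, b1 = self.baseline_window
        w0, w1 = self.wash_window
        k0, k1 = self.kcl_window
        for lo, hi, name in [(b0, b1, "baseline"), (w0, w1, "wash"), (k0, k1, "kcl")]:
            if not (0 <= lo < hi):
                raise ValueError(f"{name}_window must be a non-empty interval, got {(lo, hi)}")
        if not (b1 <= self.compound_frame <= w0 and w1 <= k0):
            raise ValueError(
                "epochs must be ordered: baseline < compound <= wash < kcl, got "
                f"baseline={self.baseline_window}, compound={self.compound_frame}, "
                f"wash={self.wash_window}, kcl={self.kcl_window}"
            )

    @property
    def drug_window(self) -> FrameWindow:
        """Drug epoch: from compound application to the start of the wash."""
        return (self.compound_frame, self.wash_window[0])

    @property
    def n_frames(self) -> int:
        return self.kcl_window[1]

    def validate_length(self, n: int) -> None:
        if n < self.n_frames:
            raise ValueError(f"trace has {n} frames but timeline needs {self.n_frames}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AcquisitionTimeline":
        d = json.loads(Path(path).read_text())
        return cls(
            frame_period_s=d["frame_period_s"],
            baseline_window=tuple(d["baseline_window"]),
            compound_frame=d["compound_frame"],
            wash_window=tuple(d["wash_window"]),
            kcl_window=tuple(d["kcl_window"]),
        )

    @classmethod
    def from_epoch_durations(
        cls,
        frame_period_s: float,
        epoch_durations_s: tuple[float, float, float, float],
    ) -> "AcquisitionTimeline":
        """Build a timeline from per-epoch durations in seconds.

        Epochs are (baseline, drug, wash, kcl); each is rounded to a whole
        number of frames.
        """
        n = [int(round(d / frame_period_s)) for d in epoch_durations_s]
        if any(x <= 0 for x in n):
            raise ValueError("every epoch must span at least one frame")
        b, d, w, k = n
        return cls(
            frame_period_s=frame_period_s,
            baseline_window=(0, b),
            compound_frame=b,
            wash_window=(b + d, b + d + w),
            kcl_window=(b + d + w, b + d + w + k),
        )
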