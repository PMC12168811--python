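"""Synthetic multi-channel immunofluorescence slides with ground truth.

Renders a DAPI channel (all nuclei plus sub-threshold debris specks) and
two marker channels (signal only on double-positive nuclei) as disks on
a noisy background.  Optional merged nucleus pairs are rendered as a
single connected component whose area falls in the 2-nucleus band of
the area-to-count rule, and debris specks fall below the exclusion
threshold, so the truth table directly encodes the rule-corrected
counts the purity pipeline must recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: default area-to-count rule boundaries (um^2); see imagequant.AreaRule
_EXCLUDE_UM2 = 30.0

_FOREGROUND = 200.0
_BACKGROUND = 10.0
_NOISE_SD = 3.0


@dataclass(frozen=True)
class ImageSimConfig:
    image_size_px: int = 512
    pixel_size_um: float = 0.62        # 20x objective
    n_nuclei: int = 50                 # singleton nuclei
    purity_fraction: float = 0.9       # double-positive fraction of singletons
    n_merged_pairs: int = 0            # pairs rendered as one component
    n_debris: int = 0                  # sub-threshold specks (DAPI only)
    nucleus_radius_um: float = 5.0
    debris_radius_um: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity_fraction <= 1.0):
            raise ValueError("purity_fraction must lie in [0, 1]")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        area = math.pi * self.nucleus_radius_um ** 2
        if area <= _EXCLUDE_UM2:
            raise ValueError(
                f"nucleus area {area:.1f} um^2 does not exceed the "
                f"{_EXCLUDE_UM2:.0f} um^2 exclusion threshold"
            )
        if math.pi * self.debris_radius_um ** 2 >= _EXCLUDE_UM2:
            raise ValueError("debris must be smaller than the exclusion threshold")
        if min(self.n_nuclei, self.n_merged_pairs, self.n_debris) < 0:
            raise ValueError("object counts must be non-negative")


def _draw_disk(canvas: np.ndarray, cy: float, cx: float, r_px: float) -> None:
    h, w = canvas.shape
    y0, y1 = max(0, int(cy - r_px) - 1), min(h, int(cy + r_px) + 2)
    x0, x1 = max(0, int(cx - r_px) - 1), min(w, int(cx + r_px) + 2)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    canvas[y0:y1, x0:x1] |= ((yy - cy) ** 2 + (xx - cx) ** 2) <= r_px ** 2


def _place_centers(rng, n: int, size: int, r_px: float, min_sep_px: float,
                   existing: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Rejection-sample n centers keeping min_sep_px from all placed objects."""
    centers = []
    margin = r_px + 2
    for _ in range(n):
        for _attempt in range(20000):
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            if all((cy - y) ** 2 + (cx - x) ** 2 >= min_sep_px ** 2
                   for y, x in existing + centers):
                centers.append((cy, cx))
                break
        else:
            raise RuntimeError("could not place objects without overlap; "
                               "reduce counts or enlarge the image")
    return centers


def gen_if_image(config: ImageSimConfig) -> tuple[np.ndarray, pd.DataFrame]:
    """Render one synthetic slide.

    Returns
    -------
    stack
        float array of shape (3, H, W): channel 0 DAPI, channels 1-2
        markers.
    truth
        One row per intended component: ``kind`` in
        {nucleus, merged_pair, debris}, ``n_nuclei`` the multiplicity the
        area rule must assign (1, 2 or 0), and ``double_positive``.
        Summing ``n_nuclei`` gives the intended DAPI count.
    """
    rng = np.random.default_rng(config.seed)
    size = config.image_size_px
    px = config.pixel_size_um
    r_n = config.nucleus_radius_um / px
    r_d = config.debris_radius_um / px
    # merged pairs: two disks at 1.7 r separation give a union area around
    # 1.93 * pi r^2, squarely inside the (130, 200] um^2 two-nucleus band
    pair_sep = 1.7 * r_n

    min_sep = 2 * r_n + pair_sep + 4
    placed: list[tuple[float, float]] = []
    nuc_centers = _place_centers(rng, config.n_nuclei, size, r_n, min_sep, placed)
    placed += nuc_centers
    pair_centers = _place_centers(rng, config.n_merged_pairs, size,
                                  r_n + pair_sep / 2, min_sep, placed)
    placed += pair_centers
    debris_centers = _place_centers(rng, config.n_debris, size, r_d, min_sep, placed)

    dapi = np.zeros((size, size), dtype=bool)
    m1 = np.zeros_like(dapi)
    m2 = np.zeros_like(dapi)

    n_dp = int(round(config.purity_fraction * config.n_nuclei))
    dp_flags = np.zeros(config.n_nuclei, dtype=bool)
    dp_flags[rng.choice(config.n_nuclei, size=n_dp, replace=False)] = True

    rows = []
    for (cy, cx), dp in zip(nuc_centers, dp_flags):
        _draw_disk(dapi, cy, cx, r_n)
        if dp:
            _draw_disk(m1, cy, cx, r_n)
            _draw_disk(m2, cy, cx, r_n)
        rows.append(dict(kind="nucleus", n_nuclei=1, double_positive=bool(dp)))

    for cy, cx in pair_centers:
        ang = rng.uniform(0, math.pi)
        dy, dx = (pair_sep / 2) * math.sin(ang), (pair_sep / 2) * math.cos(ang)
        for canvas in (dapi, m1, m2):  # merged pairs are double-positive
            _draw_disk(canvas, cy - dy, cx - dx, r_n)
            _draw_disk(canvas, cy + dy, cx + dx, r_n)
        rows.append(dict(kind="merged_pair", n_nuclei=2, double_positive=True))

    for cy, cx in debris_centers:
        _draw_disk(dapi, cy, cx, r_d)
        rows.append(dict(kind="debris", n_nuclei=0, double_positive=False))

    stack = np.empty((3, size, size))
    for c, mask in enumerate((dapi, m1, m2)):
        stack[c] = np.where(mask, _FOREGROUND, _BACKGROUND)
        stack[c] += rng.normal(0.0, _NOISE_SD, mask.shape)
    truth = pd.DataFrame(rows)
    truth.insert(0, "component_id", np.arange(len(truth)))
    return stack, truth
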