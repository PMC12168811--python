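"""Immunofluorescence purity quantification.

Reproduces the particle-counting workflow used to score the fraction
of nuclei double-positive for a neuronal and a sensory marker: maximum
intensity projection, per-channel binarisation, connected-component
counting of DAPI+ nuclei with an area-to-count correction (components
below 30 um^2 are debris and count 0; components above 130 um^2 count
as 2 joined nuclei and above 200 um^2 as 3), and pairwise colocalized
counting via the intersection of the channel masks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops

__all__ = [
    "AreaRule",
    "PurityResult",
    "max_project",
    "binarize",
    "count_nuclei",
    "coloc_count",
    "compute_purity",
]


@dataclass(frozen=True)
class AreaRule:
    """Area-to-nucleus-count mapping (um^2, strict inequalities)."""

    exclude_below_um2: float = 30.0
    two_above_um2: float = 130.0
    three_above_um2: float = 200.0

    def __post_init__(self) -> None:
        if not (0 < self.exclude_below_um2 < self.two_above_um2 < self.three_above_um2):
            raise ValueError("area rule must satisfy 0 < exclude < two_above < three_above")

    def contribution(self, area_um2: float) -> int:
        """Nuclei contributed by one connected component of the given area."""
        if area_um2 < self.exclude_below_um2:
            return 0
        if area_um2 > self.three_above_um2:
            return 3
        if area_um2 > self.two_above_um2:
            return 2
        return 1


@dataclass
class PurityResult:
    n_dapi: int
    n_double_positive: int
    purity_pct: float
    #: set when n_double_positive exceeds n_dapi after area correction
    inconsistent: bool = False


def max_project(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum intensity projection over the planes of a z-stack."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ValueError("z-stack must be a non-empty (Z, H, W) array")
    return zstack.max(axis=0)


def binarize(
    image: np.ndarray,
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: float | None = None,
) -> np.ndarray:
    """Binary mask ``image >= t`` with t from Otsu's method or supplied."""
    image = np.asarray(image, dtype=float)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires an explicit threshold")
        t = threshold
    elif method == "otsu":
        if np.ptp(image) == 0:
            raise ValueError("degenerate threshold: image is constant")
        t = threshold_otsu(image)
    else:
        raise ValueError(f"unknown binarisation method {method!r}")
    return image >= t


def count_nuclei(
    mask: np.ndarray,
    pixel_size_um: float,
    rule: AreaRule = AreaRule(),
) -> tuple[int, pd.DataFrame]:
    """Area-rule-corrected nucleus count of a binary mask.

    8-connected components are measured in um^2 and each contributes 0,
    1, 2 or 3 nuclei per the rule.  Returns the total and a
    per-component table (label, area_um2, n_nuclei).
    """
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    mask = np.asarray(mask, dtype=bool)
    lab = label(mask, connectivity=2)
    px_area = pixel_size_um ** 2
    rows = [
        dict(label=p.label, area_um2=p.area * px_area,
             n_nuclei=rule.contribution(p.area * px_area))
        for p in regionprops(lab)
    ]
    table = pd.DataFrame(rows, columns=["label", "area_um2", "n_nuclei"])
    return int(table["n_nuclei"].sum()) if len(table) else 0, table


def coloc_count(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    pixel_size_um: float,
    rule: AreaRule = AreaRule(),
) -> tuple[int, pd.DataFrame]:
    """Colocalized nucleus count: the two masks are intersected pixelwise
    and the result counted with the same area rule."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    return count_nuclei(mask_a & mask_b, pixel_size_um, rule)


def compute_purity(
    stack: np.ndarray,
    pixel_size_um: float,
    dapi_channel: int = 0,
    marker_channels: tuple[int, int] = (1, 2),
    rule: AreaRule = AreaRule(),
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: float | None = None,
) -> PurityResult:
    """Purity of a multi-channel slide: double-positive / DAPI+ nuclei.

    The stack is (C, H, W) — a projected multi-channel image — or
    (C, Z, H, W), in which case each channel is max-projected first.
    """
    stack = np.asarray(stack)
    if stack.ndim == 4:
        stack = np.stack([max_project(ch) for ch in stack])
    if stack.ndim != 3:
        raise ValueError("stack must be (C, H, W) or (C, Z, H, W)")
    dapi_mask = binarize(stack[dapi_channel], method, threshold)
    n_dapi, _ = count_nuclei(dapi_mask, pixel_size_um, rule)
    if n_dapi == 0:
        raise ValueError("no DAPI+ nuclei detected; purity undefined")
    m1 = binarize(stack[marker_channels[0]], method, threshold)
    m2 = binarize(stack[marker_channels[1]], method, threshold)
    n_dp, _ = coloc_count(m1, m2, pixel_size_um, rule)
    return PurityResult(
        n_dapi=n_dapi,
        n_double_positive=n_dp,
        purity_pct=100.0 * n_dp / n_dapi,
        inconsistent=n_dp > n_dapi,
    )
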