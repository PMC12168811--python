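"""Statistical battery for two-group sensitization comparisons.

* normality-gated two-group test: Shapiro-Wilk on each group at
  alpha = 0.05; both normal -> two-tailed unpaired t-test, otherwise
  two-tailed Mann-Whitney U
* exact Fisher test on 2x2 contingency tables (spontaneous activity,
  single vs multiple firing)
* Bonferroni family ledger over a parameter battery (14 parameters at
  family alpha 0.05 gives the displayed per-test threshold 0.003)
* literature synthesis of per-study control vs inflamed resting
  membrane potentials: effect-size binning, pooled Mann-Whitney,
  paired t, and rounded proportion summaries
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "FamilyLedger",
    "StudyExtractionRecord",
    "auto_compare",
    "fisher_exact_2x2",
    "bonferroni_ledger",
    "effect_bin",
    "literature_meta",
    "proportion_pct",
]

NORMALITY_ALPHA = 0.05
#: contiguous effect-size bin edges (mV) for the RMP literature synthesis;
#: the source legend's gapped bands (0-1, 2-6, 10+) are closed up
EFFECT_BIN_EDGES_MV = (1.5, 10.0)


@dataclass
class GroupComparison:
    parameter: str
    test_used: Literal["t_unpaired", "mann_whitney"]
    statistic: float
    p_value: float
    n_per_group: tuple[int, int]
    group_means: tuple[float, float]
    group_medians: tuple[float, float]
    normality_p: tuple[float, float]


def auto_compare(group_a: Sequence[float], group_b: Sequence[float],
                 parameter: str = "") -> GroupComparison:
    """Normality-gated two-tailed two-group comparison.

    Both groups Shapiro-Wilk normal at alpha 0.05 -> unpaired t-test;
    otherwise Mann-Whitney U (exact when both groups have n <= 12 and
    no ties, asymptotic with tie correction otherwise).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError(f"each group needs n >= 3, got {a.size} and {b.size}")
    pa = float(sps.shapiro(a).pvalue)
    pb = float(sps.shapiro(b).pvalue)
    if pa > NORMALITY_ALPHA and pb > NORMALITY_ALPHA:
        res = sps.ttest_ind(a, b, equal_var=True)
        test = "t_unpaired"
    else:
        pooled = np.concatenate([a, b])
        method = "exact" if (a.size <= 12 and b.size <= 12
                             and np.unique(pooled).size == pooled.size) else "asymptotic"
        res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
        test = "mann_whitney"
    return GroupComparison(
        parameter=parameter,
        test_used=test,
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_per_group=(int(a.size), int(b.size)),
        group_means=(float(a.mean()), float(b.mean())),
        group_medians=(float(np.median(a)), float(np.median(b))),
        normality_p=(pa, pb),
    )


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 count table.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose probability does not exceed the observed
    table's.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("degenerate table: every row and column margin must be positive")
    return float(sps.fisher_exact(t, alternative="two-sided").pvalue)


@dataclass
class FamilyLedger:
    family_size: int
    family_alpha: float
    per_test_threshold: float
    per_test_threshold_display: float  # truncated to 3 decimals
    p_values: dict[str, float]
    significant: dict[str, bool]


def bonferroni_ledger(p_values: dict[str, float] | Sequence[float],
                      family_alpha: float = 0.05) -> FamilyLedger:
    """Bonferroni correction over a family of tests.

    The per-test threshold is family_alpha / m; the displayed threshold
    truncates it to three decimal places (0.05 / 14 -> 0.003), but the
    significance flags compare against the untruncated value.
    """
    if not isinstance(p_values, dict):
        p_values = {f"param_{i + 1}": p for i, p in enumerate(p_values)}
    m = len(p_values)
    if m == 0:
        raise ValueError("empty family: at least one p-value required")
    thr = family_alpha / m
    display = math.floor(thr * 1000) / 1000
    flags = {k: (p < thr) for k, p in p_values.items()}
    return FamilyLedger(
        family_size=m,
        family_alpha=family_alpha,
        per_test_threshold=thr,
        per_test_threshold_display=display,
        p_values=dict(p_values),
        significant=flags,
    )


@dataclass(frozen=True)
class StudyExtractionRecord:
    """One literature study's control / inflamed RMP pair (mV)."""

    study_id: str
    rmp_ctrl_mV: float | None
    rmp_infl_mV: float | None
    #: optional per-parameter reported outcomes: name -> increase|decrease|no-change
    parameter_changes: dict[str, str] = field(default_factory=dict)


def effect_bin(effect_mV: float) -> str:
    """Bin an RMP shift magnitude: negligible < 1.5 <= moderate < 10 <= large."""
    mag = abs(effect_mV)
    if mag >= EFFECT_BIN_EDGES_MV[1]:
        return "large"
    if mag >= EFFECT_BIN_EDGES_MV[0]:
        return "moderate"
    return "negligible"


def proportion_pct(k: int, n: int) -> int:
    """Percentage of k out of n, rounded to the nearest integer percent."""
    if n <= 0:
        raise ValueError("n must be positive")
    return int(round(100.0 * k / n))


def literature_meta(records: Sequence[StudyExtractionRecord]) -> dict:
    """Synthesis of per-study control vs inflamed RMP values.

    Records missing either value are dropped (logged in the returned
    table).  Returns the per-study effect/bin table, the pooled
    two-sided Mann-Whitney p, the paired t p (None when the differences
    have zero variance), and the share of studies reporting an RMP
    increase.
    """
    rows = []
    for r in records:
        ok = r.rmp_ctrl_mV is not None and r.rmp_infl_mV is not None
        eff = (r.rmp_infl_mV - r.rmp_ctrl_mV) if ok else None
        rows.append(dict(
            study_id=r.study_id,
            rmp_ctrl_mV=r.rmp_ctrl_mV,
            rmp_infl_mV=r.rmp_infl_mV,
            effect_mV=eff,
            effect_bin=effect_bin(eff) if ok else None,
            dropped=not ok,
        ))
    table = pd.DataFrame(rows)
    used = table[~table["dropped"]]
    if len(used) < 2:
        raise ValueError("need at least two complete RMP pairs")
    ctrl = used["rmp_ctrl_mV"].to_numpy(dtype=float)
    infl = used["rmp_infl_mV"].to_numpy(dtype=float)
    mw = sps.mannwhitneyu(ctrl, infl, alternative="two-sided")
    diffs = infl - ctrl
    if np.allclose(diffs, diffs[0]):
        paired_p = 1.0 if np.allclose(diffs, 0.0) else None
    else:
        paired_p = float(sps.ttest_rel(infl, ctrl).pvalue)
    n_increase = int((diffs > 0).sum())
    return dict(
        table=table,
        pooled_mw_p=float(mw.pvalue),
        paired_t_p=paired_p,
        n_studies=int(len(used)),
        n_rmp_increase=n_increase,
        pct_rmp_increase=proportion_pct(n_increase, len(used)),
    )
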