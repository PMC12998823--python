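"""Subgroup interval comparison via the bias ratio, plus descriptive tests.

The bias ratio standardizes the difference between a test and a reference
limit by the reference interval's implied standard deviation,
``SD_RI = (UL0 - LL0)/3.92``; an absolute value at or above the threshold
(default 0.375) flags a significant limit difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats

from .prep import SubgroupKey

__all__ = [
    "DEFAULT_BR_THRESHOLD",
    "BiasRatioResult",
    "bias_ratio",
    "bias_ratio_limits",
    "compare_groups",
    "normality_check",
    "flag_string",
]

DEFAULT_BR_THRESHOLD = 0.375
_RI_WIDTH_IN_SD = 3.92  # central 95% of a normal spans 3.92 standard deviations


@dataclass
class BiasRatioResult:
    test_key: Optional[SubgroupKey]
    ref_key: Optional[SubgroupKey]
    sd_ri: float
    br_ll: float
    br_ul: float
    sig_ll: bool
    sig_ul: bool
    threshold: float = DEFAULT_BR_THRESHOLD

    def flags(self) -> str:
        return flag_string(self.sig_ll, self.sig_ul)


def flag_string(sig_ll: bool, sig_ul: bool) -> str:
    """Star-flag vocabulary: e.g. ``LL + UL*`` when only the upper limit differs."""
    return f"LL{'*' if sig_ll else ''} + UL{'*' if sig_ul else ''}"


def bias_ratio_limits(
    test_ll: float,
    test_ul: float,
    ref_ll: float,
    ref_ul: float,
    threshold: float = DEFAULT_BR_THRESHOLD,
    test_key: Optional[SubgroupKey] = None,
    ref_key: Optional[SubgroupKey] = None,
) -> BiasRatioResult:
    """Bias ratios of both limits from raw interval bounds."""
    if not ref_ll < ref_ul:
        raise ValueError("degenerate reference interval (LL0 >= UL0)")
    sd_ri = (ref_ul - ref_ll) / _RI_WIDTH_IN_SD
    br_ll = (test_ll - ref_ll) / sd_ri
    br_ul = (test_ul - ref_ul) / sd_ri
    return BiasRatioResult(
        test_key=test_key,
        ref_key=ref_key,
        sd_ri=sd_ri,
        br_ll=br_ll,
        br_ul=br_ul,
        sig_ll=abs(br_ll) >= threshold,
        sig_ul=abs(br_ul) >= threshold,
        threshold=threshold,
    )


def bias_ratio(test, ref, threshold: float = DEFAULT_BR_THRESHOLD) -> BiasRatioResult:
    """Bias ratios for a test-vs-reference pair of :class:`ReferenceInterval`.

    Both intervals must concern the same analyzer and analyte when subgroup
    keys are attached.
    """
    tk, rk = test.subgroup, ref.subgroup
    if tk is not None and rk is not None:
        if tk.analyte != rk.analyte:
            raise ValueError(f"analyte mismatch: {tk.analyte} vs {rk.analyte}")
        if tk.analyzer != rk.analyzer:
            raise ValueError(f"analyzer mismatch: {tk.analyzer} vs {rk.analyzer}")
    return bias_ratio_limits(test.ll, test.ul, ref.ll, ref.ul, threshold, tk, rk)


def compare_groups(a, b) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when the smaller group has at most 8 observations and
    there are no ties; otherwise the normal approximation with tie
    correction.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("compare_groups requires non-empty groups")
    combined = np.concatenate([a, b])
    has_ties = np.unique(combined).size < combined.size
    if min(a.size, b.size) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def normality_check(values, seed: int = 0) -> float:
    """Shapiro-Wilk p-value; inputs above 5000 are subsampled with the given
    seed.  Descriptive only -- never used to switch methods downstream."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise ValueError("Shapiro-Wilk requires at least 3 values")
    if arr.size > 5000:
        rng = np.random.default_rng(seed)
        arr = rng.choice(arr, size=5000, replace=False)
    return float(stats.shapiro(arr).pvalue)
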