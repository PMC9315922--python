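"""The pseudocounted (S+Rc)/Rnc ratio, ratio groups and mutation-count bins.

The ratio contrasts mutations unlikely to change B-cell-receptor structure
(silent + conservative replacements) against non-conservative replacements.
A pseudocount (0.05 for grouping; 0.5 inside the Cox log-ratio covariate)
keeps the ratio finite when a mutation type is absent:

    ratio     = (S + Rc + 0.05) / (Rnc + 0.05)
    log_ratio = ln((S + Rc + 0.5) / (Rnc + 0.5))

Sequences with ratio <= threshold (default 1.0) form the Low Ratio Group
(skewed toward structure-altering mutations), ratio > threshold the High
Ratio Group.  Zero-mutation sequences have no defined ratio and belong to
neither group.
"""

from __future__ import annotations

import enum
import logging
import math
import statistics
from dataclasses import dataclass

from .classify import MutationProfile

logger = logging.getLogger(__name__)


class RatioGroup(str, enum.Enum):
    LOW = "LOW"
    HIGH = "HIGH"
    UNDEFINED = "UNDEFINED"


class ThresholdMode(str, enum.Enum):
    FIXED = "fixed"
    MEDIAN = "median"


@dataclass
class RatioParams:
    group_pseudocount: float = 0.05
    cox_pseudocount: float = 0.5
    ratio_threshold: float = 1.0
    threshold_mode: ThresholdMode = ThresholdMode.FIXED

    def __post_init__(self) -> None:
        if self.group_pseudocount <= 0 or self.cox_pseudocount <= 0:
            raise ValueError("pseudocounts must be positive")
        if self.ratio_threshold <= 0:
            raise ValueError("ratio threshold must be positive")


@dataclass
class RatioResult:
    ratio: float | None
    log_ratio: float | None
    group: RatioGroup


def compute_ratio(
    profile: MutationProfile,
    params: RatioParams | None = None,
    threshold: float | None = None,
) -> RatioResult:
    """Pseudocounted ratio, Cox log-ratio covariate and group label.

    ``threshold`` overrides ``params.ratio_threshold`` (used when the
    threshold was derived as a sample median).  A ratio exactly equal to the
    threshold is LOW ("<= 1.0" defines the Low Ratio Group).
    """
    params = params or RatioParams()
    if threshold is None:
        threshold = params.ratio_threshold
    if profile.n_total == 0:
        return RatioResult(ratio=None, log_ratio=None, group=RatioGroup.UNDEFINED)
    c = params.group_pseudocount
    ratio = (profile.n_S + profile.n_Rc + c) / (profile.n_Rnc + c)
    cc = params.cox_pseudocount
    log_ratio = math.log((profile.n_S + profile.n_Rc + cc) / (profile.n_Rnc + cc))
    group = RatioGroup.LOW if ratio <= threshold else RatioGroup.HIGH
    return RatioResult(ratio=ratio, log_ratio=log_ratio, group=group)


def assign_groups(
    profiles: list[MutationProfile], params: RatioParams | None = None
) -> tuple[dict[str, RatioResult], float]:
    """Assign every mutated sequence to the Low or High Ratio Group.

    Returns (patient_id -> RatioResult, threshold used).  In ``median``
    mode the threshold is the sample median of ratios over sequences with
    at least one mutation.
    """
    params = params or RatioParams()
    mutated = [p for p in profiles if p.n_total >= 1]
    if not mutated:
        raise ValueError("no sequence with >= 1 mutation; ratio groups undefined")
    if params.threshold_mode == ThresholdMode.MEDIAN:
        ratios = [compute_ratio(p, params).ratio for p in mutated]
        threshold = float(statistics.median(ratios))
    else:
        threshold = params.ratio_threshold
    results = {p.patient_id: compute_ratio(p, params, threshold) for p in profiles}
    n_low = sum(1 for r in results.values() if r.group == RatioGroup.LOW)
    n_high = sum(1 for r in results.values() if r.group == RatioGroup.HIGH)
    if n_low == 0 or n_high == 0:
        logger.warning(
            "one ratio group is empty (LOW=%d, HIGH=%d, threshold=%g)",
            n_low,
            n_high,
            threshold,
        )
    return results, threshold


#: Fig-6-style mutation-count intervals: {0}, 1-4, 5-6, ..., 19-21, >21.
DEFAULT_BIN_SCHEME: list[tuple[int, int | None]] = [
    (0, 0),
    (1, 4),
    (5, 6),
    (7, 9),
    (10, 12),
    (13, 15),
    (16, 18),
    (19, 21),
    (22, None),
]


def bin_label(lo: int, hi: int | None) -> str:
    if lo == hi:
        return str(lo)
    if hi is None:
        return f">{lo - 1}"
    return f"{lo}-{hi}"


def validate_scheme(scheme: list[tuple[int, int | None]]) -> None:
    prev_hi = -1
    for i, (lo, hi) in enumerate(scheme):
        if lo != prev_hi + 1:
            raise ValueError("bin scheme must be disjoint and exhaustive")
        if hi is None:
            if i != len(scheme) - 1:
                raise ValueError("only the last bin may be unbounded")
            prev_hi = None
        else:
            if hi < lo:
                raise ValueError("bin upper bound below lower bound")
            prev_hi = hi
    if prev_hi is not None:
        raise ValueError("last bin must be unbounded to cover all counts")


def assign_bin(n_total: int, scheme: list[tuple[int, int | None]] | None = None) -> str:
    scheme = scheme if scheme is not None else DEFAULT_BIN_SCHEME
    for lo, hi in scheme:
        if n_total >= lo and (hi is None or n_total <= hi):
            return bin_label(lo, hi)
    raise ValueError(f"count {n_total} not covered by bin scheme")


def bin_by_mutation_count(
    profiles: list[MutationProfile],
    scheme: list[tuple[int, int | None]] | None = None,
) -> dict[str, list[MutationProfile]]:
    """Segregate patients into mutation-count intervals (zero kept as its own
    bin for comparison)."""
    scheme = scheme if scheme is not None else DEFAULT_BIN_SCHEME
    validate_scheme(scheme)
    out: dict[str, list[MutationProfile]] = {
        bin_label(lo, hi): [] for lo, hi in scheme
    }
    for p in profiles:
        out[assign_bin(p.n_total, scheme)].append(p)
    return out
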