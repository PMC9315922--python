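"""Exact one-to-one matching on total mutation count.

For each Low Ratio patient (visited in a seeded random order) one High
Ratio patient with the *identical* total mutation count is drawn uniformly
without replacement.  On the matched subset the two groups therefore have
equal size and identical mutation-burden multisets, removing burden as a
confounder when their survival is compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import MutationProfile

logger = logging.getLogger(__name__)


@dataclass
class MatchResult:
    matched_pairs: list[tuple[str, str]]  # (low_patient_id, high_patient_id)
    unmatched_low: list[str]
    seed: int

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)


def exact_match(
    low: list[MutationProfile],
    high: list[MutationProfile],
    seed: int,
) -> MatchResult:
    """Match each Low patient to a High patient with the same n_total.

    Deterministic given ``seed``; High patients are used at most once.  Low
    patients with no remaining same-count High candidate are recorded in
    ``unmatched_low``.
    """
    if not low or not high:
        raise ValueError("both groups must be non-empty")
    for p in low + high:
        if p.n_total < 1:
            raise ValueError(
                f"{p.patient_id}: zero-mutation sequences cannot enter matching"
            )
    rng = np.random.default_rng(seed)
    pools: dict[int, list[str]] = {}
    for p in high:
        pools.setdefault(p.n_total, []).append(p.patient_id)
    order = list(low)
    rng.shuffle(order)  # avoid order-dependent exhaustion bias
    pairs: list[tuple[str, str]] = []
    unmatched: list[str] = []
    for p in order:
        pool = pools.get(p.n_total)
        if pool:
            k = int(rng.integers(len(pool)))
            pairs.append((p.patient_id, pool.pop(k)))
        else:
            unmatched.append(p.patient_id)
    if unmatched:
        logger.warning("%d Low Ratio patients could not be matched", len(unmatched))
    if not pairs:
        logger.warning("exact match produced no pairs")
    return MatchResult(matched_pairs=pairs, unmatched_low=unmatched, seed=seed)


def matched_cohorts(
    result: MatchResult, cohort: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the cohort table into the matched Low and High subsets.

    Both outputs have one row per matched pair, in pair order, so their
    n_total multisets are identical by construction.
    """
    indexed = cohort.set_index("patient_id")
    low_ids = [lo for lo, _ in result.matched_pairs]
    high_ids = [hi for _, hi in result.matched_pairs]
    low_df = indexed.loc[low_ids].reset_index()
    high_df = indexed.loc[high_ids].reset_index()
    return low_df, high_df


def match_summary(result: MatchResult) -> dict:
    return {
        "n_matched": result.n_matched,
        "n_unmatched": len(result.unmatched_low),
        "seed": result.seed,
    }
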