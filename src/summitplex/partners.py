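"""Repeated-partner effect on failure.

Compares, within experience bins, the pooled per-category failure rate of
records climbed with at least one repeated partner against the pooled rate
over all records in the bin. Ratios below one mean failure is rarer with
repeated partners. Rates are pooled (record-weighted) within bins rather
than averaged per climber, which keeps every ratio well defined; experience
is the climber's count of logged expeditions strictly before the record.
"""
from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import (
    ClimberExpeditionRecord,
    Expedition,
    FailureCause,
    FAILURE_CATEGORIES,
    prior_climb_counts,
)


def repeated_partner_flags(
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Sequence[Expedition],
) -> dict[tuple[str, str], bool]:
    """True for (climber, expedition) iff some co-roster member shares at
    least one strictly earlier joint expedition with the climber."""
    records = list(records)
    flags: dict[tuple[str, str], bool] = {}
    seen_pairs: set[frozenset[str]] = set()
    for exp in sorted(expeditions, key=lambda e: e.time_index):
        roster = sorted(exp.roster)
        for c in roster:
            flags[(c, exp.expedition_id)] = any(
                frozenset((c, m)) in seen_pairs for m in roster if m != c
            )
        for i, a in enumerate(roster):
            for b in roster[i + 1 :]:
                seen_pairs.add(frozenset((a, b)))
    return {
        (r.climber_id, r.expedition_id): flags[(r.climber_id, r.expedition_id)]
        for r in records
    }


def default_experience_bins(
    min_total_climbs: int = 15, width: int = 5, upper: int = 40
) -> list[tuple[int, int]]:
    """Half-open [lo, hi) bins of prior-climb counts, width 5 up to 40."""
    return [(lo, lo + width) for lo in range(min_total_climbs, upper, width)]


def failure_ratio_analysis(
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Sequence[Expedition],
    flags: Mapping[tuple[str, str], bool] | None = None,
    bins: Sequence[tuple[int, int]] | None = None,
    min_total_climbs: int = 15,
) -> pd.DataFrame:
    """Per (experience bin, failure category) ratio of the flagged pooled
    failure rate to the bin's overall pooled failure rate.

    Empty cells yield NaN ratios (never a division crash); a bin whose
    flagged records contain no failures of a category gives ratio 0.
    """
    records = list(records)
    if flags is None:
        flags = repeated_partner_flags(records, expeditions)
    if bins is None:
        bins = default_experience_bins(min_total_climbs)
    prior = prior_climb_counts(records, expeditions)

    rows = []
    for lo, hi in bins:
        in_bin = [
            r for r in records if lo <= prior[(r.climber_id, r.expedition_id)] < hi
        ]
        flagged = [r for r in in_bin if flags[(r.climber_id, r.expedition_id)]]
        n_climbers = len({r.climber_id for r in in_bin})
        for cat in FAILURE_CATEGORIES:
            ratio = np.nan
            if in_bin and flagged:
                rate_all = sum(r.failure_cause is cat for r in in_bin) / len(in_bin)
                rate_flag = sum(r.failure_cause is cat for r in flagged) / len(flagged)
                if rate_all > 0:
                    ratio = rate_flag / rate_all
            rows.append(
                {
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "category": cat.value,
                    "ratio": ratio,
                    "n_climbers": n_climbers,
                    "n_records": len(in_bin),
                    "n_records_with_partner": len(flagged),
                }
            )
    return pd.DataFrame(rows)


def pooled_failure_ratios(
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Sequence[Expedition],
    flags: Mapping[tuple[str, str], bool] | None = None,
    min_total_climbs: int = 15,
) -> dict[str, float]:
    """Single pooled ratio per category, plus 'any' over all failure types,
    across every record at or above the experience floor."""
    records = list(records)
    if flags is None:
        flags = repeated_partner_flags(records, expeditions)
    prior = prior_climb_counts(records, expeditions)
    eligible = [
        r for r in records if prior[(r.climber_id, r.expedition_id)] >= min_total_climbs
    ]
    flagged = [r for r in eligible if flags[(r.climber_id, r.expedition_id)]]
    out: dict[str, float] = {}
    cats: list[tuple[str, set[FailureCause]]] = [
        (c.value, {c}) for c in FAILURE_CATEGORIES
    ]
    cats.append(("any", set(FAILURE_CATEGORIES)))
    for name, members in cats:
        ratio = np.nan
        if eligible and flagged:
            rate_all = sum(r.failure_cause in members for r in eligible) / len(eligible)
            rate_flag = sum(r.failure_cause in members for r in flagged) / len(flagged)
            if rate_all > 0:
                ratio = rate_flag / rate_all
        out[name] = ratio
    return out
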