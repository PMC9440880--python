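"""Influence as a predictor of climber success.

Compares influence (maximal simplicial dimension, zeta) between outcome
categories within experience bins, using a Mann-Whitney U rank-sum test,
and builds per-category influence histograms normalized so each category
sums to one. Only climbers belonging to a simplex of dimension >= 1 (i.e.
zeta >= min_influence) enter the comparison, matching the convention that
lone newcomers carry no relationship signal. Deaths are summarized but
never tested: the category is too small for rank statistics to mean much.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .complexes import influence_table
from .records import (
    ClimberExpeditionRecord,
    Expedition,
    Outcome,
    prior_climb_counts,
)

#: experience bins used throughout the influence analysis (prior climbs)
DEFAULT_EXPERIENCE_BINS: tuple[tuple[int, int], ...] = (
    (5, 10),
    (10, 15),
    (15, 20),
    (20, 25),
)

EXACT_LIMIT = 20  # exact permutation p-value up to this pooled sample size


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], exact_limit: int = EXACT_LIMIT
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U counts pairs (x in a, y in b) with x > y, ties counting one half.
    The p-value is exact (full enumeration of label assignments) when
    n1 + n2 <= ``exact_limit``, otherwise a normal approximation with tie
    and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # average ranks handle ties as half-wins
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    if n1 + n2 <= exact_limit:
        n = n1 + n2
        obs = abs(u - mu)
        hits = 0
        base = (n1 * (n1 + 1)) / 2.0
        for idx in combinations(range(n), n1):
            u_perm = ranks[list(idx)].sum() - base
            if abs(u_perm - mu) >= obs - 1e-9:
                hits += 1
        p = hits / comb(n, n1)
        return u, p

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    d = abs(u - mu)
    z = max(d - 0.5, 0.0) / np.sqrt(sigma2)  # continuity correction
    p = min(1.0, max(float(2.0 * norm.sf(z)), np.finfo(float).tiny))
    return u, p


@dataclass
class OutcomeInfluenceSummary:
    """Per-bin rank tests, per-(bin, outcome) quartiles, and per-outcome
    normalized influence histograms."""

    tests: pd.DataFrame  # bin_lo, bin_hi, n_success, n_no_summit, U, p, ...
    summary: pd.DataFrame  # bin_lo, bin_hi, outcome, n, median, q1, q3
    histograms: pd.DataFrame  # outcome, influence, fraction
    alpha: float = 0.1


def _influence_records_frame(
    influence_df: pd.DataFrame,
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Sequence[Expedition],
) -> pd.DataFrame:
    prior = prior_climb_counts(records, expeditions)
    rec_rows = [
        {
            "climber_id": r.climber_id,
            "expedition_id": r.expedition_id,
            "outcome": r.outcome.value,
            "prior_climbs": prior[(r.climber_id, r.expedition_id)],
        }
        for r in records
    ]
    rec_df = pd.DataFrame(rec_rows)
    return influence_df.merge(rec_df, on=["climber_id", "expedition_id"], how="inner")


def influence_by_outcome(
    influence_df: pd.DataFrame,
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Sequence[Expedition],
    experience_bins: Sequence[tuple[int, int]] | None = None,
    min_influence: int = 1,
    alpha: float = 0.1,
) -> OutcomeInfluenceSummary:
    """Summaries and success-vs-no-summit rank tests for one threshold.

    ``influence_df`` must carry a single tau (as produced by
    :func:`summitplex.complexes.influence_table`); histograms pool all
    experience levels, tests are per experience bin. No multiple-testing
    correction is applied; ``alpha`` is reported alongside each p-value.
    """
    records = list(records)
    if experience_bins is None:
        experience_bins = DEFAULT_EXPERIENCE_BINS
    taus = influence_df["tau"].unique()
    if len(taus) != 1:
        raise ValueError(f"influence_df must hold exactly one tau, got {sorted(taus)}")
    df = _influence_records_frame(influence_df, records, expeditions)
    df = df[df["influence"] >= min_influence]

    test_rows, summary_rows = [], []
    for lo, hi in experience_bins:
        sub = df[(df["prior_climbs"] >= lo) & (df["prior_climbs"] < hi)]
        groups = {
            out: sub.loc[sub["outcome"] == out, "influence"].to_numpy()
            for out in (o.value for o in Outcome)
        }
        for out, vals in groups.items():
            if vals.size:
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
            else:
                q1 = med = q3 = np.nan
            summary_rows.append(
                {
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "outcome": out,
                    "n": vals.size,
                    "median": med,
                    "q1": q1,
                    "q3": q3,
                }
            )
        succ = groups[Outcome.SUMMIT_SUCCESS.value]
        fail = groups[Outcome.NO_SUMMIT.value]
        if succ.size and fail.size:
            u, p = mann_whitney_u(succ, fail)
            reason = ""
        else:
            u = p = np.nan
            reason = "empty category"
        test_rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n_success": succ.size,
                "n_no_summit": fail.size,
                "U": u,
                "p": p,
                "alpha": alpha,
                "significant": bool(p < alpha) if p == p else False,
                "skip_reason": reason,
            }
        )

    hist_rows = []
    for out, sub in df.groupby("outcome"):
        counts = sub["influence"].value_counts().sort_index()
        total = counts.sum()
        for zeta, cnt in counts.items():
            hist_rows.append(
                {"outcome": out, "influence": int(zeta), "fraction": cnt / total}
            )
    return OutcomeInfluenceSummary(
        tests=pd.DataFrame(test_rows),
        summary=pd.DataFrame(summary_rows),
        histograms=pd.DataFrame(
            hist_rows, columns=["outcome", "influence", "fraction"]
        ),
        alpha=alpha,
    )


def influence_tau_sweep(
    expeditions: Sequence[Expedition],
    records: Iterable[ClimberExpeditionRecord],
    tau_values: Sequence[int] = (1, 2, 3, 4),
    **kwargs,
) -> tuple[pd.DataFrame, dict[int, OutcomeInfluenceSummary]]:
    """Influence distributions per threshold: raising tau keeps only
    stronger relationships, so each climber's zeta is non-increasing.

    Returns the per-tau influence table plus one summary per tau.
    """
    records = list(records)
    inf_df = influence_table(expeditions, tau_values)
    summaries = {
        tau: influence_by_outcome(
            inf_df[inf_df["tau"] == tau], records, expeditions, **kwargs
        )
        for tau in tau_values
    }
    return inf_df, summaries
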