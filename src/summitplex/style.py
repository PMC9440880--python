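"""Expedition style on the polarized-to-cooperative spectrum.

An expedition whose largest simplex is big (many climbers held weak joint
history) tends to be cooperative: members outside the core subgroup succeed
more the larger the core. Small, heavily-weighted simplices mark polarized
expeditions where outsiders fare worse. Three views are computed: outsider
success rate against maximal simplex dimension, mean maximal dimension as a
function of the weight threshold tau, and the per-tau Pearson correlation
between expedition success rate and mean maximal-simplex dimension.

Under ties, "the largest simplex" is taken as the union of all simplices
attaining the maximal dimension — the conservative outsider definition —
and the mean simplicial dimension is computed over maximal simplices only
(faces would mechanically deflate it).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .complexes import ExpeditionComplex, cohort_complexes
from .records import (
    ClimberExpeditionRecord,
    Expedition,
    Outcome,
    expedition_success_rates,
    records_by_expedition,
)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-test p-value
    (n - 2 degrees of freedom). Zero variance yields (nan, nan)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt((dx**2).sum()))
    sy = float(np.sqrt((dy**2).sum()))
    if sx == 0.0 or sy == 0.0:
        return np.nan, np.nan
    r = float((dx * dy).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    n = x.size
    if abs(r) == 1.0:
        return r, 0.0
    tval = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * t_dist.sf(abs(tval), n - 2))
    return r, p


def outsider_success_rate(
    cx: ExpeditionComplex,
    exp_records: Iterable[ClimberExpeditionRecord],
) -> float:
    """Summit fraction among roster members outside every maximal-dimension
    simplex; NaN when the complex has no multi-member simplex or no
    outsiders exist."""
    maxd = cx.max_dimension
    if maxd < 1:
        return np.nan
    core: set[str] = set()
    for ws in cx.maximal_simplices():
        if ws.dimension == maxd:
            core |= ws.vertices
    outsiders = cx.roster - core
    if not outsiders:
        return np.nan
    outcome = {r.climber_id: r.outcome for r in exp_records}
    return sum(outcome[c] is Outcome.SUMMIT_SUCCESS for c in outsiders) / len(outsiders)


@dataclass
class StyleResult:
    """Per-expedition style rows, per-tau summaries, and the tau=1
    outsider-success-by-dimension profile."""

    per_expedition: pd.DataFrame
    per_tau: pd.DataFrame
    dimension_bins: pd.DataFrame


def style_curves(
    expeditions: Sequence[Expedition],
    records: Iterable[ClimberExpeditionRecord],
    tau_values: Sequence[int] = (1, 2, 3, 4),
) -> StyleResult:
    """Style analysis across thresholds.

    Expeditions with no simplex of dimension >= 1 at a given tau are
    excluded at that tau. The per-tau Pearson correlation relates expedition
    success rate to the expedition's mean maximal-simplex dimension; it is
    NaN (with a recorded reason) for fewer than 3 expeditions or zero
    variance.
    """
    records = list(records)
    by_exp = records_by_expedition(records)
    rates = {
        s.expedition_id: s.success_rate
        for s in expedition_success_rates(records, expeditions)
    }
    base = cohort_complexes(expeditions, tau=1)

    rows = []
    for exp in sorted(expeditions, key=lambda e: e.time_index):
        cx1 = base[exp.expedition_id]
        for tau in tau_values:
            if tau == 1:
                cx = cx1
            else:
                cx = ExpeditionComplex(exp.expedition_id, exp.roster, (), tau)
                cx._intersections = cx1._intersections
            maxd = cx.max_dimension
            if maxd < 1:
                continue
            maximal = [ws for ws in cx.maximal_simplices()]
            core: set[str] = set()
            for ws in maximal:
                if ws.dimension == maxd:
                    core |= ws.vertices
            insiders_rate = np.nan
            if core:
                outcome = {r.climber_id: r.outcome for r in by_exp[exp.expedition_id]}
                insiders_rate = sum(
                    outcome[c] is Outcome.SUMMIT_SUCCESS for c in core
                ) / len(core)
            rows.append(
                {
                    "expedition_id": exp.expedition_id,
                    "tau": tau,
                    "max_dimension": maxd,
                    "mean_maximal_dimension": float(
                        np.mean([ws.dimension for ws in maximal])
                    ),
                    "outsider_success_rate": outsider_success_rate(
                        cx, by_exp[exp.expedition_id]
                    ),
                    "insider_success_rate": insiders_rate,
                    "n_outsiders": len(exp.roster) - len(core),
                    "success_rate": rates[exp.expedition_id],
                }
            )
    per_exp = pd.DataFrame(
        rows,
        columns=[
            "expedition_id",
            "tau",
            "max_dimension",
            "mean_maximal_dimension",
            "outsider_success_rate",
            "insider_success_rate",
            "n_outsiders",
            "success_rate",
        ],
    )

    tau_rows = []
    for tau in tau_values:
        sub = per_exp[per_exp["tau"] == tau]
        r = p = np.nan
        reason = ""
        if len(sub) < 3:
            reason = "fewer than 3 expeditions"
        else:
            r, p = pearson(sub["success_rate"], sub["mean_maximal_dimension"])
            if r != r:
                reason = "zero variance"
        tau_rows.append(
            {
                "tau": tau,
                "n_expeditions": len(sub),
                "mean_max_dimension": sub["max_dimension"].mean() if len(sub) else np.nan,
                "pcc_r": r,
                "pcc_p": p,
                "note": reason,
            }
        )
    per_tau = pd.DataFrame(tau_rows)

    sub1 = per_exp[(per_exp["tau"] == tau_values[0])]
    dim_rows = []
    for dim, grp in sub1.groupby("max_dimension"):
        vals = grp["outsider_success_rate"].dropna().to_numpy()
        dim_rows.append(
            {
                "max_dimension": int(dim),
                "mean_outsider_success_rate": vals.mean() if vals.size else np.nan,
                "se": (
                    vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
                ),
                "n_expeditions": int(vals.size),
            }
        )
    dimension_bins = pd.DataFrame(
        dim_rows,
        columns=["max_dimension", "mean_outsider_success_rate", "se", "n_expeditions"],
    )
    return StyleResult(per_exp, per_tau, dimension_bins)


def outsider_dimension_slope(per_expedition: pd.DataFrame, tau: int = 1) -> float:
    """Least-squares slope of outsider success rate against maximal simplex
    dimension at one threshold; NaN when underdetermined."""
    sub = per_expedition[per_expedition["tau"] == tau].dropna(
        subset=["outsider_success_rate"]
    )
    if len(sub) < 3 or sub["max_dimension"].nunique() < 2:
        return np.nan
    slope, _ = np.polyfit(
        sub["max_dimension"].to_numpy(float),
        sub["outsider_success_rate"].to_numpy(float),
        1,
    )
    return float(slope)
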