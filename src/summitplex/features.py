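"""Personal features and expedition-wide factors behind success.

Climbers of each large expedition are split into successful and
unsuccessful groups; each group forms a bipartite climber-feature incidence
matrix P over six binary personal features. Projecting into feature space,
I = P^T P, gives a weighted co-expression graph whose eigenvector
centralities rank features; the per-feature difference in mean centrality
between the groups measures how much the feature matters for success.
Expedition-wide factors (days to summit, camps, expedition size,
member-to-hired ratio) are related to expedition success rate by Pearson
correlation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .records import (
    ClimberExpeditionRecord,
    Expedition,
    Outcome,
    expedition_success_rates,
    records_by_expedition,
)
from .style import pearson

FEATURE_NAMES = (
    "age_below_median",
    "sex_male",
    "modal_nationality",
    "experience_8000m",
    "oxygen_ascent",
    "oxygen_descent",
)

FACTOR_NAMES = (
    "days_to_summit",
    "n_camps",
    "expedition_size",
    "members_to_hired_ratio",
)

#: default minimum roster size for the feature analysis
MIN_EXPEDITION_MEMBERS = 12


def feature_row(
    rec: ClimberExpeditionRecord, median_age: float, modal_nationality: str
) -> np.ndarray:
    """Binary encoding of one climber against the six personal features."""
    return np.array(
        [
            rec.age < median_age,
            rec.sex == "male",
            rec.nationality == modal_nationality,
            rec.experience_8000m > 0,
            rec.oxygen_ascent,
            rec.oxygen_descent,
        ],
        dtype=int,
    )


def cohort_feature_context(
    records: Iterable[ClimberExpeditionRecord],
) -> tuple[float, str]:
    """Median age and modal nationality of the analyzed cohort."""
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    median_age = float(np.median([r.age for r in records]))
    modal = pd.Series([r.nationality for r in records]).mode().iloc[0]
    return median_age, str(modal)


def build_feature_matrix(
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Sequence[Expedition],
    min_members: int = MIN_EXPEDITION_MEMBERS,
    median_age: float | None = None,
) -> tuple[dict[str, tuple[pd.DataFrame, pd.DataFrame]], list[str]]:
    """Per-expedition (P_success, P_failure) incidence matrices.

    Expeditions with fewer than ``min_members`` climbers are skipped and
    listed in the second return value. The age split and the modal
    nationality come from the analyzed (qualifying) records unless a median
    age is supplied.
    """
    records = list(records)
    by_exp = records_by_expedition(records)
    qualifying = [e for e in expeditions if len(e.roster) >= min_members]
    skipped = [e.expedition_id for e in expeditions if len(e.roster) < min_members]
    pool = [r for e in qualifying for r in by_exp.get(e.expedition_id, [])]
    if not pool:
        return {}, skipped
    med, modal = cohort_feature_context(pool)
    if median_age is not None:
        med = median_age

    out: dict[str, tuple[pd.DataFrame, pd.DataFrame]] = {}
    for exp in qualifying:
        groups: dict[bool, tuple[list[str], list[np.ndarray]]] = {
            True: ([], []),
            False: ([], []),
        }
        for rec in sorted(by_exp[exp.expedition_id], key=lambda r: r.climber_id):
            success = rec.outcome is Outcome.SUMMIT_SUCCESS
            groups[success][0].append(rec.climber_id)
            groups[success][1].append(feature_row(rec, med, modal))
        mats = []
        for success in (True, False):
            ids, rows = groups[success]
            mat = (
                pd.DataFrame(np.array(rows), index=ids, columns=list(FEATURE_NAMES))
                if rows
                else pd.DataFrame(
                    np.empty((0, len(FEATURE_NAMES)), dtype=int),
                    columns=list(FEATURE_NAMES),
                )
            )
            mats.append(mat)
        out[exp.expedition_id] = (mats[0], mats[1])
    return out, skipped


def project_features(P: pd.DataFrame | np.ndarray, zero_diagonal: bool = True) -> np.ndarray:
    """Feature-space projection I = P^T P of a binary incidence matrix.

    Off-diagonal entry (f, g) counts climbers expressing both features; the
    diagonal (feature self-counts) is zeroed by default so prevalence alone
    cannot dominate the centrality.
    """
    mat = np.asarray(P, dtype=float)
    I = mat.T @ mat
    if zero_diagonal:
        np.fill_diagonal(I, 0.0)
    return I


class CentralityResult(NamedTuple):
    vector: np.ndarray
    degenerate: bool


def eigenvector_centrality(
    I: np.ndarray, tol: float = 1e-10, max_iter: int = 100_000
) -> CentralityResult:
    """Dominant eigenvector of a symmetric nonnegative matrix.

    Power iteration from the uniform positive vector; iterates run on
    I + s*Id (s = max row sum), a spectral shift that leaves eigenvectors
    unchanged but makes the dominant eigenvalue strictly largest in
    magnitude, so bipartite-like graphs (whose extreme eigenvalues come in
    +/- pairs) still converge. The result is nonnegative with unit
    Euclidean norm. A zero matrix returns the uniform vector flagged
    degenerate.
    """
    I = np.asarray(I, dtype=float)
    d = I.shape[0]
    uniform = np.ones(d) / np.sqrt(d)
    if not np.any(I):
        return CentralityResult(uniform, True)
    shift = float(I.sum(axis=1).max())
    M = I + shift * np.eye(d)
    v = uniform
    for _ in range(max_iter):
        w = M @ v
        nw = float(np.linalg.norm(w))
        if nw == 0.0:
            return CentralityResult(uniform, True)
        w = w / nw
        if float(np.linalg.norm(w - v)) < tol:
            return CentralityResult(np.abs(w), False)
        v = w
    return CentralityResult(np.abs(v), True)


def expedition_feature_centralities(
    records: Iterable[ClimberExpeditionRecord],
    expeditions: Sequence[Expedition],
    min_members: int = MIN_EXPEDITION_MEMBERS,
    median_age: float | None = None,
) -> dict[str, tuple[np.ndarray | None, np.ndarray | None]]:
    """Per-expedition (success, failure) feature centralities; a group with
    no climbers contributes None (the comparison is one-sided there)."""
    matrices, _ = build_feature_matrix(records, expeditions, min_members, median_age)
    out: dict[str, tuple[np.ndarray | None, np.ndarray | None]] = {}
    for eid, (p_succ, p_fail) in matrices.items():
        cents = []
        for P in (p_succ, p_fail):
            if len(P) == 0:
                cents.append(None)
                continue
            cents.append(eigenvector_centrality(project_features(P)).vector)
        out[eid] = (cents[0], cents[1])
    return out


def centrality_comparison(
    centralities: Mapping[str, tuple[np.ndarray | None, np.ndarray | None]],
    feature_names: Sequence[str] = FEATURE_NAMES,
) -> pd.DataFrame:
    """Mean centrality per feature and group across expeditions, with
    standard errors, ordered by increasing (success - no-success)
    difference. Standard errors are NaN with fewer than 2 contributions."""
    succ = np.array([c for c, _ in centralities.values() if c is not None])
    fail = np.array([c for _, c in centralities.values() if c is not None])
    if succ.size == 0 and fail.size == 0:
        raise ValueError("no expeditions contribute centralities")

    def stats(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if arr.size == 0:
            n = len(feature_names)
            return np.full(n, np.nan), np.full(n, np.nan)
        mean = arr.mean(axis=0)
        se = (
            arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0])
            if arr.shape[0] > 1
            else np.full(arr.shape[1], np.nan)
        )
        return mean, se

    mean_s, se_s = stats(succ)
    mean_f, se_f = stats(fail)
    df = pd.DataFrame(
        {
            "feature": list(feature_names),
            "mean_success": mean_s,
            "se_success": se_s,
            "mean_failure": mean_f,
            "se_failure": se_f,
            "difference": mean_s - mean_f,
            "n_success_expeditions": succ.shape[0] if succ.size else 0,
            "n_failure_expeditions": fail.shape[0] if fail.size else 0,
        }
    )
    return df.sort_values("difference", ignore_index=True)


def factor_correlations(
    expeditions: Sequence[Expedition],
    success_rates: Mapping[str, float]
    | Iterable[ClimberExpeditionRecord]
    | None = None,
    records: Iterable[ClimberExpeditionRecord] | None = None,
) -> pd.DataFrame:
    """Pearson correlation of each expedition-wide factor with success rate.

    ``success_rates`` maps expedition_id -> rate; alternatively pass
    ``records`` and rates are computed. Expeditions without hired personnel
    drop out of the member-to-hired ratio; zero-variance factors yield NaN
    with a recorded note.
    """
    if success_rates is None:
        if records is None:
            raise ValueError("provide success_rates or records")
        success_rates = {
            s.expedition_id: s.success_rate
            for s in expedition_success_rates(list(records), expeditions)
        }
    rows = []
    for factor in FACTOR_NAMES:
        xs, ys = [], []
        for exp in expeditions:
            if exp.expedition_id not in success_rates:
                continue
            if factor == "days_to_summit":
                val = exp.days_to_summit
            elif factor == "n_camps":
                val = exp.n_camps
            elif factor == "expedition_size":
                val = len(exp.roster)
            else:
                if exp.n_hired == 0:
                    continue
                val = exp.n_members / exp.n_hired
            xs.append(float(val))
            ys.append(float(success_rates[exp.expedition_id]))
        r = p = np.nan
        note = ""
        if len(xs) < 3:
            note = "fewer than 3 expeditions"
        else:
            r, p = pearson(xs, ys)
            if r != r:
                note = "zero variance"
        rows.append({"factor": factor, "pcc": r, "p": p, "n": len(xs), "note": note})
    return pd.DataFrame(rows)
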