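"""Weighted simplicial complexes of previous joint expeditions.

For the expedition under analysis, every previous expedition contributes its
roster intersection with the current roster. A subset *s* of the current
roster (|s| >= 2) is a simplex when its *support* — the number of previous
expeditions whose roster-intersection contains *s* — reaches the weight
threshold tau; the support is the simplex weight w_sigma. Support is monotone
non-increasing under supersets, so the stored set is closed under inclusion
by construction, and raising tau yields nested (filtered) complexes.

A climber's *influence* zeta is the dimension of the largest simplex that
contains them (0 when they share no previous expedition with any roster
member at the active tau); *co-influence* is the roster mean of zeta.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .records import Expedition


class ParameterError(ValueError):
    """An analysis parameter (tau, sweep ordering) is invalid."""


@dataclass(frozen=True)
class WeightedSimplex:
    """A set of climbers with an occurrence-count weight.

    dimension = |vertices| - 1; weight counts the previous expeditions
    supporting the simplex (for vertices: previous expeditions shared with
    at least one other roster member, 0 allowed).
    """

    vertices: frozenset[str]
    weight: int

    @property
    def dimension(self) -> int:
        return len(self.vertices) - 1


class ExpeditionComplex:
    """Inclusion-closed weighted complex for one expedition at threshold tau.

    Internally the complex keeps the multiset of history-roster intersections
    and enumerates supported subsets lazily; tau = 1 queries (max dimension,
    influence, maximal simplices) short-circuit through the intersections
    because every subset of an intersection has support >= 1.
    """

    def __init__(
        self,
        expedition_id: str,
        roster: frozenset[str],
        intersections: Sequence[frozenset[str]],
        tau: int,
    ):
        if not isinstance(tau, int) or tau < 1:
            raise ParameterError(f"tau must be an integer >= 1, got {tau!r}")
        self.expedition_id = expedition_id
        self.roster = frozenset(roster)
        # only intersections of size >= 2 can support relationships
        self._intersections: Counter[frozenset[str]] = Counter(
            i for i in intersections if len(i) >= 2
        )
        self.tau = tau
        self._weights: dict[frozenset[str], int] | None = None

    # -- enumeration ---------------------------------------------------

    def _enumerate(self) -> dict[frozenset[str], int]:
        """All supported multi-member simplices with their weights."""
        if self._weights is not None:
            return self._weights
        candidates: set[frozenset[str]] = set()
        for inter in self._intersections:
            verts = sorted(inter)
            for r in range(2, len(verts) + 1):
                for comb in combinations(verts, r):
                    candidates.add(frozenset(comb))
        weights: dict[frozenset[str], int] = {}
        for cand in candidates:
            support = sum(
                mult for inter, mult in self._intersections.items() if cand <= inter
            )
            if support >= self.tau:
                weights[cand] = support
        self._weights = weights
        return weights

    # -- queries -------------------------------------------------------

    def vertex_weight(self, climber_id: str) -> int:
        self._check_member(climber_id)
        return sum(m for i, m in self._intersections.items() if climber_id in i)

    @property
    def simplices(self) -> set[WeightedSimplex]:
        """Every stored simplex, vertices included (closure is guaranteed)."""
        out = {
            WeightedSimplex(frozenset({v}), self.vertex_weight(v)) for v in self.roster
        }
        out.update(WeightedSimplex(s, w) for s, w in self._enumerate().items())
        return out

    def weight(self, vertices: Iterable[str]) -> int:
        """Weight of the simplex on ``vertices``; KeyError when absent."""
        s = frozenset(vertices)
        if len(s) == 1:
            return self.vertex_weight(next(iter(s)))
        return self._enumerate()[s]

    @property
    def max_dimension(self) -> int:
        if self.tau == 1:
            return max((len(i) for i in self._intersections), default=1) - 1
        weights = self._enumerate()
        return max((len(s) for s in weights), default=1) - 1

    def influence(self, climber_id: str) -> int:
        """Dimension of the largest simplex containing the climber."""
        self._check_member(climber_id)
        if self.tau == 1:
            best = max(
                (len(i) for i in self._intersections if climber_id in i), default=1
            )
            return best - 1
        best = max(
            (len(s) for s in self._enumerate() if climber_id in s), default=1
        )
        return best - 1

    def co_influence(self, roster: Iterable[str] | None = None) -> float:
        members = list(self.roster if roster is None else roster)
        if not members:
            raise ValueError("co-influence of an empty roster is undefined")
        return sum(self.influence(c) for c in members) / len(members)

    def maximal_simplices(self) -> list[WeightedSimplex]:
        """Supported multi-member simplices maximal under inclusion."""
        if self.tau == 1:
            sets = list(self._intersections)
        else:
            sets = list(self._enumerate())
        maximal = [
            s for s in sets if not any(s < other for other in sets)
        ]
        return sorted(
            (WeightedSimplex(s, self._support(s)) for s in set(maximal)),
            key=lambda ws: (ws.dimension, sorted(ws.vertices)),
            reverse=True,
        )

    def _support(self, s: frozenset[str]) -> int:
        return sum(m for i, m in self._intersections.items() if s <= i)

    def census(self) -> dict[int, int]:
        """Mapping dimension k -> number of stored k-simplices |S_k|."""
        counts: Counter[int] = Counter({0: len(self.roster)})
        for s in self._enumerate():
            counts[len(s) - 1] += 1
        return dict(sorted(counts.items()))

    def _check_member(self, climber_id: str) -> None:
        if climber_id not in self.roster:
            raise KeyError(
                f"climber {climber_id!r} is not on the roster of "
                f"expedition {self.expedition_id!r}"
            )


def build_complex(
    history: Sequence[Expedition], current: Expedition, tau: int = 1
) -> ExpeditionComplex:
    """Build the weighted complex for ``current`` from strictly earlier
    expeditions."""
    for h in history:
        if h.time_index >= current.time_index:
            raise ParameterError(
                f"history expedition {h.expedition_id!r} is not strictly "
                f"earlier than {current.expedition_id!r}"
            )
    intersections = [h.roster & current.roster for h in history]
    return ExpeditionComplex(current.expedition_id, current.roster, intersections, tau)


def filtration_sweep(
    history: Sequence[Expedition],
    current: Expedition,
    tau_values: Sequence[int],
) -> list[ExpeditionComplex]:
    """Complexes for ascending thresholds; simplex sets are nested."""
    if list(tau_values) != sorted(set(tau_values)) or not tau_values:
        raise ParameterError("tau_values must be strictly ascending and nonempty")
    if tau_values[0] < 1:
        raise ParameterError("tau_values must start at >= 1")
    base = build_complex(history, current, tau=1)
    out = []
    for tau in tau_values:
        cx = ExpeditionComplex(current.expedition_id, current.roster, (), tau)
        cx._intersections = base._intersections  # share the support structure
        out.append(cx)
    return out


def influence(cx: ExpeditionComplex, climber_id: str) -> int:
    return cx.influence(climber_id)


def co_influence(cx: ExpeditionComplex, roster: Iterable[str] | None = None) -> float:
    return cx.co_influence(roster)


def simplex_census(cx: ExpeditionComplex) -> dict[int, int]:
    return cx.census()


def cohort_complexes(
    expeditions: Sequence[Expedition], tau: int = 1
) -> dict[str, ExpeditionComplex]:
    """One complex per expedition, history = all strictly earlier expeditions.

    Uses a per-climber membership index so only histories actually sharing a
    member with the current roster are intersected.
    """
    ordered = sorted(expeditions, key=lambda e: e.time_index)
    member_of: dict[str, list[int]] = defaultdict(list)
    out: dict[str, ExpeditionComplex] = {}
    for idx, exp in enumerate(ordered):
        cand = set()
        for c in exp.roster:
            cand.update(member_of[c])
        intersections = [ordered[j].roster & exp.roster for j in cand]
        out[exp.expedition_id] = ExpeditionComplex(
            exp.expedition_id, exp.roster, intersections, tau
        )
        for c in exp.roster:
            member_of[c].append(idx)
    return out


def influence_table(
    expeditions: Sequence[Expedition], tau_values: Sequence[int] = (1,)
) -> pd.DataFrame:
    """Per (expedition, climber, tau) influence for a whole cohort.

    Columns: expedition_id, climber_id, tau, influence. Thresholds share a
    single support structure per expedition.
    """
    if list(tau_values) != sorted(set(tau_values)) or tau_values[0] < 1:
        raise ParameterError("tau_values must be strictly ascending, min >= 1")
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
            for c in sorted(exp.roster):
                rows.append(
                    {
                        "expedition_id": exp.expedition_id,
                        "climber_id": c,
                        "tau": tau,
                        "influence": cx.influence(c),
                    }
                )
    return pd.DataFrame(rows, columns=["expedition_id", "climber_id", "tau", "influence"])


def co_influence_table(influence_df: pd.DataFrame) -> pd.DataFrame:
    """Mean influence per (expedition, tau) from an influence table."""
    out = (
        influence_df.groupby(["expedition_id", "tau"], as_index=False)["influence"]
        .mean()
        .rename(columns={"influence": "co_influence"})
    )
    return out.sort_values(["tau", "expedition_id"], ignore_index=True)


def serialize_complex(cx: ExpeditionComplex) -> pd.DataFrame:
    """One CSV row per stored simplex: expedition, tau, sorted vertices
    joined by '|', dimension, weight."""
    rows = [
        {
            "expedition_id": cx.expedition_id,
            "tau": cx.tau,
            "vertices": "|".join(sorted(ws.vertices)),
            "dimension": ws.dimension,
            "weight": ws.weight,
        }
        for ws in cx.simplices
    ]
    return (
        pd.DataFrame(
            rows, columns=["expedition_id", "tau", "vertices", "dimension", "weight"]
        )
        .sort_values(["dimension", "vertices"], ignore_index=True)
    )
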