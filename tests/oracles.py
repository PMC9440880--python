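"""Brute-force reference implementations used only as test oracles.

These deliberately enumerate every subset / permutation / pair so the
package's lazier algorithms can be checked against first principles on
small instances.
"""
from __future__ import annotations

from itertools import combinations

import numpy as np

from summitplex.records import Expedition


def make_expedition(eid: str, t: int, roster, peak: str = "EVER", height: float = 8849.0) -> Expedition:
    roster = frozenset(roster)
    return Expedition(
        expedition_id=eid,
        peak_id=peak,
        peak_height=height,
        time_index=t,
        roster=roster,
        days_to_summit=30,
        n_camps=3,
        n_members=len(roster),
        n_hired=0,
    )


def brute_supports(history_rosters, current_roster) -> dict[frozenset, int]:
    """Support of every multi-member subset of the current roster, by direct
    containment counting over all history roster-intersections."""
    current = frozenset(current_roster)
    inters = [frozenset(h) & current for h in history_rosters]
    out: dict[frozenset, int] = {}
    verts = sorted(current)
    for r in range(2, len(verts) + 1):
        for comb in combinations(verts, r):
            s = frozenset(comb)
            supp = sum(1 for i in inters if s <= i)
            if supp >= 1:
                out[s] = supp
    return out


def brute_complex(history_rosters, current_roster, tau: int) -> dict[frozenset, int]:
    """Supported subsets (weight >= tau) from exhaustive enumeration."""
    return {s: w for s, w in brute_supports(history_rosters, current_roster).items() if w >= tau}


def brute_influence(history_rosters, current_roster, climber: str, tau: int) -> int:
    supported = brute_complex(history_rosters, current_roster, tau)
    dims = [len(s) - 1 for s in supported if climber in s]
    return max(dims, default=0)


def brute_census(history_rosters, current_roster, tau: int) -> dict[int, int]:
    supported = brute_complex(history_rosters, current_roster, tau)
    out: dict[int, int] = {0: len(frozenset(current_roster))}
    for s in supported:
        out[len(s) - 1] = out.get(len(s) - 1, 0) + 1
    return dict(sorted(out.items()))


def random_instance(seed: int, n_roster: int = 5, n_history: int = 8):
    """A random small cohort: current roster plus a short history whose
    rosters mix current members and strangers."""
    rng = np.random.default_rng(seed)
    n_climbers = n_roster + 6
    everyone = [f"p{i}" for i in range(n_climbers)]
    current_roster = frozenset(rng.choice(everyone, size=n_roster, replace=False))
    history = []
    for k in range(int(rng.integers(1, n_history + 1))):
        size = int(rng.integers(2, n_climbers))
        history.append(frozenset(rng.choice(everyone, size=size, replace=False)))
    hist_exps = [make_expedition(f"h{k}", k, r) for k, r in enumerate(history)]
    current = make_expedition("cur", len(history) + 1, current_roster)
    return hist_exps, current, history, current_roster


def brute_mwu(a, b) -> float:
    """U by literal pair counting: 1 per win, 0.5 per tie."""
    return float(
        sum(1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b)
    )


def brute_mwu_exact_p(a, b) -> float:
    """Two-sided exact p by full enumeration of label assignments."""
    pooled = list(a) + list(b)
    n1 = len(a)
    mu = n1 * (len(pooled) - n1) / 2.0
    obs = abs(brute_mwu(a, b) - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        grp_a = [pooled[i] for i in idx]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        total += 1
        if abs(brute_mwu(grp_a, grp_b) - mu) >= obs - 1e-9:
            hits += 1
    return hits / total


def brute_cooccurrence(P: np.ndarray) -> np.ndarray:
    """Explicit double-loop feature co-occurrence counts (diagonal zeroed)."""
    d = P.shape[1]
    I = np.zeros((d, d))
    for f in range(d):
        for g in range(d):
            if f == g:
                continue
            I[f, g] = sum(int(row[f] and row[g]) for row in P)
    return I
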