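"""Synthetic climber/expedition cohorts with planted structure.

The generator emulates the features of real expedition logs that the
analyses rely on: persistent subgroups (a new expedition re-uses a block of
an earlier roster with probability rho, so repeated simplices arise),
success odds that grow with a climber's influence, cooperative vs polarized
regimes that spill benefits to — or withhold them from — members outside
the core subgroup, and a repeated-partner multiplier on failure.

Influence entering the outcome model is recomputed incrementally from the
history generated so far, with exactly the analysis-side definition (largest
roster intersection with a previous joint expedition, minus one), so planted
effects and measured effects share one scale. Randomness is a single seed
split into per-expedition substreams, so cohorts are reproducible.
"""
from __future__ import annotations

import bisect
import math
from collections import defaultdict
from itertools import accumulate
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable

import numpy as np

from .records import (
    ClimberExpeditionRecord,
    Expedition,
    FailureCause,
    Outcome,
)

#: peak catalogue: id -> height in meters (four peaks reach the 8000 m zone)
PEAKS: tuple[tuple[str, float], ...] = (
    ("EVER", 8849.0),
    ("KANG", 8586.0),
    ("DHA1", 8167.0),
    ("ANN1", 8091.0),
    ("HIML", 7126.0),
    ("PUMO", 7161.0),
    ("AMAD", 6812.0),
    ("ISLA", 6189.0),
)

#: order of the six binary personal features drawn from feature_prevalences
FEATURE_ORDER = (
    "age_below_median",
    "sex_male",
    "modal_nationality",
    "experience_8000m",
    "oxygen_ascent",
    "oxygen_descent",
)


class GeneratorConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic cohort.

    Log-odds parameters act on the per-member success logit
    ``beta0 + beta_zeta * zeta_i + regime term + feature effects``;
    ``cooperative_spillover`` is log-odds per unit of the expedition's
    maximal simplicial dimension granted to members outside the core
    subgroup, ``polarized_penalty`` a flat log-odds deduction for the same
    members in polarized expeditions. ``partner_failure_multiplier`` scales
    the failure probability of records with at least one repeated partner.
    """

    n_climbers: int = 150
    n_expeditions: int = 400
    expedition_size_range: tuple[int, int] = (8, 12)
    group_persistence: float = 0.6  # rho
    seed_block_size_range: tuple[int, int] = (2, 5)
    base_success_logit: float = -0.4  # beta0
    influence_effect: float = 0.8  # beta_zeta, log-odds per unit influence
    regime: str = "mixed"  # cooperative | polarized | mixed
    cooperative_spillover: float = 0.5  # gamma, per unit max dimension
    polarized_penalty: float = 1.0  # delta
    death_prob: float = 0.03
    failure_cause_weights: tuple[float, float, float, float] = (0.35, 0.25, 0.25, 0.15)
    partner_failure_multiplier: float = 1.0  # kappa in (0, 1]
    feature_prevalences: tuple[float, ...] = (0.5, 0.7, 0.3, 0.3, 0.6, 0.2)
    feature_effects: tuple[float, ...] = (0.0,) * 6
    rng_seed: int = 0

    def validate(self) -> None:
        lo, hi = self.expedition_size_range
        if lo < 2 or hi < lo:
            raise GeneratorConfigError("expedition sizes must satisfy 2 <= lo <= hi")
        if self.n_climbers < hi:
            raise GeneratorConfigError(
                f"n_climbers ({self.n_climbers}) must be >= max expedition size ({hi})"
            )
        blo, bhi = self.seed_block_size_range
        if blo < 2 or bhi < blo:
            raise GeneratorConfigError("seed block sizes must satisfy 2 <= lo <= hi")
        for name in ("group_persistence", "death_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GeneratorConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.partner_failure_multiplier <= 1.0:
            raise GeneratorConfigError("partner_failure_multiplier must be in (0, 1]")
        if len(self.failure_cause_weights) != 4 or not math.isclose(
            sum(self.failure_cause_weights), 1.0, abs_tol=1e-9
        ):
            raise GeneratorConfigError("failure_cause_weights must be a 4-vector summing to 1")
        if len(self.feature_prevalences) != 6 or any(
            not 0.0 <= p <= 1.0 for p in self.feature_prevalences
        ):
            raise GeneratorConfigError("feature_prevalences must be six probabilities")
        if len(self.feature_effects) != 6:
            raise GeneratorConfigError("feature_effects must have six entries")
        if self.regime not in ("cooperative", "polarized", "mixed"):
            raise GeneratorConfigError(f"unknown regime {self.regime!r}")


@dataclass
class _Climber:
    climber_id: str
    base_age: int
    young: bool
    sex: str
    nationality: str
    is_hired: bool
    veteran_8000m: bool
    oxygen_ascent: bool
    oxygen_descent: bool


@dataclass
class CohortTruth:
    """Ground truth exposed for parameter-recovery tests."""

    config: GeneratorConfig
    influence: dict[tuple[str, str], int]  # (expedition_id, climber_id) -> zeta
    has_partner: dict[tuple[str, str], bool]
    success_prob: dict[tuple[str, str], float]
    regime_of: dict[str, str]
    core_of: dict[str, frozenset[str]]
    max_dimension: dict[str, int]


def _expit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _truncated_age(rng: np.random.Generator, young: bool) -> int:
    """Discretized normal(38, 9) age, truncated to [18, 75]; the young flag
    selects the below/above-38 half so the age feature has the configured
    prevalence."""
    lo, hi = (18, 38) if young else (38, 75)
    while True:
        a = rng.normal(38.0, 9.0)
        if lo <= a <= hi:
            return int(round(a))


_CAUSES = (
    FailureCause.ALTITUDE,
    FailureCause.LOGISTICS,
    FailureCause.FATIGUE,
    FailureCause.ACCIDENT,
)

_NATIONS = ("USA", "GBR", "JPN", "FRA", "IND")
_EXPEDITIONS_PER_YEAR = 40  # time_index steps per year of climber ageing


@lru_cache(maxsize=8)
def _generate(config: GeneratorConfig) -> tuple[
    tuple[ClimberExpeditionRecord, ...], tuple[Expedition, ...], CohortTruth
]:
    config.validate()
    ss = np.random.SeedSequence(config.rng_seed)
    children = ss.spawn(config.n_expeditions + 1)
    rng_c = np.random.default_rng(children[0])

    p = config.feature_prevalences
    climbers: list[_Climber] = []
    for i in range(config.n_climbers):
        young = rng_c.random() < p[0]
        hired = rng_c.random() < p[2]
        climbers.append(
            _Climber(
                climber_id=f"c{i:05d}",
                young=young,
                base_age=_truncated_age(rng_c, young),
                sex="male" if rng_c.random() < p[1] else "female",
                is_hired=hired,
                nationality="NPL" if hired else _NATIONS[rng_c.integers(len(_NATIONS))],
                veteran_8000m=rng_c.random() < p[3],
                oxygen_ascent=rng_c.random() < p[4],
                oxygen_descent=rng_c.random() < p[5],
            )
        )
    by_id = {c.climber_id: c for c in climbers}
    ids = [c.climber_id for c in climbers]

    member_history: dict[str, list[frozenset[str]]] = defaultdict(list)
    seen_pairs: set[frozenset[str]] = set()
    high_count: dict[str, int] = defaultdict(int)

    records: list[ClimberExpeditionRecord] = []
    expeditions: list[Expedition] = []
    truth = CohortTruth(config, {}, {}, {}, {}, {}, {})

    slo, shi = config.expedition_size_range
    blo, bhi = config.seed_block_size_range
    beta0 = config.base_success_logit
    beta_z = config.influence_effect
    kappa = config.partner_failure_multiplier
    effects = config.feature_effects
    cause_cum = tuple(accumulate(config.failure_cause_weights))

    for e in range(config.n_expeditions):
        rng = np.random.default_rng(children[e + 1])
        eid = f"e{e:05d}"
        size = int(rng.integers(slo, shi + 1))

        roster: list[str] = []
        if e > 0 and rng.random() < config.group_persistence:
            src = expeditions[int(rng.integers(len(expeditions)))]
            src_roster = sorted(src.roster)
            bsize = min(int(rng.integers(blo, bhi + 1)), len(src_roster), size)
            roster = list(rng.choice(src_roster, size=bsize, replace=False))
        chosen = set(roster)
        while len(roster) < size:  # uniform fill by rejection, O(size)
            c = ids[int(rng.integers(config.n_climbers))]
            if c not in chosen:
                chosen.add(c)
                roster.append(c)
        roster_set = frozenset(roster)

        # analysis-side influence at tau=1, computed from the history so far
        zeta: dict[str, int] = {}
        for c in roster:
            best = max(
                (len(prev & roster_set) for prev in member_history[c]), default=1
            )
            zeta[c] = max(best, 1) - 1
        maxd = max(zeta.values())
        core = frozenset(c for c in roster if maxd >= 1 and zeta[c] == maxd)

        if config.regime == "mixed":
            style = "cooperative" if rng.random() < 0.5 else "polarized"
        else:
            style = config.regime

        peak_id, peak_height = PEAKS[int(rng.integers(len(PEAKS)))]
        year_offset = e // _EXPEDITIONS_PER_YEAR

        n_hired = sum(by_id[c].is_hired for c in roster)
        exp = Expedition(
            expedition_id=eid,
            peak_id=peak_id,
            peak_height=peak_height,
            time_index=e,
            roster=roster_set,
            days_to_summit=int(5 + rng.poisson(20)),
            n_camps=int(rng.integers(2, 6)),
            n_members=size - n_hired,
            n_hired=n_hired,
        )

        truth.regime_of[eid] = style
        truth.core_of[eid] = core
        truth.max_dimension[eid] = maxd

        for c in sorted(roster):
            cl = by_id[c]
            has_partner = any(
                frozenset((c, m)) in seen_pairs for m in roster if m != c
            )
            logit = beta0 + beta_z * zeta[c]
            feats = (
                cl.young,
                cl.sex == "male",
                cl.is_hired,
                cl.veteran_8000m or high_count[c] > 0,
                cl.oxygen_ascent,
                cl.oxygen_descent,
            )
            logit += sum(eff for eff, on in zip(effects, feats) if on)
            if maxd >= 1 and c not in core:
                if style == "cooperative":
                    logit += config.cooperative_spillover * maxd
                else:
                    logit -= config.polarized_penalty
            p_success = _expit(logit)
            p_fail = 1.0 - p_success
            if has_partner:
                p_fail *= kappa

            truth.influence[(eid, c)] = zeta[c]
            truth.has_partner[(eid, c)] = has_partner
            truth.success_prob[(eid, c)] = 1.0 - p_fail

            if rng.random() < p_fail:
                if rng.random() < config.death_prob:
                    outcome, cause = Outcome.DEATH, FailureCause.ACCIDENT
                else:
                    outcome = Outcome.NO_SUMMIT
                    cause = _CAUSES[
                        min(bisect.bisect_right(cause_cum, rng.random()), 3)
                    ]
            else:
                outcome, cause = Outcome.SUMMIT_SUCCESS, FailureCause.NONE

            records.append(
                ClimberExpeditionRecord(
                    climber_id=c,
                    expedition_id=eid,
                    age=min(cl.base_age + year_offset, 95),
                    sex=cl.sex,
                    nationality=cl.nationality,
                    is_hired=cl.is_hired,
                    oxygen_ascent=cl.oxygen_ascent,
                    oxygen_descent=cl.oxygen_descent,
                    experience_8000m=int(cl.veteran_8000m) + high_count[c],
                    outcome=outcome,
                    failure_cause=cause,
                )
            )

        expeditions.append(exp)
        for c in roster:
            member_history[c].append(roster_set)
            if peak_height >= 8000.0:
                high_count[c] += 1
        for a, b in ((a, b) for i, a in enumerate(roster) for b in roster[i + 1 :]):
            seen_pairs.add(frozenset((a, b)))

    return tuple(records), tuple(expeditions), truth


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[list[ClimberExpeditionRecord], list[Expedition]]:
    """Generate a cohort under ``config``; deterministic in ``rng_seed``."""
    records, expeditions, _ = _generate(config)
    return list(records), list(expeditions)


def planted_truth(config: GeneratorConfig) -> CohortTruth:
    """Ground truth (planted parameters, latent influence trajectories,
    regimes, partner flags) for the cohort ``config`` generates."""
    return _generate(config)[2]
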