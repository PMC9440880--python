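"""Repeated-partner flags and failure-ratio analysis."""
import numpy as np
import pytest

from summitplex.partners import (
    default_experience_bins,
    failure_ratio_analysis,
    repeated_partner_flags,
)
from summitplex.records import ClimberExpeditionRecord, FailureCause, Outcome
from oracles import make_expedition


def _rec(c, e, outcome=Outcome.NO_SUMMIT, cause=FailureCause.FATIGUE):
    if outcome is Outcome.SUMMIT_SUCCESS:
        cause = FailureCause.NONE
    return ClimberExpeditionRecord(
        climber_id=c, expedition_id=e, age=30, sex="male", nationality="USA",
        is_hired=False, oxygen_ascent=False, oxygen_descent=False,
        experience_8000m=0, outcome=outcome, failure_cause=cause,
    )


def test_first_expeditions_have_no_repeated_partners():
    exps = [make_expedition("e1", 1, {"a", "b"}), make_expedition("e2", 2, {"c", "d"})]
    records = [_rec(c, e) for e, cs in [("e1", "ab"), ("e2", "cd")] for c in cs]
    flags = repeated_partner_flags(records, exps)
    assert not any(flags.values())


def test_repeat_pair_flags_second_meeting_only():
    exps = [make_expedition("e1", 1, {"a", "b"}), make_expedition("e2", 2, {"a", "b"})]
    records = [_rec(c, e) for e in ("e1", "e2") for c in "ab"]
    flags = repeated_partner_flags(records, exps)
    assert flags == {
        ("a", "e1"): False, ("b", "e1"): False,
        ("a", "e2"): True, ("b", "e2"): True,
    }


def test_flags_match_bruteforce_pairwise_history():
    from summitplex.synthetic import GeneratorConfig, generate_cohort

    cfg = GeneratorConfig(n_climbers=30, n_expeditions=50,
                          expedition_size_range=(3, 6), rng_seed=9)
    records, expeditions = generate_cohort(cfg)
    flags = repeated_partner_flags(records, expeditions)
    order = {e.expedition_id: e.time_index for e in expeditions}
    rosters = {e.expedition_id: e.roster for e in expeditions}
    for rec in records:
        t = order[rec.expedition_id]
        expected = any(
            rec.climber_id in rosters[o] and m in rosters[o]
            for m in rosters[rec.expedition_id] - {rec.climber_id}
            for o in rosters
            if order[o] < t
        )
        assert flags[(rec.climber_id, rec.expedition_id)] == expected


def _toy_bin_cohort():
    """One climber accumulates prior climbs with always-new partners; the
    late expeditions (prior climbs 15+) mix fatigue failures and summits so
    the experience bin has a nonzero pooled failure rate."""
    exps, records = [], []
    for i in range(20):
        e = make_expedition(f"w{i:02d}", i, {"x", f"f{i}"})
        exps.append(e)
        x_outcome = Outcome.NO_SUMMIT if i >= 15 else Outcome.SUMMIT_SUCCESS
        records += [_rec("x", e.expedition_id, x_outcome),
                    _rec(f"f{i}", e.expedition_id, Outcome.SUMMIT_SUCCESS)]
    return exps, records


def test_empty_bin_yields_nan_not_crash():
    exps, records = _toy_bin_cohort()
    table = failure_ratio_analysis(records, exps, bins=[(100, 105)])
    assert table["ratio"].isna().all()
    assert (table["n_records"] == 0).all()


def test_flagged_records_without_failures_give_zero_ratio():
    exps, records = _toy_bin_cohort()
    # x meets f0 again at t=30 (flagged) and summits; unflagged stranger fails
    e = make_expedition("meet", 30, {"x", "f0", "s1"})
    exps.append(e)
    records += [
        _rec("x", "meet", Outcome.SUMMIT_SUCCESS),
        _rec("f0", "meet", Outcome.SUMMIT_SUCCESS),
        _rec("s1", "meet", Outcome.NO_SUMMIT, FailureCause.FATIGUE),
    ]
    table = failure_ratio_analysis(records, exps, bins=[(15, 25)])
    fat = table[table["category"] == "fatigue"].iloc[0]
    assert fat["n_records_with_partner"] == 1
    assert fat["ratio"] == 0.0


def test_ratios_invariant_to_record_duplication():
    """Pooled rates are record-weighted, so duplicating every record leaves
    every defined ratio unchanged."""
    from summitplex.synthetic import GeneratorConfig, generate_cohort

    cfg = GeneratorConfig(n_climbers=25, n_expeditions=60,
                          expedition_size_range=(3, 5),
                          group_persistence=0.4, rng_seed=2)
    records, exps = generate_cohort(cfg)
    bins = [(2, 6), (6, 10)]
    base = failure_ratio_analysis(records, exps, bins=bins)
    flags = repeated_partner_flags(records, exps)
    # duplication: double-weight every record by repeating the pooled lists
    import summitplex.partners as sp

    doubled = failure_ratio_analysis(records + records, exps,
                                     flags=flags, bins=bins)
    for (_, r1), (_, r2) in zip(base.iterrows(), doubled.iterrows()):
        if np.isnan(r1["ratio"]):
            assert np.isnan(r2["ratio"])
        else:
            assert r2["ratio"] == pytest.approx(r1["ratio"])


def test_null_ratios_stay_inside_band_across_seeds():
    """With no planted partner effect (kappa = 1) the per-bin per-category
    failure ratios are unbiased at 1; fewer than 10% of defined entries may
    leave [0.8, 1.2] across 20 seeded cohorts of ~5000+ binned records."""
    from summitplex.synthetic import GeneratorConfig, generate_cohort

    outside = total = 0
    for seed in range(20):
        cfg = GeneratorConfig(
            n_climbers=500, n_expeditions=4000, expedition_size_range=(3, 5),
            group_persistence=0.5, seed_block_size_range=(2, 3),
            influence_effect=0.0, cooperative_spillover=0.0,
            polarized_penalty=0.0, partner_failure_multiplier=1.0,
            rng_seed=100 + seed,
        )
        records, exps = generate_cohort(cfg)
        table = failure_ratio_analysis(records, exps)
        defined = table["ratio"].dropna()
        outside += int(((defined < 0.8) | (defined > 1.2)).sum())
        total += len(defined)
    assert total >= 20 * 15  # bins are populated
    assert outside / total < 0.10


def test_default_bins_run_up_to_forty():
    assert default_experience_bins() == [
        (15, 20), (20, 25), (25, 30), (30, 35), (35, 40)
    ]
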