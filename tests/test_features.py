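"""Feature bipartite projection, eigenvector centrality, factor PCCs."""
import numpy as np
import pytest

from summitplex.features import (
    FEATURE_NAMES,
    build_feature_matrix,
    centrality_comparison,
    eigenvector_centrality,
    factor_correlations,
    feature_row,
    project_features,
)
from summitplex.records import ClimberExpeditionRecord, FailureCause, Outcome
from oracles import brute_cooccurrence, make_expedition


def _rec(c, e, success=True, **kw):
    defaults = dict(
        age=30, sex="male", nationality="USA", is_hired=False,
        oxygen_ascent=False, oxygen_descent=False, experience_8000m=0,
    )
    defaults.update(kw)
    return ClimberExpeditionRecord(
        climber_id=c, expedition_id=e,
        outcome=Outcome.SUMMIT_SUCCESS if success else Outcome.NO_SUMMIT,
        failure_cause=FailureCause.NONE if success else FailureCause.FATIGUE,
        **defaults,
    )


def test_feature_row_direct_encoding():
    """Climber aged 30 (median 40), male, oxygen both ways, no high-altitude
    experience, non-modal nationality -> (1,1,0,0,1,1)."""
    rec = _rec("a", "e1", age=30, sex="male", nationality="USA",
               oxygen_ascent=True, oxygen_descent=True, experience_8000m=0)
    row = feature_row(rec, median_age=40.0, modal_nationality="NPL")
    assert row.tolist() == [1, 1, 0, 0, 1, 1]


def test_small_expeditions_are_skipped():
    exps = [make_expedition("tiny", 1, {"a", "b"})]
    records = [_rec("a", "tiny"), _rec("b", "tiny")]
    matrices, skipped = build_feature_matrix(records, exps, min_members=12)
    assert matrices == {} and skipped == ["tiny"]


def test_empty_failure_group_yields_zero_rows():
    roster = {f"c{i}" for i in range(12)}
    exps = [make_expedition("big", 1, roster)]
    records = [_rec(c, "big", success=True) for c in roster]
    matrices, _ = build_feature_matrix(records, exps, min_members=12)
    p_succ, p_fail = matrices["big"]
    assert len(p_succ) == 12 and len(p_fail) == 0


def test_projection_counts_cooccurrences():
    P = np.array([[1, 1, 1, 1, 1, 1]])
    I = project_features(P)
    off = I[~np.eye(6, dtype=bool)]
    assert (off == 1).all() and (np.diag(I) == 0).all()
    P2 = np.array([[1, 1, 0, 0, 0, 0], [0, 0, 1, 1, 0, 0]])
    assert project_features(P2)[0, 2] == 0


def test_projection_matches_double_loop(default_cohort):
    records, expeditions = default_cohort
    rng = np.random.default_rng(29)
    P = rng.integers(0, 2, size=(40, 6))
    I = project_features(P)
    assert np.array_equal(I, brute_cooccurrence(P))
    assert np.array_equal(I, I.T)


def test_uniform_centrality_on_complete_graph():
    I = np.ones((6, 6)) - np.eye(6)
    res = eigenvector_centrality(I)
    assert not res.degenerate
    assert np.allclose(res.vector, np.ones(6) / np.sqrt(6), atol=1e-9)


def test_star_graph_closed_form():
    """Star with 4 leaves: center 1/sqrt(2), each leaf 1/(2*sqrt(2))."""
    I = np.zeros((5, 5))
    I[0, 1:] = I[1:, 0] = 1.0
    res = eigenvector_centrality(I)
    assert res.vector[0] == pytest.approx(1 / np.sqrt(2), abs=1e-8)
    assert np.allclose(res.vector[1:], 1 / (2 * np.sqrt(2)), atol=1e-8)


def test_centrality_matches_dense_eigensolver():
    rng = np.random.default_rng(29)
    P = rng.integers(0, 2, size=(40, 6))
    I = project_features(P)
    res = eigenvector_centrality(I)
    vals, vecs = np.linalg.eigh(I)
    ref = np.abs(vecs[:, np.argmax(vals)])
    assert np.allclose(res.vector, ref, atol=1e-8)
    assert res.vector.min() >= 0
    assert np.linalg.norm(res.vector) == pytest.approx(1.0, abs=1e-9)


def test_centrality_permutation_equivariance():
    rng = np.random.default_rng(31)
    P = rng.integers(0, 2, size=(25, 6))
    I = project_features(P)
    perm = rng.permutation(6)
    base = eigenvector_centrality(I).vector
    permuted = eigenvector_centrality(I[np.ix_(perm, perm)]).vector
    assert np.allclose(permuted, base[perm], atol=1e-8)


def test_zero_matrix_is_degenerate_uniform():
    res = eigenvector_centrality(np.zeros((6, 6)))
    assert res.degenerate
    assert np.allclose(res.vector, np.ones(6) / np.sqrt(6))


def test_identical_groups_have_zero_differences():
    c = np.arange(1.0, 7.0)
    c /= np.linalg.norm(c)
    cents = {"e1": (c, c.copy()), "e2": (c * 1.0, c.copy())}
    table = centrality_comparison(cents)
    assert np.allclose(table["difference"], 0.0)


def test_single_expedition_gives_nan_standard_errors():
    c = np.ones(6) / np.sqrt(6)
    table = centrality_comparison({"e1": (c, None)})
    assert table["se_success"].isna().all()
    assert table["mean_failure"].isna().all()


def test_planted_oxygen_effect_ranks_top_two():
    """A strong planted oxygen-ascent effect must surface among the two
    largest success-minus-failure centrality differences."""
    from summitplex.features import expedition_feature_centralities
    from summitplex.synthetic import GeneratorConfig, generate_cohort

    cfg = GeneratorConfig(
        n_climbers=200, n_expeditions=40, expedition_size_range=(13, 16),
        group_persistence=0.3, influence_effect=0.2,
        cooperative_spillover=0.0, polarized_penalty=0.0,
        base_success_logit=-0.6,
        feature_effects=(0.0, 0.0, 0.0, 0.0, 1.5, 0.0),
        rng_seed=42,
    )
    records, expeditions = generate_cohort(cfg)
    cents = expedition_feature_centralities(records, expeditions)
    table = centrality_comparison(cents)  # ascending difference
    top_two = set(table["feature"].iloc[-2:])
    assert "oxygen_ascent" in top_two


def test_factor_pcc_sign_recovery_and_null():
    rng = np.random.default_rng(5)
    exps, rates = [], {}
    for i in range(200):
        days = int(rng.integers(10, 60))
        roster = frozenset({f"a{i}", f"b{i}", f"h{i}"})
        import dataclasses

        e = dataclasses.replace(
            make_expedition(f"e{i}", i, roster),
            days_to_summit=days, n_camps=int(rng.integers(2, 6)),
            n_members=2, n_hired=1,
        )
        exps.append(e)
        rates[e.expedition_id] = float(np.clip(1 - days / 60 + rng.normal(0, 0.1), 0, 1))
    table = factor_correlations(exps, rates).set_index("factor")
    assert table.loc["days_to_summit", "pcc"] < -0.5
    assert table.loc["days_to_summit", "p"] < 1e-6

    # permuted rates: no factor should correlate
    rng6 = np.random.default_rng(6)
    vals = list(rates.values())
    rng6.shuffle(vals)
    shuffled = dict(zip(rates.keys(), vals))
    null = factor_correlations(exps, shuffled).set_index("factor")
    defined = null["pcc"].dropna()
    assert (defined.abs() < 0.2).all()


def test_constant_factor_is_undefined():
    exps = [make_expedition(f"e{i}", i, {f"a{i}", f"b{i}"}) for i in range(5)]
    rates = {e.expedition_id: 0.1 * i for i, e in enumerate(exps)}
    table = factor_correlations(exps, rates).set_index("factor")
    assert np.isnan(table.loc["n_camps", "pcc"])  # constant n_camps=3
    assert table.loc["n_camps", "note"] == "zero variance"
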