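"""Simplicial-complex construction, weights, filtration, and influence."""
import pytest
from hypothesis import given, settings, strategies as st

from summitplex.complexes import (
    ParameterError,
    build_complex,
    co_influence,
    filtration_sweep,
    influence,
    serialize_complex,
    simplex_census,
)
from oracles import (
    brute_census,
    brute_complex,
    brute_influence,
    make_expedition,
    random_instance,
)


def _triangle_instance():
    """Three climbers with four previous joint expeditions."""
    hist = [
        make_expedition(f"h{k}", k, {"i", "j", "k", f"s{k}"}) for k in range(4)
    ]
    cur = make_expedition("cur", 9, {"i", "j", "k", "newcomer"})
    return hist, cur


def test_repeated_triple_becomes_weighted_triangle():
    hist, cur = _triangle_instance()
    cx = build_complex(hist, cur, tau=1)
    assert cx.weight({"i", "j", "k"}) == 4
    assert cx.max_dimension == 2
    # closure: both edges and vertices of the triangle are stored
    assert cx.weight({"i", "j"}) == 4
    assert cx.vertex_weight("i") == 4
    assert cx.vertex_weight("newcomer") == 0


def test_empty_history_leaves_only_vertices():
    cur = make_expedition("cur", 5, {"a", "b", "c"})
    cx = build_complex([], cur, tau=1)
    assert cx.max_dimension == 0
    assert simplex_census(cx) == {0: 3}
    assert all(cx.influence(c) == 0 for c in cur.roster)
    assert co_influence(cx) == 0.0


def test_filled_triangle_census():
    hist, cur = _triangle_instance()
    cx = build_complex(hist, make_expedition("c2", 9, {"i", "j", "k"}), tau=1)
    assert simplex_census(cx) == {0: 3, 1: 3, 2: 1}


def test_influence_from_nested_joint_histories():
    """Roster intersections of sizes 3, 5, 7 containing the climber give
    influence 6; an isolated climber has influence 0."""
    roster = {"c"} | {f"m{i}" for i in range(8)}
    sizes = (3, 5, 7)
    hist = [
        make_expedition(f"h{k}", k, {"c"} | {f"m{i}" for i in range(n - 1)} | {f"z{k}"})
        for k, n in enumerate(sizes)
    ]
    cur = make_expedition("cur", 10, roster)
    cx = build_complex(hist, cur, tau=1)
    assert influence(cx, "c") == 6
    assert cx.influence("m5") == 6  # member of the size-7 intersection
    assert cx.influence("m7") == 0  # never climbed with roster members


def test_influence_requires_roster_membership():
    cur = make_expedition("cur", 5, {"a", "b"})
    cx = build_complex([], cur, tau=1)
    with pytest.raises(KeyError):
        cx.influence("stranger")


def test_tau_must_be_positive():
    cur = make_expedition("cur", 5, {"a", "b"})
    with pytest.raises(ParameterError):
        build_complex([], cur, tau=0)
    with pytest.raises(ParameterError):
        filtration_sweep([], cur, [2, 1])


def test_history_must_be_strictly_earlier():
    cur = make_expedition("cur", 5, {"a", "b"})
    late = make_expedition("late", 5, {"a", "c"})
    with pytest.raises(ParameterError):
        build_complex([late], cur, tau=1)


def test_triangle_persistence_across_thresholds():
    """Weight-4 triangle persists for tau <= 4 and vanishes at tau = 5."""
    hist, cur = _triangle_instance()
    for tau, present in [(1, True), (4, True), (5, False)]:
        cx = build_complex(hist, cur, tau)
        has = frozenset({"i", "j", "k"}) in cx._enumerate()
        assert has is present


@pytest.mark.parametrize("seed", range(10))
def test_complex_matches_subset_enumeration(seed):
    """Lazy intersection-based construction equals exhaustive subset
    enumeration, at tau = 1 and tau = 2."""
    hist_exps, current, history, roster = random_instance(seed)
    for tau in (1, 2):
        cx = build_complex(hist_exps, current, tau)
        expected = brute_complex(history, roster, tau)
        assert cx._enumerate() == expected
        assert simplex_census(cx) == brute_census(history, roster, tau)
        for c in roster:
            assert cx.influence(c) == brute_influence(history, roster, c, tau)


def test_filtration_nesting_and_monotonicity():
    for seed in (3, 7, 11):
        hist_exps, current, history, roster = random_instance(seed)
        sweep = filtration_sweep(hist_exps, current, [1, 2, 3, 4])
        prev = None
        prev_dim = None
        for cx in sweep:
            simp = set(cx._enumerate())
            if prev is not None:
                assert simp <= prev
                assert cx.max_dimension <= prev_dim
            for c in roster:
                pass  # influence monotonicity asserted below
            prev, prev_dim = simp, cx.max_dimension
        for c in roster:
            zetas = [cx.influence(c) for cx in sweep]
            assert zetas == sorted(zetas, reverse=True)


def test_face_weights_dominate_simplex_weights():
    for seed in (0, 5, 9):
        hist_exps, current, _, _ = random_instance(seed)
        cx = build_complex(hist_exps, current, tau=1)
        weights = cx._enumerate()
        for s, w in weights.items():
            for v in s:
                face = s - {v}
                if len(face) >= 2:
                    assert weights[face] >= w
                else:
                    assert cx.vertex_weight(next(iter(face))) >= w


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    seed=st.integers(0, 10_000),
    tau=st.integers(1, 3),
)
def test_closure_property(seed, tau):
    """Every face of every stored simplex is stored (closure under
    inclusion), and influence never exceeds the complex dimension."""
    hist_exps, current, _, roster = random_instance(seed, n_roster=4, n_history=6)
    cx = build_complex(hist_exps, current, tau)
    weights = cx._enumerate()
    for s in weights:
        for v in s:
            face = s - {v}
            if len(face) >= 2:
                assert face in weights
    for c in roster:
        assert cx.influence(c) <= cx.max_dimension


def test_serialization_lists_every_simplex():
    hist, cur = _triangle_instance()
    cx = build_complex(hist, cur, tau=1)
    df = serialize_complex(cx)
    assert len(df) == len(cx.simplices)
    assert set(df.columns) == {"expedition_id", "tau", "vertices", "dimension", "weight"}
    tri = df[df["vertices"] == "i|j|k"]
    assert tri["weight"].iloc[0] == 4 and tri["dimension"].iloc[0] == 2
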