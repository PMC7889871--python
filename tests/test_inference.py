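import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import commscape as cs
from commscape.inference import InferenceParams, aggregate_pathways, trimean

from conftest import constant_group_expression


# -------------------------------------------------------------- trimean

def trimean_oracle(values):
    """Independent type-7 quartile interpolation, written from scratch."""
    v = sorted(values)
    n = len(v)

    def q(p):
        h = (n - 1) * p
        lo = math.floor(h)
        if lo + 1 >= n:
            return v[lo]
        return v[lo] + (h - lo) * (v[lo + 1] - v[lo])

    return 0.5 * q(0.5) + 0.25 * (q(0.25) + q(0.75))


@pytest.mark.parametrize(
    "values,expected",
    [
        ([1, 2, 3, 4, 5], 3.0),
        ([7.0] * 6, 7.0),
        ([0, 0, 0, 0, 0, 0, 0, 1], 0.0),  # >75% zeros -> Q3 = 0
    ],
)
def test_trimean_known_values(values, expected):
    assert trimean(values) == pytest.approx(expected)


@settings(max_examples=300, deadline=None, derandomize=True)
@given(st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=8))
def test_trimean_matches_oracle_on_short_vectors(values):
    assert trimean(values) == pytest.approx(trimean_oracle(values), abs=1e-9)


def test_trimean_empty_raises():
    with pytest.raises(ValueError):
        trimean([])


def test_group_expression_cell_order_invariant():
    rng = np.random.default_rng(0)
    X = rng.random((3, 30))
    labels = rng.choice(["A", "B"], 30)
    expr = cs.ExpressionMatrix(X, ["g1", "g2", "g3"], [f"c{i}" for i in range(30)])
    ge1 = cs.group_expression(expr, cs.CellGrouping.from_labels(labels))
    perm = rng.permutation(30)
    expr2 = cs.ExpressionMatrix(X[:, perm], ["g1", "g2", "g3"], [f"c{i}" for i in range(30)])
    ge2 = cs.group_expression(expr2, cs.CellGrouping.from_labels(labels[perm]))
    np.testing.assert_allclose(ge1.EM, ge2.EM)


# ------------------------------------------------ complex / receptor algebra

@pytest.mark.parametrize(
    "vals,subunits,expected",
    [
        ({"a": 4.0, "b": 1.0}, ["a", "b"], 2.0),
        ({"a": 3.0, "b": 0.0}, ["a", "b"], 0.0),  # any zero subunit inactivates
        ({"a": 5.0}, ["a"], 5.0),
        ({"a": 5.0}, ["a", "missing"], 0.0),
    ],
)
def test_complex_expression(vals, subunits, expected):
    assert cs.complex_expression(vals, subunits) == pytest.approx(expected)


@pytest.mark.parametrize(
    "R,RA,RI,expected", [(1, 1, 0, 2.0), (1, 0, 1, 0.5), (3, 0, 0, 3.0)]
)
def test_modulated_receptor(R, RA, RI, expected):
    assert cs.modulated_receptor(R, RA, RI) == pytest.approx(expected)


# --------------------------------------------------- mass-action arithmetic

def mass_action_oracle(L, R, AG_i=None, AG_j=None, AN_i=None, AN_j=None,
                       RA_j=0.0, RI_j=0.0, Kh=0.5, n=1.0, pop=None):
    """Scalar re-derivation of the communication probability."""
    Rm = R * (1 + RA_j) / (1 + RI_j)
    x = (L * Rm) ** n
    p = x / (Kh**n + x) if x > 0 else 0.0
    for ag in (AG_i, AG_j):
        if ag is not None:
            p *= 1 + ag / (Kh + ag)
    for an in (AN_i, AN_j):
        if an is not None:
            p *= Kh / (Kh + an)
    if pop is not None:
        p *= pop
    return p


def _one_pair_db(**kw):
    return cs.LRDatabase(
        [
            cs.LRInteraction(
                id="p", ligand_subunits=["L"], receptor_subunits=["R"],
                pathway="PW", annotation="secreted_signaling", **kw,
            )
        ]
    )


def _tensor(db, levels, **params):
    expr, grouping = constant_group_expression(levels)
    ct = cs.compute_probability(
        expr, grouping, db, de=None,
        params=InferenceParams(min_cells=1, **params),
    )
    return ct.P[:, :, 0]


def test_probability_basic_hill_point():
    P = _tensor(_one_pair_db(), {"L": [1, 0], "R": [0, 1]}, population_size=False)
    assert P[0, 1] == pytest.approx(2 / 3)  # 1*1 / (0.5 + 1)
    assert P[1, 0] == 0.0


def test_population_size_factor_quarters_two_equal_groups():
    P = _tensor(_one_pair_db(), {"L": [1, 1], "R": [1, 1]}, population_size=True)
    assert P[0, 1] == pytest.approx((2 / 3) * (1 / 4))


def test_antagonist_at_Kh_quarters_probability():
    db = _one_pair_db(antagonists=frozenset({"AN"}))
    base = _tensor(db, {"L": [1, 1], "R": [1, 1], "AN": [0, 0]}, population_size=False)
    mod = _tensor(db, {"L": [1, 1], "R": [1, 1], "AN": [0.5, 0.5]}, population_size=False)
    np.testing.assert_allclose(mod, base * 0.25)


def test_zero_subunit_zeroes_whole_pair():
    db = cs.LRDatabase(
        [
            cs.LRInteraction(id="p", ligand_subunits=["L"],
                             receptor_subunits=["R1", "R2"], pathway="PW",
                             annotation="secreted_signaling")
        ]
    )
    P = _tensor(db, {"L": [1, 1], "R1": [1, 1], "R2": [0, 0]}, population_size=False)
    assert np.all(P == 0)


def test_full_model_matches_scalar_oracle():
    db = _one_pair_db(
        agonists=frozenset({"AG"}),
        antagonists=frozenset({"AN"}),
        co_stimulatory=frozenset({"RA"}),
        co_inhibitory=frozenset({"RI"}),
    )
    levels = {
        "L": [0.8, 0.1], "R": [0.2, 0.9], "AG": [0.3, 0.6],
        "AN": [0.1, 0.4], "RA": [0.5, 0.2], "RI": [0.0, 0.7],
    }
    P = _tensor(db, levels, population_size=True, Kh=0.5, hill_n=1.0)
    for i in range(2):
        for j in range(2):
            expected = mass_action_oracle(
                L=levels["L"][i], R=levels["R"][j],
                AG_i=levels["AG"][i], AG_j=levels["AG"][j],
                AN_i=levels["AN"][i], AN_j=levels["AN"][j],
                RA_j=levels["RA"][j], RI_j=levels["RI"][j],
                pop=0.25,
            )
            assert P[i, j] == pytest.approx(expected, rel=1e-9)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    L=st.floats(0.01, 5), R=st.floats(0.01, 5), dL=st.floats(0.01, 2),
    AG=st.floats(0, 3), AN=st.floats(0, 3), dAN=st.floats(0.01, 2),
)
def test_probability_monotonicity(L, R, dL, AG, AN, dAN):
    """P rises with ligand and agonist, falls with antagonist."""
    base = mass_action_oracle(L, R, AG, AG, AN, AN, 0, 0)
    assert mass_action_oracle(L + dL, R, AG, AG, AN, AN, 0, 0) >= base
    assert mass_action_oracle(L, R, AG + dL, AG, AN, AN, 0, 0) >= base
    assert mass_action_oracle(L, R, AG, AG, AN + dAN, AN, 0, 0) <= base


def test_hill_limits():
    assert mass_action_oracle(1e9, 1.0, None, None, None, None) == pytest.approx(1.0)
    # at L*R = Kh the Hill term sits at one half
    assert mass_action_oracle(0.5, 1.0, None, None, None, None) == pytest.approx(0.5)


def test_hill_exponent_uses_Kh_power():
    p = mass_action_oracle(1.0, 1.0, None, None, None, None, Kh=0.5, n=2)
    assert p == pytest.approx(1 / (0.25 + 1))


def test_population_toggle_exact_factor(planted_dataset):
    _, db, expr, grouping, _ = planted_dataset
    on = cs.compute_probability(expr, grouping, db, params=InferenceParams(population_size=True))
    off = cs.compute_probability(expr, grouping, db, params=InferenceParams(population_size=False))
    sizes = grouping.group_sizes
    factor = np.outer(sizes, sizes) / grouping.n**2
    np.testing.assert_allclose(on.P, off.P * factor[:, :, None], rtol=1e-12)


# ----------------------------------------------------------- permutation test

def test_exchangeable_cells_give_p_one():
    """Identical values in every cell: all permuted P equal observed."""
    db = _one_pair_db()
    X = np.full((2, 40), 1.0)
    expr = cs.ExpressionMatrix(X, ["L", "R"], [f"c{i}" for i in range(40)])
    grouping = cs.CellGrouping.from_labels(["A"] * 20 + ["B"] * 20)
    ct = cs.permutation_test(expr, grouping, db, params=InferenceParams(M=50, seed=0))
    assert np.all(ct.pvals == 1.0)


def test_planted_pair_significant_only_in_planted_direction():
    rng = np.random.default_rng(7)
    n = 200
    X = rng.lognormal(np.log(0.05), 0.2, size=(2, n)) * (rng.random((2, n)) < 0.15)
    labels = np.repeat(["A", "B", "C", "D"], 50)
    X[0, labels == "A"] = 5.0
    X[1, labels == "B"] = 5.0
    expr = cs.ExpressionMatrix(X, ["L", "R"], [f"c{i}" for i in range(n)])
    grouping = cs.CellGrouping.from_labels(labels)
    ct = cs.permutation_test(expr, grouping, _one_pair_db(),
                             params=InferenceParams(M=100, seed=1))
    i, j = grouping.group_names.index("A"), grouping.group_names.index("B")
    assert ct.pvals[i, j, 0] <= 0.01
    others = np.delete(ct.pvals[:, :, 0].ravel(), i * 4 + j)
    assert np.all(others > 0.05)


def test_permutation_reproducible_given_seed(planted_dataset):
    _, db, expr, grouping, _ = planted_dataset
    p = InferenceParams(M=20, seed=42)
    ct1 = cs.permutation_test(expr, grouping, db, params=p)
    ct2 = cs.permutation_test(expr, grouping, db, params=p)
    np.testing.assert_array_equal(ct1.pvals, ct2.pvals)
    np.testing.assert_array_equal(ct1.P, ct2.P)


def test_pvalues_superuniform_under_null():
    spec = cs.SyntheticSpec(seed=3, n_pairs=20, baseline_expressed_fraction=1.0, dropout=0.0)
    db = cs.make_database(spec)
    expr, grouping, _ = cs.make_expression(spec, db)
    ct = cs.permutation_test(expr, grouping, db, params=InferenceParams(seed=3))
    for thr in (0.05, 0.1, 0.25):
        frac = float((ct.pvals < thr).mean())
        se = np.sqrt(thr * (1 - thr) / ct.pvals.size)
        assert frac <= thr + 4 * se


# ------------------------------------------------------- pathway aggregation

def test_aggregate_sums_significant_pairs_and_drops_empty(tiny_db):
    K = 2
    P = np.zeros((K, K, 3))
    pv = np.ones((K, K, 3))
    P[0, 1, 0], pv[0, 1, 0] = 0.2, 0.0  # tgfb1 significant
    P[0, 1, 1], pv[0, 1, 1] = 0.1, 0.5  # wnt1 NOT significant
    P[1, 0, 2], pv[1, 0, 2] = 0.3, 0.0  # col1 significant
    grouping = cs.CellGrouping.from_labels(["A", "B"])
    ct = cs.CommunicationTensor(P=P, pvals=pv, pair_index=["tgfb1", "wnt1", "col1"],
                                grouping=grouping,
                                pathway_index=["TGFb", "WNT", "Collagen"])
    nets = aggregate_pathways(ct, tiny_db, alpha=0.05)
    by_pw = {n.pathway: n for n in nets}
    assert set(by_pw) == {"TGFb", "Collagen"}  # WNT dropped (all p >= alpha)
    assert by_pw["TGFb"].adjacency[0, 1] == pytest.approx(0.2)
    assert cs.information_flow(by_pw["Collagen"]) == pytest.approx(0.3)


def test_information_flow_sums_all_edges():
    net = cs.SignalingNetwork("X", np.array([[0, 0.2], [0.3, 0]]), ["A", "B"])
    assert cs.information_flow(net) == pytest.approx(0.5)
    empty = cs.SignalingNetwork("Y", np.zeros((2, 2)), ["A", "B"])
    assert cs.information_flow(empty) == 0.0


def test_pair_contribution_fractions(tiny_db):
    K = 2
    db = cs.LRDatabase(
        [
            cs.LRInteraction(id="a", ligand_subunits=["L1"], receptor_subunits=["R1"],
                             pathway="PW", annotation="secreted_signaling"),
            cs.LRInteraction(id="b", ligand_subunits=["L2"], receptor_subunits=["R2"],
                             pathway="PW", annotation="secreted_signaling"),
        ]
    )
    P = np.zeros((K, K, 2))
    pv = np.zeros((K, K, 2))
    P[0, 1, 0], P[0, 1, 1] = 3.0, 1.0
    ct = cs.CommunicationTensor(P=P, pvals=pv, pair_index=["a", "b"],
                                grouping=cs.CellGrouping.from_labels(["A", "B"]),
                                pathway_index=["PW", "PW"])
    frac = cs.pair_contribution(ct, db, "PW")
    assert frac == {"a": pytest.approx(0.75), "b": pytest.approx(0.25)}
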