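"""Reaction scoring, imputation, weights, alpha and the module score."""

from __future__ import annotations

import math

import numpy as np
import pytest

from bimod.gpr import GPRRule
from bimod.io import MetabolicModel, Metabolite, Reaction
from bimod.scoring import (
    Module,
    ScoreSet,
    build_score_set,
    compute_alpha,
    impute_missing,
    metabolite_weights,
    orient_scores,
    score_module,
    score_reactions,
)


def model_with_gprs(gprs: dict[str, GPRRule | None]) -> MetabolicModel:
    mets = {"M": Metabolite(id="M")}
    reactions = [
        Reaction(id=rid, metabolite_ids=("M",), gpr=gpr) for rid, gpr in gprs.items()
    ]
    return MetabolicModel(reactions=reactions, metabolites=mets)


@pytest.mark.parametrize(
    "complexes,genes,expected",
    [
        ([{"GLC3"}], {"GLC3": 2.87}, 2.87),
        ([{"g1", "g2"}], {"g1": 1.0, "g2": 3.0}, 2.0),
        # two isozymes: mean of complex means, (4.0 + 2.0)/2
        ([{"g1"}, {"g2", "g3"}], {"g1": 4.0, "g2": 1.0, "g3": 3.0}, 3.0),
    ],
)
def test_reaction_score_hand_examples(complexes, genes, expected):
    model = model_with_gprs({"R": GPRRule.from_complexes(complexes)})
    scores = score_reactions(model, genes)
    assert scores["R"] == pytest.approx(expected, abs=1e-12)


def test_partial_complex_modes():
    gpr = GPRRule.from_complexes([{"g1", "g2"}, {"g3"}])
    model = model_with_gprs({"R": gpr})
    genes = {"g1": 2.0, "g3": 4.0}  # g2 unmeasured
    # default: partial complex keeps the mean of its measured subunits
    assert score_reactions(model, genes)["R"] == pytest.approx(3.0)
    # strict: the partial complex is dropped entirely
    assert score_reactions(model, genes, "strict")["R"] == pytest.approx(4.0)
    # complex with no measured gene is dropped in both modes
    assert score_reactions(model, {"g3": 4.0})["R"] == pytest.approx(4.0)


def test_fully_unmeasured_reaction_left_unscored():
    model = model_with_gprs({
        "R1": GPRRule.from_complexes([{"g1"}]),
        "R2": GPRRule.from_complexes([{"zz"}]),
        "R3": None,
    })
    scores = score_reactions(model, {"g1": 1.5})
    assert set(scores) == {"R1"}


def test_reaction_scoring_matches_bruteforce_enumerator():
    """Randomised GPRs with <= 6 genes against an independent flat evaluator."""
    rng = np.random.default_rng(42)
    genes_all = [f"g{i}" for i in range(6)]
    for _ in range(200):
        n_cplx = int(rng.integers(1, 4))
        complexes = []
        for _ in range(n_cplx):
            size = int(rng.integers(1, 4))
            complexes.append(set(rng.choice(genes_all, size=size, replace=False)))
        measured = {g: float(rng.normal()) for g in genes_all if rng.random() < 0.7}
        model = model_with_gprs({"R": GPRRule.from_complexes(complexes)})
        got = score_reactions(model, measured)

        # oracle: explicit two-level mean over the complex list
        cplx_means = []
        for c in {frozenset(c) for c in complexes}:
            vals = [measured[g] for g in c if g in measured]
            if vals:
                cplx_means.append(sum(vals) / len(vals))
        if cplx_means:
            assert got["R"] == pytest.approx(sum(cplx_means) / len(cplx_means), abs=1e-12)
        else:
            assert "R" not in got


# --- imputation -------------------------------------------------------------


def bare_network(n_r=4, n_m=2):
    import networkx as nx
    from bimod.io import BipartiteNetwork

    g = nx.Graph()
    for i in range(n_r):
        g.add_node(f"r{i}", kind="reaction")
        for j in range(n_m):
            g.add_node(f"m{j}", kind="metabolite")
            g.add_edge(f"r{i}", f"m{j}")
    return BipartiteNetwork(g)


def test_impute_median_fills_unknowns():
    net = bare_network(4)
    known = {"r0": 1.0, "r1": 2.0, "r2": 3.0}
    full = impute_missing(known, net, "median")
    assert full["r3"] == 2.0
    assert {full[r] for r in known} == {1.0, 2.0, 3.0}


def test_impute_zero_centres_and_zeroes():
    net = bare_network(4)
    full = impute_missing({"r0": 1.0, "r1": 2.0, "r2": 3.0}, net, "zero")
    assert (full["r0"], full["r1"], full["r2"], full["r3"]) == (-1.0, 0.0, 1.0, 0.0)


def test_impute_no_unknowns_is_identity():
    net = bare_network(2)
    known = {"r0": 5.0, "r1": -1.0}
    assert impute_missing(known, net, "median") == known


def test_impute_requires_some_data():
    with pytest.raises(ValueError):
        impute_missing({}, bare_network(2), "median")


# --- weights and alpha ------------------------------------------------------


def test_metabolite_weights_are_degrees(small_synthetic_instance):
    _, net, _, _, _ = small_synthetic_instance
    w = metabolite_weights(net)
    assert all(w[c] == net.degree(c) for c in net.metabolite_nodes)
    # bipartite handshake: metabolite degrees sum to the edge count
    assert sum(w.values()) == net.n_edges


@pytest.mark.parametrize(
    "s,w,expected",
    [
        ({"a": 2.0, "b": -1.0, "c": 4.0}, {"x": 1, "y": 2, "z": 3}, 1.5),
        ({"a": 5.0}, {"x": 5}, 1.0),
    ],
)
def test_alpha_hand_examples(s, w, expected):
    assert compute_alpha(s, w) == pytest.approx(expected, abs=1e-12)


def test_alpha_requires_positive_scores():
    with pytest.raises(ValueError, match="direction"):
        compute_alpha({"a": -1.0, "b": -2.0}, {"x": 1})


def test_alpha_scales_inversely_with_weights():
    s = {"a": 2.0, "b": -1.0, "c": 4.0}
    w = {"x": 1, "y": 2, "z": 3}
    a1 = compute_alpha(s, w)
    a3 = compute_alpha(s, {k: 3 * v for k, v in w.items()})
    assert a3 == pytest.approx(a1 / 3)


# --- module score -----------------------------------------------------------


def make_scoreset(s, w, alpha):
    return ScoreSet(s=s, w=w, alpha=alpha)


def test_score_module_hand_examples():
    ss = make_scoreset({"r": 3.0}, {"c": 4}, alpha=0.5)
    mod = Module(reaction_ids=frozenset({"r"}), metabolite_ids=frozenset({"c"}))
    assert score_module(mod, ss) == pytest.approx(math.log(2) * 3 - 2.0, abs=1e-12)

    ss2 = make_scoreset({"r1": 1.0, "r2": 1.0}, {"c": 2}, alpha=1.0)
    mod2 = Module(reaction_ids=frozenset({"r1", "r2"}), metabolite_ids=frozenset({"c"}))
    assert score_module(mod2, ss2) == pytest.approx(math.log(3) * 2 - 2.0, abs=1e-12)

    ss0 = make_scoreset({"r": 0.0}, {"c": 4}, alpha=0.0)
    assert score_module(mod, ss0) == 0.0


def test_score_module_additive_in_reaction_scores():
    ss = make_scoreset({"r1": 1.3, "r2": -0.4}, {"c": 5}, alpha=0.7)
    doubled = make_scoreset({"r1": 2.6, "r2": -0.8}, {"c": 5}, alpha=0.7)
    mod = Module(reaction_ids=frozenset({"r1", "r2"}), metabolite_ids=frozenset({"c"}))
    s1 = score_module(mod, ss)
    s2 = score_module(mod, doubled)
    penalty = 0.7 * 5
    assert s2 + penalty == pytest.approx(2 * (s1 + penalty), abs=1e-12)


def test_score_module_decreasing_in_alpha():
    mod = Module(reaction_ids=frozenset({"r"}), metabolite_ids=frozenset({"c"}))
    lo = score_module(mod, make_scoreset({"r": 1.0}, {"c": 3}, alpha=0.1))
    hi = score_module(mod, make_scoreset({"r": 1.0}, {"c": 3}, alpha=0.9))
    assert hi < lo


def test_score_module_missing_node_errors():
    ss = make_scoreset({"r": 1.0}, {"c": 1}, alpha=1.0)
    mod = Module(reaction_ids=frozenset({"other"}), metabolite_ids=frozenset({"c"}))
    with pytest.raises(KeyError):
        score_module(mod, ss)


# --- orientation ------------------------------------------------------------


def test_orient_down_negates_reactions_only():
    ss = make_scoreset({"r": 2.5}, {"c": 3}, alpha=0.4)
    down = orient_scores(ss, "down")
    assert down.s["r"] == -2.5
    assert down.w == ss.w
    assert down.alpha == ss.alpha
    assert down.direction == "down"


def test_orient_down_is_involution():
    ss = make_scoreset({"r": 2.5, "r2": -1.0}, {"c": 3}, alpha=0.4)
    back = orient_scores(orient_scores(ss, "down"), "down")
    assert back.s == ss.s
    assert back.direction == "up"


def test_build_score_set_down_keeps_up_alpha(small_synthetic_instance):
    """By default alpha comes from the up-oriented scores even for the
    down-direction search; recompute_alpha derives it after negation."""
    _, net, genes, _, model = small_synthetic_instance
    up = build_score_set(net, model, genes, direction="up")
    down = build_score_set(net, model, genes, direction="down")
    assert down.alpha == up.alpha
    assert down.s == {r: -v for r, v in up.s.items()}
    down2 = build_score_set(net, model, genes, direction="down", recompute_alpha=True)
    assert down2.alpha != up.alpha
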