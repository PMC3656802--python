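"""Annealing operations and the full search, including oracle equivalence on
exhaustively enumerable networks."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from bimod.annealing import (
    AnnealingConfig,
    AnnealingState,
    accept_move,
    cool,
    default_t_init,
    default_T_init,
    equilibrium_reached,
    initialize_state,
    propose_toggle,
    run_annealing,
    total_score,
    _CompiledNetwork,
)
from bimod.scoring import Module, ScoreSet, score_module

from conftest import make_tiny_network


def exhaustive_max(net, scores):
    """Brute-force maximum of sigma over all 2^|edges| edge subsets."""
    edges = sorted(net.edges)
    best = 0.0  # empty set
    for bits in range(1, 2 ** len(edges)):
        es = {edges[i] for i in range(len(edges)) if bits >> i & 1}
        best = max(best, total_score(es, net, scores))
    return best


# --- config -----------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        {"max_steps": 0},
        {"cooling_factor": 1.0},
        {"cooling_factor": 0.0},
        {"t_init": 0},
        {"T_init": -1.0},
        {"equilibrium_tol": 0.0},
    ],
)
def test_config_validation(kwargs):
    with pytest.raises(ValueError):
        AnnealingConfig(**kwargs)


# --- state initialisation ---------------------------------------------------


def test_initialize_deterministic_under_seed(tiny_network):
    net, scores = tiny_network
    cfg = AnnealingConfig(t_init=3, seed=9)
    s1 = initialize_state(net, scores, cfg)
    s2 = initialize_state(net, scores, cfg)
    assert s1.E == s2.E
    assert s1.sigma == s2.sigma


def test_initialize_size_and_clamp(tiny_network):
    net, scores = tiny_network
    s = initialize_state(net, scores, AnnealingConfig(t_init=3, seed=0))
    assert len(s.E) == 3
    s_all = initialize_state(net, scores, AnnealingConfig(t_init=10_000, seed=0))
    assert s_all.E == net.edges


# --- total score ------------------------------------------------------------


def test_total_score_empty_and_additive(tiny_network):
    net, scores = tiny_network
    assert total_score(set(), net, scores) == 0.0
    edges = sorted(net.edges)
    # two edges sharing no node form two single-edge components
    disjoint = None
    for e1, e2 in itertools.combinations(edges, 2):
        if not set(e1) & set(e2):
            disjoint = (e1, e2)
            break
    assert disjoint is not None
    both = total_score(set(disjoint), net, scores)
    assert both == pytest.approx(
        total_score({disjoint[0]}, net, scores)
        + total_score({disjoint[1]}, net, scores)
    )


def test_total_score_single_component_matches_score_module(tiny_network):
    net, scores = tiny_network
    r, m = sorted(net.edges)[0]
    mod = Module(reaction_ids=frozenset({r}), metabolite_ids=frozenset({m}))
    assert total_score({(r, m)}, net, scores) == pytest.approx(score_module(mod, scores))


def test_kernel_agrees_with_reference_total_score():
    """The compiled union-find sigma equals the networkx implementation on
    random edge subsets of random networks."""
    rng = np.random.default_rng(0)
    for seed in range(10):
        net, scores = make_tiny_network(seed, n_r=6, n_m=6, max_edges=18)
        comp = _CompiledNetwork(net, scores)
        for _ in range(25):
            mask = rng.random(comp.n_edges) < rng.random()
            es = {comp.edge_list[i] for i in np.flatnonzero(mask)}
            assert comp.sigma(mask.astype(np.bool_)) == pytest.approx(
                total_score(es, net, scores), abs=1e-9
            )


# --- proposals and acceptance ----------------------------------------------


def test_propose_toggle_is_symmetric_difference(tiny_network):
    net, scores = tiny_network
    edges = sorted(net.edges)
    state = AnnealingState(E={edges[0], edges[1]}, sigma=0.0, best_E=set(),
                          best_sigma=0.0, t=2, T=1.0)
    rng = np.random.default_rng(4)
    P = propose_toggle(state, net, rng)
    F = P ^ state.E
    assert len(F) == 2
    assert P == state.E ^ F


def test_accept_move_rules():
    # improving moves always accepted
    assert accept_move(1.0, 0.0, 0.5, rho=0.999999)
    # worsening by exactly T: accept iff rho < 1/e
    assert not accept_move(-1.0, 0.0, 1.0, rho=0.5)
    assert accept_move(-1.0, 0.0, 1.0, rho=0.3678)
    # rho = 0 always accepts
    assert accept_move(-50.0, 0.0, 1.0, rho=0.0)
    # frozen chain: huge worsening at tiny T underflows to certain rejection
    assert not accept_move(-1000.0, 0.0, 1e-6, rho=0.0)


def test_improving_moves_always_accepted_property():
    rng = np.random.default_rng(123)
    n = 100_000
    d = rng.exponential(1.0, size=n)  # strictly positive improvements
    T = rng.uniform(1e-6, 10.0, size=n)
    rho = rng.random(n)
    assert all(accept_move(float(di), 0.0, float(Ti), float(ri))
               for di, Ti, ri in zip(d, T, rho))


# --- equilibrium and cooling ------------------------------------------------


def test_equilibrium_five_percent_rule():
    window = 5
    flat = [7.0] * 10
    assert equilibrium_reached(flat, window, 0.05)
    assert not equilibrium_reached(flat[:9], window, 0.05)
    hist = [100.0] * 5 + [104.0] * 5
    assert equilibrium_reached(hist, window, 0.05)
    hist = [100.0] * 5 + [106.0] * 5
    assert not equilibrium_reached(hist, window, 0.05)


def test_cool_schedule():
    cfg = AnnealingConfig()
    state = AnnealingState(E=set(), sigma=0.0, best_E=set(), best_sigma=0.0,
                          t=10, T=1.0, history=[1.0])
    cool(state, cfg)
    assert (state.t, state.T) == (9, 0.9)
    assert state.history == []
    state.t = 1
    cool(state, cfg)
    assert state.t == 1  # floor at one toggled edge
    T0 = 1.0
    for _ in range(5):
        T0 *= cfg.cooling_factor
    assert T0 == pytest.approx(0.9 ** 5)


# --- full runs --------------------------------------------------------------


def test_run_deterministic_and_self_consistent(tiny_network):
    net, scores = tiny_network
    cfg = AnnealingConfig(max_steps=5000, equilibrium_window=200)
    r1 = run_annealing(net, scores, cfg, seed=2)
    r2 = run_annealing(net, scores, cfg, seed=2)
    assert r1.best_edges == r2.best_edges
    assert r1.best_sigma == r2.best_sigma
    # reported module scores equal score_module recomputed from scratch,
    # and they sum to the reported best sigma
    for mod in r1.modules:
        assert mod.score == pytest.approx(score_module(mod, scores), abs=1e-9)
    assert sum(m.score for m in r1.modules) == pytest.approx(r1.best_sigma, abs=1e-9)
    assert r1.best_sigma >= 0.0  # the empty edge set is always reachable


def test_run_finds_exhaustive_optimum_on_small_networks():
    """Quick oracle check on three tiny instances (the full 20-network sweep
    is part of the acceptance suite)."""
    for seed in (3, 4, 5):
        net, scores = make_tiny_network(seed)
        cfg = AnnealingConfig(max_steps=20_000, equilibrium_window=500)
        run = run_annealing(net, scores, cfg, seed=seed)
        assert run.best_sigma == pytest.approx(exhaustive_max(net, scores), abs=1e-9)


def test_all_negative_scores_give_empty_best(tiny_network):
    net, _ = tiny_network
    s = {r: -1.0 - 0.5 * i for i, r in enumerate(sorted(net.reaction_nodes))}
    w = {m: net.degree(m) for m in net.metabolite_nodes}
    scores = ScoreSet(s=s, w=w, alpha=0.5)
    run = run_annealing(net, scores, AnnealingConfig(max_steps=5000,
                                                     equilibrium_window=200), seed=1)
    assert run.best_sigma <= 0.0
    assert not any(m.score > 0 for m in run.modules)


def test_defaults_derive_from_data(tiny_network):
    net, scores = tiny_network
    n_nodes = len(net.reaction_nodes) + len(net.metabolite_nodes)
    assert default_t_init(net) == max(1, math.ceil(0.01 * n_nodes))
    gains = [abs(scores.s[r]) for r in net.reaction_nodes]
    gains += [scores.alpha * scores.w[c] for c in net.metabolite_nodes]
    expected = (sum(gains) / len(gains)) / math.log(2)
    assert default_T_init(net, scores) == pytest.approx(expected)
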