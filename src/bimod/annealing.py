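"""Simulated-annealing search over edge subsets of the bipartite network.

The search state is a set E of network edges; the objective is the total
score sigma(E) = sum of S(m) over the connected components induced by E.
One move toggles the membership of a random set F of t edges (P = E
symmetric-difference F) and is accepted when rho < exp((sigma(P) -
sigma(E)) / T) with rho uniform on [0,1).  Toggling several edges at once
lets the chain tunnel through low-scoring intermediate configurations.

The schedule is geometric: when the chain reaches thermal equilibrium at the
current temperature (the mean of sigma over one window of steps changes by
at most 5% relative to the previous window), or a per-temperature step cap
is hit, both t and T are multiplied by 0.9.  The search stops after a fixed
total number of steps and reports the best configuration ever seen.

sigma is recomputed from scratch at every proposal by a union-find kernel
(numba-compiled), so the score can never drift from the configuration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from numba import njit

from .io import BipartiteNetwork
from .scoring import Module, ScoreSet, score_module

__all__ = [
    "AnnealingConfig",
    "AnnealingState",
    "AnnealingRun",
    "default_t_init",
    "default_T_init",
    "initialize_state",
    "total_score",
    "propose_toggle",
    "accept_move",
    "equilibrium_reached",
    "cool",
    "run_annealing",
]

log = logging.getLogger(__name__)

Edge = tuple[str, str]


@dataclass(frozen=True)
class AnnealingConfig:
    """Schedule parameters.

    ``t_init`` and ``T_init`` default to values derived from the network and
    the node scores (see :func:`default_t_init` / :func:`default_T_init`).
    """

    max_steps: int = 100_000
    t_init: int | None = None
    T_init: float | None = None
    cooling_factor: float = 0.9
    equilibrium_window: int = 5000
    equilibrium_tol: float = 0.05
    per_temperature_cap: int = 50_000
    seed: int | None = None
    log_every: int = 0  # 0 = log once per temperature stage

    def __post_init__(self) -> None:
        if self.max_steps < 1:
            raise ValueError("max_steps must be positive")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ValueError("cooling_factor must lie in (0, 1)")
        if self.t_init is not None and self.t_init < 1:
            raise ValueError("t_init must be a positive integer")
        if self.T_init is not None and self.T_init <= 0:
            raise ValueError("T_init must be positive")
        if self.equilibrium_window < 1 or self.per_temperature_cap < 1:
            raise ValueError("window and cap must be positive")
        if self.equilibrium_tol <= 0:
            raise ValueError("equilibrium_tol must be positive")


@dataclass
class AnnealingState:
    """Mutable search state (reference, set-based representation)."""

    E: set[Edge]
    sigma: float
    best_E: set[Edge]
    best_sigma: float
    t: int
    T: float
    step: int = 0
    history: list[float] = field(default_factory=list)


@dataclass
class AnnealingRun:
    """Outcome of :func:`run_annealing`: modules from the best configuration
    plus the schedule actually used."""

    modules: list[Module]
    best_sigma: float
    best_edges: set[Edge]
    steps: int
    stages: int
    t_init: int
    T_init: float
    seed: int | None


# ---------------------------------------------------------------------------
# compiled sigma kernel


@njit(cache=True)
def _sigma_masked(eu, ev, mask, gain_s, gain_w, alpha, parent, acc_s, acc_w, cnt):
    """Total score of the components induced by the active edges.

    parent/acc_s/acc_w/cnt are scratch arrays of length n_nodes; parent == -1
    marks a node not incident to any active edge.
    """
    n_nodes = parent.shape[0]
    for i in range(n_nodes):
        parent[i] = -1
    for e in range(eu.shape[0]):
        if not mask[e]:
            continue
        u = eu[e]
        v = ev[e]
        if parent[u] == -1:
            parent[u] = u
        if parent[v] == -1:
            parent[v] = v
        ru = u
        while parent[ru] != ru:
            ru = parent[ru]
        while parent[u] != ru:
            nxt = parent[u]
            parent[u] = ru
            u = nxt
        rv = v
        while parent[rv] != rv:
            rv = parent[rv]
        while parent[v] != rv:
            nxt = parent[v]
            parent[v] = rv
            v = nxt
        if ru != rv:
            parent[rv] = ru
    for i in range(n_nodes):
        acc_s[i] = 0.0
        acc_w[i] = 0.0
        cnt[i] = 0
    for i in range(n_nodes):
        if parent[i] == -1:
            continue
        r = i
        while parent[r] != r:
            r = parent[r]
        acc_s[r] += gain_s[i]
        acc_w[r] += gain_w[i]
        cnt[r] += 1
    sigma = 0.0
    for i in range(n_nodes):
        if cnt[i] > 0 and parent[i] == i:
            sigma += math.log(cnt[i]) * acc_s[i] - alpha * acc_w[i]
    return sigma


class _CompiledNetwork:
    """Index-based view of a network + score set for the hot loop.

    Nodes and edges are sorted lexicographically so the index assignment (and
    hence the whole run) is reproducible across platforms.
    """

    def __init__(self, network: BipartiteNetwork, scores: ScoreSet):
        self.nodes: list[str] = sorted(network.reaction_nodes) + sorted(
            network.metabolite_nodes
        )
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.edge_list: list[Edge] = sorted(network.edges)
        n = len(self.nodes)
        self.eu = np.array([self.index[r] for r, _ in self.edge_list], dtype=np.int64)
        self.ev = np.array([self.index[c] for _, c in self.edge_list], dtype=np.int64)
        self.gain_s = np.zeros(n)
        self.gain_w = np.zeros(n)
        for r in network.reaction_nodes:
            self.gain_s[self.index[r]] = scores.s[r]
        for c in network.metabolite_nodes:
            self.gain_w[self.index[c]] = scores.w[c]
        self.alpha = float(scores.alpha)
        self._parent = np.empty(n, dtype=np.int64)
        self._acc_s = np.empty(n)
        self._acc_w = np.empty(n)
        self._cnt = np.empty(n, dtype=np.int64)

    @property
    def n_edges(self) -> int:
        return len(self.edge_list)

    def sigma(self, mask: np.ndarray) -> float:
        return _sigma_masked(
            self.eu, self.ev, mask, self.gain_s, self.gain_w, self.alpha,
            self._parent, self._acc_s, self._acc_w, self._cnt,
        )


# ---------------------------------------------------------------------------
# reference operations (set-based; used for unit-level reasoning and tests)


def total_score(edge_set: set[Edge], network: BipartiteNetwork, scores: ScoreSet) -> float:
    """sigma(E): sum of S(m) over the connected components induced by E.

    Pure networkx implementation, independent of the compiled kernel.
    """
    if not edge_set:
        return 0.0
    g = nx.Graph()
    g.add_edges_from(edge_set)
    sigma = 0.0
    for comp in nx.connected_components(g):
        module = Module(
            reaction_ids=frozenset(comp & network.reaction_nodes),
            metabolite_ids=frozenset(comp & network.metabolite_nodes),
        )
        sigma += score_module(module, scores)
    return sigma


def default_t_init(network: BipartiteNetwork) -> int:
    """Initial toggle-set size: 1% of the node count, at least 1."""
    n_nodes = len(network.reaction_nodes) + len(network.metabolite_nodes)
    return max(1, math.ceil(0.01 * n_nodes))


def default_T_init(network: BipartiteNetwork, scores: ScoreSet) -> float:
    """Initial temperature: mean absolute single-node score contribution
    (|s(r)| for reactions, alpha*w(c) for metabolites) divided by ln 2, so a
    typical node-scale worsening move starts at ~50% acceptance."""
    gains = [abs(scores.s[r]) for r in network.reaction_nodes]
    gains += [scores.alpha * scores.w[c] for c in network.metabolite_nodes]
    mean_gain = sum(gains) / len(gains)
    return max(mean_gain / math.log(2.0), 1e-12)


def initialize_state(
    network: BipartiteNetwork,
    scores: ScoreSet,
    config: AnnealingConfig,
    rng: np.random.Generator | None = None,
) -> AnnealingState:
    """Draw a uniform random initial edge set of size min(t_init, |edges|)."""
    if network.n_edges == 0:
        raise ValueError("cannot anneal on a network without edges")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    edge_list = sorted(network.edges)
    t = config.t_init if config.t_init is not None else default_t_init(network)
    k = min(t, len(edge_list))
    chosen = rng.choice(len(edge_list), size=k, replace=False)
    E = {edge_list[i] for i in chosen}
    sigma = total_score(E, network, scores)
    T = config.T_init if config.T_init is not None else default_T_init(network, scores)
    return AnnealingState(E=E, sigma=sigma, best_E=set(E), best_sigma=sigma, t=t, T=T)


def propose_toggle(
    state: AnnealingState,
    network: BipartiteNetwork,
    rng: np.random.Generator,
) -> set[Edge]:
    """Toggle set F: t distinct edges drawn uniformly from the FULL edge set;
    the proposal is the symmetric difference E xor F."""
    edge_list = sorted(network.edges)
    k = min(state.t, len(edge_list))
    chosen = rng.choice(len(edge_list), size=k, replace=False)
    F = {edge_list[i] for i in chosen}
    return state.E ^ F


def accept_move(sigma_P: float, sigma_E: float, T: float, rho: float) -> bool:
    """Metropolis rule: accept iff rho < exp((sigma_P - sigma_E)/T).

    Improving moves are always accepted (exp >= 1 > rho); a large positive
    exponent that would overflow counts as acceptance.
    """
    d = (sigma_P - sigma_E) / T
    if d >= 0.0:
        return True
    if d < -745.0:  # exp underflows to exactly 0; rho >= 0 can never be below
        return False
    return rho < math.exp(d)


def equilibrium_reached(history: Sequence[float], window: int, tol: float) -> bool:
    """Thermal-equilibrium test: the mean of sigma over the last ``window``
    steps differs from the mean over the previous window by at most ``tol``
    (relative; absolute when the previous mean is 0)."""
    if len(history) < 2 * window:
        return False
    last = sum(history[-window:]) / window
    prev = sum(history[-2 * window:-window]) / window
    if prev == 0.0:
        return abs(last) <= tol
    return abs(last - prev) <= tol * abs(prev)


def cool(state: AnnealingState, config: AnnealingConfig) -> AnnealingState:
    """Geometric cooling: T <- c*T, t <- max(1, round(c*t)); the temperature
    history is reset."""
    state.T = config.cooling_factor * state.T
    state.t = max(1, round(config.cooling_factor * state.t))
    state.history = []
    return state


# ---------------------------------------------------------------------------
# the full search


def _sample_distinct(rng: np.random.Generator, n: int, k: int, buf: np.ndarray) -> np.ndarray:
    """k distinct integers from [0, n) into buf[:k] (rejection sampling; k << n
    in practice, falls back to a permutation draw when k is a large fraction)."""
    if k * 3 >= n:
        buf[:k] = rng.permutation(n)[:k]
        return buf[:k]
    filled = 0
    while filled < k:
        cand = int(rng.integers(0, n))
        dup = False
        for j in range(filled):
            if buf[j] == cand:
                dup = True
                break
        if not dup:
            buf[filled] = cand
            filled += 1
    return buf[:k]


def run_annealing(
    network: BipartiteNetwork,
    scores: ScoreSet,
    config: AnnealingConfig | None = None,
    seed: int | None = None,
) -> AnnealingRun:
    """Run the full annealing search and return the modules of the
    best-scoring edge set ever visited.

    A single seeded generator drives initialisation, toggle selection and the
    acceptance variable rho, so a run is fully reproducible from its seed.
    Module scores in the result are recomputed from scratch with
    :func:`score_module` on the final node sets.
    """
    if config is None:
        config = AnnealingConfig()
    if seed is None:
        seed = config.seed
    if network.n_edges == 0:
        raise ValueError("cannot anneal on a network without edges")

    net = _CompiledNetwork(network, scores)
    rng = np.random.default_rng(seed)
    n_edges = net.n_edges

    t = config.t_init if config.t_init is not None else default_t_init(network)
    T = config.T_init if config.T_init is not None else default_T_init(network, scores)
    t_init, T_init = t, T

    mask = np.zeros(n_edges, dtype=np.bool_)
    k0 = min(t, n_edges)
    mask[rng.choice(n_edges, size=k0, replace=False)] = True
    sigma = net.sigma(mask)
    best_mask = mask.copy()
    best_sigma = sigma

    window = config.equilibrium_window
    tol = config.equilibrium_tol
    buf = np.empty(n_edges, dtype=np.int64)
    steps = 0
    stages = 0

    while steps < config.max_steps:
        stages += 1
        cum = [0.0]  # cumulative sigma over this temperature stage
        m = 0
        while steps < config.max_steps:
            k = min(t, n_edges)
            F = _sample_distinct(rng, n_edges, k, buf)
            mask[F] ^= True
            sigma_P = net.sigma(mask)
            rho = float(rng.random())
            if accept_move(sigma_P, sigma, T, rho):
                sigma = sigma_P
                if sigma > best_sigma:
                    best_sigma = sigma
                    best_mask[:] = mask
            else:
                mask[F] ^= True
            steps += 1
            m += 1
            cum.append(cum[-1] + sigma)
            if config.log_every and steps % config.log_every == 0:
                log.info("step %d  T=%.4g t=%d  sigma=%.6g best=%.6g",
                         steps, T, t, sigma, best_sigma)
            if m >= config.per_temperature_cap:
                break
            if m >= 2 * window:
                last = (cum[m] - cum[m - window]) / window
                prev = (cum[m - window] - cum[m - 2 * window]) / window
                at_eq = (abs(last) <= tol if prev == 0.0
                         else abs(last - prev) <= tol * abs(prev))
                if at_eq:
                    break
        log.debug("stage %d done: %d steps, T=%.4g t=%d sigma=%.6g best=%.6g",
                  stages, m, T, t, sigma, best_sigma)
        T *= config.cooling_factor
        t = max(1, round(config.cooling_factor * t))

    best_edges = {net.edge_list[i] for i in np.flatnonzero(best_mask)}
    modules = _modules_from_edges(best_edges, network, scores)
    return AnnealingRun(
        modules=modules, best_sigma=float(best_sigma), best_edges=best_edges,
        steps=steps, stages=stages, t_init=t_init, T_init=T_init, seed=seed,
    )


def _modules_from_edges(
    edge_set: set[Edge], network: BipartiteNetwork, scores: ScoreSet
) -> list[Module]:
    """Connected components induced by an edge set, as scored modules sorted
    by score (desc), then node count, then smallest node ID."""
    if not edge_set:
        return []
    g = nx.Graph()
    g.add_edges_from(edge_set)
    modules = []
    for comp in nx.connected_components(g):
        module = Module(
            reaction_ids=frozenset(comp & network.reaction_nodes),
            metabolite_ids=frozenset(comp & network.metabolite_nodes),
        )
        module.score = score_module(module, scores)
        modules.append(module)
    modules.sort(key=lambda m: (-m.score, m.q, min(m.node_ids)))
    return modules
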