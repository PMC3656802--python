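"""Empirical module significance.

The null distribution of the module score depends on module size, so it is
estimated by resampling: for a module with n_r reactions and n_c metabolites,
draw n_r reaction scores and n_c metabolite weights uniformly without
replacement from the whole network, combine them with the same functional
form ln(n_r + n_c) * sum(s) - alpha * sum(w), and repeat P times.  The
empirical p-value is the fraction of null scores strictly greater than the
observed score.  The top M modules are tested and their p-values corrected
with the Benjamini-Hochberg step-up.

Caveat: null samples are unconstrained by connectivity, so the null is a
score-permutation null, not a random-subgraph null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .scoring import Module, ScoreSet

__all__ = [
    "SignificanceConfig",
    "null_module_score",
    "null_score_sample",
    "empirical_pvalue",
    "bh_correct",
    "flag_significant",
]


@dataclass(frozen=True)
class SignificanceConfig:
    """P: null samples per module; M: how many top modules to test (None =
    number of positive-scoring modules, capped at 50); q_cutoff: BH FDR
    threshold; pseudocount: report (k+1)/(P+1) instead of k/P so p can never
    be exactly 0; replace: sample scores with replacement."""

    n_samples: int = 10_000
    top_m: int | None = None
    q_cutoff: float = 0.05
    seed: int | None = None
    pseudocount: bool = False
    replace: bool = False

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.top_m is not None and self.top_m < 1:
            raise ValueError("top_m must be >= 1")
        if not (0.0 < self.q_cutoff < 1.0):
            raise ValueError("q_cutoff must lie in (0, 1)")


def _score_arrays(scores: ScoreSet) -> tuple[np.ndarray, np.ndarray]:
    s = np.array([scores.s[r] for r in sorted(scores.s)])
    w = np.array([float(scores.w[c]) for c in sorted(scores.w)])
    return s, w


def null_score_sample(
    n_r: int,
    n_c: int,
    scores: ScoreSet,
    rng: np.random.Generator,
    n_draws: int = 1,
    replace: bool = False,
) -> np.ndarray:
    """``n_draws`` random size-matched module scores.

    Each draw takes n_r reaction scores and n_c metabolite weights uniformly
    (without replacement by default) from the full score set and returns
    ln(n_r + n_c) * sum(s) - alpha * sum(w).
    """
    if n_r + n_c < 2:
        raise ValueError("a module has at least two nodes")
    s, w = _score_arrays(scores)
    if not replace and (n_r > s.size or n_c > w.size):
        raise ValueError("sample size exceeds network size (without replacement)")
    logq = math.log(n_r + n_c)

    def draws(pool: np.ndarray, k: int) -> np.ndarray:
        if k == 0:
            return np.zeros(n_draws)
        if replace:
            return rng.choice(pool, size=(n_draws, k), replace=True).sum(axis=1)
        # vectorised sampling without replacement: k smallest random keys
        keys = rng.random((n_draws, pool.size))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        return pool[idx].sum(axis=1)

    return logq * draws(s, n_r) - scores.alpha * draws(w, n_c)


def null_module_score(
    n_r: int, n_c: int, scores: ScoreSet, rng: np.random.Generator,
    replace: bool = False,
) -> float:
    """A single size-matched random module score."""
    return float(null_score_sample(n_r, n_c, scores, rng, 1, replace)[0])


def empirical_pvalue(
    module: Module, scores: ScoreSet, config: SignificanceConfig,
    rng: np.random.Generator | None = None,
) -> float:
    """p = (# null scores > observed) / P, with a seeded generator.

    With ``config.pseudocount`` the estimate becomes (k+1)/(P+1), which keeps
    p strictly positive at the cost of a small conservative bias.
    """
    if module.score is None:
        raise ValueError("module must be scored before significance testing")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    null = null_score_sample(
        len(module.reaction_ids), len(module.metabolite_ids), scores, rng,
        config.n_samples, config.replace,
    )
    k = int(np.sum(null > module.score))
    if config.pseudocount:
        return (k + 1) / (config.n_samples + 1)
    return k / config.n_samples


def bh_correct(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up: q_(i) = min_{j >= i} (M * p_(j) / j),
    clipped to 1, returned in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def flag_significant(
    modules: list[Module],
    scores: ScoreSet,
    config: SignificanceConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[Module]:
    """Assign p- and q-values to the top M modules (by score) and flag those
    with q < q_cutoff.

    Modules beyond rank M keep unset p and q.  The generator is consumed in
    score-rank order, so identical seeds give identical p and q vectors.
    Modules are modified in place and returned in their input order.
    """
    if config is None:
        config = SignificanceConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    for mod in modules:
        mod.p_value = None
        mod.q_value = None
        mod.significant = False
    ranked = sorted(modules, key=lambda m: -(m.score if m.score is not None else -np.inf))
    m_cap = config.top_m
    if m_cap is None:
        n_pos = sum(1 for mod in ranked if mod.score is not None and mod.score > 0)
        m_cap = min(n_pos, 50)
    tested = [mod for mod in ranked[:m_cap] if mod.score is not None]
    if not tested:
        return modules
    for mod in tested:
        mod.p_value = empirical_pvalue(mod, scores, config, rng)
    qs = bh_correct([mod.p_value for mod in tested])
    for mod, qv in zip(tested, qs):
        mod.q_value = qv
        mod.significant = qv < config.q_cutoff
    return modules
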