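"""Node and module scoring.

Reactions inherit scores from transcriptomic gene scores through their GPR
rules: the score of an enzyme complex is the mean of its subunit gene scores,
and the score of a reaction is the mean over its alternative enzymes.
Metabolites carry their degree in the full network as a weight, so highly
connected "currency" compounds (ATP, water, ...) are penalised rather than
removed.

A module m (a connected subgraph with reaction set r^m and metabolite set
c^m, q = |r^m| + |c^m| nodes) is scored

    S(m) = ln(q) * sum_i s(r_i) - alpha * sum_j w(c_j)

where alpha = (mean score of reactions with s > 0) / (mean metabolite weight
over the whole network).  The logarithmic factor biases the search towards
larger modules; alpha balances reaction rewards against connectivity
penalties.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from statistics import median
from typing import Literal

from .io import BipartiteNetwork, MetabolicModel

__all__ = [
    "ScoreSet",
    "Module",
    "score_reactions",
    "impute_missing",
    "metabolite_weights",
    "compute_alpha",
    "score_module",
    "orient_scores",
    "build_score_set",
]

Direction = Literal["up", "down"]


@dataclass(frozen=True)
class ScoreSet:
    """Per-reaction scores, per-metabolite weights and the scaling constant.

    ``w`` is always the degree in the *full* network, computed before any
    search and never altered by direction flips.
    """

    s: dict[str, float]
    w: dict[str, int]
    alpha: float
    direction: Direction = "up"
    imputation: Literal["median", "zero"] = "median"


@dataclass
class Module:
    """A connected reaction-metabolite subgraph scored as a unit."""

    reaction_ids: frozenset[str]
    metabolite_ids: frozenset[str]
    score: float | None = None
    p_value: float | None = None
    q_value: float | None = None
    significant: bool = False

    @property
    def q(self) -> int:
        """Node count |r^m| + |c^m|."""
        return len(self.reaction_ids) + len(self.metabolite_ids)

    @property
    def node_ids(self) -> frozenset[str]:
        return self.reaction_ids | self.metabolite_ids


def score_reactions(
    model: MetabolicModel,
    genes: dict[str, float],
    partial_complexes: Literal["mean", "strict"] = "mean",
) -> dict[str, float]:
    """Map gene scores onto reactions through GPR rules.

    Each complex scores as the mean of its subunit genes; the reaction scores
    as the mean over its complexes (isozymes).  With ``partial_complexes=
    "mean"`` a complex with some measured subunits uses the mean of those; in
    ``"strict"`` mode a complex with any unmeasured gene is dropped.  A
    reaction whose complexes all drop out is left unscored, to be imputed.
    """
    out: dict[str, float] = {}
    for rxn in model.reactions:
        if rxn.gpr is None:
            continue
        complex_scores = []
        for cplx in rxn.gpr.disjuncts:
            vals = [genes[g] for g in cplx if g in genes]
            if not vals:
                continue
            if partial_complexes == "strict" and len(vals) < len(cplx):
                continue
            complex_scores.append(sum(vals) / len(vals))
        if complex_scores:
            out[rxn.id] = sum(complex_scores) / len(complex_scores)
    return out


def impute_missing(
    scores: dict[str, float],
    network: BipartiteNetwork,
    mode: Literal["median", "zero"] = "median",
) -> dict[str, float]:
    """Fill in scores for network reactions without data.

    ``median``: unscored reactions get the median of the known scores.
    ``zero``: all scores are shifted by minus the median of the known scores
    and unscored reactions get 0 — equivalent, up to the shift, to median
    imputation, but centres the background so only strongly changed pathways
    stand out.
    """
    known = {r: v for r, v in scores.items() if r in network.reaction_nodes}
    if not known:
        raise ValueError("no known reaction scores: nothing to impute from")
    med = median(known.values())
    if mode == "median":
        return {r: known.get(r, med) for r in network.reaction_nodes}
    if mode == "zero":
        return {r: known[r] - med if r in known else 0.0
                for r in network.reaction_nodes}
    raise ValueError(f"unknown imputation mode {mode!r}")


def metabolite_weights(network: BipartiteNetwork) -> dict[str, int]:
    """w(c) = degree of metabolite c in the full network."""
    if not network.metabolite_nodes:
        raise ValueError("network has no metabolites")
    return {c: network.degree(c) for c in network.metabolite_nodes}


def compute_alpha(scores: dict[str, float], weights: dict[str, int]) -> float:
    """alpha = mean strictly positive reaction score / mean metabolite weight."""
    positives = [v for v in scores.values() if v > 0]
    if not positives:
        raise ValueError(
            "no reaction has a positive score; check the search direction and "
            "imputation mode"
        )
    if not weights:
        raise ValueError("empty weight map")
    mean_pos = sum(positives) / len(positives)
    mean_w = sum(weights.values()) / len(weights)
    return mean_pos / mean_w


def score_module(module: Module, scores: ScoreSet) -> float:
    """S(m) = ln(q) * sum s(r) - alpha * sum w(c); the log multiplies only the
    reaction-score sum."""
    if module.q < 2:
        raise ValueError("a module has at least two nodes")
    try:
        sum_s = sum(scores.s[r] for r in module.reaction_ids)
        sum_w = sum(scores.w[c] for c in module.metabolite_ids)
    except KeyError as exc:
        raise KeyError(f"module node {exc.args[0]!r} missing from score set") from None
    return math.log(module.q) * sum_s - scores.alpha * sum_w


def orient_scores(scores: ScoreSet, direction: Direction) -> ScoreSet:
    """Orient a score set for an up- or down-regulated search.

    ``down`` negates every reaction score so the most repressed reaction gets
    the highest score; metabolite weights (and alpha, by default) are left
    untouched.  Applying ``down`` twice returns the original scores.
    """
    if direction == "up":
        return replace(scores, direction="up")
    if direction == "down":
        flipped = "down" if scores.direction == "up" else "up"
        return replace(scores, s={r: -v for r, v in scores.s.items()},
                       direction=flipped)
    raise ValueError(f"unknown direction {direction!r}")


def build_score_set(
    network: BipartiteNetwork,
    model: MetabolicModel,
    genes: dict[str, float],
    imputation: Literal["median", "zero"] = "median",
    direction: Direction = "up",
    partial_complexes: Literal["mean", "strict"] = "mean",
    recompute_alpha: bool = False,
) -> ScoreSet:
    """End-to-end score construction: GPR scoring, imputation, weights, alpha,
    then orientation.

    alpha is computed once from the up-oriented imputed scores and reused for
    the down-direction search unless ``recompute_alpha`` is set (in which case
    it is recomputed after negation, failing if no score becomes positive).
    """
    raw = score_reactions(model, genes, partial_complexes)
    s = impute_missing(raw, network, imputation)
    w = metabolite_weights(network)
    base = ScoreSet(s=s, w=w, alpha=compute_alpha(s, w),
                    direction="up", imputation=imputation)
    if direction == "up":
        return base
    oriented = orient_scores(base, "down")
    if recompute_alpha:
        oriented = replace(oriented, alpha=compute_alpha(oriented.s, w))
    return oriented
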