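"""The model/results interface.

:class:`ModuleSearch` bundles the data (bipartite network + score set) with
the search and significance configuration; :meth:`ModuleSearch.fit` runs the
simulated-annealing search and the empirical significance tests and returns a
:class:`ModuleSearchResults`, which carries the modules, their p/q-values, a
``summary()`` table and the output writers.

Typical use::

    search = ModuleSearch.from_files("model.xml", "scores.tsv", direction="up")
    res = search.fit(seed=7)
    print(res.summary())
    res.to_tsv("modules.tsv")
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd

from .annealing import AnnealingConfig, run_annealing
from .io import (
    BipartiteNetwork,
    MetabolicModel,
    build_bipartite,
    read_gene_scores,
    read_sbml,
)
from .scoring import Module, ScoreSet, build_score_set, score_reactions
from .significance import SignificanceConfig, flag_significant
from . import output as _output

__all__ = ["ModuleSearch", "ModuleSearchResults", "run_pipeline"]

log = logging.getLogger(__name__)


class ModuleSearch:
    """Active-module search model over a bipartite reaction-metabolite
    network.

    Parameters
    ----------
    network
        The full bipartite network (weights are taken from it).
    scores
        Imputed, direction-oriented score set, including alpha.
    anneal, significance
        Search schedule and significance-testing settings.
    """

    def __init__(
        self,
        network: BipartiteNetwork,
        scores: ScoreSet,
        anneal: AnnealingConfig | None = None,
        significance: SignificanceConfig | None = None,
    ):
        missing = network.reaction_nodes - set(scores.s)
        if missing:
            raise ValueError(f"{len(missing)} network reactions lack scores")
        self.network = network
        self.scores = scores
        self.anneal = anneal or AnnealingConfig()
        self.significance = significance or SignificanceConfig()
        self.coverage: dict[str, int] = {}
        self.input_digests: dict[str, str] = {}

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_model(
        cls,
        model: MetabolicModel,
        gene_scores: dict[str, float],
        direction: Literal["up", "down"] = "up",
        imputation: Literal["median", "zero"] = "median",
        partial_complexes: Literal["mean", "strict"] = "mean",
        recompute_alpha: bool = False,
        include_boundary: bool = False,
        anneal: AnnealingConfig | None = None,
        significance: SignificanceConfig | None = None,
    ) -> "ModuleSearch":
        """Build the network and score set from a metabolic model and a gene
        score table, logging gene/reaction coverage."""
        network = build_bipartite(model, include_boundary=include_boundary)
        scores = build_score_set(
            network, model, gene_scores, imputation=imputation,
            direction=direction, partial_complexes=partial_complexes,
            recompute_alpha=recompute_alpha,
        )
        search = cls(network, scores, anneal, significance)

        gpr_genes = {g for r in model.reactions if r.gpr for g in r.gpr.genes}
        raw = score_reactions(model, gene_scores, partial_complexes)
        n_scored = len(set(raw) & network.reaction_nodes)
        search.coverage = {
            "genes_in_table": len(gene_scores),
            "genes_matched": len(set(gene_scores) & gpr_genes),
            "reactions_total": len(network.reaction_nodes),
            "reactions_scored": n_scored,
            "reactions_imputed": len(network.reaction_nodes) - n_scored,
        }
        log.info(
            "coverage: %(genes_matched)d of %(genes_in_table)d genes matched; "
            "%(reactions_scored)d of %(reactions_total)d reactions scored, "
            "%(reactions_imputed)d imputed", search.coverage,
        )
        return search

    @classmethod
    def from_files(
        cls,
        model_path: str,
        scores_path: str,
        **kwargs,
    ) -> "ModuleSearch":
        """Read an SBML model and a gene-score TSV; records input digests so
        a result archive can state exactly what it was computed from."""
        model = read_sbml(model_path)
        genes = read_gene_scores(scores_path)
        search = cls.from_model(model, genes, **kwargs)
        search.input_digests = {
            "model": _sha256_file(model_path),
            "scores": _sha256_file(scores_path),
        }
        return search

    # -- fitting -----------------------------------------------------------

    def fit(self, seed: int | None = None) -> "ModuleSearchResults":
        """Run annealing then significance testing.

        One seed reproduces the whole run: the annealing chain consumes a
        child stream of ``seed`` and the null sampler another, so results are
        bit-for-bit identical across repeats.
        """
        if seed is None:
            seed = self.anneal.seed
        ss = np.random.SeedSequence(seed)
        anneal_ss, null_ss = ss.spawn(2)
        run = run_annealing(self.network, self.scores, self.anneal, seed=anneal_ss)
        modules = flag_significant(
            run.modules, self.scores, self.significance,
            rng=np.random.default_rng(null_ss),
        )
        meta = {
            "seed": seed,
            "direction": self.scores.direction,
            "imputation": self.scores.imputation,
            "alpha": self.scores.alpha,
            "t_init": run.t_init,
            "T_init": run.T_init,
            "steps": run.steps,
            "stages": run.stages,
            "best_sigma": run.best_sigma,
            "max_steps": self.anneal.max_steps,
            "cooling_factor": self.anneal.cooling_factor,
            "equilibrium_window": self.anneal.equilibrium_window,
            "equilibrium_tol": self.anneal.equilibrium_tol,
            "per_temperature_cap": self.anneal.per_temperature_cap,
            "n_null_samples": self.significance.n_samples,
            "q_cutoff": self.significance.q_cutoff,
            "coverage": dict(self.coverage),
            "input_digests": dict(self.input_digests),
        }
        return ModuleSearchResults(
            network=self.network, scores=self.scores, modules=modules, meta=meta,
        )


@dataclass
class ModuleSearchResults:
    """Modules found by one fitted search, with their scores and empirical
    significance, plus everything needed to reproduce the run."""

    network: BipartiteNetwork
    scores: ScoreSet
    modules: list[Module]
    meta: dict

    @property
    def significant_modules(self) -> list[Module]:
        """Significant modules in score order (the TSV/GraphML rank order)."""
        sig = [m for m in self.modules if m.significant]
        return sorted(sig, key=lambda m: (-m.score, m.q, min(m.node_ids)))

    def to_dataframe(self) -> pd.DataFrame:
        """One row per module: size, score, p, q, significance flag."""
        rows = []
        for i, m in enumerate(self.modules, start=1):
            rows.append({
                "rank": i,
                "n_reactions": len(m.reaction_ids),
                "n_metabolites": len(m.metabolite_ids),
                "q_nodes": m.q,
                "score": m.score,
                "p_value": m.p_value,
                "q_value": m.q_value,
                "significant": m.significant,
            })
        return pd.DataFrame(rows)

    def summary(self, max_rows: int = 20) -> str:
        """Human-readable run summary in the style of a fitted-model report."""
        meta = self.meta
        lines = [
            "Active-module search results",
            "=" * 64,
            f"direction: {meta['direction']:>6}    imputation: {meta['imputation']}",
            f"alpha: {meta['alpha']:.6g}    t_init: {meta['t_init']}"
            f"    T_init: {meta['T_init']:.6g}",
            f"steps: {meta['steps']}    stages: {meta['stages']}"
            f"    best sigma: {meta['best_sigma']:.6g}",
            f"seed: {meta['seed']}    null samples: {meta['n_null_samples']}"
            f"    q cutoff: {meta['q_cutoff']}",
        ]
        cov = meta.get("coverage") or {}
        if cov:
            lines.append(
                f"coverage: {cov['genes_matched']}/{cov['genes_in_table']} genes; "
                f"{cov['reactions_scored']} reactions scored, "
                f"{cov['reactions_imputed']} imputed"
            )
        lines.append("-" * 64)
        lines.append(f"{'module':>6} {'n_rxn':>6} {'n_met':>6} {'score':>12} "
                     f"{'p':>8} {'q':>8}  sig")
        for i, m in enumerate(self.modules[:max_rows], start=1):
            p = "NA" if m.p_value is None else format(m.p_value, ".4g")
            q = "NA" if m.q_value is None else format(m.q_value, ".4g")
            lines.append(
                f"{i:>6} {len(m.reaction_ids):>6} {len(m.metabolite_ids):>6} "
                f"{m.score:>12.6g} {p:>8} {q:>8}  {'*' if m.significant else ''}"
            )
        if len(self.modules) > max_rows:
            lines.append(f"... ({len(self.modules) - max_rows} more modules)")
        n_sig = len(self.significant_modules)
        lines.append("-" * 64)
        lines.append(f"{len(self.modules)} modules, {n_sig} significant "
                     f"at q < {meta['q_cutoff']}")
        return "\n".join(lines)

    # -- writers -----------------------------------------------------------

    def to_tsv(self, path: str) -> None:
        _output.write_tsv(self, path)

    def to_graphml(self, path: str) -> None:
        _output.write_graphml(self, self.network, path)

    def save(self, path: str) -> None:
        _output.save_state(self, path)

    @classmethod
    def load(cls, path: str) -> "ModuleSearchResults":
        return _output.load_state(path)

    # -- (de)serialisation -------------------------------------------------

    def to_payload(self) -> dict:
        edges = sorted(self.network.edges)
        return {
            "meta": self.meta,
            "network": {
                "reactions": sorted(self.network.reaction_nodes),
                "metabolites": sorted(self.network.metabolite_nodes),
                "edges": [list(e) for e in edges],
            },
            "scores": {
                "s": {k: self.scores.s[k] for k in sorted(self.scores.s)},
                "w": {k: int(self.scores.w[k]) for k in sorted(self.scores.w)},
                "alpha": self.scores.alpha,
                "direction": self.scores.direction,
                "imputation": self.scores.imputation,
            },
            "modules": [
                {
                    "reactions": sorted(m.reaction_ids),
                    "metabolites": sorted(m.metabolite_ids),
                    "score": m.score,
                    "p_value": m.p_value,
                    "q_value": m.q_value,
                    "significant": m.significant,
                }
                for m in self.modules
            ],
        }

    @classmethod
    def from_payload(cls, payload: dict) -> "ModuleSearchResults":
        g = nx.Graph()
        net = payload["network"]
        g.add_nodes_from(net["reactions"], kind="reaction")
        g.add_nodes_from(net["metabolites"], kind="metabolite")
        g.add_edges_from((u, v) for u, v in net["edges"])
        sc = payload["scores"]
        scores = ScoreSet(
            s=dict(sc["s"]), w={k: int(v) for k, v in sc["w"].items()},
            alpha=sc["alpha"], direction=sc["direction"],
            imputation=sc["imputation"],
        )
        modules = [
            Module(
                reaction_ids=frozenset(m["reactions"]),
                metabolite_ids=frozenset(m["metabolites"]),
                score=m["score"], p_value=m["p_value"], q_value=m["q_value"],
                significant=m["significant"],
            )
            for m in payload["modules"]
        ]
        return cls(network=BipartiteNetwork(g), scores=scores,
                   modules=modules, meta=dict(payload["meta"]))

    def __eq__(self, other) -> bool:
        if not isinstance(other, ModuleSearchResults):
            return NotImplemented
        return self.to_payload() == other.to_payload()


def _sha256_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(
    model_path: str,
    scores_path: str,
    direction: Literal["up", "down"] = "up",
    imputation: Literal["median", "zero"] = "median",
    seed: int | None = None,
    anneal: AnnealingConfig | None = None,
    significance: SignificanceConfig | None = None,
    **kwargs,
) -> ModuleSearchResults:
    """File-to-results convenience wrapper: read, build, score, impute,
    orient, anneal, test.  Equivalent to ``ModuleSearch.from_files(...).fit``."""
    search = ModuleSearch.from_files(
        model_path, scores_path, direction=direction, imputation=imputation,
        anneal=anneal, significance=significance, **kwargs,
    )
    return search.fit(seed=seed)
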