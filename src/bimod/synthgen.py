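"""Synthetic bipartite networks with planted active modules.

The generator emulates the gross topology of a genome-scale metabolic
network: each reaction touches a handful of metabolites, a few
"currency-like" hub metabolites (think ATP, water) are involved in many
reactions, and the whole network is connected.  Reaction scores are drawn
from a background normal distribution centred at zero; one or more planted
modules — connected subgraphs — get their reaction scores shifted up by a
stated effect size, giving a known ground truth for recovery benchmarks.

Everything is reproducible from the seed, including the written SBML/TSV
fixture files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import BipartiteNetwork, MetabolicModel, Metabolite, Reaction, build_bipartite
from .gpr import GPRRule

__all__ = ["SynthSpec", "GroundTruth", "generate_network", "write_fixture"]


@dataclass(frozen=True)
class SynthSpec:
    """Generator settings.

    ``planted_modules`` lists (size_in_nodes, effect_size) pairs; the effect
    size is in units of the background standard deviation ``sigma_b`` and is
    added to the background score of every reaction in the module.
    ``hub_degree`` is a guaranteed minimum degree for the ``n_hubs``
    highest-degree metabolites.
    """

    n_reactions: int = 200
    n_metabolites: int = 150
    min_reaction_degree: int = 2
    max_reaction_degree: int = 6
    n_hubs: int = 2
    hub_degree: int = 30
    sigma_b: float = 1.0
    planted_modules: tuple[tuple[int, float], ...] = ((15, 3.0),)
    composite_gpr: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_reactions, self.n_metabolites) < 1:
            raise ValueError("network dimensions must be positive")
        if not (1 <= self.min_reaction_degree <= self.max_reaction_degree):
            raise ValueError("invalid reaction degree range")
        if self.max_reaction_degree > self.n_metabolites:
            raise ValueError("reaction degree exceeds metabolite count")
        if self.n_hubs < 0 or self.n_hubs > self.n_metabolites:
            raise ValueError("invalid hub count")
        if self.sigma_b <= 0:
            raise ValueError("sigma_b must be positive")
        total_nodes = self.n_reactions + self.n_metabolites
        for size, _ in self.planted_modules:
            if size < 2 or size > total_nodes:
                raise ValueError(f"planted module size {size} infeasible")
        if self.n_hubs and self.hub_degree > self.n_reactions:
            raise ValueError("hub_degree exceeds the number of reactions")


@dataclass
class GroundTruth:
    """Planted module node IDs and the gene score assignments used."""

    modules: list[frozenset[str]] = field(default_factory=list)
    gene_of_reaction: dict[str, str] = field(default_factory=dict)


def _reaction_id(i: int) -> str:
    return f"R{i:04d}"


def _metabolite_id(j: int) -> str:
    return f"M{j:04d}"


def generate_network(
    spec: SynthSpec,
) -> tuple[BipartiteNetwork, dict[str, float], GroundTruth, MetabolicModel]:
    """Generate (network, gene scores, ground truth, model) from a spec.

    Construction: hubs are pre-wired to ``hub_degree`` random reactions; each
    reaction then draws its remaining degree uniformly from the configured
    range and attaches to metabolites with two-tier preferential weights
    (hubs heavier); components are spliced together so the network is
    connected; finally planted modules are grown as connected subgraphs by
    breadth-first expansion from a random reaction and their reaction scores
    are shifted by the effect size.
    """
    rng = np.random.default_rng(spec.seed)
    rids = [_reaction_id(i) for i in range(spec.n_reactions)]
    mids = [_metabolite_id(j) for j in range(spec.n_metabolites)]
    hubs = mids[: spec.n_hubs]

    g = nx.Graph()
    g.add_nodes_from(rids, kind="reaction")
    g.add_nodes_from(mids, kind="metabolite")

    # guarantee hub connectivity first
    for hub in hubs:
        for i in rng.choice(spec.n_reactions, size=min(spec.hub_degree, spec.n_reactions),
                            replace=False):
            g.add_edge(rids[int(i)], hub)

    # two-tier preferential attachment: hubs carry extra weight
    weights = np.ones(spec.n_metabolites)
    if spec.n_hubs:
        weights[: spec.n_hubs] = max(3.0, spec.hub_degree / 4.0)
    probs = weights / weights.sum()
    for i, rid in enumerate(rids):
        target = int(rng.integers(spec.min_reaction_degree,
                                  spec.max_reaction_degree + 1))
        need = target - g.degree(rid)
        if need <= 0:
            continue
        current = {m for m in g.neighbors(rid)}
        choices = rng.choice(spec.n_metabolites, size=target * 4, replace=True, p=probs)
        for j in choices:
            mid = mids[int(j)]
            if mid not in current:
                g.add_edge(rid, mid)
                current.add(mid)
                need -= 1
                if need == 0:
                    break
        while need > 0:  # fall back to uniform fill among unused metabolites
            j = int(rng.integers(spec.n_metabolites))
            if mids[j] not in current:
                g.add_edge(rid, mids[j])
                current.add(mids[j])
                need -= 1

    # isolated metabolites: attach to a random reaction so degrees are >= 1
    for mid in mids:
        if g.degree(mid) == 0:
            g.add_edge(rids[int(rng.integers(spec.n_reactions))], mid)

    # spanning augmentation: splice every component onto the largest one
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    main = comps[0]
    for comp in comps[1:]:
        r_in = sorted(n for n in comp if n.startswith("R"))
        m_in = sorted(n for n in main if n.startswith("M"))
        if not r_in:  # metabolite-only component cannot occur (degree fill above)
            r_main = sorted(n for n in main if n.startswith("R"))
            g.add_edge(r_main[int(rng.integers(len(r_main)))],
                       sorted(comp)[int(rng.integers(len(comp)))])
        else:
            g.add_edge(r_in[int(rng.integers(len(r_in)))],
                       m_in[int(rng.integers(len(m_in)))])
        main |= comp

    # background gene scores, one gene per reaction
    truth = GroundTruth()
    scores: dict[str, float] = {}
    for rid in rids:
        gene = f"G_{rid}"
        truth.gene_of_reaction[rid] = gene
        scores[gene] = float(rng.normal(0.0, spec.sigma_b))

    # plant connected modules by BFS from a random seed reaction
    taken: set[str] = set()
    for size, effect in spec.planted_modules:
        nodes = _grow_connected(g, size, rng, exclude=taken)
        taken |= nodes
        for node in nodes:
            if node.startswith("R"):
                scores[truth.gene_of_reaction[node]] = float(
                    effect * spec.sigma_b + rng.normal(0.0, spec.sigma_b)
                )
        truth.modules.append(frozenset(nodes))

    model = _as_model(g, rids, mids, truth, spec, rng)
    return BipartiteNetwork(g), scores, truth, model


def _grow_connected(
    g: nx.Graph, size: int, rng: np.random.Generator, exclude: set[str]
) -> set[str]:
    """A connected node set of the requested size, grown breadth-first from a
    random reaction, avoiding previously planted nodes where possible."""
    starts = sorted(n for n, k in g.nodes(data="kind")
                    if k == "reaction" and n not in exclude)
    if not starts:
        raise ValueError("no reactions left to plant a module on")
    for _ in range(32):
        start = starts[int(rng.integers(len(starts)))]
        nodes = {start}
        frontier = [start]
        while frontier and len(nodes) < size:
            nxt = sorted(set(g.neighbors(frontier.pop(0))) - nodes - exclude)
            order = rng.permutation(len(nxt))
            for k in order:
                if len(nodes) >= size:
                    break
                nodes.add(nxt[int(k)])
                frontier.append(nxt[int(k)])
        if len(nodes) == size:
            return nodes
    raise ValueError(f"could not grow a connected planted module of size {size}")


def _as_model(
    g: nx.Graph,
    rids: list[str],
    mids: list[str],
    truth: GroundTruth,
    spec: SynthSpec,
    rng: np.random.Generator,
) -> MetabolicModel:
    """Materialise the generated graph as a MetabolicModel with GPRs."""
    metabolites = {m: Metabolite(id=m, name=m, compartment="c") for m in mids}
    reactions = []
    for rid in rids:
        gene = truth.gene_of_reaction[rid]
        if spec.composite_gpr and rng.random() < 0.5:
            extra = [f"{gene}x{k}" for k in range(int(rng.integers(1, 4)))]
            # random OR-of-ANDs over the reaction's genes, primary gene always
            # sufficient on its own so scores stay interpretable
            complexes = [frozenset({gene})]
            if extra:
                complexes.append(frozenset(extra))
            gpr = GPRRule.from_complexes(complexes)
        else:
            gpr = GPRRule.from_complexes([{gene}])
        mets = tuple(sorted(g.neighbors(rid)))
        reactions.append(Reaction(id=rid, name=rid, metabolite_ids=mets, gpr=gpr))
    return MetabolicModel(reactions=reactions, metabolites=metabolites,
                          name=f"synthetic-{spec.seed}")


def write_fixture(
    model: MetabolicModel,
    scores: dict[str, float],
    sbml_path: str,
    tsv_path: str,
) -> None:
    """Write the generated model as minimal SBML L3+fbc and the gene scores
    as a two-column TSV, such that reading them back reproduces the same
    network, GPRs and scores."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    sbml_model = doc.createModel()
    sbml_model.setId("synthetic_model")
    mplug = sbml_model.getPlugin("fbc")
    mplug.setStrict(False)

    comp = sbml_model.createCompartment()
    comp.setId("c")
    comp.setConstant(True)

    genes = sorted({g for r in model.reactions if r.gpr for g in r.gpr.genes})
    gene_ids = {}
    for g in genes:
        gp = mplug.createGeneProduct()
        gid = "gp_" + g.replace("-", "_")
        gp.setId(gid)
        gp.setLabel(g)
        gene_ids[g] = gid

    for m in model.metabolites.values():
        sp = sbml_model.createSpecies()
        sp.setId(m.id)
        sp.setName(m.name)
        sp.setCompartment("c")
        sp.setHasOnlySubstanceUnits(False)
        sp.setBoundaryCondition(m.boundary)
        sp.setConstant(False)

    for r in model.reactions:
        rxn = sbml_model.createReaction()
        rxn.setId(r.id)
        rxn.setName(r.name)
        rxn.setReversible(False)
        rxn.setFast(False)
        for mid in r.metabolite_ids:
            ref = rxn.createReactant()
            ref.setSpecies(mid)
            ref.setStoichiometry(1.0)
            ref.setConstant(True)
        if r.gpr is not None:
            rplug = rxn.getPlugin("fbc")
            gpa = rplug.createGeneProductAssociation()
            # libsbml resolves tokens against gene-product labels
            expr = " or ".join(
                "(" + " and ".join(sorted(c)) + ")"
                for c in sorted(r.gpr.disjuncts, key=lambda c: sorted(c))
            )
            gpa.setAssociation(expr)

    if libsbml.writeSBMLToFile(doc, str(sbml_path)) != 1:
        raise IOError(f"failed to write SBML to {sbml_path}")

    with open(tsv_path, "w", encoding="utf-8") as fh:
        fh.write("gene\tscore\n")
        for gene in sorted(scores):
            fh.write(f"{gene}\t{scores[gene]!r}\n")
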