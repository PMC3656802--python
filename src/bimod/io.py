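"""Model and score input: SBML metabolic models, gene-score tables, and the
bipartite reaction-metabolite network built from them.

The network representation is deliberately minimal: stoichiometry and
reversibility are ignored, an undirected edge joins a reaction to every
distinct metabolite that appears as substrate or product.  Metabolites in
different compartments are distinct nodes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .gpr import GPRRule, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "BipartiteNetwork",
    "SBMLReadError",
    "GeneScoreError",
    "read_sbml",
    "read_gene_scores",
    "build_bipartite",
]

log = logging.getLogger(__name__)


class SBMLReadError(ValueError):
    """SBML file could not be parsed into a valid metabolic model."""


class GeneScoreError(ValueError):
    """Gene-score table is malformed."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""
    boundary: bool = False


@dataclass(frozen=True)
class Reaction:
    id: str
    name: str = ""
    metabolite_ids: tuple[str, ...] = ()  # distinct substrates and products
    gpr: GPRRule | None = None


@dataclass
class MetabolicModel:
    reactions: list[Reaction]
    metabolites: dict[str, Metabolite]
    name: str = ""

    def __post_init__(self) -> None:
        rids = [r.id for r in self.reactions]
        if len(rids) != len(set(rids)):
            raise ValueError("duplicate reaction IDs in model")
        for r in self.reactions:
            for mid in r.metabolite_ids:
                if mid not in self.metabolites:
                    raise ValueError(
                        f"reaction {r.id!r} references undeclared species {mid!r}"
                    )


class BipartiteNetwork:
    """Undirected bipartite graph over reaction and metabolite nodes.

    Thin wrapper around a :class:`networkx.Graph`; node attribute ``kind`` is
    ``"reaction"`` or ``"metabolite"``.
    """

    def __init__(self, graph: nx.Graph):
        kinds = nx.get_node_attributes(graph, "kind")
        self.reaction_nodes = frozenset(n for n, k in kinds.items() if k == "reaction")
        self.metabolite_nodes = frozenset(n for n, k in kinds.items() if k == "metabolite")
        if self.reaction_nodes | self.metabolite_nodes != set(graph.nodes):
            raise ValueError("every node needs kind 'reaction' or 'metabolite'")
        for u, v in graph.edges:
            if (u in self.reaction_nodes) == (v in self.reaction_nodes):
                raise ValueError(f"edge ({u!r}, {v!r}) is not bipartite")
        self.graph = graph

    @property
    def edges(self) -> set[tuple[str, str]]:
        """Edges as (reaction_id, metabolite_id) pairs."""
        out = set()
        for u, v in self.graph.edges:
            out.add((u, v) if u in self.reaction_nodes else (v, u))
        return out

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def __contains__(self, node: str) -> bool:
        return node in self.graph


def _fbc_association_to_gpr(assoc, fbc_model) -> GPRRule | None:
    """Convert a libsbml fbc association tree to DNF."""

    def label_of(gp_id: str) -> str:
        gp = fbc_model.getGeneProduct(gp_id)
        if gp is not None and gp.isSetLabel() and gp.getLabel():
            return gp.getLabel()
        return gp_id

    def recurse(node) -> frozenset[frozenset[str]]:
        if node.isGeneProductRef():
            return frozenset({frozenset({label_of(node.getGeneProduct())})})
        children = [recurse(node.getAssociation(i))
                    for i in range(node.getNumAssociations())]
        if not children:
            raise SBMLReadError("empty fbc gene association operator")
        if node.isFbcOr():
            return frozenset().union(*children)
        if node.isFbcAnd():
            result = children[0]
            for rhs in children[1:]:
                result = frozenset(a | b for a in result for b in rhs)
            return result
        raise SBMLReadError("unknown fbc association node type")

    if assoc is None:
        return None
    return GPRRule(recurse(assoc))


def _notes_gene_association(notes: str) -> str | None:
    """Extract the legacy ``GENE_ASSOCIATION: ...`` line from a notes blob."""
    import re

    text = re.sub(r"<[^>]+>", "\n", notes)  # strip XHTML tags
    for line in text.splitlines():
        line = line.strip()
        m = re.match(r"GENE[ _]?ASSOCIATION\s*:\s*(.*)$", line, flags=re.IGNORECASE)
        if m:
            return m.group(1).strip()
    return None


def read_sbml(path: str) -> MetabolicModel:
    """Read an SBML Level 2/3 model into a :class:`MetabolicModel`.

    GPR rules are taken from the SBML-fbc gene-product associations when the
    fbc package is present, otherwise from a ``GENE_ASSOCIATION:`` line in the
    reaction notes.  Reactions with neither get no GPR (their scores will be
    imputed downstream).
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR) > 0:
        err = doc.getErrorWithSeverity(0, libsbml.LIBSBML_SEV_ERROR)
        raise SBMLReadError(
            f"SBML parse error in {path}: {err.getMessage().strip()} "
            f"(line {err.getLine()})"
        )
    model = doc.getModel()
    if model is None:
        raise SBMLReadError(f"{path} contains no SBML model element")

    metabolites: dict[str, Metabolite] = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        metabolites[sp.getId()] = Metabolite(
            id=sp.getId(),
            name=sp.getName() or "",
            compartment=sp.getCompartment() or "",
            boundary=bool(sp.getBoundaryCondition()),
        )

    fbc_model = model.getPlugin("fbc")
    reactions: list[Reaction] = []
    n_unparsed = 0
    for i in range(model.getNumReactions()):
        rxn = model.getReaction(i)
        mids: list[str] = []
        for refs in (rxn.getListOfReactants(), rxn.getListOfProducts()):
            for ref in refs:
                sid = ref.getSpecies()
                if sid not in metabolites:
                    raise SBMLReadError(
                        f"reaction {rxn.getId()!r} references undeclared "
                        f"species {sid!r}"
                    )
                if sid not in mids:
                    mids.append(sid)

        gpr: GPRRule | None = None
        rxn_fbc = rxn.getPlugin("fbc")
        if rxn_fbc is not None and rxn_fbc.isSetGeneProductAssociation():
            gpr = _fbc_association_to_gpr(
                rxn_fbc.getGeneProductAssociation().getAssociation(), fbc_model
            )
        elif rxn.isSetNotes():
            ga = _notes_gene_association(rxn.getNotesString())
            if ga is not None:
                try:
                    gpr = parse_gpr(ga)
                except ValueError:
                    n_unparsed += 1
                    log.warning(
                        "could not parse GENE_ASSOCIATION for %s: %r",
                        rxn.getId(), ga,
                    )
        reactions.append(
            Reaction(id=rxn.getId(), name=rxn.getName() or "",
                     metabolite_ids=tuple(mids), gpr=gpr)
        )
    if n_unparsed:
        log.warning("%d reactions had unparseable gene associations", n_unparsed)
    return MetabolicModel(reactions=reactions, metabolites=metabolites,
                          name=model.getName() or model.getId() or "")


def read_gene_scores(path: str) -> dict[str, float]:
    """Read a two-column TSV of (gene ID, log fold-change).

    A header line is detected by a non-numeric second field.  Duplicate gene
    IDs, non-numeric scores and empty files are all errors.
    """
    try:
        df = pd.read_csv(path, sep="\t", header=None, dtype=str,
                         comment=None, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise GeneScoreError(f"gene-score file {path} is empty") from None
    if df.shape[1] < 2:
        raise GeneScoreError(f"{path}: expected two tab-separated columns")
    df = df.iloc[:, :2]
    df.columns = ["gene", "score"]

    start = 0
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        start = 1  # header line
    if start >= len(df):
        raise GeneScoreError(f"gene-score file {path} has no data rows")

    scores: dict[str, float] = {}
    for row_no, (gene, raw) in enumerate(
        zip(df["gene"].iloc[start:], df["score"].iloc[start:]), start=start + 1
    ):
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise GeneScoreError(
                f"{path} row {row_no}: non-numeric score {raw!r} for gene {gene!r}"
            ) from None
        if not math.isfinite(val):
            raise GeneScoreError(f"{path} row {row_no}: non-finite score for {gene!r}")
        if gene in scores:
            raise GeneScoreError(f"{path} row {row_no}: duplicate gene ID {gene!r}")
        scores[gene] = val
    return scores


def build_bipartite(model: MetabolicModel, include_boundary: bool = False) -> BipartiteNetwork:
    """Build the undirected bipartite network from a metabolic model.

    One edge per distinct (reaction, metabolite) incidence, regardless of
    stoichiometry or of a metabolite appearing on both sides.  Species flagged
    as boundary in the SBML are excluded unless ``include_boundary`` is set.
    Reactions left with no metabolites are dropped with a warning (they could
    never join an edge-induced module).
    """
    g = nx.Graph()
    dropped = 0
    for rxn in model.reactions:
        mids = [m for m in rxn.metabolite_ids
                if include_boundary or not model.metabolites[m].boundary]
        if not mids:
            dropped += 1
            continue
        g.add_node(rxn.id, kind="reaction")
        for mid in mids:
            if mid not in g:
                g.add_node(mid, kind="metabolite")
            g.add_edge(rxn.id, mid)
    if dropped:
        log.warning("dropped %d reactions with no (non-boundary) metabolites", dropped)
    return BipartiteNetwork(g)
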