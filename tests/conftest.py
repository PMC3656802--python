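"""Shared fixtures: tiny hand-written SBML documents, small random networks
and score sets, and synthetic generated instances."""

from __future__ import annotations

import numpy as np
import networkx as nx
import pytest

from bimod.io import BipartiteNetwork
from bimod.scoring import ScoreSet
from bimod.synthgen import SynthSpec, generate_network

SBML_L2_NOTES = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="toy">
    <listOfCompartments>
      <compartment id="c"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" name="metA" compartment="c"/>
      <species id="B" name="metB" compartment="c"/>
      <species id="C" name="metC" compartment="c"/>
      <species id="X" name="metX" compartment="c" boundaryCondition="true"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R1">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>GENE_ASSOCIATION: (g1 and g2) or g3</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="A"/>
          <speciesReference species="B"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="C"/>
        </listOfProducts>
      </reaction>
      <reaction id="R2">
        <notes>
          <body xmlns="http://www.w3.org/1999/xhtml">
            <p>GENE_ASSOCIATION: g4</p>
          </body>
        </notes>
        <listOfReactants>
          <speciesReference species="C"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="A"/>
          <speciesReference species="X"/>
        </listOfProducts>
      </reaction>
      <reaction id="R3">
        <listOfReactants>
          <speciesReference species="B"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B"/>
          <speciesReference species="C"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

SBML_UNDECLARED_SPECIES = SBML_L2_NOTES.replace(
    '<speciesReference species="C"/>\n        </listOfProducts>\n      </reaction>\n      <reaction id="R2">',
    '<speciesReference species="GHOST"/>\n        </listOfProducts>\n      </reaction>\n      <reaction id="R2">',
    1,
)


@pytest.fixture
def sbml_notes_file(tmp_path):
    """3-reaction, 4-metabolite SBML L2 model with notes-dialect GPRs and one
    boundary species."""
    path = tmp_path / "toy.xml"
    path.write_text(SBML_L2_NOTES)
    return str(path)


@pytest.fixture
def sbml_bad_species_file(tmp_path):
    path = tmp_path / "bad.xml"
    path.write_text(SBML_UNDECLARED_SPECIES)
    return str(path)


def make_tiny_network(seed: int, n_r: int = 4, n_m: int = 4, max_edges: int = 12):
    """Random connected-ish bipartite net with <= max_edges edges and a score
    set with degree weights and the standard alpha."""
    rng = np.random.default_rng(seed)
    while True:
        g = nx.Graph()
        rids = [f"r{i}" for i in range(n_r)]
        mids = [f"m{j}" for j in range(n_m)]
        g.add_nodes_from(rids, kind="reaction")
        g.add_nodes_from(mids, kind="metabolite")
        possible = [(r, m) for r in rids for m in mids]
        k = int(rng.integers(6, max_edges + 1))
        for i in rng.choice(len(possible), size=k, replace=False):
            g.add_edge(*possible[i])
        g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
        if g.number_of_edges() >= 6:
            break
    net = BipartiteNetwork(g)
    s = {r: float(rng.normal(0.0, 1.0)) for r in net.reaction_nodes}
    w = {m: net.degree(m) for m in net.metabolite_nodes}
    pos = [v for v in s.values() if v > 0]
    alpha = (sum(pos) / len(pos)) / (sum(w.values()) / len(w)) if pos else 0.5
    return net, ScoreSet(s=s, w=w, alpha=alpha)


@pytest.fixture
def tiny_network():
    return make_tiny_network(seed=11)


@pytest.fixture(scope="session")
def synthetic_instance():
    """One seeded synthetic network at the generator's default study
    conditions (200 reactions, 150 metabolites, 2 hubs, one planted 15-node
    module at +3 sigma_b)."""
    spec = SynthSpec(seed=7)
    network, genes, truth, model = generate_network(spec)
    return spec, network, genes, truth, model


@pytest.fixture(scope="session")
def small_synthetic_instance():
    """A smaller synthetic instance for fast end-to-end tests."""
    spec = SynthSpec(n_reactions=50, n_metabolites=40, n_hubs=2, hub_degree=12,
                     planted_modules=((10, 3.0),), seed=5)
    network, genes, truth, model = generate_network(spec)
    return spec, network, genes, truth, model
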