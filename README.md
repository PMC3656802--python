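# bimod — active metabolic modules on bipartite networks

`bimod` finds connected parts of a metabolic network whose enzymes change
coherently between two conditions — "active modules" — from a genome-scale
metabolic model (SBML) and per-gene log fold-changes (e.g. from a microarray
or RNA-seq contrast).

Metabolism is represented as an undirected **bipartite** graph: reaction
nodes and metabolite nodes, an edge wherever a metabolite is a substrate or
product of a reaction. This keeps isozymes and multifunctional enzymes
attached to the right reactions, and it lets highly connected "currency"
metabolites (ATP, water, ...) be *penalised by degree* instead of being
deleted by an arbitrary cutoff — a hub can still join a module when the
transcriptional evidence supports it.

## The model

Gene scores are mapped to reactions through gene–protein–reaction (GPR)
rules: an enzyme complex (`and`) scores as the mean of its subunits,
alternative enzymes (`or`) as the mean over complexes. Reactions without
data get the median of the known scores (or zero after median-centring).
A module *m* with reaction set *r^m*, metabolite set *c^m* and
*q* = |*r^m*| + |*c^m*| nodes is scored

```
S(m) = ln(q) · Σᵢ s(rᵢᵐ) − α · Σⱼ w(cⱼᵐ)
```

where `s(r)` is the reaction score, `w(c)` is the metabolite's degree in the
full network, and `α` = (mean positive reaction score) / (mean metabolite
degree). The log factor biases the search towards larger modules; the
degree term charges a toll for routing a module through promiscuous
metabolites.

The search runs over *edge subsets*: simulated annealing toggles a random
set of `t` edges per step, accepts a proposal `P` against the current set
`E` when `ρ < exp((σ(P) − σ(E))/T)` with `σ` the summed score of all induced
connected components, and cools `t` and `T` geometrically (×0.9) whenever
the chain reaches thermal equilibrium at the current temperature. Module
significance is empirical: the observed score is compared with `P = 10000`
size-matched random score sums, and the top-module p-values are
Benjamini–Hochberg corrected. Down-regulated modules are found by negating
the reaction scores and running the identical machinery.

## Worked example

Everything is testable without downloads through the synthetic generator,
which emulates a metabolic network (hub metabolites, 2–6 metabolites per
reaction, connected) and plants a known high-scoring module:

```python
import bimod

spec = bimod.SynthSpec(n_reactions=50, n_metabolites=40, n_hubs=2, hub_degree=12,
                       planted_modules=((10, 3.0),), seed=5)
network, gene_scores, truth, model = bimod.generate_network(spec)

search = bimod.ModuleSearch.from_model(model, gene_scores)
result = search.fit(seed=42)
print(result.summary())
```

prints

```
Active-module search results
================================================================
direction:     up    imputation: median
alpha: 0.234231    t_init: 1    T_init: 1.58803
steps: 100000    stages: 10    best sigma: 66.2538
seed: 42    null samples: 10000    q cutoff: 0.05
coverage: 50/50 genes; 50 reactions scored, 0 imputed
----------------------------------------------------------------
module  n_rxn  n_met        score        p        q  sig
     1     28     23      66.2538        0        0  *
----------------------------------------------------------------
1 modules, 1 significant at q < 0.05
```

One module is significant (none of its 10 000 size-matched null scores
reached 66.25, so p = q = 0 at the resolution of the sampler); it covers 8
of the 10 planted nodes plus surrounding reactions pulled in by the
log-term's growth bias. `result.to_tsv(...)`, `result.to_graphml(...)` and
`result.save(...)` write the node table, a visualisation graph and a
checksummed archive that `ModuleSearchResults.load` restores exactly.
The same pipeline runs from the shell:

```
bimod model.xml scores.tsv -o run --direction both -N 100000 --seed 7
```

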