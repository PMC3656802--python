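# Methods

## Network representation

A metabolic model is read from SBML (Level 2 or 3) and reduced to an
undirected bipartite graph: one node per reaction, one node per metabolite
species, and an edge wherever the metabolite appears as substrate or product
of the reaction. Stoichiometric coefficients, reversibility and kinetics are
ignored — only connectivity matters. Metabolites in different compartments
are distinct species in the model and therefore distinct nodes. A metabolite
appearing on both sides of a reaction contributes a single edge (the graph is
simple). Species flagged `boundaryCondition="true"` are excluded by default
(they represent exchange sinks/sources and carry no pathway information);
`include_boundary=True` retains them. Reactions left without metabolites are
dropped with a warning, since modules are induced by edges and such reactions
could never join one.

GPR rules are taken from SBML-fbc gene-product associations where present,
otherwise from a `GENE_ASSOCIATION:` line in the reaction notes (the legacy
convention used by curated models). Both are normalised to OR-of-ANDs
(isozymes OR; complex subunits AND); any other or unparseable annotation
yields an absent GPR and a logged warning. Gene identifiers are matched
case-sensitively against the score table, and the run log reports how many
genes matched and how many reactions were scored versus imputed.

## Scoring

* **Reactions.** Each complex scores as the mean of its subunit gene scores;
  the reaction scores as the mean over its complexes. A complex with some
  (not all) subunits measured contributes the mean of the measured ones by
  default — discarding partially measured complexes would waste data and the
  mean is the error-damping choice; `partial_complexes="strict"` drops them
  instead. A reaction with no measurable complex is left to imputation.
* **Imputation.** `median` assigns unscored reactions the median of the known
  scores (the default, appropriate when overall metabolic change is of
  interest); `zero` subtracts the median from every score and gives unscored
  reactions 0, which centres the background so only strongly changed
  pathways stand out.
* **Metabolites.** `w(c)` is the metabolite's degree in the *full* network,
  frozen before any search. Degree is used as an information penalty: links
  through promiscuous currency-like metabolites are charged more.
* **Module score.** `S(m) = ln(q)·Σ s(r) − α·Σ w(c)`, with
  `q` the node count. The logarithm multiplies only the reaction-score sum.
  `α` is the mean strictly-positive reaction score divided by the mean
  metabolite degree over the whole network, computed once on the up-oriented
  imputed scores. For a down-regulated search every reaction score is
  negated and the same machinery runs; α is reused from the up orientation
  by default (`recompute_alpha=True` recomputes it after negation — note
  that exact up/down symmetry on a sign-flipped dataset holds only with
  recomputation, because the positive-score mean differs between
  orientations).

## Search

The state is a set `E` of network edges; the objective
`σ(E) = Σ_k S(m_k)` sums the scores of *all* connected components induced by
`E`. One step draws a toggle set `F` of `t` distinct edges uniformly from
the full edge set and proposes the symmetric difference `E Δ F`; the move is
accepted when `ρ < exp(Δσ/T)`, `ρ ~ U[0,1)`. Toggling several edges at once
lets the chain cross low-scoring intermediate configurations early on; as
`t` cools to 1 the walk becomes local.

Schedule and defaults:

* `t_init = max(1, ⌈0.01·|nodes|⌉)` — about 1% of the network per toggle.
* `T_init` = mean absolute single-node contribution (|s(r)| over reactions,
  α·w(c) over metabolites) / ln 2, so a typical node-scale worsening move
  starts near 50% acceptance.
* Equilibrium: at a given temperature the chain runs until the mean of σ
  over the last 5000 steps is within 5% of the mean over the previous 5000
  (an absolute comparison when the previous mean is 0), or a
  per-temperature cap of 50 000 steps; then `t ← max(1, round(0.9·t))`,
  `T ← 0.9·T`.
* The run stops after `max_steps` total proposals (default 100 000; a
  genome-scale analysis warrants 10⁶) and reports the best configuration
  ever visited, not the final one — the chain may drift after passing the
  optimum.

σ is recomputed from scratch at every proposal by a union-find over the
active edges (a numba-compiled kernel; ~μs per step at a few hundred edges),
so the running score can never drift from the configuration and no
incremental-update bookkeeping is needed. Reported module scores are
recomputed once more, independently, from the returned node sets. A single
seeded `numpy` generator drives initialisation, toggle selection and ρ;
node and edge indices are assigned in sorted order, so a run is bit-for-bit
reproducible from its seed across platforms. Modules are ordered by score,
then node count, then smallest node ID.

## Significance

The null distribution of `S` depends on module size, so it is estimated by
resampling: for an observed module with `n_r` reactions and `n_c`
metabolites, draw `n_r` reaction scores and `n_c` metabolite weights
uniformly without replacement from the network and combine them with the
same functional form `ln(n_r+n_c)·Σs − α·Σw`. With `P` such draws (default
10 000), `p = (#{null > observed})/P` — strictly greater, so a module tying
the whole null sample gets p = 1. An optional `(k+1)/(P+1)` pseudocount
keeps p positive for users who need it. The top `M` modules by score are
tested (default: all positive-scoring modules, capped at 50) and corrected
by Benjamini–Hochberg; a module is flagged when `q < 0.05` (strict).

Two caveats, both inherent to this design rather than this implementation:
null samples ignore connectivity (they are score permutations, not random
connected subgraphs), and the observed score is the output of an optimiser
while the null is not, so p-values for the top module of an annealing run
are anti-conservative — on pure noise the search can still assemble a
positive-scoring module that beats size-matched random sums. The
calibration test in the suite therefore evaluates p-values of modules drawn
from the null itself (where uniformity is the correct expectation), and the
false-positive check on synthetic data asks whether a *planted* (but
effect-free) module is recovered and flagged, not whether any module at all
reaches significance.

## Synthetic data

The generator emulates the gross shape of a genome-scale network, not its
biochemistry: `n_reactions` reactions each touching 2–6 metabolites;
`n_hubs` currency-like metabolites pre-wired to at least `hub_degree`
reactions and favoured during attachment (two-tier preferential weights — a
full power law adds nothing at these sizes); components spliced so the graph
is connected; one gene per reaction (optionally random composite GPRs) with
scores from N(0, σ_b²). Planted modules are connected subgraphs grown
breadth-first from a random reaction whose reaction scores are shifted by
`effect·σ_b`. Defaults — 200 reactions, 150 metabolites, 2 hubs of degree
≥ 30, σ_b = 1, one 15-node planted module at effect +3 — are the study
condition used by the recovery benchmarks. What passing on this generator
does *not* show: robustness to compartment structure, realistic degree
correlations, correlated measurement noise, or incomplete GPR coverage of
real models.

## Scale of the bundled benchmarks

The optimality check enumerates all 2^|E| edge subsets on networks of ≤ 12
edges (the largest size where exhaustive search is exact and quick) and asks
the annealer at N = 50 000 to match the optimum on ≥ 90% of 20 seeded
instances; in practice it matches on all of them. Recovery benchmarks run
ten seeded fits at the default condition with the default schedule
(N = 100 000). These sizes keep the whole suite in a few minutes on one
core while exercising every code path at the sizes where the ground truth
is computable.

## Known limitations

* **Module growth is rewarded logarithmically, without bound.** Because
  ln(q) multiplies the (typically positive) reaction-score sum, adding any
  reaction with `s > −Σs/(q·ln q)` raises `S`; on a network whose background
  scores straddle zero, the highest-scoring module is therefore large — it
  contains the strong signal plus a halo of mildly positive neighbourhood.
  The recovery benchmarks reflect this honestly: the planted module is
  found with high *recall* (median ≥ 0.9) but the top module's *Jaccard*
  against the planted set is low, because exact recovery is not the optimum
  of this objective. Users wanting compact modules should use the `zero`
  imputation/centring mode and interpret module cores (highest-scoring
  members) rather than boundaries.
* The empirical null is anti-conservative for optimised scores (above).
* Transcript abundance is a proxy for flux capacity; no regulatory or
  kinetic information is used, and genes absent from the model's GPRs are
  invisible to the analysis.
* Metabolites are scored purely by degree; the weight slot is the natural
  extension point for metabolomic data but no such scoring is implemented.
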