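# Methods

## The model

The package treats a metabolic reaction network as a bipartite directed
graph. Nodes are compartment-tagged metabolite species and *enzyme
instances*; edges encode dependency: a reactant must be present for its
enzyme to act (reactant → instance), and a product's presence depends on
its enzyme's activity (instance → product). An enzyme instance is one
catalyst bound to one specific reaction: gene–reaction rules are expanded
to disjunctive normal form, each OR-disjunct (a gene, or an AND-complex
treated as a single entity) yielding one instance per reaction. This
per-reaction duplication is what prevents incoherent jumps between
reactions that happen to share a catalyst, and the per-compartment species
tagging is what keeps paths inside their compartment unless an explicit
transport reaction bridges them.

Breadth-first search from an instance gives, for every reachable
metabolite, the minimal number of reactions separating them when following
flux (*down* distance; a direct product is at 1) and, on the edge-reversed
graph, against flux (*up* distance; a direct reactant is at 1). The
collection over all roots is the *reaction network forest*.

Distances map to weights by the dissipation law `w(d) = p**(d-1)` with
dissipation parameter `p ∈ [0, 1]`, signed + downstream and − upstream; a
metabolite reachable both ways gets the arithmetic mean of its two signed
weights. The mean (rather than, say, the dominant side) is a deliberate
choice: on a tight two-cycle the weight cancels to 0, which is the honest
statement that the metabolite's position carries no up/down information for
that enzyme. `w(1) = 1` for every `p`, including `p = 0` (`0**0 := 1`), so
direct partners are never attenuated.

A footprint is scored against a differential table by the scatter
construction (x = signed weight, y = t-value, dot size = `|t·w|`) and, as a
scalar summary, the imbalance score `Σ w·t / Σ |w|`. The score is this
package's own normalised summary statistic, not part of the original
scatter visualisation; it is linear in t and bounded by max|t|.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| dissipation `p` | 0.8 | 20% weight drop per reaction step; 1 keeps all reachable metabolites at full weight, 0 restricts to direct partners. The default is a readability compromise, not a fitted constant. |
| `min_atoms` | 4 | species with a known atom count strictly below this are removed before graph construction (strict bound: a 4-atom species stays). |
| `promiscuity_threshold` | 100 | species used as *reactants* by more than this many reactions are removed; degree is counted on the input network in a single pass. |
| explicit removals | CO2, ITP, IDP, NADH | base-name matches always removed. |
| QC RSD | 0.30 | metabolites at or above 30% relative standard deviation across pooled-QC injections are dropped. |
| contrast groups | — | moderated t is (group1 − group2) on log2 TIC-normalised areas. |

Species with a missing or unparseable formula keep an absent atom count and
are never removed by the size filter — a conservative choice, since the
size rule exists to drop currency-like small molecules, and an unknown size
is not evidence of smallness.

## Statistics

The differential pipeline is: QC-RSD filter → TIC normalisation (each
sample divided by its summed reported areas) → log2 with a half-minimum
pseudo-count → per-metabolite least-squares regression on group + batch
indicators, subtracting the fitted batch terms (QC samples participate as
their own pseudo-group; a design in which batch is confounded with group is
rejected) → empirical-Bayes moderated t.

The moderated t shrinks each metabolite's pooled variance `s²_g` (d
residual df) toward a prior `s₀²` with prior df `d₀`:
`s̃²_g = (d₀·s₀² + d·s²_g)/(d₀ + d)`, `t̃ = Δmean/(s̃·√(1/n₁+1/n₂))` on
`d₀ + d` df. Hyperparameters come from the standard moments fit on
`log s²_g` using digamma/trigamma closed forms, with the trigamma inverse
solved by Newton iteration. Degenerate regimes: when the excess log-variance
is non-positive, `d₀ = ∞` and every `s̃²` equals `s₀² = exp(mean log s²)` —
note this carries the finite-df log-scale factor `exp(log(d/2) − ψ(d/2))`,
so with identical sample variances `s₀²` approaches (but does not exactly
equal) the common value; with fewer than three metabolites the fit is
impossible and the code falls back to `d₀ = 0`, the classical pooled t,
with a warning. The implementation agrees with Bioconductor limma's
`lmFit`/`eBayes` (plain form, no trend/robust options) to ~1e-15 on test
fixtures; the trend and robust variants are intentionally not implemented.

Benjamini–Hochberg adjustment is the step-up procedure with cumulative-min
monotonicity, returned in input order.

## Synthetic data generator

`FixtureSpec`/`make_network`/`make_abundances` generate the study
conditions for every test: chains, branches, cycles, promiscuous-hub
networks, duplicated-compartment networks (with or without a transport
reaction), AND/OR gene-rule networks and random sparse networks; abundance
matrices with log-normal baselines (log2 baseline ~ N(14, 1)), residual sd
0.25 on the log2 scale, 6 samples per group across 3 batches with random
additive batch offsets (sd 0.5), and 3 pooled-QC injections at the pooled
mean — sizes chosen to mirror a typical three-batch cell-line metabolomics
design. A planted perturbation at a chosen enzyme shifts the case group by
`effect_size · noise_sd · w(root, m)`, i.e. the generator reuses the same
dissipation law the scorer applies. This makes parameter recovery a closed
loop by design: recovery tests demonstrate pipeline self-consistency
(graph, distances, weights, statistics and scoring all composed correctly),
*not* that real metabolomes decay effects geometrically with reaction
distance.

What the generator does not emulate: missing values, heteroscedastic
peak-area noise, correlated metabolites beyond the planted structure,
ion-suppression artefacts, or realistic network scale and kinetics.

## Numerical and design choices

- Distances count reactions traversed (root counts as 1), so the weight law
  starts at exactly 1 for direct partners.
- Reversible reactions that survive direction resolution expand into two
  opposed instances (`@fwd`, `@bwd`) rather than undirected edges; this
  preserves the up/down sign semantics. Their footprints are mirror images.
- Reports collapse compartment/reaction duplicates to base names by the
  minimum distance per direction, ties broken lexicographically by
  species id and recorded in provenance columns.
- A reaction that loses all reactants (or all products) to filtering is
  kept with its surviving side: it still anchors its enzyme instances to
  the remaining species. Only reactions losing both sides are dropped.
- Stoichiometric coefficients are validated and carried but do not affect
  the graph: path existence, not flux magnitude, defines the footprint.
- Promiscuity degrees are computed once, on the input network; because
  removal can only shrink degrees, the filter is idempotent.
- Measured-name aliases mapping to several network species resolve to the
  minimum-distance target.
- The channel-restricted footprint (`seed_product` / `seed_reactant`) roots
  the downstream (resp. upstream) BFS at one chosen direct partner of the
  instance, with that seed at distance 1; the other side falls back to the
  whole-reaction traversal. This separates, e.g., the two product channels
  of a transaminase.
- End-to-end determinism: all outputs sorted, floats written at %.12g, and
  a per-run JSON manifest (inputs' SHA-256, parameters, version) carries
  provenance instead of comment headers inside the CSVs, keeping every CSV
  readable by a plain `read_csv`.

## Known limitations

- Identifiability requires distance contrast. In small dense random
  digraphs (e.g. 12 species with 12 multi-substrate reactions) the graph
  diameter collapses to ~2, footprints of different enzymes become nearly
  identical, and no scoring scheme can single out the perturbed enzyme; the
  planted-recovery guarantee is therefore stated on path-like topologies
  (the 8-metabolite chain with a mid-chain perturbation), where recovery is
  100/100 across seeds. On real genome-scale networks the accessory-
  metabolite filter exists precisely to restore such contrast.
- The imbalance score has no attached null distribution; it ranks enzymes
  but does not test them.
- Shortest path only: no k-shortest-paths, path enumeration or flux
  weighting; a metabolite reachable by many long routes scores the same as
  one reachable by a single route of the same minimal length.
- The moderated-t implementation covers the plain empirical-Bayes form;
  variance-trend and robust hyperparameter fitting are out of scope.
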