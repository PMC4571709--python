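# Methods

This note records the models, conventions and design choices behind the
package, in the order the pipeline uses them.

## Food-web representation

A food web is a directed graph of trophospecies; a link (i, j) means
energy flows from prey i to predator j, so in-degree is generality
(number of prey) and out-degree vulnerability (number of predators).
Self-links encode cannibalism. Duplicate edge rows in input files are
collapsed with a logged warning rather than rejected, because real
trophic datasets routinely contain them. Identifiers are case-sensitive
exact strings; no taxon-name fuzzy matching is attempted. Isolated nodes
are retained after sub-setting (basal taxa may legitimately lose all
their consumers in a regional web); `drop_isolated` removes them on
request.

Regional webs are induced subgraphs of the meta-web on the regional
species pool: the co-occurrence assumption is that two species interact
in a region whenever they co-occur there and interact in the meta-web.
`add_species` is defined so that updating a regional web with incoming
species is exactly induction on the union — the identity
`add_species(sub(X), meta, Y) = sub(X ∪ Y)` is property-tested by
enumeration on small webs.

## Metric conventions

* **Connectance** uses the directed denominator S² (self-links allowed).
  With the published regional S and L this reproduces all three printed
  2-dp values (0.05 / 0.03 / 0.04), which a denominator of S(S−1) would
  not.
* **Path length and clustering** are computed on the undirected
  projection with self-links removed, path length over ordered reachable
  pairs within the largest connected component. This is the treatment
  under which marine webs show "two degrees of separation".
* **Loops** count the species lying in a strongly connected component of
  size ≥ 2 after removing self-links (node fraction, not loop count);
  cannibalism is reported separately.
* **Trophic level** is the short-weighted form: the mean of (i) the
  shortest-chain level, 1 + length of the shortest directed prey chain
  to a basal node (in-degree 0 after removing self-links), and (ii) the
  prey-averaged level TL_i = 1 + mean_j TL_j over i's prey, basal fixed
  at 1, solved exactly as a linear system. A node with no directed chain
  from any basal species is an error naming the node, not a silent NaN.
* **Omnivory** is not given a universal published definition, so the
  package operationalizes it and exposes both rules: a species counts as
  an omnivore when its prey span ≥ 1 trophic level (`span_threshold`
  config), and the omnivory index is the population SD of its prey's
  SWTLs, averaged over consumers with ≥ 2 prey.
* **Degree distributions** report cumulative survival P(K ≥ k) and an
  exponential rate fitted by maximum likelihood on degrees ≥ 1
  (λ = 1/mean); a log-linear regression fit of the survival curve is
  available behind a flag for comparing "steepness" between webs.
* Reports display 2 decimals (counts and percentages as integers) but
  JSON stores full precision.

## Percentage-difference convention

Comparison columns are Diff(X−Y) = 100·(m_X − m_Y)/m_X with the
first-named web in the denominator, rounded half-away-from-zero to a
whole percent, computed from the *display-rounded* metric values. The
rounded-input convention is deliberate: for connectance the published
difference columns (40 and 25) follow from the 2-dp table values, while
full-precision values would give 30 and 16. Tests pin the convention
against every published column it can reproduce (45, 12, 38, 40, 19, 25,
−30, −17).

## Modularity and the annealer

Modularity M = Σ_s [I_s/L − (d_s/2L)²] is computed on the undirected
projection with self-links dropped; mutual predation pairs collapse to
one undirected link. The directed web carries no separate weighted or
directed modularity here — the formula's single L and degree sums d_s
are undirected quantities.

The partition search is simulated annealing from a singleton start:

* moves: single-node reassignment to a random neighbour's module (5% of
  proposals open a fresh singleton module), plus collective moves
  alternating module merges and splits; splits grow a connected half
  from a random seed node so proposals follow the web's own link
  structure;
* acceptance min(1, exp(ΔM/T)); ΔM = 0 moves accepted with probability
  0.5; geometric cooling T ← cT; T₀ calibrated from trial moves so
  unfavourable moves initially accept with probability ≈ 0.8; stop at
  T < 10⁻⁴·T₀ or after a patience window without improvement;
* after annealing, a deterministic greedy refinement (improving node
  moves, best-pair merges, connected splits with local polish) removes
  the over-merged local optima a finite schedule can leave behind.

Three presets trade quality for time: `full` (c = 0.995, S² node + S
collective moves per temperature, patience 50 — the classical
convention), `standard` (c = 0.95, 10·S node moves, patience 20, the
package default) and `fast` (c = 0.90, 5·S node moves, patience 10, used
for null replicates and large seed sweeps). On every ≤ 8-node web in the
test suite `standard` matches exhaustive Bell-number search exactly, and
on 40-node planted 4-module benchmarks `fast` recovers the planted
labels with NMI = 1 in ≈ 100/100 seeds; the presets were sized on webs
of ~160–230 nodes, where a `standard` run takes ~0.3 s.

The null model preserves each node's undirected degree exactly by
double-edge swaps (10 swaps per link by default; networkx's sampler,
which never introduces self- or multi-links). Graphs with no admissible
swap (e.g. a triangle) are returned unchanged with a warning. The null
test anneals each randomized network (reduced schedule by default, since
the nulls are the compute bottleneck) and reports
p = (1 + #{M_null ≥ M_emp})/(n + 1) — the small-sample-corrected
one-sided permutation p-value, never exactly 0.

## Species roles

z and PC use the undirected projection without self-links. z uses the
population SD over the module's members, with the convention z = 0 when
SD = 0 (uniform modules produce no outliers, and infinities are avoided
in small modules). PC is the quadratic form 1 − Σ_t (k_it/k_i)², which
is the form the 0.625 threshold belongs to; a simple
fraction-of-external-links variant is available behind a flag because
the verbal description of the coefficient reads like a plain ratio.
Isolated nodes get PC = 0. Classification at z = 2.5 / PC = 0.625 is
inclusive on the hub side (a species exactly at both thresholds is a
network hub). Because module detection is stochastic, z and PC are
summarized as mean and percentile 2.5–97.5 interval over annealing
replicates; classification uses the means; reported module membership
comes from one designated (randomly chosen) replicate. Note a geometric
consequence of the quadratic PC: with only two modules PC ≤ 0.5, so
network hubs can only exist in webs partitioned into ≥ 3 modules.

## Module–trait association

Predictors are indicator-coded habitat (B, P, BP as three levels — BP is
its own level, not a 50/50 split) plus SWTL, each standardized; the
grouping is the module assignment. The separation statistic is
tr(B)/tr(T), the between-group share of total scatter — a Pillai-type
quantity chosen over discriminant classification accuracy because it is
deterministic (no cross-validation randomness) and exchangeable under
label permutation, which makes the permutation p-value exactly uniform
under the null (verified by KS test in the suite). Habitat-only and
trophic-only modes exist alongside the joint default, since either trait
alone can drive module separation. Unused habitat levels are dropped;
fully constant informative predictors are an error naming the predictor.

## Spatial degree field

Station degree centrality is the mean meta-web *total* degree (prey +
predators, self-links counted once) of the focal species recorded at the
station; stations with no qualifying species are missing, never 0.
Aggregation projects stations to km with a local equirectangular
projection about their centroid and averages station values in regular
cells (50 km default) anchored at the minimum coordinates. Gridded
averaging replaces geostatistical interpolation (kriging) deliberately:
the scientific content is the degree field itself, and smoothing is
cartographic glue that would drag in external covariates; an optional
inverse-distance pass can be layered on the cell means if smooth maps
are wanted.

## Synthetic study system

The generator produces the conditions the analysis assumes, not a fit to
any particular dataset:

* 233 trophospecies in the empirical functional-group proportions
  (2 detritus, 8 basal, 43 zooplankton, 79 benthos, 77 fish, 9 seabirds,
  15 mammals), habitat labels B/P/BP, and ~2100 feeding links;
* five habitat-structured modules (2 pelagic, 3 benthic compartments);
  consumers draw geometric diet sizes (mean 9) with an own-module
  preference (0.88 shared, 0.82 region-1-only, 0.92 region-2-only
  consumers — the region-2 pool is the more specialized, hence more
  modular, side of the contrast);
* trophic ranks (basal 0, zooplankton/benthos 1, fish 2, birds/mammals
  3) with prey drawn from strictly lower ranks, plus fish–fish
  cannibalism and mutual-predation pairs concentrated in the region-1
  pool; every consumer keeps at least one prey that occurs wherever it
  occurs, so regional sub-webs always have complete chains to basal taxa
  and trophic levels stay computable;
* two overlapping regional pools in fixed proportions (43% shared, 30%
  region-1-only, 27% region-2-only of the non-basal taxa), giving
  regional webs of 174 and 163 species with 104 shared;
* four wide-diet fish present only in region 1 (diet breadths 112, 88,
  62, 50, mirroring the degree ladder of the documented boreal
  invaders); the two largest are *super-generalists* that keep 45% of
  their diet in their home module — enough internal wiring to stand out
  within the module (z) while still spreading across all modules (PC),
  which is what real habitat-coupling generalists do;
* 60 survey stations in two latitude blocks detecting the regional fish
  pools at 30% per station.

What the generator does **not** emulate: empirical degree-distribution
tails, diet-fraction weights, the survey's spatial sampling design, sea
ice covariates, or the exact published metric values. Passing tests
therefore demonstrate that the pipeline recovers *planted, directional*
structure — region 1 denser and less modular, modularity collapsing when
the wide-diet fish enter, super-generalists in the network-hub region —
not that synthetic webs reproduce the published table numerically.
Reproducing the published absolute values requires the deposited
empirical web files (`analysis/07_dryad_reproduction.py`), for which
annealed modularity is expected within ±0.02 of the published values
under a finite stochastic schedule; the published null mean ± sd depends
additionally on the (unstated) annealing strength used for the null
replicates, so it is matched in structure, not pinned.

## Problem sizes in the shipped runs

The analysis drivers and the acceptance script default to 10–20
annealing replicates, 30–50 null networks, and 40–100-seed sweeps for
the directional claims; these sizes give stable directions and p-values
on the ~230-node system while a full run stays in the tens of seconds.
All counts are flags, and the classical 1000-replicate / 1000-null
setting is reachable by raising them.
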