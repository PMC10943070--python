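# Methods

## Scope and data model

The package analyses protein-level label-free quantification from a
proximity-labeling (BioID) experiment with a factorial design: a set of
baits plus a ligase-only negative control, each measured under two adhesion
conditions in ≥ 2 (default 3) biological replicates. All intensities are
handled on the log₂ scale; a zero or blank entry in the input table is
treated as *not detected* (the MaxQuant convention) and carried as an
explicit missing value. Protein IDs are opaque strings; group notation
("A;B") passes through preprocessing untouched and is only expanded by the
ortholog/protein-group layer.

## Normalization

Each sample's present values are shifted so its median equals the grand
median of all pre-shift sample medians. Centering on the grand median
rather than on zero preserves the absolute intensity scale, so downstream
fold changes remain interpretable; the operation is idempotent and leaves
the missingness pattern untouched. Centering is done on log-scale values.

## Interaction scoring

Scoring is a deliberate reimplementation of the SAINT decision interface
(per-replicate posterior → AvgP → ranked BFDR → 0.05 cut), not of any
particular implementation's numerics.

For a prey within one bait × condition group:

- **Control background.** μ₀ is the mean of the prey's *observed* control
  values. If the prey is absent from every control replicate, μ₀ is imputed
  at the control floor — the 5% quantile (configurable,
  `control_floor_quantile`) of all observed control intensities in that
  condition — reading total absence from controls as "below detection".
  Stochastically missing control replicates are *not* individually imputed
  at the floor: doing so drags μ₀ down for preys that are clearly observed
  in the remaining controls and converts ordinary dropout into guaranteed
  false positives.
- **Scale.** s is the pooled within-group standard deviation of the prey's
  bait and observed control replicates, floored at 0.25 log₂ units
  (`variance_floor`) so that near-identical replicates cannot produce
  degenerate certainty.
- **Posterior.** With enrichment offset δ (`enrichment_delta`, default 2
  log₂ units — the minimal shift regarded as a true interaction) and prior
  π (`prior_true`, default 0.5), each present bait replicate value x gets

      P(true | x) = π f₁(x) / (π f₁(x) + (1 − π) f₀(x)),

  where f₀ and f₁ are Student-t predictive densities centred at μ₀ and
  μ₀ + δ with scale s·√(1 + 1/r_ctrl) and degrees of freedom equal to the
  pooled residual df. The t predictive is the correct small-sample density
  when location and scale are estimated from ~3+3 replicates; plug-in
  normal densities are visibly overconfident in the tails at these sample
  sizes and inflate the realized false-discovery proportion well beyond the
  nominal BFDR. Because the t likelihood ratio is not monotone at extreme
  standardized enrichment (polynomial tails), it is clamped at its analytic
  maximum, attained at z* = (a + √(a² + 4ν))/2 with a = δ/scale; the
  posterior is therefore non-decreasing in the bait intensity.
- **AvgP and BFDR.** Missing bait replicates contribute posterior 0, and
  AvgP averages over all bait replicates. Within each bait × condition
  group, preys are ranked by AvgP descending (prey ID breaks ties); the
  BFDR at rank k is the running mean of (1 − AvgP), tied AvgP blocks share
  their worst BFDR, and preys with BFDR ≤ 0.05 (`bfdr_threshold`) are
  significant.

Fold changes are mean(present bait values) − μ₀, with the same μ₀
convention; preys absent from every bait replicate are reported as not
detected ("N.D." in text exports).

Calibration under the synthetic model (below): pooled over 20 independent
experiments with 500 background and 80 true preys at mean enrichment 3, the
empirical false-discovery proportion among BFDR ≤ 0.05 calls is ≈ 0.03–0.06
and power ≈ 0.99 (`desmoprox.benchmarks.fdr_power_sweep`; the acceptance
script recomputes both).

## Synthetic experiments

`simulate_experiment` draws, per protein, a baseline log₂ abundance from
N(`control_mean` = 20, `control_sd` = 1.5) — the wide between-protein
spread of a proteome — and adds independent N(0, `replicate_sd` = 0.5)
measurement noise per sample, the replicate-level variation typical of
label-free MS. Distinguishing the two variance components matters: the
between-protein spread is irrelevant to scoring (μ₀ is per-prey), while the
replicate noise sets the difficulty of separating a δ ≈ 3 enrichment from
background. True interactors are assigned to baits by independent
Bernoulli draws (`bait_assignment_probs`, default 0.4 per bait, at least
one bait forced), which produces the unique/shared bait structure;
per-condition enrichment deltas are drawn from
N(`enrichment_delta_mean` = 3, `enrichment_delta_sd` = 0.5) and added to
the matching bait × condition samples only (constant preys in both
conditions, the others in one). Contaminants (named carboxylases plus
synthetic RPL/RPS IDs) sit `CONTAMINANT_OFFSET` = 6 log₂ units above the
background mean in *every* sample, controls included. Missingness combines
MCAR dropout at `missing_rate_background` = 0.1 on background-prey cells
with left-censoring of any value below `dropout_threshold` = 16 log₂
units. Everything is a pure function of the config (including its seed).

What the generator does **not** model: peptide-level effects, batch and
run-order effects, intensity-dependent (non-MCAR) missingness beyond the
hard censoring threshold, correlated contaminant structure, and ratio
compression. Passing calibration on this model therefore demonstrates the
internal coherence of the scoring and classification machinery, not
performance on any particular real dataset.

Numbers used in tests and the acceptance script were sized for desk-scale
runs: 500 background + 80 true preys per experiment, 20-seed sweeps, 1000
null simulations for the rank test.

## Maturation analysis

Preys significant in ≥ 1 of the 8 datasets get a binary profile in fixed
dataset order (baits × conditions, bait-major). Clustering is
average-linkage (UPGMA) agglomerative clustering on the Jaccard distance
matrix — the common default for binary-profile heatmaps; the linkage method
is configurable in principle but average linkage is the shipped behavior.
Profiles are canonically sorted by prey ID before linkage, which makes the
result exactly invariant to input order; the dendrogram is cut at a
user-chosen k (default 11) rather than a height heuristic, because a fixed
k is reproducible; cluster indices are renumbered contiguously in
dendrogram leaf order. Categories follow from the profile alone: constant
iff significant in ≥ 1 dataset of each condition, otherwise
calcium-dependent or hyper-adhesive. Bait-sharing counts merge the two
plakoglobin termini into a single bait; the network keeps them as separate
nodes.

Note the asymmetry between the two classification statements: the fraction
of *true* interactors receiving their true category is ≈ 0.99 under the
synthetic model, while aggregate category counts carry the ≈ 5% of
estimated false discoveries the BFDR rule admits by construction (those
land mostly in the single-condition categories, since a false call in both
conditions independently is rare).

## Overlap, network, enrichment

Overlap statistics (per-bait counts, unique vs shared, Venn cells,
per-condition totals, two-termini agreement) are exact set algebra on the
binary profiles, with the plakoglobin termini merged. The proximity network
holds one *bioid* edge per (bait, prey) pair significant in ≥ 1 condition,
attributed ca_only / hyper_only / both — one edge per pair, not per
condition. STRING-style association edges are added only between node
pairs already present, classed high at score ≥ 0.7 (boundary inclusive).
Exports: SIF, GraphML, and a round-trippable edge-table TSV.

Overrepresentation uses the hypergeometric upper tail (scipy, log-space
stable) with Benjamini–Hochberg adjustment per ontology category and a
top-N (default 10) report. The universe defaults to all genes in the
annotation table and should be set to the quantified proteome when
available — the universe choice changes every p-value, which is why it is
an explicit parameter. Annotation files are taken as already propagated
over the ontology graph; no ancestor closure is performed.

## PLA quantification

A spot is junctional iff its Euclidean distance to the membrane trace (a
closed polyline; distance to the nearest segment, not to a filled region)
is ≤ 1 µm, inclusive at the boundary. Cells with zero cytoplasmic spots
have an undefined ratio and are excluded from group statistics with a log
entry. Group comparison: Kruskal–Wallis with tie correction (scipy), then
Dunn's pairwise z statistics on the pooled ranks with the standard tie
term, Bonferroni-adjusted over the comparisons actually performed. When
every observation is identical the omnibus statistic is reported as H = 0,
p = 1 rather than an error.

## Degenerate inputs and tie-breaking

- All-missing sample → normalization error naming the sample; < 2 controls
  in a condition → design error; all-zero profile → domain error for the
  Jaccard distance; k > number of profiles → parameter error.
- Ranking ties in BFDR share the worst value of their block and are ordered
  by prey ID; enrichment ties sort by gene ratio then term ID; linkage ties
  resolve deterministically through the canonical prey ordering.
- Scores of exactly 0.7 are high-confidence STRING edges; spots at exactly
  the band width are junctional.

## Known limitations

- The scoring model is intensity-based only; spectral-count variants and
  topology-aware extensions of the SAINT family are out of scope, and no
  attempt is made to reproduce any external implementation's numerics —
  externally scored tables can be consumed directly in pre-scored mode.
- Reproducing the exact cluster count of any particular real dataset is not
  promised: the cut rule is a user choice and annotation-dependent.
- Ortholog mapping consumes a user-supplied table; no live database
  queries. Unmapped IDs are retained verbatim so counts are conserved.
- The PLA band is measured from the whole membrane trace; restricting to
  cell–cell contact arcs is supported via an optional mask but off by
  default.
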