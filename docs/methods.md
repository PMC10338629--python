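# Methods

`tolnet` re-implements, as a tested and reusable pipeline, a longitudinal
multi-omic analysis of how tissue tolerates repeated toxic injury: per-week
differential statistics on a transcript and a protein layer, partition of the
response into three phases (initiation, progression, tolerance),
prior-guided sparse regression networks centered on each data layer, a
consensus across the three networks, and extraction of tolerance-specific
network modules.  Because the real study's numbers depend on deposited raw
data and versioned annotation databases, the package ships a synthetic-data
generator with planted ground truth; every stage is validated by recovering
what was planted.

## Study design emulated by the generator

The simulated design mirrors a repeated-dosing mouse time course: weeks
0–10 (default measured weeks 0, 1, 2, 4, 6, 8, 10), three animals per time
point, toxin-treated animals at every nonzero week and vehicle-treated
controls at week 0 and the final week (24 samples).  Weeks map onto phases
as initiation {1, 2}, progression {4, 6}, tolerance {8, 10}; the map is
configuration, not inference.

Per layer:

* **Transcript** — log2 expression, baseline per gene ~ N(7, 1.5²).
  Planted differentially expressed (DE) genes consist of a shared set
  (default 10) active in all three phases plus disjoint per-phase unique
  sets (defaults 8 / 12 / 10); the tolerance-unique set is the ground truth
  for module extraction.  A planted gene shifts by ±`effect_size`
  (default 2.0 log2 units) in the toxic samples of its phase's weeks;
  residual noise is N(0, 0.5²).
* **Protein** — a planted regulatory network of `n_true_edges` (default
  150) edges: ~60 % gene→coding-protein edges and ~40 % acyclic
  protein→protein edges, each with weight ±0.8 on the log2 scale.  A
  protein's log2 value is its baseline (~N(8, 1.5²)) plus the weighted,
  centered *realized* values of its parents plus noise, so the regression
  stage faces an exact linear data-generating model.  Raw reporter
  intensities are the exponentiated log2 values; the reference channel is
  the noiseless pooled mean intensity per protein.  Every tolerance-unique
  gene is guaranteed a coding edge, making the planted tolerance module
  (tolerance-unique genes plus their direct true-edge neighbors)
  recoverable in principle.
* **Missingness** — each protein measurement drops out with probability
  `1 / (1 + exp(s · (log2 I − m)))`, decreasing in intensity (defaults
  s = 1.5, m = 4.0), i.e. low-abundance dropout as in isobaric-label
  proteomics; with the default abundance distribution roughly 80–85 % of
  proteins survive the complete-case filter.  (A flat 50 % rate at s = 0 is
  the degenerate check case.)  Real TMT data additionally contain
  contaminants, batch structure, and peptide-level effects that this
  generator does not model; passing the benchmarks says the *statistical
  pipeline* behaves correctly, not that it is robust to those artifacts.
* **Clinical** — each variable is a weighted sum (3–10 features, weights
  ±U(0.5, 1), recorded in the ground truth) of planted-module features plus
  noise, emulating blood/tissue parameters that co-vary with the molecular
  module.

One pseudo-random stream per layer is split from the master seed, so adding
or resizing one layer never perturbs another's draws; identical
configurations are bit-reproducible.

## Proteome preprocessing

Proteins with any missing value are removed (complete-case analysis, with
the removed count reported), each intensity is expressed against the
reference channel as `(1 + p_js) / (1 + r_j)`, and sample columns are
quantile normalized (rank-mean; ties broken by row order so the per-column
multisets are exactly identical; idempotent).  Downstream statistics use
log2 ratios by default (symmetric fold changes); raw ratios are available
by flag.  Outlier samples can be flagged by low median Pearson correlation
to the other samples; because the appropriate threshold depends on how much
shared regulation the data carry (on sparse-signal reference ratios,
between-sample correlations are low for *every* sample), flagging is off by
default (threshold −1) and never drops samples silently.

## Differential expression

One ordinary-least-squares model per feature: intercept (pooled
vehicle-control mean; the two control weeks are pooled) plus one dummy per
treated week, so each coefficient is that week's log2 fold change against
control.  Residual variances are moderated by empirical Bayes: the prior
(d0, s0²) of the scaled-inverse-chi-square model is estimated by the method
of moments on log s² (digamma/trigamma moment matching; trigamma inverted
by Newton iteration; d0 = ∞ when the spread of log s² is within sampling
noise), and `s̃² = (d0·s0² + d·s²)/(d0 + d)` feeds a moderated t with
d + d0 degrees of freedom.  P-values are Benjamini–Hochberg adjusted per
week across features.  A transcript feature is called DE when adjusted
p < 0.05 **and** its fold change exceeds 1.5 (interpreted on the natural
scale, |log2FC| > log2 1.5; a `fc_scale="log2"` switch reads the cutoff as
a log2 value); protein calls use the FDR cutoff alone.  Both inequalities
are strict.  Phase sets are unions over the phase's weeks; unique sets
subtract all other phases; the shared set is the all-phase intersection.

## Sparse-group-lasso network inference

Every feature of the centered layer is regressed on its prior-derived
candidates with the objective

    (1/2n)·‖y − Xβ‖² + (1−α)·λ·Σ_g √p_g·‖β_g‖₂ + α·λ·‖β‖₁,

groups = predictor omic layer, α = 0.5 by default.  Candidates per center:
transcript targets draw from their mapped and one-PPI-hop proteins plus the
clinical variables; protein targets from their coding genes, PPI partners,
and the clinical variables; clinical targets from the derived clinical
prior (all features incident to an edge involving that variable in the
untrimmed transcript- or protein-centered network, plus the other clinical
variables).  Predictors are standardized to unit variance; coefficients are
reported on that scale, which is also the scale of the β trimming cutoff.

The solver is blockwise proximal descent on the Gram formulation with FISTA
inner steps (hot loop JIT-compiled); convergence is declared when the
Karush–Kuhn–Tucker residual falls below tolerance (1e-8 for direct calls,
1e-6 for network fits, 1e-4 inside cross-validation folds where only the
error curve matters), so every solution carries its own optimality
certificate, re-checkable by an independent plain-numpy implementation.

**Penalty selection.** λ runs over 50 log-spaced values from the node's
λ_max down to 0.01·λ_max, warm-started.  The default rule is the
cross-validated minimum **gated** on paired evidence of predictive
improvement: the model at the CV minimum is kept only if the mean per-fold
MSE drop relative to the empty model exceeds one standard error of that
drop; otherwise the node model stays empty.  The classical one-standard-
error rule is available (`select_rule="1se"`) but at this design's sample
size (n = 24) it discards roughly half of the genuinely predictive single
predictors; the plain ungated CV minimum, conversely, selects freely under
the null.  The gated rule meets both operating points (null candidates:
mean selected count ≈ 0.5 per node; planted predictor pairs: recovered with
correct signs in ≥ 80 % of replicates).

**Trimming** removes every edge whose target model has R² < 0.1 (in-sample,
clamped to [0, 1]) and every effect with |β| < 0.002, both strict, then
isolated nodes.

**Consensus.** The three centered networks have layer-disjoint edge
vocabularies — a gene–protein pair can never occur in the clinical-centered
network, a protein–protein pair only in the protein-centered one — so a
literal "present in all three" intersection is empty by construction.  The
default consensus therefore keeps an unordered node pair iff it carries a
consistently signed effect in *every network whose center layer can host
the pair* (gene–protein pairs must be found independently in the
transcript- and protein-centered networks; clinical pairs in the clinical
network and the partner layer's network; protein–protein pairs in the
protein network).  Sign agreement across all appearances is required; the
consensus weight is the mean β of the supporting edges.  A `strict` mode
implementing the literal triple intersection is provided for completeness.

**Known limitation (clinical double-dipping).** The clinical prior is
derived from networks inferred on the same samples, so clinical-involving
consensus edges are not protected against false positives under the null:
the clinical-centered regression retests exactly the pairs the other
networks already selected, on the same data.  This is inherent to the
derived-prior design; on fully null simulations the molecular part of the
consensus stays near zero while clinical pairs do not.  Treat clinical
consensus edges as descriptive covariation, not validated effects.

## Modules, centrality, enrichment, concordance

Seeds are the tolerance-unique DE features of both layers.  The consensus
subgraph induced on seeds plus their distance-1 neighbors (radius
configurable) is split into connected components; components with ≥ 2
nodes are modules, isolated seeds are reported separately.  Nodes are
ranked by unnormalized betweenness centrality on the undirected, unweighted
graph.  Modules are annotated against GMT gene-set collections by the
upper-tail hypergeometric test, BH-corrected per module, flagged at
FDR < 0.05.  Cross-cohort concordance maps features through a two-column
ortholog table and calls a feature concordant when the external gene passes
FDR < 0.1 and the fold-change signs agree.

## Benchmarks and how they are scored

Recovery is always scored against what is *measurable*: planted edges both
of whose endpoints survive complete-case filtering (edges lost to priors'
incompleteness remain in the reference — prior coverage is part of the
difficulty), and planted module members that survive into the analyzed
matrices.  Clinical pairs are excluded from the molecular edge metric and
module Jaccard because the generator's clinical ground truth is the weight
table, not edge membership.  At the default configuration (100 genes, 80
proteins, 6 clinical variables, 150 planted edges, prior coverage 0.9, 50
decoy prior pairs, 10 seeds) the consensus reaches median F1 ≈ 0.77 with
precision ≈ 0.83 — roughly double the average single-network precision —
and module recovery reaches median Jaccard ≈ 0.6–0.7.  Problem sizes used
by the test suite and the acceptance script (2,000 features × 200
replicates for error control, 10 simulation seeds for the network
benchmark, 1,000 random instances for the solver certificate) were chosen
so the full recomputation completes in a few minutes on one CPU.

## Numerical and degenerate-input conventions

Quantile normalization of a single sample is the identity (warned).  A
feature with zero residual variance gets a moderated variance from the
prior; if *all* variances vanish the ordinary t is used with a warning.
NaN p-values are excluded from the BH test count and propagated.  Zero-
variance predictors are left unscaled and can never be selected.  λ_max is
found by bisection on the group-zero condition; a node whose response is
constant (λ_max = 0) yields an empty model.  Missing-value token in TSVs is
the empty string; "NA" is accepted on read, never written; floats are
written in shortest round-trip form so write→read→write is byte-stable.
Run reports carry no wall-clock fields, making complete reruns bitwise
comparable.
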