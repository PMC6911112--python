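# Methods

`exploradapt` models how cells in a spatially heterogeneous tumor adapt their
gene-regulatory state from the phenotype of one anatomic location to that of
another, contrasting *intrinsic* dynamics (fixed regulatory interaction
strengths) with *exploratory adaptation* (a stochastic walk in the
interaction strengths that quiets down as the phenotype converges on its
target). This note records the model, the conventions and numerical choices
behind each stage, what the synthetic cohorts do and do not emulate, and the
known limitations.

## Phenotype: single-sample pathway activity

A sample's phenotype is the vector `y = (y_1 … y_m)` of per-pathway
activities. Each activity is a single-sample, rank-based enrichment score
(ssGSEA-style): genes are ordered by decreasing expression within the
sample, and the score is the sum over that walk of the difference between
the rank-weighted in-set empirical CDF and the unweighted out-of-set CDF.

Conventions, all fixed and documented because the statistic's literature
varies on each of them:

- **Weight exponent** `α = 0.25` on within-sample average ranks (the common
  ssGSEA default). `α = 0` gives the unweighted Kolmogorov–Smirnov-like sum.
- **Ties** receive average ranks; the walk order among tied genes follows
  the fixed gene order, so scores are deterministic and invariant to sample
  (column) permutations. Ties matter here because simulated gene states can
  saturate under `tanh`.
- **No cross-sample normalization.** The simulation scores one evolving
  sample at a time; any cohort-dependent rescaling would make trajectories
  depend on data the simulated cell cannot see.
- **Gene universe** = all genes present in the cohort/network, not only
  pathway members; the out-of-set complement is taken against it.

A score is therefore invariant under any strictly increasing transform of a
sample's expression — the property that lets simulated `tanh`-scale states
and measured expression live in one phenotype space.

A *location phenotype* is the per-pathway empirical distribution of
activities over that location's samples, summarized by the `[p10, p90]`
interval (linear interpolation between order statistics, applied identically
to data analysis and simulation targets).

## Distribution distances and tests

- **PDD** (pathway distribution distance): both locations' activity values
  for one pathway are binned on shared edges spanning the pooled min–max
  (default 20 bins), normalized to relative frequencies, and compared by
  Euclidean distance. Relative frequencies make unequal group sizes
  comparable; shared edges make the distance symmetric and zero iff the
  frequency vectors coincide. A degenerate pooled range yields distance 0
  with a warning.
- **GDD** = Σ over pathways of PDD.
- **Permutation test for GDD.** The observed GDD is computed on raw
  activities. The null pool is formed by mean-centering each group per
  pathway (removing the tested difference), then relabeling samples;
  a relabeling is admissible only if each permuted group's per-pathway mean
  lies inside the pooled centered distribution's 10–90% quantile band
  (rarely binding after centering; at most 50·n_perm draws are attempted).
  `p = (1 + #{null ≥ observed}) / (1 + n_used)`. A literal mean-centering of
  the *observed* statistic would erase exactly the mean shifts the test is
  used to detect, so centering is applied only to the null construction;
  `scheme="plain"` (classic relabeling) and `"centered"` (no band) are
  selectable. Type-I calibration at α = 0.05 is verified empirically in the
  acceptance suite.
- **Differential activity**: per-pathway two-sided Welch t-tests (the
  unequal-variance form as a robust default; pooled-variance selectable) with
  Benjamini–Hochberg correction and a significance cutoff of adjusted
  p ≤ 1e-06. Zero-variance/equal-mean pathways get t = 0, p = 1.
- **Phenotype network**: complete graph over locations with per-edge GDD,
  mean PDD, and DA count. An edge is "short" if its GDD is within a factor
  (default 1.25) of either endpoint's minimum incident GDD; spatial
  trajectories are shortest GDD-weighted paths within the short-edge
  subgraph. The factor rule is an explicit stand-in for an otherwise
  unspecified "shortest distances" classification.

## Dynamics

Gene states `X` (length n) evolve as

    dX/dt = (T ∗ J)·tanh(X) − βX,    β = 0.5

with `T` the binary TF→gene adjacency, `J` the interaction-strength matrix
(initialized as per-location Pearson correlations of gene pairs, masked to
edges; zero-variance genes get weight 0), and `∗` the Hadamard product.
Integration is explicit Euler with `h = 0.25` and 4 substeps per reported
step, i.e. one time unit per phenotype evaluation; reported `t` counts
phenotype evaluations, with `t_max = 1000` by default (scaled-down runs use
200 or less, see below). With `|tanh| ≤ 1` the state is eventually bounded
by `Σ_j |T∗J|_ij / β` per gene, which the tests assert.

**Exploration.** On every edge, `J` performs a random walk
`J ← J + sqrt(D)·z`, `z ~ N(0,1)`, with per-edge exploration scale `D`.
`D(0) = D0` uniformly on edges (default 0.1; 0.01 and 0.5 are the other
study settings; a variant drawing `|N(0, D0)|` per edge is available — the
absolute value because a scale parameter must be non-negative). Per step,
the per-pathway distance `PD_j` of the current phenotype to the target
interval is computed (0 inside the closed interval, else distance to the
nearer bound); `GD = Σ_j PD_j`; a pathway with `PD_j = 0` is converged.
Every gene all of whose containing pathways are converged has its row *and*
column of `D` damped by ×0.95 (an edge between two such genes is damped
twice); genes in any unconverged pathway, or in no pathway, keep their
scale. Noise is applied every step at the damped scale; an alternate gate
(`noise_gate="converged_only"`) that perturbs only edges whose target gene
is in a converged pathway is provided because the two readings of the
convergence-gated walk differ, with the damping reading as the default.
Runs stop early when all pathways are converged, or at `t_max`.

**Data → state mapping.** Initial states are `tanh` of per-gene z-scores
taken across the *whole cohort*. Within-location z-scoring was rejected
because it removes the location-mean differences that the targets encode:
both source and target locations would become mean-zero per gene and the
planted (or real) location signal would vanish. Simulation targets are the
`[p10, p90]` intervals of phenotypes computed from the *same transformed
data*, so simulated and target phenotypes share one space; the data-analysis
stage (PDD/GDD/DA between locations) uses raw-expression phenotypes.

## Downstream experiments

- **Transition experiments** run every source sample (optionally truncated)
  toward a target location's intervals; sample i is paired with seed
  `seeds[i mod len(seeds)]` and an independent per-sample RNG stream.
  Exploration is deemed *necessary* for a transition when the exploratory
  mean final GD is below the intrinsic one.
- **Reversal ratios** are ratios of means (reverse/forward) of final GD and
  converged fraction; a zero forward mean GD is reported as undefined.
- **Intrinsic plasticity** of a location is the mean L1 phenotype drift
  `Σ_j |y_j(t_max) − y_j(0)|` of its samples under intrinsic dynamics (no
  early stop); locations are ranked ascending (rigid → plastic). Note that
  with a rank-based phenotype, near-zero `J` produces uniform exponential
  decay that preserves ranks, so weak coupling is *not* automatically
  plastic; the ranking is defined operationally by the measured drift.
- **Vector fields**: PCA fit on the union of matched start/end phenotypes;
  arrows are embedded start→end displacements; each component's sign is
  fixed by forcing its largest-magnitude loading positive. **Angles** are
  arccos of normalized dot products between matched same-origin arrow pairs,
  in full phenotype space by default (3-component PCA space optional);
  zero-length arrows are excluded with a warning.
- **Subpopulation ablation** removes from each of two locations the k
  samples with the smallest sample-level GD to the other location's
  intervals ("closest"; the model's own distance reused as the proximity
  measure) or k uniform random samples, recomputes targets from the reduced
  populations, and re-runs the transitions in both directions against the
  un-ablated baseline.

## Synthetic cohorts

The generator produces the three inputs with planted ground truth, fully
determined by one seed:

- **Skeleton**: total edges fixed to `round(target_avg_degree · n_genes)`,
  allocated over TFs proportionally to Pareto(1.5) propensities
  (largest-remainder rounding, capped at `n_genes − 1`), targets uniform
  without replacement, no self-loops. Heavy-tailed out-degrees reflect the
  hub-dominated topology that exploratory adaptation theory requires.
- **Pathway map**: sizes uniform in the configured range; a fraction
  `1 − overlap_fraction` of each pathway is drawn from never-used genes and
  the rest from already-used genes, so overlap is tunable and
  `overlap_fraction = 0` yields pairwise-disjoint sets.
- **Cohort**: one per-gene baseline `N(8, 2²)` (a log-expression-like
  scale) shared by all locations, plus each location's planted per-pathway
  mean shifts applied to member genes, plus `N(0, noise_sd²)` noise.
  Locations therefore differ *only* by planted shifts and noise, which is
  what makes downstream recovery checkable.

Bundled study designs: `ivy_scale_spec` mirrors the scale of the Ivy GAP
anatomic-structure cohort and its focused GBM regulatory network (4121
genes, average degree 19.09, 182 pathways, five locations with
30/19/24/25/24 samples); `demo_spec` is the desk-scale design (300 genes, 60
TFs, average degree 6, 20 pathways of 8–15 genes, overlap 0.25, three
locations × 20 samples, noise sd 1, shifts of 2 expression units on 4 of 20
pathways — i.e. 20% of pathways shifted by twice the noise sd);
`asymmetric_spec` plants a heterogeneous source (noise sd 2) against a
homogeneous shifted target (noise sd 0.5) for reversal experiments; and
`collinear_spec` plants a midpoint and an off-axis location for the
intermediate-state geometry.

What the generator does **not** emulate: sequencing count/FPKM noise models,
library-size artifacts and their normalization, gene–gene correlation
structure within locations beyond what the planted shifts induce, and
realistic pathway co-membership structure. Passing tests therefore
demonstrate that the pipeline recovers planted distributional differences
and that the dynamics behave as specified — not that real multi-region tumor
data would yield any particular effect size.

## Problem sizes and stochastic margins

Simulation experiments in the test and acceptance suites use the desk-scale
designs above with `t_max` of 80–200 reported steps and 8–20 samples × 10
seeds per condition; these sizes were chosen so each experiment gives stable
directional comparisons while the full suite stays fast. Two comparisons —
collinear-vs-off-axis arrow angles and closest-vs-random ablation — have
small effect sizes relative to run-to-run exploration noise; they hold at
the fixed seeds the tests state but can invert under other seed draws, which
the acceptance script reports honestly rather than hiding.

## Limitations

- The exploration walk is unbiased; target information enters only through
  damping of converged genes' noise, so adaptation is "explore, then
  freeze", not gradient descent toward the target. Final GDs on hard targets
  remain well above zero at desk scale.
- Euler integration with `h = 0.25` is stable for correlation-scale weights
  but is not an adaptive integrator; wildly rescaled `J` can require a
  smaller step.
- GD values are sums of rank-statistic distances and scale with gene count,
  pathway count, and pathway sizes; compare GDs only within one study
  design.
- Dense `n × n` matrices are used throughout (`n = 4121` needs ~400 MB for
  `T`, `J`, `D` together); the implementation targets cohort-scale gene
  lists, not genome-wide networks.
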