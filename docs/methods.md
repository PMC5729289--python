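# Methods

This note documents the modeling choices behind `ppisig`: what each stage
assumes, which knobs matter, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Network modularization

**GTOM.** The m-step generalized topological overlap of nodes *i, j* is

    t_ij = (l_ij + r_ij) / (min(k_i, k_j) + 1 − r_ij),   t_ii = 1,

with r_ij the indicator of 0 < d(i,j) ≤ m, k_i the m-step neighborhood
size, and l_ij the shared m-step neighbor count. Published GTOM variants
differ in whether the 1-step adjacency a_ij or the m-step indicator r_ij
enters the "+" and "−" correction terms. The default here applies the TOM
formula to the m-step neighborhood graph (r_ij in both places), reading
"m-step common neighbors" literally as overlap of m-step neighborhoods;
`compute_gtom(..., variant="adjacency")` switches to the a_ij form. For
m = 1 both coincide with classical TOM. Reachability is computed by boolean
matrix powers — dense O(n²) memory, tractable to n ≈ 10⁴ — and an
independent BFS/set-intersection oracle backs the tests.

**Dendrogram and tree cut.** Complete linkage on 1 − GTOM keeps all merge
heights in [0, 1], so the static cut height is interpreted on the raw
dissimilarity scale (no rescaling). The adaptive cut proceeds in three
steps: (1) a static cut at `max_height` (default 0.6) yields candidate
branches; (2) with `deep_split` on (default), a branch whose top merge
jumps more than `deep_split_gap × max_height` (gap fraction default 0.25)
above its children's merge heights is recursively split, provided at least
one child could still form a module — this isolates nested tight
sub-branches that one static cut would lump together, while a homogeneous
branch (merges at similar heights) is never split; (3) branches with fewer
than `min_size` leaves (default 5) are left unassigned. Modules are named
`Mod1, Mod2, …` by decreasing size; dataset-specific names from any
particular cohort are not meaningful across runs. Raising `min_size` can
only remove or merge modules, never create them, and planted blocks
separated by dissimilarity above the cut height are recovered exactly
(both properties are under test).

## Expression preparation

Inputs are log-scale matrices (features × samples, TSV; a GCT preamble is
tolerated). Normalization and detection-call generation are upstream of
this package; the detection filter consumes a precomputed 0/1 flag matrix
and keeps features present in *strictly more than* `min_fraction`
(default 0.2) of samples, mirroring a "more than 20%" rule. Probe-to-gene
collapse keeps the probe with the highest mean expression (deterministic
tie-break by probe id): order-independent and preserves one observed
profile instead of averaging correlated probes. Cohorts are intersected on
sorted common genes before scoring so both profiles live in the same gene
space. Modules are mapped onto the measured genes and dropped below
`min_mapped` = 2 genes — a one-gene "set" makes the enrichment walk
degenerate in interpretation — configurable down to 1. Sample-id mismatches
between expression and clinical tables are a hard error, never a silent
intersection.

## Module scoring

The kernel-CDF statistic z_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i) uses a
Gaussian kernel with bandwidth h_i = s_i/4 (sample standard deviation,
ddof = 1), appropriate for continuous log-scale values; no count mode is
provided. Scores come from a weighted KS-like walk over each sample's gene
ranking (descending z, ties kept in input row order for determinism):
set genes step by |p/2 − r|^τ (τ default 1), non-set genes by 1/(p − |set|),
and the enrichment score is the maximum plus the minimum walk deviation
("max_diff"), bounded in [−1, 1]. Scoring is run per cohort, not jointly,
so no validation information leaks into training-cohort scores. A naive
per-sample Python implementation serves as the test oracle at 1e−10.

## Survival modeling

Cox models maximize the Efron-tie-corrected partial likelihood (via
lifelines). The interaction screen fits, per module,
`h(t) = h0(t) exp(b1·trt + b2·score + b3·trt·score)` on relapse-free
survival and BH-adjusts the Wald p of b3 across modules (threshold 0.05).
The continuous score is the default regressor — dichotomizing at the
median (`score_mode="dichotomized"`) is available but costs power and
needs an arbitrary cut-point. Only treatment and the module score enter
the screen; additional covariates can be assessed afterwards with
`fit_cox`. Non-converged fits are recorded with p = 1 and a warning so a
single pathological module cannot abort a several-hundred-module scan.
Grid-search maximization of the same partial likelihood is the test oracle
on small complete-data toys; note that exact invariance of the estimate
under row duplication holds for the Breslow tie approximation but not
Efron, so the duplication test asserts closeness, not equality.

## Signature construction

Patient clustering uses 1 − Pearson correlation between per-patient score
vectors with complete linkage, cut at k = 2; label 1 is the larger
cluster (the original sub-group labels of any given cohort are not
recoverable, so a size convention replaces them). Correlation distance is
undefined for a single-module profile; that corner falls back to absolute
score distance. Note this metric is blind to a uniform level shift across
all modules — a direct consequence of per-patient centering — which is why
a subtype expressed only as "all modules up" cannot be clustered this way
(see the generator notes below).

Backward elimination ranks modules once, by permutation importance of the
first forest (5000 trees), and never re-ranks — re-estimated importances
inside the loop bias selection toward noise. Each iteration drops the
bottom 20% (at least one) and refits a 3000-tree forest, recording OOB
error with its binomial standard error sqrt(e(1−e)/n). The chosen panel is
the smallest subset with error ≤ min error + SE(at the min). Training-set
class probabilities are read from out-of-bag votes: in-bag random-forest
probabilities are nearly degenerate, so OOB is the defensible basis for
the training ROC (AUC with a DeLong 95% CI) and for the training benefit
report; `predict_cohort` on new data uses ordinary forest votes with the
strict cut-off P(Cluster 1) > 0.5.

The benefit report compares treated vs untreated patients (KM curves,
log-rank, univariate Cox treatment coefficient) within the whole cohort
and within each predicted sub-group, for every available endpoint, plus a
cohort-level Cox `treatment + cluster + treatment×cluster` interaction
test. Strata without events keep their curves and skip the tests with a
warning.

## Synthetic cohorts

The generator plants, in order: a partition network (within-module edge
probability `p_in` = 0.9, elsewhere `p_out` = 0.001, 60 modules of 5–15
nodes plus 600 background nodes); factor-model expression
x_ij = λ f_mj + ε with λ = 1, ε ~ N(0, 0.5²) and module factors
f_mj ~ N(0, 1); a latent two-class subtype (P = 0.5) that shifts the
factors of 6 predictive modules by Δ = 2.5, with alternating sign across
those modules (half up-, half down-regulated in subtype 2 — a mixed
pattern like real signatures, and necessary because correlation-based
patient clustering cannot see a uniform shift); Bernoulli(0.5) treatment;
and exponential survival with hazard
h0 · exp(β_trt·trt + β_int·trt·[subtype 2]), h0 = 0.12/year,
β_trt = log 0.5 and β_int = log 4, so treatment halves the hazard in
subtype 1 and doubles it in subtype 2. Censoring is independent uniform
U(0, c) with c calibrated by bisection on the drawn event times so the
expected censored fraction meets the target (0.2); RFS and OS are
independent draws from the same hazard. Two cohorts (300 + 150 samples)
share one truth but no samples. Δ = 2.5 (vs unit within-subtype factor
spread) encodes a clearly separated molecular subtype; smaller shifts make
the module score too weak a subtype proxy for a 300-sample
treatment-interaction screen to flag reliably, which is a statement about
that design's power, not about the implementation.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, informative censoring, correlated module factors, subtype
main effects on survival, or imbalanced treatment assignment. Passing the
recovery tests therefore shows the pipeline's stages compose correctly and
recover a planted signal of realistic strength — not that any real cohort
contains such a signal.

## Numerical and reproducibility choices

- All stochastic stages take explicit integer seeds; identical inputs,
  config and seeds give byte-identical primary outputs (TSV/GMT/JSON).
- Ranking ties in the enrichment walk, probe-collapse ties, and module
  naming all break deterministically (input order / lexicographic / size).
- The boolean-matrix GTOM is exact, not approximate; degenerate pairs with
  empty neighborhoods score 0 by convention.
- The enrichment walk's rank weight |p/2 − r| vanishes at the middle rank,
  so a tiny gene set can carry zero total weight in a sample (even p);
  such samples fall back to unweighted hit counting instead of dividing
  by zero.
- The screen records non-convergence rather than raising; the training
  phase stops with an explicit error when no module passes the FDR screen.
- Analysis defaults follow the studied workflow (GTOM m = 2, cut 0.6 / 5 /
  deep split, detection 0.2, FDR 0.05, k = 2, forests 5000/3000, drop 20%,
  cut-off 0.5). The 20-seed recovery experiments in the acceptance tests
  and `scripts/acceptance.py` run the forests at 1500/1000 trees with 3
  permutation repeats — at n = 300 the OOB error is stable well below the
  default tree counts, and this keeps twenty full-pipeline replicates
  desk-scale; the generator's truth parameters are never reduced.

## Known limitations

- The training-cohort AUC/accuracy are computed on the same cohort whose
  clustering defined the labels; even with OOB probabilities this
  screen-then-cluster-then-classify loop is optimistic. Only the
  independent-cohort metrics are honest estimates of generalization; a
  nested cross-validation of the whole pipeline is out of scope.
- The dynamic tree cut implements the "tree" flavor (static cut + gap-based
  deep split + minimum size); the "hybrid" PAM-stage variant is not
  provided, and the deep-split gap fraction is a heuristic with no claim of
  equivalence to any particular reference implementation's internals.
- Cox models assume proportional hazards and no time-varying covariates;
  no diagnostics are provided.
- The screen tests each module marginally; correlated modules (e.g. all
  tracking one subtype) pass or fail together, and BH controls FDR only
  under the usual positive-dependence conditions.
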