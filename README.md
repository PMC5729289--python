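# ppisig

Network-derived gene-expression signatures that predict **who benefits from a
treatment** — not merely who has a good prognosis.

`ppisig` re-implements, as a tested and reusable Python pipeline, a
systems-biology strategy for building predictive biomarkers in oncology
cohorts: tightly connected sub-modules are extracted from a protein–protein
interaction (PPI) network, each patient's expression profile is condensed
into per-module enrichment scores, and the modules whose scores *modify the
treatment effect on survival* are distilled into a compact random-forest
classifier that splits patients into sub-groups with opposite treatment
benefit. It is aimed at computational biologists and biostatisticians who
want each stage — network modularization, single-sample scoring, interaction
screening, panel selection, survival evaluation — as an importable,
seedable, individually testable component.

## The method

1. **Module discovery.** From an undirected PPI network with adjacency
   $a_{ij}$, the $m$-step generalized topological overlap (GTOM) is

   $$t_{ij} = \frac{l_{ij} + r_{ij}}{\min(k_i, k_j) + 1 - r_{ij}},$$

   where $r_{ij}$ indicates that $j$ lies within $m$ steps of $i$,
   $k_i = \sum_u r_{iu}$, and $l_{ij} = \sum_{u \neq i,j} r_{iu} r_{uj}$
   counts shared $m$-step neighbors ($m = 2$ by default; $m = 1$ recovers
   the classical TOM). Complete-linkage clustering of the dissimilarity
   $1 - t_{ij}$ followed by an adaptive (dynamic) tree cut — static cut
   height 0.6, minimum size 5, optional deep split of nested branches —
   yields disjoint sub-modules.
2. **Single-sample scoring.** Expression values become kernel-CDF
   statistics $z_{ij} = \frac{1}{n}\sum_k \Phi\!\big((x_{ij} - x_{ik})/h_i\big)$
   with bandwidth $h_i = s_i/4$; each module is scored per sample by a
   weighted Kolmogorov–Smirnov-like walk over the sample's gene ranking
   (weight $|p/2 - r|^\tau$, score = max + min walk deviation, in
   $[-1, 1]$).
3. **Interaction screen.** Per module, a Cox proportional-hazards model
   $h(t) = h_0(t)\,e^{\beta_1 \mathrm{trt} + \beta_2 s + \beta_3\, \mathrm{trt}\cdot s}$
   is fitted on relapse-free survival; the Wald $p$ of $\beta_3$ is
   Benjamini–Hochberg adjusted across modules and modules with $q < 0.05$
   are kept. A *predictive* marker is exactly one with $\beta_3 \neq 0$.
4. **Signature construction.** Patients are clustered on the screened
   module scores ($1 - $ Pearson $r$, complete linkage, $k = 2$); a
   backward-elimination random forest (5000 trees first, 3000 per
   iteration, dropping 20% of modules each round, importances ranked once)
   selects the smallest panel whose out-of-bag (OOB) error is within one
   standard error of the minimum; the final forest classifies any cohort
   via class probability > 0.5.
5. **Evaluation.** ROC/AUC with DeLong confidence intervals on OOB
   probabilities, Kaplan–Meier curves and log-rank tests of treated vs
   untreated patients within each predicted sub-group, and a Cox
   treatment × sub-group interaction test.

Because the real cohorts behind the original analysis live in external
repositories, the package ships a first-class synthetic-data generator
(`ppisig.synthetic`) that plants a modular network, factor-model
expression, a latent two-class subtype, and survival with a reversed
treatment effect (hazard ratio 0.5 in subtype 1 vs 2.0 in subtype 2), so
the whole pipeline is exercised against a known ground truth.

## Worked example

`examples/05_full_pipeline.py` (about half a minute; the other examples
demonstrate one stage each):

```text
cohorts: 300 training / 150 validation samples
discovered 64 modules (60 planted, 6 predictive)
screen selected 8 modules at FDR < 0.05
final panel: ['Mod11', 'Mod1', 'Mod27', 'Mod40', 'Mod61', 'Mod52', 'Mod12'] (Jaccard vs planted predictive set: 0.86)
training OOB AUC: 0.997
validation subtype accuracy: 0.987
validation Cluster1: treatment log HR +0.85, log-rank p 0.0009
validation Cluster2: treatment log HR -0.82, log-rank p 0.0090
validation treatment x cluster interaction p: 3.79e-05
```

Reading the numbers: the tree cut found 64 modules (the 60 planted ones,
some with a stray background protein absorbed, plus a few background
clumps); the interaction screen kept 8, and backward elimination kept 7,
of which 6 map onto planted predictive modules (Jaccard 0.86). Applied to
the held-out cohort, the predictor recovers the latent subtype for 98.7%
of patients, and the two predicted sub-groups show opposite-signed
treatment effects — benefit in one stratum, harm in the other — with a
significant treatment × sub-group interaction, which is precisely the
property a *predictive* (rather than prognostic) signature must have.

The same workflow is scriptable from a shell:

```bash
ppisig simulate --out scenario --seed 5
ppisig discover --network scenario/network_edges.tsv --output-dir out
ppisig train    --modules out/modules.gmt \
                --expression scenario/training_expression.tsv \
                --clinical scenario/training_clinical.tsv --output-dir out
ppisig validate --modules out/modules.gmt \
                --expression scenario/validation_expression.tsv \
                --clinical scenario/validation_clinical.tsv \
                --predictor out/predictor.bin --output-dir out
```

or in one shot on a simulated scenario: `ppisig all --output-dir out --seed 5`.

## Layout

- `src/ppisig/network.py` — edge-list parsing (incl. the HPRD flat-file
  dialect), GTOM, dissimilarity
- `src/ppisig/modules.py` — complete-linkage dendrogram, dynamic tree cut,
  GMT round-trip
- `src/ppisig/prep.py` — detection filtering, probe collapse, cohort
  intersection, module mapping, clinical tables
- `src/ppisig/gsva.py` — kernel-CDF statistic and random-walk module scores
- `src/ppisig/survival.py` — Cox fits, interaction screen, BH, KM,
  log-rank, Yates chi-square
- `src/ppisig/signature.py` — patient clustering, RF backward elimination,
  predictor, ROC/DeLong, benefit report
- `src/ppisig/synthetic.py` — planted-truth cohort generator
- `src/ppisig/pipeline.py`, `src/ppisig/cli.py` — orchestration, manifests,
  CLI

See `docs/methods.md` for modeling assumptions, parameter defaults, and
known limitations.
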