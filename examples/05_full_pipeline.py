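"""End-to-end run: module discovery, training, independent validation.

Generates two cohorts from one planted truth (a latent patient subtype
reverses the treatment effect: hazard ratio 0.5 in subtype 1, 2.0 in
subtype 2), then checks how much of that truth the pipeline recovers.
Takes about half a minute.
"""

import numpy as np

from ppisig.pipeline import RunConfig, discover_modules, train_signature, validate_signature
from ppisig.synthetic import SyntheticConfig, generate_cohorts, panel_jaccard

config = SyntheticConfig(seed=11)
network, train, valid, truth = generate_cohorts(config)
print(f"cohorts: {config.n_train} training / {config.n_valid} validation samples")

modules = discover_modules(network)
print(f"discovered {len(modules)} modules "
      f"({config.n_modules} planted, {len(truth.predictive_modules)} predictive)")

run_config = RunConfig(seed=11, ntree_first=1500, ntree_iter=1000,
                       importance_repeats=3)
result = train_signature(train.expression, train.clinical, modules, run_config)
print(f"screen selected {len(result.screen.selected_modules)} modules at "
      f"FDR < {run_config.fdr_threshold}")
print(f"final panel: {result.predictor.modules} "
      f"(Jaccard vs planted predictive set: "
      f"{panel_jaccard(result.predictor.modules, modules, truth):.2f})")
print(f"training OOB AUC: {result.roc.auc:.3f}")

validation = validate_signature(
    valid.expression, valid.clinical, modules, result.predictor, run_config
)
subtype = truth.subtypes["validation"].to_numpy()
predicted = validation.predictions["cluster"].to_numpy()
accuracy = max((predicted == subtype).mean(), (predicted == 3 - subtype).mean())
print(f"validation subtype accuracy: {accuracy:.3f}")

for stratum in ("Cluster1", "Cluster2"):
    rec = validation.benefit.strata[(stratum, "rfs")]
    print(f"validation {stratum}: treatment log HR "
          f"{rec.get('treatment_log_hr', np.nan):+.2f}, "
          f"log-rank p {rec.get('logrank_p', np.nan):.4f}")
print(f"validation treatment x cluster interaction p: "
      f"{validation.benefit.interaction['rfs']['p']:.2e}")
print("opposite-signed hazard ratios in the two predicted sub-groups plus a")
print("significant interaction reproduce the planted benefit reversal")
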