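"""Stratified five-fold cross-validation of the full pipeline.

Each fold holds out ~20% for testing and splits the rest 75/25 into train
and validation (60/20/20 overall). Everything fold-local: normalization,
orthology expansion, model weights, decision threshold.
"""

import tempfile

from dlam.evaluation import run_cv
from dlam.pipeline import FeatureConfig, build_dataset
from dlam.synthetic_data import StudyConfig, generate_study, write_study
from dlam.training import TrainConfig

with tempfile.TemporaryDirectory() as tmp:
    write_study(generate_study(StudyConfig(n_proteins=500, seed=1)), tmp)
    dataset, _ = build_dataset(tmp, FeatureConfig(seed=1))

result = run_cv(dataset, k=5, train_cfg=TrainConfig(seed=1), seed=1)

print("fold  acc    prec   rec    F1     AUC    AP")
for i, r in enumerate(result.fold_reports, 1):
    print(f"{i:>4}  {r.accuracy:.3f}  {r.precision:.3f}  {r.recall:.3f}  "
          f"{r.f_measure:.3f}  {r.auc:.3f}  {r.ap:.3f}")
print("\nmean +/- sd across folds:")
for metric, (mean, sd) in result.summary().items():
    print(f"  {metric:<10} {mean:.3f} +/- {sd:.3f}")
# With the default planted effect sizes the model should recover the signal
# clearly (mean AUC well above 0.85); fold-to-fold spread reflects the
# sampling noise of ~100-protein test folds.
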