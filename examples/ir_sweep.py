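"""Sweep the training balance ratio and watch sensitivity respond.

On an imbalanced weak-signal table, a classifier trained at low balance
ratios favours the majority class (high specificity, low sensitivity);
raising r towards 1.0 gives the model more minority examples and typically
raises sensitivity.  Metrics are mean +/- std over repeated 80/20 splits;
test rows are untouched real rows.
"""

from dermaug import SyntheticTableSpec, generate_feature_table
from dermaug.evaluate import ir_sweep_experiment

table, _ = generate_feature_table(SyntheticTableSpec(
    n_maj=160, n_min=40, n_features=20, n_informative=5,
    effect_size=0.8, block_corr=0.3, seed=1))

result = ir_sweep_experiment(
    table, models=("lasso",), oversampler="smote",
    r_values=(0.5, 0.75, 1.0), repeats=5, seed=1)

print("balance ratio r | AUCROC        | sensitivity   | specificity")
for r in (0.5, 0.75, 1.0):
    rec = result.lookup("lasso", "smote", r)
    print(f"      {r:4.2f}      | {rec['aucroc_mean']:.3f}+/-{rec['aucroc_std']:.3f} |"
          f" {rec['sensitivity_mean']:.3f}+/-{rec['sensitivity_std']:.3f} |"
          f" {rec['specificity_mean']:.3f}+/-{rec['specificity_std']:.3f}")
print("sensitivity (melanoma detection rate) should not fall as r rises; "
      "specificity may dip as the decision boundary shifts toward the "
      "minority class.")
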