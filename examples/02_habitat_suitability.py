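"""Fit and evaluate a habitat-suitability model on synthetic occurrences.

Samples presence points proportional to known suitability on a
sharp-response world, places pseudo-absences by rejection sampling, runs
backward collinearity selection (|r| > 0.8 pairs, then VIF < 4), fits the
random-forest suitability model on a 7:3 split, and prints the four
standard evaluation statistics plus the variable importances. The
continuous Boyce index (CBI) is the presence-only calibration measure:
values near +1 mean predicted suitability ranks habitat use correctly.
"""

import numpy as np

from spreadca import SyntheticSpec, gen_landscape, gen_occurrences
from spreadca.habitat import (
    LABEL_COLUMN, evaluate_model, extract_covariates, fit_suitability,
    select_variables, split_train_test, variable_importance,
)
from spreadca.occurrences import ThinningConfig, sample_pseudo_absences

spec = SyntheticSpec(nx=120, ny=120, seed=7, intercept=-2.0,
                     response_coefficients={"temperature": 4.0,
                                            "precipitation": -3.0, "hfp": 3.0})
bundle = gen_landscape(spec)
presences = gen_occurrences(bundle.suitability_truth, n=300, seed=8)
mask = bundle.landcover.with_values(np.ones(bundle.landcover.shape, dtype=np.int64))
pas = sample_pseudo_absences(
    mask, presences,
    ThinningConfig(min_interpoint=1.0, pa_min_dist=400.0,
                   n_pseudo_absence=300, seed=9))

table = extract_covariates(presences.concat(pas), bundle.covariates)
selection = select_variables(table)
print("selected covariates:", selection.kept,
      f"(dropped {len(selection.log)})")

train, test = split_train_test(table[selection.kept + [LABEL_COLUMN]], seed=1)
model = fit_suitability(train, n_trees=300, seed=2)
report = evaluate_model(test[LABEL_COLUMN], model.predict(test))
print(f"test metrics: CBI={report.cbi:.3f}  AUC={report.auc:.3f}  "
      f"kappa={report.kappa:.3f}  TSS={report.tss:.3f} "
      f"(threshold {report.threshold:.2f} = max-TSS cut)")

print("node-impurity importances:")
for name, score in variable_importance(model):
    truth = spec.response_coefficients.get(name, 0.0)
    print(f"  {name:>13}: {score:.3f}  (true effect on logit suitability: {truth:+.1f})")
print("\nThe strongest true effect should rank first; CBI/AUC well above 0.5")
print("show the model recovered the known occurrence response.")
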