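"""Evaluate predictions: IPCW Brier curve, IBS, C-index and calibration.

A Cox model is fitted on a training split and judged on the test split:
the prediction-error curve at years 1..10, its time average (IBS), the
concordance of the prognostic index, and a decile calibration table at
2 years.
"""

import numpy as np

from plannsurv import (
    GeneratorSpec, calibration_table, concordance_index, fit_cox, generate,
    integrated_brier, make_interval_grid, predict_cox_survival,
    prediction_error_curve, reverse_km, split_sample,
)

grid = make_interval_grid(10, 10)
cohort = generate(GeneratorSpec(n=4000, seed=5))
train_set, test_set = split_sample(cohort, seed=5)

fit = fit_cox(train_set)
times = np.asarray(grid.boundaries[1:])
surv = predict_cox_survival(fit, test_set.covariates, times)

censoring = reverse_km(train_set)
curve = prediction_error_curve(surv, test_set, times, censoring)
print("prediction-error (Brier) curve:")
for t, err in curve.items():
    print(f"  year {int(t):2d}: {err:.3f}")
print(f"IBS (0-10 years): {integrated_brier(curve, t_hor=10):.3f}")

cindex = concordance_index(fit.prognostic_index(test_set.covariates), test_set)
print(f"C-index of the prognostic index: {cindex:.3f}")

cal = calibration_table(surv[:, 1], test_set, t=2.0, n_groups=10)
print("\ncalibration at 2 years (per risk decile):")
print(cal.round(3).to_string(index=False))
# a well-calibrated model keeps mean_predicted inside the Kaplan-Meier
# confidence band [ci_lower, ci_upper] in (almost) every decile.
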