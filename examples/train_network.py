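"""Train a discrete-time survival network and predict survival curves.

A 1-hidden-layer PLANN is trained on person-period rows; its sigmoid
output is the conditional hazard per year, composed into survival by
S(t_m) = prod_{j<=m} (1 - h_j).
"""

import numpy as np

from plannsurv import (
    GeneratorSpec, PlannConfig, build_plann, count_weights, generate,
    hazards_to_survival, make_interval_grid, predict_hazards, split_sample,
    to_long_test, to_long_train, train,
)

grid = make_interval_grid(10, 10)
cohort = generate(GeneratorSpec(n=3000, seed=2))
train_set, test_set = split_sample(cohort, train_frac=2 / 3, seed=2)

config = PlannConfig(node_size=16, dropout_rate=0.1, learning_rate=0.2,
                     momentum=0.9, n_epochs=30, seed=2)
model = build_plann(config, len(cohort.covariate_names), grid.k)
print(f"network: {model.n_inputs} inputs, {config.node_size} hidden nodes, "
      f"{count_weights(model)} trainable weights")

train(model, to_long_train(train_set, grid))
print(f"training loss: {model.loss_trace[0]:.4f} (epoch 1) -> "
      f"{model.loss_trace[-1]:.4f} (epoch {config.n_epochs})")

hazards = predict_hazards(model, to_long_test(test_set, grid))
survival = hazards_to_survival(hazards)
print("\nfirst test subject, yearly hazard and survival:")
for j in range(grid.k):
    print(f"  year {j + 1:2d}:  h = {hazards[0, j]:.3f}   S = {survival[0, j]:.3f}")
print(f"\nmean predicted 10-year survival: {survival[:, -1].mean():.3f}")
# hazards are conditional probabilities of the event in each year given
# survival to its start; the survival column is their running product.
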