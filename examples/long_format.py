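"""Person-period expansion: from (time, event, x) to interval rows.

Discrete-time models see one row per subject per year at risk, with the
year encoded as 10 indicator columns and a binary target marking the
event year.
"""

import numpy as np
import pandas as pd

from plannsurv import SurvivalDataset, make_interval_grid, to_long_test, to_long_train

data = SurvivalDataset(
    time=np.array([2.5, 2.5, 0.12]),
    event=np.array([1, 0, 1]),
    covariates=pd.DataFrame({"diabetes": [1.0, 0.0, 1.0]}),
)
grid = make_interval_grid(10, 10)  # yearly intervals (0,1], ..., (9,10]

long_train = to_long_train(data, grid)
print("training expansion (one row per interval observed):")
print(long_train.frame[["subject_id", "interval", "diabetes", "target"]].to_string(index=False))

long_test = to_long_test(data, grid)
print(f"\ntest expansion: {long_test.frame.shape[0]} rows "
      f"({data.n} subjects x {grid.k} intervals, for full hazard profiles)")
# the subject who died at 0.12 years contributes a single row with target 1;
# the censored subject contributes target-0 rows for every interval observed.
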