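"""Train the 2x10 network on a 60/40 record split and predict 3-month Hb.

The network must beat two baselines to show the dosing features carry
signal: predicting no change, and a linear fit on the current Hb alone.
"""

import numpy as np

from hbforecast import (Hyperparams, SimulationConfig, SplitSpec,
                        apply_inclusion_criteria, build_records, predict,
                        simulate_cohort, train)

cohort = simulate_cohort(SimulationConfig(n_patients=100, calendar_days=1095, seed=21))
kept, _ = apply_inclusion_criteria(cohort.profiles, cohort.doses)
records = build_records(cohort, kept)

model = train(records, SplitSpec(train_frac=0.6, seed=1), Hyperparams(), seed=2)
valid = records[records["valid"]].set_index("record_id", drop=False)
test = valid.loc[model.test_ids]
train_df = valid.loc[model.train_ids]

preds = predict(model, test)
y = test["delta_hb"].to_numpy()
mae = np.abs(y - preds["delta_hb_pred"]).mean()

A = np.column_stack([np.ones(len(train_df)), train_df["hb_t"]])
coef, *_ = np.linalg.lstsq(A, train_df["delta_hb"].to_numpy(), rcond=None)
mae_linear = np.abs(y - (coef[0] + coef[1] * test["hb_t"].to_numpy())).mean()

print(f"trained on {len(train_df)} records, tested on {len(test)}")
print(f"test MAE            {mae:.3f} g/dL   (the model)")
print(f"zero-change baseline {np.abs(y).mean():.3f} g/dL")
print(f"Hb(t)-only baseline  {mae_linear:.3f} g/dL")
print("\nA lower model MAE than both baselines means the dose history and the")
print("planned ESA/iron therapy genuinely inform the 3-month Hb forecast.")
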