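"""Cause-specific Cox models of incident HF by trajectory, plus discrimination.

Generates a testing-style cohort (n=4419, single echo at ~75 y) with the
published hazard-ratio configuration and recovers the hazard ratios, then
compares model discrimination with and without trajectory information.
"""

import numpy as np

import cardiotraj as ct
from cardiotraj.survival import (cause_specific_dataset, compare_c, fit_cox,
                                 harrell_c)

config = ct.testing_config(seed=11)
_, covariates, survival, truth = ct.generate_cohort(config)

print("endpoint            group         HR (recovered)  generator")
gen = {"any_hf": ("traj[orange]", 2.32), "hf_pef": ("traj[blue]", 1.76),
       "hf_ref": ("traj[dark_green]", 8.08)}
risk_cols = {}
for endpoint, (col, target) in gen.items():
    ds = cause_specific_dataset(survival, endpoint)
    res = fit_cox(ds, trajectory=truth["group"], reference_group="pink",
                  endpoint=endpoint)
    print(f"{endpoint:<18}  {col:<13} {res.hazard_ratio(col):>8.2f}       {target}")
    risk_cols[endpoint] = (ds, res)

# discrimination: age+sex vs. age+sex+trajectory for any incident HF
ds, _ = risk_cols["any_hf"]
base_cov = covariates[["age_years", "male"]].reset_index(drop=True)
base = fit_cox(ds, covariates=base_cov)
full = fit_cox(ds, covariates=base_cov, trajectory=truth["group"],
               reference_group="pink")
lin_base = base_cov.to_numpy() @ base.table["coef"].to_numpy()
X_full = np.column_stack([
    *(np.asarray(truth["group"] == g, dtype=float)
      for g in sorted(set(truth["group"]) - {"pink"})),
    base_cov.to_numpy()])
lin_full = X_full @ full.table["coef"].to_numpy()
c_base, c_full = harrell_c(lin_base, ds), harrell_c(lin_full, ds)
delta, p = compare_c(lin_base, lin_full, ds, n_boot=500, seed=3)
print(f"\nHarrell C: {c_base:.3f} (age+sex) vs {c_full:.3f} (+trajectory); "
      f"delta {delta:+.3f}, bootstrap p {p:.2g}")
print("a positive delta with small p means trajectory membership adds "
      "discrimination for incident HF beyond age and sex.")
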