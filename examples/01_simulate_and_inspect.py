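"""Generate a synthetic Likert sample and inspect its generative truth.

The generator draws multivariate-normal latent responses from a correlated
common-factor model and cuts them into the five observed categories, so the
population correlation matrix — and hence the right answer for every
dimensionality method — is known exactly.
"""

import numpy as np

from netdim import population_correlation, scenario_config, simulate_dataset

cfg = scenario_config("online_4dim", seed=7)  # 32 items, 4 factors, n=480
ds = simulate_dataset(cfg)

print(f"sample: n={ds.responses.n}, p={ds.responses.p}")
print("items per true dimension:", np.bincount(ds.true_membership).tolist())
print("factor correlations:\n", cfg.factor_correlations)

sigma = population_correlation(cfg)
emp = np.corrcoef(ds.responses.values, rowvar=False)
print(f"max |empirical - population| correlation: {np.abs(emp - sigma).max():.3f}")
print("(ordinal discretization attenuates the empirical values below the "
      "latent population ones, so this gap does not vanish with n)")
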