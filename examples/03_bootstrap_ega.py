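"""Stabilize the dimension count with a parametric bootstrap.

Each replicate resamples n observations from a multivariate normal with the
sample correlation matrix and re-runs the whole network + walktrap
estimation; the median community solution over replicates is the headline
dimension count.
"""

from netdim import bootstrap_ega, scenario_config, simulate_dataset

ds = simulate_dataset(scenario_config("online_4dim", seed=5))  # n=480

boot = bootstrap_ega(ds.responses, B=100, seed=5)
print(f"B = {boot.B} replicates; median community solution: "
      f"{boot.median_dimensions} -> headline {boot.n_dimensions} dimensions")
print("how often each count occurred:")
for k, v in sorted(boot.frequency_table.items()):
    print(f"  {k} dimensions: {100 * v:.0f}% of replicates")
print("(a spread-out table means the sample is too small to pin the count "
      "down — the rule of thumb wants p(p-1)/2 = 496 participants here)")
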