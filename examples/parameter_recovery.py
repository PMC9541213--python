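"""How well can the rate be recovered at different noise levels?

Simulates many experiments per condition and tabulates bias, RMSE and how
often the residual-standard-error comparison picks the generating shape —
the check to run before trusting rates estimated from a design like yours.
"""

import acclimate as a

grid = [
    a.SimulationConfig(shape="exponential", lam_true=0.05, noise_sd=sd,
                       times=a.default_times(0.05), n_replicates=5)
    for sd in (0.0, 0.02, 0.05, 0.1)
]
table = a.recovery_experiment(grid, n_sims=200, seed=0)
cols = ["noise_sd", "relative_bias", "rmse", "select_exponential"]
print(table[cols].to_string(index=False, float_format=lambda x: f"{x:8.4f}"))
print("\nAt zero noise the rate is recovered exactly and the generating"
      " shape always wins; both degrade gracefully as noise grows.")
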