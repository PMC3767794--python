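"""Validate every fitting stage by parameter recovery on synthetic data.

Simulates seasons under the study conditions (growth calibration, phase and
logistic parameters, additive sigma = 0.2 Mg/ha noise), refits each stage,
and summarizes estimator bias and RMSE.  A noiseless run closes exactly
because every linearization is exact on clean data.
"""

from growthquant import NoiseModel, SimConfig, recovery_experiment

clean = recovery_experiment(SimConfig(noise=NoiseModel(kind="none"), seed=1),
                            n_reps=1)
print("noiseless closure (max relative error over all parameters):",
      f"{clean['median_rel_err'].max():.2e}")

cfg = SimConfig(noise=NoiseModel("additive_gaussian", sigma=0.2), seed=1)
summary = recovery_experiment(cfg, n_reps=200)
print("\nadditive noise sigma = 0.2 Mg/ha, 200 replicates:")
print(summary.to_string(index=False,
                        float_format=lambda v: f"{v:.4g}"))

print("\nn_failed counts replicates whose linearized fit degenerated (the"
      "\nratio transform is fragile at small biomass); they are reported,"
      "\nnever silently dropped.")
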