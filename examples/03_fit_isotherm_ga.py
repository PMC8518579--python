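"""Fit Moreau isotherm parameters to batch-equilibrium data with the GA.

Generates a synthetic 36-point equilibrium dataset (pH 4-9.5 x 1-60 mM,
2% measurement noise) from known parameters, then recovers them with the
steady-state genetic algorithm: population 10, single elite, recombination
of the top five, 20% per-gene mutation.  A reduced budget (10,000
iterations x 4 restarts) keeps this demo under ~10 s; the study-scale
budget is 20,000 x 10 or more.
"""

from cdisorb import (
    GAConfig,
    MALEIC_ACID,
    TABLE_PARAMS_MALEIC,
    generate_synthetic_batch,
    run_ga,
)

dataset = generate_synthetic_batch(TABLE_PARAMS_MALEIC, noise_cv=0.02, seed=3)
print(f"synthetic dataset: {len(dataset)} points, "
      f"pH {dataset.pH.min():.1f}-{dataset.pH.max():.1f}, "
      f"{dataset.c_eq_mM.min():.0f}-{dataset.c_eq_mM.max():.0f} mM")

config = GAConfig(max_iterations=10_000, n_restarts=4, seed=3)
fit = run_ga(dataset, config, MALEIC_ACID)

print(f"\nbest R^2 = {fit.r_squared:.4f}   (restart mean +- SD below)")
truth = TABLE_PARAMS_MALEIC
for name, true_val in [("K_A", truth.K_A), ("K_B", truth.K_B),
                       ("q_max", truth.q_max)]:
    mean, sd = fit.mean_params[name], fit.sd_params[name]
    print(f"  {name:6s} {mean:8.2f} +- {sd:6.2f}   (true {true_val})")
print("\nAt this reduced budget individual restarts still stall on a flat"
      " K/q_max ridge, so the restart means sit 10-20% off; the study-scale"
      " budget (20k x 10) brings K_A and q_max within ~5-10%. The pairwise"
      " interaction energies stay weakly identified at any budget - many"
      " strongly repulsive U_AB values fit equally well.")
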