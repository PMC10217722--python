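"""Small-scale robustness benchmark: informational CCA (tau = 0) versus the
robust setting tau = 0.5 under 5% contamination.

Each replicate draws the 8x3 linear-plus-quadratic design plus a coupled
contaminated twin in which the two structured responses are swapped in 5%
of rows.  The P2 statistic measures how far the contaminated fit's first
canonical direction rotates away from the clean fit's: smaller is more
stable.  A desk-scale run (10 replicates); the full benchmark lives in
scripts/acceptance.py.
"""

from rpcca import SimulationConfig, run_monte_carlo

config = SimulationConfig(
    n=100, epsilon=0.05, tau_grid=(0.0, 0.5), replicates=10, seed=1, restarts=4
)
report = run_monte_carlo(config)
wide = report.to_wide()
print(wide.round(4).to_string())

first_pair = report.table.set_index(["tau", "pair", "metric"])["mean"]
print()
print(f"P2 stability, first pair:  tau=0: {first_pair.loc[(0.0, 1, 'p2_a')]:.3f}   "
      f"tau=0.5: {first_pair.loc[(0.5, 1, 'p2_a')]:.3f}")

# Expected pattern: recovery correlations (rho_a, rho_b) stay near 1 for
# both tau values, while the clean-vs-contaminated distances (p2_*, l2_*)
# shrink at tau = 0.5 — the robustness gain of a positive tuning parameter
# costs almost no accuracy.
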