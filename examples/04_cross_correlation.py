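"""Time-lagged cross-correlation with a known ground truth.

A coupled Ornstein-Uhlenbeck pair is generated with target peak
correlation 0.6 at a 50-step delay (12.5 fs), then the estimator recovers
both numbers; an independent pair shows what 'no correlation' looks like
under the |r| > 0.45 retention rule.
"""

import numpy as np

from pocketdyn import (CouplingSpec, OUParams, correlation_matrix,
                       cross_correlation, find_extrema, simulate_coupled_pair,
                       simulate_ou)

base = OUParams(mean=0.0, theta=1 / 25.0, sigma=1.0, dt=0.25, n_steps=10_000,
                seed=11)
x, y, truth = simulate_coupled_pair(
    base, CouplingSpec(rho=0.6, lag_steps=50, noise_seed=13),
    x_name="O(Tyr66)-O(Wat)", y_name="cavity_volume")

cc = cross_correlation(x, y, max_lag=1250.0)
lead = find_extrema(cc, min_separation=50.0)[0]
print(f"ground truth : r = {truth.expected_peak_r} at "
      f"{truth.expected_peak_lag_fs} fs")
print(f"recovered    : r = {lead.r_value:.2f} at {lead.lag} fs "
      f"({lead.sign})")
print("The negative delay means the volume lags behind the H-bond "
      "distance by ~12.5 fs.")

# Retention rule on a roster including an uncorrelated control pair.
ctrl = simulate_ou(OUParams(0.0, 1 / 25.0, 1.0, 0.25, 10_000, seed=99),
                   name="O(Ser205)-O(Glu222)")
report = correlation_matrix(
    [x, y, ctrl],
    [("O(Tyr66)-O(Wat)", "cavity_volume"),
     ("O(Ser205)-O(Glu222)", "cavity_volume")],
    max_lag=1250.0)
print("\n" + report.format_table(significant_only=False))
print("\nOnly correlation functions whose extrema exceed |r| = 0.45 are "
      "retained as significant.")
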