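#!/usr/bin/env python
"""Uncertainty analyses: one-way DSA tornado, PSA/CEAC, DCEA-PSA quadrants.

Desk-scale replication settings (2 imputation replicates × 25 bootstrap
replications, n = 2,000) keep the run in minutes; the machinery is identical
at full scale. Writes results/tornado.csv, results/ceac.csv,
results/quadrants.csv and results/psa_replications.csv.
"""
import sys
from pathlib import Path

import numpy as np

from cvdcea import default_population_config, load_parameters
from cvdcea.synthetic_population import generate_imputation_replicates
from cvdcea.uncertainty import ceac, dcea_psa, dsa_tornado, monte_carlo_se, run_psa

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = load_parameters()
cfg = default_population_config()
cfg["n"] = 2000
samples = generate_imputation_replicates(cfg, seed=SEED, m=2)

tornado = dsa_tornado(samples[0], params, seed=SEED)
tornado.to_csv(OUT / "tornado.csv", index=False)
print("one-way DSA (±20%), most influential first:")
print(tornado[["parameter", "inhb_low", "inhb_base", "inhb_high", "range"]]
      .round(4).to_string(index=False))

reps = run_psa(samples, params, n_boot=25, seed=SEED)
reps.to_csv(OUT / "psa_replications.csv", index=False)
lambda_grid = np.array([0, 25_000, 50_000, 100_000, 150_000, 250_000, 500_000, 1_000_000],
                       dtype=float)
curve = ceac(reps, lambda_grid)
curve.to_csv(OUT / "ceac.csv", index=False)
print("\ncost-effectiveness acceptability curve:")
print(curve.to_string(index=False))

tot = reps[reps["group"] == "Total"]
inhb = tot["delta_qalys"] - tot["delta_cost"] / params.wtp
print(f"\nP(cost-effective at $150k) = "
      f"{float((inhb > 0).mean()):.2f} "
      f"(mean INHB {inhb.mean():+.4f}, MC SE {monte_carlo_se(inhb):.4f}, "
      f"{len(tot)} replications)")

quad = dcea_psa(reps, params.wtp, params.epsilon)
quad.to_csv(OUT / "quadrants.csv", index=False)
print("\nDCEA-PSA quadrant probabilities (lambda=$150k, epsilon=0.5):")
print(quad.pivot(index="partition", columns="quadrant", values="probability")
      .round(2).to_string())
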