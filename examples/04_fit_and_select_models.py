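"""Fit random-intercept logistic models and select by AICc.

Simulates a cluster-feature table from a known truth, runs all-subsets AICc
selection, and evaluates the preferred model's classification performance —
the workflow used to build the predation and carcass-size models.
"""

import numpy as np

from killscan import (
    all_subsets_rank,
    classification_report,
    predict_population,
    simulate_cluster_table,
)

terms_true = ["log10_n_gps_obs", "sex", "stod"]
beta_true = [-1.0, 2.0, 0.8, -1.5, -1.0]  # intercept, ngps, male, night, twilight
df, truth = simulate_cluster_table(800, 15, terms_true, beta_true, sigma2=0.5, seed=42)
print(f"simulated {len(df)} clusters from 15 animals; "
      f"outcome prevalence {df['y'].mean():.2f}")

candidates = ["log10_n_gps_obs", "log10_duration", "spread", "sex", "stod"]
ranked = all_subsets_rank(df, candidates, "y")
print(f"\nfitted {len(ranked)} candidate models; top three by AICc:")
for m in ranked[:3]:
    mark = "  <- preferred (highest sensitivity at 0.5)" if m.preferred else ""
    print(f"  AICc {m.aicc:7.2f}  dAICc {m.delta_aicc:5.2f}  w {m.weight:.3f}  "
          f"sens {m.sensitivity_at_half:.2f}  {' + '.join(m.terms)}{mark}")

best = next(m for m in ranked if m.preferred)
rep = classification_report(predict_population(best, df), df["y"].to_numpy())
print(f"\npreferred model: sigma2 = {best.sigma2:.2f}, "
      f"coefficients {({k: round(v, 2) for k, v in best.coef.items()})}")
print(f"AUC = {rep.auc:.3f} (SE {rep.auc_se:.3f}); at threshold 0.5: "
      f"sensitivity {rep.sensitivity[0]:.2f}, specificity {rep.specificity[0]:.2f}")
print("\nThe generating terms should dominate the AICc ranking and the "
      "coefficients should sit near the simulated truth.")
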