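"""Univariate statistics of the original field campaigns.

Recomputes, from the packaged outcome count tables and group summaries, the
chi-square and t statistics that established the protocol's value: predation
sites concentrate inside detected clusters, and cluster-guided visits nearly
triple the per-visit detection rate.
"""

from killscan import detection_probability, pearson_chi2, published, welch_t

stat, dof = pearson_chi2(published.WITHIN_OUTSIDE_2006, continuity=True)
print(f"predation within vs outside clusters (2006-07, Yates): "
      f"chi2 = {stat:.3f}, dof = {dof}")

stat, dof = pearson_chi2(published.CAMPAIGN_COMPARISON)
p_rand = detection_probability(27, 464)
p_clus = detection_probability(54, 335)
print(f"cluster-guided vs random visits: chi2 = {stat:.2f}, dof = {dof}; "
      f"detection rate {p_rand:.3f} -> {p_clus:.3f} "
      f"({p_clus / p_rand:.2f}x improvement)")

for name, table in [
    ("season", published.PREDATION_BY_SEASON),
    ("starting time of day", published.PREDATION_BY_STOD),
    ("sex", published.PREDATION_BY_SEX),
]:
    stat, dof = pearson_chi2(table)
    print(f"predation by {name}: chi2 = {stat:.2f} (dof {dof})")

g = published.GROUP_SUMMARIES
t = welch_t(g["no_predation"]["n_gps_obs"][0], g["no_predation"]["n_gps_obs"][1],
            g["predation"]["n_gps_obs"][0], g["predation"]["n_gps_obs"][1])
print(f"\nnGPSObs, no-predation vs predation clusters: Welch t = {t:.2f}")
print("(predation clusters hold ~3.5x more fixes; the strongest univariate signal)")
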