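"""Detect space-time clusters in a simulated grizzly bear trajectory.

Simulates a 28-day hourly collar deployment with planted kill-site and
rest-site bouts, runs the windowed permutation scan, removes duplicate
clusters found in overlapping windows, and compares detections against the
planted ground truth.
"""

import numpy as np

from killscan import ScanConfig, SimConfig, deduplicate, detect_clusters, simulate_trajectory

traj, events = simulate_trajectory(SimConfig(days=28, rng_seed=11), animal_id="bear01")
kills = [e for e in events if e.event_type == "kill_site"]
print(f"simulated {len(traj)} hourly fixes with {len(kills)} planted kill bouts")

config = ScanConfig(max_radius=50.0, max_span=168.0, n_replicates=199, rng_seed=1)
clusters = deduplicate(detect_clusters(traj, config))
print(f"detected {len(clusters)} significant space-time clusters (p <= {config.alpha})")

ranked = sorted(clusters, key=lambda cl: -cl.cylinder.log_glr)
print("top 8 by likelihood ratio:")
for cl in ranked[:8]:
    cy = cl.cylinder
    hit = next((ev for ev in kills if ev.member_fix_ids & cl.member_fix_ids), None)
    tag = "KILL SITE" if hit else ("rest bout" if any(
        ev.member_fix_ids & cl.member_fix_ids for ev in events) else "forage patch")
    print(
        f"  {cl.cluster_id}: {cy.c} fixes, radius {cy.radius:.1f} m, "
        f"GLR {cy.glr:.3g}, p = {cy.p:.3f}  -> {tag}"
    )

recovered = sum(
    any(cl.member_fix_ids & ev.member_fix_ids for cl in clusters) for ev in kills
)
print(f"\nkill-bout recall: {recovered}/{len(kills)}")
print("Each cluster is a cylinder (circle x time interval) whose fix count "
      "exceeds the space-time-permutation expectation; p is its Monte Carlo rank.")
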