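# killscan

Early detection of predation (kill) sites from GPS collar telemetry using a
retrospective **space–time permutation scan statistic** (STPSS).

Large predators linger where they feed: a kill site shows up in hourly GPS
collar data as many fixes packed into a small area over one or more days.
`killscan` finds those signatures statistically, characterizes them, and
predicts which ones are worth a field visit — the workflow behind
cluster-guided carcass surveys of grizzly bears (*Ursus arctos*), where
visiting detected clusters instead of random GPS locations nearly tripled
the per-visit probability of finding a predation event (0.058 → 0.161).

It is a library first (importable API plus `examples/` scripts), with a thin
`killscan` command-line front end for the field-pipeline stages.

## The method

For one animal and one 14-day window of hourly fixes, every space–time
cylinder — a circle through an observed fix (radius ≤ 50 m) extruded over an
interval of observed fix times (span ≤ 7 d) — is scored with the Poisson
generalized likelihood ratio

```
mu  = n_s · n_t / N                      (expectation given both marginals)
GLR = (c/mu)^c · ((N−c)/(N−mu))^(N−c)    for observed count c > mu, else 1
```

Significance comes from Monte Carlo permutation of times over locations:
p = (1 + #{replicate max GLR ≥ GLR}) / (R + 1).  Because the null conditions
on both the spatial and temporal marginals, only genuine space–time
interaction — residency — can score.  Windows overlap by 7 days so no bout
is bisected; duplicate clusters re-found in the overlap share member fixes
and are collapsed.  Detected clusters are then described by seven
spatiotemporal variables (spread, nGPSObs, duration, occupation, return
events, starting time of day, season) that feed random-intercept logistic
models (per-animal random effect, adaptive Gauss–Hermite likelihood, AICc
all-subsets selection) predicting predation presence and carcass size.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```
python examples/01_detect_kill_site_clusters.py
```

```
simulated 673 hourly fixes with 4 planted kill bouts
detected 44 significant space-time clusters (p <= 0.05)
top 8 by likelihood ratio:
  bear01-w0-c0: 50 fixes, radius 40.0 m, GLR 7.12e+19, p = 0.005  -> KILL SITE
  bear01-w2-c0: 25 fixes, radius 27.9 m, GLR 9.35e+16, p = 0.005  -> KILL SITE
  bear01-w1-c1: 15 fixes, radius 31.8 m, GLR 1.08e+13, p = 0.005  -> KILL SITE
  bear01-w0-c1: 13 fixes, radius 45.2 m, GLR 4.3e+12, p = 0.005  -> forage patch
  ...
kill-bout recall: 4/4
```

Each line is one cylinder: its member fix count, spatial radius, likelihood
ratio against the permutation expectation, and Monte Carlo p-value.  Kill
bouts (long, fix-dense residencies) dominate the ranking, while rest bouts
and foraging patches form many weaker clusters — matching the field reality
that only a minority of visited clusters hold a carcass, and exactly why the
downstream classifier uses cluster size, duration and timing to separate
predation from bedding and grazing.

The univariate field statistics reproduce from the packaged campaign tables:

```
python examples/03_field_tables_and_tests.py
```

```
predation within vs outside clusters (2006-07, Yates): chi2 = 22.064, dof = 1
cluster-guided vs random visits: chi2 = 22.66, dof = 1; detection rate 0.058 -> 0.161 (2.77x improvement)
predation by season: chi2 = 11.18 (dof 2)
predation by starting time of day: chi2 = 37.35 (dof 2)
predation by sex: chi2 = 2.01 (dof 1)

nGPSObs, no-predation vs predation clusters: Welch t = -5.85
```

Other examples: `02_characterize_and_score.py` (seven-variable cluster
features + published-model predation probabilities) and
`04_fit_and_select_models.py` (GLMM fitting, AICc all-subsets selection,
ROC/AUC).

## Command line

```
killscan simulate --seed 3 --days 28 --out fixes.csv --truth truth.csv
killscan detect   --fixes fixes.csv --seed 1 --out clusters.csv
killscan characterize --clusters clusters.csv --fixes fixes.csv --out features.csv
killscan score    --features features.csv --model predation
killscan fit      --features features.csv --outcome y --select
killscan label / xtab / evaluate ...
```

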