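# Methods

`killscan` implements an early-detection protocol for predation (kill) sites
of GPS-collared predators, built around a retrospective space–time
permutation scan statistic (STPSS) applied to hourly collar fixes, followed
by spatiotemporal characterization of detected clusters and random-intercept
logistic models that predict whether a cluster holds a predation event and
how large the carcass is.

## The scan statistic

Each animal-window of fixes is scanned with cylinders: a circle in projected
planar space (radius capped at `max_radius`, default 50 m, the scale at
which a bear handles a carcass) extruded over a closed time interval (span
capped at `max_span`, default 168 h, from maximum kill handling time).
Candidate geometry is a finite sufficient set — circles pass through
observed fix locations, radii are enumerated only at center-to-fix
distances, interval endpoints only at member fix times; any other cylinder
has membership identical to an enumerated one.  Cylinders with identical
member sets are collapsed to the tightest representative: smallest expected
count, then smallest radius, then smallest center index.  This keeps, for
every distinct member set, the representation with the largest attainable
likelihood ratio.

Conditioning on the spatial and temporal marginals, the expected count in a
cylinder with n_s spatially-inside fixes and n_t temporally-inside fixes is

    mu = n_s * n_t / N,

and the score is the Poisson generalized likelihood ratio

    GLR = (c/mu)^c * ((N-c)/(N-mu))^(N-c)   if c > mu, else 1,

computed in log space (the second factor is 1 when c = N).  Only space–time
*interaction* scores: a spatial hotspot the animal uses uniformly through
the window, or a globally busy period, raises the marginals and so raises
mu in step with c.

Inference is Monte Carlo: times are uniformly re-permuted over locations
(`n_replicates`, default 999), the replicate statistic is the maximum GLR
over all candidates, and each reported cluster gets the rank p-value
p = (1 + #{replicate maxima >= GLR}) / (R + 1), ties counted against
significance.  Reported clusters are the maximum-GLR cylinder followed by
secondary cylinders in GLR order that share no member fix with a
higher-ranked cluster; only cylinders with c > mu are reported (a cylinder
at or below expectation carries no evidence), and `min_observed` (default
2) suppresses singleton "clusters" that could never justify a field visit.
Equal GLRs break deterministically: smaller radius, earlier start, smaller
center index.

Because the permutation null is exchangeable by construction, the Monte
Carlo p-value is exact up to discreteness of the statistic.  With hourly
fixes the statistic is discrete; on sparse windows with little co-location
the null maximum can take few values and the test becomes conservative.
On movement with realistic foraging-scale co-location the attained
significance tracks the nominal level closely (the type-I suite measures
this directly).

## Detection protocol

Trajectories are regularized to at most one fix per clock hour (each fix
assigned to its nearest hour mark; nearest wins, earlier on ties) and split
into 14-day windows overlapping by 7 days, so a residency bout bisected by
one window boundary is intact in the neighbor.  Windows are
[t0 + 7k, t0 + 7k + 14) days for k = 0..max(0, floor(span/7d) − 1): every
instant of the study period is covered, interior instants exactly twice.
Each window scan draws its RNG stream from the master seed and the window
index, so a run is reproducible and windows are independent.

Clusters surviving the significance filter are pooled per animal and
de-duplicated: clusters from different windows are duplicates iff their
member-fix sets intersect (connected components under intersection); each
component keeps its largest-GLR member (tie: earlier window).  Field-visit
selection takes the largest two clusters per animal per ISO week — size
meaning member-fix count, then duration, then GLR — plus a seeded random
fraction of the remainder.  The retrospective labeler marks a location
"within" a cluster iff it falls inside the cluster's time span and within
the 50 m radius of the cylinder center, mirroring the constraint the scan
itself used.

## Cluster features

Seven variables summarize a cluster: spread (standard distance — RMS
distance of member fixes about their mean center, meters); nGPSObs (member
fix count); duration (hours from first to last member fix, floored at 1 h);
occupation (nGPSObs / duration — deliberately not clamped, so a fully
contiguous 20-fix cluster scores 20/19); return events (maximal runs of
missing hourly slots strictly inside the span — the only observable
definition of "left and returned" at hourly resolution, which counts a
missed fix as absence); starting time of day (day / twilight / night of the
first member fix, by default from solar elevation with civil twilight at
−6°, configurable to fixed clock bins); and season (spring May 1–Jun 15,
summer Jun 16–Aug 15, fall Aug 16–Oct 15, in a configured local UTC
offset).  The search start point for field crews is the member fix nearest
the mean center (earliest on ties) — a location the animal demonstrably
occupied, unlike the centroid of a sprawling cluster.

## Predictive models

Predation presence and carcass size (small/medium vs large; positive class
small/medium) are modeled as logistic GLMMs with a per-animal random
intercept, b_g ~ N(0, sigma^2), fitted by maximizing the marginal
likelihood with adaptive Gauss–Hermite quadrature (15 nodes centered and
scaled at each group's conditional mode; one node recovers the Laplace
approximation; sigma = 0 degenerates to plain logistic regression, which is
also the single-animal behavior).  Fits were validated against
`lme4::glmer(nAGQ = 15)`: coefficients, standard errors and log-likelihood
agree to ~1e-5 on simulated tables.  Complete separation is detected
(coefficient divergence) and raised as an error naming the offending term.

Count and duration predictors enter as log10 — the base is a package
decision: with the packaged published coefficients only base-10 logs
produce sensible probabilities at the published group means (natural log
saturates the inverse logit everywhere), and the published carcass model's
spread coefficient (−3.48) likewise only behaves on the log10 scale, so
spread enters that model as log10(spread).  K counts the fixed coefficients
(including intercept) plus one for the random-intercept variance;
AICc = −2LL + 2K + 2K(K+1)/(n−K−1).  All-subsets selection fits every
admissible term subset (interactions only with both main effects), ranks by
AICc with Akaike weights over the full candidate set, and flags, among the
top three, the model with the highest sensitivity at the 0.5 threshold —
in the field a missed predation site costs more than a wasted visit.

ROC analysis uses the Mann–Whitney construction (ties 1/2), the
Hanley–McNeil variance approximation for the AUC's SE and normal-theory 95%
CI, and the two-sided Mann–Whitney test against AUC = 0.5.

The packaged reference coefficients (from the protocol's original
west-central Alberta deployment) allow population-level scoring (random
intercept 0) of new clusters without refitting.  Two rows of the source
coefficient table are internally inconsistent (printed odds ratio ≠
exp(printed estimate) for the intercept and the duration term, the latter
also duplicating a z statistic); the printed coefficient estimates are
packaged and the odds-ratio consistency checks cover the four coherent
rows.

## Synthetic data

No collar data are deposited with the original study, so the generator
emulates its sampling design.  Hourly fixes over a configurable deployment
(default 28 days, 673 fixes, endpoints inclusive); between bouts a
two-state correlated random walk — fast directed travel (gamma steps, mean
300 m/h, shape 2; turning angles wrapped-normal sd 0.8) alternating with
slow tortuous foraging (mean 45 m/h, shape 1.5, turn sd 1.6; per-hour
switching hazards 0.20/0.15).  The foraging state matters beyond realism:
it supplies the fix co-location that makes the scan's null distribution
rich; on pure fast travel the statistic is so discrete that Monte Carlo
p-values become visibly conservative.

Residency bouts are planted non-overlapping at random times.  Kill-site
bouts: lognormal duration targeting a 41 h mean, uniform-in-disc positions
with 28 m radius (standard distance ≈ r/√2 ≈ 20 m), per-present-hour
excursion hazard 0.11 with mean 6 h absences — yielding roughly 25 member
fixes, occupation ≈ 0.6–0.7 and one to two return events per bout, the
magnitudes reported for verified predation clusters.  Rest bouts are
shorter and looser (19 h mean, 23 m radius, higher excursion hazard) to
play the part of the no-predation clusters.  Defaults are generator
targets, not acceptance values.  Uniform-in-disc is the simplest process
matching the observed spread; an Ornstein–Uhlenbeck tether would be the
natural refinement.  The generator does not emulate habitat-driven
movement, GPS fix failure or location error, so passing detection tests
demonstrate statistical behavior under the stated movement model, not
robustness to real-world data loss.

The cluster-table generator draws features from distributions matched to
the published cluster tables (log10 nGPSObs ~ N(0.95, 0.30); time-of-day
and season multinomials at the published margins), assigns clusters to
animals round-robin — a balanced collaring campaign; grossly unequal group
sizes degrade Wald calibration at 20 animals — and draws outcomes from a
user-specified coefficient vector and random-intercept variance, returning
the generating truth for recovery tests.

## Problem sizes and numerical choices

The validation suites use: 20 random 30-fix windows for exact brute-force
oracle agreement; 500 permutation-null windows of 336 hourly fixes at 99
replicates for type-I calibration (exact binomial 95% band around 0.05);
100 refit replicates (n = 2000 clusters, 20 animals, sigma^2 = 0.5) for
Wald-interval coverage; and 100 planted kill bouts across 25 simulated
deployments for end-to-end recall (target ≥ 0.9).  Detection examples and
the acceptance script use 99–199 Monte Carlo replicates; the 999-replicate
default changes only p-value resolution, not which bouts are found, since
planted kill bouts typically achieve the minimum attainable p.

Numerical details worth knowing: GLR comparisons run on log-GLR; Monte
Carlo rank comparisons use a 1e-12 tie tolerance counting ties against
significance; the quadrature modes are found by per-group Newton iterations
(concave 1D problems, tolerance 1e-9); Wald SEs come from a
central-difference Hessian of the negative marginal log-likelihood; hour
assignment in regularization uses round-half-to-even at exact half-hour
ties, with the earlier fix winning within a mark.  Timestamps are stored in
UTC and labeled in a fixed configured local offset — no daylight-saving
logic, by design.  Coordinates are planar meters throughout; geographic
input is projected on read through a local spherical azimuthal-equidistant
projection (centimeter-level distortion at study-area scales), and the
solar time-of-day scheme uses a standard low-precision solar ephemeris
(~0.1° elevation accuracy against the −6° twilight threshold).

## Limitations

The scan is single-animal (no joint or multi-animal clusters), circular
(no elliptic cylinders), retrospective (no prospective surveillance mode)
and unadjusted (no covariates in the expectation).  The published-model
scoring cannot be re-derived here — the raw field data are not public — so
its checks are consistency checks (printed odds ratios, probabilities at
printed group means), not refits.  Monte Carlo p-values are conservative
under heavy ties; at hourly resolution this matters for very sparse
windows.  Duration's 1 h floor makes occupation of single-hour clusters
exactly the fix count.
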