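# Methods

This note documents the models, parameter choices and numerical decisions
behind `mpcmap`, and what the synthetic-data validation does and does not
establish about real data.

## The cortical-sheet stand-in

All analyses operate on a regular grid of "surface nodes" per hemisphere
(default 40 × 30), axis 0 posterior→anterior, axis 1 ventral→dorsal, with
4-neighbourhood adjacency.  A grid preserves the properties the analyses
actually use — node adjacency for clustering, two anatomical axes for peak
and band geometry, disjoint hemispheres — while avoiding surface meshes and
anatomical registration, which are upstream preprocessing concerns outside
this package's scope.  Two rectangular blocks play the roles of VTC (nodes
2–25 × 2–9, split 3 × 2 into the six seed parcels) and MPC (nodes
8–37 × 14–27, 420 nodes per hemisphere).  Left and right hemispheres carry
identical planted structure in grid coordinates, i.e. mirror-symmetric maps
once embedded anatomically.

## Synthetic BOLD model

All signals sit on a baseline of 100 arbitrary units, so amplitudes in
fraction-of-mean units read directly as percent signal change.  Every run
is a deterministic function of (master seed, paradigm, participant, run)
via `numpy.random.SeedSequence` substreams.

**Noise.**  AR(1) with coefficient φ = 0.3 and innovation SD σ = 1.0
(≈1% of baseline), matching the temporal autocorrelation the prewhitened
GLM is designed to remove; |φ| ≥ 1 is rejected.  Slow drift is a random
Legendre combination of orders 1–4 (coefficient SD 0.3 units).  Six smooth
motion-like nuisance series (smoothed random walks, SD 0.2) leak into each
node with small random weights (SD 0.05); the same series are supplied to
the GLM as nuisance regressors, mirroring the use of estimated motion
parameters as regressors of no interest.

**Paradigms.**  The memory task has 6 runs × 24 trials (six 10-s recall
trials per condition of the 2×2 Famous/Personal × People/Places design,
randomized order), with inter-trial intervals drawn uniformly from
{2.5, 5.0, 7.5} s — the stated 2.5–7.5 s range discretized to TR multiples
so that all event timing is TR-locked (TR 2.5 s) and designs remain exactly
confound-checkable.  The distributional form within the range is an
implementation choice; only the range is specified by the design.  The
localizer has 6 runs × twelve 16-s category blocks (six categories, each
exactly twice per run; block order is a seeded base permutation rotated per
run, giving counterbalancing across runs), separated by 8-s fixation gaps,
TR 2.0 s.  Rest is a single 21-min run (630 volumes, TR 2.0 s) whose first
30 volumes are discarded, leaving 600 for analysis.

**Planted structure.**  The MPC block is divided into four diagonal bands
along the ventral/posterior→dorsal/anterior axis, with category preference
alternating places/people/places/people.  Memory amplitudes are
`A = g · (±amp + δ·[personal])` with amp = 0.01 (1% signal change),
familiarity boost δ = 0.01, a Gaussian within-band taper *g* (SD 4 nodes
about the band centroid, so each band has a unique amplitude peak and the
people peak of band 2 lies strictly anterior and dorsal of the places peak
of band 1), and bands 3–4 scaled by 0.8 so the per-subject global peaks
fall in the posterior pair.  Localizer amplitudes are negative for every
category and graded so that scenes are least negative in places-preferring
bands and faces least negative in people-preferring bands.  For rest, the
six seed parcels carry independent unit-variance smooth latent signals;
each MPC node mixes them with weight 1.0 for its band's planted winner
(anterior medial / anterior lateral for bands 1–2, middle medial / middle
lateral for bands 3–4) and 0.1 for the rest.

**What the generator does not emulate:** spatial autocorrelation of noise
across nodes, between-subject anatomical and amplitude variability, HRF
shape variability, physiological noise spectra, susceptibility artifacts,
or any acquisition physics.  Passing recovery tests therefore demonstrates
that the analysis chain is correct and well calibrated under its own
modelling assumptions — not that those assumptions hold in human data.

## GLM

The HRF is the gamma variate h(t) ∝ t^8.6 e^(−t/0.547), normalized to unit
peak at t* = ab ≈ 4.70 s — the conventional default gamma for block
designs; no empirical HRF parameters were available to match, so the
package documents this as its choice.  Boxcars are sampled at TR
resolution without microtime upsampling, which is exact here because the
generator TR-locks all event timing.  Drift uses Legendre polynomials
(orders 0–4; order 0 is the intercept) for numerical stability over raw
monomials.  Baseline is 0 in run-mean-scaled units and condition *t* maps
test β against 0 with ν = volumes − rank(X).

Generalized least squares with fully estimated autocorrelation is
approximated by single-pass Cochrane–Orcutt prewhitening: OLS residuals are
pooled across nodes for a single lag-1 autocorrelation estimate ρ̂, data and
design are transformed (first row scaled by √(1−ρ̂²)), and OLS is re-run.
One pass with a pooled ρ̂ is cheap, deterministic, and demonstrably improves
null calibration over OLS on AR(1) data (tested); per-node REML estimation
is a documented non-goal.  Per-participant results combine runs as fixed
effects: β̄ over runs, SE = √(Σ SE_r²)/R.

## Winner-take-all parcellation

Seed series are parcel means scaled by their own temporal mean (a
variance-normalizing z-score alternative is exposed as an option).  The
node-wise multiple regression includes an intercept; drift columns are off
by default but exposed (`drift_order`), since whether the original analysis
included nuisance terms is not documented.  The selectivity index
subtracts the *mean* of the five non-winning coefficients (the sum variant
is not scale-comparable across nodes and is not implemented).  Ties break
to the lowest parcel label for determinism.  ROI derivation keeps, per
wanted seed label, the largest 4-connected cluster of winning nodes of at
least `min_cluster` (default 10) nodes; anterior-medial → MPCv,
anterior-lateral → MPCd.

## ROI statistics

Trial curves sample the ROI-mean series at 6 TRs from onset and subtract
the onset sample, so every curve begins at zero; using the onset TR itself
(rather than a pre-onset average) as the baseline is the simplest reading
of "begin at baseline" and is applied uniformly.  ROI magnitude is the
mean of node-wise *t* values over the ROI (matching per-participant
magnitude points); the *t* of the ROI-mean series is not implemented.

The RM-ANOVA implements the standard fully-within-subject partition for
1–3 crossed factors via a Yates-style recursion on marginal means: the
effect term for factor subset S is its cell-mean array minus all
lower-order terms, SS is the replication-weighted sum of squared terms, and
each effect is tested against its own effect × subject interaction with
df₁ = Π(levels−1), df₂ = df₁(n−1).  Partial η² = SS_eff/(SS_eff+SS_err),
which satisfies the identity η²p = F·df₁/(F·df₁+df₂).  No sphericity
correction is applied: 2-level factors need none, and for the 6-level
factor uncorrected dfs are reported by design.  When a three-way
interaction is significant at p < .05, two-way follow-up ANOVAs within each
level of a designated factor are emitted.  Bonferroni pairwise tests
correct over all C(levels, 2) pairs within a hemisphere (15 for six
categories) and flag survival at corrected p < .01.

## Group maps

The node-wise group model for the balanced 2×2 design is computed via the
repeated-measures partition rather than an iterative mixed-model fit: with
2-level factors, each effect F is exactly the squared paired *t* of the
corresponding within-subject contrast on (1, n−1) df.  For balanced data
with a random participant intercept this partition is the natural exact
test with per-effect error terms, and it vectorizes across all nodes;
an iterative likelihood fit would add cost and convergence concerns
without changing the balanced-design answer for these hypotheses.  Nodes
with zero contrast variance across participants (e.g. duplicated
participants) are flagged as degenerate and return NaN.

FDR is Benjamini–Hochberg over in-mask nodes; the cluster report includes
the largest q among suprathreshold nodes (the "q at threshold").  The
default node-wise threshold is p = 1e-4.  Clusters are 4-connected
components computed **within each preference sign separately** — hot
(places) and cold (people) regions are distinct objects, and sign-splitting
prevents adjacent opposite-preference bands from merging into one
component — with a minimum size of 5 nodes to suppress speckle at grid
scale, ordered by centroid position along the posterior/ventral →
anterior/dorsal diagonal.

Split-half analysis averages per-run betas within Odd (runs 1, 3, 5) and
Even (runs 2, 4, 6) splits per participant, re-fits the node-wise model per
split, and correlates the category F maps (Pearson r over in-mask nodes,
r² reported rounded to two decimals).  Cross-defined sampling measures each
split-defined ROI in the opposite split's data in both directions and
averages, removing node-selection bias from the ROI response estimates.

## Problem sizes and determinism

Default validation runs use the study sample sizes (29 localizer, 24
memory participants; 6 runs each) on the 40 × 30 grid per hemisphere.  The
resting-state winner-take-all analysis is a per-participant computation, so
recovery is assessed on 3 independently simulated participants rather than
the full rest cohort of 65 — each is a replicate of the same single-subject
analysis.  Calibration checks use ≥1000 white-noise nodes (GLM type-I
error) and the full 1200-node hemisphere under a planted null (group-level
type-I error).  All randomness flows from a single master seed; identical
configurations produce byte-identical datasets.

## Known limitations

* Single-pass pooled-ρ prewhitening under-corrects when the true
  autocorrelation varies strongly across nodes.
* The run-mean scaling makes noise-free amplitude recovery exact only to
  first order in the amplitude (second-order terms ≈ A² ≈ 1e-4 here).
* The RM-ANOVA requires perfectly balanced complete data; missing cells are
  an error, not an estimation problem.
* Cluster ordering along a single diagonal assumes the band axis of the
  default geometry; other topographies may need a different ordering axis.
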