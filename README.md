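# mpcmap

Medial parietal cortex (MPC) sits at the heart of the default-mode network
and is engaged both by viewing visual categories and by recalling them from
memory.  `mpcmap` implements, as a tested and reusable pipeline, an analysis
chain for (1) parcellating MPC by its resting-state functional connectivity
with ventral temporal cortex (VTC) and (2) quantifying category- and
familiarity-selective memory-recall responses across an MPC sheet — exercised
end to end on synthetic BOLD data whose generative structure matches the
experimental designs (a long resting-state run, a six-category block
localizer, and a 2×2 People/Places × Famous/Personal recall task).

The pipeline's core pieces, in the field's standard notation:

* **GLM.**  Each node's run-mean-scaled series *y* is modelled as
  *y = Xβ + ε*, with one task regressor per condition (condition boxcar
  convolved with a unit-peak gamma HRF *h(t) ∝ t^a e^(−t/b)*, defaults
  *a* = 8.6, *b* = 0.547 s, peak at *ab* ≈ 4.7 s), Legendre drift polynomials
  of orders 0–4 and motion nuisance columns.  Fitting is OLS or single-pass
  Cochrane–Orcutt AR(1) prewhitening; "response magnitude" is the
  *t*-statistic of β against baseline (0 in scaled units).
* **Winner-take-all parcellation.**  Six VTC seed parcels
  ({posterior, middle, anterior} × {medial, lateral}) give mean-scaled
  parcel series; each MPC node is regressed on all six simultaneously, the
  winner is argmax β, and the selectivity index is
  β_winner − mean(β_others).  The largest clusters winning for the anterior
  medial / anterior lateral seeds define MPCv and MPCd.
* **ROI statistics.**  Trial-averaged response curves (6 TRs from onset,
  zeroed at onset), per-condition ROI magnitudes, fully-within-subject
  repeated-measures ANOVAs for 1–3 factors with partial
  η² = SS_effect/(SS_effect+SS_error), and Bonferroni-corrected pairwise
  *t*-tests.
* **Group maps.**  Node-wise 2×2 Category × Familiarity tests across
  participants (each effect *F* on (1, n−1) df), Benjamini–Hochberg FDR
  *q*-values, sign-split 4-connected suprathreshold clusters ordered along
  the ventral/posterior → dorsal/anterior diagonal, and an odd/even
  split-half procedure that re-fits the group maps per split, correlates the
  node-wise category *F* maps, and samples each split-defined ROI from the
  opposite split.

The cortical surface is stood in for by a 40 × 30 node grid per hemisphere
with 4-neighbourhood adjacency; the synthetic generator plants a known
winner map, a four-band alternating places/people topography, a familiarity
amplitude boost, AR(1) noise, polynomial drift and motion nuisance, so every
analysis can be validated against ground truth.

## Worked example

```python
import numpy as np
from mpcmap import (SimulationConfig, nodewise_effects, clusterize,
                    split_half, pipeline)

cfg = SimulationConfig(seed=1)                 # n=24 participants, 6 runs
cohort = pipeline.simulate_memory_cohort(cfg, "L")
gt = cohort["gt"]

em = nodewise_effects(cohort["subject_betas"], gt.grid, gt.mpc_mask)
clusters = clusterize(em)
print("clusters:", len(clusters), "| alternation:", clusters.alternation)
print(clusters.table()[["name", "preference", "size"]].to_string(index=False))

_, _, r, r2 = split_half(cohort["run_betas"], gt.grid, gt.mpc_mask)
print(f"split-half category-map reliability: r = {r:.2f} (r^2 = {r2})")

rest = pipeline.run_rest_wta(cfg)
print(f"WTA label accuracy: {rest['accuracy']:.3f}, "
      f"MPCv dice: {rest['dice_mpcv']:.2f}, MPCd dice: {rest['dice_mpcd']:.2f}")
```

prints

```
clusters: 4 | alternation: places,people,places,people
name preference  size
ROI1     places    59
ROI2     people   114
ROI3     places   111
ROI4     people    59
split-half category-map reliability: r = 0.86 (r^2 = 0.74)
WTA label accuracy: 1.000, MPCv dice: 1.00, MPCd dice: 1.00
```

i.e. the group category map recovers exactly the four planted alternating
subdivisions along the MPC diagonal, the split-half maps are highly
reliable, and the connectivity parcellation recovers the planted winner map
and the MPCv/MPCd subdivisions perfectly at the default noise level.

A command-line interface mirrors the library
(`mpcmap simulate|glm|wta|recall|groupmap|splithalf --help`).

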