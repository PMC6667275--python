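"""End-to-end cohort pipelines tying the generator to the analyses.

These helpers run the per-participant chain (simulate run -> run-mean
scaling -> design -> prewhitened GLM) for whole simulated cohorts and
return the arrays the group analyses consume.
"""

from __future__ import annotations

import numpy as np

from . import glm as _glm
from .grid import CortexGrid
from .synthdata import (GroundTruth, SimulationConfig, make_ground_truth,
                        make_paradigm, simulate_rest, simulate_task_run,
                        MEMORY_CONDITIONS, LOCALIZER_CATEGORIES)
from .wta import (derive_rois, dice, extract_seed_timeseries, label_accuracy,
                  wta_regress)


def fit_task_run(config: SimulationConfig, gt: GroundTruth, participant: int,
                 run: int, kind: str, ar_order: int = 1) -> _glm.GLMResult:
    """Simulate one task run and fit its GLM (drift + motion nuisance)."""
    events = make_paradigm(kind, run, config, participant)
    ds = simulate_task_run(config, events, kind, participant, gt=gt)
    scaled = _glm.scale_by_run_mean(ds.data)
    conditions = MEMORY_CONDITIONS if kind == "memory" else LOCALIZER_CATEGORIES
    design = _glm.build_design(events.table, events.n_volumes, events.tr,
                               hrf=_glm.gamma_hrf(_glm.HRFSpec(), events.tr),
                               drift_order=config.drift_order,
                               nuisance=ds.motion, conditions=conditions)
    return _glm.fit_glm(scaled, design, ar_order=ar_order)


def simulate_memory_cohort(config: SimulationConfig, hemi: str = "L",
                           ar_order: int = 1) -> dict:
    """Full memory cohort for one hemisphere.

    Returns a dict with:

    * ``gt`` — the planted ground truth;
    * ``run_betas`` — (n_sub, n_runs, 2, 2, n_nodes) per-run condition betas
      (familiarity axis famous/personal, category axis people/places);
    * ``subject_betas`` — run-averaged (n_sub, 2, 2, n_nodes);
    * ``tmaps`` — {(participant, hemi): {condition: flat t map}} from the
      fixed-effects combination across runs.
    """
    gt = make_ground_truth(config, hemi)
    n_sub, n_runs = config.n_participants_memory, config.n_runs_memory
    N = gt.grid.n_nodes
    run_betas = np.empty((n_sub, n_runs, 2, 2, N))
    tmaps: dict = {}
    for p in range(n_sub):
        results = []
        for r in range(n_runs):
            res = fit_task_run(config, gt, p, r, "memory", ar_order)
            results.append(res)
            run_betas[p, r] = res.condition_betas().reshape(2, 2, N)
        comb = _glm.combine_runs(results)
        tmaps[(p, hemi)] = {c: comb.t_map(c) for c in MEMORY_CONDITIONS}
    return {"gt": gt, "run_betas": run_betas,
            "subject_betas": run_betas.mean(axis=1), "tmaps": tmaps}


def simulate_localizer_cohort(config: SimulationConfig, hemi: str = "L",
                              ar_order: int = 1) -> dict:
    """Full localizer cohort: per-participant category t maps."""
    gt = make_ground_truth(config, hemi)
    tmaps: dict = {}
    for p in range(config.n_participants_localizer):
        results = [fit_task_run(config, gt, p, r, "localizer", ar_order)
                   for r in range(config.n_runs_localizer)]
        comb = _glm.combine_runs(results)
        tmaps[(p, hemi)] = {c: comb.t_map(c) for c in LOCALIZER_CATEGORIES}
    return {"gt": gt, "tmaps": tmaps}


def run_rest_wta(config: SimulationConfig, participant: int = 0,
                 hemi: str = "L", min_cluster: int = 10,
                 scaling: str = "mean") -> dict:
    """One participant's rest run through the winner-take-all chain."""
    ds, gt = simulate_rest(config, participant, hemi)
    scaled = _glm.scale_by_run_mean(ds.data)
    seeds = extract_seed_timeseries(scaled, gt.seeds, scaling=scaling)
    wmap = wta_regress(scaled, seeds, gt.mpc_mask, gt.grid)
    rois = derive_rois(wmap, gt.mpc_mask, min_cluster=min_cluster)
    return {
        "gt": gt, "wtamap": wmap, "rois": rois,
        "accuracy": label_accuracy(wmap, gt.winner),
        "dice_mpcv": dice(rois["MPCv"], gt.band_mask(0)),
        "dice_mpcd": dice(rois["MPCd"], gt.band_mask(1)),
    }
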