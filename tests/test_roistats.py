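"""ROI statistics tests: trial curves, magnitudes, RM-ANOVA, peaks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from mpcmap import (HRFSpec, MEMORY_CONDITIONS, SimulationConfig,
                    gamma_hrf, make_ground_truth, make_paradigm,
                    pairwise_bonferroni, peak_shift, rm_anova,
                    roi_condition_magnitudes, simulate_task_run,
                    trial_average)
from mpcmap.glm import scale_by_run_mean


# ---------------------------------------------------------------------------
# independent brute-force RM-ANOVA oracle (totals-based computational
# formulas, explicit python loops — no shared code with the implementation)

def brute_force_rm_anova(table, factors, dv="value", subject="participant"):
    subs = sorted(table[subject].unique())
    levels = {f: sorted(table[f].unique()) for f in factors}
    n_total = len(table)
    grand = table[dv].sum()
    ct = grand ** 2 / n_total

    def margin_ss(cols):
        ss = 0.0
        groups = table.groupby(cols, observed=True)[dv] if cols else None
        for _, g in groups:
            ss += g.sum() ** 2 / len(g)
        return ss - ct

    raw = {}
    all_units = [subject] + factors
    for r in range(1, len(all_units) + 1):
        for combo in itertools.combinations(all_units, r):
            raw[frozenset(combo)] = margin_ss(list(combo))
    effect_ss = {}
    for key, val in raw.items():
        ss = val
        for sub_key in raw:
            if sub_key < key:
                ss -= effect_ss[sub_key]
        effect_ss[key] = ss
    out = {}
    for r in range(1, len(factors) + 1):
        for combo in itertools.combinations(factors, r):
            S = frozenset(combo)
            df1 = int(np.prod([len(levels[f]) - 1 for f in combo]))
            df2 = df1 * (len(subs) - 1)
            ss_eff = effect_ss[S]
            ss_err = effect_ss[S | {subject}]
            F = (ss_eff / df1) / (ss_err / df2)
            out[" x ".join(combo)] = dict(SS_effect=ss_eff, SS_error=ss_err,
                                          df1=df1, df2=df2, F=F)
    return out


def random_table(rng, n_sub, factor_levels):
    rows = []
    for s in range(n_sub):
        for combo in itertools.product(*factor_levels.values()):
            rows.append((s, *combo, rng.standard_normal()))
    return pd.DataFrame(rows, columns=["participant",
                                       *factor_levels.keys(), "value"])


class TestRMAnova:
    def test_one_way_six_levels_dfs(self, rng):
        t = random_table(rng, 29, {"condition": [f"c{i}" for i in range(6)]})
        res = rm_anova(t, ["condition"]).effect("condition")
        assert (res["df1"], res["df2"]) == (5, 140)

    def test_three_way_two_level_dfs(self, rng):
        t = random_table(rng, 24, {"category": ["people", "places"],
                                   "familiarity": ["famous", "personal"],
                                   "hemisphere": ["L", "R"]})
        res = rm_anova(t, ["category", "familiarity", "hemisphere"])
        assert (res.table["df1"] == 1).all()
        assert (res.table["df2"] == 23).all()
        assert len(res.table) == 7          # 3 mains, 3 two-way, 1 three-way

    @pytest.mark.parametrize("factor_levels", [
        {"a": ["x", "y", "z"]},
        {"a": ["x", "y"], "b": ["u", "v", "w"]},
        {"a": ["x", "y"], "b": ["u", "v"], "c": ["p", "q"]},
    ], ids=["1way", "2way", "3way"])
    def test_matches_brute_force_oracle(self, rng, factor_levels):
        t = random_table(rng, 9, factor_levels)
        mine = rm_anova(t, list(factor_levels))
        oracle = brute_force_rm_anova(t, list(factor_levels))
        for eff, vals in oracle.items():
            row = mine.effect(eff)
            for key in ("SS_effect", "SS_error", "F"):
                assert row[key] == pytest.approx(vals[key], abs=1e-8)

    def test_matches_statsmodels_anovarm(self, rng):
        from statsmodels.stats.anova import AnovaRM
        t = random_table(rng, 12, {"category": ["people", "places"],
                                   "familiarity": ["famous", "personal"]})
        mine = rm_anova(t, ["category", "familiarity"])
        sm = AnovaRM(t, depvar="value", subject="participant",
                     within=["category", "familiarity"]).fit().anova_table
        assert mine.effect("category")["F"] == pytest.approx(
            sm.loc["category", "F Value"])
        assert mine.effect("category x familiarity")["F"] == pytest.approx(
            sm.loc["category:familiarity", "F Value"])

    def test_partial_eta_sq_identity_and_range(self, rng):
        t = random_table(rng, 10, {"a": ["x", "y", "z"], "b": ["u", "v"]})
        res = rm_anova(t, ["a", "b"]).table
        for _, row in res.iterrows():
            assert 0 <= row["partial_eta_sq"] <= 1
            ident = (row["F"] * row["df1"]
                     / (row["F"] * row["df1"] + row["df2"]))
            assert row["partial_eta_sq"] == pytest.approx(ident)

    def test_constant_condition_means_give_zero_f(self):
        rows = [(s, c, 1.0 + s) for s in range(6) for c in "xyz"]
        t = pd.DataFrame(rows, columns=["participant", "condition", "value"])
        res = rm_anova(t, ["condition"]).effect("condition")
        assert res["SS_effect"] == pytest.approx(0.0, abs=1e-12)

    def test_unbalanced_design_rejected(self, rng):
        t = random_table(rng, 5, {"a": ["x", "y"]})
        with pytest.raises(ValueError, match="not balanced"):
            rm_anova(t.iloc[:-1], ["a"])

    def test_followups_emitted_on_threeway_interaction(self, rng):
        t = random_table(rng, 12, {"category": ["people", "places"],
                                   "familiarity": ["famous", "personal"],
                                   "hemisphere": ["L", "R"]})
        # plant a strong three-way interaction
        sign = ((t["category"] == "places").astype(int) * 2 - 1) \
            * ((t["familiarity"] == "personal").astype(int) * 2 - 1) \
            * ((t["hemisphere"] == "R").astype(int) * 2 - 1)
        t["value"] = t["value"] * 0.1 + sign * 2.0
        res = rm_anova(t, ["category", "familiarity", "hemisphere"],
                       followup_by="hemisphere")
        assert res.followups is not None
        assert set(res.followups) == {"L", "R"}
        assert "category x familiarity" in list(
            res.followups["L"].table["effect"])


class TestPairwiseBonferroni:
    def test_fifteen_pairs_for_six_levels(self, rng):
        rows = [(s, f"c{i}", rng.standard_normal())
                for s in range(8) for i in range(6)]
        t = pd.DataFrame(rows, columns=["participant", "condition", "value"])
        pw = pairwise_bonferroni(t, "condition")
        assert len(pw) == 15

    def test_identical_samples_flagged_not_surviving(self):
        rows = [(s, c, float(s)) for s in range(6) for c in "ab"]
        t = pd.DataFrame(rows, columns=["participant", "condition", "value"])
        pw = pairwise_bonferroni(t, "condition")
        assert np.isnan(pw.loc[0, "t"])
        assert not pw.loc[0, "survives"]

    def test_planted_dominant_level_survives(self, rng):
        rows = []
        for s in range(12):
            for i in range(6):
                val = rng.standard_normal() * 0.2 + (5.0 if i == 0 else 0.0)
                rows.append((s, f"c{i}", val))
        t = pd.DataFrame(rows, columns=["participant", "condition", "value"])
        pw = pairwise_bonferroni(t, "condition")
        dom = pw[(pw["level_a"] == "c0") | (pw["level_b"] == "c0")]
        assert dom["survives"].all()

    def test_single_level_rejected(self):
        t = pd.DataFrame({"participant": [0, 1], "condition": "a",
                          "value": [1.0, 2.0]})
        with pytest.raises(ValueError, match="two levels"):
            pairwise_bonferroni(t, "condition")


@pytest.fixture(scope="module")
def noise_free():
    cfg = SimulationConfig(seed=8, sigma=1e-10, drift_sd=0.0,
                           motion_coupling_sd=0.0)
    gt = make_ground_truth(cfg, "L")
    ev = make_paradigm("memory", 0, cfg)
    ds = simulate_task_run(cfg, ev, gt=gt)
    return cfg, gt, ev, ds


class TestTrialAverage:

    def test_constant_signal_gives_zero_curves(self, gt_left, config):
        ev = make_paradigm("memory", 0, config)
        data = np.full((ev.n_volumes, gt_left.grid.n_nodes), 3.0)
        curves = trial_average(data, ev, gt_left.mpc_mask, ev.tr)
        assert curves["value"].abs().max() == 0.0

    def test_curves_start_at_zero_and_match_convolution_oracle(self,
                                                               noise_free):
        cfg, gt, ev, ds = noise_free
        roi = gt.band_mask(0) & (gt.taper > 0.5)
        scaled = scale_by_run_mean(ds.data)
        curves = trial_average(scaled, ev, roi, ev.tr, window=6)
        pp = curves[curves["condition"] == "personal_places"] \
            .sort_values("tr_index")["value"].to_numpy()
        assert pp[0] == 0.0
        # oracle: reconstruct the ROI-mean series from the planted
        # convolution model (all four conditions, direct summation), then
        # window and baseline-subtract with an explicit loop
        h = gamma_hrf(HRFSpec(), ev.tr)
        T = ev.n_volumes
        series = np.ones(T)
        for c, cond in enumerate(MEMORY_CONDITIONS):
            box = np.zeros(T)
            sel = ev.table[ev.table["trial_type"] == cond]
            for onset in sel["onset"]:
                i0 = int(round(onset / ev.tr))
                box[i0:i0 + int(10 / ev.tr)] = 1.0
            reg = np.array([sum(box[t - k] * h[k]
                                for k in range(min(t + 1, len(h))))
                            for t in range(T)])
            series += reg * gt.A_memory[roi, c].mean()
        series /= series.mean()
        segs = []
        for onset in ev.table[ev.table["trial_type"]
                              == "personal_places"]["onset"]:
            i0 = int(round(onset / ev.tr))
            seg = series[i0:i0 + 6]
            segs.append(seg - seg[0])
        oracle = np.mean(segs, axis=0)
        np.testing.assert_allclose(pp, oracle, atol=1e-4)

    def test_linearity_in_the_data(self, gt_left, config, rng):
        ev = make_paradigm("memory", 0, config)
        data = rng.standard_normal((ev.n_volumes, gt_left.grid.n_nodes))
        c1 = trial_average(data, ev, gt_left.mpc_mask, ev.tr)
        c3 = trial_average(3.0 * data, ev, gt_left.mpc_mask, ev.tr)
        np.testing.assert_allclose(c3["value"], 3.0 * c1["value"], atol=1e-12)

    def test_window_one_gives_zero_point_curves(self, gt_left, config, rng):
        ev = make_paradigm("memory", 0, config)
        data = rng.standard_normal((ev.n_volumes, gt_left.grid.n_nodes))
        curves = trial_average(data, ev, gt_left.mpc_mask, ev.tr, window=1)
        assert (curves["value"] == 0.0).all()

    def test_truncated_trials_dropped_with_warning(self, gt_left, config,
                                                   rng):
        ev = make_paradigm("memory", 0, config)
        data = rng.standard_normal((20, gt_left.grid.n_nodes))
        with pytest.warns(UserWarning, match="dropped"):
            trial_average(data, ev, gt_left.mpc_mask, config.tr_memory)

    def test_empty_roi_rejected(self, gt_left, config, rng):
        ev = make_paradigm("memory", 0, config)
        data = rng.standard_normal((ev.n_volumes, gt_left.grid.n_nodes))
        with pytest.raises(ValueError, match="empty ROI"):
            trial_average(data, ev, np.zeros(gt_left.grid.n_nodes, bool),
                          ev.tr)


class TestMagnitudes:
    def test_single_node_roi_equals_node_t(self, gt_left, rng):
        tmap = rng.standard_normal(gt_left.grid.n_nodes)
        node = 137
        roi = np.zeros(gt_left.grid.n_nodes, bool)
        roi[node] = True
        tmaps = {(0, "L"): {"famous_people": tmap}}
        out = roi_condition_magnitudes(tmaps, {"L": {"solo": roi}},
                                       ["famous_people"])
        assert out["value"].iloc[0] == pytest.approx(tmap[node])

    def test_missing_condition_rejected(self, gt_left, rng):
        tmaps = {(0, "L"): {"famous_people":
                            rng.standard_normal(gt_left.grid.n_nodes)}}
        rois = {"L": {"MPCv": gt_left.band_mask(0)}}
        with pytest.raises(ValueError, match="lacks conditions"):
            roi_condition_magnitudes(tmaps, rois, ["famous_people",
                                                   "famous_places"])


class TestPeakShift:
    def test_same_condition_gives_zero_fraction(self, gt_left, rng):
        tmap = rng.standard_normal(gt_left.grid.n_nodes)
        tmaps = {(0, "L"): {"a": tmap}, (1, "L"): {"a": tmap}}
        _, frac = peak_shift(tmaps, gt_left.mpc_mask, gt_left.grid, "a", "a")
        assert frac == 0.0

    def test_single_node_mask_gives_zero_fraction(self, gt_left, rng):
        mask = np.zeros(gt_left.grid.n_nodes, bool)
        mask[int(np.flatnonzero(gt_left.mpc_mask)[0])] = True
        tmaps = {(0, "L"): {"a": rng.standard_normal(gt_left.grid.n_nodes),
                            "b": rng.standard_normal(gt_left.grid.n_nodes)}}
        _, frac = peak_shift(tmaps, mask, gt_left.grid, "a", "b")
        assert frac == 0.0

    def test_planted_band_geometry_orders_peaks(self, gt_left):
        # amplitude maps themselves: people peak (band 1) is anterior+dorsal
        # of the places peak (band 0)
        i_pp = MEMORY_CONDITIONS.index("personal_places")
        i_pe = MEMORY_CONDITIONS.index("personal_people")
        tmaps = {(p, "L"): {"personal_places": gt_left.A_memory[:, i_pp],
                            "personal_people": gt_left.A_memory[:, i_pe]}
                 for p in range(4)}
        records, frac = peak_shift(tmaps, gt_left.mpc_mask, gt_left.grid,
                                   "personal_places", "personal_people")
        assert frac == 1.0
        assert len(records) == 2 * 4

    def test_flat_map_warns(self, gt_left):
        tmaps = {(0, "L"): {"a": np.zeros(gt_left.grid.n_nodes),
                            "b": np.zeros(gt_left.grid.n_nodes)}}
        with pytest.warns(UserWarning, match="flat map"):
            peak_shift(tmaps, gt_left.mpc_mask, gt_left.grid, "a", "b")
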