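"""ROI-level inference: trial-averaged response curves, per-condition
response magnitudes, repeated-measures ANOVA with partial eta squared,
Bonferroni-corrected pairwise tests, and per-subject peak geometry.

The RM-ANOVA implements the standard fully-within-subject sums-of-squares
partition for 1-3 crossed factors: each effect is tested against its own
effect-by-subject interaction, F = MS_effect / MS_(effect x subject), and
partial eta squared is SS_effect / (SS_effect + SS_error).  No sphericity
correction is applied (2-level factors need none; for the 6-level factor the
uncorrected dfs are reported).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# trial-averaged response curves

def trial_average(data: np.ndarray, events, roi: np.ndarray, tr: float,
                  window: int = 6) -> pd.DataFrame:
    """Per-condition mean response curve over ``window`` TRs from trial onset.

    For each trial the ROI-mean series is sampled at onset + 0..window-1 TRs
    and the onset sample is subtracted, so every curve begins at baseline
    (zero).  Returns a tidy frame with columns condition, tr_index, value
    (one run; average runs/participants downstream).  Trials whose window
    runs past the end of the run are dropped with a warning.
    """
    roi = np.asarray(roi, bool)
    if not roi.any():
        raise ValueError("empty ROI")
    data = np.asarray(data, float)
    roi_series = data[:, roi].mean(axis=1)
    table = events.table if hasattr(events, "table") else events
    curves: dict[str, list[np.ndarray]] = {}
    dropped = 0
    for _, row in table.iterrows():
        i0 = int(round(row["onset"] / tr))
        if i0 + window > len(roi_series):
            dropped += 1
            continue
        seg = roi_series[i0:i0 + window]
        curves.setdefault(row["trial_type"], []).append(seg - seg[0])
    if dropped:
        warnings.warn(f"{dropped} trial(s) dropped: window extends past run "
                      "end", stacklevel=2)
    rows = []
    for cond, segs in curves.items():
        mean = np.mean(segs, axis=0)
        for k in range(window):
            rows.append((cond, k, mean[k]))
    return pd.DataFrame(rows, columns=["condition", "tr_index", "value"])


def curve_set(per_participant: list[pd.DataFrame]) -> pd.DataFrame:
    """Aggregate per-participant curves: mean and SEM across participants."""
    allc = pd.concat(per_participant, keys=range(len(per_participant)),
                     names=["participant"]).reset_index(level=0)
    g = allc.groupby(["condition", "tr_index"])["value"]
    out = g.agg(mean="mean", sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)))
    return out.reset_index()


def plot_curves(curves: pd.DataFrame, path, tr: float = 2.5,
                title: str = "") -> None:
    """Plot condition response curves (mean +/- SEM) to a file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cond, g in curves.groupby("condition"):
        g = g.sort_values("tr_index")
        t = g["tr_index"] * tr
        ax.plot(t, g["mean"] if "mean" in g else g["value"], label=cond)
        if "sem" in g:
            m = g["mean"].to_numpy()
            s = g["sem"].to_numpy()
            ax.fill_between(t, m - s, m + s, alpha=0.2)
    ax.axhline(0.0, color="gray", lw=0.5)
    ax.set_xlabel("time from trial onset (s)")
    ax.set_ylabel("response (fraction of run mean)")
    ax.set_title(title)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# response magnitudes

def roi_condition_magnitudes(tmaps: dict, rois: dict,
                             conditions: list[str]) -> pd.DataFrame:
    """Mean node t-versus-baseline per participant/hemisphere/ROI/condition.

    Parameters
    ----------
    tmaps
        ``{(participant, hemi): {condition: flat t-map}}``.
    rois
        ``{hemi: {roi_name: flat bool mask}}``.
    """
    rows = []
    for (p, hemi), by_cond in tmaps.items():
        missing = set(conditions) - set(by_cond)
        if missing:
            raise ValueError(f"participant {p} hemi {hemi} lacks conditions "
                             f"{sorted(missing)}")
        for roi_name, mask in rois[hemi].items():
            mask = np.asarray(mask, bool)
            if not mask.any():
                raise ValueError(f"ROI {roi_name!r} ({hemi}) is empty")
            for cond in conditions:
                t = np.asarray(by_cond[cond])[mask]
                rows.append((p, hemi, roi_name, cond, float(np.nanmean(t))))
    return pd.DataFrame(rows, columns=["participant", "hemisphere", "roi",
                                       "condition", "value"])


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

@dataclass
class AnovaTable:
    """Effect-wise repeated-measures ANOVA results."""

    table: pd.DataFrame                       # one row per effect
    followups: dict[str, "AnovaTable"] | None = None

    def effect(self, name: str) -> pd.Series:
        m = self.table[self.table["effect"] == name]
        if m.empty:
            raise KeyError(f"no effect {name!r}; have "
                           f"{list(self.table['effect'])}")
        return m.iloc[0]


def _pivot_balanced(table: pd.DataFrame, dv: str, subject: str,
                    factors: list[str]):
    levels = [sorted(table[f].unique()) for f in factors]
    subjects = sorted(table[subject].unique())
    expected = len(subjects) * int(np.prod([len(l) for l in levels]))
    cells = table.groupby([subject, *factors], observed=True)[dv].count()
    if (cells != 1).any() or len(cells) != expected:
        full = pd.MultiIndex.from_product([subjects, *levels],
                                          names=[subject, *factors])
        missing = full.difference(cells[cells > 0].index)
        raise ValueError(
            "design is not balanced (one observation per subject x cell "
            f"required); problem cells: {list(missing[:10])}"
            f"{' ...' if len(missing) > 10 else ''}")
    wide = table.set_index([subject, *factors])[dv].unstack(factors)
    order = pd.MultiIndex.from_product(levels, names=factors) \
        if len(factors) > 1 else pd.Index(levels[0], name=factors[0])
    y = wide[order].to_numpy().reshape(len(subjects),
                                       *[len(l) for l in levels])
    return y, levels, subjects


def rm_anova(table: pd.DataFrame, factors: list[str], dv: str = "value",
             subject: str = "participant",
             followup_by: str | None = None) -> AnovaTable:
    """Fully-within-subject ANOVA for 1-3 crossed factors.

    ``followup_by``: with three factors, if the three-way interaction is
    significant (p < .05), also fit the two-way ANOVA within each level of
    this factor (the conventional simple-effects follow-up).
    """
    if not 1 <= len(factors) <= 3:
        raise ValueError("1 to 3 within-subject factors supported")
    y, levels, subjects = _pivot_balanced(table, dv, subject, factors)
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least two subjects")
    k = len(factors)
    # factor axes are 1..k; axis 0 is subject.  Yates-style recursion:
    # effect term for axis-subset S = cell means over S minus all
    # lower-order terms; SS = (#observations per S-cell) * sum(term^2).
    axes_all = tuple(range(y.ndim))
    terms: dict[frozenset, np.ndarray] = {frozenset(): y.mean(keepdims=True)}
    sizes = y.shape

    def term(S: frozenset) -> np.ndarray:
        if S in terms:
            return terms[S]
        keep = S
        m = y.mean(axis=tuple(a for a in axes_all if a not in keep),
                   keepdims=True)
        t = m.copy()
        for r in range(len(S)):
            for sub in itertools.combinations(sorted(S), r):
                t = t - term(frozenset(sub))
        terms[S] = t
        return t

    def ss(S: frozenset) -> float:
        t = term(S)
        nrep = int(np.prod([sizes[a] for a in axes_all if a not in S]))
        return float(nrep * (t ** 2).sum())

    rows = []
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(1, k + 1), r):
            S = frozenset(combo)
            ss_eff = ss(S)
            ss_err = ss(S | {0})
            df1 = int(np.prod([sizes[a] - 1 for a in combo]))
            df2 = df1 * (n - 1)
            ms_eff, ms_err = ss_eff / df1, ss_err / df2
            F = ms_eff / ms_err if ms_err > 0 else np.nan
            p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else np.nan
            rows.append({
                "effect": " x ".join(factors[a - 1] for a in combo),
                "SS_effect": ss_eff, "SS_error": ss_err,
                "df1": df1, "df2": df2, "F": F, "p": p,
                "partial_eta_sq": ss_eff / (ss_eff + ss_err)
                if ss_eff + ss_err > 0 else np.nan,
            })
    result = AnovaTable(table=pd.DataFrame(rows))

    if followup_by is not None and k == 3:
        if followup_by not in factors:
            raise ValueError(f"{followup_by!r} is not one of the factors")
        threeway = result.effect(" x ".join(factors))
        if threeway["p"] < 0.05:
            others = [f for f in factors if f != followup_by]
            result.followups = {
                lev: rm_anova(table[table[followup_by] == lev],
                              others, dv=dv, subject=subject)
                for lev in sorted(table[followup_by].unique())}
    return result


# ---------------------------------------------------------------------------
# pairwise comparisons

def pairwise_bonferroni(table: pd.DataFrame, factor: str, dv: str = "value",
                        subject: str = "participant",
                        alpha: float = 0.01) -> pd.DataFrame:
    """Paired t-tests over all level pairs with Bonferroni correction.

    Corrected p = min(1, p * n_pairs); the survival flag marks corrected
    p < ``alpha``.  Identical paired samples give an undefined t (NaN) and
    never survive.
    """
    levels = sorted(table[factor].unique())
    if len(levels) < 2:
        raise ValueError("need at least two levels for pairwise comparisons")
    wide = table.pivot_table(index=subject, columns=factor, values=dv)
    if wide.isna().any().any() or len(wide) < 2:
        raise ValueError("need >= 2 subjects with complete data")
    pairs = list(itertools.combinations(levels, 2))
    rows = []
    for a, b in pairs:
        d = wide[a] - wide[b]
        if np.allclose(d.std(ddof=1), 0):
            t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_rel(wide[a], wide[b])
        p_corr = min(1.0, p * len(pairs)) if np.isfinite(p) else np.nan
        rows.append({"level_a": a, "level_b": b, "t": t, "p": p,
                     "p_bonferroni": p_corr,
                     "survives": bool(np.isfinite(p_corr) and p_corr < alpha)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# peak geometry

def peak_shift(tmaps: dict, mask: np.ndarray, grid, cond_a: str,
               cond_b: str) -> tuple[pd.DataFrame, float]:
    """Per-participant peak coordinates and the strict-ordering fraction.

    ``tmaps`` is ``{(participant, hemi): {condition: flat map}}``.  For each
    participant/hemisphere the peak (argmax within the mask, ties to the
    lowest node index) is found for both conditions; the summary is the
    fraction of (participant, hemisphere) pairs whose ``cond_b`` peak is
    strictly greater than the ``cond_a`` peak on *both* the
    posterior->anterior and ventral->dorsal axes.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    idx = np.flatnonzero(mask)
    coords = grid.coords()
    rows = []
    n_ordered = 0
    for (p, hemi), by_cond in sorted(tmaps.items()):
        peaks = {}
        for cond in (cond_a, cond_b):
            vals = np.asarray(by_cond[cond])[idx]
            if np.allclose(vals, vals[0]):
                warnings.warn(f"flat map for {cond!r} (participant {p}, "
                              f"{hemi}); tie-break to lowest node",
                              stacklevel=2)
            node = idx[int(np.nanargmax(vals))]
            peaks[cond] = coords[node]
            rows.append({"participant": p, "hemisphere": hemi,
                         "condition": cond, "pa": int(coords[node][0]),
                         "vd": int(coords[node][1])})
        ordered = (peaks[cond_b][0] > peaks[cond_a][0]
                   and peaks[cond_b][1] > peaks[cond_a][1])
        n_ordered += bool(ordered)
    frac = n_ordered / max(len(tmaps), 1)
    return pd.DataFrame(rows), float(frac)
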