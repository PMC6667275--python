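"""Node-wise group effect mapping and the split-half reliability procedure.

For the balanced 2x2 within-subject design (Category x Familiarity), the
node-wise mixed model with a random participant intercept is computed via
the exactly-equivalent repeated-measures partition: with 2-level factors
each effect F is the square of the paired t on the corresponding
within-subject contrast, tested on (1, n-1) degrees of freedom.  This is
vectorized across all nodes.

FDR control is Benjamini-Hochberg over in-mask nodes.  Suprathreshold
clusters are 4-connected components computed within each preference sign
separately (hot/cold regions of the category map), ordered along the
ventral/posterior -> dorsal/anterior diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .grid import CortexGrid
from .wta import FOUR_CONN, ROISet

EFFECTS = ("category", "familiarity", "interaction")


@dataclass
class EffectMap:
    """Per-node F/p for the 2x2 effects plus signed preferences."""

    grid: CortexGrid
    mask: np.ndarray                       # flat bool analysis mask
    F: dict[str, np.ndarray]               # effect -> flat map (NaN outside)
    p: dict[str, np.ndarray]
    sign_category: np.ndarray              # sign of mean(places - people)
    sign_familiarity: np.ndarray           # sign of mean(personal - famous)
    n: int
    q: dict[str, np.ndarray] = field(default_factory=dict)


def nodewise_effects(subject_betas: np.ndarray, grid: CortexGrid,
                     mask: np.ndarray | None = None) -> EffectMap:
    """Node-wise 2x2 within-subject model across a cohort.

    Parameters
    ----------
    subject_betas
        (n_subjects, 2, 2, n_nodes): axis 1 is familiarity
        (famous, personal), axis 2 is category (people, places); one beta
        per participant per condition per node (runs already averaged).
    """
    y = np.asarray(subject_betas, float)
    if y.ndim != 4 or y.shape[1:3] != (2, 2):
        raise ValueError("subject_betas must be (n_subjects, 2, 2, n_nodes)")
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least two participants")
    if np.isnan(y).any():
        raise ValueError("missing participant cells (NaN betas)")
    N = y.shape[3]
    if mask is None:
        mask = np.ones(N, dtype=bool)
    mask = np.asarray(mask, bool)

    # within-subject contrasts, one value per subject per node
    contrasts = {
        "category": (y[:, :, 1] - y[:, :, 0]).mean(axis=1),      # places-people
        "familiarity": (y[:, 1] - y[:, 0]).mean(axis=1),         # personal-famous
        "interaction": (y[:, 1, 1] - y[:, 1, 0]
                        - y[:, 0, 1] + y[:, 0, 0]),
    }
    F, P = {}, {}
    degenerate = np.zeros(N, dtype=bool)
    for eff, c in contrasts.items():
        mean = c.mean(axis=0)
        var = c.var(axis=0, ddof=1)
        zero = var <= 0
        degenerate |= zero & (np.abs(mean) > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = n * mean ** 2 / var
        f[zero] = np.nan
        p = stats.f.sf(f, 1, n - 1)
        f_map = np.full(N, np.nan)
        p_map = np.full(N, np.nan)
        f_map[mask] = f[mask]
        p_map[mask] = p[mask]
        F[eff], P[eff] = f_map, p_map
    if degenerate[mask].any():
        warnings.warn(f"{int(degenerate[mask].sum())} node(s) with "
                      "degenerate (zero) contrast variance across "
                      "participants", stacklevel=2)
    sign_cat = np.sign(contrasts["category"].mean(axis=0))
    sign_fam = np.sign(contrasts["familiarity"].mean(axis=0))
    sign_cat[~mask] = 0
    sign_fam[~mask] = 0
    return EffectMap(grid=grid, mask=mask, F=F, p=P,
                     sign_category=sign_cat, sign_familiarity=sign_fam, n=n)


def fdr_q(p_map: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values over in-mask nodes."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    q = np.full(np.asarray(p_map).shape, np.nan)
    p = np.asarray(p_map)[mask]
    ok = np.isfinite(p)
    qv = np.full(p.shape, np.nan)
    if ok.any():
        qv[ok] = multipletests(p[ok], method="fdr_bh")[1]
    q[mask] = qv
    return q


@dataclass(frozen=True)
class ThresholdSpec:
    """Node-wise p threshold with BH FDR reporting."""

    p: float = 1.0e-4
    min_cluster: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.p < 1:
            raise ValueError("p threshold must be in (0, 1)")


@dataclass
class Cluster:
    name: str
    preference: str                # "places" or "people"
    size: int
    centroid: tuple[float, float]  # (pa, vd)
    diag: float                    # ordering coordinate along the diagonal
    mask: np.ndarray               # flat bool


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    q_at_threshold: float = float("nan")

    def __len__(self) -> int:
        return len(self.clusters)

    @property
    def alternation(self) -> str:
        return ",".join(c.preference for c in self.clusters)

    def as_roiset(self) -> ROISet:
        return ROISet(masks={c.name: c.mask for c in self.clusters},
                      provenance="effect-defined")

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "name": c.name, "preference": c.preference, "size": c.size,
            "centroid_pa": c.centroid[0], "centroid_vd": c.centroid[1],
            "diag": c.diag} for c in self.clusters])


def clusterize(effect_map: EffectMap, spec: ThresholdSpec = ThresholdSpec(),
               effect: str = "category",
               mask: np.ndarray | None = None) -> ClusterSet:
    """Suprathreshold 4-connected clusters of one effect, sign-split.

    Thresholds the effect's p-map at ``spec.p`` within the analysis mask,
    finds 4-connected components separately within places-preferring
    (sign > 0) and people-preferring (sign < 0) nodes, drops components
    smaller than ``spec.min_cluster``, and orders the survivors along the
    posterior/ventral -> anterior/dorsal diagonal of their centroids.
    """
    grid = effect_map.grid
    m = effect_map.mask if mask is None else np.asarray(mask, bool)
    p = effect_map.p[effect]
    supra = m & np.isfinite(p) & (p < spec.p)
    sign = effect_map.sign_category if effect == "category" \
        else effect_map.sign_familiarity
    qmap = fdr_q(p, m)
    with np.errstate(invalid="ignore"):
        at = supra & np.isfinite(qmap)
    q_at = float(np.nanmax(qmap[at])) if at.any() else float("nan")

    coords = grid.coords().astype(float)
    clusters: list[Cluster] = []
    for pref, s in (("places", 1), ("people", -1)):
        img = (supra & (sign == s)).reshape(grid.shape)
        lab, ncomp = ndimage.label(img, structure=FOUR_CONN)
        for i in range(1, ncomp + 1):
            cm = (lab == i).ravel()
            if cm.sum() < spec.min_cluster:
                continue
            cen = coords[cm].mean(axis=0)
            clusters.append(Cluster(
                name="", preference=pref, size=int(cm.sum()),
                centroid=(float(cen[0]), float(cen[1])),
                diag=float(cen[0] + cen[1]), mask=cm))
    clusters.sort(key=lambda c: c.diag)
    for i, c in enumerate(clusters):
        c.name = f"ROI{i + 1}"
    return ClusterSet(clusters=clusters, q_at_threshold=q_at)


# ---------------------------------------------------------------------------
# split-half reliability

def split_half(run_betas: np.ndarray, grid: CortexGrid,
               mask: np.ndarray | None = None
               ) -> tuple[EffectMap, EffectMap, float, float]:
    """Odd/even split of the memory runs with re-fit effect maps.

    ``run_betas`` is (n_subjects, n_runs, 2, 2, n_nodes) in the same
    condition layout as :func:`nodewise_effects`.  Runs 1, 3, 5 (indices
    0, 2, 4) form the Odd split.  Returns the two effect maps, the Pearson
    correlation of their node-wise category F maps over the mask, and r^2
    rounded to two decimals.
    """
    y = np.asarray(run_betas, float)
    if y.ndim != 5 or y.shape[2:4] != (2, 2):
        raise ValueError("run_betas must be (n_subjects, n_runs, 2, 2, n_nodes)")
    n_runs = y.shape[1]
    if n_runs < 2 or n_runs % 2:
        raise ValueError(f"need an even number of runs >= 2, got {n_runs}")
    odd = y[:, 0::2].mean(axis=1)
    even = y[:, 1::2].mean(axis=1)
    em_odd = nodewise_effects(odd, grid, mask)
    em_even = nodewise_effects(even, grid, mask)
    r = split_map_correlation(em_odd, em_even)
    return em_odd, em_even, r, round(r ** 2, 2)


def split_map_correlation(em_a: EffectMap, em_b: EffectMap,
                          effect: str = "category") -> float:
    """Pearson r between two effect maps' node-wise F statistics."""
    m = em_a.mask & em_b.mask
    a, b = em_a.F[effect][m], em_b.F[effect][m]
    ok = np.isfinite(a) & np.isfinite(b)
    return float(stats.pearsonr(a[ok], b[ok])[0])


def cross_defined_sampling(rois_odd: ROISet, rois_even: ROISet,
                           mags_odd: np.ndarray, mags_even: np.ndarray,
                           conditions: list[str]) -> pd.DataFrame:
    """Unbiased ROI response estimates: define in one split, sample the other.

    ``mags_*`` are (n_subjects, n_conditions, n_nodes) response magnitudes
    from each split.  For each ROI name present in both splits, responses
    are sampled odd-defined -> even-data and even-defined -> odd-data, then
    averaged.  A direction with an empty ROI is skipped with a warning.
    """
    mags_odd = np.asarray(mags_odd, float)
    mags_even = np.asarray(mags_even, float)
    rows = []
    names = [n for n in rois_odd.names() if n in rois_even.names()]
    for name in names:
        parts = []
        for roi_set, mags, direction in ((rois_odd, mags_even, "odd->even"),
                                         (rois_even, mags_odd, "even->odd")):
            m = np.asarray(roi_set[name], bool)
            if not m.any():
                warnings.warn(f"ROI {name!r} empty in one split; direction "
                              f"{direction} skipped", stacklevel=2)
                continue
            parts.append(mags[:, :, m].mean(axis=2))   # (n_sub, n_cond)
        if not parts:
            continue
        avg = np.mean(parts, axis=0)
        for s in range(avg.shape[0]):
            for c, cond in enumerate(conditions):
                rows.append({"roi": name, "participant": s,
                             "condition": cond, "value": float(avg[s, c])})
    return pd.DataFrame(rows)
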