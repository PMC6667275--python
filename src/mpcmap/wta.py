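"""Winner-take-all seed-based connectivity parcellation.

Mean time series are extracted from the six VTC seed parcels and scaled by
their own temporal mean (optionally z-scored).  Each target node's series is
then regressed on all six seed series simultaneously (multiple regression
with an intercept, optionally a drift basis), the winning parcel is the one
with the maximum coefficient, and the node's selectivity index is the
winner's coefficient minus the mean of the other five.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import legendre
from scipy import ndimage

from .grid import CortexGrid, SeedGeometry, SEED_LABELS, SEED_NAMES

#: 4-neighbourhood structuring element for cluster labelling
FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass
class SeedTimeSeries:
    """6 x T matrix of parcel-mean series, each row scaled by its own mean."""

    series: np.ndarray            # (6, T)
    labels: list[int]             # parcel labels in row order (1..6)
    scaling: str = "mean"


def extract_seed_timeseries(data: np.ndarray, seeds: SeedGeometry,
                            scaling: str = "mean") -> SeedTimeSeries:
    """Average each parcel's nodes and scale the row.

    ``scaling="mean"`` divides by the temporal mean (row mean becomes 1);
    ``scaling="zscore"`` standardizes the row instead (variance-normalized
    alternative).
    """
    data = np.asarray(data, float)
    rows = []
    for lab in sorted(SEED_LABELS):
        m = seeds.parcel_mask(lab)
        if not m.any():
            raise ValueError(f"seed parcel {lab} ({SEED_LABELS[lab]}) is empty")
        rows.append(data[:, m].mean(axis=1))
    S = np.array(rows)
    if scaling == "mean":
        mu = S.mean(axis=1, keepdims=True)
        if (mu <= 0).any():
            raise ValueError("seed parcel with non-positive mean cannot be "
                             "mean-scaled")
        S = S / mu
    elif scaling == "zscore":
        S = (S - S.mean(axis=1, keepdims=True)) / S.std(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown scaling {scaling!r}")
    return SeedTimeSeries(series=S, labels=sorted(SEED_LABELS), scaling=scaling)


@dataclass
class WTAMap:
    """Per-target-node seed coefficients, winner label and selectivity."""

    node_index: np.ndarray        # flat indices of target nodes
    beta: np.ndarray              # (n_targets, 6) seed coefficients
    winner: np.ndarray            # (n_targets,) labels 1..6
    selectivity: np.ndarray       # (n_targets,) beta_w - mean(others)
    grid: CortexGrid

    def winner_map(self) -> np.ndarray:
        """Full-grid flat winner-label map (0 outside the target mask)."""
        out = np.zeros(self.grid.n_nodes, dtype=int)
        out[self.node_index] = self.winner
        return out

    def selectivity_map(self) -> np.ndarray:
        out = np.full(self.grid.n_nodes, np.nan)
        out[self.node_index] = self.selectivity
        return out


def wta_regress(data: np.ndarray, seeds: SeedTimeSeries,
                target_mask: np.ndarray, grid: CortexGrid,
                drift_order: int | None = None) -> WTAMap:
    """Multiple regression of every target node on the six seed series.

    The design is [intercept, seed_1..seed_6] plus, if ``drift_order`` is
    given, Legendre drift columns of orders 1..drift_order.  Winner is the
    argmax coefficient; ties break to the lowest parcel label.
    """
    data = np.asarray(data, float)
    T = data.shape[0]
    S = seeds.series
    if S.shape[1] != T:
        raise ValueError("seed series length must match data")
    cols = [np.ones(T), *S]
    if drift_order:
        x = np.linspace(-1, 1, T)
        cols.extend(legendre.legvander(x, drift_order)[:, 1:].T)
    X = np.column_stack(cols)
    if T <= X.shape[1] + 2:
        raise ValueError("too few volumes for the regression design")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("seed series are mutually collinear")
    idx = np.flatnonzero(np.asarray(target_mask))
    Y = data[:, idx]
    beta_full, *_ = np.linalg.lstsq(X, Y, rcond=None)
    beta = beta_full[1:7].T                     # (n_targets, 6)
    winner_row, sel = winner_and_selectivity(beta)
    return WTAMap(node_index=idx, beta=beta,
                  winner=np.array(seeds.labels)[winner_row],
                  selectivity=sel, grid=grid)


def winner_and_selectivity(beta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Winner rows (argmax, ties to lowest index) and selectivity index.

    Selectivity is the winning coefficient minus the mean of the other
    coefficients, which is non-negative and invariant to adding a common
    constant to the whole coefficient vector.
    """
    beta = np.atleast_2d(np.asarray(beta, float))
    k = beta.shape[1]
    winner_row = np.argmax(beta, axis=1)
    bw = beta[np.arange(len(beta)), winner_row]
    other_mean = (beta.sum(axis=1) - bw) / (k - 1)
    return winner_row, bw - other_mean


@dataclass
class ROISet:
    """Named, disjoint node masks with a provenance tag."""

    masks: dict[str, np.ndarray]
    provenance: str = "connectivity-defined"

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]

    def names(self) -> list[str]:
        return list(self.masks)


def derive_rois(wtamap: WTAMap, target_mask: np.ndarray,
                wanted_labels: dict[int, str] | None = None,
                min_cluster: int = 10) -> ROISet:
    """Largest 4-connected cluster of winning nodes per wanted label.

    Default wanted labels name the anterior-medial winner MPCv and the
    anterior-lateral winner MPCd (the connectivity-defined subdivisions).
    """
    if wanted_labels is None:
        wanted_labels = {SEED_NAMES["anterior_medial"]: "MPCv",
                         SEED_NAMES["anterior_lateral"]: "MPCd"}
    bad = set(wanted_labels) - set(SEED_LABELS)
    if bad:
        raise ValueError(f"unknown seed labels {sorted(bad)}")
    grid = wtamap.grid
    winner = wtamap.winner_map() * np.asarray(target_mask)
    masks: dict[str, np.ndarray] = {}
    for lab, name in wanted_labels.items():
        img = (winner == lab).reshape(grid.shape)
        lab_img, n = ndimage.label(img, structure=FOUR_CONN)
        best = np.zeros(grid.n_nodes, dtype=bool)
        if n > 0:
            sizes = ndimage.sum_labels(img, lab_img, index=np.arange(1, n + 1))
            if sizes.max() >= min_cluster:
                best = (lab_img == (np.argmax(sizes) + 1)).ravel()
        if not best.any():
            warnings.warn(f"no cluster of >= {min_cluster} nodes wins for "
                          f"label {lab}; ROI {name!r} is empty", stacklevel=2)
        masks[name] = best
    return ROISet(masks=masks, provenance="connectivity-defined")


def label_accuracy(wtamap: WTAMap, true_winner: np.ndarray) -> float:
    """Fraction of target nodes whose winner matches the planted label."""
    truth = np.asarray(true_winner)[wtamap.node_index]
    return float((wtamap.winner == truth).mean())


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two boolean masks."""
    a, b = np.asarray(a, bool), np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return float(2.0 * (a & b).sum() / denom) if denom else float("nan")
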