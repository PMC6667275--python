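"""Seeded synthetic BOLD generator with known ground truth.

Emulates the three study designs on the :class:`~mpcmap.grid.CortexGrid`
stand-in for the cortical surface:

* **rest** — one 21-minute run (630 volumes at TR 2.0 s, first 30 discarded,
  leaving 600) in which the six VTC seed parcels carry independent latent
  signals and every MPC node is a weighted mixture of them plus AR(1) noise,
  polynomial drift and motion-coupled nuisance.
* **localizer** — six runs of 16 s category blocks (six categories, each
  twice per run, order counterbalanced across runs), with planted
  negative-but-graded response amplitudes in MPC.
* **memory** — six runs of 10 s recall trials (2x2 People/Places x
  Famous/Personal, six trials per condition per run, ITI in
  {2.5, 5.0, 7.5} s), with an alternating four-band category topography
  along the ventral/posterior -> dorsal/anterior diagonal of MPC and a
  familiarity amplitude boost.

All planted amplitudes are in fraction-of-mean units on a baseline of 100,
so 0.01 is a 1% signal change.  Every dataset is a deterministic function of
(config, participant, run).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .glm import HRFSpec, gamma_hrf
from .grid import (CortexGrid, SeedGeometry, SEED_NAMES,
                   DEFAULT_MPC_BLOCK, DEFAULT_VTC_BLOCK, block_mask)

MEMORY_CONDITIONS = ["famous_people", "famous_places",
                     "personal_people", "personal_places"]
LOCALIZER_CATEGORIES = ["scenes", "faces", "bodies",
                        "buildings", "objects", "scrambled"]
#: category preference of the four MPC bands, posterior/ventral -> anterior/dorsal
BAND_PREFS = ["places", "people", "places", "people"]
#: planted winner seed parcel for each band (bands 1/2 are the MPCv/MPCd story)
BAND_WINNERS = ["anterior_medial", "anterior_lateral",
                "middle_medial", "middle_lateral"]

_STREAM = {"rest": 0, "localizer": 1, "memory": 2, "paradigm": 3}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level simulation parameters (defaults are the study conditions)."""

    n_participants_rest: int = 65
    n_participants_localizer: int = 29
    n_participants_memory: int = 24
    tr_rest: float = 2.0
    tr_localizer: float = 2.0
    tr_memory: float = 2.5
    rest_volumes_total: int = 630     # 21 min at TR 2.0
    rest_discard: int = 30
    n_runs_localizer: int = 6
    n_runs_memory: int = 6
    n_pa: int = 40
    n_vd: int = 30
    baseline: float = 100.0
    amp: float = 0.01                 # category amplitude (fraction of mean)
    familiarity_boost: float = 0.01   # delta, added for personal conditions
    anterior_band_scale: float = 0.8  # bands 3/4 amplitude relative to 1/2
    taper_sd: float = 4.0             # grid units; within-band Gaussian taper
    rest_signal_scale: float = 1.0    # raw units (1% of baseline)
    offwinner_weight: float = 0.1     # W entries for non-winning seeds in MPC
    phi: float = 0.3                  # AR(1) noise coefficient
    sigma: float = 1.0                # AR(1) innovation SD (raw units)
    drift_order: int = 4
    drift_sd: float = 0.3             # SD of random Legendre drift coefs
    motion_sd: float = 0.2            # SD of simulated motion series
    motion_coupling_sd: float = 0.05  # node-wise motion leakage (raw units)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_participants_rest", "n_participants_localizer",
                     "n_participants_memory", "rest_volumes_total",
                     "n_runs_localizer", "n_runs_memory"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.phi) >= 1:
            raise ValueError("AR(1) coefficient must satisfy |phi| < 1")
        if self.sigma <= 0:
            raise ValueError("noise innovation SD must be positive")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    def rng(self, kind: str, participant: int = 0, run: int = 0,
            extra: int = 0) -> np.random.Generator:
        """Deterministic per-(paradigm, participant, run) substream."""
        ss = np.random.SeedSequence(
            (self.seed, _STREAM[kind], participant, run, extra))
        return np.random.default_rng(ss)


@dataclass
class EventTable:
    """One run's trial/block timing (BIDS-style onset/duration/trial_type)."""

    table: pd.DataFrame
    tr: float
    n_volumes: int
    kind: str
    run_index: int

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TimeSeriesDataset:
    """node x time BOLD for one run (stored as (T, n_nodes))."""

    data: np.ndarray
    tr: float
    grid: CortexGrid
    kind: str
    participant: int = 0
    run_index: int = 0
    motion: np.ndarray | None = None   # (T, 6) simulated motion series

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]


@dataclass
class GroundTruth:
    """Planted structure for one hemisphere's grid."""

    grid: CortexGrid
    seeds: SeedGeometry
    mpc_mask: np.ndarray           # flat bool
    band: np.ndarray               # flat int, -1 outside MPC, 0..3 inside
    band_centers: np.ndarray       # (4, 2) float (pa, vd)
    winner: np.ndarray             # flat int, 0 outside MPC, 1..6 inside
    W: np.ndarray                  # (n_nodes, 6) connectivity weights
    A_memory: np.ndarray           # (n_nodes, 4), MEMORY_CONDITIONS order
    A_localizer: np.ndarray        # (n_nodes, 6), LOCALIZER_CATEGORIES order
    taper: np.ndarray              # flat float in [0, 1]
    config: SimulationConfig = field(repr=False, default=None)

    def band_mask(self, k: int) -> np.ndarray:
        return self.band == k

    def validate(self) -> None:
        self.seeds.validate()
        inside = self.band >= 0
        if not np.array_equal(inside, self.mpc_mask):
            raise ValueError("band map must cover exactly the MPC mask")
        # within each band the argmax condition must match the declared
        # preference (checked on the personal conditions, where taper > 0)
        for k, pref in enumerate(BAND_PREFS):
            m = self.band_mask(k) & (np.ptp(self.A_memory, axis=1) > 0)
            if not m.any():        # planted null: no preference to check
                continue
            best = np.argmax(self.A_memory[m], axis=1)
            want = MEMORY_CONDITIONS.index(f"personal_{pref}")
            if not (best == want).all():
                raise ValueError(f"band {k} amplitude argmax does not match "
                                 f"its declared preference {pref!r}")


def _band_geometry(grid: CortexGrid, mpc_block):
    pa_sl, vd_sl = mpc_block
    coords = grid.coords().astype(float)
    mpc = block_mask(grid, pa_sl, vd_sl)
    pa_frac = (coords[:, 0] - pa_sl.start) / max(pa_sl.stop - 1 - pa_sl.start, 1)
    vd_frac = (coords[:, 1] - vd_sl.start) / max(vd_sl.stop - 1 - vd_sl.start, 1)
    diag = (pa_frac + vd_frac) / 2.0
    band = np.full(grid.n_nodes, -1, dtype=int)
    band[mpc] = np.minimum((diag[mpc] * 4).astype(int), 3)
    centers = np.stack([coords[band == k].mean(axis=0) for k in range(4)])
    return mpc, band, centers


def make_ground_truth(config: SimulationConfig, hemi: str = "L",
                      mpc_block=DEFAULT_MPC_BLOCK,
                      vtc_block=DEFAULT_VTC_BLOCK) -> GroundTruth:
    """Construct the planted maps for one hemisphere.

    The maps depend only on the config's deterministic geometry parameters,
    so left and right hemispheres carry identical structure in grid
    coordinates (mirror-symmetric once the grids are embedded anatomically).
    """
    grid = CortexGrid(config.n_pa, config.n_vd, hemi)
    seeds = SeedGeometry.default(grid, vtc_block)
    mpc, band, centers = _band_geometry(grid, mpc_block)
    coords = grid.coords().astype(float)

    # within-band Gaussian taper about the band centroid: gives each band a
    # unique amplitude peak so per-subject peak geometry is well defined
    taper = np.zeros(grid.n_nodes)
    for k in range(4):
        m = band == k
        d2 = ((coords[m] - centers[k]) ** 2).sum(axis=1)
        taper[m] = np.exp(-d2 / (2.0 * config.taper_sd ** 2))

    band_scale = np.array([1.0, 1.0,
                           config.anterior_band_scale,
                           config.anterior_band_scale])

    winner = np.zeros(grid.n_nodes, dtype=int)
    W = np.zeros((grid.n_nodes, 6))
    for lab in range(1, 7):          # VTC seed nodes: one-hot own parcel
        W[seeds.labels == lab, lab - 1] = 1.0
    for k, wname in enumerate(BAND_WINNERS):
        lab = SEED_NAMES[wname]
        m = band == k
        winner[m] = lab
        W[m] = config.offwinner_weight
        W[m, lab - 1] = 1.0

    A_mem = np.zeros((grid.n_nodes, 4))
    for k, pref in enumerate(BAND_PREFS):
        m = band == k
        g = taper[m] * band_scale[k]
        for c, cond in enumerate(MEMORY_CONDITIONS):
            fam, cat = cond.split("_")
            sign = 1.0 if cat == pref else -1.0
            A_mem[m, c] = g * (sign * config.amp
                               + (config.familiarity_boost
                                  if fam == "personal" else 0.0))

    # visually evoked responses in MPC are negative but category-graded:
    # scene-preferring bands are least negative for scenes, people bands for
    # faces (amplitudes relative to config.amp)
    grade_places = {"scenes": -0.2, "buildings": -0.8, "objects": -1.0,
                    "bodies": -1.2, "faces": -1.4, "scrambled": -1.6}
    grade_people = {"faces": -0.4, "objects": -0.8, "scenes": -1.2,
                    "bodies": -1.4, "buildings": -1.6, "scrambled": -1.8}
    A_loc = np.zeros((grid.n_nodes, 6))
    for k, pref in enumerate(BAND_PREFS):
        m = band == k
        grade = grade_places if pref == "places" else grade_people
        for c, cat in enumerate(LOCALIZER_CATEGORIES):
            A_loc[m, c] = taper[m] * band_scale[k] * grade[cat] * config.amp

    gt = GroundTruth(grid=grid, seeds=seeds, mpc_mask=mpc, band=band,
                     band_centers=centers, winner=winner, W=W,
                     A_memory=A_mem, A_localizer=A_loc, taper=taper,
                     config=config)
    gt.validate()
    return gt


# ---------------------------------------------------------------------------
# paradigm timing

MEMORY_LEAD = 12.5      # s of fixation before the first / after the last trial
LOCALIZER_LEAD = 16.0
LOCALIZER_GAP = 8.0     # s of fixation between blocks
MEMORY_ITI_CHOICES = (2.5, 5.0, 7.5)


def make_paradigm(kind: str, run_index: int, seed: int | SimulationConfig = 0,
                  participant: int = 0) -> EventTable:
    """Generate one run's event table.

    memory: 24 randomized 10 s recall trials (6 per condition), ITI drawn
    uniformly from {2.5, 5.0, 7.5} s.  localizer: twelve 16 s blocks, each of
    the six categories exactly twice, order counterbalanced across runs by
    rotating a seeded base order.
    """
    if isinstance(seed, SimulationConfig):
        config = seed
    else:
        config = SimulationConfig(seed=int(seed))
    if kind == "memory":
        if not 0 <= run_index < config.n_runs_memory:
            raise ValueError(f"memory run index {run_index} out of range")
        rng = config.rng("paradigm", participant, run_index, extra=2)
        order = rng.permutation(np.repeat(np.arange(4), 6))
        itis = rng.choice(MEMORY_ITI_CHOICES, size=len(order) - 1)
        onset = MEMORY_LEAD
        rows = []
        for i, c in enumerate(order):
            rows.append((onset, 10.0, MEMORY_CONDITIONS[c]))
            onset += 10.0 + (itis[i] if i < len(itis) else 0.0)
        total = onset + MEMORY_LEAD
        tr = config.tr_memory
    elif kind == "localizer":
        if not 0 <= run_index < config.n_runs_localizer:
            raise ValueError(f"localizer run index {run_index} out of range")
        rng = config.rng("paradigm", participant, 0, extra=1)
        base = rng.permutation(6)
        order = [base[(i + run_index) % 6] for i in range(6)] + \
                [base[(i + run_index + 3) % 6] for i in range(6)]
        onset = LOCALIZER_LEAD
        rows = []
        for c in order:
            rows.append((onset, 16.0, LOCALIZER_CATEGORIES[c]))
            onset += 16.0 + LOCALIZER_GAP
        total = onset - LOCALIZER_GAP + LOCALIZER_LEAD
        tr = config.tr_localizer
    else:
        raise ValueError(f"unknown paradigm kind {kind!r}")
    table = pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])
    n_volumes = int(np.ceil(total / tr - 1e-9))
    return EventTable(table=table, tr=tr, n_volumes=n_volumes,
                      kind=kind, run_index=run_index)


# ---------------------------------------------------------------------------
# signal components

def _ar1(rng: np.random.Generator, phi: float, sigma: float,
         shape: tuple[int, ...]) -> np.ndarray:
    """AR(1) series along axis 0 with a 50-sample burn-in."""
    n = shape[0]
    innov = rng.standard_normal((n + 50,) + shape[1:]) * sigma
    out = lfilter([1.0], [1.0, -phi], innov, axis=0)
    return out[50:]


def _drift(rng: np.random.Generator, n_volumes: int, n_nodes: int,
           order: int, sd: float) -> np.ndarray:
    from numpy.polynomial import legendre
    x = np.linspace(-1, 1, n_volumes)
    basis = legendre.legvander(x, order)[:, 1:]       # exclude constant
    coefs = rng.standard_normal((order, n_nodes)) * sd
    return basis @ coefs


def _motion(rng: np.random.Generator, n_volumes: int, sd: float) -> np.ndarray:
    """Six smooth low-amplitude nuisance series (smoothed random walks)."""
    steps = rng.standard_normal((n_volumes, 6))
    walk = np.cumsum(steps, axis=0)
    kernel = np.hanning(11)
    kernel /= kernel.sum()
    smooth = np.apply_along_axis(
        lambda s: np.convolve(s, kernel, mode="same"), 0, walk)
    smooth -= smooth.mean(axis=0)
    std = smooth.std(axis=0)
    std[std == 0] = 1.0
    return smooth / std * sd


def simulate_rest(config: SimulationConfig, participant: int = 0,
                  hemi: str = "L",
                  gt: GroundTruth | None = None
                  ) -> tuple[TimeSeriesDataset, GroundTruth]:
    """One resting-state run: seed latents mixed into targets via W.

    Simulates the full 630-volume scan and discards the first
    ``config.rest_discard`` volumes, leaving 600 for analysis.
    """
    if gt is None:
        gt = make_ground_truth(config, hemi)
    rng = config.rng("rest", participant, 0)
    T = config.rest_volumes_total
    N = gt.grid.n_nodes
    # six independent smooth latent signals, unit variance
    lat = _ar1(rng, 0.6, 1.0, (T, 6))
    lat = (lat - lat.mean(axis=0)) / lat.std(axis=0)
    signal = lat @ gt.W.T * config.rest_signal_scale
    noise = _ar1(rng, config.phi, config.sigma, (T, N))
    drift = _drift(rng, T, N, config.drift_order, config.drift_sd)
    motion = _motion(rng, T, config.motion_sd)
    coupling = rng.standard_normal((6, N)) * config.motion_coupling_sd
    data = config.baseline + signal + noise + drift + motion @ coupling
    keep = slice(config.rest_discard, None)
    ds = TimeSeriesDataset(data=data[keep], tr=config.tr_rest, grid=gt.grid,
                           kind="rest", participant=participant,
                           motion=motion[keep])
    return ds, gt


def simulate_task_run(config: SimulationConfig, events: EventTable,
                      paradigm_kind: str | None = None,
                      participant: int = 0,
                      gt: GroundTruth | None = None,
                      hemi: str = "L",
                      hrf: HRFSpec = HRFSpec()) -> TimeSeriesDataset:
    """One task run: baseline * (1 + sum_c A[:, c] * (boxcar_c (*) h)(t))
    plus AR(1) noise, drift and motion-coupled nuisance."""
    kind = paradigm_kind or events.kind
    if kind == "memory":
        conditions, A_attr = MEMORY_CONDITIONS, "A_memory"
    elif kind == "localizer":
        conditions, A_attr = LOCALIZER_CATEGORIES, "A_localizer"
    else:
        raise ValueError(f"unknown paradigm kind {kind!r}")
    present = set(events.table["trial_type"])
    unknown = present - set(conditions)
    if unknown:
        raise ValueError(f"events contain conditions with no planted "
                         f"amplitude: {sorted(unknown)}")
    if gt is None:
        gt = make_ground_truth(config, hemi)
    A = getattr(gt, A_attr)
    T, N = events.n_volumes, gt.grid.n_nodes
    kernel = gamma_hrf(hrf, events.tr)
    X = np.zeros((T, len(conditions)))
    for c, cond in enumerate(conditions):
        sel = events.table[events.table["trial_type"] == cond]
        if len(sel) == 0:
            continue
        box = np.zeros(T)
        for onset, dur in zip(sel["onset"], sel["duration"]):
            i0 = int(round(onset / events.tr))
            i1 = int(np.ceil((onset + dur) / events.tr - 1e-9))
            box[i0:min(i1, T)] = 1.0
        X[:, c] = np.convolve(box, kernel)[:T]
    rng = config.rng(kind, participant, events.run_index)
    noise = _ar1(rng, config.phi, config.sigma, (T, N))
    drift = _drift(rng, T, N, config.drift_order, config.drift_sd)
    motion = _motion(rng, T, config.motion_sd)
    coupling = rng.standard_normal((6, N)) * config.motion_coupling_sd
    data = (config.baseline * (1.0 + X @ A.T)
            + noise + drift + motion @ coupling)
    return TimeSeriesDataset(data=data, tr=events.tr, grid=gt.grid,
                             kind=kind, participant=participant,
                             run_index=events.run_index, motion=motion)
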