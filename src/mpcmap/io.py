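"""NIfTI / TSV / JSON serialization of grids, runs, events and maps.

Grid datasets are embedded in 4D NIfTI volumes of shape
(n_pa, n_vd, 1, T) with an identity affine; flat node maps become
(n_pa, n_vd, 1) volumes.  Event tables are BIDS-style TSV with columns
onset, duration, trial_type.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grid import CortexGrid
from .synthdata import EventTable, GroundTruth, TimeSeriesDataset


def save_run(ds: TimeSeriesDataset, path: str | Path) -> None:
    g = ds.grid
    vol = ds.data.T.reshape(g.n_pa, g.n_vd, ds.n_volumes)[:, :, None, :]
    img = nib.Nifti1Image(vol.astype(np.float32), np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, ds.tr))
    nib.save(img, str(path))


def load_run(path: str | Path, kind: str = "unknown",
             hemi: str = "L") -> TimeSeriesDataset:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=float)
    if vol.ndim != 4 or vol.shape[2] != 1:
        raise ValueError(f"expected an (X, Y, 1, T) volume, got {vol.shape}")
    n_pa, n_vd, _, T = vol.shape
    data = vol[:, :, 0, :].reshape(n_pa * n_vd, T).T
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 \
        else 1.0
    return TimeSeriesDataset(data=data, tr=tr,
                             grid=CortexGrid(n_pa, n_vd, hemi), kind=kind)


def save_map(flat: np.ndarray, grid: CortexGrid, path: str | Path) -> None:
    """Save a flat per-node map (labels or statistics) as a 3D NIfTI."""
    flat = np.asarray(flat)
    vol = flat.reshape(grid.n_pa, grid.n_vd, 1)
    dtype = np.int16 if np.issubdtype(vol.dtype, np.integer) else np.float32
    nib.save(nib.Nifti1Image(vol.astype(dtype), np.eye(4)), str(path))


def load_map(path: str | Path) -> np.ndarray:
    vol = np.asarray(nib.load(str(path)).dataobj)
    return vol.reshape(vol.shape[0] * vol.shape[1])


def save_events(events: EventTable, path: str | Path) -> None:
    events.table.to_csv(path, sep="\t", index=False)


def load_events(path: str | Path, tr: float, kind: str = "unknown",
                n_volumes: int | None = None, run_index: int = 0,
                lead_out: float = 12.5) -> EventTable:
    table = pd.read_csv(path, sep="\t")
    for col in ("onset", "duration", "trial_type"):
        if col not in table.columns:
            raise ValueError(f"events file lacks required column {col!r}")
    if n_volumes is None:
        end = (table["onset"] + table["duration"]).max() + lead_out
        n_volumes = int(np.ceil(end / tr))
    return EventTable(table=table, tr=tr, n_volumes=n_volumes, kind=kind,
                      run_index=run_index)


def save_ground_truth(gt: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_map(gt.winner, gt.grid, out / "planted_winner.nii.gz")
    save_map(gt.seeds.labels, gt.grid, out / "seed_labels.nii.gz")
    save_map(gt.mpc_mask.astype(int), gt.grid, out / "mpc_mask.nii.gz")
    save_map(gt.band, gt.grid, out / "bands.nii.gz")
    meta = {
        "hemi": gt.grid.hemi,
        "grid": [gt.grid.n_pa, gt.grid.n_vd],
        "band_centers": gt.band_centers.tolist(),
        "familiarity_boost": gt.config.familiarity_boost,
        "amp": gt.config.amp,
        "phi": gt.config.phi,
        "sigma": gt.config.sigma,
        "seed": gt.config.seed,
        "A_memory_nonzero_nodes": int((np.abs(gt.A_memory).sum(axis=1) > 0).sum()),
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2))
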