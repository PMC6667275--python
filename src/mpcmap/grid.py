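"""Cortical-sheet stand-in: a rectangular grid of surface nodes per hemisphere.

The real analyses run on surface meshes; here each hemisphere is a regular
``n_pa x n_vd`` grid whose axis 0 runs posterior->anterior and axis 1 runs
ventral->dorsal.  Two rectangular sub-blocks play the roles of ventral
temporal cortex (VTC, source of the six connectivity seed parcels) and medial
parietal cortex (MPC, the parcellation target).  Node adjacency is the
4-neighbourhood, which is what all cluster operations use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: seed parcel labels: {posterior, middle, anterior} x {medial, lateral}
SEED_LABELS = {
    1: "posterior_medial",
    2: "middle_medial",
    3: "anterior_medial",
    4: "posterior_lateral",
    5: "middle_lateral",
    6: "anterior_lateral",
}
SEED_NAMES = {v: k for k, v in SEED_LABELS.items()}


@dataclass(frozen=True)
class CortexGrid:
    """One hemisphere's node grid.

    Nodes are indexed in row-major (flat) order: ``idx = pa * n_vd + vd``.
    Axis 0 (``pa``) is posterior->anterior; axis 1 (``vd``) is
    ventral->dorsal.
    """

    n_pa: int = 40
    n_vd: int = 30
    hemi: str = "L"

    def __post_init__(self) -> None:
        if self.n_pa < 2 or self.n_vd < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.hemi not in ("L", "R"):
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemi!r}")

    @property
    def n_nodes(self) -> int:
        return self.n_pa * self.n_vd

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_pa, self.n_vd)

    def coords(self) -> np.ndarray:
        """(n_nodes, 2) integer (pa, vd) coordinates in flat-index order."""
        pa, vd = np.meshgrid(
            np.arange(self.n_pa), np.arange(self.n_vd), indexing="ij"
        )
        return np.column_stack([pa.ravel(), vd.ravel()])

    def flat_index(self, pa: np.ndarray, vd: np.ndarray) -> np.ndarray:
        return np.asarray(pa) * self.n_vd + np.asarray(vd)

    def adjacency_pairs(self) -> np.ndarray:
        """(n_edges, 2) array of 4-neighbourhood edges, each edge once."""
        idx = np.arange(self.n_nodes).reshape(self.shape)
        right = np.column_stack([idx[:, :-1].ravel(), idx[:, 1:].ravel()])
        down = np.column_stack([idx[:-1, :].ravel(), idx[1:, :].ravel()])
        return np.vstack([right, down])

    def to_image(self, flat: np.ndarray) -> np.ndarray:
        """Reshape a flat node vector to the (n_pa, n_vd) grid image."""
        flat = np.asarray(flat)
        return flat.reshape(flat.shape[:-1] + self.shape)


def block_mask(grid: CortexGrid, pa: slice, vd: slice) -> np.ndarray:
    """Boolean flat mask for a rectangular block of the grid."""
    m = np.zeros(grid.shape, dtype=bool)
    m[pa, vd] = True
    return m.ravel()


# default block geometry (grid units); chosen so the two blocks are disjoint
# and MPC leaves a surround of null nodes on the sheet
DEFAULT_VTC_BLOCK = (slice(2, 26), slice(2, 10))
DEFAULT_MPC_BLOCK = (slice(8, 38), slice(14, 28))


@dataclass(frozen=True)
class SeedGeometry:
    """Six seed parcels partitioning the VTC block.

    The block is split into three posterior->anterior thirds and two
    medial/lateral halves (axis 1 of the block is treated as medial->lateral
    within VTC), giving the labels in :data:`SEED_LABELS`.
    """

    grid: CortexGrid
    labels: np.ndarray = field(repr=False)  # flat int array, 0 outside VTC

    @classmethod
    def default(cls, grid: CortexGrid,
                vtc_block: tuple[slice, slice] = DEFAULT_VTC_BLOCK) -> "SeedGeometry":
        pa_sl, vd_sl = vtc_block
        lab = np.zeros(grid.shape, dtype=int)
        pa0, pa1 = pa_sl.start, pa_sl.stop
        vd0, vd1 = vd_sl.start, vd_sl.stop
        if pa1 - pa0 < 3 or vd1 - vd0 < 2:
            raise ValueError("VTC block too small to hold a 3 x 2 parcel scheme")
        pa_edges = np.linspace(pa0, pa1, 4).round().astype(int)
        vd_mid = (vd0 + vd1) // 2
        for third in range(3):  # 0 posterior, 1 middle, 2 anterior
            rows = slice(pa_edges[third], pa_edges[third + 1])
            lab[rows, vd0:vd_mid] = third + 1          # medial: labels 1..3
            lab[rows, vd_mid:vd1] = third + 4          # lateral: labels 4..6
        return cls(grid=grid, labels=lab.ravel())

    def parcel_mask(self, label: int) -> np.ndarray:
        if label not in SEED_LABELS:
            raise ValueError(f"unknown seed label {label}")
        return self.labels == label

    def validate(self) -> None:
        present = set(np.unique(self.labels)) - {0}
        if present != set(SEED_LABELS):
            raise ValueError(f"seed parcels must be exactly labels 1..6, got {present}")
        for lab in SEED_LABELS:
            if not (self.labels == lab).any():
                raise ValueError(f"seed parcel {lab} is empty")
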