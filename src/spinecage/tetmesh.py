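"""Tetrahedral meshes built from labelled voxel grids.

Meshing uses the Freudenthal (Kuhn) subdivision: every labelled voxel cube is
split into six tetrahedra sharing the main diagonal, with the same
orientation in every cube so faces match across neighbours and the mesh is
conforming.  Element volumes are exactly 1/6 of the voxel volume, so the mesh
volume equals the labelled voxel volume by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Freudenthal 6-tet split of the unit cube; corners indexed by (dx, dy, dz)
# bit pattern.  All tets share the 0-7 diagonal.
_CUBE_TETS = np.array(
    [
        [0, 1, 7, 3],
        [0, 1, 5, 7],
        [0, 2, 3, 7],
        [0, 2, 7, 6],
        [0, 4, 7, 5],
        [0, 4, 6, 7],
    ],
    dtype=np.int64,
)
_CORNER_OFFSETS = np.array(
    [[(c >> 2) & 1, (c >> 1) & 1, c & 1] for c in range(8)], dtype=np.int64
)


@dataclass
class TetMesh:
    """4-node tetrahedral mesh with named sets and per-element material ids."""

    nodes: np.ndarray  # (n, 3) mm
    elements: np.ndarray  # (m, 4) int
    element_material: np.ndarray | None = None  # (m,) int material/label id
    element_sets: dict[str, np.ndarray] = field(default_factory=dict)
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, float)
        self.elements = np.asarray(self.elements, np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 3:
            raise ValueError("nodes must be (n, 3)")
        if self.elements.ndim != 2 or self.elements.shape[1] != 4:
            raise ValueError("elements must be (m, 4)")
        if self.elements.size and self.elements.max() >= len(self.nodes):
            raise ValueError("element connectivity references missing nodes")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    def element_coords(self) -> np.ndarray:
        return self.nodes[self.elements]  # (m, 4, 3)

    def volumes(self) -> np.ndarray:
        """Signed tet volumes (positive for correctly oriented elements)."""
        x = self.element_coords()
        d = x[:, 1:] - x[:, :1]
        return np.einsum("mi,mi->m", d[:, 0], np.cross(d[:, 1], d[:, 2])) / 6.0

    def centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def quality(self) -> dict:
        """Shape quality q = 6*sqrt(2)*V / l_rms^3 (1 for the regular tet)."""
        x = self.element_coords()
        pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
        l2 = np.stack(
            [((x[:, a] - x[:, b]) ** 2).sum(axis=1) for a, b in pairs], axis=1
        )
        lrms = np.sqrt(l2.mean(axis=1))
        q = 6.0 * np.sqrt(2.0) * np.abs(self.volumes()) / lrms**3
        return {
            "min": float(q.min()),
            "mean": float(q.mean()),
            "n_elements": int(self.n_elements),
        }

    def check(self) -> None:
        v = self.volumes()
        if v.size == 0:
            raise ValueError("mesh has no elements")
        if v.min() <= 0:
            raise ValueError("mesh contains non-positive element volumes")
        used = np.zeros(self.n_nodes, bool)
        used[self.elements.ravel()] = True
        if not used.all():
            raise ValueError("mesh contains orphan nodes")


def mesh_from_labels(
    labels: np.ndarray,
    spacing: tuple[float, float, float],
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TetMesh:
    """Conforming tet mesh of all non-zero voxels; material = voxel label."""
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError("labels must be 3-D")
    vox = np.argwhere(labels != 0)
    if len(vox) == 0:
        raise ValueError("label volume is empty; nothing to mesh")
    nx, ny, nz = labels.shape
    stride = np.array([(ny + 1) * (nz + 1), nz + 1, 1], dtype=np.int64)
    corner_ids = (vox[:, None, :] + _CORNER_OFFSETS[None, :, :]) @ stride  # (v, 8)
    elems = corner_ids[:, _CUBE_TETS].reshape(-1, 4)  # (6v, 4)
    mat = np.repeat(labels[labels != 0].astype(np.int64), 6)

    used, inverse = np.unique(elems, return_inverse=True)
    elems = inverse.reshape(-1, 4)
    gi = np.stack(
        [used // stride[0], (used % stride[0]) // stride[1], used % stride[1]],
        axis=1,
    )
    # voxel centres sit at index*spacing + origin, so cube corners are offset
    # by half a voxel
    nodes = (gi - 0.5) * np.asarray(spacing, float) + np.asarray(origin, float)
    return TetMesh(nodes=nodes, elements=elems, element_material=mat)


def resample_labels(
    labels: np.ndarray,
    spacing: tuple[float, float, float],
    target_edge_mm: float,
) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Nearest-neighbour resampling of an integer label grid to cubic voxels."""
    if target_edge_mm <= 0:
        raise ValueError("target_edge_mm must be positive")
    labels = np.asarray(labels)
    extent = [labels.shape[a] * spacing[a] for a in range(3)]
    new_shape = [max(1, int(round(extent[a] / target_edge_mm))) for a in range(3)]
    idx = [
        np.clip(
            np.floor(
                (np.arange(new_shape[a]) + 0.5) * target_edge_mm / spacing[a]
            ).astype(int),
            0,
            labels.shape[a] - 1,
        )
        for a in range(3)
    ]
    out = labels[np.ix_(idx[0], idx[1], idx[2])]
    return out, (target_edge_mm,) * 3


def make_tet_mesh(
    labels: np.ndarray,
    target_edge_mm: float,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0),
) -> TetMesh:
    """Mesh a label volume at a target element edge length.

    The label grid is first resampled (nearest neighbour) to cubic cells of
    edge ``target_edge_mm``, then each labelled cell is split into six tets.
    Raises with diagnostics if the region is empty or degenerates away during
    resampling.
    """
    coarse, new_spacing = resample_labels(labels, spacing, target_edge_mm)
    if not (coarse != 0).any():
        n_in = int((np.asarray(labels) != 0).sum())
        raise ValueError(
            f"meshing failed: {n_in} labelled voxels vanished when resampled to "
            f"{target_edge_mm} mm; use a finer target edge"
        )
    mesh = mesh_from_labels(coarse, new_spacing, origin)
    mesh.check()
    return mesh
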