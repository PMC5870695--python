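"""Geometry-adapted hexahedral meshing of labeled tissue volumes.

One 8-node hexahedral element is created per nonzero voxel, with nodes at the
voxel corners and shared nodes deduplicated.  With ``node_shift > 0`` the
nodes that touch a tissue interface are moved toward the interface to smooth
staircase artifacts: for each such node the minority label among the eight
incident voxels is found, and the node moves by ``node_shift`` times the
vector from the node to the centroid of the minority-label voxel centers.
Displacements are halved where necessary so that all element Jacobians stay
strictly positive.

Electrode alignment with the mesh surface (nearest surface node) also lives
here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from ._element import CORNER_OFFSETS, HEX_FACES, jacobian_determinants
from .volume import ConductivityTable, LabeledVolume

logger = logging.getLogger("hexfem")


@dataclass
class HexMesh:
    """Hexahedral FEM mesh: the discretized head volume conductor.

    Attributes
    ----------
    nodes : (N, 3) world-mm node coordinates.
    elements : (E, 8) node indices in the right-handed unit-cube corner order.
    element_label : (E,) integer tissue label per element.
    element_conductivity : (E,) conductivity in S/m per element.
    voxel_index : (E, 3) source voxel of each element (voxel-mesh provenance).
    voxel_size, origin : geometry of the generating raster.
    """

    nodes: np.ndarray
    elements: np.ndarray
    element_label: np.ndarray
    element_conductivity: np.ndarray
    voxel_index: np.ndarray | None = None
    voxel_size: np.ndarray | None = None
    origin: np.ndarray | None = None
    _surface_faces: np.ndarray | None = field(default=None, repr=False)
    _node_elem: sparse.csr_matrix | None = field(default=None, repr=False)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_coords(self, elems: np.ndarray | slice = slice(None)) -> np.ndarray:
        """Corner coordinates (..., 8, 3) of the selected elements."""
        return self.nodes[self.elements[elems]]

    # -- surface -----------------------------------------------------------
    def surface_faces(self) -> np.ndarray:
        """Boundary quads (F, 4): faces that belong to exactly one element."""
        if self._surface_faces is None:
            faces = self.elements[:, HEX_FACES].reshape(-1, 4)
            key = np.sort(faces, axis=1)
            order = np.lexsort(key.T[::-1])
            skey = key[order]
            new = np.ones(len(skey), dtype=bool)
            new[1:] = np.any(skey[1:] != skey[:-1], axis=1)
            # face is boundary iff its sorted key occurs exactly once
            grp = np.cumsum(new) - 1
            counts = np.bincount(grp)
            boundary = counts[grp] == 1
            self._surface_faces = faces[order[boundary]]
        return self._surface_faces

    def surface_nodes(self) -> np.ndarray:
        """Sorted indices of nodes lying on the mesh boundary."""
        return np.unique(self.surface_faces())

    def surface_area(self) -> float:
        """Total boundary area in mm^2 (each quad split into two triangles)."""
        f = self.surface_faces()
        p = self.nodes[f]  # (F, 4, 3)
        a1 = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )
        a2 = 0.5 * np.linalg.norm(
            np.cross(p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]), axis=1
        )
        return float(np.sum(a1 + a2))

    # -- adjacency ---------------------------------------------------------
    def node_to_elements(self) -> sparse.csr_matrix:
        """Sparse (N, E) incidence matrix of nodes to elements."""
        if self._node_elem is None:
            e = np.repeat(np.arange(self.n_elements), 8)
            n = self.elements.ravel()
            self._node_elem = sparse.csr_matrix(
                (np.ones(len(n), dtype=np.int8), (n, e)),
                shape=(self.n_nodes, self.n_elements),
            )
        return self._node_elem

    def elements_of_node(self, node: int) -> np.ndarray:
        m = self.node_to_elements()
        return m.indices[m.indptr[node] : m.indptr[node + 1]]

    def centroid(self) -> np.ndarray:
        return self.nodes.mean(axis=0)

    # -- point location (voxel-derived meshes) -----------------------------
    def elements_at(self, points: np.ndarray) -> np.ndarray:
        """Element index containing each point, -1 where outside the mesh.

        Uses the generating voxel raster; points in a boundary element whose
        nodes were shift-adapted are resolved by their voxel, which is exact
        for interior points and nearest-voxel for points on the boundary.
        """
        if self.voxel_index is None or self.voxel_size is None:
            raise ValueError("mesh carries no voxel provenance")
        lookup = getattr(self, "_voxel_lookup", None)
        if lookup is None:
            dims = self.voxel_index.max(axis=0) + 1
            flat = np.ravel_multi_index(tuple(self.voxel_index.T), tuple(dims))
            order = np.argsort(flat)
            lookup = (dims, flat[order], order)
            self._voxel_lookup = lookup  # type: ignore[attr-defined]
        dims, flat_sorted, order = lookup
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vox = np.floor((pts - self.origin) / self.voxel_size).astype(np.int64)
        ok = np.all((vox >= 0) & (vox < dims), axis=1)
        vox_c = np.clip(vox, 0, dims - 1)
        f = np.ravel_multi_index(tuple(vox_c.T), tuple(dims))
        pos = np.searchsorted(flat_sorted, f)
        pos_c = np.minimum(pos, len(flat_sorted) - 1)
        found = flat_sorted[pos_c] == f
        out = np.where(ok & found, order[pos_c], -1)
        return out

    def element_at(self, point: np.ndarray) -> int:
        el = int(self.elements_at(np.asarray(point, dtype=float).reshape(1, 3))[0])
        if el < 0:
            raise ValueError("point outside mesh")
        return el


@dataclass
class ElectrodeSet:
    """EEG electrodes: labels, raw positions and surface-node assignment."""

    labels: list[str]
    positions: np.ndarray  # (S, 3) mm
    node_index: np.ndarray | None = None  # (S,) after projection

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("electrode labels must be unique")
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.labels) != self.positions.shape[0]:
            raise ValueError("labels/positions length mismatch")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)


def build_hex_mesh(
    vol: LabeledVolume,
    node_shift: float = 0.3,
    conductivities: ConductivityTable | None = None,
) -> HexMesh:
    """Mesh every nonzero voxel of ``vol`` into a hexahedral element.

    Parameters
    ----------
    node_shift : fraction in [0, 0.49).  0 gives the axis-aligned voxel grid;
        positive values move interface nodes toward the smoothed tissue
        boundary (geometry adaptation).
    conductivities : table assigning sigma (S/m) to every nonzero label.
    """
    if not (0.0 <= node_shift < 0.5):
        raise ValueError("node_shift must lie in [0, 0.49]")
    vol.validate(conductivities)

    vox = np.argwhere(vol.data > 0)  # (E, 3)
    labels = vol.data[vox[:, 0], vox[:, 1], vox[:, 2]].astype(np.int64)

    dims = np.asarray(vol.shape, dtype=np.int64) + 1  # node lattice dims
    corner_lattice = vox[:, None, :] + CORNER_OFFSETS[None, :, :]  # (E, 8, 3)
    flat = np.ravel_multi_index(
        (corner_lattice[..., 0], corner_lattice[..., 1], corner_lattice[..., 2]), dims
    )
    uniq, inverse = np.unique(flat, return_inverse=True)
    elements = inverse.reshape(-1, 8).astype(np.int64)
    lattice = np.stack(np.unravel_index(uniq, dims), axis=1)  # (N, 3)
    nodes = vol.origin + lattice * vol.voxel_size

    if conductivities is not None:
        sig = conductivities.as_array(int(labels.max()))[labels]
    else:
        sig = np.ones(len(labels))

    mesh = HexMesh(
        nodes=nodes,
        elements=elements,
        element_label=labels,
        element_conductivity=sig,
        voxel_index=vox,
        voxel_size=vol.voxel_size.copy(),
        origin=vol.origin.copy(),
    )

    if node_shift > 0.0:
        _apply_node_shift(mesh, vol, lattice, node_shift)

    return mesh


def _apply_node_shift(
    mesh: HexMesh, vol: LabeledVolume, lattice: np.ndarray, node_shift: float
) -> None:
    """Shift interface nodes toward the minority-label voxel centroid (in place)."""
    padded = np.pad(vol.data, 1, mode="constant", constant_values=0)
    # the 8 voxels incident to node (i,j,k) are padded[i..i+1, j..j+1, k..k+1]
    cells = np.empty((lattice.shape[0], 8), dtype=padded.dtype)
    for c, off in enumerate(CORNER_OFFSETS):
        idx = lattice + off[None, :]  # padded-space voxel index
        cells[:, c] = padded[idx[:, 0], idx[:, 1], idx[:, 2]]

    uniq_labels = np.unique(cells)
    counts = np.stack([(cells == lab).sum(axis=1) for lab in uniq_labels], axis=1)
    present = counts > 0
    n_present = present.sum(axis=1)
    boundary = n_present >= 2

    cnt = np.where(present, counts, np.iinfo(np.int64).max)
    min_cnt = cnt.min(axis=1)
    strict = (cnt == min_cnt[:, None]).sum(axis=1) == 1
    movable = boundary & strict
    minority_col = cnt.argmin(axis=1)
    minority_label = uniq_labels[minority_col]

    # centroid offset of minority voxels relative to the node, in voxel units:
    # incident voxel centers sit at the 8 half-step sign patterns around the node
    sign_off = (CORNER_OFFSETS - 0.5)[None, :, :]  # (1, 8, 3)
    sel = cells == minority_label[:, None]
    nsel = sel.sum(axis=1)
    nsel_safe = np.maximum(nsel, 1)
    centroid_off = (sel[:, :, None] * sign_off).sum(axis=1) / nsel_safe[:, None]
    disp = node_shift * centroid_off * vol.voxel_size[None, :]
    disp[~movable] = 0.0

    # clip displacements until all Jacobians are strictly positive
    base = mesh.nodes.copy()
    scale = np.ones(len(base))
    for _ in range(30):
        mesh.nodes = base + scale[:, None] * disp
        dets = jacobian_determinants(mesh.element_coords())
        bad = np.min(dets, axis=1) <= 1e-12 * float(np.prod(vol.voxel_size))
        if not bad.any():
            break
        bad_nodes = np.unique(mesh.elements[bad])
        scale[bad_nodes] *= 0.5
        logger.debug("node shift: halving displacement of %d nodes", len(bad_nodes))
    else:
        raise RuntimeError("node shift could not preserve positive Jacobians")
    mesh._surface_faces = None


def project_electrodes(mesh: HexMesh, electrodes: ElectrodeSet) -> ElectrodeSet:
    """Assign each electrode the nearest mesh surface node.

    Ties in distance break toward the lowest node index.  Positions are kept
    as given; only ``node_index`` is filled in.
    """
    surf = mesh.surface_nodes()  # sorted ascending
    if surf.size == 0:
        raise RuntimeError("mesh has no surface nodes")
    pts = mesh.nodes[surf]
    d2 = (
        np.sum(electrodes.positions**2, axis=1)[:, None]
        - 2.0 * electrodes.positions @ pts.T
        + np.sum(pts**2, axis=1)[None, :]
    )
    # argmin returns the first minimizer; surf is sorted, so ties -> lowest index
    nearest = surf[np.argmin(d2, axis=1)]
    return ElectrodeSet(
        labels=list(electrodes.labels),
        positions=electrodes.positions.copy(),
        node_index=nearest.astype(np.int64),
    )
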