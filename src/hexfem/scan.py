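"""Gray-matter source spaces and the goal-function single-dipole scan.

A regular grid of candidate positions is laid over the mesh bounding box; a
candidate is admissible when the mesh node nearest to it touches only
gray-matter elements, so the St. Venant patch stays inside the compartment.
Source orientations follow the normal constraint: the normalized gradient of
the distance transform to the white-matter compartment when one exists
(discrete analogue of "orthogonal to the white-matter surface"), radially
outward otherwise.

The dipole scan fits, at every admissible position, the least-squares moment
of the measured topography against the 3-column gain block and reports the
goodness of fit

    GoF = 1 - ||data - L_k m||^2 / ||data||^2,

taking the maximizer (ties break to the lowest position index).
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .fem import Leadfield
from .mesh import HexMesh

logger = logging.getLogger("hexfem")


@dataclass
class SourceSpace:
    """Candidate dipole positions with admissibility flags and orientations."""

    positions: np.ndarray  # (n, 3) mm
    admissible: np.ndarray  # (n,) bool
    orientations: np.ndarray | None = None  # (n, 3) unit vectors

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        self.admissible = np.asarray(self.admissible, dtype=bool).ravel()
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float).reshape(-1, 3)

    @property
    def admissible_positions(self) -> np.ndarray:
        return self.positions[self.admissible]

    @property
    def admissible_orientations(self) -> np.ndarray | None:
        if self.orientations is None:
            return None
        return self.orientations[self.admissible]


@dataclass
class MomentFit:
    moment: np.ndarray
    gof: float
    rank_deficient: bool = False


@dataclass
class ScanResult:
    """Outcome of the goal-function scan."""

    best_index: int
    position: np.ndarray
    moment: np.ndarray
    gof: float
    gof_per_position: np.ndarray
    rank_deficient: bool = False


def build_source_grid(
    mesh: HexMesh,
    resolution: float,
    gm_label: int,
    wm_label: int | None = None,
) -> SourceSpace:
    """Regular source grid with the gray-matter admissibility rule.

    Grid points cover the node bounding box at the given spacing (offset by
    half a step).  A point is admissible iff every element adjacent to its
    nearest mesh node carries ``gm_label``.
    """
    if gm_label not in mesh.element_label:
        raise ValueError(f"gray-matter label {gm_label} absent from mesh")
    lo = mesh.nodes.min(axis=0)
    hi = mesh.nodes.max(axis=0)
    axes = [np.arange(lo[d] + resolution / 2, hi[d], resolution) for d in range(3)]
    if any(len(a) == 0 for a in axes):
        axes = [a if len(a) else np.array([(lo[d] + hi[d]) / 2]) for d, a in enumerate(axes)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    from scipy.spatial import cKDTree

    tree = cKDTree(mesh.nodes)
    _, nearest = tree.query(grid)

    incidence = mesh.node_to_elements()
    is_gm = mesh.element_label == gm_label
    # node is interior-gray iff all incident elements are gray
    n_inc = np.diff(incidence.indptr)
    n_gm = incidence @ is_gm.astype(np.int64)
    node_ok = (n_inc > 0) & (n_gm == n_inc)
    admissible = node_ok[nearest]
    # ... and the position itself must fall in a gray-matter element
    if mesh.voxel_index is not None:
        els = mesh.elements_at(grid)
        admissible &= (els >= 0) & (mesh.element_label[np.maximum(els, 0)] == gm_label)
    if not admissible.any():
        warnings.warn("source grid has no admissible positions", stacklevel=2)

    orientations = _orientations(mesh, grid, wm_label)
    logger.info(
        "source grid: %d/%d admissible positions at %.1f mm",
        int(admissible.sum()),
        len(grid),
        resolution,
    )
    return SourceSpace(positions=grid, admissible=admissible, orientations=orientations)


def _orientations(mesh: HexMesh, grid: np.ndarray, wm_label: int | None) -> np.ndarray:
    if wm_label is not None and wm_label in mesh.element_label and mesh.voxel_index is not None:
        dims = tuple(mesh.voxel_index.max(axis=0) + 1)
        wm = np.zeros(dims, dtype=bool)
        sel = mesh.element_label == wm_label
        vi = mesh.voxel_index[sel]
        wm[vi[:, 0], vi[:, 1], vi[:, 2]] = True
        dist = ndimage.distance_transform_edt(~wm, sampling=mesh.voxel_size)
        gx, gy, gz = np.gradient(dist, *mesh.voxel_size)
        idx = np.round((grid - mesh.origin) / mesh.voxel_size - 0.5).astype(np.int64)
        idx = np.clip(idx, 0, np.asarray(dims) - 1)
        g = np.stack(
            [a[idx[:, 0], idx[:, 1], idx[:, 2]] for a in (gx, gy, gz)], axis=1
        )
        norms = np.linalg.norm(g, axis=1)
        fallback = grid - mesh.centroid()
        fb_norm = np.linalg.norm(fallback, axis=1)
        fallback = np.where(
            fb_norm[:, None] > 1e-12, fallback / np.maximum(fb_norm, 1e-12)[:, None],
            np.array([0.0, 0.0, 1.0]),
        )
        out = np.where(norms[:, None] > 1e-12, g / np.maximum(norms, 1e-12)[:, None], fallback)
        return out
    # radial from the mesh centroid (sphere phantoms)
    c = mesh.centroid()
    v = grid - c
    n = np.linalg.norm(v, axis=1)
    out = np.where(n[:, None] > 1e-12, v / np.maximum(n, 1e-12)[:, None], np.array([0.0, 0.0, 1.0]))
    return out


def fit_moment(gain: np.ndarray, data: np.ndarray) -> MomentFit:
    """Least-squares dipole moment and goodness of fit for one position.

    GoF = 1 - relative residual variance, clipped into [0, 1].  Rank-deficient
    gains yield the minimum-norm moment with ``rank_deficient`` set.
    """
    gain = np.asarray(gain, dtype=float)
    data = np.asarray(data, dtype=float).ravel()
    d2 = float(data @ data)
    if d2 == 0.0:
        raise ValueError("data vector is zero")
    m, _, rank, _ = np.linalg.lstsq(gain, data, rcond=None)
    resid = data - gain @ m
    gof = 1.0 - float(resid @ resid) / d2
    return MomentFit(
        moment=m, gof=float(np.clip(gof, 0.0, 1.0)), rank_deficient=rank < gain.shape[1]
    )


def dipole_scan(leadfield: Leadfield, data: np.ndarray) -> ScanResult:
    """Goal-function scan: best-fitting single dipole over the source space."""
    if leadfield.n_sources == 0:
        raise ValueError("empty source space")
    data = np.asarray(data, dtype=float).ravel()
    if leadfield.average_referenced:
        data = data - data.mean()
    gofs = np.empty(leadfield.n_sources)
    fits: list[MomentFit] = []
    for k in range(leadfield.n_sources):
        fit = fit_moment(leadfield.gain(k), data)
        gofs[k] = fit.gof
        fits.append(fit)
    best = int(np.argmax(gofs))  # ties -> lowest index
    return ScanResult(
        best_index=best,
        position=leadfield.positions[best].copy(),
        moment=fits[best].moment,
        gof=float(gofs[best]),
        gof_per_position=gofs,
        rank_deficient=fits[best].rank_deficient,
    )
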