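"""Labeled tissue volumes: the raster input of the meshing stage.

A :class:`LabeledVolume` is a 3D array of non-negative integer tissue labels
(0 = background) together with its voxel geometry.  Operations on the raster
level live here: conductivity lookup, majority-vote downsampling, minimum
skull-thickness enforcement against current-leakage artifacts, and the radial
run-length measurement used to verify the enforced thickness.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

logger = logging.getLogger("hexfem")

#: Standard isotropic tissue conductivities in S/m (common literature values).
DEFAULT_CONDUCTIVITIES = {
    "skin": 0.43,
    "skull": 0.01,
    "csf": 1.79,
    "gray": 0.33,
    "white": 0.14,
}

#: Default label coding used by the phantoms: innermost compartment first.
DEFAULT_LABELS = {"gray": 1, "csf": 2, "skull": 3, "skin": 4, "white": 5}


@dataclass(frozen=True)
class ConductivityTable:
    """Mapping tissue label -> scalar conductivity in S/m (all values > 0)."""

    values: Mapping[int, float]

    def __post_init__(self) -> None:
        vals = {int(k): float(v) for k, v in self.values.items()}
        for lab, sig in vals.items():
            if not sig > 0.0:
                raise ValueError(f"conductivity for label {lab} must be > 0, got {sig}")
            if lab < 0:
                raise ValueError("tissue labels must be non-negative")
        object.__setattr__(self, "values", vals)

    @classmethod
    def default_head(cls) -> "ConductivityTable":
        """Five-compartment table under the default phantom label coding."""
        return cls(
            {
                DEFAULT_LABELS["gray"]: DEFAULT_CONDUCTIVITIES["gray"],
                DEFAULT_LABELS["csf"]: DEFAULT_CONDUCTIVITIES["csf"],
                DEFAULT_LABELS["skull"]: DEFAULT_CONDUCTIVITIES["skull"],
                DEFAULT_LABELS["skin"]: DEFAULT_CONDUCTIVITIES["skin"],
                DEFAULT_LABELS["white"]: DEFAULT_CONDUCTIVITIES["white"],
            }
        )

    def __getitem__(self, label: int) -> float:
        return self.values[int(label)]

    def __contains__(self, label: int) -> bool:
        return int(label) in self.values

    @property
    def labels(self) -> list[int]:
        return sorted(self.values)

    def as_array(self, max_label: int | None = None) -> np.ndarray:
        """Dense lookup array sigma[label]; unknown labels map to nan."""
        m = max(self.labels) if max_label is None else max_label
        out = np.full(m + 1, np.nan)
        for lab, sig in self.values.items():
            if lab <= m:
                out[lab] = sig
        return out


@dataclass
class LabeledVolume:
    """3D integer tissue raster with voxel geometry.

    Attributes
    ----------
    data : (nx, ny, nz) int array of non-negative labels, 0 = background.
    voxel_size : (3,) voxel edge lengths in mm, all > 0.
    origin : (3,) world-mm position of the corner of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.ascontiguousarray(np.asarray(self.data))
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("volume data must be an integer array")
        if self.data.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size = np.broadcast_to(
            np.asarray(self.voxel_size, dtype=float), (3,)
        ).copy()
        if not np.all(self.voxel_size > 0):
            raise ValueError("voxel_size must be > 0 on each axis")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3).copy()

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def labels_present(self) -> np.ndarray:
        return np.unique(self.data)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """World-mm centers of voxels given integer index triples (..., 3)."""
        return self.origin + (np.asarray(indices, dtype=float) + 0.5) * self.voxel_size

    @property
    def center(self) -> np.ndarray:
        """World-mm centroid of the nonzero (tissue) voxels."""
        idx = np.argwhere(self.data > 0)
        if idx.size == 0:
            return self.origin + 0.5 * self.voxel_size * np.asarray(self.shape)
        return self.voxel_centers(idx).mean(axis=0)

    def validate(self, conductivities: ConductivityTable | None = None) -> None:
        """Check the meshing preconditions; raise ValueError on violation."""
        if not np.any(self.data > 0):
            raise ValueError("no elements: volume has no nonzero voxels")
        if conductivities is not None:
            for lab in self.labels_present:
                if lab != 0 and lab not in conductivities:
                    raise ValueError(f"label not in conductivity table: {lab}")


def downsample_volume(vol: LabeledVolume, factor: int) -> LabeledVolume:
    """Coarsen a labeled volume by majority vote over ``factor**3`` blocks.

    Dimensions not divisible by ``factor`` are zero-padded; ties in the vote
    resolve to the smallest label, so an all-background block stays background.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return LabeledVolume(vol.data.copy(), vol.voxel_size.copy(), vol.origin.copy())
    data = vol.data
    pad = [(0, (-s) % factor) for s in data.shape]
    if any(p[1] for p in pad):
        data = np.pad(data, pad, mode="constant", constant_values=0)
    nb = tuple(s // factor for s in data.shape)
    blocks = data.reshape(nb[0], factor, nb[1], factor, nb[2], factor)
    blocks = blocks.transpose(0, 2, 4, 1, 3, 5).reshape(*nb, factor**3)
    nlab = int(data.max()) + 1
    counts = np.zeros((*nb, nlab), dtype=np.int32)
    # count labels per block; label axis is small so loop over it
    for lab in range(nlab):
        counts[..., lab] = (blocks == lab).sum(axis=3)
    out = counts.argmax(axis=3).astype(vol.data.dtype)  # ties -> smallest label
    return LabeledVolume(out, vol.voxel_size * factor, vol.origin.copy())


def _inside_mask(data: np.ndarray, skull_label: int) -> np.ndarray:
    """Voxels enclosed by the skull shell: non-skull regions not connected to
    the array border through non-skull voxels (6-connectivity)."""
    non_skull = data != skull_label
    lab, _ = ndimage.label(non_skull)
    border = np.zeros(data.shape, dtype=bool)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    outside_ids = np.unique(lab[border & non_skull])
    outside_ids = outside_ids[outside_ids > 0]
    inside = non_skull & ~np.isin(lab, outside_ids)
    return inside


def enforce_min_skull_thickness(
    vol: LabeledVolume, skull_label: int, min_mm: float
) -> LabeledVolume:
    """Guarantee a minimum radial skull thickness.

    Any voxel outside the skull-enclosed region (skin or background side) whose
    Euclidean distance to the enclosed compartments is at most
    ``min_mm + sqrt(3) * voxel`` is relabeled skull.  The distance transform
    measures voxel centers, while a ray can enter/leave a voxel cell up to
    half a diagonal (sqrt(3)/2 voxel) away from its center at each end of the
    skull band; the sqrt(3)-voxel margin therefore guarantees the radial
    run-length bound along arbitrary ray directions, at the cost of a slightly
    thicker-than-requested shell.  Labels inside the skull are never touched.
    """
    skull_label = int(skull_label)
    if skull_label not in vol.labels_present:
        raise ValueError(f"skull label {skull_label} absent from volume")
    inside = _inside_mask(vol.data, skull_label)
    if not inside.any():
        raise ValueError("skull shell encloses no interior compartment")
    dist = ndimage.distance_transform_edt(~inside, sampling=vol.voxel_size)
    thr = float(min_mm) + np.sqrt(3.0) * float(vol.voxel_size.max())
    convert = (~inside) & (vol.data != skull_label) & (dist <= thr)
    if not convert.any():
        return LabeledVolume(vol.data.copy(), vol.voxel_size.copy(), vol.origin.copy())
    out = vol.data.copy()
    out[convert] = skull_label
    logger.info(
        "skull thickness enforcement: converted %d voxels to skull", int(convert.sum())
    )
    return LabeledVolume(out, vol.voxel_size.copy(), vol.origin.copy())


def radial_skull_runlength(
    vol: LabeledVolume,
    skull_label: int,
    n_rays: int = 1000,
    seed: int | None = 0,
    step_mm: float | None = None,
) -> np.ndarray:
    """Contiguous skull run-length (mm) along radial rays from the volume center.

    Rays are uniformly distributed directions (seeded); labels are sampled at
    ``step_mm`` (default: quarter of the smallest voxel) by nearest voxel.  The
    longest contiguous skull run per ray is returned, one value per ray.
    """
    if step_mm is None:
        step_mm = 0.25 * float(vol.voxel_size.min())
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_rays, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    center = vol.center
    extent = np.asarray(vol.shape) * vol.voxel_size
    r_max = float(np.linalg.norm(extent))
    t = np.arange(0.0, r_max, step_mm)
    pts = center[None, None, :] + t[None, :, None] * v[:, None, :]  # (R, T, 3)
    idx = np.floor((pts - vol.origin) / vol.voxel_size).astype(np.int64)
    valid = np.all((idx >= 0) & (idx < np.asarray(vol.shape)), axis=2)
    idx_c = np.clip(idx, 0, np.asarray(vol.shape) - 1)
    labels = vol.data[idx_c[..., 0], idx_c[..., 1], idx_c[..., 2]]
    hit = (labels == skull_label) & valid  # (R, T)
    # longest run of True per ray
    run = np.zeros(n_rays)
    padded = np.zeros((n_rays, hit.shape[1] + 2), dtype=np.int8)
    padded[:, 1:-1] = hit
    d = np.diff(padded, axis=1)
    for r in range(n_rays):
        starts = np.flatnonzero(d[r] == 1)
        ends = np.flatnonzero(d[r] == -1)
        run[r] = (ends - starts).max(initial=0) * step_mm
    return run
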