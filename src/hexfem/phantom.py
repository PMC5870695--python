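"""Concentric-sphere phantoms: synthetic labeled volumes and electrode caps.

The phantom stands in for a segmented MRI so the whole pipeline runs without
any external data: voxel labels follow the innermost shell whose radius
contains the voxel center, and a deterministic spiral places the electrode
cap on the outer sphere.  All randomness (the spiral's azimuthal phase) flows
through the recorded seed.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import ElectrodeSet
from .volume import LabeledVolume

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class PhantomSpec:
    """Concentric-sphere phantom description.

    radii : outer radius of each shell in mm, strictly increasing
            (innermost compartment first).
    labels : integer label per shell (same order).
    voxel_size : isotropic voxel edge in mm.
    margin_voxels : background margin around the outer shell.
    n_electrodes, cap_deg : electrode count and cap coverage angle from the
            +z pole (180 = whole sphere).
    seed : seeds the electrode spiral phase; recorded in outputs.
    """

    radii: tuple[float, ...]
    labels: tuple[int, ...] = ()
    voxel_size: float = 1.0
    margin_voxels: int = 2
    n_electrodes: int = 33
    cap_deg: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.labels:
            self.labels = tuple(range(1, len(self.radii) + 1))
        if len(self.labels) != len(self.radii):
            raise ValueError("labels/radii length mismatch")
        r = np.asarray(self.radii, dtype=float)
        if np.any(np.diff(r) <= 0) or np.any(r <= 0):
            raise ValueError("radii must be positive and strictly increasing")
        if any(l <= 0 for l in self.labels):
            raise ValueError("shell labels must be positive")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.n_electrodes < 2:
            raise ValueError("need at least two electrodes")


def generate_sphere_phantom(spec: PhantomSpec) -> tuple[LabeledVolume, ElectrodeSet]:
    """Build the labeled sphere volume and the raw (on-sphere) electrode cap.

    The grid is centered on the world origin; voxel label = label of the
    innermost shell whose radius is >= the voxel-center distance.  Output is
    fully reproducible from the spec (including seed).
    """
    h = float(spec.voxel_size)
    R = float(spec.radii[-1])
    half = int(np.ceil(R / h)) + int(spec.margin_voxels)
    n = 2 * half
    origin = -np.full(3, half * h)
    ax = origin[0] + (np.arange(n) + 0.5) * h
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    dist = np.sqrt(X**2 + Y**2 + Z**2)
    data = np.zeros((n, n, n), dtype=np.int16)
    for r, lab in zip(reversed(spec.radii), reversed(spec.labels)):
        data[dist <= r] = lab
    vol = LabeledVolume(data, voxel_size=np.full(3, h), origin=origin)

    electrodes = spherical_cap_electrodes(
        radius=R,
        n_electrodes=spec.n_electrodes,
        cap_deg=spec.cap_deg,
        seed=spec.seed,
    )
    return vol, electrodes


def spherical_cap_electrodes(
    radius: float,
    n_electrodes: int,
    cap_deg: float = 150.0,
    seed: int = 0,
    center: np.ndarray | None = None,
) -> ElectrodeSet:
    """Deterministic spiral electrode cap around the +z pole.

    Polar angles spread uniformly in cos(theta) over the cap; azimuths follow
    the golden-angle spiral with a seed-derived phase.
    """
    if center is None:
        center = np.zeros(3)
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(n_electrodes)
    cos_cap = np.cos(np.deg2rad(cap_deg))
    cos_t = 1.0 - (1.0 - cos_cap) * (i + 0.5) / n_electrodes
    sin_t = np.sqrt(1.0 - cos_t**2)
    phi = phase + i * _GOLDEN_ANGLE
    pos = center + radius * np.stack(
        [sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t], axis=1
    )
    labels = [f"E{k + 1:03d}" for k in range(n_electrodes)]
    return ElectrodeSet(labels=labels, positions=pos)
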