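"""File I/O: NIfTI and plain-text rasters, electrode files, HDF5 containers
for meshes / transfer matrices / leadfields, and YAML/JSON configs.

HDF5 datasets are written with ``track_times=False`` so identical inputs
produce byte-identical files (reproducibility of pipeline reruns).
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .fem import Leadfield, TransferMatrix
from .mesh import ElectrodeSet, HexMesh
from .volume import LabeledVolume

_RASTER_MAGIC = "# hexfem raster v1"


# ---------------------------------------------------------------------------
# labeled volumes
# ---------------------------------------------------------------------------

def save_nifti(vol: LabeledVolume, path: str | Path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(vol.voxel_size)
    # NIfTI convention: affine maps voxel index -> mm position of the center
    affine[:3, 3] = vol.origin + 0.5 * vol.voxel_size
    img = nib.Nifti1Image(vol.data.astype(np.int16), affine)
    nib.save(img, str(path))


def load_nifti(path: str | Path) -> LabeledVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError("NIfTI volume does not hold integer labels")
        data = rounded.astype(np.int32)
    aff = img.affine
    if not np.allclose(aff[:3, :3], np.diag(np.diag(aff[:3, :3])), atol=1e-9):
        raise ValueError("only axis-aligned NIfTI affines are supported")
    voxel = np.diag(aff[:3, :3]).copy()
    if np.any(voxel <= 0):
        raise ValueError("NIfTI affine must have positive diagonal voxel sizes")
    origin = aff[:3, 3] - 0.5 * voxel
    return LabeledVolume(np.ascontiguousarray(data), voxel, origin)


def save_raster(vol: LabeledVolume, path: str | Path) -> None:
    """Tiny plain-text raster for test fixtures: header lines + C-order labels."""
    with open(path, "w") as fh:
        fh.write(_RASTER_MAGIC + "\n")
        fh.write("shape: %d %d %d\n" % vol.shape)
        fh.write("voxel_size: %.17g %.17g %.17g\n" % tuple(vol.voxel_size))
        fh.write("origin: %.17g %.17g %.17g\n" % tuple(vol.origin))
        flat = vol.data.ravel()
        for start in range(0, flat.size, 16):
            fh.write(" ".join(str(int(v)) for v in flat[start : start + 16]) + "\n")


def load_raster(path: str | Path) -> LabeledVolume:
    with open(path) as fh:
        magic = fh.readline().strip()
        if magic != _RASTER_MAGIC:
            raise ValueError(f"not a hexfem raster file: {path}")
        shape = tuple(int(v) for v in fh.readline().split(":")[1].split())
        voxel = np.array([float(v) for v in fh.readline().split(":")[1].split()])
        origin = np.array([float(v) for v in fh.readline().split(":")[1].split()])
        data = np.array(fh.read().split(), dtype=np.int32).reshape(shape)
    return LabeledVolume(data, voxel, origin)


# ---------------------------------------------------------------------------
# electrodes
# ---------------------------------------------------------------------------

def save_electrodes(electrodes: ElectrodeSet, path: str | Path) -> None:
    """ASCII electrode file: one 'label x y z' row per electrode, mm units."""
    with open(path, "w") as fh:
        for lab, pos in zip(electrodes.labels, electrodes.positions):
            fh.write(f"{lab} {pos[0]:.17g} {pos[1]:.17g} {pos[2]:.17g}\n")


def load_electrodes(path: str | Path) -> ElectrodeSet:
    labels, positions = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"bad electrode row: {line!r}")
            labels.append(parts[0])
            positions.append([float(v) for v in parts[1:]])
    return ElectrodeSet(labels=labels, positions=np.asarray(positions))


# ---------------------------------------------------------------------------
# HDF5 containers
# ---------------------------------------------------------------------------

def _write(group: h5py.Group, name: str, data) -> None:
    group.create_dataset(name, data=data, track_times=False)


def save_mesh(mesh: HexMesh, path: str | Path, provenance: dict | None = None) -> None:
    with h5py.File(path, "w", track_order=True) as fh:
        _write(fh, "nodes", mesh.nodes)
        _write(fh, "elements", mesh.elements)
        _write(fh, "element_label", mesh.element_label)
        _write(fh, "element_conductivity", mesh.element_conductivity)
        if mesh.voxel_index is not None:
            _write(fh, "voxel_index", mesh.voxel_index)
        if mesh.voxel_size is not None:
            fh.attrs["voxel_size"] = mesh.voxel_size
        if mesh.origin is not None:
            fh.attrs["origin"] = mesh.origin
        if provenance:
            fh.attrs["provenance"] = json.dumps(provenance, sort_keys=True)


def load_mesh(path: str | Path) -> HexMesh:
    with h5py.File(path, "r") as fh:
        return HexMesh(
            nodes=fh["nodes"][()],
            elements=fh["elements"][()],
            element_label=fh["element_label"][()],
            element_conductivity=fh["element_conductivity"][()],
            voxel_index=fh["voxel_index"][()] if "voxel_index" in fh else None,
            voxel_size=fh.attrs.get("voxel_size"),
            origin=fh.attrs.get("origin"),
        )


def _write_electrodes(fh: h5py.File, electrodes: ElectrodeSet) -> None:
    _write(fh, "electrode_labels", np.array(electrodes.labels, dtype="S"))
    _write(fh, "electrode_positions", electrodes.positions)
    if electrodes.node_index is not None:
        _write(fh, "electrode_nodes", electrodes.node_index)


def _read_electrodes(fh: h5py.File) -> ElectrodeSet:
    return ElectrodeSet(
        labels=[s.decode() for s in fh["electrode_labels"][()]],
        positions=fh["electrode_positions"][()],
        node_index=fh["electrode_nodes"][()] if "electrode_nodes" in fh else None,
    )


def save_transfer(T: TransferMatrix, path: str | Path, provenance: dict | None = None) -> None:
    with h5py.File(path, "w", track_order=True) as fh:
        _write(fh, "transfer", T.matrix)
        _write_electrodes(fh, T.electrodes)
        fh.attrs["ref_index"] = T.ref_index
        if provenance:
            fh.attrs["provenance"] = json.dumps(provenance, sort_keys=True)


def load_transfer(path: str | Path) -> TransferMatrix:
    with h5py.File(path, "r") as fh:
        return TransferMatrix(
            matrix=fh["transfer"][()],
            electrodes=_read_electrodes(fh),
            ref_index=int(fh.attrs["ref_index"]),
        )


def save_leadfield(L: Leadfield, path: str | Path, provenance: dict | None = None) -> None:
    with h5py.File(path, "w", track_order=True) as fh:
        _write(fh, "leadfield", L.matrix)
        _write(fh, "positions", L.positions)
        _write(fh, "skipped", np.asarray(L.skipped, dtype=np.int64))
        _write_electrodes(fh, L.electrodes)
        fh.attrs["average_referenced"] = L.average_referenced
        if provenance:
            fh.attrs["provenance"] = json.dumps(provenance, sort_keys=True)


def load_leadfield(path: str | Path) -> Leadfield:
    with h5py.File(path, "r") as fh:
        return Leadfield(
            matrix=fh["leadfield"][()],
            positions=fh["positions"][()],
            electrodes=_read_electrodes(fh),
            average_referenced=bool(fh.attrs["average_referenced"]),
            skipped=[int(v) for v in fh["skipped"][()]],
        )


# ---------------------------------------------------------------------------
# configs and small tables
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_scan_data(path: str | Path) -> tuple[list[str], np.ndarray]:
    """TSV of electrode label + value rows -> (labels, values)."""
    labels, values = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace("\t", " ").split()
            labels.append(parts[0])
            values.append(float(parts[1]))
    return labels, np.asarray(values)
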