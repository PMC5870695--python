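"""End-to-end forward pipeline: segmented volume (or phantom) -> hexahedral
mesh -> stiffness -> transfer matrix -> source grid -> leadfield ->
(optional) dipole scan, each stage written to disk with provenance metadata
(config hash, package version, seed) and timed logging."""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .fem import assemble_stiffness, compute_leadfield, transfer_matrix
from .io import (
    load_config,
    load_electrodes,
    load_nifti,
    load_raster,
    load_scan_data,
    save_electrodes,
    save_leadfield,
    save_mesh,
    save_nifti,
    save_transfer,
)
from .mesh import build_hex_mesh, project_electrodes
from .phantom import PhantomSpec, generate_sphere_phantom
from .scan import build_source_grid, dipole_scan
from .volume import ConductivityTable, downsample_volume, enforce_min_skull_thickness

logger = logging.getLogger("hexfem")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run the forward pipeline described by ``config``; returns artifact paths.

    Config keys (YAML/JSON): ``phantom`` (radii/labels/voxel_size/...) or
    ``input`` (volume + electrodes paths), ``conductivities`` (label -> S/m),
    ``node_shift``, optional ``downsample``, optional ``min_skull``
    (skull_label + min_mm), ``source_grid`` (resolution + gm_label
    [+ wm_label]), optional ``reference_electrode``, ``solver`` (rel_tol),
    optional ``scan_data`` (TSV path), ``seed``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {
        "config_hash": _config_hash(config),
        "hexfem_version": __version__,
        "seed": int(config.get("seed", 0)),
    }
    artifacts: dict[str, Path] = {}
    timings: dict[str, float] = {}

    def stage(name):
        class _Timer:
            def __enter__(self_):
                logger.info("stage %s: start", name)
                self_.t0 = time.perf_counter()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                dt = time.perf_counter() - self_.t0
                timings[name] = dt
                if exc is not None:
                    logger.error("stage %s: FAILED after %.2fs (%s)", name, dt, exc)
                    raise StageError(name, exc) from exc
                logger.info("stage %s: done in %.2fs", name, dt)
                return False

        return _Timer()

    # ----- input volume + electrodes -------------------------------------
    with stage("segment-input"):
        if "phantom" in config:
            ph = dict(config["phantom"])
            ph.setdefault("seed", int(config.get("seed", 0)))
            ph["radii"] = tuple(ph["radii"])
            if "labels" in ph:
                ph["labels"] = tuple(ph["labels"])
            vol, electrodes = generate_sphere_phantom(PhantomSpec(**ph))
        else:
            inp = config["input"]
            vol_path = str(inp["volume"])
            vol = load_raster(vol_path) if vol_path.endswith(".txt") else load_nifti(vol_path)
            electrodes = load_electrodes(inp["electrodes"])
        if int(config.get("downsample", 1)) > 1:
            vol = downsample_volume(vol, int(config["downsample"]))
        table = ConductivityTable(
            {int(k): float(v) for k, v in config["conductivities"].items()}
        )
        vol.validate(table)
        if "min_skull" in config:
            ms = config["min_skull"]
            vol = enforce_min_skull_thickness(
                vol, int(ms["skull_label"]), float(ms["min_mm"])
            )
        p = outdir / "segmentation.nii"
        save_nifti(vol, p)
        artifacts["segmentation"] = p
        p = outdir / "electrodes_raw.txt"
        save_electrodes(electrodes, p)
        artifacts["electrodes_raw"] = p

    # ----- mesh -----------------------------------------------------------
    with stage("mesh"):
        mesh = build_hex_mesh(
            vol, node_shift=float(config.get("node_shift", 0.3)), conductivities=table
        )
        p = outdir / "mesh.h5"
        save_mesh(mesh, p, provenance)
        artifacts["mesh"] = p

    # ----- stiffness + electrodes + transfer ------------------------------
    with stage("stiffness"):
        A = assemble_stiffness(mesh)
    with stage("transfer"):
        proj = project_electrodes(mesh, electrodes)
        rel_tol = float(config.get("solver", {}).get("rel_tol", 1e-8))
        T = transfer_matrix(
            A, proj, ref_electrode=config.get("reference_electrode"), rel_tol=rel_tol
        )
        p = outdir / "transfer.h5"
        save_transfer(T, p, provenance)
        artifacts["transfer"] = p

    # ----- source grid + leadfield ----------------------------------------
    with stage("source-grid"):
        sg = config["source_grid"]
        space = build_source_grid(
            mesh,
            resolution=float(sg["resolution"]),
            gm_label=int(sg["gm_label"]),
            wm_label=int(sg["wm_label"]) if sg.get("wm_label") is not None else None,
        )
    with stage("leadfield"):
        gm = int(sg["gm_label"])
        L = compute_leadfield(
            T,
            mesh,
            space.admissible_positions,
            admissible_labels={gm},
            to_average_reference=bool(config.get("average_reference", True)),
        )
        p = outdir / "leadfield.h5"
        save_leadfield(L, p, provenance)
        artifacts["leadfield"] = p

    # ----- optional scan ---------------------------------------------------
    if config.get("scan_data"):
        with stage("scan"):
            labels, values = load_scan_data(config["scan_data"])
            order = [labels.index(lab) for lab in T.electrodes.labels]
            result = dipole_scan(L, values[order])
            p = outdir / "scan.json"
            p.write_text(
                json.dumps(
                    {
                        "best_index": result.best_index,
                        "position_mm": result.position.tolist(),
                        "moment": result.moment.tolist(),
                        "gof": result.gof,
                        "gof_per_position": result.gof_per_position.tolist(),
                        "provenance": provenance,
                    },
                    indent=1,
                )
            )
            artifacts["scan"] = p

    (outdir / "provenance.json").write_text(
        json.dumps({**provenance, "timings_s": timings}, indent=1, sort_keys=True)
    )
    artifacts["provenance"] = outdir / "provenance.json"
    return artifacts
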