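"""Phantom generation, container I/O round trips, the pipeline and the CLI."""
import hashlib
import json

import numpy as np
import pytest

import hexfem as hx
from hexfem import io as hio
from hexfem.pipeline import StageError, run_pipeline


class TestPhantom:
    def test_thresholding(self):
        spec = hx.PhantomSpec(radii=(8.0,), labels=(1,), voxel_size=1.0, seed=0)
        vol, _ = hx.generate_sphere_phantom(spec)
        ctr = vol.center
        # center voxel labeled, voxel at 10 mm not
        ijk = np.floor((np.zeros(3) - vol.origin) / vol.voxel_size).astype(int)
        assert vol.data[tuple(ijk)] == 1
        ijk10 = np.floor((np.array([9.5, 0, 0]) - vol.origin) / vol.voxel_size)
        assert vol.data[tuple(ijk10.astype(int))] == 0
        assert np.allclose(ctr, 0.0, atol=0.2)

    def test_volume_matches_analytic(self):
        spec = hx.PhantomSpec(radii=(20.0,), labels=(1,), voxel_size=1.0, seed=0)
        vol, _ = hx.generate_sphere_phantom(spec)
        v_meas = (vol.data == 1).sum() * float(np.prod(vol.voxel_size))
        v_true = 4.0 / 3.0 * np.pi * 20.0**3
        assert abs(v_meas - v_true) <= 0.05 * v_true

    def test_determinism(self):
        spec = hx.PhantomSpec(radii=(10.0, 12.0), labels=(1, 2), voxel_size=2.0,
                              n_electrodes=8, seed=42)
        v1, e1 = hx.generate_sphere_phantom(spec)
        v2, e2 = hx.generate_sphere_phantom(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(e1.positions, e2.positions)

    def test_electrodes_on_outer_sphere(self):
        spec = hx.PhantomSpec(radii=(10.0, 12.0), labels=(1, 2), voxel_size=2.0,
                              n_electrodes=20, cap_deg=140, seed=1)
        _, elec = hx.generate_sphere_phantom(spec)
        r = np.linalg.norm(elec.positions, axis=1)
        assert np.allclose(r, 12.0, atol=1e-12)
        cos_t = elec.positions[:, 2] / r
        assert cos_t.min() >= np.cos(np.deg2rad(140)) - 1e-12

    def test_validation(self):
        with pytest.raises(ValueError):
            hx.PhantomSpec(radii=(10.0, 9.0))
        with pytest.raises(ValueError):
            hx.PhantomSpec(radii=(10.0,), voxel_size=0.0)


class TestContainers:
    def test_volume_roundtrips(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = hx.LabeledVolume(
            rng.integers(0, 5, (4, 5, 6)).astype(np.int32),
            voxel_size=[1.0, 2.0, 0.5],
            origin=[-3.0, 0.0, 1.5],
        )
        for save, load, name in (
            (hio.save_nifti, hio.load_nifti, "v.nii"),
            (hio.save_raster, hio.load_raster, "v.txt"),
        ):
            p = tmp_path / name
            save(vol, p)
            back = load(p)
            assert np.array_equal(back.data, vol.data)
            assert np.allclose(back.voxel_size, vol.voxel_size)
            assert np.allclose(back.origin, vol.origin)

    def test_electrode_roundtrip(self, tmp_path):
        elec = hx.ElectrodeSet(["Cz", "Pz", "LO2"], np.arange(9.0).reshape(3, 3))
        p = tmp_path / "elec.txt"
        hio.save_electrodes(elec, p)
        back = hio.load_electrodes(p)
        assert back.labels == elec.labels
        assert np.array_equal(back.positions, elec.positions)

    def test_mesh_and_leadfield_roundtrip(self, tmp_path, four_shell_scan):
        mesh, L = four_shell_scan["mesh"], four_shell_scan["L"]
        pm = tmp_path / "mesh.h5"
        hio.save_mesh(mesh, pm, provenance={"seed": 3})
        back = hio.load_mesh(pm)
        assert np.array_equal(back.nodes, mesh.nodes)
        assert np.array_equal(back.elements, mesh.elements)
        assert np.array_equal(back.element_label, mesh.element_label)
        assert np.array_equal(back.element_conductivity, mesh.element_conductivity)

        pl = tmp_path / "lf.h5"
        hio.save_leadfield(L, pl)
        lback = hio.load_leadfield(pl)
        assert np.array_equal(lback.matrix, L.matrix)
        assert np.array_equal(lback.positions, L.positions)
        assert lback.electrodes.labels == L.electrodes.labels


def _pipeline_config(**overrides):
    cfg = {
        "seed": 5,
        "phantom": {
            "radii": [14.0, 16.0, 18.0, 21.0],
            "labels": [1, 2, 3, 4],
            "voxel_size": 2.0,
            "n_electrodes": 16,
            "cap_deg": 160,
        },
        "conductivities": {1: 0.33, 2: 1.79, 3: 0.01, 4: 0.43},
        "node_shift": 0.3,
        "source_grid": {"resolution": 5.0, "gm_label": 1},
    }
    cfg.update(overrides)
    return cfg


class TestPipeline:
    def test_end_to_end_recovers_planted_source(self, tmp_path):
        out1 = tmp_path / "run1"
        art = run_pipeline(_pipeline_config(), out1)
        for key in ("segmentation", "mesh", "transfer", "leadfield", "provenance"):
            assert art[key].exists()
        L = hio.load_leadfield(art["leadfield"])
        k = 4
        data = L.gain(k) @ np.array([1.0, -0.5, 0.25])
        tsv = tmp_path / "data.tsv"
        tsv.write_text(
            "".join(f"{lab}\t{v:.17g}\n" for lab, v in zip(L.electrodes.labels, data))
        )
        art2 = run_pipeline(
            _pipeline_config(scan_data=str(tsv)), tmp_path / "run_scan"
        )
        scan = json.loads(art2["scan"].read_text())
        assert scan["best_index"] == k
        assert scan["gof"] == pytest.approx(1.0, abs=1e-10)

    def test_rerun_is_byte_identical(self, tmp_path):
        a1 = run_pipeline(_pipeline_config(), tmp_path / "a")
        a2 = run_pipeline(_pipeline_config(), tmp_path / "b")
        for key in ("mesh", "leadfield", "transfer"):
            h1 = hashlib.sha256(a1[key].read_bytes()).hexdigest()
            h2 = hashlib.sha256(a2[key].read_bytes()).hexdigest()
            assert h1 == h2, key

    def test_missing_conductivity_aborts_with_label(self, tmp_path):
        cfg = _pipeline_config(conductivities={1: 0.33, 2: 1.79, 3: 0.01})
        with pytest.raises(StageError, match="label not in conductivity table: 4"):
            run_pipeline(cfg, tmp_path / "bad")


class TestCli:
    def test_phantom_mesh_forward_scan_chain(self, tmp_path):
        from click.testing import CliRunner

        from hexfem.cli import main

        runner = CliRunner()
        vol = tmp_path / "seg.nii"
        elec = tmp_path / "elec.txt"
        cond = tmp_path / "cond.json"
        cond.write_text(json.dumps({"1": 0.33}))
        r = runner.invoke(main, [
            "phantom", "--radii", "12", "--voxel", "2", "--electrodes", "10",
            "--seed", "2", "--out-volume", str(vol), "--out-electrodes", str(elec),
        ])
        assert r.exit_code == 0, r.output
        mesh = tmp_path / "mesh.h5"
        r = runner.invoke(main, [
            "mesh", "--in", str(vol), "--cond", str(cond), "--out", str(mesh),
        ])
        assert r.exit_code == 0, r.output
        lf = tmp_path / "lf.h5"
        r = runner.invoke(main, [
            "forward", "--mesh", str(mesh), "--elec", str(elec),
            "--grid-mm", "5", "--gm-label", "1", "--out", str(lf),
        ])
        assert r.exit_code == 0, r.output
        L = hio.load_leadfield(lf)
        data = L.gain(0) @ np.array([0.0, 0.0, 1.0])
        tsv = tmp_path / "data.tsv"
        tsv.write_text(
            "".join(f"{lab}\t{v:.17g}\n" for lab, v in zip(L.electrodes.labels, data))
        )
        out = tmp_path / "scan.json"
        r = runner.invoke(main, ["scan", "--lf", str(lf), "--data", str(tsv),
                                 "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert json.loads(out.read_text())["best_index"] == 0

    def test_compare_command(self, tmp_path):
        from click.testing import CliRunner

        from hexfem.cli import main

        rng = np.random.default_rng(0)
        elec = hx.ElectrodeSet([f"E{i}" for i in range(8)], rng.standard_normal((8, 3)))
        L = hx.Leadfield(matrix=rng.standard_normal((8, 12)),
                         positions=rng.standard_normal((4, 3)),
                         electrodes=elec, average_referenced=True)
        a, b, out = tmp_path / "a.h5", tmp_path / "b.h5", tmp_path / "rep.tsv"
        hio.save_leadfield(L, a)
        hio.save_leadfield(
            hx.Leadfield(matrix=2.0 * L.matrix, positions=L.positions,
                         electrodes=elec, average_referenced=True), b)
        r = CliRunner().invoke(main, ["compare", "--num", str(a), "--ref", str(b),
                                      "--out", str(out)])
        assert r.exit_code == 0, r.output
        assert out.exists()
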