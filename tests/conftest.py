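"""Shared fixtures: small sphere phantoms meshed once per session."""
import pytest

import hexfem as hx


@pytest.fixture(scope="session")
def brain_sphere():
    """Homogeneous 20 mm sphere at 2 mm voxels with a 12-electrode cap."""
    spec = hx.PhantomSpec(
        radii=(20.0,), labels=(1,), voxel_size=2.0, n_electrodes=12,
        cap_deg=150.0, seed=1,
    )
    vol, elec = hx.generate_sphere_phantom(spec)
    mesh = hx.build_hex_mesh(vol, node_shift=0.3,
                             conductivities=hx.ConductivityTable({1: 0.33}))
    A = hx.assemble_stiffness(mesh)
    proj = hx.project_electrodes(mesh, elec)
    return {"spec": spec, "vol": vol, "elec": elec, "mesh": mesh, "A": A,
            "proj": proj}


@pytest.fixture(scope="session")
def brain_sphere_transfer(brain_sphere):
    """Tightly solved transfer matrix for the homogeneous sphere."""
    return hx.transfer_matrix(brain_sphere["A"], brain_sphere["proj"],
                              rel_tol=1e-10)


@pytest.fixture(scope="session")
def four_shell_scan():
    """4-shell sphere (gray/CSF/skull/skin), 4 mm gray source grid, leadfield."""
    spec = hx.PhantomSpec(
        radii=(20.0, 22.0, 24.0, 27.0), labels=(1, 2, 3, 4), voxel_size=2.0,
        n_electrodes=32, cap_deg=165.0, seed=3,
    )
    vol, elec = hx.generate_sphere_phantom(spec)
    table = hx.ConductivityTable({1: 0.33, 2: 1.79, 3: 0.01, 4: 0.43})
    mesh = hx.build_hex_mesh(vol, node_shift=0.3, conductivities=table)
    A = hx.assemble_stiffness(mesh)
    proj = hx.project_electrodes(mesh, elec)
    T = hx.transfer_matrix(A, proj)
    space = hx.build_source_grid(mesh, resolution=4.0, gm_label=1)
    L = hx.compute_leadfield(T, mesh, space.admissible_positions,
                             admissible_labels={1})
    return {"spec": spec, "vol": vol, "mesh": mesh, "A": A, "proj": proj,
            "T": T, "space": space, "L": L}
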