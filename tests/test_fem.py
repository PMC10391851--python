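import numpy as np
import pytest
from scipy.stats import special_ortho_group

from cervifem import fem
from cervifem.geometry import voxel_to_hexmesh
from cervifem.materials import (
    MaterialSpec,
    MaterialTable,
    NBM,
    Role,
    base_material_table,
    lame_parameters,
)

from conftest import make_bar_model

UNIT_CUBE = np.array(
    [[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], dtype=float
)


def table_of(e, nu, role=Role.CORTICAL):
    return MaterialTable(NBM, {role: MaterialSpec("m", role, e, nu)})


def bar_system(nx, ny, nz, e, nu, force, role=Role.CORTICAL, voxel_size=1.0):
    mesh = voxel_to_hexmesh(make_bar_model(nx, ny, nz, role, voxel_size))
    table = table_of(e, nu, role)
    system = fem.assemble(mesh, table)
    system = fem.fix_nodes(system, mesh.node_sets["inferior_fixed_nodes"])
    system = fem.apply_axial_load(system, mesh.face_sets["superior_C4_faces"],
                                  force, mesh)
    return mesh, table, system


# --- element stiffness ------------------------------------------------------

def test_element_stiffness_symmetric_with_six_rigid_modes():
    k = fem.element_stiffness(UNIT_CUBE, lam=123.0, mu=45.0)
    assert np.allclose(k, k.T, atol=1e-12)
    eig = np.linalg.eigvalsh(k)
    assert (eig > -1e-9).all()
    assert (np.abs(eig) < 1e-9 * eig.max()).sum() == 6


def test_element_strain_energy_uniaxial_unit_strain():
    # E = 1, nu = 0 -> lam = 0, mu = 0.5; u_z = z gives energy 0.5*E*V = 0.5
    k = fem.element_stiffness(UNIT_CUBE, lam=0.0, mu=0.5)
    u = np.zeros(24)
    u[2::3] = UNIT_CUBE[:, 2]
    assert 0.5 * u @ k @ u == pytest.approx(0.5, rel=1e-12)


def test_element_stiffness_scales_linearly_with_edge_length():
    k1 = fem.element_stiffness(UNIT_CUBE, lam=7.0, mu=3.0)
    k2 = fem.element_stiffness(2 * UNIT_CUBE, lam=7.0, mu=3.0)
    assert np.allclose(k2, 2 * k1, rtol=1e-12)


def test_inverted_element_rejected():
    coords = UNIT_CUBE.copy()
    coords[:, 2] *= -1  # flips the Jacobian sign
    with pytest.raises(ValueError, match="Jacobian"):
        fem.element_stiffness(coords, lam=1.0, mu=1.0)


# --- assembly ---------------------------------------------------------------

def test_assemble_single_element_equals_element_matrix():
    mesh = voxel_to_hexmesh(make_bar_model(1, 1, 1, Role.CORTICAL))
    table = base_material_table()
    lam, mu = table.lame(Role.CORTICAL)
    k_elem = fem.element_stiffness(UNIT_CUBE, lam, mu)
    system = fem.assemble(mesh, table)
    # global dof order must match element-local order via the connectivity
    edof = (mesh.elements[0][:, None] * 3 + np.arange(3)).ravel()
    assert np.allclose(system.stiffness.toarray()[np.ix_(edof, edof)], k_elem)
    assert system.n_dofs == 3 * mesh.n_nodes


def test_assembled_matrix_annihilates_rigid_translation():
    mesh = voxel_to_hexmesh(make_bar_model(2, 2, 2, Role.CANCELLOUS))
    system = fem.assemble(mesh, base_material_table())
    for axis in range(3):
        u = np.zeros(system.n_dofs)
        u[axis::3] = 1.0
        assert np.abs(system.stiffness @ u).max() < 1e-8


def test_missing_material_role_is_an_error():
    mesh = voxel_to_hexmesh(make_bar_model(1, 1, 1, Role.PEEK))
    with pytest.raises(KeyError, match="peek"):
        fem.assemble(mesh, table_of(1.0, 0.0, Role.CORTICAL))


# --- load application -------------------------------------------------------

def test_axial_load_sums_exactly_and_weights_by_tributary_area():
    mesh = voxel_to_hexmesh(make_bar_model(2, 2, 1, Role.CORTICAL))
    system = fem.assemble(mesh, base_material_table())
    system = fem.apply_axial_load(system, mesh.face_sets["superior_C4_faces"],
                                  100.0, mesh)
    fz = system.load_vector[2::3]
    assert fz.sum() == pytest.approx(-100.0, abs=1e-12)
    top = mesh.node_sets["superior_C4_nodes"]
    xy = mesh.nodes[top][:, :2]
    mag = -fz[top]
    corner = mag[np.all((xy == 0) | (xy == 2), axis=1)]
    center = mag[np.all(xy == 1, axis=1)]
    edge = mag[np.sum((xy == 1), axis=1) == 1]
    assert np.allclose(edge, 2 * corner[0])
    assert np.allclose(center, 4 * corner[0])


def test_empty_surface_rejected():
    mesh = voxel_to_hexmesh(make_bar_model(1, 1, 1, Role.CORTICAL))
    system = fem.assemble(mesh, base_material_table())
    with pytest.raises(ValueError, match="zero area"):
        fem.apply_axial_load(system, np.empty((0, 4), int), 100.0, mesh)


# --- solver oracles ---------------------------------------------------------

def test_uniaxial_bar_matches_closed_form():
    """Homogeneous bar, E=3600, nu=0, F=100 N: delta = FL/(EA), sigma = -F/A."""
    e, force, length = 3600.0, 100.0, 10.0
    area = 14 * 16
    mesh, table, system = bar_system(14, 16, 10, e, 0.0, force)
    sol = fem.solve(system)
    sol = fem.recover_stress(mesh, sol, table)
    tip = mesh.node_sets["superior_C4_nodes"]
    delta = -sol.displacements[tip, 2].mean() * 1000  # um
    expected = force * length / (e * area) * 1000  # 1.240 um
    assert delta == pytest.approx(expected, rel=0.005)
    assert expected == pytest.approx(1.2400, rel=1e-3)
    assert sol.element_stress[:, 2, 2] == pytest.approx(-force / area, rel=0.005)
    assert np.abs(sol.element_stress[:, 0, 0]).max() < 1e-8


def test_solution_scales_linearly_with_load():
    _, _, s100 = bar_system(4, 4, 6, 3600.0, 0.0, 100.0)
    mesh, _, s200 = bar_system(4, 4, 6, 3600.0, 0.0, 200.0)
    fac = fem.StiffnessFactorization(s100)
    u100 = fac.solve(s100.load_vector).displacements
    u200 = fac.solve(s200.load_vector).displacements
    assert np.allclose(u200, 2 * u100, rtol=1e-12, atol=1e-18)


def test_two_material_stacked_bar_springs_in_series():
    e1, e2, force = 12_000.0, 450.0, 100.0
    nx, ny, half = 6, 6, 5
    model = make_bar_model(nx, ny, 2 * half, Role.CORTICAL)
    from cervifem.geometry import ROLE_CODES

    model.labels[:, :, half:] = ROLE_CODES[Role.CANCELLOUS]
    mesh = voxel_to_hexmesh(model)
    table = MaterialTable(NBM, {
        Role.CORTICAL: MaterialSpec("a", Role.CORTICAL, e1, 0.0),
        Role.CANCELLOUS: MaterialSpec("b", Role.CANCELLOUS, e2, 0.0),
    })
    system = fem.assemble(mesh, table)
    system = fem.fix_nodes(system, mesh.node_sets["inferior_fixed_nodes"])
    system = fem.apply_axial_load(system, mesh.face_sets["superior_C4_faces"],
                                  force, mesh)
    sol = fem.solve(system)
    tip = mesh.node_sets["superior_C4_nodes"]
    delta = -sol.displacements[tip, 2].mean()
    area = nx * ny
    expected = force * half / area * (1 / e1 + 1 / e2)
    assert delta == pytest.approx(expected, rel=0.005)


def test_reactions_balance_applied_load():
    mesh, _, system = bar_system(4, 4, 6, 3600.0, 0.3, 150.0)
    sol = fem.solve(system)
    total = sol.reaction_total()
    assert total[2] == pytest.approx(150.0, rel=1e-10)
    assert abs(total[0]) < 1e-8 and abs(total[1]) < 1e-8
    assert sol.residual <= 1e-10


def test_patch_test_affine_field_reproduced_exactly():
    """Affine displacement on the boundary is reproduced in the interior."""
    mesh = voxel_to_hexmesh(make_bar_model(3, 3, 3, Role.CORTICAL))
    table = base_material_table()
    system = fem.assemble(mesh, table)
    a = np.array([[1e-3, 2e-4, -1e-4],
                  [5e-5, -8e-4, 3e-4],
                  [-2e-4, 1e-4, 6e-4]])
    b = np.array([1e-3, -2e-3, 5e-4])
    exact = mesh.nodes @ a.T + b
    on_boundary = np.any((mesh.nodes == 0) | (mesh.nodes == 3), axis=1)
    bnodes = np.flatnonzero(on_boundary)
    dofs = (bnodes[:, None] * 3 + np.arange(3)).ravel()
    system = system.constrain(dofs, exact[bnodes].ravel())
    sol = fem.solve(system)
    assert np.abs(sol.displacements - exact).max() < 1e-10


def test_mesh_refinement_leaves_affine_bar_solution_unchanged():
    """The uniform-strain bar is exact at any h; refinement must not drift."""
    def tip_disp(h):
        mesh, _, system = bar_system(round(4 / h), round(4 / h), round(6 / h),
                                     3600.0, 0.0, 100.0, voxel_size=h)
        sol = fem.solve(system)
        return -sol.displacements[mesh.node_sets["superior_C4_nodes"], 2].mean()

    d1, d2 = tip_disp(1.0), tip_disp(0.5)
    assert abs(d2 - d1) / d1 < 1e-3


def test_floating_fragment_reported_as_singular():
    # two disjoint blocks would be caught at meshing; an unconstrained mesh
    # reaching the solver must also fail loudly
    mesh = voxel_to_hexmesh(make_bar_model(2, 2, 2, Role.CORTICAL))
    system = fem.assemble(mesh, base_material_table())
    system = fem.apply_axial_load(system, mesh.face_sets["superior_C4_faces"],
                                  100.0, mesh)
    with pytest.raises(fem.SingularSystemError):
        fem.solve(system)


# --- stress recovery and Von Mises ------------------------------------------

def test_rigid_translation_produces_zero_stress():
    mesh = voxel_to_hexmesh(make_bar_model(2, 2, 2, Role.CORTICAL))
    table = base_material_table()
    sol = fem.FieldSolution(
        displacements=np.ones((mesh.n_nodes, 3)),
        reactions=np.zeros(3 * mesh.n_nodes),
        residual=0.0,
        constrained_dofs=np.empty(0, dtype=np.int64),
    )
    sol = fem.recover_stress(mesh, sol, table)
    assert np.abs(sol.element_stress).max() < 1e-9
    assert np.abs(sol.element_von_mises).max() < 1e-9


def test_uniform_uniaxial_strain_follows_hookes_law():
    e, strain = 3600.0, 1e-3
    mesh = voxel_to_hexmesh(make_bar_model(2, 2, 2, Role.PEEK))
    table = table_of(e, 0.0, Role.PEEK)
    sol = fem.FieldSolution(
        displacements=np.column_stack(
            [np.zeros(mesh.n_nodes), np.zeros(mesh.n_nodes),
             strain * mesh.nodes[:, 2]]),
        reactions=np.zeros(3 * mesh.n_nodes),
        residual=0.0,
        constrained_dofs=np.empty(0, dtype=np.int64),
    )
    sol = fem.recover_stress(mesh, sol, table)
    assert sol.element_stress[:, 2, 2] == pytest.approx(e * strain, rel=1e-12)
    off = sol.element_stress.copy()
    off[:, 2, 2] = 0.0
    assert np.abs(off).max() < 1e-12


@pytest.mark.parametrize(
    "tensor, expected",
    [
        (np.diag([5.0, 0, 0]), 5.0),  # uniaxial -> |sigma|
        (7.0 * np.eye(3), 0.0),  # hydrostatic -> 0
        (np.array([[0, 3.0, 0], [3.0, 0, 0], [0, 0, 0]]), 3.0 * np.sqrt(3)),
    ],
)
def test_von_mises_classical_identities(tensor, expected):
    assert fem.von_mises(tensor) == pytest.approx(expected, abs=1e-12)


def test_von_mises_rotation_invariant(rng):
    tensors = rng.normal(size=(100, 3, 3))
    tensors = 0.5 * (tensors + tensors.transpose(0, 2, 1))
    rots = special_ortho_group.rvs(3, size=100, random_state=1234)
    vm = fem.von_mises(tensors)
    rotated = np.einsum("nab,nbc,ndc->nad", rots, tensors, rots)
    assert np.allclose(fem.von_mises(rotated), vm, rtol=1e-10)
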