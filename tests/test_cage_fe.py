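"""Beam-FE solver: analytic oracles, an independent dense stiffness oracle,
contact equilibrium and strain-recovery identities."""

import math

import numpy as np
import pytest

import trusscage as tc
from trusscage.beam import KAPPA_S, Section, element_frame, global_stiffness
from trusscage.cage_fe import ContactParams, Solution, assemble
from trusscage.metrics import ContactField

E_TI, NU_TI = 116_000.0, 0.32


# ---------------------------------------------------------------------------
# independent oracle: element stiffness via the flexibility route
# ---------------------------------------------------------------------------

def _skew(r):
    return np.array([[0, -r[2], r[1]], [r[2], 0, -r[0]], [-r[1], r[0], 0.0]])


def oracle_global_stiffness(d, E, nu, p1, p2):
    """Element stiffness derived independently: invert the cantilever
    flexibility (closed-form Timoshenko end deflections) and complete by
    rigid-body equilibrium, then rotate to global axes."""
    A = math.pi * d**2 / 4
    I = math.pi * d**4 / 64
    J = math.pi * d**4 / 32
    G = E / (2 * (1 + nu))
    R, L = element_frame(p1, p2)
    F = np.zeros((6, 6))
    F[0, 0] = L / (E * A)
    F[3, 3] = L / (G * J)
    bend = L**3 / (3 * E * I) + L / (KAPPA_S * G * A)
    F[1, 1] = F[2, 2] = bend
    F[4, 4] = F[5, 5] = L / (E * I)
    F[1, 5] = F[5, 1] = L**2 / (2 * E * I)
    F[2, 4] = F[4, 2] = -(L**2) / (2 * E * I)
    K22 = np.linalg.inv(F)
    S = np.eye(6)
    S[3:, :3] = _skew([L, 0.0, 0.0])
    K = np.block([[S @ K22 @ S.T, -S @ K22], [-K22 @ S.T, K22]])
    T = np.zeros((12, 12))
    for b in range(4):
        T[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] = R
    return T.T @ K @ T


@pytest.mark.parametrize(
    "p2", [(10.0, 0, 0), (0, 0, 7.0), (3.0, -4.0, 5.0)]
)
def test_element_stiffness_matches_flexibility_oracle(p2):
    p1 = np.zeros(3)
    sec = Section(diameter=0.8, E=E_TI, nu=NU_TI)
    K = global_stiffness(sec, p1, np.array(p2))
    K_oracle = oracle_global_stiffness(0.8, E_TI, NU_TI, p1, np.array(p2))
    np.testing.assert_allclose(K, K_oracle, rtol=1e-9, atol=1e-9 * K.max())


def test_free_free_element_has_six_rigid_modes():
    sec = Section(diameter=0.8, E=E_TI, nu=NU_TI)
    K = global_stiffness(sec, np.zeros(3), np.array([10.0, 0, 0]))
    w = np.linalg.eigvalsh(K)
    assert np.sum(np.abs(w) < 1e-8 * np.abs(w).max()) == 6
    assert np.all(w > -1e-8 * np.abs(w).max())  # positive semi-definite


def _dense_solve(K, f, fixed):
    free = [i for i in range(len(f)) if i not in set(fixed)]
    u = np.zeros(len(f))
    u[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
    return u


def test_axial_rod_closed_form():
    sec = Section(diameter=0.8, E=E_TI, nu=NU_TI)
    L, F = 10.0, 100.0
    K = global_stiffness(sec, np.zeros(3), np.array([L, 0, 0]))
    f = np.zeros(12)
    f[6] = F
    u = _dense_solve(K, f, fixed=range(6))
    assert u[6] == pytest.approx(F * L / (E_TI * sec.A), rel=1e-12)


def test_timoshenko_cantilever_closed_form():
    sec = Section(diameter=0.8, E=E_TI, nu=NU_TI)
    L, P = 10.0, 10.0
    K = global_stiffness(sec, np.zeros(3), np.array([L, 0, 0]))
    f = np.zeros(12)
    f[7] = P
    u = _dense_solve(K, f, fixed=range(6))
    expected = P * L**3 / (3 * E_TI * sec.I) + P * L / (KAPPA_S * sec.G * sec.A)
    assert u[7] == pytest.approx(expected, rel=1e-8)


def test_three_strut_frame_matches_dense_oracle():
    """Bent 3-strut frame: package assembly vs the flexibility-route dense
    oracle, displacement agreement to 1e-10 relative."""
    nodes = np.array(
        [[0.0, 0, 0], [10.0, 0, 0], [10.0, 10.0, 0], [10.0, 10.0, 8.0]]
    )
    struts = [(0, 1, 0.8), (1, 2, 0.8), (2, 3, 0.8)]
    lat = tc.CageLattice(
        nodes=nodes, struts=struts,
        sets={"caudal_surface": {0}, "cranial_surface": {3}},
        material=(E_TI, NU_TI),
    )
    model = assemble(lat)
    K_pkg = model.K_lattice.toarray()
    K_orc = np.zeros_like(K_pkg)
    for i, j, d in struts:
        ke = oracle_global_stiffness(d, E_TI, NU_TI, nodes[i], nodes[j])
        dofs = np.r_[6 * i + np.arange(6), 6 * j + np.arange(6)]
        K_orc[np.ix_(dofs, dofs)] += ke
    f = np.zeros(24)
    f[18:21] = [5.0, -3.0, -20.0]  # mixed load at the free tip
    u_pkg = _dense_solve(K_pkg, f, fixed=range(6))
    u_orc = _dense_solve(K_orc, f, fixed=range(6))
    np.testing.assert_allclose(u_pkg, u_orc, rtol=1e-10, atol=1e-14)


def test_lattice_stiffness_has_exactly_six_zero_modes(default_lattice):
    model = assemble(default_lattice)
    w = np.linalg.eigvalsh(model.K_lattice.toarray())
    scale = np.abs(w).max()
    assert np.sum(np.abs(w) < 1e-9 * scale) == 6
    assert np.all(w > -1e-9 * scale)


def test_rigid_body_patch_test(default_lattice):
    """Rigid translation+rotation of the whole lattice stores no energy."""
    model = assemble(default_lattice)
    rot = np.array([2e-3, -1e-3, 3e-3])
    trans = np.array([0.1, 0.2, -0.3])
    centre = default_lattice.nodes.mean(axis=0)
    u = np.zeros(6 * len(default_lattice.nodes))
    for k, p in enumerate(default_lattice.nodes):
        u[6 * k : 6 * k + 3] = trans + np.cross(rot, p - centre)
        u[6 * k + 3 : 6 * k + 6] = rot
    energy_J = 0.5 * float(u @ (model.K_lattice @ u)) * 1e-3  # N*mm -> J
    assert abs(energy_J) < 1e-12


# ---------------------------------------------------------------------------
# load-case solves
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def default_model(default_lattice):
    return assemble(default_lattice)


def _bc(rot=0.0, force=500.0, **kw):
    return tc.SegmentBC(cranial_plate_rotation_deg=rot, axial_force_N=force, **kw)


def test_near_zero_load_gives_near_zero_response(default_model):
    sol = tc.solve_load_case(default_model, _bc(rot=0.0, force=1e-9))
    assert np.abs(sol.u).max() < 1e-12
    field = tc.surface_strain(sol)
    assert np.abs(field.principal_ue).max() < 1e-6
    assert tc.von_mises_peak(sol) < 1e-6


def test_bonded_axial_pressures_mirror_symmetric(default_model):
    """Pure axial compression on the symmetric lattice: caudal pressures
    equal across the midsagittal plane."""
    sol = tc.solve_load_case(
        default_model, _bc(force=500.0),
        contact=ContactParams(mode="bonded"),
    )
    pos = sol.caudal.position_mm
    press = sol.caudal.pressure_MPa
    lut = {(round(x, 6), round(y, 6)): p
           for (x, y, _), p in zip(pos, press)}
    for (x, y), p in lut.items():
        q = lut[(x, round(-y, 6))]
        assert p == pytest.approx(q, rel=1e-6)


@pytest.mark.parametrize("rot,force", [(0.0, 500.0), (0.3, 550.0),
                                       (-0.2, 420.0)])
def test_unilateral_equilibrium(default_model, rot, force):
    """Caudal contact force + instrumentation share balances the applied
    follower-load share; no tensile contact pressure survives."""
    sol = tc.solve_load_case(default_model, _bc(rot=rot, force=force))
    assert sol.equilibrium_residual() < 1e-8 * force
    assert sol.caudal.pressure_MPa[sol.caudal.active].min(initial=0.0) >= -1e-9


def test_friction_cap_respected(default_model):
    sol = tc.solve_load_case(default_model, _bc(rot=0.35, force=550.0))
    for cf in (sol.caudal, sol.cranial):
        cap = 0.20 * np.maximum(cf.normal_force_N, 0.0)
        assert np.all(cf.tangential_force_N <= cap + 1e-6)


def test_ramp_path_independence(default_model):
    """A linear(ised) monotonic ramp ends at the same state regardless of
    the number of steps."""
    sols = {}
    for n in (1, 10):
        bc = _bc(rot=0.3, force=550.0, n_ramp_steps=n)
        sol = None
        for step in bc.ramp():
            sol = tc.solve_load_case(default_model, step)
        sols[n] = sol
    np.testing.assert_allclose(sols[1].u, sols[10].u, rtol=1e-9, atol=1e-12)


def test_zero_length_strut_rejected_at_assembly():
    nodes = np.array([[0.0, 0, 0], [10.0, 0, 0]])
    lat = tc.CageLattice(
        nodes=nodes, struts=[(0, 1, 0.8)],
        sets={"caudal_surface": {0}, "cranial_surface": {1}},
    )
    lat.nodes = np.array([[0.0, 0, 0], [0.0, 0, 0]])
    with pytest.raises(ValueError):
        assemble(lat)


# ---------------------------------------------------------------------------
# strain recovery identities on manufactured single-strut states
# ---------------------------------------------------------------------------

def _single_strut_solution(u12, d=1.0, L=10.0):
    nodes = np.array([[0.0, 0, 0], [L, 0, 0]])
    lat = tc.CageLattice(
        nodes=nodes, struts=[(0, 1, d)],
        sets={"caudal_surface": {0}, "cranial_surface": {1}},
        material=(E_TI, NU_TI),
    )
    model = assemble(lat)
    empty = ContactField(
        node_id=np.array([], dtype=int), position_mm=np.zeros((0, 3)),
        normal_force_N=np.array([]), tangential_force_N=np.array([]),
        tributary_area_mm2=np.array([]), active=np.array([], dtype=bool),
    )
    return Solution(
        model=model, bc=_bc(force=1.0), contact_params=ContactParams(),
        u=np.asarray(u12, dtype=float), plate_uz=0.0, plate_rotation_rad=0.0,
        caudal=empty, cranial=empty, instrumentation_force_N=0.0,
        reaction_moment_Nmm=0.0, n_iterations=1,
    )


def test_uniform_axial_strain_recovered_everywhere():
    L, eps = 10.0, 300e-6
    u = np.zeros(12)
    u[6] = eps * L
    field = tc.surface_strain(_single_strut_solution(u, L=L))
    np.testing.assert_allclose(field.principal_ue, 300.0, rtol=1e-9)


def test_pure_bending_extreme_fiber():
    """Constant-curvature state: extreme fibers read +/- kappa d/2."""
    L, d, kappa = 10.0, 1.0, 1e-4  # 1/mm
    u = np.zeros(12)
    u[7] = kappa * L**2 / 2  # deflection v(L)
    u[11] = kappa * L  # end rotation theta_z(L)
    field = tc.surface_strain(_single_strut_solution(u, d=d, L=L))
    expected = kappa * d / 2 * 1e6  # microstrain
    assert np.abs(field.principal_ue).max() == pytest.approx(expected, rel=1e-6)
    # opposite-sign fibers half a revolution apart
    mid = field.s_mm == 5.0
    th0 = mid & np.isclose(field.theta_rad, 0.0)
    thpi = mid & np.isclose(field.theta_rad, np.pi)
    assert field.principal_ue[th0][0] == pytest.approx(
        -field.principal_ue[thpi][0], rel=1e-6
    )


def test_pure_torsion_principal_strain():
    """Twist phi' gives principal strain (d/4) phi' at every angle."""
    L, d, phi = 10.0, 1.0, 2e-3
    u = np.zeros(12)
    u[9] = phi  # end twist
    field = tc.surface_strain(_single_strut_solution(u, d=d, L=L))
    expected = 0.25 * d * (phi / L) * 1e6
    np.testing.assert_allclose(field.principal_ue, expected, rtol=1e-10)


def test_von_mises_uniaxial_and_shear():
    L = 10.0
    u = np.zeros(12)
    u[6] = 1000e-6 * L  # 1000 microstrain
    sol = _single_strut_solution(u, L=L)
    assert tc.von_mises_peak(sol) == pytest.approx(116.0, rel=1e-9)

    u = np.zeros(12)
    u[9] = 2e-3
    sol = _single_strut_solution(u, d=1.0, L=L)
    G = E_TI / (2 * (1 + NU_TI))
    tau = G * 0.5 * 1.0 * (2e-3 / L)
    assert tc.von_mises_peak(sol) == pytest.approx(math.sqrt(3) * tau, rel=1e-9)


def test_surface_strain_sampling_preconditions(default_model):
    sol = tc.solve_load_case(default_model, _bc())
    with pytest.raises(ValueError):
        tc.surface_strain(sol, n_axial=1)
    with pytest.raises(ValueError):
        tc.surface_strain(sol, n_circ=3)


def test_strain_field_weights_sum_to_lateral_area(default_model, default_lattice):
    sol = tc.solve_load_case(default_model, _bc())
    field = tc.surface_strain(sol)
    assert field.weight_mm2.sum() == pytest.approx(
        default_lattice.lateral_surface_area(), rel=1e-9
    )


def test_median_strain_decreases_with_strut_diameter(default_cohort):
    """Thicker struts shed strain at fixed loads (the design-tuning premise)."""
    from dataclasses import replace

    p = default_cohort[0]
    fsus = tc.build_fsu_chain(p)
    lc = tc.make_load_case(p, "neutral")
    state = tc.distribute_rotation(fsus, "L4-5", lc)
    bc = tc.segment_bc(state, p, lc)
    bc = replace(bc, axial_force_N=bc.axial_force_N / 2)
    medians = []
    for d in (0.6, 0.8, 1.0):
        lat = tc.generate_cage(tc.CageParams(strut_diameter_mm=d))
        sol = tc.solve_load_case(assemble(lat), bc)
        f = tc.surface_strain(sol)
        order = np.argsort(np.abs(f.principal_ue))
        v = np.abs(f.principal_ue)[order]
        w = f.weight_mm2[order]
        medians.append(v[np.searchsorted(np.cumsum(w), 0.5 * w.sum())])
    assert medians[0] > medians[1] > medians[2]
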