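"""Operated-segment beam-FE model of the trussed cage.

The strut lattice is discretised with two-node 3D Timoshenko beams. The
caudal endplate is fixed; the cranial endplate is a rigid plate with a
prescribed sagittal rotation and an applied axial (follower-load share)
force, all off-axis plate motions constrained. Each contact-surface node
couples to its plate through a Winkler-type foundation spring derived from
the 2-mm interface layer (k_n = E_layer * A_trib / t normal, k_t =
k_n / (2 (1 + nu_layer)) tangential). Unilateral mode releases springs that
go into tension (active-set iteration); tangential forces are capped at
mu * N by a secant Coulomb return. The pedicle-screw/rod construct enters
as a parallel vertical spring at a posterior lever arm between the cranial
plate and ground.

Units: mm, N, MPa; rotations rad internally, degrees at the interface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve

from .beam import Section, element_frame, local_stiffness, transformation
from .lattice import CageLattice, write_lattice_vtk
from .metrics import ContactField, StrainField
from .spine import ModelError, NumericalError, SegmentBC

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactParams:
    """Cage-endplate interface layer and friction parameters."""

    layer_E_MPa: float = 1000.0
    layer_nu: float = 0.30
    layer_thickness_mm: float = 2.0
    friction_mu: float = 0.20
    mode: str = "unilateral"  # or "bonded"

    def __post_init__(self) -> None:
        if self.layer_E_MPa <= 0 or self.layer_thickness_mm <= 0:
            raise ValueError("layer modulus and thickness must be > 0")
        if not 0 <= self.layer_nu < 0.5:
            raise ValueError("layer_nu must lie in [0, 0.5)")
        if self.friction_mu < 0:
            raise ValueError("friction_mu must be >= 0")
        if self.mode not in ("unilateral", "bonded"):
            raise ValueError(f"unknown contact mode {self.mode!r}")


@dataclass
class _Element:
    i: int
    j: int
    section: Section
    R: np.ndarray  # 3x3 local frame
    L: float
    k_local: np.ndarray  # 12x12


@dataclass
class BeamModel:
    """Assembled lattice model: 6 DOF per node + 1 plate DOF (axial)."""

    lattice: CageLattice
    elements: list[_Element]
    K_lattice: sparse.csr_matrix  # (6n, 6n)
    footprint_area_mm2: float
    plate_centroid: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.lattice.nodes)

    @property
    def n_dof(self) -> int:
        return 6 * self.n_nodes + 1  # +1: plate axial translation


def assemble(lattice: CageLattice) -> BeamModel:
    """Assemble the sparse global stiffness of the strut lattice.

    Symmetric, positive semi-definite with exactly the six rigid-body
    zero-energy modes before any constraint or foundation spring is added.
    """
    lattice.validate()
    E, nu = lattice.material
    n = len(lattice.nodes)
    rows, cols, vals = [], [], []
    elements: list[_Element] = []
    for i, j, d in lattice.struts:
        sec = Section(diameter=d, E=E, nu=nu)
        R, L = element_frame(lattice.nodes[i], lattice.nodes[j])
        k_loc = local_stiffness(sec, L)
        T = transformation(R)
        k_glob = T.T @ k_loc @ T
        elements.append(_Element(i, j, sec, R, L, k_loc))
        dofs = np.r_[6 * i + np.arange(6), 6 * j + np.arange(6)]
        for a in range(12):
            rows.extend([dofs[a]] * 12)
            cols.extend(dofs)
            vals.extend(k_glob[a])
    K = sparse.coo_matrix((vals, (rows, cols)), shape=(6 * n, 6 * n)).tocsr()

    cranial = sorted(lattice.sets["cranial_surface"])
    xyz = lattice.nodes
    xs, ys = xyz[:, 0], xyz[:, 1]
    footprint = float((xs.max() - xs.min()) * (ys.max() - ys.min()))
    centroid = np.array(
        [xyz[cranial, 0].mean(), xyz[cranial, 1].mean(), xyz[cranial, 2].mean()]
    )
    return BeamModel(
        lattice=lattice,
        elements=elements,
        K_lattice=K,
        footprint_area_mm2=footprint,
        plate_centroid=centroid,
    )


@dataclass
class Solution:
    """Solved displacement state plus interface and reaction bookkeeping."""

    model: BeamModel
    bc: SegmentBC
    contact_params: ContactParams
    u: np.ndarray  # 6n lattice DOFs
    plate_uz: float
    plate_rotation_rad: float
    caudal: ContactField
    cranial: ContactField
    instrumentation_force_N: float  # vertical force the rod path carries
    reaction_moment_Nmm: float
    n_iterations: int

    def applied_force_N(self) -> float:
        return self.bc.axial_force_N

    def equilibrium_residual(self) -> float:
        """|caudal contact force + instrumentation share - applied| (N)."""
        contact = float(self.caudal.normal_force_N[self.caudal.active].sum())
        return abs(contact + self.instrumentation_force_N - self.applied_force_N())

    def element_local_forces(self, e: int) -> np.ndarray:
        el = self.model.elements[e]
        dofs = np.r_[6 * el.i + np.arange(6), 6 * el.j + np.arange(6)]
        u_loc = transformation(el.R) @ self.u[dofs]
        return el.k_local @ u_loc

    def element_local_disp(self, e: int) -> np.ndarray:
        el = self.model.elements[e]
        dofs = np.r_[6 * el.i + np.arange(6), 6 * el.j + np.arange(6)]
        return transformation(el.R) @ self.u[dofs]


def _face_springs(model: BeamModel, contact: ContactParams, face: str):
    ids = sorted(model.lattice.sets[f"{face}_surface"])
    a_trib = model.footprint_area_mm2 / len(ids)
    k_n = contact.layer_E_MPa * a_trib / contact.layer_thickness_mm
    k_t = k_n / (2.0 * (1.0 + contact.layer_nu))
    return np.array(ids), a_trib, k_n, k_t


def solve_load_case(
    model: BeamModel,
    bc: SegmentBC,
    contact: ContactParams = ContactParams(),
    rod_share: float = 1.0,
    max_outer: int = 100,
    force_tol_N: float = 1e-8,
) -> Solution:
    """Solve one load case of the operated-segment cage model.

    ``rod_share`` is the number of rods acting in parallel with THIS cage
    model (1.0 when the two cages of a PLIF construct are solved as
    independent half-models, 2.0 for a single whole-segment model).

    Unilateral mode iterates the contact active set (springs in tension are
    released together with their tangential partner) and applies a secant
    Coulomb cap ``|T| <= mu N`` on the tangential springs, until the active
    set is fixed and spring forces change by less than ``force_tol_N``.
    """
    n = model.n_nodes
    theta = math.radians(bc.cranial_plate_rotation_deg)
    F = bc.axial_force_N
    cx = float(model.plate_centroid[0])

    caud_ids, a_caud, kn_c, kt_c = _face_springs(model, contact, "caudal")
    cran_ids, a_cran, kn_r, kt_r = _face_springs(model, contact, "cranial")
    # prescribed plate motion at each cranial node: u_plate_z = U_z + g_k
    g = -theta * (model.lattice.nodes[cran_ids, 0] - cx)

    instr = bc.instrumentation
    k_rod = rod_share * instr.rod_translational_stiffness()
    rod_arm = instr.posterior_offset_mm  # rod sits posterior of the centroid

    p = 6 * n  # plate axial DOF index
    bonded = contact.mode == "bonded"
    active_c = np.ones(len(caud_ids), dtype=bool)
    active_r = np.ones(len(cran_ids), dtype=bool)
    fric_scale_c = np.ones(len(caud_ids))
    fric_scale_r = np.ones(len(cran_ids))
    u = np.zeros(model.n_dof)

    for it in range(1, max_outer + 1):
        rows, cols, vals = [], [], []
        rhs = np.zeros(model.n_dof)

        def add(r, c, v):
            rows.append(r)
            cols.append(c)
            vals.append(v)

        # caudal foundation springs to ground
        for k, nid in enumerate(caud_ids):
            if not active_c[k]:
                continue
            dz = 6 * nid + 2
            add(dz, dz, kn_c)
            kt_eff = kt_c * fric_scale_c[k]
            add(6 * nid + 0, 6 * nid + 0, kt_eff)
            add(6 * nid + 1, 6 * nid + 1, kt_eff)
        # cranial springs node <-> rigid plate
        for k, nid in enumerate(cran_ids):
            if not active_r[k]:
                continue
            dz = 6 * nid + 2
            add(dz, dz, kn_r)
            add(p, p, kn_r)
            add(dz, p, -kn_r)
            add(p, dz, -kn_r)
            rhs[dz] += kn_r * g[k]
            rhs[p] -= kn_r * g[k]
            kt_eff = kt_r * fric_scale_r[k]
            # plate in-plane translation is constrained to zero; the plate's
            # prescribed in-plane motion at z = const is zero as well
            add(6 * nid + 0, 6 * nid + 0, kt_eff)
            add(6 * nid + 1, 6 * nid + 1, kt_eff)
        # instrumentation rod: vertical spring plate <-> ground at -rod_arm
        add(p, p, k_rod)
        rhs[p] -= k_rod * theta * rod_arm
        rhs[p] -= F  # applied compressive follower-load share

        K_extra = sparse.coo_matrix(
            (vals, (rows, cols)), shape=(model.n_dof, model.n_dof)
        )
        K_full = sparse.bmat(
            [[model.K_lattice, None], [None, sparse.csr_matrix((1, 1))]]
        ).tocsr() + K_extra.tocsr()

        if not np.any(active_c):
            raise ModelError("caudal face fully separated: system is singular")
        try:
            u = spsolve(K_full.tocsc(), rhs)
        except Exception as exc:  # pragma: no cover - singular configs
            raise ModelError(f"singular system: {exc}") from exc

        uz_plate = float(u[p])
        plate_z = uz_plate + g
        # raw spring forces at the CURRENT geometry (compression positive);
        # released nodes keep a raw value so penetration can re-admit them
        raw_N_c = -kn_c * u[6 * caud_ids + 2]
        raw_N_r = kn_r * (u[6 * cran_ids + 2] - plate_z)
        N_c = np.where(active_c, raw_N_c, 0.0)
        N_r = np.where(active_r, raw_N_r, 0.0)
        T_c = np.where(
            active_c,
            np.hypot(
                kt_c * fric_scale_c * u[6 * caud_ids + 0],
                kt_c * fric_scale_c * u[6 * caud_ids + 1],
            ),
            0.0,
        )
        T_r = np.where(
            active_r,
            np.hypot(
                kt_r * fric_scale_r * u[6 * cran_ids + 0],
                kt_r * fric_scale_r * u[6 * cran_ids + 1],
            ),
            0.0,
        )

        changed = False
        if not bonded:
            # release active springs in tension; re-admit released springs
            # only on strict penetration. Past half the iteration budget,
            # stop re-admitting: the active set then shrinks monotonically,
            # which breaks release/re-admit limit cycles.
            allow_admit = it <= max_outer // 2
            new_c = np.where(
                active_c, raw_N_c > -1e-12,
                (raw_N_c > 1e-9) if allow_admit else False,
            )
            new_r = np.where(
                active_r, raw_N_r > -1e-12,
                (raw_N_r > 1e-9) if allow_admit else False,
            )
            if not np.array_equal(new_c, active_c):
                changed = True
                fric_scale_c[new_c & ~active_c] = 1.0
                active_c = new_c
            if not np.array_equal(new_r, active_r):
                changed = True
                fric_scale_r[new_r & ~active_r] = 1.0
                active_r = new_r
            # Coulomb cap |T| <= mu N via secant scaling of k_t
            mu = contact.friction_mu
            for T, N, scale, act in (
                (T_c, N_c, fric_scale_c, active_c),
                (T_r, N_r, fric_scale_r, active_r),
            ):
                cap = mu * np.maximum(N, 0.0)
                slip = act & (T > cap + force_tol_N)
                if np.any(slip):
                    changed = True
                    with np.errstate(divide="ignore", invalid="ignore"):
                        f = np.where(T > 0, cap / T, 1.0)
                    scale[slip] *= np.clip(f[slip], 0.0, 1.0)

        # with an unchanged spring configuration a re-solve reproduces the
        # same linear solution exactly: converged
        if not changed:
            break
    else:
        raise NumericalError(
            f"contact iteration did not settle in {max_outer} outer iterations "
            f"(last active caudal {int(active_c.sum())}/{len(active_c)}, "
            f"cranial {int(active_r.sum())}/{len(active_r)})"
        )

    rod_e = uz_plate + theta * rod_arm
    instr_force = -k_rod * rod_e  # downward force transmitted to ground

    caudal = ContactField(
        node_id=caud_ids,
        position_mm=model.lattice.nodes[caud_ids],
        normal_force_N=N_c,
        tangential_force_N=T_c,
        tributary_area_mm2=np.full(len(caud_ids), a_caud),
        active=active_c & (N_c > 0),
        face="caudal",
    )
    cranial = ContactField(
        node_id=cran_ids,
        position_mm=model.lattice.nodes[cran_ids],
        normal_force_N=N_r,
        tangential_force_N=T_r,
        tributary_area_mm2=np.full(len(cran_ids), a_cran),
        active=active_r & (N_r > 0),
        face="cranial",
    )
    # reaction moment about the plate centroid (y axis): cranial spring
    # vertical forces at lever arms + rod contribution
    arms = model.lattice.nodes[cran_ids, 0] - cx
    react_m = float(np.sum(N_r * arms)) + (-instr_force) * (-rod_arm)

    return Solution(
        model=model,
        bc=bc,
        contact_params=contact,
        u=np.asarray(u[: 6 * n]),
        plate_uz=uz_plate,
        plate_rotation_rad=theta,
        caudal=caudal,
        cranial=cranial,
        instrumentation_force_N=float(instr_force),
        reaction_moment_Nmm=react_m,
        n_iterations=it,
    )


# ---------------------------------------------------------------------------
# surface strain sampling
# ---------------------------------------------------------------------------

def _strut_samples(
    solution: Solution,
    n_axial: int,
    n_circ: int,
    include_block: bool = True,
):
    """Yield (e, s, theta, eps_axial, gamma, weight, position) samples.

    Axial fiber strain at station s and circumferential angle theta:
    eps = eps_m + (d/2) (kappa_y sin(theta) + kappa_z cos(theta)), with
    curvatures from the linear internal bending-moment distribution;
    torsional shear gamma = (d/2) * twist rate. Each sample's weight is its
    share of the strut's lateral surface, pi d L / (n_axial n_circ).
    """
    model = solution.model
    block = model.lattice.sets.get("screw_block", set())
    thetas = np.arange(n_circ) * 2.0 * math.pi / n_circ
    sin_t, cos_t = np.sin(thetas), np.cos(thetas)
    for e, el in enumerate(model.elements):
        if not include_block and el.i in block and el.j in block:
            continue
        u_loc = solution.element_local_disp(e)
        f_loc = solution.element_local_forces(e)
        L, d = el.L, el.section.diameter
        EI = el.section.E * el.section.I
        eps_m = (u_loc[6] - u_loc[0]) / L
        twist = (u_loc[9] - u_loc[3]) / L
        gamma = 0.5 * d * twist
        w = math.pi * d * L / (n_axial * n_circ)
        p1 = model.lattice.nodes[el.i]
        p2 = model.lattice.nodes[el.j]
        for s in np.linspace(0.0, L, n_axial):
            m_y = -f_loc[4] - s * f_loc[2]
            m_z = -f_loc[5] + s * f_loc[1]
            k_y, k_z = m_y / EI, m_z / EI
            pos = p1 + (p2 - p1) * (s / L)
            eps = eps_m + 0.5 * d * (k_y * sin_t + k_z * cos_t)
            for t_idx in range(n_circ):
                yield e, s, thetas[t_idx], eps[t_idx], gamma, w, pos


def surface_strain(
    solution: Solution,
    n_axial: int = 3,
    n_circ: int = 8,
    include_block: bool = True,
) -> StrainField:
    """Sample absolute maximum principal strains on the strut surfaces.

    With axial fiber strain ``eps`` and torsional engineering shear
    ``gamma`` the absolute maximum principal strain is
    ``|eps|/2 + sqrt((eps/2)^2 + (gamma/2)^2)``, reported in microstrain
    with the sign of ``eps`` attached (tensile positive). Samples are
    classified anterior/posterior by the sign of their x position relative
    to the cage midplane.
    """
    if n_axial < 2 or n_circ < 4:
        raise ValueError("need n_axial >= 2 and n_circ >= 4")
    mid_x = float(solution.model.plate_centroid[0])
    strut_id, s_mm, th, pr, region, wt = [], [], [], [], [], []
    for e, s, t, eps, gamma, w, pos in _strut_samples(
        solution, n_axial, n_circ, include_block
    ):
        mag = abs(eps) / 2.0 + math.sqrt((eps / 2.0) ** 2 + (gamma / 2.0) ** 2)
        sign = -1.0 if eps < 0 else 1.0
        strut_id.append(e)
        s_mm.append(s)
        th.append(t)
        pr.append(sign * mag * 1e6)
        region.append("anterior" if pos[0] >= mid_x else "posterior")
        wt.append(w)
    return StrainField(
        strut_id=np.array(strut_id),
        s_mm=np.array(s_mm),
        theta_rad=np.array(th),
        principal_ue=np.array(pr),
        region=np.array(region),
        weight_mm2=np.array(wt),
    )


def von_mises_peak(
    solution: Solution,
    n_axial: int = 3,
    n_circ: int = 8,
    include_block: bool = True,
) -> float:
    """Peak von Mises stress over all surface samples, MPa.

    Per sample sigma = E * eps (axial fiber stress), tau = G * gamma,
    von Mises = sqrt(sigma^2 + 3 tau^2).
    """
    peak = 0.0
    E = solution.model.lattice.material[0]
    nu = solution.model.lattice.material[1]
    G = E / (2.0 * (1.0 + nu))
    for _, _, _, eps, gamma, _, _ in _strut_samples(
        solution, n_axial, n_circ, include_block
    ):
        vm = math.sqrt((E * eps) ** 2 + 3.0 * (G * gamma) ** 2)
        peak = max(peak, vm)
    return peak


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def export_solution_vtk(solution: Solution, path) -> None:
    """VTK legacy export: lattice lines, nodal displacements, per-strut
    peak |principal strain|."""
    field = surface_strain(solution)
    n_struts = len(solution.model.elements)
    per_strut = np.zeros(n_struts)
    for e in range(n_struts):
        mask = field.strut_id == e
        if np.any(mask):
            per_strut[e] = np.abs(field.principal_ue[mask]).max()
    disp = solution.u.reshape(-1, 6)[:, :3]
    write_lattice_vtk(
        solution.model.lattice,
        path,
        point_data={"displacement_mm": disp},
        cell_data={"max_abs_principal_ue": per_strut},
    )


def export_strains_csv(field: StrainField, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "strut_id": field.strut_id,
            "s_mm": field.s_mm,
            "theta_rad": field.theta_rad,
            "principal_ue": field.principal_ue,
            "region": field.region,
            "weight_mm2": field.weight_mm2,
        }
    ).to_csv(path, index=False)
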