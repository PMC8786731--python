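"""Cohort orchestration and the built-in validation suite.

``run_cohort`` walks patient x condition x cage (left/right), feeding each
case through surrogate loading -> cage FE -> metrics, amalgamating left and
right cages per patient by averaging, and summarising cohort variability.
The two cages of a PLIF construct are solved as independent mirror-image
half-models, each carrying half the segment's axial follower-load share,
the full rotation share, and one of the two rods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import cage_fe, metrics as mt, spine
from .cohort import VirtualPatient, export_cohort_csv, sample_cohort
from .config import RunConfig
from .lattice import CageLattice, generate_cage
from .beam import Section, global_stiffness

log = logging.getLogger(__name__)


@dataclass
class CaseResult:
    patient_id: str
    condition: str
    side: str
    solution: cage_fe.Solution
    strain: mt.StrainField
    fraction_pct: float
    histogram: tuple[np.ndarray, np.ndarray]
    mean_pressure_MPa: float
    peak_vm_MPa: float


@dataclass
class RunResult:
    config: RunConfig
    patients: list[VirtualPatient]
    cases: list[CaseResult]
    reports: dict[tuple[str, str], mt.CaseMetrics]
    summary: mt.CohortSummary
    spine_states: dict[tuple[str, str], spine.SpineState]
    failures: list[dict] = field(default_factory=list)

    def report_dict(self) -> dict:
        return {
            "cases": {
                f"{p}|{c}": rep.as_dict() for (p, c), rep in sorted(self.reports.items())
            },
            "cohort": self.summary.as_dict(),
            "spine": {
                f"{p}|{c}": {
                    "rotations_deg": st.rotations_deg,
                    "moment_Nm": st.moment_Nm,
                    "idp_MPa": st.idp_MPa,
                    "follower_load_N": st.follower_load_N,
                }
                for (p, c), st in sorted(self.spine_states.items())
            },
            "failures": self.failures,
        }


def _patient_contact(config: RunConfig, patient: VirtualPatient) -> cage_fe.ContactParams:
    if not config.bone_quality_layer_coupling:
        return config.contact
    scale = 0.7 + 0.6 * patient.bone_quality
    return replace(config.contact, layer_E_MPa=config.contact.layer_E_MPa * scale)


def _solve_case(
    model: cage_fe.BeamModel,
    bc: spine.SegmentBC,
    contact: cage_fe.ContactParams,
    config: RunConfig,
) -> cage_fe.Solution:
    sol = None
    for step_bc in bc.ramp():
        sol = cage_fe.solve_load_case(model, step_bc, contact, rod_share=1.0)
    assert sol is not None
    return sol


def run_cohort(config: RunConfig = RunConfig(), out_dir=None) -> RunResult:
    """Run the full cohort protocol and (optionally) write all exports.

    With ``out_dir`` (or ``config.out_dir`` if ``export_csv``/``export_vtk``
    are set and ``out_dir`` is not given) the function writes ``report.json``,
    ``cohort.csv``, a long-format ``metrics.csv``, per-case strain CSV/VTK
    files and a ``failures.json`` manifest. Fixed seed implies identical
    numeric outputs.
    """
    patients = sample_cohort(config.n_patients, config.seed, config.cohort_ranges)
    right = generate_cage(config.cage, seed=config.seed)
    left = right.mirrored()
    models = {"right": cage_fe.assemble(right), "left": cage_fe.assemble(left)}

    cases: list[CaseResult] = []
    reports: dict[tuple[str, str], mt.CaseMetrics] = {}
    states: dict[tuple[str, str], spine.SpineState] = {}
    failures: list[dict] = []

    for patient in patients:
        fsus = spine.build_fsu_chain(patient, config.spine)
        contact = _patient_contact(config, patient)
        for condition in config.conditions:
            try:
                lc = spine.make_load_case(
                    patient, condition, config.total_deflection_deg,
                    config.n_ramp_steps,
                )
                state = spine.distribute_rotation(
                    fsus, config.instrumented_level, lc,
                    config.instrumentation, config.spine,
                )
                bc = spine.segment_bc(
                    state, patient, lc, config.instrumentation,
                    config.instrumented_level,
                )
            except Exception as exc:
                failures.append(
                    {"patient": patient.id, "condition": condition,
                     "stage": "surrogate", "error": str(exc)}
                )
                log.error("surrogate failed for %s/%s: %s",
                          patient.id, condition, exc)
                continue
            states[(patient.id, condition)] = state
            side_results = []
            for side, model in models.items():
                try:
                    half_bc = replace(bc, axial_force_N=bc.axial_force_N / 2.0)
                    sol = _solve_case(model, half_bc, contact, config)
                    strain = cage_fe.surface_strain(
                        sol, config.n_axial, config.n_circ,
                        config.include_block_surface,
                    )
                    frac = mt.threshold_fraction(strain, config.threshold_ue)
                    hist = mt.strain_histogram(strain, config.bin_edges_ue)
                    if config.pressure_normalisation == "nominal":
                        press = mt.mean_nominal_pressure(sol.caudal)
                    else:
                        press = mt.mean_contact_pressure(sol.caudal)
                    vm = cage_fe.von_mises_peak(
                        sol, config.n_axial, config.n_circ,
                        config.include_block_surface,
                    )
                    res = CaseResult(
                        patient_id=patient.id, condition=condition, side=side,
                        solution=sol, strain=strain, fraction_pct=frac,
                        histogram=hist, mean_pressure_MPa=press, peak_vm_MPa=vm,
                    )
                    cases.append(res)
                    side_results.append(res)
                    log.info(
                        "%s/%s/%s: residual %.3e N, %d contact iterations, "
                        "fraction>%g ue = %.2f%%",
                        patient.id, condition, side, sol.equilibrium_residual(),
                        sol.n_iterations, config.threshold_ue, frac,
                    )
                except Exception as exc:
                    failures.append(
                        {"patient": patient.id, "condition": condition,
                         "side": side, "stage": "cage_fe", "error": str(exc)}
                    )
                    log.error("cage FE failed for %s/%s/%s: %s",
                              patient.id, condition, side, exc)
            if side_results:
                # amalgamate left/right by averaging before cohort statistics
                amal = mt.CaseMetrics(
                    fraction_above_threshold_pct=float(
                        np.mean([r.fraction_pct for r in side_results])
                    ),
                    histogram_edges_ue=list(side_results[0].histogram[0]),
                    histogram_pct=list(
                        np.mean([r.histogram[1] for r in side_results], axis=0)
                    ),
                    mean_caudal_pressure_MPa=float(
                        np.mean([r.mean_pressure_MPa for r in side_results])
                    ),
                    peak_von_mises_MPa=float(
                        np.mean([r.peak_vm_MPa for r in side_results])
                    ),
                    anterior_mean_abs_ue=float(np.mean([
                        _region_mean(r.strain, "anterior") for r in side_results
                    ])),
                    posterior_mean_abs_ue=float(np.mean([
                        _region_mean(r.strain, "posterior") for r in side_results
                    ])),
                    median_abs_ue=float(np.mean([
                        _weighted_median(np.abs(r.strain.principal_ue),
                                         r.strain.weight_mm2)
                        for r in side_results
                    ])),
                )
                reports[(patient.id, condition)] = amal

    summary = mt.cohort_summary(reports) if reports else mt.CohortSummary()
    result = RunResult(
        config=config, patients=patients, cases=cases, reports=reports,
        summary=summary, spine_states=states, failures=failures,
    )
    if out_dir is None and (config.export_csv or config.export_vtk):
        out_dir = config.out_dir
    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _region_mean(field: mt.StrainField, region: str) -> float:
    mask = field.region == region
    w = field.weight_mm2[mask]
    return float(np.average(np.abs(field.principal_ue[mask]), weights=w))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cum = np.cumsum(w)
    return float(v[np.searchsorted(cum, 0.5 * cum[-1])])


def _write_outputs(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    with open(out / "report.json", "w") as fh:
        json.dump(result.report_dict(), fh, indent=1, sort_keys=True)
    with open(out / "failures.json", "w") as fh:
        json.dump(result.failures, fh, indent=1)
    export_cohort_csv(result.patients, out / "cohort.csv")
    rows = []
    for (pid, cond), rep in sorted(result.reports.items()):
        for metric, value in rep.as_dict().items():
            if isinstance(value, (int, float)):
                rows.append(
                    {"patient": pid, "condition": cond,
                     "metric": metric, "value": value}
                )
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
    cfg.to_yaml(out / "config.yaml")
    if cfg.export_csv:
        for case in result.cases:
            stem = f"{case.patient_id}_{case.condition}_{case.side}"
            cage_fe.export_strains_csv(case.strain, out / f"strains_{stem}.csv")
    if cfg.export_vtk:
        for case in result.cases:
            stem = f"{case.patient_id}_{case.condition}_{case.side}"
            cage_fe.export_solution_vtk(case.solution, out / f"solution_{stem}.vtk")


# ---------------------------------------------------------------------------
# validation suite (analytic oracles as a runtime self-check)
# ---------------------------------------------------------------------------

@dataclass
class Check:
    name: str
    measured: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.measured < self.tolerance


@dataclass
class ValidationReport:
    checks: list[Check]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            tag = "PASS" if c.passed else "FAIL"
            lines.append(
                f"[{tag}] {c.name}: measured {c.measured:.3e} "
                f"(tolerated {c.tolerance:.1e})"
            )
        lines.append("validation " + ("PASSED" if self.passed else "FAILED"))
        return "\n".join(lines)


def _dense_solve(K: np.ndarray, f: np.ndarray, fixed: list[int]) -> np.ndarray:
    free = [i for i in range(len(f)) if i not in set(fixed)]
    u = np.zeros(len(f))
    u[free] = np.linalg.solve(K[np.ix_(free, free)], f[free])
    return u


def validate_suite(fault_injection: bool = False) -> ValidationReport:
    """Run the analytic-oracle and equilibrium self-checks.

    ``fault_injection`` perturbs the solved contact forces by 0.1% before
    the equilibrium check, as a negative control demonstrating that the
    check can fail.
    """
    checks: list[Check] = []
    E, nu = 116_000.0, 0.32
    sec = Section(diameter=0.8, E=E, nu=nu)
    L = 10.0
    p1, p2 = np.zeros(3), np.array([L, 0.0, 0.0])
    K = global_stiffness(sec, p1, p2)

    # axial rod: u = F L / (E A)
    F = 100.0
    f = np.zeros(12)
    f[6] = F
    u = _dense_solve(K, f, fixed=list(range(6)))
    checks.append(
        Check("axial rod tip displacement vs FL/EA",
              abs(u[6] - F * L / (E * sec.A)) / (F * L / (E * sec.A)), 1e-10)
    )

    # Timoshenko cantilever: delta = PL^3/3EI + PL/(kappa G A)
    P = 10.0
    f = np.zeros(12)
    f[7] = P
    u = _dense_solve(K, f, fixed=list(range(6)))
    from .beam import KAPPA_S
    delta = P * L**3 / (3 * E * sec.I) + P * L / (KAPPA_S * sec.G * sec.A)
    checks.append(
        Check("Timoshenko cantilever tip deflection", abs(u[7] - delta) / delta,
              1e-8)
    )

    # torsion: surface principal strain (d/4) * twist rate
    T = 5.0
    f = np.zeros(12)
    f[9] = T
    u = _dense_solve(K, f, fixed=list(range(6)))
    twist_rate = u[9] / L
    gamma = 0.5 * sec.diameter * twist_rate
    principal = gamma / 2.0  # pure shear
    expected = 0.25 * sec.diameter * T / (sec.G * sec.J)
    checks.append(
        Check("torsion surface principal strain vs (d/4) phi'",
              abs(principal - expected) / expected, 1e-10)
    )

    # rigid-body patch test on the default lattice
    lattice = generate_cage()
    model = cage_fe.assemble(lattice)
    trans = np.array([0.3, -0.2, 0.5])
    rot = np.array([1e-3, -2e-3, 1.5e-3])
    centre = lattice.nodes.mean(axis=0)
    u_rigid = np.zeros(6 * len(lattice.nodes))
    for k, pos in enumerate(lattice.nodes):
        u_rigid[6 * k : 6 * k + 3] = trans + np.cross(rot, pos - centre)
        u_rigid[6 * k + 3 : 6 * k + 6] = rot
    energy = 0.5 * float(u_rigid @ (model.K_lattice @ u_rigid))  # N*mm
    checks.append(Check("rigid-body patch test strain energy [J]",
                        abs(energy) * 1e-3, 1e-12))

    # equilibrium on a solved representative case
    patient = sample_cohort(1, seed=7)[0]
    fsus = spine.build_fsu_chain(patient)
    lc = spine.make_load_case(patient, "flexion")
    state = spine.distribute_rotation(fsus, "L4-5", lc)
    bc = spine.segment_bc(state, patient, lc)
    half_bc = replace(bc, axial_force_N=bc.axial_force_N / 2.0)
    sol = cage_fe.solve_load_case(model, half_bc)
    if fault_injection:
        sol.caudal.normal_force_N = sol.caudal.normal_force_N * 1.001
    checks.append(
        Check("global force balance |sum reactions - applied| / |applied|",
              sol.equilibrium_residual() / half_bc.axial_force_N, 1e-8)
    )
    tension = float(np.minimum(sol.caudal.pressure_MPa, 0.0).min(initial=0.0))
    checks.append(
        Check("no tensile unilateral contact pressure [MPa]", abs(tension), 1e-9)
    )
    return ValidationReport(checks)
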