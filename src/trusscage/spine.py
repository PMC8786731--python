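"""Lumped lumbar-spine surrogate.

The full continuum L1-S1 model (poro-hyperelastic discs, ligaments, facets)
is collapsed into a serial chain of five functional spinal units (FSUs),
each described by an invertible moment-rotation map

    M(theta) = k0 * a(theta) * b * sinh(theta / b)

with initial stiffness ``k0`` (Nm/deg), softening-to-stiffening shape
parameter ``b`` (deg; ``b == 0`` degenerates to the linear map
``M = k0*theta``) and an extension/flexion asymmetry factor ``a`` (< 1 makes
extension more compliant, reproducing the stiff-in-flexion behaviour of the
instrumented spine). Disc degeneration (Pfirrmann grade) stiffens the map
and lowers the nucleus swelling pressure through per-grade multiplier
tables.

A prescribed total sagittal deflection is shared among the FSUs by solving
the series-equilibrium problem: one chain moment M such that the inverted
per-FSU rotations sum to the target. The instrumented (operated) level acts
in parallel with the pedicle-screw/rod construct, whose rotational stiffness
is derived from two titanium rods treated as fixed-guided beams acting at a
posterior lever arm.

Sign convention: positive rotations/moments are flexion, negative extension.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .cohort import DISC_LEVELS, VirtualPatient

log = logging.getLogger(__name__)

CONDITIONS = ("neutral", "extension", "flexion")


class ModelError(RuntimeError):
    """A surrogate model is ill-posed (non-invertible map, bad geometry)."""


class NumericalError(RuntimeError):
    """An iterative solve failed to converge within its iteration cap."""


# ---------------------------------------------------------------------------
# follower load
# ---------------------------------------------------------------------------

# Bilinear reference tables of the compressive follower-load resultant at L1
# (N) over (weight kg, height cm), one per condition. Calibrated so the
# default cohort hull (60-74 kg x 164-172 cm) maps into the physiological
# ranges 368-454 N (neutral), 748-888 N (extension) and 976-1148 N (flexion).
_FL_WEIGHTS = np.array([55.0, 80.0])
_FL_HEIGHTS = np.array([158.0, 178.0])
_FL_COEFFS = {  # base at (67 kg, 168 cm), dN/dkg, dN/dcm
    "neutral": (411.0, 5.5, 1.0),
    "extension": (818.0, 8.8, 1.4),
    "flexion": (1062.0, 11.0, 1.8),
}


def _follower_table(condition: str) -> RegularGridInterpolator:
    base, cw, ch = _FL_COEFFS[condition]
    w, h = np.meshgrid(_FL_WEIGHTS, _FL_HEIGHTS, indexing="ij")
    values = base + cw * (w - 67.0) + ch * (h - 168.0)
    return RegularGridInterpolator((_FL_WEIGHTS, _FL_HEIGHTS), values)


_FL_INTERP = {c: _follower_table(c) for c in _FL_COEFFS}


def follower_load(patient: VirtualPatient, condition: str) -> float:
    """Patient-specific follower-load magnitude (N) for one load condition.

    Bilinear interpolation of the built-in reference table over (weight,
    height); monotonically non-decreasing in weight. Queries outside the
    table hull are clamped to it with a logged warning.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    w, h = patient.weight_kg, patient.height_cm
    wc = float(np.clip(w, _FL_WEIGHTS[0], _FL_WEIGHTS[-1]))
    hc = float(np.clip(h, _FL_HEIGHTS[0], _FL_HEIGHTS[-1]))
    if wc != w or hc != h:
        log.warning(
            "patient %s (%.1f kg, %.1f cm) outside follower-load table hull; "
            "clamped to (%.1f kg, %.1f cm)", patient.id, w, h, wc, hc,
        )
    return float(_FL_INTERP[condition]((wc, hc)))


# ---------------------------------------------------------------------------
# FSU chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpineCalibration:
    """Tunable surrogate parameters (all overridable via the run config).

    ``k0_Nm_per_deg`` is the healthy-disc flexion stiffness at the origin;
    ``nonlinearity_deg`` the sinh shape parameter b; ``asymmetry`` the
    extension/flexion stiffness ratio. The IDP model is
    ``pi_swell * f_grade + c_u * F/A + c_m * |M| * g(condition)`` — an
    undrained short-time superposition of swelling pressure, follower-load
    pressurisation and bending-induced nucleus pressurisation.
    """

    k0_Nm_per_deg: float = 2.5
    nonlinearity_deg: float = 3.0
    asymmetry: float = 0.40
    grade_stiffness: dict[int, float] = field(
        default_factory=lambda: {1: 0.85, 2: 1.0, 3: 1.2, 4: 1.45, 5: 1.7}
    )
    grade_swell: dict[int, float] = field(
        default_factory=lambda: {1: 1.1, 2: 1.0, 3: 0.7, 4: 0.45, 5: 0.3}
    )
    swelling_pressure_MPa: float = 0.45
    disc_area_mm2: float = 1700.0  # at 168 cm stature, scaled by height^2
    c_undrained: float = 0.6
    c_moment_MPa_per_Nm: float = 0.06
    g_flexion: float = 1.0
    g_extension: float = 0.25
    lordosis_asym_slope: float = 0.01  # per degree of lordosis off 34.5


@dataclass(frozen=True)
class FSUModel:
    """One functional spinal unit of the serial chain.

    ``k0_Nm_per_deg`` is already grade-adjusted; ``pfirrmann_factor``
    multiplies the swelling pressure in the IDP superposition.
    """

    level: str
    k0_Nm_per_deg: float
    nonlinearity_deg: float = 3.0
    asymmetry: float = 0.40
    pfirrmann_factor: float = 1.0
    disc_area_mm2: float = 1700.0
    swelling_pressure_MPa: float = 0.45

    def __post_init__(self) -> None:
        if self.k0_Nm_per_deg <= 0:
            raise ModelError(f"{self.level}: k0 must be > 0")
        if self.asymmetry <= 0:
            raise ModelError(f"{self.level}: asymmetry must be > 0")
        if self.disc_area_mm2 <= 0:
            raise ModelError(f"{self.level}: disc area must be > 0")
        if self.swelling_pressure_MPa < 0:
            raise ModelError(f"{self.level}: swelling pressure must be >= 0")

    def moment(self, theta_deg: float) -> float:
        """Moment (Nm) at rotation ``theta_deg``; odd, strictly monotone."""
        k0 = self.k0_Nm_per_deg * (1.0 if theta_deg >= 0 else self.asymmetry)
        b = self.nonlinearity_deg
        if b == 0:
            return k0 * theta_deg
        return k0 * b * math.sinh(theta_deg / b)

    def rotation(self, moment_Nm: float) -> float:
        """Inverse moment-rotation map (deg), closed form."""
        k0 = self.k0_Nm_per_deg * (1.0 if moment_Nm >= 0 else self.asymmetry)
        b = self.nonlinearity_deg
        if b == 0:
            return moment_Nm / k0
        return b * math.asinh(moment_Nm / (k0 * b))


@dataclass(frozen=True)
class InstrumentationParams:
    """Pedicle-screw/rod construct bridging the operated level.

    The two titanium rods are modelled as fixed-guided beams of free length
    ``rod_length_mm`` (the posterior height of the segment); relative
    translation of the screw heads loads them in the guided-end deflection
    mode, giving a translational stiffness ``12 E I / L^3`` per rod acting at
    ``posterior_offset_mm`` behind the disc centre. Screws are rigid anchors.
    """

    rod_diameter_mm: float = 5.0
    screw_length_mm: float = 32.0
    screw_diameter_mm: float = 5.0
    posterior_offset_mm: float = 40.0
    rod_length_mm: float = 28.0
    material: tuple[float, float] = (116_000.0, 0.32)

    def __post_init__(self) -> None:
        for name in (
            "rod_diameter_mm", "screw_length_mm", "screw_diameter_mm",
            "posterior_offset_mm", "rod_length_mm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def rod_translational_stiffness(self) -> float:
        """Fixed-guided lateral stiffness of ONE rod, N/mm."""
        E, _ = self.material
        I = math.pi * self.rod_diameter_mm**4 / 64.0
        return 12.0 * E * I / self.rod_length_mm**3

    def rotational_stiffness_Nm_per_deg(self) -> float:
        """Rotational stiffness of the two-rod construct about the disc centre."""
        k_t = 2.0 * self.rod_translational_stiffness()  # N/mm
        k_rot = k_t * self.posterior_offset_mm**2  # N*mm/rad
        return k_rot / 1000.0 * math.pi / 180.0  # Nm/deg


@dataclass(frozen=True)
class LoadCase:
    condition: str
    total_rotation_deg: float
    follower_load_N: float
    n_ramp_steps: int = 1

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "neutral" and self.total_rotation_deg != 0.0:
            raise ValueError("neutral condition requires zero total rotation")
        if self.follower_load_N <= 0:
            raise ValueError("follower_load_N must be > 0")
        if self.n_ramp_steps < 1:
            raise ValueError("n_ramp_steps must be >= 1")


@dataclass
class SpineState:
    """Solved chain state for one patient x condition."""

    rotations_deg: dict[str, float]
    moment_Nm: float
    idp_MPa: dict[str, float]
    reaction_moment_Nm: float
    condition: str
    follower_load_N: float


def build_fsu_chain(
    patient: VirtualPatient, calib: SpineCalibration = SpineCalibration()
) -> list[FSUModel]:
    """Instantiate the five-level FSU chain from a patient's spine state."""
    area = calib.disc_area_mm2 * (patient.height_cm / 168.0) ** 2
    asym = calib.asymmetry * (
        1.0 + calib.lordosis_asym_slope * (patient.lordosis_deg - 34.5)
    )
    asym = max(asym, 0.05)
    fsus = []
    for level in DISC_LEVELS:
        grade = patient.pfirrmann.get(level, 2)
        fsus.append(
            FSUModel(
                level=level,
                k0_Nm_per_deg=calib.k0_Nm_per_deg * calib.grade_stiffness[grade],
                nonlinearity_deg=calib.nonlinearity_deg,
                asymmetry=asym,
                pfirrmann_factor=calib.grade_swell[grade],
                disc_area_mm2=area,
                swelling_pressure_MPa=calib.swelling_pressure_MPa,
            )
        )
    return fsus


def make_load_case(
    patient: VirtualPatient,
    condition: str,
    total_deflection_deg: float = 20.0,
    n_ramp_steps: int = 1,
) -> LoadCase:
    """Default loading protocol: 0 / -20 / +20 deg with the condition's
    follower load."""
    sign = {"neutral": 0.0, "extension": -1.0, "flexion": 1.0}[condition]
    return LoadCase(
        condition=condition,
        total_rotation_deg=sign * total_deflection_deg,
        follower_load_N=follower_load(patient, condition),
        n_ramp_steps=n_ramp_steps,
    )


def _instrumented_rotation(
    fsu: FSUModel, k_instr_Nm_per_deg: float, moment_Nm: float
) -> float:
    """Invert M = M_fsu(theta) + k_instr*theta (monotone) by bisection."""
    if math.isinf(k_instr_Nm_per_deg):
        return 0.0
    if moment_Nm == 0.0:
        return 0.0

    def f(theta: float) -> float:
        return fsu.moment(theta) + k_instr_Nm_per_deg * theta - moment_Nm

    hi = max(1e-6, abs(moment_Nm) / k_instr_Nm_per_deg if k_instr_Nm_per_deg
             else 1.0)
    sgn = 1.0 if moment_Nm > 0 else -1.0
    for _ in range(200):
        if f(sgn * hi) * sgn >= 0:
            break
        hi *= 2.0
    lo, hi_b = (0.0, sgn * hi) if sgn > 0 else (sgn * hi, 0.0)
    for _ in range(200):
        mid = 0.5 * (lo + hi_b)
        if f(mid) <= 0:
            lo = mid
        else:
            hi_b = mid
        if hi_b - lo < 1e-14:
            break
    return 0.5 * (lo + hi_b)


def distribute_rotation(
    fsus: list[FSUModel],
    instrumented_level: str,
    load_case: LoadCase,
    instrumentation: InstrumentationParams = InstrumentationParams(),
    calib: SpineCalibration = SpineCalibration(),
) -> SpineState:
    """Share a prescribed total sagittal deflection over the serial FSU chain.

    Solves for the single chain moment M with sum_i theta_i(M) equal to the
    requested total rotation (series equilibrium: the moment is identical in
    every FSU). The instrumented level deflects against the FSU plus the
    parallel rod-construct stiffness. Bisection on M to |sum theta - target|
    < 1e-10 deg, capped at 200 iterations.
    """
    levels = [f.level for f in fsus]
    if levels.count(instrumented_level) != 1:
        raise ValueError(
            f"exactly one FSU must match instrumented level {instrumented_level!r}"
        )
    k_instr = instrumentation.rotational_stiffness_Nm_per_deg()

    def total_rotation(moment: float) -> float:
        tot = 0.0
        for fsu in fsus:
            if fsu.level == instrumented_level:
                tot += _instrumented_rotation(fsu, k_instr, moment)
            else:
                tot += fsu.rotation(moment)
        return tot

    target = load_case.total_rotation_deg
    if target == 0.0:
        moment = 0.0
    else:
        # bracket, then bisect on M
        hi = 1.0
        sgn = 1.0 if target > 0 else -1.0
        for _ in range(200):
            if (total_rotation(sgn * hi) - target) * sgn >= 0:
                break
            hi *= 2.0
        else:
            raise NumericalError("failed to bracket the chain moment")
        lo_m, hi_m = (0.0, sgn * hi) if sgn > 0 else (sgn * hi, 0.0)
        converged = False
        for _ in range(200):
            mid = 0.5 * (lo_m + hi_m)
            r = total_rotation(mid) - target
            if abs(r) < 1e-10:
                converged = True
                lo_m = hi_m = mid
                break
            if r < 0:
                lo_m = mid
            else:
                hi_m = mid
        moment = 0.5 * (lo_m + hi_m)
        if not converged and abs(total_rotation(moment) - target) > 1e-8:
            raise NumericalError(
                "chain-moment bisection did not converge in 200 iterations"
            )

    rotations: dict[str, float] = {}
    for fsu in fsus:
        if fsu.level == instrumented_level:
            rotations[fsu.level] = _instrumented_rotation(fsu, k_instr, moment)
        else:
            rotations[fsu.level] = fsu.rotation(moment)
    # renormalise the O(1e-10) bisection residual so the rotation budget is
    # conserved exactly
    resid = target - sum(rotations.values())
    if rotations and abs(resid) > 0:
        key = max(rotations, key=lambda k: abs(rotations[k]))
        if target != 0.0:
            rotations[key] += resid

    idp = {
        fsu.level: disc_idp(
            fsu, load_case.follower_load_N, moment, load_case.condition, calib
        )
        for fsu in fsus
    }
    return SpineState(
        rotations_deg=rotations,
        moment_Nm=moment,
        idp_MPa=idp,
        reaction_moment_Nm=moment,
        condition=load_case.condition,
        follower_load_N=load_case.follower_load_N,
    )


def disc_idp(
    fsu: FSUModel,
    axial_force_N: float,
    moment_Nm: float,
    condition: str,
    calib: SpineCalibration = SpineCalibration(),
) -> float:
    """Intradiscal pressure (MPa) of one disc under the chain loads.

    Undrained short-time superposition: grade-scaled swelling pressure, a
    follower-load pressurisation term linear in F/A, and a bending term
    linear in |M| that is stronger in flexion than in extension. No time
    integration (5-s load steps are fast against the disc's drainage time).
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    if fsu.disc_area_mm2 <= 0:
        raise ModelError("disc area must be positive")
    if not (math.isfinite(axial_force_N) and math.isfinite(moment_Nm)):
        raise ValueError("loads must be finite")
    if axial_force_N < 0:
        raise ValueError("axial_force_N must be >= 0")
    g = {"neutral": 0.0, "extension": calib.g_extension,
         "flexion": calib.g_flexion}[condition]
    return (
        fsu.swelling_pressure_MPa * fsu.pfirrmann_factor
        + calib.c_undrained * axial_force_N / fsu.disc_area_mm2
        + calib.c_moment_MPa_per_Nm * abs(moment_Nm) * g
    )


@dataclass(frozen=True)
class SegmentBC:
    """Boundary conditions delivered to the operated-segment cage model."""

    cranial_plate_rotation_deg: float
    axial_force_N: float
    instrumentation: InstrumentationParams = InstrumentationParams()
    n_ramp_steps: int = 1

    def __post_init__(self) -> None:
        if self.axial_force_N <= 0:
            raise ValueError("axial_force_N must be > 0 in every load case")

    def ramp(self) -> list["SegmentBC"]:
        """Linear simultaneous ramp of rotation and force over the steps."""
        return [
            replace(
                self,
                cranial_plate_rotation_deg=self.cranial_plate_rotation_deg * s,
                axial_force_N=self.axial_force_N * s,
                n_ramp_steps=1,
            )
            for s in np.linspace(1.0 / self.n_ramp_steps, 1.0, self.n_ramp_steps)
        ]


def segment_bc(
    state: SpineState,
    patient: VirtualPatient,
    load_case: LoadCase,
    instrumentation: InstrumentationParams = InstrumentationParams(),
    instrumented_level: str = "L4-5",
) -> SegmentBC:
    """Extract the operated segment's share of the chain solution.

    The cranial plate of the cage model rotates by the instrumented level's
    rotation share; the axial force is the condition-level follower load
    (no per-level attenuation). Rotation and force ramp simultaneously.
    """
    if instrumented_level not in state.rotations_deg:
        raise ValueError(f"state does not contain level {instrumented_level!r}")
    return SegmentBC(
        cranial_plate_rotation_deg=state.rotations_deg[instrumented_level],
        axial_force_N=state.follower_load_N,
        instrumentation=instrumentation,
        n_ramp_steps=load_case.n_ramp_steps,
    )
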