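"""Spine surrogate: follower loads, series chain, IDP superposition."""

import math

import numpy as np
import pytest

import trusscage as tc
from trusscage.cohort import DISC_LEVELS
from trusscage.spine import FSUModel, InstrumentationParams, LoadCase

RANGES = {"neutral": (368.0, 454.0), "extension": (748.0, 888.0),
          "flexion": (976.0, 1148.0)}


def _patient(weight=67.0, height=168.0, lordosis=34.5, grades=None, bq=0.8):
    return tc.VirtualPatient(
        id="T", weight_kg=weight, height_cm=height, lordosis_deg=lordosis,
        pfirrmann=grades or {lv: 2 for lv in DISC_LEVELS}, bone_quality=bq,
    )


# ---------------------------------------------------------------------------
# follower load
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("condition", ["neutral", "extension", "flexion"])
def test_follower_load_within_physiological_range(default_cohort, condition):
    lo, hi = RANGES[condition]
    for p in default_cohort:
        assert lo <= tc.follower_load(p, condition) <= hi


@pytest.mark.parametrize("condition", ["neutral", "extension", "flexion"])
def test_follower_load_monotone_in_weight(condition):
    light = _patient(weight=60.0)
    heavy = _patient(weight=74.0)
    assert tc.follower_load(heavy, condition) >= tc.follower_load(light, condition)


def test_follower_load_clamps_outside_hull(caplog):
    import logging

    giant = _patient(weight=200.0, height=210.0)
    with caplog.at_level(logging.WARNING, logger="trusscage.spine"):
        val = tc.follower_load(giant, "neutral")
    assert any("clamped" in r.message for r in caplog.records)
    corner = _patient(weight=80.0, height=178.0)
    assert val == tc.follower_load(corner, "neutral")


# ---------------------------------------------------------------------------
# rotation distribution over the serial chain
# ---------------------------------------------------------------------------

def _linear_fsus(k=2.0, n=5):
    return [
        FSUModel(level=lv, k0_Nm_per_deg=k, nonlinearity_deg=0.0, asymmetry=1.0)
        for lv in DISC_LEVELS[:n]
    ]


def _soft_instr(length=1e6):
    # rod stiffness ~ 1/L^3: a kilometre-long rod removes the parallel path
    return InstrumentationParams(rod_length_mm=length)


def test_zero_rotation_identity(default_cohort):
    p = default_cohort[0]
    fsus = tc.build_fsu_chain(p)
    lc = tc.make_load_case(p, "neutral")
    state = tc.distribute_rotation(fsus, "L4-5", lc)
    assert state.moment_Nm == 0.0
    assert all(v == 0.0 for v in state.rotations_deg.values())
    # IDP at the (follower-loaded) swelling baseline
    for lv, fsu in zip(DISC_LEVELS, fsus):
        base = tc.disc_idp(fsu, lc.follower_load_N, 0.0, "neutral")
        assert state.idp_MPa[lv] == pytest.approx(base)


def test_identical_linear_springs_share_equally():
    """Five identical linear FSUs in series: each takes 4 deg, M = 4k."""
    k = 2.0
    lc = LoadCase("flexion", 20.0, 1000.0)
    state = tc.distribute_rotation(
        _linear_fsus(k), "L4-5", lc, instrumentation=_soft_instr()
    )
    for theta in state.rotations_deg.values():
        assert theta == pytest.approx(4.0, abs=1e-8)
    assert state.moment_Nm == pytest.approx(4.0 * k, rel=1e-8)


def test_rigid_instrumentation_locks_operated_level():
    """k_instr -> infinity: instrumented rotation -> 0, others -> 5 deg."""
    lc = LoadCase("flexion", 20.0, 1000.0)
    stiff = InstrumentationParams(rod_length_mm=0.5)  # k ~ 1/L^3 -> huge
    state = tc.distribute_rotation(_linear_fsus(), "L4-5", lc, stiff)
    assert abs(state.rotations_deg["L4-5"]) < 1e-3
    for lv in ("L1-2", "L2-3", "L3-4", "L5-S1"):
        assert state.rotations_deg[lv] == pytest.approx(5.0, abs=1e-3)


@pytest.mark.parametrize("condition,target", [("extension", -20.0),
                                              ("flexion", 20.0)])
def test_rotation_budget_conserved(default_cohort, condition, target):
    for p in default_cohort:
        fsus = tc.build_fsu_chain(p)
        lc = tc.make_load_case(p, condition)
        state = tc.distribute_rotation(fsus, "L4-5", lc)
        assert sum(state.rotations_deg.values()) == pytest.approx(
            target, abs=1e-9
        )
        # series equilibrium: the chain moment is a single shared value
        assert state.reaction_moment_Nm == state.moment_Nm


def test_flexion_stiffer_than_extension(default_cohort):
    """|reaction moment| at 20 deg flexion exceeds 20 deg extension."""
    for p in default_cohort:
        fsus = tc.build_fsu_chain(p)
        m = {}
        for cond in ("extension", "flexion"):
            lc = tc.make_load_case(p, cond)
            m[cond] = tc.distribute_rotation(fsus, "L4-5", lc).moment_Nm
        assert m["extension"] < 0 < m["flexion"]
        assert abs(m["flexion"]) > abs(m["extension"])


def test_duplicate_instrumented_level_rejected():
    fsus = _linear_fsus(n=5)
    with pytest.raises(ValueError):
        tc.distribute_rotation(fsus, "T12-L1", LoadCase("flexion", 20.0, 500.0))


# ---------------------------------------------------------------------------
# intradiscal pressure
# ---------------------------------------------------------------------------

def _fsu(grade=2):
    calib = tc.SpineCalibration()
    p = _patient(grades={lv: grade for lv in DISC_LEVELS})
    return tc.build_fsu_chain(p, calib)[2]  # L3-4


def test_unloaded_grade2_idp_in_neutral_band():
    assert 0.4 <= tc.disc_idp(_fsu(2), 0.0, 0.0, "neutral") <= 0.8


def test_degenerated_disc_has_lower_idp():
    idp2 = tc.disc_idp(_fsu(2), 1000.0, 20.0, "flexion")
    idp3 = tc.disc_idp(_fsu(3), 1000.0, 20.0, "flexion")
    assert idp3 < idp2


def test_force_term_is_linear():
    fsu = _fsu(2)
    base = tc.disc_idp(fsu, 0.0, 0.0, "neutral")
    inc1 = tc.disc_idp(fsu, 400.0, 0.0, "neutral") - base
    inc2 = tc.disc_idp(fsu, 800.0, 0.0, "neutral") - base
    assert inc2 == pytest.approx(2.0 * inc1, rel=1e-12)


def test_idp_flexion_exceeds_extension_everywhere(default_cohort):
    for p in default_cohort:
        fsus = tc.build_fsu_chain(p)
        states = {}
        for cond in ("extension", "flexion"):
            lc = tc.make_load_case(p, cond)
            states[cond] = tc.distribute_rotation(fsus, "L4-5", lc)
        for lv in DISC_LEVELS:
            assert states["flexion"].idp_MPa[lv] > states["extension"].idp_MPa[lv] > 0


def test_idp_rejects_bad_inputs():
    with pytest.raises(ValueError):
        tc.disc_idp(_fsu(), -10.0, 0.0, "neutral")
    with pytest.raises(ValueError):
        tc.disc_idp(_fsu(), 0.0, float("nan"), "neutral")


# ---------------------------------------------------------------------------
# segment boundary conditions
# ---------------------------------------------------------------------------

def test_segment_bc_signs_and_neutral_force(default_cohort):
    for p in default_cohort:
        fsus = tc.build_fsu_chain(p)
        for cond, sign in (("neutral", 0), ("extension", -1), ("flexion", 1)):
            lc = tc.make_load_case(p, cond)
            state = tc.distribute_rotation(fsus, "L4-5", lc)
            bc = tc.segment_bc(state, p, lc)
            if sign == 0:
                assert bc.cranial_plate_rotation_deg == 0.0
                assert 368.0 <= bc.axial_force_N <= 454.0
            else:
                assert math.copysign(1, bc.cranial_plate_rotation_deg) == sign


def test_segment_bc_missing_level():
    p = _patient()
    fsus = tc.build_fsu_chain(p)
    lc = tc.make_load_case(p, "flexion")
    state = tc.distribute_rotation(fsus, "L4-5", lc)
    with pytest.raises(ValueError):
        tc.segment_bc(state, p, lc, instrumented_level="T12-L1")


def test_ramp_is_linear_and_ends_at_full_load():
    bc = tc.SegmentBC(cranial_plate_rotation_deg=0.4, axial_force_N=1000.0,
                      n_ramp_steps=4)
    steps = bc.ramp()
    assert len(steps) == 4
    np.testing.assert_allclose(
        [s.axial_force_N for s in steps], [250.0, 500.0, 750.0, 1000.0]
    )
    assert steps[-1].cranial_plate_rotation_deg == pytest.approx(0.4)
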