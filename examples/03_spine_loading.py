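"""Share a 20-degree lumbar deflection over the spine surrogate.

For one virtual patient, solves the serial FSU chain (L1-2 .. L5-S1, the
operated L4-5 stiffened by the pedicle-screw/rod construct) in neutral,
extension and flexion, and prints the follower loads, the chain reaction
moment, the rotation share of the operated level and the intradiscal
pressures (IDP). Negative values are extension.
"""

import trusscage as tc

patient = tc.sample_cohort(4, seed=42)[0]
fsus = tc.build_fsu_chain(patient)
print(f"patient {patient.id}: {patient.weight_kg:.1f} kg, "
      f"{patient.height_cm:.1f} cm, grades {patient.pfirrmann}")

for cond in ("neutral", "extension", "flexion"):
    lc = tc.make_load_case(patient, cond)
    state = tc.distribute_rotation(fsus, "L4-5", lc)
    idp = ", ".join(f"{lv} {v:.2f}" for lv, v in state.idp_MPa.items())
    print(
        f"\n{cond:10s} follower load {lc.follower_load_N:6.0f} N, "
        f"chain moment {state.moment_Nm:6.2f} Nm, "
        f"L4-5 rotation share {state.rotations_deg['L4-5']:6.3f} deg"
    )
    print(f"           IDP [MPa]: {idp}")

print(
    "\nThe instrumented L4-5 level rotates far less than the free levels; "
    "IDP rises more in flexion than extension and is lower in degenerated "
    "discs."
)
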