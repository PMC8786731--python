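"""Sample a virtual patient cohort.

Draws four virtual patients with the demographic spread of a narrow
spinal-fusion study population (weight 60-74 kg, height 164-172 cm,
lordosis 29-40 deg, per-disc Pfirrmann grades II-IV) and prints them. The
weight/height pair drives the follower-load magnitudes; the grades drive
segment stiffness and disc swelling pressure; bone quality scales the
cage-endplate interface stiffness.
"""

import trusscage as tc

cohort = tc.sample_cohort(n=4, seed=42)
frame = tc.cohort_to_frame(cohort)
print(frame.to_string(index=False, float_format=lambda v: f"{v:.1f}"))
print(
    "\nEach row is one virtual patient; pfirrmann_* columns are the "
    "disc degeneration grades (II-IV) per lumbar level."
)
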