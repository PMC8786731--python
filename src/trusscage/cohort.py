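"""Virtual patient cohort generation.

A :class:`VirtualPatient` carries the demographic and spine-state parameters
that drive the loading (weight/height enter the follower-load interpolation)
and the lumped-segment stiffness (Pfirrmann grades, bone quality). The
default sampling ranges reproduce the spread of the four-patient study
population: body weight 60-74 kg, height 164-172 cm, lumbar lordosis 29-40
degrees and disc degeneration grades II-IV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DISC_LEVELS = ("L1-2", "L2-3", "L3-4", "L4-5", "L5-S1")

#: Cohort parameter bounds of the reference study population.
DEFAULT_RANGES = {
    "weight_kg": (60.0, 74.0),
    "height_cm": (164.0, 172.0),
    "lordosis_deg": (29.0, 40.0),
    "pfirrmann": (2, 4),
    "bone_quality": (0.6, 1.0),
}


@dataclass(frozen=True)
class VirtualPatient:
    """Demographic + spine-state parameter set for one simulated patient.

    Parameters
    ----------
    pfirrmann
        MRI-based disc degeneration grade (1 healthy .. 5 severe) per disc
        level ``L1-2`` .. ``L5-S1``.
    bone_quality
        Dimensionless scalar in (0, 1] standing in for trabecular bone
        density; scales the cage-endplate interface stiffness downstream.
    """

    id: str
    weight_kg: float
    height_cm: float
    lordosis_deg: float
    pfirrmann: dict[str, int] = field(default_factory=dict)
    bone_quality: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.weight_kg <= 0:
            raise ValueError(f"weight_kg must be > 0, got {self.weight_kg}")
        if self.height_cm <= 0:
            raise ValueError(f"height_cm must be > 0, got {self.height_cm}")
        if not 0 < self.bone_quality <= 1:
            raise ValueError(
                f"bone_quality must be in (0, 1], got {self.bone_quality}"
            )
        for level, grade in self.pfirrmann.items():
            if level not in DISC_LEVELS:
                raise ValueError(f"unknown disc level {level!r}")
            if not 1 <= int(grade) <= 5:
                raise ValueError(f"Pfirrmann grade must be 1..5, got {grade}")


def sample_cohort(
    n: int = 4,
    seed: int = 42,
    ranges: dict | None = None,
) -> list[VirtualPatient]:
    """Draw ``n`` virtual patients, uniformly and independently per parameter.

    Weight, height, lordosis and bone quality are sampled from continuous
    uniform distributions over the configured bounds; each disc's Pfirrmann
    grade is an independent integer uniform draw. No joint structure is
    imposed. Deterministic for a fixed ``seed``.

    Parameters
    ----------
    n
        Cohort size (default 4, the study cohort size).
    ranges
        Mapping overriding entries of :data:`DEFAULT_RANGES`; each value is a
        ``(low, high)`` pair with ``low <= high``.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    bounds = dict(DEFAULT_RANGES)
    if ranges:
        unknown = set(ranges) - set(bounds)
        if unknown:
            raise ValueError(f"unknown range keys: {sorted(unknown)}")
        bounds.update(ranges)
    for key, (lo, hi) in bounds.items():
        if lo > hi:
            raise ValueError(f"inverted bounds for {key}: ({lo}, {hi})")

    rng = np.random.default_rng(seed)
    patients = []
    for i in range(n):
        w = rng.uniform(*bounds["weight_kg"])
        h = rng.uniform(*bounds["height_cm"])
        lo_deg = rng.uniform(*bounds["lordosis_deg"])
        bq = rng.uniform(*bounds["bone_quality"])
        g_lo, g_hi = bounds["pfirrmann"]
        grades = {
            level: int(rng.integers(int(g_lo), int(g_hi) + 1))
            for level in DISC_LEVELS
        }
        patients.append(
            VirtualPatient(
                id=f"P{i + 1}",
                weight_kg=float(w),
                height_cm=float(h),
                lordosis_deg=float(lo_deg),
                pfirrmann=grades,
                bone_quality=float(bq),
                seed=int(seed),
            )
        )
    return patients


def cohort_to_frame(patients: list[VirtualPatient]) -> pd.DataFrame:
    """One row per patient; Pfirrmann grades expanded into per-level columns."""
    rows = []
    for p in patients:
        row = {
            "id": p.id,
            "weight_kg": p.weight_kg,
            "height_cm": p.height_cm,
            "lordosis_deg": p.lordosis_deg,
            "bone_quality": p.bone_quality,
            "seed": p.seed,
        }
        for level in DISC_LEVELS:
            row[f"pfirrmann_{level}"] = p.pfirrmann.get(level, 2)
        rows.append(row)
    return pd.DataFrame(rows)


def export_cohort_csv(patients: list[VirtualPatient], path) -> None:
    cohort_to_frame(patients).to_csv(path, index=False)
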