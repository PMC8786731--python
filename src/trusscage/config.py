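"""Run configuration: one serialisable object covering cohort, cage,
spine-surrogate calibration, contact, loading protocol and outputs.

Every field has a documented default; ``RunConfig`` round-trips through YAML
losslessly (tuples and integer-keyed tables are restored on load).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields, replace

import yaml

from .cage_fe import ContactParams
from .lattice import CageParams
from .metrics import DEFAULT_BIN_EDGES_UE, DEFAULT_THRESHOLD_UE
from .spine import InstrumentationParams, SpineCalibration


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of a cohort run.

    ``bone_quality_layer_coupling`` scales the interface-layer modulus with
    the patient's bone quality (0.7x at the floor to 1.3x at the ceiling),
    standing in for denser endplate bone stiffening the interface.
    """

    n_patients: int = 4
    seed: int = 42
    cohort_ranges: dict | None = None
    cage: CageParams = field(default_factory=CageParams)
    spine: SpineCalibration = field(default_factory=SpineCalibration)
    contact: ContactParams = field(default_factory=ContactParams)
    instrumentation: InstrumentationParams = field(
        default_factory=InstrumentationParams
    )
    instrumented_level: str = "L4-5"
    conditions: tuple[str, ...] = ("neutral", "extension", "flexion")
    total_deflection_deg: float = 20.0
    n_ramp_steps: int = 1
    threshold_ue: float = DEFAULT_THRESHOLD_UE
    bin_edges_ue: tuple[float, ...] = DEFAULT_BIN_EDGES_UE
    n_axial: int = 3
    n_circ: int = 8
    include_block_surface: bool = True
    bone_quality_layer_coupling: bool = True
    pressure_normalisation: str = "active"  # or "nominal"
    export_csv: bool = True
    export_vtk: bool = False
    out_dir: str = "trusscage_out"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        sub = {
            "cage": (CageParams, ("footprint_mm", "material")),
            "spine": (SpineCalibration, ()),
            "contact": (ContactParams, ()),
            "instrumentation": (InstrumentationParams, ("material",)),
        }
        kwargs = {}
        valid = {f.name for f in fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, value in data.items():
            if key in sub and isinstance(value, dict):
                klass, tuple_fields = sub[key]
                value = dict(value)
                for tf in tuple_fields:
                    if tf in value and isinstance(value[tf], list):
                        value[tf] = tuple(value[tf])
                for gk in ("grade_stiffness", "grade_swell"):
                    if gk in value and isinstance(value[gk], dict):
                        value[gk] = {int(k): float(v) for k, v in value[gk].items()}
                kwargs[key] = klass(**value)
            elif key in ("conditions", "bin_edges_ue") and isinstance(value, list):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_updates(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def _plain(obj):
    """Recursively convert tuples to lists for clean YAML emission."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj
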