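"""Mechanobiological output statistics.

The central quantity is the area-weighted share of the cage's strut surface
whose absolute maximum principal strain exceeds the bone-maintenance
stimulus threshold of 200 microstrain. Area weighting replaces node counting
on an unknown mesh; with uniform sampling density the two coincide.
Thresholding uses strict inequality ("exceeds"): samples at exactly the
threshold do not count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

log = logging.getLogger(__name__)

#: Bone homeostasis / formation stimulus threshold, microstrain.
DEFAULT_THRESHOLD_UE = 200.0
#: Default histogram bin edges, microstrain (final bin open-ended).
DEFAULT_BIN_EDGES_UE = (0.0, 100.0, 200.0, 500.0)


@dataclass
class StrainField:
    """Surface strain samples on the strut lattice.

    ``principal_ue`` is the absolute maximum principal strain in microstrain
    with the sign of the dominant axial fiber strain attached (negative =
    compressive). ``weight_mm2`` is each sample's share of lateral strut
    surface area; weights sum to the total lateral surface.
    """

    strut_id: np.ndarray
    s_mm: np.ndarray
    theta_rad: np.ndarray
    principal_ue: np.ndarray
    region: np.ndarray  # 'anterior' | 'posterior'
    weight_mm2: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.principal_ue)
        for name in ("strut_id", "s_mm", "theta_rad", "region", "weight_mm2"):
            if len(getattr(self, name)) != n:
                raise ValueError("strain-field arrays must share one length")
        if n and np.any(self.weight_mm2 <= 0):
            raise ValueError("sample weights must be positive")

    def __len__(self) -> int:
        return len(self.principal_ue)

    def subset(self, mask: np.ndarray) -> "StrainField":
        return StrainField(
            self.strut_id[mask], self.s_mm[mask], self.theta_rad[mask],
            self.principal_ue[mask], self.region[mask], self.weight_mm2[mask],
        )


@dataclass
class ContactField:
    """Per-node interface state on one contact face (normally the caudal)."""

    node_id: np.ndarray
    position_mm: np.ndarray  # (n, 3)
    normal_force_N: np.ndarray  # compression positive
    tangential_force_N: np.ndarray
    tributary_area_mm2: np.ndarray
    active: np.ndarray  # bool
    face: str = "caudal"

    @property
    def pressure_MPa(self) -> np.ndarray:
        return self.normal_force_N / self.tributary_area_mm2


def threshold_fraction(
    field: StrainField, threshold_ue: float = DEFAULT_THRESHOLD_UE
) -> float:
    """Area-weighted percentage of surface with |strain| strictly above
    ``threshold_ue``."""
    if len(field) == 0:
        raise ValueError("strain field is empty")
    w = field.weight_mm2
    above = np.abs(field.principal_ue) > threshold_ue
    return float(100.0 * w[above].sum() / w.sum())


def strain_histogram(
    field: StrainField, edges=DEFAULT_BIN_EDGES_UE
) -> tuple[np.ndarray, np.ndarray]:
    """Area-weighted |strain| histogram.

    Bins are half-open ``[e_i, e_{i+1})`` with a final open-ended bin
    ``[e_last, inf)``; samples below the first edge are folded into the
    first bin so the percentages always sum to 100.

    Returns ``(edges, percentages)`` with ``len(percentages) == len(edges)``.
    """
    if len(field) == 0:
        raise ValueError("strain field is empty")
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing")
    a = np.abs(field.principal_ue)
    w = field.weight_mm2
    # np.digitize right-open bins; index 0 (below first edge) folds into bin 0
    idx = np.digitize(a, edges[1:], right=False)
    pct = np.zeros(len(edges))
    np.add.at(pct, idx, w)
    pct *= 100.0 / w.sum()
    return edges, pct


def mean_contact_pressure(contact: ContactField) -> float:
    """Mean interface pressure over the area actually in contact, MPa.

    Total normal contact force divided by the tributary area of active
    nodes; 0 when nothing is in contact. Invariant to node ordering and to
    splitting a node's area between co-located nodes carrying the same
    total force.
    """
    act = contact.active
    area = float(contact.tributary_area_mm2[act].sum())
    if area == 0.0:
        return 0.0
    return float(contact.normal_force_N[act].sum() / area)


def mean_nominal_pressure(contact: ContactField) -> float:
    """Alternative normalisation by the full (nominal) face area."""
    area = float(contact.tributary_area_mm2.sum())
    return float(contact.normal_force_N[contact.active].sum() / area) if area else 0.0


@dataclass
class CaseMetrics:
    """Outputs of one solved patient x condition (left/right amalgamated)."""

    fraction_above_threshold_pct: float
    histogram_edges_ue: list[float]
    histogram_pct: list[float]
    mean_caudal_pressure_MPa: float
    peak_von_mises_MPa: float
    anterior_mean_abs_ue: float = float("nan")
    posterior_mean_abs_ue: float = float("nan")
    median_abs_ue: float = float("nan")

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _cv(values: np.ndarray) -> float:
    """Coefficient of variation, % (unbiased sd, n-1 denominator)."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        return float("nan")
    mean = values.mean()
    if mean == 0.0:
        log.warning("CV undefined for zero-mean values; reporting NaN")
        return float("nan")
    return float(values.std(ddof=1) / mean * 100.0)


def _mean_ci(values: np.ndarray) -> tuple[float, float]:
    """Descriptive mean and 95% t-interval half-width."""
    values = np.asarray(values, dtype=float)
    m = float(values.mean())
    if len(values) < 2:
        return m, float("nan")
    sem = values.std(ddof=1) / np.sqrt(len(values))
    hw = float(_st.t.ppf(0.975, len(values) - 1) * sem)
    return m, hw


#: metrics summarised across the cohort
COHORT_METRICS = ("fraction_above_threshold_pct", "mean_caudal_pressure_MPa")


@dataclass
class CohortSummary:
    """Cross-cohort variability of the headline metrics.

    For each metric: CV across patients within each condition, CV across
    conditions within each patient, their means, mean +/- 95% CI per
    condition, and the flag ``condition_variation_dominates`` (mean
    across-condition CV exceeds mean across-patient CV).
    """

    cv_across_patients: dict[str, dict[str, float]] = field(default_factory=dict)
    cv_across_conditions: dict[str, dict[str, float]] = field(default_factory=dict)
    mean_cv_across_patients: dict[str, float] = field(default_factory=dict)
    mean_cv_across_conditions: dict[str, float] = field(default_factory=dict)
    condition_means: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    condition_variation_dominates: dict[str, bool] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "cv_across_patients_pct": self.cv_across_patients,
            "cv_across_conditions_pct": self.cv_across_conditions,
            "mean_cv_across_patients_pct": self.mean_cv_across_patients,
            "mean_cv_across_conditions_pct": self.mean_cv_across_conditions,
            "condition_mean_ci95": {
                m: {c: list(v) for c, v in d.items()}
                for m, d in self.condition_means.items()
            },
            "condition_variation_dominates": self.condition_variation_dominates,
        }


def cohort_summary(
    reports: dict[tuple[str, str], CaseMetrics | dict],
) -> CohortSummary:
    """Summarise per-case metrics across the patient x condition grid.

    ``reports`` maps ``(patient_id, condition)`` to a :class:`CaseMetrics`
    (or an equivalent mapping). Left/right cage values must already be
    amalgamated (averaged) per patient. A degenerate grid (a single
    condition or patient) yields NaN for the corresponding CV.
    """
    if not reports:
        raise ValueError("no case metrics supplied")

    def get(case, metric):
        return case[metric] if isinstance(case, dict) else getattr(case, metric)

    patients = sorted({p for p, _ in reports})
    conditions = sorted({c for _, c in reports})
    out = CohortSummary()
    for metric in COHORT_METRICS:
        by_cond = {
            c: np.array([get(reports[(p, c)], metric) for p in patients
                         if (p, c) in reports])
            for c in conditions
        }
        by_pat = {
            p: np.array([get(reports[(p, c)], metric) for c in conditions
                         if (p, c) in reports])
            for p in patients
        }
        out.cv_across_patients[metric] = {c: _cv(v) for c, v in by_cond.items()}
        out.cv_across_conditions[metric] = {p: _cv(v) for p, v in by_pat.items()}
        pat_cvs = [v for v in out.cv_across_patients[metric].values()
                   if np.isfinite(v)]
        cond_cvs = [v for v in out.cv_across_conditions[metric].values()
                    if np.isfinite(v)]
        out.mean_cv_across_patients[metric] = (
            float(np.mean(pat_cvs)) if pat_cvs else float("nan")
        )
        out.mean_cv_across_conditions[metric] = (
            float(np.mean(cond_cvs)) if cond_cvs else float("nan")
        )
        out.condition_means[metric] = {c: _mean_ci(v) for c, v in by_cond.items()}
        a, b = (out.mean_cv_across_conditions[metric],
                out.mean_cv_across_patients[metric])
        out.condition_variation_dominates[metric] = bool(
            np.isfinite(a) and np.isfinite(b) and a > b
        )
    return out
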