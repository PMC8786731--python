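"""3D two-node Timoshenko beam element for circular struts.

Local convention: x along the strut axis, 6 DOF per node ordered
(ux, uy, uz, rx, ry, rz). Section properties of a solid circular strut of
diameter d: A = pi d^2/4, I = pi d^4/64 (both bending planes),
J = pi d^4/32, shear correction factor kappa_s = 0.9. Shear flexibility
enters through Phi = 12 E I / (kappa_s G A L^2); Phi -> 0 recovers the
Euler-Bernoulli element.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

KAPPA_S = 0.9  # shear correction factor, solid circular section


@dataclass(frozen=True)
class Section:
    """Circular strut section + isotropic material."""

    diameter: float  # mm
    E: float  # MPa
    nu: float

    @property
    def A(self) -> float:
        return math.pi * self.diameter**2 / 4.0

    @property
    def I(self) -> float:
        return math.pi * self.diameter**4 / 64.0

    @property
    def J(self) -> float:
        return math.pi * self.diameter**4 / 32.0

    @property
    def G(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu))


def local_stiffness(section: Section, L: float) -> np.ndarray:
    """12x12 local Timoshenko stiffness matrix (N, mm units)."""
    if L <= 0:
        raise ValueError("element length must be > 0")
    E, G = section.E, section.G
    A, I, J = section.A, section.I, section.J
    phi = 12.0 * E * I / (KAPPA_S * G * A * L**2)

    k = np.zeros((12, 12))
    ax = E * A / L
    tr = G * J / L
    c = E * I / (L**3 * (1.0 + phi))
    k1 = 12.0 * c
    k2 = 6.0 * L * c
    k3 = (4.0 + phi) * L**2 * c
    k4 = (2.0 - phi) * L**2 * c

    k[0, 0] = k[6, 6] = ax
    k[0, 6] = k[6, 0] = -ax
    k[3, 3] = k[9, 9] = tr
    k[3, 9] = k[9, 3] = -tr

    # bending about local z (deflection in y): dofs (1, 5, 7, 11)
    iy = [1, 5, 7, 11]
    kb = np.array(
        [
            [k1, k2, -k1, k2],
            [k2, k3, -k2, k4],
            [-k1, -k2, k1, -k2],
            [k2, k4, -k2, k3],
        ]
    )
    k[np.ix_(iy, iy)] += kb

    # bending about local y (deflection in z): dofs (2, 4, 8, 10), moment
    # coupling signs flipped
    iz = [2, 4, 8, 10]
    kb2 = np.array(
        [
            [k1, -k2, -k1, -k2],
            [-k2, k3, k2, k4],
            [-k1, k2, k1, k2],
            [-k2, k4, k2, k3],
        ]
    )
    k[np.ix_(iz, iz)] += kb2
    return k


def element_frame(p1: np.ndarray, p2: np.ndarray) -> tuple[np.ndarray, float]:
    """Rotation matrix R (rows = local axes in global coordinates) and length.

    The local y axis is built from the global z axis unless the strut is
    near-vertical, in which case the global x axis seeds the triad.
    """
    d = np.asarray(p2, dtype=float) - np.asarray(p1, dtype=float)
    L = float(np.linalg.norm(d))
    if L < 1e-12:
        raise ValueError("zero-length strut")
    ex = d / L
    ref = np.array([0.0, 0.0, 1.0])
    if abs(float(ex @ ref)) > 0.99:
        ref = np.array([1.0, 0.0, 0.0])
    ey = np.cross(ref, ex)
    ey /= np.linalg.norm(ey)
    ez = np.cross(ex, ey)
    return np.vstack([ex, ey, ez]), L


def transformation(R: np.ndarray) -> np.ndarray:
    """12x12 block-diagonal global->local transformation."""
    T = np.zeros((12, 12))
    for b in range(4):
        T[3 * b : 3 * b + 3, 3 * b : 3 * b + 3] = R
    return T


def global_stiffness(section: Section, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Element stiffness in global coordinates."""
    R, L = element_frame(p1, p2)
    T = transformation(R)
    return T.T @ local_stiffness(section, L) @ T
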