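"""Stokes/Mueller algebra and polarization-state-generator (PSG) modeling.

Polarization states are represented as length-4 NumPy arrays
``S = (S0, S1, S2, S3)`` — total intensity, horizontal/vertical linear
preference, +/-45 deg linear preference and circular preference — and
optical elements as 4x4 real Mueller matrices acting by ``S_out = M @ S_in``.

Sign convention
---------------
``S3 > 0`` denotes right-circular polarization.  Axes are measured
counterclockwise from horizontal when facing the source; angles are radians
throughout the library (degrees only at CLI boundaries).  The retarder sign
is fixed so that a horizontal polarizer followed by a quarter-wave plate
with its fast axis at +15 deg emits the elliptical state
``E1 = (1, 0.750, 0.433, 0.500)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StokesVector",
    "NamedState",
    "NAMED_STATES",
    "stokes",
    "apply_mueller",
    "rotation_mueller",
    "linear_polarizer",
    "retarder",
    "psg_state",
    "degree_of_polarization",
    "poincare_point",
]

#: Numerical slack allowed on the physicality constraint s1^2+s2^2+s3^2 <= s0^2.
PHYSICALITY_EPS = 1e-9

StokesVector = np.ndarray  # shape (4,), float


def stokes(s0: float, s1: float, s2: float, s3: float) -> StokesVector:
    """Build a Stokes vector, validating physicality.

    Raises
    ------
    ValueError
        If ``s0 < 0`` or the polarized intensity exceeds ``s0`` beyond
        numerical tolerance.
    """
    s = np.array([s0, s1, s2, s3], dtype=float)
    if s[0] < 0:
        raise ValueError(f"S0 must be non-negative, got {s[0]}")
    if s[1] ** 2 + s[2] ** 2 + s[3] ** 2 > s[0] ** 2 * (1.0 + PHYSICALITY_EPS):
        raise ValueError(f"unphysical Stokes vector {s}: DoP > 1")
    return s


@dataclass(frozen=True)
class NamedState:
    """One of the six canonical illumination states of polarization (SOP)."""

    label: str
    stokes: StokesVector

    def __post_init__(self) -> None:
        object.__setattr__(self, "stokes", np.asarray(self.stokes, dtype=float))


# The two elliptical states are stored at the printed 3-decimal precision so
# that comparisons against the reference values are exact.  They sit on the
# Poincare-sphere trace swept by rotating the PSG quarter-wave plate, at
# fast-axis angles +15 deg (E1) and -15 deg (E2).
NAMED_STATES: dict[str, NamedState] = {
    "LIN45": NamedState("LIN45", np.array([1.0, 0.0, 1.0, 0.0])),
    "LIN135": NamedState("LIN135", np.array([1.0, 0.0, -1.0, 0.0])),
    "RCP": NamedState("RCP", np.array([1.0, 0.0, 0.0, 1.0])),
    "LCP": NamedState("LCP", np.array([1.0, 0.0, 0.0, -1.0])),
    "E1": NamedState("E1", np.array([1.0, 0.750, 0.433, 0.500])),
    "E2": NamedState("E2", np.array([1.0, 0.750, -0.433, -0.500])),
}


def apply_mueller(m: np.ndarray, s: StokesVector) -> StokesVector:
    """Propagate a Stokes vector through an element: ``S_out = M @ S_in``."""
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    if m.shape != (4, 4) or s.shape != (4,):
        raise ValueError(f"expected (4,4) matrix and (4,) vector, got {m.shape}, {s.shape}")
    return m @ s


def rotation_mueller(theta: float) -> np.ndarray:
    """Mueller rotation matrix for a frame rotation by ``theta`` radians."""
    c, s = np.cos(2 * theta), np.sin(2 * theta)
    return np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, c, s, 0.0],
            [0.0, -s, c, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )


def linear_polarizer(angle: float) -> np.ndarray:
    """Ideal linear polarizer (diattenuator) with transmission axis ``angle``.

    At ``angle = 0`` this is the textbook horizontal polarizer
    ``0.5 * [[1,1,0,0],[1,1,0,0],[0,0,0,0],[0,0,0,0]]``; general angles are
    obtained by rotation conjugation.  Idempotent: ``M @ M == M``.
    """
    if not np.isfinite(angle):
        raise ValueError("polarizer angle must be finite")
    c, s = np.cos(2 * angle), np.sin(2 * angle)
    return 0.5 * np.array(
        [
            [1.0, c, s, 0.0],
            [c, c * c, c * s, 0.0],
            [s, c * s, s * s, 0.0],
            [0.0, 0.0, 0.0, 0.0],
        ]
    )


def retarder(retardance: float, fast_axis: float = 0.0) -> np.ndarray:
    """Ideal linear retarder of given ``retardance`` with fast axis ``fast_axis``.

    Built as the rotation conjugation ``R(-theta) @ M0 @ R(theta)`` of the
    canonical axis-0 retarder

    .. code-block:: text

        M0 = [[1, 0,    0,    0],
              [0, 1,    0,    0],
              [0, 0,  cos d, sin d],
              [0, 0, -sin d, cos d]]

    whose sign convention anchors a quarter-wave plate at +15 deg to E1.
    """
    cd, sd = np.cos(retardance), np.sin(retardance)
    m0 = np.array(
        [
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
            [0.0, 0.0, cd, sd],
            [0.0, 0.0, -sd, cd],
        ]
    )
    return rotation_mueller(-fast_axis) @ m0 @ rotation_mueller(fast_axis)


def psg_state(qwp_angle: float) -> StokesVector:
    """Illumination state emitted by the PSG for a quarter-wave-plate angle.

    The PSG is a fixed horizontal linear polarizer followed by a rotating
    quarter-wave plate; sweeping ``qwp_angle`` over half a turn traces a
    closed figure on the Poincare sphere containing the linear, circular and
    elliptical states used as illumination SOPs.  Unit intensity output.

    Parameters
    ----------
    qwp_angle : float
        Fast-axis angle of the quarter-wave plate, radians.
    """
    s_in = np.array([1.0, 0.0, 0.0, 0.0])
    s = apply_mueller(linear_polarizer(0.0), s_in)
    s = apply_mueller(retarder(np.pi / 2, qwp_angle), s)
    return s / s[0]


def degree_of_polarization(s: StokesVector) -> float:
    """Polarized fraction ``sqrt(S1^2+S2^2+S3^2)/S0`` of a beam, in [0, 1]."""
    s = np.asarray(s, dtype=float)
    if s[0] <= 0:
        raise ValueError(f"degree of polarization undefined for S0 = {s[0]} <= 0")
    dop = float(np.sqrt(s[1] ** 2 + s[2] ** 2 + s[3] ** 2) / s[0])
    return min(dop, 1.0 + PHYSICALITY_EPS)


def poincare_point(s: StokesVector) -> np.ndarray:
    """Unit direction of a state on the Poincare sphere.

    Fully polarized states land on the unit sphere: the equator holds linear
    polarization, the poles circular.  Undefined for unpolarized light.
    """
    s = np.asarray(s, dtype=float)
    dop = degree_of_polarization(s)
    if dop <= 0:
        raise ValueError("Poincare direction undefined for unpolarized light")
    return s[1:] / (s[0] * dop)
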