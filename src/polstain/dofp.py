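"""Forward model and inversion for a dual division-of-focal-plane (DoFP)
full-Mueller microscope.

The polarization state analyzer (PSA) is modeled as eight intensity
channels: camera A is a bare DoFP polarimeter with micro-polarizers at
0/45/90/135 deg, camera B sees the same four analyzers behind a
quarter-wave retarder (default fast axis 45 deg) so that S3 becomes
observable.  Each channel's analyzer vector is the top row of its Mueller
chain; stacked they form the 8x4 instrument matrix ``A_PSA`` with

    I = A_PSA @ S        (per pixel)

Stokes reconstruction inverts this overdetermined system by Moore-Penrose
least squares, and the full Mueller matrix follows from four illumination
states via ``M = [S_out][S_in]^-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .polarimetry import linear_polarizer, psg_state, retarder

__all__ = [
    "PsaChannel",
    "PsaConfig",
    "InstrumentMatrix",
    "IncidentStateSet",
    "build_instrument_matrix",
    "simulate_intensities",
    "reconstruct_stokes",
    "reconstruct_mueller",
    "calibrate_psa",
    "DEFAULT_QWP_ANGLES_DEG",
]

#: Default PSG quarter-wave-plate preset angles (degrees) for the four-state
#: Mueller acquisition; chosen so the incident-state matrix is well
#: conditioned (condition number < 10, checked at construction).
DEFAULT_QWP_ANGLES_DEG = (-45.0, 0.0, 30.0, 60.0)


@dataclass(frozen=True)
class PsaChannel:
    """One analyzer channel: optional (retardance, fast_axis) retarder
    followed by a linear analyzer at ``analyzer_angle`` (radians)."""

    analyzer_angle: float
    retarder: tuple[float, float] | None = None

    def analyzer_vector(self) -> np.ndarray:
        """Top row of this channel's Mueller chain (intensity response)."""
        chain = linear_polarizer(self.analyzer_angle)
        if self.retarder is not None:
            delta, axis = self.retarder
            chain = chain @ retarder(delta, axis)
        return chain[0]


def _default_channels() -> tuple[PsaChannel, ...]:
    angles = [0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4]
    cam_a = [PsaChannel(a) for a in angles]
    cam_b = [PsaChannel(a, retarder=(np.pi / 2, np.pi / 4)) for a in angles]
    return tuple(cam_a + cam_b)


@dataclass(frozen=True)
class PsaConfig:
    """Eight-channel PSA description; default = dual DoFP with a
    quarter-wave plate at 45 deg in front of camera B."""

    channels: tuple[PsaChannel, ...] = field(default_factory=_default_channels)

    def __post_init__(self) -> None:
        if len(self.channels) != 8:
            raise ValueError(f"PSA must have exactly 8 channels, got {len(self.channels)}")


@dataclass(frozen=True)
class InstrumentMatrix:
    """8x4 instrument matrix ``A_PSA``; rows are analyzer vectors."""

    a: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        if self.a.shape != (8, 4):
            raise ValueError(f"instrument matrix must be 8x4, got {self.a.shape}")

    @property
    def rank(self) -> int:
        return int(np.linalg.matrix_rank(self.a))

    @property
    def condition_number(self) -> float:
        sv = np.linalg.svd(self.a, compute_uv=False)
        return float(sv[0] / sv[-1]) if sv[-1] > 0 else float("inf")

    @property
    def pinv(self) -> np.ndarray:
        return np.linalg.pinv(self.a)


@dataclass(frozen=True)
class IncidentStateSet:
    """Four PSG illumination states stacked as the columns of ``sin``."""

    sin: np.ndarray
    qwp_angles_deg: tuple[float, ...] = DEFAULT_QWP_ANGLES_DEG
    max_condition: float = 10.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sin", np.asarray(self.sin, dtype=float))
        if self.sin.shape != (4, 4):
            raise ValueError(f"incident state matrix must be 4x4, got {self.sin.shape}")
        cond = np.linalg.cond(self.sin)
        if not np.isfinite(cond) or cond > self.max_condition:
            raise ValueError(
                f"incident state set ill-conditioned: condition number {cond:.3g} "
                f"exceeds bound {self.max_condition}"
            )

    @classmethod
    def from_qwp_angles(cls, angles_deg=DEFAULT_QWP_ANGLES_DEG, max_condition: float = 10.0):
        cols = [psg_state(np.deg2rad(a)) for a in angles_deg]
        return cls(np.stack(cols, axis=1), tuple(angles_deg), max_condition)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.sin))


def build_instrument_matrix(cfg: PsaConfig | None = None) -> InstrumentMatrix:
    """Assemble ``A_PSA`` from a PSA configuration.

    Raises
    ------
    ValueError
        If the resulting matrix has numerical rank below 4 (some Stokes
        component unobservable), naming the deficient configuration.
    """
    cfg = cfg or PsaConfig()
    a = np.stack([ch.analyzer_vector() for ch in cfg.channels])
    inst = InstrumentMatrix(a)
    if inst.rank < 4:
        raise ValueError(
            f"PSA configuration is rank-deficient (rank {inst.rank} < 4); "
            f"channels: {cfg.channels}"
        )
    return inst


def simulate_intensities(
    a: InstrumentMatrix,
    stokes_map: np.ndarray,
    noise: str | None = None,
    noise_level: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Forward-model the eight DoFP intensity images for a Stokes field.

    Parameters
    ----------
    stokes_map : (H, W, 4) array
        Per-pixel exiting Stokes vectors.
    noise : {None, "gaussian", "poisson"}
        Optional measurement noise: additive gaussian with standard
        deviation ``noise_level``, or poisson with ``noise_level`` photons
        per unit intensity.

    Returns
    -------
    (H, W, 8) array of non-negative intensities.
    """
    stokes_map = np.asarray(stokes_map, dtype=float)
    if stokes_map.ndim != 3 or stokes_map.shape[-1] != 4:
        raise ValueError(f"stokes_map must be (H, W, 4), got {stokes_map.shape}")
    i = np.einsum("ks,hws->hwk", a.a, stokes_map)
    if noise == "gaussian":
        rng = rng or np.random.default_rng()
        i = i + rng.normal(0.0, noise_level, size=i.shape)
    elif noise == "poisson":
        rng = rng or np.random.default_rng()
        i = rng.poisson(np.clip(i, 0, None) * noise_level) / noise_level
    elif noise is not None:
        raise ValueError(f"unknown noise model {noise!r}")
    return np.clip(i, 0.0, None)


def reconstruct_stokes(a: InstrumentMatrix, intensities: np.ndarray) -> np.ndarray:
    """Recover the Stokes field from the eight intensity channels.

    Solves ``I = A_PSA @ S`` per pixel in the least-squares sense via the
    Moore-Penrose pseudoinverse of the 8x4 instrument matrix.
    """
    intensities = np.asarray(intensities, dtype=float)
    if intensities.ndim != 3 or intensities.shape[-1] != 8:
        raise ValueError(f"intensities must be (H, W, 8), got {intensities.shape}")
    if not np.all(np.isfinite(intensities)):
        raise ValueError("intensities contain non-finite values")
    if a.rank < 4:
        raise ValueError(f"instrument matrix rank {a.rank} < 4: Stokes not recoverable")
    return np.einsum("sk,hwk->hws", a.pinv, intensities)


def reconstruct_mueller(
    stokes_outs: list[np.ndarray] | np.ndarray, states: IncidentStateSet
) -> np.ndarray:
    """Per-pixel Mueller map from four exiting Stokes images.

    ``M = [S_out][S_in]^-1`` where the columns of ``[S_out]`` are the
    exiting states for the four illumination states in ``states``.

    Returns
    -------
    (H, W, 16) array, row-major element order m11..m44.
    """
    stokes_outs = np.asarray(stokes_outs, dtype=float)  # (4, H, W, 4)
    if stokes_outs.shape[0] != 4 or stokes_outs.shape[-1] != 4:
        raise ValueError(f"need four (H, W, 4) Stokes images, got {stokes_outs.shape}")
    sout = np.moveaxis(stokes_outs, 0, -1)  # (H, W, 4 components, 4 states)
    sin_inv = np.linalg.inv(states.sin)
    m = np.einsum("hwcs,sj->hwcj", sout, sin_inv)  # (H, W, 4, 4)
    h, w = m.shape[:2]
    return m.reshape(h, w, 16)


def calibrate_psa(known_states: np.ndarray, measured: np.ndarray) -> InstrumentMatrix:
    """Least-squares PSA calibration from reference illumination states.

    Parameters
    ----------
    known_states : (n, 4) array, n >= 4
        Reference Stokes vectors presented to the analyzer.
    measured : (n, 8) array
        Measured eight-channel intensities for each state.

    Returns
    -------
    InstrumentMatrix estimated as ``A = I_measured @ pinv(S_known)``.
    """
    s = np.asarray(known_states, dtype=float)
    i = np.asarray(measured, dtype=float)
    if s.ndim != 2 or s.shape[1] != 4 or i.ndim != 2 or i.shape[1] != 8:
        raise ValueError(f"expected (n,4) states and (n,8) intensities, got {s.shape}, {i.shape}")
    if s.shape[0] != i.shape[0]:
        raise ValueError("state/measurement count mismatch")
    if s.shape[0] < 4:
        raise ValueError(f"calibration underdetermined: {s.shape[0]} states < 4")
    if np.linalg.matrix_rank(s) < 4:
        raise ValueError("calibration states do not span Stokes space (rank < 4)")
    a = i.T @ np.linalg.pinv(s.T)
    return InstrumentMatrix(a)
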