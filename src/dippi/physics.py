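"""Hollow-cylinder myelin phase physics.

A myelinated axon is idealized as an infinite hollow cylinder whose myelin
sheath carries an anisotropic magnetic susceptibility. Inside the lumen the
induced off-resonance field is uniform and proportional to the log g-ratio
(inner/outer sheath radius) and to sin^2 of the angle between the axon and
the main field; outside, the sheath produces a dipole-like field decaying
as 1/r^2 in the cross-section plane.

Sign and unit conventions used throughout the package:

* angular frequencies are rad/s internally, Hz only at user interfaces;
* susceptibilities are supplied in ppb and stored dimensionless;
* the susceptibility phase enters the signal as ``exp(+1j * omega * t)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAMMA_PROTON",
    "PhysicalConstants",
    "FiberGeometry",
    "MyelinPool",
    "omega_myelin",
    "twopool_complex",
    "twopool_phase",
    "gratio_bias",
    "extraaxonal_dipole_omega",
    "scale_tphase",
]

#: Proton gyromagnetic ratio (rad s^-1 T^-1).
GAMMA_PROTON = 2.675221874e8

_UNIT_TOL = 1e-10


@dataclass(frozen=True)
class PhysicalConstants:
    """Field strength and myelin susceptibility constants.

    Parameters
    ----------
    B0 : float
        Main field strength in tesla.
    chi_A_ppb, chi_I_ppb : float
        Anisotropic / isotropic myelin susceptibility components in parts
        per billion (typically negative, about -100 ppb each).
    gamma : float
        Gyromagnetic ratio in rad/s/T.
    """

    B0: float = 7.0
    chi_A_ppb: float = -100.0
    chi_I_ppb: float = -100.0
    gamma: float = GAMMA_PROTON

    @property
    def omega0(self) -> float:
        """Larmor angular frequency gamma * B0 (rad/s)."""
        return self.gamma * self.B0

    @property
    def chi_A(self) -> float:
        """Anisotropic susceptibility, dimensionless."""
        return self.chi_A_ppb * 1e-9

    @property
    def chi_I(self) -> float:
        """Isotropic susceptibility, dimensionless."""
        return self.chi_I_ppb * 1e-9


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != 3:
        raise ValueError(f"{name} must be a 3-vector")
    norm = np.linalg.norm(v, axis=-1)
    if np.any(np.abs(norm - 1.0) > 1e-8):
        raise ValueError(f"{name} must be unit-norm (|v|={norm})")
    return v


@dataclass(frozen=True)
class FiberGeometry:
    """Orientation of one fiber population relative to the main field.

    ``sin2theta`` = 1 - (n_hat . B0_hat)^2 is invariant under fiber sign
    flips (fibers are axial, not directed).
    """

    n_hat: np.ndarray
    B0_hat: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        object.__setattr__(self, "n_hat", _check_unit(self.n_hat, "n_hat"))
        object.__setattr__(self, "B0_hat", _check_unit(self.B0_hat, "B0_hat"))

    @property
    def sin2theta(self) -> float:
        c = float(np.dot(self.n_hat, self.B0_hat))
        return float(np.clip(1.0 - c * c, 0.0, 1.0))


#: lower bound on the mean log g-ratio of myelinated axons used as a fit
#: bound and prior support (g-ratios below 0.6 are not observed in healthy
#: mammalian white matter).
LOG_G_MIN = float(np.log(0.6))


@dataclass(frozen=True)
class MyelinPool:
    """Two-pool description of one fiber population's axons.

    ``f_myelin`` is the signal fraction of myelinated axons;
    ``log_g_myelin`` the mean log g-ratio of the myelinated axons alone
    (<= 0). The signal-weighted mean log g across all axons is the product
    ``f_myelin * log_g_myelin`` (unmyelinated axons have g = 1, log g = 0).
    """

    f_myelin: float
    log_g_myelin: float

    def __post_init__(self):
        if not 0.0 <= self.f_myelin <= 1.0:
            raise ValueError("f_myelin must be in [0, 1]")
        if self.log_g_myelin > 1e-12:
            raise ValueError("log_g_myelin must be <= 0")

    @property
    def log_g_mean(self) -> float:
        return self.f_myelin * self.log_g_myelin


def omega_myelin(geom, log_g: float, consts: PhysicalConstants) -> float:
    """Intra-axonal myelin-induced angular frequency (rad/s).

    omega = -(3/4) * omega0 * chi_A * log g * sin^2(theta).

    With chi_A < 0 and log g < 0 the result is negative. ``geom`` may be a
    :class:`FiberGeometry` or a plain sin^2(theta) scalar/array.
    """
    sin2 = geom.sin2theta if isinstance(geom, FiberGeometry) else np.asarray(geom, float)
    if np.any(sin2 < -1e-12) or np.any(sin2 > 1 + 1e-12):
        raise ValueError("sin2theta must be in [0, 1]")
    if np.any(np.asarray(log_g) > 1e-12):
        raise ValueError("log_g must be <= 0")
    return -0.75 * consts.omega0 * consts.chi_A * log_g * sin2


def twopool_complex(pool: MyelinPool, omega_my: float, t_phase) -> complex:
    """Unit-amplitude mixture signal of unmyelinated + myelinated axons.

    (1 - f) + f * exp(1j * omega_my * t_phase) with t_phase in seconds.
    The magnitude lies in [|1 - 2 f|, 1]; for f = 0.5 and phase pi the
    mixture vanishes and its angle is undefined.
    """
    t = np.asarray(t_phase, dtype=float)
    f = pool.f_myelin
    return (1.0 - f) + f * np.exp(1j * omega_my * t)


def twopool_phase(pool: MyelinPool, omega_my: float, t_phase) -> float:
    """Principal angle of the two-pool mixture signal (rad).

    For small |omega_my * t| this equals f * omega_my * t to first order;
    for large dephasing it approaches the phase of the dominant pool.
    Raises for the degenerate zero-magnitude mixture.
    """
    z = twopool_complex(pool, omega_my, t_phase)
    if np.any(np.abs(z) <= 1e-12):
        raise ValueError("two-pool mixture magnitude vanished; phase undefined")
    return np.angle(z)


def gratio_bias(
    delta_omega_hz,
    geom,
    consts: PhysicalConstants,
    sin2_floor: float = 1e-3,
):
    """Bias in log g induced by a frequency error ``delta_omega_hz`` (Hz).

    delta(log g) = 4 * (2 pi delta_omega) / (3 * omega0 * |chi_A| * sin^2 theta)

    which evaluates to ~0.045 * delta_omega[Hz] / sin^2(theta) at 7 T with
    chi_A = -100 ppb. Diverges for fibers parallel to the field; sin^2
    below ``sin2_floor`` raises.
    """
    sin2 = geom.sin2theta if isinstance(geom, FiberGeometry) else float(geom)
    if sin2 < sin2_floor:
        raise ValueError(
            f"sin2theta={sin2:g} below floor {sin2_floor:g}: "
            "g-ratio sensitivity diverges for fibers parallel to B0"
        )
    d_omega = 2.0 * np.pi * np.asarray(delta_omega_hz, dtype=float)
    return 4.0 * d_omega / (3.0 * consts.omega0 * abs(consts.chi_A) * sin2)


def extraaxonal_dipole_omega(
    position,
    center,
    r_inner: float,
    r_outer: float,
    geom,
    consts: PhysicalConstants,
):
    """Dipole-like field of one myelin annulus outside its axon (rad/s).

    ``position`` and ``center`` are 2-vectors in the axon cross-section
    plane (um), with the second coordinate along the projection of B0 onto
    that plane. Hollow-cylinder external field:

        omega = omega0 * (chi_I + chi_A/4) * sin^2(theta) * cos(2 phi)
                * (r_o^2 - r_i^2) / (2 r^2)

    where phi is measured from the in-plane B0 projection. The angular
    mean over any circle centred on the axon is exactly zero and the
    amplitude decays as 1/r^2. Positions inside the annulus are rejected
    (myelin water is not modelled).
    """
    if not 0.0 <= r_inner <= r_outer:
        raise ValueError("need 0 <= r_inner <= r_outer")
    sin2 = geom.sin2theta if isinstance(geom, FiberGeometry) else float(geom)
    pos = np.asarray(position, dtype=float) - np.asarray(center, dtype=float)
    r2 = pos[..., 0] ** 2 + pos[..., 1] ** 2
    if np.any(r2 < r_outer**2 * (1 - 1e-12)):
        raise ValueError("position inside the axon: external dipole field invalid there")
    if r_outer == r_inner:
        return np.zeros(np.shape(r2)) if np.ndim(r2) else 0.0
    # cos(2 phi) with phi from the in-plane B0 projection (second axis)
    cos2phi = (pos[..., 1] ** 2 - pos[..., 0] ** 2) / r2
    amp = consts.omega0 * (consts.chi_I + consts.chi_A / 4.0) * sin2
    return amp * cos2phi * (r_outer**2 - r_inner**2) / (2.0 * r2)


def scale_tphase(t_phase, B0_from: float, B0_to: float):
    """Scale phase-accumulation times between field strengths.

    Equal myelin phase accumulation requires t_phase * B0 = const, so
    moving from 7 T to 3 T multiplies the times by 7/3.
    """
    return np.asarray(t_phase, dtype=float) * (B0_from / B0_to)
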