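"""Generative voxel model for diffusion-prepared phase imaging.

A voxel holds K crossing fiber populations. The magnitude over gradient
directions is a sum of Watson-profile lobes (one per population, maximal
perpendicular to the fiber); the phase of the first (SE) readout is an
arbitrary per-excitation constant, while the phase accumulated between the
SE and ASE readouts carries the eddy-current term plus, per population, the
susceptibility phase (omega_myelin + omega_bulk) * t_phase — with the
myelin part generalized to the two-pool unmyelinated/myelinated mixture
when the myelinated signal fraction is below one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .acquisition import Scheme
from .eddy import EddyCoefficients, SHBasis, eddy_phase
from .physics import (
    FiberGeometry,
    MyelinPool,
    PhysicalConstants,
    omega_myelin,
    twopool_complex,
)

__all__ = [
    "FiberPopulation",
    "VoxelModel",
    "SimulatedDataset",
    "watson_factor",
    "ase_amplitude",
    "se_signal",
    "ase_signal",
    "evaluate_signals",
    "simulate_dataset",
    "default_crossing_voxel",
]

MS = 1e-3  # ms -> s


@dataclass(frozen=True)
class FiberPopulation:
    """One crossing fiber population.

    ``Delta_D`` is the Watson width lambda_parallel - lambda_perp
    (um^2/ms), shared between the SE and ASE readouts; amplitudes decay
    from ``A_SE`` with T2 (ms) and T2' (ms) dephasing.
    """

    n_hat: np.ndarray
    A_SE: float = 1.0
    Delta_D: float = 1.7
    T2: float = 60.0
    T2p: float = 84.0
    pool: MyelinPool = field(default_factory=lambda: MyelinPool(0.5, float(np.log(0.7))))

    def __post_init__(self):
        n = np.asarray(self.n_hat, dtype=float)
        if abs(np.linalg.norm(n) - 1) > 1e-8:
            raise ValueError("fiber orientation must be unit-norm")
        object.__setattr__(self, "n_hat", n)
        if self.A_SE < 0 or self.Delta_D < 0:
            raise ValueError("A_SE and Delta_D must be non-negative")
        if self.T2 <= 0 or self.T2p <= 0:
            raise ValueError("relaxation times must be positive")


@dataclass
class VoxelModel:
    """Full generative parameter set for one voxel.

    ``omega_bulk`` (rad/s) is the non-myelin susceptibility frequency,
    shared by all populations within one head orientation (dict keyed by
    orientation id, or a scalar). ``phi_SE`` is the random per-excitation
    phase at the first readout; ``eddy`` the SH eddy-phase coefficients.
    """

    populations: list
    omega_bulk: float | dict = 0.0
    phi_SE: np.ndarray | None = None
    eddy: EddyCoefficients | None = None
    consts: PhysicalConstants = field(default_factory=PhysicalConstants)

    def omega_bulk_for(self, orientation_id: int) -> float:
        if isinstance(self.omega_bulk, dict):
            return float(self.omega_bulk[int(orientation_id)])
        return float(self.omega_bulk)


def watson_factor(b, g_hat, n_hat, Delta_D):
    """Watson-profile magnitude factor exp(-b DeltaD (g.n)^2), in (0, 1].

    Maximal for gradients perpendicular to the fiber; even in g, so
    magnitudes are invariant under gradient reversal.
    """
    g = np.asarray(g_hat, dtype=float)
    n = np.asarray(n_hat, dtype=float)
    dot = g @ n if g.ndim > 1 else float(np.dot(g, n))
    return np.exp(-np.asarray(b, float) * Delta_D * dot**2)


def ase_amplitude(A_SE, T2, T2p, t_phase, TE1, TE2):
    """ASE readout amplitude after T2 and T2' dephasing (times in ms).

    A_ASE = A_SE * exp(-((TE2-TE1) + t_phase)/T2) * exp(-t_phase/T2'),
    the standard asymmetric-spin-echo decomposition: irreversible T2 decay
    over the full extra echo time, reversible T2' dephasing only over the
    asymmetry t_phase.
    """
    if np.any(np.asarray(T2) <= 0) or np.any(np.asarray(T2p) <= 0):
        raise ValueError("relaxation times must be positive")
    t = np.asarray(t_phase, dtype=float)
    return A_SE * np.exp(-((TE2 - TE1) + t) / T2) * np.exp(-t / T2p)


def se_signal(voxel: VoxelModel, vol, index: int = 0) -> complex:
    """Complex SE signal of one volume: sum_k A_SE,k W_k * exp(i phi_SE)."""
    phi = 0.0 if voxel.phi_SE is None else float(voxel.phi_SE[index])
    total = sum(p.A_SE * watson_factor(vol.b, vol.g_hat, p.n_hat, p.Delta_D)
                for p in voxel.populations)
    return total * np.exp(1j * phi)


def ase_signal(voxel: VoxelModel, vol, index: int = 0) -> complex:
    """Complex ASE signal of one volume.

    Each population contributes its Watson lobe, T2/T2'-decayed amplitude,
    two-pool myelin phase factor and the shared phi_SE, eddy and bulk
    phases.
    """
    phi = 0.0 if voxel.phi_SE is None else float(voxel.phi_SE[index])
    t_s = vol.t_phase * MS
    w_bulk = voxel.omega_bulk_for(vol.orientation_id)
    if voxel.eddy is not None and vol.b > 0:
        phi += eddy_phase(voxel.eddy, vol.g_hat, vol.t_phase)
    total = 0.0 + 0.0j
    for p in voxel.populations:
        geom = FiberGeometry(p.n_hat, vol.B0_hat)
        w_my = omega_myelin(geom, p.pool.log_g_myelin, voxel.consts)
        amp = ase_amplitude(p.A_SE, p.T2, p.T2p, vol.t_phase, vol.TE1, vol.TE2)
        factor = twopool_complex(p.pool, w_my, t_s)
        total += (amp * watson_factor(vol.b, vol.g_hat, p.n_hat, p.Delta_D)
                  * factor)
    return total * np.exp(1j * (phi + w_bulk * t_s))


def evaluate_signals(voxel: VoxelModel, scheme: Scheme):
    """Vectorized noise-free (S_SE, S_ASE) arrays over a scheme."""
    n = len(scheme)
    phi = np.zeros(n) if voxel.phi_SE is None else np.asarray(voxel.phi_SE, float)
    t_s = scheme.t_phase * MS
    w_bulk = np.array([voxel.omega_bulk_for(o) for o in scheme.orientation_id])
    eddy = np.zeros(n)
    if voxel.eddy is not None:
        dwi = scheme.b > 0  # no diffusion gradient, no eddy currents
        for t in np.unique(scheme.t_phase):
            sel = (scheme.t_phase == t) & dwi
            if sel.any():
                eddy[sel] = eddy_phase(voxel.eddy, scheme.bvecs[sel], float(t))
    S_SE = np.zeros(n, dtype=complex)
    S_ASE = np.zeros(n, dtype=complex)
    cos_b0 = scheme.B0_hat  # (n, 3)
    for p in voxel.populations:
        w = watson_factor(scheme.b, scheme.bvecs, p.n_hat, p.Delta_D)
        S_SE += p.A_SE * w
        sin2 = 1.0 - (cos_b0 @ p.n_hat) ** 2
        w_my = omega_myelin(np.clip(sin2, 0, 1), p.pool.log_g_myelin, voxel.consts)
        amp = ase_amplitude(p.A_SE, p.T2, p.T2p, scheme.t_phase,
                            scheme.TE1, scheme.TE2)
        f = p.pool.f_myelin
        factor = (1 - f) + f * np.exp(1j * w_my * t_s)
        S_ASE += amp * w * factor
    S_SE = S_SE * np.exp(1j * phi)
    S_ASE = S_ASE * np.exp(1j * (phi + eddy + w_bulk * t_s))
    return S_SE, S_ASE


@dataclass
class SimulatedDataset:
    """Simulated DIPPI signals plus the generating ground truth."""

    scheme: Scheme
    S_SE: np.ndarray
    S_ASE: np.ndarray
    truth: VoxelModel
    snr: float | None = None
    seed: int | None = None


def simulate_dataset(voxel: VoxelModel, scheme: Scheme, snr: float | None = 20.0,
                     seed=None, omega_bulk_band=(200.0, 2000.0)) -> SimulatedDataset:
    """Simulate a DIPPI dataset with random nuisance terms.

    Missing nuisances on ``voxel`` are drawn here (deterministically given
    ``seed``): phi_SE ~ U(0, 2 pi) per excitation; omega_bulk uniform over
    ``omega_bulk_band`` (rad/s) with a random sign, independently per head
    orientation — large enough that the bulk phase wraps several times
    between successive t_phase values; first-order (l=1) eddy coefficients
    a + b * t_phase with a ~ N(0, 1.4 rad), b ~ N(0, 18 Hz). Circular
    complex Gaussian noise is added with per-channel standard deviation
    equal to the b=0 SE magnitude divided by ``snr`` (``None`` for
    noise-free data). Returns the signals and the completed ground truth.
    """
    if snr is not None and snr <= 0:
        raise ValueError("snr must be positive (or None for noise-free)")
    rng = np.random.default_rng(seed)
    truth = replace(voxel)
    if truth.phi_SE is None:
        truth.phi_SE = rng.uniform(0, 2 * np.pi, size=len(scheme))
    if truth.omega_bulk is None:
        lo, hi = omega_bulk_band
        truth.omega_bulk = {
            int(o): float(rng.choice([-1, 1]) * rng.uniform(lo, hi))
            for o in np.unique(scheme.orientation_id)}
    if truth.eddy is None:
        basis = SHBasis(lmax=1)
        t_grid = scheme.tphase_values
        a = rng.normal(0.0, 1.4, size=3)
        b = rng.normal(0.0, 2 * np.pi * 18.0, size=3)  # 18 Hz -> rad/s
        c = np.zeros((t_grid.size, basis.n_coeff))
        c[:, 1:] = a[None, :] + b[None, :] * (t_grid[:, None] * MS)
        truth.eddy = EddyCoefficients(basis, t_grid, c)
    S_SE, S_ASE = evaluate_signals(truth, scheme)
    if snr is not None:
        s0 = sum(p.A_SE for p in truth.populations)
        sigma = s0 / snr
        noise = rng.normal(0, sigma, (2, len(scheme), 2))
        S_SE = S_SE + noise[0, :, 0] + 1j * noise[0, :, 1]
        S_ASE = S_ASE + noise[1, :, 0] + 1j * noise[1, :, 1]
    return SimulatedDataset(scheme, S_SE, S_ASE, truth, snr, seed)


def default_crossing_voxel(crossing_angle_deg: float = 90.0,
                           f_myelin: float = 0.5, g_myelin: float = 0.7,
                           Delta_D: float = 1.7, T2: float = 60.0,
                           T2p: float = 84.0, A_SE=(1.0, 1.0),
                           consts: PhysicalConstants | None = None) -> VoxelModel:
    """Two fiber populations crossing in the x-y plane (both perpendicular
    to B0 = z in the rest head position), with the default myelination.

    T2' = 84 ms follows from T2 = 60 ms and T2* = 35 ms via
    1/T2* = 1/T2 + 1/T2'.
    """
    half = np.deg2rad(crossing_angle_deg) / 2
    n1 = np.array([np.cos(half), np.sin(half), 0.0])
    n2 = np.array([np.cos(half), -np.sin(half), 0.0])
    pool = MyelinPool(f_myelin, float(np.log(g_myelin)))
    pops = [
        FiberPopulation(n1, A_SE[0], Delta_D, T2, T2p, pool),
        FiberPopulation(n2, A_SE[1], Delta_D, T2, T2p, pool),
    ]
    return VoxelModel(pops, omega_bulk=None, phi_SE=None, eddy=None,
                      consts=consts or PhysicalConstants())
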