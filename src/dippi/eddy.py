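"""Spherical-harmonic model of the eddy-current inter-readout phase.

Residual eddy-current fields after the strong diffusion gradients add a
phase between the two readouts that depends smoothly on the gradient
direction; it is expanded in real spherical harmonics over the gradient
sphere. Only odd-order terms (antisymmetric under gradient reversal) are
identifiable in anisotropic media — even orders are degenerate with the
susceptibility phase — except that a t_phase = 0 calibration shell pins
down the even orders accumulated between the two spin echoes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree, breadth_first_order
from scipy.sparse import csr_matrix
from scipy.special import sph_harm_y

__all__ = [
    "SHBasis",
    "EddyCoefficients",
    "eddy_phase",
    "unwrap_on_sphere",
    "fit_eddy",
    "tphase0_correction",
]


class SHBasis:
    """Real orthonormal spherical harmonics up to order ``lmax``.

    Coefficients are indexed l-major: (0,0), (1,-1), (1,0), (1,1), (2,-2)…
    Parity: Y_lm(-g) = (-1)^l Y_lm(g).
    """

    def __init__(self, lmax: int = 3):
        self.lmax = int(lmax)
        self.lm = [(l, m) for l in range(self.lmax + 1) for m in range(-l, l + 1)]

    @property
    def n_coeff(self) -> int:
        return len(self.lm)

    @property
    def l_values(self) -> np.ndarray:
        return np.array([l for l, _ in self.lm])

    @property
    def odd_mask(self) -> np.ndarray:
        return self.l_values % 2 == 1

    @property
    def even_mask(self) -> np.ndarray:
        return self.l_values % 2 == 0

    def design_matrix(self, directions) -> np.ndarray:
        """Evaluate all basis functions at unit ``directions`` (n, 3)."""
        g = np.asarray(directions, dtype=float).reshape(-1, 3)
        g = g / np.linalg.norm(g, axis=1, keepdims=True)
        theta = np.arccos(np.clip(g[:, 2], -1, 1))
        phi = np.arctan2(g[:, 1], g[:, 0])
        cols = []
        for l, m in self.lm:
            y = sph_harm_y(l, abs(m), theta, phi)
            if m == 0:
                cols.append(y.real)
            elif m > 0:
                cols.append(np.sqrt(2.0) * (-1) ** m * y.real)
            else:
                cols.append(np.sqrt(2.0) * (-1) ** m * y.imag)
        return np.column_stack(cols)


@dataclass
class EddyCoefficients:
    """SH coefficients c_lm(t_phase) of the inter-readout eddy phase (rad).

    ``c`` has shape (n_tphase, n_coeff) over the ``t_grid`` of
    phase-accumulation times (ms).
    """

    basis: SHBasis
    t_grid: np.ndarray  # (n_t,), ms
    c: np.ndarray  # (n_t, n_coeff), rad

    def __post_init__(self):
        self.t_grid = np.atleast_1d(np.asarray(self.t_grid, dtype=float))
        self.c = np.asarray(self.c, dtype=float).reshape(
            self.t_grid.size, self.basis.n_coeff)

    @classmethod
    def zeros(cls, basis: SHBasis, t_grid) -> "EddyCoefficients":
        t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
        return cls(basis, t_grid, np.zeros((t_grid.size, basis.n_coeff)))

    def at_tphase(self, t_phase: float, interpolate: bool = False) -> np.ndarray:
        idx = np.nonzero(np.isclose(self.t_grid, t_phase))[0]
        if idx.size:
            return self.c[idx[0]]
        if not interpolate:
            raise ValueError(
                f"t_phase={t_phase} not on the calibrated grid {self.t_grid}")
        if not (self.t_grid.min() <= t_phase <= self.t_grid.max()):
            raise ValueError("t_phase outside the calibrated grid")
        out = np.empty(self.basis.n_coeff)
        for j in range(self.basis.n_coeff):
            out[j] = np.interp(t_phase, self.t_grid, self.c[:, j])
        return out

    def per_l_power(self, t_index: int = 0) -> dict:
        """Sum of squared coefficients per order l (rad^2)."""
        lv = self.basis.l_values
        return {int(l): float(np.sum(self.c[t_index, lv == l] ** 2))
                for l in np.unique(lv)}


def eddy_phase(coeffs: EddyCoefficients, g_hat, t_phase: float,
               interpolate: bool = False) -> np.ndarray:
    """Evaluate the eddy phase (rad) at gradient direction(s) ``g_hat``."""
    c = coeffs.at_tphase(t_phase, interpolate=interpolate)
    Y = coeffs.basis.design_matrix(np.atleast_2d(g_hat))
    out = Y @ c
    return out if np.ndim(g_hat) > 1 else float(out[0])


def unwrap_on_sphere(phases, directions, k: int = 5,
                     reference: int | None = None) -> np.ndarray:
    """Unwrap per-direction phases over the gradient sphere.

    Region-growing along the minimum-spanning-tree of a k-nearest-neighbour
    direction graph: starting from the reference direction, each neighbour
    gets an integer multiple of 2 pi added so that adjacent differences are
    below pi. Output is congruent to the input mod 2 pi per direction and
    the reference direction is unchanged.
    """
    phases = np.asarray(phases, dtype=float).copy()
    g = np.asarray(directions, dtype=float).reshape(-1, 3)
    n = g.shape[0]
    if n < 2:
        return phases
    k = min(k, n - 1)
    # angular distance graph, symmetrized k-NN
    dots = np.clip(g @ g.T, -1, 1)
    ang = np.arccos(dots)
    np.fill_diagonal(ang, np.inf)
    rows, cols, vals = [], [], []
    for i in range(n):
        nb = np.argpartition(ang[i], k)[:k]
        for j in nb:
            rows.append(i)
            cols.append(int(j))
            vals.append(ang[i, j] + 1e-9)
    W = csr_matrix((vals, (rows, cols)), shape=(n, n))
    W = W.maximum(W.T)
    mst = minimum_spanning_tree(W)
    tree = mst.maximum(mst.T)
    ref = 0 if reference is None else int(reference)
    order, pred = breadth_first_order(tree, ref, directed=False)
    if order.size < n:
        raise ValueError("direction graph is disconnected; cannot unwrap")
    for node in order[1:]:
        p = pred[node]
        diff = phases[node] - phases[p]
        phases[node] -= 2 * np.pi * np.round(diff / (2 * np.pi))
    return phases


def fit_eddy(phase_samples, directions, basis: SHBasis | None = None,
             parity: str = "odd_only", t_phase: float = 0.0):
    """Least-squares SH fit of per-direction phases (rad).

    With ``parity='odd_only'`` only odd-l columns enter the design (even
    orders are degenerate with susceptibility); ``'all'`` uses every order.
    Returns ``(EddyCoefficients, residuals)``; excluded-parity coefficients
    are zero in the output.
    """
    if basis is None:
        basis = SHBasis()
    phases = np.asarray(phase_samples, dtype=float).ravel()
    Y = basis.design_matrix(directions)
    if parity == "odd_only":
        mask = basis.odd_mask
    elif parity == "all":
        mask = np.ones(basis.n_coeff, dtype=bool)
    else:
        raise ValueError("parity must be 'odd_only' or 'all'")
    Ysub = Y[:, mask]
    if phases.size < Ysub.shape[1]:
        raise ValueError("fewer directions than coefficients")
    if np.linalg.matrix_rank(Ysub) < Ysub.shape[1]:
        raise ValueError("rank-deficient SH design matrix")
    sol, *_ = np.linalg.lstsq(Ysub, phases, rcond=None)
    c = np.zeros(basis.n_coeff)
    c[mask] = sol
    coeffs = EddyCoefficients(basis, [t_phase], c[None, :])
    residuals = phases - Ysub @ sol
    return coeffs, residuals


def tphase0_correction(coeffs_t0: EddyCoefficients,
                       coeffs_t: EddyCoefficients) -> EddyCoefficients:
    """Replace the even-l part of ``coeffs_t`` by the t_phase=0 calibration.

    Any inter-readout phase at t_phase = 0 is pure eddy current (the
    susceptibility phase vanishes), so its even orders estimate the even
    eddy components accumulated between the spin echoes. Odd components of
    ``coeffs_t`` are untouched.
    """
    if coeffs_t0.basis.lmax != coeffs_t.basis.lmax:
        raise ValueError("basis mismatch between calibration and target")
    even = coeffs_t.basis.even_mask
    c = coeffs_t.c.copy()
    c[:, even] = coeffs_t0.c[0, even]
    return EddyCoefficients(coeffs_t.basis, coeffs_t.t_grid, c)
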