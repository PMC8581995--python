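"""Voxel-wise parameter estimation from complex DIPPI data.

The estimation is staged, each stage providing the initialization of the
next:

1. magnitude fit — fiber orientations, Watson widths (shared between
   readouts) and per-readout amplitudes, with multiple restarts;
2. the per-excitation SE phase, read directly off the SE readout;
3. inter-readout phases arg(S_ASE conj(S_SE)), unwrapped on the gradient
   sphere;
4. per (head orientation, t_phase): odd-order eddy SH coefficients plus a
   susceptibility phase per fiber population, by weighted complex least
   squares;
5. mapping of the susceptibility phases onto myelin parameters — either
   the signal-averaged log g-ratio per population (single-pool, valid for
   short t_phase) or the two-pool myelinated-fraction model across several
   t_phase — with the bulk-frequency wrap ambiguity resolved by a grid
   search;
6. optional joint complex refinement of the full model.

In the single-pool (average log g) model only the phase constrains the
myelination; the two-pool refinement additionally exploits the
non-exponential magnitude evolution of the myelinated/unmyelinated
mixture, without which the myelinated fraction and the myelinated log g
are degenerate whenever the mixture phase stays in its linear regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .acquisition import Scheme
from .eddy import EddyCoefficients, SHBasis, fit_eddy, unwrap_on_sphere
from .physics import LOG_G_MIN, PhysicalConstants, omega_myelin
from .signal import MS, ase_amplitude, watson_factor

__all__ = [
    "MagnitudeFit",
    "FitResult",
    "fit_magnitude",
    "estimate_phiSE",
    "interreadout_phase",
    "fit_phase_single_tphase",
    "myelin_freq_difference",
    "fit_average_logg",
    "fit_twopool",
    "fit_voxel",
]


def _wrap(x):
    """Wrap angles to (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(x)))


def _to_upper_hemisphere(n):
    """Antipodal gauge: z > 0, ties broken lexicographically."""
    n = np.asarray(n, float)
    key = n[2] if abs(n[2]) > 1e-12 else (n[1] if abs(n[1]) > 1e-12 else n[0])
    return -n if key < 0 else n


def _angles_to_vec(theta, phi):
    s = np.sin(theta)
    return np.array([s * np.cos(phi), s * np.sin(phi), np.cos(theta)])


# ---------------------------------------------------------------------------
# stage 1: magnitude


@dataclass
class MagnitudeFit:
    """Orientations, widths and amplitudes from the magnitude data.

    ASE amplitudes are free per (head orientation, t_phase) group: besides
    relaxation decay they soak up the two-pool magnitude modulation, which
    differs between head orientations (only the phase constrains the
    myelination).
    """

    n_hat: np.ndarray  # (K, 3)
    Delta_D: np.ndarray  # (K,)
    A_SE: np.ndarray  # (K,)
    A_ASE: np.ndarray  # (K, n_groups)
    groups: np.ndarray  # (n_groups, 2): orientation_id, t_phase
    residual: float = np.nan
    widths_identifiable: bool = True

    @property
    def t_grid(self) -> np.ndarray:
        return np.unique(self.groups[:, 1])

    def group_index(self, scheme: Scheme) -> np.ndarray:
        key = np.column_stack([scheme.orientation_id, scheme.t_phase])
        idx = np.empty(len(scheme), dtype=int)
        for j, g in enumerate(self.groups):
            idx[np.all(np.isclose(key, g), axis=1)] = j
        return idx

    def weights(self, scheme: Scheme):
        """(K, n) ASE Watson amplitudes per excitation."""
        g_idx = self.group_index(scheme)
        out = np.empty((len(self.n_hat), len(scheme)))
        for k, n in enumerate(self.n_hat):
            out[k] = self.A_ASE[k, g_idx] * watson_factor(
                scheme.b, scheme.bvecs, n, self.Delta_D[k])
        return out

    def se_weights(self, scheme: Scheme):
        out = np.empty((len(self.n_hat), len(scheme)))
        for k, n in enumerate(self.n_hat):
            out[k] = self.A_SE[k] * watson_factor(
                scheme.b, scheme.bvecs, n, self.Delta_D[k])
        return out

    def relaxation_times(self, TE1: float, TE2: float):
        """(T2, T2') per population from the ASE amplitude decay.

        log(A_ASE/A_SE) = -dTE/T2 - t * (1/T2 + 1/T2'): the intercept
        gives T2 (dTE = TE2 - TE1 known), the slope the total 1/T2*.
        Requires >= 2 distinct t_phase.
        """
        t_grid = self.t_grid
        if t_grid.size < 2:
            raise ValueError("need >= 2 t_phase values to separate T2 and T2'")
        dte = TE2 - TE1
        T2 = np.empty(len(self.n_hat))
        T2p = np.empty(len(self.n_hat))
        for k in range(len(self.n_hat)):
            a_t = np.array([self.A_ASE[k, np.isclose(self.groups[:, 1], t)].mean()
                            for t in t_grid])
            y = np.log(np.maximum(a_t / self.A_SE[k], 1e-300))
            slope, intercept = np.polyfit(t_grid, y, 1)
            T2[k] = dte / max(-intercept, 1e-12)
            r2star = max(-slope, 1e-12)
            T2p[k] = 1.0 / max(r2star - 1.0 / T2[k], 1e-12)
        return T2, T2p


def _mag_model(params, scheme, K, t_idx, n_t):
    th = params[0:K]
    ph = params[K:2 * K]
    dd = params[2 * K:3 * K]
    a_se = params[3 * K:4 * K]
    a_ase = params[4 * K:].reshape(K, n_t)
    se = np.zeros(len(scheme))
    ase = np.zeros(len(scheme))
    for k in range(K):
        n = _angles_to_vec(th[k], ph[k])
        w = watson_factor(scheme.b, scheme.bvecs, n, dd[k])
        se += a_se[k] * w
        ase += a_ase[k, t_idx] * w
    return se, ase


def fit_magnitude(mag_se, mag_ase, scheme: Scheme, K: int = 2,
                  n_restarts: int = 5, seed=None) -> MagnitudeFit:
    """Nonlinear least-squares fit of K Watson lobes to SE/ASE magnitudes.

    The width of each lobe is shared between readouts; amplitudes are free
    per readout and, for the ASE, per t_phase. Initialized from a coarse
    search over candidate orientation pairs with linearized amplitudes;
    populations are returned ordered by descending SE amplitude with
    orientations in the upper hemisphere.
    """
    mag_se = np.asarray(mag_se, float)
    mag_ase = np.asarray(mag_ase, float)
    key = np.column_stack([scheme.orientation_id, scheme.t_phase])
    groups = np.unique(key, axis=0)
    n_t = len(groups)
    t_idx = np.empty(len(scheme), dtype=int)
    for j, g in enumerate(groups):
        t_idx[np.all(np.isclose(key, g), axis=1)] = j
    dwi = scheme.b > 0
    n_dirs = len(np.unique(np.round(scheme.bvecs[dwi], 6), axis=0)) if dwi.any() else 0
    if n_dirs == 0:
        # b=0 only: amplitudes recoverable, widths are not
        a_se = np.full(K, mag_se.mean() / K)
        a_ase = np.array([[mag_ase[t_idx == j].mean() / K for j in range(n_t)]
                          for _ in range(K)])
        n = np.tile([0.0, 0.0, 1.0], (K, 1))
        return MagnitudeFit(n, np.zeros(K), a_se, a_ase, groups,
                            widths_identifiable=False)
    if n_dirs < 2 * K + 1:
        raise ValueError(
            f"{n_dirs} distinct directions cannot identify {K} populations")

    rng = np.random.default_rng(seed)
    # coarse init: candidate orientations on an upper-hemisphere lattice
    from .acquisition import fibonacci_directions
    cand = fibonacci_directions(80)
    cand = cand[cand[:, 2] >= 0]
    dd0 = 1.5

    def linear_score(ns):
        cols = [watson_factor(scheme.b, scheme.bvecs, n, dd0) for n in ns]
        X = np.column_stack(cols)
        # SE block and per-t ASE blocks share the design
        sol_se, *_ = np.linalg.lstsq(X, mag_se, rcond=None)
        err = np.sum((X @ sol_se - mag_se) ** 2)
        sols_ase = np.empty((len(ns), n_t))
        for j in range(n_t):
            sel = t_idx == j
            s, *_ = np.linalg.lstsq(X[sel], mag_ase[sel], rcond=None)
            sols_ase[:, j] = s
            err += np.sum((X[sel] @ s - mag_ase[sel]) ** 2)
        return err, sol_se, sols_ase

    if K == 2:
        # vectorized scoring of all candidate orientation pairs via 2x2
        # normal equations per data block (SE plus one block per group)
        W = np.stack([watson_factor(scheme.b, scheme.bvecs, n, dd0)
                      for n in cand])  # (nc, n_exc)
        blocks = [(np.ones(len(scheme), bool), mag_se)] + [
            (t_idx == j, mag_ase) for j in range(n_t)]
        iu, ku = np.triu_indices(len(cand), k=1)
        keep = np.abs(np.einsum("ij,ij->i", cand[iu], cand[ku])) <= 0.95
        iu, ku = iu[keep], ku[keep]
        err = np.zeros(iu.size)
        for sel, y in blocks:
            Ws = W[:, sel]
            ys = y[sel]
            G = Ws @ Ws.T
            r = Ws @ ys
            a11, a22, a12 = G[iu, iu], G[ku, ku], G[iu, ku]
            b1, b2 = r[iu], r[ku]
            det = np.maximum(a11 * a22 - a12**2, 1e-30)
            x1 = (a22 * b1 - a12 * b2) / det
            x2 = (a11 * b2 - a12 * b1) / det
            err += ys @ ys - (b1 * x1 + b2 * x2)
        order = np.argsort(err)[:max(1, n_restarts)]
        scores = []
        for idx in order:
            combo = (int(iu[idx]), int(ku[idx]))
            e, s_se, s_ase = linear_score(cand[list(combo)])
            scores.append((e, combo, s_se, s_ase))
    else:
        import itertools
        combos = list(itertools.combinations(range(len(cand)), K))
        scores = []
        for combo in combos:
            err_c, s_se, s_ase = linear_score(cand[list(combo)])
            scores.append((err_c, combo, s_se, s_ase))
    scores.sort(key=lambda x: x[0])

    def pack(ns, dd, a_se, a_ase):
        th = np.arccos(np.clip(ns[:, 2], -1, 1))
        ph = np.arctan2(ns[:, 1], ns[:, 0])
        return np.concatenate([th, ph, dd, a_se, a_ase.ravel()])

    lo = np.concatenate([np.full(2 * K, -np.inf), np.zeros(K),
                         np.zeros(K), np.zeros(K * n_t)])
    hi = np.full(lo.size, np.inf)

    def residual(p):
        se, ase = _mag_model(p, scheme, K, t_idx, n_t)
        return np.concatenate([se - mag_se, ase - mag_ase])

    best = None
    for r, (err, combo, s_se, s_ase) in enumerate(scores[:max(1, n_restarts)]):
        ns = cand[list(combo)]
        p0 = pack(ns, np.full(K, dd0), np.clip(s_se, 1e-6, None),
                  np.clip(s_ase, 1e-6, None))
        sol = least_squares(residual, p0, bounds=(lo, hi), xtol=1e-14,
                            ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost:
            best = sol
    p = best.x
    ns = np.array([_to_upper_hemisphere(_angles_to_vec(p[k], p[K + k]))
                   for k in range(K)])
    dd = p[2 * K:3 * K].copy()
    a_se = p[3 * K:4 * K].copy()
    a_ase = p[4 * K:].reshape(K, n_t).copy()
    order = np.lexsort((-ns[:, 0], -ns[:, 1], -ns[:, 2], -a_se))
    return MagnitudeFit(ns[order], dd[order], a_se[order], a_ase[order],
                        groups, residual=float(np.sqrt(2 * best.cost)))


# ---------------------------------------------------------------------------
# stages 2-4: phases


def estimate_phiSE(S_SE) -> np.ndarray:
    """Per-excitation phase at the first readout (principal angle)."""
    return np.angle(np.asarray(S_SE))


def interreadout_phase(S_SE, S_ASE) -> np.ndarray:
    """Phase accumulated between the readouts: arg(S_ASE conj(S_SE)).

    Independent of the (random) SE phase by construction.
    """
    return np.angle(np.asarray(S_ASE) * np.conj(np.asarray(S_SE)))


@dataclass
class PhaseFit:
    """Susceptibility phases and odd eddy coefficients at one t_phase."""

    phi_susc: np.ndarray  # (K,), rad
    eddy: EddyCoefficients
    residual: float
    cov: np.ndarray | None = None  # Laplace covariance of phi_susc
    identifiable: np.ndarray | None = None  # per-population flag


def fit_phase_single_tphase(S_SE, S_ASE, scheme: Scheme, magfit: MagnitudeFit,
                            basis: SHBasis | None = None,
                            eddy_even: EddyCoefficients | None = None) -> PhaseFit:
    """Weighted complex fit of per-population susceptibility phases plus
    odd-order eddy SH coefficients, for one (orientation, t_phase) subset.

    The model for each excitation's inter-readout phasor is the
    magnitude-weighted mixture of population phases times the eddy phase;
    fitting the complex residuals avoids any phase-wrap problems. If
    ``eddy_even`` is given (a t_phase = 0 calibration), its even part is
    removed from the data first. Populations whose Watson weight never
    dominates anywhere on the shell are flagged unidentifiable.
    """
    if basis is None:
        basis = SHBasis(lmax=1)
    t_vals = np.unique(scheme.t_phase)
    if t_vals.size != 1:
        raise ValueError("expected a single-t_phase subset")
    t = float(t_vals[0])
    p = np.asarray(S_ASE) * np.conj(np.asarray(S_SE))
    dwi = scheme.b > 0
    p = p[dwi]
    dirs = scheme.bvecs[dwi]
    sub = Scheme(scheme.b[dwi], dirs, scheme.t_phase[dwi], scheme.TE1,
                 scheme.TE2, B0_hat=scheme.B0_hat[dwi],
                 orientation_id=scheme.orientation_id[dwi])
    a = magfit.weights(sub)  # (K, n)
    K, n = a.shape
    Y = basis.design_matrix(dirs)
    odd = basis.odd_mask
    Y_odd = Y[:, odd]
    n_odd = int(odd.sum())
    if eddy_even is not None:
        even = eddy_even.basis.even_mask
        corr = eddy_even.basis.design_matrix(dirs)[:, even] @ eddy_even.c[0, even]
        p = p * np.exp(-1j * corr)
    u = p / np.maximum(np.abs(p), 1e-300)
    w = np.abs(p)
    w = w / w.max()

    # identifiability: each population must dominate the weights somewhere
    share = a / np.maximum(a.sum(axis=0, keepdims=True), 1e-300)
    identifiable = share.max(axis=1) > 0.6

    # init: sphere-unwrap, odd-SH fit (susceptibility mixture is even in g,
    # so the odd projection isolates the eddy part), then weighted means
    psi = unwrap_on_sphere(np.angle(p), dirs, reference=int(np.argmax(w)))
    c_odd0, _ = np.linalg.lstsq(Y_odd, psi, rcond=None)[:2]
    rho = psi - Y_odd @ c_odd0
    phi0 = np.array([np.angle(np.sum(a[k] * w * np.exp(1j * rho)))
                     for k in range(K)])

    def model_unit(phi, c):
        mix = (a * np.exp(1j * phi[:, None])).sum(axis=0)
        m = mix * np.exp(1j * (Y_odd @ c))
        return m / np.maximum(np.abs(m), 1e-300)

    def residual(params):
        phi, c = params[:K], params[K:]
        d = model_unit(phi, c) - u
        return np.concatenate([w * d.real, w * d.imag])

    sol = least_squares(residual, np.concatenate([phi0, c_odd0]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    # large eddy coefficients wrap the phase between neighbouring
    # directions and can defeat the unwrap-based init; re-initialize from
    # the residual phase field until the fit stops improving
    for _ in range(3):
        if sol.cost < 1e-3 * np.sum(w**2):
            break
        r = u * np.conj(model_unit(sol.x[:K], sol.x[K:]))
        rho_r = unwrap_on_sphere(np.angle(r), dirs,
                                 reference=int(np.argmax(w)))
        dc, *_ = np.linalg.lstsq(Y_odd, rho_r, rcond=None)
        mean_r = rho_r - Y_odd @ dc
        p1 = np.concatenate([
            sol.x[:K] + np.array([np.angle(np.sum(
                a[k] * w * np.exp(1j * mean_r))) for k in range(K)]),
            sol.x[K:] + dc])
        sol2 = least_squares(residual, p1, xtol=1e-14, ftol=1e-14,
                             gtol=1e-14)
        if sol2.cost < sol.cost * (1 - 1e-9):
            sol = sol2
        else:
            break
    phi = _wrap(sol.x[:K])
    c = np.zeros(basis.n_coeff)
    c[odd] = sol.x[K:]
    # Laplace covariance of the susceptibility phases
    cov = None
    try:
        JTJ = sol.jac.T @ sol.jac
        s2 = 2 * sol.cost / max(2 * n - (K + n_odd), 1)
        cov = (np.linalg.pinv(JTJ) * s2)[:K, :K]
    except np.linalg.LinAlgError:
        pass
    return PhaseFit(phi, EddyCoefficients(basis, [t], c[None, :]),
                    float(np.sqrt(2 * sol.cost)), cov, identifiable)


def myelin_freq_difference(phi_susc, t_phase_ms: float) -> np.ndarray:
    """Pairwise myelin frequency differences (rad/s) from the
    susceptibility phases of one t_phase: (phi_k - phi_k') / t_phase.
    The shared bulk frequency cancels exactly. Returns a (K, K)
    antisymmetric matrix."""
    phi = np.asarray(phi_susc, float)
    if t_phase_ms <= 0:
        raise ValueError("t_phase must be positive")
    return (phi[:, None] - phi[None, :]) / (t_phase_ms * MS)


# ---------------------------------------------------------------------------
# stage 5: myelin parameters


def _sin2_per_orientation(n_hat, B0_hats):
    """(n_orient, K) sin^2 theta for fitted orientations under each B0."""
    B0 = np.atleast_2d(B0_hats)
    return np.clip(1.0 - (B0 @ np.asarray(n_hat).T) ** 2, 0.0, 1.0)


def fit_average_logg(phi_table, t_grid, sin2, consts: PhysicalConstants,
                     seed=None, n_starts: int = 1):
    """MAP estimate of the per-population average log g (single-pool).

    ``phi_table`` maps orientation index -> (n_t, K) measured
    susceptibility phases; ``sin2`` is (n_orient, K). Model:
    phi = (omega_myelin(log g, sin^2) + omega_bulk_o) * t, with log g
    bounded to the [log 0.6, 0] prior support and one free bulk frequency
    per orientation. Circular residuals absorb phase wraps. When the data
    only constrain a combination of the log g (e.g. two fibers with equal
    sin^2 theta at one orientation), the optimizer returns the point of
    the degenerate ridge closest to its random start.
    """
    rng = np.random.default_rng(seed)
    t_s = np.asarray(t_grid, float) * MS
    n_orient = len(phi_table)
    K = sin2.shape[1]
    scale = -0.75 * consts.omega0 * consts.chi_A  # omega per unit log g

    def model(logg, wb):
        out = {}
        for o in range(n_orient):
            w_my = scale * logg[None, :] * sin2[o][None, :]
            out[o] = (w_my + wb[o]) * t_s[:, None]
        return out

    def make_residual(logg0):
        def residual(params):
            logg, wb = params[:K], params[K:]
            m = model(logg, wb)
            res = []
            for o in range(n_orient):
                res.append(_wrap(m[o] - phi_table[o]).ravel())
            # weak proximal term: on an exactly-fitting degenerate ridge
            # (e.g. equal sin^2 theta, single orientation) this selects the
            # ridge point nearest the start without biasing identified fits
            res.append(1e-2 * (logg - logg0))
            return np.concatenate(res)
        return residual

    lo = np.concatenate([np.full(K, LOG_G_MIN), np.full(n_orient, -np.inf)])
    hi = np.concatenate([np.zeros(K), np.full(n_orient, np.inf)])
    best = None
    for _ in range(max(1, n_starts)):
        # one shared draw from the prior: on a degenerate ridge every MAP
        # point is equivalent, and starting on the prior diagonal makes the
        # returned ridge point sample the full prior spread
        logg0 = np.full(K, rng.uniform(LOG_G_MIN, 0.0))
        wb0 = np.empty(n_orient)
        for o in range(n_orient):
            # bulk init consistent with the drawn log g start, so on a
            # degenerate ridge the optimizer starts (and stays) at the
            # sampled prior position; circular mean of the measured phases
            # (they are only known mod 2 pi and may straddle +-pi)
            nz = np.nonzero(t_s > 0)[0]
            if nz.size:
                j = nz[np.argmin(t_s[nz])]
                slope = float(np.angle(np.mean(
                    np.exp(1j * phi_table[o][j])))) / t_s[j]
            else:
                slope = 0.0
            wb0[o] = slope - scale * logg0[0] * np.mean(sin2[o])
        sol = least_squares(make_residual(logg0), np.concatenate([logg0, wb0]),
                            bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    logg = best.x[:K]
    wb = best.x[K:]
    return logg, wb, float(np.sqrt(2 * best.cost))


def fit_twopool(phi_table, t_grid, sin2, consts: PhysicalConstants,
                seed=None, n_starts: int = 4, n_wrap_grid: int = 48,
                max_nfev: int = 400):
    """Two-pool fit: myelinated signal fraction and myelinated log g.

    Same inputs as :func:`fit_average_logg` but across >= 3 distinct
    t_phase, modelling the nonlinear phase evolution
    angle((1-f) + f exp(i omega_my t)) + omega_bulk t per population. The
    bulk frequency is only identifiable modulo 2 pi / dt for a uniform
    t_phase grid; each start seeds it from a 1D grid search over one
    period. Returns (f, log_g_myelin, omega_bulk, cost).
    """
    rng = np.random.default_rng(seed)
    t_s = np.asarray(t_grid, float) * MS
    if np.unique(t_s).size < 3:
        raise ValueError("two-pool fit needs >= 3 distinct t_phase")
    n_orient = len(phi_table)
    K = sin2.shape[1]
    scale = -0.75 * consts.omega0 * consts.chi_A

    def pop_phase(f, logg, s2):
        w = scale * logg * s2
        z = (1 - f) + f * np.exp(1j * w * t_s)
        return np.angle(z)

    def residual(params):
        f = params[:K]
        logg = params[K:2 * K]
        wb = params[2 * K:]
        res = []
        for o in range(n_orient):
            m = np.column_stack([pop_phase(f[k], logg[k], sin2[o, k])
                                 for k in range(K)])
            m = m + wb[o] * t_s[:, None]
            res.append(_wrap(m - phi_table[o]).ravel())
        return np.concatenate(res)

    dt = np.min(np.diff(np.unique(t_s)))
    period = 2 * np.pi / dt
    lo = np.concatenate([np.zeros(K), np.full(K, LOG_G_MIN),
                         np.full(n_orient, -np.inf)])
    hi = np.concatenate([np.ones(K), np.zeros(K), np.full(n_orient, np.inf)])
    wb_grid = np.linspace(-period / 2, period / 2, n_wrap_grid, endpoint=False)
    best = None
    for _ in range(max(1, n_starts)):
        f0 = rng.uniform(0.05, 0.95, K)
        logg0 = rng.uniform(LOG_G_MIN, -0.01, K)
        wb0 = np.empty(n_orient)
        for o in range(n_orient):
            costs = []
            for wb in wb_grid:
                m = np.column_stack([pop_phase(f0[k], logg0[k], sin2[o, k])
                                     for k in range(K)]) + wb * t_s[:, None]
                costs.append(np.sum(_wrap(m - phi_table[o]) ** 2))
            wb0[o] = wb_grid[int(np.argmin(costs))]
        sol = least_squares(residual, np.concatenate([f0, logg0, wb0]),
                            bounds=(lo, hi), xtol=1e-10, ftol=1e-10,
                            gtol=1e-10, max_nfev=max_nfev)
        if best is None or sol.cost < best.cost - 1e-12:
            best = sol
    f = best.x[:K]
    logg = best.x[K:2 * K]
    wb = best.x[2 * K:]
    return f, logg, wb, float(np.sqrt(2 * best.cost))


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class FitResult:
    """Estimated voxel parameters with diagnostics.

    ``populations`` is a list of dicts with keys ``n_hat``, ``A_SE``,
    ``A_ASE``, ``Delta_D``, ``phi_susc`` (dict (orientation, t_phase) ->
    rad), and either ``log_g_mean`` (single-pool) or ``f_myelin`` +
    ``log_g_myelin`` (two-pool), plus ``T2``/``T2p`` when >= 2 t_phase are
    available.
    """

    populations: list
    phi_SE: np.ndarray
    omega_bulk: dict
    eddy: dict  # (orientation, t_phase) -> EddyCoefficients
    mode: str
    uncertainties: dict = field(default_factory=dict)
    diagnostics: dict = field(default_factory=dict)

    def myelin_freq_difference_matrix(self, orientation: int = 0,
                                      t_phase: float | None = None):
        keys = [k for k in self.populations[0]["phi_susc"] if k[0] == orientation]
        if t_phase is not None:
            keys = [k for k in keys if np.isclose(k[1], t_phase)]
        key = max(keys, key=lambda k: k[1])
        phis = [p["phi_susc"][key] for p in self.populations]
        return myelin_freq_difference(phis, key[1])


def fit_voxel(S_SE, S_ASE, scheme: Scheme, K: int = 2, mode: str = "auto",
              consts: PhysicalConstants | None = None, lmax_eddy: int = 1,
              seed=None, n_restarts: int = 5, refine: bool = True,
              even_correction: bool = False) -> FitResult:
    """Full staged fit of one voxel of complex DIPPI data.

    ``mode`` is ``'single_pool'`` (average log g; forced for single-
    t_phase data), ``'two_pool'`` (myelinated fraction + myelinated log g,
    needs >= 3 distinct t_phase) or ``'auto'``.
    """
    consts = consts or PhysicalConstants()
    rng = np.random.default_rng(seed)
    S_SE = np.asarray(S_SE)
    S_ASE = np.asarray(S_ASE)
    t_nonzero = np.unique(scheme.t_phase[scheme.t_phase > 0])
    if mode == "auto":
        mode = "two_pool" if t_nonzero.size >= 3 else "single_pool"
    if mode == "two_pool" and t_nonzero.size < 3:
        raise ValueError("two-pool mode needs >= 3 distinct nonzero t_phase")

    magfit = fit_magnitude(np.abs(S_SE), np.abs(S_ASE), scheme, K=K,
                           n_restarts=n_restarts,
                           seed=int(rng.integers(2**31)))
    phi_se = estimate_phiSE(S_SE)

    orient_ids = np.unique(scheme.orientation_id)
    basis = SHBasis(lmax=lmax_eddy)
    eddy_even = None
    phase_fits: dict = {}
    for oid in orient_ids:
        sel0 = (scheme.orientation_id == oid) & (scheme.t_phase == 0) \
            & (scheme.b > 0)
        if even_correction and sel0.any():
            psi0 = unwrap_on_sphere(
                interreadout_phase(S_SE[sel0], S_ASE[sel0]), scheme.bvecs[sel0])
            eddy_even, _ = fit_eddy(psi0, scheme.bvecs[sel0], basis,
                                    parity="all", t_phase=0.0)
        for t in t_nonzero:
            sel = (scheme.orientation_id == oid) & (scheme.t_phase == t)
            sub = Scheme(scheme.b[sel], scheme.bvecs[sel], scheme.t_phase[sel],
                         scheme.TE1, scheme.TE2, B0_hat=scheme.B0_hat[sel],
                         orientation_id=scheme.orientation_id[sel])
            phase_fits[(int(oid), float(t))] = fit_phase_single_tphase(
                S_SE[sel], S_ASE[sel], sub, magfit, basis=basis,
                eddy_even=eddy_even)

    # per-orientation sin^2 theta of the fitted orientations
    B0_by_oid = {int(o): scheme.B0_hat[scheme.orientation_id == o][0]
                 for o in orient_ids}
    sin2 = _sin2_per_orientation(magfit.n_hat,
                                 np.array([B0_by_oid[int(o)] for o in orient_ids]))
    phi_table = {i: np.array([[phase_fits[(int(o), float(t))].phi_susc[k]
                               for k in range(K)] for t in t_nonzero])
                 for i, o in enumerate(orient_ids)}

    if mode == "single_pool":
        logg, wb, cost = fit_average_logg(
            phi_table, t_nonzero, sin2, consts,
            seed=int(rng.integers(2**31)))
        f = None
    else:
        f, logg, wb, cost = fit_twopool(
            phi_table, t_nonzero, sin2, consts,
            seed=int(rng.integers(2**31)))

    if refine:
        f, logg, wb, phase_fits, cost = _joint_refine(
            S_SE, S_ASE, scheme, magfit, phase_fits, f, logg, wb, sin2,
            orient_ids, t_nonzero, consts, mode)

    populations = []
    for k in range(K):
        pop = dict(
            n_hat=magfit.n_hat[k], A_SE=magfit.A_SE[k],
            A_ASE={(int(o), float(t)): magfit.A_ASE[k, j]
                   for j, (o, t) in enumerate(magfit.groups)},
            Delta_D=magfit.Delta_D[k],
            phi_susc={key: pf.phi_susc[k] for key, pf in phase_fits.items()},
        )
        if mode == "single_pool":
            pop["log_g_mean"] = float(logg[k])
        else:
            pop["f_myelin"] = float(f[k])
            pop["log_g_myelin"] = float(logg[k])
            pop["log_g_mean"] = float(f[k] * logg[k])
        if hasattr(magfit, "refined_T2"):
            pop["T2"] = float(magfit.refined_T2[k])
            pop["T2p"] = float(magfit.refined_T2p[k])
        elif magfit.t_grid.size >= 2:
            T2, T2p = magfit.relaxation_times(scheme.TE1, scheme.TE2)
            pop["T2"], pop["T2p"] = float(T2[k]), float(T2p[k])
        populations.append(pop)

    unc = {}
    for key, pf in phase_fits.items():
        if pf.cov is not None:
            unc[("phi_susc", key)] = np.sqrt(np.clip(np.diag(pf.cov), 0, None))
    return FitResult(
        populations=populations, phi_SE=phi_se,
        omega_bulk={int(o): float(wb[i]) for i, o in enumerate(orient_ids)},
        eddy={key: pf.eddy for key, pf in phase_fits.items()},
        mode=mode, uncertainties=unc,
        diagnostics=dict(
            objective=cost, magnitude_residual=magfit.residual,
            widths_identifiable=magfit.widths_identifiable,
            phase_identifiable={key: pf.identifiable
                                for key, pf in phase_fits.items()},
        ),
    )


def _joint_refine(S_SE, S_ASE, scheme, magfit, phase_fits, f, logg, wb, sin2,
                  orient_ids, t_nonzero, consts, mode):
    """Joint complex refinement of the full voxel model.

    The staged estimates only initialize this final fit, which optimizes
    orientations, widths, amplitudes, myelin parameters, bulk frequencies
    and the odd eddy coefficients together against the SE magnitudes and
    the phi_SE-free complex inter-readout products S_ASE conj(S_SE). The
    staged magnitude fit is biased wherever crossing populations decohere
    (the magnitude of the population sum falls below the sum of
    magnitudes); the joint fit models that interference explicitly.

    In two-pool mode the ASE amplitudes follow the T2/T2' decay law and
    each population carries its full complex two-pool factor, whose
    non-exponential magnitude evolution is what separates the myelinated
    fraction from the myelinated log g once the mixture phase is close to
    linear. In single-pool mode amplitudes stay free per (orientation,
    t_phase) group and the susceptibility factor has unit modulus.
    """
    K = len(magfit.n_hat)
    scale = -0.75 * consts.omega0 * consts.chi_A
    keys = sorted(phase_fits.keys())
    n_keys = len(keys)
    basis = phase_fits[keys[0]].eddy.basis
    odd = basis.odd_mask
    n_odd = int(odd.sum())
    oid_index = {int(o): i for i, o in enumerate(orient_ids)}
    n_orient = len(orient_ids)
    B0s = np.array([scheme.B0_hat[scheme.orientation_id == o][0]
                    for o in orient_ids])
    twopool = mode == "two_pool"
    lg_anchor = np.asarray(logg, float).copy()

    subsets = []
    for key in keys:
        oid, t = key
        sel = ((scheme.orientation_id == oid) & (scheme.t_phase == t)
               & (scheme.b > 0))
        p = S_ASE[sel] * np.conj(S_SE[sel])
        # noise sd of the product is sigma * sqrt(|S_SE|^2 + |S_ASE|^2)
        # (circular complex noise on both readouts): inverse-sd weights
        # make the product block commensurate with the magnitude block
        w_p = 1.0 / np.sqrt(np.abs(S_SE[sel]) ** 2 + np.abs(S_ASE[sel]) ** 2
                            + 1e-300)
        Y_odd = basis.design_matrix(scheme.bvecs[sel])[:, odd]
        subsets.append((key, p, scheme.b[sel], scheme.bvecs[sel], Y_odd, w_p))
    mag_se = np.abs(S_SE)

    # parameter layout: th(K) ph(K) dd(K) a_se(K) | amplitude block |
    # [f(K)] logg(K) wb(n_orient) c_odd(n_keys*n_odd)
    n_amp = 2 * K if twopool else K * n_keys  # T2+T2p vs free per group

    def unpack(params):
        th, ph = params[0:K], params[K:2 * K]
        dd = params[2 * K:3 * K]
        a_se = params[3 * K:4 * K]
        i = 4 * K
        amp = params[i:i + n_amp]
        i += n_amp
        fv = params[i:i + K] if twopool else None
        i += K if twopool else 0
        lg = params[i:i + K]
        i += K
        wbv = params[i:i + n_orient]
        i += n_orient
        cs = params[i:].reshape(n_keys, n_odd)
        return th, ph, dd, a_se, amp, fv, lg, wbv, cs

    def residual(params):
        th, ph, dd, a_se, amp, fv, lg, wbv, cs = unpack(params)
        ns = np.stack([_angles_to_vec(th[k], ph[k]) for k in range(K)])
        s2 = np.clip(1.0 - (B0s @ ns.T) ** 2, 0.0, 1.0)  # (n_orient, K)
        res = []
        se_model = np.zeros(len(scheme))
        for k in range(K):
            se_model += a_se[k] * watson_factor(scheme.b, scheme.bvecs,
                                                ns[k], dd[k])
        res.append(se_model - mag_se)
        for j, (key, p, b_sub, g_sub, Y_odd, w_p) in enumerate(subsets):
            oid, t = key
            t_s = t * MS
            o = oid_index[int(oid)]
            w_my = scale * lg * s2[o]
            if twopool:
                z = (1 - fv) + fv * np.exp(1j * w_my * t_s)
                a_k = ase_amplitude(a_se, amp[:K], amp[K:], t,
                                    scheme.TE1, scheme.TE2)
            else:
                z = np.exp(1j * w_my * t_s)
                a_k = amp.reshape(K, n_keys)[:, j]
            ase = np.zeros(len(b_sub), dtype=complex)
            se = np.zeros(len(b_sub))
            for k in range(K):
                w = watson_factor(b_sub, g_sub, ns[k], dd[k])
                ase += a_k[k] * w * z[k]
                se += a_se[k] * w
            m = ase * se * np.exp(1j * (Y_odd @ cs[j] + wbv[o] * t_s))
            d = (m - p) * w_p
            res.append(d.real)
            res.append(d.imag)
        if not twopool:
            # anchor the prior-flat direction: orientation noise gives the
            # log-g ridge a spurious shallow minimum that would otherwise
            # drag every ridge point toward it; the weight is far below
            # the Fisher information of any genuinely identified log g
            res.append(0.1 * (lg - lg_anchor))
        return np.concatenate(res)

    th0 = np.arccos(np.clip(magfit.n_hat[:, 2], -1, 1))
    ph0 = np.arctan2(magfit.n_hat[:, 1], magfit.n_hat[:, 0])
    if twopool:
        try:
            T20, T2p0 = magfit.relaxation_times(scheme.TE1, scheme.TE2)
        except ValueError:
            T20, T2p0 = np.full(K, 60.0), np.full(K, 84.0)
        amp0 = np.concatenate([np.clip(T20, 10, 400), np.clip(T2p0, 10, 400)])
        amp_lo = np.full(2 * K, 5.0)
        amp_hi = np.full(2 * K, 500.0)
    else:
        amp0 = np.empty((K, n_keys))
        for j, key in enumerate(keys):
            gsel = np.all(np.isclose(magfit.groups, key), axis=1)
            amp0[:, j] = magfit.A_ASE[:, gsel].ravel()
        amp0 = amp0.ravel()
        amp_lo = np.zeros(K * n_keys)
        amp_hi = np.full(K * n_keys, np.inf)
    c0 = np.concatenate([phase_fits[key].eddy.c[0, odd] for key in keys])
    parts = [th0, ph0, magfit.Delta_D, magfit.A_SE, amp0] + \
        ([np.asarray(f, float)] if twopool else []) + \
        [np.asarray(logg, float), np.asarray(wb, float), c0]
    p0 = np.concatenate(parts)
    inf = np.inf
    lo = np.concatenate(
        [np.full(2 * K, -inf), np.zeros(K), np.zeros(K), amp_lo]
        + ([np.zeros(K)] if twopool else [])
        + [np.full(K, LOG_G_MIN), np.full(n_orient, -inf),
           np.full(c0.size, -inf)])
    hi = np.concatenate(
        [np.full(2 * K, inf), np.full(2 * K, inf), amp_hi]
        + ([np.ones(K)] if twopool else [])
        + [np.zeros(K), np.full(n_orient, inf), np.full(c0.size, inf)])
    sol = least_squares(residual, np.clip(p0, lo, hi), bounds=(lo, hi),
                        xtol=1e-12, ftol=1e-12, gtol=1e-12)
    th, ph, dd, a_se, amp, fv, lg, wbv, cs = unpack(sol.x)
    ns = np.stack([_angles_to_vec(th[k], ph[k]) for k in range(K)])
    s2 = np.clip(1.0 - (B0s @ ns.T) ** 2, 0.0, 1.0)
    magfit.n_hat = np.stack([_to_upper_hemisphere(n) for n in ns])
    magfit.Delta_D = dd
    magfit.A_SE = a_se
    if twopool:
        magfit.refined_T2 = amp[:K].copy()
        magfit.refined_T2p = amp[K:].copy()
        for j, key in enumerate(keys):
            gsel = np.all(np.isclose(magfit.groups, key), axis=1)
            oid, t = key
            w_my = scale * lg * s2[oid_index[int(oid)]]
            z = (1 - fv) + fv * np.exp(1j * w_my * t * MS)
            a_k = ase_amplitude(a_se, amp[:K], amp[K:], t,
                                scheme.TE1, scheme.TE2) * np.abs(z)
            magfit.A_ASE[:, gsel] = a_k[:, None]
    else:
        a_ase = amp.reshape(K, n_keys)
        for j, key in enumerate(keys):
            gsel = np.all(np.isclose(magfit.groups, key), axis=1)
            magfit.A_ASE[:, gsel] = a_ase[:, j][:, None]
    new_fits = {}
    for j, key in enumerate(keys):
        pf = phase_fits[key]
        c = np.zeros(basis.n_coeff)
        c[odd] = cs[j]
        oid, t = key
        t_s = t * MS
        w_my = scale * lg * s2[oid_index[int(oid)]]
        if twopool:
            z = (1 - fv) + fv * np.exp(1j * w_my * t_s)
            phi = _wrap(np.angle(z) + wbv[oid_index[int(oid)]] * t_s)
        else:
            phi = _wrap((w_my + wbv[oid_index[int(oid)]]) * t_s)
        new_fits[key] = PhaseFit(phi, EddyCoefficients(basis, [t], c[None, :]),
                                 pf.residual, pf.cov, pf.identifiable)
    return fv, lg, wbv, new_fits, float(np.sqrt(2 * sol.cost))
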