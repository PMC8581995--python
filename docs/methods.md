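# Methods

## The model

Diffusion-prepared phase imaging (DIPPI) appends a second, asymmetric
spin-echo readout to a standard diffusion-weighted spin-echo sequence. The
second readout is offset from the second spin echo by a tuneable phase
accumulation time `t_phase`, during which the off-resonance field of the
tissue rephases into the signal. The phase *difference* between the two
readouts is therefore sensitive to the local susceptibility field of the
water still visible after diffusion weighting — predominantly intra-axonal
water — and is unaffected by the (large, effectively random) phase
accumulated during the diffusion preparation itself.

For a myelinated axon idealized as an infinite hollow cylinder with
anisotropic sheath susceptibility, the induced field in the lumen is
uniform:

    omega_myelin = -(3/4) * omega0 * chi_A * log(g) * sin^2(theta)

with `omega0 = gamma B0` the Larmor angular frequency, `chi_A` the
anisotropic susceptibility of myelin (default −100 ppb), `g` the g-ratio
(inner/outer sheath radius) and `theta` the angle between the axon and the
main field. At 7 T with g = 0.7 and a perpendicular fiber this is
−50.1 rad/s (−7.97 Hz). Because the relation is linear in `log g`, a
frequency error `delta_omega` maps to a log-g bias of
`4·(2π·delta_omega) / (3·omega0·|chi_A|·sin^2 theta)` ≈
0.045 per Hz at 7 T for a perpendicular fiber, diverging for fibers
parallel to the field.

### Voxel signal

A voxel holds K crossing fiber populations. Magnitudes over gradient
directions are sums of Watson-profile lobes `A_k exp(-b ΔD_k (g·n_k)^2)`
with the width `ΔD_k` shared between the two readouts; ASE amplitudes
additionally decay with T2 over the full extra echo time and with T2′ over
`t_phase` (the standard asymmetric-spin-echo decomposition, which makes T2
and T2′ identifiable from multi-`t_phase` amplitudes; 1/T2\* = 1/T2 +
1/T2′). The SE phase is one arbitrary constant per excitation. The
inter-readout phase carries, per population, the two-pool susceptibility
factor

    z_k(t) = (1 - f_myelin) + f_myelin * exp(i * omega_myelin,k * t)

(whose angle is `f·omega·t` to first order, approaching the dominant
pool's phase as `omega·t → π`), a voxel-wide bulk frequency `omega_bulk`
shared by interdigitating populations, and an eddy-current phase expanded
in real spherical harmonics over the gradient sphere. Only odd SH orders
are identifiable in tissue (even orders are degenerate with the
susceptibility phase); a `t_phase = 0` calibration shell pins the even
orders accumulated between the spin echoes.

## Estimation

Fitting is staged, each stage initializing the next, followed by a joint
refinement:

1. **Magnitude fit** — nonlinear least squares of K Watson lobes with
   shared widths, initialized by a vectorized search over candidate
   orientation pairs with linearized amplitudes; populations ordered by
   descending SE amplitude, orientations gauged to the upper hemisphere.
2. **SE phases** read directly off the SE readouts (their exact
   conditional optimum given magnitudes).
3. **Inter-readout phases** `arg(S_ASE conj(S_SE))`, unwrapped over the
   gradient sphere by region-growing along the minimum-spanning tree of a
   k-nearest-neighbour (k = 5) direction graph.
4. **Per (orientation, t_phase) shell**: odd-order eddy coefficients plus
   one susceptibility phase per population by weighted complex least
   squares (complex residuals are wrap-free). Large eddy draws can defeat
   the unwrap-based initialization, so the fit re-initializes from its own
   residual phase field until the cost stops improving.
5. **Myelin parameters**: either the signal-averaged log g per population
   (single-pool, valid for short `t_phase`) or the two-pool
   `(f_myelin, log g_myelin)` model across ≥3 `t_phase`, with circular
   residuals and a grid search over the bulk-frequency wrap (for a uniform
   `t_phase` grid the bulk frequency is identifiable only modulo
   `2π/Δt_phase`, which does not affect the myelin parameters).
6. **Joint complex refinement** of orientations, widths, amplitudes,
   myelin parameters, bulk frequencies and odd eddy coefficients against
   the SE magnitudes and the phi_SE-free inter-readout products, with
   residuals inverse-noise weighted (product noise sd is
   `sigma·sqrt(|S_SE|^2+|S_ASE|^2)`).

Two estimation details deserve emphasis:

* **What identifies the two-pool parameters.** For `f_myelin = 0.5` the
  mixture phase is exactly linear in `t` until the π jump, so phase alone
  cannot separate `f_myelin` from `log g_myelin` below that point — only
  their product. The refinement therefore models the *full complex*
  two-pool factor with T2/T2′-parametrized amplitudes: the mixture's
  non-exponential magnitude decay is what breaks the ridge. In single-pool
  mode amplitudes stay free per (orientation, t_phase) group and the
  susceptibility factor is unit-modulus.
* **Behaviour on degenerate ridges.** When only the sin²θ-weighted log-g
  difference is identified (equal angles, one head orientation), the MAP
  point under the uniform prior is any ridge point. The optimizer draws
  one ridge position from the prior (a single shared uniform draw for all
  populations) and a weak proximal term anchors it there, so repeated
  noise realizations trace out the degeneracy line across the prior box —
  without biasing identified parameters, whose Fisher information exceeds
  the anchor weight by more than two orders of magnitude.

Uncertainties on the per-shell susceptibility phases are Laplace
(inverse-curvature) approximations and flagged as such.

## Absolute g-ratios from multiple head orientations

One head orientation yields `log g_1 sin^2 theta_1 - log g_2 sin^2
theta_2` per voxel. Rotating the head changes the weights; a Gaussian
linear model over the four standard positions (rest, forward, right,
left; rotation angle shared) then gives a closed-form posterior for each
`log g`, with the uniform prior on [log 0.6, 0] approximated by a Gaussian
of equal mean and sd (−log 0.6/√12 ≈ 0.1475, i.e. 15.9% in
`100·(exp(sd)−1)` terms). The posterior sd never exceeds the prior sd; at
zero rotation a perpendicular pair is pinned only in its difference, so
each marginal sits at prior/√2. The posterior sd is a Bayesian quantity
(not a frequentist bound); an optional rejection-sampling posterior under
the exact uniform prior is available for cross-checking.

## Synthetic data: what it emulates

`simulate_dataset` reproduces the degeneracy-study conditions: stick-like
diffusion (d∥ = 1.7 µm²/ms, so ΔD = 1.7 and amplitudes are
b-independent), T2 = 60 ms and T2\* = 35 ms (hence T2′ = 84 ms) as
appropriate at 7 T, two fibers crossing at 90° with half the axons
myelinated at g = 0.7, SE phase uniform on [0, 2π) per excitation, bulk
frequency uniform over ±[200, 2000] rad/s (large enough to wrap several
times between successive `t_phase`), and first-order eddy coefficients
`a + b·t_phase` with `a ~ N(0, 1.4 rad)`, `b ~ N(0, 18 Hz)`. Defaults the
study leaves open, chosen once: b = 3 ms/µm² (the b value recommended to
suppress extra-axonal signal), a 60-direction shell acquired together with
its reversed polarities (as in the phantom protocol; antipodal pairs are
what separate odd eddy from even susceptibility phase), and SNR = 20 at
the b = 0 SE magnitude with circular complex Gaussian noise.

Not emulated: EPI readout artefacts, partial Fourier, motion between
volumes, myelin-water signal, spatially varying bulk fields. Passing tests
therefore show correctness of the estimator under the model's own
assumptions, not robustness to those effects in vivo.

Problem sizes used by the simulation studies: the degeneracy-line
experiment runs 50 noise realizations of a 120-volume single-`t_phase`
shell; the two-pool concentration experiment runs 50 realizations of a
30-direction shell at four `t_phase` (0–60 ms span) under two head
orientations.

## Monte Carlo substrate

White matter with 90°-crossing fibers is modelled as perfect cylinders
along x or y in interleaved single-axon-thick planes, planes 1 µm apart,
in-plane centres 1 µm apart, half the axons myelinated (g = 0.7),
impermeable walls, free diffusivity 2 µm²/ms. Successive same-orientation
planes are staggered by half a spacing (brick-like; periodic cell
2×2×4 µm): an aligned grid would leave straight extra-axonal channels
along z through which extra water escapes the diffusion weighting
entirely. The hollow-cylinder field is uniform in each myelinated lumen
and dipole-like outside with prefactor `omega0 (chi_I + chi_A/4) sin²θ
(r_o²−r_i²)/(2 r²)`; walkers read it from periodic 2D lookup tables
(bilinear, ~8 nm grid) with each cylinder's own external term masked
inside itself. The myelin annulus carries no water (the wall is a single
infinitely thin surface at the outer radius).

Spin evolution runs through the full sequence (excitation; 10 ms
rectangular gradient pulses 30 ms apart; two refocusing pulses; SE readout
and ASE readout `t_phase = 30 ms` after the second spin echo), with the
per-axis rms step held below a fifth of the cylinder radius and specular
wall reflection (sub-step circle intersection, up to six bounces, rare
pathological steps rejected). Because the trajectory does not depend on
the gradient amplitude, one trajectory set serves every b value via a
single gradient moment per spin. The default gradient is along z,
perpendicular to both fiber axes: the intra-axonal water of both
populations is then retained while the extra-axonal signal decays with b,
the regime in which the measured frequency falls short of the pure
intra-axonal value (an in-axis gradient instead leaves extra water trapped
in the strong-field lobes, biasing the frequency the other way).

**Known limitation.** In this geometry the 1 µm plane spacing leaves open
slabs of thickness (1 − d) µm between adjacent planes, so extra-axonal
hindrance — and with it the b = 3 extra-axonal signal fraction — depends
strongly on the outer diameter d: ≈10% at d = 0.98 µm (extra volume
fraction 0.25) but only a few percent at d ≤ 0.74 µm where the slabs are
open. The headline contamination numbers are therefore computed on the
dense substrate, the configuration that realizes the hindered regime; the
spread across the 0.5–0.98 µm range stays below 10 percentage points only
because all values are small. At 10⁴ spins the extra-signal magnitude at
b = 3 also carries a small positive Rayleigh-floor bias (~0.3 points).

## Numerical choices

* Angular frequencies are rad/s internally; Hz only at user interfaces.
  b values are ms/µm² (s/mm² converted on input). γ = 2.675221874e8
  rad s⁻¹ T⁻¹, configurable.
* The susceptibility phase enters signals as `exp(+i ω t_phase)`.
* Spherical harmonics: real orthonormal basis, l-major ordering, default
  lmax 3 for eddy QA and 1 for simulation fits (the simulated eddy field
  is first order).
* Optimizers: bounded trust-region least squares throughout; magnitude
  fit restarts from the best coarse-search candidates (default 5); fit
  tolerances 1e-12–1e-14 on noise-free paths, relaxed where the stage only
  provides initialization. Degenerate inputs (b = 0 only, single-sided
  weights, zero-magnitude mixtures) are flagged rather than silently
  fitted.
* Population gauge: orientations in the upper hemisphere, descending SE
  amplitude, antipodal flips broken lexicographically.
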