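# dippi

Modelling, simulation and estimation for **diffusion-prepared phase
imaging (DIPPI)** — an MRI approach that measures the myelin-induced phase
of diffusion-weighted water to estimate a **log g-ratio per crossing fiber
population** within a voxel, rather than a voxel-averaged myelin measure.

A DIPPI acquisition adds a second, asymmetric spin-echo readout after a
diffusion-weighted spin echo; the readout is offset from the second spin
echo by a phase accumulation time *t*<sub>phase</sub>. The phase
difference between the two readouts isolates the off-resonance frequency
of the water that survives diffusion weighting — predominantly
intra-axonal water, for which the hollow-cylinder model gives a uniform
myelin-induced frequency

&nbsp;&nbsp;&nbsp;&nbsp;ω<sub>myelin</sub> = −(3/4) ω₀ χ<sub>A</sub> log *g* sin²θ,

linear in the log g-ratio (−50.1 rad/s at 7 T for *g* = 0.7, sin²θ = 1,
χ<sub>A</sub> = −100 ppb). The package is aimed at researchers developing
or evaluating the sequence: it contains the generative voxel model
(Watson-profile magnitudes, two-pool myelinated/unmyelinated phase
evolution, bulk susceptibility, spherical-harmonic eddy phase), the staged
voxel-wise estimator with joint complex refinement, orientation/degeneracy
analyses (how much head rotation buys absolute g-ratios), and a Monte
Carlo spin walker in crossing-cylinder substrates that quantifies the bias
from residual extra-axonal signal.

## Worked example

Simulate a 90°-crossing voxel (half the axons myelinated, *g* = 0.7,
default 7 T constants) under two head orientations and four
*t*<sub>phase</sub> values, then fit the two-pool model:

```python
import numpy as np
from dataclasses import replace
from dippi import Scheme, default_crossing_voxel, simulate_dataset, fit_voxel

voxel = default_crossing_voxel()          # two fibers, f_myelin=0.5, g=0.7
voxel.populations = [
    replace(voxel.populations[0], n_hat=np.array([1.0, 0.0, 0.0])),
    replace(voxel.populations[1], n_hat=np.array([0.0, 1.0, 0.0])),
]
t_phases = (15.0, 30.0, 45.0, 60.0)
scheme = Scheme.concatenate([
    Scheme.dippi_shell(15, b=3.0, t_phases=t_phases).with_B0([0, 0, 1], 0),
    Scheme.dippi_shell(15, b=3.0, t_phases=t_phases).with_B0([1, 0, 0], 1),
])
data = simulate_dataset(voxel, scheme, snr=None, seed=42)   # noise-free
result = fit_voxel(data.S_SE, data.S_ASE, scheme, K=2, mode="two_pool", seed=0)
for k, pop in enumerate(result.populations):
    print(f"population {k}: n = {np.round(np.abs(pop['n_hat']), 3)}, "
          f"f_myelin = {pop['f_myelin']:.3f}, "
          f"g_myelin = {np.exp(pop['log_g_myelin']):.3f}")
dw = result.myelin_freq_difference_matrix(1)[0, 1]
print(f"myelin frequency difference (tilted orientation): {dw/(2*np.pi):.2f} Hz")
```

which prints

```
population 0: n = [0. 1. 0.], f_myelin = 0.500, g_myelin = 0.700
population 1: n = [1. 0. 0.], f_myelin = 0.500, g_myelin = 0.700
myelin frequency difference (tilted orientation): -3.99 Hz
```

Both fiber orientations, the myelinated signal fraction and the g-ratio of
the myelinated axons are recovered exactly from noise-free data. The last
line is the pairwise myelin frequency difference under the tilted head
orientation (B₀ along x): the fiber parallel to the field contributes no
myelin phase, so the difference equals the perpendicular fiber's effective
two-pool frequency, −3.99 Hz — the bulk susceptibility frequency cancels
in this difference by construction.

A thin command-line interface wraps the same library:

```bash
dippi simulate --seed 1 --out sim     # synthetic voxel dataset
dippi fit sim --seed 2 --out fitted   # staged + joint fit
dippi mc --seed 3 --n-spins 5000      # crossing-cylinder Monte Carlo
dippi precision-map --out prec        # head-rotation precision grid
dippi sin2theta --n-draws 100000      # crossing-fiber angle statistics
dippi eddy-qa ...                     # phantom-style eddy SH power report
```

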