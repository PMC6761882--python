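# tta2d

Kinetics of a bimolecular reaction confined to a true two-dimensional
medium: triplet–triplet annihilation (TTA) of porphyrins adsorbed at a
liquid–liquid interface, where molecular crowding turns ordinary diffusion
into transiently subdiffusive, memory-bearing motion and drags the reaction
kinetics along with it.

The package is for photochemists and membrane/interface biophysicists who
need to (i) model second-order decays with a *time-dependent* 2D rate
coefficient, (ii) fit pump–probe ground-state-recovery traces, (iii)
characterise anomalous diffusion in 2D trajectories (MSD scaling,
ergodicity, displacement memory, encounter statistics), and (iv) generate
all of the above synthetically with seeded simulators.

## The models

Two excited triplets that meet destroy each other's excitation,
T₁ + T₁ → S₁ + S₀, so the triplet surface concentration `T*(t)`
(mol m⁻²) obeys

    dT*/dt = −k T*²,        T*(t) = T0/(1 + k T0 t),    t½ = 1/(k T0).

In two dimensions the diffusion-controlled "constant" is not constant.
Solving the Smoluchowski problem in cylindrical coordinates (an absorbing
disk of radius R in a plane) gives

    k(t) = N_A (8D/π) ∫₀^∞ exp(−Du²t) / ( u [J₀²(uR) + Y₀²(uR)] ) du ,

which decays logarithmically forever — 2D exploration is compact, a walker
keeps revisiting its own neighbourhood. Inserting k(t) into the rate law
gives the 2D diffusion model (solved numerically; fitted for D with
R = 1.5 nm, the porphyrin-core contact distance).

When crowding makes the motion subdiffusive (MSD ∝ t^d, d < 1), the decay
follows the fractal rate law

    dT*/dt = −k_f t^(−h) T*²,   1/T*(t) = 1/T0 + k_f t^(1−h)/(1−h),

with h = 0 recovering classical kinetics. The collision-theory bridge
`rate = f · T*²` links the kinetics to trajectory statistics: f is the
new-encounter frequency, the time-derivative of the mean number of
*distinct* partners that ever came within 1.5 nm of a focal molecule
(N_enc ∝ t^m ⇒ f ∝ t^(m−1)).

## Worked example

```python
import numpy as np
from tta2d import DiffusionKineticsParams, solve_tta_2d
from tta2d.fitting import fit_diffusion_2d, fit_fractal, extract_half_life
from tta2d.kinetics import FractalParams, fractal_solution

# a triplet decay governed by the 2D time-dependent coefficient,
# observed from the 20 ns instrument resolution onwards
params = DiffusionKineticsParams(D=1.1e-9, T0=1e-7)   # SI units
times = np.geomspace(2e-8, 5e-6, 60)
trace = solve_tta_2d(params, times)

print(fit_diffusion_2d(trace).params["D"])   # 1.1000909918483456e-09
print(extract_half_life(trace))              # 2.468239039191977e-08

# crowded-regime kinetics: the fractal law and its recovery
frac = fractal_solution(FractalParams(k_frac=3e14, h=0.13, T0=1e-7),
                        np.geomspace(1e-9, 1e-5, 60))
print(fit_fractal(frac).params["h"])         # 0.129999999999926
```

The fitted D recovers the generating value to better than 0.01%; the
half-life (24.7 ns absolute, i.e. ~4.7 ns past the observation start) is
short because the 2D coefficient is at its largest right after t_min; and
the fractal fit recovers h = 0.13 exactly on a noiseless trace.

The numbered scripts under `analysis/` run the full study pipeline
(coverage arithmetic → rate-coefficient certification → trajectory
statistics → encounter counting → annihilation kinetics) and write tables
to `results/`.

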