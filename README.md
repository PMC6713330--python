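# spiralchaos

Transient spiral-wave chaos in two-dimensional human cardiac tissue
models: simulation, spiral-tip detection, and the statistics of
self-termination.

During fibrillation-like arrhythmias the electrical activity of cardiac
tissue is organised by rotating spiral waves. In simulations this
chaotic multi-spiral dynamics is often *transient*: spirals are
continuously created and annihilated until, at some unpredictable
moment, the last one vanishes and the tissue returns to rest. This
package reproduces that phenomenology with two human ventricular ionic
models and quantifies it:

* **BOCF** — the four-variable Bueno-Orovio–Cherry–Fenton minimal model
  (with the parameter set tuned to ten-Tusscher–Noble–Noble–Panfilov
  dynamics), and
* **TNNP** — the 2006 revision of the ten-Tusscher–Panfilov model
  (12 currents, 19 state variables, epicardial set with the
  breakup-enabling "slope 1.8" restitution variant),

both advanced by the monodomain equation
∂t V_m = ∇·(D∇V_m) − (I_ion + I_stim)/C_m on a square no-flux domain
(nine-point Laplacian; explicit Euler plus Rush-Larsen gating updates).

The analysis layer measures, for ensembles of seeded initial
conditions:

* **Escape rate / average lifetime.** The number of episodes still
  chaotic at time t decays as N_Ch(t) ∼ exp(−κt); the fit of this
  survival curve gives the escape rate κ and the average transient
  lifetime ⟨T⟩ ≈ κ⁻¹.
* **Supertransient size scaling.** ⟨T⟩ grows with the domain area A as
  ⟨T⟩ ∼ exp[(ãA)^γ] (type-II supertransient scaling), fitted by linear
  least squares on ln ln⟨T⟩ vs ln A.
* **Spiral-count Markov statistics.** N_spiral(t) — counted as the
  number of phase singularities, i.e. points where the winding number
  of the local phase θ around an elementary plaquette is ±1 — performs
  a random walk with jumps ΔN ∈ {−2, −1, 0, +1, +2} and absorbing 0;
  the package estimates the transition probabilities P_ΔN per state,
  occupancy distributions, termination-aligned ensemble averages, and
  dwell times in the single-spiral state.

Audience: researchers in computational cardiac electrophysiology and
nonlinear dynamics who want a workstation-scale, fully seeded
re-implementation of this pipeline with testable oracles at every
stage.

## Worked example

Generate an ensemble of 200 synthetic transient lifetimes with escape
rate κ = 0.25 s⁻¹ and recover κ from the survival curve:

```bash
$ spiralchaos synth --kind lifetimes --kappa 0.25 --n 200 --seed 3 --out lt.csv
wrote lt.csv
$ spiralchaos survival-fit --lifetimes lt.csv --out fit.json
kappa = 0.2103 /s, <T> = 4.756 s
```

This draw recovers κ = 0.210 ± 0.018 s⁻¹ (bootstrap standard
deviation, written to `fit.json`) against the true 0.25 s⁻¹ — about
two standard deviations low, typical scatter for 200 episodes, where
the estimator's relative RMSE is ≈ 8%. The average transient lifetime
is its inverse, ⟨T⟩ ≈ 4.8 s. The same estimator applied to simulated
episode ensembles gives the per-size ⟨T⟩ values that enter the
size-scaling fit:

```bash
$ spiralchaos synth --kind scaling-samples --a-tilde 1e-5 --gamma 1.1 \
      --noise-sd 0.0 --seed 1 --out scaling.csv
wrote scaling.csv
$ spiralchaos scaling-fit --data scaling.csv --out scaling.json
a_tilde = 1e-05 /mm^2, gamma = 1.100
```

On noise-free data the supertransient parameters (ã, γ) are recovered
exactly; `scaling.json` also carries their standard deviations.

In Python, a complete miniature episode — plant a BOCF spiral pair on a
100 × 100 mm sheet, run it to self-termination, and count tips along
the way:

```python
from spiralchaos import Grid, NumericsConfig, run_episode
from spiralchaos.initial_conditions import planted_spiral_pair_state
from spiralchaos.models import load_bocf_params
from spiralchaos.phase import SpiralCounter

params = load_bocf_params()            # BOCF, "TNNP" parameter set
cfg = NumericsConfig.bocf_defaults()   # h = 1 mm, dt = 1e-4 s
grid = Grid.square(100.0, cfg.h)

state = planted_spiral_pair_state(grid, params, cfg)
counter = SpiralCounter()
record = run_episode(state, params, cfg, t_max=10.0, observers=[counter])
t, n = counter.series()
print(record.status, record.lifetime, n.max())
# terminated 0.42 14
```

The pair of counter-rotating spirals survives 0.42 s before
annihilating at the boundary — domains this small sit below one
excitation wavelength (~160 mm), so transients are short; lifetimes
grow steeply with domain size. `spiralchaos run-experiment --config
exp.yaml` drives whole multi-size ensembles with per-episode manifests
and resumability.

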