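# Methods

`spiralchaos` simulates transient spiral-wave chaos in two human cardiac
ionic models on 2-D tissue and quantifies how the chaotic episodes
terminate: ensemble survival curves and escape rates, the growth of the
average transient lifetime with domain size, and Markov-chain statistics
of the spiral count. This note records the models, the numerics, the
statistical estimators, and the design decisions that were genuinely
open, together with what the synthetic-data generators do and do not
emulate.

## Tissue model

Electrical propagation follows the monodomain reaction-diffusion
equation

    dV_m/dt = div(D grad V_m) - (I_ion + I_stim)/C_m

with isotropic diffusion D on a square domain of area A = L_x × L_y and
no-flux (zero normal gradient) boundaries. `I_stim` is used only while
manufacturing initial conditions.

**BOCF** (Bueno-Orovio–Cherry–Fenton) is the four-variable minimal
ventricular model: dimensionless potential
u = (V_m − V_rest)/(V_fi − V_rest) and gates v, w, s, with three
rescaled currents J_fi, J_so, J_si in units of 1/s. The package ships
the published "TNNP" parameter column (tuned to reproduce
ten-Tusscher–Noble–Noble–Panfilov dynamics) in a versioned YAML file,
`src/spiralchaos/models/data/bocf_params.yaml`, with provenance notes;
the loader converts the source's millisecond time constants to seconds.
The slope parameter `tau_winf` = 0.07 is dimensionless despite its name
and is not converted. Tissue defaults: D = 2×10² mm²/s, h = 1 mm,
Δt = 1×10⁻⁴ s. Rescaling constants V_rest = −84 mV, V_fi = 1.7 mV
(85.7 mV span).

**TNNP** is the 2006 revision of the ten-Tusscher–Panfilov human
ventricular model: twelve transmembrane currents, twelve gates, and six
intracellular-ion state variables (Na_i, K_i, Ca_i, Ca_SR, Ca_SS and
the ryanodine-receptor adaptation variable), epicardial parameter set,
transcribed from the authors'/CellML description into
`data/tnnp_params.yaml`. The ionic right-hand side works in the model's
native units (mV, ms, mM, pA/pF); currents are per-capacitance, so
dV/dt = −(I_ion + I_stim) without an explicit C_m, and the tissue-level
capacitance override C_m = 0.2×10⁻² μF/mm² is metadata used only to
convert physical stimulus densities. Tissue defaults:
D = 1.54×10² mm²/s, h = 0.2 mm, Δt = 2×10⁻⁵ s. The named `slope18`
variant applies the published restitution-steepening changes that
enable spiral breakup (G_Kr = 0.172, G_Ks = 0.441, G_pCa = 0.8666,
G_pK = 0.00219 nS/pF, and the voltage-gated inactivation time constant
τ_f doubled for V > 0). Only the changed quantities are named in the
primary description of the spiral-chaos study; the numeric values come
from the model publication's restitution table and should be treated as
a faithful transcription, not as independently validated against that
study.

Heaviside factors use the right-continuous convention H(0) = 1; any
consistent choice affects only measure-zero states, and right
continuity is what the tests assert.

## Numerics

* **Laplacian**: the isotropic nine-point stencil,
  (1/6h²)[[1,4,1],[4,−20,4],[1,4,1]], exact for quadratics.
* **Boundaries**: ghost cells mirror the boundary value across the
  domain *face* (half a grid cell outside the outermost nodes). This
  cell-centred mirror makes the discrete integral of the Laplacian
  vanish identically, so diffusion conserves total mass to rounding —
  the node-centred alternative (ghost = second row) does not, and the
  conservation test at 10⁻¹⁰ relative drift would expose it. Corners
  mirror both axes automatically through the padding.
* **Time stepping**: first-order explicit Euler for the potential and
  the concentration-like variables; first-order Rush-Larsen for every
  gate, i.e. the exact exponential solution of the locally linear gate
  ODE with rates frozen at the start-of-step potential. The exponential
  update interpolates between the current value and y_inf, so gates can
  never leave [0, 1] regardless of step size.
* **Stability guard**: steps with dt > 0.25 h²/D are refused outright.
  A numerical blow-up (NaN/overflow mid-episode) aborts with a status
  distinct from physiological self-termination, so explicit-Euler
  failures can never masquerade as terminated transients.
* **Precision**: float64 throughout.
* Pure vectorised numpy: at the domain sizes used here (≤ 260²) the
  stepping rate (~10⁶ grid-point updates per second per field) keeps
  every budgeted check in minutes, so no compiled kernel is used.

## Initial conditions

Independent multi-spiral states are manufactured from rest by a seeded
stimulation protocol: an S1 plane excitation along the left edge
followed by 3–5 point stimuli (discs of 15 mm) whose onsets target the
S1 repolarization front — each point x fires near
t = x/CV + APD + jitter with CV ≈ 535 mm/s and APD ≈ 0.30 s (both
exposed as knobs). A stimulus disc straddling the moving recovery
front excites a crescent wave with free ends that curl into rotors.
Near-simultaneous onsets are thinned to a minimum spacing of 80 ms:
simultaneous stimuli merge into one synchronised wave that annihilates
freshly created rotors. After a settling interval the state is accepted
if it holds at least `min_spirals` phase singularities (default 4),
otherwise the protocol is resampled with a deterministic sub-seed
(SeedSequence of (seed, attempt)) up to a retry cap.

This scheme is standard cross-field induction practice; it is NOT a
reconstruction of any specific published protocol, and every knob is
config-exposed. A practical limit follows from the BOCF wavelength
(CV × APD ≈ 160 mm): on domains much below ~200 mm the chaotic
transients are shorter than any reasonable settling interval, so
protocol-based acceptance needs L ≳ 200 mm. For cheap seeded ensembles
on smaller domains the package provides `randomized_spiral_state`, a
randomized cut-a-wave construction (plane wave truncated to a band with
two free ends, cut position/band drawn from the seed, optional extra
point stimuli), which produces statistically distinct spiral
configurations in a fraction of a second of simulated time.

## Phase singularities

The spiral count N_spiral is the number of phase singularities. Phase
is a two-dimensional projection of the local dynamics:
θ = atan2(obs₂ − o₂, obs₁ − o₁), with BOCF default (u, v) about
(0.3, 0.5) and TNNP default (V_m, V_m delayed by 10 ms) about
(−40, −40) mV — a state-variable pair needs no history for BOCF, while
delay embedding is the robust generic choice for TNNP. Both are
config-exposed; the observer keeps the ring buffer for the delayed
copy and reports 0 until it fills.

Singularities are detected by closed line integrals of grad θ around
elementary 2×2 plaquettes, each difference wrapped into (−π, π]; a
plaquette whose winding sum exceeds half a turn carries charge ±1.
Adjacent flagged plaquettes of equal charge are merged by
8-connectivity to the centroid. Boundary plaquettes are evaluated (no
margin) by default; an exclusion margin exists as an option. On
synthetic fields with planted singularities separated by ≥ 3 cells the
detector is exact (no misses, no spurious tips, positions within one
cell) over randomized placements — this is an acceptance check.

## Termination and lifetimes

Self-termination is the return to the global resting state: the
maximum potential stays below the excitation threshold (u < θ_v for
BOCF, V_m < −70 mV for TNNP) continuously for a 0.2 s confirmation
window. The recorded lifetime is the time of the *last downward
threshold crossing*, not the end of the window, so the window length
never inflates lifetimes. Episodes that reach t_max with activity are
censored; censoring is always explicit because t_max is mandatory.

**Escape rate.** The number of still-chaotic episodes decays as
N_Ch(t) ≈ N₀ exp(−κt); κ⁻¹ ≈ ⟨T⟩. The estimator fits N₀ exp(−κt) to
the empirical survival curve by nonlinear least squares, keeping only
points with N_Ch(t) above a threshold fraction (default 10% of the
ensemble, i.e. threshold 20 at N = 200) so the poorly-sampled tail is
ignored; the initial guess comes from the log-linear slope. Survival
points share episodes and are strongly correlated, so the raw
least-squares covariance understates the uncertainty by an order of
magnitude; the reported κ standard deviation is instead a seeded
nonparametric bootstrap over episodes (default 100 resamples). On 500
synthetic ensembles of 200 exponential lifetimes this gives ≈ 0.3%
bias, ≈ 8% relative RMSE and 95% two-sigma coverage. Censored episodes
contribute to the curve up to their censoring time; grid points at or
beyond the earliest censoring time are excluded from the fit.

**Size scaling.** Type-II supertransients obey
⟨T⟩ ~ exp[(ãA)^γ]. Taking logarithms twice gives
ln ln⟨T⟩ = γ ln A + γ ln ã, fitted by ordinary least squares; the slope
is γ, and ã = exp(intercept/γ) with its standard deviation from the
regression covariance by the delta method. Lifetimes enter in seconds,
so the fit requires ⟨T⟩ > 1 s for every size — the unit is absorbed
into ã's calibration and the choice is fixed here. Rescaling all areas
by c multiplies ã by 1/c and leaves γ unchanged (asserted numerically).

## Markov spiral-count statistics

All series are uniformly sampled (observer default 10 ms, roughly 30
samples per rotation). Per starting state N the estimator tabulates
the conditional frequencies of ΔN ∈ {−2, −1, 0, +1, +2}; jumps outside
that set are *reported separately*, never folded in, because the ±2
bound holds only for sufficiently fine sampling. State 0 is absorbing
and emits no transitions. Further statistics: occupancy distributions,
time averages ⟨N_spiral⟩_t over a configurable observation window
(default 80 s of usable samples, excluding 1 s of post-IC settling),
termination-aligned ensemble averages (series shifted so termination
is t = 0; each offset averages the episodes long enough to reach it),
and dwell times in the single-spiral state split by whether the dwell
ends in termination or breakup.

## Synthetic generators

Every analysis stage has a generator with planted ground truth, all
pure functions of (parameters, seed) via numpy's PCG64:

* phase fields θ = wrap(Σ q_k atan2(y−y_k, x−x_k)) with known tip
  positions and charges (on-node positions jittered by h/2);
* i.i.d. exponential lifetime ensembles with known κ and optional
  censoring;
* integer spiral-count chains with per-state jump tables, absorbing 0
  and a reflecting ceiling; the `bocf_like` preset makes the
  single-spiral state sticky (exit probability 0.02 per step), the
  `tnnp_like` preset makes breakup frequent (0.3 per step). These
  encode the qualitative rare-vs-frequent-breakup contrast as stylized,
  documented fixtures — they are not fitted to any simulation;
* (A, ⟨T⟩) samples following exp[(ãA)^γ] with log-normal noise.

What they do not emulate: spatiotemporal voltage fields, meander of
real tips, detection noise, correlated lifetimes, or breakup-rate
dependence on N. Tests passing against these oracles validate the
*estimators*; they say nothing about the ionic models, which are
exercised by the simulation tests instead.

## Scaled-down study conditions

The full study design (ensembles of 200 initial conditions per size on
domains up to ~5×10⁵ mm², lifetimes of minutes) is cluster-scale. The
package's own end-to-end checks use conditions a workstation handles,
chosen once: ensembles of 8 seeded cut-a-wave episodes on BOCF squares
of L = 50, 75, 100 mm (areas 2.5–10×10³ mm²) with t_max = 8 s, which
give strictly increasing mean lifetimes (≈ 0.2, 0.26, 0.42 s for one
seed set) — the qualitative size dependence — while exponential survival shape and
estimator calibration are verified on synthetic ensembles at the full
N = 200. At these sizes the medium is below one wavelength, so episodes
are dominated by rotor drift to the boundary rather than sustained
chaos; the first genuinely chaotic, breakup-rich episodes appear around
L ≈ 125 mm. Conclusions about the supertransient scaling *exponents*
therefore require larger domains than the bundled checks use.

## Known limitations

* The TNNP equation set is a transcription; beyond resting-state,
  bookkeeping and action-potential shape checks it has no independent
  desk-scale oracle here. 2-D TNNP runs are supported but expensive
  (h = 0.2 mm) and not part of the bundled checks.
* The induction protocol's success probability drops sharply below
  L ≈ 200 mm (wavelength physics, not a bug); use the cut-a-wave
  generator for small-domain ensembles.
* Tip *trajectories* (linking detections across time) are out of scope;
  only counts and positions per snapshot are produced.
* The escape-rate fit assumes a single-exponential survival curve; it
  is not a general survival-analysis tool.
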