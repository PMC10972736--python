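# Methods

This note records the models, numerical choices and design decisions behind
`inhibnet`, and what the synthetic fixtures do and do not establish.

## Neuron models

**Quadratic resonator (Izhikevich form).**  `dV/dt = 0.04V² + 5V + 140 − u + I`,
`du/dt = a(bV − u)`, reset `V ← c, u ← u + d` at `V ≥ V_peak`.  Defaults
a = 0.1 ms⁻¹, b = 0.26, c = −65 mV, d = 0, C_m = 1 (so currents, quoted
per cm², add directly to dV/dt in mV/ms).  With b > a the rest state is a
focus that loses stability through a subcritical Andronov–Hopf (AH)
bifurcation; the closed form is I_AH = −(0.04V*² + 5V* + 140 − bV*) with
V* = (a − 5)/0.08, giving 0.2625 for the defaults.  The spike cutoff V_peak
is not part of the published parameter set; we adopt the conventional
+30 mV and expose it.  The coefficients are treated as the standard
dimensionless-style Izhikevich constants; the nominal units sometimes
attached to b and d are not dimensionally consistent with the equations and
are ignored.

**Saddle-node of periodics (SNP) and minimum rate.**  The SNP is found by
bisection (tolerance 1e-4) on the persistence of repetitive firing — at
least 20 spikes in a 2 s window after a 0.5 s transient — starting from the
post-reset state (c, b·c), which lies in the basin of the stable spiking
orbit all the way down to the SNP.  With the equations and reset above, the
bisection (and an adaptive-step event-detecting integrator used as an
independent oracle in the tests) places the SNP at I ≈ 0.1556 with a
minimum sustained rate of ≈ 20–21 Hz.  Published analyses of this model
quote a higher SNP current (≈ 0.18) and minimum rate (≈ 27 Hz); those
values are not reproducible from the printed equations under any reset
convention we tested (V_peak from −40 to +40 mV, varied reset potential,
post-spike increments, refractory clamps, step sizes 0.2–0.0005 ms), so the
package reports what the stated model actually does.  The AH value, which
is analytic, agrees exactly.

**PV+ fast-spiking conductance model.**  Single compartment, C_m = 81.4 pF,
I_Na = g_Na m³h(E_Na − V), I_Kv7 = g_Kv7 a⁴(E_K − V), I_Kv3 = g_Kv3 n⁴(E_K − V),
leak g_L(E_L − V); g_Na = 18929 nS, g_Kv7 = 58.5 nS, g_Kv3 = 784.5 nS,
g_L = 13.8 nS, E_Na = 50, E_K = −90, E_L = −77.8 mV.  Gating rates follow
α(V) = k₁(θ − V)/(exp((θ − V)/σ₁) − 1) (evaluated by its limit k₁σ₁ at the
removable singularity) and β(V) = k₂ exp(V/σ₂).  Activation gates (m, n, a)
integrate dx/dt = α(1 − x) − βx.  For the inactivation gate h the k₁-form
rate is negative at every voltage (σ₁ = −20 < 0); its magnitude decays with
depolarization and is the only candidate for the de-inactivation rate, while
the k₂-form rate grows with depolarization and closes the gate:
dh/dt = |α|(1 − h) − βh.  Under any other role assignment h pins at a
boundary and the model cannot fire repetitively; under this one the model
rests at −77.8 mV with h ≈ 1 and fires abruptly from ≈ 0.33 nA at a ≈ 34 Hz
minimum rate (Type 2), reaching ≈ 87 Hz at 0.5 nA — fast-spiking behaviour
consistent with the 0.5 nA operating bias used in the network studies.
Via-model currents are quoted in nA at the interface and converted to pA
internally (conductances in nS × mV give pA).  Spikes are upward crossings
of 0 mV.

## Synapses

The biexponential kernel s(t) is zero for t < τ_L and
(e^{−(t−τ_L)/τ_D} − e^{−(t−τ_L)/τ_R})/(τ_D − τ_R) afterwards
(τ_L = 1, τ_R = 1, τ_D = 6 ms).  Charge mode integrates to 1; peak mode is
scaled so the maximum is 1.  In the frequency domain the cascade has gain
|H_S(ω)| = [(1 + ω²τ_R²)(1 + ω²τ_D²)]^{−1/2} and phase
−ωτ_L + arctan(−ωτ_R) + arctan(−ωτ_D), plus −180° for the inhibitory sign
inversion.  The latency term is implemented as a lag (a pure delay can only
lag; the −360° closure requires it).

**Network normalization.**  Network coupling uses the **peak-normalized**
kernel in both synapse modes: J/N is the per-spike PSC peak.  This is the
convention under which the published strong-coupling operating points are
self-consistent — with a charge-normalized kernel the mean recurrent
inhibition at J ≈ 7.94 would be ≈ 8.6× weaker, the 30 Hz operating points
sit at ≈ 41 Hz, and no population oscillation survives.  The analytic
|H_S| above keeps the unit-DC-gain (charge) convention, which is standard
for transfer functions; phase closures are unaffected by normalization, and
a critical coupling expressed against the peak-normalized network scale is
J_net = J_crit,charge / (∫s_peak dt) with ∫s_peak dt ≈ 8.586 ms.

**Sign conventions.**  The recurrent current-based input is
−(J/N)Σs(t − t_jk) (inhibition is hyperpolarizing; J quoted positive), and
the conductance-based driving force is (E_syn − V), matching the intrinsic
currents.

## Network simulation

Explicit Euler (Euler–Maruyama with noise) at dt = 0.01 ms by default
(0.02 ms for the transfer measurements and heterogeneous runs); a
convergence check on spike times is part of the test suite.  Noise is an
independent Gaussian increment per neuron per step of sd σ√dt/C_m, i.e. σ
carries units current·√ms in the strict SDE sense although it is quoted in
current units; all quoted σ values are used verbatim.  The shared synaptic
filter is advanced once per step (O(N) total); spike counts enter it
through a ring buffer after the latency, which is exactly equivalent to
convolving the step-binned spike train with the sampled kernel (machine-
precision test).  Non-finite states abort with a diagnostic.

Initial conditions: membrane potentials uniform over rest-to-threshold
bands (Izhikevich −70..−45 mV with u = bV, Via −80..−55 mV with gating at
steady state), so that bistable rebound regimes ignite from the initial
spread; the first second is discarded.  In the homogeneous conductance
network with a uniform reversal distribution, E_syn is drawn per
postsynaptic neuron (the mean over its afferents) to preserve the shared-
filter fast path — an O(1/√N) approximation; the heterogeneous sparse
network draws E_syn per synapse exactly, carrying two filter banks per
neuron (conductance and conductance×E_syn) so that the synaptic current is
B_i − G_i·V_i for arbitrary reversal mixtures.

**Heterogeneous slice network.**  321 neurons placed uniformly in an
800×300×800 µm box; each ordered pair within 150 µm connects with
probability 0.36; conductances are lognormal with mean J_scale·1.65 nS and
sd 1.56 nS (moments mapped to log-space parameters); delays grow linearly
with distance from 0.4 to 1.2 ms.  The published heterogeneous cell
population is not reprinted anywhere accessible, so `sample_via_population`
emulates it: 50 unique parameter sets with lognormal 20% CV on conductances,
10% CV on capacitance, and 2 mV sd on the leak reversal, cloned across the
population.  This sampler is synthetic; conclusions drawn from the
heterogeneous network here are ordering-level (which reversal mode
synchronizes best), not quantitative matches to any specific cell ensemble.

## Mean-field procedure

The bias current holding a prescribed mean rate (tolerance 0.5 Hz) is found
by bisection, with rates averaged over 3 s (after a 1 s transient) across
independent realizations.  The transfer function is measured with a
sinusoidal drive of amplitude 0.1·I_ext; per frequency the measurement
window is trimmed to a whole number of drive periods, the trial-averaged
rate (1 ms bins) is Fourier-analyzed at the drive frequency, and gain and
phase are read from the ratio to the sampled input's coefficient.  Default
budgets (≈ 150–400 realizations × 2–2.5 s per frequency, 1 Hz grid) are
scaled one to two orders of magnitude below a cluster-scale protocol.
Phases are unwrapped and anchored to the quasi-static (≈ 0°) low-frequency
branch; crossings of −360k° are located by linear interpolation (k = 1
global synchrony, k = 2 two-cluster).  At low noise the crossing is steep
(the phase drops through the closure level within ~1 Hz of the firing
rate), so modest budgets pin it tightly; at high noise the crossing is
shallow (~1.7°/Hz) and the location inherits the phase noise, hence the
larger default budget there.  The high-noise closure at a 30 Hz operating
rate converges near 52 Hz in this implementation — consistent with the
~50–53 Hz population rhythm the package's own N = 3000 network produces at
matched noise, though a few Hz above some published transfer-function
estimates for the same operating point.

## Metrics

χ is the square root of Var_t[mean_i V_i]/mean_i Var_t[V_i], clipped to
[0, 1] (the raw ratio is exposed via `sqrt=False`); the square root is
required for the χ∞ + δχ/√N finite-size law to hold on shared-plus-
independent ensembles, which the surrogate fixtures verify analytically.
χ is computed on raw simulated voltages including spike excursions; the
reset transients inflate individual variances for sparse firing, which
lowers χ slightly — a sensitivity, not a bias, since all regimes are
treated identically.  The critical-noise law χ∞ = A√(σ_C − σ) (0 above σ_C)
is fitted by profiling A out analytically and minimizing over σ_C
(curve_fit stalls on the kink at the plateau boundary).

**Participation.**  The population rate is binned at 1 ms and smoothed with
a unit-area truncated Gaussian; cycles are delimited by downward zero
crossings of the first derivative (peaks) with a minimum-prominence guard;
SPC is the spike count between first and last peak divided by the number of
complete cycles and N.  The smoothing width adapts to the measured dominant
population frequency (sd = period/6, clipped to [1.5, 10] ms, prominence 2%)
because a fixed 10 ms sd attenuates a rhythm at frequency f by
exp(−(2πf·sd)²/2) — over two orders of magnitude in the upper gamma band —
burying fast sparse-synchrony cycles below the finite-size noise floor.
Rhythm detection uses an extreme-value bound on the rate spectrum so that
rhythm-free rasters fall back to the fixed 10 ms / 5% settings, where
detected peaks are noise excursions and SPC degenerates to rate per
detected cycle.  The adaptive pipeline is validated against synthetic
rasters with known cycle structure (20–83 Hz, participation 0.2–1.0,
error < 0.01).  `smoothed_population_rate` itself keeps the fixed
1/10/100 ms defaults.

Vector length maps each spike to phase 2π(t − peak_k)/(peak_{k+1} − peak_k)
and takes the modulus of the mean unit vector.  Regime labels: SPC < 0.6 →
SPO; 0.6–0.9 → TO (transitional, cycle skipping); > 0.9 → CO, refined to
PIR when the instantaneous mean current (bias + recurrent) stays below the
single-neuron AH current throughout.  ISI descriptors (pooled histogram at
10 ms bins, per-neuron CV, subharmonic-mode flags) are reported
descriptively, not as formal hypothesis tests.

## Synthetic fixtures

`gen_sync_raster` (periodic volleys, per-cycle participation p, Gaussian
jitter folded into the cycle), `gen_poisson_raster` (refractory-modified
Poisson trains) and `gen_voltage_surrogates` (shared sinusoid-plus-noise
signal plus independent noise, with analytic χ(N)) carry exact ground truth
for every metric and fit.  They emulate the *statistical* structure the
metrics respond to — cycle participation, phase concentration, shared
variance — not network dynamics: passing these fixtures shows the metrics
are correct, not that the simulator is; the simulator is checked separately
(convergence, filter equivalence, regime reproduction).

## Scale choices

Desk-scale defaults throughout: network runs use N = 3000 and 3 s (1 s
discarded) for the regime points, N ≤ 1400 for χ-scaling sweeps, 10
replicate networks for the heterogeneous comparison, and reduced
realization budgets for transfer measurements (flags restore larger
budgets).  These sizes were chosen so every reported number is reproducible
on a single CPU while keeping estimator noise comfortably inside the
comparison tolerances used in the tests.

## Known limitations

* Electrical synapses, synaptic depression/facilitation, GABA_B kinetics
  and excitatory populations are out of scope.
* The SNP current and minimum sustained rate of the resonator differ from
  some published figures for this model (see above); the AH current and all
  network-level results are unaffected.
* The heterogeneous cell sampler is an emulation (above), so heterogeneous-
  network results are qualitative.
* The uniform-reversal homogeneous network approximates per-synapse draws
  by per-neuron means (exact in the sparse heterogeneous network).
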