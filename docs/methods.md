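# Methods

This note documents the models, the numerical choices, and the design
decisions behind `spikemf`, in the spirit of a methods section: what is
computed, under which assumptions, and what the tests do and do not show.

## Network and synapse model

A directed Erdős–Rényi graph of N neurons (default 10⁴; desk-scale runs
use N = 2500), 80% excitatory regular-spiking (RS) and 20% inhibitory
fast-spiking (FS) cells, each ordered pair connected independently with
probability P (0.05 at N = 10⁴).  Synapses are conductance-based with
instantaneous rise and exponential decay,

    G_syn(t) = Q Σ_n Θ(t − t_n) exp(−(t − t_n)/τ),   τ = 5 ms,

and the synaptic current I_syn = G_e (E_e − v) + G_i (E_i − v).  Quantal
conductances are Q_e = 1.5 nS, Q_i = 5 nS (AdEx and HH networks) and
Q_e = 4 nS, Q_i = 10 nS (ML).  The synaptic reversals are not part of
the quoted parameter sets; we use the standard cortical values E_e = 0
mV, E_i = −80 mV (configurable).

Every neuron additionally receives an external excitatory Poisson
stream.  A single 4 Hz train through one synapse would be negligible, so
the drive is interpreted as K_e_ext = 400 independent external synapses,
each at ν_drive = 4 Hz — the same convention under which the mean field
adds ν_drive to the excitatory argument of the transfer functions, and
the only one under which network and mean field close quantitatively.
Stimuli enter as a time-varying increment of this external rate,
targeting both populations.

Synaptic transmission is delayless on the integration grid: a spike at
step k increments its targets' conductances at step k + 1.

### Scaled networks

Desk-scale runs shrink N to 2500 while adjusting P to preserve the
in-degrees K_e = 400, K_i = 100.  Because the mean field sees the network
only through per-neuron input statistics, this preserves the operating
point; only finite-size fluctuations grow (∝ 1/N).

## Single-neuron models

All models live in one absolute unit system (pF, nS, mV, ms, pA).

**AdEx** (RS and FS): c_m = 150 pF, g_L = 10 nS, E_L = −65 mV, sharpness
Δ = 2 mV (RS) / 0.5 mV (FS), threshold parameter v_t = −50 mV, reset
v_rest = −65 mV, refractory 5 ms; adaptation dw/dt = (a(v−E_L) − w)/τ_w
with spike increment b, a = 4 nS, b = 60 pA, τ_w = 500 ms for RS and no
adaptation for FS.  The spike condition integrates the exponential
upswing until v > v_t + 5Δ before resetting.  Resetting already at v_t
(a literal reading of the spike rule) is *not* equivalent: near v_t the
exponential current (g_L Δ ≈ 20 pA) is far below the synaptic
fluctuation scale, so most v_t crossings recover without spiking; the
literal rule counts them all, inflates RS excitability ~2–3×, and
destroys the low-rate fixed point — the network then saturates at the
refractory bound instead of the asynchronous-irregular state it is known
to occupy.  The 5Δ cutoff is the standard AdEx convention.

**Hodgkin–Huxley** (Traub–Miles kinetics with a slow non-inactivating K⁺
current I_M for adaptation): the quoted per-area densities map onto the
common cortical single-compartment benchmark when read as absolute
values — c_m = 200 pF, g_L = 10 nS, g_Na = 20 µS, g_K = 6 µS (i.e. the
active conductances take a ×1000 scale relative to the printed density
figures, exposed as `HH_ACTIVE_SCALE`), g_M = 30 nS (RS) / 0 (FS),
E_L = −65 mV, E_Na = 50 mV, E_K = −90 mV, kinetics offset V_T = −53.5
mV, τ_max = 400 ms.  This gives a resting τ_m = 20 ms and confines
depolarization block to very high rates (the measured peak before block
is ≈560 Hz), both required of any sensible absolute reading.  Spikes are
upward crossings of +10 mV.  The three removable singularities of the
gating rates are evaluated by their analytic limits (`expm1` forms
elsewhere).

**Morris–Lecar** (type II): dv/dt carries leak, calcium with
instantaneous activation M_ss(v), potassium with gating variable N, a
constant bias I0 and the synaptic current; dN/dt = (N_ss − N)/τ_N with
τ_N = 1/(2φ cosh((v−V3)/(2V4))) (implemented multiplicatively so extreme
voltages cannot underflow τ_N).  V1 = −1.2, V2 = 18, V3 = 2, V4 = 30 mV
and the reversals E_Ca = 120, E_K = −84 mV, E_L = −50 (RS) / −70 (FS)
are as quoted.  No standard absolute calibration exists for this cell,
so the remaining parameters were calibrated once and frozen:
conductances read directly in nS (g_L = 20, g_Ca = 80, g_K = 160),
c_m = 150 pF, φ = 0.05 ms⁻¹, I0 = 1300 pA.  The calibration criteria
were (a) type II excitability — the DC response jumps discontinuously
from silence to ≈15 Hz; (b) a bell-shaped transfer function under
Poisson bombardment (Q_e = 4, Q_i = 10 nS, ν_i = 8 Hz) peaking near
ν_e = 8 Hz; a 60-seed reference measurement places the peak at
ν_e = 8.0 Hz.  These criteria fix the defaults; they were not revisited
afterwards.

### Integration

Fixed-step explicit Euler: dt = 0.1 ms for AdEx and ML, dt = 0.01 ms for
HH (fast Na⁺ gating).  In the stochastic-input setting trajectories are
non-smooth and high-order schemes buy nothing.  Euler is conditionally
stable in the total conductance (g·dt/c_m < 2); the simulators detect
the resulting divergence (|v| > 500 mV or non-finite state) and raise an
integration error naming time and neuron, and the transfer-function
scout treats that boundary as the end of the measurable range.

Poisson input uses the exact per-step law: the number of events from K
independent synapses at rate ν in one step is Binomial(K, ν dt).  All
simulations are bit-reproducible given their integer seed.

## Transfer-function machinery

Conductance moments (shot noise), voltage moments, and the erfc rate
formula are implemented exactly as stated in the README.  Two
conventions deserve note:

* the moment calculus keeps only the leak and synaptic currents — spike
  currents and adaptation are deliberately excluded and absorbed by the
  fitted threshold polynomial;
* the polynomial coordinates are normalized as (x − x₀)/δx₀ with
  μ_V0 = −60 mV, δμ_V0 = 10 mV, σ_V0 = 4 mV, δσ_V0 = 6 mV,
  (τ_V^N)₀ = 0.5, δ(τ_V^N)₀ = 1 — the standard constants for this
  expansion.  The normalization is a pure reparameterization (tested),
  so fitted coefficients are only comparable across identical
  conventions; the packaged reference coefficient tables
  (`spikemf/data/*_reference_thresholds.tsv`) are shipped for
  orientation, not as ground truth for fresh fits.
* at zero input σ_V = 0 and τ_V is taken at its limiting value
  τ_m + τ; the rate formula returns 0 below threshold.

**Fit protocol.**  The measurement grid takes ν_i ∈ {0.5, 2, 4, 6, 8,
12, 16, 20} Hz by default and, per row, 12 excitatory rates spanning
outputs 0–30 Hz (located by geometric scan plus bisection; for
bell-shaped cells the scan instead covers the full bell).  Each point is
simulated 10 s × 4 seeds.  Stage 1 inverts the measured rates in the
attainable range (0 < F < 0.98 α/τ_V) to empirical thresholds via the
exact erfc inverse and solves the ten-term polynomial by ordinary least
squares; stage 2 refines the coefficients with Levenberg–Marquardt on
the rate residuals of *all* samples (zero-rate samples included).
Degenerate designs (fewer than 10 invertible samples, or a
rank-deficient term matrix) raise a fit error advising a broader grid.
α = 1 throughout the asynchronous-irregular regime; α = 2 is available
for wide-range fits that include near-block rates, where the erfc
formula's amplitude saturates.  Typical rms errors on the fitted domain:
0.15–0.8 Hz.

## Mean field

State (ν_e, ν_i, c_ee, c_ei, c_ii), rates in Hz, T = 20 ms.  The 1/T in
the finite-size source is converted to Hz (1000/T).  Transfer-function
derivatives are central finite differences with step 0.05 Hz (one-sided
at the ν = 0 boundary; unequal-spacing 3-point formulas, exact for
quadratics; mixed partials symmetric by construction).  Integration is
fixed-step RK4, dt = 0.1 ms by default (well below T/20); rates are
clamped at zero from below and clamping events are counted.

Stationary states are found by relaxation from ν = (1, 1) Hz until the
state-derivative norm falls below 10⁻⁸ Hz/ms, with divergence flagged
beyond 200 Hz (outside the theory's validity anyway).  For the
second-order system the rate equations are settled *first* with
covariances frozen at zero, then the full system is relaxed: starting
the covariance dynamics far from the fixed point lets the drift term
(F−ν)(F−ν) source explosively large covariances (observed numerically —
the transient (F−ν) ~ 10–100 Hz enters squared).

The covariance equation is implemented with the Kronecker prefactor
δ_λη on the finite-size term exactly as the master-equation form states,
which yields the closed-form stationary covariance c = F(1/T − F)/(2N)
for input-independent F (tested against this closed form).

## Validation experiments and what they show

* **Transfer functions** (per model, RS and FS): fitted curves track the
  simulated rates to ≲1 Hz rms below 30 Hz; FS gain exceeds RS gain by
  a factor 4–5 (AdEx); the ML fit reproduces the rise-then-fall bell.
* **Spontaneous activity**: the scaled AdEx network settles into an
  asynchronous-irregular state (single-neuron ISI CV ≈ 1,
  population-rate autocorrelation time < 100 ms), exc ≈ 2.2 Hz,
  inh ≈ 14.3 Hz; the mean field predicts (3.0, 16.5) Hz, first and
  second order within 5% of each other.
* **Stimulus response**: a double-Gaussian rate envelope (A = 2 Hz,
  t₀ = 2 s, T₁ = 100 ms, T₂ = 150 ms) produces a positive transient in
  the AdEx network and mean field alike; in the ML network the same
  excitatory stimulus *suppresses* both populations (depolarization
  block), and the mean field reproduces the sign and time course.

The synthetic inputs are stationary (or slowly modulated) Poisson
processes; passing tests therefore certify the pipeline under exactly
those statistics.  Real cortical input carries correlations, synaptic
depression and dendritic filtering that none of this machinery models.

## Known limitations

* The second-order covariance *under*-predicts the network's windowed
  population-rate variance by a factor ~2–2.5 at N = 2500: the printed
  finite-size source is half the empirical counting variance of a
  Poisson population, and slow network fluctuations (adaptation, E–I
  loop) lie outside the Markovian description.  The covariance test
  asserts order-of-magnitude agreement with the correct direction, not
  equality.
* The erfc formula degrades above ~30–50 Hz output; wide-range fits
  need α > 1 and remain qualitative near depolarization block.
* Euler at dt = 0.1 ms limits ML/AdEx drive to total conductances below
  the stability bound (≈3 µS at c_m = 150 pF); the HH sweep at
  dt = 0.01 ms is safe throughout the measured range.
* Bursting, frequency-dependent (dynamic) transfer functions, synaptic
  delays/plasticity, and spatially structured connectivity are out of
  scope.

## Problem sizes

Library defaults reproduce the full protocol (N = 10⁴ via `--full`,
10 s × 4-seed transfer-function points).  The shipped tests and the
acceptance script run the same pipeline at desk scale — N = 2500 with
preserved in-degrees, 5–10 s measurements, reduced grids — sizes chosen
as the smallest at which every qualitative regime (AI state, gain
separation, depolarization block, anticorrelated ML response) is
unambiguous.  The acceptance script's ML peak location uses 16 seeds per
grid point and reports the vertex of a local quadratic fit to the
measured bell: the bell is nearly flat within ±1 Hz of its maximum, so
the raw grid argmax has a sampling sd of ~0.9 Hz while the vertex
estimator achieves ~0.3 Hz for the same estimand.
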