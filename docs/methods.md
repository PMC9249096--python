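# Methods

## Scope

`achnet` simulates how acetylcholine (ACh) reshapes the collective dynamics
and the synaptic structure of a heterogeneous cortical-like network.  ACh
enters through a single knob: the maximal conductance `g_Ks` of a slow,
low-threshold, non-inactivating M-type potassium current, which muscarinic
ACh receptors suppress in vivo.  `g_Ks = 0 mS/cm²` therefore models a
high-ACh (waking) state and `g_Ks = 1.5 mS/cm²` a low-ACh (slow-wave-sleep)
state.  Everything else — topology, synapses, plasticity, noise — is held
fixed across states.

## Neuron model

Each cell is a single-compartment conductance-based model with four state
variables (V, h, n, z):

    C dV/dt = − g_Na·m∞³(V)·h·(V − E_Na) − g_Kdr·n⁴·(V − E_K)
              − g_Ks·z·(V − E_K) − g_L·(V − E_L)
              + I_drive + I_noise − I_syn

with instantaneous sodium activation m∞ and first-order kinetics for h, n
and z (`dz/dt = (z∞ − z)/75 ms`).  Parameters (mS/cm², mV, ms):
C = 1 µF/cm², g_Na = 24, g_Kdr = 3, g_L = 0.02, E_Na = 55, E_K = −90,
E_L = −60, τ_z = 75.  The gating sigmoids have half-activations at
−30 (m, slope 9.5), −53 (h, 7), −30 (n, 10), −40.5/−27 (τ_h/τ_n midpoints)
and −39 (z, 5) mV.  The m-activation slope matters qualitatively: it sets
the resting-state stability margin, and with the steep leak used here it
places the g_Ks = 0 rheobase slightly *below* zero current (≈ −0.13
µA/cm²), so the drive-selection grid spans negative currents.

The M-current switches the spike-onset bifurcation: at `g_Ks = 0` the cell
is Type I (continuous f-I curve rising from 0 Hz, strictly positive phase
response curve), at `g_Ks = 1.5` Type II (discontinuous f-I onset near
6–7 Hz, flat f-I slope, biphasic PRC).  Both signatures are asserted by the
test suite.

Numerics: classical RK4 at dt = 0.1 ms; external currents (drive, noise,
synaptic) are evaluated at the step start and held constant across the four
substages; gates are clipped to [0, 1] after each step (guards O(dt⁴)
overshoot).  Initial conditions: V ~ Uniform[−70, 0] mV, h = 1, n = z = 0.
Spikes are the upward crossings of 0 mV at grid resolution (no
interpolation).  Halving dt moves early spike times by less than the grid
quantization and changes the firing period by < 10⁻⁴ relative.

**Drive selection.**  `I_drive` is the *highest subthreshold current*: the
largest value on a 0.01 µA/cm² grid over [−1, 3] for which the neuron,
started from rest, fires no spike in the second half of a 2-s noiseless
run (the steady-state criterion ignores the onset transient a current step
can fire from rest).  The grid is scanned from the top so the definition is
exact even where firing is non-monotone in I; results are cached per
`g_Ks`.  Typical values: −0.12 (g_Ks = 0), 0.09 (0.5), 0.46 (1.0),
1.12 (1.5) µA/cm².

**Noise.**  Independent per neuron and step, a 2-ms square pulse of 0.7
µA/cm² is initiated with probability 0.02 per 0.1-ms step (≈200
initiations/s); a new initiation during an active pulse restarts its clock
rather than stacking amplitudes.

**PRC probe.**  The phase response curve uses an excitatory synaptic-kernel
conductance pulse (w = 0.04 mS/cm², E_syn = 0 mV) delivered at equally
spaced phases of the unperturbed period; the baseline drive is the smallest
grid current giving regular firing at ≥ 7.5 Hz.  The mid-band target keeps
the Type II operating point away from the bistable region just above its
rheobase, where a perturbation can terminate the oscillation outright.

## Network construction

250 neurons.  The undirected substrate is grown by the linearized
chord-diagram (LCD) preferential-attachment process, executed 15 times over
the same node set: within a pass, each node in turn attaches to one
earlier node chosen proportionally to accumulated degree (uniformly when
all legal partners still have degree zero); self-loops and duplicate edges
are excluded by sampling the degree-weighted conditional over legal
partners.  When a low-index node has exhausted its predecessors in a later
pass it attaches instead to a degree-weighted draw over all non-adjacent
nodes, so each pass keeps its budget of n − 1 attachments; the result has
exactly 15·249 = 3735 edges (average in-degree 14.94 after orientation)
and a heavy-tailed degree distribution.

Each undirected edge becomes exactly one directed synapse of conductance
w₀ = 0.04 mS/cm²: with probability `p_in` it points *into* its
higher-degree endpoint.  `p_in` ∈ {0.1, 0.3, 0.5, 0.7, 0.9} gives the five
standard configurations from "strong hub outgoing" to "strong hub
incoming".  The hub is the top 10% of excitatory neurons by total degree
(25 cells at n = 250), ties broken toward lower index.

Mixed E-I networks replace a fraction (10–20%) of cells with inhibitory
neurons: the excitatory subpopulation keeps the oriented scale-free
topology, while each inhibitory cell receives K = 15 inputs from distinct
random excitatory cells (at w₀) and sends K = 15 outputs to distinct
random cells of any class at 0.01 mS/cm².  K was matched to the network
average degree since no separate value is specified for the random wiring;
consequently inhibitory cells can receive extra inhibitory inputs on top
of their K excitatory ones.  Hub removal zeroes every synapse into or out
of hub cells while leaving the cells (and their drive and noise) in place.

## Synapses and plasticity

A presynaptic spike at t_k contributes a double-exponential conductance
transient `w_ij·(e^{−(t−t_k)/τ_d} − e^{−(t−t_k)/τ_r})·(V_i − E_syn)` with
τ_d = 0.5 ms, τ_r = 0.2 ms, E_syn = 0 mV (excitatory) or −75 mV
(inhibitory).  The integrator carries two exponentially decaying traces
per presynaptic neuron, which reproduces the event sum exactly (no cutoff
error); the module-level event-sum implementation (cutoff 10·τ_d) is the
reference oracle in the tests.

STDP is fully asymmetric and all-to-all within a hard ±40 ms pairing
window: each (pre, post) spike pair contributes
±A_L·e^{−|Δt|/τ_STDP} (potentiation when the presynaptic spike leads),
with τ_STDP = 10 ms and hard bounds [0, 2w₀].  Simultaneous spikes
contribute nothing; synapses absent at initialization are never created;
only excitatory→excitatory synapses are plastic.  Updates are applied at
spike events inside the integration loop through an exactly recursive
windowed trace; the test suite verifies bit-level agreement with the
whole-train pairing sum when no weight touches a bound (clipping is
path-dependent, so the event-by-event form is definitive).

A_L defaults to 0.002 mS/cm² (5% of w₀ per pairing).  Under this
calibration three seconds of low-ACh activity produce substantial
regional reorganization (hub→non-hub ≈ +25% in the moderate-hub-incoming
configuration, as the acceptance script recomputes); a tenfold smaller
amplitude is accepted by the configuration and yields proportionally
weaker reorganization.

## Measures

All pairwise statistics are computed on the second half of each analysis
segment (transient discard) over ordered pairs with defined values;
neurons with too few spikes are masked, not errors.

* **Mean phase coherence (MPC).**  For each spike of train j, its phase
  within the bracketing interspike interval of train i; σ_ij is the
  resultant length of e^{iφ}.  1 = perfect locking.
* **Cross-correlation (CC).**  Trains binned at dt, convolved with a
  unit-area Gaussian (σ = 1 ms, truncated at ±5σ), mean-subtracted, then
  normalized zero-lag inner product.
* **AMD / AMD-Z / asymmetry.**  AMD_ij is the mean distance from each
  spike of i to the most recent preceding spike of j.  The null moments
  come from the *reference* train j's interval structure: placing i's
  spikes uniformly at random, the preceding distance has mean
  μ₁ = ΣL²/(2T) and SD √(μ₂ − μ₁²) with μ₂ = ΣL³/(3T), T = ΣL (the train
  span).  The preceding-distance (not nearest-event) reading is used
  because μ₁ is exactly the uniform-placement expectation of that
  quantity — the nearest-event version would have mean ΣL²/(4T) — and the
  test suite verifies the calibration to 2% at 10⁵ samples.
  Z_ij = (AMD_ij − μ₁)/σ (no √N factor), asymmetry = Z_ij − Z_ji (exactly
  antisymmetric).  Note that without the √N factor a perfectly periodic
  reference bounds |Z| by √3 ≈ 1.73; the conventional |Z| > 2 significance
  flag is kept as a constant but is attainable only for irregular
  reference trains.
* **Region-resolved Δg_syn.**  For each of the four regions defined by hub
  membership of pre- and postsynaptic cells, Σ(w_after − w_before)
  normalized by (synapse count in region)·w₀.
* **LFP spectrum.**  The summed excitatory voltage is z-scored and
  Fourier-transformed; the dominant frequency is the power argmax in
  1–100 Hz.  Synchronized low-ACh networks oscillate at ≈ 8–10 Hz here
  (upper theta by rodent conventions).

## Protocols

Every protocol runs `n_trials` (default 10) independent repetitions, each
with a freshly grown topology and fresh initial conditions, and reports
trial means with standard errors.  Standard runs last 2 s; reorganization
runs 3 s; hub removal 2 s + 2 s; the wake–sleep–wake experiment 3+3+3 s
(STDP active only in the middle, low-ACh segment; firing rates measured
over the latter 2 s of each wake segment; `I_drive` re-selected per
segment's `g_Ks`).  State variables carry over continuously across
segment switches.

The wake–sleep regression (Δf vs initial f) is reported two ways: OLS per
trial with across-trial averaging of slope/R², and OLS on trial-averaged
per-neuron points (neuron index is comparable across independently grown
topologies because the growth process ties index to expected degree).
The latter is the headline: averaging removes the ≈5 Hz rate-estimation
noise a 2-s window carries, which otherwise bounds per-trial R² near 0.5
regardless of the underlying structure.

## Determinism and performance

A configuration plus seed determines every output bit-for-bit: topology,
initial conditions and noise use seeds derived from the config seed via
`SeedSequence`, and the integrator is a compiled (numba) kernel seeded
explicitly.  Trials are independent given distinct derived seeds.  The
kernels use CSR connectivity with a fixed sparsity pattern (STDP updates
in place through matched CSR/CSC index maps); a 2-s, 250-neuron run takes
a few seconds on one core.

The test suite exercises full-size (n = 250) networks for the headline
protocol checks and 40–80-neuron networks for mechanical properties;
trial counts in the heaviest checks follow the protocol default of 10
where the quantity under test demands it and 3–5 where only a sign or
ordering is asserted.

## Known limitations

* The model is a point-neuron caricature: no morphology, no nicotinic
  effects, no short-term plasticity, no conduction delays, no
  distance-dependent wiring.
* The wake–sleep frequency-renormalization slope measures how completely
  the low-ACh segment equalizes total input weights across neurons.  Its
  magnitude is sensitive to the degree of phase-ordering jitter during
  the synchronized state and to the weight bounds; the strong-hub-incoming
  configuration equalizes least under the default calibration.
* Pairwise-measure masking means sparsely firing cells drop out of
  network averages; at the default conditions every cell fires, so this
  matters only for strongly hyperpolarized variants.
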