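# Methods

This note documents the models, numerical schemes, default parameters and
design choices behind `embsnn`, and states precisely what the desk-scale
tests do and do not establish.

## Kernel

### Time, spikes and delays

Simulation is clock-driven at a fixed resolution h (default 0.1 ms). All
spike times live on the grid; a neuron crossing threshold during the step
ending at time t is stamped t. Synaptic delays are positive integer
multiples of h, bounded below by `min_delay`; a spike stamped t with delay
d is consumed by its target at the start of the step beginning at t + d.
Parrot neurons re-emit every incoming spike (with multiplicity) at exactly
its arrival time, which gives the relay identity `t_out = t_in + delay`
used by the relay tests.

### Integration schemes

*Current-based LIF* (`lif_current`, also the readout integrator with the
threshold disabled): the state (y₁, y₂, V) of the alpha-PSC/membrane
system is linear, so the update is the exact matrix exponential, computed
per neuron in closed form at creation. Constant bias current is folded in
analytically. The propagator is exact to float rounding; the test suite
holds it to 1e-9 mV against the closed-form membrane solution and to
1e-6 mV against a 1000×-oversampled RK4 reference for a PSC event. Spike
weights are peak PSC amplitudes in pA (an incoming spike of weight w adds
w·e/τ_syn to y₁, so the PSC peaks at exactly w after τ_syn).

*Conductance-based LIF* (`lif_conductance`): four alpha-conductance
receptor channels with per-neuron reversal potentials and time constants.
The conductances are advanced by their exact propagator. For the membrane,
the coefficient g_tot(t) and drive b(t) of the linear ODE are known in
closed form within a step, so the update uses the exact integrating
factor

V(h) = e^(−G(h)/C) V(0) + ∫₀ʰ e^(−(G(h)−G(s))/C) b(s)/C ds,

with G(s) the analytic integral of the conductances and the remaining
drive integral evaluated by 2-point Gauss quadrature. The scheme is
verified to ~2e-9 mV against an oversampled reference; its only
approximation error is the quadrature (the rest-state fixed point is held
to ~1e-10 rather than exactly). V never exceeds the excitatory reversal
under saturating drive because V(h) is a convex-ish combination of values
inside the reversal hull. Refractoriness clamps V at V_reset for
round(t_ref/h) steps while synaptic states continue to evolve.

*STDP* (power-law potentiation, multiplicative depression): all-to-all
exponential traces. On a presynaptic spike the synapse is first depressed
with the postsynaptic trace, then delivers; on a postsynaptic spike all
incoming plastic synapses are potentiated with the presynaptic trace.
Trace timing uses spike stamps (no dendritic-delay correction), and
depression is applied once per presynaptic spike regardless of
multiplicity. Defaults follow the benchmark lineage the rule comes from
(μ = 0.4, τ₊ = 15 ms, λ = 0.1, α = 0.05, τ₋ = 30 ms); all are
configurable and none enters acceptance. Depression floors the weight at
1e-12·w₀ so the multiplicative invariant survives floating point.

### Distribution and reproducibility

Neurons are distributed round-robin (`owner = gid mod n_workers`) over
logical workers; each worker stores exactly the synapses of its own
postsynaptic neurons and only instantiates those during construction.
Workers advance in lockstep, exchanging (stamp, gid, multiplicity)
triples once per step, merged in (stamp, gid) order.

Every random draw is a pure function of `(master seed, purpose tag,
global ids, step)` through a splitmix64-style avalanche hash (numpy's
counter-based generators cannot take a distinct key per array element in
one vectorized call, which is the access pattern required here). Normals
come from Box–Muller on two sub-streams, Poisson counts from CDF
inversion (intended for the small per-step means that arise at h=0.1 ms).
Consequences, enforced by test: identical seed ⇒ bitwise identical
spikes across repeated runs *and across any worker count*; connectivity,
placement, bias draws and Poisson drive are keyed to the consuming
neuron, never to iteration order.

Poisson generators deliver an independent realization per (generator,
target) pair, sampled on the target's owner. Rate changes take effect at
the next kernel step.

## Control plane

The in-process master broadcasts each API call to all workers (the master
itself is worker 0) and combines per-worker responses with an explicit
per-endpoint registry: identical scalars collapse, registered additive
fields (locally owned counts) are summed, event lists are merge-sorted by
(t, gid), records recurse field-wise, and any disagreement on a
non-additive field raises a divergence error rather than being masked.
The registry is explicit because the combination heuristics it models are
not published; making it a table keeps the behavior testable. A JSON/HTTP
binding (`POST /api/<Endpoint>`, default port 5000) is implemented on the
standard library and is interchangeable with the in-process binding;
`LoadNetwork` accepts only the declarative network-description schema,
never code.

## Closed-loop engine

Brain and plant advance the same exchange window (default 20 ms) before
any transfer function runs. "Parallel" execution is enforced as an
ordering contract, not a threading mandate: components are timed
individually and a step's wall time is the critical path
max(brain, plant) + transfers. Brain step time is the maximum over
logical workers of their per-step wall time — the time an actually
concurrent deployment of the same shards would take; the same convention
gives the benchmark build time. This is the package's way of making
scaling behavior observable on one machine, and the reason the
"build time non-increasing in worker count" property is meaningful
without real parallel hardware. The first CLE step carries initialization
overhead; it stays in the profile and is excluded only from derived
metrics: RTF = (exchange interval)/(mean wall time of steps 2..N),
step ratio = mean brain time / mean plant time (NaN when the plant time
is zero), node-hours = runtime/3600 × nodes with nodes = 1 + ⌈workers/2⌉
(two simulation workers per node plus one orchestrator node).

## Transfer functions

A spike sink is one current-based integrator with V_th = +∞ receiving a
static synapse from every neuron of its population; activation is
clip((V − E_L)/v_span, 0, 1). Its τ_m (default 10 ms) is the smoothing
window. v_span defaults to the deflection at which the population firing
at a reference rate (default 8 Hz; 40 Hz in the embodied benchmark, where
resting cortical rates are higher) yields activation 0.8 — computed from
the steady-state mean current `count · rate · w · e · τ_syn`. A spike
source is a Poisson generator wired to every neuron of its target.

## Plant

An explicit surrogate of the original rigid-body/Hill-muscle rig: three
moving forelimb segments (humerus, ulna/radius, foot; default masses
10/6/2 g, order-of-magnitude mouse anatomy), four limb DOF (two shoulder,
one elbow, one wrist) with per-DOF decoupled inertias, centering springs
and viscous damping; eight muscles, one antagonist pair per axis, with
constant moment arms (±4 mm), force-length/velocity factors set to one
and exact first-order activation dynamics (τ_act = 10 ms,
τ_deact = 40 ms). The foot's ball joint is reduced to a stiff spring
coupling from a linear combination of limb angles onto the two joystick
DOF (forward/backward, lateral/medial); the joystick carries the
−0.001 Nm bias torque and its own damping. Integration is semi-implicit
Euler at 1 ms with implicit viscous damping (unconditionally stable in
the damping constant). With zero excitation all forces are conservative
(springs, bias potential) or dissipative, so the mechanical energy
reported by `energy()` is non-increasing — the passivity test. Gravity
and contacts are omitted. Boundedness is exercised over 10⁵ steps in the
suite (the dynamics are linear and damped, so longer horizons add nothing
but runtime).

## Benchmark networks

### Balanced network

neurons = round(11250·scale) (banker's rounding), split 4:1 into
excitatory and inhibitory; recurrent indegree fixed at 11,250 per neuron
(9,000 E + 2,250 I) at every scale, so sub-unit scales realize it with
multapses; E→E plastic, everything touching inhibitory neurons static;
one external Poisson device with one connection per neuron. The census
identities `nodes = N + 1` and `connections = 11250·N + N` reproduce the
full-scale figures exactly and are what acceptance checks. Weights
(w = 2 pA, g = 5), delay (1.5 ms) and drive rate (30 kHz aggregate per
neuron) are unpublished for the benchmark and are documented
configuration. At desk scales the heavy multapses make the dynamics
correlation-dominated: the defaults keep the network in a sparse,
fluctuation-driven regime (a few Hz at scale 0.01) rather than the
asynchronous-irregular state of the full model, and no test asserts
firing statistics. Instantiation above a synapse budget (default 6×10⁶)
is refused with the dry-run census in the message.

### CBCT model

The packaged composition table reproduces every published regional total
exactly (M1 58,805; S1 94,396; VL/VM 6,144 each; BG 10,976; 414,720 per
cerebellar module; 1,005,905 in total over 33 layers). The split of each
regional total over layers and types is not published; the packaged rows
are constrained to the published structure (per-layer type lists, E:I =
4:1 outside L1, 1024 TC/IN/RT per thalamic zone, eight granular and four
upper-molecular sheets, granule-dominated cerebellum) and are otherwise
this package's own documented choice, as are all Gaussian kernel
parameters, weights, delays and bias-current moments
(`data/cbct_params.yaml`). Scaled counts use banker's rounding per
population; totals are sums of rounded parts, so scale 1 is exact.
Neurons are placed uniformly on 1×1 mm² sheets from keyed streams; at
reduced scale the sheet keeps its extent and density drops, which thins
Gaussian connectivity accordingly. Builds below scale ≈ 0.005 are
rejected when a population would round to zero.

Inter-regional pathways implement the published ten-pathway list; "to
TH"/"CB DCN to TH" entries fan out to both nuclei/modules consistent
with the VL↔M1, VM↔S1 assignment. Each pathway is topographic: every
postsynaptic neuron connects deterministically to its nearest presynaptic
sheet coordinate (preserving spatial order) plus Gaussian-sampled spread.
Parrot relays are inserted at the cortex→BG, cortex→Pons and TH→cortex
interfaces, mirroring the original model's use of relays to swap
optimization-time Poisson inputs for real afferents; relays and
generators are counted in a separate device census, with no claim of
matching the published node total (whose device breakdown is
unpublished).

The Pons (mossy-fiber) population is conductance-based LIF under private
Poisson drive (the original adjusted Pons rates and weights, implying
model neurons rather than pure relays). The packaged drive rate
(419.92 Hz at 2 nS AMPA) was produced by `calibrate_resting_input` — a
bracketing bisection over the drive rate against a simulated probe — for
the published 8 Hz resting target, and re-verified by acceptance with a
5 s simulation of the scale-0.02 module (measured 8.0–8.2 Hz across
seeds; sampling error ≈ 0.1 Hz). Pons receives no recurrent input at
rest, so the calibration transfers across scales.

### Resting state

Bias currents (normal per neuron, population-specific moments) are set
for sparse low-rate cortical activity, high-rate pallidal firing, sparse
granule and regular Purkinje firing. These are qualitative targets only;
no acceptance value depends on them apart from the mossy-fiber 8 Hz
point.

## Benchmark procedure

A plan sweeps worker counts (strictly increasing, default doubling) ×
repetitions; every cell rebuilds from scratch with the same seed, so
spike output is identical across the grid and only timings vary. Each
cell records critical-path build time, the CLE profile (default 50 steps
of 20 ms), the last brain-step time, RTF, step ratio and node-hours; a
cell failure is recorded and the grid continues. The embodied protocol:
steps 1–5 send the base activation (default 0.2, unpublished) to all 8
muscles; every step pins all source rates to 0 except that the ENGC
source is 5000 Hz from step 25; from step 6 the ENGC sink's clipped
readout drives its three muscles; a status line is logged from step 5 and
the joystick trajectory is returned. In this package the observable
consequence is a step increase of ENGC activation at step 25 followed by
forward joystick motion, and the drive-response monotonicity test
asserts exactly that ordering.

## What the desk-scale tests do and do not show

They establish the combinatorial and structural identities (censuses,
fixed indegree, E:I ratios, pathway presence), the numerical correctness
of the integrators and plasticity rule against independent oracles, the
distribution contract (bitwise worker-count invariance), the metric
formulas, and the protocol's ordering semantics. They do not establish
anything about wall-clock performance at HPC scale, about the biological
fidelity of the unpublished connectivity parameters, or about the
full-scale models' emergent dynamics: reduced-scale networks have
multapse-heavy (balanced network) or thinned (CBCT) connectivity whose
dynamics differ qualitatively from the originals, and only the
mossy-fiber calibration point is asserted quantitatively.

## Problem sizes used by the shipped runs

Dry-run censuses: full scale (exact arithmetic). Instantiated balanced
network: scale 0.02 (225 neurons, 2,531,475 synapses). Cerebellum module:
scale 0.02 (8,293 neurons), 5 s of simulation for the calibration check.
Full CBCT structural build: scale 0.01 (10,054 neurons). Embodied
protocol: M1-only at scale 0.01 (588 neurons), 50 CLE steps. Build-time
scaling: balanced network at scale 0.02 over 1/2/4 workers, medians of 5
repetitions.
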