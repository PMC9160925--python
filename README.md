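# embsnn

A desk-scale, pure-Python re-implementation of a distributed *embodied*
spiking-neural-network simulation stack: a leaky integrate-and-fire network
kernel with logical master–worker distribution, a closed-loop engine that
couples the network to a simplified musculoskeletal plant through transfer
functions, constructors for two benchmark brain models, and a benchmark
harness for real-time-factor and scaling measurements.

It is aimed at computational neuroscientists and simulator engineers who
want to study, test or teach the *orchestration semantics* of large-scale
embodied simulations — worker distribution and reproducibility, brain/body
lockstep exchange, spike-to-muscle transfer functions, benchmark
methodology — on a laptop, without an HPC allocation, MPI, or a robotics
middleware stack.

## The models

**Kernel.** Clock-driven simulation at fixed resolution h = 0.1 ms.
Current-based neurons follow

dV/dt = −(V − E_L)/τ_m + (I_syn(t) + I_e)/C_m,

with alpha-shaped postsynaptic currents, advanced by the *exact*
exponential propagator of the linear (PSC, membrane) system.
Conductance-based neurons follow

C_m dV/dt = −g_L (V − E_L) − Σ_r g_r(t) (V − E_r) + I_bias,

with alpha conductances on four receptor channels (AMPA, NMDA, GABA_A,
GABA_B), advanced by an integrating-factor scheme that uses the closed-form
integral of the alpha conductances (accurate to ~1e-9 mV against an
oversampled reference). Excitatory–excitatory plasticity is the power-law
potentiation / multiplicative depression STDP rule

Δw⁺ = λ w₀^(1−μ) w^μ e^(−Δt/τ₊),  Δw⁻ = −λ α w e^(−Δt/τ₋).

Neurons are assigned to logical workers round-robin by global id, and every
synapse lives with its postsynaptic owner. All randomness (connectivity
sampling, Poisson drive, bias currents, placement) comes from counter-based
streams keyed by `(seed, purpose, global id)`, so spike output is **bitwise
identical for any worker count** — the property the test suite leans on
hardest.

**Benchmark networks.** (1) A scale-parameterized balanced random network:
`round(11250·scale)` neurons, fixed recurrent indegree 11,250 regardless of
scale (multapses allowed), plastic E→E synapses, one external Poisson drive
device; at scale 20 the dry-run census is 225,000 neurons / 225,001 nodes /
2,531,475,000 connections. (2) A multi-region cortico–basal
ganglia–cerebellar–thalamic (CBCT) rodent brain: 1,005,905 neurons at full
scale across M1, S1, two thalamic nuclei, basal ganglia and two cerebellar
modules, placed on 1×1 mm² sheets with distance-dependent Gaussian
connectivity, ten topographic inter-regional pathways with parrot-relay
interfaces, and a Poisson drive on the Pons calibrated so the mossy fibers
rest at 8 Hz.

**Embodiment.** A 3-segment mouse forelimb (8 Hill-type muscles with
first-order activation dynamics, 2 per rotation axis) coupled to a 2-DOF
joystick carrying a −0.001 Nm bias torque. Spike *sinks* read a population
through an integrator neuron with disabled threshold and map its membrane
deflection to muscle activation in [0, 1]; spike *sources* inject
rate-coded Poisson drive. The closed-loop engine advances brain and plant
in 20 ms lockstep windows, runs transfer functions strictly after both, and
profiles every step (the first, initialization-laden step is excluded from
the real-time factor `RTF = step interval / mean wall time`).

## Worked example

```bash
python examples/04_cbct_census_and_resting_state.py
```

```
full-scale census (scale 1):
  M1        58,805
  S1        94,396
  VL         6,144
  VM         6,144
  BG        10,976
  CB_M1    414,720
  CB_S1    414,720
  total  1,005,905 neurons over 33 layers

cerebellar module at scale 0.02: 8,293 neurons; simulating 2 s of rest ...
  CB_M1/mol_upper:stellate     2.81 Hz
  CB_M1/mol_lower:basket       2.44 Hz
  CB_M1/purkinje:PC           90.30 Hz
  CB_M1/granular:granule       0.97 Hz
  CB_M1/granular:golgi         9.93 Hz
  CB_M1/dcn:DCN                5.77 Hz
  CB_M1/pons:MF                8.19 Hz
```

The census is exact arithmetic on the packaged composition table; the
rates come from an actual 2 s simulation of the reduced cerebellar module:
granule cells fire sparsely, Purkinje cells regularly, and the Pons (mossy
fibers) sits at its 8 Hz calibration point. The other examples demonstrate
the exact-propagator oracle and STDP rule (`01`), bitwise worker-count
invariance (`02`), the balanced-network censuses (`03`) and the embodied
50-step joystick protocol with profiler metrics (`05`).

A thin CLI wraps the same library calls:

```bash
embsnn count brunel --scale 20
embsnn count cbct --scale 1
embsnn embodied --scale 0.01
embsnn serve --workers 4 --port 5000   # POST /api/<Endpoint>, JSON
```

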