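"""Parameter records for the kernel: neuron, synapse and kernel configuration.

Conventions follow the common usage in point-neuron simulators: membrane
potentials in mV, currents in pA, capacitances in pF, conductances in nS,
times in ms.  Synaptic kinetics are alpha functions whose ``weight`` is the
peak amplitude (pA for current-based, nS for conductance-based synapses).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
import math

__all__ = [
    "KernelConfig",
    "LIFCurrentParams",
    "LIFConductanceParams",
    "Receptor",
    "StaticSynapse",
    "STDPPowerLawSynapse",
    "stdp_update",
]


@dataclass(frozen=True)
class KernelConfig:
    """Global kernel settings.

    resolution : integration step in ms; all spike times and delays live on
        this grid.
    seed : master seed; every random stream in the simulation is derived
        from it together with a purpose tag and the consuming entity's
        global id, so results do not depend on ``n_workers``.
    n_workers : number of logical workers neurons are distributed over
        (round-robin by global id).
    min_delay : lower bound on synaptic delays in ms.
    """

    resolution: float = 0.1
    seed: int = 1
    n_workers: int = 1
    min_delay: float = 0.1

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        if self.min_delay < self.resolution - 1e-12:
            raise ValueError("min_delay must be at least one resolution step")

    def steps(self, t_ms: float) -> int:
        """Convert a time to an integer number of steps; reject off-grid times."""
        s = t_ms / self.resolution
        r = round(s)
        if abs(s - r) > 1e-9 * max(1.0, abs(s)) + 1e-9:
            raise ValueError(
                f"{t_ms} ms is not a multiple of the resolution {self.resolution} ms"
            )
        return int(r)


@dataclass(frozen=True)
class LIFCurrentParams:
    """Leaky integrate-and-fire neuron with alpha-shaped current synapses."""

    tau_m: float = 10.0      # membrane time constant, ms
    C_m: float = 250.0       # capacitance, pF
    E_L: float = -70.0       # resting potential, mV
    V_th: float = -55.0      # spike threshold, mV (math.inf disables spiking)
    V_reset: float = -70.0   # reset potential, mV
    t_ref: float = 2.0       # absolute refractory period, ms
    tau_syn: float = 2.0     # PSC alpha time constant, ms
    I_e: float = 0.0         # constant bias current, pA

    def __post_init__(self):
        if not self.V_reset < self.V_th:
            raise ValueError("V_reset must be below V_th")
        for name in ("tau_m", "C_m", "tau_syn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")


@dataclass(frozen=True)
class Receptor:
    """One alpha-conductance receptor channel."""

    label: str               # AMPA, NMDA, GABA_A, GABA_B
    E_rev: float             # reversal potential, mV
    tau: float               # alpha conductance time constant, ms

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("receptor time constant must be > 0")


# Default receptor kinetics.  NMDA is a slow alpha conductance (no
# voltage-dependent magnesium block); GABA_B a slow inhibitory one.
DEFAULT_RECEPTORS = (
    Receptor("AMPA", 0.0, 2.0),
    Receptor("NMDA", 0.0, 50.0),
    Receptor("GABA_A", -85.0, 6.0),
    Receptor("GABA_B", -85.0, 80.0),
)


@dataclass(frozen=True)
class LIFConductanceParams:
    """Leaky integrate-and-fire neuron with conductance-based alpha synapses."""

    tau_m: float = 10.0
    C_m: float = 250.0
    E_L: float = -70.0
    V_th: float = -55.0
    V_reset: float = -70.0
    t_ref: float = 2.0
    I_bias: float = 0.0      # constant bias current, pA
    receptors: tuple = DEFAULT_RECEPTORS

    def __post_init__(self):
        if not self.V_reset < self.V_th:
            raise ValueError("V_reset must be below V_th")
        for name in ("tau_m", "C_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        exc = [r.E_rev for r in self.receptors if r.label in ("AMPA", "NMDA")]
        inh = [r.E_rev for r in self.receptors if r.label.startswith("GABA")]
        if exc and inh and min(exc) <= max(inh):
            raise ValueError("excitatory reversal must exceed inhibitory reversal")

    @property
    def g_L(self) -> float:
        """Leak conductance in nS."""
        return self.C_m / self.tau_m


@dataclass(frozen=True)
class StaticSynapse:
    weight: float = 1.0      # pA (current-based) or nS (conductance-based)
    delay: float = 1.5       # ms
    receptor: str | None = None   # channel label for conductance targets


@dataclass(frozen=True)
class STDPPowerLawSynapse:
    """Power-law potentiation / multiplicative depression STDP synapse.

    Potentiation at a post-spike uses the presynaptic trace:
        w -> w + lambda_ * w0**(1 - mu) * w**mu * K_plus
    depression at a pre-spike uses the postsynaptic trace:
        w -> w - lambda_ * alpha_ * w * K_minus
    with exponential all-to-all traces of time constants tau_plus/tau_minus.
    Weights stay strictly positive (floored at 1e-12 * w0).
    """

    weight: float = 1.0
    delay: float = 1.5
    lambda_: float = 0.1
    mu: float = 0.4
    alpha_: float = 0.05
    tau_plus: float = 15.0
    tau_minus: float = 30.0
    w0: float = 1.0
    receptor: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.mu <= 1.0:
            raise ValueError("mu must lie in [0, 1]")
        if self.weight <= 0 or self.w0 <= 0:
            raise ValueError("STDP weights must be positive")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("trace time constants must be > 0")

    @property
    def w_min(self) -> float:
        return 1e-12 * self.w0


def stdp_update(syn: STDPPowerLawSynapse, dt_pre_post: float) -> float:
    """Single spike-pair weight update; returns the new weight.

    ``dt_pre_post`` is t_post - t_pre: positive values (pre before post)
    potentiate, negative values depress.  A zero learning rate leaves the
    weight untouched.
    """
    w = syn.weight
    if dt_pre_post >= 0:
        w = w + syn.lambda_ * syn.w0 ** (1.0 - syn.mu) * w ** syn.mu * math.exp(
            -dt_pre_post / syn.tau_plus
        )
    else:
        w = w - syn.lambda_ * syn.alpha_ * w * math.exp(dt_pre_post / syn.tau_minus)
    return max(w, syn.w_min)


def _replace(obj, **kw):
    return replace(obj, **kw)
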