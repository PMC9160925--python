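"""Simplified musculoskeletal surrogate: rodent forelimb plus joystick.

The rig models the three moving segments of a mouse's left forelimb
(humerus, ulna/radius, foot) anchored at the shoulder: two revolute
shoulder DOF, one elbow DOF, one wrist DOF, actuated by 8 muscles -- one
antagonist pair per rotation axis -- with first-order activation dynamics
and constant moment arms.  The foot couples kinematically onto a joystick
with two revolute DOF (forward/backward and lateral/medial) that carries a
constant bias torque (default -0.001 Nm) and viscous damping.

This is an explicit surrogate of a full rigid-body/Hill-muscle simulation:
per-DOF decoupled inertias, force-length/velocity factors set to one, no
gravity or contacts.  What it preserves is the interface exercised by the
embodied benchmark: activations in [0, 1], two behaviorally meaningful
joystick angles, deterministic and passive dynamics, and a configurable
inner time step (default 1 ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Segment", "MuscleParams", "PlantConfig", "PlantState",
           "Plant", "build_default_forelimb"]

N_MUSCLES = 8
N_LIMB_DOF = 4     # shoulder flex, shoulder abduction, elbow, wrist
N_JOY_DOF = 2      # forward/backward, lateral/medial


@dataclass(frozen=True)
class Segment:
    name: str
    mass: float      # kg
    length: float    # m
    inertia: float   # kg m^2 about its joint axis

    def __post_init__(self):
        if min(self.mass, self.length, self.inertia) <= 0:
            raise ValueError("segment mass, length, inertia must be > 0")


@dataclass(frozen=True)
class MuscleParams:
    F_max: float = 2.0            # N
    tau_act: float = 0.01         # s
    tau_deact: float = 0.04       # s
    # signed moment arms (m) per limb DOF; antagonists get opposite signs
    moment_arms: tuple = (0.0,) * N_LIMB_DOF


@dataclass(frozen=True)
class PlantConfig:
    segments: tuple                       # 3 Segment records
    muscles: tuple                        # 8 MuscleParams
    joint_damping: tuple                  # N m s/rad per limb DOF
    joint_stiffness: tuple                # N m/rad centering springs
    joystick_bias_torque: float = -0.001  # Nm, applied to both joystick DOF
    joystick_damping: float = 0.002
    joystick_stiffness: float = 0.01
    joystick_inertia: float = 2e-5
    # kinematic coupling: joystick angle tracks C @ q_limb through a stiff
    # spring; row 0 = forward/backward, row 1 = lateral/medial
    coupling: tuple = ((0.6, 0.0, 0.4, 0.2), (0.0, 0.8, 0.0, 0.2))
    coupling_stiffness: float = 0.05      # N m/rad
    inner_dt: float = 1.0                 # ms

    def __post_init__(self):
        if len(self.segments) != 3:
            raise ValueError("exactly three moving segments")
        if len(self.muscles) != N_MUSCLES:
            raise ValueError("exactly 8 muscles (2 per rotation axis)")
        if self.inner_dt <= 0:
            raise ValueError("inner_dt must be > 0")


@dataclass
class PlantState:
    q: np.ndarray       # 6 joint angles, rad (4 limb + 2 joystick)
    qdot: np.ndarray    # rad/s
    a: np.ndarray       # 8 muscle activations in [0, 1]

    @classmethod
    def initial(cls):
        return cls(np.zeros(6), np.zeros(6), np.zeros(N_MUSCLES))

    def validate(self):
        if not (np.isfinite(self.q).all() and np.isfinite(self.qdot).all()
                and np.isfinite(self.a).all()):
            raise ValueError("non-finite plant state")


def build_default_forelimb() -> PlantConfig:
    """Documented default rig; free dimensions are order-of-magnitude mouse
    anatomy (not printed anywhere authoritative)."""
    segments = (
        Segment("humerus", 0.010, 0.016, 1.2e-6),
        Segment("ulna_radius", 0.006, 0.018, 8.0e-7),
        Segment("foot", 0.002, 0.009, 1.5e-7),
    )
    arm = 0.004   # m, constant moment arm magnitude
    muscles = []
    for dof in range(N_LIMB_DOF):
        for sign in (+1.0, -1.0):
            arms = [0.0] * N_LIMB_DOF
            arms[dof] = sign * arm
            muscles.append(MuscleParams(moment_arms=tuple(arms)))
    return PlantConfig(
        segments=segments,
        muscles=tuple(muscles),
        joint_damping=(0.004, 0.004, 0.003, 0.002),
        joint_stiffness=(0.02, 0.02, 0.015, 0.01),
    )


class Plant:
    """Semi-implicit-Euler integrator over a :class:`PlantConfig`."""

    def __init__(self, config: PlantConfig | None = None):
        self.config = config if config is not None else build_default_forelimb()
        c = self.config
        self.state = PlantState.initial()
        self.R = np.array([m.moment_arms for m in c.muscles]).T   # (4, 8)
        self.F_max = np.array([m.F_max for m in c.muscles])
        self.tau_act = np.array([m.tau_act for m in c.muscles])
        self.tau_deact = np.array([m.tau_deact for m in c.muscles])
        seg_inertia = np.array([s.inertia for s in c.segments])
        # per-DOF decoupled inertia: shoulder DOF carry the whole chain,
        # elbow the forearm+foot, wrist the foot
        chain = np.array([seg_inertia.sum(), seg_inertia.sum(),
                          seg_inertia[1:].sum(), seg_inertia[2]])
        self.I = np.concatenate([chain, [c.joystick_inertia] * N_JOY_DOF])
        self.D = np.concatenate([np.asarray(c.joint_damping),
                                 [c.joystick_damping] * N_JOY_DOF])
        self.K = np.concatenate([np.asarray(c.joint_stiffness),
                                 [c.joystick_stiffness] * N_JOY_DOF])
        self.C = np.asarray(c.coupling)                            # (2, 4)
        self.time_ms = 0.0

    # ---- dynamics ------------------------------------------------------

    def _torques(self, q, qdot, a):
        tau = np.zeros(6)
        tau[:N_LIMB_DOF] = self.R @ (self.F_max * a)
        # conservative coupling spring between limb posture and joystick
        stretch = self.C @ q[:N_LIMB_DOF] - q[N_LIMB_DOF:]
        tau[N_LIMB_DOF:] += self.config.coupling_stiffness * stretch
        tau[:N_LIMB_DOF] -= self.config.coupling_stiffness * (self.C.T @ stretch)
        tau[N_LIMB_DOF:] += self.config.joystick_bias_torque
        tau -= self.K * q
        return tau            # damping applied implicitly in step()

    def step(self, u, dt_ms: float | None = None) -> PlantState:
        """Advance one inner step under muscle excitations u in [0,1]^8."""
        self.state.validate()
        dt = (dt_ms if dt_ms is not None else self.config.inner_dt) * 1e-3  # s
        if dt <= 0:
            raise ValueError("dt must be > 0")
        u = np.clip(np.asarray(u, dtype=float), 0.0, 1.0)
        s = self.state
        tau_a = np.where(u > s.a, self.tau_act, self.tau_deact)
        # exact update of da/dt = (u - a)/tau for piecewise-constant u
        a_new = np.clip(u + (s.a - u) * np.exp(-dt / tau_a), 0.0, 1.0)
        tau = self._torques(s.q, s.qdot, a_new)
        # semi-implicit Euler with implicit viscous damping (stable for any
        # damping coefficient at the default inner step)
        qdot_new = (s.qdot + dt * tau / self.I) / (1.0 + dt * self.D / self.I)
        q_new = s.q + dt * qdot_new
        self.state = PlantState(q=q_new, qdot=qdot_new, a=a_new)
        self.time_ms += dt * 1e3
        return self.state

    def advance(self, duration_ms: float, u=None):
        """Advance by duration_ms in inner steps under constant excitation."""
        if u is None:
            u = np.zeros(N_MUSCLES)
        n = max(1, int(round(duration_ms / self.config.inner_dt)))
        for _ in range(n):
            self.step(u)
        return self.state

    # ---- observables ---------------------------------------------------

    def joystick_angles(self) -> tuple[float, float]:
        """(forward/backward, lateral/medial) joystick angles in rad."""
        return float(self.state.q[4]), float(self.state.q[5])

    def energy(self) -> float:
        """Mechanical energy (J): kinetic + spring potential, with the
        constant bias torque folded in as a linear potential."""
        s = self.state
        kin = 0.5 * float(self.I @ s.qdot**2)
        pot = 0.5 * float(self.K @ s.q**2)
        stretch = self.C @ s.q[:N_LIMB_DOF] - s.q[N_LIMB_DOF:]
        pot += 0.5 * self.config.coupling_stiffness * float(stretch @ stretch)
        pot -= self.config.joystick_bias_torque * float(s.q[N_LIMB_DOF:].sum())
        return kin + pot
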