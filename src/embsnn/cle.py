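"""Closed-Loop Engine: lockstep brain/plant windows with profiling.

Each CLE step advances the brain simulation and the plant by one exchange
interval (default 20 ms of simulated time), and only after both have
completed runs the transfer functions.  "Parallel" execution is a contract
about ordering and clock synchrony, not a threading mandate: components are
timed individually, and the recorded brain time is the critical path
(max over logical workers), i.e. the wall time a genuinely concurrent
execution would take.

The profile keeps every step, including the first; the first step carries
initialization overhead and is excluded only in the derived metrics
(real-time factor, step ratio).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from time import perf_counter

import pandas as pd

__all__ = [
    "CLEConfig",
    "StepProfile",
    "ClosedLoopEngine",
    "real_time_factor",
    "step_ratio",
    "node_hours",
    "write_metrics",
    "read_metrics",
]


@dataclass(frozen=True)
class CLEConfig:
    exchange_interval: float = 20.0   # ms of simulated time per CLE step
    total_duration: float = 1000.0    # ms
    first_step_excluded: bool = True  # for derived metrics

    def __post_init__(self):
        if self.exchange_interval <= 0:
            raise ValueError("exchange_interval must be > 0")
        if self.total_duration < self.exchange_interval:
            raise ValueError("total_duration shorter than one step")


@dataclass
class StepProfile:
    """Per-step wall times in seconds, append-only."""

    brain: list = field(default_factory=list)
    robot: list = field(default_factory=list)
    tf: list = field(default_factory=list)
    wall: list = field(default_factory=list)

    def append(self, brain_s, robot_s, tf_s, wall_s):
        for v in (brain_s, robot_s, tf_s, wall_s):
            if v < 0:
                raise ValueError("step times must be >= 0")
        self.brain.append(brain_s)
        self.robot.append(robot_s)
        self.tf.append(tf_s)
        self.wall.append(wall_s)

    def __len__(self):
        return len(self.wall)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": range(1, len(self) + 1),
            "brain_s": self.brain, "robot_s": self.robot,
            "tf_s": self.tf, "wall_s": self.wall,
        })


def real_time_factor(profile: StepProfile, exchange_interval_ms: float,
                     first_step_excluded: bool = True) -> float:
    """Simulated step time over mean wall time per step.

    The first step carries initialization and is excluded from the mean.
    """
    start = 1 if first_step_excluded else 0
    walls = profile.wall[start:]
    if len(profile) < 2:
        raise ValueError("need at least 2 recorded steps")
    return (exchange_interval_ms * 1e-3) / (sum(walls) / len(walls))


def step_ratio(profile: StepProfile, first_step_excluded: bool = True) -> float:
    """Mean brain step time over mean plant step time (first step excluded).

    Returns NaN when the plant time is identically zero (undefined ratio);
    a ratio of 1 marks the most efficient brain/body balance.
    """
    start = 1 if first_step_excluded else 0
    if len(profile) < 2:
        raise ValueError("need at least 2 recorded steps")
    brain = sum(profile.brain[start:]) / (len(profile) - start)
    robot = sum(profile.robot[start:]) / (len(profile) - start)
    if robot == 0.0:
        return math.nan
    return brain / robot


def node_hours(runtime_s: float, n_nodes: int) -> float:
    """Cost metric: wall runtime in hours times the number of nodes."""
    if runtime_s < 0 or n_nodes < 1:
        raise ValueError("runtime_s >= 0 and n_nodes >= 1 required")
    return runtime_s / 3600.0 * n_nodes


class ClosedLoopEngine:
    """Advance a brain handle and a plant handle in lockstep windows.

    ``brain`` must expose ``advance(ms) -> float`` returning the critical-
    path wall time of the window; ``plant`` exposes ``advance(ms)``; each
    transfer binding is a callable run after both components complete.
    """

    def __init__(self, brain, plant, transfers=(), config: CLEConfig | None = None):
        self.brain = brain
        self.plant = plant
        self.transfers = list(transfers)
        self.config = config if config is not None else CLEConfig()
        self.profile = StepProfile()
        self.steps_done = 0
        self.sim_time = 0.0

    @property
    def max_steps(self) -> int:
        return int(round(self.config.total_duration / self.config.exchange_interval))

    def step(self):
        """One CLE step; returns the appended profile entry."""
        if self.steps_done >= self.max_steps:
            raise RuntimeError("total_duration reached")
        dt = self.config.exchange_interval
        brain_s = self.brain.advance(dt)
        t1 = perf_counter()
        self.plant.advance(dt)
        robot_s = perf_counter() - t1
        t2 = perf_counter()
        for tf in self.transfers:
            tf(self)
        tf_s = perf_counter() - t2
        # brain and plant advance concurrently by contract, transfer
        # functions strictly after both: the step's wall time is the
        # critical path of that schedule
        wall = max(brain_s, robot_s) + tf_s
        self.profile.append(brain_s, robot_s, tf_s, wall)
        self.steps_done += 1
        self.sim_time += dt
        return brain_s, robot_s, tf_s, wall

    def run(self):
        """Run to total_duration; returns the profile."""
        while self.steps_done < self.max_steps:
            self.step()
        return self.profile

    def metrics(self, n_nodes: int = 1, runtime_s: float | None = None) -> dict:
        runtime = runtime_s if runtime_s is not None else sum(self.profile.wall)
        return {
            "rtf": real_time_factor(self.profile, self.config.exchange_interval,
                                    self.config.first_step_excluded),
            "step_ratio": step_ratio(self.profile,
                                     self.config.first_step_excluded),
            "runtime_s": runtime,
            "node_hours": node_hours(runtime, n_nodes),
            "steps": self.steps_done,
        }


def write_metrics(profile: StepProfile, path, summary: dict | None = None):
    """Profile to CSV; optional summary to a sibling .json file."""
    path = Path(path)
    profile.to_frame().to_csv(path, index=False)
    if summary is not None:
        path.with_suffix(".json").write_text(json.dumps(summary, indent=2))


def read_metrics(path) -> StepProfile:
    df = pd.read_csv(path)
    prof = StepProfile()
    for _, row in df.iterrows():
        prof.append(row["brain_s"], row["robot_s"], row["tf_s"], row["wall_s"])
    return prof
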