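"""Center-out cursor task: target scheduling, cursor kinematics, trial outcomes.

A trial starts with the cursor at the screen center and one peripheral target
presented; the decoded control signal is integrated as cursor velocity.  The
trial succeeds when the cursor touches the target (center distance within the
sum of the radii) and fails when the maximum trial length (10 s) elapses
first.  Every trial is followed by an inter-trial interval (2 s) during which
neither cursor nor target is shown and control input is ignored.

Geometry: unit-square workspace [-1, 1]^2 centered on the origin, targets on
a circle of radius 0.8, target/cursor radii 0.1.  For the 1-D (two-target)
variant the targets sit on the vertical axis and a length-1 control signal
moves the cursor vertically only, positive up.

The task feeds the current target direction back to the acquisition side each
frame — it both drives the signal simulator and provides the desired-movement
regressor for decoder training.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .core import ControlSignal

__all__ = [
    "TaskConfig",
    "TrialState",
    "target_position",
    "schedule_targets",
    "step_task",
    "CenterOutTask",
    "session_summary",
]


@dataclass(frozen=True)
class TaskConfig:
    """Center-out geometry and timing (screen units, seconds)."""

    n_targets: int = 8
    target_radius: float = 0.1
    cursor_radius: float = 0.1
    target_distance: float = 0.8
    trial_timeout: float = 10.0
    iti: float = 2.0
    hold_time: float = 0.0
    workspace_half: float = 1.0

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if self.trial_timeout <= 0:
            raise ValueError("trial_timeout must be positive")
        if self.iti < 0:
            raise ValueError("iti must be non-negative")

    def target_angle(self, k: int) -> float:
        """Angle of target k; two-target layouts are vertical (up, down)."""
        if self.n_targets == 2:
            return np.pi / 2 if k == 0 else -np.pi / 2
        return 2.0 * np.pi * k / self.n_targets


def target_position(cfg: TaskConfig, k: int) -> np.ndarray:
    ang = cfg.target_angle(k)
    return cfg.target_distance * np.array([np.cos(ang), np.sin(ang)])


@dataclass
class TrialState:
    """Mutable state of the task state machine for one trial (plus its ITI)."""

    phase: str = "active"  # active | iti | done
    target_index: int = 0
    target_pos: np.ndarray = field(default_factory=lambda: np.zeros(2))
    cursor_pos: np.ndarray = field(default_factory=lambda: np.zeros(2))
    elapsed: float = 0.0
    iti_elapsed: float = 0.0
    hold_elapsed: float = 0.0
    outcome: str = "pending"  # pending | success | failure


def schedule_targets(cfg: TaskConfig, seed=0) -> Iterator[int]:
    """Endless pseudo-random balanced target sequence.

    Targets come in blocks: each block contains every target exactly once in
    a shuffled order, so any prefix of n_targets * k trials is balanced.
    """
    rng = np.random.default_rng(seed)
    while True:
        block = rng.permutation(cfg.n_targets)
        yield from (int(t) for t in block)


def _as_velocity(control: ControlSignal | np.ndarray) -> np.ndarray:
    v = control.velocity if isinstance(control, ControlSignal) else np.atleast_1d(control)
    if v.size == 1:  # 1-D control moves the vertical axis only, positive = up
        return np.array([0.0, float(v[0])])
    return np.asarray(v, dtype=np.float64)[:2]


def step_task(
    state: TrialState, control: ControlSignal | np.ndarray, dt: float, cfg: TaskConfig
) -> tuple[TrialState, dict]:
    """Advance the state machine one frame; returns (state, feedback items).

    During the active phase the control signal (screen-units/s) is integrated
    into cursor position (clamped to the workspace); during the ITI control
    input is ignored and the cursor stays frozen at the center.  The feedback
    dict carries the target direction and drive flag for the acquisition side.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if state.phase == "active":
        v = _as_velocity(control)
        state.cursor_pos = np.clip(
            state.cursor_pos + v * dt, -cfg.workspace_half, cfg.workspace_half
        )
        state.elapsed += dt
        dist = float(np.linalg.norm(state.cursor_pos - state.target_pos))
        if dist <= cfg.target_radius + cfg.cursor_radius:
            state.hold_elapsed += dt
            if state.hold_elapsed >= cfg.hold_time:
                state.outcome = "success"
                state.phase = "iti"
        else:
            state.hold_elapsed = 0.0
        if state.phase == "active" and state.elapsed >= cfg.trial_timeout - 1e-12:
            state.outcome = "failure"
            state.phase = "iti"
    elif state.phase == "iti":
        state.iti_elapsed += dt
        if state.iti_elapsed >= cfg.iti - 1e-12:
            state.phase = "done"
    active = state.phase == "active"
    feedback = {
        "target_angle": cfg.target_angle(state.target_index),
        "drive_active": 1 if active else 0,
        "phase": state.phase,
        "cursor_x": float(state.cursor_pos[0]),
        "cursor_y": float(state.cursor_pos[1]),
        "target_index": state.target_index,
        "outcome": state.outcome,
    }
    return state, feedback


class CenterOutTask:
    """Sequencer over trials: pulls targets from the balanced schedule and
    starts a fresh trial (cursor recentered) whenever the previous one — and
    its ITI — has finished."""

    def __init__(self, cfg: TaskConfig, seed=0):
        self.cfg = cfg
        self._schedule = schedule_targets(cfg, seed)
        self.completed: list[TrialState] = []
        self.state = self._new_trial()

    def _new_trial(self) -> TrialState:
        k = next(self._schedule)
        return TrialState(
            phase="active",
            target_index=k,
            target_pos=target_position(self.cfg, k),
            cursor_pos=np.zeros(2),
        )

    @property
    def n_completed(self) -> int:
        return len(self.completed)

    def step(self, control: ControlSignal | np.ndarray, dt: float) -> dict:
        self.state, feedback = step_task(self.state, control, dt, self.cfg)
        if self.state.phase == "done":
            self.completed.append(self.state)
            self.state = self._new_trial()
        return feedback


def session_summary(trials: list[TrialState]) -> dict:
    """Success-rate summary over finished trials (overall and per target)."""
    if not trials:
        raise ValueError("no trials to summarize")
    if any(t.outcome == "pending" for t in trials):
        raise ValueError("all trials must be finished before summarizing")
    n = len(trials)
    n_success = sum(t.outcome == "success" for t in trials)
    per_target: dict[int, dict] = {}
    for t in trials:
        d = per_target.setdefault(t.target_index, {"n_trials": 0, "n_success": 0})
        d["n_trials"] += 1
        d["n_success"] += t.outcome == "success"
    for d in per_target.values():
        d["success_rate"] = d["n_success"] / d["n_trials"]
    return {
        "n_trials": n,
        "n_success": n_success,
        "success_rate": n_success / n,
        "per_target": dict(sorted(per_target.items())),
    }
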