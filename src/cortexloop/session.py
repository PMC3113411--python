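"""Scripted end-to-end brain-control session on the simulator.

The four-step workflow runs as one continuous session — no engine ever
restarts; every transition is a live, index-stamped parameter change:

1. **Baseline** — the simulator's modulation drive is inactive; per-feature
   mean and standard deviation accumulate for pseudo-Z normalization.
2. **Training-data collection** — the cursor is computer-driven toward each
   scheduled target; the simulator modulates high-gamma power by the cosine
   of the angle between each channel's preferred direction and the target
   direction, and (features, target-direction) pairs are buffered.
3. **Decoder training** — directional tuning is regressed per feature, the
   target-shuffle R^2 null sets the selection threshold (95th percentile by
   default), and the population-vector decoder plus an output gain are
   published to the signal-processing engine as parameter updates.
4. **Closed-loop control** — the population vector drives the cursor through
   the center-out task; optional mid-session refits re-publish the decoder
   without stopping.

Engine hooks: the acquisition engine owns the simulator and the AR feature
extractor (spectral estimation lives with acquisition); the signal-processing
engine owns normalization, the training buffer and the decoder; the
application engine owns the center-out task and feeds target information back
to acquisition for the simulator drive and decoder training.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .core import FeatureMatrix, VariableBundle
from .decoding import (
    TrainingBuffer,
    TuningModel,
    fit_tuning,
    population_vector,
    select_features,
    shuffle_null,
)
from .engine import FRAME_PERIOD_DEFAULT, EngineSpec, System, launch
from .features import ArSpec, BaselineStats, FeatureExtractor, normalize
from .recording import Recorder, RunMetadata, export_mat
from .simulate import CursorDrive, SimConfig, SimEcog
from .task import CenterOutTask, TaskConfig, session_summary

__all__ = ["SessionPlan", "SessionConfig", "SessionResult", "run_session", "SessionError"]

log = logging.getLogger(__name__)


class SessionError(RuntimeError):
    """The session could not proceed (e.g. a degenerate baseline)."""


@dataclass(frozen=True)
class SessionPlan:
    """What to run: baseline length, trial counts, optional mid-session refits.

    ``retrain_points`` are control-trial indices after which the decoder is
    refit from the (still-growing) training buffer and re-published live.
    """

    baseline_s: float = 180.0
    training_trials: int = 24
    control_trials: int = 40
    retrain_points: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.baseline_s <= 0:
            raise ValueError("baseline_s must be positive")
        if self.training_trials < 0 or self.control_trials < 0:
            raise ValueError("trial counts must be non-negative")


@dataclass(frozen=True)
class SessionConfig:
    """Study conditions: simulator, features, task, clock and decoder knobs.

    ``cursor_speed`` (screen-units/s) sets both the scripted training drive
    and the target closed-loop speed; the decoder gain is calibrated after
    training so the median population-vector magnitude maps to it (the live
    gain a human operator would otherwise adjust by hand).
    """

    sim: SimConfig = field(default_factory=SimConfig)
    ar: ArSpec = field(default_factory=ArSpec)
    task: TaskConfig = field(default_factory=TaskConfig)
    frame_period: float = FRAME_PERIOD_DEFAULT
    cursor_speed: float = 0.4
    null_iterations: int = 1000
    null_max_features: int = 64
    null_seed: int = 1
    save_features: bool = False

    @property
    def frame_samples(self) -> int:
        return int(round(self.sim.sample_rate * self.frame_period))


@dataclass
class SessionResult:
    """Everything a session produced, for analysis and assertions."""

    run_path: str
    summary: dict | None
    model: TuningModel | None
    baseline: BaselineStats
    n_frames: int
    gain: float
    mat_path: str | None = None


# --------------------------------------------------------------------------
# engine hooks


def make_acquisition_hook(cfg: SessionConfig):
    """SimECoG + AR feature extraction; drive angle comes from task feedback."""

    def hook(upstream: VariableBundle, params: dict, state: dict):
        sim = state.get("sim")
        if sim is None:
            sim = state["sim"] = SimEcog(cfg.sim)
            state["extractor"] = FeatureExtractor(
                cfg.ar, cfg.sim.sample_rate, cfg.sim.n_channels
            )
        drive = CursorDrive(
            angle=float(upstream.get("target_angle", 0.0)),
            active=bool(upstream.get("drive_active", 0)),
        )
        block = sim.next_block(drive, cfg.frame_samples)
        fm = state["extractor"].push(block)
        down = {
            "warmed": int(fm is not None),
            "features": fm.power.reshape(-1) if fm is not None else np.zeros(1),
            "drive_active": int(drive.active),
            "target_angle": drive.angle,
        }
        save = {"drive_active": int(drive.active)}
        if cfg.save_features and fm is not None:
            save["features"] = fm.power.reshape(-1)
        return down, {"n_channels": cfg.sim.n_channels}, save

    return hook


def make_signal_processing_hook(cfg: SessionConfig):
    """Normalization, training-buffer collection and the population-vector decoder."""

    n_features = cfg.sim.n_channels * cfg.ar.n_bands

    def hook(upstream: VariableBundle, params: dict, state: dict):
        stats = state.setdefault(
            "baseline", BaselineStats(cfg.sim.n_channels, cfg.ar.n_bands)
        )
        buffer = state.setdefault("buffer", TrainingBuffer())
        phase = params["phase"]
        warmed = bool(upstream.get("warmed", 0))
        control = np.zeros(2)
        z_flat = np.full(n_features, np.nan)
        if warmed:
            fm = FeatureMatrix(
                np.asarray(upstream["features"]).reshape(cfg.sim.n_channels, cfg.ar.n_bands),
                cfg.ar.band_edges,
                cfg.ar.window_s,
                upstream.index,
            )
            if phase == "baseline":
                stats.update(fm)
            elif stats.n_frames >= 2:
                z = normalize(fm, stats)
                z_flat = z.power.reshape(-1)
                driven = bool(upstream.get("drive_active", 0))
                if driven and params.get("collect", 1):
                    ang = float(upstream.get("target_angle", 0.0))
                    buffer.append(z_flat, np.array([np.cos(ang), np.sin(ang)]))
                if phase == "control" and params["dec_sel"].size > 0:
                    model = TuningModel(
                        b0=np.asarray(params["dec_b0"]),
                        bx=np.asarray(params["dec_pd"])[:, 0],
                        by=np.asarray(params["dec_pd"])[:, 1],
                        r2=np.zeros(n_features),
                        pd=np.asarray(params["dec_pd"]),
                        selected=np.asarray(params["dec_sel"], dtype=int),
                    )
                    control = population_vector(
                        model, z_flat, gain=float(params["gain"]), index=upstream.index
                    ).velocity
        down = {"control": control, "phase": phase}
        save = {"control_x": float(control[0]), "control_y": float(control[1]), "phase": phase}
        return down, {"control": control}, save

    return hook


def _training_velocity(task: CenterOutTask, cfg: SessionConfig) -> np.ndarray:
    """Computer-driven training cursor: straight toward the target, capped."""
    to_target = task.state.target_pos - task.state.cursor_pos
    dist = float(np.linalg.norm(to_target))
    if dist <= 1e-12:
        return np.zeros(2)
    speed = min(cfg.cursor_speed, dist / cfg.frame_period)
    return to_target / dist * speed


def make_application_hook(cfg: SessionConfig):
    """Center-out task; scripted drive during training, decoded drive during control."""

    def hook(upstream: VariableBundle, params: dict, state: dict):
        mode = params["mode"]
        task: CenterOutTask = state.get("task")
        if task is None:
            task = state["task"] = CenterOutTask(cfg.task, seed=params.get("task_seed", 0))
        if mode == "idle":
            feedback = {
                "target_angle": 0.0,
                "drive_active": 0,
                "phase": "idle",
                "cursor_x": 0.0,
                "cursor_y": 0.0,
                "target_index": -1,
                "outcome": "pending",
            }
            st = None
        else:
            if mode == "training":
                velocity = _training_velocity(task, cfg)
            else:  # control
                velocity = np.asarray(upstream.get("control", np.zeros(2)))
            st = task.state
            feedback = task.step(velocity, cfg.frame_period)
        feedback["n_completed"] = task.n_completed
        save = {
            "cursor_x": feedback["cursor_x"],
            "cursor_y": feedback["cursor_y"],
            "phase": feedback["phase"] if mode != "idle" else "idle",
            "mode": mode,
            "target_index": feedback["target_index"],
            "target_angle": feedback["target_angle"],
            "trial_seq": task.n_completed,
            "elapsed": float(st.elapsed) if st is not None else 0.0,
            "outcome": feedback["outcome"],
        }
        return feedback, {"cursor": np.array([feedback["cursor_x"], feedback["cursor_y"]])}, save

    return hook


# --------------------------------------------------------------------------
# orchestration


def _fit_and_publish(
    system: System, cfg: SessionConfig, buffer: TrainingBuffer
) -> tuple[TuningModel, float]:
    """Decoder training (the parallel-channel step): fit, null, select, gain."""
    model = fit_tuning(buffer)
    percentiles = shuffle_null(
        buffer,
        n_iter=cfg.null_iterations,
        seed=cfg.null_seed,
        max_features=cfg.null_max_features,
    )
    from dataclasses import replace

    model = replace(model, null_percentiles=percentiles)
    model = select_features(model, percentiles["p95"])
    if model.selection_empty:
        raise SessionError("no feature cleared the shuffle-null threshold")
    # gain calibration: median population-vector magnitude -> cursor_speed
    sel = model.selected
    excess = buffer.features[:, sel] - model.b0[sel]
    P = excess @ model.pd[sel]
    median_mag = float(np.median(np.linalg.norm(P, axis=1)))
    if median_mag <= 0:
        raise SessionError("degenerate population-vector magnitude during calibration")
    gain = cfg.cursor_speed / median_mag
    pd_clean = np.where(np.isfinite(model.pd), model.pd, 0.0)
    system.set_parameter("signal_processing", "dec_b0", model.b0.copy())
    system.set_parameter("signal_processing", "dec_pd", pd_clean)
    system.set_parameter("signal_processing", "dec_sel", model.selected.astype(np.int64))
    system.set_parameter("signal_processing", "gain", gain)
    system.set_parameter("signal_processing", "threshold", float(percentiles["p95"]))
    return model, gain


def build_system(
    cfg: SessionConfig,
    meta: RunMetadata,
    run_path,
    recorder: Recorder | None = None,
    task_seed: int = 0,
) -> System:
    """Assemble and launch the three session engines on the local transport."""
    n_features = cfg.sim.n_channels * cfg.ar.n_bands
    specs = {
        "acquisition": EngineSpec("acquisition", "sim_ecog", parameters={}),
        "signal_processing": EngineSpec(
            "signal_processing",
            "population_vector",
            parameters={
                "phase": "baseline",
                "collect": 1,
                "gain": 1.0,
                "threshold": 1.0,
                "dec_b0": np.zeros(n_features),
                "dec_pd": np.zeros((n_features, 2)),
                "dec_sel": np.zeros(0, dtype=np.int64),
            },
        ),
        "application": EngineSpec(
            "application",
            "center_out",
            parameters={"mode": "idle", "task_seed": task_seed},
        ),
    }
    hooks = {
        "acquisition": make_acquisition_hook(cfg),
        "signal_processing": make_signal_processing_hook(cfg),
        "application": make_application_hook(cfg),
    }
    if recorder is None:
        recorder = Recorder()
    return launch(specs, hooks, meta, run_path, recorder, cfg.frame_period, clock="sim")


def run_session(
    plan: SessionPlan,
    cfg: SessionConfig,
    run_path,
    meta: RunMetadata | None = None,
    export_to_mat: bool = False,
    max_frames: int = 200_000,
) -> SessionResult:
    """Execute the full four-step session; returns the result handle.

    The run file at ``run_path`` records every engine's sampled variables and
    all control changes (including the published decoder weights), so the
    session replays exactly.
    """
    meta = meta or RunMetadata(subject_id="sim", session_number=1, date="simulated")
    recorder = Recorder()
    system = build_system(cfg, meta, run_path, recorder, task_seed=cfg.sim.seed)
    sp_state = system.engines["signal_processing"].state
    app_state = system.engines["application"].state

    # step 1: baseline
    n_baseline = int(round(plan.baseline_s / cfg.frame_period))
    system.run(n_baseline)
    stats: BaselineStats = sp_state["baseline"]
    if stats.n_frames < 2 or np.any(stats.sd == 0):
        system.stop()
        raise SessionError(
            f"degenerate baseline: {stats.n_frames} frames, "
            f"{int(np.sum(stats.sd == 0))} zero-variance features"
        )

    model: TuningModel | None = None
    gain = 0.0
    summary = None
    # step 2: training-data collection (computer-driven cursor)
    if plan.training_trials > 0:
        system.set_parameter("signal_processing", "phase", "training")
        system.set_parameter("application", "mode", "training")
        while True:
            system.step()
            if app_state["task"].n_completed >= plan.training_trials:
                break
            if system.next_index > max_frames:
                raise SessionError("training phase exceeded the frame budget")
        # step 3: decoder training (runs alongside; published atomically between frames)
        model, gain = _fit_and_publish(system, cfg, sp_state["buffer"])

    # step 4: closed-loop control
    if plan.control_trials > 0:
        if model is None:
            raise SessionError("cannot run control trials without decoder training")
        system.set_parameter("signal_processing", "phase", "control")
        system.set_parameter("application", "mode", "control")
        task: CenterOutTask = app_state["task"]
        first_control = task.n_completed
        retrain_pending = sorted(set(plan.retrain_points))
        while task.n_completed - first_control < plan.control_trials:
            system.step()
            done = task.n_completed - first_control
            while retrain_pending and done >= retrain_pending[0]:
                retrain_pending.pop(0)
                model, gain = _fit_and_publish(system, cfg, sp_state["buffer"])
            if system.next_index > max_frames:
                raise SessionError("control phase exceeded the frame budget")
        control_trials = task.completed[first_control : first_control + plan.control_trials]
        summary = session_summary(control_trials)

    n_frames = system.next_index
    system.stop()
    mat_path = export_mat(run_path) if export_to_mat else None
    return SessionResult(
        run_path=str(run_path),
        summary=summary,
        model=model,
        baseline=stats,
        n_frames=n_frames,
        gain=gain,
        mat_path=mat_path,
    )


def first_second_heading_errors(run_path) -> np.ndarray:
    """Per-control-trial cursor heading error (degrees) one second in.

    For every closed-loop trial, takes the cursor position at the first frame
    with at least 1 s of trial time (or the last active frame for faster
    trials) and measures the absolute angle between the cursor's displacement
    from center and the target direction — an outcome-independent measure of
    decoding accuracy early in the movement.
    """
    from .recording import read_run

    record = read_run(run_path)
    app = record.sampled["center_out"]
    _, modes = app["mode"]
    _, phases = app["phase"]
    _, seqs = app["trial_seq"]
    _, elapsed = app["elapsed"]
    _, cx = app["cursor_x"]
    _, cy = app["cursor_y"]
    _, tangles = app["target_angle"]
    by_trial: dict[int, list[int]] = {}
    for pos in range(len(modes)):
        if modes[pos] == "control" and phases[pos] == "active":
            by_trial.setdefault(int(seqs[pos]), []).append(pos)
    errors = []
    for positions in by_trial.values():
        pick = positions[-1]
        for pos in positions:
            if elapsed[pos] >= 1.0:
                pick = pos
                break
        dx, dy = cx[pick], cy[pick]
        if np.hypot(dx, dy) < 1e-9:
            errors.append(180.0)
            continue
        err = np.degrees(np.arctan2(dy, dx)) - np.degrees(tangles[pick])
        errors.append(abs((err + 180.0) % 360.0 - 180.0))
    return np.asarray(errors)


def replay_trajectory(run_path, cfg: SessionConfig, task_seed: int | None = None):
    """Re-execute the task from a run file's recorded control signals.

    Rebuilds the center-out state machine from the configuration, feeds it
    the recorded per-frame control signals (decoded drive during control
    phases, recomputed scripted drive during training) and returns
    ``(replayed, recorded)`` cursor trajectories, frame-aligned.  A faithful
    recording makes them identical.
    """
    from .recording import read_run

    record = read_run(run_path)
    app = record.sampled["center_out"]
    sp = record.sampled["population_vector"]
    task_seed = cfg.sim.seed if task_seed is None else task_seed
    mode_idx, modes = app["mode"]
    cx_idx, cx = app["cursor_x"]
    _, cy = app["cursor_y"]
    ctrl_pos = {int(i): p for p, i in enumerate(sp["control_x"][0])}
    task = CenterOutTask(cfg.task, seed=task_seed)
    replayed, recorded = [], []
    for pos, frame in enumerate(mode_idx):
        frame = int(frame)
        mode = modes[pos]
        if mode == "idle":
            continue
        if mode == "training":
            velocity = _training_velocity(task, cfg)
        else:
            p = ctrl_pos[frame]
            velocity = np.array([sp["control_x"][1][p], sp["control_y"][1][p]])
        fb = task.step(velocity, cfg.frame_period)
        replayed.append([fb["cursor_x"], fb["cursor_y"]])
        recorded.append([float(cx[pos]), float(cy[pos])])
    return np.asarray(replayed), np.asarray(recorded)
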