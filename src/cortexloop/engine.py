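"""Engine lifecycle and the frame loop: the deterministic heart of the ring.

Three engines — acquisition, signal processing, application — process every
frame in a fixed cycle.  The acquisition engine owns the clock: it emits
frame k only after the application engine's feedback for frame k-1 has come
back around the ring, so each block is fully processed and a system output
generated before the next block begins.  Per frame, an engine executes
exactly this order:

    1. receive the upstream bundle
    2. apply pending parameter updates (atomically, stamped with this frame)
    3. run the engine-specific hook
    4. send the downstream bundle
    5. enqueue a visualization snapshot   (non-blocking, drop-oldest)
    6. enqueue the save record            (non-blocking FIFO)

Hooks are plain callables ``hook(upstream, params, state) -> (down, viz,
save)`` receiving the upstream bundle (stamped with the current frame index),
the live parameter dict and a persistent state dict, and returning item
mappings for the downstream bundle, the visualization channel and the
recorder.  This is the extension surface: a new engine is just a new hook.

Two clocks are supported: wall (sleep to the frame period) and simulated
(as fast as possible, virtual timestamps) — the latter makes runs exactly
reproducible and drives the timing bench.  Engines can be hot-swapped between
frames, preserving the state of the engines that remain; suspending closes
the current run file and resuming opens a new one without losing in-memory
state (baseline statistics, decoder weights, ...).
"""

from __future__ import annotations

import logging
import time
from collections import deque
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .core import PacketIndex, ParameterUpdate, VariableBundle, make_bundle
from .recording import Recorder, RunMetadata
from .wire import LinkConfig

__all__ = [
    "EngineSpec",
    "Engine",
    "EngineFault",
    "System",
    "launch",
    "template_acquisition_hook",
    "template_passthrough_hook",
    "template_application_hook",
    "FRAME_PERIOD_DEFAULT",
]

log = logging.getLogger(__name__)

ENGINE_KINDS = ("acquisition", "signal_processing", "application")

#: default frame period in seconds (33.3 ms; 40 samples at 1200 Hz)
FRAME_PERIOD_DEFAULT = 1.0 / 30.0

Hook = Callable[[VariableBundle, dict, dict], tuple[dict, dict, dict]]


class EngineFault(RuntimeError):
    """A hook raised: the engine is faulted and the ring notified."""


@dataclass
class EngineSpec:
    """Static description of one engine: kind, name, initial parameters,
    which produced variables to save, and where it lives on the network."""

    kind: str
    name: str
    parameters: dict = field(default_factory=dict)
    saved_variable_names: list[str] | None = None
    host: LinkConfig = field(default_factory=LinkConfig)

    def __post_init__(self) -> None:
        if self.kind not in ENGINE_KINDS:
            raise ValueError(f"unknown engine kind {self.kind!r}")


class Engine:
    """One running engine: live parameters, persistent state, queues."""

    VIZ_CAPACITY = 8  # snapshots; beyond this the oldest is dropped

    def __init__(self, spec: EngineSpec, hook: Hook):
        self.spec = spec
        self.hook = hook
        self.params: dict = dict(spec.parameters)
        self.state: dict = {}
        self.pending: list[tuple[str, object]] = []
        self.viz_queue: deque = deque(maxlen=self.VIZ_CAPACITY)
        self.viz_dropped = 0
        self.applied_log: list[ParameterUpdate] = []
        self.faulted = False

    @property
    def name(self) -> str:
        return self.spec.name

    def queue_update(self, name: str, value) -> None:
        """Queue a parameter change; it takes effect at the start of the next frame."""
        self.pending.append((name, value))

    def apply_parameter_updates(
        self, index: PacketIndex, recorder: Recorder | None
    ) -> list[ParameterUpdate]:
        """Apply all pending updates atomically before processing frame ``index``.

        Each applied update is stamped ``applied_at = index`` and forwarded to
        the recorder's control log; unknown parameter names are logged and
        skipped; repeated updates to one name are last-writer-wins (all are
        logged).
        """
        applied = []
        for name, value in self.pending:
            if name not in self.params:
                log.warning("engine %s: unknown parameter %r skipped", self.name, name)
                continue
            self.params[name] = value
            update = ParameterUpdate(name, value, index)
            applied.append(update)
            self.applied_log.append(update)
            if recorder is not None:
                recorder.record_control(self.name, update)
        self.pending.clear()
        return applied

    def process(
        self, upstream: VariableBundle, index: PacketIndex, recorder: Recorder | None
    ) -> VariableBundle:
        """Run one main-sequence iteration; returns the downstream bundle."""
        if self.faulted:
            raise EngineFault(f"engine {self.name} is faulted")
        upstream_now = make_bundle(list(upstream.items()), index)
        self.apply_parameter_updates(index, recorder)
        try:
            down, viz, save = self.hook(upstream_now, self.params, self.state)
        except Exception as exc:
            self.faulted = True
            log.error("engine %s hook failed at frame %d: %s", self.name, index, exc)
            raise EngineFault(f"engine {self.name} failed at frame {index}: {exc}") from exc
        downstream = make_bundle(list((down or {}).items()), index)
        if viz:
            if len(self.viz_queue) == self.viz_queue.maxlen:
                self.viz_dropped += 1
            self.viz_queue.append(make_bundle(list(viz.items()), index))
        if save and recorder is not None:
            names = self.spec.saved_variable_names
            items = [
                (n, v) for n, v in save.items() if names is None or n in names
            ]
            if items:
                recorder.record_sampled(self.name, make_bundle(items, index))
        return downstream

    def log_initial_controls(self, recorder: Recorder | None) -> None:
        """Record every parameter's initial value at index 0 of a new run."""
        if recorder is None:
            return
        for name, value in self.params.items():
            recorder.record_control(self.name, ParameterUpdate(name, value, 0))


# --------------------------------------------------------------------------
# template (pass-through) hooks: maintain dataflow, do no work


def template_acquisition_hook(upstream: VariableBundle, params: dict, state: dict):
    """Empty acquisition engine: emits a small deterministic noise block to
    keep the ring's dataflow alive."""
    rng = state.setdefault("rng", np.random.default_rng(params.get("seed", 0)))
    n_ch = int(params.get("n_channels", 4))
    n_samp = int(params.get("frame_samples", 40))
    data = rng.standard_normal((n_ch, n_samp))
    down = {"raw": data}
    return down, {}, {"frame_mean": float(data.mean())}


def template_passthrough_hook(upstream: VariableBundle, params: dict, state: dict):
    """Empty signal-processing engine: forwards its input unchanged."""
    return dict(upstream.items()), {}, {}


def template_application_hook(upstream: VariableBundle, params: dict, state: dict):
    """Empty application engine: counts display updates and closes the loop."""
    state["displays"] = state.get("displays", 0) + 1
    return {"ack": upstream.index}, {}, {}


# --------------------------------------------------------------------------
# the system


class System:
    """A launched three-engine ring on the in-process deterministic transport.

    ``clock`` is ``"sim"`` (virtual time, as fast as possible — fully
    reproducible) or ``"wall"`` (sleeps to the frame period).  The system owns
    the frame index; it restarts from 0 for every run file, and the feedback
    bundle of frame k must exist before frame k+1 is emitted (structural in
    this transport, and asserted).
    """

    def __init__(
        self,
        specs: dict[str, EngineSpec],
        hooks: dict[str, Hook],
        meta: RunMetadata,
        recorder: Recorder | None = None,
        frame_period: float = FRAME_PERIOD_DEFAULT,
        clock: str = "sim",
    ):
        if sorted(specs) != sorted(ENGINE_KINDS):
            missing = set(ENGINE_KINDS) - set(specs)
            extra = set(specs) - set(ENGINE_KINDS)
            raise ValueError(f"need exactly one engine per kind (missing={missing}, extra={extra})")
        if clock not in ("sim", "wall"):
            raise ValueError("clock must be 'sim' or 'wall'")
        self.engines = {kind: Engine(specs[kind], hooks[kind]) for kind in ENGINE_KINDS}
        self.meta = meta
        self.recorder = recorder
        self.frame_period = frame_period
        self.clock = clock
        self.next_index: PacketIndex = 0
        self._feedback = make_bundle([], 0)
        self._feedback_for: PacketIndex | None = None
        self.suspended = True
        self.run_paths: list[str] = []
        # timing instrumentation
        self.proc_times: list[float] = []  # measured per-frame processing (s)
        self.virtual_costs: list[float] = []  # injected virtual processing (s)
        self.display_times: list[float] = []  # virtual display-update timestamps
        self.overruns = 0

    def _config_snapshot(self) -> dict:
        return {
            "frame_period": self.frame_period,
            "clock": self.clock,
            "engines": {
                kind: {"name": e.spec.name, "parameters": _jsonable(e.params)}
                for kind, e in self.engines.items()
            },
        }

    def start_run(self, run_path) -> None:
        """Open a run file and (re)start the frame index from 0."""
        if not self.suspended:
            raise ValueError("system already running")
        if self.recorder is not None:
            self.recorder.open_run(
                run_path,
                self.meta,
                [e.spec.name for e in self.engines.values()],
                self._config_snapshot(),
            )
            for engine in self.engines.values():
                engine.log_initial_controls(self.recorder)
        self.run_paths.append(str(run_path))
        self.next_index = 0
        self._feedback = make_bundle([], 0)
        self._feedback_for = None
        self.suspended = False

    def step(self) -> PacketIndex:
        """Process exactly one frame through the full ring."""
        if self.suspended:
            raise ValueError("system is suspended")
        index = self.next_index
        if index > 0 and self._feedback_for != index - 1:
            raise AssertionError(
                "cyclical dataflow violated: feedback for previous frame missing"
            )
        t0 = time.perf_counter()
        acq, sp, app = (self.engines[k] for k in ENGINE_KINDS)
        a_out = acq.process(self._feedback, index, self.recorder)
        s_out = sp.process(a_out, index, self.recorder)
        p_out = app.process(s_out, index, self.recorder)
        self._feedback = p_out
        self._feedback_for = index
        measured = time.perf_counter() - t0
        virtual = sum(
            float(e.params.get("virtual_cost_s", 0.0)) for e in self.engines.values()
        )
        self.proc_times.append(measured)
        self.virtual_costs.append(virtual)
        # display update happens at the end of the application engine's frame
        self.display_times.append((index + 1) * self.frame_period)
        effective = virtual if virtual > 0 else measured
        if effective > self.frame_period:
            self.overruns += 1
        if self.clock == "wall":
            remaining = self.frame_period - measured
            if remaining > 0:
                time.sleep(remaining)
        self.next_index += 1
        return index

    def run(self, n_frames: int) -> None:
        for _ in range(n_frames):
            self.step()

    def set_parameter(self, kind: str, name: str, value) -> None:
        """Queue a live parameter change on one engine (applied next frame)."""
        self.engines[kind].queue_update(name, value)

    def suspend(self) -> None:
        """Close the current run file; engine in-memory state is preserved.

        The current frame always completes before a suspend takes effect
        (suspension happens between frames by construction); double-suspend
        is an idempotent no-op.  In-flight visualization snapshots are
        discarded.
        """
        if self.suspended:
            return
        self.suspended = True
        if self.recorder is not None:
            self.recorder.close_run()
        for engine in self.engines.values():
            engine.viz_queue.clear()

    def resume(self, run_path) -> None:
        """Open a new run file and continue with all engine state intact."""
        if not self.suspended:
            return
        self.start_run(run_path)

    def swap_engine(self, kind: str, spec: EngineSpec, hook: Hook) -> None:
        """Replace one engine with another of the same kind between frames;
        the state of the engines that remain running is preserved."""
        if spec.kind != kind:
            raise ValueError(f"cannot swap a {spec.kind} engine into the {kind} slot")
        self.engines[kind] = Engine(spec, hook)

    def stop(self) -> None:
        self.suspend()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def launch(
    specs: dict[str, EngineSpec],
    hooks: dict[str, Hook],
    meta: RunMetadata,
    run_path,
    recorder: Recorder | None = None,
    frame_period: float = FRAME_PERIOD_DEFAULT,
    clock: str = "sim",
) -> System:
    """Validate the configuration, form the ring, open the run file and
    return the running system handle."""
    system = System(specs, hooks, meta, recorder, frame_period, clock)
    system.start_run(run_path)
    return system
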