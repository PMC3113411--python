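"""Run the three-engine ring over real TCP links (single- or multi-host).

Engines run in their own threads, connected by the wire-protocol ring; save
records travel to the data-saving side over point links as encoded bundles.
Because every engine is deterministic and the ring preserves order, a
distributed run of the same specs and seeds produces exactly the same saved
streams as the in-process transport — which is also how this module is
tested.

This runner executes a fixed number of frames; interactive suspend/resume and
hot-swap live on the in-process transport (:class:`cortexloop.engine.System`).
"""

from __future__ import annotations

import threading
from .core import ParameterUpdate, VariableBundle, make_bundle
from .engine import ENGINE_KINDS, Engine, EngineSpec, Hook
from .recording import Recorder, RunMetadata
from .wire import Connector, LinkConfig, Listener, RingTopology, establish_ring

__all__ = ["run_distributed"]

_META_ENGINE = "__engine__"
_META_CONTROL = "__control__"
_META_EOF = "__eof__"


class _WireRecorderClient:
    """Duck-typed recorder stand-in that ships records over a point link."""

    def __init__(self, connector: Connector):
        self._conn = connector

    def record_sampled(self, engine: str, bundle: VariableBundle) -> None:
        wrapped = make_bundle([(_META_ENGINE, engine), *bundle.items()], bundle.index)
        self._conn.send_bundle(wrapped)

    def record_control(self, engine: str, update: ParameterUpdate) -> None:
        wrapped = make_bundle(
            [(_META_ENGINE, engine), (_META_CONTROL, update.name), ("value", update.value)],
            update.applied_at,
        )
        self._conn.send_bundle(wrapped)

    def finish(self) -> None:
        self._conn.send_bundle(make_bundle([(_META_EOF, 1)], 0))
        self._conn.close()


def _saver_thread(listener: Listener, recorder: Recorder, lock: threading.Lock) -> None:
    while True:
        bundle = listener.recv_bundle(timeout=30.0)
        if _META_EOF in bundle:
            return
        engine = bundle[_META_ENGINE]
        with lock:
            if _META_CONTROL in bundle:
                recorder.record_control(
                    engine, ParameterUpdate(bundle[_META_CONTROL], bundle["value"], bundle.index)
                )
            else:
                items = [(n, v) for n, v in bundle.items() if n != _META_ENGINE]
                recorder.record_sampled(engine, make_bundle(items, bundle.index))


def run_distributed(
    specs: dict[str, EngineSpec],
    hooks: dict[str, Hook],
    meta: RunMetadata,
    run_path,
    n_frames: int,
    recorder: Recorder | None = None,
    host: str = "127.0.0.1",
) -> list[str]:
    """Execute ``n_frames`` through a TCP ring on ``host``; returns any errors.

    The run file is opened before and closed after the run; initial parameter
    values are control-logged at index 0 exactly as on the local transport.
    """
    if sorted(specs) != sorted(ENGINE_KINDS):
        raise ValueError("need exactly one engine spec per kind")
    engines = {kind: Engine(specs[kind], hooks[kind]) for kind in ENGINE_KINDS}
    if recorder is not None:
        recorder.open_run(
            run_path, meta, [e.spec.name for e in engines.values()],
            {"transport": "tcp", "n_frames": n_frames},
        )
    ring = establish_ring(
        RingTopology(*(LinkConfig(host=host, port=0) for _ in range(3)))
    )
    lock = threading.Lock()
    saver_listeners: dict[str, Listener] = {}
    saver_threads: list[threading.Thread] = []
    clients: dict[str, _WireRecorderClient] = {}
    for kind in ENGINE_KINDS:
        if recorder is None:
            continue
        listener = Listener(host, 0)
        saver_listeners[kind] = listener
        t = threading.Thread(target=_saver_thread, args=(listener, recorder, lock), daemon=True)
        t.start()
        saver_threads.append(t)
        clients[kind] = _WireRecorderClient(Connector(host, listener.port))
        engines[kind].log_initial_controls(clients[kind])

    errors: list[str] = []

    def _engine_loop(kind: str) -> None:
        engine = engines[kind]
        node = ring[kind]
        saver = clients.get(kind)
        try:
            for k in range(n_frames):
                if kind == "acquisition":
                    upstream = make_bundle([], 0) if k == 0 else node.recv()
                else:
                    upstream = node.recv()
                out = engine.process(upstream, k, saver)
                node.send(out)
            if kind == "acquisition" and n_frames > 0:
                node.recv()  # drain the final feedback so the ring closes cleanly
        except Exception as exc:  # pragma: no cover - surfaced to the caller
            errors.append(f"{kind}: {exc!r}")
        finally:
            if saver is not None:
                saver.finish()

    threads = [
        threading.Thread(target=_engine_loop, args=(kind,), daemon=True)
        for kind in ENGINE_KINDS
    ]
    for t in threads:
        t.start()
    for t in threads:
        t.join(timeout=120)
    for t in saver_threads:
        t.join(timeout=30)
    ring.close()
    for listener in saver_listeners.values():
        listener.close()
    if recorder is not None:
        recorder.close_run()
    return errors
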