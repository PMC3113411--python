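"""Session recording: FIFO save queue, per-run HDF5 files, MAT export, replay.

One run file is written per experimental run; suspending or stopping the
system closes it, and resuming opens a new one.  Within a file, each engine's
data splits into two groups:

* ``sampled`` variables — values recorded every frame (cursor position,
  features, control signal, ...), stored as per-variable streams;
* ``controls`` — parameters that change rarely (number of targets, decoder
  weights, thresholds); only *changes* are stored, with the initial value
  logged at index 0.

Every stored value is keyed by the packet index of the frame it belongs to,
so streams from different engines align exactly in time and the full system
state can be reconstructed (replayed) offline.  Arrays may change size
between packets; they are stored per-packet (ragged), and the MAT exporter
emits them as cell arrays.

HDF5 layout::

    /header                       (attrs: metadata, engine list, config JSON)
    /<engine>/sampled/<var>/index, values [, shapes]
    /<engine>/controls/<name>/index, values [, shapes]
"""

from __future__ import annotations

import json
import logging
import re
from collections import deque
from dataclasses import dataclass
from typing import Any, Iterator

import h5py
import numpy as np
from scipy.io import savemat

from .core import PacketIndex, ParameterUpdate, VariableBundle, _canon_value

__all__ = [
    "RunMetadata",
    "SaveQueue",
    "RunWriter",
    "Recorder",
    "RunRecord",
    "read_run",
    "export_mat",
    "replay",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunMetadata:
    """Session-level metadata written to every run-file header."""

    subject_id: str
    session_number: int = 1
    investigators: str = ""
    date: str = ""

    def __post_init__(self) -> None:
        if not self.subject_id:
            raise ValueError("subject_id must be non-empty")


class SaveQueue:
    """Bounded FIFO between the real-time path and the recorder.

    Producers never block: beyond capacity the *newest* record is dropped and
    counted (recording loss is logged, never silent).
    """

    def __init__(self, capacity: int = 1024):
        self.capacity = capacity
        self._q: deque = deque()
        self.dropped = 0

    def put(self, item: Any) -> bool:
        if len(self._q) >= self.capacity:
            self.dropped += 1
            if self.dropped in (1, 100, 10000):
                log.warning("save queue overflow; %d records dropped so far", self.dropped)
            return False
        self._q.append(item)
        return True

    def drain(self) -> list:
        out = list(self._q)
        self._q.clear()
        return out

    def __len__(self) -> int:
        return len(self._q)


def _kind_of(value: Any) -> str:
    if isinstance(value, str):
        return "str"
    if isinstance(value, int):
        return "i8"
    if isinstance(value, float):
        return "f8"
    if isinstance(value, np.ndarray):
        return "arr_i8" if value.dtype.kind in "ui" else "arr_f8"
    raise TypeError(f"unsupported recorded value type: {type(value).__name__}")


class _VarStream:
    """Accumulated (index, value) pairs for one variable, fixed kind per run."""

    def __init__(self, kind: str):
        self.kind = kind
        self.indices: list[int] = []
        self.values: list[Any] = []

    def append(self, index: int, value: Any) -> None:
        if _kind_of(value) != self.kind:
            raise TypeError(f"value kind changed mid-run ({self.kind} -> {_kind_of(value)})")
        self.indices.append(index)
        self.values.append(value)


def _write_stream(group: h5py.Group, name: str, stream: _VarStream) -> None:
    g = group.create_group(name)
    g.attrs["kind"] = stream.kind
    order = np.argsort(np.asarray(stream.indices, dtype=np.int64), kind="stable")
    idx = np.asarray(stream.indices, dtype=np.int64)[order]
    vals = [stream.values[i] for i in order]
    g.create_dataset("index", data=idx, track_times=False)
    if stream.kind in ("f8", "i8"):
        dt = np.float64 if stream.kind == "f8" else np.int64
        g.create_dataset("values", data=np.asarray(vals, dtype=dt), track_times=False)
    elif stream.kind == "str":
        g.create_dataset(
            "values", data=vals, dtype=h5py.string_dtype("utf-8"), track_times=False
        )
    else:
        dt = np.float64 if stream.kind == "arr_f8" else np.int64
        flat = g.create_dataset(
            "values", (len(vals),), dtype=h5py.vlen_dtype(dt), track_times=False
        )
        shapes = g.create_dataset(
            "shapes", (len(vals),), dtype=h5py.vlen_dtype(np.int64), track_times=False
        )
        for i, v in enumerate(vals):
            flat[i] = np.asarray(v, dtype=dt).reshape(-1)
            shapes[i] = np.asarray(np.shape(v), dtype=np.int64)


class RunWriter:
    """Accumulates one run in memory and writes a consistent HDF5 file on close.

    Records may arrive out of order over the network; streams are index-sorted
    when the file is finalized.
    """

    def __init__(
        self,
        path,
        metadata: RunMetadata,
        engine_names: list[str] | None = None,
        config_snapshot: dict | None = None,
    ):
        self.path = str(path)
        self.metadata = metadata
        self.engine_names = list(engine_names or [])
        self.config_snapshot = config_snapshot or {}
        self._sampled: dict[str, dict[str, _VarStream]] = {}
        self._controls: dict[str, dict[str, _VarStream]] = {}
        self.closed = False
        self.partial = False

    def _check_open(self) -> None:
        if self.closed:
            raise ValueError("run file already closed")

    def record_sampled(self, engine: str, bundle: VariableBundle) -> None:
        self._check_open()
        streams = self._sampled.setdefault(engine, {})
        for name, value in bundle.items():
            stream = streams.get(name)
            if stream is None:
                stream = streams[name] = _VarStream(_kind_of(value))
            stream.append(bundle.index, value)

    def record_control(self, engine: str, update: ParameterUpdate) -> None:
        self._check_open()
        streams = self._controls.setdefault(engine, {})
        value = _canon_value(update.value)
        stream = streams.get(update.name)
        if stream is None:
            stream = streams[update.name] = _VarStream(_kind_of(value))
        stream.append(update.applied_at, value)

    def close(self) -> str:
        self._check_open()
        self.closed = True
        with h5py.File(self.path, "w", track_order=True) as h5:
            header = h5.create_group("header")
            header.attrs["subject_id"] = self.metadata.subject_id
            header.attrs["session_number"] = self.metadata.session_number
            header.attrs["investigators"] = self.metadata.investigators
            header.attrs["date"] = self.metadata.date
            header.attrs["engines"] = json.dumps(self.engine_names)
            header.attrs["config"] = json.dumps(self.config_snapshot, sort_keys=True)
            header.attrs["partial"] = self.partial
            engines = set(self._sampled) | set(self._controls)
            for engine in sorted(engines):
                eg = h5.create_group(engine)
                sg = eg.create_group("sampled")
                for name, stream in sorted(self._sampled.get(engine, {}).items()):
                    _write_stream(sg, name, stream)
                cg = eg.create_group("controls")
                for name, stream in sorted(self._controls.get(engine, {}).items()):
                    _write_stream(cg, name, stream)
        return self.path


class Recorder:
    """Run-file manager surviving suspend/resume.

    While no run is open, incoming records are buffered in a bounded FIFO
    (capacity 1024, drop-with-counter beyond) and flushed into the next run.
    """

    def __init__(self) -> None:
        self._writer: RunWriter | None = None
        self._pending = SaveQueue()

    @property
    def writer(self) -> RunWriter | None:
        return self._writer

    @property
    def dropped(self) -> int:
        return self._pending.dropped

    def open_run(
        self,
        path,
        metadata: RunMetadata,
        engine_names: list[str] | None = None,
        config_snapshot: dict | None = None,
    ) -> RunWriter:
        if self._writer is not None and not self._writer.closed:
            raise ValueError("a run is already open")
        self._writer = RunWriter(path, metadata, engine_names, config_snapshot)
        for kind, engine, payload in self._pending.drain():
            if kind == "sampled":
                self._writer.record_sampled(engine, payload)
            else:
                self._writer.record_control(engine, payload)
        return self._writer

    def record_sampled(self, engine: str, bundle: VariableBundle) -> None:
        if self._writer is None or self._writer.closed:
            self._pending.put(("sampled", engine, bundle))
            return
        self._writer.record_sampled(engine, bundle)

    def record_control(self, engine: str, update: ParameterUpdate) -> None:
        if self._writer is None or self._writer.closed:
            self._pending.put(("control", engine, update))
            return
        self._writer.record_control(engine, update)

    def close_run(self) -> str | None:
        """Drain and finalize the current run file; idempotent."""
        if self._writer is None or self._writer.closed:
            return None
        return self._writer.close()


# --------------------------------------------------------------------------
# reading, export, replay


@dataclass
class RunRecord:
    """An in-memory run: header plus per-engine sampled and control streams.

    Streams are ``{engine: {var: (index_array, [values...])}}`` with values in
    index order.
    """

    header: dict
    sampled: dict
    controls: dict

    def engines(self) -> list[str]:
        return sorted(set(self.sampled) | set(self.controls))


def _read_stream(g: h5py.Group) -> tuple[np.ndarray, list]:
    kind = g.attrs["kind"]
    idx = g["index"][...].astype(np.int64)
    if kind in ("f8", "i8"):
        vals = list(g["values"][...])
        vals = [float(v) if kind == "f8" else int(v) for v in vals]
    elif kind == "str":
        vals = [v.decode() if isinstance(v, bytes) else str(v) for v in g["values"][...]]
    else:
        dt = np.float64 if kind == "arr_f8" else np.int64
        vals = [
            np.asarray(flat, dtype=dt).reshape(tuple(shape.astype(int)))
            for flat, shape in zip(g["values"][...], g["shapes"][...])
        ]
    return idx, vals


def read_run(path) -> RunRecord:
    """Load a run file back into memory."""
    with h5py.File(path, "r") as h5:
        header = {k: v for k, v in h5["header"].attrs.items()}
        header["engines"] = json.loads(header.get("engines", "[]"))
        header["config"] = json.loads(header.get("config", "{}"))
        sampled: dict = {}
        controls: dict = {}
        for engine in h5:
            if engine == "header":
                continue
            for group_name, dest in (("sampled", sampled), ("controls", controls)):
                grp = h5[engine].get(group_name)
                if grp is None:
                    continue
                dest[engine] = {name: _read_stream(grp[name]) for name in grp}
    return RunRecord(header=header, sampled=sampled, controls=controls)


def _mat_name(name: str) -> str:
    clean = re.sub(r"\W", "_", name)
    return clean if clean and not clean[0].isdigit() else "v_" + clean


def export_mat(run_path, mat_path=None) -> str:
    """Convert a run file to MAT v5: per engine, ``sampled`` and ``controls``
    structs whose fields carry a value array (cell-style for ragged arrays)
    and the packet-number index array."""
    record = read_run(run_path)
    mat_path = str(mat_path or re.sub(r"\.h5$", "", str(run_path)) + ".mat")
    out: dict = {
        "header": {
            _mat_name(k): (json.dumps(v) if isinstance(v, (dict, list)) else v)
            for k, v in record.header.items()
        }
    }
    for engine in record.engines():
        eng: dict = {}
        for group_name, source in (("sampled", record.sampled), ("controls", record.controls)):
            grp: dict = {}
            for name, (idx, vals) in source.get(engine, {}).items():
                if vals and isinstance(vals[0], np.ndarray):
                    cell = np.empty(len(vals), dtype=object)
                    for i, v in enumerate(vals):
                        cell[i] = v
                    packed: Any = cell
                elif vals and isinstance(vals[0], str):
                    cell = np.empty(len(vals), dtype=object)
                    cell[:] = vals
                    packed = cell
                else:
                    packed = np.asarray(vals)
                grp[_mat_name(name)] = {"index": idx, "values": packed}
            eng[group_name] = grp or {"empty": True}
        out[_mat_name(engine)] = eng
    savemat(mat_path, out, long_field_names=True)
    return mat_path


def stream_fingerprint(record: RunRecord) -> dict:
    """Canonical byte representation of every sampled-variable stream.

    Two runs are byte-identical in their sampled data iff their fingerprints
    are equal — the determinism check for repeated seeded runs.
    """
    out: dict = {}
    for engine, streams in sorted(record.sampled.items()):
        for name, (idx, vals) in sorted(streams.items()):
            if vals and isinstance(vals[0], str):
                payload = "|".join(vals).encode()
            else:
                payload = b"".join(
                    np.atleast_1d(np.asarray(v)).tobytes() for v in vals
                )
            out[f"{engine}/{name}"] = (tuple(int(i) for i in idx), payload)
    return out


def replay(run_path) -> Iterator[tuple[PacketIndex, dict, dict]]:
    """Frame-by-frame reconstruction of a recorded run.

    Yields ``(index, sampled, controls)`` per packet index present in the
    file: ``sampled`` maps ``"engine/var"`` to that frame's value, and
    ``controls`` maps ``"engine/name"`` to the value in effect at that frame
    (piecewise-constant from the change log).  Gaps in the index sequence are
    logged as warnings.
    """
    record = read_run(run_path)
    all_indices: set[int] = set()
    for streams in record.sampled.values():
        for idx, _ in streams.values():
            all_indices.update(int(i) for i in idx)
    if not all_indices:
        return
    ordered = sorted(all_indices)
    for a, b in zip(ordered, ordered[1:]):
        if b != a + 1:
            log.warning("replay: packet index gap %d -> %d", a, b)
    # controls as sorted change lists with cursors
    control_streams = {
        f"{engine}/{name}": (idx, vals)
        for engine, streams in record.controls.items()
        for name, (idx, vals) in streams.items()
    }
    sample_lookup = {
        f"{engine}/{name}": (idx, vals, {int(i): pos for pos, i in enumerate(idx)})
        for engine, streams in record.sampled.items()
        for name, (idx, vals) in streams.items()
    }
    cursors = {key: -1 for key in control_streams}
    current_controls: dict[str, Any] = {}
    for frame in ordered:
        for key, (idx, vals) in control_streams.items():
            cur = cursors[key]
            while cur + 1 < len(idx) and idx[cur + 1] <= frame:
                cur += 1
            cursors[key] = cur
            if cur >= 0:
                current_controls[key] = vals[cur]
        sampled = {
            key: vals[pos[frame]]
            for key, (idx, vals, pos) in sample_lookup.items()
            if frame in pos
        }
        yield frame, sampled, dict(current_controls)
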