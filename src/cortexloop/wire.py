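"""Wire protocol: bundle serialization and the self-establishing TCP links.

Every message on every link is one encoded :class:`~cortexloop.core.VariableBundle`.
The codec is binary, little-endian and self-describing — the decoder needs no
schema.  Layout (protocol version 1)::

    u32  length of the remainder of the message (bytes after this field)
    u8   protocol version (= 1)
    u64  packet index
    u16  item count
    per item:
        u16  name length (bytes)         name  (utf-8)
        u8   type tag                    u8    rank
        u32 × rank   dims
        payload (little-endian)

Type tags: 0 float64 scalar, 1 int64 scalar, 2 utf-8 text (rank 1, dims[0] =
byte count), 3 float64 array, 4 int64 array.  Arrays are C-order.

Inter-engine links form a closed ring (acquisition → signal processing →
application → acquisition); the visualization channel and the recorder hang
off point links.  All links are TCP with small-packet coalescing (Nagle's
algorithm) disabled — latency matters, bandwidth does not — and batching is
done at the application layer instead: one message per frame per link.
Links self-repair: a dropped connection is re-established with exponential
backoff capped at 2 s, and the in-flight frame is re-sent (receivers treat
frames as idempotent by packet index).
"""

from __future__ import annotations

import socket
import struct
import threading
import time
from dataclasses import dataclass

import numpy as np

from .core import PacketIndex, VariableBundle

__all__ = [
    "PROTOCOL_VERSION",
    "NeedMoreBytes",
    "FramingError",
    "encode_bundle",
    "decode_bundle",
    "StreamDecoder",
    "match_items",
    "LinkConfig",
    "RingTopology",
    "Listener",
    "Connector",
    "RingNode",
    "establish_ring",
]

PROTOCOL_VERSION = 1

_TAG_F8 = 0
_TAG_I8 = 1
_TAG_STR = 2
_TAG_F8_ARR = 3
_TAG_I8_ARR = 4

_HEAD = struct.Struct("<I")          # message length prefix
_FIXED = struct.Struct("<BQH")       # version, index, item count
_ITEM_HEAD = struct.Struct("<H")     # name length
_TYPE_RANK = struct.Struct("<BB")


class NeedMoreBytes(Exception):
    """Raised on a truncated message; ``missing`` says how many bytes are needed."""

    def __init__(self, missing: int):
        super().__init__(f"need {missing} more bytes")
        self.missing = missing


class FramingError(Exception):
    """Raised on a corrupted message header; carries the byte offset of the fault."""

    def __init__(self, offset: int, reason: str):
        super().__init__(f"framing error at byte {offset}: {reason}")
        self.offset = offset


def encode_bundle(bundle: VariableBundle) -> bytes:
    """Serialize a bundle to one length-prefixed, self-describing message."""
    parts: list[bytes] = []
    for name, value in bundle.items():
        name_b = name.encode("utf-8")
        parts.append(_ITEM_HEAD.pack(len(name_b)))
        parts.append(name_b)
        if isinstance(value, str):
            payload = value.encode("utf-8")
            parts.append(_TYPE_RANK.pack(_TAG_STR, 1))
            parts.append(struct.pack("<I", len(payload)))
            parts.append(payload)
        elif isinstance(value, int):
            parts.append(_TYPE_RANK.pack(_TAG_I8, 0))
            parts.append(struct.pack("<q", value))
        elif isinstance(value, float):
            parts.append(_TYPE_RANK.pack(_TAG_F8, 0))
            parts.append(struct.pack("<d", value))
        elif isinstance(value, np.ndarray):
            if value.dtype == np.float64:
                tag = _TAG_F8_ARR
            elif value.dtype == np.int64:
                tag = _TAG_I8_ARR
            else:
                raise TypeError(f"unsupported array dtype for item {name!r}: {value.dtype}")
            parts.append(_TYPE_RANK.pack(tag, value.ndim))
            parts.append(struct.pack(f"<{value.ndim}I", *value.shape))
            parts.append(np.ascontiguousarray(value).astype("<" + value.dtype.str[1:]).tobytes())
        else:
            raise TypeError(f"unsupported value kind for item {name!r}: {type(value).__name__}")
    body = _FIXED.pack(PROTOCOL_VERSION, bundle.index, len(bundle)) + b"".join(parts)
    return _HEAD.pack(len(body)) + body


def decode_bundle(data: bytes | bytearray | memoryview) -> tuple[VariableBundle, int]:
    """Decode one bundle from the head of ``data``.

    Returns ``(bundle, bytes_consumed)``.  On partial input raises
    :class:`NeedMoreBytes` with the number of additional bytes required, so a
    stream reader can wait rather than fail.
    """
    buf = memoryview(bytes(data))
    if len(buf) < _HEAD.size:
        raise NeedMoreBytes(_HEAD.size - len(buf))
    (body_len,) = _HEAD.unpack_from(buf, 0)
    total = _HEAD.size + body_len
    if len(buf) < total:
        raise NeedMoreBytes(total - len(buf))
    if body_len < _FIXED.size:
        raise FramingError(0, f"message body too short ({body_len} bytes)")
    off = _HEAD.size
    version, index, n_items = _FIXED.unpack_from(buf, off)
    if version != PROTOCOL_VERSION:
        raise FramingError(off, f"unknown protocol version {version}")
    off += _FIXED.size
    bundle = VariableBundle(index=int(index))
    for _ in range(n_items):
        if off + _ITEM_HEAD.size > total:
            raise FramingError(off, "item header overruns message")
        (name_len,) = _ITEM_HEAD.unpack_from(buf, off)
        off += _ITEM_HEAD.size
        if off + name_len + _TYPE_RANK.size > total:
            raise FramingError(off, "item name overruns message")
        name = bytes(buf[off : off + name_len]).decode("utf-8")
        off += name_len
        tag, rank = _TYPE_RANK.unpack_from(buf, off)
        off += _TYPE_RANK.size
        if off + 4 * rank > total:
            raise FramingError(off, "item dims overrun message")
        dims = struct.unpack_from(f"<{rank}I", buf, off)
        off += 4 * rank
        if tag == _TAG_F8:
            value: object = struct.unpack_from("<d", buf, off)[0]
            off += 8
        elif tag == _TAG_I8:
            value = struct.unpack_from("<q", buf, off)[0]
            off += 8
        elif tag == _TAG_STR:
            (n_bytes,) = dims
            if off + n_bytes > total:
                raise FramingError(off, "string payload overruns message")
            value = bytes(buf[off : off + n_bytes]).decode("utf-8")
            off += n_bytes
        elif tag in (_TAG_F8_ARR, _TAG_I8_ARR):
            count = int(np.prod(dims, dtype=np.int64)) if rank else 1
            n_bytes = 8 * count
            if off + n_bytes > total:
                raise FramingError(off, "array payload overruns message")
            dt = "<f8" if tag == _TAG_F8_ARR else "<i8"
            value = np.frombuffer(buf, dtype=dt, count=count, offset=off).reshape(dims).copy()
            if tag == _TAG_I8_ARR:
                value = value.astype(np.int64)
            off += n_bytes
        else:
            raise FramingError(off - _TYPE_RANK.size, f"unknown type tag {tag}")
        bundle.append(name, value)
    if off != total:
        raise FramingError(off, "trailing bytes inside message")
    return bundle, total


class StreamDecoder:
    """Incremental decoder: feed raw stream chunks, pull complete bundles in order."""

    def __init__(self) -> None:
        self._buf = bytearray()

    def feed(self, chunk: bytes) -> list[VariableBundle]:
        self._buf.extend(chunk)
        out: list[VariableBundle] = []
        while True:
            try:
                bundle, used = decode_bundle(self._buf)
            except NeedMoreBytes:
                break
            del self._buf[:used]
            out.append(bundle)
        return out

    @property
    def pending_bytes(self) -> int:
        return len(self._buf)


def match_items(local: dict, bundle: VariableBundle) -> tuple[dict, list[str]]:
    """Apply a received bundle to a local variable table, BCI-style name matching.

    Items whose names exist locally overwrite the local value; unknown names
    are retained (added) and reported in the returned ``unmatched`` list.
    """
    unmatched = [name for name, _ in bundle.items() if name not in local]
    updated = dict(local)
    for name, value in bundle.items():
        updated[name] = value
    return updated, unmatched


# --------------------------------------------------------------------------
# TCP links


@dataclass(frozen=True)
class LinkConfig:
    """One endpoint of a link; port 0 asks the OS for an ephemeral port."""

    host: str = "127.0.0.1"
    port: int = 0
    role: str = "ring_downstream"

    def __post_init__(self) -> None:
        if self.port != 0 and not (1024 <= self.port <= 65535):
            raise ValueError(f"port must be 0 (auto) or in [1024, 65535], got {self.port}")
        if self.role not in ("ring_upstream", "ring_downstream", "viz", "saver"):
            raise ValueError(f"unknown link role {self.role!r}")


_BACKOFF_START = 0.05
_BACKOFF_CAP = 2.0


class Listener:
    """Receiving half of a link: accepts one peer at a time, frames bundles.

    If the peer drops, the listener simply accepts the next connection —
    this is the self-repairing property on the receive side.
    """

    def __init__(self, host: str = "127.0.0.1", port: int = 0):
        self._srv = socket.socket(socket.AF_INET, socket.SOCK_STREAM)
        self._srv.setsockopt(socket.SOL_SOCKET, socket.SO_REUSEADDR, 1)
        self._srv.bind((host, port))
        self._srv.listen(4)
        self.host, self.port = self._srv.getsockname()[:2]
        self._conn: socket.socket | None = None
        self._decoder = StreamDecoder()
        self._ready: list[VariableBundle] = []
        self._closed = False

    def _accept(self, timeout: float | None) -> None:
        self._srv.settimeout(timeout)
        conn, _ = self._srv.accept()
        conn.setsockopt(socket.IPPROTO_TCP, socket.TCP_NODELAY, 1)
        self._conn = conn
        self._decoder = StreamDecoder()

    def recv_bundle(self, timeout: float | None = 10.0) -> VariableBundle:
        """Block until one complete bundle arrives (re-accepting if the peer dropped)."""
        deadline = None if timeout is None else time.monotonic() + timeout
        while True:
            if self._ready:
                return self._ready.pop(0)
            if self._closed:
                raise ConnectionError("listener closed")
            remaining = None if deadline is None else max(0.0, deadline - time.monotonic())
            if self._conn is None:
                self._accept(remaining)
                continue
            self._conn.settimeout(remaining)
            try:
                chunk = self._conn.recv(65536)
            except socket.timeout:
                raise TimeoutError("recv_bundle timed out") from None
            if not chunk:  # peer closed; await reconnect
                self._conn.close()
                self._conn = None
                continue
            self._ready.extend(self._decoder.feed(chunk))

    def close(self) -> None:
        self._closed = True
        if self._conn is not None:
            self._conn.close()
            self._conn = None
        self._srv.close()


class Connector:
    """Sending half of a link: connects (with capped exponential backoff),
    disables Nagle coalescing, and re-sends the in-flight frame after a drop."""

    def __init__(self, host: str, port: int):
        self.host, self.port = host, port
        self._sock: socket.socket | None = None
        self._lock = threading.Lock()

    def _connect(self, timeout: float) -> None:
        deadline = time.monotonic() + timeout
        backoff = _BACKOFF_START
        while True:
            try:
                sock = socket.create_connection((self.host, self.port), timeout=1.0)
                sock.setsockopt(socket.IPPROTO_TCP, socket.TCP_NODELAY, 1)
                self._sock = sock
                return
            except OSError:
                if time.monotonic() + backoff > deadline:
                    raise ConnectionError(
                        f"could not reach {self.host}:{self.port} within {timeout:.1f}s"
                    ) from None
                time.sleep(backoff)
                backoff = min(backoff * 2, _BACKOFF_CAP)

    def send_bundle(self, bundle: VariableBundle, timeout: float = 10.0) -> None:
        payload = encode_bundle(bundle)
        with self._lock:
            for attempt in (0, 1):
                if self._sock is None:
                    self._connect(timeout)
                try:
                    self._sock.sendall(payload)
                    return
                except OSError:
                    # drop + reconnect once, re-sending the in-flight frame;
                    # receivers dedupe by packet index
                    self._sock.close()
                    self._sock = None
                    if attempt:
                        raise

    def close(self) -> None:
        with self._lock:
            if self._sock is not None:
                self._sock.close()
                self._sock = None


@dataclass(frozen=True)
class RingTopology:
    """The closed three-engine cycle: acquisition → signal_processing → application → acquisition."""

    acquisition: LinkConfig
    signal_processing: LinkConfig
    application: LinkConfig

    ORDER = ("acquisition", "signal_processing", "application")

    def endpoint(self, kind: str) -> LinkConfig:
        return getattr(self, kind)

    def downstream_of(self, kind: str) -> str:
        i = self.ORDER.index(kind)
        return self.ORDER[(i + 1) % 3]


class RingNode:
    """One engine's seat on the ring: an upstream listener and a downstream connector."""

    def __init__(self, kind: str, upstream: Listener, downstream: Connector):
        self.kind = kind
        self.upstream = upstream
        self.downstream = downstream
        self._last_index: PacketIndex | None = None

    def send(self, bundle: VariableBundle) -> None:
        self.downstream.send_bundle(bundle)

    def recv(self, timeout: float | None = 10.0) -> VariableBundle:
        """Receive the next bundle, deduplicating re-sent frames by packet index."""
        while True:
            bundle = self.upstream.recv_bundle(timeout)
            if self._last_index is not None and bundle.index == self._last_index:
                continue  # duplicate after a reconnect re-send
            self._last_index = bundle.index
            return bundle

    def close(self) -> None:
        self.upstream.close()
        self.downstream.close()


class Ring:
    """Handle over the three connected ring nodes, keyed by engine kind."""

    def __init__(self, nodes: dict[str, RingNode]):
        self.nodes = nodes

    def __getitem__(self, kind: str) -> RingNode:
        return self.nodes[kind]

    def close(self) -> None:
        for node in self.nodes.values():
            node.close()


def establish_ring(topology: RingTopology, connect_timeout: float = 10.0) -> Ring:
    """Bind all three listeners, then close the cycle with three connectors.

    Endpoints with port 0 get OS-assigned ephemeral ports (ports are
    auto-selected; the only required input is each engine's address).
    """
    listeners = {
        kind: Listener(topology.endpoint(kind).host, topology.endpoint(kind).port)
        for kind in RingTopology.ORDER
    }
    nodes: dict[str, RingNode] = {}
    for kind in RingTopology.ORDER:
        nxt = topology.downstream_of(kind)
        conn = Connector(listeners[nxt].host, listeners[nxt].port)
        conn._connect(connect_timeout)
        nodes[kind] = RingNode(kind, listeners[kind], conn)
    return Ring(nodes)
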