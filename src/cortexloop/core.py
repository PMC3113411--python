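"""Core domain types shared by every stage of the processing ring.

The unit of time in the system is the acquisition *frame* (one block of
multichannel samples, 33.3 ms by default).  Frames are counted by a packet
index — a non-negative integer that increases by exactly 1 per frame within a
run — and every value that crosses an engine boundary or reaches disk carries
exactly one packet index, which is what makes offline reconstruction of the
full system state possible.

Conventions used throughout the package: times in seconds, frequencies in Hz,
angles in radians measured counter-clockwise from screen-right, screen origin
at the center of the workspace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Iterable, Iterator

import numpy as np

__all__ = [
    "PacketIndex",
    "SignalBlock",
    "FeatureMatrix",
    "ControlSignal",
    "ParameterUpdate",
    "VariableBundle",
    "make_bundle",
    "check_index",
]

#: Packet index type — a plain non-negative int, counted from 0 per run.
PacketIndex = int


def check_index(index: int) -> int:
    """Validate a packet index (non-negative integer)."""
    if not isinstance(index, (int, np.integer)) or isinstance(index, bool):
        raise TypeError(f"packet index must be an integer, got {type(index).__name__}")
    if index < 0:
        raise ValueError(f"packet index must be non-negative, got {index}")
    return int(index)


@dataclass(frozen=True)
class SignalBlock:
    """One frame of raw time-domain data, ``data[channel, sample]`` in microvolts."""

    data: np.ndarray
    sample_rate: float
    index: PacketIndex

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError("SignalBlock.data must be 2-D [n_channels, n_samples]")
        if data.shape[0] < 1:
            raise ValueError("SignalBlock needs at least one channel")
        if not np.all(np.isfinite(data)):
            raise ValueError("SignalBlock.data contains non-finite values")
        object.__setattr__(self, "data", data)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        object.__setattr__(self, "index", check_index(self.index))

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-frame band-power features, ``power[channel, band]``.

    ``band_edges`` has length ``n_bands + 1`` and is strictly increasing.
    Raw band power is non-negative; after pseudo-Z normalization values may be
    any real number.
    """

    power: np.ndarray
    band_edges: np.ndarray
    window_s: float
    index: PacketIndex

    def __post_init__(self) -> None:
        power = np.asarray(self.power, dtype=np.float64)
        edges = np.asarray(self.band_edges, dtype=np.float64)
        if power.ndim != 2:
            raise ValueError("FeatureMatrix.power must be 2-D [n_channels, n_bands]")
        if edges.ndim != 1 or edges.size != power.shape[1] + 1:
            raise ValueError("band_edges must have length n_bands + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("band_edges must be strictly increasing")
        object.__setattr__(self, "power", power)
        object.__setattr__(self, "band_edges", edges)
        object.__setattr__(self, "index", check_index(self.index))

    @property
    def n_channels(self) -> int:
        return self.power.shape[0]

    @property
    def n_bands(self) -> int:
        return self.power.shape[1]

    def flatten(self) -> np.ndarray:
        """Channel-major flat feature vector (channel 0 bands, channel 1 bands, ...)."""
        return self.power.reshape(-1)


@dataclass(frozen=True)
class ControlSignal:
    """A decoded velocity command in screen-units per second (1-, 2- or 3-D)."""

    velocity: np.ndarray
    index: PacketIndex

    def __post_init__(self) -> None:
        v = np.atleast_1d(np.asarray(self.velocity, dtype=np.float64))
        if v.ndim != 1 or v.size not in (1, 2, 3):
            raise ValueError("ControlSignal.velocity must be a vector of length 1, 2 or 3")
        if not np.all(np.isfinite(v)):
            raise ValueError("ControlSignal.velocity must be finite")
        object.__setattr__(self, "velocity", v)
        object.__setattr__(self, "index", check_index(self.index))

    @property
    def dim(self) -> int:
        return self.velocity.size


@dataclass(frozen=True)
class ParameterUpdate:
    """A change to a live engine parameter, stamped with the first frame that saw it."""

    name: str
    value: Any
    applied_at: PacketIndex


# value kinds allowed inside a bundle: float/int scalars, text, numeric arrays
BundleValue = Any


def _canon_value(value: Any) -> Any:
    """Canonicalize a bundle value: python scalars stay, sequences become float/int arrays."""
    if isinstance(value, str):
        return value
    if isinstance(value, bool):
        return int(value)
    if isinstance(value, (int, np.integer)):
        return int(value)
    if isinstance(value, (float, np.floating)):
        return float(value)
    arr = np.asarray(value)
    if arr.dtype.kind in "ui":
        return arr.astype(np.int64)
    if arr.dtype.kind in "fb":
        return arr.astype(np.float64)
    raise TypeError(f"unsupported bundle value kind: {arr.dtype}")


def _values_equal(a: Any, b: Any) -> bool:
    if isinstance(a, str) or isinstance(b, str):
        return a == b
    a_arr, b_arr = np.asarray(a), np.asarray(b)
    return a_arr.shape == b_arr.shape and bool(np.array_equal(a_arr, b_arr))


class VariableBundle:
    """An ordered, uniquely-named collection of values plus one packet index.

    The bundle is the single unit of traffic everywhere: between engines on the
    ring, towards the visualization channel, and towards the recorder.  All
    variables an engine sends in a frame travel in one bundle (one message per
    frame per link), and arrays may change size from packet to packet.
    """

    __slots__ = ("_names", "_values", "index")

    def __init__(self, pairs: Iterable[tuple[str, BundleValue]] = (), index: PacketIndex = 0):
        self._names: list[str] = []
        self._values: dict[str, BundleValue] = {}
        self.index: PacketIndex = check_index(index)
        for name, value in pairs:
            self.append(name, value)

    def append(self, name: str, value: BundleValue) -> None:
        if not isinstance(name, str) or not name:
            raise ValueError("bundle item names must be non-empty strings")
        if name in self._values:
            raise ValueError(f"duplicate name in bundle: {name!r}")
        self._names.append(name)
        self._values[name] = _canon_value(value)

    def __contains__(self, name: str) -> bool:
        return name in self._values

    def __getitem__(self, name: str) -> BundleValue:
        return self._values[name]

    def get(self, name: str, default: Any = None) -> BundleValue:
        return self._values.get(name, default)

    def names(self) -> list[str]:
        return list(self._names)

    def items(self) -> Iterator[tuple[str, BundleValue]]:
        for name in self._names:
            yield name, self._values[name]

    def __len__(self) -> int:
        return len(self._names)

    def __eq__(self, other: object) -> bool:
        """Structural equality: same names, same order, same index, identical values."""
        if not isinstance(other, VariableBundle):
            return NotImplemented
        if self.index != other.index or self._names != other._names:
            return False
        return all(_values_equal(self._values[n], other._values[n]) for n in self._names)

    def __repr__(self) -> str:
        inner = ", ".join(self._names)
        return f"VariableBundle(index={self.index}, items=[{inner}])"


def make_bundle(pairs: Iterable[tuple[str, BundleValue]], index: PacketIndex) -> VariableBundle:
    """Build a bundle from name–value pairs, preserving order; duplicate names are rejected."""
    return VariableBundle(pairs, index)
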