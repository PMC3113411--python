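"""Synthetic directionally-tuned ECoG signals and the raw-UDP acquisition source.

The simulator emits, per channel, a pink-noise (1/f power) background whose
high-gamma band (70–120 Hz by default) is amplitude-modulated by the cosine of
the angle between the channel's preferred direction and the current drive
direction (the vector from screen center to the driven cursor/target):

    S = S1 + d * cos(theta - PD) * S2

where S1 is the pink-noise background, S2 is its band-passed high-gamma
component, and d in [0, 1] is the modulation depth.  During baseline the
modulation term is omitted entirely.  Because S2 is the band component of the
same noise process, in-band power scales as (1 + d*cos)^2 — monotone in the
cosine — which gives each channel a single preferred direction recoverable by
linear regression, the property the downstream population-vector decoder
relies on.

Pink noise is produced by streaming white Gaussian noise through a cascade of
first-order pole/zero "pinking" sections (log-spaced, bilinear-transformed),
which keeps generation exactly block-size-invariant: two consecutive 40-sample
frames equal one 80-sample call from the same generator state.
"""

from __future__ import annotations

import logging
import socket
import struct
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core import SignalBlock

__all__ = [
    "PinkNoise",
    "pink_noise",
    "assign_preferred_directions",
    "CursorDrive",
    "SimConfig",
    "SimEcog",
    "encode_udp_frame",
    "parse_udp_frame",
    "UdpReader",
    "UDP_HEADER",
]

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# pink noise


def _pinking_sos(sample_rate: float) -> tuple[np.ndarray, float]:
    """Design the pinking cascade for one sample rate.

    First-order analog sections H(s) = (1 + s/wz) / (1 + s/wp) with poles
    log-spaced over the band of interest and each zero half a spacing above
    its pole, so the cascade falls at ~10 dB/decade (amplitude ~ 1/sqrt(f),
    power ~ 1/f).  Returns (sos, gain) with gain normalizing the output of
    unit-variance white input to unit variance.
    """
    f_lo, f_hi = 0.4, 0.45 * sample_rate
    per_decade = 3
    n_dec = np.log10(f_hi / f_lo)
    n_sections = int(np.ceil(per_decade * n_dec))
    ratio = (f_hi / f_lo) ** (1.0 / n_sections)
    fp = f_lo * ratio ** np.arange(n_sections)
    fz = fp * np.sqrt(ratio)
    first_order = []
    for p, z in zip(fp, fz):
        wp, wz = 2 * np.pi * p, 2 * np.pi * z
        b, a = signal.bilinear([1.0 / wz, 1.0], [1.0 / wp, 1.0], fs=sample_rate)
        first_order.append((b, a))
    # pair first-order sections into biquads for sosfilt
    sos_rows = []
    for i in range(0, len(first_order) - 1, 2):
        b1, a1 = first_order[i]
        b2, a2 = first_order[i + 1]
        sos_rows.append(np.concatenate([np.convolve(b1, b2), np.convolve(a1, a2)]))
    if len(first_order) % 2:
        b1, a1 = first_order[-1]
        sos_rows.append(np.concatenate([[*b1, 0.0], [*a1, 0.0]]))
    sos = np.asarray(sos_rows, dtype=np.float64)
    # unit-variance normalization from impulse-response energy
    impulse = np.zeros(1 << 16)
    impulse[0] = 1.0
    energy = float(np.sum(signal.sosfilt(sos, impulse) ** 2))
    return sos, 1.0 / np.sqrt(energy)


_SOS_CACHE: dict[float, tuple[np.ndarray, float]] = {}


def _get_pinking_sos(sample_rate: float) -> tuple[np.ndarray, float]:
    if sample_rate not in _SOS_CACHE:
        _SOS_CACHE[sample_rate] = _pinking_sos(sample_rate)
    return _SOS_CACHE[sample_rate]


class PinkNoise:
    """Streaming multichannel pink-noise generator with persistent filter state.

    ``generate(n)`` returns an ``(n_channels, n)`` block; successive calls are
    sample-continuous (identical to one longer call from the same state).
    """

    def __init__(self, sample_rate: float, n_channels: int = 1, seed=0):
        if n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        self.sample_rate = float(sample_rate)
        self.n_channels = int(n_channels)
        self._rng = np.random.default_rng(seed)
        self._sos, self._gain = _get_pinking_sos(self.sample_rate)
        self._zi = np.zeros((self._sos.shape[0], self.n_channels, 2))

    def generate(self, n_samples: int) -> np.ndarray:
        if n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        # drawn as (samples, channels) so streaming calls concatenate per channel
        white = self._rng.standard_normal((int(n_samples), self.n_channels)).T
        out, self._zi = signal.sosfilt(self._sos, white, axis=-1, zi=self._zi)
        return out * self._gain


def pink_noise(n_samples: int, sample_rate: float, seed=0) -> np.ndarray:
    """One single-channel pink-noise series (unit variance, PSD ~ 1/f)."""
    return PinkNoise(sample_rate, 1, seed).generate(n_samples)[0]


def assign_preferred_directions(n: int) -> np.ndarray:
    """n preferred directions uniformly covering the plane: 2*pi*k/n, k = 0..n-1."""
    if n < 1:
        raise ValueError("need at least one channel")
    return 2.0 * np.pi * np.arange(n) / n


# --------------------------------------------------------------------------
# simulator


@dataclass(frozen=True)
class CursorDrive:
    """The direction currently driving modulation (target or cursor direction).

    ``active=False`` is the baseline condition: no high-gamma modulation.
    """

    angle: float = 0.0
    active: bool = False

    def __post_init__(self) -> None:
        if self.active and not np.isfinite(self.angle):
            raise ValueError("drive angle must be finite while active")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the directionally-tuned ECoG simulator.

    ``depth`` is the modulation depth d in [0, 1]; ``mod_band`` the modulated
    band in Hz; ``amplitude_scale`` the per-channel RMS in microvolts.
    Preferred directions default to ``n_channels`` angles uniform over 2D.
    """

    n_channels: int = 32
    sample_rate: float = 1200.0
    mod_band: tuple[float, float] = (70.0, 120.0)
    depth: float = 0.3
    preferred_directions: np.ndarray | None = None
    amplitude_scale: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.depth <= 1.0):
            raise ValueError("depth must be in [0, 1]")
        lo, hi = self.mod_band
        if not (0.0 < lo < hi < self.sample_rate / 2):
            raise ValueError("mod_band must lie inside (0, Nyquist)")
        pds = self.preferred_directions
        if pds is None:
            pds = assign_preferred_directions(self.n_channels)
        else:
            pds = np.asarray(pds, dtype=np.float64)
            if pds.shape != (self.n_channels,):
                raise ValueError("preferred_directions length must match n_channels")
        object.__setattr__(self, "preferred_directions", pds)


class SimEcog:
    """Stateful multichannel simulator emitting consecutive SignalBlocks.

    The band component S2 is extracted with a linear-phase FIR band-pass and
    the background S1 is delayed by the filter's group delay, so the two stay
    phase-aligned sample by sample.  In-band, the output transfer is then
    (1 + d*cos) * S1band: band power scales as (1 + d*cos)^2, monotone in the
    cosine of the angle to the preferred direction — a *directional* tuning
    curve with a single maximum.  (A causal IIR band-pass would rotate S2's
    phase against S1 and destroy the linear modulation term, leaving only the
    even d^2*cos^2 component, which has no preferred direction.)

    Both generators advance every block regardless of drive state or depth,
    so the unmodulated background of a run is independent of the modulation
    schedule: with d = 0 (or drive inactive) the output equals the background
    exactly.
    """

    #: FIR band-pass length; odd, so the group delay (numtaps-1)/2 is integer.
    #: 401 taps at 1200 Hz give a ~10 Hz transition band.
    BP_TAPS = 401

    def __init__(self, cfg: SimConfig):
        self.cfg = cfg
        self._pink = PinkNoise(cfg.sample_rate, cfg.n_channels, seed=cfg.seed)
        self._fir = signal.firwin(
            self.BP_TAPS, list(cfg.mod_band), pass_zero=False, fs=cfg.sample_rate
        )
        self._delay = (self.BP_TAPS - 1) // 2
        self._fir_zi = np.zeros((cfg.n_channels, self.BP_TAPS - 1))
        self._s1_buf = np.zeros((cfg.n_channels, self._delay))
        self._index = 0

    def next_block(self, drive: CursorDrive, n_samples: int) -> SignalBlock:
        """Advance the generators by ``n_samples`` and emit the next SignalBlock."""
        cfg = self.cfg
        raw = self._pink.generate(n_samples)
        s2, self._fir_zi = signal.lfilter(
            self._fir, [1.0], raw, axis=-1, zi=self._fir_zi
        )
        joined = np.concatenate([self._s1_buf, raw], axis=1)
        s1 = joined[:, :n_samples]  # background, delayed to align with s2
        self._s1_buf = joined[:, n_samples:]
        if drive.active and cfg.depth > 0.0:
            gain = cfg.depth * np.cos(drive.angle - cfg.preferred_directions)
            data = s1 + gain[:, None] * s2
        else:
            data = s1
        block = SignalBlock(data * cfg.amplitude_scale, cfg.sample_rate, self._index)
        self._index += 1
        return block

    @property
    def next_index(self) -> int:
        return self._index


# --------------------------------------------------------------------------
# raw UDP binary acquisition source

#: datagram header: u32 frame counter, u16 channel count, u16 samples/channel
UDP_HEADER = struct.Struct("<IHH")


def encode_udp_frame(counter: int, data: np.ndarray) -> bytes:
    """Pack one frame as a datagram: header then channel-major float32 samples."""
    data = np.asarray(data, dtype=np.float32)
    if data.ndim != 2:
        raise ValueError("frame data must be 2-D [channels, samples]")
    return UDP_HEADER.pack(counter, data.shape[0], data.shape[1]) + data.tobytes()


def parse_udp_frame(
    datagram: bytes, n_channels: int, frame_samples: int
) -> tuple[int, np.ndarray]:
    """Parse one datagram; raises ValueError on any dialect violation."""
    if len(datagram) < UDP_HEADER.size:
        raise ValueError("datagram shorter than header")
    counter, ch, ns = UDP_HEADER.unpack_from(datagram)
    if ch != n_channels or ns != frame_samples:
        raise ValueError(f"unexpected geometry {ch}x{ns}, want {n_channels}x{frame_samples}")
    expect = UDP_HEADER.size + 4 * ch * ns
    if len(datagram) != expect:
        raise ValueError(f"datagram length {len(datagram)} != expected {expect}")
    data = np.frombuffer(datagram, dtype="<f4", offset=UDP_HEADER.size).reshape(ch, ns)
    return counter, data.astype(np.float64)


class UdpReader:
    """Receives the binary UDP dialect and yields SignalBlocks.

    Packet indices are assigned by arrival order (0, 1, 2, ...).  Malformed
    datagrams are dropped and counted; gaps in the sender's frame counter are
    logged but do not interrupt the stream.
    """

    def __init__(self, port: int, n_channels: int, sample_rate: float, frame_samples: int,
                 host: str = "127.0.0.1"):
        self.n_channels = n_channels
        self.sample_rate = sample_rate
        self.frame_samples = frame_samples
        self._sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
        self._sock.bind((host, port))
        self.port = self._sock.getsockname()[1]
        self.dropped = 0
        self.gaps = 0
        self._last_counter: int | None = None
        self._index = 0

    def read_block(self, timeout: float = 5.0) -> SignalBlock:
        self._sock.settimeout(timeout)
        while True:
            datagram, _ = self._sock.recvfrom(1 << 20)
            try:
                counter, data = parse_udp_frame(datagram, self.n_channels, self.frame_samples)
            except ValueError as exc:
                self.dropped += 1
                log.warning("dropped malformed datagram: %s", exc)
                continue
            if self._last_counter is not None and counter != self._last_counter + 1:
                self.gaps += 1
                log.warning("frame counter gap: %d -> %d", self._last_counter, counter)
            self._last_counter = counter
            block = SignalBlock(data, self.sample_rate, self._index)
            self._index += 1
            return block

    def close(self) -> None:
        self._sock.close()
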