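import socket
import threading

import numpy as np
import pytest
from scipy import signal as sg

from cortexloop.simulate import (
    CursorDrive,
    PinkNoise,
    SimConfig,
    SimEcog,
    UdpReader,
    assign_preferred_directions,
    encode_udp_frame,
    parse_udp_frame,
    pink_noise,
)

FS = 1200.0


def band_power(x, lo, hi, fs=FS):
    f, p = sg.welch(x, fs=fs, nperseg=1024, axis=-1)
    m = (f >= lo) & (f < hi)
    return p[..., m].sum(axis=-1)


class TestPinkNoise:
    def test_same_seed_identical(self):
        assert np.array_equal(pink_noise(500, FS, seed=4), pink_noise(500, FS, seed=4))

    def test_streaming_blocks_equal_one_call(self):
        g1 = PinkNoise(FS, 3, seed=9)
        chunks = np.concatenate([g1.generate(40) for _ in range(5)], axis=1)
        g2 = PinkNoise(FS, 3, seed=9)
        assert np.array_equal(chunks, g2.generate(200))

    def test_psd_slope_near_minus_one(self):
        x = pink_noise(int(60 * FS), FS, seed=11)
        f, p = sg.welch(x, fs=FS, nperseg=4096)
        m = (f >= 2) & (f <= 300)
        slope = np.polyfit(np.log10(f[m]), np.log10(p[m]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.2)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pink_noise(1, FS)


class TestPreferredDirections:
    def test_four_channels_cardinal(self):
        assert np.allclose(
            assign_preferred_directions(4), [0, np.pi / 2, np.pi, 3 * np.pi / 2]
        )

    def test_32_equally_spaced(self):
        pds = assign_preferred_directions(32)
        assert len(pds) == 32
        assert np.allclose(np.diff(pds), 2 * np.pi / 32)

    def test_single_channel_zero(self):
        assert np.allclose(assign_preferred_directions(1), [0.0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            assign_preferred_directions(0)


class TestSimEcog:
    def test_zero_depth_equals_background(self):
        cfg0 = SimConfig(n_channels=4, depth=0.0, seed=5)
        inactive = SimEcog(SimConfig(n_channels=4, depth=0.7, seed=5))
        modulated = SimEcog(cfg0)
        for _ in range(10):
            a = modulated.next_block(CursorDrive(1.0, True), 40)
            b = inactive.next_block(CursorDrive(1.0, False), 40)
            assert np.array_equal(a.data, b.data)

    def test_orthogonal_drive_leaves_channel_unmodulated(self):
        """cos(pi/2) = 0: a channel driven orthogonally to its PD sees no
        modulation, channel-wise."""
        cfg = SimConfig(n_channels=4, depth=0.8, seed=6)  # PDs at 0, 90, 180, 270 deg
        driven = SimEcog(cfg)
        baseline = SimEcog(cfg)
        a = np.concatenate(
            [driven.next_block(CursorDrive(np.pi / 2, True), 40).data for _ in range(5)],
            axis=1,
        )
        b = np.concatenate(
            [baseline.next_block(CursorDrive(0.0, False), 40).data for _ in range(5)],
            axis=1,
        )
        # channels 0 and 2 (PDs 0 and pi) are orthogonal to the drive at pi/2
        assert np.allclose(a[0], b[0]) and np.allclose(a[2], b[2])
        assert not np.allclose(a[1], b[1])

    def test_band_power_increases_with_depth(self):
        powers = []
        for d in (0.1, 0.3, 0.5):
            sim = SimEcog(SimConfig(n_channels=1, depth=d, seed=13))
            x = np.concatenate(
                [sim.next_block(CursorDrive(0.0, True), 40).data for _ in range(450)],
                axis=1,
            )
            powers.append(band_power(x[0], 70, 120))
        assert powers[0] < powers[1] < powers[2]

    def test_depth_linearity(self):
        """Output at depth d equals background + d * (full modulation - background)."""
        drive = CursorDrive(0.3, True)
        blocks = {}
        for d in (0.0, 0.5, 1.0):
            sim = SimEcog(SimConfig(n_channels=2, depth=d, seed=3))
            blocks[d] = sim.next_block(drive, 80).data
        assert np.allclose(blocks[0.5], blocks[0.0] + 0.5 * (blocks[1.0] - blocks[0.0]))

    def test_indices_consecutive(self):
        sim = SimEcog(SimConfig(n_channels=2, seed=0))
        idx = [sim.next_block(CursorDrive(), 40).index for _ in range(10)]
        assert idx == list(range(10))

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(depth=1.5)


@pytest.mark.timeout(30)
class TestUdpReader:
    def test_ramp_round_trip(self):
        reader = UdpReader(0, n_channels=2, sample_rate=FS, frame_samples=8)
        sender = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
        ramp = np.arange(16.0).reshape(2, 8)
        sender.sendto(encode_udp_frame(0, ramp), ("127.0.0.1", reader.port))
        block = reader.read_block()
        assert np.allclose(block.data, ramp)
        assert block.index == 0
        sender.close()
        reader.close()

    def test_wrong_channel_count_dropped(self):
        reader = UdpReader(0, n_channels=2, sample_rate=FS, frame_samples=8)
        sender = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
        bad = encode_udp_frame(0, np.zeros((3, 8)))
        good = encode_udp_frame(1, np.ones((2, 8)))
        sender.sendto(bad, ("127.0.0.1", reader.port))
        sender.sendto(good, ("127.0.0.1", reader.port))
        block = reader.read_block()
        assert reader.dropped == 1
        assert np.allclose(block.data, 1.0)
        sender.close()
        reader.close()

    def test_many_frames_indexed_by_arrival(self):
        n = 200
        reader = UdpReader(0, n_channels=1, sample_rate=FS, frame_samples=4)
        sender = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)

        def send_all():
            for k in range(n):
                sender.sendto(
                    encode_udp_frame(k, np.full((1, 4), float(k))),
                    ("127.0.0.1", reader.port),
                )

        t = threading.Thread(target=send_all)
        t.start()
        blocks = [reader.read_block() for _ in range(n)]
        t.join()
        assert [b.index for b in blocks] == list(range(n))
        assert reader.gaps == 0
        sender.close()
        reader.close()

    def test_parse_rejects_short_datagram(self):
        with pytest.raises(ValueError):
            parse_udp_frame(b"\x00\x01", 2, 8)
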