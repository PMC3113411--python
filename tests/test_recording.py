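import numpy as np
import pytest

from cortexloop.core import ParameterUpdate, make_bundle
from cortexloop.recording import (
    Recorder,
    RunMetadata,
    RunWriter,
    SaveQueue,
    export_mat,
    read_run,
    replay,
)

META = RunMetadata(subject_id="s1", session_number=2, investigators="ab", date="simulated")


def writer(path):
    return RunWriter(path, META, ["eng"], {"frame_period": 1 / 30})


class TestSaveQueue:
    def test_fifo_order(self):
        q = SaveQueue(capacity=10)
        for i in range(5):
            q.put(i)
        assert q.drain() == list(range(5))

    def test_overflow_drops_with_counter(self):
        q = SaveQueue(capacity=3)
        results = [q.put(i) for i in range(5)]
        assert results == [True, True, True, False, False]
        assert q.dropped == 2


class TestSampledStreams:
    def test_hundred_frames_in_order(self, tmp_path):
        w = writer(tmp_path / "r.h5")
        for k in range(100):
            w.record_sampled("eng", make_bundle([("cursor", np.array([k, -k], float))], k))
        w.close()
        record = read_run(tmp_path / "r.h5")
        idx, vals = record.sampled["eng"]["cursor"]
        assert list(idx) == list(range(100))
        assert np.allclose(vals[7], [7.0, -7.0])

    def test_variable_size_arrays(self, tmp_path):
        w = writer(tmp_path / "r.h5")
        w.record_sampled("eng", make_bundle([("v", np.arange(3.0))], 0))
        w.record_sampled("eng", make_bundle([("v", np.arange(5.0))], 1))
        w.close()
        record = read_run(tmp_path / "r.h5")
        _, vals = record.sampled["eng"]["v"]
        assert vals[0].shape == (3,) and vals[1].shape == (5,)

    def test_out_of_order_arrival_sorted_on_close(self, tmp_path, rng):
        w = writer(tmp_path / "r.h5")
        order = rng.permutation(50)
        for k in order:
            w.record_sampled("eng", make_bundle([("x", float(k))], int(k)))
        w.close()
        idx, vals = read_run(tmp_path / "r.h5").sampled["eng"]["x"]
        assert list(idx) == list(range(50))
        assert vals == [float(k) for k in range(50)]

    def test_closed_writer_rejects(self, tmp_path):
        w = writer(tmp_path / "r.h5")
        w.close()
        with pytest.raises(ValueError):
            w.record_sampled("eng", make_bundle([("x", 1.0)], 0))


class TestControls:
    def test_changes_plus_initial(self, tmp_path):
        w = writer(tmp_path / "r.h5")
        w.record_control("eng", ParameterUpdate("n_targets", 8, 0))
        w.record_control("eng", ParameterUpdate("n_targets", 4, 10))
        w.record_control("eng", ParameterUpdate("n_targets", 2, 50))
        w.close()
        idx, vals = read_run(tmp_path / "r.h5").controls["eng"]["n_targets"]
        assert list(idx) == [0, 10, 50] and vals == [8, 4, 2]

    def test_unchanged_parameter_single_record(self, tmp_path):
        w = writer(tmp_path / "r.h5")
        w.record_control("eng", ParameterUpdate("gain", 1.5, 0))
        w.close()
        idx, vals = read_run(tmp_path / "r.h5").controls["eng"]["gain"]
        assert list(idx) == [0] and vals == [1.5]


class TestRecorderLifecycle:
    def test_empty_run_valid_header_only(self, tmp_path):
        w = writer(tmp_path / "r.h5")
        w.close()
        record = read_run(tmp_path / "r.h5")
        assert record.header["subject_id"] == "s1"
        assert record.sampled == {} and record.controls == {}

    def test_suspend_then_resume_two_files(self, tmp_path):
        rec = Recorder()
        rec.open_run(tmp_path / "a.h5", META)
        rec.record_sampled("eng", make_bundle([("x", 1.0)], 0))
        rec.close_run()
        rec.open_run(tmp_path / "b.h5", META)
        rec.record_sampled("eng", make_bundle([("x", 2.0)], 0))
        rec.close_run()
        a = read_run(tmp_path / "a.h5").sampled["eng"]["x"][1]
        b = read_run(tmp_path / "b.h5").sampled["eng"]["x"][1]
        assert a == [1.0] and b == [2.0]

    def test_records_between_runs_buffered_into_next(self, tmp_path):
        rec = Recorder()
        rec.record_sampled("eng", make_bundle([("x", 9.0)], 3))
        rec.open_run(tmp_path / "a.h5", META)
        rec.close_run()
        idx, vals = read_run(tmp_path / "a.h5").sampled["eng"]["x"]
        assert list(idx) == [3] and vals == [9.0]


class TestExportMat:
    def test_round_trip_values(self, tmp_path):
        from scipy.io import loadmat

        w = writer(tmp_path / "r.h5")
        for k in range(10):
            w.record_sampled("eng", make_bundle([("x", float(k) * 2)], k))
        w.record_control("eng", ParameterUpdate("gain", 1.5, 0))
        w.close()
        mat_path = export_mat(tmp_path / "r.h5")
        m = loadmat(mat_path, simplify_cells=True)
        assert np.allclose(m["eng"]["sampled"]["x"]["values"], np.arange(10) * 2.0)
        assert np.allclose(m["eng"]["sampled"]["x"]["index"], np.arange(10))
        assert m["eng"]["controls"]["gain"]["values"] == 1.5

    def test_ragged_arrays_exported_as_cells(self, tmp_path):
        from scipy.io import loadmat

        w = writer(tmp_path / "r.h5")
        w.record_sampled("eng", make_bundle([("v", np.arange(3.0))], 0))
        w.record_sampled("eng", make_bundle([("v", np.arange(5.0))], 1))
        w.close()
        m = loadmat(export_mat(tmp_path / "r.h5"), simplify_cells=True)
        cells = m["eng"]["sampled"]["v"]["values"]
        assert len(cells[0]) == 3 and len(cells[1]) == 5


class TestReplay:
    def test_control_change_visible_from_its_frame_on(self, tmp_path):
        w = writer(tmp_path / "r.h5")
        for k in range(20):
            w.record_sampled("eng", make_bundle([("x", float(k))], k))
        w.record_control("eng", ParameterUpdate("thr", 1.0, 0))
        w.record_control("eng", ParameterUpdate("thr", 2.0, 10))
        w.close()
        frames = list(replay(tmp_path / "r.h5"))
        assert len(frames) == 20
        for index, sampled, controls in frames:
            assert sampled["eng/x"] == float(index)
            assert controls["eng/thr"] == (1.0 if index < 10 else 2.0)

    def test_empty_run_empty_stream(self, tmp_path):
        w = writer(tmp_path / "r.h5")
        w.close()
        assert list(replay(tmp_path / "r.h5")) == []
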