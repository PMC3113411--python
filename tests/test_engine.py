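import pytest
from cortexloop.engine import (
    Engine,
    EngineFault,
    EngineSpec,
    System,
    launch,
    template_acquisition_hook,
    template_application_hook,
    template_passthrough_hook,
)
from cortexloop.recording import Recorder, RunMetadata, read_run

META = RunMetadata(subject_id="t", date="simulated")


def identity_hook(upstream, params, state):
    return dict(upstream.items()), {}, {}


def counting_hook(upstream, params, state):
    state["frames"] = state.get("frames", 0) + 1
    return {"index_seen": upstream.index, "gain": params.get("gain", 0.0)}, {"snap": 1}, {
        "index_seen": upstream.index
    }


def make_system(recorder=None, acq_hook=None, sp_hook=None, app_hook=None):
    specs = {
        "acquisition": EngineSpec("acquisition", "acq", parameters={"gain": 1.0, "seed": 0}),
        "signal_processing": EngineSpec("signal_processing", "sp", parameters={"gain": 1.0}),
        "application": EngineSpec("application", "app", parameters={"gain": 1.0}),
    }
    hooks = {
        "acquisition": acq_hook or counting_hook,
        "signal_processing": sp_hook or identity_hook,
        "application": app_hook or identity_hook,
    }
    return System(specs, hooks, META, recorder)


class TestFrameLoop:
    def test_identity_ring_indices_in_order(self, tmp_path):
        system = make_system()
        system.start_run(tmp_path / "r.h5")
        emitted = [system.step() for _ in range(100)]
        assert emitted == list(range(100))

    def test_cyclical_dataflow_feedback_required(self, tmp_path):
        system = make_system()
        system.start_run(tmp_path / "r.h5")
        system.step()
        system._feedback_for = None  # simulate a missing feedback bundle
        with pytest.raises(AssertionError, match="feedback"):
            system.step()

    def test_hook_exception_faults_engine(self, tmp_path):
        def bad_hook(upstream, params, state):
            raise RuntimeError("boom")

        system = make_system(sp_hook=bad_hook)
        system.start_run(tmp_path / "r.h5")
        with pytest.raises(EngineFault, match="sp"):
            system.step()
        assert system.engines["signal_processing"].faulted


class TestParameterUpdates:
    def test_update_applies_at_next_frame(self, tmp_path):
        recorder = Recorder()
        system = make_system(recorder)
        system.start_run(tmp_path / "r.h5")
        for _ in range(5):
            system.step()
        system.set_parameter("acquisition", "gain", 2.5)
        system.step()  # frame 5: sees the new value throughout
        engine = system.engines["acquisition"]
        update = engine.applied_log[-1]
        assert update.name == "gain" and update.applied_at == 5
        recorder.close_run()
        record = read_run(tmp_path / "r.h5")
        idx, vals = record.controls["acq"]["gain"]
        assert list(idx) == [0, 5] and vals == [1.0, 2.5]

    def test_empty_pending_is_noop(self):
        engine = Engine(EngineSpec("acquisition", "a", parameters={"x": 1}), identity_hook)
        assert engine.apply_parameter_updates(0, None) == []

    def test_same_name_twice_last_writer_wins_both_logged(self):
        engine = Engine(EngineSpec("acquisition", "a", parameters={"x": 1}), identity_hook)
        engine.queue_update("x", 2)
        engine.queue_update("x", 3)
        applied = engine.apply_parameter_updates(7, None)
        assert engine.params["x"] == 3
        assert [u.value for u in applied] == [2, 3]
        assert all(u.applied_at == 7 for u in applied)

    def test_unknown_parameter_skipped(self):
        engine = Engine(EngineSpec("acquisition", "a", parameters={"x": 1}), identity_hook)
        engine.queue_update("nope", 9)
        assert engine.apply_parameter_updates(0, None) == []
        assert "nope" not in engine.params


class TestVisualization:
    def test_stalled_consumer_drops_oldest_without_blocking(self, tmp_path):
        system = make_system()
        system.start_run(tmp_path / "r.h5")
        for _ in range(30):  # nobody drains the viz queue
            system.step()
        engine = system.engines["acquisition"]
        assert len(engine.viz_queue) == Engine.VIZ_CAPACITY
        assert engine.viz_dropped == 30 - Engine.VIZ_CAPACITY
        # the newest snapshots survive; the main sequence never stalled
        assert engine.viz_queue[-1].index == 29
        assert system.next_index == 30


class TestSuspendResume:
    def test_suspend_closes_file_resume_opens_new(self, tmp_path):
        recorder = Recorder()
        system = make_system(recorder)
        system.start_run(tmp_path / "run1.h5")
        for _ in range(10):
            system.step()
        system.suspend()
        assert (tmp_path / "run1.h5").exists()
        system.resume(tmp_path / "run2.h5")
        for _ in range(3):
            system.step()
        system.suspend()
        assert (tmp_path / "run2.h5").exists()
        assert system.run_paths == [str(tmp_path / "run1.h5"), str(tmp_path / "run2.h5")]

    def test_double_suspend_idempotent(self, tmp_path):
        system = make_system(Recorder())
        system.start_run(tmp_path / "r.h5")
        system.step()
        system.suspend()
        system.suspend()  # no error

    def test_state_preserved_across_suspend(self, tmp_path):
        system = make_system()
        system.start_run(tmp_path / "r1.h5")
        for _ in range(6):
            system.step()
        before = system.engines["acquisition"].state["frames"]
        system.suspend()
        system.resume(tmp_path / "r2.h5")
        assert system.engines["acquisition"].state["frames"] == before
        system.step()
        assert system.engines["acquisition"].state["frames"] == before + 1

    def test_swap_application_preserves_acquisition_state(self, tmp_path):
        system = make_system()
        system.start_run(tmp_path / "r1.h5")
        for _ in range(5):
            system.step()
        checksum = system.engines["acquisition"].state["frames"]
        system.suspend()
        system.swap_engine(
            "application", EngineSpec("application", "app2"), template_application_hook
        )
        system.resume(tmp_path / "r2.h5")
        system.step()
        assert system.engines["acquisition"].state["frames"] == checksum + 1
        assert system.engines["application"].spec.name == "app2"

    def test_swap_wrong_kind_rejected(self, tmp_path):
        system = make_system()
        with pytest.raises(ValueError):
            system.swap_engine("application", EngineSpec("acquisition", "x"), identity_hook)


class TestLaunch:
    def test_missing_engine_kind_refused(self):
        specs = {
            "acquisition": EngineSpec("acquisition", "a"),
            "application": EngineSpec("application", "p"),
        }
        with pytest.raises(ValueError, match="signal_processing"):
            System(specs, {}, META)

    def test_template_ring_idles_gap_free(self, tmp_path):
        specs = {
            "acquisition": EngineSpec(
                "acquisition", "acq_t", parameters={"n_channels": 2, "frame_samples": 8,
                                                    "seed": 0}
            ),
            "signal_processing": EngineSpec("signal_processing", "sp_t"),
            "application": EngineSpec("application", "app_t"),
        }
        hooks = {
            "acquisition": template_acquisition_hook,
            "signal_processing": template_passthrough_hook,
            "application": template_application_hook,
        }
        system = launch(specs, hooks, META, tmp_path / "r.h5", Recorder())
        system.run(200)
        assert system.engines["application"].state["displays"] == 200
        assert system.next_index == 200
        system.stop()
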