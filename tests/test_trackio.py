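"""Track container, table IO, filtering and drift correction."""

import numpy as np
import pandas as pd
import pytest

from meiotrack import (
    MotionModelConfig,
    Track,
    TrackSet,
    drift_correct,
    filter_tracks,
    load_tracks,
    simulate_tracks,
    write_tracks,
)
from meiotrack.errors import (
    ConfigurationError,
    DriftReferenceError,
    SchemaError,
    TrackFormatError,
)

from conftest import make_track


class TestTrackContainer:
    def test_rejects_non_increasing_times(self):
        with pytest.raises(TrackFormatError, match="strictly increasing"):
            Track("bad", [0.0, 0.0, 1.0], np.zeros((3, 3)))

    def test_rejects_single_frame(self):
        with pytest.raises(TrackFormatError):
            Track("bad", [0.0], np.zeros((1, 3)))

    def test_rejects_nonfinite(self):
        xyz = np.zeros((3, 3))
        xyz[1, 2] = np.nan
        with pytest.raises(TrackFormatError, match="non-finite"):
            Track("bad", [0.0, 1.0, 2.0], xyz)

    def test_duration_and_steps(self, straight_track):
        assert straight_track.duration == 8.0
        assert straight_track.steps.shape == (4, 3)
        np.testing.assert_allclose(straight_track.steps[:, 0], 0.1)


class TestTableIO:
    def test_roundtrip_preserves_everything(self, tmp_path, two_track_set):
        path = tmp_path / "tracks.csv"
        write_tracks(two_track_set, path)
        loaded = load_tracks(path)
        assert len(loaded) == 2
        assert loaded.frame_interval == two_track_set.frame_interval
        for orig, back in zip(two_track_set, loaded):
            assert back.track_id == orig.track_id
            assert back.compartment == orig.compartment
            assert back.stage == orig.stage
            assert back.cell_id == orig.cell_id
            np.testing.assert_array_equal(back.t, orig.t)
            np.testing.assert_array_equal(back.xyz, orig.xyz)

    def test_missing_column_names_the_column(self, tmp_path):
        df = pd.DataFrame(
            {"track_id": ["a", "a"], "anther_id": "x", "cell_id": "c",
             "compartment": "meiotic", "time_s": [0.0, 1.0], "x_um": 0.0, "y_um": 0.0}
        )
        path = tmp_path / "bad.csv"
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="missing column: z"):
            load_tracks(path)

    def test_out_of_order_rows_are_sorted(self, tmp_path):
        df = pd.DataFrame(
            {
                "track_id": "a",
                "anther_id": "x",
                "cell_id": "c",
                "compartment": "meiotic",
                "stage": "zygotene",
                "frame": [2, 0, 1],
                "time_s": [4.0, 0.0, 2.0],
                "x_um": [2.0, 0.0, 1.0],
                "y_um": 0.0,
                "z_um": 0.0,
            }
        )
        path = tmp_path / "scrambled.csv"
        df.to_csv(path, index=False)
        tr = load_tracks(path).tracks[0]
        assert np.all(np.diff(tr.t) > 0)
        np.testing.assert_array_equal(tr.xyz[:, 0], [0.0, 1.0, 2.0])

    def test_duplicate_timestamps_rejected(self, tmp_path):
        df = pd.DataFrame(
            {"track_id": "a", "anther_id": "x", "cell_id": "c", "compartment": "meiotic",
             "time_s": [0.0, 0.0, 2.0], "x_um": [0.0, 1.0, 2.0], "y_um": 0.0, "z_um": 0.0,
             "frame": [0, 0, 1]}
        )
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(TrackFormatError, match="duplicate"):
            load_tracks(path)

    def test_frame_interval_is_modal_step(self, tmp_path):
        # one irregular gap must not change the inferred nominal interval
        tr = Track("a", [0.0, 2.5, 5.0, 7.5, 12.5], np.zeros((5, 3)), frames=[0, 1, 2, 3, 5])
        write_path = tmp_path / "t.csv"
        write_tracks(TrackSet([tr], frame_interval=2.5), write_path)
        (tmp_path / "t.meta.json").unlink()  # force re-inference from the table
        assert load_tracks(write_path).frame_interval == 2.5


class TestFilterTracks:
    def test_short_track_removed_at_15s(self):
        short = make_track(np.zeros((5, 3)) + np.arange(5)[:, None] * 0.1, dt=2.0)  # 8 s
        long = make_track(np.zeros((11, 3)), dt=2.0, track_id="long")  # 20 s
        ts = TrackSet([short, long], frame_interval=2.0)
        out = filter_tracks(ts, min_duration=15.0)
        assert [tr.track_id for tr in out] == ["long"]

    def test_boundary_margin_removes_edge_touching_track(self):
        inner = make_track(np.full((3, 3), 5.0), track_id="inner")
        edge = make_track([[0.1, 5.0, 5.0], [5.0, 5.0, 5.0], [5.0, 5.0, 5.0]], track_id="edge")
        ts = TrackSet([inner, edge], frame_interval=1.0,
                      image_bounds=[[0.0, 0.0, 0.0], [10.0, 10.0, 10.0]])
        out = filter_tracks(ts, min_duration=0.0, boundary_margin=0.5)
        assert [tr.track_id for tr in out] == ["inner"]

    def test_margin_without_bounds_is_an_error(self):
        ts = TrackSet([make_track(np.zeros((3, 3)))], frame_interval=1.0)
        with pytest.raises(ConfigurationError):
            filter_tracks(ts, boundary_margin=0.5)

    def test_noop_and_idempotent(self, two_track_set):
        out = filter_tracks(two_track_set, min_duration=5.0)
        assert len(out) == len(two_track_set)
        again = filter_tracks(out, min_duration=5.0)
        assert [t.track_id for t in again] == [t.track_id for t in out]


class TestDriftCorrect:
    def _acquisition(self, drift_per_frame=(0.1, 0.0, 0.0), n=6):
        drift = np.arange(n)[:, None] * np.asarray(drift_per_frame)
        som = [
            make_track(drift + off, dt=2.0, track_id=f"s{i}", compartment="somatic")
            for i, off in enumerate([0.0, 1.0, 2.0])
        ]
        meio = make_track(np.full((n, 3), 5.0), dt=2.0, track_id="m0")
        return TrackSet(som + [meio], frame_interval=2.0)

    def test_stationary_meiotic_gets_opposite_drift(self):
        ts = self._acquisition()
        out = drift_correct(ts)
        m = next(tr for tr in out if tr.track_id == "m0")
        np.testing.assert_allclose(m.steps[:, 0], -0.1, atol=1e-12)

    def test_somatic_mean_displacement_zero_after_correction(self):
        out = drift_correct(self._acquisition())
        mean_steps = np.mean([tr.steps for tr in out.somatic], axis=0)
        np.testing.assert_allclose(mean_steps, 0.0, atol=1e-12)

    def test_idempotent(self):
        once = drift_correct(self._acquisition())
        twice = drift_correct(once)
        for a, b in zip(once, twice):
            np.testing.assert_allclose(a.xyz, b.xyz, atol=1e-12)

    def test_commutes_with_global_translation(self):
        ts = self._acquisition()
        shifted = TrackSet(
            [make_track(tr.xyz + [1.0, -2.0, 3.0], dt=2.0, track_id=tr.track_id,
                        compartment=tr.compartment) for tr in ts],
            frame_interval=2.0,
        )
        a = drift_correct(ts)
        b = drift_correct(shifted)
        for ta, tb in zip(a, tb_list := list(b)):
            np.testing.assert_allclose(tb.xyz - tb.xyz[0], ta.xyz - ta.xyz[0], atol=1e-12)

    def test_no_somatic_reference_is_an_error(self):
        ts = TrackSet([make_track(np.zeros((4, 3)))], frame_interval=1.0)
        with pytest.raises(DriftReferenceError, match="no drift reference"):
            drift_correct(ts)

    def test_simulated_drift_roundtrip(self):
        from meiotrack import HierarchyConfig

        cfg = HierarchyConfig(
            n_anthers=1, cells_per_anther=1, tracks_per_cell=2,
            drift_velocity=(0.02, 0.0, 0.0), seed=5,
            base=MotionModelConfig(n_steps=40),
        )
        from meiotrack import simulate_anther

        ts = simulate_anther(cfg)
        corrected = drift_correct(ts)
        net = np.mean(
            [np.linalg.norm(tr.xyz[-1] - tr.xyz[0]) for tr in corrected.somatic]
        )
        net_raw = np.mean([np.linalg.norm(tr.xyz[-1] - tr.xyz[0]) for tr in ts.somatic])
        assert net < net_raw / 2  # the 2.4 µm rigid drift is gone
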