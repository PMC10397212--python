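"""Event classification tests: distances, collisions, conversions, cohorts."""

import numpy as np
import pandas as pd
import pytest

from endomat import syndata
from endomat.events import (EventConfig, SurfaceDistanceSeries, analyse,
                            classify_induction, classify_kind,
                            detect_collisions, evaluate_against_truth,
                            summarize, surface_distance)


def traj(track_id, frames, pos, radius=0.3, intensity=100.0, channel="APPL1",
         dt=3.0):
    pos = np.atleast_2d(pos)
    if len(pos) == 1:
        pos = np.repeat(pos, len(frames), axis=0)
    return pd.DataFrame({
        "track_id": track_id, "channel": channel, "frame": frames,
        "t": np.asarray(frames) * dt,
        "z": pos[:, 0], "y": pos[:, 1], "x": pos[:, 2],
        "radius": radius, "intensity": intensity, "gap_flag": 0})


class TestSurfaceDistance:
    def test_concentric_equal_spheres_touch(self):
        a = traj(0, range(5), [[0, 0, 0]], radius=0.3)
        b = traj(1, range(5), [[0, 0, 0]], radius=0.3, channel="EEA1")
        s = surface_distance(a, b)
        assert np.allclose(s.separation, 0.0)

    def test_simple_arithmetic(self):
        a = traj(0, range(3), [[0, 0, 0]], radius=0.3)
        b = traj(1, range(3), [[0, 0, 1.0]], radius=0.3, channel="EEA1")
        s = surface_distance(a, b)
        assert np.allclose(s.separation, 0.4)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        a = traj(0, range(6), rng.normal(size=(6, 3)), radius=0.2)
        b = traj(1, range(6), rng.normal(size=(6, 3)), radius=0.25)
        assert np.allclose(surface_distance(a, b).separation,
                           surface_distance(b, a).separation)

    def test_no_overlap_gives_empty_series(self):
        a = traj(0, range(0, 4), [[0, 0, 0]])
        b = traj(1, range(10, 14), [[0, 0, 0]])
        assert len(surface_distance(a, b).times) == 0


def series_from(seps, dt=3.0):
    seps = np.asarray(seps, dtype=float)
    return SurfaceDistanceSeries((0, 1), np.arange(len(seps)) * dt, seps)


class TestDetectCollisions:
    def test_single_dip_below_threshold(self):
        out = detect_collisions(series_from([0.5, 0.4, 0.15, 0.4, 0.5]))
        assert len(out) == 1
        assert out.min_separation.iloc[0] == pytest.approx(0.15)

    def test_dip_above_threshold_not_counted(self):
        out = detect_collisions(series_from([0.5, 0.4, 0.25, 0.4, 0.5]))
        assert len(out) == 0

    def test_two_separated_dips(self):
        out = detect_collisions(series_from(
            [0.5, 0.1, 0.5, 0.6, 0.5, 0.12, 0.5]))
        assert len(out) == 2

    def test_threshold_sharpness(self):
        """Approaches at threshold +-25% flip the collision call."""
        cfg = EventConfig()
        below = series_from([0.5, 0.75 * cfg.collision_threshold, 0.5])
        above = series_from([0.5, 1.25 * cfg.collision_threshold, 0.5])
        assert len(detect_collisions(below, config=cfg)) == 1
        assert len(detect_collisions(above, config=cfg)) == 0

    def test_contact_plateau_counts_once(self):
        out = detect_collisions(series_from([0.5, 0.0, 0.0, 0.0, 0.5]))
        assert len(out) == 1

    def test_cotrack_interval_excludes_minima(self):
        s = series_from([0.5, 0.1, 0.5])
        assert len(detect_collisions(s, [(0.0, 10.0)])) == 0

    def test_nearby_minima_merge(self):
        s = series_from([0.5, 0.1, 0.3, 0.05, 0.5])
        out = detect_collisions(s)
        assert len(out) == 1
        assert out.min_separation.iloc[0] == pytest.approx(0.05)


class TestKindAndInduction:
    def cfg(self):
        return EventConfig()

    def event(self, onset=60.0):
        return pd.Series({"appl1_track": 0, "eea1_track": 1,
                          "cotrack_onset": onset, "cotrack_duration": 30.0})

    def test_preexisting_partner_is_fusion(self):
        te = {1: traj(1, range(0, 40), [[0, 0, 0]], channel="EEA1")}
        assert classify_kind(self.event(onset=60.0), te) == "fusion"

    def test_partner_born_at_onset_is_conversion(self):
        te = {1: traj(1, range(20, 40), [[0, 0, 0]], channel="EEA1")}
        assert classify_kind(self.event(onset=60.0), te) == "conversion"

    def test_one_frame_preexistence_is_conversion(self):
        # below the 2-frame pre-existence margin
        te = {1: traj(1, range(19, 40), [[0, 0, 0]], channel="EEA1")}
        assert classify_kind(self.event(onset=60.0), te) == "conversion"

    def test_newborn_intensity_overrides_track_birth(self):
        """A pre-existing track whose intensity collapses at onset absorbed
        a newly appearing signal: classified conversion."""
        g = traj(1, range(0, 40), [[0, 0, 0]], channel="EEA1")
        g.loc[g.frame >= 20, "intensity"] = 20.0
        g.loc[g.frame < 20, "intensity"] = 100.0
        assert classify_kind(self.event(onset=60.0), {1: g}) == "conversion"

    def test_induction_window(self):
        coll = pd.DataFrame({"track_a": [0], "track_b": [9],
                             "time": [50.0], "min_separation": [0.1]})
        label, n = classify_induction(self.event(onset=60.0), coll)
        assert (label, n) == ("collision-induced", 1)
        label, n = classify_induction(self.event(onset=100.0), coll)
        assert (label, n) == ("unaided", 0)
        label, n = classify_induction(self.event(onset=60.0),
                                      coll.iloc[0:0])
        assert (label, n) == ("unaided", 0)


class TestOracleEquivalence:
    def test_scripted_scene_recovered_exactly(self, default_scene):
        """On ideal (latent) trajectories the classification rules recover
        every scripted event with correct kind and induction, with onset
        within one frame of the script."""
        _, tracks, gt = default_scene
        ideal = syndata.tracks_to_trajectories(tracks)
        events, _ = analyse(ideal)
        scripted = gt[gt.event_type.isin(["fusion", "conversion"])]
        assert len(events) == len(scripted)
        for _, ev in scripted.iterrows():
            match = events[np.abs(events.cotrack_onset - ev.time) <= 3.0]
            assert len(match) == 1, f"missing {ev.event_type} at {ev.time}"
            got = match.iloc[0]
            assert got.kind == ev.event_type
            expected_label = ("collision-induced" if ev.induced
                              else "unaided")
            assert got.induction == expected_label

    def test_reversion_rejected(self):
        """APPL1 reappearing near the EEA1 track shortly after loss (as in
        nocodazole-treated cells) disqualifies the candidate."""
        frames = range(0, 30)
        a = traj(0, range(0, 10), [[0, 0, 0]], channel="APPL1")
        e = traj(1, frames, [[0, 0, 0]], channel="EEA1")
        # a second APPL1 track reappears at the same spot 3 frames later
        a2 = traj(2, range(13, 30), [[0, 0, 0]], channel="APPL1")
        events, _ = analyse(pd.concat([a, e, a2], ignore_index=True))
        assert len(events) == 0

    def test_single_frame_colocalisation_no_event(self):
        a = pd.concat([traj(0, [0, 1, 2, 3, 4], [[0, 0, 5.0]]),
                       ], ignore_index=True)
        a.loc[a.frame == 2, ["z", "y", "x"]] = 0.0
        e = traj(1, range(0, 30), [[0, 0, 0]], channel="EEA1")
        events, _ = analyse(pd.concat([a, e], ignore_index=True))
        assert len(events) == 0


class TestSummaries:
    def make_events(self, n_fus=20, n_conv=10):
        rows = []
        for i in range(n_fus):
            rows.append({"appl1_track": i, "eea1_track": 100 + i,
                         "cotrack_onset": 50.0, "cotrack_duration": 15.0,
                         "kind": "fusion",
                         "induction": "collision-induced" if i % 2 else "unaided",
                         "n_preceding_collisions": i % 2})
        for i in range(n_conv):
            rows.append({"appl1_track": 50 + i, "eea1_track": 200 + i,
                         "cotrack_onset": 80.0, "cotrack_duration": 25.0,
                         "kind": "conversion", "induction": "unaided",
                         "n_preceding_collisions": 0})
        return pd.DataFrame(rows)

    def test_single_event_single_cell(self):
        ev = self.make_events(n_fus=1, n_conv=0)
        out = summarize(ev)
        assert out["heatmap"].to_numpy().sum() == pytest.approx(1.0)
        assert (out["heatmap"].to_numpy() == 1.0).sum() == 1

    def test_fractions_sum_to_one(self):
        out = summarize(self.make_events())
        assert out["heatmap"].to_numpy().sum() == pytest.approx(1.0)

    def test_scripted_cohort_composition(self):
        ev = self.make_events(n_fus=20, n_conv=10)
        out = summarize(ev)
        counts = out["counts"]
        assert counts["unaided fusion"] == 10
        assert counts["collision-induced fusion"] == 10
        assert counts["unaided conversion"] == 10
        assert counts["collision-induced conversion"] == 0
        assert sum(counts.values()) == 30
        # 15-s fusions in the 10-20s bin, 25-s conversions in 20-30s
        heat = out["heatmap"]
        assert heat.loc["10-20s"].sum() == pytest.approx(20 / 30)
        assert heat.loc["20-30s"].sum() == pytest.approx(10 / 30)

    def test_empty_events_empty_summary(self):
        out = summarize(pd.DataFrame())
        assert out["counts"] == {}


class TestEvaluation:
    def truth(self):
        return pd.DataFrame({
            "event_type": ["collision", "fusion", "conversion"],
            "time": [30.0, 60.0, 90.0]})

    def test_perfect_detection(self):
        scores = evaluate_against_truth(self.truth(), self.truth(), 6.0)
        assert (scores.precision == 1.0).all()
        assert (scores.recall == 1.0).all()

    def test_empty_detection_zero_recall(self):
        det = self.truth().iloc[0:0]
        scores = evaluate_against_truth(det, self.truth(), 6.0)
        assert (scores.recall == 0.0).all()

    def test_shift_within_tolerance_matches(self):
        det = self.truth().assign(time=lambda d: d.time + 4.0)
        scores = evaluate_against_truth(det, self.truth(), 6.0)
        assert (scores.recall == 1.0).all()
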