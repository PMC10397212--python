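"""Generator tests: motility statistics, event scripting, rendering, TCSPC."""

import numpy as np
import pandas as pd
import pytest

from endomat import syndata
from endomat.flim import DecayModel
from endomat.syndata import (EventSpec, MotionParams, NoiseParams,
                             OpticsParams, ScriptingError, assign_channels,
                             render_movie, script_events, simulate_flim_photons,
                             simulate_motion)


def analytic_msd(p: MotionParams, lag: int) -> float:
    """Closed-form ensemble MSD of the discrete run-and-pause process.

    Derivation: per-step displacement is v*dt along a persistent unit
    direction while running (stationary probability pi_run) and isotropic
    Gaussian with per-axis variance 2*D*dt while paused.  Cross terms are
    non-zero only for steps within one uninterrupted run, which persists
    over k state updates with probability q**k, q = exp(-rate_rp*dt).
    """
    dt = p.frame_interval
    r1, r2 = p.rate_run_to_pause, p.rate_pause_to_run
    pi_run = r2 / (r1 + r2)
    q = np.exp(-r1 * dt)
    v2 = (p.run_speed * dt) ** 2
    dif = 6 * p.pause_diffusion * dt
    base = lag * (pi_run * v2 + (1 - pi_run) * dif)
    cross = 2 * v2 * pi_run * sum((lag - k) * q ** k for k in range(1, lag))
    return base + cross


class TestSimulateMotion:
    def test_degenerate_rates_give_stationary_tracks(self):
        p = MotionParams(run_speed=0.0, pause_diffusion=0.0)
        tracks = simulate_motion(p, 3, seed=0)
        for _, g in tracks.groupby("track_id"):
            pos = g[["z", "y", "x"]].to_numpy()
            assert np.allclose(pos, pos[0])

    def test_same_seed_is_byte_identical(self):
        p = MotionParams(n_frames=20)
        a = simulate_motion(p, 5, seed=11)
        b = simulate_motion(p, 5, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_positions_stay_inside_bounds(self):
        p = MotionParams(bounds=(1.0, 1.0, 1.0), n_frames=50)
        tracks = simulate_motion(p, 10, seed=2)
        assert (tracks[["z", "y", "x"]].abs().to_numpy() <= 1.0 + 1e-9).all()

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MotionParams(frame_interval=0.0)
        with pytest.raises(ValueError):
            MotionParams(n_frames=0)
        with pytest.raises(ValueError):
            simulate_motion(MotionParams(), 0, seed=0)

    def test_ensemble_msd_matches_closed_form(self):
        # large box so reflections are negligible; 1e3 tracks
        p = MotionParams(bounds=(500.0, 500.0, 500.0), n_frames=40)
        tracks = simulate_motion(p, 1000, seed=5, brightness_cv=0.0)
        P = np.stack([g[["z", "y", "x"]].to_numpy()
                      for _, g in tracks.groupby("track_id")])
        for lag in (1, 3, 10):
            d = P[:, lag:, :] - P[:, :-lag, :]
            sq = (d ** 2).sum(axis=2)
            per_track = sq.mean(axis=1)
            se = per_track.std() / np.sqrt(len(per_track))
            z = (sq.mean() - analytic_msd(p, lag)) / se
            assert abs(z) < 3.0, f"lag {lag}: z = {z:.2f}"


class TestScriptEvents:
    @pytest.fixture()
    def two_tracks(self):
        p = MotionParams(n_frames=30)
        tracks = simulate_motion(p, 2, seed=3, brightness_cv=0.0)
        return assign_channels(tracks, appl1_ids=[0], eea1_ids=[1])

    def test_empty_spec_is_identity(self, two_tracks):
        out, log = script_events(two_tracks, [])
        pd.testing.assert_frame_equal(
            out.reset_index(drop=True),
            two_tracks.sort_values(["track_id", "frame"]).reset_index(drop=True))
        assert log.empty

    def test_scripted_collision_dips_below_threshold(self, two_tracks):
        spec = [EventSpec("collision", time=30.0, track_a=0, track_b=1)]
        out, log = script_events(two_tracks, spec)
        a = out[out.track_id == 0].set_index("frame")
        b = out[out.track_id == 1].set_index("frame")
        seps = {}
        for f in range(8, 13):
            d = np.linalg.norm(a.loc[f, ["z", "y", "x"]].to_numpy(dtype=float)
                               - b.loc[f, ["z", "y", "x"]].to_numpy(dtype=float))
            seps[f] = d - a.loc[f, "radius"] - b.loc[f, "radius"]
        # minimum surface separation < 200 nm within +-1 frame of t=30 s
        assert min(seps[9], seps[10], seps[11]) < 0.200

    def test_fusion_merges_positions(self, two_tracks):
        spec = [EventSpec("fusion", time=30.0, track_a=0, track_b=1,
                          cotrack_duration=15.0)]
        out, _ = script_events(two_tracks, spec)
        a = out[out.track_id == 0].set_index("frame")
        b = out[out.track_id == 1].set_index("frame")
        for f in a.index[a.index >= 10]:
            assert np.allclose(a.loc[f, ["z", "y", "x"]].to_numpy(dtype=float),
                               b.loc[f, ["z", "y", "x"]].to_numpy(dtype=float))
        # APPL1 brightness decays to zero over the cotracking window
        assert a["b_appl1"].iloc[-1] < a["b_appl1"].iloc[0]

    def test_conversion_switches_identity(self, two_tracks):
        spec = [EventSpec("conversion", time=30.0, track_a=0, track_b=0,
                          cotrack_duration=15.0)]
        out, log = script_events(two_tracks, spec)
        a = out[out.track_id == 0]
        assert (a[a.frame < 10].b_eea1 == 0).all()
        late = a[a.frame > 16]
        assert (late.b_appl1 == 0).all()
        assert (late.b_eea1 > 0).all()
        assert log.iloc[0].event_type == "conversion"

    def test_conflicting_scripts_rejected(self, two_tracks):
        spec = [EventSpec("collision", time=30.0, track_a=0, track_b=1),
                EventSpec("fusion", time=30.0, track_a=0, track_b=1)]
        with pytest.raises(ScriptingError):
            script_events(two_tracks, spec)

    def test_out_of_range_time_rejected(self, two_tracks):
        with pytest.raises(ScriptingError):
            script_events(two_tracks, [EventSpec("collision", time=1e4,
                                                 track_a=0, track_b=1)])

    def test_induced_flag_follows_preceding_collision(self, two_tracks):
        spec = [EventSpec("collision", time=21.0, track_a=0, track_b=1),
                EventSpec("conversion", time=33.0, track_a=0, track_b=0,
                          cotrack_duration=15.0)]
        _, log = script_events(two_tracks, spec)
        conv = log[log.event_type == "conversion"].iloc[0]
        assert bool(conv.induced)


class TestRenderMovie:
    def test_zero_noise_peak_at_blob_centre(self, single_blob_movie,
                                            small_optics):
        vol = single_blob_movie.intensity[0, 0]
        peak = np.unravel_index(np.argmax(vol), vol.shape)
        centre_vox = (small_optics.extent / 2
                      / np.asarray(small_optics.voxel_size))
        assert np.all(np.abs(np.asarray(peak) - centre_vox) <= 1)

    def test_zero_noise_photon_conservation(self, single_blob_movie):
        # blob integrates to its brightness up to discretisation error
        total = single_blob_movie.intensity[0, 0].sum()
        assert total == pytest.approx(5000.0, rel=0.02)

    def test_default_frame_interval_is_three_seconds(self):
        p = MotionParams(n_frames=3)
        tracks = assign_channels(simulate_motion(p, 1, seed=0), [0], [])
        movie = render_movie(tracks, OpticsParams(shape=(8, 32, 32)),
                             NoiseParams(poisson=False, read_sigma=0.0))
        assert movie.frame_interval == 3.0

    def test_movie_is_nonnegative_with_noise(self):
        p = MotionParams(n_frames=2)
        tracks = assign_channels(simulate_motion(p, 2, seed=1), [0], [1])
        movie = render_movie(tracks, OpticsParams(shape=(8, 32, 32)),
                             NoiseParams(), seed=4)
        assert movie.intensity.min() >= 0


class TestFlimPhotons:
    def test_counts_sum_to_total(self):
        _, counts = simulate_flim_photons(0.3, 5000, seed=1)
        assert counts.sum() == 5000

    @pytest.mark.parametrize("f_n,tau", [(1.0, 1.006), (0.0, 2.600)])
    def test_pure_component_mean_arrival(self, f_n, tau):
        # long window so truncation is negligible; vanishing IRF width
        model = DecayModel(irf_sigma=1e-6, window=60.0, n_bins=2048, t0=1.0)
        edges, counts = simulate_flim_photons(f_n, 100_000, model, seed=9)
        centers = 0.5 * (edges[:-1] + edges[1:])
        mean_t = (centers * counts).sum() / counts.sum() - model.t0
        se = tau / np.sqrt(counts.sum())
        assert abs(mean_t - tau) < 3 * se + 60.0 / 2048

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            simulate_flim_photons(1.5, 100, seed=0)


class TestLatentOracles:
    def test_tracks_to_trajectories_splits_channels(self, default_scene):
        _, tracks, _ = default_scene
        traj = syndata.tracks_to_trajectories(tracks)
        assert set(traj.channel) == {"APPL1", "EEA1"}
        # a conversion creates an EEA1 track born mid-movie
        births = traj[traj.channel == "EEA1"].groupby("track_id").frame.min()
        assert (births > 0).any()

    def test_latent_collisions_include_scripted_ones(self, default_scene):
        _, tracks, events = default_scene
        log = syndata.latent_collision_log(tracks, events)
        scripted = events[events.event_type == "collision"]
        for _, ev in scripted.iterrows():
            near = log[(np.abs(log.time - ev.time) <= 15.0)]
            assert len(near) > 0, f"scripted collision at {ev.time} missing"
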