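"""Detection tests: preprocessing, LoG scale selection, templates, 2-means."""

import numpy as np
import pandas as pd
import pytest

from endomat import detect, syndata
from endomat.detect import (BankError, DetectConfig, build_template_bank,
                            classify_candidates, detect_candidates,
                            extract_patch, log_scale_response,
                            patch_shape_for, preprocess, rank_image)


class TestPreprocess:
    def test_constant_frame_maps_to_constant(self):
        out = preprocess(np.full((8, 16, 16), 7.0))
        assert np.allclose(out, out.flat[0])

    def test_impulse_removed_by_median(self):
        frame = np.full((8, 16, 16), 10.0)
        frame[4, 8, 8] = 1000.0
        out = preprocess(frame, median_radius=1)
        assert out[4, 8, 8] == out[4, 8, 9]

    def test_output_range_unit_interval(self):
        rng = np.random.default_rng(0)
        out = preprocess(rng.poisson(5.0, (8, 16, 16)).astype(float))
        assert out.min() == 0.0 and out.max() == 1.0

    def test_empty_frame_rejected(self):
        with pytest.raises(ValueError):
            preprocess(np.empty((0, 0, 0)))


class TestLoGScale:
    def test_solid_ball_scale_optimum(self):
        """Brute-force LoG response over a dense scale grid peaks at
        sigma = r/sqrt(3) for an ideal solid sphere."""
        voxel = 0.05
        r = 0.3
        zz, yy, xx = np.meshgrid(*[np.arange(48)] * 3, indexing="ij")
        ball = (((zz - 24) ** 2 + (yy - 24) ** 2 + (xx - 24) ** 2)
                <= (r / voxel) ** 2).astype(float)
        sigmas = np.geomspace(0.8 * voxel, 0.4, 50)
        resp = [log_scale_response(ball, s, (voxel,) * 3).max()
                for s in sigmas]
        best = sigmas[int(np.argmax(resp))]
        expected = r / np.sqrt(3)
        step = sigmas[1] / sigmas[0]
        assert expected / step <= best <= expected * step

    def test_single_blob_detected_within_one_voxel(self, single_blob_movie,
                                                   small_optics):
        vol = single_blob_movie.intensity[0, 0]
        cand = detect_candidates(vol / vol.max(), small_optics.voxel_size,
                                 (0.15, 0.5))
        assert len(cand) == 1
        centre_vox = (small_optics.extent / 2
                      / np.asarray(small_optics.voxel_size))
        got = cand[["zv", "yv", "xv"]].to_numpy()[0]
        assert np.all(np.abs(got - centre_vox) <= 1)

    def test_empty_frame_yields_no_candidates(self):
        cand = detect_candidates(np.zeros((12, 48, 48)),
                                 (0.268, 0.104, 0.104), (0.15, 0.5))
        assert len(cand) == 0

    def test_bad_size_range_rejected(self):
        with pytest.raises(ValueError):
            detect_candidates(np.zeros((12, 48, 48)),
                              (0.268, 0.104, 0.104), (0.5, 0.2))


def _fake_candidates(n, rng):
    return pd.DataFrame({
        "frame": 0,
        "zv": rng.integers(2, 10, n), "yv": rng.integers(2, 40, n),
        "xv": rng.integers(2, 40, n),
        "z": 0.0, "y": 0.0, "x": 0.0,
        "scale": 0.3, "response": rng.random(n),
        "peak_intensity": rng.random(n),
    })


class TestTemplateBank:
    def test_bank_sizes_and_disjointness(self):
        rng = np.random.default_rng(1)
        cand = _fake_candidates(300, rng)
        frames = {0: rng.random((12, 48, 48))}
        bank = build_template_bank(cand, frames, 100, (5, 7, 7))
        assert len(bank.bright) == 100 and len(bank.dim) == 100
        bright_set = {a.tobytes() for a in bank.bright}
        dim_set = {a.tobytes() for a in bank.dim}
        # a candidate cannot be both a bright and a dim template
        ranked = cand.sort_values("peak_intensity", ascending=False)
        assert set(ranked.index[:100]).isdisjoint(set(ranked.index[-100:]))
        assert bright_set  # patches extracted
        del dim_set

    def test_too_few_candidates_raises(self):
        rng = np.random.default_rng(2)
        cand = _fake_candidates(300, rng)
        with pytest.raises(BankError):
            build_template_bank(cand, {0: rng.random((12, 48, 48))},
                                200, (5, 7, 7))

    def test_tie_break_is_deterministic(self):
        rng = np.random.default_rng(3)
        cand = _fake_candidates(40, rng)
        cand["peak_intensity"] = 1.0  # all tied
        frames = {0: rng.random((12, 48, 48))}
        a = build_template_bank(cand, frames, 10, (3, 5, 5))
        b = build_template_bank(cand.sample(frac=1, random_state=0),
                                frames, 10, (3, 5, 5))
        assert np.array_equal(a.bright, b.bright)
        assert np.array_equal(a.dim, b.dim)


class TestClassification:
    @pytest.fixture(scope="class")
    def labelled_scene(self):
        movie, tracks, _ = syndata.default_movie_scene(seed=4, n_frames=20)
        det = detect.detect_movie(movie, seed=0)
        half = (np.asarray(movie.voxel_size)
                * np.asarray(movie.intensity.shape[2:]) / 2)
        return movie, tracks, det, half

    def test_detection_accuracy_on_known_blobs(self, labelled_scene):
        """Signal/background split >= 0.95 accurate against rendered truth
        at SNR 5 (generator ground truth as oracle)."""
        movie, tracks, det, half = labelled_scene
        correct = total = 0
        for ch, b in (("APPL1", "b_appl1"), ("EEA1", "b_eea1")):
            for f in range(20):
                g = tracks[(tracks.frame == f) & (tracks[b] > 0)]
                pos_t = g[["z", "y", "x"]].to_numpy() + half
                dd = det[(det.channel == ch) & (det.frame == f)]
                for r in dd.itertuples():
                    d = (np.linalg.norm(pos_t - [r.z, r.y, r.x], axis=1).min()
                         if len(pos_t) else np.inf)
                    total += 1
                    correct += d < 0.35
        assert total > 0
        assert correct / total >= 0.95

    def test_same_seed_identical_labels(self):
        rng = np.random.default_rng(5)
        frames = {0: rng.random((12, 48, 48))}
        cand = _fake_candidates(120, rng)
        bank = build_template_bank(cand, frames, 30, (3, 5, 5))
        a = classify_candidates(cand, frames, bank, seed=1)
        b = classify_candidates(cand, frames, bank, seed=1)
        assert (a.label == b.label).all()

    def test_intensity_scaling_invariance(self):
        """Global intensity scaling leaves the signal/background split
        unchanged (features are standardised)."""
        rng = np.random.default_rng(6)
        frames = {0: rng.random((12, 48, 48))}
        cand = _fake_candidates(120, rng)
        bank = build_template_bank(cand, frames, 30, (3, 5, 5))
        a = classify_candidates(cand, frames, bank, seed=1)
        cand2 = cand.copy()
        cand2["peak_intensity"] *= 50.0
        cand2["response"] *= 50.0
        b = classify_candidates(cand2, frames, bank, seed=1)
        assert (a.label == b.label).all()

    def test_degenerate_features_rejected(self):
        rng = np.random.default_rng(7)
        frames = {0: np.zeros((12, 48, 48))}
        cand = _fake_candidates(80, rng)
        cand["peak_intensity"] = 1.0
        cand["response"] = 1.0
        bank = build_template_bank(cand, frames, 20, (3, 5, 5))
        with pytest.raises(ValueError):
            classify_candidates(cand, frames, bank, seed=0)


class TestPatches:
    def test_patch_is_zero_padded_at_border(self):
        frame = np.ones((8, 16, 16))
        patch = extract_patch(frame, (0, 0, 0), (5, 5, 5))
        assert patch.shape == (5, 5, 5)
        assert patch[0, 0, 0] == 0.0 and patch[4, 4, 4] == 1.0

    def test_patch_shape_scales_with_anisotropy(self):
        shape = patch_shape_for((0.15, 0.5), (0.268, 0.104, 0.104))
        assert shape[1] == shape[2] > shape[0]

    def test_rank_image_constant_frame(self):
        assert np.allclose(rank_image(np.full((4, 8, 8), 3.0)), 0.0)
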