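"""Scoring the imaging pipeline against the generator's ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import detect as detect_mod
from . import events as events_mod
from . import syndata
from . import track as track_mod

__all__ = ["detection_scores", "run_pipeline", "pipeline_event_scores"]


def detection_scores(movie, latent_tracks: pd.DataFrame,
                     detections: pd.DataFrame,
                     match_radius: float = 0.35,
                     visible_fraction: float = 0.5) -> dict:
    """Per-detection precision/recall against rendered blob positions.

    A detection within ``match_radius`` µm of a rendered blob of its
    channel is a true positive (one-to-one, greedy by distance).  Misses
    only count against recall when the blob held at least
    ``visible_fraction`` of the median channel brightness that frame —
    fainter blobs are below the rendering's detection floor.
    """
    half = (np.asarray(movie.voxel_size)
            * np.asarray(movie.intensity.shape[2:]) / 2)
    n_frames = movie.intensity.shape[0]
    tp = fp = fn = 0
    for ch, bcol in (("APPL1", "b_appl1"), ("EEA1", "b_eea1")):
        for f in range(n_frames):
            g = latent_tracks[(latent_tracks.frame == f)
                              & (latent_tracks[bcol] > 0)]
            pos_t = g[["z", "y", "x"]].to_numpy() + half
            bright = g[bcol].to_numpy()
            dd = detections[(detections.channel == ch)
                            & (detections.frame == f)]
            pos_d = dd[["z", "y", "x"]].to_numpy()
            used: set[int] = set()
            ref = np.median(bright) if len(bright) else 0.0
            for i, p in enumerate(pos_t):
                if len(pos_d):
                    d = np.linalg.norm(pos_d - p, axis=1)
                    j = int(np.argmin(d))
                    if d[j] < match_radius and j not in used:
                        used.add(j)
                        tp += 1
                        continue
                if bright[i] >= visible_fraction * ref:
                    fn += 1
            fp += len(pos_d) - len(used)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    return {"tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall}


def run_pipeline(movie, seed: int = 0):
    """Detection -> linking -> event classification on one movie."""
    det = detect_mod.detect_movie(movie, seed=seed)
    traj = track_mod.link(det, frame_interval=movie.frame_interval)
    events, collisions = events_mod.analyse(traj)
    return det, traj, events, collisions


def pipeline_event_scores(events: pd.DataFrame, collisions: pd.DataFrame,
                          latent_tracks: pd.DataFrame,
                          scripted_events: pd.DataFrame,
                          time_tolerance: float = 15.0) -> pd.DataFrame:
    """Score detected events against the scripted + latent-chance truth."""
    latent_coll = syndata.latent_collision_log(latent_tracks, scripted_events)
    truth = pd.concat([
        scripted_events[scripted_events.event_type != "collision"],
        latent_coll], ignore_index=True)
    detected = pd.concat([
        pd.DataFrame({"event_type": "collision", "time": collisions["time"]}),
        pd.DataFrame({"event_type": events["kind"],
                      "time": events["cotrack_onset"]}),
    ], ignore_index=True) if len(events) or len(collisions) else \
        pd.DataFrame(columns=["event_type", "time"])
    return events_mod.evaluate_against_truth(detected, truth, time_tolerance)
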