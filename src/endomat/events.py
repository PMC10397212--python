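"""Collision, conversion and fusion classification from paired trajectories.

The rules mirror the trajectory analysis used on the light-sheet data:

* surface separation between an APPL1 and an EEA1 endosome is the
  centre distance minus both radii (clipped at zero), along the line
  joining the centres of mass;
* strict local minima of that separation below 200 nm ("roughly two
  pixels") are heterotypic collisions, except where they fall inside a
  cotracking interval of the same pair (those are conversion-like, not
  collisions);
* an APPL1/EEA1 cotracking interval that ends with APPL1 loss, a
  persisting EEA1 track and no APPL1 reversion is a maturation event;
* the event is a *fusion* if the EEA1 track pre-existed the cotracking
  (by at least two frames), else a *conversion*;
* it is *collision-induced* if the APPL1 endosome collided with any EEA1
  endosome in the 30 s before onset, else *unaided*;
* cohorts are summarised as a fraction heatmap over (cotracking duration
  in 10-s bins) x (number of preceding collisions), plus the four
  category counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EventConfig",
    "SurfaceDistanceSeries",
    "surface_distance",
    "detect_collisions",
    "close_contact_runs",
    "extract_conversion_events",
    "classify_kind",
    "classify_induction",
    "analyse",
    "summarize",
    "evaluate_against_truth",
]


@dataclass(frozen=True)
class EventConfig:
    """Event-classification parameters (distances µm, times s)."""

    collision_threshold: float = 0.200
    collision_merge_window: float = 10.0
    pre_event_window: float = 30.0
    cohort_bin: float = 10.0
    coloc_radius: float = 0.2
    appl1_terminal_fraction: float = 1.2
    eea1_persistence_frames: int = 10
    no_reversion_window: float = 30.0
    fusion_preexist_frames: int = 2
    eea1_newborn_fraction: float = 0.7

    def __post_init__(self) -> None:
        for name in ("collision_threshold", "pre_event_window", "cohort_bin",
                     "coloc_radius", "appl1_terminal_fraction",
                     "no_reversion_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SurfaceDistanceSeries:
    """Surface-to-surface separation of one APPL1/EEA1 pair over time."""

    pair: tuple[int, int]
    times: np.ndarray
    separation: np.ndarray


def _track_interp(track: pd.DataFrame):
    """Linear position/radius interpolators over the track's time support.

    Interpolation only bridges linking gaps; nothing is extrapolated.
    """
    tr = track.sort_values("t")
    t = tr["t"].to_numpy(dtype=float)
    pos = tr[["z", "y", "x"]].to_numpy(dtype=float)
    rad = tr["radius"].to_numpy(dtype=float)

    def at(times: np.ndarray):
        p = np.column_stack([np.interp(times, t, pos[:, k]) for k in range(3)])
        r = np.interp(times, t, rad)
        return p, r

    return t[0], t[-1], at


def surface_distance(traj_a: pd.DataFrame, traj_b: pd.DataFrame,
                     frame_interval: float | None = None) -> SurfaceDistanceSeries:
    """Surface separation series for one trajectory pair.

    Evaluated on the union of sample times inside the overlapping support
    (so ≤1-frame offsets between the channels are bridged by linear
    interpolation).  Empty if the supports do not overlap.
    """
    pair = (int(traj_a["track_id"].iloc[0]), int(traj_b["track_id"].iloc[0]))
    a0, a1, at_a = _track_interp(traj_a)
    b0, b1, at_b = _track_interp(traj_b)
    lo, hi = max(a0, b0), min(a1, b1)
    if lo > hi:
        return SurfaceDistanceSeries(pair, np.empty(0), np.empty(0))
    times = np.union1d(traj_a["t"].to_numpy(), traj_b["t"].to_numpy())
    times = times[(times >= lo) & (times <= hi)]
    pa, ra = at_a(times)
    pb, rb = at_b(times)
    centre = np.linalg.norm(pa - pb, axis=1)
    sep = np.maximum(centre - ra - rb, 0.0)
    return SurfaceDistanceSeries(pair, times, sep)


def detect_collisions(series: SurfaceDistanceSeries,
                      cotrack_intervals: list[tuple[float, float]] | None = None,
                      config: EventConfig = EventConfig()) -> pd.DataFrame:
    """Strict sub-threshold local minima of the separation series.

    Minima inside any cotracking interval of the same pair are excluded so
    that conversion-like contact is not double-counted as collision, and
    minima of one pair closer than ``collision_merge_window`` s collapse
    to the deepest (one touch-and-go encounter, not several collisions).
    Returns a table (track_a, track_b, time, min_separation).
    """
    t, s = series.times, series.separation
    rows = []
    # compress runs of equal separation so a clipped-at-zero contact
    # plateau still registers as one local minimum (at its midpoint)
    seg_start = [0]
    for i in range(1, len(s)):
        if s[i] != s[seg_start[-1]]:
            seg_start.append(i)
    for k in range(1, len(seg_start) - 1):
        i0, i1 = seg_start[k], seg_start[k + 1] - 1
        val = s[i0]
        if not (val < s[seg_start[k - 1]] and val < s[seg_start[k + 1]]):
            continue
        if val >= config.collision_threshold:
            continue
        tmid = float(0.5 * (t[i0] + t[i1]))
        if cotrack_intervals and any(lo <= tmid <= hi
                                     for lo, hi in cotrack_intervals):
            continue
        rows.append({"track_a": series.pair[0], "track_b": series.pair[1],
                     "time": tmid, "min_separation": float(val)})
    merged: list[dict] = []
    for row in rows:  # rows are in time order
        if merged and row["time"] - merged[-1]["time"] < config.collision_merge_window:
            if row["min_separation"] < merged[-1]["min_separation"]:
                merged[-1] = row
            continue
        merged.append(row)
    return pd.DataFrame(merged, columns=["track_a", "track_b", "time",
                                         "min_separation"])


def _cotrack_interval(ta: pd.DataFrame, te: pd.DataFrame,
                      config: EventConfig) -> tuple[float, float] | None:
    """First ≥2-consecutive-frame window with centres within coloc_radius."""
    a = ta.sort_values("frame").set_index("frame")
    e = te.sort_values("frame").set_index("frame")
    common = a.index.intersection(e.index)
    if len(common) < 2:
        return None
    d = np.linalg.norm(a.loc[common, ["z", "y", "x"]].to_numpy()
                       - e.loc[common, ["z", "y", "x"]].to_numpy(), axis=1)
    close = d < config.coloc_radius
    frames = common.to_numpy()
    for i in range(len(frames) - 1):
        if close[i] and close[i + 1] and frames[i + 1] == frames[i] + 1:
            onset = float(a.loc[frames[i], "t"])
            end = float(a["t"].iloc[-1])  # APPL1 loss closes cotracking
            return onset, end, int(close.sum())
    return None


def close_contact_runs(ta: pd.DataFrame, te: pd.DataFrame,
                       config: EventConfig) -> list[tuple[float, float]]:
    """Maximal runs of ≥2 consecutive frames with centres within
    coloc_radius — the sustained-contact episodes of a pair.

    These (not the full cotracking-to-APPL1-loss window) are what is
    excluded from collision counting: a transient sub-threshold approach
    outside them is a genuine collision.
    """
    a = ta.sort_values("frame").set_index("frame")
    e = te.sort_values("frame").set_index("frame")
    common = a.index.intersection(e.index)
    if len(common) < 2:
        return []
    d = np.linalg.norm(a.loc[common, ["z", "y", "x"]].to_numpy()
                       - e.loc[common, ["z", "y", "x"]].to_numpy(), axis=1)
    close = d < config.coloc_radius
    frames = common.to_numpy()
    segments: list[list[int]] = []
    cur: list[int] = []
    for i in range(len(frames)):
        if close[i] and (not cur or frames[i] == frames[cur[-1]] + 1):
            cur.append(i)
        else:
            if len(cur) >= 2:
                segments.append(cur)
            cur = [i] if close[i] else []
    if len(cur) >= 2:
        segments.append(cur)
    return [(float(a.loc[frames[s[0]], "t"]), float(a.loc[frames[s[-1]], "t"]))
            for s in segments]


def extract_conversion_events(trajs_appl1: dict[int, pd.DataFrame],
                              trajs_eea1: dict[int, pd.DataFrame],
                              config: EventConfig = EventConfig(),
                              all_appl1: pd.DataFrame | None = None
                              ) -> tuple[pd.DataFrame, dict]:
    """Candidate maturation events with their cotracking intervals.

    A candidate pair must colocalise for ≥2 consecutive frames; it becomes
    an event iff (i) the APPL1 track's terminal intensity drops below
    ``appl1_terminal_fraction`` of its pre-interval median, (ii) the EEA1
    track persists ≥ ``eea1_persistence_frames`` after APPL1 loss, and
    (iii) no APPL1 signal reappears near the EEA1 track within
    ``no_reversion_window`` s (rejects reversions).

    One APPL1 endosome matures at most once (and one EEA1 track absorbs
    at most one APPL1 partner here), so when several pairs survive the
    filters, each track keeps the partner with the most colocalised
    frames: the true partner stays close for the whole window, passers-by
    only briefly.

    Returns the event table and {(a, e): (onset, end)} cotrack intervals
    (intervals are returned for all candidate pairs, so collision detection
    can exclude conversion-like minima even for rejected candidates).
    """
    rows = []
    intervals: dict[tuple[int, int], tuple[float, float]] = {}
    for aid, ta in trajs_appl1.items():
        ta = ta.sort_values("frame")
        for eid, te in trajs_eea1.items():
            te = te.sort_values("frame")
            iv = _cotrack_interval(ta, te, config)
            if iv is None:
                continue
            onset, end, n_close = iv
            intervals[(aid, eid)] = (onset, end)
            pre = ta[ta["t"] < onset]["intensity"]
            ref = float(pre.median()) if len(pre) else float(ta["intensity"].median())
            terminal = float(ta["intensity"].iloc[-1])
            if terminal > config.appl1_terminal_fraction * ref:
                continue
            appl1_end_frame = int(ta["frame"].iloc[-1])
            persist = (te["frame"] > appl1_end_frame).sum()
            if persist < config.eea1_persistence_frames:
                continue
            if _appl1_reverts(te, appl1_end_frame, config,
                              all_appl1 if all_appl1 is not None
                              else pd.concat(trajs_appl1.values())
                              if trajs_appl1 else None,
                              exclude=aid):
                continue
            rows.append({
                "appl1_track": aid, "eea1_track": eid,
                "cotrack_onset": onset,
                "cotrack_duration": end - onset,
                "n_close_frames": n_close,
            })
    events = pd.DataFrame(rows, columns=["appl1_track", "eea1_track",
                                         "cotrack_onset", "cotrack_duration",
                                         "n_close_frames"])
    if len(events):
        events = (events.sort_values(["n_close_frames", "cotrack_onset"],
                                     ascending=[False, True])
                  .drop_duplicates("appl1_track"))
        # an EEA1 endosome may take part in several events, but not in
        # two with overlapping cotracking windows (those are duplicate
        # claims on the same physical episode)
        keep = []
        claimed: dict[int, list[tuple[float, float]]] = {}
        for idx, ev in events.iterrows():
            lo = ev["cotrack_onset"]
            hi = lo + ev["cotrack_duration"]
            spans = claimed.setdefault(int(ev["eea1_track"]), [])
            if any(lo <= h and l <= hi for l, h in spans):
                continue
            spans.append((lo, hi))
            keep.append(idx)
        events = (events.loc[keep]
                  .sort_values("cotrack_onset").reset_index(drop=True))
    return events, intervals


def _appl1_reverts(te: pd.DataFrame, appl1_end_frame: int,
                   config: EventConfig, all_appl1: pd.DataFrame | None,
                   exclude: int) -> bool:
    if all_appl1 is None or len(all_appl1) == 0:
        return False
    t_end = float(te[te["frame"] <= appl1_end_frame]["t"].iloc[-1]) \
        if (te["frame"] <= appl1_end_frame).any() else float(te["t"].iloc[0])
    win = all_appl1[(all_appl1["t"] > t_end)
                    & (all_appl1["t"] <= t_end + config.no_reversion_window)
                    & (all_appl1["track_id"] != exclude)]
    if len(win) == 0:
        return False
    e = te.set_index("frame")
    for _, r in win.iterrows():
        f = int(r["frame"])
        if f in e.index:
            d = np.linalg.norm(e.loc[f, ["z", "y", "x"]].to_numpy()
                               - r[["z", "y", "x"]].to_numpy(dtype=float))
            if d < config.coloc_radius:
                return True
    return False


def classify_kind(event: pd.Series, trajs_eea1: dict[int, pd.DataFrame],
                  config: EventConfig = EventConfig(),
                  frame_interval: float = 3.0) -> str:
    """'fusion' iff the EEA1 track pre-existed cotracking by ≥2 frames.

    Besides the birth-time test, the partner's intensity is cross-checked:
    a conversion's EEA1 signal appears dim and ramps up, so if the track's
    intensity around onset drops below ``eea1_newborn_fraction`` of its
    pre-onset median, the "pre-existing" track is a linking artefact that
    absorbed a newly appearing signal, and the event is a conversion.
    """
    te = trajs_eea1[int(event["eea1_track"])].sort_values("t")
    onset = float(event["cotrack_onset"])
    birth = float(te["t"].min())
    margin = config.fusion_preexist_frames * frame_interval
    if birth > onset - margin:
        return "conversion"
    pre = te[te["t"] < onset]["intensity"]
    at_onset = te[(te["t"] >= onset)
                  & (te["t"] <= onset + frame_interval)]["intensity"]
    if len(pre) >= 2 and len(at_onset):
        if float(at_onset.min()) < config.eea1_newborn_fraction * float(pre.median()):
            return "conversion"
    return "fusion"


def classify_induction(event: pd.Series, collisions: pd.DataFrame,
                       config: EventConfig = EventConfig()) -> tuple[str, int]:
    """Count collisions of the event's APPL1 track with *any* EEA1 track
    in the pre-event window; ≥1 makes the event collision-induced."""
    onset = float(event["cotrack_onset"])
    if len(collisions) == 0:
        return "unaided", 0
    sel = collisions[(collisions["track_a"] == event["appl1_track"])
                     & (collisions["time"] >= onset - config.pre_event_window)
                     & (collisions["time"] < onset)]
    n = int(len(sel))
    return ("collision-induced" if n >= 1 else "unaided"), n


def analyse(trajectories: pd.DataFrame,
            config: EventConfig = EventConfig(),
            frame_interval: float | None = None
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full event analysis of a linked two-channel trajectory table.

    Returns (events, collisions).  Events carry kind, induction and the
    preceding-collision count.
    """
    if frame_interval is None:
        t = np.sort(trajectories["t"].unique())
        frame_interval = float(np.min(np.diff(t))) if len(t) > 1 else 1.0
    appl1 = {int(tid): g for tid, g in
             trajectories[trajectories.channel == "APPL1"].groupby("track_id")}
    eea1 = {int(tid): g for tid, g in
            trajectories[trajectories.channel == "EEA1"].groupby("track_id")}

    events, intervals = extract_conversion_events(appl1, eea1, config)

    coll_rows = []
    for aid, ta in appl1.items():
        for eid, te in eea1.items():
            series = surface_distance(ta, te)
            if len(series.times) == 0:
                continue
            runs = close_contact_runs(ta, te, config)
            found = detect_collisions(series, runs or None, config)
            if len(found):
                coll_rows.append(found)
    collisions = (pd.concat(coll_rows, ignore_index=True) if coll_rows
                  else pd.DataFrame(columns=["track_a", "track_b", "time",
                                             "min_separation"]))

    kinds, inductions, counts = [], [], []
    for _, ev in events.iterrows():
        kinds.append(classify_kind(ev, eea1, config, frame_interval))
        label, n = classify_induction(ev, collisions, config)
        inductions.append(label)
        counts.append(n)
    events = events.assign(kind=kinds, induction=inductions,
                           n_preceding_collisions=counts)
    return events, collisions


def summarize(events: pd.DataFrame,
              config: EventConfig = EventConfig(),
              normalise: str = "global") -> dict:
    """Cohort heatmap and category counts.

    The heatmap is the fraction of events per (cotracking-duration 10-s
    bin, preceding-collision count) cell; ``normalise`` is 'global'
    (fractions sum to 1 over all cells) or 'row'.
    """
    if len(events) == 0:
        return {"heatmap": pd.DataFrame(), "counts": {}}
    max_dur = float(events["cotrack_duration"].max())
    n_bins = max(1, int(np.ceil((max_dur + 1e-9) / config.cohort_bin)))
    edges = np.arange(n_bins + 1) * config.cohort_bin
    dur_bin = np.clip(np.digitize(events["cotrack_duration"], edges) - 1,
                      0, n_bins - 1)
    max_coll = int(events["n_preceding_collisions"].max())
    heat = np.zeros((n_bins, max_coll + 1))
    for db, nc in zip(dur_bin, events["n_preceding_collisions"]):
        heat[db, int(nc)] += 1
    if normalise == "row":
        sums = heat.sum(axis=1, keepdims=True)
        heat = np.divide(heat, sums, out=np.zeros_like(heat), where=sums > 0)
    else:
        heat = heat / heat.sum()
    heatmap = pd.DataFrame(
        heat,
        index=[f"{edges[i]:.0f}-{edges[i + 1]:.0f}s" for i in range(n_bins)],
        columns=[str(c) for c in range(max_coll + 1)])
    counts = {}
    for kind in ("fusion", "conversion"):
        for ind in ("unaided", "collision-induced"):
            counts[f"{ind} {kind}"] = int(((events["kind"] == kind)
                                           & (events["induction"] == ind)).sum())
    return {"heatmap": heatmap, "counts": counts}


def evaluate_against_truth(detected: pd.DataFrame, truth: pd.DataFrame,
                           time_tolerance: float = 6.0) -> pd.DataFrame:
    """Per-event-type precision/recall/F1 by greedy one-to-one matching.

    Both tables need ``event_type`` and ``time`` columns in the same time
    base.  Detections are matched to the nearest unmatched truth event of
    the same type within the tolerance.
    """
    types = sorted(set(truth["event_type"]) | set(detected["event_type"])) \
        if len(truth) or len(detected) else []
    rows = []
    for etype in types:
        det_t = np.sort(detected[detected.event_type == etype]["time"].to_numpy())
        tru_t = truth[truth.event_type == etype]["time"].to_numpy()
        matched = np.zeros(len(tru_t), dtype=bool)
        tp = 0
        for td in det_t:
            diffs = np.abs(tru_t - td)
            diffs[matched] = np.inf
            if len(diffs) and diffs.min() <= time_tolerance:
                matched[int(np.argmin(diffs))] = True
                tp += 1
        fp = len(det_t) - tp
        fn = len(tru_t) - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows.append({"event_type": etype, "tp": tp, "fp": fp, "fn": fn,
                     "precision": prec, "recall": rec, "f1": f1})
    return pd.DataFrame(rows)
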