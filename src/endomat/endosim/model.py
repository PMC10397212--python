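"""Run-level and ensemble-level drivers for the surface simulator."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import SurfaceGrid, build_grid
from .kernel import run_kernel
from .params import SimParams, DEFAULT_PARAMS

__all__ = ["SimTrace", "EnsembleResult", "run", "ensemble",
           "histogram_mode"]

COUNT_COLUMNS = ["appl1", "inpp4a", "nt_eea1", "ct_eea1", "pi34p2", "pi3p"]


@dataclass
class SimTrace:
    """Recorded count time series of one run.

    ``conversion_time`` is the first time the PI(3)P node fraction reaches
    the threshold; None when the run was censored at t_max.
    """

    times: np.ndarray
    counts: pd.DataFrame
    conversion_time: float | None
    collision_times: np.ndarray
    n_collisions_before_conversion: int
    n_nodes: int

    @property
    def censored(self) -> bool:
        return self.conversion_time is None

    def to_frame(self) -> pd.DataFrame:
        out = self.counts.copy()
        out.insert(0, "t", self.times)
        return out


@dataclass
class EnsembleResult:
    """Conversion-time samples of independent runs, stratified by the
    number of collisions each run experienced before converting."""

    conversion_times: np.ndarray          # censored runs excluded
    collision_counts: np.ndarray          # same length, per completed run
    censored_fraction: float
    bin_width: float = 10.0
    min_stratum: int = 20

    def stratum_times(self, n_collisions: int) -> np.ndarray:
        return self.conversion_times[self.collision_counts == n_collisions]

    def stratum_mode(self, n_collisions: int) -> float | None:
        """10-s-bin histogram mode of one stratum (None below min size)."""
        t = self.stratum_times(n_collisions)
        if len(t) < self.min_stratum:
            return None
        return histogram_mode(t, self.bin_width)

    def modes(self) -> dict[int, float]:
        out = {}
        for k in np.unique(self.collision_counts):
            m = self.stratum_mode(int(k))
            if m is not None:
                out[int(k)] = m
        return out


def histogram_mode(samples: np.ndarray, bin_width: float = 10.0) -> float:
    """Bin-centre of the maximal fixed-width histogram bin (ties: earliest)."""
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("no samples")
    n_bins = int(np.floor(samples.max() / bin_width)) + 1
    edges = np.arange(n_bins + 1) * bin_width
    hist, _ = np.histogram(samples, bins=edges)
    best = int(np.argmax(hist))  # argmax takes the earliest maximal bin
    return float((edges[best] + edges[best + 1]) / 2)


def run(params: SimParams = DEFAULT_PARAMS, seed: int = 0,
        collision_times: np.ndarray | None = None,
        grid: SurfaceGrid | None = None) -> SimTrace:
    """One seeded simulation run.

    ``collision_times`` overrides the Poisson schedule implied by
    ``params.collision_rate``; pass an empty array for an isolated
    endosome.
    """
    if grid is None:
        grid = build_grid(params.n_nodes, params.k_neighbors)
    rng = np.random.default_rng(seed)
    if collision_times is None:
        collision_times = poisson_schedule(params, rng)
    collision_times = np.sort(np.asarray(collision_times, dtype=float))
    kseed = int(rng.integers(0, 2**31 - 1))
    times, counts, conv, applied = run_kernel(
        grid.n_nodes, grid.nbr, grid.nbr_ptr, grid.nbr2, grid.nbr2_ptr,
        params.rate_vector(), params.cluster_attach, params.cluster_detach,
        params.recent_window, params.clustering,
        params.p_convert, params.p_jump,
        collision_times, params.collision_influx, params.influx_window,
        params.theta, params.dt, params.t_max, params.burn_in,
        params.record_every, kseed)
    return SimTrace(
        times=times,
        counts=pd.DataFrame(counts, columns=COUNT_COLUMNS),
        conversion_time=None if conv < 0 else float(conv),
        collision_times=collision_times,
        n_collisions_before_conversion=int(applied),
        n_nodes=grid.n_nodes)


def poisson_schedule(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Poisson collision times over [0, t_max) at params.collision_rate."""
    lam = params.collision_rate
    if lam <= 0:
        return np.empty(0)
    n = rng.poisson(lam * params.t_max)
    return np.sort(rng.uniform(0, params.t_max, n))


def ensemble(params: SimParams = DEFAULT_PARAMS, n_reps: int = 500,
             seed: int = 0, bin_width: float = 10.0,
             collision_times: np.ndarray | None = None) -> EnsembleResult:
    """Independent seeded runs with Poisson (or fixed) collision schedules.

    Completed runs are stratified by the number of collisions applied
    before conversion; censored runs only contribute to the censoring
    fraction.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    grid = build_grid(params.n_nodes, params.k_neighbors)
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=n_reps)
    conv, colls = [], []
    n_censored = 0
    for s in seeds:
        tr = run(params, seed=int(s), collision_times=collision_times,
                 grid=grid)
        if tr.censored:
            n_censored += 1
        else:
            conv.append(tr.conversion_time)
            colls.append(tr.n_collisions_before_conversion)
    return EnsembleResult(
        conversion_times=np.asarray(conv),
        collision_counts=np.asarray(colls, dtype=int),
        censored_fraction=n_censored / n_reps,
        bin_width=bin_width)
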