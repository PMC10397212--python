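"""File I/O: OME-TIFF movies with sidecar metadata, tidy CSV tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .syndata import SyntheticMovie

__all__ = ["write_movie", "read_movie"]


def write_movie(movie: SyntheticMovie, path) -> None:
    """Write a movie as OME-TIFF (TCZYX) plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(
        path, movie.intensity.astype(np.float32),
        metadata={
            "axes": "TCZYX",
            "PhysicalSizeZ": movie.voxel_size[0],
            "PhysicalSizeY": movie.voxel_size[1],
            "PhysicalSizeX": movie.voxel_size[2],
            "TimeIncrement": movie.frame_interval,
        })
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "voxel_size": list(movie.voxel_size),
        "frame_interval": movie.frame_interval,
        "channel_names": list(movie.channel_names),
    }))


def read_movie(path) -> SyntheticMovie:
    """Read a movie written by :func:`write_movie`."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim != 5:
        raise ValueError("expected a TCZYX stack")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text())
    return SyntheticMovie(
        intensity=np.asarray(data, dtype=float),
        voxel_size=tuple(meta["voxel_size"]),
        frame_interval=float(meta["frame_interval"]),
        channel_names=tuple(meta["channel_names"]))
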