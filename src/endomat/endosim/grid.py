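"""Bi-layered Fibonacci-sphere lattice.

The endosome surface is a near-uniform spherical point set (Fibonacci
lattice) in which each node carries two stacked sites: a Rab5 site
(protein layer) and a phosphoinositide site (lipid layer).  Neighbourhoods
are k-nearest-neighbour lists symmetrised to a mutual relation; "adjacent
across layers" means the same node or one of its lattice neighbours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["SurfaceGrid", "build_grid", "fibonacci_sphere"]


def fibonacci_sphere(n_nodes: int) -> np.ndarray:
    """Unit-sphere Fibonacci lattice: n approximately equidistant points."""
    i = np.arange(n_nodes)
    golden = (1 + np.sqrt(5)) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - (2 * i + 1) / n_nodes
    r = np.sqrt(np.maximum(1 - z * z, 0.0))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


@dataclass
class SurfaceGrid:
    """Lattice coordinates plus CSR neighbour structure.

    ``nbr`` / ``nbr_ptr`` hold the symmetrised k-NN lists; ``nbr2`` /
    ``nbr2_ptr`` the distance-≤2 neighbourhood (used for the phosphatase's
    post-conversion jump).
    """

    coords: np.ndarray
    nbr: np.ndarray
    nbr_ptr: np.ndarray
    nbr2: np.ndarray
    nbr2_ptr: np.ndarray

    @property
    def n_nodes(self) -> int:
        return len(self.coords)

    def neighbors(self, i: int) -> np.ndarray:
        return self.nbr[self.nbr_ptr[i]:self.nbr_ptr[i + 1]]

    def spacing_ratio(self) -> float:
        """Max/min nearest-neighbour spacing over the lattice."""
        tree = cKDTree(self.coords)
        d, _ = tree.query(self.coords, k=2)
        nn = d[:, 1]
        return float(nn.max() / nn.min())


def build_grid(n_nodes: int = 400, k_neighbors: int = 6) -> SurfaceGrid:
    """Build the simulation lattice.

    k-NN lists are symmetrised by union, so every list has length ≥ k and
    the neighbour relation is mutual.
    """
    if n_nodes < 50:
        raise ValueError("n_nodes must be >= 50")
    if k_neighbors < 3:
        raise ValueError("k_neighbors must be >= 3")
    coords = fibonacci_sphere(n_nodes)
    tree = cKDTree(coords)
    _, idx = tree.query(coords, k=k_neighbors + 1)
    sets = [set() for _ in range(n_nodes)]
    for i in range(n_nodes):
        for j in idx[i, 1:]:
            sets[i].add(int(j))
            sets[int(j)].add(i)

    def to_csr(neigh_sets):
        ptr = np.zeros(n_nodes + 1, dtype=np.int32)
        for i, s in enumerate(neigh_sets):
            ptr[i + 1] = ptr[i] + len(s)
        flat = np.empty(ptr[-1], dtype=np.int32)
        for i, s in enumerate(neigh_sets):
            flat[ptr[i]:ptr[i + 1]] = sorted(s)
        return flat, ptr

    nbr, nbr_ptr = to_csr(sets)
    sets2 = []
    for i in range(n_nodes):
        s2 = set(sets[i])
        for j in sets[i]:
            s2 |= sets[j]
        s2.discard(i)
        sets2.append(s2)
    nbr2, nbr2_ptr = to_csr(sets2)
    return SurfaceGrid(coords=coords, nbr=nbr, nbr_ptr=nbr_ptr,
                       nbr2=nbr2, nbr2_ptr=nbr2_ptr)
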