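"""Cubic octree decomposition of a boxed system.

A depth-d tree subdivides the cubic box into 8^l cells at every level
l <= d.  The deepest level carries the particle occupancy; near-field
neighbor sets and the classical well-separated ("interaction") lists are
derived per level.  Boundaries are open: there is no periodic wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .systems import ParticleSystem


@dataclass
class Octree:
    """Depth-d hierarchy of cubic cells over a box of edge ``box_side``.

    Cells at level l are addressed by integer triples in [0, 2^l)^3 and
    stored as flat C-order indices ix*4^l + iy*2^l + iz.  Only occupancy at
    the deepest level is materialized; ``occupied(level)`` derives the
    occupied set at coarser levels.
    """

    depth: int
    box_side: float
    cell_of_particle: np.ndarray          # (N,) flat deepest-level cell ids
    occupancy: dict = field(repr=False)   # deepest cell id -> particle index array

    def n_cells_per_side(self, level: int) -> int:
        return 1 << level

    def cell_edge(self, level: int) -> float:
        return self.box_side / (1 << level)

    def cell_center(self, level: int, cell) -> np.ndarray:
        edge = self.cell_edge(level)
        return (np.asarray(self.unflatten(level, cell)) + 0.5) * edge

    def flatten(self, level: int, triple) -> int:
        ns = 1 << level
        ix, iy, iz = triple
        return int((ix * ns + iy) * ns + iz)

    def unflatten(self, level: int, cell: int):
        ns = 1 << level
        cell = int(cell)
        return (cell // (ns * ns), (cell // ns) % ns, cell % ns)

    def parent(self, level: int, cell: int) -> int:
        ix, iy, iz = self.unflatten(level, cell)
        return self.flatten(level - 1, (ix >> 1, iy >> 1, iz >> 1))

    def children(self, level: int, cell: int):
        """Flat ids of the 8 children at level+1."""
        ix, iy, iz = self.unflatten(level, cell)
        out = []
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    out.append(self.flatten(level + 1,
                                            (2 * ix + dx, 2 * iy + dy, 2 * iz + dz)))
        return out

    def occupied(self, level: int) -> np.ndarray:
        """Sorted flat ids of occupied cells at the given level."""
        cells = np.fromiter(self.occupancy.keys(), dtype=np.int64)
        shift = self.depth - level
        if shift:
            triples = np.array([self.unflatten(self.depth, c) for c in cells])
            triples >>= shift
            ns = 1 << level
            cells = (triples[:, 0] * ns + triples[:, 1]) * ns + triples[:, 2]
        return np.unique(cells)

    def describe(self) -> dict:
        """Per-level cell counts and an occupancy histogram (for --describe-tree)."""
        counts = np.array([len(v) for v in self.occupancy.values()])
        hist, edges = np.histogram(counts, bins=min(10, max(1, counts.size)))
        return {
            "depth": self.depth,
            "box_side_nm": self.box_side,
            "cells_per_level": {l: 8 ** l for l in range(self.depth + 1)},
            "occupied_deepest": int(counts.size),
            "occupancy_histogram": {
                "bin_edges": edges.tolist(),
                "counts": hist.tolist(),
            },
        }


def build_octree(system: ParticleSystem, depth: int) -> Octree:
    """Assign every particle of a boxed system to its deepest-level cell.

    Cells are found by floor(position / cell_edge); particles sitting
    exactly on the upper box boundary are clamped into the last cell.
    """
    if system.box_side is None:
        raise ValueError("system must be placed in a cubic box first")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    ns = 1 << depth
    edge = system.box_side / ns
    ijk = np.floor(system.positions / edge).astype(np.int64)
    # clamp exact-boundary particles into the final cell
    np.clip(ijk, 0, ns - 1, out=ijk)
    outside = (system.positions < -1e-9) | (system.positions > system.box_side + 1e-9)
    if np.any(outside):
        bad = int(np.nonzero(outside.any(axis=1))[0][0])
        raise ValueError(f"particle {bad} lies outside the box")
    flat = (ijk[:, 0] * ns + ijk[:, 1]) * ns + ijk[:, 2]
    order = np.argsort(flat, kind="stable")
    sorted_cells = flat[order]
    boundaries = np.flatnonzero(np.diff(sorted_cells)) + 1
    groups = np.split(order, boundaries)
    occupancy = {int(g_cells): g for g_cells, g in
                 zip(sorted_cells[np.r_[0, boundaries]], groups)}
    return Octree(depth=depth, box_side=float(system.box_side),
                  cell_of_particle=flat, occupancy=occupancy)


def near_field_cells(tree: Octree, cell: int) -> list[int]:
    """The deepest-level cell itself plus every deepest-level cell sharing a
    face, edge or corner with it (up to 27 in total; fewer at the walls)."""
    level = tree.depth
    ns = tree.n_cells_per_side(level)
    ix, iy, iz = tree.unflatten(level, cell)
    out = []
    for dx in (-1, 0, 1):
        jx = ix + dx
        if not 0 <= jx < ns:
            continue
        for dy in (-1, 0, 1):
            jy = iy + dy
            if not 0 <= jy < ns:
                continue
            for dz in (-1, 0, 1):
                jz = iz + dz
                if 0 <= jz < ns:
                    out.append(tree.flatten(level, (jx, jy, jz)))
    return sorted(out)


def interaction_list(tree: Octree, cell: int, level: int,
                     occupied_only: bool = False) -> list[int]:
    """Classical well-separated list of a cell at the given level (>= 2).

    Children of the 27-neighborhood of the cell's parent that are not in the
    cell's own 27-neighborhood: at most 189 cells in the interior.  These
    are exactly the cells handled by M2L at this level.  When
    ``occupied_only`` is set, cells with no particles are dropped.
    """
    if level < 2:
        return []
    ns = tree.n_cells_per_side(level)
    ix, iy, iz = tree.unflatten(level, cell)
    px, py, pz = ix >> 1, iy >> 1, iz >> 1
    nsp = ns >> 1
    out = []
    for qx in range(max(0, px - 1), min(nsp, px + 2)):
        for qy in range(max(0, py - 1), min(nsp, py + 2)):
            for qz in range(max(0, pz - 1), min(nsp, pz + 2)):
                for cx in (2 * qx, 2 * qx + 1):
                    for cy in (2 * qy, 2 * qy + 1):
                        for cz in (2 * qz, 2 * qz + 1):
                            if max(abs(cx - ix), abs(cy - iy), abs(cz - iz)) >= 2:
                                out.append(tree.flatten(level, (cx, cy, cz)))
    out.sort()
    if occupied_only:
        occ = set(int(c) for c in tree.occupied(level))
        out = [c for c in out if c in occ]
    return out
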