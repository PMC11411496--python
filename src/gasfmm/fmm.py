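"""The fast-multipole Coulomb solver: tree + operator pipeline + tallies.

Pipeline for a boxed system at settings (d, p): build the depth-d octree,
P2M on the deepest level, M2M up to level 2, M2L across every level's
well-separated lists, L2L down, and L2P plus explicit near-field pair
summation at the deepest level.  Near-field pairs use exactly the same
kernels as the direct oracle; with d = 0 the solver degenerates to the
oracle itself, bit for bit.  Traversal order is deterministic (sorted cell
indices), so fixed inputs give bit-stable outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import harmonics as _h
from .constants import COULOMB_K
from .direct import ForceResult, _accumulate_cross, _accumulate_self, _BLOCK, coulomb_direct
from .octree import Octree, build_octree, interaction_list, near_field_cells
from .systems import ParticleSystem


@dataclass(frozen=True)
class FmmSettings:
    """Octree depth d and multipole truncation order p.  d = 0 forces pure
    direct summation regardless of p."""

    depth: int
    order: int

    def __post_init__(self):
        if self.depth < 0 or self.order < 0:
            raise ValueError("depth and order must be >= 0")

    def __str__(self):
        return f"fmm(d={self.depth},p={self.order})"


#: cost-model constants for the scalar operation tally, in real flops:
#: one near-field pair interaction (difference, dot product, rsqrt and
#: scale, force accumulation) and one complex multiply-add, of which an
#: M2L/M2M/L2L translation performs (p+1)^4 and a per-particle expansion
#: pass (p+1)^2.
NEAR_PAIR_FLOPS = 25.0
COMPLEX_MADD_FLOPS = 8.0


@dataclass
class OperationTally:
    """Counts of the work the solver performs for one force evaluation."""

    settings: FmmSettings
    near_field_pairs: int
    m2l_translations: int
    m2m_translations: int
    l2l_translations: int
    p2m_particles: int
    l2p_particles: int

    @property
    def weighted_total(self) -> float:
        """Scalar cost in flop units: near pairs at
        :data:`NEAR_PAIR_FLOPS` each, cell translations at 8(p+1)^4,
        per-particle expansion passes at 8(p+1)^2."""
        p1 = self.settings.order + 1
        return (
            NEAR_PAIR_FLOPS * self.near_field_pairs
            + COMPLEX_MADD_FLOPS * p1 ** 4 * (
                self.m2l_translations + self.m2m_translations
                + self.l2l_translations)
            + COMPLEX_MADD_FLOPS * p1 ** 2 * (
                self.p2m_particles + self.l2p_particles)
        )


class FmmCalculator:
    """Reusable FMM state for one boxed system at one tree depth.

    Separating the depth-d near field (independent of p) from the far
    field lets accuracy sweeps over p reuse the expensive near-field pair
    summation.
    """

    def __init__(self, system: ParticleSystem, depth: int):
        self.system = system
        self.depth = depth
        self._near = None
        self._tally_near = 0
        if depth >= 1:
            self.tree = build_octree(system, depth)
            order = np.argsort(self.tree.cell_of_particle, kind="stable")
            self._order = order
            self._pos = system.positions[order]
            self._q = system.charges[order]
            self._cells = self.tree.cell_of_particle[order]
            starts = np.r_[0, np.flatnonzero(np.diff(self._cells)) + 1]
            self._starts = starts
            self._occ_d = self._cells[starts]
        else:
            self.tree = None

    # -- near field ---------------------------------------------------------

    def near_field(self):
        """Explicit pair forces/energy within and between adjacent deepest
        cells (computed once, independent of p)."""
        if self._near is not None:
            return self._near
        n = self.system.n
        forces = np.zeros((n, 3))
        energy = 0.0
        npairs = 0
        slices = {int(c): (self._starts[i],
                           self._starts[i + 1] if i + 1 < len(self._starts) else n)
                  for i, c in enumerate(self._occ_d)}
        for c in sorted(slices):
            a0, a1 = slices[c]
            energy += _tiled_self(self._pos[a0:a1], self._q[a0:a1],
                                  forces[a0:a1], self._order[a0:a1])
            na = a1 - a0
            npairs += na * (na - 1) // 2
            for cn in near_field_cells(self.tree, c):
                if cn <= c or cn not in slices:
                    continue
                b0, b1 = slices[cn]
                energy += _tiled_cross(self._pos[a0:a1], self._q[a0:a1],
                                       self._pos[b0:b1], self._q[b0:b1],
                                       forces[a0:a1], forces[b0:b1],
                                       self._order[a0:a1], self._order[b0:b1])
                npairs += na * (b1 - b0)
        out = np.zeros((n, 3))
        out[self._order] = forces
        self._near = (out, energy)
        self._tally_near = npairs
        return self._near

    # -- far field ----------------------------------------------------------

    def far_field(self, p: int):
        """Multipole far-field forces and energy at truncation order p."""
        n = self.system.n
        if self.depth < 2:
            return np.zeros((n, 3)), 0.0, 0
        tree = self.tree
        d = self.depth

        # upward: P2M at the deepest level
        centers = _cell_centers(tree, d, self._cells)
        disp = self._pos - centers
        R = _h.regular_tables(disp, p)
        M = {d: np.add.reduceat(self._q[:, None] * R, self._starts, axis=0)}
        occ = {d: self._occ_d}
        trip = {d: _unflatten(self._occ_d, d)}
        parent_row = {}
        parity = {}
        for level in range(d - 1, 1, -1):
            child_trip = trip[level + 1]
            pt = child_trip >> 1
            pflat = _flatten(pt, level)
            occ[level], inv = np.unique(pflat, return_inverse=True)
            parent_row[level + 1] = inv
            trip[level] = _unflatten(occ[level], level)
            parity[level + 1] = ((child_trip[:, 0] & 1) << 2 |
                                 (child_trip[:, 1] & 1) << 1 |
                                 (child_trip[:, 2] & 1))
            Mp = np.zeros((occ[level].size, _h.n_coeffs(p)), dtype=np.complex128)
            e_child = tree.cell_edge(level + 1)
            for par in range(8):
                sel = parity[level + 1] == par
                if not np.any(sel):
                    continue
                t = (np.array([par >> 2 & 1, par >> 1 & 1, par & 1]) - 0.5) * e_child
                A = _h.m2m_matrix(t, p)
                np.add.at(Mp, inv[sel], M[level + 1][sel] @ A.T)
            M[level] = Mp

        # downward: M2L per level, L2L to children
        L = {2: np.zeros_like(M[2])}
        m2l_count = 0
        for level in range(2, d + 1):
            row_of = {int(c): i for i, c in enumerate(occ[level])}
            edge = tree.cell_edge(level)
            groups = {}
            tl = trip[level]
            for i, c in enumerate(occ[level]):
                for s in interaction_list(tree, int(c), level):
                    j = row_of.get(s)
                    if j is None:
                        continue
                    off = tuple(tl[j] - tl[i])
                    groups.setdefault(off, ([], []))
                    groups[off][0].append(i)
                    groups[off][1].append(j)
            for off in sorted(groups):
                t_rows, s_rows = groups[off]
                C = _h.m2l_matrix(np.asarray(off, dtype=float) * edge, p)
                L[level][t_rows] += M[level][s_rows] @ C.T
                m2l_count += len(t_rows)
            if level < d:
                Lc = np.zeros((occ[level + 1].size, _h.n_coeffs(p)),
                              dtype=np.complex128)
                e_child = tree.cell_edge(level + 1)
                for par in range(8):
                    sel = parity[level + 1] == par
                    if not np.any(sel):
                        continue
                    t = (np.array([par >> 2 & 1, par >> 1 & 1, par & 1]) - 0.5) * e_child
                    B = _h.l2l_matrix(t, p)
                    Lc[sel] = L[level][parent_row[level + 1][sel]] @ B.T
                L[level + 1] = Lc

        # L2P: evaluate local expansions at the particles
        rows = np.searchsorted(occ[d], self._cells)
        phi, grad = _h.evaluate_local(L[d][rows], disp, p)
        forces = np.zeros((n, 3))
        forces[self._order] = -COULOMB_K * self._q[:, None] * grad
        energy = 0.5 * COULOMB_K * float(np.dot(self._q, phi))
        return forces, energy, m2l_count

    def forces(self, p: int) -> ForceResult:
        near_f, near_e = self.near_field()
        far_f, far_e, _ = self.far_field(p)
        return ForceResult(near_f + far_f, near_e + far_e,
                           provenance=str(FmmSettings(self.depth, p)))


def fmm_forces(system: ParticleSystem, settings: FmmSettings) -> ForceResult:
    """FMM Coulomb forces and energy; with ``settings.depth == 0`` this is
    explicit pairwise summation, identical to :func:`coulomb_direct`."""
    if settings.depth == 0:
        res = coulomb_direct(system)
        return ForceResult(res.forces, res.potential_energy,
                           provenance=str(settings))
    if system.box_side is None:
        raise ValueError("FMM requires a cubic box; call place_in_cubic_box first")
    calc = FmmCalculator(system, settings.depth)
    return calc.forces(settings.order)


# ---------------------------------------------------------------------------
# operation counting (no force math; occupancy-grid arithmetic only)
# ---------------------------------------------------------------------------

def count_operations(system: ParticleSystem, settings: FmmSettings) -> OperationTally:
    """Tally the work one force evaluation at these settings would perform:
    near-field pair interactions, M2L/M2M/L2L translations between occupied
    cells, and per-particle expansion passes.  Empty cells contribute
    nothing."""
    n = system.n
    d, p = settings.depth, settings.order
    if d == 0:
        return OperationTally(settings, n * (n - 1) // 2, 0, 0, 0, 0, 0)
    if system.box_side is None:
        raise ValueError("FMM tallies require a cubic box")
    tree = build_octree(system, d)
    ns = 1 << d
    counts = np.bincount(tree.cell_of_particle, minlength=ns ** 3)
    grid = counts.reshape(ns, ns, ns)
    kernel = np.ones((3, 3, 3))
    neigh = ndimage.correlate(grid.astype(float), kernel, mode="constant")
    near_pairs = int(round((float((grid * neigh).sum()) - n) / 2.0))
    if d < 2:
        # d = 1: every cell pair is adjacent, all work is near-field
        return OperationTally(settings, near_pairs, 0, 0, 0, 0, 0)

    m2l = 0
    m2m = 0
    l2l = 0
    occ_child = grid > 0
    for level in range(d, 1, -1):
        occ = occ_child
        ind = occ.astype(float)
        own = ndimage.correlate(ind, kernel, mode="constant")
        nsp = 1 << (level - 1)
        child_per_parent = ind.reshape(nsp, 2, nsp, 2, nsp, 2).sum(axis=(1, 3, 5))
        parents = ndimage.correlate(child_per_parent, kernel, mode="constant")
        # count1 per occupied target = occupied children of parent 27-hood
        big = np.repeat(np.repeat(np.repeat(parents, 2, 0), 2, 1), 2, 2)
        m2l += int(round(float((big[occ] - own[occ]).sum())))
        if level > 2:
            m2m += int(occ.sum())
            l2l += int(occ.sum())
        occ_child = child_per_parent > 0
    return OperationTally(settings, near_pairs, m2l, m2m, l2l, n, n)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _unflatten(flat: np.ndarray, level: int) -> np.ndarray:
    ns = 1 << level
    flat = np.asarray(flat, dtype=np.int64)
    return np.stack([flat // (ns * ns), (flat // ns) % ns, flat % ns], axis=1)


def _flatten(trip: np.ndarray, level: int) -> np.ndarray:
    ns = 1 << level
    return (trip[:, 0] * ns + trip[:, 1]) * ns + trip[:, 2]


def _cell_centers(tree: Octree, level: int, cells: np.ndarray) -> np.ndarray:
    edge = tree.cell_edge(level)
    return (_unflatten(cells, level) + 0.5) * edge


def _tiled_cross(pos_a, q_a, pos_b, q_b, f_a, f_b, idx_a, idx_b) -> float:
    """Chunked mutual forces between two disjoint sets (memory-bounded)."""
    nb = pos_b.shape[0]
    step = max(1, int(_BLOCK * _BLOCK // max(nb, 1)))
    energy = 0.0
    for a0 in range(0, pos_a.shape[0], step):
        a1 = min(a0 + step, pos_a.shape[0])
        energy += _accumulate_cross(pos_a[a0:a1], q_a[a0:a1], pos_b, q_b,
                                    f_a[a0:a1], f_b, idx_a[a0:a1], idx_b)
    return energy


def _tiled_self(pos, q, f, idx) -> float:
    """Chunked all-pairs forces within one set."""
    n = pos.shape[0]
    energy = 0.0
    for a0 in range(0, n, _BLOCK):
        a1 = min(a0 + _BLOCK, n)
        energy += _accumulate_self(pos[a0:a1], q[a0:a1], f[a0:a1], idx[a0:a1])
        if a1 < n:
            energy += _tiled_cross(pos[a0:a1], q[a0:a1], pos[a1:], q[a1:],
                                   f[a0:a1], f[a1:], idx[a0:a1], idx[a1:])
    return energy
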