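"""Exact pairwise Coulomb forces and energy: the ground truth.

All-pairs summation of Coulomb's law with no cutoff and no periodicity,
in double precision.  Every accuracy statement about the FMM solver in
this package is made relative to this oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import COULOMB_K
from .systems import ParticleSystem


class CoincidentParticlesError(ValueError):
    """Two particles occupy the same point, so 1/r is undefined."""

    def __init__(self, i: int, j: int):
        self.pair = (i, j)
        super().__init__(f"particles {i} and {j} are coincident")


@dataclass
class ForceResult:
    """Per-particle Cartesian forces (kJ mol^-1 nm^-1) and total Coulomb
    potential energy (kJ/mol), tagged with the method that produced them."""

    forces: np.ndarray
    potential_energy: float
    provenance: str = "direct"

    @property
    def n(self) -> int:
        return self.forces.shape[0]


# block edge for the tiled pair loops; ~1.4e6 pairs per tile keeps the
# temporaries comfortably in cache-friendly territory
_BLOCK = 1200


def coulomb_direct(system: ParticleSystem) -> ForceResult:
    """Exact Coulomb forces F_i = k sum_{j != i} q_i q_j r_ij / r_ij^3 and
    energy E = k sum_{i<j} q_i q_j / r_ij, with k = 138.935458 kJ mol^-1 nm e^-2.

    O(N^2); evaluated over upper-triangular position blocks so the pairwise
    antisymmetry (and hence momentum conservation) holds to round-off.
    """
    pos = system.positions
    q = system.charges
    n = system.n
    forces = np.zeros((n, 3))
    energy = 0.0
    for a0 in range(0, n, _BLOCK):
        a1 = min(a0 + _BLOCK, n)
        ia = np.arange(a0, a1)
        energy += _accumulate_self(pos[a0:a1], q[a0:a1], forces[a0:a1], ia)
        for b0 in range(a1, n, _BLOCK):
            b1 = min(b0 + _BLOCK, n)
            energy += _accumulate_cross(
                pos[a0:a1], q[a0:a1], pos[b0:b1], q[b0:b1],
                forces[a0:a1], forces[b0:b1],
                np.arange(a0, a1), np.arange(b0, b1),
            )
    return ForceResult(forces, energy, provenance="direct")


def _accumulate_cross(pos_a, q_a, pos_b, q_b, f_a, f_b, idx_a, idx_b) -> float:
    """Add mutual forces between two disjoint particle sets; return energy."""
    d = pos_b[None, :, :] - pos_a[:, None, :]          # (na, nb, 3)
    r2 = np.einsum("abk,abk->ab", d, d)
    if np.any(r2 == 0.0):
        ii, jj = np.nonzero(r2 == 0.0)
        raise CoincidentParticlesError(int(idx_a[ii[0]]), int(idx_b[jj[0]]))
    inv_r = 1.0 / np.sqrt(r2)
    qq = q_a[:, None] * q_b[None, :]
    w = COULOMB_K * qq * inv_r / r2                    # k q_i q_j / r^3
    fd = w[:, :, None] * d
    f_a -= fd.sum(axis=1)
    f_b += fd.sum(axis=0)
    return float(COULOMB_K * np.sum(qq * inv_r))


def _accumulate_self(pos, q, f, idx) -> float:
    """Add forces within one particle set (i < j); return energy."""
    n = pos.shape[0]
    if n < 2:
        return 0.0
    d = pos[None, :, :] - pos[:, None, :]
    r2 = np.einsum("abk,abk->ab", d, d)
    iu = np.triu_indices(n, k=1)
    if np.any(r2[iu] == 0.0):
        flat = np.zeros_like(r2, dtype=bool)
        flat[iu] = r2[iu] == 0.0
        ii, jj = np.nonzero(flat)
        raise CoincidentParticlesError(int(idx[ii[0]]), int(idx[jj[0]]))
    np.fill_diagonal(r2, np.inf)
    inv_r = 1.0 / np.sqrt(r2)
    qq = q[:, None] * q[None, :]
    w = COULOMB_K * qq * inv_r / r2
    fd = w[:, :, None] * d
    f -= fd.sum(axis=1)
    return float(0.5 * COULOMB_K * np.sum(qq * inv_r))
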