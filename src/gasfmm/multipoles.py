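"""Truncated multipole/local expansions and the five FMM operators.

A charge set inside a cell is summarized by a :class:`MultipoleExpansion`
about the cell center, truncated at order p; far potentials of other cells
are accumulated into a :class:`LocalExpansion`.  For real charges the
coefficient tables obey ``c(l, -m) = (-1)^m conj(c(l, m))``, so only the
m >= 0 half is stored; the full table is reconstructed on demand.

Operator chain: P2M (particles to multipole), M2M (multipole translation
up the tree, lossless at fixed p), M2L (far multipole to local expansion,
truncation error decreasing with order and separation), L2L (local
translation down, lossless), L2P (potential and analytic force at a
particle).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import harmonics as _h


class DivergentExpansionWarning(UserWarning):
    """The probe lies inside the expansion's bounding sphere, where the
    truncated series is not guaranteed to converge."""


@dataclass
class MultipoleExpansion:
    """Solid-harmonic moments of a charge set about ``center``.

    ``coeffs[l, m]`` holds the (l, m >= 0) coefficients in an upper-
    triangular (p+1, p+1) complex array; ``coeff(0, 0)`` equals the total
    enclosed charge.
    """

    order: int
    center: np.ndarray
    coeffs: np.ndarray

    def coeff(self, l: int, m: int) -> complex:
        if abs(m) > l or l > self.order:
            raise IndexError(f"(l={l}, m={m}) outside order-{self.order} table")
        if m >= 0:
            return complex(self.coeffs[l, m])
        return (-1) ** m * np.conj(self.coeffs[l, -m])

    def full_vector(self) -> np.ndarray:
        return _full_vector(self.order, self.coeffs)

    def to_debug_dict(self) -> dict:
        """JSON-serializable dump of the coefficient table (m >= 0 half)."""
        return {
            "order": int(self.order),
            "center": [float(c) for c in self.center],
            "coeffs": {
                f"{l},{m}": [float(self.coeffs[l, m].real),
                             float(self.coeffs[l, m].imag)]
                for l in range(self.order + 1) for m in range(l + 1)
            },
        }

    @classmethod
    def from_full_vector(cls, order, center, vec):
        return cls(order, np.asarray(center, dtype=float), _half_table(order, vec))


@dataclass
class LocalExpansion:
    """Local (Taylor-like) expansion of a far field about ``center``; same
    storage and symmetry as :class:`MultipoleExpansion`."""

    order: int
    center: np.ndarray
    coeffs: np.ndarray

    coeff = MultipoleExpansion.coeff
    full_vector = MultipoleExpansion.full_vector
    to_debug_dict = MultipoleExpansion.to_debug_dict

    @classmethod
    def from_full_vector(cls, order, center, vec):
        return cls(order, np.asarray(center, dtype=float), _half_table(order, vec))


def _full_vector(p: int, half: np.ndarray) -> np.ndarray:
    vec = np.zeros(_h.n_coeffs(p), dtype=np.complex128)
    for l in range(p + 1):
        for m in range(0, l + 1):
            vec[_h.lm_index(l, m)] = half[l, m]
            if m > 0:
                vec[_h.lm_index(l, -m)] = (-1) ** m * np.conj(half[l, m])
    return vec


def _half_table(p: int, vec: np.ndarray) -> np.ndarray:
    half = np.zeros((p + 1, p + 1), dtype=np.complex128)
    for l in range(p + 1):
        for m in range(0, l + 1):
            half[l, m] = vec[_h.lm_index(l, m)]
    return half


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

def p2m(positions, charges, center, p: int) -> MultipoleExpansion:
    """Regular solid-harmonic moments of a charge set about ``center``:
    M_l^m = sum_j q_j R_l^m(x_j - center), all l <= p."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    charges = np.atleast_1d(np.asarray(charges, dtype=float))
    center = np.asarray(center, dtype=float)
    R = _h.regular_tables(positions - center, p)
    vec = charges @ R
    return MultipoleExpansion.from_full_vector(p, center, vec)


def m2m(children, parent_center) -> MultipoleExpansion:
    """Translate and sum child multipole expansions about ``parent_center``.

    Lossless at fixed p: the parent moments up to p are exactly those of
    the union of the children's charges.
    """
    children = list(children)
    p = children[0].order
    parent_center = np.asarray(parent_center, dtype=float)
    vec = np.zeros(_h.n_coeffs(p), dtype=np.complex128)
    for child in children:
        t = np.asarray(child.center, dtype=float) - parent_center
        if np.allclose(t, 0.0):
            vec += child.full_vector()
        else:
            vec += _h.m2m_matrix(t, p) @ child.full_vector()
    return MultipoleExpansion.from_full_vector(p, parent_center, vec)


def m2l(source: MultipoleExpansion, target_center,
        cell_edge: float | None = None) -> LocalExpansion:
    """Convert a far multipole into a local expansion about ``target_center``.

    When ``cell_edge`` is given, enforces the classical well-separateness
    contract (centers at least two cell edges apart on some axis).
    """
    target_center = np.asarray(target_center, dtype=float)
    t = np.asarray(source.center, dtype=float) - target_center
    if cell_edge is not None:
        if np.max(np.abs(t)) < 2.0 * cell_edge - 1e-9:
            raise ValueError(
                "m2l called on cells that are not well-separated "
                f"(center offset {t} with cell edge {cell_edge})"
            )
    p = source.order
    vec = _h.m2l_matrix(t, p) @ source.full_vector()
    return LocalExpansion.from_full_vector(p, target_center, vec)


def l2l(parent: LocalExpansion, child_center) -> LocalExpansion:
    """Re-center a local expansion (lossless at fixed p)."""
    child_center = np.asarray(child_center, dtype=float)
    t = child_center - np.asarray(parent.center, dtype=float)
    if np.allclose(t, 0.0):
        vec = parent.full_vector()
    else:
        vec = _h.l2l_matrix(t, parent.order) @ parent.full_vector()
    return LocalExpansion.from_full_vector(parent.order, child_center, vec)


def l2p(local: LocalExpansion, position, charge: float = 1.0,
        cell_edge: float | None = None):
    """Potential energy factor and force on a charge inside the local cell.

    Returns ``(potential, force)`` where potential is the electrostatic
    potential (per unit Coulomb factor) at the particle position and force
    is ``-charge * grad(potential)``, both from analytic gradients of the
    regular harmonics (no finite differences).
    """
    position = np.asarray(position, dtype=float)
    disp = position - np.asarray(local.center, dtype=float)
    if cell_edge is not None and np.max(np.abs(disp)) > 0.5 * cell_edge + 1e-9:
        raise ValueError("particle lies outside the local expansion's cell")
    phi, grad = _h.evaluate_local(local.full_vector()[None, :], disp[None, :],
                                  local.order)
    return float(phi[0]), -charge * grad[0]


def eval_multipole_potential(expansion: MultipoleExpansion, probe,
                             bounding_radius: float | None = None) -> float:
    """Truncated far-field potential of a multipole expansion at ``probe``.

    If ``bounding_radius`` (radius of the sphere containing the expanded
    charges) is supplied and the probe lies inside it, a
    :class:`DivergentExpansionWarning` is issued because the series may
    diverge there; the truncated value is still returned.
    """
    probe = np.asarray(probe, dtype=float)
    disp = probe - np.asarray(expansion.center, dtype=float)
    r = float(np.linalg.norm(disp))
    if bounding_radius is not None and r < bounding_radius:
        warnings.warn(
            f"probe at r={r:.3g} lies inside the bounding sphere "
            f"(radius {bounding_radius:.3g}); the expansion may diverge",
            DivergentExpansionWarning,
            stacklevel=2,
        )
    I = _h.irregular_tables(disp[None, :], expansion.order)
    return float(np.real(np.conj(I[0]) @ expansion.full_vector()))
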