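"""Scaled solid harmonics and the FMM translation machinery.

Conventions (stable against factorial overflow, standard in FMM codes):

* regular  ``R_l^m(r) = r^l P_l^m(cos th) e^{i m phi} / (l+m)!``
* irregular ``I_l^m(r) = (l-m)! P_l^m(cos th) e^{i m phi} / r^{l+1}``

with the conjugate symmetry ``X_l^{-m} = (-1)^m conj(X_l^m)``.  They obey

* ``1/|b - a| = sum_{l,m} R_l^m(a) conj(I_l^m(b))``            (|a| < |b|)
* ``R_l^m(a + b) = sum_{j,k} R_j^k(a) R_{l-j}^{m-k}(b)``        (exact)
* ``I_l^m(b - a) = sum_{j,k} conj(R_j^k(a)) I_{l+j}^{m+k}(b)``  (|a| small)
* ``dz R = R_{l-1}^m``, ``(dx + i dy) R = R_{l-1}^{m+1}``,
  ``(dx - i dy) R = -R_{l-1}^{m-1}``

from which the five FMM operators follow as finite convolutions.  Tables
are stored as flat complex vectors of length (p+1)^2 with index
``l^2 + l + m``; the convolutions are materialized as dense matrices per
translation vector so that batches of expansions translate via matmul.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np


def n_coeffs(p: int) -> int:
    return (p + 1) * (p + 1)


def lm_index(l: int, m: int) -> int:
    return l * l + l + m


@lru_cache(maxsize=64)
def lm_arrays(p: int):
    """(l, m) of every flat index, as two int arrays of length (p+1)^2."""
    ls = np.concatenate([np.full(2 * l + 1, l) for l in range(p + 1)])
    ms = np.concatenate([np.arange(-l, l + 1) for l in range(p + 1)])
    return ls, ms


def regular_tables(points: np.ndarray, p: int) -> np.ndarray:
    """R_l^m tables for a batch of points; shape (N, (p+1)^2), complex."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    r2 = x * x + y * y + z * z
    xy = x + 1j * y
    n = pts.shape[0]
    R = np.zeros((n, n_coeffs(p)), dtype=np.complex128)
    R[:, 0] = 1.0
    for l in range(1, p + 1):
        R[:, lm_index(l, l)] = -xy / (2 * l) * R[:, lm_index(l - 1, l - 1)]
        for m in range(l - 1, -1, -1):
            prev2 = R[:, lm_index(l - 2, m)] if l - 2 >= m else 0.0
            R[:, lm_index(l, m)] = (
                (2 * l - 1) * z * R[:, lm_index(l - 1, m)] - r2 * prev2
            ) / ((l + m) * (l - m))
        for m in range(1, l + 1):
            R[:, lm_index(l, -m)] = (-1) ** m * np.conj(R[:, lm_index(l, m)])
    return R


def irregular_tables(points: np.ndarray, p: int) -> np.ndarray:
    """I_l^m tables for a batch of points; shape (N, (p+1)^2), complex."""
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    r2 = x * x + y * y + z * z
    if np.any(r2 == 0.0):
        raise ValueError("irregular harmonics are singular at the origin")
    xy = x + 1j * y
    n = pts.shape[0]
    I = np.zeros((n, n_coeffs(p)), dtype=np.complex128)
    I[:, 0] = 1.0 / np.sqrt(r2)
    for l in range(1, p + 1):
        I[:, lm_index(l, l)] = -(2 * l - 1) * xy / r2 * I[:, lm_index(l - 1, l - 1)]
        for m in range(l - 1, -1, -1):
            prev2 = I[:, lm_index(l - 2, m)] if l - 2 >= m else 0.0
            I[:, lm_index(l, m)] = (
                (2 * l - 1) * z * I[:, lm_index(l - 1, m)]
                - ((l - 1) ** 2 - m * m) * prev2
            ) / r2
        for m in range(1, l + 1):
            I[:, lm_index(l, -m)] = (-1) ** m * np.conj(I[:, lm_index(l, m)])
    return I


# ---------------------------------------------------------------------------
# index maps for the operator matrices (cached per order)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _m2m_map(p: int):
    """src[row, col] = flat index of R_{l-j}^{m-k}, or -1 where invalid."""
    nc = n_coeffs(p)
    ls, ms = lm_arrays(p)
    src = np.full((nc, nc), -1, dtype=np.int64)
    for row in range(nc):
        l, m = ls[row], ms[row]
        for col in range(nc):
            j, k = ls[col], ms[col]
            dl, dm = l - j, m - k
            if dl >= 0 and abs(dm) <= dl:
                src[row, col] = lm_index(dl, dm)
    return src


@lru_cache(maxsize=64)
def _l2l_map(p: int):
    """src[row, col] = flat index of R_{j-n}^{k-nu} (row=(n,nu), col=(j,k))."""
    return _m2m_map(p).T.copy()


@lru_cache(maxsize=64)
def _m2l_map(p: int):
    """src[row, col] into the order-2p irregular table: I_{j+n}^{k+nu};
    sign[col] = (-1)^n.  Row = (j, k) of the local, col = (n, nu) of the
    multipole."""
    nc = n_coeffs(p)
    ls, ms = lm_arrays(p)
    src = np.empty((nc, nc), dtype=np.int64)
    for row in range(nc):
        j, k = ls[row], ms[row]
        for col in range(nc):
            n, nu = ls[col], ms[col]
            src[row, col] = lm_index(j + n, k + nu)
    sign = np.where(ls % 2 == 0, 1.0, -1.0)
    return src, sign


def m2m_matrix(t: np.ndarray, p: int) -> np.ndarray:
    """Matrix A with A @ M = moments re-centered by translation ``t``
    (t = old center - new center)."""
    R = regular_tables(t, p)[0]
    src = _m2m_map(p)
    A = np.where(src >= 0, R[np.clip(src, 0, None)], 0.0)
    return A


def l2l_matrix(t: np.ndarray, p: int) -> np.ndarray:
    """Matrix B with B @ L = local expansion re-centered by ``t``
    (t = new center - old center)."""
    R = regular_tables(t, p)[0]
    src = _l2l_map(p)
    return np.where(src >= 0, R[np.clip(src, 0, None)], 0.0)


def m2l_matrix(t: np.ndarray, p: int) -> np.ndarray:
    """Matrix C with C @ M = local expansion of a far multipole,
    ``t = source center - target center``."""
    I = irregular_tables(t, 2 * p)[0]
    src, sign = _m2l_map(p)
    return np.conj(I[src]) * sign[None, :]


# ---------------------------------------------------------------------------
# local-expansion evaluation with analytic gradients
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _gradient_maps(p: int):
    """Flat indices of (l-1, m), (l-1, m+1), (l-1, m-1) per coefficient
    (-1 where the shifted index does not exist)."""
    nc = n_coeffs(p)
    ls, ms = lm_arrays(p)
    gz = np.full(nc, -1, dtype=np.int64)
    gp = np.full(nc, -1, dtype=np.int64)
    gm = np.full(nc, -1, dtype=np.int64)
    for i in range(nc):
        l, m = ls[i], ms[i]
        if l >= 1:
            if abs(m) <= l - 1:
                gz[i] = lm_index(l - 1, m)
            if abs(m + 1) <= l - 1:
                gp[i] = lm_index(l - 1, m + 1)
            if abs(m - 1) <= l - 1:
                gm[i] = lm_index(l - 1, m - 1)
    return gz, gp, gm


def evaluate_local(L: np.ndarray, disp: np.ndarray, p: int):
    """Potential and Cartesian gradient of local expansions at particle
    displacements from their cell centers.

    Parameters
    ----------
    L : (N, (p+1)^2) complex
        Local-expansion coefficients gathered per particle.
    disp : (N, 3)
        Particle position minus expansion center.

    Returns
    -------
    phi : (N,) potential values (real)
    grad : (N, 3) gradient of the potential (real)
    """
    R = regular_tables(disp, p)
    phi = np.real(np.einsum("nc,nc->n", L, R))
    gz, gp, gm = _gradient_maps(p)
    Rz = _shifted(R, gz)
    Rp = _shifted(R, gp)
    Rm = _shifted(R, gm)
    # dx = Re[ sum L (Rp - Rm) / 2 ];  dy = Re[ sum L (Rp + Rm) / (2i) ]
    sp = np.einsum("nc,nc->n", L, Rp)
    sm = np.einsum("nc,nc->n", L, Rm)
    gx = 0.5 * np.real(sp - sm)
    gy = 0.5 * np.imag(sp + sm)
    gzv = np.real(np.einsum("nc,nc->n", L, Rz))
    return phi, np.stack([gx, gy, gzv], axis=1)


def _shifted(R: np.ndarray, idx: np.ndarray) -> np.ndarray:
    out = R[:, np.clip(idx, 0, None)]
    out[:, idx < 0] = 0.0
    return out


def evaluate_multipole(M: np.ndarray, disp: np.ndarray, p: int) -> np.ndarray:
    """Far potential of multipole coefficient vector(s) at displacements
    ``disp`` from the expansion center: sum_lm M_lm conj(I_lm(disp))."""
    I = irregular_tables(disp, p)
    M = np.atleast_2d(M)
    return np.real(np.einsum("nc,nc->n", M, np.conj(I))) if M.shape[0] == I.shape[0] \
        else np.real(np.conj(I) @ M[0])
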