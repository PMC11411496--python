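"""Solid-harmonic expansions and the P2M/M2M/M2L/L2L/L2P operator chain.

The first block checks the mathematical identities the operators are
built on against brute-force evaluation; the rest exercises the operator
contracts and convergence behavior.
"""

import numpy as np
import pytest

import gasfmm.harmonics as h
from gasfmm.multipoles import (
    DivergentExpansionWarning,
    LocalExpansion,
    MultipoleExpansion,
    eval_multipole_potential,
    l2l,
    l2p,
    m2l,
    m2m,
    p2m,
)

RNG = np.random.default_rng(42)


# ---------------------------------------------------------------------------
# identities behind the operators
# ---------------------------------------------------------------------------

def test_addition_theorem_reconstructs_coulomb_kernel():
    """1/|b - a| = sum R_l^m(a) conj(I_l^m(b)) to machine precision."""
    a = RNG.normal(size=3) * 0.2
    b = RNG.normal(size=3) * 3.0
    p = 25
    Ra = h.regular_tables(a, p)[0]
    Ib = h.irregular_tables(b, p)[0]
    approx = float(np.real(Ra @ np.conj(Ib)))
    exact = 1.0 / np.linalg.norm(b - a)
    assert approx == pytest.approx(exact, rel=1e-12)


def test_regular_harmonics_gradient_relations():
    """dz R = R_{l-1}^m, (dx + i dy) R = R_{l-1}^{m+1}, (dx - i dy) R = -R_{l-1}^{m-1}."""
    pt = RNG.normal(size=3)
    p = 5
    eps = 1e-6
    R0 = h.regular_tables(pt, p)[0]
    grads = []
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = eps
        grads.append((h.regular_tables(pt + e, p)[0]
                      - h.regular_tables(pt - e, p)[0]) / (2 * eps))
    for l in range(1, p + 1):
        for m in range(-l, l + 1):
            i = h.lm_index(l, m)
            dz = grads[2][i]
            dxp = grads[0][i] + 1j * grads[1][i]
            dxm = grads[0][i] - 1j * grads[1][i]
            ez = R0[h.lm_index(l - 1, m)] if abs(m) <= l - 1 else 0.0
            ep = R0[h.lm_index(l - 1, m + 1)] if abs(m + 1) <= l - 1 else 0.0
            em = -R0[h.lm_index(l - 1, m - 1)] if abs(m - 1) <= l - 1 else 0.0
            assert dz == pytest.approx(ez, abs=1e-8)
            assert dxp == pytest.approx(ep, abs=1e-8)
            assert dxm == pytest.approx(em, abs=1e-8)


# ---------------------------------------------------------------------------
# P2M
# ---------------------------------------------------------------------------

def test_p2m_single_charge_at_center_is_pure_monopole():
    exp = p2m([[1.0, 2.0, 3.0]], [2.5], [1.0, 2.0, 3.0], p=6)
    assert exp.coeff(0, 0) == pytest.approx(2.5)
    vec = exp.full_vector()
    assert np.allclose(vec[1:], 0.0, atol=1e-14)


def test_p2m_monopole_equals_total_charge():
    pts = RNG.normal(size=(20, 3))
    q = RNG.uniform(-1, 1, 20)
    exp = p2m(pts, q, [0.0, 0.0, 0.0], p=4)
    assert exp.coeff(0, 0) == pytest.approx(q.sum())


def test_p2m_dipole_pair_matches_point_dipole_far_field():
    """A +-q pair split along z: zero monopole, and the far potential
    matches the point-dipole closed form mu cos(theta)/r^2."""
    q, sep = 0.8, 0.2
    exp = p2m([[0, 0, sep / 2], [0, 0, -sep / 2]], [q, -q], [0.0, 0.0, 0.0], p=8)
    assert exp.coeff(0, 0) == pytest.approx(0.0, abs=1e-14)
    assert abs(exp.coeff(1, 0)) == pytest.approx(q * sep, rel=1e-12)
    for probe in ([0, 0, 5.0], [3.0, 0, 4.0]):
        probe = np.asarray(probe, dtype=float)
        r = np.linalg.norm(probe)
        dipole = q * sep * probe[2] / r ** 3
        assert eval_multipole_potential(exp, probe) == pytest.approx(
            dipole, rel=5e-3)


def test_debug_dump_is_json_serializable():
    import json
    exp = p2m([[0.1, 0.0, 0.0]], [2.0], [0.0, 0.0, 0.0], p=2)
    dump = json.loads(json.dumps(exp.to_debug_dict()))
    assert dump["order"] == 2
    assert dump["coeffs"]["0,0"] == [2.0, 0.0]


def test_p2m_conjugate_symmetry():
    pts = RNG.normal(size=(10, 3))
    exp = p2m(pts, RNG.uniform(-1, 1, 10), [0.0, 0.0, 0.0], p=5)
    for l in range(6):
        for m in range(0, l + 1):
            assert exp.coeff(l, -m) == pytest.approx(
                (-1) ** m * np.conj(exp.coeff(l, m)))


# ---------------------------------------------------------------------------
# M2M
# ---------------------------------------------------------------------------

def test_m2m_empty_children_give_zero():
    zero = MultipoleExpansion(4, np.zeros(3), np.zeros((5, 5), dtype=complex))
    out = m2m([zero] * 8, [1.0, 1.0, 1.0])
    assert np.allclose(out.full_vector(), 0.0)


def test_m2m_identity_translation_preserves_coefficients():
    pts = RNG.normal(size=(10, 3)) * 0.3
    exp = p2m(pts, RNG.uniform(-1, 1, 10), [0.0, 0.0, 0.0], p=5)
    out = m2m([exp], [0.0, 0.0, 0.0])
    assert np.allclose(out.full_vector(), exp.full_vector(), atol=1e-14)


def test_m2m_is_lossless_at_fixed_order():
    """Translating child moments equals recomputing moments about the
    parent center directly (M2M is exact at fixed p)."""
    pts = RNG.normal(size=(30, 3)) * 0.3
    q = RNG.uniform(-1, 1, 30)
    child = p2m(pts, q, [0.0, 0.0, 0.0], p=6)
    parent_center = np.array([0.5, -0.25, 0.25])
    translated = m2m([child], parent_center)
    recomputed = p2m(pts, q, parent_center, p=6)
    assert np.allclose(translated.full_vector(), recomputed.full_vector(),
                       rtol=1e-12, atol=1e-12)


def test_m2m_far_potential_error_decreases_with_order():
    pts = RNG.normal(size=(40, 3)) * 0.4
    q = RNG.uniform(-1, 1, 40)
    probes = RNG.normal(size=(10, 3))
    probes *= 6.0 / np.linalg.norm(probes, axis=1)[:, None]
    errs = []
    for p in (2, 4, 8):
        parent = m2m([p2m(pts, q, [0.0, 0.0, 0.0], p=p)], [0.4, 0.2, -0.3])
        rel = []
        for probe in probes:
            exact = float(np.sum(q / np.linalg.norm(probe - pts, axis=1)))
            rel.append(abs(eval_multipole_potential(parent, probe) - exact)
                       / abs(exact))
        errs.append(np.mean(rel))
    assert errs[0] > errs[1] > errs[2]


# ---------------------------------------------------------------------------
# M2L
# ---------------------------------------------------------------------------

def test_m2l_zero_source_gives_zero_local():
    zero = MultipoleExpansion(5, np.zeros(3), np.zeros((6, 6), dtype=complex))
    loc = m2l(zero, [4.0, 0.0, 0.0])
    assert np.allclose(loc.full_vector(), 0.0)


def test_m2l_single_distant_charge_reproduces_coulomb():
    """Local expansion of one distant unit charge, 4 cell edges away:
    the potential at the target center matches 1/r to < 1e-6 at p = 10."""
    edge = 1.0
    src_center = np.zeros(3)
    tgt_center = np.array([4.0 * edge, 0.0, 0.0])
    charge_pos = np.array([0.2, -0.1, 0.15])
    exp = p2m([charge_pos], [1.0], src_center, p=10)
    loc = m2l(exp, tgt_center, cell_edge=edge)
    phi, _ = l2p(loc, tgt_center)
    exact = 1.0 / np.linalg.norm(tgt_center - charge_pos)
    assert abs(phi - exact) / exact < 1e-6


def test_m2l_error_decreases_with_separation():
    edge = 1.0
    charge_pos = np.array([0.3, 0.2, -0.25])
    exp = p2m([charge_pos], [1.0], np.zeros(3), p=4)
    errs = []
    for sep in (2.0, 6.0):
        tgt = np.array([sep * edge, 0.0, 0.0])
        probe = tgt + np.array([0.2, 0.1, -0.1])
        loc = m2l(exp, tgt, cell_edge=edge)
        phi, _ = l2p(loc, probe)
        exact = 1.0 / np.linalg.norm(probe - charge_pos)
        errs.append(abs(phi - exact) / exact)
    assert errs[1] < errs[0]


def test_m2l_rejects_adjacent_cells():
    exp = p2m([[0.0, 0, 0]], [1.0], np.zeros(3), p=4)
    with pytest.raises(ValueError, match="well-separated"):
        m2l(exp, [1.0, 0.0, 0.0], cell_edge=1.0)


# ---------------------------------------------------------------------------
# L2L / L2P
# ---------------------------------------------------------------------------

def _local_from_charge(charge_pos, center, p):
    exp = p2m([charge_pos], [1.0], np.zeros(3), p=p)
    return m2l(exp, center)


def test_l2l_zero_and_identity():
    zero = LocalExpansion(4, np.zeros(3), np.zeros((5, 5), dtype=complex))
    assert np.allclose(l2l(zero, [1.0, 0, 0]).full_vector(), 0.0)
    loc = _local_from_charge([0.1, 0.05, -0.1], np.array([4.0, 1.0, 0.0]), p=8)
    out = l2l(loc, loc.center)
    assert np.allclose(out.full_vector(), loc.full_vector(), atol=1e-14)


def test_l2l_preserves_potential_at_fixed_probe():
    """Evaluating before and after re-centering agrees to round-off."""
    center = np.array([4.0, 1.0, 0.0])
    loc = _local_from_charge([0.1, 0.05, -0.1], center, p=10)
    child_center = center + np.array([0.25, -0.25, 0.25])
    child = l2l(loc, child_center)
    probe = center + np.array([0.3, 0.1, 0.2])
    phi_parent, _ = l2p(loc, probe)
    phi_child, _ = l2p(child, probe)
    assert phi_child == pytest.approx(phi_parent, rel=1e-12)


def test_l2p_zero_expansion():
    zero = LocalExpansion(4, np.zeros(3), np.zeros((5, 5), dtype=complex))
    phi, force = l2p(zero, [0.1, 0.0, 0.0], charge=2.0)
    assert phi == 0.0
    assert np.allclose(force, 0.0)


def test_l2p_monopole_field_matches_coulomb():
    """The local field of one distant charge reproduces the Coulomb
    potential and force direction at the particle, within truncation."""
    src = np.array([0.05, 0.0, 0.0])
    center = np.array([5.0, 0.0, 0.0])
    loc = _local_from_charge(src, center, p=12)
    particle = center + np.array([0.2, 0.1, 0.0])
    phi, force = l2p(loc, particle, charge=1.0)
    r = particle - src
    assert phi == pytest.approx(1.0 / np.linalg.norm(r), rel=1e-8)
    expected_force = r / np.linalg.norm(r) ** 3
    assert np.allclose(force, expected_force, rtol=1e-6)


def test_l2p_force_is_gradient_of_l2p_potential():
    center = np.array([4.0, -1.0, 2.0])
    loc = _local_from_charge([0.2, 0.1, -0.1], center, p=10)
    particle = center + np.array([0.15, -0.2, 0.1])
    _, force = l2p(loc, particle, charge=1.0)
    eps = 1e-6
    num = np.zeros(3)
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = eps
        up, _ = l2p(loc, particle + e)
        dn, _ = l2p(loc, particle - e)
        num[ax] = -(up - dn) / (2 * eps)
    assert np.allclose(force, num, rtol=1e-6, atol=1e-10)


# ---------------------------------------------------------------------------
# multipole evaluation and convergence
# ---------------------------------------------------------------------------

def test_eval_multipole_far_probe_high_order_accuracy():
    pts = RNG.normal(size=(30, 3)) * 0.3
    q = RNG.uniform(-1, 1, 30)
    exp = p2m(pts, q, np.zeros(3), p=20)
    probe = np.array([4.0, 2.0, 3.0])
    exact = float(np.sum(q / np.linalg.norm(probe - pts, axis=1)))
    assert eval_multipole_potential(exp, probe) == pytest.approx(exact, rel=1e-8)


def test_eval_multipole_order_zero_is_monopole():
    pts = RNG.normal(size=(10, 3)) * 0.2
    q = RNG.uniform(-1, 1, 10)
    exp = p2m(pts, q, np.zeros(3), p=0)
    probe = np.array([0.0, 0.0, 3.0])
    assert eval_multipole_potential(exp, probe) == pytest.approx(q.sum() / 3.0)


def test_truncation_error_decreases_with_order():
    """A tight positive cluster seen from afar: each added order improves
    the truncated potential (the expansion ratio is small enough that the
    series converges monotonically)."""
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(15, 3)) * 0.15
    q = np.abs(rng.uniform(0.2, 1, 15))
    probe = np.array([2.5, 0.5, 1.0])
    exact = float(np.sum(q / np.linalg.norm(probe - pts, axis=1)))
    errs = [abs(eval_multipole_potential(p2m(pts, q, np.zeros(3), p=p), probe)
                - exact) for p in (0, 1, 2)]
    assert errs[2] <= errs[1] <= errs[0]


def test_probe_inside_bounding_sphere_warns():
    exp = p2m(RNG.normal(size=(5, 3)), RNG.uniform(0, 1, 5), np.zeros(3), p=3)
    with pytest.warns(DivergentExpansionWarning):
        eval_multipole_potential(exp, [0.5, 0.0, 0.0], bounding_radius=3.0)


def test_convergence_is_geometric_up_to_p12():
    """Random 50-charge cluster, probe at 3x the cluster radius: the
    truncation error decays at least geometrically in p."""
    pts = RNG.normal(size=(50, 3))
    pts *= 1.0 / np.max(np.linalg.norm(pts, axis=1))
    q = RNG.uniform(-1, 1, 50)
    probe = np.array([3.0, 0.0, 0.0])
    exact = float(np.sum(q / np.linalg.norm(probe - pts, axis=1)))
    errs = np.array([
        abs(eval_multipole_potential(p2m(pts, q, np.zeros(3), p=p), probe)
            - exact)
        for p in range(13)
    ])
    # geometric decay with ratio <= 1/2 on average over four-step windows
    for i in range(0, 8, 4):
        assert errs[i + 4] < 0.25 * errs[i] + 1e-14
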