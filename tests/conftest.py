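"""Shared fixtures.

The expensive fixture is ``accuracy_panel``: a 2e4-particle globular
charged system with its exact direct-summation reference and the FMM
force error over a (d, p) grid.  It is session-scoped because the direct
reference and the depth-2 near field each cost tens of seconds; several
acceptance-level checks share it.
"""

import numpy as np
import pytest

import gasfmm as g


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_system(n, rng, spread=2.0, boxed=True, padding=3.0):
    """Uniform random charged particles in a cube of the given spread (nm)."""
    positions = rng.random((n, 3)) * spread
    charges = rng.uniform(-0.5, 0.5, n)
    system = g.ParticleSystem(positions, charges,
                              np.full(n, 0.15), np.full(n, 12.0))
    return g.place_in_cubic_box(system, padding) if boxed else system


@pytest.fixture()
def small_globular():
    spec = g.ShapeSpec("globular", 500, target_net_charge=5, seed=3)
    return g.place_in_cubic_box(g.generate_synthetic_system(spec), 3.0)


@pytest.fixture(scope="session")
def accuracy_panel():
    """2e4-particle globular system (+30 e, 3 nm padding): direct reference
    and FMM force errors for d in {2, 3} over p = 2..16."""
    spec = g.ShapeSpec("globular", 20000, target_net_charge=30, seed=1)
    system = g.place_in_cubic_box(g.generate_synthetic_system(spec), 3.0)
    reference = g.coulomb_direct(system)
    p_values = list(range(2, 17))
    deltas = {}
    for d in (2, 3):
        calc = g.FmmCalculator(system, d)
        for p in p_values:
            report = g.force_error(reference, calc.forces(p))
            deltas[(d, p)] = report.delta_percent
    return {
        "system": system,
        "reference": reference,
        "p_values": p_values,
        "deltas": deltas,
    }
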