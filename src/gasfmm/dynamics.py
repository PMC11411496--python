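"""Minimal gas-phase MD: velocity Verlet, stochastic velocity rescaling,
center-of-mass motion removal, 12-6 Lennard-Jones plus pluggable Coulomb.

This is a demonstration-scale integrator for vacuum systems: all-pairs
open-boundary Lennard-Jones, Coulomb electrostatics from either the direct
oracle or the FMM solver, a canonical (Bussi) velocity-rescaling
thermostat, and optional removal of net translation or rotation, the
standard hygiene for a molecule spinning freely in vacuum.  MD units:
nm, ps, Da, kJ/mol (1 Da nm^2/ps^2 = 1 kJ/mol).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import BOLTZMANN_KB, LJ_PARAMS
from .direct import ForceResult, coulomb_direct
from .fmm import FmmCalculator, FmmSettings
from .systems import ParticleSystem, place_in_cubic_box


@dataclass
class MdConfig:
    """Integration settings.

    timestep is in fs (1 fs default: no constraints, no virtual sites);
    thermostat_tau in ps; electrostatics is ``"direct"``, ``"fmm"`` or
    ``"none"``; comm_removal is ``"none"``, ``"linear"`` or ``"angular"``
    and is applied every ``comm_stride`` steps.
    """

    timestep: float = 1.0
    n_steps: int = 1000
    temperature: float = 300.0
    thermostat_tau: float = 0.2
    thermostat: bool = True
    electrostatics: str = "direct"
    fmm_depth: int = 3
    fmm_order: int = 8
    box_padding: float = 3.0
    lj_enabled: bool = True
    seed: int = 0
    comm_removal: str = "angular"
    comm_stride: int = 100
    snapshot_stride: int = 100

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.thermostat and self.thermostat_tau <= 0:
            raise ValueError("thermostat_tau must be positive when thermostatted")
        if self.electrostatics not in ("direct", "fmm", "none"):
            raise ValueError("electrostatics must be 'direct', 'fmm' or 'none'")
        if self.comm_removal not in ("none", "linear", "angular"):
            raise ValueError("comm_removal must be 'none', 'linear' or 'angular'")


@dataclass
class MdResult:
    """Trajectory snapshots and scalar series from one run."""

    frames: np.ndarray              # (n_frames, N, 3) positions, nm
    frame_steps: np.ndarray
    series: dict                    # step, time_ps, e_pot, e_kin, temperature
    final_positions: np.ndarray
    final_velocities: np.ndarray


# ---------------------------------------------------------------------------
# force terms
# ---------------------------------------------------------------------------

def lj_forces(system: ParticleSystem, lj_params: dict | None = None) -> ForceResult:
    """All-pairs 12-6 Lennard-Jones forces and energy (no cutoff).

    ``lj_params`` maps particle labels to (sigma nm, epsilon kJ/mol);
    Lorentz-Berthelot combination rules give the pair parameters.
    """
    params = LJ_PARAMS if lj_params is None else lj_params
    try:
        sig = np.array([params[str(l)][0] for l in system.labels])
        eps = np.array([params[str(l)][1] for l in system.labels])
    except KeyError as exc:
        raise KeyError(f"no Lennard-Jones parameters for particle type {exc}") from None
    pos = system.positions
    n = system.n
    d = pos[None, :, :] - pos[:, None, :]
    r2 = np.einsum("abk,abk->ab", d, d)
    np.fill_diagonal(r2, np.inf)
    sij = 0.5 * (sig[:, None] + sig[None, :])
    eij = np.sqrt(eps[:, None] * eps[None, :])
    s6 = (sij * sij / r2) ** 3
    s12 = s6 * s6
    energy = float(0.5 * np.sum(4.0 * eij * (s12 - s6)))
    w = 24.0 * eij * (2.0 * s12 - s6) / r2
    forces = -(w[:, :, None] * d).sum(axis=1)
    return ForceResult(forces, energy, provenance="lj")


# ---------------------------------------------------------------------------
# thermostat and COM removal
# ---------------------------------------------------------------------------

def vrescale_step(velocities, masses, target_temperature: float, tau: float,
                  dt: float, rng, ndof: int | None = None) -> np.ndarray:
    """One stochastic velocity-rescaling (canonical-sampling) update.

    Relaxes the kinetic energy toward the canonical distribution at the
    target temperature with time constant ``tau`` (ps); ``dt`` is the step
    in ps.  In the deterministic limit tau -> inf the velocities are
    unchanged; for tau -> 0 the kinetic energy is resampled from the
    canonical distribution in a single step.
    """
    v = np.asarray(velocities, dtype=float)
    m = np.asarray(masses, dtype=float)
    if ndof is None:
        ndof = 3 * v.shape[0]
    if ndof < 1:
        raise ValueError("need at least one degree of freedom")
    kinetic = 0.5 * float(np.sum(m[:, None] * v * v))
    if kinetic == 0.0:
        return v.copy()
    target_k = 0.5 * ndof * BOLTZMANN_KB * target_temperature
    c = np.exp(-dt / tau)
    r1 = rng.standard_normal()
    s = rng.chisquare(ndof - 1) if ndof > 1 else 0.0
    k_new = (
        kinetic
        + (1.0 - c) * (target_k * (r1 * r1 + s) / ndof - kinetic)
        + 2.0 * r1 * np.sqrt(c * (1.0 - c) * target_k * kinetic / ndof)
    )
    alpha = np.sqrt(max(k_new, 0.0) / kinetic)
    return v * alpha


def remove_com_motion(system: ParticleSystem, velocities, mode: str = "angular"):
    """Zero the net translation (linear) or translation+rotation (angular).

    Angular mode subtracts the rigid-body rotation omega x r about the
    center of mass, with omega from the inertia tensor; it requires a
    non-degenerate (non-collinear) mass distribution.
    """
    v = np.asarray(velocities, dtype=float).copy()
    m = system.masses
    total_m = m.sum()
    v -= (m[:, None] * v).sum(axis=0) / total_m
    if mode == "linear":
        return v
    if mode != "angular":
        raise ValueError("mode must be 'linear' or 'angular'")
    if system.n < 2:
        raise ValueError("angular removal needs at least 2 particles")
    com = (m[:, None] * system.positions).sum(axis=0) / total_m
    r = system.positions - com
    ang_mom = (m[:, None] * np.cross(r, v)).sum(axis=0)
    r2 = np.einsum("ij,ij->i", r, r)
    inertia = np.einsum("i,ij,ik->jk", m, r, r) * -1.0
    inertia[np.diag_indices(3)] += (m * r2).sum()
    eigvals = np.linalg.eigvalsh(inertia)
    if eigvals[0] < 1e-10 * max(eigvals[-1], 1e-300):
        raise ValueError("inertia tensor is singular (collinear mass distribution)")
    omega = np.linalg.solve(inertia, ang_mom)
    v -= np.cross(omega, r)
    return v


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------

def run_md(system: ParticleSystem, config: MdConfig,
           lj_params: dict | None = None) -> MdResult:
    """Velocity-Verlet integration with the configured force providers.

    Velocities start from the Maxwell-Boltzmann distribution at the target
    temperature (seeded); snapshots and scalar series are recorded at the
    configured strides.  Bitwise deterministic for a given seed and
    configuration.  Aborts with the step index if forces or energies turn
    non-finite.
    """
    rng = np.random.default_rng(config.seed)
    pos = system.positions.copy()
    m = system.masses
    dt = config.timestep * 1.0e-3  # fs -> ps
    v = rng.standard_normal(pos.shape) * np.sqrt(
        BOLTZMANN_KB * config.temperature / m
    )[:, None]
    ndof = 3 * system.n
    if config.comm_removal == "linear":
        v = remove_com_motion(system.replace(positions=pos), v, "linear")
        ndof -= 3
    elif config.comm_removal == "angular":
        v = remove_com_motion(system.replace(positions=pos), v, "angular")
        ndof -= 6

    def compute_forces(positions, step):
        current = system.replace(positions=positions, box_side=None)
        f = np.zeros_like(positions)
        e_pot = 0.0
        if config.lj_enabled:
            res = lj_forces(current, lj_params)
            f += res.forces
            e_pot += res.potential_energy
        if config.electrostatics == "direct":
            res = coulomb_direct(current)
            f += res.forces
            e_pot += res.potential_energy
        elif config.electrostatics == "fmm":
            boxed = place_in_cubic_box(current, config.box_padding)
            res = FmmCalculator(boxed, config.fmm_depth).forces(config.fmm_order)
            f += res.forces
            e_pot += res.potential_energy
        if not (np.all(np.isfinite(f)) and np.isfinite(e_pot)):
            raise RuntimeError(f"non-finite forces or energy at step {step}")
        return f, e_pot

    forces, e_pot = compute_forces(pos, 0)
    frames, frame_steps = [pos.copy()], [0]
    series = {k: [] for k in ("step", "time_ps", "e_pot", "e_kin", "temperature")}

    def record(step):
        e_kin = 0.5 * float(np.sum(m[:, None] * v * v))
        series["step"].append(step)
        series["time_ps"].append(step * dt)
        series["e_pot"].append(e_pot)
        series["e_kin"].append(e_kin)
        series["temperature"].append(2.0 * e_kin / (ndof * BOLTZMANN_KB))

    record(0)
    for step in range(1, config.n_steps + 1):
        v += 0.5 * dt * forces / m[:, None]
        pos += dt * v
        if not np.all(np.isfinite(pos)):
            raise RuntimeError(f"non-finite positions at step {step}")
        forces, e_pot = compute_forces(pos, step)
        v += 0.5 * dt * forces / m[:, None]
        if config.thermostat:
            v = vrescale_step(v, m, config.temperature, config.thermostat_tau,
                              dt, rng, ndof=ndof)
        if config.comm_removal != "none" and step % config.comm_stride == 0:
            v = remove_com_motion(system.replace(positions=pos, box_side=None),
                                  v, config.comm_removal)
        if step % config.snapshot_stride == 0:
            frames.append(pos.copy())
            frame_steps.append(step)
            record(step)

    return MdResult(
        frames=np.array(frames),
        frame_steps=np.array(frame_steps),
        series={k: np.array(vals) for k, vals in series.items()},
        final_positions=pos,
        final_velocities=v,
    )
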