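"""Charged particle systems: I/O, synthesis, charge assignment, and boxing.

The central container is :class:`ParticleSystem`, which holds positions
(nm), partial charges (e), hard-sphere radii (nm) and masses (Da) for N
particles, plus an optional cubic bounding box.  Systems come from PQR/PDB
files or from the synthetic generator, which emulates all-atom protein
matter at ~100 atoms/nm^3 in globular, extended (prolate) or hollow-shell
envelopes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .constants import (
    ELEMENT_MASSES,
    ELEMENT_RADII,
    PROTEIN_DENSITY,
    SYNTHETIC_COMPOSITION,
)


class PqrFormatError(ValueError):
    """Raised when a PQR/PDB record cannot be parsed."""


@dataclass
class ParticleSystem:
    """N charged hard spheres, optionally inside a cubic box.

    Attributes
    ----------
    positions : (N, 3) float array, nm
    charges : (N,) float array, elementary charges
    radii : (N,) float array, nm (used by SASA and CCS)
    masses : (N,) float array, Da
    labels : (N,) array of atom/element identifiers
    box_side : float or None
        Edge length of the cubic box, nm.  When set, every position must
        lie inside [0, box_side]^3.
    """

    positions: np.ndarray
    charges: np.ndarray
    radii: np.ndarray
    masses: np.ndarray
    labels: np.ndarray = None
    box_side: float | None = None

    def __post_init__(self):
        self.positions = np.ascontiguousarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        n = self.positions.shape[0]
        if n < 1:
            raise ValueError("a ParticleSystem needs at least one particle")
        self.charges = np.ascontiguousarray(self.charges, dtype=np.float64)
        self.radii = np.ascontiguousarray(self.radii, dtype=np.float64)
        self.masses = np.ascontiguousarray(self.masses, dtype=np.float64)
        if self.labels is None:
            self.labels = np.array(["X"] * n, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
        for name in ("charges", "radii", "masses", "labels"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match positions ({n})")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if np.any(self.radii <= 0):
            raise ValueError("radii must be positive")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        if self.box_side is not None:
            self.box_side = float(self.box_side)
            lo, hi = self.positions.min(), self.positions.max()
            if lo < -1e-9 or hi > self.box_side + 1e-9:
                raise ValueError(
                    "boxed system has particles outside [0, box_side]^3"
                )

    @property
    def n(self) -> int:
        return self.positions.shape[0]

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    def replace(self, **updates) -> "ParticleSystem":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **updates)

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            self.positions.copy(),
            self.charges.copy(),
            self.radii.copy(),
            self.masses.copy(),
            self.labels.copy(),
            self.box_side,
        )


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for a synthetic charged system.

    kind is one of ``globular`` (uniform sphere), ``extended`` (prolate
    spheroid of the given aspect ratio) or ``hollow_shell`` (spherical
    shell of the given relative thickness).  All shapes are filled at
    protein-like all-atom density, so box sizes versus N mimic real
    proteins.
    """

    kind: str
    n_atoms: int
    target_net_charge: int = 0
    aspect_ratio: float = 3.0
    shell_thickness_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("globular", "extended", "hollow_shell"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.n_atoms < 2:
            raise ValueError("n_atoms must be >= 2")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")
        if not 0 < self.shell_thickness_fraction <= 1:
            raise ValueError("shell_thickness_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# PQR / PDB / XYZ input and output
# ---------------------------------------------------------------------------

def read_pqr(path) -> ParticleSystem:
    """Read a whitespace-delimited PQR file.

    One particle per ATOM/HETATM record; the last two fields of a record
    are charge (e) and radius (Angstrom), preceded by x, y, z in Angstrom.
    Coordinates and radii are converted to nm.  Malformed records raise
    :class:`PqrFormatError` naming the offending line.
    """
    path = Path(path)
    positions, charges, radii, labels = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line.split()
            if not rec or rec[0] not in ("ATOM", "HETATM"):
                continue
            if len(rec) < 10:
                raise PqrFormatError(
                    f"{path.name}:{lineno}: ATOM record has {len(rec)} fields, "
                    "expected at least 10 (missing charge/radius columns?)"
                )
            try:
                x, y, z = (float(v) for v in rec[-5:-2])
                q, r = float(rec[-2]), float(rec[-1])
            except ValueError as exc:
                raise PqrFormatError(
                    f"{path.name}:{lineno}: could not parse numeric fields: {exc}"
                ) from None
            positions.append((x, y, z))
            charges.append(q)
            radii.append(r)
            labels.append(rec[2])
    if not positions:
        raise PqrFormatError(f"{path.name}: no ATOM/HETATM records found")
    positions = np.asarray(positions) * 0.1  # A -> nm
    radii = np.asarray(radii) * 0.1
    masses = np.array([_element_mass(lbl) for lbl in labels])
    return ParticleSystem(positions, np.asarray(charges), radii, masses,
                          np.asarray(labels, dtype=object))


def write_pqr(path, system: ParticleSystem) -> None:
    """Write a whitespace-delimited PQR file (coordinates back in Angstrom)."""
    with open(path, "w") as fh:
        for i in range(system.n):
            x, y, z = system.positions[i] * 10.0
            fh.write(
                "ATOM  %5d %-4s RES A %4d    %8.3f %8.3f %8.3f %8.4f %7.4f\n"
                % (i + 1, str(system.labels[i])[:4], i + 1, x, y, z,
                   system.charges[i], system.radii[i] * 10.0)
            )


def read_pdb(path, uniform_charge: float = 0.0) -> ParticleSystem:
    """Read ATOM/HETATM records from a plain PDB file via biotite.

    PDB files carry no partial charges or radii, so every particle gets
    ``uniform_charge`` and an element-table radius; a net charge must then
    be set explicitly with :func:`assign_net_charge`.
    """
    import biotite.structure.io.pdb as pdb

    arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    positions = np.asarray(arr.coord, dtype=np.float64) * 0.1
    elements = [str(e).capitalize() if str(e) else "C" for e in arr.element]
    radii = np.array([ELEMENT_RADII.get(e, 0.17) for e in elements])
    masses = np.array([ELEMENT_MASSES.get(e, 12.011) for e in elements])
    charges = np.full(len(elements), uniform_charge)
    return ParticleSystem(positions, charges, radii, masses,
                          np.asarray(elements, dtype=object))


def write_xyz(path, frames, labels=None, comment="gasfmm") -> None:
    """Write one or more coordinate frames (nm) as multi-frame XYZ (Angstrom)."""
    frames = np.asarray(frames, dtype=np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    if labels is None:
        labels = ["X"] * n
    with open(path, "w") as fh:
        for f, frame in enumerate(frames):
            fh.write(f"{n}\n{comment} frame {f}\n")
            for lbl, (x, y, z) in zip(labels, frame * 10.0):
                fh.write(f"{lbl} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path):
    """Read a multi-frame XYZ file; returns (frames [nframes,N,3] nm, labels)."""
    frames, labels = [], None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        block = lines[i + 2:i + 2 + n]
        labels = [ln.split()[0] for ln in block]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(coords * 0.1)
        i += 2 + n
    return np.array(frames), np.asarray(labels, dtype=object)


def _element_mass(label: str) -> float:
    key = str(label)[:1].capitalize()
    return ELEMENT_MASSES.get(key, 12.011)


# ---------------------------------------------------------------------------
# Synthetic systems
# ---------------------------------------------------------------------------

def generate_synthetic_system(spec: ShapeSpec) -> ParticleSystem:
    """Sample a protein-like all-atom system for the given shape recipe.

    Particles are drawn uniformly inside the shape envelope at
    ~:data:`~gasfmm.constants.PROTEIN_DENSITY` atoms/nm^3 with an H/C/N/O
    composition; partial charges are uniform on [-0.5, 0.5] and then
    shifted on randomly chosen surface sites so the total equals
    ``spec.target_net_charge`` exactly.  Bitwise deterministic for a given
    seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_atoms
    volume = n / PROTEIN_DENSITY

    if spec.kind == "globular":
        radius = (3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0)
        positions = _sample_ball(rng, n) * radius
        r_frac = np.linalg.norm(positions, axis=1) / radius
    elif spec.kind == "extended":
        a = (3.0 * volume / (4.0 * np.pi * spec.aspect_ratio)) ** (1.0 / 3.0)
        positions = _sample_ball(rng, n)
        r_frac = np.linalg.norm(positions, axis=1)
        positions = positions * (a, a, a * spec.aspect_ratio)
    else:  # hollow_shell
        f = spec.shell_thickness_fraction
        outer = (3.0 * volume / (4.0 * np.pi * (1.0 - (1.0 - f) ** 3))) ** (1.0 / 3.0)
        inner = outer * (1.0 - f)
        u = rng.random(n)
        r = (u * (outer ** 3 - inner ** 3) + inner ** 3) ** (1.0 / 3.0)
        direction = rng.normal(size=(n, 3))
        direction /= np.linalg.norm(direction, axis=1)[:, None]
        positions = direction * r[:, None]
        r_frac = r / outer

    elements, fracs = zip(*SYNTHETIC_COMPOSITION)
    kinds = rng.choice(len(elements), size=n, p=fracs)
    labels = np.array([elements[k] for k in kinds], dtype=object)
    radii = np.array([ELEMENT_RADII[e] for e in labels])
    masses = np.array([ELEMENT_MASSES[e] for e in labels])

    charges = rng.uniform(-0.5, 0.5, size=n)
    # spread the deficit over surface sites (outer 20% of the envelope)
    surface = np.flatnonzero(r_frac >= np.quantile(r_frac, 0.8))
    n_sites = max(1, min(surface.size, int(round(abs(spec.target_net_charge))) or 8))
    sites = rng.choice(surface, size=n_sites, replace=False)
    deficit = spec.target_net_charge - charges.sum()
    charges[sites] += deficit / n_sites

    return ParticleSystem(positions, charges, radii, masses, labels)


def _sample_ball(rng, n):
    """n points uniform in the unit ball."""
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1)[:, None]
    return direction * rng.random(n)[:, None] ** (1.0 / 3.0)


# ---------------------------------------------------------------------------
# SASA, net-charge assignment, boxing
# ---------------------------------------------------------------------------

def shrake_rupley_sasa(system: ParticleSystem, probe_radius: float = 0.14,
                       n_sphere_points: int = 960) -> np.ndarray:
    """Per-particle solvent-accessible surface area in Angstrom^2.

    Shrake-Rupley point sampling (via biotite) with the given probe radius
    (nm) and number of mesh points per sphere.
    """
    import biotite.structure as struc

    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")
    if n_sphere_points < 12:
        raise ValueError("n_sphere_points must be >= 12")
    arr = struc.AtomArray(system.n)
    arr.coord = np.asarray(system.positions, dtype=np.float32) * 10.0
    arr.element = np.array(["C"] * system.n)
    arr.res_id = np.arange(1, system.n + 1)
    arr.atom_name = np.array(["X"] * system.n)
    arr.res_name = np.array(["RES"] * system.n)
    area = struc.sasa(
        arr,
        probe_radius=probe_radius * 10.0,
        point_number=n_sphere_points,
        vdw_radii=np.asarray(system.radii, dtype=np.float64) * 10.0,
        ignore_ions=False,
    )
    return np.asarray(area, dtype=np.float64)


def assign_net_charge(system: ParticleSystem, target: int,
                      sasa_threshold: float = 5.0, seed: int = 0,
                      probe_radius: float = 0.14,
                      n_sphere_points: int = 960) -> ParticleSystem:
    """Protonate random surface sites until the net charge reaches ``target``.

    +1 e is added to distinct randomly chosen sites whose SASA exceeds
    ``sasa_threshold`` (Angstrom^2) until the total charge rounds to the
    integer target, mirroring charge assignment for positive-mode ESI.
    Deterministic for a given seed.
    """
    current = int(round(system.net_charge))
    n_add = target - current
    if n_add == 0:
        return system
    if n_add < 0:
        raise ValueError(
            f"target {target} is below the current net charge {current}; "
            "only protonation (+1 increments) is supported"
        )
    sasa = shrake_rupley_sasa(system, probe_radius, n_sphere_points)
    eligible = np.flatnonzero(sasa > sasa_threshold)
    if eligible.size < n_add:
        raise ValueError(
            f"need {n_add} protonation sites with SASA > {sasa_threshold} A^2 "
            f"but only {eligible.size} are eligible (short by {n_add - eligible.size})"
        )
    rng = np.random.default_rng(seed)
    sites = rng.choice(eligible, size=n_add, replace=False)
    charges = system.charges.copy()
    charges[sites] += 1.0
    return system.replace(charges=charges)


def place_in_cubic_box(system: ParticleSystem, padding: float = 3.0) -> ParticleSystem:
    """Center the system in an exactly cubic box with the given face clearance.

    The box edge is the largest Cartesian extent plus twice ``padding``
    (nm); particles are translated so that the minimum gap between any
    particle and every box face is at least ``padding``.
    """
    if padding < 0:
        raise ValueError("padding must be non-negative")
    lo = system.positions.min(axis=0)
    hi = system.positions.max(axis=0)
    extent = hi - lo
    box_side = float(extent.max() + 2.0 * padding)
    # center each axis inside the cube
    shift = -lo + padding + (extent.max() - extent) / 2.0
    positions = system.positions + shift
    return system.replace(positions=positions, box_side=box_side)
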