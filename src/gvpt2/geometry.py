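"""Molecular geometries: container, XYZ I/O, inertia analysis.

Coordinates are stored in bohr and masses in amu.  The geometry is the
reference configuration for every expansion performed by the engine; it
is treated as immutable (methods return new objects).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import ANGSTROM_TO_BOHR, BOHR_TO_ANGSTROM, isotope_mass


@dataclass(frozen=True)
class Geometry:
    """Atoms with masses and Cartesian coordinates (bohr)."""

    symbols: tuple[str, ...]
    coords: np.ndarray  # (n_atoms, 3), bohr
    masses: np.ndarray = field(default=None)  # (n_atoms,), amu

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "coords", coords)
        if len(self.symbols) != coords.shape[0]:
            raise ValueError("symbol/coordinate count mismatch")
        if self.masses is None:
            masses = np.array([isotope_mass(s) for s in self.symbols])
        else:
            masses = np.asarray(self.masses, dtype=float)
        if masses.shape != (coords.shape[0],):
            raise ValueError("mass array has wrong length")
        if np.any(masses <= 0.0):
            raise ValueError("masses must be positive")
        object.__setattr__(self, "masses", masses)

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def x(self) -> np.ndarray:
        """Flat coordinate vector of length 3*n_atoms (bohr)."""
        return self.coords.reshape(-1)

    def with_coords(self, coords: np.ndarray) -> "Geometry":
        return Geometry(self.symbols, np.asarray(coords, float).reshape(-1, 3), self.masses)

    def mass_vector(self) -> np.ndarray:
        """Per-Cartesian-component masses (amu), length 3*n_atoms."""
        return np.repeat(self.masses, 3)

    # -- rotational analysis -------------------------------------------------

    def center_of_mass(self) -> np.ndarray:
        return self.masses @ self.coords / self.masses.sum()

    def inertia_tensor(self) -> np.ndarray:
        """Inertia tensor about the centre of mass (amu * bohr^2)."""
        r = self.coords - self.center_of_mass()
        m = self.masses
        eye = np.eye(3)
        return (m[:, None, None] * ((r**2).sum(axis=1)[:, None, None] * eye
                                    - r[:, :, None] * r[:, None, :])).sum(axis=0)

    def principal_axes(self) -> tuple[np.ndarray, np.ndarray]:
        """Principal moments (amu*bohr^2, ascending) and axes (columns)."""
        moments, axes = np.linalg.eigh(self.inertia_tensor())
        # right-handed, deterministic sign convention
        for c in range(3):
            k = int(np.argmax(np.abs(axes[:, c])))
            if axes[k, c] < 0:
                axes[:, c] = -axes[:, c]
        if np.linalg.det(axes) < 0:
            axes[:, 2] = -axes[:, 2]
        return moments, axes

    def is_linear(self, tol: float = 1e-8) -> bool:
        moments, _ = self.principal_axes()
        return moments[0] < tol * max(moments[-1], 1.0)


def read_xyz(path, units: str = "angstrom") -> Geometry:
    """Read a standard XYZ file; ``units`` is 'angstrom' or 'bohr'."""
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    n = int(lines[0].split()[0])
    body = lines[2:2 + n] if len(lines) >= n + 2 and not _is_atom_line(lines[1]) else lines[1:1 + n]
    symbols, coords = [], []
    for ln in body:
        parts = ln.split()
        symbols.append(parts[0])
        coords.append([float(v) for v in parts[1:4]])
    coords = np.asarray(coords)
    if units.lower().startswith("a"):
        coords = coords * ANGSTROM_TO_BOHR
    elif not units.lower().startswith("b"):
        raise ValueError(f"unknown units {units!r}")
    return Geometry(tuple(symbols), coords)


def _is_atom_line(line: str) -> bool:
    parts = line.split()
    if len(parts) < 4:
        return False
    try:
        [float(v) for v in parts[1:4]]
        return True
    except ValueError:
        return False


def write_xyz(path, geometry: Geometry, comment: str = "") -> None:
    with open(path, "w") as fh:
        fh.write(f"{geometry.n_atoms}\n{comment}\n")
        for sym, xyz in zip(geometry.symbols, geometry.coords * BOHR_TO_ANGSTROM):
            fh.write(f"{sym:4s} {xyz[0]:18.10f} {xyz[1]:18.10f} {xyz[2]:18.10f}\n")
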