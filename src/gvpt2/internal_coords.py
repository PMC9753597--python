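"""Primitive internal coordinates and Wilson tensors.

The primitive set (all bonds, valence angles -- linear and non-linear --
and dihedrals implied by the molecular topology) is generally redundant;
redundancy is harmless because null-space modes are discarded after the
harmonic problem is solved.

Conventions: bond values in bohr, angles/dihedrals in radians, dihedrals
reported in (-pi, pi] with continuous unwrapping relative to a reference
available for displaced geometries.  The B matrix rows are closed-form
analytic derivatives; B' is obtained by propagating those closed forms
through forward-mode dual numbers (exact, no truncation error) and is
explicitly symmetrised in its two Cartesian indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._dual import Dual, darccos, datan2, vcross, vdot, vnorm
from .geometry import Geometry
from .units import covalent_radius_bohr

LINEAR_ANGLE_THRESHOLD = np.deg2rad(175.0)

KIND_ORDER = {"bond": 0, "angle": 1, "linear-angle": 2, "dihedral": 3}


class InternalCoordinateError(ValueError):
    pass


@dataclass(frozen=True)
class InternalCoordinate:
    """One primitive: bond, (linear-)angle or dihedral.

    ``axis`` is only used by linear-angle coordinates: the in-plane unit
    vector against which the bending component is measured.  It is fixed
    when the coordinate is defined (at the reference geometry) so that
    displaced geometries are measured against the same axis.
    """

    kind: str
    indices: tuple[int, ...]
    axis: Optional[tuple[float, float, float]] = None

    def __post_init__(self):
        n_expected = {"bond": 2, "angle": 3, "linear-angle": 3, "dihedral": 4}
        if self.kind not in n_expected:
            raise InternalCoordinateError(f"unknown coordinate kind {self.kind!r}")
        if len(self.indices) != n_expected[self.kind]:
            raise InternalCoordinateError(f"{self.kind} needs {n_expected[self.kind]} atoms")
        if len(set(self.indices)) != len(self.indices):
            raise InternalCoordinateError("atom indices must be distinct")
        if self.kind == "linear-angle" and self.axis is None:
            raise InternalCoordinateError("linear-angle requires a reference axis")

    def canonical_key(self):
        i = self.indices
        if self.kind == "bond":
            key = tuple(sorted(i))
        elif self.kind in ("angle", "linear-angle"):
            key = (min(i[0], i[2]), i[1], max(i[0], i[2]))
        else:
            key = i if (i[1], i[0]) < (i[2], i[3]) else tuple(reversed(i))
        comp = 0
        if self.kind == "linear-angle" and self.axis is not None:
            comp = 1 if abs(self.axis[2]) > 0.5 or self.axis[0] < 0 else 0
        return (KIND_ORDER[self.kind], key, comp)


@dataclass(frozen=True)
class InternalSet:
    coordinates: tuple[InternalCoordinate, ...]

    def __post_init__(self):
        keys = [c.canonical_key()[:2] + (tuple(c.axis) if c.axis else (),)
                for c in self.coordinates]
        if len(set(keys)) != len(keys):
            raise InternalCoordinateError("duplicate internal coordinates in set")

    def __len__(self):
        return len(self.coordinates)

    def __iter__(self):
        return iter(self.coordinates)

    def max_atom(self) -> int:
        return max(max(c.indices) for c in self.coordinates)


@dataclass(frozen=True)
class BTensors:
    B: np.ndarray  # (N, 3*n_atoms)
    Bp: np.ndarray  # (N, 3*n_atoms, 3*n_atoms), symmetric in last two axes


@dataclass(frozen=True)
class GTensors:
    G: np.ndarray  # (N, N), units 1/amu (times bohr^2/rad^2 as appropriate)
    Gp: np.ndarray  # (N, N, 3*n_atoms)


# ---------------------------------------------------------------------------
# topology perception
# ---------------------------------------------------------------------------

def detect_bonds(geometry: Geometry, bond_scale: float = 1.3) -> list[tuple[int, int]]:
    bonds = []
    for a in range(geometry.n_atoms):
        for b in range(a + 1, geometry.n_atoms):
            r = np.linalg.norm(geometry.coords[a] - geometry.coords[b])
            cutoff = bond_scale * (covalent_radius_bohr(geometry.symbols[a])
                                   + covalent_radius_bohr(geometry.symbols[b]))
            if r <= cutoff:
                bonds.append((a, b))
    return bonds


def _fragments(n_atoms: int, bonds) -> list[list[int]]:
    adj = {a: set() for a in range(n_atoms)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)
    seen, frags = set(), []
    for start in range(n_atoms):
        if start in seen:
            continue
        stack, comp = [start], []
        while stack:
            a = stack.pop()
            if a in seen:
                continue
            seen.add(a)
            comp.append(a)
            stack.extend(adj[a] - seen)
        frags.append(sorted(comp))
    return frags


def _linear_bend_axes(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to u, chosen deterministically."""
    w = np.zeros(3)
    w[int(np.argmin(np.abs(u)))] = 1.0
    e1 = w - np.dot(w, u) * u
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    return e1, e2


def detect_primitives(geometry: Geometry, bond_scale: float = 1.3,
                      linear_threshold: float = LINEAR_ANGLE_THRESHOLD) -> InternalSet:
    """All bonds, valence angles and dihedrals implied by the topology.

    Near-linear valence angles are replaced by two orthogonal linear-angle
    coordinates; dihedrals through near-linear centres are dropped (they
    are undefined there).  The ordering is deterministic: bonds, then
    angles, then dihedrals, each sorted by canonical index tuple.
    """
    if geometry.n_atoms < 2:
        raise InternalCoordinateError("need at least two atoms")
    bonds = detect_bonds(geometry, bond_scale)
    frags = _fragments(geometry.n_atoms, bonds)
    if len(frags) > 1:
        raise InternalCoordinateError(
            f"disconnected topology; fragments: {frags} "
            f"(consider raising bond_scale={bond_scale})")

    adj = {a: set() for a in range(geometry.n_atoms)}
    for a, b in bonds:
        adj[a].add(b)
        adj[b].add(a)

    coords: list[InternalCoordinate] = []
    for a, b in sorted(bonds):
        coords.append(InternalCoordinate("bond", (a, b)))

    angles, linear_bends, is_linear_center = [], [], set()
    for b in range(geometry.n_atoms):
        nb = sorted(adj[b])
        for ii, a in enumerate(nb):
            for c in nb[ii + 1:]:
                val = _plain_angle(geometry.coords[a], geometry.coords[b], geometry.coords[c])
                if val > linear_threshold:
                    u = geometry.coords[c] - geometry.coords[a]
                    u /= np.linalg.norm(u)
                    e1, e2 = _linear_bend_axes(u)
                    linear_bends.append(InternalCoordinate("linear-angle", (a, b, c), tuple(e1)))
                    linear_bends.append(InternalCoordinate("linear-angle", (a, b, c), tuple(e2)))
                    is_linear_center.add((a, b, c))
                    is_linear_center.add((c, b, a))
                else:
                    angles.append(InternalCoordinate("angle", (a, b, c)))
    coords.extend(sorted(angles, key=InternalCoordinate.canonical_key))
    coords.extend(sorted(linear_bends, key=InternalCoordinate.canonical_key))

    dihedrals = []
    seen = set()
    for b, c in sorted(bonds):
        for b0, c0 in ((b, c), (c, b)):
            for a in sorted(adj[b0] - {c0}):
                for d in sorted(adj[c0] - {b0}):
                    if a == d:
                        continue
                    if (a, b0, c0) in is_linear_center or (b0, c0, d) in is_linear_center:
                        continue
                    cand = InternalCoordinate("dihedral", (a, b0, c0, d))
                    key = cand.canonical_key()
                    if key in seen:
                        continue
                    seen.add(key)
                    dihedrals.append(cand)
    coords.extend(sorted(dihedrals, key=InternalCoordinate.canonical_key))
    return InternalSet(tuple(coords))


# ---------------------------------------------------------------------------
# values
# ---------------------------------------------------------------------------

def _plain_angle(xa, xb, xc) -> float:
    u = xa - xb
    v = xc - xb
    c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def _value(coord: InternalCoordinate, atom_xyz):
    """Coordinate value; works on plain arrays and on Duals."""
    k = coord.kind
    if k == "bond":
        xa, xb = atom_xyz
        return vnorm(xa - xb)
    if k == "angle":
        xa, xb, xc = atom_xyz
        u, v = xa - xb, xc - xb
        return darccos(vdot(u, v) / (vnorm(u) * vnorm(v)))
    if k == "linear-angle":
        xa, xb, xc = atom_xyz
        e = np.asarray(coord.axis)
        u, v = xa - xb, xc - xb
        return vdot(e, u) / vnorm(u) + vdot(e, v) / vnorm(v)
    # dihedral
    xa, xb, xc, xd = atom_xyz
    b1, b2, b3 = xb - xa, xc - xb, xd - xc
    n1, n2 = vcross(b1, b2), vcross(b2, b3)
    m = vcross(n1, b2 / vnorm(b2))
    return datan2(vdot(m, n2), vdot(n1, n2))


def coordinate_values(geometry: Geometry, iset: InternalSet,
                      reference: Optional[np.ndarray] = None) -> np.ndarray:
    """Values of all internals; dihedrals unwrapped against ``reference``."""
    if iset.max_atom() >= geometry.n_atoms:
        raise InternalCoordinateError("coordinate refers to a missing atom")
    vals = np.empty(len(iset))
    for i, coord in enumerate(iset):
        xs = [geometry.coords[a] for a in coord.indices]
        vals[i] = _value(coord, xs)
        if coord.kind == "dihedral" and reference is not None:
            vals[i] = reference[i] + _wrap_pi(vals[i] - reference[i])
    return vals


def _wrap_pi(d: float) -> float:
    return (d + np.pi) % (2.0 * np.pi) - np.pi


# ---------------------------------------------------------------------------
# B matrix (closed forms) and B' (dual-propagated)
# ---------------------------------------------------------------------------

def _b_row_blocks(coord: InternalCoordinate, atom_xyz):
    """Per-atom 3-vector derivative blocks; generic over ndarray/Dual."""
    k = coord.kind
    if k == "bond":
        xa, xb = atom_xyz
        d = xa - xb
        r = vnorm(d)
        u = d / r
        return [u, -1.0 * u]
    if k == "angle":
        xa, xb, xc = atom_xyz
        u_ = xa - xb
        v_ = xc - xb
        lu, lv = vnorm(u_), vnorm(v_)
        u, v = u_ / lu, v_ / lv
        cphi = vdot(u, v)
        sin2 = 1.0 - cphi * cphi
        sval = sin2.val if isinstance(sin2, Dual) else sin2
        if sval < 1e-14:
            raise InternalCoordinateError(
                f"angle {coord.indices} is (anti)linear; use the linear-angle kind")
        sphi = (sin2).sqrt() if isinstance(sin2, Dual) else np.sqrt(sin2)
        ga = (u * cphi - v) / (lu * sphi)
        gc = (v * cphi - u) / (lv * sphi)
        return [ga, -1.0 * ga - 1.0 * gc, gc]
    if k == "linear-angle":
        xa, xb, xc = atom_xyz
        e = np.asarray(coord.axis)
        ga = _dir_projection_grad(xa - xb, e)
        gc = _dir_projection_grad(xc - xb, e)
        return [ga, -1.0 * ga - 1.0 * gc, gc]
    # dihedral: standard closed-form gradient
    xa, xb, xc, xd = atom_xyz
    b1, b2, b3 = xb - xa, xc - xb, xd - xc
    n1, n2 = vcross(b1, b2), vcross(b2, b3)
    n1sq, n2sq = vdot(n1, n1), vdot(n2, n2)
    v1 = n1sq.val if isinstance(n1sq, Dual) else n1sq
    v2 = n2sq.val if isinstance(n2sq, Dual) else n2sq
    if min(v1, v2) < 1e-20:
        raise InternalCoordinateError(
            f"dihedral {coord.indices} has a (anti)linear arm and is undefined")
    lb2 = vnorm(b2)
    ga = (lb2 / n1sq) * n1
    gd = -1.0 * (lb2 / n2sq) * n2
    f1 = vdot(b1, b2) / (lb2 * lb2)
    f3 = vdot(b3, b2) / (lb2 * lb2)
    gb = -1.0 * (1.0 + f1) * ga + f3 * gd
    gc = f1 * ga - 1.0 * (1.0 + f3) * gd
    return [ga, gb, gc, gd]


def _dir_projection_grad(d, e):
    """Gradient of e . unit(d) with respect to the head of d."""
    r = vnorm(d)
    u = d / r
    return (e - u * vdot(u, e)) / r


def b_matrix(geometry: Geometry, iset: InternalSet) -> np.ndarray:
    """Wilson B matrix, shape (N, 3*n_atoms): analytic d s_i / d x."""
    n3 = 3 * geometry.n_atoms
    B = np.zeros((len(iset), n3))
    for i, coord in enumerate(iset):
        xs = [geometry.coords[a] for a in coord.indices]
        for a, blk in zip(coord.indices, _b_row_blocks(coord, xs)):
            B[i, 3 * a:3 * a + 3] = blk
    return B


def b_prime(geometry: Geometry, iset: InternalSet) -> np.ndarray:
    """B' tensor (N, 3N, 3N): analytic d^2 s_i / dx dx, exactly symmetric."""
    n3 = 3 * geometry.n_atoms
    x = Dual.seed(geometry.x)
    Bp = np.zeros((len(iset), n3, n3))
    for i, coord in enumerate(iset):
        xs = [x[3 * a:3 * a + 3] for a in coord.indices]
        for a, blk in zip(coord.indices, _b_row_blocks(coord, xs)):
            Bp[i, 3 * a:3 * a + 3, :] = blk.grad
    Bp = 0.5 * (Bp + np.transpose(Bp, (0, 2, 1)))
    return Bp


def b_tensors(geometry: Geometry, iset: InternalSet) -> BTensors:
    return BTensors(b_matrix(geometry, iset), b_prime(geometry, iset))


# ---------------------------------------------------------------------------
# G matrix and its Cartesian derivative
# ---------------------------------------------------------------------------

def g_matrix(B: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Wilson G = B M^-1 B^T with per-component masses (amu)."""
    minv = 1.0 / np.repeat(np.asarray(masses, float), 3)
    if B.shape[1] != minv.size:
        raise ValueError("B and masses disagree on atom count")
    G = (B * minv) @ B.T
    return 0.5 * (G + G.T)


def g_prime(B: np.ndarray, Bp: np.ndarray, masses: np.ndarray) -> np.ndarray:
    """Cartesian first derivatives G'_ij,c = d G_ij / d x_c."""
    minv = 1.0 / np.repeat(np.asarray(masses, float), 3)
    # G'_ijc = sum_e Bp[i,e,c] minv[e] B[j,e] + B[i,e] minv[e] Bp[j,e,c]
    t = np.einsum("iec,e,je->ijc", Bp, minv, B, optimize=True)
    Gp = t + np.transpose(t, (1, 0, 2))
    return Gp


def g_tensors(geometry: Geometry, iset: InternalSet) -> GTensors:
    B = b_matrix(geometry, iset)
    Bp = b_prime(geometry, iset)
    return GTensors(g_matrix(B, geometry.masses), g_prime(B, Bp, geometry.masses))


# ---------------------------------------------------------------------------
# external B / B' exchange format
# ---------------------------------------------------------------------------
# Plain-text archive so that B and B' tensors generated by other programs
# (different coordinate constructions) can drive the reference-point
# machinery.  Layout: a header, one "coord" definition line per internal
# coordinate, then row-major "B i <3N floats>" lines and "BP i row
# <3N floats>" lines.  Values are written in full repr precision.

def write_b_tensors(path, iset: InternalSet, tensors: BTensors) -> None:
    n3 = tensors.B.shape[1]
    with open(path, "w") as fh:
        fh.write("# gvpt2 B-tensor archive v1\n")
        fh.write(f"natoms {n3 // 3}\n")
        for c in iset:
            axis = "" if c.axis is None else " axis " + " ".join(float(v).hex() for v in c.axis)
            fh.write(f"coord {c.kind} {' '.join(map(str, c.indices))}{axis}\n")
        for i, row in enumerate(tensors.B):
            fh.write(f"B {i} " + " ".join(float(v).hex() for v in row) + "\n")
        for i, block in enumerate(tensors.Bp):
            for r, row in enumerate(block):
                fh.write(f"BP {i} {r} " + " ".join(float(v).hex() for v in row) + "\n")


def read_b_tensors(path) -> tuple[InternalSet, BTensors]:
    coords: list[InternalCoordinate] = []
    n_atoms = None
    b_rows: dict[int, np.ndarray] = {}
    bp_rows: dict[tuple[int, int], np.ndarray] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if parts[0] == "natoms":
                n_atoms = int(parts[1])
            elif parts[0] == "coord":
                kind = parts[1]
                if "axis" in parts:
                    cut = parts.index("axis")
                    idx = tuple(int(v) for v in parts[2:cut])
                    axis = tuple(float.fromhex(v) for v in parts[cut + 1:cut + 4])
                else:
                    idx = tuple(int(v) for v in parts[2:])
                    axis = None
                coords.append(InternalCoordinate(kind, idx, axis))
            elif parts[0] == "B":
                b_rows[int(parts[1])] = np.array([float.fromhex(v) for v in parts[2:]])
            elif parts[0] == "BP":
                bp_rows[(int(parts[1]), int(parts[2]))] = \
                    np.array([float.fromhex(v) for v in parts[3:]])
    if n_atoms is None:
        raise InternalCoordinateError(f"{path}: missing natoms header")
    n3 = 3 * n_atoms
    N = len(coords)
    B = np.zeros((N, n3))
    Bp = np.zeros((N, n3, n3))
    for i in range(N):
        B[i] = b_rows[i]
        for r in range(n3):
            Bp[i, r] = bp_rows[(i, r)]
    return InternalSet(tuple(coords)), BTensors(B, Bp)
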