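"""Engine-free analytic potentials and brute-force oracles.

Two families of desk-scale test systems make the whole engine testable
without any electronic-structure code:

* analytic model potentials (Morse diatomic, polynomial PES in internal
  coordinates) implementing the engine contract with exact gradients and
  Hessians, and
* a sum-over-states Rayleigh-Schroedinger PT2 oracle (plus full
  variational diagonalization) built from explicit harmonic-oscillator
  matrices of the expanded Hamiltonian, including the symmetrised
  p q p orderings of the kinetic terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import EngineResult
from .force_field import KineticDerivatives, QuarticForceField
from .geometry import Geometry
from .internal_coords import InternalSet, b_matrix, b_prime, coordinate_values
from .units import AMU_TO_ME, HARTREE_TO_CM
from .vpt2 import CoriolisData


# ---------------------------------------------------------------------------
# Morse diatomic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MorseDiatomic:
    """V(r) = D (1 - exp(-a (r - re)))^2 with exact Cartesian derivatives.

    The exact levels are E_v = we (v + 1/2) - wexe (v + 1/2)^2 with
    we = a sqrt(2 D / mu) and wexe = a^2 / (2 mu) (atomic units), the
    standard exactness benchmark for second-order perturbation theory.
    """

    D: float            # well depth, hartree
    a: float            # range parameter, 1/bohr
    re: float           # equilibrium distance, bohr
    symbols: tuple[str, str] = ("H", "H")
    masses: Optional[tuple[float, float]] = None  # amu; default from symbols

    def geometry(self) -> Geometry:
        coords = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, self.re]])
        return Geometry(self.symbols, coords, None if self.masses is None
                        else np.asarray(self.masses))

    # -- spectroscopic constants -------------------------------------------

    def reduced_mass_au(self) -> float:
        m = self.geometry().masses * AMU_TO_ME
        return float(m[0] * m[1] / (m[0] + m[1]))

    @property
    def omega_e_cm(self) -> float:
        mu = self.reduced_mass_au()
        return self.a * np.sqrt(2.0 * self.D / mu) * HARTREE_TO_CM

    @property
    def omega_exe_cm(self) -> float:
        mu = self.reduced_mass_au()
        return self.a**2 / (2.0 * mu) * HARTREE_TO_CM

    def exact_level(self, v: int) -> float:
        """E_v - E_0 in cm^-1."""
        x = v + 0.5
        return self.omega_e_cm * v - self.omega_exe_cm * (x**2 - 0.25)

    def exact_fundamental(self) -> float:
        return self.omega_e_cm - 2.0 * self.omega_exe_cm

    # -- engine contract ------------------------------------------------------

    def _radial(self, r: float):
        e = np.exp(-self.a * (r - self.re))
        V = self.D * (1.0 - e) ** 2
        V1 = 2.0 * self.D * self.a * e * (1.0 - e)
        V2 = 2.0 * self.D * self.a**2 * e * (2.0 * e - 1.0)
        return V, V1, V2

    def compute(self, geometry: Geometry) -> EngineResult:
        d = geometry.coords[0] - geometry.coords[1]
        r = float(np.linalg.norm(d))
        u = d / r
        V, V1, V2 = self._radial(r)
        grad = np.zeros((2, 3))
        grad[0] = V1 * u
        grad[1] = -V1 * u
        proj = np.outer(u, u)
        blk = V2 * proj + V1 * (np.eye(3) - proj) / r
        hess = np.block([[blk, -blk], [-blk, blk]])
        return EngineResult(V, grad.reshape(-1), hess)

    def exact_force_field(self) -> QuarticForceField:
        """Dimensionless cubic/quartic constants from the analytic
        derivatives V''' = -6 D a^3, V'''' = 14 D a^4 at re."""
        mu = self.reduced_mass_au()
        w_au = self.a * np.sqrt(2.0 * self.D / mu)
        v3 = -6.0 * self.D * self.a**3
        v4 = 14.0 * self.D * self.a**4
        phi3 = v3 / mu**1.5 / w_au**1.5 * HARTREE_TO_CM
        phi4 = v4 / mu**2 / w_au**2 * HARTREE_TO_CM
        return QuarticForceField(np.array([w_au * HARTREE_TO_CM]),
                                 np.full((1, 1, 1), phi3),
                                 np.full((1, 1, 1, 1), phi4), "curvilinear")


def morse_diatomic(D: float, a: float, mu_amu: float = None, re: float = 1.4,
                   symbols=("H", "H"), masses=None) -> MorseDiatomic:
    """Construct a Morse diatomic; ``mu_amu`` overrides the atomic masses
    with two equal masses of 2*mu."""
    if mu_amu is not None:
        masses = (2.0 * mu_amu, 2.0 * mu_amu)
    if D <= 0 or a <= 0:
        raise ValueError("D and a must be positive")
    return MorseDiatomic(D, a, re, tuple(symbols), masses)


# ---------------------------------------------------------------------------
# polynomial PES in internal coordinates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolynomialPES:
    """Quartic polynomial PES in chosen internal coordinates.

    V(s) = 1/2 F.dd + 1/6 C.ddd + 1/24 Q.dddd with d = s - s_ref; exact
    Cartesian gradient and Hessian follow from the chain rule through the
    analytic B and B' tensors (the Hessian picks up the g_s B' term away
    from stationary points, which exercises the same machinery the
    Cartesian-to-internal transformation must undo).
    """

    geometry_ref: Geometry
    iset: InternalSet
    F: np.ndarray                       # (N, N) hartree / unit^2
    C: Optional[np.ndarray] = None      # (N, N, N)
    Q: Optional[np.ndarray] = None      # (N, N, N, N)
    s_ref: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.s_ref is None:
            object.__setattr__(self, "s_ref",
                               coordinate_values(self.geometry_ref, self.iset))
        n = len(self.iset)
        if np.asarray(self.F).shape != (n, n):
            raise ValueError("harmonic block has wrong shape")
        w = np.linalg.eigvalsh(np.asarray(self.F))
        if w.min() <= 0:
            raise ValueError("harmonic block must be positive definite")

    def _sderivs(self, d: np.ndarray):
        F = np.asarray(self.F)
        V = 0.5 * d @ F @ d
        g = F @ d
        H = F.copy()
        if self.C is not None:
            C = np.asarray(self.C)
            V += np.einsum("ijk,i,j,k", C, d, d, d) / 6.0
            g += 0.5 * np.einsum("ijk,j,k->i", C, d, d)
            H += np.einsum("ijk,k->ij", C, d)
        if self.Q is not None:
            Qt = np.asarray(self.Q)
            V += np.einsum("ijkl,i,j,k,l", Qt, d, d, d, d) / 24.0
            g += np.einsum("ijkl,j,k,l->i", Qt, d, d, d) / 6.0
            H += 0.5 * np.einsum("ijkl,k,l->ij", Qt, d, d)
        return V, g, H

    def compute(self, geometry: Geometry) -> EngineResult:
        s = coordinate_values(geometry, self.iset, reference=self.s_ref)
        d = s - self.s_ref
        V, g_s, H_s = self._sderivs(d)
        B = b_matrix(geometry, self.iset)
        Bp = b_prime(geometry, self.iset)
        g_x = B.T @ g_s
        H_x = B.T @ H_s @ B + np.einsum("i,ijk->jk", g_s, Bp)
        return EngineResult(V, g_x, 0.5 * (H_x + H_x.T))


def synthetic_polyatomic(geometry: Geometry, iset: InternalSet, F, C=None,
                         Q=None) -> PolynomialPES:
    return PolynomialPES(geometry, iset, np.asarray(F, float),
                         None if C is None else np.asarray(C, float),
                         None if Q is None else np.asarray(Q, float))


# ---------------------------------------------------------------------------
# canonical synthetic systems (fixed study conditions)
# ---------------------------------------------------------------------------

def co_like_morse() -> MorseDiatomic:
    """CO-like Morse oscillator: w_e ~ 2133 cm^-1, w_e x_e ~ 12.6 cm^-1.

    Realistic first-row diatomic anharmonicity; the exactness benchmark
    used throughout the tests.
    """
    return MorseDiatomic(D=0.41, a=1.20, re=2.13, symbols=("C", "O"))


def water_like_pes():
    """Bent triatomic (water-like masses/geometry) with a realistic
    internal-coordinate quartic PES: stretch force constants ~8.5
    mdyn/Angstrom, Morse-type stretch cubics, a soft bend, and mild
    stretch-bend coupling.  Semi-rigid and free of Fermi resonances.

    Returns (geometry, internal set, PES).
    """
    from .units import ANGSTROM_TO_BOHR
    xyz = np.array([[0.0, 0.0, 0.1173],
                    [0.0, 0.7572, -0.4692],
                    [0.0, -0.7572, -0.4692]]) * ANGSTROM_TO_BOHR
    geom = Geometry(("O", "H", "H"), xyz)
    from .internal_coords import detect_primitives
    iset = detect_primitives(geom)  # bonds (0,1), (0,2), angle (1,0,2)
    F = np.array([[0.50, -0.005, 0.02],
                  [-0.005, 0.50, 0.02],
                  [0.02, 0.02, 0.16]])
    n = 3
    C = np.zeros((n, n, n))
    C[0, 0, 0] = C[1, 1, 1] = -1.7        # Morse-like OH stretches
    C[2, 2, 2] = -0.10                    # soft bend cubic
    for (i, j, k) in ((0, 0, 2), (1, 1, 2)):
        from itertools import permutations as _perm
        for p in set(_perm((i, j, k))):
            C[p] = -0.06                  # stretch-bend coupling
    Q = np.zeros((n, n, n, n))
    Q[0, 0, 0, 0] = Q[1, 1, 1, 1] = 5.0
    Q[2, 2, 2, 2] = 0.12
    return geom, iset, synthetic_polyatomic(geom, iset, F, C, Q)


def fermi_pair_system(detuning: float = 10.0, coupling: float = 30.0):
    """Two-mode toy with a weak type-I Fermi resonance 2 w_1 ~ w_2.

    Returns (omega, f3, f4) in cm^-1; the default detuning/coupling give
    a Martin K of ~3 cm^-1 (clearly accepted) in the weak-coupling
    regime where the polyad treatment should track the variational
    reference to better than 1 cm^-1.
    """
    from itertools import permutations as _perm
    omega = np.array([1000.0, 2000.0 - detuning])
    f3 = np.zeros((2, 2, 2))
    for p in set(_perm((0, 0, 1))):
        f3[p] = coupling
    f3[0, 0, 0] = -18.0
    f3[1, 1, 1] = -25.0
    f4 = np.zeros((2, 2, 2, 2))
    f4[0, 0, 0, 0] = 6.0
    f4[1, 1, 1, 1] = 8.0
    for p in set(_perm((0, 0, 1, 1))):
        f4[p] = 2.0
    return omega, f3, f4


def _symmetrize3(a):
    from itertools import permutations as _perm
    out = np.zeros_like(a)
    for p in _perm(range(3)):
        out += np.transpose(a, p)
    return out / 6.0


def random_nonresonant_system(n_modes: int, rng: np.random.Generator,
                              potential: bool = True, kinetic: bool = True,
                              coriolis: bool = False, scale: float = 6.0,
                              guard: float = 150.0):
    """Random toy Hamiltonian with all resonance detunings above
    ``guard`` cm^-1 and couplings of the given scale (cm^-1).

    Returns (omega, f3, f4, g1, g2, coriolis_data).
    """
    from itertools import permutations as _perm
    M = n_modes
    while True:
        omega = rng.uniform(900.0, 3500.0, M)
        ok = all(abs(2 * omega[i] - omega[k]) > guard
                 for i in range(M) for k in range(M) if i != k)
        ok = ok and all(abs(omega[i] + omega[j] - omega[k]) > guard
                        for i in range(M) for j in range(i + 1, M)
                        for k in range(M) if k not in (i, j))
        if ok:
            break
    f3 = np.zeros((M,) * 3)
    f4 = np.zeros((M,) * 4)
    g1 = np.zeros((M,) * 3)
    g2 = np.zeros((M,) * 4)
    if potential:
        f3 = _symmetrize3(rng.normal(0.0, scale, (M,) * 3))
        for i in range(M):
            f4[i, i, i, i] = rng.normal(0.0, scale)
            for j in range(M):
                if j == i:
                    continue
                v = rng.normal(0.0, scale)
                for p in set(_perm((i, i, j, j))):
                    f4[p] = v
    if kinetic:
        g1 = rng.normal(0.0, scale, (M,) * 3)
        g1 = 0.5 * (g1 + np.transpose(g1, (1, 0, 2)))
        g2 = rng.normal(0.0, scale, (M,) * 4)
        g2 = 0.5 * (g2 + np.transpose(g2, (1, 0, 2, 3)))
        g2 = 0.5 * (g2 + np.transpose(g2, (0, 1, 3, 2)))
    cor = None
    if coriolis:
        zeta = np.zeros((3, M, M))
        for a in range(3):
            z = rng.normal(0.0, 0.4, (M, M))
            zeta[a] = z - z.T
        cor = CoriolisData(zeta, np.abs(rng.normal(1.5, 0.5, 3)))
    return omega, f3, f4, g1, g2, cor


# ---------------------------------------------------------------------------
# harmonic-oscillator matrix oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OracleSpec:
    """Model Hamiltonian for the sum-over-states oracle (all cm^-1)."""

    omega: np.ndarray
    f3: Optional[np.ndarray] = None
    f4: Optional[np.ndarray] = None
    g1: Optional[np.ndarray] = None
    g2: Optional[np.ndarray] = None
    coriolis: Optional[CoriolisData] = None
    n_basis: int = 0  # quanta per mode; 0 -> default by mode count
    kinetic_ordering: str = "pqp"  # "pqp" (symmetrised) or "qpp" (naive)

    def __post_init__(self):
        object.__setattr__(self, "omega", np.asarray(self.omega, float))
        if self.n_basis == 0:
            nb = 20 if self.omega.size <= 2 else 12
            object.__setattr__(self, "n_basis", nb)

    @property
    def n_modes(self) -> int:
        return self.omega.size


class OracleResonanceError(ArithmeticError):
    """The oracle refuses near-degenerate denominators."""


def _ladder(nb: int):
    n = np.arange(nb)
    a = np.zeros((nb, nb))
    a[n[:-1], n[1:]] = np.sqrt(n[1:])
    q = ((a + a.T) / np.sqrt(2.0)).astype(complex)
    p = 1j * (a.T - a) / np.sqrt(2.0)
    return q, p


class _OracleOperators:
    """Matrix-free application of H1/H2 on harmonic product states.

    State vectors live on a (nb,)*M tensor; one-mode operators act by a
    tensordot along the corresponding axis, so no Kronecker matrices are
    ever formed.  Operator products are applied right to left, preserving
    the exact (symmetrised p q p) ordering of the kinetic terms.
    """

    def __init__(self, spec: OracleSpec):
        self.spec = spec
        self.q1, self.p1 = _ladder(spec.n_basis)
        M, nb = spec.n_modes, spec.n_basis
        counts = np.indices((nb,) * M).reshape(M, nb**M)
        self.e0 = (spec.omega[:, None] * (counts + 0.5)).sum(axis=0)
        self._terms1 = self._build_terms1()
        self._terms2 = self._build_terms2()

    def _build_terms1(self):
        spec = self.spec
        M = spec.n_modes
        terms = []  # (coeff, [(op, mode), ...]) applied right to left
        for i in range(M):
            for j in range(M):
                for k in range(M):
                    if spec.f3 is not None and spec.f3[i, j, k] != 0.0:
                        terms.append((spec.f3[i, j, k] / 6.0,
                                      [("q", i), ("q", j), ("q", k)]))
                    if spec.g1 is not None and spec.g1[i, j, k] != 0.0:
                        if spec.kinetic_ordering == "pqp":
                            ops = [("p", i), ("q", k), ("p", j)]
                        else:  # naive ordering sensitivity check
                            ops = [("q", k), ("p", i), ("p", j)]
                        terms.append((0.5 * spec.g1[i, j, k], ops))
        return terms

    def _build_terms2(self):
        spec = self.spec
        M = spec.n_modes
        terms = []
        for idx in np.ndindex(M, M, M, M):
            i, j, k, l = idx
            if spec.f4 is not None and spec.f4[idx] != 0.0:
                terms.append((spec.f4[idx] / 24.0,
                              [("q", i), ("q", j), ("q", k), ("q", l)]))
            if spec.g2 is not None and spec.g2[idx] != 0.0:
                if spec.kinetic_ordering == "pqp":
                    ops = [("p", i), ("q", k), ("q", l), ("p", j)]
                else:
                    ops = [("q", k), ("q", l), ("p", i), ("p", j)]
                terms.append((0.25 * spec.g2[idx], ops))
        if spec.coriolis is not None:
            w = spec.omega
            for alpha in range(3):
                pi_terms = []
                for i in range(M):
                    for j in range(M):
                        z = spec.coriolis.zeta[alpha, i, j]
                        if z != 0.0:
                            pi_terms.append((z * np.sqrt(w[j] / w[i]),
                                             [("q", i), ("p", j)]))
                b = spec.coriolis.b_rot[alpha]
                if b != 0.0 and pi_terms:
                    terms.append((b, ("pi2", pi_terms)))
        return terms

    def _apply_one(self, vec, op, mode):
        mat = self.q1 if op == "q" else self.p1
        out = np.tensordot(mat, vec, axes=([1], [mode]))
        return np.moveaxis(out, 0, mode)

    def _apply_ops(self, vec, ops):
        for op, mode in reversed(ops):
            vec = self._apply_one(vec, op, mode)
        return vec

    def _apply_terms(self, vec, terms):
        out = np.zeros_like(vec)
        for coeff, ops in terms:
            if isinstance(ops, tuple) and ops[0] == "pi2":
                pi_terms = ops[1]
                inner = np.zeros_like(vec)
                for c2, ops2 in pi_terms:
                    inner += c2 * self._apply_ops(vec, ops2)
                acc = np.zeros_like(vec)
                for c2, ops2 in pi_terms:
                    acc += c2 * self._apply_ops(inner, ops2)
                out += coeff * acc
            else:
                out += coeff * self._apply_ops(vec, ops)
        return out

    def h1_column(self, vec):
        return self._apply_terms(vec, self._terms1)

    def h2_column(self, vec):
        return self._apply_terms(vec, self._terms2)

    def basis_vector(self, v: Sequence[int]):
        nb, M = self.spec.n_basis, self.spec.n_modes
        vec = np.zeros((nb,) * M, complex)
        for quantum in v:
            if not 0 <= quantum < nb:
                raise ValueError("state outside the oracle basis")
        vec[tuple(v)] = 1.0
        return vec

    def state_index(self, v: Sequence[int]) -> int:
        nb = self.spec.n_basis
        idx = 0
        for quantum in v:
            idx = idx * nb + quantum
        return idx


def _oracle(spec: OracleSpec) -> _OracleOperators:
    return _OracleOperators(spec)


def sum_over_states_pt2(spec: OracleSpec, state: Sequence[int],
                        denom_tol: float = 1e-3,
                        _mats: Optional[_OracleOperators] = None) -> float:
    """Second-order energy (harmonic + eps2, cm^-1, absolute incl. ZPVE)
    of one basis state by explicit Rayleigh-Schroedinger summation."""
    mats = _mats if _mats is not None else _oracle(spec)
    vec = mats.basis_vector(state)
    r = mats.state_index(state)
    col1 = mats.h1_column(vec).reshape(-1)
    if abs(col1[r]) > 1e-9:
        raise AssertionError("first-order correction must vanish for odd H1")
    de = mats.e0[r] - mats.e0
    mask = np.ones(de.size, bool)
    mask[r] = False
    coupled = mask & (np.abs(col1) > 1e-12)
    if np.any(np.abs(de[coupled]) < denom_tol):
        worst = np.abs(de[coupled]).min()
        raise OracleResonanceError(
            f"near-degenerate denominator ({worst:.2e} cm^-1); the "
            "perturbative oracle declines this state")
    eps2 = float(np.real(np.vdot(vec.reshape(-1), mats.h2_column(vec).reshape(-1))))
    eps2 += float(np.sum((np.abs(col1[coupled]) ** 2) / de[coupled]))
    return float(mats.e0[r]) + eps2


def transition_pt2(spec: OracleSpec, state: Sequence[int],
                   _mats: Optional[_OracleOperators] = None, **kw) -> float:
    """PT2 transition energy state <- ground (cm^-1)."""
    mats = _mats if _mats is not None else _oracle(spec)
    ground = (0,) * spec.n_modes
    return (sum_over_states_pt2(spec, state, _mats=mats, **kw)
            - sum_over_states_pt2(spec, ground, _mats=mats, **kw))


def fvci_reference(spec: OracleSpec, states: Sequence[Sequence[int]],
                   check_convergence: bool = False,
                   conv_tol: float = 1e-8) -> np.ndarray:
    """Variational (full diagonalization) transition energies for the
    requested harmonic-basis states, assigned by maximum overlap."""

    def _solve(sp):
        mats = _oracle(sp)
        dim = sp.n_basis ** sp.n_modes
        H = np.zeros((dim, dim), complex)
        eye = np.eye(dim, dtype=complex)
        shape = (sp.n_basis,) * sp.n_modes
        for c in range(dim):
            vec = eye[:, c].reshape(shape)
            H[:, c] = (mats.h1_column(vec) + mats.h2_column(vec)).reshape(-1)
        H += np.diag(mats.e0)
        evals, evecs = np.linalg.eigh(H)
        weights = np.abs(evecs) ** 2
        out = []
        g = int(np.argmax(weights[mats.state_index((0,) * sp.n_modes)]))
        for st in states:
            idx = int(np.argmax(weights[mats.state_index(st)]))
            out.append(evals[idx] - evals[g])
        return np.array(out)

    result = _solve(spec)
    if check_convergence:
        bigger = OracleSpec(spec.omega, spec.f3, spec.f4, spec.g1, spec.g2,
                            spec.coriolis, spec.n_basis + 6, spec.kinetic_ordering)
        if np.abs(_solve(bigger) - result).max() > conv_tol:
            raise OracleResonanceError("FVCI energies not converged with basis "
                                       "size; enlarge n_basis")
    return result
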