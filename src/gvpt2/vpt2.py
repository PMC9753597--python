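"""Second-order vibrational perturbation theory in curvilinear internal
or Cartesian normal coordinates.

The vibrational Hamiltonian is expanded as H0 + H1 + H2 with

    H0 = (1/2) sum_i w_i (p_i^2 + q_i^2)
    H1 = (1/6) sum f_ijk q_i q_j q_k + (1/2) sum g1[i,j,k] p_i q_k p_j
    H2 = (1/24) sum f_ijkl q... + (1/4) sum g2[i,j,k,l] p_i q_k q_l p_j
         (+ Coriolis  sum_a B_a pi_a^2  in the Cartesian frame)

in dimensionless normal coordinates (everything in cm^-1).  Second-order
energies take the customary bilinear form in (v + 1/2) with an
anharmonicity matrix chi.  Collecting the second-order sum by
intermediate-state "channels" shows that every cubic-type contribution
enters through only two effective tensors,

    rho[i,j,k]   = f_ijk - g1[i,j,k] + g1[i,k,j] + g1[j,k,i]
    sigma[i,j,k] = f_ijk - g1[i,j,k] - g1[i,k,j] - g1[j,k,i]

where rho multiplies "difference" denominators w_i + w_j - w_k (hence
Fermi resonances: its slot pattern rho[i,k,i] covers the 1/w_k terms) and
the fully symmetric sigma multiplies "sum" denominators, while the
quartic/metric diagonal terms combine into

    eta[i,j,k,l] = f_ijkl + g2[i,j,k,l] + g2[k,l,i,j].

With all kinetic derivatives zero these reduce to rho = sigma = f3 and
eta = f4, recovering the textbook Cartesian expressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Optional

import numpy as np

from .force_field import KineticDerivatives, QuarticForceField
from .geometry import Geometry
from .harmonic import HarmonicSolution
from .units import AMU_TO_ME, HARTREE_TO_CM

#: denominators (cm^-1) smaller than this that are not deperturbed abort
#: the calculation instead of silently producing huge chi entries
DENOMINATOR_FLOOR = 1e-6


class ResonanceBlowupError(ArithmeticError):
    """An exactly (or numerically) resonant denominator was hit that no
    accepted resonance accounts for."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DerivedTensors:
    """Effective tensors of the recast chi expressions (cm^-1)."""

    eta: np.ndarray     # (M, M, M, M)
    sigma: np.ndarray   # (M, M, M), fully symmetric
    rho: np.ndarray     # (M, M, M), symmetric in the first two indices
    omega: np.ndarray   # (M,) harmonic wavenumbers the tensors belong to

    @property
    def n_modes(self) -> int:
        return self.omega.size


@dataclass
class ChiMatrix:
    """Symmetric anharmonicity matrix chi (cm^-1) with a registry of the
    contributions removed by deperturbation.

    ``removed`` maps a resonance key -- ("I", i, k) for 2w_i ~ w_k or
    ("II", i, j, k) for w_i + w_j ~ w_k -- to the (a, b): value dict of
    chi entries that were discarded; adding them back restores plain VPT2.
    """

    chi: np.ndarray
    omega: np.ndarray
    removed: dict = field(default_factory=dict)

    def restored(self) -> "ChiMatrix":
        chi = self.chi.copy()
        for terms in self.removed.values():
            for (a, b), val in terms.items():
                chi[a, b] += val
                if a != b:
                    chi[b, a] += val
        return ChiMatrix(chi, self.omega.copy(), {})


@dataclass(frozen=True)
class CoriolisData:
    """Coriolis zeta constants and equilibrium rotational constants."""

    zeta: np.ndarray        # (3, M, M), antisymmetric in the mode indices
    b_rot: np.ndarray       # (3,) rotational constants, cm^-1

    def __post_init__(self):
        z = np.asarray(self.zeta, float)
        if np.abs(z + np.transpose(z, (0, 2, 1))).max() > 1e-10:
            raise ValueError("zeta must be antisymmetric in its mode indices")


VibState = tuple[int, ...]


def fundamental(M: int, k: int) -> VibState:
    v = [0] * M
    v[k] = 1
    return tuple(v)


def overtone(M: int, k: int) -> VibState:
    v = [0] * M
    v[k] = 2
    return tuple(v)


def combination(M: int, i: int, j: int) -> VibState:
    v = [0] * M
    v[i] += 1
    v[j] += 1
    return tuple(v)


# ---------------------------------------------------------------------------
# derived tensors
# ---------------------------------------------------------------------------

def derived_tensors(ff: QuarticForceField, kin: Optional[KineticDerivatives],
                    omega: Optional[np.ndarray] = None) -> DerivedTensors:
    """Assemble eta / sigma / rho from the force field and the metric
    derivatives.  With ``kin`` absent or zero, eta = f4 and
    sigma = rho = f3."""
    M = ff.n_modes
    if kin is None:
        kin = KineticDerivatives.zero(M)
    if kin.g1.shape != (M, M, M):
        raise ValueError("force field and kinetic derivatives disagree on mode count")
    f3, f4, g1, g2 = ff.f3, ff.f4, kin.g1, kin.g2
    gA = np.transpose(g1, (0, 2, 1))   # gA[i,j,k] = g1[i,k,j]
    gB = np.transpose(g1, (2, 0, 1))   # gB[i,j,k] = g1[j,k,i]
    rho = f3 - g1 + gA + gB
    sigma = f3 - g1 - gA - gB
    eta = f4 + g2 + np.transpose(g2, (2, 3, 0, 1))
    w = ff.omega if omega is None else np.asarray(omega, float)
    return DerivedTensors(eta, sigma, rho, w.copy())


# ---------------------------------------------------------------------------
# the channel engine
# ---------------------------------------------------------------------------

def _resonance_keyset(deperturb) -> set:
    keys = set()
    for item in (deperturb or ()):
        key = item.key if hasattr(item, "key") else tuple(item)
        if key[0] == "II":
            key = ("II",) + tuple(sorted(key[1:3])) + (key[3],)
        keys.add(key)
    return keys


def _chi_bilinear(omega: np.ndarray, A: tuple, B: tuple,
                  deperturb: set, removed: Optional[dict]) -> np.ndarray:
    """Bilinear channel sum: contributions of Re(amp_A amp_B) to chi.

    ``A`` and ``B`` are (rho, sigma) pairs; passing the same tensors twice
    gives the plain quadratic result.  Channels whose resonance key is in
    ``deperturb`` are skipped and logged in ``removed``.
    """
    rhoA, sigA = A
    rhoB, sigB = B
    M = omega.size
    chi = np.zeros((M, M))

    def add(a, b, val):
        chi[min(a, b), max(a, b)] += val

    def record(key, a, b, val):
        if removed is not None:
            entry = removed.setdefault(key, {})
            ab = (min(a, b), max(a, b))
            entry[ab] = entry.get(ab, 0.0) + val

    def denom(value, key):
        if abs(value) < DENOMINATOR_FLOOR:
            raise ResonanceBlowupError(
                f"exact resonance {key} (denominator {value:.3e} cm^-1) is not "
                "deperturbed; flag it explicitly before computing chi")
        return value

    # --- 1/w_k channels (intermediates v +- 1_k) ---------------------------
    for k in range(M):
        for a in range(M):
            for b in range(a, M):
                pr = 0.5 * (rhoA[a, k, a] * rhoB[b, k, b] + rhoB[a, k, a] * rhoA[b, k, b])
                if a == b == k:
                    add(a, b, -3.0 * pr / (32.0 * omega[k]))
                else:
                    fac = 1.0 if a == b else 2.0
                    add(a, b, -fac * pr / (8.0 * omega[k]))
        # 3 w_k channel of the (k,k,k) triple
        add(k, k, -sigA[k, k, k] * sigB[k, k, k] / (96.0 * omega[k]))

    # --- (i,i,k) channels, i != k ------------------------------------------
    for i in range(M):
        for k in range(M):
            if k == i:
                continue
            ps = 0.5 * (sigA[i, i, k] * sigB[i, i, k] + sigB[i, i, k] * sigA[i, i, k])
            dplus = 2.0 * omega[i] + omega[k]
            add(i, i, -ps / (32.0 * dplus))
            add(i, k, -ps / (8.0 * dplus))
            pr = 0.5 * (rhoA[i, i, k] * rhoB[i, i, k] + rhoB[i, i, k] * rhoA[i, i, k])
            key = ("I", i, k)
            if key in deperturb:
                d = 2.0 * omega[i] - omega[k]
                if abs(d) < DENOMINATOR_FLOOR:
                    d = np.inf  # exact degeneracy: nothing finite removed
                record(key, i, i, pr / (32.0 * d))
                record(key, i, k, -pr / (8.0 * d))
            else:
                d = denom(2.0 * omega[i] - omega[k], key)
                add(i, i, pr / (32.0 * d))
                add(i, k, -pr / (8.0 * d))

    # --- distinct triples ---------------------------------------------------
    for i in range(M):
        for j in range(i + 1, M):
            for k in range(j + 1, M):
                ps = 0.5 * (sigA[i, j, k] * sigB[i, j, k] + sigB[i, j, k] * sigA[i, j, k])
                s = omega[i] + omega[j] + omega[k]
                for (a, b) in ((i, j), (i, k), (j, k)):
                    add(a, b, -ps / (8.0 * s))
                for (p, q, r) in ((i, j, k), (i, k, j), (j, k, i)):
                    pr = 0.5 * (rhoA[p, q, r] * rhoB[p, q, r]
                                + rhoB[p, q, r] * rhoA[p, q, r])
                    key = ("II", p, q, r)
                    if key in deperturb:
                        d = omega[p] + omega[q] - omega[r]
                        if abs(d) < DENOMINATOR_FLOOR:
                            d = np.inf
                        record(key, p, q, pr / (8.0 * d))
                        record(key, p, r, -pr / (8.0 * d))
                        record(key, q, r, -pr / (8.0 * d))
                    else:
                        d = denom(omega[p] + omega[q] - omega[r], key)
                        add(p, q, pr / (8.0 * d))
                        add(p, r, -pr / (8.0 * d))
                        add(q, r, -pr / (8.0 * d))

    return chi + np.triu(chi, 1).T


def _chi_quartic(eta: np.ndarray) -> np.ndarray:
    M = eta.shape[0]
    chi = np.zeros((M, M))
    for i in range(M):
        chi[i, i] = eta[i, i, i, i] / 16.0
        for j in range(i + 1, M):
            chi[i, j] = chi[j, i] = eta[i, i, j, j] / 4.0
    return chi


def coriolis_chi(omega: np.ndarray, coriolis: Optional[CoriolisData]) -> np.ndarray:
    """Coriolis contribution sum_a B_a zeta_ij^2 (w_i/w_j + w_j/w_i)."""
    M = omega.size
    chi = np.zeros((M, M))
    if coriolis is None:
        return chi
    for i in range(M):
        for j in range(i + 1, M):
            z2 = (coriolis.zeta[:, i, j] ** 2 * coriolis.b_rot).sum()
            val = z2 * (omega[i] / omega[j] + omega[j] / omega[i])
            chi[i, j] = chi[j, i] = val
    return chi


def chi_from_tensors(t: DerivedTensors, deperturb=(),
                     coriolis: Optional[CoriolisData] = None) -> ChiMatrix:
    """chi from the recast (eta/sigma/rho) expressions."""
    if np.any(t.omega <= 0):
        raise ValueError("harmonic frequencies must be positive")
    keys = _resonance_keyset(deperturb)
    removed: dict = {}
    chi = _chi_quartic(t.eta)
    chi = chi + _chi_bilinear(t.omega, (t.rho, t.sigma), (t.rho, t.sigma),
                              keys, removed)
    chi = chi + coriolis_chi(t.omega, coriolis)
    return ChiMatrix(chi, t.omega.copy(), removed)


def chi_curvilinear(t: DerivedTensors, deperturb=()) -> ChiMatrix:
    """Curvilinear-frame chi (no Coriolis term: the kinetic expansion
    carries the equivalent physics through g1/g2)."""
    return chi_from_tensors(t, deperturb=deperturb, coriolis=None)


def chi_cartesian(ff: QuarticForceField, coriolis: Optional[CoriolisData],
                  deperturb=(), include_coriolis: bool = True,
                  omega: Optional[np.ndarray] = None) -> ChiMatrix:
    """Standard rectilinear VPT2 chi with optional Coriolis coupling."""
    t = derived_tensors(ff, None, omega=omega)
    return chi_from_tensors(t, deperturb=deperturb,
                            coriolis=coriolis if include_coriolis else None)


# ---------------------------------------------------------------------------
# component split and the classic combined transcription
# ---------------------------------------------------------------------------

def chi_potential_combined(omega: np.ndarray, f3: np.ndarray, f4: np.ndarray,
                           coriolis: Optional[CoriolisData] = None) -> np.ndarray:
    """Textbook closed-form Cartesian-type chi from the potential alone.

    Independent transcription of the combined rational expressions; kept
    separate from the channel engine as an internal consistency check.
    Not resonance-aware: use only away from Fermi resonances.
    """
    w = np.asarray(omega, float)
    M = w.size
    chi = np.zeros((M, M))
    for i in range(M):
        acc = f4[i, i, i, i] / 16.0
        for k in range(M):
            acc -= (f3[i, i, k] ** 2 / 16.0 * (8.0 * w[i] ** 2 - 3.0 * w[k] ** 2)
                    / (w[k] * (4.0 * w[i] ** 2 - w[k] ** 2)))
        chi[i, i] = acc
    for i in range(M):
        for j in range(i + 1, M):
            acc = f4[i, i, j, j] / 4.0
            for k in range(M):
                acc -= 0.25 * f3[i, i, k] * f3[j, j, k] / w[k]
                delta = ((w[i] + w[j]) ** 2 - w[k] ** 2) * ((w[i] - w[j]) ** 2 - w[k] ** 2)
                acc -= (0.5 * f3[i, j, k] ** 2 * w[k]
                        * (w[k] ** 2 - w[i] ** 2 - w[j] ** 2) / delta)
            chi[i, j] = chi[j, i] = acc
    return chi + coriolis_chi(w, coriolis)


def chi_components(ff: QuarticForceField, kin: Optional[KineticDerivatives],
                   coriolis: Optional[CoriolisData] = None,
                   omega: Optional[np.ndarray] = None):
    """(chi_pot, chi_kin, chi_cross): potential, kinetic and cross terms.

    chi_pot is evaluated through the combined closed-form transcription,
    the kinetic and cross parts through the bilinear channel engine; their
    sum equals the recast chi (an identity that is tested, not assumed).
    """
    M = ff.n_modes
    if kin is None:
        kin = KineticDerivatives.zero(M)
    w = ff.omega if omega is None else np.asarray(omega, float)
    zero3 = np.zeros((M, M, M))
    g1 = kin.g1
    rho_kin = -g1 + np.transpose(g1, (0, 2, 1)) + np.transpose(g1, (2, 0, 1))
    sig_kin = -g1 - np.transpose(g1, (0, 2, 1)) - np.transpose(g1, (2, 0, 1))
    eta_kin = kin.g2 + np.transpose(kin.g2, (2, 3, 0, 1))

    pot = chi_potential_combined(w, ff.f3, ff.f4, coriolis)
    kin_chi = (_chi_quartic(eta_kin)
               + _chi_bilinear(w, (rho_kin, sig_kin), (rho_kin, sig_kin), set(), None))
    cross = 2.0 * _chi_bilinear(w, (ff.f3, ff.f3), (rho_kin, sig_kin), set(), None)
    return pot, kin_chi, cross


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------

def state_energy(chi: ChiMatrix, omega: np.ndarray, v: Iterable[int]) -> float:
    """Transition energy eps(v) - eps(0) in cm^-1 (ZPVE excluded)."""
    v = np.asarray(tuple(v), float)
    w = np.asarray(omega, float)
    if v.size != w.size:
        raise ValueError("state vector has wrong length")
    x = v + 0.5
    c = chi.chi
    quad = 0.0
    for i in range(w.size):
        quad += c[i, i] * (x[i] ** 2 - 0.25)
        for j in range(i + 1, w.size):
            quad += c[i, j] * (x[i] * x[j] - 0.25)
    return float(w @ v + quad)


def fundamental_energies(chi: ChiMatrix, omega: np.ndarray) -> np.ndarray:
    M = omega.size
    return np.array([state_energy(chi, omega, fundamental(M, k)) for k in range(M)])


# ---------------------------------------------------------------------------
# coupling-order restriction and analysis utilities
# ---------------------------------------------------------------------------

def _n_distinct(index_tuple) -> int:
    return len(set(index_tuple))


def restrict_coupling_order(ff: QuarticForceField, kin: KineticDerivatives,
                            order: int):
    """Keep only constants involving at most ``order`` distinct modes.

    order 1: diagonal (single-mode) anharmonicity only; order 2: adds all
    two-mode couplings; order 3: identity.
    """
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    if order == 3:
        return ff, kin
    M = ff.n_modes

    def mask(arr, nd):
        out = arr.copy()
        it = np.ndindex(*arr.shape)
        for idx in it:
            if _n_distinct(idx) > order:
                out[idx] = 0.0
        return out

    ff2 = QuarticForceField(ff.omega.copy(), mask(ff.f3, 3), mask(ff.f4, 4), ff.frame)
    kin2 = KineticDerivatives(mask(kin.g1, 3), mask(kin.g2, 4))
    return ff2, kin2


def single_mode_anharmonic(ff: QuarticForceField, kin: KineticDerivatives,
                           mode: int) -> float:
    """Fundamental of one mode with every inter-mode coupling discarded."""
    M = ff.n_modes
    k = mode
    omega = np.array([ff.omega[k]])
    f3 = np.full((1, 1, 1), ff.f3[k, k, k])
    f4 = np.full((1, 1, 1, 1), ff.f4[k, k, k, k])
    g1 = np.full((1, 1, 1), kin.g1[k, k, k] if kin is not None else 0.0)
    g2 = np.full((1, 1, 1, 1), kin.g2[k, k, k, k] if kin is not None else 0.0)
    ff1 = QuarticForceField(omega, f3, f4, ff.frame)
    kin1 = KineticDerivatives(g1, g2)
    t = derived_tensors(ff1, kin1)
    chi = chi_from_tensors(t)
    return state_energy(chi, omega, (1,))


def count_couplings(ff: QuarticForceField, kin: Optional[KineticDerivatives],
                    threshold: float) -> dict:
    """Numbers of three-mode potential and kinetic constants above a
    threshold (cm^-1): |f_ijk| (i,j,k distinct), |f_ijkk| (i != j != k),
    and three-distinct-index g1/g2 entries."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    M = ff.n_modes
    n_f3 = n_f4 = n_g1 = n_g2 = 0
    for i in range(M):
        for j in range(i + 1, M):
            for k in range(j + 1, M):
                if abs(ff.f3[i, j, k]) > threshold:
                    n_f3 += 1
                if kin is not None:
                    for (a, b, c) in set(permutations((i, j, k))):
                        if a < b and abs(kin.g1[a, b, c]) > threshold:
                            n_g1 += 1
    for k in range(M):
        for i in range(M):
            for j in range(i + 1, M):
                if i != k and j != k and abs(ff.f4[i, j, k, k]) > threshold:
                    n_f4 += 1
    if kin is not None:
        seen = set()
        for idx in np.ndindex(M, M, M, M):
            if _n_distinct(idx) != 3 or abs(kin.g2[idx]) <= threshold:
                continue
            i, j, k, l = idx
            key = (tuple(sorted((i, j))), tuple(sorted((k, l))))
            key = min(key, (key[1], key[0]))
            if key not in seen:
                seen.add(key)
                n_g2 += 1
    return {"f3_three_mode": n_f3, "f4_three_mode": n_f4,
            "g1_three_mode": n_g1, "g2_three_mode": n_g2}


# ---------------------------------------------------------------------------
# Coriolis data from Cartesian modes
# ---------------------------------------------------------------------------

def coriolis_data(geometry: Geometry, solution: HarmonicSolution) -> CoriolisData:
    """Zeta constants and rotational constants in the principal-axis frame."""
    if solution.frame != "cartesian":
        raise ValueError("Coriolis constants require Cartesian-frame modes")
    moments, axes = geometry.principal_axes()
    M = solution.n_modes
    n = geometry.n_atoms
    modes = solution.modes_mw.reshape(n, 3, M)
    modes = np.einsum("ab,nbM->naM", axes.T, modes)  # rotate into principal axes
    zeta = np.zeros((3, M, M))
    for i in range(M):
        for j in range(M):
            cr = np.cross(modes[:, :, i], modes[:, :, j])  # (n, 3)
            zeta[:, i, j] = cr.sum(axis=0)
    b_rot = np.zeros(3)
    for a in range(3):
        I_au = moments[a] * AMU_TO_ME
        b_rot[a] = 0.0 if I_au < 1e-12 else HARTREE_TO_CM / (2.0 * I_au)
    return CoriolisData(zeta, b_rot)
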