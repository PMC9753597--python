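"""Harmonic analysis: Wilson GF in internal coordinates and the
mass-weighted Cartesian route.

Both solvers return a :class:`HarmonicSolution` whose frequencies are in
cm^-1.  For the curvilinear frame the normal-mode matrix ``L`` maps
mass-weighted normal coordinates Q (amu^1/2 bohr) to internal
displacements, normalised as L^T G^-1 L = 1 on the non-null subspace; in
these conventions the metric in the normal-mode basis is the identity at
equilibrium, i.e. the dimensionless-coordinate metric is diag(omega).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .geometry import Geometry
from .units import AMU_TO_ME, HARTREE_TO_CM

#: eigenvalues of G below this fraction of the largest are redundancies
NULLSPACE_RTOL = 1e-8
#: |omega| below this (cm^-1) counts as a zero mode
ZERO_MODE_CM = 0.01


class ImaginaryFrequencyError(ValueError):
    """The harmonic problem has an imaginary frequency; anharmonic
    perturbation theory is undefined at such a geometry."""


@dataclass(frozen=True)
class HarmonicSolution:
    omega_cm: np.ndarray          # (M,) harmonic wavenumbers, ascending
    L: Optional[np.ndarray]       # (N, M) internal-coordinate modes (curvilinear)
    frame: str                    # "curvilinear" | "cartesian"
    modes_mw: Optional[np.ndarray] = None  # (3N_a, M) mass-weighted Cartesian modes
    n_removed: int = 0            # null-space vectors removed (redundancy / trans+rot)

    @property
    def n_modes(self) -> int:
        return self.omega_cm.size

    @property
    def omega_au(self) -> np.ndarray:
        return self.omega_cm / HARTREE_TO_CM


def _modes_from_lambda(lam_mixed: np.ndarray):
    """Convert GF/mass-weighted eigenvalues (hartree/(amu bohr^2)) to cm^-1."""
    lam_au = lam_mixed / AMU_TO_ME
    omega_cm = np.sqrt(np.abs(lam_au)) * HARTREE_TO_CM
    return np.where(lam_au >= 0, omega_cm, -omega_cm)


def _screen_modes(omega_signed: np.ndarray):
    """Split eigenvalues into kept / zero; raise on imaginary modes."""
    imag = omega_signed < -ZERO_MODE_CM
    if np.any(imag):
        vals = ", ".join(f"{abs(w):.1f}i" for w in omega_signed[imag])
        raise ImaginaryFrequencyError(
            f"imaginary harmonic frequencies ({vals} cm^-1); the reference "
            "geometry is not a minimum and the anharmonic treatment is refused")
    keep = omega_signed > ZERO_MODE_CM
    return keep


def gf_solve(G: np.ndarray, F: np.ndarray) -> HarmonicSolution:
    """Wilson GF eigenproblem with redundancy removal.

    Parameters: G in 1/amu (from :func:`gvpt2.internal_coords.g_matrix`),
    F in hartree/bohr^2 (angles: hartree/rad^2 and mixed units).
    """
    G = np.asarray(G, float)
    F = np.asarray(F, float)
    if G.shape != F.shape or G.shape[0] != G.shape[1]:
        raise ValueError("G and F must be square matrices of equal dimension")
    g_eval, U = np.linalg.eigh(G)
    keep = g_eval > NULLSPACE_RTOL * g_eval.max()
    n_removed = int(np.count_nonzero(~keep))
    X = U[:, keep] * np.sqrt(g_eval[keep])  # G^(1/2) factor on the range
    K = X.T @ F @ X
    K = 0.5 * (K + K.T)
    lam, W = np.linalg.eigh(K)
    omega_signed = _modes_from_lambda(lam)
    keep2 = _screen_modes(omega_signed)
    if np.count_nonzero(~keep2):
        warnings.warn("dropping zero-frequency GF modes", stacklevel=2)
        n_removed += int(np.count_nonzero(~keep2))
    omega = omega_signed[keep2]
    L = X @ W[:, keep2]
    order = np.argsort(omega, kind="stable")
    sol = HarmonicSolution(omega[order], L[:, order], "curvilinear",
                           n_removed=n_removed)
    return fix_mode_phases(sol)


def _trans_rot_basis(geometry: Geometry) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors (3N, 5 or 6)."""
    n = geometry.n_atoms
    sq = np.sqrt(geometry.masses)
    r = geometry.coords - geometry.center_of_mass()
    vecs = []
    for alpha in range(3):
        t = np.zeros((n, 3))
        t[:, alpha] = sq
        vecs.append(t.reshape(-1))
    for alpha in range(3):
        e = np.zeros(3)
        e[alpha] = 1.0
        rot = np.cross(r, e) * sq[:, None]
        vecs.append(rot.reshape(-1))
    V = np.array(vecs).T
    q, s, _ = np.linalg.svd(V, full_matrices=False)
    return q[:, s > 1e-8 * s.max()]


def cartesian_harmonic(Hx: np.ndarray, geometry: Geometry) -> HarmonicSolution:
    """Mass-weighted normal-mode analysis with trans/rot projection."""
    n3 = 3 * geometry.n_atoms
    Hx = np.asarray(Hx, float)
    if Hx.shape != (n3, n3):
        raise ValueError("Hessian has wrong shape")
    sqm = np.sqrt(np.repeat(geometry.masses, 3))
    Hmw = Hx / np.outer(sqm, sqm)  # hartree / (amu bohr^2)
    V = _trans_rot_basis(geometry)
    # orthonormal complement of translations/rotations
    q, s, _ = np.linalg.svd(np.eye(n3) - V @ V.T)
    C = q[:, s > 0.5]
    lam, W = np.linalg.eigh(C.T @ Hmw @ C)
    omega_signed = _modes_from_lambda(lam)
    keep = _screen_modes(omega_signed)
    if np.count_nonzero(~keep):
        warnings.warn("dropping zero-frequency Cartesian modes", stacklevel=2)
    omega = omega_signed[keep]
    modes = C @ W[:, keep]
    order = np.argsort(omega, kind="stable")
    sol = HarmonicSolution(omega[order], None, "cartesian",
                           modes_mw=modes[:, order],
                           n_removed=int(n3 - np.count_nonzero(keep)))
    return fix_mode_phases(sol)


def fix_mode_phases(solution: HarmonicSolution) -> HarmonicSolution:
    """Fix each mode's sign so its largest-|component| entry is positive.

    Idempotent; makes cubic-constant signs reproducible across runs and
    across degenerate eigensolver back-ends.
    """
    def _fixed(mat):
        if mat is None:
            return None
        mat = mat.copy()
        for c in range(mat.shape[1]):
            k = int(np.argmax(np.abs(mat[:, c])))
            if mat[k, c] < 0.0:
                mat[:, c] = -mat[:, c]
        return mat

    # phase is anchored on L for the curvilinear frame, on the Cartesian
    # modes otherwise
    if solution.L is not None:
        return replace(solution, L=_fixed(solution.L))
    return replace(solution, modes_mw=_fixed(solution.modes_mw))
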