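"""Quartic force fields and kinetic-metric derivatives by finite
differences of analytic Hessians / analytic G' tensors.

Scheme: one displaced geometry per active mode and sign (2M+1 engine
jobs).  Cubic constants come from antisymmetric differences of
normal-coordinate Hessians, semi-diagonal quartics from symmetric
differences; the first g-matrix derivatives are analytic and their
finite differences over the same displacements give the second
derivatives.  All finite-difference estimates converge as O(dQ^2).

Units: engine quantities are atomic units; the mass-weighted normal
coordinate step ``delta_q`` is in amu^1/2 bohr (default 0.02); assembled
force constants and kinetic derivatives are wavenumber-scaled,
dimensionless-normal-coordinate quantities in cm^-1.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass
from itertools import permutations
from typing import Callable, Optional

import numpy as np

from .engine import EngineAdapter, EngineResult
from .geometry import Geometry
from .harmonic import HarmonicSolution
from .internal_coords import (InternalSet, b_matrix, b_prime, coordinate_values,
                              g_matrix, g_prime)
from .units import AMU_TO_ME, DEFAULT_DELTA_Q, HARTREE_TO_CM

ARCHIVE_VERSION = 1


class ForceFieldError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuarticForceField:
    """Harmonic wavenumbers plus cubic and semi-diagonal quartic constants
    in wavenumber-reduced dimensionless-normal-coordinate units (cm^-1).

    ``f3`` is fully symmetric; ``f4`` is stored as a full symmetric array
    whose populated entries are the iiii / iijj / ijkk classes (quartics
    with four distinct indices are not obtainable from single-mode Hessian
    displacements and are not needed by second-order theory).
    """

    omega: np.ndarray       # (M,) cm^-1
    f3: np.ndarray          # (M, M, M) cm^-1
    f4: np.ndarray          # (M, M, M, M) cm^-1
    frame: str = "curvilinear"

    @property
    def n_modes(self) -> int:
        return self.omega.size


@dataclass(frozen=True)
class KineticDerivatives:
    """First/second derivatives of the wavenumber-scaled metric g with
    respect to dimensionless normal coordinates (cm^-1).

    ``g1[i, j, k]`` is symmetric in (i, j); ``g2[i, j, k, l]`` in (i, j)
    and (k, l).  A Cartesian-frame calculation has all entries zero.
    """

    g1: np.ndarray          # (M, M, M)
    g2: np.ndarray          # (M, M, M, M)

    @classmethod
    def zero(cls, n_modes: int) -> "KineticDerivatives":
        return cls(np.zeros((n_modes,) * 3), np.zeros((n_modes,) * 4))

    @property
    def is_zero(self) -> bool:
        return not (np.any(self.g1) or np.any(self.g2))


# ---------------------------------------------------------------------------
# displacements
# ---------------------------------------------------------------------------

def displace(geometry: Geometry, solution: HarmonicSolution, mode: int,
             step: float, iset: Optional[InternalSet] = None,
             max_iter: int = 100) -> Geometry:
    """Geometry displaced by ``step`` (amu^1/2 bohr) along one normal mode.

    Cartesian frame: a straight-line displacement of the mass-weighted
    mode.  Curvilinear frame: the displacement is applied to the internal
    coordinates (s -> s + step * L[:, mode]) and transformed back to
    Cartesians iteratively, with step-halving damping, to a projected
    residual below 1e-10 bohr.
    """
    if step == 0.0:
        return geometry
    if solution.frame == "cartesian":
        dx = step * solution.modes_mw[:, mode] / np.sqrt(np.repeat(geometry.masses, 3))
        return geometry.with_coords(geometry.x + dx)

    if iset is None:
        raise ValueError("curvilinear displacement requires the internal set")
    s0 = coordinate_values(geometry, iset)
    s_target = s0 + step * solution.L[:, mode]
    minv = 1.0 / np.repeat(geometry.masses, 3)
    x = geometry.x.copy()
    prev_norm = np.inf
    for _ in range(max_iter):
        geo = geometry.with_coords(x)
        B = b_matrix(geo, iset)
        G = g_matrix(B, geometry.masses)
        Gp_inv = np.linalg.pinv(G, rcond=1e-10)
        resid = s_target - coordinate_values(geo, iset, reference=s_target)
        proj = G @ (Gp_inv @ resid)
        norm = float(np.linalg.norm(proj))
        if norm < 1e-10:
            return geo
        dx = minv * (B.T @ (Gp_inv @ resid))
        scale = 1.0
        if norm > prev_norm:  # diverging: damp
            scale = 0.5
        x = x + scale * dx
        prev_norm = norm
    raise ForceFieldError(
        f"back-transformation for mode {mode}, step {step:+g} did not "
        f"converge (residual {prev_norm:.2e})")


# ---------------------------------------------------------------------------
# Cartesian -> internal transformations
# ---------------------------------------------------------------------------

def _b_pinv(B: np.ndarray, cond_bound: float = 1e10) -> np.ndarray:
    sv = np.linalg.svd(B, compute_uv=False)
    kept = sv[sv > 1e-10 * sv[0]]
    if kept[0] / kept[-1] > cond_bound:
        raise ForceFieldError(
            f"B matrix ill-conditioned (cond {kept[0] / kept[-1]:.2e}); "
            "revise the internal-coordinate set")
    return np.linalg.pinv(B, rcond=1e-10)


def gradient_to_internal(result: EngineResult, B: np.ndarray) -> np.ndarray:
    """Internal gradient g_s from the Cartesian one (generalized inverse)."""
    Bplus = _b_pinv(B)
    P = Bplus @ B
    return Bplus.T @ (P @ result.gradient)


def hessian_to_internal(result: EngineResult, B: np.ndarray, Bp: np.ndarray) -> np.ndarray:
    """Internal Hessian F with the gradient (B') correction and with
    translations/rotations projected out by P = B^+ B."""
    Bplus = _b_pinv(B)
    P = Bplus @ B
    g_s = Bplus.T @ (P @ result.gradient)
    Htil = result.hessian - np.einsum("i,ijk->jk", g_s, Bp)
    Htil = P @ Htil @ P
    F = Bplus.T @ Htil @ Bplus
    return 0.5 * (F + F.T)


def normal_mode_hessian(result: EngineResult, solution: HarmonicSolution,
                        geometry: Geometry,
                        iset: Optional[InternalSet] = None) -> np.ndarray:
    """Hessian in mass-weighted normal coordinates, atomic units
    (hartree / (m_e bohr^2)), evaluated at an arbitrary geometry."""
    if solution.frame == "cartesian":
        sqm = np.sqrt(np.repeat(geometry.masses, 3))
        Hmw = result.hessian / np.outer(sqm, sqm)
        HQ = solution.modes_mw.T @ Hmw @ solution.modes_mw
    else:
        B = b_matrix(geometry, iset)
        Bp = b_prime(geometry, iset)
        F = hessian_to_internal(result, B, Bp)
        HQ = solution.L.T @ F @ solution.L
    return 0.5 * (HQ + HQ.T) / AMU_TO_ME


# ---------------------------------------------------------------------------
# surface runner and archive
# ---------------------------------------------------------------------------

def surface_labels(n_modes: int) -> list[str]:
    labels = ["ref"]
    for k in range(n_modes):
        labels += [f"mode{k}+", f"mode{k}-"]
    return labels


def _label_to_displacement(label: str):
    if label == "ref":
        return None
    sign = {"+": 1.0, "-": -1.0}[label[-1]]
    return int(label[4:-1]), sign


def settings_hash(geometry: Geometry, solution: HarmonicSolution,
                  delta_q: float) -> str:
    payload = {
        "symbols": list(geometry.symbols),
        "coords": np.round(geometry.coords, 10).tolist(),
        "masses": np.round(geometry.masses, 8).tolist(),
        "frame": solution.frame,
        "omega": np.round(solution.omega_cm, 6).tolist(),
        "delta_q": delta_q,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


class SurfaceArchive:
    """JSON container persisting engine results keyed by displacement label.

    Round trips are bit-exact (values stored via float hex) so that a
    replayed archive reproduces reports byte for byte.
    """

    def __init__(self, path: str, shash: str):
        self.path = path
        self.shash = shash
        self.data = {"version": ARCHIVE_VERSION, "settings_hash": shash, "results": {}}
        if path is not None and os.path.exists(path):
            with open(path) as fh:
                loaded = json.load(fh)
            if loaded.get("version", 0) > ARCHIVE_VERSION:
                raise ForceFieldError(
                    f"archive {path} has version {loaded.get('version')}, newer "
                    f"than supported {ARCHIVE_VERSION}")
            if loaded.get("settings_hash") not in (None, shash):
                raise ForceFieldError(
                    f"archive {path} was produced with different settings "
                    f"(hash {loaded.get('settings_hash')} != {shash})")
            self.data = loaded

    @staticmethod
    def _enc(a: np.ndarray):
        return [float.hex(float(v)) for v in np.asarray(a, float).reshape(-1)]

    @staticmethod
    def _dec(vals, shape):
        return np.array([float.fromhex(v) for v in vals]).reshape(shape)

    def get(self, label: str, n3: int) -> Optional[EngineResult]:
        rec = self.data["results"].get(label)
        if rec is None:
            return None
        try:
            grad = self._dec(rec["gradient"], (n3,))
            hess = self._dec(rec["hessian"], (n3, n3))
            res = EngineResult(float.fromhex(rec["energy"]), grad, hess, label)
        except Exception:
            return None  # corrupted entry -> recompute
        if not (np.isfinite(res.gradient).all() and np.isfinite(res.hessian).all()):
            return None
        return res

    def put(self, label: str, result: EngineResult, geometry: Geometry) -> None:
        self.data["results"][label] = {
            "energy": float.hex(float(result.energy)),
            "gradient": self._enc(result.gradient),
            "hessian": self._enc(result.hessian),
            "geometry": self._enc(geometry.x),
        }
        self.save()

    def save(self) -> None:
        if self.path is None:
            return
        tmp = self.path + ".tmp"
        with open(tmp, "w") as fh:
            json.dump(self.data, fh)
        os.replace(tmp, self.path)


def run_surface(geometry: Geometry, adapter: EngineAdapter,
                solution: HarmonicSolution, iset: Optional[InternalSet] = None,
                delta_q: float = DEFAULT_DELTA_Q,
                archive_path: Optional[str] = None,
                progress: Optional[Callable[[str], None]] = None) -> dict[str, EngineResult]:
    """Run (or replay) the 2M+1 displaced-geometry jobs.

    Completed jobs found in the archive are not recomputed; corrupted
    entries are detected and that label alone is re-run.
    """
    shash = settings_hash(geometry, solution, delta_q)
    archive = SurfaceArchive(archive_path, shash)
    n3 = 3 * geometry.n_atoms
    results: dict[str, EngineResult] = {}
    for label in surface_labels(solution.n_modes):
        cached = archive.get(label, n3)
        if cached is not None:
            results[label] = cached
            continue
        disp = _label_to_displacement(label)
        geo = geometry if disp is None else displace(
            geometry, solution, disp[0], disp[1] * delta_q, iset)
        if progress:
            progress(label)
        try:
            res = adapter.compute(geo)
        except Exception as exc:
            raise ForceFieldError(f"engine failure at geometry {label!r}: {exc}") from exc
        res = EngineResult(res.energy, res.gradient, res.hessian, label)
        archive.put(label, res, geo)
        results[label] = res
    return results


# ---------------------------------------------------------------------------
# force-field assembly
# ---------------------------------------------------------------------------

def _check_labels(results, n_modes):
    missing = [lb for lb in surface_labels(n_modes) if lb not in results]
    if missing:
        raise ForceFieldError(f"missing displaced-geometry results: {missing}")


def assemble_force_field(results: dict[str, EngineResult],
                         solution: HarmonicSolution, geometry: Geometry,
                         iset: Optional[InternalSet] = None,
                         delta_q: float = DEFAULT_DELTA_Q) -> QuarticForceField:
    """Cubic/semi-diagonal quartic constants from displaced Hessians."""
    M = solution.n_modes
    _check_labels(results, M)
    delta_au = delta_q * np.sqrt(AMU_TO_ME)
    HQ = {}
    for label in surface_labels(M):
        disp = _label_to_displacement(label)
        geo = geometry if disp is None else displace(
            geometry, solution, disp[0], disp[1] * delta_q, iset)
        HQ[label] = normal_mode_hessian(results[label], solution, geo, iset)

    raw3 = np.zeros((M, M, M))
    diag2 = np.zeros((M, M, M))
    for k in range(M):
        raw3[k] = (HQ[f"mode{k}+"] - HQ[f"mode{k}-"]) / (2.0 * delta_au)
        diag2[k] = (HQ[f"mode{k}+"] + HQ[f"mode{k}-"] - 2.0 * HQ["ref"]) / delta_au**2

    f3 = np.zeros((M, M, M))
    for p in permutations(range(3)):
        f3 += np.transpose(raw3, p)
    f3 /= 6.0

    f4 = np.zeros((M, M, M, M))
    for i in range(M):
        f4[i, i, i, i] = diag2[i][i, i]
        for j in range(M):
            if j == i:
                continue
            viijj = 0.5 * (diag2[j][i, i] + diag2[i][j, j])
            for p in set(permutations((i, i, j, j))):
                f4[p] = viijj
            for k in range(j + 1, M):
                if k == i or k == j:
                    continue
                vijkk = diag2[i][j, k]  # displace i, read H_jk; = f_{jkii}
                for p in set(permutations((j, k, i, i))):
                    f4[p] = vijkk

    w = solution.omega_au
    s3 = np.sqrt(w[:, None, None] * w[None, :, None] * w[None, None, :])
    f3_cm = f3 / s3 * HARTREE_TO_CM
    s4 = np.sqrt(np.einsum("i,j,k,l->ijkl", w, w, w, w))
    f4_cm = f4 / s4 * HARTREE_TO_CM
    return QuarticForceField(solution.omega_cm.copy(), f3_cm, f4_cm, solution.frame)


# ---------------------------------------------------------------------------
# kinetic-metric derivatives
# ---------------------------------------------------------------------------

def metric_in_normal_basis(geometry: Geometry, iset: InternalSet,
                           solution: HarmonicSolution) -> np.ndarray:
    """g_Q = (L^T G^+ L)^-1 at an arbitrary geometry (identity at eq)."""
    B = b_matrix(geometry, iset)
    G = g_matrix(B, geometry.masses)
    m = solution.L.T @ np.linalg.pinv(G, rcond=1e-10) @ solution.L
    return np.linalg.inv(m)


def dimensionless_metric(geometry: Geometry, iset: InternalSet,
                         solution: HarmonicSolution) -> np.ndarray:
    """Wavenumber-scaled metric in dimensionless coordinates (cm^-1);
    equals diag(omega) at the equilibrium geometry."""
    gQ = metric_in_normal_basis(geometry, iset, solution)
    w = solution.omega_au
    return np.sqrt(np.outer(w, w)) * gQ * HARTREE_TO_CM


def metric_first_derivatives(geometry: Geometry, iset: InternalSet,
                             solution: HarmonicSolution) -> np.ndarray:
    """Analytic d g_Q / d Q_k (per amu^1/2 bohr) at an arbitrary geometry.

    Chain rule through the analytic Cartesian G' tensor; the pseudo-inverse
    derivative keeps the expression exact for redundant (rank-deficient)
    primitive sets of constant rank.
    """
    L = solution.L
    B = b_matrix(geometry, iset)
    Bp = b_prime(geometry, iset)
    G = g_matrix(B, geometry.masses)
    Gp = g_prime(B, Bp, geometry.masses)
    Gplus = np.linalg.pinv(G, rcond=1e-10)
    P = G @ Gplus
    eyeP = np.eye(G.shape[0]) - P
    minv = 1.0 / np.repeat(geometry.masses, 3)
    J = (minv[:, None] * B.T) @ (Gplus @ L)        # dx/dQ, (3N, M)
    dG = np.einsum("ijc,ck->ijk", Gp, J)           # (N, N, M)
    m = L.T @ Gplus @ L
    gQ = np.linalg.inv(m)
    out = np.empty((L.shape[1], L.shape[1], L.shape[1]))
    GpGp = Gplus @ Gplus
    for k in range(L.shape[1]):
        dGk = dG[:, :, k]
        dGplus = (-Gplus @ dGk @ Gplus
                  + GpGp @ dGk @ eyeP
                  + eyeP @ dGk @ GpGp)
        dm = L.T @ dGplus @ L
        out[:, :, k] = -gQ @ dm @ gQ
    return 0.5 * (out + np.transpose(out, (1, 0, 2)))


def assemble_kinetic_derivatives(geometry: Geometry, iset: Optional[InternalSet],
                                 solution: HarmonicSolution,
                                 delta_q: float = DEFAULT_DELTA_Q) -> KineticDerivatives:
    """g1 (analytic) and g2 (finite differences of g1) in cm^-1.

    For the Cartesian frame the metric is constant and every entry is
    zero by definition.
    """
    M = solution.n_modes
    if solution.frame == "cartesian":
        return KineticDerivatives.zero(M)
    g1_raw = metric_first_derivatives(geometry, iset, solution)
    g2_raw = np.empty((M, M, M, M))
    for l in range(M):
        gp = metric_first_derivatives(
            displace(geometry, solution, l, +delta_q, iset), iset, solution)
        gm = metric_first_derivatives(
            displace(geometry, solution, l, -delta_q, iset), iset, solution)
        g2_raw[:, :, :, l] = (gp - gm) / (2.0 * delta_q)
    g2_raw = 0.5 * (g2_raw + np.transpose(g2_raw, (0, 1, 3, 2)))

    w = solution.omega_au
    sw = np.sqrt(w)
    # per-Q_amu -> per-Q_au, then dimensionless wavenumber scaling
    g1 = (np.einsum("i,j,k,ijk->ijk", sw, sw, 1.0 / sw, g1_raw)
          / np.sqrt(AMU_TO_ME) * HARTREE_TO_CM)
    g2 = (np.einsum("i,j,k,l,ijkl->ijkl", sw, sw, 1.0 / sw, 1.0 / sw, g2_raw)
          / AMU_TO_ME * HARTREE_TO_CM)
    return KineticDerivatives(g1, g2)
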