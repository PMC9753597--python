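"""Fermi-resonance diagnostics and the variational (GVPT2) correction.

The two-step Martin test flags near-degeneracies 2w_i ~ w_k (type I) and
w_i + w_j ~ w_k (type II) whose perturbative denominators would corrupt
chi: step one is a detuning filter (default 200 cm^-1), step two an
interaction-strength filter on the fourth-order energy shift a 2x2
variational treatment would recover (default 1 cm^-1).  The coupling
strength is carried by rho_iik / rho_ijk, which reduce to the plain cubic
constants in the Cartesian frame.

Accepted resonances are removed from chi (DVPT2) and the interacting
states are collected into polyads whose small Hamiltonians -- deperturbed
energies on the diagonal, contact-transformed interaction elements off
the diagonal -- are diagonalised exactly (GVPT2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .vpt2 import ChiMatrix, DerivedTensors, chi_from_tensors, state_energy

DEFAULT_DELTA_OMEGA = 200.0  # cm^-1, step-1 detuning threshold
DEFAULT_K = 1.0              # cm^-1, step-2 strength threshold


@dataclass(frozen=True)
class ResonanceCandidate:
    """A candidate Fermi resonance with its test statistics."""

    type: str                 # "I" (2w_i ~ w_k) or "II" (w_i + w_j ~ w_k)
    modes: tuple[int, ...]    # (i, k) or (i, j, k)
    detuning: float           # cm^-1
    strength: float           # Martin K statistic, cm^-1
    accepted: bool
    auto_accepted: bool = False  # exact degeneracy short-circuit

    @property
    def key(self):
        if self.type == "I":
            i, k = self.modes
            return ("I", i, k)
        i, j, k = self.modes
        return ("II", min(i, j), max(i, j), k)

    def describe(self) -> str:
        if self.type == "I":
            lbl = f"2w{self.modes[0] + 1} ~ w{self.modes[1] + 1}"
        else:
            lbl = f"w{self.modes[0] + 1}+w{self.modes[1] + 1} ~ w{self.modes[2] + 1}"
        flag = "accepted" if self.accepted else "rejected"
        return (f"type {self.type:2s} {lbl:18s} detuning {self.detuning:9.3f} "
                f"K {self.strength:11.4f}  {flag}")


def martin_test(omega: np.ndarray, rho: np.ndarray,
                dw_thresh: float = DEFAULT_DELTA_OMEGA,
                k_thresh: float = DEFAULT_K) -> list[ResonanceCandidate]:
    """Two-step Fermi-resonance identification.

    ``rho`` is the effective cubic tensor (equal to f3 for the Cartesian
    frame).  Candidates passing step 1 are returned with their K value;
    ``accepted`` requires both steps.  An exact degeneracy (detuning 0)
    is auto-accepted since its strength is formally infinite.
    """
    if dw_thresh <= 0 or k_thresh <= 0:
        raise ValueError("thresholds must be positive")
    M = omega.size
    out: list[ResonanceCandidate] = []
    for i in range(M):
        for k in range(M):
            if k == i:
                continue
            delta = abs(2.0 * omega[i] - omega[k])
            if delta > dw_thresh:
                continue
            if delta == 0.0:
                out.append(ResonanceCandidate("I", (i, k), 0.0, np.inf, True, True))
                continue
            K = rho[i, i, k] ** 4 / (256.0 * delta**3)
            out.append(ResonanceCandidate("I", (i, k), delta, K, K >= k_thresh))
    for i in range(M):
        for j in range(i + 1, M):
            for k in range(M):
                if k in (i, j):
                    continue
                delta = abs(omega[i] + omega[j] - omega[k])
                if delta > dw_thresh:
                    continue
                if delta == 0.0:
                    out.append(ResonanceCandidate("II", (i, j, k), 0.0, np.inf,
                                                  True, True))
                    continue
                K = rho[i, j, k] ** 4 / (64.0 * delta**3)
                out.append(ResonanceCandidate("II", (i, j, k), delta, K,
                                              K >= k_thresh))
    return out


def deperturb(t: DerivedTensors, candidates: Iterable[ResonanceCandidate],
              coriolis=None) -> ChiMatrix:
    """DVPT2 chi: resonant-denominator terms of accepted candidates are
    discarded and registered (the round trip chi.restored() is exact)."""
    accepted = [c for c in candidates if c.accepted]
    return chi_from_tensors(t, deperturb=[c.key for c in accepted],
                            coriolis=coriolis)


# ---------------------------------------------------------------------------
# polyads
# ---------------------------------------------------------------------------

def _resonance_moves(candidates):
    """Quantum-number difference vectors of accepted resonances."""
    moves = []
    for c in candidates:
        if not c.accepted:
            continue
        moves.append(c)
    return moves


def _partners(state: tuple, cand: ResonanceCandidate, M: int):
    """States reachable from ``state`` through one resonance exchange."""
    v = np.array(state)
    out = []
    if cand.type == "I":
        i, k = cand.modes
        d = np.zeros(M, int)
        d[i] = 2
        d[k] = -1
    else:
        i, j, k = cand.modes
        d = np.zeros(M, int)
        d[i] += 1
        d[j] += 1
        d[k] -= 1
    for step in (d, -d):
        w = v + step
        if np.all(w >= 0):
            out.append(tuple(int(x) for x in w))
    return out


def build_polyads(candidates: Iterable[ResonanceCandidate],
                  states: Sequence[tuple]) -> list[list[tuple]]:
    """Transitive closure of the requested states under accepted
    resonances; unaffected states come back as singletons."""
    states = [tuple(s) for s in states]
    M = len(states[0]) if states else 0
    moves = _resonance_moves(candidates)
    # closure: collect every state reachable from the requested ones
    pool = list(dict.fromkeys(states))
    frontier = list(pool)
    while frontier:
        nxt = []
        for st in frontier:
            for c in moves:
                for p in _partners(st, c, M):
                    if p not in pool and sum(p) > 0:
                        pool.append(p)
                        nxt.append(p)
        frontier = nxt

    parent = {s: s for s in pool}

    def find(s):
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for st in pool:
        for c in moves:
            for p in _partners(st, c, M):
                if p in parent and sum(p) > 0:
                    union(st, p)
    groups: dict[tuple, list[tuple]] = {}
    for s in pool:
        groups.setdefault(find(s), []).append(s)
    polyads = [sorted(g) for g in groups.values()]
    polyads.sort()
    return polyads


def interaction_element(t: DerivedTensors, state_a: tuple, state_b: tuple) -> float:
    """Contact-transformed interaction element <a|H~|b> (cm^-1) between
    two states differing by a Fermi-resonance pattern; 0 otherwise.

    Type I:  <v+2_i|H~|v+1_k> = rho_iik sqrt((v_i+1)(v_i+2)(v_k+1)) / (4 sqrt 2)
    Type II: <v+1_i+1_j|H~|v+1_k> = rho_ijk sqrt((v_i+1)(v_j+1)(v_k+1)) / (2 sqrt 2)
    """
    a = np.array(state_a, int)
    b = np.array(state_b, int)
    d = a - b
    for sgn in (1, -1):
        dd = sgn * d
        pos = np.where(dd > 0)[0]
        neg = np.where(dd < 0)[0]
        if neg.size != 1 or dd[neg[0]] != -1:
            continue
        k = int(neg[0])
        hi = a if sgn == 1 else b  # the (v+2_i / v+1_i+1_j) member
        lo = b if sgn == 1 else a
        v = lo.copy()
        v[k] -= 1
        if np.any(v < 0):
            continue
        if pos.size == 1 and dd[pos[0]] == 2:
            i = int(pos[0])
            return float(t.rho[i, i, k]
                         * np.sqrt((v[i] + 1) * (v[i] + 2) * (v[k] + 1))
                         / (4.0 * np.sqrt(2.0)))
        if pos.size == 2 and np.all(dd[pos] == 1):
            i, j = (int(pos[0]), int(pos[1]))
            return float(t.rho[i, j, k]
                         * np.sqrt((v[i] + 1) * (v[j] + 1) * (v[k] + 1))
                         / (2.0 * np.sqrt(2.0)))
    return 0.0


@dataclass
class Polyad:
    states: list[tuple]
    matrix: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    assignment: dict = field(default_factory=dict)  # state -> eigenindex
    ambiguous: list = field(default_factory=list)

    @property
    def is_singleton(self) -> bool:
        return len(self.states) == 1


def diagonalize_polyad(states: Sequence[tuple], chi_dep: ChiMatrix,
                       omega: np.ndarray, t: DerivedTensors) -> Polyad:
    """Variational matrix: deperturbed energies on the diagonal,
    interaction elements off-diagonal; assignment by largest squared
    eigenvector component with a deterministic tie-break."""
    states = [tuple(s) for s in states]
    n = len(states)
    H = np.zeros((n, n))
    for a in range(n):
        H[a, a] = state_energy(chi_dep, omega, states[a])
        for b in range(a + 1, n):
            H[a, b] = H[b, a] = interaction_element(t, states[a], states[b])
    evals, evecs = np.linalg.eigh(H)
    pol = Polyad(states, H, evals, evecs)
    weights = evecs**2
    for a, st in enumerate(states):
        row = weights[a]
        best = float(row.max())
        cands = np.where(row > best - 1e-6)[0]
        idx = int(cands.min())
        if cands.size > 1:
            pol.ambiguous.append(st)
        pol.assignment[st] = idx
    return pol


def gvpt2_energies(polyads: Sequence[Sequence[tuple]], chi_dep: ChiMatrix,
                   omega: np.ndarray, t: DerivedTensors,
                   states: Sequence[tuple]) -> dict:
    """DVPT2 and GVPT2 transition energies for the requested states.

    Singleton polyads give GVPT2 = DVPT2 exactly; for true polyads the
    GVPT2 value is the eigenvalue assigned to the state's dominant
    component.
    """
    diag = {}
    for group in polyads:
        pol = diagonalize_polyad(group, chi_dep, omega, t)
        for st in group:
            diag[st] = (pol, float(pol.eigenvalues[pol.assignment[st]]))
    out = {}
    for st in map(tuple, states):
        dv = state_energy(chi_dep, omega, st)
        if st in diag:
            pol, gv = diag[st]
        else:
            pol, gv = None, dv
        out[st] = {"dvpt2": dv, "gvpt2": gv, "polyad": pol}
    return out
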