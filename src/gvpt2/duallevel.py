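"""Dual-level (hybrid) anharmonic schemes.

Harmonic frequencies converge much more slowly with the electronic-
structure level than cubic/quartic couplings, so a high-level harmonic
calculation can be combined with a cheaper anharmonic force field:

* Add: the low-level anharmonic shift nu^L - w^L is added to the
  high-level harmonic frequency.  Cheap, but the perturbative
  denominators keep their low-level values.
* Sub: the full VPT2/DVPT2/GVPT2 machinery is re-run with the high-level
  frequencies substituted into the harmonic term and every denominator
  (and into the resonance test), while the low-level cubic/quartic and
  kinetic couplings are retained.

Modes are matched across levels by maximum-overlap assignment (Hungarian
algorithm on |mode overlap|), overridable with an explicit map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .force_field import KineticDerivatives, QuarticForceField
from .resonance import (DEFAULT_DELTA_OMEGA, DEFAULT_K, build_polyads,
                        deperturb, gvpt2_energies, martin_test)
from .vpt2 import CoriolisData, derived_tensors


@dataclass(frozen=True)
class DualLevelInput:
    """High-level harmonic frequencies matched onto the low-level modes."""

    omega_high: np.ndarray
    mode_map: Optional[np.ndarray] = None  # high = omega_high[mode_map[low]]

    def matched(self, n_low: int) -> np.ndarray:
        w = np.asarray(self.omega_high, float)
        if w.size != n_low:
            raise ValueError(
                f"high-level frequency count {w.size} does not match the "
                f"low level ({n_low}); dual-level needs a bijective mode map")
        if self.mode_map is None:
            return w
        mm = np.asarray(self.mode_map, int)
        if sorted(mm.tolist()) != list(range(n_low)):
            raise ValueError("mode_map must be a permutation")
        return w[mm]


def match_modes(modes_low: np.ndarray, modes_high: np.ndarray) -> np.ndarray:
    """Maximum-overlap assignment between two mode matrices (columns).

    Returns ``mode_map`` such that high-level mode ``mode_map[k]``
    corresponds to low-level mode ``k``.  Frequency-order matching breaks
    on near-degenerate reorderings; overlap matching does not.
    """
    a = modes_low / np.linalg.norm(modes_low, axis=0)
    b = modes_high / np.linalg.norm(modes_high, axis=0)
    overlap = np.abs(a.T @ b)
    rows, cols = linear_sum_assignment(-overlap)
    mode_map = np.empty(a.shape[1], int)
    mode_map[rows] = cols
    return mode_map


def add_scheme(nu_low: np.ndarray, omega_low: np.ndarray,
               dual: DualLevelInput) -> np.ndarray:
    """nu_Add = w^H + (nu^L - w^L), per matched mode."""
    nu_low = np.asarray(nu_low, float)
    omega_low = np.asarray(omega_low, float)
    wH = dual.matched(omega_low.size)
    return wH + (nu_low - omega_low)


def sub_scheme(ff: QuarticForceField, kin: Optional[KineticDerivatives],
               dual: DualLevelInput, coriolis: Optional[CoriolisData] = None,
               dw_thresh: float = DEFAULT_DELTA_OMEGA,
               k_thresh: float = DEFAULT_K,
               states: Optional[Sequence[tuple]] = None) -> dict:
    """Full re-run of the perturbative + variational machinery with the
    high-level frequencies in all denominators and harmonic terms.

    Returns {"omega", "candidates", "chi", "results"} where results maps
    each state to its DVPT2/GVPT2 energies (see
    :func:`gvpt2.resonance.gvpt2_energies`).
    """
    M = ff.n_modes
    wH = dual.matched(M)
    t = derived_tensors(ff, kin, omega=wH)
    candidates = martin_test(wH, t.rho, dw_thresh, k_thresh)
    chi_dep = deperturb(t, candidates, coriolis=coriolis)
    if states is None:
        states = [tuple(np.eye(M, dtype=int)[k]) for k in range(M)]
    polyads = build_polyads(candidates, states)
    results = gvpt2_energies(polyads, chi_dep, wH, t, states)
    return {"omega": wH, "candidates": candidates, "chi": chi_dep,
            "results": results}
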