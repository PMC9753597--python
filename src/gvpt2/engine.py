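"""Electronic-structure engine contract.

The anharmonic driver only ever needs energies, Cartesian gradients and
Cartesian Hessians at prescribed geometries; anything that can supply
those through :class:`EngineResult` (an external quantum-chemistry
package, an archive of previous results, or an analytic model potential)
can drive the whole machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .geometry import Geometry


@dataclass(frozen=True)
class EngineResult:
    """Energy (hartree), gradient (hartree/bohr), Hessian (hartree/bohr^2)."""

    energy: float
    gradient: np.ndarray   # (3*n_atoms,)
    hessian: np.ndarray    # (3*n_atoms, 3*n_atoms), symmetric
    label: str = ""

    def __post_init__(self):
        g = np.asarray(self.gradient, float).reshape(-1)
        h = np.asarray(self.hessian, float)
        if h.shape != (g.size, g.size):
            raise ValueError("gradient/Hessian shape mismatch")
        if not np.allclose(h, h.T, atol=1e-10 * max(1.0, np.abs(h).max())):
            raise ValueError("Hessian must be symmetric")
        object.__setattr__(self, "gradient", g)
        object.__setattr__(self, "hessian", 0.5 * (h + h.T))


@runtime_checkable
class EngineAdapter(Protocol):
    """Pure-function adapter: geometry in, EngineResult out."""

    def compute(self, geometry: Geometry) -> EngineResult:  # pragma: no cover
        ...
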