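"""End-to-end driver: coordinates -> harmonic -> surface -> VPT2 ->
resonances -> (dual level) -> report.

The report is deterministic (no timestamps, fixed formatting, hashes for
provenance): identical configuration and archive reproduce it byte for
byte.
"""

from __future__ import annotations

import hashlib
import io
import json
import os
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import __version__
from .engine import EngineAdapter, EngineResult
from .force_field import (KineticDerivatives, QuarticForceField,
                          assemble_force_field, assemble_kinetic_derivatives,
                          hessian_to_internal, run_surface)
from .geometry import Geometry, read_xyz
from .harmonic import cartesian_harmonic, gf_solve
from .internal_coords import (InternalSet, b_matrix, b_prime, detect_primitives,
                              g_matrix)
from .models import MorseDiatomic, synthetic_polyatomic
from .resonance import (DEFAULT_DELTA_OMEGA, DEFAULT_K, build_polyads,
                        deperturb, gvpt2_energies, martin_test)
from .duallevel import DualLevelInput, add_scheme, sub_scheme
from .units import DEFAULT_DELTA_Q
from .vpt2 import (ChiMatrix, chi_from_tensors, combination, coriolis_data,
                   derived_tensors, fundamental, overtone, state_energy)


class StageError(RuntimeError):
    """Failure attributed to a named pipeline stage (mapped to an exit code)."""

    STAGES = ("config", "geometry", "coordinates", "harmonic", "surface",
              "force-field", "vpt2", "resonance", "dual-level", "report")

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage

    @property
    def exit_code(self) -> int:
        return 10 + self.STAGES.index(self.stage)


@dataclass
class RunConfig:
    geometry: object                     # path to XYZ or a Geometry
    frame: str = "curvilinear"           # or "cartesian"
    geometry_units: str = "angstrom"
    coords: str = "auto"                 # topology-detected primitives
    bond_scale: float = 1.3
    delta_q: float = DEFAULT_DELTA_Q
    dw_thresh: float = DEFAULT_DELTA_OMEGA
    k_thresh: float = DEFAULT_K
    scheme: str = "gvpt2"                # vpt2 | dvpt2 | gvpt2
    coupling_order: int = 3
    include_coriolis: bool = True
    dual_level: Optional[object] = None  # DualLevelInput, path, or list
    engine: object = None                # EngineAdapter, dict spec, or "archive"
    archive: Optional[str] = None
    seed: int = 0

    def validate(self):
        if self.frame not in ("curvilinear", "cartesian"):
            raise StageError("config", f"unknown frame {self.frame!r}")
        if self.scheme not in ("vpt2", "dvpt2", "gvpt2"):
            raise StageError("config", f"unknown scheme {self.scheme!r}")
        if self.delta_q <= 0:
            raise StageError("config", "delta_q must be positive")
        if self.dw_thresh <= 0 or self.k_thresh <= 0:
            raise StageError("config", "Martin thresholds must be positive")
        if self.coupling_order not in (1, 2, 3):
            raise StageError("config", "coupling_order must be 1, 2 or 3")

    def canonical(self) -> str:
        d = {k: v for k, v in self.__dict__.items()}
        d["geometry"] = (self.geometry if isinstance(self.geometry, str)
                         else "<inline>")
        d["engine"] = (self.engine if isinstance(self.engine, (str, dict))
                       else type(self.engine).__name__)
        d["dual_level"] = (self.dual_level if isinstance(self.dual_level, (str, list))
                           else None if self.dual_level is None else "<inline>")
        return json.dumps(d, sort_keys=True, default=str)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:12]


class _ArchiveOnlyAdapter:
    """Replay adapter: every compute() call is an error -- all results
    must already be present in the archive."""

    def compute(self, geometry: Geometry) -> EngineResult:
        raise RuntimeError("archive replay requested but a result is missing")


def _resolve_engine(config: RunConfig, geometry: Geometry):
    eng = config.engine
    if eng is None:
        raise StageError("config", "no engine adapter configured")
    if isinstance(eng, str):
        if eng == "archive":
            return _ArchiveOnlyAdapter()
        raise StageError("config", f"unknown engine id {eng!r}")
    if isinstance(eng, dict):
        spec = dict(eng)
        kind = spec.pop("model", None)
        if kind == "morse":
            return MorseDiatomic(spec["D"], spec["a"], spec.get("re", 1.4),
                                 tuple(spec.get("symbols", geometry.symbols)))
        if kind == "polynomial":
            iset = detect_primitives(geometry, config.bond_scale)
            return synthetic_polyatomic(geometry, iset,
                                        np.asarray(spec["F"], float),
                                        None if "C" not in spec else np.asarray(spec["C"], float),
                                        None if "Q" not in spec else np.asarray(spec["Q"], float))
        raise StageError("config", f"unknown model engine {kind!r}")
    if isinstance(eng, EngineAdapter):
        return eng
    raise StageError("config", "engine does not satisfy the adapter contract")


def _load_dual_level(dual) -> Optional[DualLevelInput]:
    if dual is None:
        return None
    if isinstance(dual, DualLevelInput):
        return dual
    if isinstance(dual, (list, tuple, np.ndarray)):
        return DualLevelInput(np.asarray(dual, float))
    if isinstance(dual, str):
        with open(dual) as fh:
            data = json.load(fh) if dual.endswith(".json") else None
            if data is None:
                import yaml
                fh.seek(0)
                data = yaml.safe_load(fh)
        if isinstance(data, dict):
            return DualLevelInput(np.asarray(data["omega"], float),
                                  None if "mode_map" not in data
                                  else np.asarray(data["mode_map"], int))
        return DualLevelInput(np.asarray(data, float))
    raise StageError("config", "unrecognised dual-level input")


@dataclass
class PipelineResult:
    config: RunConfig
    geometry: Geometry
    solution: object
    iset: Optional[InternalSet]
    ff: QuarticForceField
    kin: KineticDerivatives
    chi_vpt2: Optional[ChiMatrix]
    chi_dvpt2: Optional[ChiMatrix]
    candidates: list
    states: list
    table: dict                  # state -> {"omega","vpt2","dvpt2","gvpt2"}
    dual: Optional[dict]
    report: str


def default_states(M: int) -> list[tuple]:
    states = [fundamental(M, k) for k in range(M)]
    states += [overtone(M, k) for k in range(M)]
    states += [combination(M, i, j) for i in range(M) for j in range(i + 1, M)]
    return states


def state_label(v: tuple) -> str:
    parts = []
    for k, n in enumerate(v):
        if n == 1:
            parts.append(f"nu{k + 1}")
        elif n > 1:
            parts.append(f"{n}nu{k + 1}")
    return "+".join(parts) if parts else "gs"


def harmonic_energy(omega: np.ndarray, v: tuple) -> float:
    return float(np.dot(omega, v))


def run_pipeline(config: RunConfig) -> PipelineResult:
    config.validate()

    # geometry ---------------------------------------------------------------
    try:
        geometry = (config.geometry if isinstance(config.geometry, Geometry)
                    else read_xyz(config.geometry, config.geometry_units))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("geometry", str(exc)) from exc

    engine = _resolve_engine(config, geometry)

    # coordinates ------------------------------------------------------------
    iset = None
    if config.frame == "curvilinear":
        try:
            iset = detect_primitives(geometry, config.bond_scale)
        except Exception as exc:
            raise StageError("coordinates", str(exc)) from exc

    # harmonic ---------------------------------------------------------------
    try:
        ref = engine.compute(geometry)
        if config.frame == "curvilinear":
            B = b_matrix(geometry, iset)
            Bp = b_prime(geometry, iset)
            F = hessian_to_internal(ref, B, Bp)
            G = g_matrix(B, geometry.masses)
            solution = gf_solve(G, F)
        else:
            solution = cartesian_harmonic(ref.hessian, geometry)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("harmonic", str(exc)) from exc

    # surface ----------------------------------------------------------------
    try:
        results = run_surface(geometry, engine, solution, iset,
                              config.delta_q, config.archive)
    except Exception as exc:
        raise StageError("surface", str(exc)) from exc

    # force field ------------------------------------------------------------
    try:
        ff = assemble_force_field(results, solution, geometry, iset,
                                  config.delta_q)
        kin = assemble_kinetic_derivatives(geometry, iset, solution,
                                           config.delta_q)
        if config.coupling_order < 3:
            from .vpt2 import restrict_coupling_order
            ff, kin = restrict_coupling_order(ff, kin, config.coupling_order)
    except Exception as exc:
        raise StageError("force-field", str(exc)) from exc

    # vpt2 + resonance -------------------------------------------------------
    try:
        cor = (coriolis_data(geometry, solution)
               if (config.frame == "cartesian" and config.include_coriolis)
               else None)
        t = derived_tensors(ff, kin)
        M = ff.n_modes
        states = default_states(M)
        candidates = martin_test(solution.omega_cm, t.rho,
                                 config.dw_thresh, config.k_thresh)
        accepted = [c for c in candidates if c.accepted]
        chi_vpt2 = None
        try:
            chi_vpt2 = chi_from_tensors(t, coriolis=cor)
        except ArithmeticError:
            pass  # exact resonance: plain VPT2 undefined, columns stay empty
        chi_dvpt2 = deperturb(t, candidates, coriolis=cor)
        polyads = build_polyads(candidates, states)
        gv = gvpt2_energies(polyads, chi_dvpt2, ff.omega, t, states)
        table = {}
        for st in states:
            row = {"omega": harmonic_energy(ff.omega, st),
                   "vpt2": (None if chi_vpt2 is None
                            else state_energy(chi_vpt2, ff.omega, st))}
            if config.scheme in ("dvpt2", "gvpt2"):
                row["dvpt2"] = gv[st]["dvpt2"]
            if config.scheme == "gvpt2":
                row["gvpt2"] = gv[st]["gvpt2"]
            table[st] = row
    except StageError:
        raise
    except Exception as exc:
        raise StageError("vpt2", str(exc)) from exc

    # dual level -------------------------------------------------------------
    dual_result = None
    dual = _load_dual_level(config.dual_level)
    if dual is not None:
        try:
            nu_low = np.array([table[fundamental(M, k)]["gvpt2"
                                                        if config.scheme == "gvpt2"
                                                        else "vpt2"]
                               for k in range(M)])
            adds = add_scheme(nu_low, ff.omega, dual)
            sub = sub_scheme(ff, kin, dual, coriolis=cor,
                             dw_thresh=config.dw_thresh,
                             k_thresh=config.k_thresh,
                             states=[fundamental(M, k) for k in range(M)])
            dual_result = {"input": dual, "add": adds, "sub": sub}
        except Exception as exc:
            raise StageError("dual-level", str(exc)) from exc

    report = _render_report(config, geometry, solution, candidates, states,
                            table, dual_result)
    return PipelineResult(config, geometry, solution, iset, ff, kin,
                          chi_vpt2, chi_dvpt2, candidates, states, table,
                          dual_result, report)


def _fmt(val, width=9) -> str:
    if val is None:
        return " " * (width - 1) + "-"
    return f"{val:{width}.1f}"


def _render_report(config, geometry, solution, candidates, states, table,
                   dual_result) -> str:
    out = io.StringIO()
    w = out.write
    w(f"# gvpt2 {__version__} transition energies (cm^-1)\n")
    w(f"# frame: {config.frame}  scheme: {config.scheme}  "
      f"delta_q: {config.delta_q}  thresholds: {config.dw_thresh}/{config.k_thresh}\n")
    w(f"# config hash: {config.config_hash()}\n")
    if config.archive and os.path.exists(config.archive):
        with open(config.archive, "rb") as fh:
            w(f"# archive hash: {hashlib.sha256(fh.read()).hexdigest()[:12]}\n")
    w(f"# atoms: {' '.join(geometry.symbols)}\n")
    w("#\n")
    w(f"{'assignment':14s} {'omega':>9s} {'VPT2':>9s} {'DVPT2':>9s} {'GVPT2':>9s}\n")
    for st in states:
        row = table[st]
        w(f"{state_label(st):14s} {_fmt(row['omega'])} {_fmt(row.get('vpt2'))} "
          f"{_fmt(row.get('dvpt2'))} {_fmt(row.get('gvpt2'))}\n")
    w("#\n# resonance analysis\n")
    if not candidates:
        w("# no candidates within the detuning window\n")
    for c in candidates:
        w(f"# {c.describe()}\n")
    if dual_result is not None:
        w("#\n# dual-level fundamentals (Add / Sub)\n")
        w(f"{'assignment':14s} {'omega_H':>9s} {'Add':>9s} {'Sub':>9s}\n")
        M = solution.n_modes
        wH = dual_result["sub"]["omega"]
        for k in range(M):
            st = fundamental(M, k)
            sub_v = dual_result["sub"]["results"][st]["gvpt2"]
            w(f"{state_label(st):14s} {_fmt(wH[k])} "
              f"{_fmt(dual_result['add'][k])} {_fmt(sub_v)}\n")
    return out.getvalue()
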