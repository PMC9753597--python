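import numpy as np
import pytest

from gvpt2.force_field import (assemble_force_field,
                               assemble_kinetic_derivatives,
                               hessian_to_internal, run_surface)
from gvpt2.harmonic import cartesian_harmonic, gf_solve
from gvpt2.internal_coords import b_matrix, b_prime, g_matrix
from gvpt2.models import co_like_morse, water_like_pes
from gvpt2.vpt2 import coriolis_data


@pytest.fixture(scope="session")
def water():
    """(geometry, internal set, analytic PES) for the bent triatomic."""
    return water_like_pes()


@pytest.fixture(scope="session")
def water_curvi(water):
    """Curvilinear-frame context: harmonic solution, force field, kinetic
    derivatives for the water-like PES."""
    geom, iset, pes = water
    res0 = pes.compute(geom)
    B = b_matrix(geom, iset)
    Bp = b_prime(geom, iset)
    F = hessian_to_internal(res0, B, Bp)
    sol = gf_solve(g_matrix(B, geom.masses), F)
    results = run_surface(geom, pes, sol, iset)
    ff = assemble_force_field(results, sol, geom, iset)
    kin = assemble_kinetic_derivatives(geom, iset, sol)
    return {"geometry": geom, "iset": iset, "pes": pes, "solution": sol,
            "results": results, "ff": ff, "kin": kin}


@pytest.fixture(scope="session")
def water_cart(water):
    """Cartesian-frame context for the same PES (with Coriolis data)."""
    geom, iset, pes = water
    res0 = pes.compute(geom)
    sol = cartesian_harmonic(res0.hessian, geom)
    results = run_surface(geom, pes, sol)
    ff = assemble_force_field(results, sol, geom)
    kin = assemble_kinetic_derivatives(geom, None, sol)
    cor = coriolis_data(geom, sol)
    return {"geometry": geom, "pes": pes, "solution": sol, "ff": ff,
            "kin": kin, "coriolis": cor}


@pytest.fixture(scope="session")
def morse():
    return co_like_morse()
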