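import numpy as np
import pytest

from gvpt2.engine import EngineResult
from gvpt2.force_field import (ForceFieldError, assemble_force_field,
                               assemble_kinetic_derivatives,
                               dimensionless_metric, displace,
                               gradient_to_internal, hessian_to_internal,
                               metric_first_derivatives, run_surface,
                               surface_labels)
from gvpt2.harmonic import cartesian_harmonic, gf_solve
from gvpt2.internal_coords import (b_matrix, b_prime, coordinate_values,
                                   detect_primitives, g_matrix)
from gvpt2.units import AMU_TO_ME


class TestDisplace:
    def test_zero_step_identity(self, water_curvi):
        ctx = water_curvi
        geo = displace(ctx["geometry"], ctx["solution"], 0, 0.0, ctx["iset"])
        assert geo is ctx["geometry"]

    @pytest.mark.parametrize("mode", [0, 1, 2])
    def test_internal_values_move_by_step_times_mode(self, water_curvi, mode):
        ctx = water_curvi
        step = 0.02
        geo = displace(ctx["geometry"], ctx["solution"], mode, step, ctx["iset"])
        s0 = coordinate_values(ctx["geometry"], ctx["iset"])
        s1 = coordinate_values(geo, ctx["iset"], reference=s0)
        assert np.abs(s1 - s0 - step * ctx["solution"].L[:, mode]).max() < 1e-8

    def test_plus_minus_pair_averages_to_reference(self, water_curvi):
        ctx = water_curvi
        gp = displace(ctx["geometry"], ctx["solution"], 1, +0.02, ctx["iset"])
        gm = displace(ctx["geometry"], ctx["solution"], 1, -0.02, ctx["iset"])
        avg = 0.5 * (gp.x + gm.x)
        assert np.abs(avg - ctx["geometry"].x).max() < 5e-6

    def test_cartesian_displacement_is_linear(self, water_cart):
        ctx = water_cart
        sol = ctx["solution"]
        gp = displace(ctx["geometry"], sol, 0, +0.02)
        dx = gp.x - ctx["geometry"].x
        expected = 0.02 * sol.modes_mw[:, 0] / np.sqrt(np.repeat(ctx["geometry"].masses, 3))
        assert np.abs(dx - expected).max() < 1e-14


class TestTransforms:
    def test_zero_gradient_maps_to_zero(self, water_curvi):
        ctx = water_curvi
        B = b_matrix(ctx["geometry"], ctx["iset"])
        res = ctx["pes"].compute(ctx["geometry"])
        assert np.abs(gradient_to_internal(res, B)).max() < 1e-12

    def test_diatomic_gradient_and_hessian(self, morse):
        geom = morse.geometry()
        stretched = geom.with_coords(geom.coords + np.array([[0, 0, -0.05],
                                                             [0, 0, 0.05]]))
        iset = detect_primitives(stretched)
        res = morse.compute(stretched)
        B = b_matrix(stretched, iset)
        Bp = b_prime(stretched, iset)
        r = np.linalg.norm(stretched.coords[0] - stretched.coords[1])
        _, V1, V2 = morse._radial(r)
        assert gradient_to_internal(res, B)[0] == pytest.approx(V1, rel=1e-10)
        assert hessian_to_internal(res, B, Bp)[0, 0] == pytest.approx(V2, rel=1e-10)

    def test_projection_identity(self, water_curvi):
        # B g_s reproduces P g_x at a non-stationary geometry
        ctx = water_curvi
        geo = displace(ctx["geometry"], ctx["solution"], 2, 0.05, ctx["iset"])
        res = ctx["pes"].compute(geo)
        B = b_matrix(geo, ctx["iset"])
        Bplus = np.linalg.pinv(B, rcond=1e-10)
        g_s = gradient_to_internal(res, B)
        assert np.abs(B.T @ g_s - (Bplus @ B) @ res.gradient).max() < 1e-10

    def test_hessian_transform_round_trip_at_displaced_geometry(self, water_curvi):
        # at a non-stationary geometry the gradient (B') correction is
        # essential: B^T F B + g_s . B' must reconstruct the projected
        # Cartesian Hessian exactly
        ctx = water_curvi
        geo = displace(ctx["geometry"], ctx["solution"], 0, 0.05, ctx["iset"])
        res = ctx["pes"].compute(geo)
        B = b_matrix(geo, ctx["iset"])
        Bp = b_prime(geo, ctx["iset"])
        F = hessian_to_internal(res, B, Bp)
        g_s = gradient_to_internal(res, B)
        Bplus = np.linalg.pinv(B, rcond=1e-10)
        P = Bplus @ B
        lhs = B.T @ F @ B + np.einsum("i,ijk->jk", g_s, Bp)
        rhs = P @ res.hessian @ P + np.einsum(
            "i,ijk->jk", g_s, Bp) - P @ np.einsum("i,ijk->jk", g_s, Bp) @ P
        assert np.abs(lhs - rhs).max() < 1e-9
        # and without the B' term the reconstruction fails visibly
        wrong = B.T @ F @ B
        assert np.abs(wrong - rhs).max() > 1e-4


class TestForceFieldAssembly:
    def test_harmonic_pes_gives_zero_anharmonicity(self, water):
        from gvpt2.models import synthetic_polyatomic
        geom, iset, _ = water
        F = np.array([[0.50, -0.005, 0.02], [-0.005, 0.50, 0.02],
                      [0.02, 0.02, 0.16]])
        pes = synthetic_polyatomic(geom, iset, F)
        res0 = pes.compute(geom)
        sol = gf_solve(g_matrix(b_matrix(geom, iset), geom.masses),
                       hessian_to_internal(res0, b_matrix(geom, iset),
                                           b_prime(geom, iset)))
        results = run_surface(geom, pes, sol, iset)
        ff = assemble_force_field(results, sol, geom, iset)
        # FD noise bound: curvature of the back-transformation only
        assert np.abs(ff.f3).max() < 5e-2
        assert np.abs(ff.f4).max() < 5e-2

    def test_planted_cubic_quartic_recovered_1d(self, morse):
        geom = morse.geometry()
        iset = detect_primitives(geom)
        res0 = morse.compute(geom)
        sol = gf_solve(g_matrix(b_matrix(geom, iset), geom.masses),
                       hessian_to_internal(res0, b_matrix(geom, iset),
                                           b_prime(geom, iset)))
        results = run_surface(geom, morse, sol, iset)
        ff = assemble_force_field(results, sol, geom, iset)
        exact = morse.exact_force_field()
        assert ff.f3[0, 0, 0] == pytest.approx(exact.f3[0, 0, 0], rel=2e-3)
        assert ff.f4[0, 0, 0, 0] == pytest.approx(exact.f4[0, 0, 0, 0], rel=5e-3)

    def test_fd_error_is_second_order_in_step(self, morse):
        geom = morse.geometry()
        iset = detect_primitives(geom)
        res0 = morse.compute(geom)
        sol = gf_solve(g_matrix(b_matrix(geom, iset), geom.masses),
                       hessian_to_internal(res0, b_matrix(geom, iset),
                                           b_prime(geom, iset)))
        exact = morse.exact_force_field().f3[0, 0, 0]
        errs = []
        for dq in (0.04, 0.02):
            results = run_surface(geom, morse, sol, iset, delta_q=dq)
            ff = assemble_force_field(results, sol, geom, iset, delta_q=dq)
            errs.append(abs(ff.f3[0, 0, 0] - exact))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.25)

    def test_missing_displacement_raises(self, water_curvi):
        ctx = water_curvi
        partial = {k: v for k, v in ctx["results"].items() if k != "mode1-"}
        with pytest.raises(ForceFieldError, match="mode1-"):
            assemble_force_field(partial, ctx["solution"], ctx["geometry"],
                                 ctx["iset"])


class TestKineticDerivatives:
    def test_diatomic_constant_metric_all_zero(self, morse):
        geom = morse.geometry()
        iset = detect_primitives(geom)
        res0 = morse.compute(geom)
        sol = gf_solve(g_matrix(b_matrix(geom, iset), geom.masses),
                       hessian_to_internal(res0, b_matrix(geom, iset),
                                           b_prime(geom, iset)))
        kin = assemble_kinetic_derivatives(geom, iset, sol)
        assert np.abs(kin.g1).max() < 1e-10
        assert np.abs(kin.g2).max() < 1e-8

    def test_cartesian_frame_identically_zero(self, water_cart):
        assert water_cart["kin"].is_zero

    def test_g1_matches_fd_of_metric(self, water_curvi):
        ctx = water_curvi
        geom, iset, sol = ctx["geometry"], ctx["iset"], ctx["solution"]
        dq = 1e-4
        g1_fd = np.zeros((3, 3, 3))
        for k in range(3):
            gp = dimensionless_metric(displace(geom, sol, k, +dq, iset), iset, sol)
            gm = dimensionless_metric(displace(geom, sol, k, -dq, iset), iset, sol)
            g1_fd[:, :, k] = (gp - gm) / (2 * dq)
        conv = np.sqrt(sol.omega_au) * np.sqrt(AMU_TO_ME)
        g1_fd /= conv[None, None, :]
        assert np.abs(g1_fd - ctx["kin"].g1).max() < 1e-6

    def test_symmetries(self, water_curvi):
        kin = water_curvi["kin"]
        assert np.abs(kin.g1 - np.transpose(kin.g1, (1, 0, 2))).max() < 1e-12
        assert np.abs(kin.g2 - np.transpose(kin.g2, (1, 0, 2, 3))).max() < 1e-9
        assert np.abs(kin.g2 - np.transpose(kin.g2, (0, 1, 3, 2))).max() < 1e-12


class TestSurfaceRunner:
    def test_job_count_and_idempotence(self, water, tmp_path):
        geom, iset, pes = water
        res0 = pes.compute(geom)
        sol = gf_solve(g_matrix(b_matrix(geom, iset), geom.masses),
                       hessian_to_internal(res0, b_matrix(geom, iset),
                                           b_prime(geom, iset)))
        calls = []

        class Counting:
            def compute(self, g):
                calls.append(1)
                return pes.compute(g)

        arch = str(tmp_path / "surface.json")
        results = run_surface(geom, Counting(), sol, iset, archive_path=arch)
        assert len(results) == 2 * sol.n_modes + 1
        assert set(results) == set(surface_labels(sol.n_modes))
        assert len(calls) == 7
        run_surface(geom, Counting(), sol, iset, archive_path=arch)
        assert len(calls) == 7  # fully replayed, zero engine calls

    def test_corrupted_entry_rerun_specifically(self, water, tmp_path):
        import json
        geom, iset, pes = water
        res0 = pes.compute(geom)
        sol = gf_solve(g_matrix(b_matrix(geom, iset), geom.masses),
                       hessian_to_internal(res0, b_matrix(geom, iset),
                                           b_prime(geom, iset)))
        arch = str(tmp_path / "surface.json")
        run_surface(geom, pes, sol, iset, archive_path=arch)
        data = json.load(open(arch))
        data["results"]["mode2+"]["hessian"][5] = "not-a-float"
        json.dump(data, open(arch, "w"))
        calls = []

        class Counting:
            def compute(self, g):
                calls.append(1)
                return pes.compute(g)

        run_surface(geom, Counting(), sol, iset, archive_path=arch)
        assert len(calls) == 1  # only the corrupted label recomputed

    def test_engine_failure_reports_label(self, water):
        geom, iset, pes = water
        res0 = pes.compute(geom)
        sol = gf_solve(g_matrix(b_matrix(geom, iset), geom.masses),
                       hessian_to_internal(res0, b_matrix(geom, iset),
                                           b_prime(geom, iset)))

        class Failing:
            def compute(self, g):
                if np.abs(g.x - geom.x).max() > 1e-12:
                    raise RuntimeError("scf exploded")
                return pes.compute(g)

        with pytest.raises(ForceFieldError, match="mode0"):
            run_surface(geom, Failing(), sol, iset)

    def test_job_order_invariance(self, water_curvi):
        # permuting the results dict must not change assembled constants
        ctx = water_curvi
        shuffled = dict(reversed(list(ctx["results"].items())))
        ff2 = assemble_force_field(shuffled, ctx["solution"], ctx["geometry"],
                                   ctx["iset"])
        assert np.array_equal(ff2.f3, ctx["ff"].f3)
        assert np.array_equal(ff2.f4, ctx["ff"].f4)
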