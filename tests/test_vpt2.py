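import numpy as np
import pytest

from gvpt2.force_field import KineticDerivatives, QuarticForceField
from gvpt2.models import (OracleSpec, _oracle, random_nonresonant_system,
                          transition_pt2)
from gvpt2.vpt2 import (ChiMatrix, CoriolisData, ResonanceBlowupError,
                        chi_cartesian, chi_components, chi_curvilinear,
                        chi_from_tensors, chi_potential_combined, coriolis_data,
                        count_couplings, derived_tensors, restrict_coupling_order,
                        single_mode_anharmonic, state_energy)


def _system(seed, M=3, **kw):
    rng = np.random.default_rng(seed)
    omega, f3, f4, g1, g2, cor = random_nonresonant_system(M, rng, **kw)
    ff = QuarticForceField(omega, f3, f4, "curvilinear")
    kin = KineticDerivatives(g1, g2)
    return ff, kin, cor


class TestDerivedTensors:
    def test_kinetic_free_reduction(self):
        ff, _, _ = _system(0, kinetic=False)
        t = derived_tensors(ff, None)
        assert np.array_equal(t.sigma, ff.f3)
        assert np.array_equal(t.rho, ff.f3)
        assert np.array_equal(t.eta, ff.f4)

    def test_all_zero_input(self):
        M = 2
        ff = QuarticForceField(np.array([1000.0, 2500.0]),
                               np.zeros((M,) * 3), np.zeros((M,) * 4))
        t = derived_tensors(ff, KineticDerivatives.zero(M))
        assert not np.any(t.sigma) and not np.any(t.rho) and not np.any(t.eta)

    def test_symmetries(self):
        ff, kin, _ = _system(1)
        t = derived_tensors(ff, kin)
        # rho symmetric in its first two indices, sigma fully symmetric
        assert np.abs(t.rho - np.transpose(t.rho, (1, 0, 2))).max() < 1e-12
        for p in ((1, 0, 2), (0, 2, 1), (2, 1, 0)):
            assert np.abs(t.sigma - np.transpose(t.sigma, p)).max() < 1e-12


class TestComponentIdentity:
    @pytest.mark.parametrize("seed", range(6))
    def test_component_sum_equals_recast(self, seed):
        M = 2 + seed % 3
        ff, kin, cor = _system(seed, M=M, coriolis=True)
        pot, kinc, cross = chi_components(ff, kin, coriolis=cor)
        chi = chi_from_tensors(derived_tensors(ff, kin), coriolis=cor)
        assert np.abs(pot + kinc + cross - chi.chi).max() < 1e-8

    def test_cartesian_reduction_with_coriolis(self):
        # chi_curvilinear with zero kinetic derivatives plus Coriolis must
        # equal the independent combined-form Cartesian transcription
        ff, _, cor = _system(5, kinetic=False, coriolis=True)
        t = derived_tensors(ff, KineticDerivatives.zero(ff.n_modes))
        chi_curv = chi_curvilinear(t)
        from gvpt2.vpt2 import coriolis_chi
        combined = chi_potential_combined(ff.omega, ff.f3, ff.f4, cor)
        assert np.abs(chi_curv.chi + coriolis_chi(ff.omega, cor)
                      - combined).max() < 1e-8
        chi_cart = chi_cartesian(ff, cor)
        assert np.abs(chi_cart.chi - combined).max() < 1e-8


class TestOracleEquivalence:
    @pytest.mark.parametrize("M,potential,kinetic,coriolis", [
        (2, True, False, False), (2, False, True, False), (2, True, True, False),
        (3, True, False, True), (3, True, True, False), (3, False, True, False),
    ])
    def test_transitions_match_sum_over_states(self, M, potential, kinetic,
                                               coriolis):
        rng = np.random.default_rng(11 + M + 2 * potential + 4 * kinetic)
        omega, f3, f4, g1, g2, cor = random_nonresonant_system(
            M, rng, potential=potential, kinetic=kinetic, coriolis=coriolis)
        ff = QuarticForceField(omega, f3, f4)
        kin = KineticDerivatives(g1, g2)
        chi = chi_from_tensors(derived_tensors(ff, kin), coriolis=cor)
        spec = OracleSpec(omega, f3, f4, g1, g2, cor, n_basis=9)
        mats = _oracle(spec)
        states = [tuple(row) for row in np.eye(M, dtype=int)]
        states += [tuple(2 * row) for row in np.eye(M, dtype=int)]
        states += [tuple((np.eye(M, dtype=int)[i] + np.eye(M, dtype=int)[j]))
                   for i in range(M) for j in range(i + 1, M)]
        for st in states:
            assert state_energy(chi, omega, st) == pytest.approx(
                transition_pt2(spec, st, _mats=mats), abs=1e-6)


class TestStateEnergy:
    def test_ground_state_zero(self):
        ff, kin, _ = _system(2)
        chi = chi_from_tensors(derived_tensors(ff, kin))
        assert state_energy(chi, ff.omega, (0, 0, 0)) == 0.0

    def test_fundamental_closed_form(self):
        ff, kin, _ = _system(3)
        chi = chi_from_tensors(derived_tensors(ff, kin))
        k = 1
        expected = (ff.omega[k] + 2 * chi.chi[k, k]
                    + 0.5 * sum(chi.chi[k, j] for j in range(3) if j != k))
        assert state_energy(chi, ff.omega, (0, 1, 0)) == pytest.approx(expected)


class TestResonanceGuard:
    def test_exact_resonance_raises_when_not_deperturbed(self):
        omega = np.array([1000.0, 2000.0])
        f3 = np.zeros((2, 2, 2))
        f3[0, 0, 1] = f3[0, 1, 0] = f3[1, 0, 0] = 25.0
        ff = QuarticForceField(omega, f3, np.zeros((2,) * 4))
        t = derived_tensors(ff, None)
        with pytest.raises(ResonanceBlowupError, match="not\\s+deperturbed"):
            chi_from_tensors(t)
        # explicitly deperturbed: fine
        chi = chi_from_tensors(t, deperturb=[("I", 0, 1)])
        assert np.isfinite(chi.chi).all()


class TestModeRelabeling:
    def test_energies_invariant_under_mode_reordering(self):
        ff, kin, _ = _system(7)
        chi = chi_from_tensors(derived_tensors(ff, kin))
        perm = np.array([2, 0, 1])
        ffp = QuarticForceField(ff.omega[perm],
                                ff.f3[np.ix_(perm, perm, perm)],
                                ff.f4[np.ix_(perm, perm, perm, perm)])
        kinp = KineticDerivatives(kin.g1[np.ix_(perm, perm, perm)],
                                  kin.g2[np.ix_(perm, perm, perm, perm)])
        chip = chi_from_tensors(derived_tensors(ffp, kinp))
        v = (1, 2, 0)
        vp = tuple(np.array(v)[perm])
        assert state_energy(chip, ffp.omega, vp) == pytest.approx(
            state_energy(chi, ff.omega, v), abs=1e-9)


class TestCouplingOrder:
    def test_order3_is_identity(self):
        ff, kin, _ = _system(4)
        ff2, kin2 = restrict_coupling_order(ff, kin, 3)
        assert ff2 is ff and kin2 is kin

    def test_order1_keeps_only_diagonal(self):
        ff, kin, _ = _system(4)
        ff1, kin1 = restrict_coupling_order(ff, kin, 1)
        for i in range(3):
            assert ff1.f3[i, i, i] == ff.f3[i, i, i]
        off = ff1.f3.copy()
        for i in range(3):
            off[i, i, i] = 0.0
        assert not np.any(off)
        assert not np.any(kin1.g1 - np.where(
            np.fromfunction(lambda i, j, k: (i == j) & (j == k), (3, 3, 3)),
            kin.g1, 0.0))

    def test_order1_on_purely_offdiagonal_field_is_harmonic(self):
        omega = np.array([900.0, 1300.0, 3100.0])
        f3 = np.zeros((3,) * 3)
        f3[0, 1, 2] = f3[1, 0, 2] = f3[0, 2, 1] = 5.0
        f3[2, 0, 1] = f3[1, 2, 0] = f3[2, 1, 0] = 5.0
        ff = QuarticForceField(omega, f3, np.zeros((3,) * 4))
        ff1, kin1 = restrict_coupling_order(ff, KineticDerivatives.zero(3), 1)
        chi = chi_from_tensors(derived_tensors(ff1, kin1))
        assert np.abs(chi.chi).max() == 0.0

    def test_curvilinear_two_mode_truncation_tighter_than_cartesian(
            self, water_curvi, water_cart):
        # the coupling-order ladder converges faster in curvilinear
        # coordinates (weaker three-mode couplings)
        def mae(ctx, cor):
            full = chi_from_tensors(derived_tensors(ctx["ff"], ctx["kin"]),
                                    coriolis=cor)
            two, kin2 = restrict_coupling_order(ctx["ff"], ctx["kin"], 2)
            trunc = chi_from_tensors(derived_tensors(two, kin2), coriolis=cor)
            M = ctx["ff"].n_modes
            devs = [abs(state_energy(full, ctx["ff"].omega, tuple(np.eye(M, dtype=int)[k]))
                        - state_energy(trunc, ctx["ff"].omega, tuple(np.eye(M, dtype=int)[k])))
                    for k in range(M)]
            return np.mean(devs)
        assert mae(water_curvi, None) <= mae(water_cart, water_cart["coriolis"]) + 1e-9


class TestSingleMode:
    def test_harmonic_mode_unchanged(self):
        omega = np.array([1000.0, 2500.0])
        ff = QuarticForceField(omega, np.zeros((2,) * 3), np.zeros((2,) * 4))
        kin = KineticDerivatives.zero(2)
        assert single_mode_anharmonic(ff, kin, 0) == pytest.approx(1000.0)

    def test_morse_single_mode_exact(self, morse):
        ff = morse.exact_force_field()
        val = single_mode_anharmonic(ff, KineticDerivatives.zero(1), 0)
        assert val == pytest.approx(morse.exact_fundamental(), abs=1e-9)


class TestCountCouplings:
    def test_planted_counts(self):
        M = 4
        ff = QuarticForceField(np.linspace(800, 3000, M),
                               np.zeros((M,) * 3), np.zeros((M,) * 4))
        f3 = ff.f3
        import itertools
        for p in itertools.permutations((0, 1, 2)):
            f3[p] = 12.0
        for p in itertools.permutations((1, 2, 3)):
            f3[p] = 0.5
        f4 = ff.f4
        for p in set(itertools.permutations((0, 1, 3, 3))):
            f4[p] = 7.0
        g1 = np.zeros((M,) * 3)
        g1[0, 1, 2] = g1[1, 0, 2] = 4.0
        kin = KineticDerivatives(g1, np.zeros((M,) * 4))
        counts = count_couplings(ff, kin, threshold=1.0)
        assert counts["f3_three_mode"] == 1   # the 0.5 one is below threshold
        assert counts["f4_three_mode"] == 1
        assert counts["g1_three_mode"] == 1
        counts0 = count_couplings(ff, kin, threshold=0.0)
        assert counts0["f3_three_mode"] == 2
        huge = count_couplings(ff, kin, threshold=1e9)
        assert all(v == 0 for v in huge.values())


class TestCoriolis:
    def test_zeta_antisymmetric_and_toggle(self, water_cart):
        cor = water_cart["coriolis"]
        assert np.abs(cor.zeta + np.transpose(cor.zeta, (0, 2, 1))).max() < 1e-12
        ff = water_cart["ff"]
        with_c = chi_cartesian(ff, cor, include_coriolis=True)
        without = chi_cartesian(ff, cor, include_coriolis=False)
        # Coriolis must shift at least one fundamental measurably
        M = ff.n_modes
        shifts = [abs(state_energy(with_c, ff.omega, tuple(np.eye(M, dtype=int)[k]))
                      - state_energy(without, ff.omega, tuple(np.eye(M, dtype=int)[k])))
                  for k in range(M)]
        assert max(shifts) > 0.1

    def test_zero_zeta_equals_toggle_off(self, water_cart):
        ff = water_cart["ff"]
        cor0 = CoriolisData(np.zeros_like(water_cart["coriolis"].zeta),
                            water_cart["coriolis"].b_rot)
        a = chi_cartesian(ff, cor0, include_coriolis=True)
        b = chi_cartesian(ff, water_cart["coriolis"], include_coriolis=False)
        assert np.array_equal(a.chi, b.chi)
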