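"""λ-dependent energy models: end-state identities, smoothness, invariances."""

import numpy as np
import pytest

from alchemfe.potentials import (
    AlchemicalLJFluid,
    AlchemicalSystem,
    BodyOrderedModel,
    HarmonicTetherModel,
    LJParams,
    beutler_softcore_lj,
    edge_scaling_factors,
    linear_hamiltonian,
    reduced_potential,
)
from alchemfe.softcore import fit_force_polynomial
from alchemfe.synthetic import analytic_dimer


def _random_system(rng, n=6, n_solute=2, lam=0.5, species=("C", "H")):
    pos = rng.uniform(0, 3.0, (n, 3))
    sp = tuple(species[i % len(species)] for i in range(n))
    return AlchemicalSystem(positions=pos, species=sp,
                           solute=frozenset(range(n_solute)), lam=lam)


class TestEdgeScaling:
    def test_cross_edges_get_lambda(self, rng):
        s = _random_system(rng, lam=0.3)
        alpha = edge_scaling_factors(s, [(0, 3), (1, 5)])  # solute-solvent
        np.testing.assert_array_equal(alpha, [0.3, 0.3])

    def test_internal_edges_get_unity(self, rng):
        s = _random_system(rng, lam=0.3)
        alpha = edge_scaling_factors(s, [(0, 1), (3, 4)])  # within solute / solvent
        np.testing.assert_array_equal(alpha, [1.0, 1.0])

    def test_fully_coupled_state_all_unity(self, rng):
        s = _random_system(rng, lam=1.0)
        edges = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        np.testing.assert_array_equal(edge_scaling_factors(s, edges), np.ones(15))

    def test_invalid_edge_rejected(self, rng):
        s = _random_system(rng)
        with pytest.raises(ValueError):
            edge_scaling_factors(s, [(0, 99)])


class TestBeutlerSoftcore:
    def test_reduces_to_plain_lj_at_full_coupling(self):
        p = LJParams(epsilon=0.7, sigma=1.3)
        r = np.linspace(0.8, 3.0, 50)
        expected = 4 * p.epsilon * ((p.sigma / r) ** 12 - (p.sigma / r) ** 6)
        np.testing.assert_allclose(beutler_softcore_lj(r, 1.0, p), expected, rtol=1e-12)
        assert beutler_softcore_lj(p.sigma, 1.0, p) == pytest.approx(0.0, abs=1e-12)

    def test_vanishes_at_decoupled_state(self):
        p = LJParams(epsilon=2.0, sigma=0.9)
        r = np.linspace(0.0, 3.0, 20)
        np.testing.assert_array_equal(beutler_softcore_lj(r, 0.0, p), np.zeros(20))

    @pytest.mark.parametrize("eps", [1.0, 2.5])
    def test_contact_value_original_constants(self, eps):
        """α_LJ=0.5, n=4, m=2 at λ=0.5, r=0: inner term 0.125 → U = 14ε."""
        p = LJParams(epsilon=eps, sigma=1.0, alpha_lj=0.5, m=2, n=4)
        assert beutler_softcore_lj(0.0, 0.5, p) == pytest.approx(14.0 * eps, rel=1e-12)

    def test_finite_at_contact_for_partial_coupling(self):
        p = LJParams(epsilon=1.0, sigma=1.0)
        for lam in (0.1, 0.5, 0.99):
            assert np.isfinite(beutler_softcore_lj(0.0, lam, p))

    def test_singular_at_contact_when_fully_coupled(self):
        p = LJParams(epsilon=1.0, sigma=1.0)
        with pytest.raises(FloatingPointError):
            beutler_softcore_lj(0.0, 1.0, p)


class TestLinearHamiltonian:
    def test_end_states_exact(self):
        u0, u1 = (lambda x: 2 * x), (lambda x: x**2)
        assert linear_hamiltonian(u0, u1, 0.0)(3.0) == u0(3.0)
        assert linear_hamiltonian(u0, u1, 1.0)(3.0) == u1(3.0)

    def test_degenerate_hamiltonians_lambda_independent(self):
        u = lambda x: np.sin(x)
        for lam in (0.0, 0.3, 0.7, 1.0):
            h = linear_hamiltonian(u, u, lam)
            assert h(1.2) == pytest.approx(u(1.2))
            assert h.dudl(1.2) == pytest.approx(0.0, abs=1e-15)

    def test_harmonic_mixing_matches_pointwise(self):
        """½(λk1 + (1−λ)k0)x² on a grid vs the mixture evaluation."""
        k0, k1, lam = 1.0, 4.0, 0.35
        h = linear_hamiltonian(lambda x: 0.5 * k0 * x**2, lambda x: 0.5 * k1 * x**2, lam)
        x = np.linspace(-2, 2, 41)
        k_mix = lam * k1 + (1 - lam) * k0
        np.testing.assert_allclose([h(v) for v in x], 0.5 * k_mix * x**2, rtol=1e-14)
        np.testing.assert_allclose([h.dudl(v) for v in x], 0.5 * (k1 - k0) * x**2, rtol=1e-14)


class TestReducedPotential:
    def test_zero_energy_nvt(self):
        assert reduced_potential(0.0, 300.0) == 0.0

    def test_kbt_is_unity(self):
        kT = 1.9872e-3 * 298.15
        assert reduced_potential(kT, 298.15) == pytest.approx(1.0, rel=1e-12)

    def test_one_kcal_at_room_temperature(self):
        assert reduced_potential(1.0, 298.15) == pytest.approx(1.6878, abs=2e-4)

    def test_npt_requires_volume(self):
        with pytest.raises(ValueError, match="volume"):
            reduced_potential(1.0, 300.0, pressure=1.0)

    def test_pv_term_added(self):
        u_nvt = reduced_potential(1.0, 300.0)
        u_npt = reduced_potential(1.0, 300.0, pressure=2.0, volume=3.0)
        assert u_npt - u_nvt == pytest.approx(2.0 * 3.0 / (1.9872e-3 * 300.0), rel=1e-10)


@pytest.fixture(scope="module")
def model():
    return BodyOrderedModel.random(species=("C", "H"), cutoff=4.0, seed=7)


class TestBodyOrderedModel:

    def test_decoupled_state_equals_sum_of_components(self, model, rng):
        """At λ=0 the energy factorizes into isolated solute + solvent."""
        for trial in range(3):
            r = np.random.default_rng(100 + trial)
            s = _random_system(r, n=7, n_solute=3, lam=0.0)
            solute_idx = sorted(s.solute)
            solvent_idx = [i for i in range(s.n_atoms) if i not in s.solute]
            sub_solute = AlchemicalSystem(
                positions=s.positions[solute_idx],
                species=tuple(s.species[i] for i in solute_idx),
                solute=frozenset(range(len(solute_idx))), lam=0.0)
            sub_solvent = AlchemicalSystem(
                positions=s.positions[solvent_idx],
                species=tuple(s.species[i] for i in solvent_idx),
                solute=frozenset(), lam=0.0)
            e_total = model.energy(s)
            e_parts = model.energy(sub_solute) + model.energy(sub_solvent)
            assert abs(e_total - e_parts) < 1e-8

    def test_fully_coupled_state_ignores_solute_partition(self, model, rng):
        """At λ=1 the α factors drop out: any solute choice gives the same energy."""
        s = _random_system(rng, n=6, lam=1.0)
        e1 = model.energy(s)
        e2 = model.energy(s.with_(solute=frozenset({0, 4})))
        e3 = model.energy(s.with_(solute=frozenset()))
        assert e1 == pytest.approx(e2, rel=1e-12)
        assert e1 == pytest.approx(e3, rel=1e-12)

    def test_two_atom_energy_matches_hand_expansion(self):
        """Body-order-2 readout on a dimer equals the explicit polynomial in α·φ(r)."""
        model = BodyOrderedModel.random(species=("C", "H"), cutoff=4.0,
                                        body_order=2, n_layers=1, seed=3)
        lam, d = 0.5, 1.7
        s = AlchemicalSystem(positions=[[0, 0, 0], [d, 0, 0]], species=("C", "H"),
                            solute=frozenset({0}), lam=lam)
        # hand expansion: A_0 = α R(d) ⊙ (U h_H), A_1 = α R(d) ⊙ (U h_C)
        R = model._radial_basis(np.array([d]))[0]
        U = model.mix[0]
        w1, w2 = model.readout[0]
        a0 = lam * R * (U @ model.embeddings["H"])
        a1 = lam * R * (U @ model.embeddings["C"])
        expected = (w1 @ a0 + w2 @ a0**2) + (w1 @ a1 + w2 @ a1**2)
        assert model.energy(s) == pytest.approx(expected, rel=1e-12)

    def test_rotation_translation_permutation_invariance(self, model, rng):
        s = _random_system(rng, n=6, lam=0.6)
        e0 = model.energy(s)
        # rotation
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        e_rot = model.energy(s.with_(positions=s.positions @ rot.T))
        # translation
        e_tr = model.energy(s.with_(positions=s.positions + [1.0, -2.0, 0.5]))
        # permutation of two same-species solvent atoms (2 and 4 are both C)
        perm = list(range(6))
        assert s.species[2] == s.species[4]
        perm[2], perm[4] = perm[4], perm[2]
        e_perm = model.energy(s.with_(positions=s.positions[perm],
                                      species=tuple(s.species[i] for i in perm)))
        for e in (e_rot, e_tr, e_perm):
            assert abs(e - e0) <= 1e-10 * max(abs(e0), 1.0)

    def test_energy_smooth_in_lambda(self, model, rng):
        """Finite-difference dE/dλ continuous across a dense λ grid."""
        s = _random_system(rng, n=6, lam=0.5)
        lams = np.linspace(0, 1, 101)
        e = np.array([model.energy(s.with_(lam=l)) for l in lams])
        de = np.diff(e) / np.diff(lams)
        # derivative of a polynomial in λ: successive FD slopes change slowly
        assert np.max(np.abs(np.diff(de))) < 0.05 * (np.max(np.abs(de)) + 1.0)

    def test_forces_match_energy_gradient(self, rng):
        model = BodyOrderedModel.random(species=("C", "H"), cutoff=4.0, seed=11)
        s = _random_system(rng, n=4, lam=0.4)
        f = model.forces(s, h=1e-5)
        h = 1e-4  # independent step for the cross-check
        for i in range(s.n_atoms):
            for k in range(3):
                dp = np.zeros_like(s.positions)
                dp[i, k] = h
                num = -(model.energy(s.with_(positions=s.positions + dp))
                        - model.energy(s.with_(positions=s.positions - dp))) / (2 * h)
                assert f[i, k] == pytest.approx(num, abs=1e-5)

    def test_overlapping_atoms_finite_with_softcore_table(self):
        dimer = analytic_dimer("LJ", pair_label="C-H")
        spec = fit_force_polynomial(dimer.curve, 0.95)
        model = BodyOrderedModel.random(species=("C", "H"), cutoff=4.0, seed=5)
        model.softcore_table = {"C-H": spec}
        s = AlchemicalSystem(positions=[[0, 0, 0], [1e-9, 0, 0]], species=("C", "H"),
                            solute=frozenset({0}), lam=0.5)
        e = model.energy(s)
        assert np.isfinite(e)
        # pair term bounded by the table's contact cap (α = λ < 1 shrinks it)
        body_only = BodyOrderedModel.random(species=("C", "H"), cutoff=4.0, seed=5)
        assert e - body_only.energy(s) <= 0.5 * spec.energy_at_contact + 1e-9

    def test_unknown_species_rejected(self, model, rng):
        s = _random_system(rng, species=("C", "Zr"))
        with pytest.raises(ValueError, match="species"):
            model.energy(s)

    def test_small_box_rejected(self, model, rng):
        s = _random_system(rng).with_(box=np.diag([5.0, 5.0, 5.0]))
        with pytest.raises(ValueError, match="cutoff"):
            model.energy(s)


class TestPairModels:
    def test_lj_fluid_forces_match_gradient(self, rng):
        model = AlchemicalLJFluid(params=LJParams(1.0, 1.0), cutoff=2.3)
        pos = rng.uniform(0, 4.79, (8, 3))
        s = AlchemicalSystem(positions=pos, species=("Xe",) + ("Ar",) * 7,
                            solute=frozenset({0}), lam=0.5,
                            box=np.diag([4.79, 4.79, 4.79]))
        f = model.forces(s)
        h = 1e-6
        for i in (0, 3):
            for k in range(3):
                dp = np.zeros_like(pos)
                dp[i, k] = h
                num = -(model.energy(s.with_(positions=pos + dp))
                        - model.energy(s.with_(positions=pos - dp))) / (2 * h)
                assert f[i, k] == pytest.approx(num, abs=1e-5)

    def test_lj_fluid_end_state_is_plain_lj(self, rng):
        model = AlchemicalLJFluid(params=LJParams(1.0, 1.0), cutoff=2.3)
        pos = rng.uniform(0, 4.79, (6, 3))
        box = np.diag([4.79, 4.79, 4.79])
        s1 = AlchemicalSystem(positions=pos, species=("Ar",) * 6,
                             solute=frozenset({0}), lam=1.0, box=box)
        s_none = AlchemicalSystem(positions=pos, species=("Ar",) * 6,
                                 solute=frozenset(), lam=1.0, box=box)
        assert model.energy(s1) == pytest.approx(model.energy(s_none), rel=1e-12)

    def test_harmonic_tether_dudl(self):
        m = HarmonicTetherModel(k0=1.0, k1=4.0)
        s = AlchemicalSystem(positions=[[1.0, 0, 0]], species=("X",),
                            solute=frozenset({0}), lam=0.25)
        assert m.energy(s) == pytest.approx(0.5 * (0.75 * 1 + 0.25 * 4) * 1.0)
        assert m.dudl(s) == pytest.approx(0.5 * 3.0 * 1.0)
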