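"""Langevin/barostat/replica-exchange samplers against closed-form oracles."""

import numpy as np
import pytest
from scipy.stats import ks_2samp, kstest

from alchemfe.potentials import (
    AlchemicalLJFluid,
    AlchemicalSystem,
    HarmonicTetherModel,
    IdealGasModel,
    LJParams,
)
from alchemfe.sampling import (
    MCBarostat,
    Replica,
    ReplicaEnsemble,
    ThermoState,
    langevin_step,
    mc_barostat_move,
    minimize,
    replica_exchange_sweep,
    run_md,
    swap_acceptance_probability,
    transition_probability_matrix,
)


def _particle(lam=1.0, x=(0.0, 0.0, 0.0)):
    return AlchemicalSystem(positions=[list(x)], species=("X",),
                           solute=frozenset({0}), lam=lam)


class TestLangevin:
    def test_harmonic_equipartition(self):
        """⟨x²⟩ = kBT/k for a 1D-projected harmonic well within 3 SE."""
        model = HarmonicTetherModel(k0=2.0, k1=2.0)
        state = ThermoState(temperature=1.5, lam=1.0, kB=1.0)
        rng = np.random.default_rng(5)
        s = _particle()
        s = run_md(s, model, state, 2_000, dt=0.05, friction=1.0, rng=rng)  # burn-in
        xs = []
        for _ in range(8_000):
            s, _ = langevin_step(s, model, 0.05, 1.0, state, rng)
            xs.append(s.positions[0, 0])
        xs = np.asarray(xs)
        expected = state.kB * state.temperature / 2.0
        # crude SE accounting for autocorrelation (τ ≈ 1/(k dt) steps)
        n_eff = len(xs) / 50
        se = expected * np.sqrt(2.0 / n_eff)
        assert np.var(xs) == pytest.approx(expected, abs=3 * se)

    def test_zero_temperature_is_damped_descent(self):
        """No noise, zero initial velocity: energy monotonically non-increasing."""
        model = HarmonicTetherModel(k0=1.0, k1=1.0)
        state = ThermoState(temperature=1e-12, lam=1.0, kB=1.0)
        rng = np.random.default_rng(0)
        s = _particle(x=(2.0, 0, 0)).with_(velocities=np.zeros((1, 3)))
        energies = [model.energy(s)]
        for _ in range(200):
            s, _ = langevin_step(s, model, 0.05, 2.0, state, rng)
            energies.append(model.energy(s))
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-12)

    def test_infinite_friction_decorrelates_velocity(self):
        """γdt ≫ 1: the O-step replaces velocity with fresh thermal noise."""
        model = HarmonicTetherModel(k0=1.0, k1=1.0)
        state = ThermoState(temperature=1.0, lam=1.0, kB=1.0)
        rng = np.random.default_rng(1)
        s = _particle().with_(velocities=np.full((1, 3), 10.0))
        s, _ = langevin_step(s, model, 1e-4, 1e8, state, rng)
        # memory of the huge initial velocity is gone after one step
        assert np.all(np.abs(s.velocities) < 6.0)

    def test_nonfinite_force_reported(self):
        class BadModel:
            def forces(self, s):
                return np.full_like(s.positions, np.nan)
            def energy(self, s):
                return 0.0
        with pytest.raises(FloatingPointError, match="atom"):
            langevin_step(_particle(), BadModel(), 0.01, 1.0,
                          ThermoState(1.0, 1.0, kB=1.0), np.random.default_rng(0))


class TestBarostat:
    def _gas(self, n=40, L=10.0):
        rng = np.random.default_rng(3)
        return AlchemicalSystem(positions=rng.uniform(0, L, (n, 3)),
                               species=("Ar",) * n, solute=frozenset(), lam=1.0,
                               box=np.diag([L, L, L]))

    def test_ideal_gas_density(self):
        """MC barostat on an ideal gas: ⟨ρ⟩ → p/kBT within 3 SE."""
        state = ThermoState(temperature=2.0, lam=1.0, pressure=0.5, kB=1.0)
        model = IdealGasModel()
        s = self._gas()
        rng = np.random.default_rng(11)
        bar = MCBarostat(max_dV=60.0)
        dens = []
        for i in range(6_000):
            s = bar.attempt(s, model, state, rng)
            if i > 1_000:
                dens.append(s.n_atoms / s.volume)
        dens = np.asarray(dens)
        expected = state.pressure / (state.kB * state.temperature)
        n_eff = len(dens) / 100  # volume moves are strongly correlated
        se = np.std(dens) / np.sqrt(n_eff)
        assert np.mean(dens) == pytest.approx(expected, abs=3 * se)

    def test_zero_volume_proposal_always_accepted(self):
        state = ThermoState(temperature=1.0, lam=1.0, pressure=1.0, kB=1.0)
        s = self._gas()
        for seed in range(5):
            out, accepted = mc_barostat_move(s, IdealGasModel(), state,
                                             np.random.default_rng(seed), max_dV=1e-14)
            assert accepted

    def test_tuner_steers_toward_target_acceptance(self):
        state = ThermoState(temperature=1.0, lam=1.0, pressure=1.0, kB=1.0)
        s = self._gas()
        bar = MCBarostat(max_dV=500.0, tune_interval=50)  # absurdly large proposals
        rng = np.random.default_rng(7)
        for _ in range(2_000):
            s = bar.attempt(s, IdealGasModel(), state, rng)
        window = bar.n_accepted / bar.n_attempted
        assert 0.15 < window < 0.75
        assert bar.max_dV < 500.0

    def test_non_periodic_rejected(self):
        state = ThermoState(temperature=1.0, lam=1.0, pressure=1.0, kB=1.0)
        with pytest.raises(ValueError, match="periodic"):
            mc_barostat_move(_particle(), IdealGasModel(), state,
                             np.random.default_rng(0), 1.0)


class TestMinimize:
    def test_already_at_minimum_returns_immediately(self):
        model = HarmonicTetherModel(k0=3.0, k1=3.0)
        res = minimize(_particle(), model)
        assert res.converged and res.energy == pytest.approx(0.0, abs=1e-12)
        assert res.n_iter == 0

    def test_perturbed_lj_dimer_converges_to_sigma_min(self):
        model = AlchemicalLJFluid(params=LJParams(1.0, 1.0), cutoff=3.0)
        s = AlchemicalSystem(positions=[[0, 0, 0], [1.4, 0.1, -0.05]],
                            species=("Ar", "Ar"), solute=frozenset(), lam=1.0)
        res = minimize(s, model, gtol=1e-8)
        d = np.linalg.norm(res.system.positions[1] - res.system.positions[0])
        assert d == pytest.approx(2 ** (1 / 6), abs=1e-4)

    def test_overlapping_softcore_pair_stays_finite(self):
        """Beutler coupling at λ=0.5 keeps an overlapping pair minimizable."""
        model = AlchemicalLJFluid(params=LJParams(1.0, 1.0), cutoff=3.0)
        s = AlchemicalSystem(positions=[[0, 0, 0], [0.05, 0, 0]],
                            species=("Xe", "Ar"), solute=frozenset({0}), lam=0.5)
        res = minimize(s, model)
        assert np.isfinite(res.energy)
        assert res.energy <= res.initial_energy


def _harmonic_ensemble(k_values, temperature=1.0, seed=0, x0=0.5):
    """K replicas of a 1-particle harmonic model; λ linearly interpolates k."""
    K = len(k_values)
    lams = np.linspace(0, 1, K)
    model = HarmonicTetherModel(k0=k_values[0], k1=k_values[-1])
    states = [ThermoState(temperature=temperature, lam=float(l), kB=1.0) for l in lams]
    ss = np.random.SeedSequence(seed).spawn(K)
    replicas = [
        Replica(system=_particle(lam=float(lams[k]), x=(x0, 0, 0)), state_index=k,
                rng=np.random.default_rng(ss[k]))
        for k in range(K)
    ]
    return ReplicaEnsemble(replicas=replicas, states=states), model


class TestReplicaExchange:
    def test_identical_states_always_accept(self):
        ensemble, model = _harmonic_ensemble([2.0, 2.0])
        replica_exchange_sweep(ensemble, model, np.random.default_rng(0), n_attempts=50)
        assert all(rec[3] for rec in ensemble.swap_records)

    def test_acceptance_matches_hand_computed_metropolis(self):
        """Two harmonic states at fixed positions: Δ evaluated by hand."""
        k0, k1, T = 1.0, 4.0, 1.0
        x_i, x_j = 0.8, 1.3
        ensemble, model = _harmonic_ensemble([k0, k1], temperature=T)
        ensemble.replicas[0].system = _particle(lam=0.0, x=(x_i, 0, 0))
        ensemble.replicas[1].system = _particle(lam=1.0, x=(x_j, 0, 0))
        delta = 0.5 * (k0 * x_j**2 + k1 * x_i**2 - k0 * x_i**2 - k1 * x_j**2) / T
        p_hand = min(1.0, np.exp(-delta))
        assert swap_acceptance_probability(delta) == pytest.approx(p_hand, rel=1e-12)
        # empirical acceptance over many single attempts from the same layout
        n_acc = 0
        trials = 4_000
        for seed in range(trials):
            ens, _ = _harmonic_ensemble([k0, k1], temperature=T)
            ens.replicas[0].system = _particle(lam=0.0, x=(x_i, 0, 0))
            ens.replicas[1].system = _particle(lam=1.0, x=(x_j, 0, 0))
            replica_exchange_sweep(ens, model, np.random.default_rng(10_000 + seed),
                                   n_attempts=1)
            n_acc += ens.swap_records[0][3]
        se = np.sqrt(p_hand * (1 - p_hand) / trials)
        assert n_acc / trials == pytest.approx(p_hand, abs=max(4 * se, 0.02))

    def test_detailed_balance_of_swap_flux(self):
        """On a long 2-replica run, i→j and j→i swap counts balance."""
        ensemble, model = _harmonic_ensemble([1.0, 3.0], seed=4)
        state = ThermoState(temperature=1.0, lam=0.0, kB=1.0)
        for it in range(600):
            for rep in ensemble.replicas:
                st = ensemble.states[rep.state_index]
                rep.system = run_md(rep.system, model, st, 10, 0.05, 1.0, rep.rng)
            replica_exchange_sweep(ensemble, model, np.random.default_rng(900 + it),
                                   n_attempts=1)
        # flux balance: replica 0 moves up as often as it moves down (within noise)
        hist = np.array(ensemble.index_history)
        ups = np.sum((hist[1:, 0] == 1) & (hist[:-1, 0] == 0))
        downs = np.sum((hist[1:, 0] == 0) & (hist[:-1, 0] == 1))
        assert abs(ups - downs) <= 1  # alternating occupancy forces near-exact balance
        total = ups + downs
        assert total > 50  # the run actually mixed

    def test_remd_leaves_identical_marginals_unchanged(self):
        """All states identical: swapping must not perturb the sampled marginal."""
        def run(n_attempts):
            ensemble, model = _harmonic_ensemble([2.0, 2.0], seed=9)
            xs = []
            for it in range(400):
                for rep in ensemble.replicas:
                    st = ensemble.states[rep.state_index]
                    rep.system = run_md(rep.system, model, st, 5, 0.08, 1.0, rep.rng)
                if n_attempts:
                    replica_exchange_sweep(ensemble, model,
                                           np.random.default_rng(it), n_attempts)
                xs.append(ensemble.replicas[0].system.positions[0, 0])
            return np.asarray(xs[100:])
        with_swaps = run(4)
        no_swaps = run(0)
        assert ks_2samp(with_swaps, no_swaps).pvalue > 0.01

    def test_two_replica_marginals_match_analytic_gaussians(self):
        """REMD-sampled positions per window follow N(0, kBT/k)."""
        ensemble, model = _harmonic_ensemble([1.0, 4.0], seed=12)
        samples = {0: [], 1: []}
        for it in range(1_500):
            for rep in ensemble.replicas:
                st = ensemble.states[rep.state_index]
                rep.system = run_md(rep.system, model, st, 5, 0.05, 1.0, rep.rng)
            for rep in ensemble.replicas:
                samples[rep.state_index].append(rep.system.positions[0, 0])
            replica_exchange_sweep(ensemble, model, np.random.default_rng(5_000 + it),
                                   n_attempts=2)
        for k, kk in ((0, 1.0), (1, 4.0)):
            x = np.asarray(samples[k][200:])[::10]  # decorrelate
            sd = np.sqrt(1.0 / kk)
            assert kstest(x, "norm", args=(0, sd)).pvalue > 0.01


class TestTransitionMatrix:
    def test_no_swaps_gives_identity(self):
        ensemble, model = _harmonic_ensemble([1.0, 2.0, 4.0, 8.0][:4])
        for _ in range(10):
            ensemble.record_iteration()
        T = transition_probability_matrix(ensemble)
        np.testing.assert_array_equal(T, np.eye(4))

    def test_alternating_pattern_matches_hand_count(self):
        """Force a known swap sequence and count transitions by hand."""
        ensemble, _ = _harmonic_ensemble([1.0, 2.0])
        # manual bookkeeping: swap every iteration → indices alternate
        for it in range(6):
            r0, r1 = ensemble.replicas
            r0.state_index, r1.state_index = r1.state_index, r0.state_index
            ensemble.record_iteration()
        T = transition_probability_matrix(ensemble)
        # every recorded transition is a flip
        np.testing.assert_allclose(T, [[0, 1], [1, 0]], atol=1e-12)

    def test_rows_sum_to_one(self):
        ensemble, model = _harmonic_ensemble([1.0, 2.0, 4.0])
        rng = np.random.default_rng(2)
        for _ in range(30):
            replica_exchange_sweep(ensemble, model, rng, n_attempts=3)
        T = transition_probability_matrix(ensemble)
        np.testing.assert_allclose(T.sum(axis=1), 1.0, atol=1e-12)
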