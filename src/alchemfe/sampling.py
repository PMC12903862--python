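"""Equilibrium sampling per λ window.

Langevin dynamics (BAOAB splitting — accurate configurational sampling
at finite time step), an isotropic Monte Carlo barostat, L-BFGS energy
minimization, and Hamiltonian replica exchange across a λ schedule with
full swap bookkeeping.

Replica-exchange bookkeeping swaps *thermodynamic states* (the λ label
and its ThermoState) between replicas rather than coordinates: the two
are statistically identical and state swaps are free.  Each replica owns
an independent seeded random stream, so results are reproducible
regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize as _scipy_minimize

from .potentials import AlchemicalSystem, reduced_potential
from .units import KB_KCAL_MOL_K

__all__ = [
    "ThermoState",
    "Replica",
    "ReplicaEnsemble",
    "langevin_step",
    "mc_barostat_move",
    "MCBarostat",
    "minimize",
    "MinimizeResult",
    "replica_exchange_sweep",
    "transition_probability_matrix",
]


@dataclass(frozen=True)
class ThermoState:
    """Thermodynamic state of one window: T, optional p (NPT), and λ.

    ``kB`` selects the unit system (kcal/mol/K by default; pass 1.0 for
    reduced units).
    """

    temperature: float
    lam: float
    pressure: float | None = None
    kB: float = KB_KCAL_MOL_K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    @property
    def beta(self) -> float:
        return 1.0 / (self.kB * self.temperature)

    def reduced_u(self, energy: float, volume: float | None) -> float:
        return reduced_potential(
            energy, self.temperature, pressure=self.pressure, volume=volume, kB=self.kB
        )


def _masses(system: AlchemicalSystem) -> np.ndarray:
    if system.masses is not None:
        return system.masses
    return np.ones(system.n_atoms)


def _ensure_velocities(system: AlchemicalSystem, state: ThermoState, rng: np.random.Generator):
    if system.velocities is not None:
        return system
    m = _masses(system)
    sigma = np.sqrt(state.kB * state.temperature / m)[:, None]
    return system.with_(velocities=rng.normal(size=(system.n_atoms, 3)) * sigma)


def langevin_step(
    system: AlchemicalSystem,
    model,
    dt: float,
    friction: float,
    state: ThermoState,
    rng: np.random.Generator,
    forces: np.ndarray | None = None,
) -> tuple[AlchemicalSystem, np.ndarray]:
    """One BAOAB Langevin update; returns (new system, forces at new positions).

    Deterministic given the rng stream.  Velocities are drawn from the
    Maxwell–Boltzmann distribution on first use.  Passing the previous
    step's forces avoids one model evaluation per step.
    """
    system = _ensure_velocities(system, state, rng)
    m = _masses(system)[:, None]
    if forces is None:
        forces = model.forces(system)
    if not np.all(np.isfinite(forces)):
        bad = np.where(~np.isfinite(forces).all(axis=1))[0]
        raise FloatingPointError(f"non-finite force on atoms {bad.tolist()}")
    v = system.velocities + 0.5 * dt * forces / m  # B
    x = system.positions + 0.5 * dt * v  # A
    if friction > 0:  # O
        c1 = np.exp(-friction * dt)
        c2 = np.sqrt(state.kB * state.temperature / m.squeeze(-1))[:, None] * np.sqrt(1.0 - c1**2)
        v = c1 * v + c2 * rng.normal(size=v.shape)
    x = x + 0.5 * dt * v  # A
    trial = system.with_(positions=x, velocities=v)
    f_new = model.forces(trial)
    if not np.all(np.isfinite(f_new)):
        _, _, r = trial.pair_displacements()
        raise FloatingPointError(
            f"non-finite force after step; closest pair distance {np.min(r):.4g}"
        )
    v = v + 0.5 * dt * f_new / m  # B
    return trial.with_(velocities=v), f_new


def run_md(
    system: AlchemicalSystem,
    model,
    state: ThermoState,
    n_steps: int,
    dt: float,
    friction: float,
    rng: np.random.Generator,
) -> AlchemicalSystem:
    """Convenience loop over :func:`langevin_step`, reusing forces."""
    f = model.forces(system)
    for _ in range(n_steps):
        system, f = langevin_step(system, model, dt, friction, state, rng, forces=f)
    return system


def mc_barostat_move(
    system: AlchemicalSystem,
    model,
    state: ThermoState,
    rng: np.random.Generator,
    max_dV: float,
) -> tuple[AlchemicalSystem, bool]:
    """One isotropic volume move of the Monte Carlo barostat.

    Proposes ΔV ~ U(−max_dV, max_dV), scales the box and coordinates by
    (V'/V)^{1/3}, and accepts with the Metropolis weight
    exp(−[Δu + p ΔV − N kBT ln(V'/V)] / kBT).
    """
    if system.box is None:
        raise ValueError("MC barostat requires a periodic system")
    if state.pressure is None:
        raise ValueError("MC barostat requires a pressure in the thermodynamic state")
    V = system.volume
    dV = rng.uniform(-max_dV, max_dV)
    V_new = V + dV
    if V_new <= 0:
        return system, False
    s = (V_new / V) ** (1.0 / 3.0)
    trial = system.with_(positions=system.positions * s, box=system.box * s)
    du = model.energy(trial) - model.energy(system)
    n = system.n_atoms
    arg = -(du + state.pressure * dV - n * state.kB * state.temperature * np.log(V_new / V)) * state.beta
    if arg >= 0 or rng.random() < np.exp(arg):
        return trial, True
    return system, False


@dataclass
class MCBarostat:
    """Barostat with acceptance-driven tuning of the volume-move size.

    The proposal width is nudged toward a ~40% acceptance fraction,
    re-evaluated every ``tune_interval`` attempts and kept within
    [min_frac, max_frac] of the current volume.
    """

    max_dV: float
    interval: int = 25  # MD steps between volume attempts
    tune_interval: int = 50
    target_acceptance: float = 0.4
    n_attempted: int = 0
    n_accepted: int = 0
    _window_attempted: int = 0
    _window_accepted: int = 0

    def attempt(self, system, model, state, rng) -> AlchemicalSystem:
        system, accepted = mc_barostat_move(system, model, state, rng, self.max_dV)
        self.n_attempted += 1
        self.n_accepted += accepted
        self._window_attempted += 1
        self._window_accepted += accepted
        if self._window_attempted >= self.tune_interval:
            frac = self._window_accepted / self._window_attempted
            if frac > self.target_acceptance + 0.1:
                self.max_dV *= 1.1
            elif frac < self.target_acceptance - 0.1:
                self.max_dV *= 0.9
            vol = system.volume
            self.max_dV = float(np.clip(self.max_dV, 1e-4 * vol, 0.3 * vol))
            self._window_attempted = self._window_accepted = 0
        return system

    @property
    def acceptance_fraction(self) -> float:
        return self.n_accepted / max(self.n_attempted, 1)


@dataclass
class MinimizeResult:
    system: AlchemicalSystem
    energy: float
    initial_energy: float
    grad_max: float
    converged: bool
    n_iter: int


def minimize(system: AlchemicalSystem, model, gtol: float = 1e-4, max_iter: int = 1000,
             dr_max: float = 0.1) -> MinimizeResult:
    """Energy minimization: capped steepest descent, then L-BFGS polish.

    Steep pair-potential walls defeat generic line searches (a trial step
    can push atoms through each other), so the first stage takes
    backtracking descent steps with per-atom displacements capped at
    ``dr_max``; once the landscape is tame, L-BFGS finishes to ``gtol``.
    The final energy never exceeds the initial one; hitting ``max_iter``
    returns the best configuration found, flagged unconverged.
    """
    x = system.positions.ravel().copy()
    e = model.energy(system)
    e0 = e
    if not np.isfinite(e0):
        raise ValueError("starting energy is not finite")

    def fun(xv):
        s = system.with_(positions=xv.reshape(-1, 3))
        return model.energy(s), -model.forces(s).ravel()

    # stage 1: robust descent with displacement cap
    n_desc = 0
    step = dr_max
    for _ in range(max_iter):
        _, g = fun(x)
        gmax = float(np.max(np.abs(g)))
        if gmax <= gtol:
            break
        direction = -g / gmax  # per-component displacement <= 1
        improved = False
        while step > 1e-12:
            e_try = fun(x + step * direction)[0]
            if np.isfinite(e_try) and e_try < e:
                x = x + step * direction
                e = e_try
                step = min(step * 1.5, dr_max)
                improved = True
                break
            step *= 0.5
        n_desc += 1
        if not improved:
            break

    # stage 2: quasi-Newton polish from the tamed configuration
    res = _scipy_minimize(fun, x, jac=True, method="L-BFGS-B",
                          options={"gtol": gtol, "maxiter": max_iter, "maxls": 60})
    if np.isfinite(res.fun) and res.fun <= e:
        x, e = res.x, float(res.fun)
    out = system.with_(positions=x.reshape(-1, 3))
    gmax = float(np.max(np.abs(model.forces(out))))
    return MinimizeResult(
        system=out,
        energy=e,
        initial_energy=e0,
        grad_max=gmax,
        converged=bool(gmax <= gtol),
        n_iter=n_desc + int(res.nit),
    )


# ---------------------------------------------------------------------------
# replica exchange
# ---------------------------------------------------------------------------


@dataclass
class Replica:
    system: AlchemicalSystem
    state_index: int  # slot in the λ schedule this replica currently samples
    rng: np.random.Generator


@dataclass
class ReplicaEnsemble:
    """K replicas spanning a λ schedule, with swap bookkeeping.

    ``index_history`` records each replica's λ-slot after every sweep;
    ``swap_records`` logs every attempted neighbor exchange as
    (iteration, state_i, state_j, accepted).
    """

    replicas: list[Replica]
    states: list[ThermoState]  # one per λ-schedule slot, fixed order
    swap_records: list[tuple[int, int, int, bool]] = field(default_factory=list)
    index_history: list[list[int]] = field(default_factory=list)
    iteration: int = 0

    def __post_init__(self) -> None:
        lams = [s.lam for s in self.states]
        if len(self.replicas) != len(self.states):
            raise ValueError("one replica per schedule slot required")
        if not np.all(np.diff(lams) > 0):
            raise ValueError("λ schedule must be strictly increasing")
        if abs(lams[0]) > 1e-12 or abs(lams[-1] - 1.0) > 1e-12:
            raise ValueError("λ schedule must span 0 and 1")
        self._sync_lambdas()

    def _sync_lambdas(self) -> None:
        for rep in self.replicas:
            lam = self.states[rep.state_index].lam
            if rep.system.lam != lam:
                rep.system = rep.system.with_(lam=lam)

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def replica_holding(self, state_index: int) -> Replica:
        for rep in self.replicas:
            if rep.state_index == state_index:
                return rep
        raise KeyError(state_index)

    def record_iteration(self) -> None:
        self.index_history.append([r.state_index for r in self.replicas])
        self.iteration += 1


def replica_exchange_sweep(
    ensemble: ReplicaEnsemble,
    model,
    rng: np.random.Generator,
    n_attempts: int | None = None,
) -> ReplicaEnsemble:
    """Attempt randomized adjacent-window state swaps.

    For the pair of replicas currently holding neighboring λ slots
    (k, k+1), the exchange is accepted with probability min(1, e^{−Δ}),

        Δ = [u*_k(x_j) + u*_{k+1}(x_i)] − [u*_k(x_i) + u*_{k+1}(x_j)],

    with u* the reduced potential of each state evaluated on each
    configuration.  Many randomized neighbor attempts per sweep
    (default K²) approximate all-pair mixing while keeping every
    individual move a nearest-neighbor exchange.
    """
    K = ensemble.n_replicas
    if n_attempts is None:
        n_attempts = K * K
    for _ in range(n_attempts):
        k = int(rng.integers(0, K - 1))
        rep_i = ensemble.replica_holding(k)
        rep_j = ensemble.replica_holding(k + 1)
        si, sj = ensemble.states[k], ensemble.states[k + 1]
        e_i, v_i = model.energy(rep_i.system), rep_i.system.volume
        e_j, v_j = model.energy(rep_j.system), rep_j.system.volume
        # cross terms: each state's Hamiltonian on the other's configuration
        e_i_at_j = model.energy_at(rep_j.system, si.lam)
        e_j_at_i = model.energy_at(rep_i.system, sj.lam)
        delta = (
            si.reduced_u(e_i_at_j, v_j)
            + sj.reduced_u(e_j_at_i, v_i)
            - si.reduced_u(e_i, v_i)
            - sj.reduced_u(e_j, v_j)
        )
        accepted = delta <= 0 or rng.random() < np.exp(-delta)
        if accepted:
            rep_i.state_index, rep_j.state_index = rep_j.state_index, rep_i.state_index
            rep_i.system = rep_i.system.with_(lam=sj.lam)
            rep_j.system = rep_j.system.with_(lam=si.lam)
        ensemble.swap_records.append((ensemble.iteration, k, k + 1, bool(accepted)))
    ensemble.record_iteration()
    return ensemble


def swap_acceptance_probability(delta: float) -> float:
    """Metropolis acceptance min(1, e^{−Δ}) for a proposed state swap."""
    return float(min(1.0, np.exp(-delta)))


def transition_probability_matrix(ensemble: ReplicaEnsemble) -> np.ndarray:
    """Empirical K×K row-stochastic matrix of λ-slot transitions.

    Entry (a, b) is the frequency with which a replica sitting in slot a
    at one recorded iteration sits in slot b at the next.  With no
    accepted swaps this is the identity; good mixing shows a strong
    tridiagonal band.
    """
    K = ensemble.n_replicas
    hist = ensemble.index_history
    if len(hist) < 1:
        raise ValueError("no recorded sweeps")
    counts = np.zeros((K, K))
    for prev, cur in zip(hist[:-1], hist[1:]):
        for a, b in zip(prev, cur):
            counts[a, b] += 1
    # the first recorded iteration transitions from the initial identity layout
    if len(hist) >= 1:
        for a, b in zip(range(K), hist[0]):
            counts[a, b] += 1
    T = np.zeros_like(counts)
    for k in range(K):
        row = counts[k]
        T[k] = row / row.sum() if row.sum() > 0 else np.eye(K)[k]
    return T
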