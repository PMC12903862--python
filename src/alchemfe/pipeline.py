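"""End-to-end solvation free-energy and log P workflows.

A leg runs build → minimize → equilibrate → Hamiltonian replica
exchange over the λ schedule → per-window equilibration detection and
decorrelation → MBAR → report.  Everything is driven by a validated
:class:`RunConfig` and a single master seed that fans out
deterministically to per-replica streams, so a leg is exactly
reproducible from its config.

The default protocol constants mirror a standard condensed-phase
replica-exchange setup — 16 λ windows, swap attempts every 1000 MD
steps, Langevin dynamics, optional Monte Carlo barostat, a 50 000-step
NPT equilibration at full coupling — and every one is configurable.
Shipped system kinds are the synthetic fixtures (LJ fluid, tethered
harmonic particle, ideal gas) plus coordinate-file input for the
body-ordered model.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import io as afio
from .estimators import (
    FreeEnergyResult,
    ReducedPotentialMatrix,
    detect_equilibration,
    log_p,
    mbar_estimate,
    read_ukn,
    subsample_indices,
    write_ukn,
)
from .potentials import (
    AlchemicalLJFluid,
    AlchemicalSystem,
    BodyOrderedModel,
    HarmonicTetherModel,
    IdealGasModel,
    LJParams,
)
from .sampling import (
    MCBarostat,
    Replica,
    ReplicaEnsemble,
    ThermoState,
    minimize,
    replica_exchange_sweep,
    run_md,
    transition_probability_matrix,
)
from .units import KB_KCAL_MOL_K, LN10

logger = logging.getLogger("alchemfe")

__all__ = [
    "ConfigError",
    "RunConfig",
    "SolvationReport",
    "build_box",
    "default_lambda_schedule",
    "run_solvation_leg",
    "run_logp",
    "reestimate_from_archive",
]


class ConfigError(ValueError):
    """Raised with every validation violation listed at once."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid run configuration:\n  - " + "\n  - ".join(problems))


def default_lambda_schedule(K: int = 16) -> np.ndarray:
    """Monotone λ schedule from 0 to 1 concentrating windows in [0.15, 0.4].

    Roughly half of the windows sit inside [0.15, 0.4], where the
    curvature of ⟨∂H/∂λ⟩ is typically largest for decoupling
    transformations; the endpoints are exact.
    """
    if K < 4:
        raise ValueError("need at least 4 windows")
    n_mid = K // 2
    n_lo = max(1, round((K - n_mid) * 0.4))
    n_hi = K - n_mid - n_lo
    lo = np.linspace(0.0, 0.15, n_lo, endpoint=False)
    mid = np.linspace(0.15, 0.4, n_mid, endpoint=False)
    hi = np.linspace(0.4, 1.0, n_hi + 1)[1:] if n_hi > 0 else np.array([])
    sched = np.concatenate([lo, mid, hi])
    sched[-1] = 1.0
    if sched.size != K:
        sched = np.unique(np.concatenate([sched, [0.0, 1.0]]))[:K]
        sched[-1] = 1.0
    assert np.all(np.diff(sched) > 0)
    return sched


@dataclass
class FluidSpec:
    """Synthetic cubic fluid: solvent on a jittered lattice around a solute."""

    n_solvent: int
    density: float  # particles per volume, counting the solute
    n_solute: int = 1
    solvent_species: str = "Ar"
    solute_species: str = "Xe"
    jitter: float = 0.1  # fraction of the lattice spacing
    min_separation: float = 0.7  # build fails if any pair is closer


def build_box(spec: FluidSpec, seed: int, cutoff: float | None = None,
              lam: float = 1.0) -> AlchemicalSystem:
    """Cubic periodic box with the solute at the center.

    The box side is ((n_solvent + n_solute)/density)^{1/3}; solvent sits
    on a jittered cubic lattice.  Deterministic for a fixed seed.  Fails
    if the requested density forces pairs below ``min_separation`` (the
    softcore range) or the box violates the minimum-image constraint for
    the supplied cutoff.
    """
    n_total = spec.n_solvent + spec.n_solute
    L = (n_total / spec.density) ** (1.0 / 3.0)
    if cutoff is not None and L < 2.0 * cutoff:
        raise ConfigError(
            [f"box side {L:.4g} < 2×cutoff {2 * cutoff:.4g}: lower the density, "
             "particle count, or cutoff"]
        )
    rng = np.random.default_rng(seed)
    n_side = int(np.ceil(n_total ** (1.0 / 3.0)))
    spacing = L / n_side
    sites = np.array(
        [[i, j, k] for i in range(n_side) for j in range(n_side) for k in range(n_side)],
        dtype=float,
    )
    sites = (sites + 0.5) * spacing
    # solute takes the site closest to the box center
    center = np.full(3, L / 2.0)
    order = np.argsort(np.linalg.norm(sites - center, axis=1))
    chosen = sites[order[:n_total]].copy()
    chosen += rng.uniform(-spec.jitter, spec.jitter, chosen.shape) * spacing
    positions = np.concatenate([chosen[: spec.n_solute], chosen[spec.n_solute :]])
    species = (spec.solute_species,) * spec.n_solute + (spec.solvent_species,) * spec.n_solvent
    system = AlchemicalSystem(
        positions=positions,
        species=species,
        solute=frozenset(range(spec.n_solute)),
        lam=lam,
        box=np.diag([L, L, L]),
    )
    _, _, r = system.pair_displacements()
    if np.min(r) < spec.min_separation:
        raise ConfigError(
            [f"density {spec.density:.4g} too high: closest pair "
             f"{np.min(r):.4g} < min_separation {spec.min_separation:.4g}"]
        )
    return system


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_SYSTEM_KINDS = ("lj_fluid", "harmonic", "ideal_gas", "xyz")


@dataclass
class RunConfig:
    """Validated configuration of one solvation leg."""

    system: dict[str, Any]
    thermo: dict[str, Any]
    sampler: dict[str, Any]
    lambda_schedule: np.ndarray
    output_dir: Path
    seed: int
    write_trajectories: bool = False

    DEFAULT_SAMPLER = {
        "dt": 0.002,
        "friction": 1.0,
        "steps_per_iteration": 1000,  # swap attempt interval (1 ps at 1 fs steps)
        "n_iterations": 50,
        "equilibration_steps": 2000,
        "barostat": False,
        "barostat_interval": 25,
        "minimize": True,
        "swap_attempts": None,  # default K² inside the sweep
    }

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base_dir: Path | None = None) -> "RunConfig":
        problems: list[str] = []
        system = dict(raw.get("system") or {})
        kind = system.get("kind")
        if kind not in _SYSTEM_KINDS:
            problems.append(f"system.kind must be one of {_SYSTEM_KINDS}, got {kind!r}")
        thermo = dict(raw.get("thermo") or {})
        T = thermo.get("temperature")
        if not (isinstance(T, (int, float)) and T > 0):
            problems.append("thermo.temperature must be a positive number")
        thermo.setdefault("pressure", None)
        thermo.setdefault("kB", KB_KCAL_MOL_K)
        sampler = {**cls.DEFAULT_SAMPLER, **(raw.get("sampler") or {})}
        for key in ("dt", "friction"):
            if not (isinstance(sampler.get(key), (int, float)) and sampler[key] > 0):
                problems.append(f"sampler.{key} must be a positive number")
        for key in ("steps_per_iteration", "n_iterations"):
            if not (isinstance(sampler.get(key), int) and sampler[key] >= 1):
                problems.append(f"sampler.{key} must be an integer >= 1")
        if sampler.get("barostat") and thermo.get("pressure") is None:
            problems.append("sampler.barostat requires thermo.pressure")
        sched_raw = raw.get("lambda_schedule", {"preset": "default", "K": 16})
        if isinstance(sched_raw, dict):
            try:
                schedule = default_lambda_schedule(int(sched_raw.get("K", 16)))
            except ValueError as exc:
                problems.append(str(exc))
                schedule = default_lambda_schedule(16)
        else:
            schedule = np.asarray(sched_raw, dtype=float)
            if schedule.size < 2 or not np.all(np.diff(schedule) > 0):
                problems.append("lambda_schedule must be strictly increasing")
            elif abs(schedule[0]) > 1e-12 or abs(schedule[-1] - 1) > 1e-12:
                problems.append("lambda_schedule must include 0 and 1")
        out = raw.get("output_dir")
        if not out:
            problems.append("output_dir is required")
            out = "."
        out_path = Path(out)
        if base_dir is not None and not out_path.is_absolute():
            out_path = base_dir / out_path
        seed = raw.get("seed")
        if not isinstance(seed, int):
            problems.append("seed must be an integer")
            seed = 0
        if kind == "xyz":
            p = system.get("path")
            path = Path(p) if p else None
            if base_dir is not None and path is not None and not path.is_absolute():
                path = base_dir / path
                system["path"] = str(path)
            if path is None or not path.exists():
                problems.append(f"system.path does not resolve: {p!r}")
        if problems:
            raise ConfigError(problems)
        return cls(
            system=system,
            thermo=thermo,
            sampler=sampler,
            lambda_schedule=schedule,
            output_dir=out_path,
            seed=seed,
            write_trajectories=bool(raw.get("write_trajectories", False)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        return cls.from_dict(raw, base_dir=path.parent)


def _build_system_and_model(config: RunConfig, seed: int):
    kind = config.system["kind"]
    if kind == "lj_fluid":
        s = config.system
        params = LJParams(
            epsilon=float(s.get("epsilon", 1.0)),
            sigma=float(s.get("sigma", 1.0)),
            alpha_lj=float(s.get("alpha_lj", 0.5)),
            m=float(s.get("m", 2.0)),
            n=float(s.get("n", 4.0)),
        )
        cutoff = float(s.get("cutoff", 2.3 * params.sigma))
        model = AlchemicalLJFluid(params=params, cutoff=cutoff)
        spec = FluidSpec(
            n_solvent=int(s.get("n_solvent", 32)),
            density=float(s.get("density", 0.3)),
        )
        system = build_box(spec, seed=seed, cutoff=cutoff, lam=1.0)
        return system, model
    if kind == "harmonic":
        s = config.system
        model = HarmonicTetherModel(k0=float(s.get("k0", 1.0)), k1=float(s.get("k1", 4.0)))
        system = AlchemicalSystem(
            positions=np.zeros((1, 3)), species=("X",), solute=frozenset({0}), lam=1.0
        )
        return system, model
    if kind == "ideal_gas":
        s = config.system
        spec = FluidSpec(n_solvent=int(s.get("n_solvent", 32)),
                         density=float(s.get("density", 0.2)))
        system = build_box(spec, seed=seed, lam=1.0)
        return system, IdealGasModel()
    if kind == "xyz":
        s = config.system
        frames = afio.read_xyz(s["path"])
        system = frames[0]
        if "solute" in s:
            system = system.with_(solute=frozenset(int(i) for i in s["solute"]))
        model = BodyOrderedModel.random(
            species=sorted(set(system.species)),
            cutoff=float(s.get("cutoff", 5.0)),
            seed=int(s.get("model_seed", 0)),
        )
        return system.with_(lam=1.0), model
    raise ConfigError([f"unhandled system kind {kind!r}"])


# ---------------------------------------------------------------------------
# the leg
# ---------------------------------------------------------------------------


@dataclass
class SolvationReport:
    """Everything one leg produced, in both human and machine form."""

    dG: float
    dG_err: float
    f_k: np.ndarray
    lambda_schedule: np.ndarray
    t0: np.ndarray
    g: np.ndarray
    n_eff: np.ndarray
    transition_matrix: np.ndarray
    overlap_matrix: np.ndarray
    convergence_trace: list[tuple[float, float]]  # (fraction of run, dG)
    converged: bool
    archive_dir: Path

    def to_dict(self) -> dict:
        return {
            "dG": self.dG,
            "dG_err": self.dG_err,
            "f_k": self.f_k.tolist(),
            "lambda_schedule": self.lambda_schedule.tolist(),
            "t0": self.t0.tolist(),
            "g": self.g.tolist(),
            "n_eff": self.n_eff.tolist(),
            "convergence_trace": self.convergence_trace,
            "converged": self.converged,
        }

    def summary(self) -> str:
        lines = [
            f"dG = {self.dG:.6f} ± {self.dG_err:.6f} (energy units of the run)",
            f"windows: {len(self.lambda_schedule)}  converged: {self.converged}",
            "window   λ        t0     g       Neff",
        ]
        for k, lam in enumerate(self.lambda_schedule):
            lines.append(
                f"{k:>4}   {lam:7.4f}  {int(self.t0[k]):>5} {self.g[k]:6.2f} {self.n_eff[k]:8.1f}"
            )
        return "\n".join(lines)


def run_solvation_leg(config: RunConfig) -> SolvationReport:
    """Execute one alchemical decoupling leg end to end.

    ΔG is reported as G(λ=1) − G(λ=0) — the free energy of coupling the
    solute to its environment (the excess chemical potential for a
    particle-insertion transformation).  All sampled reduced potentials
    are archived so the estimate can be reproduced bit-for-bit by
    :func:`reestimate_from_archive`.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    K = config.lambda_schedule.size
    seeds = ss.spawn(K + 3)
    build_rng_seed = seeds[0].generate_state(1)[0] % (2**31)
    equil_rng = np.random.default_rng(seeds[1])
    swap_rng = np.random.default_rng(seeds[2])
    replica_rngs = [np.random.default_rng(s) for s in seeds[3:]]

    system, model = _build_system_and_model(config, seed=int(build_rng_seed))
    thermo = config.thermo
    kB = float(thermo["kB"])
    T = float(thermo["temperature"])
    pressure = thermo.get("pressure")
    sp = config.sampler
    dt, friction = float(sp["dt"]), float(sp["friction"])

    states = [
        ThermoState(temperature=T, lam=float(lam), pressure=pressure, kB=kB)
        for lam in config.lambda_schedule
    ]
    full = states[-1]  # λ = 1

    if sp.get("minimize", True):
        system = minimize(system, model).system
        logger.info("minimized: E = %.6g", model.energy(system))

    barostats: list[MCBarostat | None]
    use_barostat = bool(sp.get("barostat"))
    if sp["equilibration_steps"] > 0:
        system = _propagate(
            system, model, full, sp["equilibration_steps"], dt, friction, equil_rng,
            MCBarostat(max_dV=0.05 * (system.volume or 1.0),
                       interval=int(sp["barostat_interval"])) if use_barostat else None,
        )
        logger.info("equilibrated %d steps at λ=1", sp["equilibration_steps"])

    replicas = [
        Replica(system=system.with_(lam=states[k].lam, velocities=None), state_index=k,
                rng=replica_rngs[k])
        for k in range(K)
    ]
    ensemble = ReplicaEnsemble(replicas=replicas, states=states)
    barostats = [
        MCBarostat(max_dV=0.05 * (system.volume or 1.0), interval=int(sp["barostat_interval"]))
        if use_barostat else None
        for _ in range(K)
    ]

    n_iter = int(sp["n_iterations"])
    steps = int(sp["steps_per_iteration"])
    # per-window time series of reduced potentials across all states
    u_series: list[list[np.ndarray]] = [[] for _ in range(K)]
    traj_paths = [out / f"replica_{k:02d}.xyz" for k in range(K)]
    if config.write_trajectories:
        for p in traj_paths:
            p.unlink(missing_ok=True)

    for it in range(n_iter):
        for rep in ensemble.replicas:
            bar = barostats[rep.state_index]
            state = ensemble.states[rep.state_index]
            rep.system = _propagate(rep.system, model, state, steps, dt, friction, rep.rng, bar)
        # sample before swapping: configuration belongs to the state it was run at
        for rep in ensemble.replicas:
            vol = rep.system.volume
            row = np.array(
                [s.reduced_u(model.energy_at(rep.system, s.lam), vol) for s in states]
            )
            u_series[rep.state_index].append(row)
            if config.write_trajectories:
                afio.write_xyz(traj_paths[rep.state_index], rep.system, append=True)
        replica_exchange_sweep(ensemble, model, swap_rng,
                               n_attempts=sp.get("swap_attempts"))
        if (it + 1) % max(1, n_iter // 5) == 0:
            logger.info("iteration %d/%d", it + 1, n_iter)

    # --- decorrelate and estimate ---------------------------------------
    series = [np.stack(s) for s in u_series]  # each (n_iter, K)
    sched = [float(x) for x in config.lambda_schedule]
    result, t0s, gs, neffs, matrix = _estimate_from_series(
        series, kB=kB, temperature=T, schedule=sched, pressure=pressure
    )

    trace = []
    for frac in (0.25, 0.5, 0.75, 1.0):
        n = max(10, int(round(n_iter * frac)))
        if n > n_iter:
            n = n_iter
        r_frac, *_ = _estimate_from_series(
            [s[:n] for s in series], kB=kB, temperature=T, schedule=sched, pressure=pressure
        )
        trace.append((frac, float(r_frac.dG)))

    tmat = transition_probability_matrix(ensemble)

    # --- archive ---------------------------------------------------------
    write_ukn(out / "u_kn.dat", matrix)
    np.savetxt(out / "transition_matrix.tsv", tmat, fmt="%.10g", delimiter="\t")
    with open(out / "swap_log.tsv", "w") as fh:
        fh.write("iteration\tstate_i\tstate_j\taccepted\n")
        for rec in ensemble.swap_records:
            fh.write("\t".join(str(int(v)) for v in rec) + "\n")

    report = SolvationReport(
        dG=float(result.dG),
        dG_err=float(result.dG_err),
        f_k=result.f_k,
        lambda_schedule=config.lambda_schedule,
        t0=t0s,
        g=gs,
        n_eff=neffs,
        transition_matrix=tmat,
        overlap_matrix=result.overlap,
        convergence_trace=trace,
        converged=result.converged,
        archive_dir=out,
    )
    (out / "report.json").write_text(json.dumps(report.to_dict(), indent=1))
    (out / "report.txt").write_text(report.summary() + "\n")
    if not result.converged:
        logger.warning("MBAR did not reach the gradient tolerance; report flagged")
    return report


def _propagate(system, model, state, n_steps, dt, friction, rng, barostat):
    if barostat is None:
        return run_md(system, model, state, n_steps, dt, friction, rng)
    done = 0
    while done < n_steps:
        chunk = min(barostat.interval, n_steps - done)
        system = run_md(system, model, state, chunk, dt, friction, rng)
        system = barostat.attempt(system, model, state, rng)
        done += chunk
    return system


def _estimate_from_series(series: list[np.ndarray], kB: float, temperature: float,
                          schedule: list[float] | None = None,
                          pressure: float | None = None):
    """Equilibration-detect, subsample, pool, and run MBAR on per-window series."""
    K = len(series)
    cols, N_k = [], np.zeros(K, dtype=int)
    t0s = np.zeros(K, dtype=int)
    gs = np.zeros(K)
    neffs = np.zeros(K)
    for k, s in enumerate(series):
        own = s[:, k]
        t0, g, neff = detect_equilibration(own)
        idx = subsample_indices(t0, g, s.shape[0])
        t0s[k], gs[k], neffs[k] = t0, g, neff
        cols.append(s[idx].T)  # (K, n_decorrelated)
        N_k[k] = idx.size
    u_kn = np.concatenate(cols, axis=1)
    matrix = ReducedPotentialMatrix(
        u_kn=u_kn, N_k=N_k,
        meta={"temperature": temperature, "kB": kB, "pressure": pressure,
              "lambda_schedule": schedule or []},
    )
    result = mbar_estimate(matrix, kB_T=kB * temperature)
    return result, t0s, gs, neffs, matrix


def reestimate_from_archive(archive_dir: str | Path) -> FreeEnergyResult:
    """Re-run MBAR on an archived u_kn; reproduces the reported ΔG exactly."""
    d = Path(archive_dir)
    m = read_ukn(d / "u_kn.dat")
    kB = float(m.meta.get("kB", KB_KCAL_MOL_K))
    T = float(m.meta.get("temperature", 298.15))
    return mbar_estimate(m, kB_T=kB * T)


# ---------------------------------------------------------------------------
# log P
# ---------------------------------------------------------------------------


@dataclass
class LogPReport:
    log_p: float
    log_p_err: float
    water: SolvationReport
    octanol: SolvationReport

    def to_dict(self) -> dict:
        return {
            "log_p": self.log_p,
            "log_p_err": self.log_p_err,
            "dG_water": self.water.dG,
            "dG_octanol": self.octanol.dG,
        }


def run_logp(config_water: RunConfig, config_octanol: RunConfig) -> LogPReport:
    """Two solvation legs → partition coefficient.

    log P = (ΔG_hyd − ΔG_oct) / (2.303 R T), with the leg uncertainties
    combined in quadrature.  Both legs must describe the same solute.
    """
    if config_water.system != config_octanol.system:
        sw = {k: v for k, v in config_water.system.items()}
        so = {k: v for k, v in config_octanol.system.items()}
        if sw.get("kind") != so.get("kind") or sw.get("solute") != so.get("solute"):
            raise ConfigError(["water and octanol legs must share the same solute definition"])
    water = run_solvation_leg(config_water)
    octanol = run_solvation_leg(config_octanol)
    kB = float(config_water.thermo["kB"])
    T = float(config_water.thermo["temperature"])
    # both legs share the sign convention, so the difference is convention-free
    lp = (water.dG - octanol.dG) / (LN10 * kB * T)
    err = float(np.hypot(water.dG_err, octanol.dG_err) / (LN10 * kB * T))
    return LogPReport(log_p=float(lp), log_p_err=err, water=water, octanol=octanol)
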