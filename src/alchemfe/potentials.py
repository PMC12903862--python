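"""Energy models with an explicit alchemical parameter λ.

Three families of λ-dependence live here:

* ``linear_hamiltonian`` — the classic mixed Hamiltonian
  H(r, λ) = λ H1(r) + (1 − λ) H0(r), whose λ-derivative H1 − H0 feeds
  thermodynamic integration.
* ``beutler_softcore_lj`` — the Beutler softcore Lennard-Jones form that
  stays finite as decoupled atoms overlap.
* :class:`BodyOrderedModel` — a miniature invariant body-ordered graph
  potential in which λ enters as a per-edge factor α_ij multiplying the
  two-body (one-particle-basis) features of edges that cross the
  solute/solvent boundary.  Site energies are nonlinear (body order up
  to 3) in the pooled, α-scaled features, so decoupling scales
  *many-body* interactions smoothly while the end states remain exact:
  at λ = 1 the α factors vanish from the expression, and at λ = 0 the
  interaction graph factorizes into the isolated solute and solvent.

The pairwise models at the bottom (:class:`AlchemicalLJFluid`,
:class:`HarmonicTetherModel`, :class:`IdealGasModel`) provide
analytic-force systems for the sampling and pipeline layers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np

from .softcore import SoftcoreSpec, softened_energy
from .units import KB_KCAL_MOL_K

__all__ = [
    "AlchemicalSystem",
    "LJParams",
    "BodyOrderedModel",
    "edge_scaling_factors",
    "beutler_softcore_lj",
    "linear_hamiltonian",
    "LinearMixture",
    "reduced_potential",
    "AlchemicalLJFluid",
    "HarmonicTetherModel",
    "IdealGasModel",
    "pair_key",
]


@dataclass(frozen=True)
class AlchemicalSystem:
    """A configuration plus its alchemical state.

    Parameters
    ----------
    positions
        N×3 Cartesian coordinates (Å, or reduced length units).
    species
        Per-atom element labels.
    solute
        Indices of the atoms being alchemically decoupled.
    lam
        Coupling parameter λ ∈ [0, 1]; 1 = fully interacting.
    box
        3×3 lattice vectors for a periodic system, or None for gas
        phase.  Only diagonal (orthorhombic) boxes are supported, and
        the minimum box edge must exceed twice the model cutoff so the
        minimum-image convention is valid.
    velocities, masses
        Optional dynamic state used by the integrators.
    """

    positions: np.ndarray
    species: tuple[str, ...]
    solute: frozenset[int]
    lam: float
    box: np.ndarray | None = None
    velocities: np.ndarray | None = None
    masses: np.ndarray | None = None

    def __post_init__(self) -> None:
        pos = np.atleast_2d(np.asarray(self.positions, dtype=float))
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "solute", frozenset(int(i) for i in self.solute))
        n = pos.shape[0]
        if pos.shape != (n, 3):
            raise ValueError("positions must be N×3")
        if len(self.species) != n:
            raise ValueError("species length must match positions")
        if any(i < 0 or i >= n for i in self.solute):
            raise ValueError("solute indices out of range")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.box is not None:
            box = np.asarray(self.box, dtype=float)
            if box.shape != (3, 3):
                raise ValueError("box must be 3×3 lattice vectors")
            if np.any(np.abs(box - np.diag(np.diag(box))) > 1e-12):
                raise ValueError("only diagonal (orthorhombic) boxes are supported")
            object.__setattr__(self, "box", box)
        if self.velocities is not None:
            v = np.asarray(self.velocities, dtype=float)
            if v.shape != pos.shape:
                raise ValueError("velocities must match positions shape")
            object.__setattr__(self, "velocities", v)
        if self.masses is not None:
            m = np.asarray(self.masses, dtype=float)
            if m.shape != (n,):
                raise ValueError("masses must be length N")
            object.__setattr__(self, "masses", m)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    @property
    def volume(self) -> float | None:
        if self.box is None:
            return None
        return float(np.prod(np.diag(self.box)))

    def validate_box_for_cutoff(self, cutoff: float) -> None:
        if self.box is not None and np.min(np.diag(self.box)) < 2.0 * cutoff:
            raise ValueError(
                f"minimum box edge {np.min(np.diag(self.box)):.4g} < 2×cutoff "
                f"{2 * cutoff:.4g}: minimum-image convention would be violated"
            )

    def with_(self, **kwargs) -> "AlchemicalSystem":
        return dataclasses.replace(self, **kwargs)

    def displacement(self, i: int | np.ndarray, j: int | np.ndarray) -> np.ndarray:
        """Minimum-image displacement r_j − r_i."""
        d = self.positions[j] - self.positions[i]
        if self.box is not None:
            L = np.diag(self.box)
            d -= L * np.round(d / L)
        return d

    def pair_displacements(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All i<j pairs: (i_idx, j_idx, minimum-image distance)."""
        n = self.n_atoms
        iu, ju = np.triu_indices(n, k=1)
        d = self.positions[ju] - self.positions[iu]
        if self.box is not None:
            L = np.diag(self.box)
            d -= L * np.round(d / L)
        return iu, ju, np.linalg.norm(d, axis=1)


def pair_key(s1: str, s2: str) -> str:
    """Canonical (sorted) pair label for table lookups."""
    return "-".join(sorted((s1, s2)))


def edge_scaling_factors(
    system: AlchemicalSystem, edges: Sequence[tuple[int, int]] | np.ndarray
) -> np.ndarray:
    """Per-edge alchemical factors: λ on solute↔solvent edges, 1 otherwise.

    An edge is scaled exactly when one endpoint is in the solute and the
    other is not (exclusive-or), i.e. when it crosses the alchemical
    boundary.
    """
    edges = np.asarray(edges, dtype=int)
    if edges.size == 0:
        return np.zeros(0)
    if edges.min() < 0 or edges.max() >= system.n_atoms:
        raise ValueError("edge endpoint out of range")
    in_solute = np.zeros(system.n_atoms, dtype=bool)
    in_solute[list(system.solute)] = True
    cross = in_solute[edges[:, 0]] ^ in_solute[edges[:, 1]]
    return np.where(cross, system.lam, 1.0)


@dataclass(frozen=True)
class LJParams:
    """Lennard-Jones well plus Beutler softcore constants.

    Defaults follow the original softcore parametrization
    (α_LJ = 0.5, n = 4, m = 2).
    """

    epsilon: float
    sigma: float
    alpha_lj: float = 0.5
    m: float = 2.0
    n: float = 4.0

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")
        if self.alpha_lj < 0 or self.m < 1 or self.n < 1:
            raise ValueError("require alpha_lj >= 0, m >= 1, n >= 1")


def beutler_softcore_lj(r, lam: float, p: LJParams):
    """Beutler softcore Lennard-Jones energy.

    U(λ, r) = 4 ε λ^n [ (α_LJ (1−λ)^m + (r/σ)^6)^−2 − (α_LJ (1−λ)^m + (r/σ)^6)^−1 ]

    Finite at r = 0 for λ < 1 (the softcore offset α_LJ (1−λ)^m keeps the
    denominator away from zero); reduces exactly to 4ε[(σ/r)^12 − (σ/r)^6]
    at λ = 1 and vanishes identically at λ = 0.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation must be non-negative")
    offset = p.alpha_lj * (1.0 - lam) ** p.m
    if lam == 1.0 and np.any(r == 0.0) and offset == 0.0:
        raise FloatingPointError("singular evaluation: r = 0 at lambda = 1")
    if lam == 0.0:
        return np.zeros_like(r) if r.ndim else 0.0
    x = offset + (r / p.sigma) ** 6
    u = 4.0 * p.epsilon * lam**p.n * (x**-2 - x**-1)
    return u if r.ndim else float(u)


def beutler_softcore_lj_force(r, lam: float, p: LJParams):
    """Radial force −dU/dr of the Beutler softcore LJ."""
    r = np.asarray(r, dtype=float)
    if lam == 0.0:
        return np.zeros_like(r) if r.ndim else 0.0
    x = p.alpha_lj * (1.0 - lam) ** p.m + (r / p.sigma) ** 6
    dxdr = 6.0 * r**5 / p.sigma**6
    dudx = 4.0 * p.epsilon * lam**p.n * (-2.0 * x**-3 + x**-2)
    f = -dudx * dxdr
    return f if r.ndim else float(f)


@dataclass(frozen=True)
class LinearMixture:
    """H(r, λ) = λ H1(r) + (1 − λ) H0(r), with ∂H/∂λ = H1 − H0."""

    u0: Callable
    u1: Callable
    lam: float

    def __call__(self, *args, **kwargs) -> float:
        if self.lam == 0.0:
            return self.u0(*args, **kwargs)
        if self.lam == 1.0:
            return self.u1(*args, **kwargs)
        return self.lam * self.u1(*args, **kwargs) + (1.0 - self.lam) * self.u0(*args, **kwargs)

    def dudl(self, *args, **kwargs) -> float:
        return self.u1(*args, **kwargs) - self.u0(*args, **kwargs)


def linear_hamiltonian(u0: Callable, u1: Callable, lam: float) -> LinearMixture:
    """Mix two Hamiltonians linearly in λ (exact end states by construction)."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    return LinearMixture(u0, u1, lam)


def reduced_potential(
    u: float,
    temperature: float,
    pressure: float | None = None,
    volume: float | None = None,
    kB: float = KB_KCAL_MOL_K,
) -> float:
    """Dimensionless reduced potential u* = u/kBT (+ pV/kBT in NPT).

    Multistate estimators compare configurations across thermodynamic
    states only through this quantity.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    beta = 1.0 / (kB * temperature)
    ustar = beta * u
    if pressure is not None:
        if volume is None:
            raise ValueError("NPT reduced potential requires a volume")
        ustar += beta * pressure * volume
    return ustar


# ---------------------------------------------------------------------------
# invariant body-ordered graph potential
# ---------------------------------------------------------------------------


def _cutoff_envelope(r: np.ndarray, cutoff: float) -> np.ndarray:
    """Smooth C² envelope: 1 at r=0, 0 at cutoff, zero slope at both ends."""
    u = np.clip(r / cutoff, 0.0, 1.0)
    return 1.0 - 10.0 * u**3 + 15.0 * u**4 - 6.0 * u**5


@dataclass
class BodyOrderedModel:
    """Miniature invariant body-ordered potential with α_ij edge scaling.

    Each atom i pools two-body features over its neighborhood::

        A_i,k = Σ_j α_ij · R_k(r_ij) · (U h_j)_k

    where R_k are Gaussian radial basis functions under a smooth cutoff
    envelope and h_j are species embeddings (updated linearly across
    layers).  The site energy is a polynomial readout in the pooled
    features, E_i = Σ_t Σ_k Σ_ν w_{tνk} A_i,k^ν with ν up to
    ``body_order`` — nonlinear in the α-scaled two-body features, which
    is what makes the λ-scaling act on genuinely many-body terms.

    The model is invariant under rotation, translation and same-species
    permutation because it only consumes interatomic distances and
    species labels.  An optional per-pair softcore table replaces the
    radial pair interaction below each pair's ``r_switch``, keeping
    overlap energies finite.
    """

    cutoff: float
    species: tuple[str, ...]
    n_features: int = 8
    body_order: int = 3
    n_layers: int = 1
    embeddings: dict[str, np.ndarray] = field(default_factory=dict)
    mix: list[np.ndarray] = field(default_factory=list)  # per-layer feature mixer U_t
    update: list[np.ndarray] = field(default_factory=list)  # per-layer node update M_t
    readout: list[np.ndarray] = field(default_factory=list)  # per-layer (body_order, K)
    softcore_table: dict[str, SoftcoreSpec] = field(default_factory=dict)

    @classmethod
    def random(
        cls,
        species: Iterable[str],
        cutoff: float = 5.0,
        n_features: int = 8,
        body_order: int = 3,
        n_layers: int = 1,
        seed: int = 0,
        weight_scale: float = 0.1,
    ) -> "BodyOrderedModel":
        """Model with small fixed random weights (recorded seed, untrained).

        The properties this model is used to exercise — end-state
        consistency, smoothness in λ, invariances — hold for any weights.
        """
        rng = np.random.default_rng(seed)
        species = tuple(dict.fromkeys(species))
        K = n_features
        return cls(
            cutoff=cutoff,
            species=species,
            n_features=K,
            body_order=body_order,
            n_layers=n_layers,
            embeddings={s: rng.normal(0, weight_scale, K) for s in species},
            mix=[rng.normal(0, weight_scale, (K, K)) for _ in range(n_layers)],
            update=[rng.normal(0, weight_scale, (K, K)) for _ in range(n_layers)],
            readout=[rng.normal(0, weight_scale, (body_order, K)) for _ in range(n_layers)],
        )

    # -- internals -------------------------------------------------------
    def _radial_basis(self, r: np.ndarray) -> np.ndarray:
        """(n_edges, K) Gaussian radial features under the cutoff envelope."""
        centers = np.linspace(0.0, self.cutoff, self.n_features)
        width = self.cutoff / max(self.n_features - 1, 1)
        g = np.exp(-0.5 * ((r[:, None] - centers[None, :]) / width) ** 2)
        return g * _cutoff_envelope(r, self.cutoff)[:, None]

    def _neighbor_lists(self, system: AlchemicalSystem):
        iu, ju, r = system.pair_displacements()
        mask = r < self.cutoff
        iu, ju, r = iu[mask], ju[mask], r[mask]
        # directed edges both ways: i pools from j and vice versa
        src = np.concatenate([iu, ju])
        dst = np.concatenate([ju, iu])
        rr = np.concatenate([r, r])
        return src, dst, rr, iu, ju, r

    def energy(self, system: AlchemicalSystem) -> float:
        for s in system.species:
            if s not in self.embeddings:
                raise ValueError(f"unknown species {s!r} for this model")
        system.validate_box_for_cutoff(self.cutoff)
        n = system.n_atoms
        src, dst, rr, iu, ju, r_undir = self._neighbor_lists(system)
        alpha = edge_scaling_factors(system, np.stack([src, dst], axis=1)) if src.size else np.zeros(0)
        R = self._radial_basis(rr) if src.size else np.zeros((0, self.n_features))
        h = np.stack([self.embeddings[s] for s in system.species])  # (N, K)
        total = 0.0
        for t in range(self.n_layers):
            if src.size:
                # one-particle basis φ_ij = α_ij R(r_ij) ⊙ (U_t h_j), pooled over j
                msg = alpha[:, None] * R * (h[dst] @ self.mix[t].T)
                A = np.zeros((n, self.n_features))
                np.add.at(A, src, msg)
            else:
                A = np.zeros((n, self.n_features))
            # body-ordered readout: powers of pooled two-body features
            for nu in range(1, self.body_order + 1):
                total += float(np.sum(A**nu @ self.readout[t][nu - 1]))
            h = A @ self.update[t].T  # linear node update keeps λ=0 factorization exact
        # explicit pair term from the softcore table (finite at overlap)
        if self.softcore_table and iu.size:
            alpha_pair = edge_scaling_factors(system, np.stack([iu, ju], axis=1))
            for a_ij, i, j, rij in zip(alpha_pair, iu, ju, r_undir):
                key = pair_key(system.species[i], system.species[j])
                spec = self.softcore_table.get(key)
                if spec is not None:
                    total += a_ij * softened_energy(spec, float(rij))
        return total

    def forces(self, system: AlchemicalSystem, h: float = 1e-5) -> np.ndarray:
        """Forces by central finite differences (the model is used on
        small systems; pair models below carry analytic forces)."""
        f = np.zeros_like(system.positions)
        pos = system.positions
        for i in range(system.n_atoms):
            for k in range(3):
                dp = np.zeros_like(pos)
                dp[i, k] = h
                ep = self.energy(system.with_(positions=pos + dp))
                em = self.energy(system.with_(positions=pos - dp))
                f[i, k] = -(ep - em) / (2 * h)
        return f

    def energy_at(self, system: AlchemicalSystem, lam: float) -> float:
        return self.energy(system.with_(lam=lam))


# ---------------------------------------------------------------------------
# analytic-force pair models for sampling
# ---------------------------------------------------------------------------


@dataclass
class AlchemicalLJFluid:
    """LJ fluid with Beutler-softcore solute↔solvent coupling.

    Solvent–solvent and solute–solute pairs interact through the plain
    truncated-and-shifted LJ potential; solute–solvent pairs through the
    Beutler softcore form at the system's λ (shifted by its own cutoff
    value so the energy stays continuous at the cutoff for every λ).
    At λ = 1 every pair is plain LJ; at λ = 0 the solute is an ideal-gas
    particle with respect to the solvent.
    """

    params: LJParams
    cutoff: float

    # exact-overlap guard: keeps line searches finite instead of NaN at r = 0
    _R_FLOOR = 1e-6

    def _plain_lj(self, r: np.ndarray) -> np.ndarray:
        p = self.params
        r = np.maximum(r, self._R_FLOOR * p.sigma)
        x = (p.sigma / r) ** 6
        return 4.0 * p.epsilon * (x**2 - x)

    def _plain_lj_force(self, r: np.ndarray) -> np.ndarray:
        p = self.params
        r = np.maximum(r, self._R_FLOOR * p.sigma)
        x = (p.sigma / r) ** 6
        return 24.0 * p.epsilon * (2.0 * x**2 - x) / r

    def energy(self, system: AlchemicalSystem) -> float:
        system.validate_box_for_cutoff(self.cutoff)
        iu, ju, r = system.pair_displacements()
        mask = r < self.cutoff
        iu, ju, r = iu[mask], ju[mask], r[mask]
        if r.size == 0:
            return 0.0
        in_solute = np.zeros(system.n_atoms, dtype=bool)
        in_solute[list(system.solute)] = True
        cross = in_solute[iu] ^ in_solute[ju]
        e = 0.0
        plain = ~cross
        if np.any(plain):
            shift = self._plain_lj(np.array([self.cutoff]))[0]
            e += float(np.sum(self._plain_lj(r[plain]) - shift))
        if np.any(cross):
            lam = system.lam
            shift = beutler_softcore_lj(self.cutoff, lam, self.params)
            e += float(np.sum(beutler_softcore_lj(r[cross], lam, self.params) - shift))
        return e

    def forces(self, system: AlchemicalSystem) -> np.ndarray:
        iu, ju, rvec, r = self._pair_vectors(system)
        f = np.zeros_like(system.positions)
        if r.size == 0:
            return f
        in_solute = np.zeros(system.n_atoms, dtype=bool)
        in_solute[list(system.solute)] = True
        cross = in_solute[iu] ^ in_solute[ju]
        fr = np.where(
            cross,
            beutler_softcore_lj_force(r, system.lam, self.params),
            self._plain_lj_force(r),
        )
        # force on j along +rhat (r grows), reaction on i
        rhat = rvec / r[:, None]
        fij = fr[:, None] * rhat
        np.add.at(f, ju, fij)
        np.add.at(f, iu, -fij)
        return f

    def _pair_vectors(self, system: AlchemicalSystem):
        iu, ju = np.triu_indices(system.n_atoms, k=1)
        d = system.positions[ju] - system.positions[iu]
        if system.box is not None:
            L = np.diag(system.box)
            d -= L * np.round(d / L)
        r = np.linalg.norm(d, axis=1)
        mask = r < self.cutoff
        return iu[mask], ju[mask], d[mask], r[mask]

    def energy_at(self, system: AlchemicalSystem, lam: float) -> float:
        return self.energy(system.with_(lam=lam))


@dataclass
class HarmonicTetherModel:
    """One particle tethered harmonically with λ-interpolated stiffness.

    H(x, λ) = ½ k(λ) |x − c|² with k(λ) = (1 − λ) k0 + λ k1.  The reduced
    free-energy difference between the end states is (d/2) ln(k1/k0)
    exactly, which makes this the workhorse analytic fixture for the
    estimators and the pipeline.
    """

    k0: float
    k1: float
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def k(self, lam: float) -> float:
        return (1.0 - lam) * self.k0 + lam * self.k1

    def energy(self, system: AlchemicalSystem) -> float:
        d = system.positions - np.asarray(self.center)
        return 0.5 * self.k(system.lam) * float(np.sum(d * d))

    def forces(self, system: AlchemicalSystem) -> np.ndarray:
        d = system.positions - np.asarray(self.center)
        return -self.k(system.lam) * d

    def dudl(self, system: AlchemicalSystem) -> float:
        d = system.positions - np.asarray(self.center)
        return 0.5 * (self.k1 - self.k0) * float(np.sum(d * d))

    def energy_at(self, system: AlchemicalSystem, lam: float) -> float:
        return self.energy(system.with_(lam=lam))


@dataclass
class IdealGasModel:
    """No interactions at all: E = 0, F = 0 (barostat and null-leg fixture)."""

    def energy(self, system: AlchemicalSystem) -> float:
        return 0.0

    def forces(self, system: AlchemicalSystem) -> np.ndarray:
        return np.zeros_like(system.positions)

    def energy_at(self, system: AlchemicalSystem, lam: float) -> float:
        return 0.0
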