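"""Synthetic fixtures with exact known answers.

Every stage of the free-energy machinery is testable without external
data through four families of fixtures:

* analytic dimer curves (Lennard-Jones, Morse) with exact energy, force
  and force-derivative callables — these stand in for ab initio pair
  reference curves when fitting softcore polynomials;
* harmonic λ-families, whose reduced free energies
  f(λ) = (d/2) ln(k(λ)/k(0)) are available in closed form;
* Gaussian work models, Crooks-consistent by construction, with implied
  Δf = μ − σ²/2;
* ideal-gas and small LJ fluid boxes, with Widom test-particle insertion
  as an estimator-independent route to the excess chemical potential.

Fluid fixtures use reduced (dimensionless) units: kB = 1, lengths in σ,
energies in ε.  All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .potentials import AlchemicalSystem
from .estimators import ReducedPotentialMatrix
from .softcore import DimerCurve

__all__ = [
    "AnalyticDimer",
    "analytic_dimer",
    "HarmonicFamily",
    "sample_harmonic_ukn",
    "GaussianWorkModel",
    "widom_insertion",
    "WidomResult",
    "lj_second_virial",
]


# ---------------------------------------------------------------------------
# analytic dimer curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AnalyticDimer:
    """A tabulated curve plus the exact callables it was generated from."""

    curve: DimerCurve
    energy: Callable[[float], float]
    force: Callable[[float], float]
    dforce: Callable[[float], float]


def analytic_dimer(
    kind: str,
    params: dict | None = None,
    r_grid: np.ndarray | None = None,
    pair_label: str | None = None,
) -> AnalyticDimer:
    """Analytic reference dimer curve.

    kind="LJ": params epsilon, sigma (default 1, 1);
    kind="Morse": params D, a, r_e (default 1, 2, 1.2).
    The returned :class:`DimerCurve` carries the analytic callables, so
    downstream fits are exact rather than grid-limited.
    """
    params = dict(params or {})
    if kind.upper() == "LJ":
        eps = params.pop("epsilon", 1.0)
        sig = params.pop("sigma", 1.0)
        if params:
            raise ValueError(f"unknown LJ params: {sorted(params)}")

        def energy(r):
            x = (sig / r) ** 6
            return 4.0 * eps * (x**2 - x)

        def force(r):
            x = (sig / r) ** 6
            return 24.0 * eps * (2.0 * x**2 - x) / r

        def dforce(r):
            x = (sig / r) ** 6
            return 24.0 * eps * (-26.0 * x**2 + 7.0 * x) / r**2

        if r_grid is None:
            r_grid = np.linspace(0.70 * sig, 3.0 * sig, 200)
        label = pair_label or "LJ"
    elif kind.capitalize() == "Morse":
        D = params.pop("D", 1.0)
        a = params.pop("a", 2.0)
        r_e = params.pop("r_e", 1.2)
        if params:
            raise ValueError(f"unknown Morse params: {sorted(params)}")

        def energy(r):
            u = np.exp(-a * (r - r_e))
            return D * ((1.0 - u) ** 2 - 1.0)

        def force(r):  # -dE/dr
            u = np.exp(-a * (r - r_e))
            return 2.0 * D * a * (1.0 - u) * (-u)

        def dforce(r):
            u = np.exp(-a * (r - r_e))
            return 2.0 * D * a * a * u * (1.0 - 2.0 * u)

        if r_grid is None:
            r_grid = np.linspace(max(r_e - 1.2 / a, 0.05), r_e + 4.0 / a, 200)
        label = pair_label or "Morse"
    else:
        raise ValueError(f"unknown dimer kind {kind!r}")

    r = np.asarray(r_grid, dtype=float)
    curve = DimerCurve(
        pair_label=label,
        r=r,
        energy=np.array([energy(x) for x in r]),
        force=np.array([force(x) for x in r]),
        energy_fn=energy,
        force_fn=force,
        dforce_fn=dforce,
    )
    return AnalyticDimer(curve=curve, energy=energy, force=force, dforce=dforce)


# ---------------------------------------------------------------------------
# harmonic λ-family
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonicFamily:
    """d-dimensional harmonic wells with per-window stiffness k(λ).

    The reduced free energy of window l relative to window 0 is exactly
    (d/2) ln(k_l / k_0), independent of temperature — the cleanest
    possible oracle for TI/BAR/MBAR.
    """

    k: tuple[float, ...]
    d: int = 1
    temperature: float = 1.0
    kB: float = 1.0

    def __post_init__(self) -> None:
        if any(kk <= 0 for kk in self.k):
            raise ValueError("spring constants must be positive")
        if self.d < 1 or self.temperature <= 0:
            raise ValueError("invalid dimension or temperature")
        object.__setattr__(self, "k", tuple(float(x) for x in self.k))

    @property
    def n_windows(self) -> int:
        return len(self.k)

    def exact_f(self) -> np.ndarray:
        """Exact reduced free energies, gauge f[0] = 0."""
        k = np.asarray(self.k)
        return 0.5 * self.d * np.log(k / k[0])

    def dudl_means(self, lambdas: np.ndarray, k0: float, k1: float) -> np.ndarray:
        """Exact ⟨∂H/∂λ⟩ for linear mixing k(λ) = (1−λ)k0 + λk1.

        ∂H/∂λ = ½ (k1 − k0) |x|², and ⟨|x|²⟩ = d kBT / k(λ), so the
        mean is ½ (k1 − k0) d kBT / k(λ).
        """
        kl = (1.0 - lambdas) * k0 + lambdas * k1
        return 0.5 * (k1 - k0) * self.d * self.kB * self.temperature / kl


def sample_harmonic_ukn(
    family: HarmonicFamily, n_per_window: int, seed: int
) -> ReducedPotentialMatrix:
    """Exact Gaussian draws per window, cross-evaluated into u_kn.

    Window l samples x ~ N(0, kBT/k_l I_d); the reduced potential of
    window k on any x is ½ β k_k |x|².
    """
    if n_per_window < 1:
        raise ValueError("need n >= 1 per window")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (family.kB * family.temperature)
    k = np.asarray(family.k)
    xs = []
    for kl in k:
        sd = np.sqrt(1.0 / (beta * kl))
        xs.append(rng.normal(0.0, sd, size=(n_per_window, family.d)))
    x_all = np.concatenate(xs, axis=0)  # (K*n, d)
    r2 = np.sum(x_all**2, axis=1)
    u_kn = 0.5 * beta * k[:, None] * r2[None, :]
    N_k = np.full(family.n_windows, n_per_window)
    return ReducedPotentialMatrix(u_kn=u_kn, N_k=N_k, meta={"family": "harmonic"})


# ---------------------------------------------------------------------------
# Gaussian work model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianWorkModel:
    """Gaussian forward reduced-work distribution with Crooks-consistent reverse.

    Work is measured on the 0→1 axis throughout: w = u_1 − u_0 on a
    configuration, whichever state it was drawn from.  Forward samples
    (from state 0) have w_F ~ N(μ, σ²), implying Δf = μ − σ²/2; the
    Crooks fluctuation relation P_1(w) = P_0(w) e^{Δf − w} then fixes
    the reverse-sample distribution to w_R ~ N(μ − σ², σ²).
    """

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("variance must be non-negative")

    @property
    def delta_f(self) -> float:
        return self.mu - 0.5 * self.sigma2

    def sample(self, n_forward: int, n_reverse: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
        rng = np.random.default_rng(seed)
        sd = np.sqrt(self.sigma2)
        w_f = rng.normal(self.mu, sd, n_forward)
        w_r = rng.normal(self.mu - self.sigma2, sd, n_reverse)
        return w_f, w_r

    def to_ukn(self, n_forward: int, n_reverse: int, seed: int) -> ReducedPotentialMatrix:
        """Pack work samples as a K = 2 reduced-potential matrix.

        Samples from state 0 see u_0 = 0, u_1 = w_F; samples from state 1
        see u_1 = 0, u_0 = −w_R (w_R is the 0→1 energy difference).
        """
        w_f, w_r = self.sample(n_forward, n_reverse, seed)
        u_kn = np.zeros((2, n_forward + n_reverse))
        u_kn[1, :n_forward] = w_f
        u_kn[0, n_forward:] = -w_r
        return ReducedPotentialMatrix(u_kn=u_kn, N_k=np.array([n_forward, n_reverse]))


# ---------------------------------------------------------------------------
# fluids and Widom insertion
# ---------------------------------------------------------------------------


@dataclass
class WidomResult:
    mu_ex: float
    se: float
    n_insertions: int
    low_reliability: bool = False


def widom_insertion(
    frames: Sequence[AlchemicalSystem],
    pair_energy: Callable[[AlchemicalSystem, np.ndarray], float],
    temperature: float,
    n_insertions: int,
    seed: int,
    kB: float = 1.0,
) -> WidomResult:
    """Excess chemical potential by test-particle insertion.

    μ_ex = −kBT ln ⟨exp(−β Δu)⟩ over random insertion positions in
    equilibrated solvent frames; ``pair_energy(frame, position)`` is the
    interaction energy of the ghost particle with the frame.  The
    standard error follows from the variance of the Boltzmann factor by
    the delta method.  If every insertion overlaps (all Boltzmann
    factors underflow) the estimate is flagged low-reliability.
    """
    if not frames:
        raise ValueError("need at least one solvent frame")
    rng = np.random.default_rng(seed)
    beta = 1.0 / (kB * temperature)
    boltz = np.empty(n_insertions)
    for i in range(n_insertions):
        frame = frames[int(rng.integers(0, len(frames)))]
        L = np.diag(frame.box)
        pos = rng.uniform(0.0, 1.0, 3) * L
        du = pair_energy(frame, pos)
        boltz[i] = np.exp(-beta * du)
    mean = float(np.mean(boltz))
    low = mean <= 0.0 or not np.isfinite(mean)
    if low:
        return WidomResult(mu_ex=np.inf, se=np.inf, n_insertions=n_insertions, low_reliability=True)
    mu_ex = -kB * temperature * np.log(mean)
    se_mean = float(np.std(boltz, ddof=1) / np.sqrt(n_insertions))
    se = kB * temperature * se_mean / mean
    return WidomResult(mu_ex=float(mu_ex), se=se, n_insertions=n_insertions)


def lj_second_virial(
    temperature: float,
    epsilon: float = 1.0,
    sigma: float = 1.0,
    cutoff: float | None = None,
    shifted: bool = True,
    kB: float = 1.0,
    n_quad: int = 20_000,
) -> float:
    """Second virial coefficient B2(T) = −2π ∫ (e^{−βu(r)} − 1) r² dr.

    Numerical quadrature for the (optionally truncated-and-shifted) LJ
    potential; at low density μ_ex ≈ 2 ρ B2 kBT, giving an independent
    oracle for insertion estimates.
    """
    beta = 1.0 / (kB * temperature)
    rc = cutoff if cutoff is not None else 10.0 * sigma

    def u(r):
        x = (sigma / r) ** 6
        val = 4.0 * epsilon * (x**2 - x)
        if shifted and cutoff is not None:
            xs = (sigma / rc) ** 6
            val = val - 4.0 * epsilon * (xs**2 - xs)
        return val

    r = np.linspace(1e-6, rc, n_quad)
    integrand = (np.exp(-beta * u(r)) - 1.0) * r**2
    return float(-2.0 * np.pi * np.trapezoid(integrand, r))
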