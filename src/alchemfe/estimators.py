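"""Free-energy estimators and sample-quality diagnostics.

The estimation layer is deliberately self-contained: it consumes a
:class:`ReducedPotentialMatrix` (the dimensionless u_kn samples every
multistate estimator is defined on) and produces a
:class:`FreeEnergyResult`.  Three estimators are provided —
thermodynamic integration (trapezoidal quadrature of ⟨∂H/∂λ⟩), the
Bennett acceptance ratio for a single state pair, and the multistate
Bennett acceptance ratio (MBAR), solved by self-consistent iteration
polished with a Newton stage.  BAR and MBAR are implemented through
independent routes, so their K = 2 agreement is a genuine cross-check
rather than a tautology.

Sample decorrelation follows the standard autocorrelation-based
statistical inefficiency g and the automated equilibration-detection
rule of maximizing the effective sample count (T − t0)/g over candidate
truncation points t0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp

from .units import KB_KCAL_MOL_K, LN10

__all__ = [
    "ReducedPotentialMatrix",
    "FreeEnergyResult",
    "statistical_inefficiency",
    "detect_equilibration",
    "subsample_indices",
    "ti_estimate",
    "bar_estimate",
    "mbar_estimate",
    "mbar_solve",
    "overlap_matrix",
    "log_p",
    "write_ukn",
    "read_ukn",
]


@dataclass(frozen=True)
class ReducedPotentialMatrix:
    """u_kn: K thermodynamic states evaluated on N pooled configurations.

    ``u_kn[k, n]`` is the reduced potential of configuration n in state
    k; ``N_k[k]`` counts how many of the pooled configurations were
    drawn from state k (Σ N_k = N).  States with N_k = 0 are allowed —
    they are evaluated perturbatively.
    """

    u_kn: np.ndarray
    N_k: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        # contiguous layout so estimates are bit-reproducible across
        # serialization round trips (summation order is layout-dependent)
        u = np.ascontiguousarray(np.atleast_2d(np.asarray(self.u_kn, dtype=float)))
        n_k = np.asarray(self.N_k, dtype=int)
        object.__setattr__(self, "u_kn", u)
        object.__setattr__(self, "N_k", n_k)
        K, N = u.shape
        if K < 2:
            raise ValueError("need at least 2 states")
        if n_k.shape != (K,):
            raise ValueError("N_k must have length K")
        if n_k.sum() != N:
            raise ValueError(f"sum(N_k)={n_k.sum()} != N={N}")
        if np.any(n_k < 0):
            raise ValueError("N_k must be non-negative")
        if n_k.sum() == 0:
            raise ValueError("all N_k are zero: no samples")
        if not np.all(np.isfinite(u)):
            raise ValueError("u_kn contains non-finite entries")

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[0]

    @property
    def n_samples(self) -> int:
        return self.u_kn.shape[1]


@dataclass
class FreeEnergyResult:
    """Per-state reduced free energies plus end-to-end ΔG and diagnostics."""

    f_k: np.ndarray  # reduced, gauge f_k[0] = 0
    dG: float  # working energy units (kcal/mol unless kB says otherwise)
    dG_err: float
    kB_T: float = 1.0
    overlap: np.ndarray | None = None
    t0: np.ndarray | None = None  # per-window equilibration index
    g: np.ndarray | None = None  # per-window statistical inefficiency
    n_eff: np.ndarray | None = None
    theta: np.ndarray | None = None  # asymptotic covariance of f_k
    converged: bool = True
    method: str = ""

    def __post_init__(self) -> None:
        self.f_k = np.asarray(self.f_k, dtype=float)
        if abs(self.f_k[0]) > 1e-12:
            raise ValueError("gauge violation: f_k[0] must be 0")
        if self.dG_err < 0:
            raise ValueError("dG_err must be non-negative")


# ---------------------------------------------------------------------------
# decorrelation
# ---------------------------------------------------------------------------


def statistical_inefficiency(series: np.ndarray, mintime: int = 1) -> float:
    """g = 1 + 2 Σ_t C(t) (1 − t/T), truncated at the first non-positive C(t).

    g is the factor by which correlated samples are less informative than
    independent ones; g = 1 for white noise.  A zero-variance series is
    degenerate and returns g = 1.
    """
    x = np.asarray(series, dtype=float)
    T = x.size
    if T < 4:
        raise ValueError("series too short (need >= 4 points)")
    dx = x - x.mean()
    var = float(np.dot(dx, dx)) / T
    if var <= 1e-15 * max(1.0, float(np.mean(np.abs(x))) ** 2):
        return 1.0  # degenerate (constant) series
    g = 1.0
    for t in range(1, T):
        c = float(np.dot(dx[: T - t], dx[t:])) / ((T - t) * var)
        if c <= 0.0 and t > mintime:
            break
        g += 2.0 * c * (1.0 - t / T)
    return max(g, 1.0)


def detect_equilibration(series: np.ndarray, nmax_scan: int = 10_000) -> tuple[int, float, float]:
    """Choose the truncation t0 maximizing Neff = (T − t0)/g(series[t0:]).

    Scans every candidate index while the series is short, striding once
    it exceeds ``nmax_scan`` points to keep the cost bounded.  Ties break
    toward smaller t0.  Returns (t0, g, Neff).
    """
    x = np.asarray(series, dtype=float)
    T = x.size
    if T < 10:
        raise ValueError("series too short (need >= 10 points)")
    stride = max(1, T // nmax_scan)
    best = (0, 1.0, -np.inf)
    for t0 in range(0, T - 8, stride):
        g = statistical_inefficiency(x[t0:])
        neff = (T - t0) / g
        if neff > best[2] * (1.0 + 1e-12):
            best = (t0, g, neff)
    return best


def subsample_indices(t0: int, g: float, T: int) -> np.ndarray:
    """Indices of approximately decorrelated samples in series[t0:T]."""
    stride = max(1, int(np.ceil(g)))
    return np.arange(t0, T, stride)


# ---------------------------------------------------------------------------
# thermodynamic integration
# ---------------------------------------------------------------------------


def ti_estimate(
    dudl_means: np.ndarray,
    lambdas: np.ndarray,
    dudl_errs: np.ndarray | None = None,
    kB_T: float = 1.0,
) -> FreeEnergyResult:
    """ΔG = ∫₀¹ ⟨∂H/∂λ⟩ dλ by trapezoidal quadrature.

    ``dudl_means`` are per-window ensemble averages in energy units;
    errors (if given) are propagated through the trapezoid weights
    assuming independent windows.  λ nodes must be strictly monotone;
    a decreasing schedule negates ΔG exactly.
    """
    lam = np.asarray(lambdas, dtype=float)
    m = np.asarray(dudl_means, dtype=float)
    if lam.size != m.size or lam.size < 2:
        raise ValueError("need matching lambda nodes and means, >= 2 nodes")
    d = np.diff(lam)
    if not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("lambda nodes must be strictly monotone")
    # trapezoid weights
    w = np.zeros_like(lam)
    w[:-1] += d / 2.0
    w[1:] += d / 2.0
    dG = float(np.dot(w, m))
    if dudl_errs is not None:
        e = np.asarray(dudl_errs, dtype=float)
        err = float(np.sqrt(np.dot(w**2, e**2)))
    else:
        err = 0.0
    # cumulative reduced free energy along the schedule
    f = np.concatenate([[0.0], np.cumsum((m[:-1] + m[1:]) / 2.0 * d)]) / kB_T
    return FreeEnergyResult(f_k=f, dG=dG, dG_err=err, kB_T=kB_T, method="TI")


# ---------------------------------------------------------------------------
# BAR
# ---------------------------------------------------------------------------


def _fermi(x: np.ndarray) -> np.ndarray:
    # overflow-safe logistic 1/(1+e^x)
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = np.exp(-x[pos]) / (1.0 + np.exp(-x[pos]))
    out[~pos] = 1.0 / (1.0 + np.exp(x[~pos]))
    return out


def bar_estimate(w_F: np.ndarray, w_R: np.ndarray, tol: float = 1e-10) -> tuple[float, float]:
    """Bennett acceptance ratio from forward/reverse reduced work samples.

    Both arrays are measured on the same 0→1 axis: ``w_F[n] = u_1 − u_0``
    on configurations drawn from state 0 and ``w_R[n] = u_1 − u_0`` on
    configurations drawn from state 1 (so a perfectly symmetric pair of
    states has w_R = −w_F and Δf = 0).  Solves the self-consistent
    Bennett equation

        Σ_F f(M + w_F − Δf) = Σ_R f(−M − w_R + Δf),   f(x) = 1/(1+e^x),
        M = ln(n_F / n_R)

    for the reduced free-energy difference Δf of the 0→1 transformation.
    Returns (Δf, asymptotic standard error).  Distributions with
    essentially no overlap still converge but carry a large error bar.
    """
    wf = np.asarray(w_F, dtype=float)
    wr = np.asarray(w_R, dtype=float)
    if wf.size == 0 or wr.size == 0:
        raise ValueError("both work arrays must be non-empty")
    M = np.log(wf.size / wr.size)

    def imbalance(df: float) -> float:
        lhs = logsumexp(-np.logaddexp(0.0, M + wf - df))
        rhs = logsumexp(-np.logaddexp(0.0, -M - wr + df))
        return lhs - rhs

    # bracket the root by expansion around the exponential-average guesses
    lo = min(-logsumexp(-wf) + np.log(wf.size), float(np.min(-wr))) - 10.0
    hi = max(logsumexp(-wr) - np.log(wr.size), float(np.max(wf))) + 10.0
    # imbalance is increasing in df: expand until lo/hi straddle the root
    span = 1.0
    while imbalance(lo) > 0:
        lo -= span
        span *= 2
    span = 1.0
    while imbalance(hi) < 0:
        hi += span
        span *= 2
    df = brentq(imbalance, lo, hi, xtol=tol, rtol=8.9e-16)

    # Bennett asymptotic variance from fermi-function second moments
    ff = _fermi(M + wf - df)
    fr = _fermi(-M - wr + df)
    nf, nr = wf.size, wr.size
    var = (np.mean(ff**2) / np.mean(ff) ** 2 - 1.0) / nf + (
        np.mean(fr**2) / np.mean(fr) ** 2 - 1.0
    ) / nr
    return float(df), float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------


def _mbar_log_denominator(f_k: np.ndarray, u_kn: np.ndarray, log_N_k: np.ndarray) -> np.ndarray:
    """log Σ_k N_k exp(f_k − u_kn) per sample (the MBAR mixture weight)."""
    return logsumexp(f_k[:, None] - u_kn + log_N_k[:, None], axis=0)


def mbar_solve(
    u_kn: np.ndarray,
    N_k: np.ndarray,
    tol: float = 1e-12,
    grad_tol: float = 1e-10,
    max_sc: int = 10_000,
    max_newton: int = 100,
) -> tuple[np.ndarray, bool]:
    """Solve the MBAR self-consistency equations for reduced free energies.

    Self-consistent iteration from f = 0 (globally convergent, slow near
    the solution) followed by Newton polish on the states with samples
    (quadratic near the solution).  Gauge: f_0 = 0.  Returns
    (f_k, converged) where convergence means the gradient max-norm of the
    MBAR objective dropped below ``grad_tol``.
    """
    u = np.asarray(u_kn, dtype=float)
    N = np.asarray(N_k, dtype=float)
    K = u.shape[0]
    sampled = N > 0
    with np.errstate(divide="ignore"):
        log_N = np.where(sampled, np.log(np.maximum(N, 1)), -np.inf)
    f = np.zeros(K)

    def update(f_k: np.ndarray) -> np.ndarray:
        log_denom = _mbar_log_denominator(f_k, u, log_N)
        f_new = -logsumexp(-u - log_denom[None, :], axis=1)
        return f_new - f_new[0]

    for _ in range(max_sc):
        f_new = update(f)
        delta = np.max(np.abs(f_new - f))
        f = f_new
        if delta < 1e-6:  # hand over to Newton once in the basin
            break

    def gradient_and_weights(f_k: np.ndarray):
        log_denom = _mbar_log_denominator(f_k, u, log_N)
        logW = f_k[:, None] - u - log_denom[None, :]  # (K, N) normalized per state
        W = np.exp(logW)
        grad = N * (W.sum(axis=1) - 1.0)
        return grad, W

    converged = False
    idx = np.where(sampled)[0]
    for _ in range(max_newton):
        grad, W = gradient_and_weights(f)
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        # Hessian of the MBAR objective restricted to sampled states, f_0 fixed
        WN = W * N[:, None]  # N_k W_kn
        H = -(WN[idx] @ WN[idx].T)
        H[np.diag_indices_from(H)] += N[idx] * W[idx].sum(axis=1)
        free = idx[idx != 0]
        sel = [int(np.where(idx == j)[0][0]) for j in free]
        Hf = H[np.ix_(sel, sel)]
        gf = grad[free]
        try:
            step = np.linalg.solve(Hf, gf)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hf, gf, rcond=None)[0]
        # damped Newton: halve until the gradient norm does not explode
        scale = 1.0
        g0 = np.max(np.abs(grad))
        for _ in range(30):
            f_try = f.copy()
            f_try[free] -= scale * step
            g_try = np.max(np.abs(gradient_and_weights(f_try)[0]))
            if g_try < g0 or g_try < grad_tol:
                f = f_try
                break
            scale *= 0.5
        else:
            f = update(f)
    else:
        grad, _ = gradient_and_weights(f)
        converged = bool(np.max(np.abs(grad)) < grad_tol)
    # unsampled states: perturbative evaluation
    if np.any(~sampled):
        log_denom = _mbar_log_denominator(f, u, log_N)
        f_unsampled = -logsumexp(-u[~sampled] - log_denom[None, :], axis=1)
        f[~sampled] = f_unsampled
        f = f - f[0]
    return f, converged


def _mbar_weights(f_k: np.ndarray, u_kn: np.ndarray, N_k: np.ndarray) -> np.ndarray:
    """W_nk = exp(f_k − u_kn)/Σ_l N_l exp(f_l − u_ln); Σ_n W_nk = 1 at the solution."""
    N = np.asarray(N_k, dtype=float)
    with np.errstate(divide="ignore"):
        log_N = np.where(N > 0, np.log(np.maximum(N, 1)), -np.inf)
    log_denom = _mbar_log_denominator(f_k, u_kn, log_N)
    return np.exp(f_k[None, :] - u_kn.T - log_denom[:, None])  # (N, K)


def _mbar_covariance(W: np.ndarray, N_k: np.ndarray) -> np.ndarray:
    """Asymptotic covariance Θ of the reduced free energies (SVD form)."""
    Nmat = np.diag(np.asarray(N_k, dtype=float))
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    S = np.diag(s)
    V = Vt.T
    inner = np.eye(len(s)) - S @ V.T @ Nmat @ V @ S
    theta = V @ S @ np.linalg.pinv(inner, rcond=1e-12) @ S @ V.T
    return theta


def mbar_estimate(m: ReducedPotentialMatrix, kB_T: float = 1.0) -> FreeEnergyResult:
    """Multistate Bennett acceptance ratio estimate over all K states.

    ΔG is reported between the first and last state of the matrix, in
    energy units via ``kB_T``; the per-state reduced free energies and
    the overlap matrix come along as diagnostics.
    """
    f_k, converged = mbar_solve(m.u_kn, m.N_k)
    W = _mbar_weights(f_k, m.u_kn, m.N_k)
    theta = _mbar_covariance(W, m.N_k)
    var = theta[0, 0] + theta[-1, -1] - 2.0 * theta[0, -1]
    err = float(np.sqrt(max(var, 0.0)))
    O = overlap_matrix(m, f_k)
    return FreeEnergyResult(
        f_k=f_k,
        dG=float((f_k[-1] - f_k[0]) * kB_T),
        dG_err=err * kB_T,
        kB_T=kB_T,
        overlap=O,
        theta=theta,
        converged=converged,
        method="MBAR",
    )


def overlap_matrix(m: ReducedPotentialMatrix, f_k: np.ndarray) -> np.ndarray:
    """O_ij = Σ_n W_ni W_nj N_j — phase-space overlap between states.

    Rows sum to 1; near-zero off-diagonal blocks flag disconnected
    states.  The subdominant eigenvalue gap is a standard connectivity
    diagnostic (closer to 1 ⇒ poorer mixing between blocks).
    """
    W = _mbar_weights(np.asarray(f_k, dtype=float), m.u_kn, m.N_k)
    return W.T @ (W * np.asarray(m.N_k, dtype=float)[None, :])


def overlap_eigenvalue_gap(O: np.ndarray) -> float:
    """1 − |second-largest eigenvalue| of the overlap matrix."""
    ev = np.sort(np.abs(np.linalg.eigvals(O)))[::-1]
    return float(1.0 - ev[1]) if ev.size > 1 else 1.0


# ---------------------------------------------------------------------------
# log P
# ---------------------------------------------------------------------------


def log_p(dG_hyd: float, dG_oct: float, temperature: float = 298.15) -> float:
    """Octanol/water partition coefficient from the two solvation legs.

    log P = (ΔG_hyd − ΔG_oct) / (2.303 R T), free energies in kcal/mol.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return (dG_hyd - dG_oct) / (LN10 * KB_KCAL_MOL_K * temperature)


def log_p_error(err_hyd: float, err_oct: float, temperature: float = 298.15) -> float:
    """Quadrature-propagated uncertainty of :func:`log_p`."""
    return float(np.hypot(err_hyd, err_oct) / (LN10 * KB_KCAL_MOL_K * temperature))


# ---------------------------------------------------------------------------
# u_kn serialization: delimited text + JSON sidecar
# ---------------------------------------------------------------------------


def write_ukn(path: str | Path, m: ReducedPotentialMatrix) -> None:
    """Write u_kn as whitespace-delimited text (K rows) with a .json sidecar."""
    path = Path(path)
    np.savetxt(path, m.u_kn, fmt="%.17g")
    sidecar = {"K": int(m.n_states), "N_k": [int(x) for x in m.N_k], **m.meta}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_ukn(path: str | Path) -> ReducedPotentialMatrix:
    path = Path(path)
    u = np.atleast_2d(np.loadtxt(path))
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    meta = {k: v for k, v in sidecar.items() if k not in ("K", "N_k")}
    return ReducedPotentialMatrix(u_kn=u, N_k=np.asarray(sidecar["N_k"]), meta=meta)
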