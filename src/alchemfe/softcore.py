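"""Softcore construction for short-range pairwise curves.

Machine-learned and ab initio pair interactions diverge as two atoms
overlap, which breaks alchemical simulations at intermediate coupling
where partially decoupled atoms can pass through one another.  This
module replaces the repulsive wall of a tabulated dimer curve, below a
switching separation ``r_switch``, with the force polynomial

    F_sc(r) = a r^10 + b,

fitted so that the force value and its first derivative match the
reference at ``r_switch``.  The softened energy is the analytic integral
of the polynomial, so energy and force stay consistent and the energy is
finite down to r = 0.  Everything at and beyond ``r_switch`` — in
particular the position and curvature of the minimum — is untouched.

The switching point itself is chosen per curve as the largest separation
on the repulsive wall (strictly below the energy minimum) where the
magnitude of the force gradient still reaches a floor (default 3 eV/Å²):
softer walls would displace the minimum, harder ones blow up the contact
energy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import brentq

from .units import DEFAULT_GRADIENT_FLOOR

__all__ = [
    "DimerCurve",
    "SoftcoreSpec",
    "UnsoftenableCurveError",
    "fit_force_polynomial",
    "select_switch_point",
    "softened_energy",
    "softened_force",
    "build_softcore_table",
    "SoftcoreTableReport",
    "read_dimer_curve",
    "write_dimer_curve",
    "write_softcore_curve",
    "read_softcore_curve",
]


class UnsoftenableCurveError(ValueError):
    """The repulsive wall never reaches the requested gradient floor."""

    def __init__(self, pair_label: str, max_gradient: float, floor: float):
        self.pair_label = pair_label
        self.max_gradient = max_gradient
        self.floor = floor
        super().__init__(
            f"curve {pair_label!r}: |dF/dr| never reaches the floor "
            f"{floor:.6g} on the repulsive wall (maximum found: {max_gradient:.6g})"
        )


@dataclass(frozen=True)
class DimerCurve:
    """Tabulated pair energy/force versus separation for one element pair.

    Parameters
    ----------
    pair_label
        Ordered element pair, e.g. ``"C-H"``.
    r
        Separations in Å, strictly increasing, at least 10 points.
    energy
        Pair energy in kcal/mol.
    force
        Radial force in kcal/mol/Å with the convention F = -dE/dr
        (repulsive wall positive).
    energy_fn, force_fn, dforce_fn
        Optional analytic callables.  When present they take precedence
        over grid interpolation, which mirrors how an analytic reference
        potential stands in for an ab initio curve.
    """

    pair_label: str
    r: np.ndarray
    energy: np.ndarray
    force: np.ndarray
    energy_fn: Callable[[float], float] | None = None
    force_fn: Callable[[float], float] | None = None
    dforce_fn: Callable[[float], float] | None = None
    consistency_rtol: float = 5e-2

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        e = np.asarray(self.energy, dtype=float)
        f = np.asarray(self.force, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "energy", e)
        object.__setattr__(self, "force", f)
        if r.ndim != 1 or r.size < 10:
            raise ValueError(f"curve {self.pair_label!r}: need >= 10 grid points")
        if not (e.shape == r.shape and f.shape == r.shape):
            raise ValueError(f"curve {self.pair_label!r}: column length mismatch")
        if not np.all(np.diff(r) > 0):
            raise ValueError(f"curve {self.pair_label!r}: r must be strictly increasing")
        if not (np.all(np.isfinite(e)) and np.all(np.isfinite(f))):
            raise ValueError(f"curve {self.pair_label!r}: non-finite tabulated values")
        self._check_force_consistency()

    def _check_force_consistency(self) -> None:
        # F must agree with -dE/dr on the interior grid; central differences
        # are 2nd order so the tolerance is scale-aware rather than strict.
        r, e, f = self.r, self.energy, self.force
        dEdr = (e[2:] - e[:-2]) / (r[2:] - r[:-2])
        ref = -dEdr
        scale = np.maximum(np.abs(f[1:-1]), np.max(np.abs(f)) * 1e-3 + 1e-12)
        rel = np.abs(f[1:-1] - ref) / scale
        # central differences on a coarse wall overshoot; compare medians too
        if np.median(rel) > self.consistency_rtol and np.max(rel) > 10 * self.consistency_rtol:
            raise ValueError(
                f"curve {self.pair_label!r}: tabulated force disagrees with -dE/dr "
                f"(median relative deviation {np.median(rel):.3g})"
            )

    # -- interpolation helpers -------------------------------------------
    def energy_at(self, r: float) -> float:
        if self.energy_fn is not None:
            return float(self.energy_fn(r))
        return float(CubicSpline(self.r, self.energy)(r))

    def force_at(self, r: float) -> float:
        if self.force_fn is not None:
            return float(self.force_fn(r))
        return float(CubicSpline(self.r, self.force)(r))

    def force_derivative_at(self, r: float) -> float:
        """dF/dr at ``r``: analytic if available, else a local 4th-order fit."""
        if self.dforce_fn is not None:
            return float(self.dforce_fn(r))
        return _local_polynomial_derivative(self.r, self.force, r)

    @property
    def r_min_energy(self) -> float:
        """Grid separation of the tabulated energy minimum."""
        return float(self.r[int(np.argmin(self.energy))])


def _local_polynomial_derivative(x: np.ndarray, y: np.ndarray, x0: float, npts: int = 5) -> float:
    """Derivative of y(x) at x0 from a local degree-(npts-1) polynomial fit.

    Equivalent to 4th-order central differences on uniform grids while
    remaining exact on nonuniform ones.
    """
    idx = np.argsort(np.abs(x - x0))[:npts]
    idx = np.sort(idx)
    xs, ys = x[idx], y[idx]
    # center for conditioning
    coef = np.polynomial.polynomial.polyfit(xs - x0, ys, deg=len(xs) - 1)
    return float(coef[1])


@dataclass(frozen=True)
class SoftcoreSpec:
    """Fitted ``a r^10 + b`` softening of one dimer curve.

    The softened force is ``a r^10 + b`` for r <= r_switch and the
    reference force beyond; the softened energy integrates the polynomial
    analytically from the seam, so both are C1 at ``r_switch``.
    """

    pair_label: str
    r_switch: float
    a: float  # kcal/mol/Å^11
    b: float  # kcal/mol/Å
    E_switch: float  # kcal/mol
    gradient_floor: float = DEFAULT_GRADIENT_FLOOR
    curve: DimerCurve | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.r_switch > 0:
            raise ValueError("r_switch must be positive")

    @property
    def energy_at_contact(self) -> float:
        """Softened energy at r = 0 (finite by construction)."""
        return self.E_switch + self.a * self.r_switch**11 / 11.0 + self.b * self.r_switch

    def energy_cap(self) -> float:
        """E(0) minus the curve minimum — the pairwise barrier a fully
        overlapping pair must climb (diagnostic; typically a few hundred
        kcal/mol for chemically sensible walls)."""
        if self.curve is None:
            return math.nan
        if self.curve.energy_fn is not None:
            # refine the minimum off-grid with the analytic energy
            i = int(np.argmin(self.curve.energy))
            lo = self.curve.r[max(i - 1, 0)]
            hi = self.curve.r[min(i + 1, self.curve.r.size - 1)]
            from scipy.optimize import minimize_scalar

            res = minimize_scalar(self.curve.energy_fn, bounds=(lo, hi), method="bounded")
            e_min = float(res.fun)
        else:
            e_min = float(np.min(self.curve.energy))
        return self.energy_at_contact - e_min


def fit_force_polynomial(curve: DimerCurve, r_switch: float) -> SoftcoreSpec:
    """Fit ``F_sc(r) = a r^10 + b`` matching F and dF/dr at ``r_switch``.

    ``a = F'(r_switch) / (10 r_switch^9)`` and
    ``b = F(r_switch) - a r_switch^10`` reproduce the reference force
    value and first derivative at the seam exactly.

    Raises
    ------
    ValueError
        If ``r_switch`` lies outside the tabulated grid (range error) or
        at/beyond the energy-minimum separation (softening the minimum
        would shift equilibrium properties).
    """
    if not (curve.r[0] <= r_switch <= curve.r[-1]):
        raise ValueError(
            f"r_switch={r_switch:.6g} outside curve grid "
            f"[{curve.r[0]:.6g}, {curve.r[-1]:.6g}]"
        )
    if r_switch >= curve.r_min_energy:
        raise ValueError(
            f"r_switch={r_switch:.6g} at or beyond the energy minimum "
            f"({curve.r_min_energy:.6g} Å): refusing to soften the minimum"
        )
    F = curve.force_at(r_switch)
    dF = curve.force_derivative_at(r_switch)
    a = dF / (10.0 * r_switch**9)
    b = F - a * r_switch**10
    return SoftcoreSpec(
        pair_label=curve.pair_label,
        r_switch=float(r_switch),
        a=a,
        b=b,
        E_switch=curve.energy_at(r_switch),
        curve=curve,
    )


def select_switch_point(
    curve: DimerCurve,
    gradient_floor: float = DEFAULT_GRADIENT_FLOOR,
    tol: float = 1e-6,
) -> float:
    """Largest admissible separation where |dF/dr| still reaches the floor.

    The admissible region is the repulsive wall strictly below the energy
    minimum (upper bound: the grid point immediately below the tabulated
    minimum).  On an LJ-like wall |dF/dr| grows monotonically toward
    small r, so the constraint-minimizing point is the root of
    |dF/dr| = floor, located by bisection to ``tol`` Å.

    Raises
    ------
    UnsoftenableCurveError
        If the wall never reaches the floor.
    """
    i_min = int(np.argmin(curve.energy))
    if i_min == 0:
        raise ValueError(f"curve {curve.pair_label!r}: no repulsive wall below the minimum")
    r_hi = float(curve.r[i_min - 1])
    r_lo = float(curve.r[0])

    def g(r: float) -> float:
        return abs(curve.force_derivative_at(r))

    if g(r_hi) >= gradient_floor:
        return r_hi
    if g(r_lo) < gradient_floor:
        grid = np.linspace(r_lo, r_hi, 256)
        raise UnsoftenableCurveError(
            curve.pair_label, max(g(r) for r in grid), gradient_floor
        )
    root = brentq(lambda r: g(r) - gradient_floor, r_lo, r_hi, xtol=tol)
    return float(root)


def softened_force(spec: SoftcoreSpec, r: float) -> float:
    """Softened radial force: polynomial below the seam, reference above."""
    if r > spec.r_switch:
        if spec.curve is None:
            raise ValueError("reference curve required to evaluate beyond r_switch")
        return spec.curve.force_at(r)
    return spec.a * r**10 + spec.b


def softened_energy(spec: SoftcoreSpec, r: float) -> float:
    """Softened pair energy, finite down to r = 0.

    For r <= r_switch this is the analytic integral of the force
    polynomial upward from the seam::

        E(r) = E_switch + a (r_switch^11 - r^11)/11 + b (r_switch - r)

    (recall F = -dE/dr, so integrating the force from r to r_switch adds
    energy on approach).  For r > r_switch the reference energy is
    returned unchanged.
    """
    if r < 0:
        raise ValueError("separation must be non-negative")
    if r > spec.r_switch:
        if spec.curve is None:
            raise ValueError("reference curve required to evaluate beyond r_switch")
        return spec.curve.energy_at(r)
    rs = spec.r_switch
    return spec.E_switch + spec.a * (rs**11 - r**11) / 11.0 + spec.b * (rs - r)


# ---------------------------------------------------------------------------
# batch fitting and serialization
# ---------------------------------------------------------------------------


@dataclass
class SoftcoreTableReport:
    """Outcome of fitting a batch of pair curves.

    ``specs`` holds successful fits; ``failures`` maps pair labels to the
    error message, so partial output is visible instead of dropped.
    """

    specs: dict[str, SoftcoreSpec]
    failures: dict[str, str]
    r_switch: dict[str, float]
    energy_cap: dict[str, float]

    @property
    def ok(self) -> bool:
        return not self.failures

    def summary(self) -> str:
        lines = ["pair        r_switch(Å)   E(0)-E(min) (kcal/mol)"]
        for label, spec in self.specs.items():
            lines.append(f"{label:<12}{spec.r_switch:>9.4f}   {spec.energy_cap():>12.2f}")
        for label, msg in self.failures.items():
            lines.append(f"{label:<12}FAILED: {msg}")
        return "\n".join(lines)


def build_softcore_table(
    curves: Sequence[DimerCurve] | Mapping[str, DimerCurve],
    gradient_floor: float = DEFAULT_GRADIENT_FLOOR,
    out_dir: str | Path | None = None,
) -> SoftcoreTableReport:
    """Fit one :class:`SoftcoreSpec` per pair curve; optionally serialize.

    Per-pair failures (e.g. a wall that never reaches the gradient floor)
    are collected in the report rather than aborting the batch.
    """
    if isinstance(curves, Mapping):
        items: Iterator[DimerCurve] = iter(curves.values())
    else:
        items = iter(curves)
    specs: dict[str, SoftcoreSpec] = {}
    failures: dict[str, str] = {}
    for curve in items:
        try:
            rs = select_switch_point(curve, gradient_floor)
            specs[curve.pair_label] = fit_force_polynomial(curve, rs)
        except (ValueError, UnsoftenableCurveError) as exc:
            failures[curve.pair_label] = str(exc)
    report = SoftcoreTableReport(
        specs=specs,
        failures=failures,
        r_switch={k: s.r_switch for k, s in specs.items()},
        energy_cap={k: s.energy_cap() for k, s in specs.items()},
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, spec in specs.items():
            write_softcore_curve(out / f"{label}.softcore.dat", spec)
        (out / "report.txt").write_text(report.summary() + "\n")
    return report


# -- file formats: 3-column whitespace-delimited text, '#' comments ---------


def write_dimer_curve(path: str | Path, curve: DimerCurve) -> None:
    header = f"# pair={curve.pair_label}\n# r(A)  energy(kcal/mol)  force(kcal/mol/A)\n"
    body = "\n".join(
        f"{r:.17g} {e:.17g} {f:.17g}"
        for r, e, f in zip(curve.r, curve.energy, curve.force)
    )
    Path(path).write_text(header + body + "\n")


def read_dimer_curve(path: str | Path, consistency_rtol: float = 5e-2) -> DimerCurve:
    pair = Path(path).stem
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if "pair=" in line:
                pair = line.split("pair=", 1)[1].split()[0]
            continue
        rows.append([float(v) for v in line.split()])
    arr = np.asarray(rows, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError(f"{path}: expected 3 columns (r, energy, force)")
    return DimerCurve(pair, arr[:, 0], arr[:, 1], arr[:, 2], consistency_rtol=consistency_rtol)


def write_softcore_curve(path: str | Path, spec: SoftcoreSpec, n_below: int = 50) -> None:
    """Write the softened curve as r/energy/force text.

    The grid is the reference grid above ``r_switch`` plus ``n_below``
    evenly spaced points covering (0, r_switch].
    """
    if spec.curve is None:
        raise ValueError("spec carries no reference curve to serialize")
    r_below = np.linspace(0.0, spec.r_switch, n_below, endpoint=False)
    r_above = spec.curve.r[spec.curve.r > spec.r_switch]
    r_all = np.concatenate([r_below, [spec.r_switch], r_above])
    e = np.array([softened_energy(spec, r) for r in r_all])
    f = np.array([softened_force(spec, r) for r in r_all])
    header = (
        f"# pair={spec.pair_label} r_switch={spec.r_switch:.17g} "
        f"a={spec.a:.17g} b={spec.b:.17g} E_switch={spec.E_switch:.17g}\n"
        "# r(A)  energy(kcal/mol)  force(kcal/mol/A)\n"
    )
    body = "\n".join(f"{r:.17g} {ee:.17g} {ff:.17g}" for r, ee, ff in zip(r_all, e, f))
    Path(path).write_text(header + body + "\n")


def read_softcore_curve(path: str | Path) -> tuple[dict, np.ndarray]:
    """Read a serialized softened curve: (header metadata, Nx3 array)."""
    meta: dict = {}
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for tok in line[1:].split():
                if "=" in tok:
                    key, val = tok.split("=", 1)
                    try:
                        meta[key] = float(val)
                    except ValueError:
                        meta[key] = val
            continue
        rows.append([float(v) for v in line.split()])
    return meta, np.asarray(rows, dtype=float)
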