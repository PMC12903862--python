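# Methods

This note records the models, numerical choices, and validation logic
behind `alchemfe`, in the order the pipeline uses them.

## Softcore construction (`alchemfe.softcore`)

A tabulated dimer curve (r, E, F with F = −dE/dr, repulsive positive) is
softened by replacing the force below a switching separation r_s with

    F_sc(r) = a r¹⁰ + b,
    a = F′(r_s) / (10 r_s⁹),    b = F(r_s) − a r_s¹⁰,

which matches the reference force in value and slope at the seam
exactly. The energy below r_s is the analytic integral

    E_sc(r) = E(r_s) + a (r_s¹¹ − r¹¹)/11 + b (r_s − r),

so energy and force remain mutually consistent, the curve is C¹ at the
seam, and E(0) is finite. A tenth-order polynomial keeps contact
energies and forces smaller than lower-order softening forms with the
same seam conditions, because its force rises steeply only near the
seam.

**Switching-point rule.** r_s is the largest separation strictly below
the energy minimum at which |dF/dr| ≥ floor. The floor defaults to
3 eV/Å² (69.18 kcal/mol/Å², using 1 eV = 23.0605 kcal/mol); the working
units are kcal/mol and Å throughout so free energies come out in
kcal/mol. Because |dF/dr| grows monotonically down an LJ-like wall, the
constrained maximizer is the root of |dF/dr| = floor, found by bisection
to 1e−6 Å between the first grid point and the grid point immediately
below the tabulated minimum (with floor = 0 the upper bound itself is
returned). This rule minimizes the seam gradient subject to the floor,
i.e. it softens as much as allowed without touching the minimum's
position or curvature. A wall that never reaches the floor raises an
"unsoftenable" error carrying the largest gradient found. The search
direction and discretization of this rule were a genuinely open design
point; the monotone-wall reading above is the one implemented and
asserted.

**Derivatives on grids.** When a curve carries analytic callables they
are used directly; otherwise F′ comes from a local degree-4 polynomial
fit through the 5 nearest grid points (equivalent to 4th-order central
differences on uniform grids, well-defined on nonuniform ones), and
off-grid E and F values from cubic splines.

The per-pair contact cap E(0) − E(min) is reported as a diagnostic
only — it is an emergent property of the floor, not an enforced
constraint. Softened curves serialize as 3-column text with a header
naming the pair, r_s, a, b and E(r_s), at 17 significant digits so round
trips are bit-exact.

## λ-dependent potentials (`alchemfe.potentials`)

*Linear mixing.* `linear_hamiltonian` returns
H(λ) = λH₁ + (1−λ)H₀ with ∂H/∂λ = H₁ − H₀; end states are returned
verbatim (no floating-point mixing at λ ∈ {0, 1}).

*Beutler softcore LJ.* Implemented exactly as
U = 4ελⁿ[(α_LJ(1−λ)ᵐ + (r/σ)⁶)⁻² − (α_LJ(1−λ)ᵐ + (r/σ)⁶)⁻¹] with the
original constants α_LJ = 0.5, m = 2, n = 4 as defaults. At λ = 1 and
r = 0 the evaluation is genuinely singular and raises rather than
returning inf.

*Body-ordered graph model.* The miniature model keeps the part of the
architecture the λ-scaling acts on and drops everything orthogonal to
it: features are rotation-invariant (the l = 0 limit; no spherical
harmonics or Clebsch–Gordan products), built from Gaussian radial basis
functions under a C² polynomial cutoff envelope and per-species
embeddings. Per atom,

    A_i,k = Σ_j α_ij R_k(r_ij) (U h_j)_k,
    E_i = Σ_t Σ_ν Σ_k w_tνk (A_i,k)^ν,   ν = 1..3,

with α_ij = λ on boundary-crossing edges and 1 otherwise, applied
identically in every message-passing layer (the one-particle basis is
rebuilt per layer, so the factor reappears wherever the basis does).
The node update between layers is linear in the pooled features; the
readout powers carry the nonlinearity. This preserves the two
end-state identities structurally: all α = 1 at λ = 1 removes the
factor from the expression, and α = 0 across the boundary at λ = 0
makes every quantity a function of one component only, so the total
energy equals the sum over isolated components without any cancellation
error beyond arithmetic round-off. Weights are drawn once from a
recorded seed and never trained — every property the model is used to
demonstrate (end-state consistency, λ-smoothness, invariances) holds
for arbitrary weights.

An optional per-pair softcore table adds the softened dimer energy as an
explicit pair term, scaled by the same α_ij, giving finite energies for
overlapping atoms at any λ < 1. Forces for this model come from central
finite differences; it is exercised on few-atom systems where that is
exact enough (1e−5) and cheap. The analytic-force models used for
actual sampling are pairwise: `AlchemicalLJFluid` (plain
truncated-shifted LJ within solvent/solute, Beutler softcore across the
boundary, each shifted by its own cutoff value so the energy is
continuous at r_c for every λ), `HarmonicTetherModel`
(k(λ) = (1−λ)k₀ + λk₁), and `IdealGasModel`.

Periodicity is handled by the minimum-image convention for diagonal
(orthorhombic) boxes only, with the box edge required to exceed twice
the model cutoff — asserted, not assumed. The LJ pair evaluation floors
r at 1e−6 σ so that exact overlaps produced by an optimizer's line
search give astronomically large but finite energies instead of NaN.

## Sampling (`alchemfe.sampling`)

*Langevin.* BAOAB splitting, chosen for its configurational accuracy at
finite step size; velocities are drawn from Maxwell–Boltzmann on first
use. Protocol defaults mirror a standard condensed-phase setup — 1 fs
time step, 1 ps⁻¹ friction, 1 atm, swap attempts every 1000 steps
(1 ps), 16 windows, 50 ps NPT equilibration at full coupling — and every
one is configurable; the shipped reduced-unit fixtures use
correspondingly reduced values (dt = 0.004–0.05 τ).

*Barostat.* Isotropic volume moves accepted with
exp(−β[Δu + pΔV − N kBT ln(V′/V)]), proposal width auto-tuned toward
~40% acceptance every 50 attempts and clamped to [1e−4, 0.3] of the
current volume.

*Minimization.* Generic quasi-Newton line searches fail on stiff pair
walls (a trial step can push atoms through each other), so minimization
runs a backtracking steepest-descent stage with per-component
displacements capped at 0.1 length units before an L-BFGS polish to the
gradient tolerance. The final energy never exceeds the initial one.

*Replica exchange.* Swap bookkeeping exchanges thermodynamic states
(λ labels), not coordinates — statistically identical and free. Each
sweep makes many randomized adjacent-pair attempts (default K²), which
approximates all-pair mixing while keeping each individual move a
nearest-neighbor Metropolis exchange on the reduced-potential cross
terms; this reconciles per-pair exchange with effectively global
mixing and is a deliberate design choice, not a claim about any
particular reference scheme. Every replica owns an independent stream
spawned from the master seed, plus one stream for swap decisions, so
results are independent of evaluation order. The empirical transition
matrix of λ-slot occupancy between consecutive sweeps (row-stochastic;
identity when nothing swaps) is the standard mixing diagnostic — a
healthy schedule shows at least a connected tridiagonal band.

## Estimation (`alchemfe.estimators`)

*Decorrelation.* g = 1 + 2Σ C(t)(1 − t/T), truncated at the first
non-positive autocorrelation; equilibration detection scans candidate
truncation points t0 (every sample up to 10⁴ points, strided beyond)
and keeps the one maximizing N_eff = (T − t0)/g, ties toward smaller
t0. Subsampling takes every ⌈g⌉-th sample after t0.

*TI.* Trapezoidal quadrature of per-window ⟨∂H/∂λ⟩ with independent
window errors propagated through the weights. Trapezoid was chosen over
spline quadrature for transparency; with a dense schedule its bias is
below the statistical noise of any realistic run.

*BAR.* The Bennett self-consistent equation solved by bracketed Brent
iteration to 1e−10, with the Bennett asymptotic variance from
fermi-function moments. Work convention: both arrays are u₁ − u₀
evaluated on samples from state 0 (forward) and state 1 (reverse), so
perfectly symmetric states give Δf = 0 with w_R = −w_F.

*MBAR.* Self-consistent iteration from f = 0 until within 1e−6, then
damped Newton on the sampled states (f₀ gauge-fixed at 0) to a gradient
max-norm of 1e−10; unsampled states are evaluated perturbatively
afterwards. The asymptotic covariance uses the SVD form of the weight
matrix; reported ΔG errors are √(Θ₀₀ + Θ_KK − 2Θ₀K) · kBT. The overlap
matrix O = Wᵀ diag(N) W is row-stochastic by construction and its
subdominant eigenvalue gap is reported as a connectivity diagnostic.
BAR and MBAR are deliberately independent code paths so their K = 2
agreement (asserted to 1e−8) is a real cross-check. u_kn matrices are
stored C-contiguously so estimates are bit-reproducible across
serialization round trips (pairwise summation is layout-dependent).

*log P.* (ΔG_hyd − ΔG_oct)/(2.303 R T) with R = 1.9872×10⁻³
kcal/(mol K) and leg errors combined in quadrature.

## Pipeline (`alchemfe.pipeline`)

A leg runs build → minimize → equilibrate at λ = 1 → seed all replicas
from the last frame → REMD → per-window equilibration detection and
g-subsampling → MBAR → report. Configurations are validated up front
with *every* violation listed at once. The master seed fans out through
`SeedSequence.spawn` to the builder, equilibration, each replica, and
the swap stream; the same config is exactly reproducible, and the
archived u_kn (text + JSON sidecar with K, N_k, T, p, kB, schedule)
re-estimates to bit-identical ΔG via the standalone estimator.

Boxes are cubic with the solute at the center of a jittered solvent
lattice — at toy scale solvent economy is irrelevant and cubic boxes
keep minimum-image logic trivially correct (and asserted). The default
λ schedule places half its windows in [0.15, 0.4] with exact endpoints.
Samples are recorded *before* each swap sweep so every configuration is
attributed to the state that generated it. Convergence is traced by
re-estimating on growing prefixes (25/50/75/100% of iterations).

## Synthetic fixtures and what passing means (`alchemfe.synthetic`)

The fixtures target statistical, not chemical, realism:

- **Analytic dimers** (LJ, Morse) carry exact energy/force/curvature
  callables, standing in for ab initio reference curves. They validate
  the softcore fit to machine precision but say nothing about how well
  a learned model fits real walls.
- **Harmonic λ-families** have exact reduced free energies
  (d/2) ln(k/k₀), exercising TI/BAR/MBAR and the full REMD pipeline
  with zero oracle error. They are unimodal and trivially ergodic, so
  they do not probe slow conformational sampling.
- **Gaussian work models** generate Crooks-consistent forward/reverse
  samples with Δf = μ − σ²/2, probing estimator correctness in the
  regime where BAR is provably optimal.
- **Fluids**: the ideal gas (exact zero excess chemical potential,
  exact barostat density p/kBT) and a 32+1-particle LJ fluid at reduced
  T* = 2.0, ρ* = 0.3 in reduced units (kB = 1, lengths in σ, energies
  in ε). The fluid's decoupling ΔG is cross-checked against Widom
  test-particle insertion on independent pure-solvent trajectories —
  two estimators, two codepaths, one physical quantity. The state point
  is supercritical and moderately dilute so both routes converge in
  seconds; dense liquids would need far longer runs and inserted-ghost
  statistics the Widom method handles poorly.

Problem sizes in the shipped tests and the acceptance script (10⁴
samples per harmonic window, 10⁵ Gaussian work samples, 200 REMD
iterations × 100 steps for the LJ leg, 3×10⁴ insertions) were chosen so
every stochastic assertion sits at ≥3 estimated standard errors from
its oracle while the whole suite remains a desk-scale computation.

## Known limitations

- The body-ordered model is invariant-only (l = 0) and untrained;
  equivariant channels and learned weights would change none of the
  identities tested but all of the physics.
- No long-range electrostatics anywhere; pair interactions are cut off
  and shifted.
- Only diagonal boxes; no constraint algorithms, no multi-timestep
  integration, serial execution only.
- The MBAR error bar assumes decorrelated samples after g-subsampling;
  replica-exchange-induced correlations between windows are neglected,
  which is the standard practice the diagnostics (overlap and
  transition matrices) are meant to keep honest.
- The Bennett BAR variance underestimates uncertainty for essentially
  disjoint work distributions; the estimate still converges and is
  flagged by its magnitude relative to well-overlapped runs.
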