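# Methods

## Model

A closed, embedded plane curve Γ(t) is parameterized by
**x**(ξ, t), ξ ∈ [0, 1] periodic, and evolves with normal velocity

    V = ẋ · n = α(x, t) κ + β(x, t),      α ≥ 0,

which is classical curve shortening flow for α = 1, β = 0. The shape of the
curve is fully determined by V; the tangential velocity is free and is used
here to control mesh quality. It is derived from a gradient flow for an
equidistribution functional of a positive monitor function M(x, t): the
parameterization equidistributes M when (M |x_ξ|)_ξ = 0, and the relaxation
toward that state at time scale τ gives

    ẋ · t = P (M |x_ξ|)_ξ / (τ (M |x_ξ|)²),

where the positive operator P selects the gradient-flow metric: P = 1 is
steepest descent, while P = M |x_ξ|² ("balanced") makes the relaxation rate
approximately uniform along the curve and, in practice, makes the results
insensitive to τ over several orders of magnitude.

Assumptions: the curve stays closed and non-degenerate (no chord collapse);
α ≥ 0; the monitor is built from geometry only (no solution fields). A
self-intersecting initial curve is allowed — the method evolves it until
the geometric singularity, where the fully implicit solver stops (this is
singularity *detection*); no topological surgery is attempted.

## Monitor function

Two monitors are implemented:

* `uniform`: M = 1, equidistributing arc length;
* `curvature`: M_i = ½ M_floor + ½ |κ_i|^γ, with the adaptive floor

      M_floor = (1/|Γ_h|) Σ_j ((|κ_{j+1}|^γ + |κ_j|^γ)/2) h_j

  (trapezoid quadrature of the mean of |κ|^γ over the polygon). The floor
  keeps M > 0 on flat segments with no a-priori parameter and adapts to the
  evolving curve; it is recomputed from the current frame at every
  evaluation.

The exponent γ defaults to ½: equidistributing |κ|^{1/2} minimizes the
maximal distance between a smooth curve and its linear interpolant, which
follows from the standard interpolation bound h²|κ|/8 per segment. γ = 1/3
(minimal enclosed-area discrepancy) and γ = 2/3 (minimal length
discrepancy) are exposed as options through `MonitorSpec.exponent`.

Monitor values are smoothed by a periodic weighted average with weights
(q/(q+1))^{|k|} for offsets |k| ≤ p (defaults p = 2, q = 3, i.e. weights
9/16, 3/4, 1, 3/4, 9/16). Smoothing is a convex combination — positivity
and bounds are preserved — and is applied at every monitor evaluation
(each time step and inside the de Boor iteration); it can be disabled via
`MonitorSpec.smoothing_enabled` for diagnostics.

## Spatial discretization

N nodes x_i, i = 0..N−1, with periodic index arithmetic and uniform
parameter step Δξ = 1/N. Central differences give

    t_i = (x_{i+1} − x_{i−1}) / |x_{i+1} − x_{i−1}|,     n_i = (t_{i,2}, −t_{i,1}),
    κ_i = 4 (x_{i−1} − 2 x_i + x_{i+1}) · n_i / |x_{i+1} − x_{i−1}|².

With this normal convention a counterclockwise convex curve has κ < 0 and
an outward normal, so V = κ moves it inward, consistent with the shrinking
circle r(t) = √(1 − 2t). (The continuous convention det(t, n) = 1 has the
opposite sign; the discrete recipe above is used consistently throughout,
so no sign flip is ever needed.) Edge j has length h_j = |x_{j+1} − x_j|
and |Γ_h| = Σ h_j; the enclosed area is the shoelace sum.

## Time integration

The interval (0, T] is split into N_T steps Δt = T/N_T. Per node, the
normal equation is projected on the (lagged) normal and the tangential
equation on the (lagged) tangent, giving 2N scalar equations. With
μ_i = 4Δt α_i / |x_{i+1} − x_{i−1}|² the normal stencils are

* **BE**: (−μ x_{i−1} + (1+2μ) x_i − μ x_{i+1}) · n_i = x_i^n · n_i + Δt β_i,
  everything geometric at the current Picard iterate;
* **CNBE**: (−μ/2 x_{i−1} + (1+μ) x_i − μ/2 x_{i+1}) · n̄_i with the
  *unnormalized* averaged normal n̄_i = (n_i^{iter} + n_i^n)/2, and the
  right-hand side carrying the explicit half of the diffusion,
  (μ_i^n/2)(x_{i−1}^n − 2x_i^n + x_{i+1}^n) · n̄_i + x_i^n · n̄_i
  + (Δt/2)(β_i^{iter} + β_i^n).

The tangential equation uses backward Euler for both schemes (its job is
mesh relaxation, and BE's stability dominates any accuracy argument):

    (−ν x_{i−1} + (1+2ν) x_i − ν x_{i+1}) · t_i
        = x_i^n · t_i + Δt P_i (M_{i+1} − M_{i−1}) / (τ M_i² |x_{i+1} − x_{i−1}|),

with ν_i = 4Δt M_i P_i / (τ (M_i |x_{i+1} − x_{i−1}|)²). The drive term's
form follows from writing the tangential PDE as
(ẋ − PM/(τ(M|x_ξ|)²) x_ξξ) · t = P M_ξ |x_ξ| / (τ (M|x_ξ|)²) before
discretizing: the central-difference chord in M_ξ|x_ξ| cancels one chord
power of the denominator. M and P are always evaluated at the previous
*time level* (explicit treatment), once per step, and reused across Picard
sweeps.

**Discrete P.** For `p_mode="balanced"`, P_i = M_i (|x_{i+1} − x_{i−1}| /
(2Δξ))², i.e. |x_ξ| by scaled central differences. Retaining the Δξ scaling
keeps τ's meaning independent of N (the relaxation rate per step scales as
Δt N²/τ for a fixed curve), which matches the observed robustness of the
balanced operator to τ; the bare-chord variant (Δξ absorbed into τ) is
available via `SchemeConfig.p_dxi_scaling=False`. The default is the
variant under which the benchmark iteration counts and the singularity
window reproduce.

## Picard iteration and linear solves

Starting from x^{[0]} = x^n, each sweep freezes the geometric coefficients
at the current iterate and solves the resulting linear system exactly. The
stopping rule is max_i |x_i^{[m+1]} − x_i^{[m]}| < 10⁻⁶ (maximum over nodes
of the Euclidean nodal displacement — the scale-free, strictest common
reading of a tolerance on the iterate difference), with a hard budget of
200 sweeps; exhausting the budget stops the simulation and reports the time
(singularity detection). In semi-implicit mode (`picard_cap`) exactly 1
(BE) or 2 (CNBE) sweeps are taken with no tolerance test, which allows
stepping across the singular time.

The 2N×2N matrix couples only nodes {i−1, i, i+1} (interleaved unknowns
x_0, y_0, x_1, y_1, …), i.e. a bandwidth-3 band plus two 2×2 periodic
corner blocks. The solve factorizes the band with LAPACK's pivoted banded
LU and folds the corners in by a rank-4 Woodbury update — O(N) per solve
and verified against dense solves to machine precision; a sparse direct
solve is the fallback if the band factorization fails or produces
non-finite values. Runs are deterministic: there is no randomness anywhere
in the method.

## Initial mesh: iterated de Boor equidistribution

Given a parametric generator x(u), one de Boor step approximates
ρ(u) = M(u)|x_u| as piecewise constant per cell (midpoint values: M by
averaging the two neighbouring node values, |x_u| analytically when the
generator supplies a derivative, otherwise by small-step central
differences), builds the cumulative integral R and places the new break
points at R⁻¹(k R(1)/N) by inverse linear interpolation — exact, since R is
piecewise linear and increasing. The curve is re-sampled and the monitor
re-evaluated each iteration; the loop stops when the partition update drops
below `tol` (default 10⁻¹⁰, `max_iter` 100 — on the benchmark curves
convergence takes well under 20 iterations). Non-convergence raises a
warning and returns the last partition rather than failing, since the
iteration is contractive on all tested fixtures.

A note on diagnostics: the discrete equidistribution ratio
max_j w_j / min_j w_j with w_j = ((M_j + M_{j+1})/2) h_j is evaluated on
*chords* and node-trapezoid monitor values, which differ from the midpoint
density the de Boor step equidistributes by O(1/N²). The converged mesh
therefore shows a ratio of 1 + O(1/N²) (≈ 1.00004 at N = 128 on the
ellipse), not 1 + O(tol); exact equidistribution holds at the level of the
parametric density.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| `scheme` | BE or CNBE time integrator | CNBE | CNBE is second-order in the area error |
| `dt`, `t_final` | time step and horizon (time units of the flow) | — | `t_final` must be a multiple of `dt` |
| `tau` | mesh relaxation time | 1.0 | smaller = faster equidistribution; avoid τ ≪ Δt with P = 1 |
| `p_mode` | P = 1 or P = M\|x_ξ\|² | identity | balanced is robust to τ over 0.1–10 |
| `picard_tol` | nodal-update stopping tolerance | 1e−6 | absolute, in curve coordinates |
| `picard_max` | sweep budget | 200 | exhaustion ⇒ singularity signal |
| `picard_cap` | semi-implicit fixed sweep count | off | 1 for BE, 2 for CNBE |
| `MonitorSpec.exponent` | γ in \|κ\|^γ | 0.5 | 1/3, 2/3 supported |
| `MonitorSpec.smooth_p/q` | smoothing stencil | 2 / 3.0 | weights (q/(q+1))^{\|k\|} |
| de Boor `tol` / `max_iter` | partition update tolerance | 1e−10 / 100 | |

## Benchmark curves and what the tests show

The named generators (`circle`, `ellipse` 3:1, a multi-lobed `nonconvex`
curve, the `selfintersect` double-traversal curve, the unit `lpball` with
p = 10) are analytic closed curves sampled at run time; they exercise
constant curvature, moderate and extreme curvature variation,
self-intersection, and near-flat segments with corner-like regions. They
are *not* noisy, open, or data-derived contours: passing the suite shows
correct geometry, convergence orders (first-order BE, second-order CNBE in
time; second-order in space), monitor-driven accuracy gains, and
singularity detection on smooth analytic inputs — it does not exercise
measurement noise, image-derived forcing fields, or curves given only as
pixel chains, and the area-based error norm can in principle hide
shape-preserving error components.

Problem sizes used by the bundled studies: the circle studies use N = 10⁴
with N_T ∈ {10..160} (temporal) and N ∈ {160..2560} with N_T = 10⁴
(spatial); the ellipse monitor comparison N = 160, N_T = 10⁴; the
singularity run N = 10³, Δt = 10⁻⁵, τ = 10⁻³; the forced l_p-ball study
N = 160 with N_T ∈ {40..160} against a gold standard at ten times the
finest temporal resolution — for forced flow no closed-form area exists,
so the reference is a self-computed CNBE run, and errors are measured at
the final time.

## Known limitations

* Fixed time step; Picard non-convergence could drive temporal adaptivity
  but currently only stops (or, capped, skips) the step.
* No self-intersection detection or surgery; evolution past a singularity
  in capped mode is a formal continuation, not a weak solution.
* The tangential scheme is first-order in time by design; the observed
  second-order area accuracy of CNBE relies on tangential motion not
  affecting shape.
* Geometric monitors only; solution-field monitors (e.g. for
  membrane-bound concentrations) are out of scope.
* Planar curves only — no surfaces, no 3D.
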