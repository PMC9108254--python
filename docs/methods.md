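# Methods

## Model

`rpinverse` implements a one-dimensional reaction–diffusion model of
photoreceptor degeneration in retinitis pigmentosa (RP) under the trophic
factor hypothesis: rods produce a diffusible factor (rod-derived cone
viability factor, RdCVF) that cones require; mutation-driven rod loss
depletes the factor and secondary cone death follows.

The domain is the temporal horizontal meridian of a spherical retina,
parameterized by scaled eccentricity θ ∈ [0, 1] between the foveal centre
(θ = 0) and the ora serrata (θ = 1, physically Θ = 1.33 rad).  All
quantities are dimensionless.  The state is the TF concentration f(θ, t),
rod density p_r(θ, t), and cone density p_c(θ, t):

    ∂f/∂t   = D_f [ ∂²f/∂θ² + Θ cot(Θθ) ∂f/∂θ ] + α p_r − β f p_c − η f
    ∂p_r/∂t = −φ_r(θ) p_r
    ∂p_c/∂t = −p_c λ₂(f),     λ₂ = 1 − H(f − f_crit(θ))

with zero-flux conditions ∂f/∂θ = 0 at both ends.  Healthy densities are
p̃_r(θ) = B₃ θ e^(−b₃θ) (rods vanish at the fovea, peak mid-periphery) and
p̃_c(θ) = B₁ e^(−b₁θ) + B₂ e^(−b₂θ) (cones densest at the fovea).  The
initial condition is the healthy state: p_r, p_c at their healthy profiles
and f at the steady state consistent with them.

Cones are healthy while f stays at or above the local threshold
f_crit(θ) and decay at unit dimensionless rate below it — there is no
separate cone decay constant; the rate 1 is built into λ₂ and is easy to
misread.

### Parameters

| symbol | meaning | default |
|---|---|---|
| Θ  | ora serrata eccentricity | 1.33 rad |
| D_f | TF diffusivity | 0.237 |
| α  | TF production by rods | 7.01×10⁴ (Scaling 1) or 7.01×10² (Scaling 2) |
| β  | TF consumption by cones | 1.79×10⁶ (Scaling 1) or 1.79×10⁴ (Scaling 2) |
| η  | TF decay | 1.79×10² |
| φ_r | rod degeneration rate | 7.33×10⁻² (constant default; may be spatial) |
| f_crit | TF threshold | 3×10⁻⁵ (constant default; may be spatial) |
| B₁, B₂, B₃ | profile amplitudes | 1.56, 0.158, 10.6 |
| b₁, b₂, b₃ | profile decay rates | 71.8, 2.67, 3.06 |

The two scalings are distinct asymptotic regimes: under Scaling 1 TF
production/consumption dominate decay; under Scaling 2 all three balance.
Both share α/β, so the production:consumption ratio is preserved (their
rates differ by a factor of 100).  The bookkeeping parameter ε = 10⁻²
appears only in derivation cross-checks, never at runtime; in particular
p_c is *not* rescaled by ε in the solver.

## Forward solver

Method of lines: second-order central differences on a uniform θ mesh,
zero-flux via mirrored ghost nodes, integrated by SciPy's BDF
(variable-step, variable-order implicit multistep) with relative/absolute
tolerances 10⁻⁶/10⁻¹⁰ and a banded Jacobian sparsity pattern.  Mesh sizes
follow the 26/51/101/401/4001 ladder (any N ≥ 11 is accepted); 4001 nodes
corresponds to roughly one photoreceptor width per cell.

**Pole treatment.** The spherical operator's cot(Θθ) term diverges at
θ = 0.  By symmetry f_θ(0) = 0 and cot(x) ≈ 1/x, so the operator limits to
2 D_f ∂²f/∂θ², which the discrete scheme reproduces exactly for quadratic
fields (4 D_f = 0.948 for f = θ²).  No singularity arises at θ = 1 since
Θ = 1.33 < π.

**Smoothed switch.** The Heaviside in λ₂ is replaced by
(1 − tanh(k(f − f_crit)))/2 with k = s / f_crit(θ) and sharpness s = 10 by
default, i.e. a transition width one-tenth of the local threshold.  The
smoothing advances the apparent onset of cone loss by ≈ 1/(s φ_r) time
units (≈ 2.4 at the defaults), because cones accumulate ~1% loss while f is
still slightly above threshold.  This bias cancels in the numerical inverse
(target and candidate contours are extracted from the same forward model)
but matters when comparing simulated contours against the asymptotic
formulas; self-consistency checks therefore use s = 300.  An exact
Heaviside option exists (`SolverConfig.heaviside`) but the implicit
integrator steps over the discontinuity unreliably; it is not the default.

**Steady state.** The stationary TF equation is linear in f, so the
healthy initial profile f_init solves one sparse direct system
(D_f L − diag(β p_c + η)) f = −α p_r, with a residual check (< 10⁻⁸
relative) and a positivity check.  This is the fixed point a damped-Newton
nonlinear solver would reach, computed in one step.

**Foveal boundary layer.** Near θ = 0 TF balances diffusion against
consumption over a layer of width √(D_f/(β p̃_c)) ≈ 3×10⁻⁴ under Scaling 1.
Only the 4001-node mesh (h = 2.5×10⁻⁴) resolves it; coarser meshes
underestimate f_init(0) (1.2×10⁻⁵ at N ≤ 101 versus the converged
1.06×10⁻⁴).  Consequences: (i) the statement "minimum steady-state TF
exceeds the 3×10⁻⁵ threshold" is a statement about the resolved solution
and is checked at N = 4001; (ii) no-degeneration control runs must either
use N = 4001 or place the threshold below the coarse-mesh minimum,
otherwise the foveal node degenerates spuriously.

## Degeneration times

Degeneration at a node is deemed to initiate when p_c/p̃_c first reaches
0.99.  Crossing times are interpolated linearly between saved outputs
(default spacing Δt = 0.5); each node reports its *first* crossing (under
Scaling 2 two degeneration fronts can exist — one from the fovea, one from
the ora serrata).  Nodes that never cross within the horizon carry an
explicit boolean sentinel, never a large placeholder time, so objective
functions cannot silently treat "never degenerated" as a number.

## Asymptotic (QSSA) theory

TF equilibrates much faster than rods decay, so on the rod timescale
f tracks the instantaneous production/consumption balance with cones
frozen at their healthy profile:

    f_QSSA = α p_r(θ, t) / (β p̃_c(θ))        (Scaling 1)
    f_QSSA = α p_r(θ, t) / (β p̃_c(θ) + η)    (Scaling 2)

Setting f_QSSA = f_crit and using the exponential rod solution
p_r = p̃_r e^(−φ_r t) gives closed forms for the degeneration time and the
two inverses; e.g. under Scaling 1

    t_degen(θ)  = (1/φ_r)[ ln(α B₃ θ / (β B₂ f_crit)) − (b₃ − b₂) θ ]

with φ_r_inv and f_crit_inv obtained by solving for the respective
variable (these round-trip exactly, to machine precision).  Under
Scaling 2, β B₂ is replaced by β B₂ + η e^(b₂θ) throughout.  Two
approximations are embedded: the steep foveal cone term B₁ e^(−b₁θ) is
dropped (relative error ~10⁻⁵ at θ = 0.2, negligible beyond), and
diffusion is neglected, which fails near the fovea where the logarithm
diverges.  Profile-level evaluation therefore starts at the first interior
mesh node and extends flat to θ = 0, with the numerical inverse expected
to supersede that region.  Negative predicted times (possible for extreme
parameters) are clamped to zero rather than raised, keeping parameter
sweeps total.

A structural fact worth noting: p̃_r(0) = 0 exactly, so φ_r(0) has no
influence on the model whatsoever and is unidentifiable; the numerical
inverse ties the pole node to its first interior neighbour when inverting
φ_r.  f_crit(0) remains identifiable (cones are present at the fovea).

## Numerical inverse

The simulation-in-the-loop inverse adjusts profile values only at the
nodes where the analytic inverse fails.  The failure region is found by
simulating with the analytic inverse and flagging nodes whose contour
misses the target by more than 5% (relative), dilated one node each side —
an operational version of identification by eye.  Free parameters are the
log-values at those nodes (positivity without constraints); the objective
is Σ (t_degen_sim − t_target)² over the region's nodes, with a finite
penalty (horizon − target)² for nodes that fail to degenerate within the
simulation horizon (1.5 × the target's latest landmark).  φ_r profiles use
Nelder–Mead (SciPy); f_crit profiles use an in-package coordinate compass
search with a halving step schedule (initial log-step 0.5, floor 10⁻³),
which copes better with the threshold's switch-like effect on the
objective.  Stopping: objective ≤ 10⁻² (squared time units) or
200 × (free-node count) evaluations.  The result is stitched with the
analytic inverse outside the region; boundary jumps beyond the larger of
10% or one mesh-spacing times the local analytic gradient are warned
about, not enforced.  Everything is deterministic: two identical runs give
bit-identical results.

Typical problem sizes: inversions run at N = 26–101 mesh nodes with
horizon save-spacing 0.5.  A full φ_r recovery at N = 26 takes ~50
forward solves.

## Synthetic data and what tests show

`generate_fixture` produces (i) smooth positive rate/threshold profiles —
low-order polynomials around the standard constants (φ_r ≈ 7.33×10⁻²,
f_crit ≈ 3×10⁻⁵) with seeded coefficients, emulating the modest spatial
heterogeneity the inverse problem is about; and (ii) synthetic simulation
objects whose survival fraction is exp(−max(0, t − g(θ))) for a known
onset curve g, so the extracted contour has the closed form
g(θ) + ln(1/0.99).  These exercise the contour extraction and the
recovery machinery without the PDE.  They do not emulate measurement
noise, patient-to-patient variability, or azimuthal asymmetry (Pattern 2
geometries are outside a 1D model); recovery tests therefore demonstrate
correctness of the inversion machinery under the model's own dynamics,
not robustness to real clinical data.

## Target library

Eleven built-in degeneration-time patterns (Uniform; 1A linear/quadratic
up/quadratic down; 1B linear/quadratic/exponential; Pattern 3 linear 1/
linear 2/quadratic/cubic) with landmarks t₀ = 100 < t₁ = 150 < t₂ = 200
and breakpoints θ_d1..θ_d5 = 0.1, 0.55, 0.3, 0.4, 0.6 (θ_d2 is tied to
(θ_d1 + 1)/2).  Discontinuous targets are evaluated exactly as specified
(right-continuous at breakpoints), with no smoothing.  The Pattern 3
cubic is pinned by four conditions — value t₂ at the fovea, stationary
minimum t₀ at θ_d4, value t₁ at the edge — yielding closed-form rational
coefficients (200, −577.8, 1013.9, −486.1 at the defaults).  The 1B
exponential form A₁e^(−a₁θ) + A₂θe^(−a₂θ) + A₃ is validated by its foveal
value A₁ + A₃ = t₂ and an interior maximum ≈ t₁ near θ = 1/a₂.
Reporting conversions: degrees = θ·Θ·180/π; years = 0.1105 × dimensionless
time (reporting only, never used in computation).

## Known limitations

- 1D (radially symmetric) only; azimuthally asymmetric degeneration
  geometries cannot be represented.
- The inverse is solved for one spatial profile at a time with the other
  held constant; if both φ_r(θ) and f_crit(θ) vary, the inverse is
  non-unique.
- Contour timing near the fovea is sensitive to the smoothed switch at the
  very low TF concentrations there (f < 10⁻⁴); numerical inverses correct
  most, not all, of the resulting early onset.
- The coarse-mesh foveal TF underestimate described above is a
  discretization artifact users should be aware of when running below
  N = 4001.
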