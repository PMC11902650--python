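# Methods

## Problem and model

`mwtomo` reconstructs a 2D map of relative permittivity (and, for tissue,
conductivity) inside a square domain of interest from multistatic
scattered-field data collected by a circular ring of antennas.  The setting
is scalar TMz scattering: every antenna is an infinite electric line source
perpendicular to the imaging plane, so the electric field has a single
out-of-plane component and obeys the 2D Helmholtz equation.  The governing
volume integral equation links the total field `E_tot`, the incident field
`E_inc` and the contrast

    chi(r) = eps_r(r)/eps_b - 1 - j (sigma(r) - sigma_b) / (omega eps0 eps_b),

through the outgoing background Green kernel
`G(r, r') = -(j k_b^2 / 4) H0^(2)(k_b |r - r'|)` (time convention
`e^{+j omega t}`; the conductivity term is normalized by the *absolute*
background permittivity `eps0 * eps_b`, which makes chi dimensionless).

### Forward solver

The domain is discretized into square cells with pulse basis functions and
point matching.  Kernel entries are integrated over an equal-area disk per
cell (Richmond's rule), giving closed forms for both the off-diagonal
entries and the singular self term.  The dense system
`(I - G_D diag(chi)) E_tot = E_inc` is never materialized on production
grids: `G_D` is a discrete convolution and is applied through zero-padded
FFTs, and the system is solved by a batched BiCGStab iteration over all
right-hand sides at once (relative residual 1e-8 for data simulation).  A
dense LU factorization is kept as a fallback for small grids when the
Krylov iteration fails to converge.  Receiver data are
`E_sca = G_S diag(chi) E_tot`.

Validation: scattered fields for a homogeneous dielectric cylinder agree
with the analytic cylindrical-harmonic series to below 1% relative RMS on
the canonical 64x64 grid (the cylinder is rasterized with sub-cell fill
fractions in that comparison so the rasterization error does not mask the
solver error), and the error decreases under grid refinement.

Synthetic experiments always simulate data on a grid finer than the
reconstruction grid (factor 2 by default, with the phantom regenerated at
the fine resolution) so the inversion never sees data produced by its own
discretization.

### Inverse solver

The reconstruction is a distorted-Born outer iteration enhanced with
subspace-extracted deterministic contrast sources:

1. Background operators.  At the current estimate chi_b, the secondary
   incident field `E_bac` and the inhomogeneous receiver operator
   `G_bS = G_S (I - chi_b G_D)^{-1}` are formed by one batched solve (the
   `n_tx + n_rx` right-hand sides share the operator because G_D is
   symmetric); `G_bD` is applied matrix-free through a push-through
   identity.
2. Deterministic current.  A thin SVD `G_bS = sum u_i s_i v_i*` spans the
   radiating part of the current space.  The data residual
   `r = Esca - G_S chi_b E_bac` is projected onto the leading L triplets,
   `C = sum_{i<=L} (u_i* r / s_i) v_i`, and refines the total field,
   `E_tot = E_bac + G_bD C`.  L = 0 reproduces plain DBIM; large L folds
   the small singular values' noise amplification into the update.
3. Linear update.  The real unknown per masked cell is the permittivity
   update; conductivity is slaved through the linear tissue model (below),
   so `dchi = c_f dx` with a per-cell complex coefficient.  The
   Tikhonov-regularized cost `||r - G_bS diag(dchi) E_tot||^2 + gamma ||dx||^2`
   is minimized by the two-step iterative shrinkage/thresholding (TwIST)
   recursion after normalizing the operator to unit spectral norm; with the
   quadratic penalty the proximal map is the linear shrinkage `v/(1+gamma')`
   and the recursion is a stationary two-step Richardson iteration whose
   fixed point is the regularized normal-equations solution.  The two-step
   weights follow the optimal spectral rule for eigenvalues in
   `[gamma', 1 + gamma']`.
4. Projection.  The permittivity prior interval is enforced both inside the
   proximal step (the prox of the quadratic penalty plus a box indicator)
   and by clipping after the outer update.  The in-solver box matters when
   the estimate sits on a bound: a clip applied only after the solve
   annihilates updates whose unconstrained optimum points out of the box,
   stalling the outer loop.

### Adaptive rank selection

The truncation rank L trades noise suppression against total-field bias,
and its optimum depends on the (unknown) noise level.  Every outer
iteration the adaptive policy evaluates candidate ranks (default 5, 10,
15, 20) on a half-resolution copy of the problem — the current map is
block-averaged by a factor 2 per axis; the physical measurements are
unchanged — and keeps the rank with the smallest regularized cost.  Only
the chosen rank crosses back to full resolution, where the update is
recomputed (the alternative, upsampling the coarse update itself, sits
behind `carry_coarse_solution`).  All candidates share one background
solve, one SVD and one batched `G_bD` application per frequency.  On grids
with odd dimensions the coarse copy crops the trailing boundary row/column
and shifts the grid origin accordingly; this only affects the rank ranking,
never the full-resolution update.

Multi-frequency data are processed in groups of three frequencies, low to
high, five outer iterations per group (a trailing remainder group is
processed like any other).  The outer loop stops when the relative update
of the solution norm falls below 1e-4, or at `max_outer` (default 50; a
schedule shorter than `max_outer` is extended by repeating its last group
so single-frequency scenarios can iterate to convergence).  The norm-based
rule is deliberate: with noisy data the raw step size plateaus at the
noise level and would never trigger the tolerance, while the norm of the
estimate stabilizes.

## Tunable parameters

| Parameter | Default | Units / meaning |
| --- | --- | --- |
| `gamma` | `1.0 * \|\|A^T rhs\|\|_inf`, frozen per frequency group at first visit | Tikhonov weight; also the outer step damping |
| `l_candidates` | (5, 10, 15, 20) | adaptive rank candidates |
| `coarse_factor` | 2 | candidate-evaluation resolution reduction per axis |
| `outer_tol` | 1e-4 | stop on relative change of the solution norm |
| `freq_group_size`, `iters_per_group` | 3, 5 | frequency-hopping schedule |
| `bounds` | (1, 3) free-space scenes; (2, 55) breast | permittivity prior box |
| `solver_tol` | 1e-5 (1e-4 for coarse candidate solves) | background-operator Krylov tolerance |
| TwIST `alpha`, `beta` | spectral rule | two-step weights |
| TwIST `max_inner`, `inner_tol` | 200, 1e-5 | inner stopping control |

The regularization weight deserves comment.  It is the single most
important stability control of the outer loop: the linearized update must
stay inside the trust region of the distorted-Born approximation, and with
weights much below the default the estimate overshoots and the iteration
diverges even on noise-free data.  The default multiplier (1.0) was chosen
on small-grid diagnostics before freezing; it is deliberately on the
damped side, trading a few extra outer iterations for robustness across
noise levels.  Freezing gamma per frequency group (rather than rescaling
it every iteration) keeps candidate costs comparable across ranks and
prevents slow noise creep late in a run.  Both the weight and the policy
are exposed in the configuration.

Solver tolerances are deliberately multi-level: data simulation at 1e-8,
reconstruction-side background operators at 1e-5 (with a single-precision
Krylov pass verified in double), and the half-resolution candidate
evaluation at 1e-4.  The linearization error of a distorted-Born update is
on the percent scale, so operator errors at these levels are invisible in
the update while cutting the dominant FFT cost severalfold.

## Tissue model and phantoms

Breast tissue conductivity correlates strongly with permittivity at
microwave frequencies; the package uses the linear fit
`sigma = 0.0190 eps_r - 0.0505` (S/m), clamped at zero below its root
(eps_r ~ 2.66), which reduces the unknowns to one real parameter per
pixel.  Inside the update operator the conductivity derivative is applied
per cell: 0.0190 above the clamp root and 0 below it — with a uniform
slope the operator carries a persistent error over low-permittivity
adipose cells.

The Austria profile (two eps_r = 2 disks and an annulus in free space, 2 m
domain, 400 MHz) is the standard strongly-scattering benchmark; cells are
classified by their centers, matching pixelated renderings.  The
synthetic breast generator emulates MRI-derived numerical phantoms on a
15 cm domain in an eps_r = 10 lossless matching medium: a randomly
deformed elliptical support, a ~2 mm skin ring at eps_r = 36 (a typical
literature value; the emulated repository does not state one), a smooth
adipose interior in [2, 10] and fibroglandular blobs in [35, 55] whose
areal fraction follows the mammographic density class (10/25/45/65% of the
interior for classes I-IV).  Conductivity follows the tissue fit, and all
tissue permittivities stay within [2, 55].  What the generator does *not*
emulate: the anatomical connectivity of real fibroglandular trees, the
transitional tissue classes of MRI-derived phantoms, slice-to-slice
anatomy, or frequency dispersion (set aside in favor of the linear fit).
Passing tests on these phantoms therefore demonstrate the solver chain and
the rank-selection logic under realistic contrasts and noise, not clinical
image quality.

## Numerical choices

- Coordinates: grid centered on the origin, x rightward, y upward, cell
  centers at `(i + 0.5) * cell` offsets; arrays indexed `[ix, iy]`,
  flattened in C order.
- Transmitters: every third antenna of the 30-element ring (indices 0, 3,
  ..., 27); the scattered field is recorded at all 30 antennas.  Array
  radius 1.5 m for the 2 m free-space domain and 0.13 m for the breast
  domain (the ring must clear the domain half-diagonal); both configurable.
- Incident amplitude is unity: the cost function and both error metrics
  are invariant to a global field scale.
- Candidate costs with non-finite values are excluded from the rank
  argmin; ties break toward the smaller rank.  If every candidate fails
  the selection raises and advises the plain-DBIM fallback (L = 0).
- TwIST declares divergence only on ten consecutive cost increases that
  also exceed the best cost seen by 1% — the projected two-step recursion
  oscillates benignly near a constraint face.
- The spectral-norm estimate for TwIST normalization runs a power
  iteration to 1e-4 relative stagnation with a randomized (seeded) start
  and a 15% safety margin; an underestimated norm would place the top of
  the spectrum outside the two-step stability interval.
- Seeds govern only measurement noise (and phantom generation where
  requested); the solver chain is deterministic.

## Error metrics

Both metrics are averaged *squared* relative deviations in percent (no
square root): `xi_pixel` averages `((eps_rec - eps_true)/eps_true)^2` over
the masked pixels, and `xi_signal` averages, per (frequency, transmitter)
view, `||E_pred - E_obs||^2 / ||E_obs||^2`.  The ratio-of-norms form keeps
`xi_signal` bounded near receiver nulls; a strict elementwise variant is
available behind a flag.  A value of 1% thus corresponds to a 10% RMS
relative deviation.

## Known limitations

- Strong-scattering scenes admit data-consistent local minima.  On the
  synthetic breast scenario initialized at the lower permittivity bound,
  the true nonlinear misfit landscape slopes *away* from the truth along
  the bulk (DC) direction — the phase through the ~12 cm breast is already
  wrapped at 0.8 GHz in the eps_r = 10 medium — and the outer iteration
  converges to a data-consistent ghost whose cost keeps decreasing while
  the image error grows.  This was verified not to be an implementation
  artifact: the linearized gradient matches a finite-difference gradient
  of the true nonlinear misfit to four digits, the truth is a fixed point
  of the iteration, and the behavior persists with inverse-crime
  noise-free data, with and without the skin ring, with a known-skin
  prior, at halved frequencies and across two orders of magnitude of
  regularization.  Escaping such basins requires better initialization,
  lower starting frequencies, or priors beyond the box/support used here.
- The equal-area-disk self term differs from exact square-cell quadrature
  by ~0.7%; this is the standard pulse-basis choice and is dominated by
  the cell-size discretization error at the grids used.
- The 2D scalar model ignores polarization coupling, antenna feeds and
  mutual coupling; no attempt is made to model a physical acquisition
  chain beyond additive white Gaussian receiver noise.
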