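# Methods

## Model and estimator

Oxygen transport between a penetrating arteriole and the surrounding
cortical tissue is modelled as steady-state diffusion with a spatially
distributed net sink.  With the pO2 field `P` assumed constant along the
cortical axis, the governing equation is the 2-D Poisson relation
`∇²P = M`, where `M = s/(D·α)` bundles the net consumption rate `s`, the
diffusion coefficient `D` and the solubility `α` into a single observable
with units mmHg·μm⁻².  Oxygen-supplying arterioles enter as interior
Dirichlet discs (`P = P_ves` on a disc of radius `R_ves`), capillary
sources can be folded into a locally reduced or negative `M`, and the
outer edge of the modelled tissue carries a zero-normal-gradient
condition.

The estimator inverts this relation pointwise: `M̂_est = ∇²P_smooth`, the
5-point discrete Laplacian (full Laplacian, i.e. four times the common
`del2`-style helper output) of a smoothed version of the measured map.
Everything runs internally in dimensionless variables `r̂ = r/r*`,
`P̂ = P/(M*·r*²)`, `M̂ = M/M*`; the defaults `r* = 141 μm`,
`M* = 10⁻³ mmHg·μm⁻²` place the nominal tissue-cylinder radius 200 μm at
`R̂_t ≈ √2` and make the nominal consumption `M̂ = 1`.  Unit bookkeeping is
explicit: every map carries a unit flag and mixed-unit operations raise.

## Smoothing

The smoother minimizes, per axis,
`(1−q)·Σ(P_data − f)² + q·∫ f''²`, the cubic smoothing-spline objective in
the convention where `q = 0` means interpolation (backends parameterized
by `p` correspond to `p = 1 − q`).  For gridded 2-D data the univariate
smoother is applied dimension-wise (y then x), the tensor-product
construction used by the standard curve-fitting tools; the impulse
response is then separable and the penalty contains only the two pure
second-derivative terms.  The univariate solver is the classical
Reinsch/de Boor second-divided-difference scheme with natural end
conditions; it is cross-checked in the test suite against
`scipy.interpolate.make_smoothing_spline` (an independent implementation
of the same objective with `λ = q/(1−q)`) to ~1e-11.

The practical smoothing dial is the smoothing length `d_q`: the radius at
which the normalized response to a single-node impulse falls to 50%,
read off a finely evaluated axis profile by linear interpolation.
Numerically `d_q = k(q·d_data)^(1/4)`; the constant is *measured* by
`calibrate_k` rather than assumed, because it depends mildly on the
backend's boundary handling.  With this package's spline the
measurement gives `d_q = 0.0570` at `d_data = 5×10⁻³`, `q = 5×10⁻⁴`,
hence `k = 1.433`, reported rounded to `1.4`, which is also the default
used when calibration is skipped.  The calibration window defaults to
`max(0.25, 10·d_q)` half-width so boundary effects cannot reach the
readout region.  Smoothed maps are evaluated on a refined grid of
spacing `d_est` (default 0.001) to keep the Laplacian's stencil error
negligible; coarser `d_est` (0.0035–0.007) is used deliberately where
maps are pooled anyway, since the stencil error is far below the
Monte-Carlo targets there.

## Forward models (synthetic ground truth)

All validation inputs are generated internally; no external data exist.

* **Krogh–Erlang closed form** — single centred vessel, uniform `M`,
  tissue cylinder of radius `R_t` with zero flux at its rim:
  `P(r) = P_ves + M(r²−R_ves²)/4 − M·R_t²·ln(r/R_ves)/2`, and
  `P = P_ves` inside the vessel.
* **Polar finite-volume solver** for disc domains with a centred vessel:
  conservative cells in `(r, θ)`, Dirichlet at the wall face, zero flux
  at the exact outer-rim face.  At the default resolution (2000 radial
  cells) it agrees with the closed form to <0.1% in the field and <0.1%
  in wall-flux balance, and converges under mesh refinement against a
  dense 1-D radial reference solve.
* **Cartesian 5-point solver** for square domains and arbitrary vessel
  layouts: mirror-ghost Neumann edges, vessel nodes fixed at `P_ves`
  (the wall is resolved to within one mesh cell), direct sparse solve
  with residual checked against 1e-10-scale tolerance.  A discrete
  divergence-theorem identity (consumption over free cells, with half
  and quarter volumes on mirrored edges and corners, equal to the
  interface flux out of the vessel nodes) holds to solver precision.

Solutions are sampled onto uniform measurement grids; nodes inside a
vessel are overwritten with that vessel's wall pressure, mimicking how
measured maps report intravascular pO2.  When the measurement grid is
nested in the solver grid the sampling is exact; otherwise a bicubic
interpolant is used.  Sampling the numerical solution from a different
(finer) mesh than the measurement grid also avoids the inverse crime of
differentiating a field on the grid it was solved on.

Measurement noise is additive i.i.d. Gaussian with SD `σ_P` in map units,
applied to every node including vessel interiors, after the vessel
overwrite.  Replicate `j` draws from the child stream `(seed, j)`, so
Monte-Carlo runs are reproducible and order-independent.  Draws are not
truncated at zero pressure; the estimator is linear, so negative draws at
extreme noise are harmless.

## Performance measures

Over `N` replicates, per node (or per pooled average): `bias` is the mean
error, `SD` the population standard deviation (divisor `N`), and
`RMSE = sqrt(bias² + SD²)` — an identity that holds exactly with these
divisor-`N` definitions and is asserted per node in the tests.  All three
are reported as percent of the local true `M̂`.  The clean map is computed
once per run; noise is the only stochastic element, so bias computed from
noise-free input equals the large-`N` limit of the mean error.

## Spatially averaged estimation and the exclusion disc

When maps are too noisy for resolved estimates, `M̂_est` is pooled over
the map, excluding a disc around each vessel where the smoothing-induced
bias concentrates.  `average_M(est, vessels, d_cut)` excludes all nodes
closer than `d_cut` to a vessel centre, i.e. `d_cut` is the **radius** of
the removed disc.  This choice was calibrated against the method's own
behaviour: with `d_q = 0.1` and `d_data = 0.035` the bias lobes extend to
`r̂ ≈ 0.25` (verified with two independent spline backends), so an
exclusion reaching 0.3 from the centre is what keeps the pooled average
essentially unbiased (+0.6% bias, RMSE ≈ 5% at σ̂_P = 5×10⁻², N = 300),
whereas a disc of half that size would leave a −45% bias.  The validity
mask additionally flags the outermost node ring and nodes within one
smoothing length of a vessel wall; flags are advisory — values are
reported, not altered.

## Numerical choices and degenerate inputs

* Grids are node-centred and exactly uniform (checked to 1e-12); windows
  built by `GridSpec.centered` are symmetric with an odd node count, so a
  centred vessel sits on a node.
* `q = 0` is handled by the same spline path (interpolation); `q ≥ 1` is
  rejected, and a requested `d_q` that would push `q` past 1 raises an
  error naming the maximum feasible smoothing length for the spacing.
* The Laplacian's boundary ring is filled by copying the nearest interior
  value and flagged invalid rather than extrapolated; quantitative
  comparisons exclude it.
* The half-maximum readout of the impulse response interpolates linearly
  between the two bracketing nodes of a 1e-3-spaced profile.
* Disc-domain solves require the (single) vessel at the disc centre;
  off-centre or multi-vessel layouts use the square-domain solver.

## Study conditions and problem sizes

The validation scenarios fix `P_ves = 80 mmHg`, `R_ves = 6 μm`,
`R_t = 200 μm`, `M = 10⁻³ mmHg·μm⁻²` (so `M̂ = 1`); the two-level scenario
raises `M̂` to 2 inside the capillary-free radius 0.7 and lowers it to 0.5
beyond, and the three-vessel scenario uses wall pressures 80/70/50 mmHg.
The two-level forward solve uses a disc of radius 1.45, which covers the
±1 measurement window; the estimator reads the local Laplacian, which is
insensitive to the outer-boundary shape.  Monte-Carlo runs use N = 200
replicates for resolved maps (evaluation spacing 0.0035) and N = 200–300
for pooled averages — sizes chosen so the whole validation executes on a
desktop in seconds while keeping the Monte-Carlo error of the reported
SD/RMSE at the few-percent level.

## What the synthetic data do and do not show

The generator reproduces the geometry, noise level and sampling density
of two-photon pO2 maps around penetrating arterioles, but idealizes real
measurements in several ways: noise is i.i.d. Gaussian (no photon-count
statistics, no spatial correlation), `D` and `α` are uniform, the pO2
field is strictly 2-D and stationary, and vessels are perfect discs at
fixed pressure.  Passing tests therefore demonstrate the estimator's
mathematical correctness and its noise/bias behaviour under these
idealized conditions, not performance on instrument data.  At a wall
pressure of 50 mmHg the third vessel of the multi-vessel scenario sits
close to the ambient tissue pO2 and delivers almost no oxygen — it need
not appear as a local pressure maximum, and the tests assert maxima only
at the clearly supplying vessels.

## Known limitations

* No 3-D or time-resolved estimation; the operator generalizes, the
  implementation does not.
* Only the L2 curvature penalty is provided (no L1 or third-derivative
  penalties, no spatially varying weights), so the near-vessel bias lobes
  are an inherent feature of the smoother.
* The Cartesian solver resolves vessel walls only to one mesh cell
  (staircase boundary); wall-flux accuracy there is first-order.
* Radially symmetric consumption fields only in the disc-domain solver;
  gridded `M` fields are supported on square domains.
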