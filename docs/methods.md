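# Methods

This note documents the models and procedures implemented in `adaptrt`, the
assumptions behind them, the parameters that matter, and what the synthetic
phantom does and does not establish about real patient data.

## Coordinate and data conventions

All rasters are axis-aligned grids in physical millimetres; arrays are
indexed `(z, y, x)` with `spacing`/`origin` in the same order, and voxel
positions refer to voxel *centres*. Dose grids hold full-course absorbed
dose in Gy. Two I/O dialects are supported: DICOM-RT (CT series, RT
Structure Set contours, RT Dose with `DoseGridScaling`) and a portable
fixture format (NRRD volumes + one `plan.json` sidecar) whose write→read
round-trip is exact. On load, dose and any off-grid masks are resampled onto
the planning image grid (dose trilinear, masks by 0.5 threshold) so all
downstream math lives on a single reference grid.

Contours are rasterized with an even-odd crossing-number rule: a voxel
belongs to a structure iff its centre is inside the polygon, with half-open
boundary semantics (a centre exactly on a lower/left edge is inside, on an
upper/right edge outside), which makes voxel counts deterministic when
contour edges coincide with voxel-centre lines.

## Deformable registration

`register(plan, daily)` estimates a dense displacement field with
multi-resolution symmetric-forces demons — an optical-flow-family method:
an intensity-difference (brightness-constancy) force drives the field, and
Gaussian smoothing of the field acts as the regularizer. We chose the
demons regularization over an explicit variational smoothness term because
the ITK implementation is deterministic, single-threaded-fast and
numerically robust; the interface (pyramid levels, iterations per level,
smoothness weight, convergence tolerance) is the same either way.

* The daily volume is first resampled to the plan grid and
  intensity-normalized (histogram matching by default) because cone-beam
  intensities are not calibrated HU and the flow force assumes comparable
  brightness.
* The field is estimated coarse-to-fine over a Gaussian pyramid
  (default 3 levels, shrink 4/2/1), with the field upsampled between levels.
* Defaults: 100 iterations/level, smoothing standard deviation 1.8 voxels,
  early stop when the RMS field update falls below 0.02 mm. The smoothing
  default was fixed by the identity and known-translation recovery
  requirements (near-zero field on identical volumes; 5 mm rigid shift
  recovered to sub-millimetre median error) and is exposed in configuration.
* Because per-iteration Gaussian smoothing never drives the update RMS to
  exactly zero on noisy data, a run that hits the iteration cap with a
  residual update below half the smallest voxel spacing is still treated as
  stationary; larger residuals set `converged=False` with a logged warning.

**Field convention.** The stored field is the *forward tissue displacement*
on the plan grid: the tissue element at plan position `x` sits at
`x + u(x)` in the daily anatomy (equivalently `daily(x + u(x)) ≈ plan(x)`).
This makes Lagrangian dose sampling direct with no field inversion. One
consequence: to measure registration quality, the *daily* image is pulled
back to the plan anatomy (`warp_image(daily, u)`) and compared against the
plan image — the same alignment measure as warping the plan forward, without
inverting the field.

## Dose accumulation model

Accumulation is Lagrangian per plan-grid tissue voxel: each structure is the
fixed set of its planning-CT voxels, and at fraction `f` the voxel at plan
position `x` receives the full-course-equivalent dose
`d̂_f(x) = D_plan(x + u_f(x))`. Assumptions:

* **Rigid-dose approximation.** The planned dose distribution is held fixed
  in room coordinates; anatomy moves through it. No dose recalculation is
  performed, so changes in radiological path length, scatter or surface
  shape are not modelled.
* **Uniform fraction weighting.** Simultaneous-integrated-boost plans
  deliver all prescription levels in every fraction, so each fraction
  contributes 1/N of the full-course grid.

The projected cumulative dose after fraction `k` of `N` is

    D_sum,k(x) = (1/N) · Σ_{f≤k} d̂_f(x) + ((N−k)/N) · d̂_k(x)

which equals the planned dose when nothing changes, and the plain
per-fraction mean at `k = N`. The day-of-treatment dose `D_day,k = d̂_k`
answers "what if today's anatomy held for the whole course". Voxels whose
displaced position leaves the dose grid sample 0 Gy and are counted; a
structure with more than 10% such voxels is flagged unreliable for that
fraction.

Forward mapping of masks (for display and QA regions) splats each voxel's
indicator trilinearly at its displaced position, normalizes by total
splatted mass — without the normalization a volume contraction inflates
occupancy and biases the warped volume high — and thresholds at 0.5.

## DVH metrics

Cumulative DVHs use uniform bins (default 0.1 Gy) of "volume receiving at
least D". The monitored metrics are computed from raw voxel samples, not
the binned curve, to avoid binning bias: V95 (fraction of volume at
≥ 0.95 × prescription), volume-weighted Dmean, Dmax, D1cc (minimum dose of
the hottest 1 cm³ by the sorted-voxel rule, with the boundary voxel
included), and hotspot (Dmax as % of prescription). Structures smaller than
1 cm³ report Dmin for D1cc with a warning. For nested SIB targets the
hotspot reference is the highest prescription among overlapping targets —
judging a lower-level target's hotspot against its own level would flag the
enclosed boost plateau in every SIB plan.

## Endpoints and crossing detection

Targets carry a lower-bound V95 endpoint (warning 95%, adaptation 93%) and
an upper-bound hotspot endpoint (110% at both levels). OARs follow a rule
table: relative endpoints (spinal cord, brainstem, cochlea, parotids) get
adaptation DE₁₀ = 1.10 × DE₀ exactly; planning-goal endpoints (mandible
D1cc, brachial plexus Dmax) keep warning = adaptation; "no hotspot" organs
(oral cavity, esophagus, larynx) bound Dmax at 110% of the highest
prescription at both levels.

Spared parotids resolve their DE₀ from the *planned* Dmean: below 20 Gy →
20 Gy; between 20 and 21 Gy → 21 Gy; a spared contralateral gland below
26 Gy → 26 Gy; outside these ranges the gland is excluded from monitoring
with a logged notice.

Violations use strict inequalities (a value exactly at threshold does not
violate), making boundary behaviour deterministic. The crossing fraction Fx
is the first fraction whose DP_sum strictly violates a level; trajectories
may recede afterwards — the event still records Fx plus whether the final
processed fraction violates. The cumulative-dose annotation of an event is
`Fx × (highest prescription / N)`, the dose-per-fraction of the highest SIB
level.

## Trend forecasting

An ordinary-least-squares line over *all* observed fractions (no sliding
window — refitting on the full history is the simplest reading of trend
analysis, and the spec of the problem gives no window) extrapolates DP_sum
for the next four fractions; fits are refused below five observations.
Predictions are deliberately not clamped to physical ranges (V95 may
extrapolate above 100%) because clamping would bias the accuracy
evaluation; out-of-range predictions carry an annotation instead.

Prediction accuracy over a set of flagged trajectories is evaluated per
lookahead `i ∈ {4, 3, 2, 1}` as the mean of
`pDP_sum[Fx−i] − DP_sum[Fx]` across trajectories, where `pDP_sum[Fx−i]` is
the prediction of the value at Fx from the fit on fractions `1..Fx−i`;
confidence intervals are Student-t with `n−1` degrees of freedom (the
cohorts are small). Trajectories with Fx < 5, or lookaheads whose anchor has
fewer than five fractions, are excluded — the model could not have produced
those predictions.

## Registration QA

Per structure, two confidence metrics: zero-mean normalized
cross-correlation between the pulled-back daily image and the plan image
over the structure mask dilated by 5 mm (the margin captures boundary
mismatch; the region choice was open and is configurable), and the maximum
displacement magnitude over the structure. NCC < 0.85 or any voxel above
7 mm flags the structure for review; both thresholds are configurable. The
any-voxel maximum is the conservative reading of the displacement criterion.
A zero-variance region leaves NCC undefined and flags the structure with a
reason code.

## Synthetic phantom

The phantom is a closed-form intensity and dose model: a body ellipsoid
with smooth low-frequency soft-tissue texture, two nested spherical SIB
targets (70/63 Gy, 35 fractions), two parotid ellipsoids, a spinal-cord
cylinder and a mandible arc, with logistic edge profiles (width 1.5 mm).
The dose is the per-target maximum of prescription plateaus with Gaussian
falloff outside the target. The falloff scale (40 mm) was set so the
lateral gradient at the parotids is ≈ 1 Gy/mm — typical of clinical
head-and-neck plans; with the default geometry the planned spared-parotid
Dmean is 19.4 Gy, mirroring the near-constraint plans that dominate
clinical flagging.

Daily anatomy composes, per fraction: medial parotid drift (default
0.5 mm/fraction, windowed around each gland), target and body-contour
contraction, and a random rigid setup error (default σ = 1.5 mm translation,
0.5° rotation), plus additive Gaussian image noise and optional bright
streak artifacts. Because the plan intensity function is analytic, daily
volumes are evaluated *exactly* at inverse-mapped positions (fixed-point
inversion of the smooth forward field), and the ground-truth deformation
is available in the same convention as the registration output. Plans are
validated at construction (target V95 = 100%, spared parotid Dmean
< 20 Gy); infeasible geometry raises.

**What the phantom does not emulate:** CBCT physics (scatter, beam
hardening, ring artifacts beyond simple streaks), sliding organ interfaces,
discontinuous anatomy change, intra-fraction motion, or realistic HU
textures. Passing the phantom recovery tests therefore demonstrates the
*pipeline's* correctness and the registration's behaviour on smooth,
well-contrasted anatomy — not clinical registration accuracy on patient
CBCTs, which degrades with artifacts and low soft-tissue contrast.

## Problem sizes and tolerances

The default phantom grid is 96×96×64 at 2 mm. The test suite and the
acceptance script run a 48×72×72 grid at 2.5 mm with 5-fraction (no-change)
and 12-fraction (drifting-parotid) courses — sizes chosen so a full run
stays desk-fast on one CPU while keeping several voxels across every
structure. Key measured behaviours at these sizes: a 5 mm rigid shift is
recovered with ≈ 0.5–0.6 mm median error inside the body; the
drifting-parotid D_sum trend is reproduced within ≈ 1.4% of ground truth
and its 20 Gy crossing fraction detected exactly; a no-change course is an
exact fixed point (zero demons force on identical volumes).

Numerical conventions worth knowing: registration is deterministic given
inputs and parameters (no stochastic sampling); OLS uses `numpy.polyfit`;
cohort summaries report the sample (ddof = 1) standard deviation and
Student-t CI95; the two-sample test is pooled-variance by default
(switchable to Welch); D1cc tie-breaks by including the voxel containing
the 1 cm³ boundary; all dose sampling is trilinear with 0 Gy outside the
grid.
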