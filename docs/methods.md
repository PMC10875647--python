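# Methods

This note documents the models behind `surftrack`, the defaults and why
they were chosen, what the synthetic scenes do and do not emulate, and the
numerical choices a user extending the package should know about.

## 1. The synthetic colonization scene

The generator is an agent-based model of rod-shaped bacteria on a channel
floor under laminar flow, rendered as brightfield frames.  It exists so
that every estimator in the pipeline can be validated against exact ground
truth; its defaults are fixed study conditions, not tuning knobs.

**Arrival and departure.** Cells arrive as a Poisson stream
(`arrival_rate_per_min`, default 1/min) during the injection window
(default 20 min, matching a 10 + 10 min two-stage inoculum injection), at
uniformly random positions subject to an excluded-volume radius
(`min_spacing_um`, default one division length — a cell cannot bind on top
of another).  Each bound cell carries an exponential detachment clock with
rate ln 2 / `detach_halflife_min`.  **Convention:** T₁/₂ is treated as a
half-life throughout (simulator and fitter use rate = ln2/T₁/₂
consistently); a mean-residence-time reading would differ by a factor ln 2,
so the two components must share one convention and this one is it.

**Growth and division.** Per-cell length follows the population growth
schedule GR(*t*) — a Gompertz in time, default y₀ = 0.045, A = 0.09
µm/min, k = 0.08/min, t_i = 45 min.  These values give an initial rate
half the final one, a lag of ~45 min, and a final duplication time
(2/3)·4.5/0.09 ≈ 33 min, i.e. realistic kinetics for surface-bound
*E. coli* adapting on a benign (mannose-like) surface.  Within a cell
cycle, growth is linear at GR(*t*) for the first 2/3 of the added length
and proportional to current length thereafter (cells elongate almost
exponentially when approaching division); the switch point is a modelling
choice.  Division triggers at `division_length_um` (4.5 µm), splitting
0.5 ± `division_asymmetry`; each daughter may immediately depart with
probability `daughter_detach_prob` (default 0.1).  A visible septation gap
(`division_gap_um` = 0.5 µm) separates newborn sisters, as constriction
does in real footage — without it, colinear butt-joined sisters are
optically a single rod and no segmentation could tell them apart.

**Minimal mechanics.** Two steric rules keep dense scenes physical:
daughters elongate away from the septum (their proximal pole stays put),
and overlapping capsules are translated apart each frame until their
centrelines clear `steric_clearance_frac` (1.5) cell widths.  The
clearance is deliberately slightly larger than contact so that the furrow
between neighbours stays optically resolvable in a pure-absorption
brightfield model (real high-NA optics resolve touching cells better than
a Gaussian-blurred absorption image does).  This is contact pushing only —
there is no hydrodynamic coupling, nutrient field, or 3-D structure.
`contact_pushing=False` disables it for large non-rendered statistical
ensembles where positions are irrelevant (it is O(n²)).

**Orientation.** Each cell's median axis angle relaxes from its binding
angle (|N(0, 8°)| off the flow axis) toward 90° with rate
`realign_rate_per_min` (default 0.02/min), emulating the formation of
additional distributed bonds that let cells turn normal to the flow.  A
mean-reverting (exact discrete Ornstein–Uhlenbeck) wiggle ∂θ with
stationary sd `wiggle_amplitude_deg` (3°) and relaxation time
`wiggle_relax_time_s` (5 s) is superimposed; the rotation is centred at
`pivot_offset_frac`·L along the axis (0 = rocking about the centre;
negative = twisting about an upstream patch).  An off-axis pivot couples
rotation to centroid translation, exactly as in the analysis model.

**Rendering.** Bound cells are projected spherocylinders drawn as
multiplicative absorption (depth `cell_contrast` = 0.35) on a bright
background, multiplied by a low-order polynomial illumination field,
blurred by a Gaussian PSF (σ = 1 px; optional sinusoidal focus drift adds
blur), with additive Gaussian sensor noise (sd 0.02 of background) and
optional persistent round nanoparticle spots (0.4 µm) as confounders.
Pixel size defaults to 0.1 µm/px (63× water-immersion with binning).  One
seeded generator drives the simulation and a derived one the renderer, so
identical config + seed reproduce truth tables and stacks bit for bit.

**What the scenes do not emulate** — phase-contrast halos, diffraction
rings, depth structure, cell-to-cell illumination scattering, flagellar or
pili visibility, motile planktonic cells crossing the field, stage drift
in x–y.  Passing round-trip tests therefore shows the estimators are
correct for near-ideal brightfield of surface-bound rods, not that the
segmentation defaults transfer unchanged to any microscope.

## 2. Segmentation

Order of operations per frame (after optional block averaging):
illumination correction (iteratively trimmed least-squares fit of a 2-D
polynomial, order 2, to the background; division by the surface; median
subtraction so background ≈ 0 and cells are positive-going), constant
`intensity_offset` subtraction clamped at zero (default 0.15 ≈ half the
typical cell depth, placing the mask contour near the half-maximum of the
blurred edge), two median-filter passes (disk radius 2 px), and a
marker-controlled watershed.  Markers are the extended maxima of the
smoothed Euclidean distance transform: within each connected component,
everything above `marker_rel_height` (0.7) of the component's distance
maximum.  A straight rod seeds a single marker along its whole ridge; a
necked pair seeds one marker per ridge and splits.  Gates: area 1–15 µm²,
aspect ratio ≥ 1.8, solidity ≥ 0.85 — these exclude round nanoparticles
and debris, and their numeric values are a calibration on the synthetic
scenes, exposed in `SegmentationParams`.

**Length estimator.** Length is the maximum Feret (caliper) diameter of
the footprint, which for a convex rod equals its tip-to-tip extent; on
rendered rods it is accurate to ~0.5 px MAE over all orientations.  The
moments-equivalent-ellipse major axis was rejected for this purpose: for
a spherocylinder footprint it overestimates tip-to-tip length by ~13%
(≈ 4 px for a 3 µm rod at 0.1 µm/px).  Width inverts the spherocylinder
area model A = wL − w²(1 − π/4), which is unbiased for rods and reduces to
w = L for round blobs; orientation comes from the image moments and is
folded to [0°, 90°] (a rod's axis has no direction) with the signed value
kept for motion analysis.

**Known limitation.** Two rods in *full-length side-by-side contact* merge
into one region that usually fails the aspect gate: such pairs are missed
(undercounted), not miscounted.  End-to-end and angled contacts split
correctly.  The steric clearance in the generator keeps synthetic colonies
out of this regime; real crowded microcolonies will undercount late in an
experiment, which biases the fitted T₁/₂ downward — the same late-stage
bias expected for any count-based binding estimate.

## 3. Tracking

Greedy frame-to-frame assignment by footprint overlap (ties: largest
overlap, then smallest relative length change), justified by near-immobile
bound cells at 0.1 fps where overlap is almost unambiguous.  A link
requires length change < 25%.  Division is declared when one trajectory's
footprint maps onto two gated footprints whose summed length is within 25%
of the mother's; both daughters start new trajectories carrying
`parent_id`.  An unmatched trajectory is held open for
`gap_tolerance_min` (1 min) and resumed if an observation reappears within
one cell length with length within 15% ("unaltered appearance"; the 15%
is our calibration of a qualitative rule).  Fates: divided / detached /
censored.  For growth analysis, trajectories shorter than 10 min are
dropped and the first/last 5 min of survivors are excluded from GR
evaluation (they are noise-prone and the ±5-min window would not fit).

## 4. Growth kinetics

GR(*t*) per cell: OLS slope of length vs time over ±5 min around each
eligible time point (≥3 samples required).  Population: per-trajectory
means in 20-min bins, then medians/quartiles across trajectories.
Gompertz fits use `scipy.optimize.curve_fit` with multi-start
initialisation (y₀/A from the data extremes, inflection swept over the
observed time quantiles, three rate seeds) because the likelihood has
local minima in (k, t_i); a fit is rejected as degenerate when the data
span < 5% of its scale or the fitted plateau is indistinguishable from the
baseline.  The parametrisation keeps an explicit nonzero baseline y₀
because surface-bound cells grow (slowly) from the moment of binding.
Note the rate k is poorly identified from 9 bins at 5% noise (per-dataset
median error ~14% at the likelihood's flatness); t_i, y₀ and A are well
identified.  "Initial GR" / "final GR" are the medians of the bin medians
strictly before / after the fitted t_i; t_end is the last populated bin's
centre.  Replicate summaries report per-experiment values with mean ± SE
and Welch (unequal-variance) two-sample t-tests, computed on
per-experiment medians so n is the number of experiments, not cells.

## 5. Binding kinetics

N(*t*) is the gated-object count per averaged frame.  Phases are annotated
by change-point search with per-phase models (line / constant /
exponential) scored by Poisson-stabilised chi-square; a piecewise-linear
SSE criterion was rejected because the exponential tail dominates it and
drags both breakpoints late.  The binding-time model is

  N(t) = N₀ · exp( ∫_{t₀}^{t} [ln2/T₂(s) − ln2/T₁/₂] ds ),  t ≥ t₀,

with t₀ the inflection of the Gompertz GR fit.  Because the division gain
D(t) = ∫ ln2/T₂ is known, the fit is *linear*: regress log N − D(t) on
(t − t₀) with weights ∝ N (variance-stabilised Poisson); the slope is
−ln2/T₁/₂ and the intercept log N₀.  T₂ may be time-varying (default) or
frozen at t_end.  A non-positive fitted release rate reports T₁/₂ = ∞
(detachment undetectable); a falling N(t) (detachment-dominated) is fitted
by the same expression.  Caveat: daughter departures at division act as an
extra release channel −ln(1 − p)/T₂ that this model folds into T₁/₂ (with
p = 0.1 and T₂ = 33 min, a true 60-min half-life reads as ≈ 47 min even
with perfect imaging); recovery benchmarks therefore use p = 0.

## 6. Motion analysis

Within a window (default 2 min at the original frame rate; ≥50% of
expected frames required), the signed axis angle series is unwrapped
modulo 180° to the direction minimising frame-to-frame flips, the median
axis M is (median centroid, median angle), and ∂θ is the deviation from M.
θ_M is the folded median; STD(θ) the sd of ∂θ.  The separation profile
evaluates, per frame and position l ∈ [−L/2, L/2], the projection of
c(t) + l·u(θ(t)) − c_M onto M's normal; sep_std(l) is its sd.  For a rigid
rotation about pivot p this is |l − p|·sd(sin ∂θ), so the profile is
V-shaped with vertex at the pivot; the estimate refines the grid argmin by
a local parabola.  The classical pure-rotation form l·sin(∂θ) is also
computed, but its sd is minimal at l = 0 *by construction* and cannot
localise an off-centre pivot; the full form (including the correlated
centroid translation) is therefore used for pivot estimation.
Classification: rocking if |pivot| ≤ 0.15·L and the end-to-end profile
ratio ≤ 1.8, twisting otherwise, undetermined (flagged) below a 1 nm
noise floor; the thresholds are our calibration of a qualitative
distinction.  Population summaries pool (θ_M, STD(θ)) and per-position
sep_std by time point with two-sample KS tests between time points.

## 7. Problem sizes and determinism

Validation scenes are desk-scale by design: 256–480 px images, 5–40
cells, 25–110 min movies at 1/30–2/15 fps, chosen so the full suite (unit,
property, and eight end-to-end checks) completes in minutes while keeping
every estimator in its intended regime.  The statistical benchmarks use
100 repeats (Gompertz, T₁/₂ Poisson recovery), 200 windows (pivot
classification), 500–1000 cells (residence-time statistics), and 5 vs 5
replicate experiments (suppression detection).  All randomness flows from
seeded `numpy` generators; identical configuration and seed reproduce
truth tables, rendered stacks, and pipeline summaries byte for byte.
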