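# Methods

## The measurement problem

Fluorescein perfused into the anterior chamber at constant pressure
drains through the conventional outflow pathway and becomes visible in
the perilimbal vessels. A canalogram records this as a grayscale
time-lapse (reference protocol: one 580×610 frame every 30 s for
20 min). The fluorescence rise at a location tracks local tracer
arrival; its timing and steepness carry the segmental outflow signal.
Absolute intensities are not comparable between eyes (dye concentration,
illumination, exposure), so all quantities are either times, rates on a
normalized intensity scale, or *shares* of a total.

## Pipeline model and assumptions

**Macropixel reduction.** Rows and columns are partitioned into 32
contiguous blocks each (block sizes differ by at most one pixel; larger
blocks come first — a fixed, documented partition so results are
stable). Each macropixel is the arithmetic block mean per frame;
block-size-weighted macropixel means conserve the frame mean exactly.
Mean rather than sum binning is used; the two differ by a constant
factor that cancels in all proportional quantities. Intensities are then
normalized to percent of the single brightest macropixel observation in
the stack — a global reference, so relative brightness between
macropixels is preserved (the dot plot encodes it). No background
subtraction or photobleaching correction is applied; baselines are
absorbed by the curve fits.

**Geometry.** The corneal disk (and, for anterior-segment cultures, the
scleral compression ring) is excluded via a per-eye config — these were
identified manually per eye in the reference workflow, and an Otsu-based
`suggest_cornea` helper only drafts config values, never overrides them.
Analysis is restricted to macropixels whose centers lie in the closed
annulus between the corneal radius and the outer radius; the outer
radius may be computed automatically as the largest circle that stays
inside the image (minus half a macropixel) and clear of any exclusion
mask ("complete ring" requirement). Clock hour 12 is centered on the
superior pole with hours advancing clockwise in the displayed image;
quadrants are the meridian-bounded 90° sectors with the nasal side at
image left for OD and image right for OS. Tie-breaks are fixed: a radius
exactly on a ring boundary goes inward, an angle exactly on a boundary
goes to the clockwise-following sector. Membership is by center point —
simple and deterministic at 32×32 resolution.

**Individual smooths.** Each macropixel series is fit by penalized least
squares on a cubic B-spline basis, `k = min(10, n_frames − 1)` equally
spaced basis functions, with an order-2 difference penalty on the
coefficients (the Eilers–Marx discretization of the integrated squared
second derivative). The smoothing parameter is selected by generalized
cross-validation, `GCV(λ) = n·RSS / (n − edf)²`, over a fixed grid of 45
log-spaced values from 10⁻⁴ to 10⁷; a fixed grid rather than a numerical
optimizer makes every fit deterministic and lets all 1024 macropixels
share one set of matrix factorizations (the whole grid fits in a few
dense 10×10 solves). The suite cross-checks this smoother against
statsmodels' GLMGam penalized B-splines on noisy logistic data.

**Half-max kinetics.** `I_max` is the fitted maximum over the
observation window on a dense grid (step = frame interval / 10, i.e. 3 s
at the reference cadence), `I_half = I_max/2` measured from absolute
zero — not baseline-corrected, matching the rate definition "from an
initial value of zero"; a baseline-relative variant would only matter
for high-baseline data and is not the default. `t_half` is the earliest
dense-grid crossing of `I_half`, refined by linear interpolation between
the bracketing grid points; for non-monotone curves the earliest
crossing wins. Filling rate is `I_half / t_half` (percent per second). A
macropixel is classified *filling* when its fitted dynamic range reaches
the noise floor (default 5 % of the global maximum — the reference
workflow's "first presentation of fluorescence" was a human judgment,
and 5 % is the smallest excursion reliably above camera noise at the
SNRs the generator emulates) and the curve ends above its start.
Non-filling macropixels carry no kinetics and zero flow; singular fits
are flagged, never fatal.

**The 36-region global model.** Region means (12 clock hours × 3 equal
radial-width rings) are fit by a single penalized model: per ring, a
tensor-product smooth of clock hour (cyclic cubic B-splines, period 12,
cyclic difference penalty) and time, with independent GCV-selected
smoothing parameters searched on a 9×9 log grid. Purely additive
hour + ring + time terms cannot produce region-specific half-max times —
additive terms shift curves vertically, not their timing — so the
hour×time interaction is a modeling necessity, not an embellishment; a
strictly additive variant (`fit_global_additive`) is retained for
comparison. Ring enters by stratification (three surfaces) rather than
as a third smooth dimension: three levels cannot support a smooth basis
worth penalizing. Cyclic continuity (surface at hour 12.0 ≡ hour 0.0)
holds by construction of the folded basis. Empty regions are excluded
from fitting and reported missing, never interpolated.

**Flow attribution.** Increment = fitted rise from the first frame to
`t_half` divided by the elapsed frame intervals, in percent per frame.
The default curve source is the region's global-fit surface; the
macropixel's own fit is available as `source="individual"` (both are
defensible bases for the increment — a per-macropixel basis is noisier
but finer-grained, the regional basis is smoother — so both are
implemented and the regional one is the default). Negative fitted rises are floored at
zero. Quadrant flow = reference total (default 3 µl/min, a literature
value for bulk aqueous production; a normalization constant, not a
measurement, and therefore a config parameter) × quadrant share of
summed increments. Consequently quadrant flows sum to the reference
total by construction, and everything downstream is invariant to
rescaling the raw stack. Each stack is normalized independently; no
cross-session rescaling (e.g. day-1 vs day-3 cultures) is attempted.
Paired comparisons use the standard two-sided paired t-test; the
zero-variance edge case is reported explicitly (t = 0, p = 1 for
identical vectors; p = 0 for a constant nonzero difference).

## Synthetic canalograms

The generator renders `I = baseline + A·vessel(x,y)·σ((t − t50)/τ)` plus
clipped Gaussian read noise, with sector-wise logistic parameters (4
quadrant sectors or 12 clock sectors), a dark corneal disk held at
baseline, and a homogeneous perilimbal annulus as the default vessel
pattern (an optional radial-branch pattern exists for visual realism
only). Logistic kinetics were chosen because the half-max crossing has a
closed form, so the ground truth (`t_half`, noiseless flow increments,
quadrant flow fractions, onset times) is exact. Defaults mirror the
reference acquisition: 580×610 px, 41 frames at 30 s, 16-bit.

Presets encode the study conditions: `whole_eye` (all quadrants active,
nasal t50 280/320 s vs temporal 560/620 s — nominally ≈300 vs ≈600 s,
made pairwise distinct so the ground-truth flow ranking is well
defined), `asc_day1` (focal filling: two quadrants near-zero amplitude,
outer radius reduced by the compression ring, slower t50) and
`asc_day3` (all quadrants active, uniformly faster than day 1).
Amplitude 1000 counts with noise SD 50 gives SNR 20, typical of a cooled
monochrome camera at moderate exposure.

What the generator does *not* emulate: vessel-tree morphology, optical
blur, photobleaching, motion, Poisson photon statistics, or eye-to-eye
anatomical variability. Passing recovery tests therefore demonstrate
correctness of the numerics on idealized kinetics, not robustness to
real-image nuisances; on real stacks the geometry config and noise floor
are the parameters a user should expect to adjust.

## Problem sizes and numerical choices

Tests and the acceptance script run full-size 580×610×41 whole-eye
stacks where the 1024-macropixel structure matters, and 96×96 px
16-frame eyes on a 16×16 grid for property sweeps — the smallest
geometry that still populates all 36 regions. The half-max evaluation
step (interval/10) bounds the crossing error at a tenth of a frame
before interpolation; recovery tolerances are one frame interval (30 s),
the resolution limit of the acquisition cadence. All randomness is
`numpy.random.default_rng` seeded explicitly; identical seeds give
bit-identical stacks and fits.

## Known limitations

Flows are relative by design: two eyes with very different absolute
outflow report the same 3 µl/min total. The 36-region model assumes
smooth circumferential variation; a single isolated fast collector
narrower than ~1 clock hour is blurred by the cyclic smooth (visible
instead in the individual-fit dot plot). Filling time uses a threshold
crossing of the *first* member macropixel and is therefore sensitive to
the noise floor at low SNR. Day-to-day registration and automatic limbus
segmentation are out of scope.
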