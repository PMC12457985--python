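# Methods

This note documents the models implemented in `granulemotion`, the
parameters that matter, the design choices made where the method family
leaves the design open, and what the synthetic benchmarks do and do not
demonstrate.

## Trajectory model and synthetic generator

Trajectories are 2-D positions (μm) at strictly increasing integer frame
indices with a fixed frame interval `dt` (default 0.204 s, 500-frame
acquisitions). Interior gaps of up to 3 consecutive frames are allowed and
never interpolated — every lag statistic uses true frame separations and
skips unavailable pairs, and windowed speeds divide by true elapsed time.

The generator produces motion by Euler steps at `dt`:

* **brownian** — per-axis increments N(0, 2 D dt);
* **drifted** — deterministic v·dt step along a heading plus the Brownian
  term;
* **confined** — Brownian step reflected on a disc of radius R about the
  segment anchor (the minimal isotropic confinement; real cages are
  irregular);
* **immobile** — the anchor position.

Localization error is additive, isotropic and uncorrelated per frame
(SD `sigma_loc`, default 0.02 μm in the benchmarks — a typical confocal
SPT precision). Switching schedules concatenate modes (each segment ≥ 5
frames so it is in principle recoverable) with per-frame truth labels
(immobile → blocked; confined, brownian → diffusive; drifted → drifted).
Gaps are emulated by random interior deletions of at most 3 in a row.

Rendering draws each particle as an isotropic Gaussian integrating to
`photons_per_spot` (default 500) on `background` counts/px (default 10)
with Poisson noise, pixel 0.1 μm, PSF SD 0.13 μm. A granule of diameter d
adds (d/4)² to the PSF variance — the second moment of a uniformly
labelled disc. For correlation analysis the field is seeded uniformly and
rendered with periodic wrapping (`wrap=True`): a non-stationary ensemble
density otherwise adds a broad static correlation pedestal that biases
the width fits, which is also why cropped cell-interior regions are the
right input for the real-data analogue.

What the generator does *not* emulate: blinking/bleaching photophysics,
3-D defocus, motion blur within a frame, heterogeneous per-granule
brightness, spatially varying background, and tracking errors
(mislinking). Passing benchmarks therefore demonstrate correctness of the
analysis given faithful tracks and stacks, not robustness to detector or
linking artifacts.

## Stop-and-go segmentation

The per-spot speed is the net displacement across a centered 5-spot
window divided by true elapsed time; edge spots use truncated windows
(≥ 3 spots). Runs with speed ≥ v_t = 0.2 μm/s lasting ≥ 5 spots become
drifted segments; shorter runs are absorbed into a flanking segment (the
longer neighbor, ties to the preceding one) so every spot stays assigned.
Segment-boundary spots belong to the earlier segment. With these
defaults a 0.5 μm/s drift against a D = 5×10⁻³ μm²/s diffusive background
localizes switch points to ±2 frames; note that at that diffusivity the
windowed speed of a genuinely Brownian track exceeds v_t in roughly 20%
of windows, so a few percent of diffusive spots classify as drifted —
an intrinsic ambiguity of speed-thresholding near
sqrt(4D/(4 dt)) ≈ 0.16 μm/s, not an implementation artifact.

## Displacement moments, γ and D₁₂

Time-averaged moments μ_p(Δ) of orders 1–6 are computed over all
same-track pairs at each frame lag Δ = 1..max(⌊n/4⌋, 5) (capped at the
span). The MSS slope γ_p is the least-squares slope of log μ_p vs log Δ;
the classification parameter γ is γ₂/2, so Brownian motion gives γ ≈ 0.5,
ballistic 1, static noise 0. D₁₂ is the slope of an intercept-bearing
linear fit of the MSD over lags {1, 2} divided by 4; the intercept
absorbs the 4σ_loc² static-noise offset, and the estimator may go
slightly negative for immobile tracks (then classified blocked).
Degenerate tracks (all spots coincident, or too few valid lags after
gaps) report D₁₂ = 0 and γ = 0.

## Transient arrest of diffusion (TAD)

Confinement is scored with the Simson–Sheetz index on sliding windows of
W = 10 spots: with R the maximum displacement from the window's first
point and t the window duration, log₁₀ψ = 0.2048 − 2.5117·(D̄ t / R²)
and L_win = max(0, −log₁₀ψ − 1), where D̄ is the segment's own D₁₂
(D̄ ≤ 0 marks the whole segment as one arrest). Each spot carries the
mean of L_win over the windows covering it.

Zone detection is seed-and-threshold: seeds are runs of the per-spot L ≥
L_c1 = 1.8 lasting ≥ t_c1 = 5 spots (endpoints inclusive); growth uses
the lower threshold L_c2 = 1.4; grown zones shorter than t_c2 = 7 are
dropped and overlapping zones merged. Growth applies L_c2 both to the
adjacent per-spot L and to whole windows: a seed absorbs any window with
L_win ≥ L_c2 that overlaps it. The window-level rule matters because the
spot-averaged L is diluted near arrest edges by windows straddling the
boundary; growing only on the averaged series trims ~W/2 spots per side
(measured: 70% of planted 40-frame arrests recovered at ≥ 80% overlap),
whereas window-level growth recovers 97% at an unchanged 1%
false-positive rate on homogeneous Brownian segments. Free spans between
zones shorter than 5 spots merge into a neighbor so spot conservation
holds exactly.

## Classification and reporting

Each (sub)trajectory is labelled from (D₁₂, γ): immobile (→ blocked)
below D_block = 2×10⁻³ μm²/s; else drifted if γ ≥ 0.75 (an MSD exponent
≥ 1.5; the method family leaves the step-2 drifted rule open, and this
threshold is exposed as `gamma_drift`); else slow/fast (→ diffusive)
split at D_lim = 10⁻² μm²/s. Acquisition summaries are length
percentages over classified spots and always sum to 100. The joint
(log₁₀ D₁₂, γ) distribution is binned 40×40 over [−5, 0] × [0, 1.5] — a
reporting choice; negative-D₁₂ or out-of-range segments simply fall
outside the binning, and marginal modes are bin centers.

Condition tables report mean ± SD over acquisitions with N. Two-group
comparisons gate each category on Shapiro–Wilk normality per group
(either failing switches that category to Mann–Whitney; otherwise Welch's
t-test, honoring unequal variances), then Holm–Šidák across the three
categories at α = 0.05. Categories with < 3 acquisitions per group are
skipped and excluded from the correction.

## iMSD

The spatiotemporal correlation is the circular FFT cross-correlation of
per-frame mean-subtracted intensity, normalized by the product of the two
frames' means and averaged over all frame pairs at each lag (the
alternative `subtract_mean_image` detrend removes the static population).
Widths come from an isotropic-Gaussian-plus-offset fit over a ±8 px
central window (uniform weights); lags whose fit fails are dropped. The
anomalous law σ²(τ) = σ₀² + 4 D_m τ^α is fit by bounded nonlinear least
squares (σ₀² > 0, D_m ≥ 0, 0.1 ≤ α ≤ 2) initialized from a log–log fit of
σ²(τ) − σ²(τ₁). The factor 4 is the 2-D diffusion convention. For a
rendered stack, σ₀² ≈ 4(σ_PSF² + (d/4)²), hence the offset's use as a
squared apparent-size metric.

The module default fits lags up to 100 frames; the benchmarks fit 25
lags (~5 s) of a 500-frame, 128×128 px, 50-particle stack — at this
problem size the long-lag widths carry few independent samples and
deepening the fit only inflates the variance of D_m and α (measured
spread roughly doubles from 25 to 40 lags), while 25 lags recovers
D = 5×10⁻³ μm²/s within a few percent with α within ±0.07 across seeds.
The offset–size comparison uses paired stacks: identical trajectories
re-rendered at each particle diameter so motion-sampling error cancels
and only the size effect and independent Poisson noise remain.

## SMLM cluster sizing

Filtering keeps localizations with frame > 500, sigma ≤ 130 nm and
uncertainty ≤ 40 nm (all strict removals, order-independent,
idempotent). DBSCAN uses ε = 50 nm and minPts = 8 counting the point
itself; points are pre-sorted on (frame, x, y) so the order-dependent
assignment of shared border points is deterministic. Cluster contours
come from a 10-nm 2-D histogram of member points: the largest 8-connected
occupied region is the footprint, its bin-count area gives the
equivalent-circle diameter 2√(area/π), and the polygon outline is
exported as WKT. Occupied-bin contouring overestimates a uniform disc by
up to about one bin of radius (a planted 150-nm disc reads ~160 nm) and
area can only grow under bin coarsening; exactly collinear clusters are
flagged and sized by bounding extent. The bin size and contour rule are
exposed as parameters.

## Determinism and problem sizes

All randomness flows from explicit seeds (`numpy` Generators); the CLI
derives per-stage seeds from one global seed via SeedSequence, and
identical configuration plus seed reproduces outputs byte-for-byte.
Benchmarks use 90–500 tracks of 100–120 frames, 200 replicates for
operating-characteristic rates, and single 500-frame 128×128 stacks —
sizes at which every reported rate is stable to a few percent across
seeds, as the acceptance script output records alongside each value.
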