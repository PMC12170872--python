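# Methods

This note documents the models, conventions, and numerical choices behind
each pipeline stage, what the synthetic data generator does and does not
emulate, and the known limitations. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Synthetic data (`synth`)

All generators draw from independent named RNG streams derived from the
master seed (`core.rng_for`): each stream is a `SeedSequence` child keyed
by a CRC32 of the stream name, so adding a generator never shifts the
randomness of existing ones, and a given seed reproduces every dataset
bit-for-bit.

Geometry defaults follow the acquisition settings the pipeline targets:
65 nm xy voxels and 200 nm z-steps for confocal stacks, 2.94 nm/px for
TEM (so one 2-px erosion step is exactly 5.88 nm), and a 3 s frame
interval for ratiometric time lapse. The confocal xy pixel size is a
declared convention, not an inferred one — plausible for a 100×/1.45 NA
spinning-disk system, and nothing downstream depends on its exact value
because all measurements carry physical units from the metadata.

**3D stacks.** Objects are ellipsoids, straight tubes, or three-armed
branched tubes built from analytic masks, placed uniformly at random with
retry-on-overlap (hard failure `placement_failed` after 200 attempts).
Cristae-like texture is a per-voxel Bernoulli draw in the 1-voxel-eroded
interior: constant density for `uniform`, linearly increasing toward the
centroid (probability `2·density·(1 − d/d_max)`, clipped to [0, 1]) for
`central`. Intensities are background 10, object 100, cristae 180
(arbitrary units) with additive Gaussian noise of SD
`gaussian_sd × object intensity` (default 5%). No optical PSF, axial
blur, or camera noise model is simulated — segmentation tests therefore
verify thresholding/labelling/measurement logic, not robustness to
diffraction-limited blur.

**Traces.** The true ratio is baseline (default 1.0) with a step of
`transient_amp` (default 0.5) at `t_on`, a 15 s plateau, and an
exponential return (τ = 40 s). Both emission channels share the same
multiplicative exponential bleach (default τ = 300 s; `inf`/`None`
disables it). This is deliberately conservative: the ratio itself is
bleach-insensitive, while the single channels still require correction,
so bleach-correction errors are observable in each channel but partially
cancel in the ratio. Additive Gaussian noise has SD `gaussian_sd × F₀`
(default 5%, i.e. SNR 20 per channel).

**Single-channel sweeps.** Each channel is a two-state Markov process
with stationary open probability Po(V) (defaults 0.10/0.20/0.30/0.40 at
−60/−80/−100/−120 mV — increasing with hyperpolarisation) and mean open
time 10 ms; the closed dwell follows from stationarity. The unitary
current is i(V) = γ·(V − V_rev)/1000 pA with γ in pS, V in mV, and
V_rev = 0 mV (symmetric pipette/bath solutions). Gaussian noise with SD
0.15·|i| (or a 0.2 pA floor for zero-conductance controls) is added
before a 4-pole low-pass Bessel filter at 1 kHz (zero-phase
`sosfiltfilt`) emulates the recording bandwidth at 10 kHz sampling. The
realized per-sweep open-time and level-time fractions are stored as
ground truth so recovery tests compare against the actual realization,
not just the nominal Po.

**Gold fields.** Membrane-associated particles sit at a uniformly random
position along the OMM contour, displaced along the inward normal by
N(μ, σ) (defaults +15 ± 5 nm; positive = matrix side); the drawn offset
is the true signed distance (polygonal-approximation error for the
256-vertex default circle is ≪ 0.1 nm). Remaining particles scatter
uniformly over the cytosol or nucleus masks, rasterised at 2.94 nm/px.

**Fraction sheets.** Band intensities are constructed by algebraic
inversion of the percentage formulas, so the noiseless sheet reproduces
the requested splits exactly; noisy mode multiplies each intensity by
mean-one lognormal noise of the requested CV.

**Dose–response sets.** Per-cell responses are the 4-parameter Hill value
times mean-one lognormal noise (CV default 10%), at 7 half-log-spaced
concentrations from 0.1 to 100 µM, 50 cells per concentration — the
scale of a pooled single-cell imaging experiment.

## Trace processing (`traces`)

Background subtraction accepts scalar or per-frame vectors; negative
corrected intensities are allowed and flagged rather than clipped.

Bleach correction fits y = A·exp(−t/τ) + C on the pre-stimulus baseline
window (≥ 10 samples) per channel and divides the full trace by the
fitted curve normalised to its value at the first sample. Numerical
choices: the initial τ comes from a log-linear fit, and A and C are
bounded non-negative — without the bounds the three-parameter model is
degenerate on short baselines (A→∞, C→−∞, τ→∞ reproduces a line whose
extrapolation collapses through zero and explodes the corrected trace).
A non-convergent fit falls back to a linear baseline model, flagged
`bleach_linear_fallback`. On noiseless exponentials the correction is
exact to machine precision; on already-flat baselines it is idempotent.
At SNR 20 the recovered τ is accurate to a few percent when the baseline
spans ~2τ; transient-amplitude recovery to 2% holds in the noiseless
limit, while at SNR 20 the extremum-based peak statistic carries the
expected upward noise bias of an order-statistic (~5–15% at the default
settings).

Ratio conventions (configurable per sensor label) are chosen so a Ca²⁺
rise is positive-going for every sensor: FRET sensors 530/480, GEM-GECO
480/530, Fura-2 340/385. Samples with non-positive denominator are
masked; >10% masked aborts with `ratio_unreliable`. The peak is the
extremum of a 5-sample moving average (noise robustness), with a
direction flag for depletion-type (downward) responses. The baseline
window defaults to the first 60 s or all pre-stimulus samples, whichever
is shorter; stimulus onset is supplied by configuration, not detected.

Hill fitting uses the 4-parameter logistic on log₁₀ concentration
(`curve_fit`, EC₅₀ initialised at the concentration nearest the
half-maximal response) and a seeded nonparametric bootstrap over
observations for the EC₅₀ CI (percentile method, B = 1000 by default).
Bootstrap was chosen over profile likelihood for simplicity and
distribution-freeness; at 50 cells × 7 concentrations its empirical
coverage in the test suite is ≥ 90%. Flat data raise
`degenerate_response`; R² < 0.5 flags `poor_fit`; an EC₅₀ outside the
tested span flags `extrapolated`.

## Morphometrics (`morpho`)

Segmentation: per-slice rolling-ball background subtraction (default
radius 50 px — no published value exists, so it is exposed), then the
AND of a global Otsu threshold on the stack histogram and a per-slice
local (rank) Otsu with a disk radius of 640 nm converted to pixels. AND
rather than OR because per-slice local Otsu marks foreground even in
empty slices; the intersection suppresses that failure mode. Components
are 26-connected (8-connected in 2D); objects under `min_object_voxels`
are removed.

Measurements: volume is voxel count × voxel volume. Surface is the sum
of exposed voxel faces with anisotropy-aware face areas (dxy² for faces
normal to z, dxy·dz otherwise) — it conservatively overestimates smooth
surfaces (staircase effect) but is exact for the voxelised object and
conserved under relabelling. Ellipsoid semi-axes use the uniform-solid
convention a = √(5λ) on the eigenvalues of the physical-coordinate
covariance, with the voxel's own variance (edge²/12) added per axis so
single voxels are well-defined. Elongation = a/b, flatness = b/c,
branching = volume / (4/3 π a b c); branching ≈ 1 for convex blobs and
decreases with branching. The denominator convention is documented
precisely because the original plugin's internal convention is
unpublished.

Cluster sizing follows blur (σ = 1 px) → Kapur maximum-entropy threshold
→ watershed on the (lightly smoothed) distance transform. The Kapur
criterion was verified against brute-force entropy maximisation; note
that on images with a tight background mode and sparse foreground the
maximum-entropy threshold genuinely sits just above the background, so
cluster areas include the Gaussian-blur halo (up to ~2 px of radius at
the defaults). This matches the behaviour of the equivalent interactive
workflow and is documented rather than "corrected". Fragments below
4 px² are discarded as specks. PLA dot counting uses a Yen default
threshold and a 2–50 px² size band (only "a threshold" is ever published
for such analyses; both are exposed).

## Cristae analysis (`cristae`)

Perimeters use the Crofton 4-direction estimator (cross-checked against
marching-squares contour length within 10% in the tests); area is the
pixel count. The radial profile fills holes (so the "centre" is defined),
erodes iteratively with a radius-2 disk (disk for isotropy; only the
"2-pixel increment" is prescribed), measures per-shell cristae coverage,
and maps shell index linearly onto 100 positions (0 = outermost,
100 = centre). Shell partition and cristae-area conservation are exact by
construction. The profile is exactly invariant under 90° rotations;
under arbitrary rotations the plateaus are stable but a sharp coverage
transition can shift by one shell (the profile is a function of discrete
erosion depth), so comparisons across orientations should use smoothed
or averaged profiles.

Membrane kinetics is the XOR fraction of state-changing pixels between
consecutive binarized frames within the analysis mask — symmetric in
frame order and bounded [0, 1]. The contact-site mask is the ER∩mito
overlap dilated by 3 px (exposed parameter) and clipped to the
mitochondrion. The IBM association index is the mean uniporter intensity
in the IBM mask over the cristae mask, with a division guard (ε = 1e−9)
and a `saturated` flag when the cristae floor is hit.

## Immunogold statistics (`gold`)

Distances are computed analytically against the polygonal OMM contour
(shapely point-to-boundary distance) rather than through a raster
distance transform, for nm precision; the raster transform serves as the
independent oracle in tests (agreement within ~1 px). Sign is by
even-odd point-in-polygon: positive inside (matrix side), negative
outside (cytosol side). Nucleus-assigned particles are excluded from
distance statistics (membrane association is defined for cytosolic and
mitochondrial particles). Compartment assignment is point-in-mask with
boundary ties resolved mitochondria > nucleus > cytosol; unassigned
particles are reported, never dropped. Histogram bin width defaults to
10 nm (no published value); the membrane window defaults to 20 nm.

## Fractionation algebra (`fraction`)

Scaled amounts are I_blot · D1 · D2 per lane (the two published scaling
formulas are typographically identical, so one rule is applied per lane
with lane-specific factors). The mitochondrial percentage is
A_mito/(A_mito + A_cyto)·K_pl·100 with the cytosolic complement; the
outer-leaflet (PK-digestible) percentage is
A_mito/(A_mito + A_mito_PK)·K_dm·100 with the inner-leaflet complement.
K factors can push a percentage outside [0, 100]; values are clamped
with an explicit `clamped` flag rather than silently truncated, to keep
the correction auditable. K_pl is computed as the D-scaled pure/crude
cytochrome-C ratio and K_dm as the −PK/+PK VDAC1 ratio; only the idea,
not the arithmetic, of these factors is published, so both helpers are
documented assumptions and the factors can equally be supplied directly.
A +PK lane exceeding the −PK lane by more than 5% is warned about as
`pk_inconsistent`.

## Single-channel analysis (`patch`)

Idealization is the standard half-amplitude threshold method. The
closed-channel baseline is taken from the all-points histogram as the
substantial mode (≥ 0.5% of the maximum) nearest 0 pA — for a
leak-subtracted mitochondria-attached sweep the closed level sits at the
holding current, and this choice keeps the estimator two-sided (a
"most-populated mode" rule inverts the idealization whenever Po > 0.5).
The unitary amplitude is the signed distance to the nearest other mode
that (a) holds ≥ 2% of the histogram mass, (b) is separated by at least
4× the baseline noise SD (estimated from the baseline mode's FWHM) and
3 histogram bins, and (c) has at least 20% of the prominence of the
strongest candidate — criterion (c) rejects the shallow histogram bumps
produced by filter-transition samples between levels. Transitions are
half-amplitude crossings with ±10% hysteresis; events shorter than 1.8×
the filter rise time (T_r ≈ 0.332/f_c, i.e. ~0.6 ms at 1 kHz) are
unresolvable and merged into their neighbours, conserving total time
exactly. A sweep with no acceptable second mode is a valid silent
idealization — which also means a channel that never closes within a
sweep cannot be idealized (the baseline precondition fails); this is an
inherent limitation of histogram-based baseline estimation.

NPo is the level-weighted open time over total time, multi-level aware.
N is estimated as the maximum number of simultaneously open levels
observed — a lower bound when channels rarely superimpose, the standard
limitation of this estimator. Slope conductance is the OLS slope of
unitary amplitude vs test potential (1 pA/mV = 1000 pS) with a seeded
bootstrap CI over sweep amplitudes; ≥ 3 potentials are required.
Occurrence is the percentage of patches with ≥ 1 resolved opening,
optionally grouped by experimental day. Voltage signs are stored exactly
as delivered (referenced to the inner membrane surface).

On two-state simulations at the default bandwidth the NPo estimator's
absolute bias is below 0.02 at Po ∈ {0.1, 0.5, 0.9} (60 s simulated per
seed, 20 seeds — computed in the acceptance suite), and the
idealization-free oracle (mean current / unitary amplitude) agrees with
NPo within 5%.

## Problem sizes

Test and acceptance runs use desk-scale versions of the experiments: 20
sweeps per potential (160 s of record) for conductance recovery, 50
cells × 7 concentrations for EC₅₀ recovery, 60 s of simulated gating per
seed for the NPo bias bound, 10-cell trace sets for τ recovery, and
stacks up to 24×160×160 voxels. These sizes were chosen so each
estimator's sampling error is well below the tolerance it is tested
against while the full suite stays fast to run.

## Known limitations

- No optical PSF/SIM reconstruction artefacts; segmentation robustness
  to realistic blur is untested by design.
- The bleach model is single-exponential and shared across channels;
  two-component bleaching or channel-specific bleaching would bias the
  correction.
- The peak statistic (max of a moving average) carries a positive noise
  bias; at SNR 20 it is several percent of the response amplitude.
- N (channel count) from maximum observed stacking underestimates N at
  low Po.
- Maximum-entropy cluster thresholds include the blur halo on
  sparse-foreground images (areas biased high by up to ~2 px of radius).
- The radial profile is a function of discrete erosion depth; sharp
  features can shift by one shell under rotation or resampling.
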