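# Methods

## FRAP model and analysis chain

Each trace is the mean intensity of a bleached junctional region (by
convention a 4×4 µm square; metadata only) and of the whole cell, sampled on
a schedule with ≥3 pre-bleach frames and post-bleach frames starting at
t = 0. The default schedule is pre-bleach at −30, −20, −10 s and post-bleach
at 0, 5, 15, 30, …, 300 s: three pre-bleach frames 10 s apart, a frame
immediately after the bleach, one 5 s later, then every 15 s for 5 minutes.
Only the cadence is canonical; the absolute pre-bleach times are a package
choice.

Per trace the chain is:

1. **Photofading correction.** Repeated imaging bleaches the whole cell.
   The correction divides the ROI signal at each frame by the whole-cell
   fading factor, defined as the whole-cell mean at that frame over the
   pre-bleach whole-cell mean. This removes any fading process that
   multiplies both channels equally. Referencing the *pre-bleach mean*
   (rather than the first frame) makes the corrected trace equal to the
   unfaded ideal times a constant — the mean pre-bleach fading factor —
   which cancels exactly in the next step, so the choice of reference frame
   has no effect downstream.
2. **Pre-bleach normalization.** All values are scaled so the pre-bleach ROI
   mean is 100; results are percentages of pre-bleach intensity.
3. **Single-exponential fit** over post-bleach frames only:
   `I(t) = P − (P − I0)·e^(−τt)`, free parameters plateau `P`, post-bleach
   level `I0`, rate `τ`. Pre-bleach frames serve normalization only.
4. **Half-life** `t½ = ln 2/τ`, and **mobile/immobile fractions** from
   `P` and `I0` (below).
5. **Pooling**: mean ± SEM (sample sd/√n) per condition over converged
   traces; non-converged traces are reported but excluded, and pooling
   fewer than 12 converged cells logs a warning, reflecting the usual
   design of pooling at least 12 cells per condition.

### Numerical choices

- Fit via `scipy.optimize.least_squares` (trf) with bounds
  τ ∈ [1e−5, 10] /s, P, I0 ∈ [0, 200] %, and tight tolerances (1e−14) so
  noiseless round trips recover parameters to better than 1e−6 relative.
- Initialization: `I0` ← first post-bleach value; `P` ← mean of the last 3
  post-bleach values; `τ` ← ln 2 / (time of first crossing of (I0+P)/2),
  falling back to 0.05/s when the trace never crosses.
- Degenerate traces: a recovery amplitude below 1e−6 % (flat trace) leaves τ
  unidentifiable, and a τ estimate pinned at either bound indicates the
  model does not describe the data; both are returned with
  `converged=False` rather than failing the batch, and are excluded from
  condition summaries.
- `compute_fractions` refuses traces with `I0 ≥ 100` (no bleach occurred).

### Fraction conventions

Two readings of "percentage recovery at plateau" exist and both are
implemented:

- `full_scale` (default): mobile = 100·(P − I0)/(100 − I0), the standard
  FRAP definition in which recovery is expressed as a fraction of the
  bleached (recoverable) range. This is the only convention under which the
  generator's mobile fraction is recovered, and the only one independent of
  bleach depth.
- `percent_of_prebleach`: mobile = P, the literal percent-of-pre-bleach
  plateau.

Similarly the plateau is the fitted asymptote `P` by default, with an
`empirical` option (mean of the last three frames) for users who define the
plateau off the curve.

## Synthetic FRAP generator

The generator emulates the experimental design, not the optics. The ideal
ROI signal is `I_pre` before the bleach and
`I_post + M·(I_pre − I_post)·(1 − e^(−τt))` after, with
`I_post = bleach_depth·I_pre` and mobile fraction `M`. Both channels are
multiplied by a shared fading exponential `e^(−photofade_rate·(t − t_first))`
— the simplest model under which ratio correction is exact — and carry
independent multiplicative Gaussian noise with sd = `noise_sd_frac` × the
ideal value, matching the intensity-proportional scaling of fluorescence
noise at typical detector settings. Defaults (pre-bleach 1000 AU, bleach
depth 0.2, τ = 0.05/s, photofading 0.002/s, noise 2%, 12 traces) represent a
routine junctional FRAP session: ~80% bleach, half-life ≈ 14 s, a few
percent whole-cell fading over 5 minutes.

Not modelled: diffusion/reaction kinetics beyond the single exponential,
bleach-spot spatial profiles, PSF, drift, or detector offsets. Passing
recovery tests therefore show the analysis arithmetic is correct under the
stated noise model, not that single-exponential kinetics describe any given
biological dataset.

## Junction images and quantification

Junctions are rendered as thin non-overlapping segments (1–3 px wide,
10–20 px long, axis-aligned or diagonal — the analysis uses only per-pixel
means, so curvature is irrelevant), each on its own tile of a regular grid
with a one-pixel gutter, with unique integer labels. The junction-protein
channel holds the configured per-pixel mean on each junction and background
elsewhere; the marker channel is elevated only on marker-positive junctions.
Additive Gaussian noise (sd `noise_sd`) is applied per channel; values are
not clipped at zero, preserving noise symmetry (images are single-plane
floating-point, 0-based row-major).

Measurement is the per-pixel mean over each label (via
`skimage.measure.regionprops_table`), which calibrates away junction
size/area differences. Classification is a threshold on the marker-channel
mean — default threshold: background mean + 5 sd of the marker channel
outside all labels; ties classify negative, deterministically. The
marker-negative population is the reference: every junction's relative
intensity is its mean over the negative-population mean, so the negative
mean is 1 by construction and the statistic is invariant under global
intensity rescaling. Records from multiple images are pooled before
normalization by default (per-image normalization is a flag), matching
designs that pool >25 junctions per condition across images.

Real segmentation is out of scope: the label mask is an input (hand-drawn
ROIs are not reproducible), and `suggest_marker_threshold` is a convenience,
not part of the validated surface.

## Densitometry and assay statistics

Densitometry: band/loading-control ratio, expressed as percent of the
control condition's mean ratio (control averages 100%). Permeability is
reported as fold over the basal condition's mean lower-chamber fluorescence;
the raw readings carry no absolute units.

ANOVA is computed from the sums-of-squares decomposition so each number is
auditable: between/within for one-way; marginal-mean, interaction and
within-cell components for balanced two-way (they sum exactly to the total
SS). p-values use the F upper tail (`scipy.stats.f.sf`, a regularized
incomplete beta) — the only special function involved. Unbalanced two-way
tables raise an explicit error instead of a silent Type-I/II/III choice;
the designs this package targets are balanced. No post-hoc tests are
provided. The assay generator draws `cell mean + N(0, sd)` replicates in a
balanced two-factor layout (default 4 replicates, matching typical n = 4
figure legends).

## Pipeline determinism

`run_pipeline` executes simulate → frap-fit / junctions → assay-stats,
deriving one independent sub-seed per stage from the run seed via
`numpy.random.SeedSequence`, and writes a manifest (config, seed, version,
sha256 per output). Identical config + seed gives hash-identical outputs.

## Validation problem sizes

The test suite validates at the scale the designs prescribe: 12 traces per
FRAP condition, 30 junctions per image, and 1000–2000 simulated tables for
the ANOVA size checks (the rejection rate under the null is asserted within
the 99.9% binomial band around α = 0.05). Whole-suite runtime is well under
a minute; the statistical checks use rejection rates rather than means of
heavy-tailed F statistics, which would need far larger simulation counts
for the same power.

## Known limitations

- Single-exponential kinetics only; two-component or reaction–diffusion
  recovery is out of scope and will be flagged only indirectly (poor fit,
  τ at bounds).
- The photofading correction assumes fading multiplies the ROI and
  whole-cell signals equally; channel-specific fading is not modelled.
- Marker classification is a single global threshold; bleed-through and
  spatially varying background are not handled.
- Synthetic images contain no segmentation difficulty, so nothing here
  validates junction *detection* — only per-pixel quantification given a
  mask.
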