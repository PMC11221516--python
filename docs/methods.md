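# Methods

## The assay and its geometry

A droplet sandwiched between two slides at spacing *h* = 220 μm is a short
cylinder of radius *R* ≈ 750 μm. Seen from above, its air–water interface
(AWI) is the rim, visible as a dark circle. With the radius normalized to 1,
the volume enclosed within radius *r* is the **volume fraction** *r*²; the
annuli with radial boundaries √(k/n), k = 0…n, partition the droplet into
*n* equal-volume sectors. Sector *n* (outermost) is the AWI sector. All
statistics in the package pool over angle: the droplet is rotationally
symmetric and no angular hypothesis is tested.

Sector assignment compares *r*² against k/n in volume-fraction space rather
than comparing *r* against rounded square-root boundaries; a value within
one part in 10⁹ of a boundary is snapped onto it, so √(k/n) round-trips into
sector k+1 despite float rounding. Intervals are half-open, [(k−1)/n, k/n),
with the outermost sector closed at 1 — rim events belong to the AWI sector.

## Bulk null and decision rule

Under bulk nucleation, onsets are uniform in volume: the normalized radius
is √U with U ~ Uniform[0,1). Each of *n* sectors then catches an onset with
probability exactly 1/n. For an experiment of *n*ₑ events, the
outermost-sector frequency is Binomial(*n*ₑ, 1/n)/*n*ₑ with mean 1/n and
SD √(p(1−p)/*n*ₑ) — 7.07% at *n*ₑ = 32, n = 5. `simulate_null` reproduces
this by direct Monte Carlo through the same sector-assignment code used on
real data (default 10,000 replicates; the MC standard error on the SD is
then ≈ 0.05 percentage points; SD uses ddof = 1).

A sample is called **AWI-influenced** when its observed outermost frequency
*strictly* exceeds mean + 3·SD of the null (≈ 0.41–0.42 at *n*ₑ = 32). The
three-sigma rule is used as-is, with no continuity correction, because
observed frequencies are multiples of 1/*n*ₑ and the rule is the assay's
operative convention; `binomial_pvalue` offers an exact-tail supplementary
readout that never overrides it. The one-sided false-positive rate of the
rule is ≈ 0.1–1% (the binomial tail P(f > 0.42) at *n*ₑ = 32 is ≈ 0.2%).

`power_analysis` maps detection probability over a grid of event counts and
mixture weights by generating synthetic experiments and classifying each
against the matching null; at *n*ₑ = 32 a 50/50 bulk/AWI mixture (expected
frequency 0.6) is detected with probability > 0.95.

## Synthetic data generator

`generate_onsets` draws a two-component mixture:

- **bulk** onsets: *r* = √U (uniform in volume), θ ~ Uniform[0, 2π);
- **AWI** onsets: *r* ~ Uniform[1 − w, 1] with shell width w = 0.02 by
  default. The assay cannot distinguish nucleation exactly at the interface
  from nucleation very close to it, so interfacial truth is a thin shell,
  not the circle r = 1. Any w ≤ 1 − √0.8 ≈ 0.106 keeps the whole shell
  inside the outermost sector, giving the mixture identity
  E[f] = p_awi + (1 − p_awi)/5.

Defaults mirror the experimental design: 8 droplets × 4 cycles = 32 events.
Freezing temperatures are Gaussian around the sample T50 (default −6.5 °C,
σ = 1 °C — a typical spread for a single sample's spectrum; only medians
and ranges are reported for real samples, and a Gaussian is the simplest
spectrum with a controllable median). An optional deterministic per-cycle
drift (`t_drift`, °C/cycle, default 0) supports freeze–thaw stability
tests. The truth tables are consumed only by tests, never by the pipeline.

`generate_video` renders 8-bit grayscale stacks: bright interior (220),
dark rim of width 3% of R (60), background 150, Gaussian pixel noise
(σ = 2 gray levels). From the onset frame, a frozen region grows radially
from the onset point; after k frames its radius is k·v/frame_rate, with a
1.5 px seed so the onset frame itself is visible. Frozen pixels lose 45% of
their intensity. Default scale: 2100 fps and a 750 μm droplet at 7.5 μm/px
(≈ 100 px radius in 256×256 frames). Geometry is expressed in normalized
coordinates throughout, so localization accuracy is independent of the
rendered resolution; the smaller-than-instrument frames keep the test suite
fast without changing what is being tested. An optional dendrite mode
modulates the front with angular lobes whose tips advance at the nominal
velocity; onset localization does not depend on front morphology. The
renderer makes no attempt at physical dendrite crystallography, latent-heat
effects, or condensation.

## Onset localization

`fit_droplet_circle` thresholds the first (pre-onset) frame at
min + 0.25·(max − min); the dark pixels are the rim. A total-least-squares
circle fit gives the center; the droplet radius is the 99th percentile of
rim-pixel distances from that center — the outer edge of the finite-width
rim, which is where the AWI actually sits. A near-uniform frame (dynamic
range < 20 gray levels) or too few dark pixels raises a detection error.

`detect_onset` compares each frame against a rolling average of preceding
unchanged frames (folding factor 0.5, so slow drifts are tracked). Change
threshold: k·σ·√2 with k = 5, where σ is the per-frame noise estimated from
the first frame pair and the √2 accounts for the difference of two noisy
images; a floor of 4 gray levels guards the noiseless case. The onset frame
is the first with ≥ `area_min_px` changed pixels inside the fitted circle
(default 25 px — small enough to catch early dendrites, large enough that
the expected false count per frame, ≈ 0.02 px, never accumulates to a
trigger). The onset point is the centroid of the largest connected changed
component: centroids are robust to dendritic shapes, unlike
closest-to-rim-pixel rules. r_norm > 1 is clamped to 1 and flagged. A
component covering most of the rim band in its first frame triggers a
warning that the event may predate the stack.

On 100 synthetic videos with volume-uniform onsets the mean localization
error is ≈ 0.1 px (mean |Δr_norm| ≈ 0.001) with no radial bias; this
validates the detector against the renderer's conventions, not against
real dendrite textures, defocus, or illumination drift.

## Spectra, blank screening, drift

The freezing spectrum is the empirical survival curve over decreasing
temperature; T50 is the sample median (mean of the two central order
statistics for even n) — at n = 32 the median's sampling error
(≈ 1.25 σ/√n) dominates any difference from curve-interpolation
definitions. Blank screening flags (rather than silently deletes) events
with freezing temperature at or below the top of the pure-water blank range
(default −23.2 °C, range −30.0 to −23.2 °C): such events cannot be
distinguished from background nucleation. Freeze–thaw stability is an OLS
slope of temperature against cycle index with its standard error, plus a
per-cycle outermost-frequency table.

## Front velocity

The frozen region in each post-onset frame is segmented with the same
change-detection rule, keeping the largest connected component (a
max-distance metric would otherwise be dominated by isolated noise pixels).
The extent is the maximum distance from the onset pixel to any frozen pixel
— the dendrite tip sets the propagation speed — converted to μm. Frames
where the front reaches within 3% of the rim are masked invalid (beyond
that the geometry, not growth, limits extent), and an OLS slope of extent
against time gives the velocity in cm/s (< 3 valid frames → error).
Synthetic recovery is within 0.5% for velocities of 1–10 cm/s at 2100 fps.
Supercooling is defined as ΔT = 0 °C − freezing temperature (solute
depression ignored); `velocity_vs_supercooling` reports a Spearman rank
correlation and an OLS slope but deliberately fits no functional form —
monotone association is the only claim quantified.

## Pipeline

`run_pipeline` composes the stages (locate → sectors → null → decision →
spectrum → optional velocity) from a JSON/YAML config. Reports embed the
seed and a SHA-256 config hash and contain no timestamps, so identical
configs give byte-identical reports. Stage failures are surfaced with the
stage name and input identifier, and a failure manifest is written next to
the partial report. At the CLI boundary angles are degrees and temperatures
°C; internally angles are radians.

## Known limitations

- The bulk/AWI decision inherits the assay's blind spots: nucleation on the
  slide surfaces projects into the same 2D coordinates as bulk nucleation,
  and onsets within the shell width of the rim are indistinguishable from
  true interfacial ones.
- The synthetic videos are idealized (clean rim, uniform illumination,
  Gaussian noise, circular or mildly lobed fronts); passing tests bound
  algorithmic error, not robustness to real imaging artifacts.
- The three-sigma threshold is a convention, not a calibrated test size;
  the exact binomial tail is provided for readers who want one.
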