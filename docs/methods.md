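# Methods

This note documents the models behind each analysis module, the
synthetic-data generators that stand in for the original microscope and
trap recordings, the numerical choices that matter, and the limits of
what passing tests demonstrate.

Conventions used throughout: motion, displacement, and force toward the
microtubule **plus end are positive**; image coordinates are pixels with
the origin at the top-left pixel center, x rightward, y downward;
trajectories and trap records are in nm and pN. Every generator takes an
explicit integer seed and is bit-reproducible; there is no global random
state. Derived seeds are produced by `SeedSequence([seed, crc32(tag)])`
and kept below 2^31.

## Spot detection and colocalization (cosmos)

Detection bandpasses the image with a difference of Gaussians (spot
scale 1.0 px, background scale 4.0 px), takes local maxima above a
threshold with a minimum separation of 3 px (brighter peak kept), and
refines each candidate by least-squares fitting a symmetric 2-D Gaussian
with fixed σ (the nominal PSF width) plus a constant background in a
9×9 window. The four parameters (x, y, amplitude, background) are
optimized by damped Gauss–Newton, vectorized across all candidates; fits
that leave the window are rejected. Integrated intensity is 2πσ²A.
A Gaussian fit rather than a centroid is used because the centroid is
biased at low signal-to-background.

Channel registration is a 6-parameter affine fit by linear least
squares on paired fiducial positions; at least three non-collinear
pairs are required for identifiability, and the residual RMS is
reported. In the pipeline the map is estimated from a dense simulated
fiducial field detected in both channels and paired by proximity.

A reference (DNA) site counts as colocalized when at least one target
(GFP) spot lies within radius r of it after registration; one target
spot may satisfy several references. The default r = 1.5 px is a
calibrated choice — large against the combined localization and
registration error (≲0.2 px) and small against the spot density — and
is always reported with the output. Fractions are computed per field of
view and aggregated as an unweighted mean ± SEM across fields, matching
how replicate fields are normally summarized; the expected chance
colocalization, 1 − exp(−ρπr²) with ρ the observed target density, is
reported alongside rather than subtracted.

Polarity-marked capture calls use the brightness rule (attached end dim
⇒ plus, bright ⇒ minus) and fall back to the length rule (longer
extension ⇒ plus) when both ends share a brightness class; fully
ambiguous filaments are excluded as undetermined. Experiments are
summarized by the unweighted mean ± SD of per-experiment plus-end
percentages, with pooled counts reported alongside.

## Photobleach step counting (bleachsteps)

Bleaching of N fluorophores produces a piecewise-constant intensity with
N downward steps at exponential times. The detector is recursive binary
segmentation: within a segment, every admissible split (≥ 5 frames per
side by default) is scored with Welch's unequal-variance t statistic,
computed for all splits at once from cumulative sums; the strongest
split is accepted when its two-sided p-value, **Bonferroni-corrected
over the candidate splits in that segment**, is below α (default 0.01),
and both halves are recursed. Without the correction, testing the
maximal t at level α would give a per-trace false-positive rate far
above α; with it, flat traces stay flat with probability ≳ 1 − α. A
merge pass then repeatedly removes the least significant changepoint
until all adjacent segments differ at level α. Zero-variance halves (a
noiseless step) are a certain detection — the Welch degrees of freedom
underflow there and are special-cased.

Copy number is the count of downward transitions; upward transitions
are detected but excluded from copy counting, since bleaching is
monotone down. The detector is scale-invariant (t statistics are), and
at signal-to-noise 5 with ≥ 10 frames per segment it recovers ≥ 90% of
traces exactly. Two fluorophores bleaching within a few frames of each
other are fundamentally unresolvable; the copy-number histogram
therefore undercounts at high copy numbers, as the real assay does.

## Flip-flop nanometry (flipflop)

The model: a kinetochore assembly is anchored to the coverslip at a
tether point t; oscillating flow flips the assembly 180° about t, so a
tagged subunit at distance d from the anchor sits at t + d·û during one
flow epoch and t − d·û during the next (û the flow axis). Tracked
positions are averaged over the steady part of each epoch, excluding a
reorientation window (default 1.0 s; the transit is modeled as a linear
sweep of the same duration) after each reversal. The tether is inferred
per reversal as the midpoint of the flanking interval means and per
assembly as the average of those midpoints; each used interval then
contributes an unsigned displacement |(x̄ − t̂)·û|. The perpendicular
residual is kept as a QC column.

For a symmetric assembly the midpoint tether is exact in the noiseless
limit and the pooled displacement estimator is unbiased. When the two
pull directions give *different* true displacements d₁ ≠ d₂ (the
side-attached geometry), the midpoint tether is biased by (d₁ − d₂)/2
along the flow axis and both displacement estimates collapse toward
(d₁ + d₂)/2 — the pairwise displacement *sum* is still exact. The
module therefore also reports a median-of-midpoints tether and warns
when the two disagree, and it exposes
`displacements_from_tether` for measuring a subunit against a tether
located independently — in practice from the co-tracked centromeric-DNA
marker, whose flips are symmetric. The pipeline uses the DNA-derived
tether for all side-attached analyses.

Displacement distributions are fit by maximum likelihood with one
Gaussian (closed form) or a two-component Gaussian mixture (EM from 20
quantile-split initializations, best likelihood kept; a fit with a
component weight < 0.05 or vanishing SD is degenerate and falls back to
k = 1 with a warning). Model choice is by BIC (−2ℓ + p·log n, p = 2 or
5). BIC is deliberately conservative: for weakly separated components
at n ≈ 90 it prefers k = 1 in a substantial fraction of draws, so a
bimodality call from this package is a strong claim. SEMs of component
means come from a 200-resample bootstrap (components matched by mean
order). Trajectory linking is nearest-neighbor with a maximum jump;
frames with no acceptable candidate become gaps, never false links.

Pixel-to-nm scale is a required input wherever pixel data enter; the
generators work directly in nm.

## Trap mechanics (trapmech)

Sliding records are segmented into epochs at force sign changes; an
epoch whose force wanders beyond ±10% of its mean is flagged
non-constant and excluded from friction. Speed is the magnitude of the
OLS slope of position vs time (≥ 10 samples), direction from its sign.
Friction uses events whose mean force magnitude falls in a half-open
bin (default 1 ± 0.5 pN): each event contributes γ = F̄/v with its own
mean force, averaged per bead–microtubule pair and per direction
(mean ± SEM), with pooled summaries emitted as well since it is not
always knowable whether published means pooled events or averaged pairs
first.

On a drifting random walk the OLS slope has heavy scatter — with
D = kT/γ, about 10% SD per ~1 µm event at 1 pN — so single-event speeds
are noisy while ensemble means converge; per-pair γ SEMs carry that
uncertainty.

Rupture analysis finds the force ramp (force rising above the preload,
estimated as the median of the record's first samples), smooths position
with a short mean filter (the snap-back is a persistent level change, so
smoothing costs a few samples of timing at most), and declares rupture
at the first sample where position drops toward the trap center by more
than a threshold (default 15 nm ≈ 6× the smoothed-difference noise at
0.2 pN-equivalent noise) within a 5-sample window. Peak force is read
from a linear regression of the ramp over the ~50 preceding samples,
which averages out force-measurement noise. If no snap-back occurs
before the trap's load limit (default 23 pN) the event is censored at
the limit; a separate censor reason exists for surface failures.
Censored events are excluded from means and SEMs but always tabulated,
and beads measured at both microtubule ends get a paired plus/minus
comparison.

## Shared statistics (statcore)

The two-sample Kolmogorov–Smirnov comparison uses the exact conditional
null distribution when n_A·n_B ≤ 400 and the asymptotic Kolmogorov
distribution with the effective-n correction otherwise (delegated to
scipy; the test suite verifies the exact branch against brute-force
enumeration of all labelings). The asymptotic tail underestimates very
small p-values at n ≈ 10, which is why the exact branch exists.
p-values below 10⁻¹⁵ are reported as that bound with a flag, never as
zero. Quartiles use linear interpolation (type 7), stated in the
output, and box whiskers are mean ± 1 SD.

`run_pipeline` chains the simulate → analyze stages, writes all tables
as CSV plus a `metrics.json` and a log with versions and seeds, and is
byte-deterministic given config + seed.

## What the generators emulate — and what they do not

- **CoSMoS fields**: symmetric Gaussian PSF, Poisson shot noise on
  spots + background, Gaussian read noise, gamma-distributed spot
  brightness, an affine inter-channel misregistration, and uniform
  false spots. Sites are placed with a minimum separation (default
  6 px), reflecting sparse tethering with optically resolvable
  molecules; EMCCD gain/excess noise, aggregates, and unresolvable
  site pairs are not modeled, so detection-recall results apply to
  resolvable spots only.
- **Bleach traces**: single-exponential bleaching, equal step heights,
  Gaussian noise. No blinking, no partial steps, no baseline drift.
- **Flip-flop trajectories**: in-plane geometry only, isotropic
  localization noise, a linear reorientation transit (default 1.0 s at
  0.2 s frames). No microtubule flexural fluctuations, no z motion, no
  bleaching-induced track loss.
- **Sliding records**: drift v = F/γ(direction) plus Brownian noise
  with D = kT/γ by default; 200 Hz sampling (the real acquisition rate
  is configurable, not asserted). No trap compliance dynamics.
- **Rupture records**: position proportional to force through a nominal
  trap stiffness (0.05 pN/nm), instantaneous snap-back, optional
  censoring at the load limit. Strengths are drawn from a configurable
  family (gamma by default); draws at or below the preload are
  rejected by the caller as preload failures, mirroring the exclusion
  of attachments that fail before ramping.

Default generator parameters reproduce the published study conditions:
~380 sites × 9 fields at 28% colocalization (inner-kinetochore-like)
with a ≤0.1% negative control; 591 bleach traces; end-attached
displacements 16/12/37/65 nm with 74/67/116/128 intervals over 13/9/19/22
assemblies and an 8 nm assembly-to-assembly spread (chosen so pooled
SEMs land near 1 nm, as observed); side-attached 39/14 nm with a 6 nm
spread; sliding drag 1/109 and 1/674 pN·s/nm with ~35% log-normal
pair-to-pair spread; rupture strength means 9.7/3.3 pN with SDs 6.6/2.5
(matching the reported SEMs at n = 43/26), preload 1 pN, ramp
0.25 pN/s, limit 23 pN.

Passing the recovery tests shows the estimators are unbiased and
correctly calibrated **under these generative models**; it does not
validate the models against raw experimental data, which are not
publicly archived.

## Known limitations

- The side-attached tether bias is removed only when a symmetric
  co-tracked marker is available; with no DNA channel, side-attached
  displacements collapse toward the direction average.
- Censored rupture events are excluded from means; if the underlying
  strength distribution has substantial mass above the load limit the
  reported mean understates the true mean (by design — it matches how
  censored data are usually summarized, and the censored count is
  always reported).
- The KS exact branch assumes continuous data; heavy ties would make
  the permutation null conservative.
- Copy-number histograms are raw step counts: no correction for
  immature or pre-bleached GFP.
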