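# Methods

## The measurement problem

Adult fly indirect flight muscle shows a stereotyped striation pattern in
fluorescence: phalloidin (F-actin) gives a bright line at each Z-disc, a
plateau over the thin-filament arrays, and a dark central trough at the
H-zone, where no filamentous actin is present; an anti-obscurin channel
marks the M-line mid-sarcomere instead. `sarcotrack` treats all geometric
questions — how long is a sarcomere, how long are its thin filaments, how
wide is its H-zone — as 1-D signal-processing problems on calibrated
intensity profiles, and wraps them together with the functional (climbing),
transcriptional (qPCR) and turnover (pulse-chase) quantifications that the
same kind of study needs.

## Morphometry

**Peak detection.** Profiles are Gaussian-smoothed (default sigma of one
pixel), local maxima below a prominence threshold (default 20% of the
profile dynamic range) are discarded, and surviving maxima are refined by
three-point parabolic interpolation, giving sub-pixel positions. M-lines
are detected as peaks in an obscurin channel or as troughs (inverted
peaks) in phalloidin. Fewer than two peaks is a no-measurement outcome
(`None`), not an error: flat or degenerate profiles must not crash a batch
run. Sarcomere lengths are consecutive peak-to-peak distances.

**Thin filament length and H-zone width.** Within one sarcomere bounded by
adjacent Z-disc peaks, intensity is normalised to [0, 1] between the
H-zone minimum (searched over the central 40% of the sarcomere) and the
thin-filament plateau level (median over bands 15–35% of the sarcomere
length from each Z-disc). On each side, the position where the descending
slope crosses 0.5 is found by linear interpolation between samples. TFL is
the mean distance from each crossing to its nearer Z-disc peak centre; HZ
is the distance between the crossings. These definitions make the closure
SL = 2·TFL + HZ an algebraic identity per sarcomere, which the tests
exploit. Design choices worth stating:

* The half-amplitude reference levels are the per-sarcomere plateau median
  and trough minimum — robust, parameter-light, and insensitive to global
  intensity scaling (all length outputs are provably scale-invariant).
* TFL is measured from the Z-disc *peak centre*, which is sub-pixel
  definable and symmetric, rather than from a peak edge.
* If the interior never dips below the plateau (no resolvable H-zone) the
  sarcomere is flagged degenerate with HZ = 0 and TFL = SL/2.
* Adjacency of the supplied Z-disc pair is checked heuristically: an
  interior sample above 85% of the Z-disc level indicates a skipped peak.

**Accuracy and its limits.** The 50%-crossing estimator is unbiased when
the optical blur is at or below the pixel scale. A PSF sigma well above
the pixel size broadens the apparent H-zone (at sigma = 0.1 µm on a
0.16 µm H-zone the overestimate reaches ~2 pixels) while leaving SL, a
pure peak-spacing quantity, unaffected. The synthetic defaults therefore
use psf_sigma = pixel_size = 0.05 µm; with 5% noise, SL, TFL and HZ are
all recovered within one pixel on average.

**Statistics.** Groups are summarised as n/mean/SD/SEM (SEM = SD/√n; a
singleton group reports SD 0 with a flag). Group comparison is the
two-sided equal-variance Student's t-test (Welch behind a flag), with
significance stars `*` p<0.05, `**` p<0.005, `***` p<0.0005. Percent
changes are computed from unrounded means and rounded only for display.

## Pulse-chase turnover

The generator's kinetic form is deliberately minimal — baseline until a
lag time, linear rise to a peak, then single-exponential decay (or a
plateau for a stable cytoplasmic control); real incorporation curves are
only known empirically, so the shape is exposed as parameters
(`TurnoverKinetics`) rather than hard-coded. Defaults follow the
experimental timing: onset 20 h, peak 95 h, with a 28 h induction pulse,
and a several-day (72 h) half-life.

* **Onset** is the earliest timepoint whose mean exceeds the t=0 baseline
  in a one-sided two-sample t-test (alpha 0.05), with all later pre-peak
  timepoints also significant. The sustained-rise requirement rejects
  single-timepoint excursions. On a 5 h grid a true lag of L is detected
  at L+5 (the mean at L itself still equals baseline) — within one
  sampling interval by construction.
* **Peak** is the timepoint of maximal mean Z-disc intensity, earliest on
  ties.
* **Half-life** is ln 2/|slope| from a least-squares fit of
  log(mean − baseline) over post-peak timepoints (≥ 3 required; baseline =
  first-timepoint mean; non-negative slope → no decay → `None`). The
  single-exponential assumption is explicit; multi-compartment decay is
  out of scope.
* The **Z-disc/body ratio** is computed per sarcomere and summarised as
  mean ± SEM per timepoint; it is scale-invariant, so uncalibrated
  intensities are fine.

## Comparative-Ct qPCR

Fold change is 2^−ΔΔCt with amplification efficiency fixed at 2 (the
method's defining assumption; efficiency correction is out of scope).
Replicates are averaged on the Ct scale before ΔCt, the common
convention. Knockdown time courses are calibrated genotype-matched: each
arm (RNAi and control) is referenced to its own day-0 sample, so both
start at fold 1 and their percent reductions are directly comparable. The
synthetic Ct generator adds Gaussian noise on the cycle scale
(default sd 0.15 cycles). Note the intrinsic precision limit: with
triplicates at sd 0.15 the ΔΔCt estimate carries sd ≈ 0.17 cycles, i.e.
~12% multiplicative fold error, so single-experiment knockdown estimates
at mid-range folds scatter by several percentage points; deep knockdowns
(small folds) are recovered much more tightly in absolute terms.

## Geotaxis screen

A fly is a success if it climbs above the line; a vial-timepoint score is
the mean success fraction over technical replicates, with SEM across
vials. Trajectories are normalised to day 0 (scores above 1 are allowed,
not clipped; a zero day-0 score marks the line unusable). "Complete loss"
is formalised as *sustained* zero — the earliest assay day from which
every later assayed day also scores zero — which is robust to a single
zero reading at small n. Severity windows (≤9, 12–21, ≥24 days, never)
partition all possible outcomes because the assay grid runs every three
days from 0 to 30: days 10–11 and 22–23 cannot occur. The synthetic
climbing generator draws per-(vial, replicate) successes from a binomial
with a per-day success probability, which reproduces both the mean decline
and the sampling noise of a real assay at the same n.

## Enrichment and networks

Enrichment ratios are purely descriptive, matching how screen heatmaps
are usually read: term frequency in a class over term frequency in the
screened set. Genes without annotations still count in denominators —
they were screened. When the classes partition the universe the weighted
ratios obey Σ_c (n_c/N)·ratio = 1 exactly, which the tests assert as an
algebraic check. No multiple-testing machinery is attached by default; a
hypergeometric p-value helper exists for exploration. The interaction
network is a multigraph (parallel genetic and physical edges allowed,
duplicates collapsed per endpoints-and-kind, self-loops kept) with node
attributes for severity, display colour and functional group; GraphML
round-trips all attributes, the TSV form round-trips the edge list.

## Synthetic data: what it does and does not emulate

The generators produce periodic striation profiles (piecewise template →
Gaussian PSF blur → pixel sampling → additive Gaussian noise, clipped at
zero as a detector would), 2-D striped-fibril fields, lag–rise–decay
pulse-chase samples, doubling-model Ct tables, binomial climbing outcomes
and class-structured screen fixtures. Profile margins continue the
periodic pattern (with flanking off-window Z-disc peaks) so edge
sarcomeres are measured under the same conditions as interior ones. All
positions are continuous µm; sampling uses the pixel-centre convention
with index 0 at the profile start. Every generator takes an explicit seed
and is bit-reproducible; no global random state is used.

Not emulated: photobleaching, spatially correlated noise, fibril
curvature or out-of-plane tilt, sarcomere-to-sarcomere length
heterogeneity within a fibril, qPCR efficiency drift, and day-to-day
assay batch effects. Passing recovery tests therefore demonstrates the
estimators are correct and unbiased under idealised imaging and sampling
noise — not that they are robust to every systematic artefact of real
confocal data.

## Problem sizes and defaults

The bundled tests and the acceptance script run at the study's own
scales, which are small: 40 profiles × 8 sarcomeres at 0.05 µm pixels for
morphometry recovery, 40 sarcomeres per timepoint on 5–15 h grids for
turnover, triplicate qPCR, and 10 vials × 10 flies × 5 technical
replicates × 11 assay days for climbing. Everything completes in seconds
on one CPU.
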