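# Methods

This note documents the models, estimators and numerical choices behind
`chromoscope`, and what the synthetic-scene validation does and does not
demonstrate about real data.

## The experimental system being modelled

A single bacterial chromosome (or plasmid) sits in a flat, quasi-2D
microfluidic chamber connected to flow channels only through thin
capillaries. Exchange of reagents is purely diffusive, so species are
retained on a timescale set by geometry and mobility. Proteins bound to the
chromosome (nucleoid-associated proteins, RNA polymerase, the condensin
MukBEF) are imaged by fluorescent fusions; nascent proteins synthesized by a
cell-free transcription–translation (TxTl) system are captured on the
antibody-functionalized surface and counted one molecule at a time; the
DNA itself is stained and segmented to follow conformational (area) changes
under macromolecular crowding.

## Compartment residence time

For a chamber of radius `R` connected by a capillary of length `L` and
width `W`, the mean residence time of a species with diffusion coefficient
`D` is

    tau = pi R^2 L / (2 D W).

This is the chamber's 2D volume divided by the diffusive conductance of the
capillary, valid when the capillary dominates the escape resistance. The
module treats the layout as having a single exchange capillary of width
`W`; the second, constricted capillary (~0.4 um high versus 1.5 um chamber
height) contributes negligibly to exchange and is kept only as a geometric
attribute. Units are fixed at micrometres/seconds everywhere; minutes
appear only in reporting properties (`lifetime_min`). The inverse design
helper returns `R = sqrt(2 D W tau / (pi L))` and round-trips with the
forward formula to floating precision.

With the default layout (R = 10 um, L = 40 um, W = 1.5 um) this gives
~7 min for an mRNA-scale species (D = 10 um^2/s) and ~41 min for a plasmid
(D = 1.7 um^2/s) — the design points the package reproduces analytically.

## Synthetic scenes and the image-formation model

Every estimator is validated against scenes with recorded ground truth:

- **Brownian tracks** — per-axis Gaussian steps of variance `2 D dt`;
  optional reflecting wall at the chamber radius. Escape through the
  capillary is *not* simulated particle by particle; the analytic lifetime
  covers retention, and no downstream analysis needs per-particle escape.
- **Surface-capture arrivals** — homogeneous Poisson event times, uniform
  positions over a disk-shaped capture area, exponential photobleaching
  (default mean 60 s at 1 Hz imaging). No blinking beyond bleaching.
- **Dissociation traces** — `I(t) = (1-A) exp(-t/tau) + A` plus i.i.d.
  Gaussian noise; `A` is the immobile (tightly bound) fraction.
- **Nucleoid scenes** — each chromosome is a smooth-edged disk (plateau
  intensity 1) carrying Gaussian sub-blobs (default sigma 0.45 um, relative
  amplitude 0.8, pairwise separation >= 2 um) that model condensed
  high-density DNA regions. The *true area* is defined as the
  half-plateau super-threshold area of the noiseless field, measured on the
  pixel grid at construction, so blob tails count toward the truth exactly
  as a thresholding segmenter would see them. Condensin-like spots sit on
  sub-blob centres (colocalized) or >= 0.7 um away (non-colocalized); the
  population-level colocalized fraction is apportioned exactly up to
  rounding to whole blobs. For compact chromosomes the sub-blob sigma
  shrinks to 0.4 of the body radius so condensed structure stays inside the
  body.
- **Kymographs** — a 1D profile whose super-threshold extent rises
  mono-exponentially toward a plateau during field-ON epochs and decays
  during OFF epochs.

Image formation: pixel-integrated Gaussian PSF (sigma 0.16 um at
0.16 um/pixel — two pixels equal the 0.32 um colocalization radius used
downstream), Poisson shot noise on signal plus background, EM gain as a
gamma-distributed multiplicative stage (shape = photon count), additive
Gaussian read noise. The gamma approximation reproduces the EMCCD excess
noise factor of 2 without modelling the full multiplication cascade, which
is sufficient for SNR-realistic detection tests. Photon budget (400/frame
per emitter), background (5/pixel), gain (30) and read noise (10 counts)
are generator defaults with no measured counterpart; they are
config-exposed and recorded with every rendered scene. A nucleoid plateau
of ~105 photons gives the SNR-10 imaging condition used in the area
validation (`plateau_photons_for_snr`).

What the scenes do **not** emulate: polymer mechanics of the chromosome,
optical aberrations beyond a Gaussian PSF, spatially structured background,
stage drift, and multi-state photophysics. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to every artefact of real microscopy data.

## Spot detection, tracking, arrival counting

Detection runs per frame: square-root variance stabilization (EM-amplified
shot noise is heavy-tailed; without stabilization a MAD-calibrated gate
leaks false positives), difference-of-Gaussians band-pass at sigma and
2 sigma, local maxima, and an SNR gate at `snr_min` (default 5) robust
standard deviations (1.4826 x MAD) above the frame median. Sub-pixel
positions come from an intensity-weighted centroid in a (4 sigma + 1)-pixel
window — adequate for the 0.32 um colocalization scale; Gaussian fitting is
a possible refinement, not implemented. Localization RMSE is below half a
pixel at SNR >= 10 on synthetic scenes.

Linking is greedy nearest-neighbour frame to frame (cost = squared
distance, rejection beyond `max_disp_um`, gaps up to `max_gap_frames`
bridged, ties broken by distance then detection index). Sparse scenes —
at most a handful of emitters per compartment — do not warrant global
assignment. MSD is time-averaged over all detection pairs per lag, up to
0.25 of the track length; the diffusion coefficient is the pair-count-
weighted least-squares slope through the origin divided by 4, with negative
slopes reported as D = 0 and flagged.

Arrival counting merges repeated detections of one immobilized molecule by
union-find linkage: detections join when closer than `radius_um` (default
0.32 um) in the plane and within `max_frame_gap` (default 5) frames;
components smaller than `min_detections` (default 2) are discarded. This
implements radius-plus-gap density clustering with the size filter applied
to whole clusters, which is the stated contract; DBSCAN core-point
semantics would differ slightly for minimum sizes > 2. Each cluster yields
one arrival event at its earliest frame. The defaults are analysis choices,
not measured values, and are logged with every run.

## Kinetics estimators

- **Dissociation**: traces are background-subtracted, normalized by the
  initial value, averaged across chromosomes, then fitted once
  (average-then-fit) by bounded nonlinear least squares with
  `A in [0, 1]`, `tau > 0`. Initialization: `A0` = mean of the last 10% of
  the trace, `tau0` = first crossing of `(1 + A0)/2`. Weighting is uniform.
  A trace that never leaves its plateau is flagged unidentifiable rather
  than fitted.
- **Arrivals**: for a homogeneous Poisson process the *waiting times*
  between events are exponential, so the empirical CDF of waiting times
  (plotting position k/n; the final point is exactly 1) is fitted by least
  squares to `1 - exp(-t/tau)`, the field's standard presentation. The
  first waiting time is measured from the start of observation and no
  dead-time offset is fitted. Least squares on the ECDF carries a small
  positive bias at low counts (~+3% at n = 200, <1% at n = 1000); the
  maximum-likelihood alternative (rate = 1/mean wait) is available through
  the same fit surface via the waiting-time helper. The bi-exponential
  model is reported in canonical `tau1 <= tau2` order; it is flagged as
  collapsed when `tau2/tau1 < 1.5` or the fast fraction sits at the
  boundary. Model selection prefers mono unless bi cuts the residual sum by
  >25% *and* both components are resolved (`tau2/tau1 > 3`, fraction in
  [0.1, 0.9]); on pure-exponential data this keeps the mono choice in
  >=95% of datasets at n = 300.
- **Bound fractions** are per-cell ratios `(after - bg)/(before - bg)`,
  clipped to [0, 1] with the clip count reported, plus the ensemble median:
  noise can push single-cell ratios past 1, and medians are the reported
  statistic.
- **Stretch cycles** are fitted per epoch (mono-exponential rise toward a
  free plateau during ON, decay during OFF), averaging time constants
  across epochs; epochs under 3 frames are skipped with a warning and time
  constants below one frame interval are flagged unresolved.

## Nucleoid segmentation and statistics

Segmentation: grey morphological opening with a 6 um disk estimates
background (removes everything chromosome-sized and smaller), Gaussian
smoothing at 0.25 um, then a global threshold — Otsu by default, with a
guard requiring the threshold to clear median + 5 robust sd of the
background-subtracted image (Otsu always splits, even pure noise), or a
constant threshold by configuration. 8-connected components below 1 um^2
are discarded; an optional watershed on the distance transform splits
touching chromosomes. This classical operator replaces learned star-convex
segmenters deliberately: it is deterministic, dependency-light, and
validated against generator truth; the output contract (labelled masks with
areas) permits swapping in a learned model. Reported areas are plain mask
areas (pixel count x pixel area) without intensity weighting.

Region linking across frames uses the literal >= 1 pixel mask-overlap rule,
largest overlap winning ties, lowest label breaking exact ties, and no gap
bridging — a chromosome absent for one frame starts a new series. The
summed-area series divides each frame's total area by the frame-0 total and
smooths with a Gaussian kernel (reflective edges).

Blob detection is scale-normalized Laplacian-of-Gaussian maxima restricted
to chromosome masks, gated by relative prominence (default 0.3 of the
strongest in-mask response) *and* an absolute floor of 5 robust sd of the
out-of-mask response, with quadratic sub-pixel interpolation. Colocalization
uses the strict rule: blob and spot match only when their distance is
*less than* 0.32 um (ties at exactly 0.32 um do not match), matched
greedily one-to-one by distance; the fraction is matched blobs over total
blobs. Cluster counts assign detected spots to regions by pixel
containment.

Dose-response aggregation reports per-condition mean areas with the
15.9%/84.1% empirical quantiles (linear interpolation between order
statistics — the +/- 1 sd band for normal data). Group comparisons use the
two-sided Mann–Whitney U test: exact null distribution for tie-free pooled
samples of <= 20 values, tie-corrected normal approximation otherwise, no
multiple-testing correction. All-identical input is degenerate and reported
as p = 1 with a flag.

## Reproducibility and problem sizes

One global seed drives everything; stage seeds derive deterministically
from it via SHA-256 (`_seeds.derive_seed`), so identical configuration and
seed reproduce bit-identical stacks and truth tables. The validation suite
and the reproduction script run the recovery pipelines at these sizes,
chosen to keep each estimate's sampling error several times smaller than
its tolerance: 50 rendered tracks x 100 frames for diffusion; 20 seeds x 4
averaged replicate traces for dissociation; 20 movies x 60 min (pooling
several hundred events) per arrival rate; 20 scenes x 6 chromosomes x 5 blobs for
colocalization; 20 scenes x 4 chromosomes for areas.

## Known limitations

- The greedy linker can fragment a track when a diffusive step exceeds the
  linking radius; pooled MSD estimates inherit a small downward bias from
  the implied displacement truncation (well within the 10% validation
  band at the plasmid mobility).
- The ECDF least-squares rate estimator is biased upward by a few percent
  at low event counts (see above); pool events before fitting.
- Segmentation accuracy is quoted for the generator's smooth-edged
  nucleoids at SNR >= 10; heavily textured or overlapping chromosomes
  need the watershed option and were not part of the validation envelope.
- Arrival counting undercounts emitters that bleach before reaching
  `min_detections` frames (~3% at the default 60 s bleach time and 1 Hz
  imaging) and merges two molecules arriving within the clustering radius
  and frame gap; both effects are inside the 10% validation band at the
  studied rates.
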