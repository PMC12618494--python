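# chromoscope

Quantitative analysis of single bacterial chromosomes in semi-open
microfluidic compartments.

When an *E. coli* chromosome is transplanted into a flat microfluidic
chamber that exchanges material with flow channels only through thin
capillaries, a handful of measurements characterize the system end to end:
how long species are retained in the chamber, how fast chromosome-bound
proteins dissociate when a cell-free expression system is introduced, how
often single nascent proteins appear on the functionalized surface, how
condensin clusters colocalize with condensed DNA blobs, and how the
chromosome's segmented area responds to macromolecular crowding.
`chromoscope` implements that analysis pipeline as a tested, reusable
library for microscopists and cell-free synthetic biologists, together with
a ground-truth-known synthetic scene generator so every stage is verifiable
without experimental data.

## What it computes

- **Compartment design** — the diffusive residence time
  τ = πR²L/(2DW) of a species with diffusion coefficient `D` in a chamber
  of radius `R` behind a capillary of length `L` and width `W`, and the
  inverse design problem (radius for a target lifetime).
- **Single-molecule detection and tracking** — difference-of-Gaussians
  detection with a robust SNR gate and sub-pixel centroids; greedy
  nearest-neighbour linking; time-averaged MSD and the diffusion
  coefficient from the ⟨r²⟩ = 4Dt fit.
- **Arrival counting and kinetics** — spatiotemporal clustering of repeated
  detections into single arrival events; least-squares fits of the
  waiting-time CDF to 1 − exp(−t/τ) (mono) and its two-component
  extension, with principled model selection; dissociation fits to
  I(t) = (1−A)exp(−t/τ) + A with the immobile fraction `A`; bound
  fractions; elongation rates; stretch/relax time constants from
  electric-field kymographs.
- **Nucleoid analysis** — classical chromosome segmentation (background
  opening, Otsu, connected components, optional watershed), overlap-based
  region tracking, normalized summed-area series, Laplacian-of-Gaussian
  blob detection, strict <0.32 µm one-to-one colocalization, condensin
  cluster counts, crowding dose-response curves with 15.9/84.1% quantile
  bands, and two-sided Mann–Whitney U comparisons.
- **Synthetic scenes** — Brownian tracks, Poisson surface arrivals with
  photobleaching, dissociation traces, nucleoid populations with known
  areas and colocalization, and stretch kymographs, rendered through a
  pixel-integrated Gaussian PSF with Poisson/EM-gain/read-noise camera
  statistics and full ground-truth tables.

See `docs/methods.md` for models, assumptions, parameter defaults and
limitations.

## Worked example

Design a compartment and verify the retention it gives an mRNA-scale
species and a plasmid:

```pycon
>>> from chromoscope import CompartmentGeometry, compartment_lifetime
>>> geom = CompartmentGeometry(radius_um=10, capillary_length_um=40,
...                            capillary_width_um=1.5)
>>> compartment_lifetime(geom, 10.0).lifetime_min   # mRNA, D = 10 um^2/s
6.9813...
>>> compartment_lifetime(geom, 1.7).lifetime_min    # plasmid, D = 1.7 um^2/s
41.0665...
```

A 20 µm chamber behind a 40 × 1.5 µm capillary holds an mRNA for ~7 min
and a plasmid for ~40 min — long enough to express from it.

Simulate a surface-capture movie and recover the protein-synthesis rate
through the full chain (detect → cluster → waiting-time CDF fit):

```pycon
>>> from chromoscope import pipelines
>>> res = pipelines.recover_arrival_rate(0.67, n_seeds=2, duration_min=60,
...                                      seed=0)
>>> round(res.value, 2), res.extra["n_events"], res.extra["n_true_events"]
(0.72, 78, 81)
```

78 of 81 simulated arrival events survive detection and overcount
suppression, and the fitted waiting-time distribution returns the
generating rate (0.67 events/min) within the sampling error of ~80 events;
pooling more movies tightens it.

The same pipelines are scriptable from the shell:

```sh
chromoscope lifetime -d 10 -d 1.7 --out results/
chromoscope simulate --kind nucleoid --out results/
chromoscope segment results/nucleoid.tif --channel dna --out results/
chromoscope coloc results/nucleoid.tif --out results/
```

Every subcommand writes its outputs next to a JSON run log with the seed,
parameters and config hash.

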