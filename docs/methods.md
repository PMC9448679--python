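# Methods

`oligofret` implements the computational pipeline used to detect, size and
structurally classify protein oligomers (the motivating system is
α-synuclein labelled with a donor/acceptor FRET pair) from four kinds of
fluorescence data: two-channel photon-count burst traces from confocal
measurements under fast flow, three-channel voxel stacks from in-cell
imaging, single-spot photobleaching traces, and two-color TIRF spot
images.  A synthetic-data module generates every one of these inputs with
ground truth, so the whole pipeline is exercisable and testable without a
microscope.

## Measurement model

All analyses reduce to four pieces of arithmetic on detector counts,
applied identically to a burst (counts summed over its bins) or a voxel:

* donor correction: `I_D = D − A_D`
* acceptor correction: `I_A = A − A_A − C·D`
* FRET efficiency: `E = I_A / (I_A + I_D)`
* apparent size: `2·(I_D + I_A/γ) / I_monomer`

`A_D`, `A_A` are instrument autofluorescence levels (counts per bin or
voxel, measured without fluorophores), `C` is the donor→acceptor
cross-talk fraction (acceptor→donor leakage is taken as negligible), and
`γ` is the gamma factor combining the relative detection efficiencies and
quantum yields of the two dyes (default 1.0, configurable; it must be
measured per instrument).  `I_monomer` is the mean brightness of a single
donor fluorophore, estimated as the average donor intensity of
*non-coincident* bursts, or supplied in configuration.  The factor 2 in
the size estimate reflects equimolar donor/acceptor labelling in which
only the donor dye is directly excited, so total corrected intensity
counts roughly half the monomers.  Sizes are "apparent": excitation,
emission and the transit path through the confocal volume are stochastic,
so the estimate is unbiased only on average.

Efficiency maps and in-cell voxel efficiencies use the efficiency
equation literally, without a γ term; γ enters only the size estimate.

**Negative corrected intensities** (counts below the autofluorescence
estimate) are never clamped, because clamping biases E toward 0 or 1.
The affected event or voxel is flagged, excluded from histograms and
sizing, and counted in the run summary.

## Burst analysis

Traces are photon counts in fixed-width bins (default 1 ms, free
parameter).  A **donor event** is a maximal run of consecutive bins with
donor counts at or above the detection threshold (default 10 counts per
bin); merging runs rather than counting bins avoids double-counting slow
transits.  The event is **coincident** — evidence of a species carrying
both dyes, i.e. an oligomer — when at least one bin of the run also
reaches the threshold in the acceptor channel.  Event intensity is the
run sum by default (a per-bin peak mode is provided, since burst software
varies on this point).  Runs touching the trace boundary are kept but
flagged.  Per-bin autofluorescence is scaled by the run length before
subtraction.  The **fraction of coincidence** is the number of coincident
events divided by all donor events.  Apparent sizes are classed as small
(< 3 monomer units, i.e. below the apparent-dimer floor of detection),
medium (3–20) or large (> 20).

## Two-Gaussian deconvolution and fraction converted

Coincident-event (or masked-voxel) efficiencies are binned at width 0.05
on [0, 1] and fit with a sum of two Gaussians by nonlinear least squares
on the counts (optionally 1/√counts-weighted).  Fitting is *global*:
centers and widths are shared across all datasets (timepoints, variants)
while component amplitudes are free per dataset.  The structural
readout, **fraction converted**, is the analytic area of the
higher-center component divided by the total fitted area
(area = amplitude × width × √(2π)); its uncertainty is first-order
(delta-method) propagation from the least-squares covariance.

Numerical choices:

* **Shared component width (default).**  With strongly overlapping
  populations (centers 0.24/0.48, spreads ≈ 0.08) sampled into 20 bins,
  two free widths are weakly identified: the broader component drifts
  into the overlap region and drags both centers.  Both structural
  classes show comparable heterogeneity, so one common width is the
  default; `share_width=False` restores independent widths.
* **Deterministic multi-start.**  Starts are the two dominant
  well-separated modes of the pooled histogram plus a fixed grid of
  center pairs; the lowest SSE wins, ties broken by start order, so the
  fit is reproducible bit-for-bit.
* **Component identity.**  Components are sorted by center; the high-E
  component is the compact/converted class.  A second component carrying
  < 1% of the pooled area *below* the dominant one is folded away
  (amplitude 0), otherwise the ordering convention would label a pure
  low-E sample as fully converted.
* **Degeneracy.**  Fits whose centers collapse within one bin width are
  flagged and refuse to report a fraction; all-zero histograms raise.

Per-cell mean efficiencies are summarized with a percentile bootstrap of
the mean (scipy.stats.bootstrap, 9,999 resamples by default, seeded).

## In-cell voxel pipeline

Voxels containing labelled protein are selected by thresholding the
directly excited acceptor channel (a FRET-independent total-protein
proxy) at `blank mean + k·sd` (default k = 3) using blank-image
statistics.  Each retained voxel gets corrected intensities and an
efficiency; per-cell summaries (mean E over retained masked voxels, mean
direct intensity, mean corrected acceptor intensity) are taken over
user-supplied label masks — cell segmentation is deliberately out of
scope.  Voxel efficiencies feed the same histogram/fit/fraction pipeline
as bursts.

## Photobleaching step counting

Spot intensity traces are fit with a piecewise-constant staircase by
iterative greedy change-point insertion: each insertion maximally reduces
the residual sum of squares (computed in closed form from cumulative
sums) and is accepted while the Gaussian-residual BIC
`n·log(RSS/n) + k·penalty·log(n)` improves.  The default penalty
multiplier is 2 — a change point adds two parameters, a location and a
plateau level; with multiplier 1 the criterion systematically
over-segments long plateaus.  Plateaus shorter than 3 frames are never
created, suppressing single-frame noise excursions.  Downward steps are
photobleaching events; upward steps are flagged as blinking and excluded
from the count.  Counts above a saturation cap (default 10) are reported
as a terminal "≥10" category, since near-simultaneous bleaching makes
larger oligomers indistinguishable.

## Two-color coincidence

Spots are detected per channel by a difference-of-Gaussians band-pass at
the PSF scale followed by local maxima above `mean + k·sd` of the
filtered image, with sub-pixel centroid refinement.  A channel-A
aggregate is coincident when any channel-B spot lies within the matching
radius (default 2 px); one-to-many matches count once (aggregate-level
counting).  The percentage coincidence is reported with a bootstrap CI
over fields of view when ≥ 3 fields are available (a normal
`mean ± 1.96·sd` mode is provided, whose interval may exceed 100%), else
a binomial interval.  The chance level is estimated by rotating channel
B 90° about the field center, which preserves density and spacing while
destroying correlations; for random fields it approaches the analytic
value `n_B·π·r²/area`.

## Synthetic data: what it emulates, and what it does not

The generators target the **statistical contract** of the analysis, not
the optics of the instrument:

* **Burst streams.**  Event arrivals are Poisson (at most one event per
  bin at default rates; collisions are recorded in ground truth).  An
  event of size *s* carries `ceil(s/2)` donor fluorophores; with total
  expected signal *B*, donor counts are Poisson(B·(1−E)) and acceptor
  FRET counts Poisson(γ·B·E), with per-event true E drawn from a
  truncated normal around the species center.  Cross-talk is a Poisson
  thinning (mean C·counts) of the *entire realized* donor channel and
  backgrounds are Poisson with the same `A_D`, `A_A` means the corrector
  subtracts, so the corrections are exactly unbiased on synthetic data.
* **`paper_mimic` scenario.**  Two hexameric oligomer populations
  (mid-range of the 4–10-mer class seen by step counting), low-E 0.24 and
  high-E 0.48 with spread 0.08, mixed 60/40; brightness 50
  photons/fluorophore/event; `A_D = A_A = 2` counts/bin, `C = 0.05`,
  `γ = 1`; 50 events/s for 100 s in 1-ms bins (≈ 5,000 events).  These
  values are fixed in `presets.yaml`; scenarios are versioned by name.
* **Voxel stacks.**  Aggregates are spheres with a compact high-E core
  and a looser low-E rim, plus a direct-channel signal proportional to
  total protein; noise is Poisson throughout.
* **Bleach traces.**  Geometric bleach times per fluorophore, Gaussian
  read noise; draws are rejected until steps are separated by ≥ 4
  frames, because merged steps are exactly the saturation regime the
  counter cannot resolve.
* **Spot fields.**  Each aggregate is independently coincident with the
  set probability (binomial per field, giving realistic field-to-field
  variation); spots are Gaussian PSFs with Poisson shot noise.

Not emulated: diffusion and flow profiles, 3-D PSFs, detector
afterpulsing, dye photophysics beyond the cross-talk/γ description,
acceptor direct excitation under donor illumination, cell morphology and
autofluorescence structure.  Passing tests therefore demonstrate that
the *analysis* is correct and unbiased under its own assumptions, not
that those assumptions hold on any particular microscope.

## Problem sizes and determinism

Simulation-backed checks use 5,000-event streams for mixture recovery
(and a 9-point grid of true fractions at the same size), 200 traces for
step-count recovery, and five 60-spot fields for coincidence recovery —
sizes at which Monte-Carlo error is comfortably below the tolerances
being checked while a full run stays fast on a laptop.  All randomness
flows from explicit seeds; fixed seeds give bit-identical outputs.

## Known limitations

* `I_monomer` from non-coincident bursts is biased high when event rates
  are high enough for bursts to overlap (pile-up inflates run sums).
* The two-component fit performs no model selection; one- or
  three-population samples must be recognized by the user (the <1%-area
  fold handles only the clean single-population case).
* Step counting assumes uniform step heights; strongly varying
  single-fluorophore brightness degrades counts before the saturation
  cap does.
* The coincidence chance control assumes approximately uniform spot
  density; strong spatial clustering inflates the rotated control above
  the analytic level.
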