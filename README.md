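# oligofret

Single-molecule and in-cell FRET analysis of protein oligomers.

Early aggregates of amyloid proteins such as α-synuclein are rare,
transient and far below the diffraction limit.  When the protein pool is
labelled with a donor/acceptor dye pair, oligomers — and only oligomers —
bring the two dyes within Förster distance, so they light up in three
complementary measurements: two-channel *coincident bursts* as species
flow through a confocal volume, a *FRET signal* in cell images, and
*stepwise photobleaching* of immobilized spots.  `oligofret` implements
the full computational side of these experiments for researchers
analysing such data (or building such instruments):

* **`oligofret.core`** — the measurement arithmetic: corrected
  intensities `I_D = D − A_D`, `I_A = A − A_A − C·D`, efficiency
  `E = I_A/(I_A + I_D)`, and apparent oligomer size
  `2(I_D + I_A/γ)/I_monomer`.
* **`oligofret.bursts`** — burst detection (≥ 10 counts/bin runs),
  two-channel coincidence, monomer-brightness estimation, per-event E,
  sizing and size classes, fraction of coincidence.
* **`oligofret.mixture`** — FRET-efficiency histograms (bin width 0.05),
  global two-Gaussian fits with centers/widths shared across datasets,
  the *fraction converted* (area of the high-E, compact-oligomer
  component over total) with propagated errors, and bootstrap CIs
  (9,999 resamples) for per-cell summaries.
* **`oligofret.incell`** — voxel-level in-cell FRET: direct-channel
  masking, per-voxel E maps, per-cell summaries.
* **`oligofret.stepfit`** — photobleaching step counting by greedy
  change-point insertion under a BIC stopping rule; monomers per
  oligomer with a ≥ 10 saturation category.
* **`oligofret.coloc`** — two-color spot detection and percentage
  coincidence with bootstrap/binomial CIs and a 90°-rotation chance
  control.
* **`oligofret.synthetic`** — seeded generators (with ground truth) for
  burst streams, three-channel voxel stacks, bleach traces and two-color
  spot fields, so every stage runs at desk scale.

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Simulate a 5,000-event lysate-like stream containing two oligomer
populations (low-E 0.24, high-E 0.48, mixed 60/40), then run the full
burst → histogram → global-fit pipeline:

```python
from oligofret.bursts import analyze_events, detect_events, fraction_of_coincidence
from oligofret.mixture import build_histogram, fraction_converted, global_fit
from oligofret.synthetic import load_preset, simulate_burst_stream

preset = load_preset("paper_mimic")
trace, truth = simulate_burst_stream(preset, seed=1, n_events=5000)
events = analyze_events(detect_events(trace, threshold=10), preset.instrument)

print(f"donor events:     {events.n_donor_events}")
print(f"coincident:       {events.n_coincident}")
print(f"coincidence:      {fraction_of_coincidence(events):.3f}")

fit = global_fit(build_histogram(events.efficiencies(), bin_width=0.05))
frac, err = fraction_converted(fit)
print(f"centers:          E = {fit.center_low:.3f} / {fit.center_high:.3f}")
print(f"shared width:     {fit.width_low:.3f}")
print(f"fraction converted: {frac:.3f} +/- {err:.3f}")
```

Output:

```
donor events:     4637
coincident:       4627
coincidence:      0.998
centers:          E = 0.240 / 0.477
shared width:     0.092
fraction converted: 0.387 +/- 0.006
```

The 4,637 donor-channel bursts are almost all coincident because this
scenario contains only dual-labelled oligomers (a monomer-dominated
`lysate_mimic` preset gives low coincidence instead).  The global fit
recovers the two generating population centers and assigns 38.7% of the
fitted area to the high-E component — the *fraction converted*, the
pipeline's structural-conversion readout — close to the 40% of events
drawn from the high-E population.

The same stages are scriptable from the shell via the `oligofret` CLI
(`simulate`, `bursts`, `mixture`, `incell`, `steps`, `coloc`); every
output JSON embeds the resolved configuration and seed.

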