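# Named burst-stream scenario presets. Presets are immutable: change a
# scenario by adding a new named entry, not by editing an existing one.
#
# paper_mimic: two oligomer populations mimicking the low-FRET (loosely
# packed, Type-A-like, E = 0.24) and high-FRET (compact, Type-B-like,
# E = 0.48) structural classes, 60/40 by number, each hexameric with a
# per-event efficiency spread of 0.08. 50 events/s for 100 s in 1-ms bins
# gives ~5,000 events.
paper_mimic:
  event_rate: 50.0
  duration: 100.0
  bin_width: 0.001
  instrument:
    autofluor_donor: 2.0
    autofluor_acceptor: 2.0
    crosstalk: 0.05
    gamma: 1.0
  species:
    - {size_true: 6, efficiency_true: 0.24, efficiency_sd: 0.08, weight: 0.6, brightness_per_monomer: 50.0}
    - {size_true: 6, efficiency_true: 0.48, efficiency_sd: 0.08, weight: 0.4, brightness_per_monomer: 50.0}

# monomer_only: donor-labelled monomers, no acceptor signal — the control
# stream used to measure monomer brightness and chance coincidence.
monomer_only:
  event_rate: 50.0
  duration: 100.0
  bin_width: 0.001
  instrument:
    autofluor_donor: 2.0
    autofluor_acceptor: 2.0
    crosstalk: 0.05
    gamma: 1.0
  species:
    - {size_true: 1, efficiency_true: 0.0, efficiency_sd: 0.0, weight: 1.0, brightness_per_monomer: 50.0}

# lysate_mimic: monomers plus both oligomer classes, emulating a cell
# lysate measured under fast flow where most events are free monomer.
lysate_mimic:
  event_rate: 50.0
  duration: 100.0
  bin_width: 0.001
  instrument:
    autofluor_donor: 2.0
    autofluor_acceptor: 2.0
    crosstalk: 0.05
    gamma: 1.0
  species:
    - {size_true: 1, efficiency_true: 0.0, efficiency_sd: 0.0, weight: 0.7, brightness_per_monomer: 50.0}
    - {size_true: 6, efficiency_true: 0.24, efficiency_sd: 0.08, weight: 0.18, brightness_per_monomer: 50.0}
    - {size_true: 6, efficiency_true: 0.48, efficiency_sd: 0.08, weight: 0.12, brightness_per_monomer: 50.0}
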