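"""Fast-flow single-molecule burst pipeline.

A labelled species transiting the confocal volume produces a transient
photon surge (a burst).  Traces are binned photon counts in two detection
channels; an event is a maximal run of consecutive bins at or above the
detection threshold in the donor channel, and it is *coincident* when at
least one bin of the run also reaches the threshold in the acceptor
channel — evidence that the species carries both dye types, i.e. is an
oligomer.  Run merging (rather than counting every supra-threshold bin)
avoids double-counting slow transits.

Intensities are summed over the run by default; a per-bin peak mode is
available (``intensity_mode="peak"``) since either convention is found in
burst-analysis software.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ChannelIntensities,
    FretEvent,
    InstrumentParams,
    InvalidParamsError,
    apparent_size,
    classify_size,
    correct_acceptor,
    correct_donor,
    fret_efficiency,
)

DEFAULT_THRESHOLD = 10  # photon counts per bin, each channel


class EmptyTraceError(ValueError):
    """The photon trace contains no bins."""


class NoMonomerEventsError(ValueError):
    """No non-coincident donor events to estimate monomer brightness from."""


class NoEventsError(ValueError):
    """No donor events above threshold."""


@dataclass
class PhotonTrace:
    """Two-channel binned photon-count time series."""

    bin_width: float  # seconds
    donor_counts: np.ndarray
    acceptor_counts: np.ndarray

    def __post_init__(self) -> None:
        self.donor_counts = np.asarray(self.donor_counts)
        self.acceptor_counts = np.asarray(self.acceptor_counts)
        if self.donor_counts.shape != self.acceptor_counts.shape:
            raise ValueError("channel series must have equal length")
        if self.donor_counts.size and (
            self.donor_counts.min() < 0 or self.acceptor_counts.min() < 0
        ):
            raise ValueError("photon counts must be >= 0")

    @property
    def n_bins(self) -> int:
        return int(self.donor_counts.size)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "bin_index": np.arange(self.n_bins),
                "donor_counts": self.donor_counts,
                "acceptor_counts": self.acceptor_counts,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, bin_width: float = 0.001) -> "PhotonTrace":
        df = pd.read_csv(path)
        return cls(
            bin_width=bin_width,
            donor_counts=df["donor_counts"].to_numpy(),
            acceptor_counts=df["acceptor_counts"].to_numpy(),
        )


@dataclass
class EventSet:
    """Detected events plus the counts the coincidence readout needs."""

    events: list[FretEvent]
    threshold: int
    bin_width: float = 0.001
    n_excluded: int = 0  # coincident events dropped for negative corrected counts

    @property
    def n_donor_events(self) -> int:
        return len(self.events)

    @property
    def n_coincident(self) -> int:
        return sum(1 for e in self.events if e.coincident)

    def coincident_events(self, include_excluded: bool = False) -> list[FretEvent]:
        return [
            e for e in self.events if e.coincident and (include_excluded or not e.excluded)
        ]

    def efficiencies(self) -> np.ndarray:
        """FRET efficiencies of retained coincident events."""
        return np.array(
            [e.efficiency for e in self.coincident_events() if e.efficiency is not None]
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for e in self.events:
            rows.append(
                {
                    "start_bin": e.start_bin,
                    "stop_bin": e.stop_bin,
                    "n_bins": e.n_bins,
                    "donor_raw": e.intensities.donor_raw,
                    "acceptor_raw": e.intensities.acceptor_raw,
                    "coincident": e.coincident,
                    "touches_edge": e.touches_edge,
                    "I_D": e.I_D,
                    "I_A": e.I_A,
                    "efficiency": e.efficiency,
                    "apparent_size": e.apparent_size,
                    "size_class": e.size_class,
                    "excluded": e.excluded,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def detect_events(
    trace: PhotonTrace,
    threshold: int = DEFAULT_THRESHOLD,
    intensity_mode: str = "sum",
) -> EventSet:
    """Detect donor-channel burst events and their acceptor coincidence.

    An event is a maximal run of consecutive bins with donor counts >=
    ``threshold``; it is coincident when any bin of the run also has
    acceptor counts >= ``threshold``.  Event intensity is the run sum
    (``intensity_mode="sum"``) or the run's per-bin maximum (``"peak"``).
    Runs touching the trace boundaries are kept but flagged.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    if trace.n_bins == 0:
        raise EmptyTraceError("trace has no bins")
    if intensity_mode not in ("sum", "peak"):
        raise ValueError("intensity_mode must be 'sum' or 'peak'")

    above = trace.donor_counts >= threshold
    padded = np.concatenate([[False], above, [False]])
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)

    events: list[FretEvent] = []
    for s, t in zip(starts, stops):
        d_run = trace.donor_counts[s:t]
        a_run = trace.acceptor_counts[s:t]
        if intensity_mode == "sum":
            d_int, a_int = float(d_run.sum()), float(a_run.sum())
        else:
            peak = int(np.argmax(d_run))
            d_int, a_int = float(d_run[peak]), float(a_run[peak])
        events.append(
            FretEvent(
                intensities=ChannelIntensities(donor_raw=d_int, acceptor_raw=a_int),
                start_bin=int(s),
                stop_bin=int(t),
                coincident=bool((a_run >= threshold).any()),
                touches_edge=bool(s == 0 or t == trace.n_bins),
            )
        )
    return EventSet(events=events, threshold=threshold, bin_width=trace.bin_width)


def monomer_brightness(
    events: EventSet, params: InstrumentParams | None = None
) -> float:
    """Mean donor intensity of non-coincident bursts — the single-monomer
    brightness ``I_monomer`` used for sizing.

    With ``params``, per-event autofluorescence (scaled by run length) is
    subtracted first, matching the corrected intensities sizing uses.
    """
    vals = []
    for e in events.events:
        if e.coincident:
            continue
        d = e.intensities.donor_raw
        if params is not None:
            d = float(correct_donor(d, params, n_bins=e.n_bins))
        vals.append(d)
    if not vals:
        raise NoMonomerEventsError(
            "no non-coincident donor events; supply monomer_brightness explicitly"
        )
    return float(np.mean(vals))


def analyze_events(events: EventSet, params: InstrumentParams) -> EventSet:
    """Fill corrected intensities, efficiency, apparent size and size class.

    Per-bin autofluorescence is scaled by each event's run length before
    subtraction.  Coincident events with a negative corrected intensity
    (or non-positive total) are flagged and excluded from histograms and
    sizing; ``EventSet.n_excluded`` records how many.  Sizing requires
    ``params.monomer_brightness``; when absent, apparent sizes stay None.
    """
    can_size = params.monomer_brightness is not None and params.monomer_brightness > 0
    n_excluded = 0
    for e in events.events:
        e.I_D = float(correct_donor(e.intensities.donor_raw, params, n_bins=e.n_bins))
        e.I_A = float(
            correct_acceptor(
                e.intensities.acceptor_raw,
                e.intensities.donor_raw,
                params,
                n_bins=e.n_bins,
            )
        )
        e.excluded = False
        e.flags = [f for f in e.flags if f not in ("negative_intensity", "undefined_E")]
        if not e.coincident:
            continue
        if e.I_D < 0 or e.I_A < 0:
            e.excluded = True
            e.flags.append("negative_intensity")
            n_excluded += 1
            continue
        if e.I_D + e.I_A <= 0:
            e.excluded = True
            e.flags.append("undefined_E")
            n_excluded += 1
            continue
        e.efficiency = float(fret_efficiency(e.I_D, e.I_A))
        if can_size:
            e.apparent_size = float(apparent_size(e.I_D, e.I_A, params))
            e.size_class = classify_size(e.apparent_size)
    events.n_excluded = n_excluded
    return events


def fraction_of_coincidence(events: EventSet) -> float:
    """Coincident events over all donor-channel events above threshold."""
    if events.n_donor_events == 0:
        raise NoEventsError("no donor events above threshold")
    return events.n_coincident / events.n_donor_events


def size_efficiency_table(events: EventSet) -> pd.DataFrame:
    """(apparent_size, E) pairs of retained coincident events, for 2-D
    contour plots of oligomer size against FRET efficiency."""
    rows = [
        {"apparent_size": e.apparent_size, "efficiency": e.efficiency}
        for e in events.coincident_events()
        if e.apparent_size is not None and e.efficiency is not None
    ]
    return pd.DataFrame(rows)
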