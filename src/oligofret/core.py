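"""Core domain types and the four FRET measurement equations.

Every analysis stage in this package reduces to the same arithmetic on
detector counts, applied either to a summed photon burst or to a single
voxel:

* donor correction        ``I_D = D - A_D``
* acceptor correction     ``I_A = A - A_A - C * D``
* FRET efficiency         ``E = I_A / (I_A + I_D)``
* apparent oligomer size  ``2 * (I_D + I_A / gamma) / I_monomer``

``A_D`` and ``A_A`` are instrument autofluorescence levels measured in the
absence of fluorophores, ``C`` is the donor-to-acceptor cross-talk fraction
and ``gamma`` combines the relative detection efficiencies and quantum
yields of the two dyes.  The factor 2 in the size estimate reflects that
only the donor dye is directly excited, so the total corrected intensity
counts donor fluorophores, roughly half the monomers in an equimolar
donor/acceptor labelling scheme.

Negative corrected intensities (counts below the autofluorescence
estimate) are never clamped: clamping would bias efficiencies toward 0 or
1.  Instead downstream modules flag and exclude such events/voxels and
report the exclusion count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class InvalidParamsError(ValueError):
    """Instrument parameters violate their physical constraints."""


@dataclass(frozen=True)
class InstrumentParams:
    """Instrument correction constants.

    Parameters
    ----------
    autofluor_donor, autofluor_acceptor:
        Autofluorescence ``A_D`` / ``A_A`` in detector counts per bin (bursts)
        or per voxel (images).
    crosstalk:
        Fraction ``C`` of donor-channel signal leaking into the acceptor
        channel.  Acceptor-to-donor cross-talk is assumed negligible.
    gamma:
        Gamma factor relating acceptor to donor detection efficiency;
        experimentally determined, defaults to 1.
    monomer_brightness:
        Mean brightness of a single donor fluorophore (``I_monomer``,
        counts per event).  May be ``None`` until estimated from
        non-coincident donor bursts.
    """

    autofluor_donor: float = 0.0
    autofluor_acceptor: float = 0.0
    crosstalk: float = 0.0
    gamma: float = 1.0
    monomer_brightness: float | None = None

    def __post_init__(self) -> None:
        if self.autofluor_donor < 0 or self.autofluor_acceptor < 0:
            raise InvalidParamsError("autofluorescence levels must be >= 0")
        if self.crosstalk < 0:
            raise InvalidParamsError("crosstalk fraction must be >= 0")
        if self.gamma <= 0:
            raise InvalidParamsError("gamma factor must be > 0")
        if self.monomer_brightness is not None and self.monomer_brightness <= 0:
            raise InvalidParamsError("monomer brightness must be > 0")


@dataclass
class ChannelIntensities:
    """Raw counts for one event or voxel.

    ``donor_raw`` and ``acceptor_raw`` are measured under donor excitation;
    ``direct_acceptor`` is the acceptor channel under direct acceptor
    excitation (the FRET-independent total-protein proxy used in cells).
    """

    donor_raw: float
    acceptor_raw: float
    direct_acceptor: float = 0.0

    def __post_init__(self) -> None:
        if self.donor_raw < 0 or self.acceptor_raw < 0 or self.direct_acceptor < 0:
            raise ValueError("raw counts must be >= 0")


# Size-class boundaries in apparent monomer units.  "Medium" runs up to 20
# monomers; the small/medium boundary at 3 separates apparent dimers (the
# smallest detectable oligomer) from larger species.
SIZE_CLASS_SMALL_MAX = 3.0
SIZE_CLASS_MEDIUM_MAX = 20.0


def classify_size(apparent_size: float) -> str:
    """Bin an apparent size into {small, medium, large}."""
    if apparent_size < SIZE_CLASS_SMALL_MAX:
        return "small"
    if apparent_size <= SIZE_CLASS_MEDIUM_MAX:
        return "medium"
    return "large"


@dataclass
class FretEvent:
    """One detected burst or voxel with its corrected readouts.

    Analysis fields stay ``None`` until :func:`oligofret.bursts.analyze_events`
    fills them.  ``excluded`` marks events with negative corrected
    intensities, which are dropped from histograms and sizing.
    """

    intensities: ChannelIntensities
    start_bin: int = 0
    stop_bin: int = 0  # exclusive
    coincident: bool = False
    touches_edge: bool = False
    I_D: float | None = None
    I_A: float | None = None
    efficiency: float | None = None
    apparent_size: float | None = None
    size_class: str | None = None
    excluded: bool = False
    flags: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return max(self.stop_bin - self.start_bin, 1)


def correct_donor(D, params: InstrumentParams, n_bins: int = 1):
    """Corrected donor intensity ``I_D = D - A_D``.

    ``n_bins`` scales the per-bin autofluorescence for bursts summed over
    several bins.  Negative results are returned unclamped; callers flag
    and exclude them.
    """
    return np.asarray(D, dtype=float) - n_bins * params.autofluor_donor


def correct_acceptor(A, D, params: InstrumentParams, n_bins: int = 1):
    """Corrected acceptor intensity ``I_A = A - A_A - C * D``."""
    A = np.asarray(A, dtype=float)
    D = np.asarray(D, dtype=float)
    return A - n_bins * params.autofluor_acceptor - params.crosstalk * D


def fret_efficiency(I_D, I_A):
    """FRET efficiency ``E = I_A / (I_A + I_D)``.

    Returns NaN where the total corrected intensity is not positive (the
    ratio is undefined there); such entries are excluded downstream.
    Accepts scalars or arrays.
    """
    I_D = np.asarray(I_D, dtype=float)
    I_A = np.asarray(I_A, dtype=float)
    total = I_D + I_A
    with np.errstate(divide="ignore", invalid="ignore"):
        E = np.where(total > 0, I_A / np.where(total > 0, total, 1.0), np.nan)
    if E.ndim == 0:
        return float(E)
    return E


def apparent_size(I_D, I_A, params: InstrumentParams):
    """Apparent oligomer size ``2 * (I_D + I_A / gamma) / I_monomer``.

    The estimate counts donor fluorophores from the total corrected burst
    intensity relative to the mean single-monomer brightness, then doubles
    it because only the donor dye is directly excited.
    """
    if params.gamma <= 0:
        raise InvalidParamsError("gamma factor must be > 0 for sizing")
    if params.monomer_brightness is None or params.monomer_brightness <= 0:
        raise InvalidParamsError("monomer brightness must be > 0 for sizing")
    I_D = np.asarray(I_D, dtype=float)
    I_A = np.asarray(I_A, dtype=float)
    size = 2.0 * (I_D + I_A / params.gamma) / params.monomer_brightness
    if size.ndim == 0:
        return float(size)
    return size
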