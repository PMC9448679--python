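"""Ground-truth-annotated generators for every input the pipeline consumes.

The generators target the *statistical contract* of the analysis rather
than the optics of the microscope: photon counts are Poisson, cross-talk
is a Poisson thinning of the donor channel, autofluorescence is a Poisson
background with the same per-bin/per-voxel means the correction equations
subtract.  There is no diffusion or 3-D point-spread-function physics.

Every generator returns its data together with a :class:`GroundTruth`
record.  Ground truth is a side channel for testing only — analysis
modules never read it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .core import InstrumentParams


class InvalidPresetError(ValueError):
    """A scenario preset violates its invariants."""


class GeometryError(ValueError):
    """Aggregate layout does not fit the image dimensions."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One diffusing species in a burst-stream scenario.

    ``size_true`` is the number of monomers in the species; the number of
    donor fluorophores is ``ceil(size/2)`` under equimolar donor/acceptor
    labelling.  Per-event true efficiency is drawn from a normal
    distribution centred on ``efficiency_true`` with spread
    ``efficiency_sd``, truncated to [0, 1] — aggregates of one structural
    class are heterogeneous, not a delta function.
    """

    size_true: int
    efficiency_true: float
    weight: float
    brightness_per_monomer: float = 50.0
    efficiency_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.size_true < 1:
            raise InvalidPresetError("size_true must be >= 1")
        if not 0.0 <= self.efficiency_true <= 1.0:
            raise InvalidPresetError("efficiency_true must be in [0, 1]")
        if self.weight < 0:
            raise InvalidPresetError("species weight must be >= 0")
        if self.brightness_per_monomer <= 0:
            raise InvalidPresetError("brightness_per_monomer must be > 0")

    @property
    def n_donor_fluorophores(self) -> int:
        return math.ceil(self.size_true / 2)


@dataclass(frozen=True)
class ScenarioPreset:
    """A named, immutable burst-stream scenario."""

    name: str
    species: tuple[SpeciesSpec, ...]
    instrument: InstrumentParams
    event_rate: float = 50.0  # events per second
    duration: float = 100.0  # seconds
    bin_width: float = 0.001  # seconds

    def __post_init__(self) -> None:
        if not self.species:
            raise InvalidPresetError("preset needs at least one species")
        total = sum(s.weight for s in self.species)
        if not np.isclose(total, 1.0, atol=1e-6):
            raise InvalidPresetError(f"species weights must sum to 1, got {total}")
        if self.event_rate <= 0 or self.duration <= 0 or self.bin_width <= 0:
            raise InvalidPresetError("event_rate, duration and bin_width must be > 0")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_width))


@dataclass
class GroundTruth:
    """Side-channel truth emitted with every synthetic dataset."""

    events: pd.DataFrame | None = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    change_points: list[int] | None = None
    n_steps: int | None = None
    spots: pd.DataFrame | None = None
    extra: dict[str, Any] = field(default_factory=dict)


def _load_preset_file() -> dict:
    text = resources.files("oligofret").joinpath("presets.yaml").read_text()
    return yaml.safe_load(text)


def load_preset(name: str) -> ScenarioPreset:
    """Load a named preset from the packaged YAML definitions."""
    presets = _load_preset_file()
    if name not in presets:
        raise InvalidPresetError(
            f"unknown preset {name!r}; available: {sorted(presets)}"
        )
    return preset_from_dict(name, presets[name])


def preset_from_dict(name: str, d: dict) -> ScenarioPreset:
    """Build a :class:`ScenarioPreset` from a plain mapping (YAML-friendly)."""
    species = tuple(SpeciesSpec(**s) for s in d["species"])
    instrument = InstrumentParams(**d.get("instrument", {}))
    return ScenarioPreset(
        name=name,
        species=species,
        instrument=instrument,
        event_rate=float(d.get("event_rate", 50.0)),
        duration=float(d.get("duration", 100.0)),
        bin_width=float(d.get("bin_width", 0.001)),
    )


def available_presets() -> list[str]:
    return sorted(_load_preset_file())


# ---------------------------------------------------------------------------
# burst streams
# ---------------------------------------------------------------------------

def simulate_burst_stream(
    preset: ScenarioPreset,
    seed: int | np.random.Generator,
    n_events: int | None = None,
):
    """Simulate a two-channel photon-count trace of single-molecule bursts.

    Each event occupies one bin (arrivals are Poisson; at default rates the
    chance of two events sharing a bin is small, and collisions are
    recorded in the ground truth).  For an event of species ``s`` with true
    efficiency ``E``:

    * expected total signal ``B = ceil(size/2) * brightness_per_monomer``
      (only donor fluorophores emit under donor excitation),
    * donor counts ~ Poisson(B * (1 - E)),
    * acceptor FRET counts ~ Poisson(gamma * B * E).

    Cross-talk is then applied to the *entire* donor channel (signal plus
    background) as a Poisson thinning with fraction ``C``, and Poisson
    autofluorescence backgrounds ``A_D`` / ``A_A`` are added per bin, so the
    correction equations are exactly unbiased for this generator.

    Parameters
    ----------
    n_events:
        Fix the number of events instead of drawing Poisson(rate*duration).

    Returns
    -------
    (PhotonTrace, GroundTruth)
    """
    from .bursts import PhotonTrace  # local import to avoid a cycle

    rng = np.random.default_rng(seed)
    ins = preset.instrument
    n_bins = preset.n_bins
    if n_events is None:
        n_events = rng.poisson(preset.event_rate * preset.duration)

    weights = np.array([s.weight for s in preset.species])
    species_idx = rng.choice(len(preset.species), size=n_events, p=weights)
    arrival_bins = rng.integers(0, n_bins, size=n_events)

    sizes = np.array([s.size_true for s in preset.species])[species_idx]
    n_donor = np.ceil(sizes / 2.0)
    brightness = np.array([s.brightness_per_monomer for s in preset.species])[species_idx]
    centers = np.array([s.efficiency_true for s in preset.species])[species_idx]
    sds = np.array([s.efficiency_sd for s in preset.species])[species_idx]
    E_true = np.clip(rng.normal(centers, sds), 0.0, 1.0)

    B = n_donor * brightness
    donor_photons = rng.poisson(B * (1.0 - E_true))
    acceptor_photons = rng.poisson(ins.gamma * B * E_true)

    donor = rng.poisson(ins.autofluor_donor, size=n_bins)
    acceptor = rng.poisson(ins.autofluor_acceptor, size=n_bins)
    np.add.at(donor, arrival_bins, donor_photons)
    np.add.at(acceptor, arrival_bins, acceptor_photons)
    if ins.crosstalk > 0:
        acceptor = acceptor + rng.poisson(ins.crosstalk * donor)

    overlap = pd.Series(arrival_bins).duplicated(keep=False).to_numpy()
    truth = GroundTruth(
        events=pd.DataFrame(
            {
                "species_id": species_idx,
                "arrival_bin": arrival_bins,
                "E_true": E_true,
                "size_true": sizes,
                "donor_photons": donor_photons,
                "acceptor_photons": acceptor_photons,
                "overlapping": overlap,
            }
        ),
        extra={"preset": preset.name, "n_events": int(n_events)},
    )
    trace = PhotonTrace(
        bin_width=preset.bin_width,
        donor_counts=donor.astype(np.int64),
        acceptor_counts=acceptor.astype(np.int64),
    )
    return trace, truth


# ---------------------------------------------------------------------------
# in-cell voxel stacks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AggregateSpec:
    """A core/rim aggregate drawn into a voxel stack.

    The core is a sphere of radius ``core_radius`` with high efficiency
    ``core_E``; the rim is the surrounding shell out to ``rim_radius``
    with low efficiency ``rim_E`` — compact, converted material inside a
    looser corona, as seen in intracellular FRET heat maps.
    ``signal`` is the expected FRET-pair signal per voxel and
    ``direct_signal`` the expected directly-excited acceptor signal.
    """

    center: tuple[float, ...]  # (z, y, x) or (y, x) for 2-D stacks
    core_radius: float
    rim_radius: float
    core_E: float = 0.48
    rim_E: float = 0.24
    signal: float = 200.0
    direct_signal: float = 300.0

    def __post_init__(self) -> None:
        if self.rim_radius < self.core_radius:
            raise GeometryError("rim_radius must be >= core_radius")
        if not (0 <= self.core_E <= 1 and 0 <= self.rim_E <= 1):
            raise GeometryError("efficiencies must be in [0, 1]")


@dataclass
class StackLayout:
    """Aggregate geometry plus optional per-cell labels for a synthetic stack."""

    shape: tuple[int, ...]  # (nz, ny, nx) or (ny, nx)
    aggregates: list[AggregateSpec] = field(default_factory=list)
    cell_labels: np.ndarray | None = None  # same shape; 0 = background
    direct_background: float = 10.0  # autofluorescence in the direct channel


def _distance_grid(shape: tuple[int, ...], center: tuple[float, ...]) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    return np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))


def simulate_incell_stack(
    layout: StackLayout,
    instrument: InstrumentParams,
    seed: int | np.random.Generator,
):
    """Render a three-channel voxel stack of core/rim aggregates.

    Channels: donor-excitation donor-emission (D), donor-excitation
    acceptor-emission (A), acceptor-excitation acceptor-emission (direct).
    Expected values per voxel with signal ``S`` and efficiency ``E``::

        D      = A_D + S * (1 - E)
        A      = A_A + S * E + C * D
        direct = direct_background + direct_signal

    with Poisson noise on every term, cross-talk realized as a Poisson
    thinning of the realized donor voxel.

    Returns ``(VoxelStack, GroundTruth)``; the ground truth carries the
    per-aggregate core and rim masks, the combined masks, the true E map
    and the cell label image.
    """
    from .incell import VoxelStack  # avoid import cycle

    rng = np.random.default_rng(seed)
    shape = tuple(layout.shape)
    signal = np.zeros(shape)
    direct_signal = np.zeros(shape)
    E_map = np.zeros(shape)
    core_mask = np.zeros(shape, dtype=bool)
    rim_mask = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)

    for i, agg in enumerate(layout.aggregates):
        if len(agg.center) != len(shape):
            raise GeometryError("aggregate center dimensionality mismatch")
        if any(not (0 <= c < s) for c, s in zip(agg.center, shape)):
            raise GeometryError(f"aggregate center {agg.center} outside stack {shape}")
        dist = _distance_grid(shape, agg.center)
        core = dist <= agg.core_radius
        rim = (dist > agg.core_radius) & (dist <= agg.rim_radius)
        signal[core | rim] += agg.signal
        direct_signal[core | rim] += agg.direct_signal
        E_map[core] = agg.core_E
        E_map[rim] = agg.rim_E
        core_mask |= core
        rim_mask |= rim
        labels[core | rim] = i + 1

    if layout.cell_labels is not None:
        if layout.cell_labels.shape != shape:
            raise GeometryError("cell_labels shape mismatch")
        labels = layout.cell_labels

    donor_mean = instrument.autofluor_donor + signal * (1.0 - E_map)
    donor = rng.poisson(donor_mean)
    acceptor = rng.poisson(instrument.autofluor_acceptor + signal * E_map)
    if instrument.crosstalk > 0:
        acceptor = acceptor + rng.poisson(instrument.crosstalk * donor)
    direct = rng.poisson(layout.direct_background + direct_signal)

    stack = VoxelStack(
        donor=donor.astype(float),
        acceptor=acceptor.astype(float),
        direct=direct.astype(float),
    )
    truth = GroundTruth(
        masks={
            "core": core_mask,
            "rim": rim_mask,
            "aggregate": core_mask | rim_mask,
            "labels": labels,
            "E_true": E_map,
        },
        extra={
            "direct_background": layout.direct_background,
            # Poisson background => sd = sqrt(mean); what make_mask needs
            "direct_background_sd": math.sqrt(layout.direct_background),
        },
    )
    return stack, truth


# ---------------------------------------------------------------------------
# photobleaching traces
# ---------------------------------------------------------------------------

def simulate_bleach_trace(
    n_fluor: int,
    step_height: float = 100.0,
    noise_sd: float = 10.0,
    bleach_prob_per_frame: float = 0.01,
    seed: int | np.random.Generator = 0,
    n_frames: int = 600,
    baseline: float = 20.0,
    min_separation: int = 4,
):
    """Simulate a stepwise photobleaching intensity trace.

    Each of ``n_fluor`` fluorophores bleaches at a geometric time with the
    given per-frame probability, dropping the intensity by ``step_height``;
    i.i.d. Gaussian read noise is added on top.  Bleach times closer than
    ``min_separation`` frames (or beyond the trace) are redrawn so every
    fluorophore produces a resolvable step — near-simultaneous bleaching
    merges steps and is exactly the saturation regime the step counter
    cannot disambiguate.

    Returns ``(BleachTrace, GroundTruth)`` with true change points.
    """
    from .stepfit import BleachTrace

    if n_fluor < 0:
        raise ValueError("n_fluor must be >= 0")
    rng = np.random.default_rng(seed)

    for _ in range(1000):
        times = rng.geometric(bleach_prob_per_frame, size=n_fluor)
        times = np.sort(times)
        if n_fluor == 0:
            break
        if times[-1] <= n_frames - min_separation and (
            n_fluor == 1 or np.min(np.diff(times)) >= min_separation
        ) and times[0] >= min_separation:
            break
    else:
        raise RuntimeError("could not draw separated bleach times; lower n_fluor or rate")

    n_alive = np.full(n_frames, 0, dtype=float)
    frames = np.arange(n_frames)
    for t in times:
        n_alive += frames < t
    intensity = baseline + step_height * n_alive + rng.normal(0.0, noise_sd, size=n_frames)

    truth = GroundTruth(
        change_points=[int(t) for t in times],
        n_steps=int(n_fluor),
        extra={"step_height": step_height, "baseline": baseline, "noise_sd": noise_sd},
    )
    return BleachTrace(intensity=intensity, frame_interval=1.0), truth


# ---------------------------------------------------------------------------
# two-color spot fields
# ---------------------------------------------------------------------------

def simulate_two_color_spots(
    n_spots: int,
    coincidence_fraction: float,
    fov: tuple[int, int] = (256, 256),
    psf_sigma: float = 1.5,
    seed: int | np.random.Generator = 0,
    amplitude: float = 2000.0,
    background: float = 50.0,
):
    """Simulate a two-channel field of diffraction-limited spots.

    Each of the ``n_spots`` aggregates per channel is coincident with
    probability ``coincidence_fraction`` (a binomial draw, so fields show
    realistic field-to-field sampling variation); coincident spots share
    coordinates in both channels, the remainder of each channel's spots
    are placed independently and uniformly (with a 4-sigma edge margin).  Spots
    are rendered as Gaussian PSFs of width ``psf_sigma`` on a constant
    background, with Poisson shot noise.

    Returns ``((image_a, image_b), GroundTruth)``; ground truth lists every
    spot with channel and coincidence flag.
    """
    if not 0.0 <= coincidence_fraction <= 1.0:
        raise ValueError("coincidence_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    h, w = fov
    margin = 4.0 * psf_sigma

    def uniform_xy(n):
        return np.column_stack(
            [rng.uniform(margin, h - margin, n), rng.uniform(margin, w - margin, n)]
        )

    n_coinc = int(rng.binomial(n_spots, coincidence_fraction))
    shared = uniform_xy(n_coinc)
    only_a = uniform_xy(n_spots - n_coinc)
    only_b = uniform_xy(n_spots - n_coinc)
    coords_a = np.vstack([shared, only_a])
    coords_b = np.vstack([shared, only_b])

    def render(coords):
        img = np.full(fov, background, dtype=float)
        yy, xx = np.mgrid[0:h, 0:w]
        for (cy, cx) in coords:
            img += amplitude * np.exp(
                -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * psf_sigma**2)
            )
        return rng.poisson(img).astype(float)

    img_a = render(coords_a)
    img_b = render(coords_b)

    rows = []
    for ch, coords, nc in (("a", coords_a, n_coinc), ("b", coords_b, n_coinc)):
        for i, (cy, cx) in enumerate(coords):
            rows.append(
                {"channel": ch, "y": cy, "x": cx, "coincident": i < nc}
            )
    truth = GroundTruth(
        spots=pd.DataFrame(rows),
        extra={"n_spots": n_spots, "coincidence_fraction": coincidence_fraction},
    )
    return (img_a, img_b), truth
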