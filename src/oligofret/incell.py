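"""Voxel-level in-cell FRET pipeline.

Cells are imaged in three channels: donor emission under donor excitation
(D), acceptor emission under donor excitation (A, the FRET channel) and
acceptor emission under direct acceptor excitation (a FRET-independent
proxy for total labelled protein).  Voxels containing protein are selected
by thresholding the direct channel against blank-image statistics, each
retained voxel is corrected for autofluorescence and cross-talk, and a
per-voxel efficiency map is computed.  Per-cell summaries (mean E, total
protein, FRET intensity) are taken over supplied label masks — cell
segmentation itself is outside this package's scope.

Voxel efficiency histograms feed :mod:`oligofret.mixture` unchanged: the
in-cell structural-conversion analysis is ``build_histogram`` +
``global_fit`` + ``fraction_converted`` on voxel E values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile

from .core import (
    InstrumentParams,
    correct_acceptor,
    correct_donor,
    fret_efficiency,
)


class EmptyCellError(ValueError):
    """A requested cell label has no voxels in the mask."""


@dataclass
class VoxelStack:
    """Three aligned imaging channels over the same voxel grid."""

    donor: np.ndarray
    acceptor: np.ndarray
    direct: np.ndarray
    voxel_size: tuple[float, ...] | None = None  # (z, y, x) or (y, x) spacing

    def __post_init__(self) -> None:
        if not (self.donor.shape == self.acceptor.shape == self.direct.shape):
            raise ValueError("channels must share dimensions")
        for ch in (self.donor, self.acceptor, self.direct):
            if ch.size and np.nanmin(ch) < 0:
                raise ValueError("intensities must be >= 0")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.donor.shape

    def to_tiff(self, path) -> None:
        tifffile.imwrite(
            path,
            np.stack([self.donor, self.acceptor, self.direct]).astype(np.float32),
            photometric="minisblack",
        )

    @classmethod
    def from_tiff(cls, path, voxel_size=None) -> "VoxelStack":
        arr = tifffile.imread(path)
        if arr.shape[0] != 3:
            raise ValueError("expected a 3-channel stack (D, A, direct) on axis 0")
        return cls(
            donor=np.asarray(arr[0], dtype=float),
            acceptor=np.asarray(arr[1], dtype=float),
            direct=np.asarray(arr[2], dtype=float),
            voxel_size=voxel_size,
        )


@dataclass
class FretMaps:
    """Per-voxel corrected intensity and efficiency maps.

    Voxels outside the mask, or excluded for negative corrected
    intensities, carry NaN.
    """

    efficiency: np.ndarray
    I_D: np.ndarray
    I_A: np.ndarray
    mask: np.ndarray
    n_excluded: int

    def efficiencies(self) -> np.ndarray:
        """Retained voxel efficiencies as a flat array (histogram input)."""
        vals = self.efficiency[self.mask]
        return vals[np.isfinite(vals)]


@dataclass
class CellSummary:
    label: int
    mean_E: float
    total_alpha_syn: float  # mean direct-channel intensity in the cell mask
    fret_intensity: float  # mean corrected acceptor intensity
    n_voxels: int
    n_excluded: int


def make_mask(
    stack: VoxelStack,
    autofluor_stats: tuple[float, float],
    k: float = 3.0,
) -> np.ndarray:
    """Threshold the directly excited acceptor channel.

    ``autofluor_stats`` is (mean, sd) of the direct channel in a blank
    region or blank image; a voxel enters the mask when its direct
    intensity exceeds ``mean + k * sd``.
    """
    mean_blank, sd_blank = autofluor_stats
    mask = stack.direct > mean_blank + k * sd_blank
    if not mask.any():
        warnings.warn("mask is empty: no voxels above the blank threshold", stacklevel=2)
    return mask


def voxel_fret_map(
    stack: VoxelStack, mask: np.ndarray, params: InstrumentParams
) -> FretMaps:
    """Apply the correction and efficiency equations voxel-wise in the mask.

    Negative corrected intensities are excluded (NaN) and counted rather
    than clamped, which would bias E toward 0 or 1.
    """
    I_D = correct_donor(stack.donor, params)
    I_A = correct_acceptor(stack.acceptor, stack.donor, params)
    valid = mask & (I_D >= 0) & (I_A >= 0) & (I_D + I_A > 0)
    n_excluded = int(mask.sum() - valid.sum())

    E = np.full(stack.shape, np.nan)
    E[valid] = fret_efficiency(I_D[valid], I_A[valid])
    I_D_out = np.where(mask, I_D, np.nan)
    I_A_out = np.where(mask, I_A, np.nan)
    I_D_out[mask & ~valid] = np.nan
    I_A_out[mask & ~valid] = np.nan
    return FretMaps(
        efficiency=E, I_D=I_D_out, I_A=I_A_out, mask=mask, n_excluded=n_excluded
    )


def summarize_cell(
    maps: FretMaps, stack: VoxelStack, labels: np.ndarray, label: int
) -> CellSummary:
    """Summarize one labelled cell: mean E over retained masked voxels,
    mean direct intensity (total protein) and mean corrected acceptor
    intensity (FRET intensity)."""
    cell = (labels == label) & maps.mask
    if not cell.any():
        raise EmptyCellError(f"cell label {label} has no masked voxels")
    E_vals = maps.efficiency[cell]
    retained = np.isfinite(E_vals)
    return CellSummary(
        label=int(label),
        mean_E=float(np.nanmean(E_vals)) if retained.any() else float("nan"),
        total_alpha_syn=float(stack.direct[cell].mean()),
        fret_intensity=float(np.nanmean(maps.I_A[cell])),
        n_voxels=int(cell.sum()),
        n_excluded=int((~retained).sum()),
    )


def summarize_cells(
    maps: FretMaps, stack: VoxelStack, labels: np.ndarray
) -> pd.DataFrame:
    """Per-cell summaries for every nonzero label, ordered by label."""
    out = []
    for label in np.unique(labels):
        if label == 0:
            continue
        try:
            s = summarize_cell(maps, stack, labels, int(label))
        except EmptyCellError:
            continue
        out.append(vars(s))
    return pd.DataFrame(out)
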