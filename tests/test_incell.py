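"""Voxel masking, per-voxel efficiency maps and per-cell summaries."""

import numpy as np
import pytest

from oligofret.core import InstrumentParams
from oligofret.incell import (
    EmptyCellError,
    VoxelStack,
    make_mask,
    summarize_cell,
    summarize_cells,
    voxel_fret_map,
)
from oligofret.synthetic import AggregateSpec, StackLayout, simulate_incell_stack


def _uniform_stack(shape, D, A, direct):
    return VoxelStack(
        donor=np.full(shape, float(D)),
        acceptor=np.full(shape, float(A)),
        direct=np.full(shape, float(direct)),
    )


class TestMakeMask:
    def test_blank_stack_gives_empty_mask(self):
        stack = _uniform_stack((8, 8), 10, 10, 5)
        with pytest.warns(UserWarning, match="empty"):
            mask = make_mask(stack, autofluor_stats=(5.0, 1.0), k=3)
        assert not mask.any()

    def test_k_zero_keeps_everything_above_blank_mean(self):
        stack = _uniform_stack((8, 8), 10, 10, 5.1)
        mask = make_mask(stack, autofluor_stats=(5.0, 1.0), k=0)
        assert mask.all()

    def test_bright_aggregate_recovered(self):
        """An aggregate at 10x background is captured by the direct-channel
        threshold (Jaccard >= 0.8 against the ground-truth mask)."""
        agg = AggregateSpec(center=(24.0, 24.0), core_radius=4.0, rim_radius=8.0,
                            direct_signal=100.0)
        layout = StackLayout(shape=(48, 48), aggregates=[agg], direct_background=10.0)
        stack, truth = simulate_incell_stack(layout, InstrumentParams(), seed=3)
        mask = make_mask(stack, (10.0, np.sqrt(10.0)), k=3)
        truth_mask = truth.masks["aggregate"]
        jaccard = (mask & truth_mask).sum() / (mask | truth_mask).sum()
        assert jaccard >= 0.8


class TestVoxelFretMap:
    def test_closed_form_uniform_stack(self):
        """D=100, A=60 with A_D=20, A_A=10, C=0.1 gives E = 40/120 everywhere."""
        stack = _uniform_stack((6, 6), 100, 60, 50)
        params = InstrumentParams(autofluor_donor=20.0, autofluor_acceptor=10.0,
                                  crosstalk=0.1)
        maps = voxel_fret_map(stack, np.ones((6, 6), bool), params)
        np.testing.assert_allclose(maps.efficiency, 40.0 / 120.0)
        np.testing.assert_allclose(maps.I_D, 80.0)
        np.testing.assert_allclose(maps.I_A, 40.0)

    def test_background_only_acceptor_gives_zero_efficiency(self):
        stack = _uniform_stack((4, 4), 100, 10, 50)
        params = InstrumentParams(autofluor_acceptor=10.0)
        maps = voxel_fret_map(stack, np.ones((4, 4), bool), params)
        np.testing.assert_allclose(maps.efficiency, 0.0)

    def test_core_has_higher_efficiency_than_rim(self):
        agg = AggregateSpec(center=(24.0, 24.0), core_radius=4.0, rim_radius=9.0,
                            core_E=0.48, rim_E=0.24, signal=400.0)
        layout = StackLayout(shape=(48, 48), aggregates=[agg])
        ins = InstrumentParams(autofluor_donor=2.0, autofluor_acceptor=2.0, crosstalk=0.05)
        stack, truth = simulate_incell_stack(layout, ins, seed=4)
        mask = truth.masks["aggregate"]
        maps = voxel_fret_map(stack, mask, ins)
        med_core = np.nanmedian(maps.efficiency[truth.masks["core"]])
        med_rim = np.nanmedian(maps.efficiency[truth.masks["rim"]])
        assert med_core > med_rim
        assert med_core == pytest.approx(0.48, abs=0.03)
        assert med_rim == pytest.approx(0.24, abs=0.03)

    def test_retained_efficiencies_bounded(self):
        rng = np.random.default_rng(0)
        stack = VoxelStack(
            donor=rng.poisson(30.0, (16, 16)).astype(float),
            acceptor=rng.poisson(20.0, (16, 16)).astype(float),
            direct=rng.poisson(40.0, (16, 16)).astype(float),
        )
        params = InstrumentParams(autofluor_donor=5.0, autofluor_acceptor=5.0,
                                  crosstalk=0.05)
        maps = voxel_fret_map(stack, np.ones((16, 16), bool), params)
        vals = maps.efficiencies()
        assert ((vals >= 0) & (vals <= 1)).all()

    def test_negative_corrections_excluded_and_counted(self):
        stack = _uniform_stack((4, 4), 10, 3, 50)
        params = InstrumentParams(autofluor_donor=20.0)
        maps = voxel_fret_map(stack, np.ones((4, 4), bool), params)
        assert maps.n_excluded == 16
        assert np.isnan(maps.efficiency).all()

    def test_offset_consistency(self):
        """Adding a constant A_D (A_A) to the channel and to the correction
        constant leaves the efficiency map unchanged."""
        rng = np.random.default_rng(2)
        D = rng.uniform(50, 150, (8, 8))
        A = rng.uniform(40, 90, (8, 8))
        stack0 = VoxelStack(donor=D, acceptor=A, direct=np.full((8, 8), 50.0))
        stack1 = VoxelStack(donor=D + 15.0, acceptor=A + 7.0,
                            direct=np.full((8, 8), 50.0))
        p0 = InstrumentParams(crosstalk=0.0)
        p1 = InstrumentParams(autofluor_donor=15.0, autofluor_acceptor=7.0)
        mask = np.ones((8, 8), bool)
        np.testing.assert_allclose(
            voxel_fret_map(stack0, mask, p0).efficiency,
            voxel_fret_map(stack1, mask, p1).efficiency,
        )


class TestCellSummaries:
    def test_single_voxel_cell(self):
        stack = _uniform_stack((3, 3), 100, 50, 80)
        mask = np.zeros((3, 3), bool)
        mask[1, 1] = True
        maps = voxel_fret_map(stack, mask, InstrumentParams())
        labels = mask.astype(int)
        s = summarize_cell(maps, stack, labels, 1)
        assert s.mean_E == pytest.approx(50.0 / 150.0)
        assert s.total_alpha_syn == 80.0
        assert s.n_voxels == 1

    def test_missing_label_raises(self):
        stack = _uniform_stack((3, 3), 100, 50, 80)
        maps = voxel_fret_map(stack, np.ones((3, 3), bool), InstrumentParams())
        with pytest.raises(EmptyCellError):
            summarize_cell(maps, stack, np.zeros((3, 3), int), 5)

    def test_disjoint_cells_summarized_in_label_order(self):
        stack = _uniform_stack((4, 4), 100, 100, 80)
        labels = np.zeros((4, 4), int)
        labels[:2] = 2
        labels[2:] = 1
        maps = voxel_fret_map(stack, np.ones((4, 4), bool), InstrumentParams())
        df = summarize_cells(maps, stack, labels)
        assert list(df["label"]) == [1, 2]
        assert np.allclose(df["mean_E"], 0.5)

    def test_known_per_cell_efficiency_recovered(self):
        """A grid of cells with known per-cell E comes back within 0.02."""
        rng = np.random.default_rng(7)
        shape = (40, 40)
        labels = np.zeros(shape, int)
        true_E = {}
        stackD = np.zeros(shape)
        stackA = np.zeros(shape)
        for i in range(10):
            r, c = divmod(i, 5)
            sl = (slice(r * 20 + 2, r * 20 + 18), slice(c * 8 + 1, c * 8 + 7))
            labels[sl] = i + 1
            E = 0.15 + 0.06 * i
            true_E[i + 1] = E
            signal = 2000.0
            stackD[sl] = rng.poisson(signal * (1 - E), size=labels[sl].shape)
            stackA[sl] = rng.poisson(signal * E, size=labels[sl].shape)
        stack = VoxelStack(donor=stackD, acceptor=stackA,
                           direct=(labels > 0) * 100.0)
        maps = voxel_fret_map(stack, labels > 0, InstrumentParams())
        df = summarize_cells(maps, stack, labels).set_index("label")
        for label, E in true_E.items():
            assert df.loc[label, "mean_E"] == pytest.approx(E, abs=0.02)

    def test_tiff_round_trip(self, tmp_path):
        stack = _uniform_stack((5, 5), 100, 60, 50)
        path = tmp_path / "stack.tif"
        stack.to_tiff(path)
        back = VoxelStack.from_tiff(path)
        np.testing.assert_allclose(back.donor, stack.donor)
        np.testing.assert_allclose(back.acceptor, stack.acceptor)
        np.testing.assert_allclose(back.direct, stack.direct)
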