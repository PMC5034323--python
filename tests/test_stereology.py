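import numpy as np
import pytest

from isletquant import make_grid, point_count_estimate, rank_panels, \
    selection_curve, every_nth_section, block_selection_estimates, \
    largest_n_ratios
from isletquant.io import BinaryMask
from isletquant.preprocess import TissueMask
from isletquant.segment import IsletRecord
from isletquant.stereology import PanelGrid, round_half_up
from isletquant.synth import generate_block_percents, generate_organ_blocks


def full_tissue(shape):
    return TissueMask(mask=BinaryMask(np.ones(shape, bool), "tissue"),
                      pixel_size=1.0, pancreas_area=float(np.prod(shape)),
                      excluded_area=0.0, applied_exclusions=[])


class TestMakeGrid:
    def test_counts_in_square_frame(self):
        grid = make_grid((100.0, 100.0), spacing=25.0)
        assert grid.n_total == 16  # 4 x 4

    def test_spacing_larger_than_frame(self):
        grid = make_grid((10.0, 10.0), spacing=100.0)
        assert grid.n_total == 1
        np.testing.assert_array_equal(grid.vertices, [[0.0, 0.0]])

    def test_offset_translates_vertices(self):
        base = make_grid((200.0, 200.0), spacing=25.0)
        shifted = make_grid((200.0, 200.0), spacing=25.0, offset=(12.5, 12.5))
        np.testing.assert_allclose(shifted.vertices[: base.n_total],
                                   base.vertices[: base.n_total] + 12.5)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(ValueError):
            make_grid((100.0, 100.0), spacing=0.0)


class TestPointCount:
    def test_all_positive_mask(self):
        mask = BinaryMask(np.ones((100, 100), bool))
        grid = make_grid((100.0, 100.0), spacing=10.0)
        res = point_count_estimate(mask, grid, 1.0)
        assert res.percent == 100.0

    def test_worked_example_30_of_945(self):
        # 27 x 35 vertex grid at 25 um; rectangle covering exactly 30 vertices
        mask = np.zeros((875, 675), bool)
        mask[:101, :126] = True  # vertices x in {0..125}: 6, y in {0..100}: 5
        grid = make_grid((675.0, 875.0), spacing=25.0)
        assert grid.n_total == 945
        res = point_count_estimate(BinaryMask(mask), grid, 1.0)
        assert res.n_positive == 30
        assert res.percent == 3.18
        assert res.percent_raw == pytest.approx(100 * 30 / 945)

    def test_half_plane_is_fifty_percent(self):
        mask = np.zeros((100, 200), bool)
        mask[:, :100] = True
        grid = make_grid((200.0, 100.0), spacing=10.0, offset=(5.0, 5.0))
        res = point_count_estimate(BinaryMask(mask), grid, 1.0)
        assert res.percent == 50.0

    def test_empty_grid_rejected(self):
        from isletquant.stereology import PointGrid
        grid = PointGrid(25.0, (0.0, 0.0), np.empty((0, 2)))
        with pytest.raises(ValueError):
            point_count_estimate(BinaryMask(np.ones((10, 10), bool)), grid, 1.0)

    def test_unbiased_over_random_offsets(self):
        rng = np.random.default_rng(0)
        mask = rng.random((400, 400)) < 0.3
        true_fraction = 100.0 * mask.mean()
        errors = []
        for spacing in (25.0, 10.0, 5.0):
            ests = []
            for _ in range(100):
                off = rng.uniform(0, spacing, 2)
                grid = make_grid((400.0, 400.0), spacing, tuple(off))
                ests.append(point_count_estimate(BinaryMask(mask), grid,
                                                 1.0).percent_raw)
            errors.append(abs(np.mean(ests) - true_fraction))
        assert errors[0] < 0.75  # coarse grid: small but nonzero MC error
        assert errors[2] < errors[0]


def test_round_half_up():
    assert round_half_up(3.175, 2) == 3.18
    assert round_half_up(3.174, 2) == 3.17
    assert round_half_up(2.5, 0) == 3.0
    assert round_half_up(100 * 30 / 945, 3) == 3.175


class TestPanels:
    def test_panels_tile_frame_exactly(self):
        panels = PanelGrid((130, 270), (100.0, 50.0), 1.0)
        cover = np.zeros((130, 270), dtype=int)
        for sl in panels.slices:
            cover[sl] += 1
        assert (cover == 1).all()

    def test_rank_all_content_in_one_panel(self):
        panels = PanelGrid((100, 100), (50.0, 50.0), 1.0)
        mask = np.zeros((100, 100), bool)
        mask[60:80, 60:80] = True  # bottom-right panel (index 3)
        order = rank_panels(panels, BinaryMask(mask))
        assert order[0] == 3

    def test_rank_ties_fall_back_to_index_order(self):
        panels = PanelGrid((100, 100), (50.0, 50.0), 1.0)
        order = rank_panels(panels, BinaryMask(np.ones((100, 100), bool)))
        np.testing.assert_array_equal(order, [0, 1, 2, 3])

    def test_rank_matches_brute_force_sort(self):
        rng = np.random.default_rng(9)
        mask = rng.random((120, 120)) < 0.2
        panels = PanelGrid((120, 120), (40.0, 40.0), 1.0)
        order = rank_panels(panels, BinaryMask(mask))
        counts = [int(mask[sl].sum()) for sl in panels.slices]
        brute = sorted(range(len(counts)), key=lambda i: (-counts[i], i))
        np.testing.assert_array_equal(order, brute)


class TestSelectionCurve:
    def setup_clustered(self):
        mask = np.zeros((200, 200), bool)
        mask[10:50, 10:50] = True  # islet-rich corner
        mask[150:155, 150:155] = True
        tissue = full_tissue((200, 200))
        panels = PanelGrid((200, 200), (50.0, 50.0), 1.0)
        endo = BinaryMask(mask)
        return panels, endo, tissue

    def test_full_k_equals_whole_section_exactly(self):
        panels, endo, tissue = self.setup_clustered()
        order = rank_panels(panels, endo)
        curve = selection_curve(panels, order, endo, tissue)
        assert curve.percent[-1] == curve.reference  # bit-exact

    def test_uniform_section_constant_curve(self):
        tissue = full_tissue((100, 100))
        mask = np.zeros((100, 100), bool)
        mask[::2, ::2] = True  # same density in every panel
        panels = PanelGrid((100, 100), (50.0, 50.0), 1.0)
        endo = BinaryMask(mask)
        order = rank_panels(panels, endo)
        curve = selection_curve(panels, order, endo, tissue)
        np.testing.assert_allclose(curve.percent, curve.reference)

    def test_islet_rich_selection_overestimates(self):
        panels, endo, tissue = self.setup_clustered()
        order = rank_panels(panels, endo)
        curve = selection_curve(panels, order, endo, tissue)
        assert curve.percent[0] >= curve.reference
        assert np.nanmax(curve.percent) > curve.reference

    def test_zero_tissue_panels_flagged_not_raised(self):
        mask = np.zeros((100, 100), bool)
        mask[:50, :50] = True
        tissue = TissueMask(mask=BinaryMask(np.zeros((100, 100), bool)),
                            pixel_size=1.0, pancreas_area=1.0,
                            excluded_area=0.0, applied_exclusions=[])
        tissue.mask.data[60:, 60:] = True
        panels = PanelGrid((100, 100), (50.0, 50.0), 1.0)
        endo = BinaryMask(mask)
        order = rank_panels(panels, endo)
        curve = selection_curve(panels, order, endo, tissue, k_values=[1, 4])
        assert curve.flagged[0]
        assert np.isnan(curve.percent[0])


class TestEveryNth:
    def test_301_sections_every_50th_gives_7(self):
        block = generate_block_percents(301, true_percent=1.0, noise_sd=0.05, seed=3)
        values, (lo, hi) = every_nth_section(block, n=50)
        assert len(values) == 7
        assert lo <= hi

    def test_n_equal_one_is_identity(self):
        block = [1.0, 2.0, 3.0]
        values, _ = every_nth_section(block, n=1)
        assert values == block

    def test_range_collapses_without_noise(self):
        block = generate_block_percents(301, true_percent=1.0, noise_sd=0.0, seed=3)
        values, (lo, hi) = every_nth_section(block, n=50)
        assert hi - lo == 0.0

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            every_nth_section([], n=50)


class TestBlockSchemes:
    def test_all_blocks_is_truth(self):
        blocks = generate_organ_blocks(seed=1)
        est = block_selection_estimates(blocks, "all")
        assert est.folds == [1.0]

    def test_tail_only_overestimates_with_dense_tail(self):
        # tail density double the head's (~1:1:2 head:body:tail)
        blocks = generate_organ_blocks(seed=2)
        est = block_selection_estimates(blocks, "region:tail")
        assert est.folds[0] > 1.0

    def test_single_block_folds_bracket_unity(self):
        blocks = generate_organ_blocks(seed=4)
        folds = [block_selection_estimates(blocks, f"single:{i}").folds[0]
                 for i in range(len(blocks))]
        assert min(folds) < 1.0 < max(folds)

    def test_random_scheme_deterministic_given_seed(self):
        blocks = generate_organ_blocks(seed=5)
        a = block_selection_estimates(blocks, "random:3", seed=42)
        b = block_selection_estimates(blocks, "random:3", seed=42)
        assert a.estimates == b.estimates
        assert len(a.estimates) == 5

    def test_empty_selection_rejected(self):
        blocks = generate_organ_blocks(seed=5)
        with pytest.raises(ValueError):
            block_selection_estimates(blocks, "region:flipper")


def make_records(n, alpha_increases_with_size=True, seed=0):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        area = float(rng.lognormal(6.5, 1.0))
        n_cells = max(1, int(area / 178))
        alpha_frac = 0.1 + (0.15 * np.log10(max(n_cells, 1)) / 3
                            if alpha_increases_with_size else 0)
        n_alpha = int(round(alpha_frac * n_cells))
        n_delta = int(round(0.1 * n_cells))
        records.append(IsletRecord(
            i + 1, area, area,
            cell_counts={"insulin": n_cells - n_alpha - n_delta,
                         "glucagon": n_alpha, "somatostatin": n_delta}))
    return records


class TestLargestN:
    def test_n_at_least_population_gives_fold_one(self):
        records = make_records(40)
        out = largest_n_ratios(records, n=100)
        for pair in out.values():
            assert pair["fold"] == pytest.approx(1.0)
            assert pair["top_n"] == pytest.approx(pair["all"])

    def test_size_dependent_alpha_biases_beta_alpha_ratio_down(self):
        records = make_records(600, alpha_increases_with_size=True, seed=8)
        out = largest_n_ratios(records, n=100)
        assert out["insulin/glucagon"]["top_n"] < out["insulin/glucagon"]["all"]
        assert out["insulin/glucagon"]["fold"] < 1.0

    def test_zero_denominator_flagged(self):
        records = [IsletRecord(1, 100.0, 100.0,
                               cell_counts={"insulin": 5, "glucagon": 0,
                                            "somatostatin": 0})]
        out = largest_n_ratios(records, n=1)
        assert out["glucagon/somatostatin"]["undefined"]
        assert np.isnan(out["glucagon/somatostatin"]["top_n"])
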