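"""Masking, median-polish spatial correction and plate-median normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sgakit import (
    ColonyPlate,
    ComputationError,
    PlateStage,
    correct_spatial,
    generate_screen,
    mask_non_experimental,
    median_polish,
    normalize_to_plate_median,
)
from sgakit.plates import PlateLayout, Role


def _full_layout(n_rows=32, n_cols=48, border=4):
    """Layout in which every inner position is one experimental singleton."""
    rows = []
    for r in range(1, n_rows + 1):
        for c in range(1, n_cols + 1):
            on_border = (
                r <= border or r > n_rows - border or c <= border or c > n_cols - border
            )
            rows.append(
                {
                    "plate": "p1",
                    "row": r,
                    "col": c,
                    "query": None if on_border else "q",
                    "gene": None if on_border else f"g{r}_{c}",
                    "replicate": 0 if on_border else 1,
                    "role": Role.BORDER_DUMMY.value if on_border else Role.EXPERIMENT.value,
                }
            )
    return PlateLayout(pd.DataFrame(rows), n_rows=n_rows, n_cols=n_cols, replicates=1,
                       border_width=border)


class TestMasking:
    def test_default_border_leaves_inner_24x40(self):
        layout = _full_layout()
        plate = ColonyPlate("p1", np.full((32, 48), 100.0))
        masked = mask_non_experimental(plate, layout)
        assert masked.n_present == 24 * 40 == 960
        assert np.isnan(masked.sizes[0, 0]) and np.isnan(masked.sizes[31, 47])
        assert masked.sizes[10, 10] == 100.0

    def test_already_missing_inner_position_stays_missing(self):
        layout = _full_layout()
        sizes = np.full((32, 48), 100.0)
        sizes[10, 10] = np.nan
        masked = mask_non_experimental(ColonyPlate("p1", sizes), layout)
        assert np.isnan(masked.sizes[10, 10])
        assert masked.n_present == 959

    def test_zero_border_width_masks_only_empties(self):
        layout = _full_layout(8, 8, border=0)
        empty_idx = layout.table.index[:3]
        layout.table.loc[empty_idx, ["query", "gene"]] = None
        layout.table.loc[empty_idx, "role"] = Role.EMPTY.value
        plate = ColonyPlate("p1", np.full((8, 8), 5.0))
        masked = mask_non_experimental(plate, layout)
        assert masked.n_present == 64 - 3

    def test_dimension_mismatch_is_an_error(self):
        layout = _full_layout()
        with pytest.raises(Exception, match="layout declares"):
            mask_non_experimental(ColonyPlate("p1", np.ones((8, 8))), layout)


class TestCorrection:
    def test_flat_plate_is_unchanged_with_unit_surface(self):
        layout = _full_layout()
        plate = ColonyPlate("p1", np.full((32, 48), 100.0))
        corrected, surface = correct_spatial(plate, layout)
        inner = corrected.sizes[4:28, 4:44]
        np.testing.assert_allclose(inner, 100.0, rtol=1e-12)
        np.testing.assert_allclose(surface.row_effects, 1.0, atol=1e-12)
        np.testing.assert_allclose(surface.col_effects, 1.0, atol=1e-12)
        assert corrected.stage is PlateStage.CORRECTED

    def test_noiseless_multiplicative_gradient_flattened_and_recovered(self):
        layout = _full_layout()
        rng = np.random.default_rng(5)
        row_log = 0.3 * np.sin(np.linspace(0, 2 * np.pi, 32) + rng.uniform(0, 6))
        col_log = 0.2 * np.cos(np.linspace(0, 2 * np.pi, 48) + rng.uniform(0, 6))
        # gauge the truth to geometric mean 1 over the experimental rows/cols
        row_log[4:28] -= row_log[4:28].mean()
        col_log[4:44] -= col_log[4:44].mean()
        truth = np.exp(row_log)[:, None] * np.exp(col_log)[None, :]
        plate = ColonyPlate("p1", 100.0 * truth)
        corrected, surface = correct_spatial(plate, layout)
        inner = corrected.sizes[4:28, 4:44]
        np.testing.assert_allclose(inner, 100.0, rtol=1e-6)
        np.testing.assert_allclose(
            surface.row_effects[4:28], np.exp(row_log)[4:28], rtol=1e-6
        )
        np.testing.assert_allclose(
            surface.col_effects[4:44], np.exp(col_log)[4:44], rtol=1e-6
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_lognormal_noise_cv_is_reduced(self, seed):
        layout = _full_layout()
        rng = np.random.default_rng(seed)
        row_log = 0.3 * np.sin(np.linspace(0, 2 * np.pi, 32) + rng.uniform(0, 6))
        col_log = 0.2 * np.cos(np.linspace(0, 2 * np.pi, 48) + rng.uniform(0, 6))
        surface = np.exp(row_log)[:, None] * np.exp(col_log)[None, :]
        noise = np.exp(rng.normal(0, 0.1, size=(32, 48)))
        plate = ColonyPlate("p1", 100.0 * surface * noise)
        masked = mask_non_experimental(plate, layout)
        corrected, _ = correct_spatial(plate, layout)

        def inner_cv(p):
            v = p.sizes[4:28, 4:44]
            return np.nanstd(v) / np.nanmean(v)

        assert inner_cv(corrected) < inner_cv(masked)

    def test_correction_equivariant_under_global_scaling(self):
        layout = _full_layout()
        rng = np.random.default_rng(9)
        sizes = np.exp(rng.normal(np.log(200), 0.2, size=(32, 48)))
        c1, s1 = correct_spatial(ColonyPlate("p1", sizes), layout)
        c2, s2 = correct_spatial(ColonyPlate("p1", 7.5 * sizes), layout)
        np.testing.assert_allclose(s2.row_effects, s1.row_effects, rtol=1e-9)
        np.testing.assert_allclose(s2.col_effects, s1.col_effects, rtol=1e-9)
        inner = ~np.isnan(c1.sizes)
        np.testing.assert_allclose(c2.sizes[inner], 7.5 * c1.sizes[inner], rtol=1e-9)

    def test_mostly_missing_plate_advises_skip(self):
        layout = _full_layout()
        sizes = np.full((32, 48), np.nan)
        sizes[10, 10:14] = 100.0
        with pytest.raises(ComputationError, match="skip"):
            correct_spatial(ColonyPlate("p1", sizes), layout)

    def test_polish_residuals_keep_grand_level(self):
        rng = np.random.default_rng(2)
        grid = rng.normal(5.0, 0.5, size=(10, 12))
        row_eff, col_eff, resid = median_polish(grid)
        assert abs(row_eff.mean()) < 1e-9
        assert abs(col_eff.mean()) < 1e-9
        np.testing.assert_allclose(
            resid + row_eff[:, None] + col_eff[None, :], grid, atol=1e-9
        )


class TestNormalization:
    @staticmethod
    def _corrected(sizes):
        return ColonyPlate("p", np.asarray(sizes, float), PlateStage.CORRECTED)

    def test_values_divided_by_median(self):
        plate = self._corrected([[1.0, 2.0, 3.0, np.nan]])
        out = normalize_to_plate_median(plate)
        np.testing.assert_allclose(out.sizes[0, :3], [0.5, 1.0, 1.5])
        assert out.stage is PlateStage.NORMALIZED

    def test_constant_plate_becomes_all_ones(self):
        out = normalize_to_plate_median(self._corrected(np.full((3, 3), 42.0)))
        np.testing.assert_allclose(out.sizes, 1.0)

    def test_all_missing_plate_is_an_error(self):
        with pytest.raises(ComputationError):
            normalize_to_plate_median(self._corrected(np.full((2, 2), np.nan)))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        values=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=30),
        k=st.floats(0.01, 1000.0),
    )
    def test_scale_invariance(self, values, k):
        a = np.array(values).reshape(1, -1)
        n1 = normalize_to_plate_median(self._corrected(a))
        n2 = normalize_to_plate_median(self._corrected(k * a))
        np.testing.assert_allclose(n2.sizes, n1.sizes, rtol=1e-9)
        assert abs(np.median(n1.sizes) - 1.0) < 1e-12
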