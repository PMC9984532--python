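"""Fitness computation, replicate exclusion, testing, BH and hit calling."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sgakit import (
    ScreenConfig,
    ValidationError,
    adjust_bh,
    call_hits,
    compute_fitness,
    exclude_dominant_replicates,
    score_screen,
    summarize_replicates,
)
from sgakit import test_interaction as interaction_test  # avoid pytest collection
from sgakit.spatial import prepare_plates


def welch_oracle(a, b):
    """Independent Welch t-test from the defining formulas."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (
        va**2 / (a.size - 1) + vb**2 / (b.size - 1)
    )
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


class TestComputeFitness:
    def test_uniform_query_gives_unit_fitness(self, clean_screen):
        plates, layout, _ = clean_screen
        normalized, _ = prepare_plates(plates, layout)
        fit = compute_fitness(normalized, layout)
        wt = fit[fit["query"] == "wt"]["fitness"]
        np.testing.assert_allclose(wt, 1.0, rtol=1e-9)

    def test_fitness_is_size_over_query_median(self):
        # one query, four genes at sizes {90,100,110,120}: median 105
        from sgakit import ColonyPlate, PlateStage
        from sgakit.plates import PlateLayout, Role

        sizes = np.array([[90.0, 100.0, 110.0, 120.0]])
        layout = PlateLayout(
            pd.DataFrame(
                {
                    "plate": "p1",
                    "row": 1,
                    "col": [1, 2, 3, 4],
                    "query": "q",
                    "gene": ["g1", "g2", "g3", "g4"],
                    "replicate": 1,
                    "role": Role.EXPERIMENT.value,
                }
            ),
            n_rows=1,
            n_cols=4,
            replicates=1,
            border_width=0,
        )
        plate = ColonyPlate("p1", sizes, PlateStage.NORMALIZED)
        fit = compute_fitness([plate], layout)
        g1 = fit.set_index("gene").loc["g1", "fitness"]
        np.testing.assert_allclose(g1, 6.0 / 7.0, rtol=1e-12)


class TestReplicateExclusion:
    def test_dominant_outlier_excluded(self):
        kept, excluded = exclude_dominant_replicates([1, 1, 1, 100])
        assert excluded == [3]
        assert kept == [0, 1, 2]

    def test_spread_values_kept(self):
        # max leave-one-out share for [1,2,3,4] is 1 - 2/5 = 0.6 < 0.9
        kept, excluded = exclude_dominant_replicates([1, 2, 3, 4])
        assert excluded == []
        assert kept == [0, 1, 2, 3]

    def test_zero_variance_excludes_nothing(self):
        kept, excluded = exclude_dominant_replicates([5, 5, 5, 5])
        assert (kept, excluded) == ([0, 1, 2, 3], [])

    def test_at_most_one_exclusion_even_with_two_outliers(self):
        kept, excluded = exclude_dominant_replicates([0.0, 0.0, 1.0, 100.0])
        assert len(excluded) == 1

    def test_fewer_than_two_values_is_an_error(self):
        with pytest.raises(Exception):
            exclude_dominant_replicates([1.0])

    def test_idempotent_on_screen_like_replicates(self):
        for values in ([1, 1, 1, 100], [1, 2, 3, 4], [1, 2, 3]):
            kept, _ = exclude_dominant_replicates(values)
            again_kept, again_excl = exclude_dominant_replicates(
                np.asarray(values, float)[kept]
            )
            assert again_excl == []


class TestInteractionTest:
    def test_identical_vectors_give_t0_p1(self):
        v = [1.0, 1.05, 0.95, 1.0]
        t, p, n = interaction_test(v, v)
        assert t == 0.0 and p == 1.0 and n == 4

    def test_clear_difference_matches_welch_oracle(self):
        q = [0.50, 0.55, 0.45, 0.50]
        w = [1.00, 1.05, 0.95, 1.00]
        t, p, n = interaction_test(q, w)
        t_ref, p_ref = welch_oracle(q, w)
        assert p < 0.001
        np.testing.assert_allclose([t, p], [t_ref, p_ref], rtol=1e-10)

    def test_outlier_then_zero_variance_path_gives_p1(self):
        t, p, n = interaction_test([1, 1, 1, 100], [1, 1, 1, 1])
        assert t == 0.0 and p == 1.0 and n == 3

    def test_too_few_replicates_is_untestable(self):
        t, p, n = interaction_test([0.5, 0.6], [1.0, 1.1, 0.9, 1.0])
        assert math.isnan(t) and math.isnan(p)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(0.1, 2.0), min_size=3, max_size=6),
        b=st.lists(st.floats(0.1, 2.0), min_size=3, max_size=6),
    )
    def test_sign_symmetry(self, a, b):
        ta, pa, _ = interaction_test(a, b)
        tb, pb, _ = interaction_test(b, a)
        if math.isnan(ta):
            assert math.isnan(tb)
        else:
            np.testing.assert_allclose(ta, -tb, rtol=1e-9, atol=1e-12)
            np.testing.assert_allclose(pa, pb, rtol=1e-9)


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        np.testing.assert_allclose(
            adjust_bh([0.01, 0.04, 0.03, 0.05]), [0.04, 0.05, 0.05, 0.05]
        )

    def test_uniform_and_single_values_unchanged(self):
        np.testing.assert_allclose(adjust_bh([0.2, 0.2, 0.2]), 0.2)
        np.testing.assert_allclose(adjust_bh([0.031]), [0.031])

    def test_missing_entries_pass_through(self):
        out = adjust_bh([0.01, np.nan, 0.02])
        assert np.isnan(out[1])
        # family size m = 2, not 3
        np.testing.assert_allclose(out[[0, 2]], [0.02, 0.02])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            adjust_bh([0.1, 1.2])

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        p=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20),
        bumps=st.data(),
    )
    def test_monotone_and_order_invariant(self, p, bumps):
        p = np.array(p)
        larger = np.minimum(
            p
            + np.array(
                bumps.draw(
                    st.lists(
                        st.floats(0.0, 0.5), min_size=len(p), max_size=len(p)
                    )
                )
            ),
            1.0,
        )
        assert (adjust_bh(larger) >= adjust_bh(p) - 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(adjust_bh(p)[perm], adjust_bh(p[perm]))


class TestSummarizeAndHits:
    def test_summarize_excludes_outlier(self):
        assert summarize_replicates([1, 1, 1, 100]) == 1.0

    def test_summarize_plain_mean_and_singleton(self):
        assert summarize_replicates([0.4, 0.5, 0.6]) == pytest.approx(0.5)
        assert summarize_replicates([0.5]) == 0.5
        assert math.isnan(summarize_replicates([np.nan]))

    @pytest.mark.parametrize(
        "ratio,p_adj,expected",
        [
            (0.79, 0.04, "yes"),
            (0.80, 0.01, "no"),  # threshold is strict
            (0.50, 0.06, "no"),  # fails the significance arm
            (0.79, 0.05, "no"),  # alpha is strict
        ],
    )
    def test_hit_criterion_strictness(self, ratio, p_adj, expected):
        table = pd.DataFrame(
            {"fitness_ratio": [ratio], "p_raw": [p_adj / 2], "p_adj": [p_adj]}
        )
        assert call_hits(table)["hit"][0] == expected

    def test_untestable_rows_unchanged(self):
        table = pd.DataFrame(
            {"fitness_ratio": [np.nan], "p_raw": [np.nan], "p_adj": [np.nan]}
        )
        assert call_hits(table)["hit"][0] == "untestable"


class TestScoreScreen:
    def test_injected_interaction_found_with_correct_ratio(
        self, normalized_noisy_screen
    ):
        normalized, layout, truth, _ = normalized_noisy_screen
        results = score_screen(normalized, layout, wt_query="wt")
        hits = set(results[results["hit"] == "yes"]["gene"])
        injected = {g for (_, g) in truth.interaction}
        assert len(hits & injected) >= 2  # detection, allowing one unlucky draw
        assert hits <= injected  # no false positives among 117 null genes
        ratios = results.set_index("gene").loc[sorted(injected), "fitness_ratio"]
        np.testing.assert_allclose(ratios, 0.5, rtol=0.2)

    def test_padj_not_smaller_than_praw(self, normalized_noisy_screen):
        normalized, layout, _, _ = normalized_noisy_screen
        results = score_screen(normalized, layout, wt_query="wt")
        ok = results["p_raw"].notna()
        assert (
            results.loc[ok, "p_adj"] >= results.loc[ok, "p_raw"] - 1e-12
        ).all()

    def test_missing_control_query_is_an_error(self, normalized_noisy_screen):
        normalized, layout, _, _ = normalized_noisy_screen
        with pytest.raises(ValidationError, match="control query"):
            score_screen(normalized, layout, wt_query="nonexistent")
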