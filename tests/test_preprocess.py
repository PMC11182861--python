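import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from volatilink import (
    PreprocessConfig,
    ValidationError,
    filter_prevalence,
    filter_rsd,
    log_center,
    normalize_by_reference,
    subtract_blanks,
)

from conftest import make_table


def corals_and_blanks(values_corals, values_blanks, compounds):
    samples = [f"C{i}" for i in range(1, 7)] + [f"H{i}" for i in range(1, 7)]
    blanks = [f"BC{i}" for i in range(1, 4)] + [f"BH{i}" for i in range(1, 4)]
    data = np.vstack([values_corals, values_blanks])
    return make_table(data, samples + blanks, compounds, stage="is_normalised")


class TestNormalize:
    def test_division_by_reference(self):
        table = make_table([[2, 4]], ["s1"], ["a", "b"])
        out = normalize_by_reference(table, {"s1": 2.0}, stage="is_normalised")
        np.testing.assert_allclose(out.values, [[1, 2]])
        assert out.stage == "is_normalised"

    def test_reference_one_is_identity(self):
        table = make_table([[2, 4], [1, 3]], ["s1", "s2"], ["a", "b"])
        out = normalize_by_reference(table, {"s1": 1.0, "s2": 1.0}, stage="is_normalised")
        np.testing.assert_array_equal(out.values, table.values)

    @pytest.mark.parametrize("ref", [0.0, -1.0])
    def test_nonpositive_reference_rejected(self, ref):
        table = make_table([[2, 4]], ["s1"], ["a", "b"])
        with pytest.raises(ValidationError, match="s1"):
            normalize_by_reference(table, {"s1": ref}, stage="is_normalised")

    def test_missing_reference_names_sample(self):
        table = make_table([[2, 4]], ["s1"], ["a", "b"])
        with pytest.raises(ValidationError, match="s1"):
            normalize_by_reference(table, {}, stage="is_normalised")


class TestSubtractBlanks:
    def test_below_blank_mean_floors_to_zero(self, meta_with_blanks):
        """A sample detecting less than the seawater background reads as 0."""
        corals = np.full((12, 2), [5.0, 10.0])
        blanks = np.full((6, 2), 7.0)
        table = corals_and_blanks(corals, blanks, ["a", "b"])
        out = subtract_blanks(table, meta_with_blanks)
        np.testing.assert_allclose(out.data["a"], 0.0)  # 5 - 7 -> floored
        np.testing.assert_allclose(out.data["b"], 3.0)  # 10 - 7
        assert set(out.sample_ids) == set(meta_with_blanks.corals())

    def test_zero_blank_mean_leaves_samples_unchanged(self, meta_with_blanks):
        corals = np.full((12, 1), 4.0)
        blanks = np.zeros((6, 1))
        table = corals_and_blanks(corals, blanks, ["a"])
        out = subtract_blanks(table, meta_with_blanks)
        np.testing.assert_allclose(out.data["a"], 4.0)

    def test_per_treatment_blank_means(self, meta_with_blanks):
        corals = np.full((12, 1), 10.0)
        blanks = np.array([[2.0]] * 3 + [[6.0]] * 3)  # control blanks 2, high-light blanks 6
        table = corals_and_blanks(corals, blanks, ["a"])
        out = subtract_blanks(table, meta_with_blanks)
        np.testing.assert_allclose(out.data.loc[[f"C{i}" for i in range(1, 7)], "a"], 8.0)
        np.testing.assert_allclose(out.data.loc[[f"H{i}" for i in range(1, 7)], "a"], 4.0)
        pooled = subtract_blanks(table, meta_with_blanks, pooled=True)
        np.testing.assert_allclose(pooled.data["a"], 6.0)

    def test_no_blanks_is_an_error(self, meta_6_6):
        table = make_table(np.ones((12, 1)), meta_6_6.sample_ids, ["a"], stage="is_normalised")
        with pytest.raises(ValidationError, match="blank"):
            subtract_blanks(table, meta_6_6)

    @given(st.integers(0, 2**31 - 1))
    def test_never_negative(self, seed):
        rng = np.random.default_rng(seed)
        corals = rng.lognormal(0, 2, size=(12, 4))
        blanks = rng.lognormal(1, 2, size=(6, 4))
        table = corals_and_blanks(corals, blanks, list("abcd"))
        out = subtract_blanks(table, _blank_meta())
        assert (out.values >= 0).all()


def _blank_meta():
    corals = [f"C{i}" for i in range(1, 7)] + [f"H{i}" for i in range(1, 7)]
    blanks = [f"BC{i}" for i in range(1, 4)] + [f"BH{i}" for i in range(1, 4)]
    from volatilink import SampleMetadata

    return SampleMetadata(
        frame=pd.DataFrame(
            {
                "treatment": ["control"] * 6 + ["high_light"] * 6 + ["control"] * 3 + ["high_light"] * 3,
                "is_blank": [False] * 12 + [True] * 6,
                "internal_standard_area": 1.0,
                "scale_factor": [1.0] * 12 + [np.nan] * 6,
            },
            index=corals + blanks,
        )
    )


class TestPrevalenceFilter:
    def _table(self, det_control, det_high, meta):
        col = np.zeros(12)
        col[:det_control] = 1.0
        col[6 : 6 + det_high] = 1.0
        return make_table(col[:, None], meta.sample_ids, ["cmp"], stage="scaled")

    def test_three_of_six_in_both_groups_removed(self, meta_6_6):
        """Detection in three or fewer replicates of every group drops the compound."""
        table = self._table(3, 3, meta_6_6)
        out, log = filter_prevalence(table, meta_6_6)
        assert out.n_compounds == 0
        assert list(log["compound_id"]) == ["cmp"]
        assert (log["reason"] == "prevalence").all()

    def test_four_in_one_group_retained(self, meta_6_6):
        """Robust presence under a single condition keeps a compound."""
        table = self._table(4, 0, meta_6_6)
        out, log = filter_prevalence(table, meta_6_6)
        assert out.compound_ids == ["cmp"]
        assert len(log) == 0

    def test_all_zero_removed(self, meta_6_6):
        table = self._table(0, 0, meta_6_6)
        out, _ = filter_prevalence(table, meta_6_6)
        assert out.n_compounds == 0

    def test_strict_mode_requires_every_group(self, meta_6_6):
        table = self._table(4, 0, meta_6_6)
        config = PreprocessConfig(prevalence_mode="all_groups")
        out, _ = filter_prevalence(table, meta_6_6, config)
        assert out.n_compounds == 0

    def test_values_never_altered(self, meta_6_6, small_table):
        scaled = small_table.replace_data(small_table.data, stage="scaled")
        out, _ = filter_prevalence(scaled, meta_6_6)
        pd.testing.assert_frame_equal(out.data, scaled.data[out.compound_ids])


class TestRsdFilter:
    def test_constant_group_retained(self, meta_6_6):
        table = make_table(np.ones((12, 1)), meta_6_6.sample_ids, ["cmp"], stage="scaled")
        out, _ = filter_rsd(table, meta_6_6)
        assert out.compound_ids == ["cmp"]

    def test_high_rsd_removed(self, meta_6_6):
        values = np.array([1, 10, 100, 1, 10, 100] * 2, dtype=float)[:, None]
        table = make_table(values, meta_6_6.sample_ids, ["cmp"], stage="scaled")
        group = values[:6, 0]
        assert np.std(group, ddof=1) / np.mean(group) > 0.5  # oracle: direct sd/mean
        out, log = filter_rsd(table, meta_6_6)
        assert out.n_compounds == 0
        assert log.iloc[0]["reason"] == "rsd"

    def test_zero_mean_group_removed(self, meta_6_6):
        values = np.concatenate([np.zeros(6), np.full(6, 5.0)])[:, None]
        table = make_table(values, meta_6_6.sample_ids, ["cmp"], stage="scaled")
        out, _ = filter_rsd(table, meta_6_6)
        assert out.n_compounds == 0

    def test_both_groups_mode(self, meta_6_6):
        noisy = np.array([1, 10, 100, 1, 10, 100], dtype=float)
        values = np.concatenate([noisy, np.full(6, 5.0)])[:, None]
        table = make_table(values, meta_6_6.sample_ids, ["cmp"], stage="scaled")
        either, _ = filter_rsd(table, meta_6_6, PreprocessConfig(rsd_mode="either_group"))
        both, _ = filter_rsd(table, meta_6_6, PreprocessConfig(rsd_mode="both_groups"))
        assert either.n_compounds == 0
        assert both.compound_ids == ["cmp"]

    def test_single_replicate_group_is_error(self):
        from volatilink import SampleMetadata

        meta = SampleMetadata(
            frame=pd.DataFrame(
                {
                    "treatment": ["control", "high_light", "high_light"],
                    "is_blank": False,
                    "internal_standard_area": 1.0,
                    "scale_factor": 1.0,
                },
                index=["s1", "s2", "s3"],
            )
        )
        table = make_table(np.ones((3, 1)), ["s1", "s2", "s3"], ["cmp"], stage="scaled")
        with pytest.raises(ValidationError, match="RSD undefined"):
            filter_rsd(table, meta)


class TestLogCenter:
    def test_powers_of_ten_centre_symmetrically(self):
        table = make_table([[1.0], [10.0], [100.0]], ["s1", "s2", "s3"], ["cmp"], stage="filtered")
        out = log_center(table)
        np.testing.assert_allclose(out.data["cmp"], [-1.0, 0.0, 1.0])
        assert out.stage == "log_centred"

    def test_zeros_replaced_by_half_minimum_positive(self):
        table = make_table([[0.0], [10.0]], ["s1", "s2"], ["cmp"], stage="filtered")
        out = log_center(table)
        # zero -> 5 before log10: column is log10([5,10]) centred
        expected = np.log10([5.0, 10.0])
        expected -= expected.mean()
        np.testing.assert_allclose(out.data["cmp"], expected)
        assert abs(out.data["cmp"].sum()) < 1e-12

    def test_all_columns_have_mean_zero(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(0, 1, size=(10, 8))
        values[values < 0.5] = 0.0
        values[0, :] = 1.0  # ensure at least one positive per column
        table = make_table(values, [f"s{i}" for i in range(10)], [f"c{i}" for i in range(8)], stage="filtered")
        out = log_center(table)
        assert np.abs(out.values.mean(axis=0)).max() < 1e-12

    def test_all_zero_compound_is_error(self):
        table = make_table([[0.0], [0.0]], ["s1", "s2"], ["cmp"], stage="filtered")
        with pytest.raises(ValidationError, match="log_center"):
            log_center(table)
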