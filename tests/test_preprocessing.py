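import numpy as np
import pandas as pd
import pytest

from lipidhads.preprocessing import (
    IntensityTable,
    PreprocessingError,
    align_temporal_batches,
    correct_batches,
    filter_unstable_features,
    filter_zero_features,
    impute_zeros,
    log2_transform,
    remove_contaminants,
    run_postprocessing,
)

from conftest import make_table


class TestZeroFilter:
    def test_strictly_above_ten_percent_removed(self):
        vals = {"keep": [1.0] * 10, "drop": [0, 0] + [1.0] * 8}
        t = make_table(vals, ["plasma"] * 10)
        out, report = filter_zero_features(t)
        assert list(out.feature_names) == ["keep"]
        assert report.removed_features == ["drop"]
        assert report.rule_values["drop"] == pytest.approx(0.2)

    def test_boundary_exactly_ten_percent_retained(self):
        t = make_table({"f": [0] + [1.0] * 9}, ["plasma"] * 10)
        out, _ = filter_zero_features(t)
        assert "f" in out.feature_names

    def test_blank_zeros_do_not_count(self):
        t = make_table({"f": [1, 1, 1, 0]}, ["plasma", "plasma", "plasma", "blank"])
        out, _ = filter_zero_features(t)
        assert "f" in out.feature_names

    def test_no_plasma_errors(self):
        t = make_table({"f": [1.0, 2.0]}, ["qc", "blank"])
        with pytest.raises(PreprocessingError, match="plasma"):
            filter_zero_features(t)


class TestImputeZeros:
    def test_zero_replaced_by_09_of_min_nonzero(self):
        t = make_table({"f": [0, 4, 8]}, ["plasma"] * 3)
        out = impute_zeros(t)
        assert out.values["f"].tolist() == [3.6, 4.0, 8.0]

    def test_blank_zero_uses_plasma_minimum(self):
        t = make_table({"f": [10, 20, 0]}, ["plasma", "plasma", "blank"])
        out = impute_zeros(t)
        assert out.values.loc["S2", "f"] == pytest.approx(9.0)

    def test_no_zeros_is_identity(self):
        t = make_table({"f": [1, 2, 3]}, ["plasma"] * 3)
        pd.testing.assert_frame_equal(impute_zeros(t).values, t.values)

    def test_all_zero_plasma_feature_errors(self):
        t = make_table({"f": [0, 0, 5]}, ["plasma", "plasma", "blank"])
        with pytest.raises(PreprocessingError, match="filter_zero_features"):
            impute_zeros(t)


class TestLog2:
    def test_values(self):
        t = make_table({"f": [8, 1]}, ["plasma"] * 2)
        out = log2_transform(t)
        assert out.values["f"].tolist() == [3.0, 0.0]
        assert out.scale == "log2"

    def test_double_application_rejected_by_scale_flag(self):
        t = log2_transform(make_table({"f": [8, 2]}, ["plasma"] * 2))
        with pytest.raises(PreprocessingError, match="raw-scale"):
            log2_transform(t)


class TestContaminants:
    def _table(self, plasma_mean, blank_mean):
        return make_table(
            {"f": [plasma_mean, plasma_mean, blank_mean]},
            ["plasma", "plasma", "blank"],
            scale="log2",
        )

    def test_small_delta_removed(self):
        out, rep = remove_contaminants(self._table(11.2, 10.5))
        assert rep.removed_features == ["f"]
        assert rep.rule_values["f"] == pytest.approx(0.7)

    def test_large_delta_retained(self):
        out, _ = remove_contaminants(self._table(15.0, 9.0))
        assert "f" in out.feature_names

    def test_delta_exactly_one_retained(self):
        out, _ = remove_contaminants(self._table(11.0, 10.0))
        assert "f" in out.feature_names

    def test_no_blanks_errors(self):
        t = make_table({"f": [1.0, 2.0]}, ["plasma"] * 2, scale="log2")
        with pytest.raises(PreprocessingError, match="blank"):
            remove_contaminants(t)


class TestBatchCorrection:
    def _two_batch_table(self):
        # feature f: QC medians 10 (batch 1) and 12 (batch 2); grand median 11
        roles = ["qc", "plasma", "plasma", "qc", "plasma", "plasma"]
        batch = [1, 1, 1, 2, 2, 2]
        return make_table(
            {"f": [10, 20, 21, 12, 20, 21]}, roles, batch=batch, scale="log2"
        )

    def test_shifts_toward_grand_median(self):
        out = correct_batches(self._two_batch_table())
        # batch 1 shifted +1, batch 2 shifted -1
        assert out.values["f"].tolist() == [11, 21, 22, 11, 19, 20]

    def test_single_batch_is_identity(self):
        t = make_table({"f": [10, 20, 21]}, ["qc", "plasma", "plasma"], scale="log2")
        out = correct_batches(t)
        pd.testing.assert_frame_equal(out.values, t.values)

    def test_qc_medians_equal_grand_after_correction(self):
        out = correct_batches(self._two_batch_table())
        qc = out.values.loc[out.mask("qc")]
        grand = out.values.loc[out.mask("qc")].median()
        for b in (1, 2):
            med = out.values.loc[out.mask("qc") & (out.batch == b)].median()
            assert np.allclose(med, grand)

    def test_idempotent(self):
        once = correct_batches(self._two_batch_table())
        twice = correct_batches(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_batch_without_qc_named_in_error(self):
        t = make_table(
            {"f": [10, 20, 21, 22]},
            ["qc", "plasma", "plasma", "plasma"],
            batch=[1, 1, 2, 2],
            scale="log2",
        )
        with pytest.raises(PreprocessingError, match="batch 2"):
            correct_batches(t)


class TestUnstableFilter:
    def test_high_qc_sd_removed(self):
        t = make_table(
            {"f": [10, 11, 10.5], "g": [10, 10, 10]},
            ["qc", "qc", "plasma"],
            scale="log2",
        )
        out, rep = filter_unstable_features(t)
        assert rep.removed_features == ["f"]  # sd {10,11} = 0.707 > 0.5
        assert rep.rule_values["f"] == pytest.approx(np.sqrt(0.5))
        assert "g" in out.feature_names

    def test_sd_exactly_at_threshold_retained(self):
        # strict ">" rule: a feature sitting exactly at the cap stays
        t = make_table({"f": [10.0, 11.0, 10]}, ["qc", "qc", "plasma"],
                       scale="log2")
        sd = t.values.loc[t.mask("qc"), "f"].std(ddof=1)
        out, _ = filter_unstable_features(t, max_qc_sd=float(sd))
        assert "f" in out.feature_names

    def test_fewer_than_two_qc_errors(self):
        t = make_table({"f": [10, 10]}, ["qc", "plasma"], scale="log2")
        with pytest.raises(PreprocessingError, match="2 QC"):
            filter_unstable_features(t)


class TestTemporalAlignment:
    def test_second_batch_aligned_to_first(self):
        t = make_table(
            {"f": [10, 5, 9, 4]},
            ["ltr", "plasma", "ltr", "plasma"],
            batch=[1, 1, 2, 2],
            temporal_batch=[1, 1, 2, 2],
            scale="log2",
        )
        out = align_temporal_batches(t)
        assert out.values["f"].tolist() == [10, 5, 10, 5]

    def test_equal_ltr_medians_identity(self):
        t = make_table(
            {"f": [10, 5, 10, 4]},
            ["ltr", "plasma", "ltr", "plasma"],
            temporal_batch=[1, 1, 2, 2],
            scale="log2",
        )
        pd.testing.assert_frame_equal(align_temporal_batches(t).values, t.values)

    def test_single_temporal_batch_identity(self):
        t = make_table({"f": [10, 5]}, ["ltr", "plasma"], scale="log2")
        pd.testing.assert_frame_equal(align_temporal_batches(t).values, t.values)

    def test_missing_ltr_errors(self):
        t = make_table(
            {"f": [10, 5, 4]},
            ["ltr", "plasma", "plasma"],
            temporal_batch=[1, 1, 2],
            scale="log2",
        )
        with pytest.raises(PreprocessingError, match="LTR"):
            align_temporal_batches(t)


class TestFullChain:
    def _raw_fixture(self):
        # 6 plasma + 2 qc + 1 blank, one batch; planted violations:
        # hz: 2/6 plasma zeros; cont: blank close to plasma; unst: QC sd >> 0.5
        roles = ["qc"] + ["plasma"] * 6 + ["qc", "blank"]
        vals = {
            "clean": [512, 500, 520, 510, 490, 505, 515, 512, 1.0],
            "hz": [512, 0, 0, 510, 490, 505, 515, 512, 1.0],
            "cont": [512, 500, 520, 510, 490, 505, 515, 512, 400.0],
            "unst": [100, 500, 520, 510, 490, 505, 515, 2000, 1.0],
        }
        return make_table(vals, roles)

    def test_each_planted_feature_removed_by_intended_rule(self):
        out, reports = run_postprocessing(self._raw_fixture())
        by_step = {r.step: set(r.removed_features) for r in reports}
        assert by_step["zero_fraction"] == {"hz"}
        assert by_step["blank_delta"] == {"cont"}
        assert by_step["qc_sd"] == {"unst"}
        assert list(out.feature_names) == ["clean"]

    def test_plasma_sample_count_conserved_and_plasma_only(self):
        out, _ = run_postprocessing(self._raw_fixture())
        assert len(out.sample_ids) == 6
        assert (out.role == "plasma").all()

    def test_no_violations_zero_removals(self):
        roles = ["qc"] + ["plasma"] * 4 + ["qc", "blank"]
        t = make_table({"a": [512, 500, 520, 510, 490, 512, 1.0],
                        "b": [64, 60, 66, 62, 58, 64, 1.0]}, roles)
        out, reports = run_postprocessing(t)
        assert all(not r.removed_features for r in reports)
        assert list(out.feature_names) == ["a", "b"]

    def test_every_removed_feature_in_exactly_one_report(self):
        _, reports = run_postprocessing(self._raw_fixture())
        removed = [f for r in reports for f in r.removed_features]
        assert len(removed) == len(set(removed))


def test_from_frame_roundtrip(tmp_path):
    t = make_table({"PC 38:6": [1, 2, 3]}, ["plasma", "qc", "blank"])
    path = tmp_path / "t.csv"
    t.to_csv(path)
    back = IntensityTable.from_csv(path, scale="raw")
    pd.testing.assert_frame_equal(back.values, t.values)
    assert (back.role == t.role).all()
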