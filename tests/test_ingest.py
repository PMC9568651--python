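"""Input reading, QC masking, missingness filtering and transforms."""

import numpy as np
import pandas as pd
import pytest

from twinewas import ingest
from twinewas.simulate import SimConfig, simulate_fixture


def test_detection_mask_strict_threshold(tiny_beta):
    detp = pd.DataFrame(0.0, index=tiny_beta.index, columns=tiny_beta.columns)
    detp.iloc[0, 0] = 0.06   # above threshold -> masked
    detp.iloc[1, 1] = 0.05   # exactly at threshold -> retained
    out = ingest.apply_detection_mask(tiny_beta, detp)
    assert np.isnan(out.iloc[0, 0])
    assert out.iloc[1, 1] == tiny_beta.iloc[1, 1]
    assert out.drop(out.index[0]).notna().all().all()


def test_detection_mask_all_clear_is_identity(tiny_beta):
    detp = pd.DataFrame(0.0, index=tiny_beta.index, columns=tiny_beta.columns)
    pd.testing.assert_frame_equal(
        ingest.apply_detection_mask(tiny_beta, detp), tiny_beta
    )


def test_detection_mask_shape_mismatch(tiny_beta):
    with pytest.raises(ValueError):
        ingest.apply_detection_mask(tiny_beta, tiny_beta.iloc[:2])


class TestMissingness:
    def test_strict_five_percent_rule(self):
        rng = np.random.default_rng(0)
        index = ["drop_6pct", "keep_5pct"] + [f"bg{i}" for i in range(98)]
        beta = pd.DataFrame(
            rng.uniform(size=(100, 100)),
            index=index,
            columns=[f"s{i}" for i in range(100)],
        )
        beta.iloc[0, :6] = np.nan   # 6% missing -> removed
        beta.iloc[1, 6:11] = np.nan  # exactly 5% -> retained
        out, removed_probes, removed_subjects = ingest.filter_missingness(beta)
        assert removed_probes == ["drop_6pct"]
        assert removed_subjects == []
        assert "keep_5pct" in out.index

    def test_probes_filtered_before_subjects(self):
        # s0 is over the cap only while the dead probes are still present;
        # filtering probes first salvages it
        beta = pd.DataFrame(
            np.ones((60, 21)),
            index=[f"p{i}" for i in range(60)],
            columns=[f"s{i}" for i in range(21)],
        )
        beta.iloc[:5, :] = np.nan         # five fully missing probes
        beta.iloc[5, 0] = np.nan          # s0: 6/60 before, 1/55 after
        out, removed_probes, removed_subjects = ingest.filter_missingness(beta)
        assert removed_probes == [f"p{i}" for i in range(5)]
        assert removed_subjects == []
        assert "s0" in out.columns

    def test_complete_matrix_unchanged(self, tiny_beta):
        out, rp, rs = ingest.filter_missingness(tiny_beta)
        pd.testing.assert_frame_equal(out, tiny_beta)
        assert rp == [] and rs == []

    def test_empty_result_raises(self):
        beta = pd.DataFrame(np.nan, index=["p0"], columns=["s0"])
        with pytest.raises(ValueError):
            ingest.filter_missingness(beta)


class TestImputeKnn:
    def test_nearest_neighbour_value(self):
        beta = pd.DataFrame(
            {
                "s1": [0.50, 0.51, 0.90],
                "s2": [0.55, 0.56, 0.10],
                "s3": [np.nan, 0.42, 0.80],
            },
            index=["target", "near", "far"],
        )
        out = ingest.impute_knn(beta, k=1)
        assert out.loc["target", "s3"] == pytest.approx(0.42)

    def test_mean_of_two_neighbours(self):
        beta = pd.DataFrame(
            {
                "s1": [0.50, 0.49, 0.51, 0.95],
                "s2": [0.60, 0.61, 0.59, 0.05],
                "s3": [np.nan, 0.40, 0.60, 0.90],
            },
            index=["target", "n1", "n2", "far"],
        )
        out = ingest.impute_knn(beta, k=2)
        assert out.loc["target", "s3"] == pytest.approx(0.50)

    def test_complete_matrix_identity(self, tiny_beta):
        pd.testing.assert_frame_equal(ingest.impute_knn(tiny_beta), tiny_beta)

    def test_no_missing_left(self, small_cohort):
        beta = small_cohort["beta"].iloc[:200].copy()
        rng = np.random.default_rng(1)
        mask = rng.random(beta.shape) < 0.01
        beta = beta.mask(mask)
        out = ingest.impute_knn(beta)
        assert out.notna().all().all()
        assert ((out >= 0) & (out <= 1)).all().all()


class TestMTransform:
    @pytest.mark.parametrize("b,m", [(0.5, 0.0), (0.8, 2.0), (0.2, -2.0)])
    def test_known_values(self, b, m):
        beta = pd.DataFrame([[b]])
        assert ingest.beta_to_m(beta).iloc[0, 0] == pytest.approx(m)

    def test_roundtrip_away_from_bounds(self):
        rng = np.random.default_rng(2)
        beta = pd.DataFrame(rng.uniform(0.001, 0.999, size=(50, 4)))
        back = ingest.m_to_beta(ingest.beta_to_m(beta))
        np.testing.assert_allclose(back.to_numpy(), beta.to_numpy(), atol=1e-9)

    def test_boundary_clipped_finite(self):
        beta = pd.DataFrame([[0.0, 1.0]])
        m = ingest.beta_to_m(beta)
        assert np.isfinite(m.to_numpy()).all()

    def test_missing_propagates(self):
        m = ingest.beta_to_m(pd.DataFrame([[0.5, np.nan]]))
        assert np.isnan(m.iloc[0, 1])


class TestSampleSheet:
    def test_two_cases_in_pair_rejected(self, tiny_sheet):
        bad = tiny_sheet.copy()
        bad.loc["p0_control", "role"] = "case"
        with pytest.raises(ingest.PairError, match="p0"):
            ingest.validate_sample_sheet(bad.reset_index(drop=True))

    def test_sex_mismatch_rejected(self, tiny_sheet):
        bad = tiny_sheet.copy()
        bad.loc["p1_case", "sex"] = "F"
        with pytest.raises(ingest.PairError, match="p1"):
            ingest.validate_sample_sheet(bad.reset_index(drop=True))


class TestFlagFailedPairs:
    def test_absolute_rule(self, tiny_sheet, tiny_beta):
        detp = pd.DataFrame(
            0.001, index=tiny_beta.index, columns=tiny_beta.columns
        )
        detp["p1_case"] = 0.2
        out = ingest.flag_failed_pairs(tiny_sheet, detp)
        assert out.loc["p1_case", "qc_fail"] and out.loc["p1_control", "qc_fail"]
        assert not out.loc["p0_case", "qc_fail"]

    def test_none_flagged_when_clean(self, tiny_sheet, tiny_beta):
        detp = pd.DataFrame(
            0.001, index=tiny_beta.index, columns=tiny_beta.columns
        )
        out = ingest.flag_failed_pairs(tiny_sheet, detp)
        assert not out["qc_fail"].any()

    def test_missing_detp_noop(self, tiny_sheet):
        out = ingest.flag_failed_pairs(tiny_sheet, None)
        assert not out["qc_fail"].any()


class TestReadInputs:
    def test_fixture_roundtrip(self, tmp_path, small_cfg, small_cohort):
        paths = simulate_fixture(small_cfg, tmp_path)
        beta, sheet, manifest, _ = ingest.read_inputs(
            paths["beta"], paths["sheet"], paths["manifest"]
        )
        orig = small_cohort["beta"]
        assert beta.shape == orig.shape
        np.testing.assert_allclose(
            beta.to_numpy(), orig.to_numpy(), atol=5e-7
        )
        assert list(sheet.index) == list(orig.columns)
        assert list(manifest.index) == list(orig.index)

    def test_subject_missing_from_sheet_dropped(self, tmp_path, small_cfg,
                                                caplog):
        paths = simulate_fixture(small_cfg, tmp_path)
        sheet = pd.read_csv(paths["sheet"])
        # drop one full pair from the sheet; its subjects must be dropped
        sheet = sheet[sheet["pair_id"] != "pair000"]
        sheet.to_csv(paths["sheet"], index=False)
        with caplog.at_level("WARNING", logger="twinewas"):
            beta, sheet_out, _, _ = ingest.read_inputs(
                paths["beta"], paths["sheet"], paths["manifest"]
            )
        assert "pair000_case" not in beta.columns
        assert any("dropping" in r.message for r in caplog.records)
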