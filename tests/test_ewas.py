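"""Conditional logistic regression: oracles, contracts, calibration."""

import numpy as np
import pandas as pd
import pytest

from twinewas.ewas import (
    CovariateSpec,
    build_design,
    fit_conditional_logistic,
    fit_single,
    run_ewas,
)
from twinewas.ingest import beta_to_m


def conditional_loglik(b, d):
    return float(-np.logaddexp(0.0, -(d * b)).sum())


def grid_maximizer(d, lo=-20.0, hi=20.0, step=1e-3):
    """Dense grid-search oracle for the single-covariate likelihood."""
    grid = np.arange(lo, hi + step, step)
    eta = np.outer(grid, d)
    ll = -np.logaddexp(0.0, -eta).sum(axis=1)
    return float(grid[np.argmax(ll)])


class TestFitSingle:
    def test_symmetric_differences_give_zero(self):
        b, se, status, _ = fit_single(np.array([[1.0], [-1.0]]))
        assert status == "ok"
        assert b[0] == pytest.approx(0.0, abs=1e-8)
        z = b[0] / se[0]
        assert 2 * (1 - 0.5) == 1.0 and abs(z) < 1e-8  # p = 1 at z = 0

    def test_monotone_likelihood_flagged_separated(self):
        _, _, status, _ = fit_single(np.array([[1.0], [1.0], [1.0]]))
        assert status == "separated"

    def test_all_zero_methylation_degenerate(self):
        _, _, status, _ = fit_single(np.zeros((5, 1)))
        assert status == "degenerate"

    def test_brute_force_example(self):
        d = np.array([0.5, 1.0, -0.2, 0.3, -0.1])
        b, _, status, _ = fit_single(d[:, None])
        assert status == "ok"
        assert abs(b[0] - grid_maximizer(d)) < 2e-3

    @pytest.mark.parametrize("seed", range(25))
    def test_grid_search_oracle_equivalence(self, seed):
        """Newton matches a dense grid maximizer on random 10-pair data."""
        rng = np.random.default_rng(seed)
        d = rng.normal(0.1, 0.8, size=10)
        if np.all(d > 0) or np.all(d < 0):
            d[0] = -d[0]  # keep the likelihood bounded
        b, _, status, _ = fit_single(d[:, None])
        assert status == "ok"
        assert abs(b[0] - grid_maximizer(d)) < 2e-3

    def test_sign_contract(self):
        """Non-negative differences with at least one positive give a
        non-negative estimate or the separated flag."""
        rng = np.random.default_rng(1)
        for _ in range(10):
            d = np.abs(rng.normal(0.3, 0.5, size=8))
            d[rng.integers(0, 8)] = 0.0
            b, _, status, _ = fit_single(d[:, None])
            assert status == "separated" or b[0] >= 0

    def test_reduction_identity_against_statsmodels(self):
        """The 1:1 conditional likelihood equals statsmodels' conditional
        logit on the expanded two-rows-per-pair data."""
        from statsmodels.discrete.conditional_models import ConditionalLogit

        rng = np.random.default_rng(3)
        n = 30
        X = np.column_stack([
            rng.normal(0, 0.7, n), rng.normal(0, 0.5, n)
        ])
        y = np.tile([1.0, 0.0], n)
        X_long = np.repeat(X, 2, axis=0)
        X_long[1::2] = 0.0
        groups = np.repeat(np.arange(n), 2)
        sm_fit = ConditionalLogit(y, X_long, groups=groups).fit(disp=False)
        b, se, status, _ = fit_single(X)
        assert status == "ok"
        np.testing.assert_allclose(b, sm_fit.params, atol=1e-4)
        np.testing.assert_allclose(se, sm_fit.bse, atol=1e-4)


class TestBuildDesign:
    def test_pair_constant_covariate_dropped(self, small_cohort, caplog):
        mvals = beta_to_m(small_cohort["beta"])
        with caplog.at_level("INFO", logger="twinewas"):
            _, cov = build_design(
                mvals, small_cohort["sheet"],
                spec=CovariateSpec(sheet_columns=("plate", "sex")),
            )
        assert not any(c.startswith("sex") for c in cov.columns)

    def test_plate_difference_coding(self, tiny_sheet, tiny_beta):
        mvals = beta_to_m(tiny_beta)
        dm, cov = build_design(mvals, tiny_sheet)
        # case on plate1 (reference), control on plate2: indicator diff -1
        assert cov["plate_plate2"].tolist() == [-1.0, -1.0, -1.0]

    def test_methylation_difference_matches_delta(self, tiny_sheet, tiny_beta):
        mvals = beta_to_m(tiny_beta)
        dm, _ = build_design(mvals, tiny_sheet)
        expected = mvals["p0_case"] - mvals["p0_control"]
        np.testing.assert_allclose(dm["p0"].to_numpy(), expected.to_numpy())

    def test_cell_reference_type_excluded(self, small_cohort):
        from twinewas.deconvolution import estimate_proportions

        props = estimate_proportions(small_cohort["beta"],
                                     small_cohort["ref"])
        mvals = beta_to_m(small_cohort["beta"])
        _, cov = build_design(mvals, small_cohort["sheet"], props)
        assert "Gran" not in cov.columns
        assert {"B", "CD4T", "CD8T", "Mono", "NK", "nRBC"} <= set(cov.columns)


class TestBatchedFit:
    def test_matches_scalar_path(self):
        rng = np.random.default_rng(8)
        n_probes, n_pairs, q = 40, 15, 2
        D = rng.normal(0.05, 0.6, size=(n_probes, n_pairs))
        C = rng.normal(0, 0.4, size=(n_pairs, q))
        dm = pd.DataFrame(D)
        cov = pd.DataFrame(C)
        res = fit_conditional_logistic(dm, cov)
        for j in range(n_probes):
            X = np.column_stack([D[j], C])
            b, se, status, _ = fit_single(X)
            assert res["status"].iloc[j] == status
            if status == "ok":
                assert res["coef"].iloc[j] == pytest.approx(b[0], abs=1e-6)
                assert res["se"].iloc[j] == pytest.approx(se[0], abs=1e-6)

    def test_degenerate_row_flagged(self):
        D = np.array([[0.0, 0.0, 0.0], [0.5, -0.2, 0.1]])
        res = fit_conditional_logistic(
            pd.DataFrame(D), pd.DataFrame(index=range(3))
        )
        assert res["status"].tolist() == ["degenerate", "ok"]
        assert np.isnan(res["p"].iloc[0])

    def test_parameter_recovery_under_model(self):
        """Consistency: data generated from the conditional logistic model
        with coefficient delta are recovered within 15% at 200 pairs."""
        rng = np.random.default_rng(12)
        delta, n_pairs, n_probes = 0.8, 200, 300
        coefs = []
        V = rng.normal(0, 1.0, size=(n_probes, n_pairs))
        # label the pair's case by the logistic probability sigma(delta * v)
        flip = rng.random((n_probes, n_pairs)) > (
            1.0 / (1.0 + np.exp(-delta * V))
        )
        D = np.where(flip, -V, V)
        res = fit_conditional_logistic(
            pd.DataFrame(D), pd.DataFrame(index=range(n_pairs))
        )
        ok = res["status"] == "ok"
        mean_b = res.loc[ok, "coef"].mean()
        assert abs(mean_b - delta) / delta < 0.15


class TestRunEwas:
    def test_full_table_contract(self, small_cohort):
        res = run_ewas(small_cohort["beta"], small_cohort["sheet"])
        assert set(res.columns) >= {
            "coef", "se", "z", "p", "q", "status", "mean_beta",
            "mean_delta_beta",
        }
        ok = res["status"] == "ok"
        # q is only defined for testable probes and never below p
        assert res.loc[~ok, "q"].isna().all()
        assert (res.loc[ok, "q"] >= res.loc[ok, "p"] - 1e-12).all()
        assert np.isfinite(res.loc[ok, "coef"]).all()

    def test_planted_hypomethylation_shifts_coefficients(self, small_cohort):
        res = run_ewas(small_cohort["beta"], small_cohort["sheet"])
        rel = small_cohort["manifest"]["island_relation"]
        ok = res["status"] == "ok"
        opensea = res.loc[ok & (rel == "OpenSea").to_numpy(), "coef"]
        # planted open-sea case effect is negative on average
        assert opensea.mean() < 0
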