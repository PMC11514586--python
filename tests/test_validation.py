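"""Validation statistics on hand-computed vectors, leverage oracles and the
model-acceptance criteria checklist."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grindqsar.validation import (ValidationReport, applicability_domain,
                                  criteria_flags, critical_leverage,
                                  external_validation, internal_validation,
                                  leverages)

# printed headline statistics of the two kinase-inhibition QSAR models this
# package's checklist mirrors (ROCK1-like and ROCK2-like reference rows)
REFERENCE_REPORTS = [
    ValidationReport(r2=0.914, q2=0.59, rmsee=0.393, r2_pred=0.792,
                     rmsep=0.561, rm2=0.759, rm2_prime=0.573, rm2_mean=0.666,
                     delta_rm2=0.186, ratio_r0p2=0.099, k_prime=0.974),
    ValidationReport(r2=0.933, q2=0.54, rmsee=0.327, r2_pred=0.851,
                     rmsep=0.499, rm2=0.753, rm2_prime=0.616, rm2_mean=0.684,
                     delta_rm2=0.137, ratio_r0p2=0.032, k_prime=0.963),
]


class TestInternalValidation:
    def test_perfect_fit(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        rep = internal_validation(y, y, press_from_loo=0.0)
        assert rep.r2 == pytest.approx(1.0)
        assert rep.press == 0.0 and rep.rmsee == 0.0

    def test_press_and_rmsee_arithmetic(self):
        e = np.array([0.1, -0.1, 0.0])
        press = float(np.sum(e ** 2))
        rep = internal_validation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], press)
        assert rep.press == pytest.approx(0.02)
        assert rep.rmsee == pytest.approx(np.sqrt(0.02 / 3), abs=1e-10)
        assert rep.rmsee == pytest.approx(0.0816, abs=1e-4)

    def test_r2_literal_formula(self):
        # R2 = sum((yhat-ybar)^2)/sum((y-ybar)^2) = 1.62/2 = 0.81
        rep = internal_validation([1.0, 2.0, 3.0], [1.1, 2.0, 2.9], 0.0)
        assert rep.r2 == pytest.approx(0.81, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            internal_validation([2.0, 2.0, 2.0], [2.0, 2.1, 1.9], 0.1)


class TestExternalValidation:
    def test_identity_predictions(self):
        y = np.array([4.0, 5.0, 6.0, 7.5, 8.0])
        rep = external_validation(y, y, ybar_train=6.0)
        assert rep.r2_pred == pytest.approx(1.0)
        assert rep.rm2 == pytest.approx(1.0)
        assert rep.rm2_prime == pytest.approx(1.0)
        assert rep.delta_rm2 == pytest.approx(0.0)
        assert rep.k_prime == pytest.approx(1.0)

    def test_constant_prediction_gives_zero_r2pred(self):
        y = np.array([4.0, 5.0, 6.0])
        rep = external_validation(y, np.full(3, 5.0), ybar_train=5.0)
        assert rep.r2_pred == pytest.approx(0.0)

    def test_generic_vector_against_independent_recomputation(self):
        y = np.array([4.2, 5.0, 5.8, 6.4, 7.1, 8.0])
        yhat = np.array([4.5, 4.8, 6.1, 6.2, 7.5, 7.6])
        ybar = 5.9
        rep = external_validation(y, yhat, ybar)
        # second, independent implementation of the published formulas
        r2 = np.corrcoef(y, yhat)[0, 1] ** 2
        k = (y @ yhat) / (y @ y)
        kp = (y @ yhat) / (yhat @ yhat)
        r02 = 1 - ((yhat - k * y) ** 2).sum() / ((yhat - yhat.mean()) ** 2).sum()
        r0p2 = 1 - ((y - kp * yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        rm2 = r2 * (1 - np.sqrt(r2 - r02))
        rm2p = r2 * (1 - np.sqrt(r2 - r0p2))
        assert rep.r2_pred == pytest.approx(
            1 - ((y - yhat) ** 2).sum() / ((y - ybar) ** 2).sum(), abs=1e-12)
        assert rep.rmsep == pytest.approx(
            np.sqrt(((y - yhat) ** 2).mean()), abs=1e-12)
        assert rep.r2_test == pytest.approx(r2, abs=1e-12)
        assert rep.k == pytest.approx(k, abs=1e-12)
        assert rep.k_prime == pytest.approx(kp, abs=1e-12)
        assert rep.rm2 == pytest.approx(rm2, abs=1e-12)
        assert rep.rm2_prime == pytest.approx(rm2p, abs=1e-12)
        assert rep.rm2_mean == pytest.approx((rm2 + rm2p) / 2, abs=1e-12)
        assert rep.delta_rm2 == pytest.approx(abs(rm2 - rm2p), abs=1e-12)
        assert rep.ratio_r0p2 == pytest.approx((r2 - r0p2) / r2, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_swapping_axes_swaps_rm2_metrics(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.uniform(3, 9, size=6)
        yhat = y + rng.normal(0, 0.5, size=6)
        a = external_validation(y, yhat, ybar_train=y.mean())
        b = external_validation(yhat, y, ybar_train=y.mean())
        assert a.rm2 == pytest.approx(b.rm2_prime, abs=1e-12)
        assert a.rm2_prime == pytest.approx(b.rm2, abs=1e-12)
        assert a.k == pytest.approx(b.k_prime, abs=1e-12)


class TestLeverage:
    def test_h_star_arithmetic(self):
        assert critical_leverage(34, 10) == pytest.approx(3 * 11 / 34)
        assert critical_leverage(34, 10) == pytest.approx(0.9706, abs=1e-4)

    def test_centroid_query_has_minimum_leverage(self, rng):
        X = rng.normal(size=(20, 4))
        h = leverages(X, X.mean(axis=0))
        assert h[0] == pytest.approx(1 / 20, abs=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_explicit_hat_matrix(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 6))
        h = leverages(X)
        Xa = np.column_stack([np.ones(20), X])
        H = Xa @ np.linalg.solve(Xa.T @ Xa, Xa.T)
        np.testing.assert_allclose(h, np.diag(H), atol=1e-8)
        assert h.sum() == pytest.approx(7.0, abs=1e-8)  # trace = p+1

    def test_singular_covariance_uses_pseudoinverse(self, rng, caplog):
        X = rng.normal(size=(10, 3))
        X = np.column_stack([X, X[:, 0]])  # rank deficient
        with caplog.at_level("WARNING"):
            h = leverages(X)
        assert np.all(np.isfinite(h))
        assert "pseudoinverse" in caplog.text


class TestApplicabilityDomain:
    def test_outlier_flags(self, rng):
        X = rng.normal(size=(15, 3))
        std_resid = np.zeros(15)
        std_resid[4] = 3.5  # residual outlier
        wd = applicability_domain(X, [f"m{i}" for i in range(15)], std_resid)
        assert "m4" in wd.outlier_ids
        assert wd.h_star == pytest.approx(critical_leverage(15, 3))
        # high-leverage query lands outside the domain
        far = X.mean(axis=0) + 50 * X.std(axis=0)
        wd2 = applicability_domain(X, [f"m{i}" for i in range(15)], std_resid,
                                   X_test=far[None, :], ids_test=["query"],
                                   std_residuals_test=np.zeros(1))
        assert "query" in wd2.outlier_ids

    def test_csv_round_trip(self, rng, tmp_path):
        import pandas as pd
        X = rng.normal(size=(10, 2))
        wd = applicability_domain(X, [f"m{i}" for i in range(10)], np.zeros(10))
        path = tmp_path / "williams.csv"
        wd.to_csv(path, config_hash="abc")
        back = pd.read_csv(path, comment="#")
        assert len(back) == 10
        assert set(back.columns) >= {"id", "leverage", "std_residual",
                                     "set", "outside_ad"}


class TestCriteriaFlags:
    @pytest.mark.parametrize("report", REFERENCE_REPORTS)
    def test_reference_models_pass_all(self, report):
        flags = criteria_flags(report)
        assert flags["valid"]
        assert all(flags.values())

    def test_strict_inequalities(self):
        base = REFERENCE_REPORTS[0]
        from dataclasses import replace
        assert not criteria_flags(replace(base, delta_rm2=0.2))["delta_rm2_lt_0.2"]
        assert not criteria_flags(replace(base, q2=0.5))["q2_gt_0.5"]
        assert not criteria_flags(replace(base, r2=0.9))["r2_gt_0.9"]
        assert criteria_flags(replace(base, k_prime=0.85))["k_prime_in_0.85_1.15"]

    def test_rmsep_vs_rmsee_coupling(self):
        from dataclasses import replace
        bad = replace(REFERENCE_REPORTS[0], rmsep=0.79)  # > 2 * 0.393
        assert not criteria_flags(bad)["rmsep_le_2rmsee"]
        assert not criteria_flags(bad)["valid"]
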