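"""PLS fitting, LOO cross-validation and internal statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from qsar3d.fields import ColumnMeta
from qsar3d.pls_model import (
    field_contributions,
    fit_pls,
    internal_stats,
    load_model,
    loo_q2,
    save_model,
    select_components,
)

from conftest import loo_q2_bruteforce, nipals_predict


def _meta(p, kind="steric"):
    return [ColumnMeta("comsia", kind, i) for i in range(p)]


def _linear_data(n=20, p=8, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + rng.normal(scale=noise, size=n)
    return X, y


class TestFitPls:
    def test_exact_linear_system_fit(self):
        X, y = _linear_data(n=20, p=5)
        model = fit_pls(X, y, 5, scaling="none")
        assert np.allclose(model.predict(X), y, atol=1e-8)

    def test_single_component_coefficient_sign(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        X = np.column_stack([x, rng.normal(scale=0.01, size=30)])
        y = 2.0 * x + rng.normal(scale=0.1, size=30)
        model = fit_pls(X, y, 1, scaling="none")
        assert np.sign(model.coefficients[0]) == np.sign(np.corrcoef(x, y)[0, 1])

    def test_matches_independent_nipals_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(20, 50))
        y = rng.normal(size=20)
        X_new = rng.normal(size=(6, 50))
        model = fit_pls(X, y, 5, scaling="none")
        assert np.allclose(
            model.predict(X_new), nipals_predict(X, y, X_new, 5), atol=1e-8
        )

    def test_full_rank_equals_least_squares(self):
        X, y = _linear_data(n=15, p=6, noise=0.3, seed=4)
        model = fit_pls(X, y, 6, scaling="none")
        Xc = np.column_stack([np.ones(len(y)), X])
        beta, *_ = np.linalg.lstsq(Xc, y, rcond=None)
        assert np.allclose(model.predict(X), Xc @ beta, atol=1e-8)

    def test_rank_deficiency_errors(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(10, 2))
        X = np.column_stack([base, base @ rng.normal(size=(2, 3))])  # rank 2
        y = rng.normal(size=10)
        with pytest.raises(ValueError, match="fewer components"):
            fit_pls(X, y, 4, scaling="none")

    def test_too_few_samples_errors(self):
        X, y = _linear_data(n=4, p=3)
        with pytest.raises(ValueError, match="samples"):
            fit_pls(X, y, 3)

    def test_block_scaling_invariance(self):
        # multiplying one block by a constant must not change predictions
        rng = np.random.default_rng(9)
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        block_ids = np.array([0] * 5 + [1] * 5)
        X2 = X.copy()
        X2[:, 5:] *= 137.0
        m1 = fit_pls(X, y, 3, block_ids=block_ids, scaling="block")
        m2 = fit_pls(X2, y, 3, block_ids=block_ids, scaling="block")
        assert np.allclose(m1.predict(X), m2.predict(X2), atol=1e-8)

    def test_round_trip_serialization(self, tmp_path):
        X, y = _linear_data(n=12, p=4, noise=0.1)
        model = fit_pls(X, y, 2, metadata=_meta(4))
        save_model(model, str(tmp_path / "m"))
        back = load_model(str(tmp_path / "m"))
        assert np.allclose(back.predict(X), model.predict(X), atol=1e-12)
        assert back.metadata == model.metadata


class TestLooQ2:
    def test_perfect_linear_system(self):
        X, y = _linear_data(n=12, p=3)
        q2, press = loo_q2(X, y, 3, scaling="none")
        assert q2 == pytest.approx(1.0, abs=1e-8)
        assert press == pytest.approx(0.0, abs=1e-8)

    @pytest.mark.parametrize("n,p,k", [(8, 3, 2), (15, 10, 3), (25, 40, 5)])
    def test_matches_bruteforce_refit_oracle(self, n, p, k):
        rng = np.random.default_rng(n * p + k)
        X = rng.normal(size=(n, p))
        y = X[:, 0] * 1.5 + rng.normal(scale=0.5, size=n)
        q2, press = loo_q2(X, y, k, scaling="none")
        q2_ref, press_ref = loo_q2_bruteforce(X, y, k)
        assert q2 == pytest.approx(q2_ref, abs=1e-10)
        assert press == pytest.approx(press_ref, abs=1e-10)

    def test_hand_computable_single_column(self):
        # n = 4, one descriptor: each fold is univariate least squares
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([0.1, 0.9, 2.2, 3.9])
        press = 0.0
        for i in range(4):
            m = np.ones(4, bool)
            m[i] = False
            b = np.cov(x[m], y[m], ddof=1)[0, 1] / np.var(x[m], ddof=1)
            a = y[m].mean() - b * x[m].mean()
            press += (y[i] - (a + b * x[i])) ** 2
        q2_expected = 1 - press / ((y - y.mean()) ** 2).sum()
        q2, _ = loo_q2(x[:, None], y, 1, scaling="none")
        assert q2 == pytest.approx(q2_expected, abs=1e-10)

    def test_zero_variance_errors(self):
        X = np.random.default_rng(0).normal(size=(6, 2))
        with pytest.raises(ValueError, match="variance"):
            loo_q2(X, np.ones(6), 1)

    @given(st.floats(-5, 5), st.floats(0.1, 10))
    def test_invariant_under_positive_affine_y(self, a, b):
        X, y = _linear_data(n=14, p=4, noise=0.5, seed=21)
        q2_base, _ = loo_q2(X, y, 2, scaling="none")
        q2_aff, _ = loo_q2(X, a + b * y, 2, scaling="none")
        assert q2_aff == pytest.approx(q2_base, abs=1e-9)


class TestSelectComponents:
    def test_single_column_gives_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        y = x + rng.normal(scale=0.1, size=12)
        pcs, profile = select_components(x[:, None], y, 5, scaling="none")
        assert pcs == 1 and len(profile) == 1

    def test_parsimony_rule_picks_smallest_within_tol(self):
        # strong 2-factor signal: q2 plateaus after 2 components
        rng = np.random.default_rng(6)
        T = rng.normal(size=(40, 2))
        X = T @ rng.normal(size=(2, 20)) + rng.normal(scale=1e-4, size=(40, 20))
        y = T @ np.array([1.0, -0.7])
        pcs, profile = select_components(X, y, 6, scaling="none")
        assert pcs == 2
        assert profile[1] >= max(profile) - 0.005

    def test_planted_three_factor_recovery(self):
        rng = np.random.default_rng(17)
        T = rng.normal(size=(50, 3))
        X = T @ rng.normal(size=(3, 30)) + rng.normal(scale=0.01, size=(50, 30))
        y = T @ np.array([1.0, 0.8, -0.6]) + rng.normal(scale=0.05, size=50)
        pcs, _ = select_components(X, y, 7, scaling="none")
        assert pcs in (3, 4)


class TestInternalStats:
    def test_perfect_fit(self):
        X, y = _linear_data(n=16, p=4)
        model = fit_pls(X, y, 4, scaling="none")
        stats = internal_stats(model, X, y)
        assert stats.r_ncv2 == pytest.approx(1.0, abs=1e-10)
        assert stats.see == pytest.approx(0.0, abs=1e-8)
        assert stats.f_value == np.inf

    def test_see_arithmetic(self):
        # n=10, pcs=2, SS_res=0.9 -> SEE = sqrt(0.9/7)
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 5))
        y = rng.normal(size=10)
        model = fit_pls(X, y, 2, scaling="none")
        stats = internal_stats(model, X, y)
        ss_res = ((y - model.predict(X)) ** 2).sum()
        assert stats.see == pytest.approx(np.sqrt(ss_res / 7), abs=1e-12)
        r2 = stats.r_ncv2
        assert stats.f_value == pytest.approx((r2 / 2) / ((1 - r2) / 7), abs=1e-9)

    def test_constant_prediction_reports_zero_with_warning(self):
        X, y = _linear_data(n=10, p=3, noise=1.0, seed=5)
        model = fit_pls(X, y, 1, scaling="none")
        model.coefficients = np.zeros_like(model.coefficients)  # degenerate
        with pytest.warns(UserWarning, match="constant"):
            stats = internal_stats(model, X, y)
        assert stats.r_ncv2 == 0.0


class TestFieldContributions:
    def test_single_block_is_unity(self):
        X, y = _linear_data(n=12, p=4, noise=0.1)
        model = fit_pls(X, y, 2, metadata=_meta(4))
        contribs = field_contributions(model, X, _meta(4))
        assert contribs == {"steric": pytest.approx(1.0)}

    def test_duplicated_block_splits_evenly(self):
        X, y = _linear_data(n=14, p=3, noise=0.2, seed=8)
        X2 = np.hstack([X, X])
        meta = _meta(3, "steric") + _meta(3, "electrostatic")
        block_ids = np.array([0, 0, 0, 1, 1, 1])
        model = fit_pls(X2, y, 2, block_ids=block_ids, scaling="block", metadata=meta)
        contribs = field_contributions(model, X2, meta)
        assert contribs["steric"] == pytest.approx(0.5, abs=1e-9)
        assert contribs["electrostatic"] == pytest.approx(0.5, abs=1e-9)
        assert sum(contribs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_model_errors(self):
        X, y = _linear_data(n=10, p=3, noise=0.1)
        model = fit_pls(X, y, 1, metadata=_meta(3))
        model.coefficients = np.zeros_like(model.coefficients)
        with pytest.raises(ValueError, match="zero"):
            field_contributions(model, X, _meta(3))
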