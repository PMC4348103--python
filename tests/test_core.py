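import math

import numpy as np
import pytest
import scipy.optimize

from dipr.core import (
    block_scales,
    default_w_grid,
    dipr_fit,
    dipr_search,
    effective_penalties,
    nested_cv_evaluate,
    scale_blocks,
)
from dipr.errors import AllUndefinedError, WOutOfRangeError
from dipr.ridge import loo_evaluate, ridge_fit


def random_blocks(rng, n=12, m1=8, m2=6):
    return rng.standard_normal((n, m1)), rng.standard_normal((n, m2)), \
        rng.standard_normal(n)


class TestScaleBlocks:
    def test_w_one_zeros_second_block(self, rng):
        X1, X2, _ = random_blocks(rng)
        combined = scale_blocks(X1, X2, 1.0, "sqrt-w")
        np.testing.assert_array_equal(combined[:, 8:], np.zeros_like(X2))
        np.testing.assert_allclose(combined[:, :8], X1)

    @pytest.mark.parametrize(
        "convention,lam_factor", [("sqrt-w", 2.0), ("paper-w", 4.0)]
    )
    def test_equal_weights_map_to_pooled_ridge(self, rng, convention, lam_factor):
        """Ridge(lam) on the w=0.5 rescaled matrix equals pooled ridge at the
        mapped penalty: 2*lam under sqrt-w scaling, 4*lam under linear-w."""
        X1, X2, y = random_blocks(rng)
        lam = 1.7
        scaled = scale_blocks(X1, X2, 0.5, convention)
        pred_scaled = scaled @ ridge_fit(scaled, y, lam).coefficients
        pooled = np.hstack([X1, X2])
        pred_pooled = pooled @ ridge_fit(pooled, y, lam_factor * lam).coefficients
        np.testing.assert_allclose(pred_scaled, pred_pooled, atol=1e-8)

    def test_w_out_of_range(self, rng):
        X1, X2, _ = random_blocks(rng)
        with pytest.raises(WOutOfRangeError):
            scale_blocks(X1, X2, 1.2)


class TestDiprFit:
    @pytest.mark.parametrize("convention", ["sqrt-w", "paper-w"])
    def test_boundary_w_reduces_to_single_block_ridge(self, rng, convention):
        X1, X2, y = random_blocks(rng)
        lam = 2.5
        top = dipr_fit(X1, X2, y, 1.0, lam, convention)
        single = ridge_fit(X1, y, lam)
        np.testing.assert_allclose(
            top.predict(X1, X2), X1 @ single.coefficients, atol=1e-12
        )
        np.testing.assert_array_equal(top.coef_block2, np.zeros(6))
        bottom = dipr_fit(X1, X2, y, 0.0, lam, convention)
        np.testing.assert_allclose(
            bottom.predict(X1, X2),
            X2 @ ridge_fit(X2, y, lam).coefficients, atol=1e-12,
        )
        np.testing.assert_array_equal(bottom.coef_block1, np.zeros(8))

    def test_minimizes_two_penalty_objective(self, rng):
        """The rescaled single-penalty fit minimizes the explicit two-penalty
        objective at the implied (lambda_a, lambda_b)."""
        X1, X2, y = random_blocks(rng, n=10, m1=5, m2=4)
        w, lam = 0.7, 1.2
        model = dipr_fit(X1, X2, y, w, lam, "sqrt-w")
        la, lb = effective_penalties(w, lam, "sqrt-w")

        def obj(b):
            b1, b2 = b[:5], b[5:]
            resid = y - X1 @ b1 - X2 @ b2
            return resid @ resid + la * (b1 @ b1) + lb * (b2 @ b2)

        res = scipy.optimize.minimize(
            obj, np.zeros(9), method="L-BFGS-B",
            options={"gtol": 1e-14, "ftol": 1e-16, "maxiter": 10_000},
        )
        fitted = np.concatenate([model.coef_block1, model.coef_block2])
        assert obj(fitted) <= res.fun + 1e-9
        np.testing.assert_allclose(fitted, res.x, atol=1e-6)

    def test_conventions_agree_at_matched_penalties(self, rng):
        """For the same (lambda_a, lambda_b), both scaling conventions give
        identical predictions."""
        X1, X2, y = random_blocks(rng)
        la, lb = 2.0, 5.0
        lam_s = 1.0 / (1.0 / la + 1.0 / lb)
        w_s = lam_s / la
        root = 1.0 / (1.0 / math.sqrt(la) + 1.0 / math.sqrt(lb))
        lam_p = root**2
        w_p = math.sqrt(lam_p / la)
        ms = dipr_fit(X1, X2, y, w_s, lam_s, "sqrt-w")
        mp = dipr_fit(X1, X2, y, w_p, lam_p, "paper-w")
        np.testing.assert_allclose(ms.penalties, (la, lb), atol=1e-10)
        np.testing.assert_allclose(mp.penalties, (la, lb), atol=1e-10)
        np.testing.assert_allclose(
            ms.predict(X1, X2), mp.predict(X1, X2), atol=1e-8
        )


class TestDiprSearch:
    def test_matches_brute_force_grid(self, rng):
        X1, X2, y = random_blocks(rng, n=14)
        w_grid = [0.0, 0.25, 0.5, 0.75, 1.0]
        lam_grid = np.geomspace(0.1, 50, 6)
        res = dipr_search(X1, X2, y, w_grid, lam_grid)
        best = -np.inf
        for w in w_grid:
            c1, c2 = block_scales(w, "sqrt-w")
            combined = np.hstack([c1 * X1, c2 * X2])
            for lam in lam_grid:
                loo = loo_evaluate(combined, y, lam)
                if loo.defined:
                    best = max(best, loo.cvc)
        assert res.loo.cvc == pytest.approx(best, abs=1e-10)

    def test_two_cell_grid_picks_better_single_block(self, rng):
        X1 = rng.standard_normal((30, 5))
        y = X1 @ rng.standard_normal(5) + 0.1 * rng.standard_normal(30)
        X2 = rng.standard_normal((30, 5))  # uninformative
        res = dipr_search(X1, X2, y, [0.0, 1.0], [1.0])
        cvc1 = loo_evaluate(X1, y, 1.0).cvc
        cvc2 = loo_evaluate(X2, y, 1.0).cvc
        assert res.w == (1.0 if cvc1 >= cvc2 else 0.0)
        assert res.loo.cvc == pytest.approx(max(cvc1, cvc2), abs=1e-10)

    def test_noise_block_pushes_w_toward_signal(self, rng):
        X1 = rng.standard_normal((50, 20))
        y = X1[:, :5] @ rng.standard_normal(5) + 0.3 * rng.standard_normal(50)
        X2 = rng.standard_normal((50, 20))
        res = dipr_search(X1, X2, y)
        assert res.w > 0.5

    def test_all_undefined_raises(self, rng):
        X1, X2, _ = random_blocks(rng)
        with pytest.raises(AllUndefinedError):
            dipr_search(X1, X2, np.zeros(12), [0.0, 0.5, 1.0], [1.0])

    def test_search_dominates_special_cases(self, rng):
        """Grid membership of w in {0, 0.5, 1} guarantees the searched CVC is
        at least that of either single block or the pooled model."""
        X1, X2, y = random_blocks(rng, n=20, m1=10, m2=7)
        lam_grid = np.geomspace(0.05, 200, 8)
        res = dipr_search(X1, X2, y, default_w_grid(), lam_grid)
        for w_special in (0.0, 0.5, 1.0):
            c1, c2 = block_scales(w_special, "sqrt-w")
            combined = np.hstack([c1 * X1, c2 * X2])
            special = max(
                loo_evaluate(combined, y, lam).cvc for lam in lam_grid
            )
            assert res.loo.cvc >= special - 1e-12


class TestNestedCv:
    def test_strong_block1_signal_recovered(self):
        rng = np.random.default_rng(7)
        n, m = 40, 10
        X1 = rng.standard_normal((n, m))
        y = X1 @ rng.standard_normal(m)  # noiseless, block 1 only
        X2 = rng.standard_normal((n, 8))
        res = nested_cv_evaluate(
            X1, X2, y, "dipr",
            w_grid=default_w_grid(0.1),
            lambda_grid=np.geomspace(1e-3, 1e2, 10),
        )
        assert res.status == "ok"
        assert res.cvc > 0.95
        assert res.mean_w > 0.8

    def test_null_trait_cvc_centered_near_zero(self):
        cvcs = []
        for seed in range(30):
            rng = np.random.default_rng(1000 + seed)
            X1 = rng.standard_normal((24, 6))
            X2 = rng.standard_normal((24, 5))
            y = rng.standard_normal(24)
            res = nested_cv_evaluate(
                X1, X2, y, "dipr",
                w_grid=[0.0, 0.5, 1.0],
                lambda_grid=np.geomspace(0.1, 100, 5),
            )
            if res.status == "ok":
                cvcs.append(res.cvc)
        assert abs(np.mean(cvcs)) < 0.15

    def test_pooled_equals_dipr_with_half_weight_grid(self):
        rng = np.random.default_rng(3)
        X1 = rng.standard_normal((16, 6))
        X2 = rng.standard_normal((16, 4))
        y = X1[:, 0] + rng.standard_normal(16)
        lam_grid = np.geomspace(0.1, 100, 6)
        pooled = nested_cv_evaluate(X1, X2, y, "pooled", lambda_grid=lam_grid)
        restricted = nested_cv_evaluate(
            X1, X2, y, "dipr", w_grid=[0.5], lambda_grid=lam_grid
        )
        np.testing.assert_array_equal(
            pooled.oof_predictions, restricted.oof_predictions
        )
        assert pooled.cvc == restricted.cvc

    def test_constant_trait_reports_failed(self):
        rng = np.random.default_rng(5)
        X1 = rng.standard_normal((12, 4))
        X2 = rng.standard_normal((12, 3))
        res = nested_cv_evaluate(
            X1, X2, np.full(12, 3.0), "dipr",
            w_grid=[0.0, 1.0], lambda_grid=[1.0, 10.0],
        )
        assert res.status == "failed"
        assert np.isnan(res.cvc)
        # fold-level outputs are still returned
        assert res.oof_predictions.shape == (12,)

    def test_full_data_standardization_mode_runs(self, rng):
        X1, X2, y = random_blocks(rng, n=15)
        res = nested_cv_evaluate(
            X1, X2, y, "dipr", w_grid=[0.0, 0.5, 1.0],
            lambda_grid=[0.5, 5.0], standardization_mode="full-data",
        )
        assert res.oof_predictions.shape == (15,)
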