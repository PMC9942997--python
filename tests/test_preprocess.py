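"""Box-Cox, PCA screen, scaling and the cross-validation plan."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fungicast import (
    ScalerParams,
    boxcox_mle,
    boxcox_transform,
    inv_boxcox_transform,
    make_cv_plan,
    pca_outlier_screen,
)
from fungicast.errors import DegenerateDataError, DomainError


def brute_force_boxcox_llf(x, lam):
    """Independent profile log-likelihood, written out from the definition:
    llf(λ) = (λ−1)·Σ ln x − n/2 · ln(σ̂²(λ)) with σ̂² the MLE variance of the
    transformed data."""
    x = np.asarray(x, float)
    n = x.size
    y = np.log(x) if lam == 0 else (x**lam - 1) / lam
    var = y.var()  # MLE variance (ddof=0)
    return (lam - 1) * np.log(x).sum() - n / 2 * np.log(var)


class TestBoxCox:
    def test_log_limit(self):
        assert np.allclose(boxcox_transform([1, 2, 4], 0.0), [0, np.log(2), np.log(4)])

    def test_identity_minus_one(self):
        assert np.allclose(boxcox_transform([1, 2, 4], 1.0), [0, 1, 3])

    def test_closed_form_lambda_two(self):
        assert boxcox_transform([3.0], 2.0)[0] == pytest.approx(4.0)

    def test_continuity_at_zero(self):
        x = np.array([0.5, 1.7, 3.2])
        assert np.allclose(boxcox_transform(x, 1e-9), boxcox_transform(x, 0.0), atol=1e-7)

    def test_inverse_round_trip(self):
        x = np.array([0.2, 1.0, 7.5, 40.0])
        for lam in (-1.3, 0.0, 0.5, 2.0):
            assert np.allclose(inv_boxcox_transform(boxcox_transform(x, lam), lam), x)

    def test_requires_positive(self):
        with pytest.raises(DomainError):
            boxcox_transform([1.0, 0.0], 0.5)

    def test_mle_recovers_lognormal(self):
        rng = np.random.default_rng(5)
        x = np.exp(rng.normal(1.0, 0.5, size=500))
        fit = boxcox_mle(x)
        assert abs(fit.lam - 0.0) <= 0.15

    def test_mle_recovers_identity_for_shifted_gaussian(self):
        rng = np.random.default_rng(6)
        x = rng.normal(50.0, 5.0, size=500)
        assert (x > 0).all()
        fit = boxcox_mle(x)
        assert abs(fit.lam - 1.0) <= 0.3

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_mle_matches_brute_force_grid(self, seed):
        """The fitted λ equals the arg-max of an independently written
        likelihood evaluated on the same grid."""
        rng = np.random.default_rng(seed)
        x = rng.gamma(shape=2.0 + seed, scale=3.0, size=80)
        fit = boxcox_mle(x)
        grid = np.linspace(-5, 5, 1001)
        llf = np.array([brute_force_boxcox_llf(x, lam) for lam in grid])
        assert fit.lam == pytest.approx(grid[np.argmax(llf)], abs=1e-12)
        assert fit.log_likelihood == pytest.approx(llf.max(), rel=1e-9)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            boxcox_mle([3.0, 3.0, 3.0, 3.0])


class TestPCAOutlierScreen:
    def test_no_flags_on_default_synthetic(self, synth_dataset):
        """Matches the observed study behavior: no outliers in the dataset."""
        cols = ["srp_days", "dphf_days", "dffh_days", "yield_g", "be_pct", "tcp_days"]
        flags, _ = pca_outlier_screen(synth_dataset.frame[cols].to_numpy())
        assert flags.sum() == 0

    def test_gross_outlier_flagged(self, synth_dataset):
        cols = ["srp_days", "dphf_days", "dffh_days", "yield_g", "be_pct", "tcp_days"]
        X = synth_dataset.frame[cols].to_numpy().copy()
        X[17] += 10 * X.std(axis=0)
        flags, dist = pca_outlier_screen(X)
        assert flags[17]
        assert dist[17] == dist.max()

    def test_pure_jitter_yields_no_flags(self):
        rng = np.random.default_rng(8)
        X = np.full((40, 5), 3.0) + rng.normal(0, 1e-9, size=(40, 5))
        flags, _ = pca_outlier_screen(X)
        assert flags.sum() == 0

    def test_needs_three_records(self):
        with pytest.raises(DomainError):
            pca_outlier_screen(np.ones((2, 3)))


class TestScaler:
    def test_endpoints_map_to_unit_interval(self):
        X = np.array([[2.0, 10.0], [4.0, 30.0], [3.0, 20.0]])
        sc = ScalerParams.fit(X)
        Z = sc.transform(X)
        assert Z.min(axis=0) == pytest.approx([-1, -1])
        assert Z.max(axis=0) == pytest.approx([1, 1])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_round_trip_identity(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 3)) * rng.uniform(0.5, 50)
        sc = ScalerParams.fit(X)
        assert np.allclose(sc.inverse_transform(sc.transform(X)), X, atol=1e-12)

    def test_out_of_range_passes_unclipped(self):
        sc = ScalerParams.fit(np.array([[0.0], [10.0]]))
        assert sc.transform(np.array([[15.0]]))[0, 0] == pytest.approx(2.0)

    def test_constant_column_named(self):
        with pytest.raises(DegenerateDataError, match="width"):
            ScalerParams.fit(np.array([[1.0, 5.0], [2.0, 5.0]]), columns=("depth", "width"))

    def test_no_leakage_from_held_out_records(self):
        """Scaler parameters are a function of the training partition only."""
        rng = np.random.default_rng(3)
        X = rng.uniform(0, 100, size=(30, 4))
        train = np.arange(20)
        sc = ScalerParams.fit(X[train])
        X_tampered = X.copy()
        X_tampered[25:] *= 100  # extreme held-out records
        sc2 = ScalerParams.fit(X_tampered[train])
        assert np.array_equal(sc.center, sc2.center)
        assert np.array_equal(sc.half, sc2.half)


class TestCVPlan:
    def test_fold_sizes_192(self):
        plan = make_cv_plan(192, seed=1)
        for rep in plan.folds:
            assert sorted(len(f) for f in rep) == [38, 38, 38, 39, 39]

    def test_partition_invariants(self):
        plan = make_cv_plan(57, seed=2)
        for rep in plan.folds:
            concat = np.concatenate(rep)
            assert len(concat) == 57
            assert len(np.unique(concat)) == 57

    def test_deterministic_in_seed(self):
        assert make_cv_plan(100, seed=4).plan_hash == make_cv_plan(100, seed=4).plan_hash
        assert make_cv_plan(100, seed=4).plan_hash != make_cv_plan(100, seed=5).plan_hash

    def test_replicates_use_distinct_permutations(self):
        plan = make_cv_plan(100, seed=1, n_replicates=10)
        first_folds = {tuple(rep[0].tolist()) for rep in plan.folds}
        assert len(first_folds) == 10

    def test_json_round_trip(self):
        plan = make_cv_plan(50, seed=9)
        from fungicast import CVPlan

        back = CVPlan.from_json(plan.to_json())
        assert back.plan_hash == plan.plan_hash

    def test_too_few_records(self):
        with pytest.raises(DomainError):
            make_cv_plan(4, seed=0)
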