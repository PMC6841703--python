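import numpy as np
import pandas as pd
import pytest

from primingkit.drivers import (
    CorrelationResult,
    coefficient_change,
    group_pc1,
    partial_correlation,
    variation_partitioning,
)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(17)


class TestPartialCorrelation:
    def test_empty_controls_is_pearson(self, rng):
        x = rng.normal(size=30)
        y = 0.6 * x + rng.normal(size=30)
        res = partial_correlation(y, x)
        assert res.r == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-14)
        assert res.df == 28

    def test_residual_on_residual_oracle(self, rng):
        """Partial r equals the correlation of OLS residuals, brute force."""
        z = rng.normal(size=(30, 2))
        x = z @ [0.5, -0.3] + rng.normal(size=30)
        y = x + z @ [0.8, 0.2] + rng.normal(size=30)
        res = partial_correlation(y, x, z)
        d = np.column_stack([np.ones(30), z])
        ry = y - d @ np.linalg.lstsq(d, y, rcond=None)[0]
        rx = x - d @ np.linalg.lstsq(d, x, rcond=None)[0]
        assert res.r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_first_order_recursive_formula(self, rng):
        """One control: r_xy.z = (r_xy - r_xz r_yz)/sqrt((1-r_xz^2)(1-r_yz^2))."""
        z = rng.normal(size=40)
        x = 0.5 * z + rng.normal(size=40)
        y = -0.4 * z + 0.6 * x + rng.normal(size=40)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_yz = np.corrcoef(y, z)[0, 1]
        expect = (r_xy - r_xz * r_yz) / np.sqrt(
            (1 - r_xz**2) * (1 - r_yz**2)
        )
        res = partial_correlation(y, x, z)
        assert res.r == pytest.approx(expect, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        z = rng.normal(size=(30, 2))
        x = z @ [1.0, 0.5] + rng.normal(size=30)
        y = 0.7 * x - z @ [0.5, 0.1] + rng.normal(size=30)
        df = pd.DataFrame({"x": x, "y": y, "z1": z[:, 0], "z2": z[:, 1]})
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
        res = partial_correlation(y, x, z)
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_control_identical_to_variable_rejected(self, rng):
        z = rng.normal(size=30)
        y = rng.normal(size=30)
        with pytest.raises(ValueError):
            partial_correlation(z, y, z)   # controls predict y exactly

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            partial_correlation([1.0, 2.0, 3.0], [2.0, 1.0, 3.0],
                                [[1.0], [2.0], [3.0]])


class TestCoefficientChange:
    @staticmethod
    def _pair(r_zero, r_ctrl):
        zero = {("x", "y"): CorrelationResult("x", "y", (), r_zero, 0.5, 30)}
        ctrl = [CorrelationResult("x", "y", ("z",), r_ctrl, 0.5, 30)]
        return coefficient_change(zero, ctrl)["pct_change"].iloc[0]

    def test_no_dependency(self):
        assert self._pair(0.6, 0.6) == pytest.approx(0.0)

    def test_eighty_percent_loss(self):
        assert self._pair(0.50, 0.10) == pytest.approx(80.0)

    def test_gain_is_negative(self):
        assert self._pair(0.30, 0.45) == pytest.approx(-50.0)

    def test_sign_ignored_through_magnitudes(self):
        assert self._pair(-0.50, 0.10) == pytest.approx(80.0)

    def test_zero_base_flagged(self):
        assert np.isnan(self._pair(0.0, 0.3))


class TestVariationPartitioning:
    def test_fractions_sum_to_full_adjusted_r2(self, rng):
        y = rng.normal(size=40)
        groups = {
            "a": rng.normal(size=(40, 2)),
            "b": rng.normal(size=(40, 3)),
            "c": rng.normal(size=(40, 1)),
            "d": rng.normal(size=(40, 2)),
        }
        pf = variation_partitioning(y, groups)
        assert sum(pf.raw.values()) == pytest.approx(pf.full_adj_r2, abs=1e-10)
        assert len(pf.raw) == 15

    def test_two_group_inclusion_exclusion_oracle(self, rng):
        """Two groups: unique and shared fractions have a closed form."""
        x1 = rng.normal(size=50)
        x2 = 0.6 * x1 + 0.8 * rng.normal(size=50)
        y = x1 + x2 + rng.normal(size=50)
        pf = variation_partitioning(y, {"g1": x1, "g2": x2})

        def adj(x):
            n, p = x.shape
            d = np.column_stack([np.ones(n), x])
            r = y - d @ np.linalg.lstsq(d, y, rcond=None)[0]
            r2 = 1 - (r @ r) / np.sum((y - y.mean()) ** 2)
            return 1 - (1 - r2) * (n - 1) / (n - p - 1)

        a = adj(x1[:, None])
        b = adj(x2[:, None])
        ab = adj(np.column_stack([x1, x2]))
        assert pf.raw[frozenset(["g1"])] == pytest.approx(ab - b, abs=1e-10)
        assert pf.raw[frozenset(["g2"])] == pytest.approx(ab - a, abs=1e-10)
        assert pf.raw[frozenset(["g1", "g2"])] == \
            pytest.approx(a + b - ab, abs=1e-10)

    def test_single_group_degenerate(self, rng):
        x = rng.normal(size=(30, 2))
        y = x @ [1.0, -0.5] + rng.normal(size=30)
        pf = variation_partitioning(y, {"only": x})
        assert pf.raw[frozenset(["only"])] == pytest.approx(pf.full_adj_r2)

    def test_noise_group_truncated_to_zero(self, rng):
        """A pure-noise group at small n draws a negative raw unique
        fraction, reported raw but truncated to zero in the headline."""
        x = rng.normal(size=(20, 2))
        y = x @ [1.0, 1.0] + 0.3 * rng.normal(size=20)
        noise = rng.normal(size=(20, 4))
        pf = variation_partitioning(y, {"signal": x, "noise": noise})
        key = frozenset(["noise"])
        assert pf.raw[key] < 0
        assert pf.truncated[key] == 0.0
        assert pf.truncated_flags[key]

    def test_collinear_columns_rejected(self, rng):
        x = rng.normal(size=30)
        with pytest.raises(ValueError, match="collinear|rank"):
            variation_partitioning(
                rng.normal(size=30),
                {"a": np.column_stack([x, 2 * x])},
            )


class TestGroupPC1:
    def test_single_column(self, rng):
        v = rng.normal(loc=5, scale=2, size=25)
        scores, var = group_pc1(v)
        z = (v - v.mean()) / v.std(ddof=1)
        assert var == pytest.approx(100.0)
        assert scores == pytest.approx(z, abs=1e-10)

    def test_perfectly_correlated_pair(self, rng):
        v = rng.normal(size=25)
        scores, var = group_pc1(np.column_stack([v, 3 * v + 1]))
        assert var == pytest.approx(100.0, abs=1e-8)

    def test_eigendecomposition_oracle(self, rng):
        x = rng.normal(size=(30, 5))
        scores, var = group_pc1(x)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        evals, evecs = np.linalg.eigh(np.corrcoef(z.T))
        ref = z @ evecs[:, -1]
        if np.corrcoef(ref, z[:, 0])[0, 1] < 0:
            ref = -ref
        assert scores == pytest.approx(ref, abs=1e-10)
        assert var == pytest.approx(100 * evals[-1] / evals.sum(), abs=1e-10)

    def test_matches_sklearn(self, rng):
        from sklearn.decomposition import PCA
        x = rng.normal(size=(30, 4))
        scores, var = group_pc1(x)
        z = (x - x.mean(0)) / x.std(0, ddof=1)
        pca = PCA(n_components=1).fit(z)
        assert var == pytest.approx(
            100 * pca.explained_variance_ratio_[0], abs=1e-8
        )
        ref = pca.transform(z)[:, 0]
        if np.corrcoef(ref, z[:, 0])[0, 1] < 0:
            ref = -ref
        # sklearn divides by n-1 consistently; scores match up to sign fix
        assert scores == pytest.approx(ref, abs=1e-8)

    def test_scores_zero_mean_and_bounds(self, rng):
        x = rng.normal(size=(30, 6))
        scores, var = group_pc1(x)
        assert abs(scores.mean()) < 1e-10
        assert 0 < var <= 100

    def test_constant_column_named(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValueError, match="constant"):
            group_pc1(x)
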