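import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from morphosize import (
    AllometryFreeResiduals,
    VariableCatalog,
    VariableDef,
    allometry_free,
    geometric_mean,
    log_shape_ratios,
    size_vector,
)

from conftest import make_table


def _abc_catalog():
    """Module-level catalog factory (hypothesis tests cannot take fixtures)."""
    return VariableCatalog(
        structure="synthetic",
        variables=(
            VariableDef("length a", "A", "linear"),
            VariableDef("length b", "B", "linear"),
            VariableDef("length c", "C", "linear"),
        ),
    )


class TestGeometricMean:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ((3.0, 3.0, 3.0), 3.0),      # equal inputs
            ((2.0, 8.0), 4.0),           # sqrt(16)
            ((1.0, 10.0, 100.0), 10.0),  # cube root of 1000
        ],
    )
    def test_hand_values(self, values, expected):
        assert geometric_mean(values) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [(1.0, 0.0), (1.0, -2.0), (1.0, np.nan)])
    def test_nonpositive_or_missing_rejected(self, bad):
        with pytest.raises(ValueError):
            geometric_mean(bad)

    def test_no_overflow_for_many_large_values(self):
        # log-space computation: the plain product would overflow
        x = np.full(400, 1e9)
        assert geometric_mean(x) == pytest.approx(1e9, rel=1e-12)


class TestLogShapeRatios:
    def test_two_variable_hand_example(self, tiny_catalog, mixed_catalog):
        table = make_table(mixed_catalog, [[2.0, 8.0, 45.0]])
        shape = log_shape_ratios(table)
        np.testing.assert_allclose(
            shape.to_array()[0],
            [-np.log(2.0), np.log(2.0), 45.0],
            atol=1e-12,
        )

    def test_equal_measurements_give_zero_shape(self, tiny_catalog):
        table = make_table(tiny_catalog, [[5.0, 5.0, 5.0]])
        assert np.allclose(log_shape_ratios(table).to_array(), 0.0)

    def test_angles_pass_through_unchanged(self, mixed_catalog):
        table = make_table(mixed_catalog, [[2.0, 8.0, 131.5], [3.0, 5.0, 12.25]])
        shape = log_shape_ratios(table)
        np.testing.assert_array_equal(shape.values["T"], [131.5, 12.25])

    def test_size_vector_matches_gm(self, random_table):
        size = size_vector(random_table)
        expected = [geometric_mean(row) for _, row in random_table.values.iterrows()]
        np.testing.assert_allclose(size.gm, expected, rtol=1e-12)
        np.testing.assert_allclose(size.log_gm, np.log(size.gm), rtol=0, atol=0)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_zero_sum_property(self, seed):
        rng = np.random.default_rng(seed)
        table = make_table(_abc_catalog(), rng.lognormal(3, 0.6, size=(8, 3)))
        sums = log_shape_ratios(table).to_array().sum(axis=1)
        assert np.all(np.abs(sums) <= 1e-10)

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 100.0))
    def test_gm_scale_equivariance(self, seed, c):
        rng = np.random.default_rng(seed)
        values = rng.lognormal(3, 0.4, size=(5, 3))
        base = make_table(_abc_catalog(), values)
        scaled = make_table(_abc_catalog(), values * c)
        np.testing.assert_allclose(
            size_vector(scaled).gm, size_vector(base).gm * c, rtol=1e-9
        )
        np.testing.assert_allclose(
            log_shape_ratios(scaled).to_array(),
            log_shape_ratios(base).to_array(),
            atol=1e-9,
        )

    def test_incomplete_table_rejected(self, tiny_catalog):
        table = make_table(tiny_catalog, [[1, 2, 3], [4, np.nan, 6]])
        with pytest.raises(ValueError, match="missing"):
            log_shape_ratios(table)


class TestAllometryFree:
    def test_perfectly_allometric_variable_has_zero_residuals(self):
        rng = np.random.default_rng(5)
        size = rng.lognormal(3, 0.5, size=10)
        X = np.column_stack([2.0 * size + 1.0, rng.lognormal(3, 0.5, 10)])
        resid = AllometryFreeResiduals().fit_transform(X, size=size)
        # exact affine dependence on size leaves zero residuals
        assert np.allclose(resid[:, 0], 0.0, atol=1e-10)

    def test_hand_least_squares_residuals(self, tiny_catalog):
        # y = (1, 2, 4) on size = (1, 2, 3): slope 1.5, intercept -2/3
        est = AllometryFreeResiduals()
        resid = est.fit_transform(
            np.array([[1.0], [2.0], [4.0]]), size=np.array([1.0, 2.0, 3.0])
        )
        np.testing.assert_allclose(
            resid[:, 0], [1 / 6, -1 / 3, 1 / 6], atol=1e-12
        )

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_residuals_zero_mean_and_size_orthogonal(self, seed):
        rng = np.random.default_rng(seed)
        table = make_table(_abc_catalog(), rng.lognormal(3, 0.5, size=(12, 3)))
        gm = size_vector(table).gm
        resid = allometry_free(table).to_array()
        assert np.all(np.abs(resid.mean(axis=0)) <= 1e-8)
        centered_gm = gm - gm.mean()
        cov = resid.T @ centered_gm / (len(gm) - 1)
        assert np.all(np.abs(cov) <= 1e-8)

    def test_two_specimens_rejected(self, tiny_catalog):
        table = make_table(tiny_catalog, [[1, 2, 3], [2, 4, 6]])
        with pytest.raises(ValueError, match="3 specimens"):
            allometry_free(table)

    def test_zero_size_variance_rejected(self, tiny_catalog):
        table = make_table(tiny_catalog, [[2, 2, 2], [1, 2, 4], [1, 4, 2]])
        # all three rows share GM = 2
        with pytest.raises(ValueError, match="variance"):
            allometry_free(table)

    def test_angles_centered_but_not_residualized_when_excluded(self, mixed_catalog):
        rng = np.random.default_rng(9)
        lin = rng.lognormal(3, 0.4, size=(8, 2))
        ang = rng.uniform(30, 120, size=(8, 1))
        table = make_table(mixed_catalog, np.hstack([lin, ang]))
        shape = allometry_free(table, include_angles=False)
        assert np.allclose(shape.values["T"], ang[:, 0] - ang[:, 0].mean(), atol=1e-10)
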