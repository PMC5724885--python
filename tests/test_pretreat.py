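import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nirscal.pretreat import (
    PretreatmentSpec,
    Pretreater,
    apply_pretreatment,
    detrend,
    msc,
    nw_derivative,
    nw_smooth,
    parse_code,
    parse_spec,
    snv,
    snvd,
)
from nirscal.spectra import SpectraSet

finite_vectors = st.lists(
    st.floats(-100, 100, allow_nan=False), min_size=8, max_size=40
).map(np.asarray)


class TestParseCode:
    @pytest.mark.parametrize(
        "text, expected",
        [("1111", (1, 1, 1, 1)), ("2551", (2, 5, 5, 1)), ("0,0,1,1", (0, 0, 1, 1))],
    )
    def test_valid_codes(self, text, expected):
        assert parse_code(text) == expected

    @pytest.mark.parametrize("text", ["111", "12345", "a111", "1,1,1"])
    def test_invalid_codes(self, text):
        with pytest.raises(ValueError):
            parse_code(text)

    def test_spec_string_round_trip(self):
        spec = parse_spec("SNVD+1551")
        assert spec.scatter == "snvd" and spec.code == (1, 5, 5, 1)
        assert str(spec) == "SNVD+1551"


class TestSNV:
    def test_simple_example(self):
        np.testing.assert_allclose(snv([0, 1, 2]), [-1, 0, 1], atol=1e-12)

    def test_constant_spectrum_rejected(self):
        with pytest.raises(ValueError, match="zero SD"):
            snv([5, 5, 5])

    def test_against_mean_sd_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 9.0])
        expected = (x - 4.0) / np.sqrt(38.0 / 3.0)
        np.testing.assert_allclose(snv(x), expected, atol=1e-12)
        np.testing.assert_allclose(
            np.round(snv(x), 4), [-0.8429, -0.5620, 0.0, 1.4049], atol=1e-12
        )

    @settings(derandomize=True, max_examples=50)
    @given(finite_vectors)
    def test_mean_zero_sd_one(self, x):
        if x.std(ddof=1) <= 1e-9:
            return
        out = snv(x)
        assert abs(out.mean()) < 1e-10
        assert abs(out.std(ddof=1) - 1.0) < 1e-10


class TestDetrend:
    def test_exact_quadratic_gives_zero(self):
        k = np.arange(10.0)
        np.testing.assert_allclose(detrend(2 + 3 * k - 0.5 * k**2), 0, atol=1e-9)

    def test_zero_vector(self):
        np.testing.assert_allclose(detrend(np.zeros(5)), 0, atol=1e-12)

    def test_against_normal_equations_oracle(self, rng):
        x = rng.standard_normal(15)
        k = np.arange(15.0)
        B = np.column_stack([np.ones(15), k, k**2])
        beta = np.linalg.solve(B.T @ B, B.T @ x)
        np.testing.assert_allclose(detrend(x), x - B @ beta, atol=1e-10)

    @settings(derandomize=True, max_examples=50)
    @given(finite_vectors)
    def test_residual_orthogonal_to_quadratic_basis(self, x):
        r = detrend(x)
        k = np.arange(x.size, dtype=float)
        scale = max(np.linalg.norm(x), 1.0)
        for basis in (np.ones_like(k), k / k.max(), (k / k.max()) ** 2):
            assert abs(r @ basis) < 1e-6 * scale

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detrend([1.0, 2.0])


class TestSNVD:
    def test_equals_composition(self, rng):
        x = rng.standard_normal(30)
        np.testing.assert_allclose(snvd(x), detrend(snv(x)), atol=1e-12)

    def test_quadratic_input_gives_zero(self):
        k = np.arange(12.0)
        np.testing.assert_allclose(snvd(1 + 0.1 * k + 0.02 * k**2), 0, atol=1e-9)


class TestMSC:
    def test_constructed_slope_offset_recovered(self, rng):
        ref = rng.standard_normal(25)
        X = np.vstack([ref, 2 * ref + 3])
        out = msc(X, reference=ref)
        np.testing.assert_allclose(out[1], ref, atol=1e-10)

    def test_reference_is_fixed_point(self, rng):
        ref = rng.standard_normal(25)
        np.testing.assert_allclose(msc(ref[None, :], reference=ref)[0], ref, atol=1e-10)

    def test_coefficients_match_ols_oracle(self, rng):
        X = rng.standard_normal((3, 30)) + 1
        ref = X.mean(axis=0)
        _, a, b = msc(X, return_coef=True)
        for i in range(3):
            slope, intercept = np.polyfit(ref, X[i], 1)
            assert abs(a[i] - slope) < 1e-10
            assert abs(b[i] - intercept) < 1e-10

    def test_idempotent_for_fixed_reference(self, rng):
        X = rng.standard_normal((4, 30)) + 2
        ref = X.mean(axis=0)
        once = msc(X, reference=ref)
        np.testing.assert_allclose(msc(once, reference=ref), once, atol=1e-10)

    def test_near_zero_slope_flagged(self):
        ref = np.linspace(0, 1, 10)
        X = np.vstack([ref, np.full(10, 3.0)])  # flat spectrum: slope ~ 0
        with pytest.raises(ValueError, match="slope"):
            msc(X, reference=ref)


class TestSmoothing:
    def test_s1_is_identity(self, rng):
        x = rng.standard_normal(20)
        np.testing.assert_array_equal(nw_smooth(x, 1), x)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(nw_smooth(np.full(11, 3.0), 5), 3.0, atol=1e-12)

    def test_hand_computed_windows_with_edge_replication(self):
        np.testing.assert_allclose(
            nw_smooth(np.array([1.0, 2, 3, 4, 5]), 3),
            [4 / 3, 2, 3, 4, 14 / 3],
            atol=1e-12,
        )

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            nw_smooth(np.arange(5.0), 2)


class TestDerivative:
    @pytest.mark.parametrize("gap", [1, 2, 3])
    def test_first_derivative_of_line_is_2g(self, gap):
        x = np.arange(20.0)
        out = nw_derivative(x, 1, gap)
        np.testing.assert_allclose(out[gap:-gap], 2.0 * gap, atol=1e-12)

    def test_second_derivative_of_constant_is_zero(self):
        np.testing.assert_allclose(nw_derivative(np.full(15, 7.0), 2, 2), 0, atol=1e-12)

    def test_second_derivative_of_square_is_2(self):
        x = np.arange(15.0) ** 2
        out = nw_derivative(x, 2, 1)
        np.testing.assert_allclose(out[1:-1], 2.0, atol=1e-12)

    def test_linearity_on_interior(self, rng):
        x, y = rng.standard_normal((2, 30))
        a, b = 2.5, -1.3
        combo = nw_derivative(a * x + b * y, 1, 2, 3, 3)
        parts = a * nw_derivative(x, 1, 2, 3, 3) + b * nw_derivative(y, 1, 2, 3, 3)
        np.testing.assert_allclose(combo, parts, atol=1e-10)

    def test_too_short_vector_rejected(self):
        with pytest.raises(ValueError):
            nw_derivative(np.arange(4.0), 1, 3)


class TestApplyPretreatment:
    def _set(self, matrix, grid):
        return SpectraSet(
            sample_ids=[f"s{i}" for i in range(len(matrix))],
            grid=grid,
            matrix=matrix,
        )

    def test_identity_spec_is_identity(self, rng):
        grid = np.arange(400.0, 700.0, 10.0)
        X = rng.standard_normal((3, grid.size))
        spec = parse_spec("NONE+0011")
        np.testing.assert_array_equal(
            apply_pretreatment(self._set(X, grid), spec).matrix, X
        )

    def test_single_segment_equals_composition(self, rng):
        grid = np.arange(400.0, 700.0, 10.0)
        X = rng.standard_normal((2, grid.size)) + 1
        spec = PretreatmentSpec("snvd", (1, 1, 1, 1), segments=((350, 1000),))
        out = apply_pretreatment(self._set(X, grid), spec)
        expected = np.vstack([nw_derivative(snvd(row), 1, 1) for row in X])
        np.testing.assert_allclose(out.matrix, expected, atol=1e-10)

    def test_per_segment_snv_centering(self, rng):
        grid = np.arange(400.0, 2500.0, 25.0)
        X = rng.standard_normal((2, grid.size)).cumsum(axis=1)
        spec = PretreatmentSpec("snvd", (0, 0, 1, 1))
        out = apply_pretreatment(self._set(X, grid), spec)
        for lo, hi in spec.segments:
            mask = (grid >= lo) & (grid <= hi)
            if mask.sum() < 3:
                continue
            # SNV then detrend leaves per-segment residuals orthogonal to 1
            resid = out.matrix[0, mask]
            assert abs(resid.sum()) < 1e-6

    def test_msc_reference_reused_for_prediction(self, rng):
        grid = np.arange(400.0, 700.0, 10.0)
        train = self._set(rng.standard_normal((5, grid.size)) + 2, grid)
        test = self._set(rng.standard_normal((2, grid.size)) + 2, grid)
        pt = Pretreater(PretreatmentSpec("msc", (0, 0, 1, 1), segments=((350, 1000),)))
        pt.fit_transform(train)
        ref = pt.msc_references_[0].copy()
        pt.transform(test)
        np.testing.assert_array_equal(pt.msc_references_[0], ref)

    def test_uncovered_wavelength_rejected(self, rng):
        grid = np.arange(300.0, 400.0, 10.0)
        spec = PretreatmentSpec("none", (0, 0, 1, 1))  # segments start at 350
        with pytest.raises(ValueError, match="not covered"):
            apply_pretreatment(self._set(np.ones((3, grid.size)), grid), spec)
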