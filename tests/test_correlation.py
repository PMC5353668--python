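import numpy as np
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

import extdebt as ed
from conftest import centered_orthogonal_design, exact_correlated_triple


class TestPearson:
    def test_perfect_positive_and_negative(self, rng):
        x = rng.standard_normal(50)
        assert ed.pearson(x, x).r == pytest.approx(1.0)
        assert ed.pearson(x, -x).r == pytest.approx(-1.0)

    def test_orthogonal_by_construction(self):
        # paired antisymmetric design: y values mirror across x duplicates
        x = np.repeat(np.arange(10.0), 2)
        y = np.tile([1.0, -1.0], 10)
        assert ed.pearson(x, y).r == pytest.approx(0.0, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ed.pearson(np.ones(10), np.arange(10.0))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            ed.pearson([1.0, 2.0], [3.0, 4.0])

    def test_missing_values_dropped_pairwise(self, rng):
        x = rng.standard_normal(30)
        y = 2 * x + rng.standard_normal(30) * 0.1
        x[3] = np.nan
        res = ed.pearson(x, y)
        assert res.n == 29


class TestModifiedTTest:
    def _coords(self, n, rng):
        return np.column_stack([rng.uniform(-60, 60, n), rng.uniform(-180, 180, n)])

    def test_iid_effective_sample_size_near_n(self):
        # simulation oracle: on iid data the effective sample size estimator
        # should recover ~n on average
        rng = np.random.default_rng(11)
        n = 500
        coords = self._coords(n, rng)
        ess = [ed.modified_ttest(rng.standard_normal(n), rng.standard_normal(n),
                                 coords).ess for _ in range(200)]
        assert abs(np.mean(ess) - n) < 0.1 * n

    def test_shared_autocorrelation_shrinks_ess_and_inflates_p(self):
        rng = np.random.default_rng(12)
        shape = (20, 30)
        lat, lon = np.meshgrid(np.linspace(-50, 50, shape[0]),
                               np.linspace(-170, 170, shape[1]), indexing="ij")
        coords = np.column_stack([lat.ravel(), lon.ravel()])

        def smooth():
            f = gaussian_filter(rng.standard_normal(shape), 5, mode="wrap")
            return ((f - f.mean()) / f.std()).ravel()

        x = smooth() + 0.1 * rng.standard_normal(coords.shape[0])
        y = smooth() + 0.1 * rng.standard_normal(coords.shape[0])
        spatial = ed.modified_ttest(x, y, coords)
        naive = ed.pearson(x, y)
        assert spatial.ess < coords.shape[0] / 5
        assert spatial.p > naive.p

    def test_constant_input_rejected(self, rng):
        coords = self._coords(20, rng)
        with pytest.raises(ValueError, match="constant"):
            ed.modified_ttest(np.zeros(20), rng.standard_normal(20), coords)

    def test_coords_shape_checked(self, rng):
        with pytest.raises(ValueError, match="coords"):
            ed.modified_ttest(rng.standard_normal(20), rng.standard_normal(20),
                              rng.standard_normal((20, 3)))


class TestSemipartial:
    def test_empty_controls_reduce_to_pearson(self, rng):
        x = rng.standard_normal(60)
        y = x + rng.standard_normal(60)
        base = ed.pearson(x, y)
        res = ed.semipartial_correlation(y, x, np.empty((60, 0)))
        assert res.r == pytest.approx(base.r, abs=1e-12)

    def test_orthogonal_controls_change_nothing(self):
        # controls exactly orthogonal (in sample) to x leave its residual = x
        cols = centered_orthogonal_design(100, 3, seed=1)
        x, z1, z2 = cols[:, 0], cols[:, 1], cols[:, 2]
        rng = np.random.default_rng(2)
        y = 2 * x + rng.standard_normal(100)
        plain = ed.pearson(y, x)
        res = ed.semipartial_correlation(y, x, np.column_stack([z1, z2]))
        assert res.r == pytest.approx(plain.r, abs=1e-10)

    def test_x_in_span_of_controls_rejected(self, rng):
        z = rng.standard_normal((50, 2))
        x = z @ np.array([1.0, -2.0]) + 3.0
        y = rng.standard_normal(50)
        with pytest.raises(ValueError, match="span"):
            ed.semipartial_correlation(y, x, z)

    def test_degrees_of_freedom_account_for_controls(self, rng):
        z = rng.standard_normal((50, 3))
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        res = ed.semipartial_correlation(y, x, z)
        assert res.df == 50 - 3 - 2


class TestPartial:
    def test_empty_controls_reduce_to_pearson(self, rng):
        x = rng.standard_normal(60)
        y = x + rng.standard_normal(60)
        res = ed.partial_correlation(y, x, np.empty((60, 0)))
        assert res.r == pytest.approx(ed.pearson(x, y).r, abs=1e-12)

    def test_three_variable_closed_form(self):
        # all pairwise sample correlations exactly 0.5 → partial r = 1/3
        x, y, z = exact_correlated_triple(n=120, seed=3)
        res = ed.partial_correlation(y, x, z)
        closed = (0.5 - 0.5 * 0.5) / np.sqrt((1 - 0.25) * (1 - 0.25))
        assert closed == pytest.approx(1 / 3)
        assert res.r == pytest.approx(closed, abs=1e-10)

    def test_agrees_with_residual_oracle(self, rng):
        z = rng.standard_normal((80, 3))
        x = z @ np.array([1.0, 0.5, -1.0]) + rng.standard_normal(80)
        y = z @ np.array([-0.5, 1.0, 0.2]) + x * 0.3 + rng.standard_normal(80)
        design = np.column_stack([np.ones(80), z])
        rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
        ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert ed.partial_correlation(y, x, z).r == pytest.approx(oracle, abs=1e-10)

    def test_y_in_span_of_controls_rejected(self, rng):
        z = rng.standard_normal((50, 2))
        y = z[:, 0] * 1.0
        x = rng.standard_normal(50)
        with pytest.raises(ValueError, match="span"):
            ed.partial_correlation(y, x, z)


class TestBonferroni:
    def test_worked_examples(self):
        assert ed.bonferroni([0.01], 8)[0] == pytest.approx(0.08)
        assert ed.bonferroni([0.2], 8)[0] == 1.0
        assert np.allclose(ed.bonferroni([0.1, 0.5], 1), [0.1, 0.5])

    def test_monotone(self, rng):
        p = np.sort(rng.random(20))
        adj = ed.bonferroni(p, 8)
        assert np.all(np.diff(adj) >= 0)
        assert np.all(adj >= p)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ed.bonferroni([0.5], 0)
        with pytest.raises(ValueError):
            ed.bonferroni([1.5], 2)


class TestRandomization:
    def test_perfect_correlation_minimal_p(self, rng):
        x = rng.standard_normal(200)
        res = ed.randomization_test(x, x, n_permutations=99, seed=0)
        assert res.p == pytest.approx(1 / 100)

    def test_same_seed_reproducible(self, rng):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        a = ed.randomization_test(y, x, 199, seed=7)
        b = ed.randomization_test(y, x, 199, seed=7)
        assert a.p == b.p

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(21)
        ps = []
        for _ in range(200):
            x = rng.standard_normal(40)
            y = rng.standard_normal(40)
            ps.append(ed.randomization_test(y, x, 199, seed=int(rng.integers(2**31))).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.001

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            ed.randomization_test(np.ones(10), np.arange(10.0), 9, seed=0)


class TestBonferroniProperties:
    from hypothesis import given, settings, strategies as st

    pvals = st.lists(st.floats(0, 1), min_size=1, max_size=20)

    @given(p=pvals, m=st.integers(1, 50))
    @settings(derandomize=True, max_examples=100)
    def test_adjusted_values_bounded_and_dominating(self, p, m):
        adj = ed.bonferroni(p, m)
        assert np.all(adj <= 1.0)
        assert np.all(adj >= np.asarray(p))

    @given(p=st.floats(0, 1), q=st.floats(0, 1), m=st.integers(1, 50))
    @settings(derandomize=True, max_examples=100)
    def test_order_preserved(self, p, q, m):
        lo, hi = sorted([p, q])
        a = ed.bonferroni([lo, hi], m)
        assert a[0] <= a[1]
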