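import numpy as np
import pytest
from scipy.stats import chi2

from assocmod import assoc_model as am
from assocmod.dataio import quantize_matrix
import pandas as pd
from assocmod.synthetic_data import conditional_probs


def one_hot(states):
    table = {-1: (1.0, 0, 0), 0: (0, 1.0, 0), 1: (0, 0, 1.0)}
    return np.array([table[s] for s in states])


class TestDriverExpectation:
    @pytest.mark.parametrize("triple,expected", [
        ((1, 0, 0), -1.0),
        ((1 / 3, 1 / 3, 1 / 3), 0.0),
        ((0.2, 0.3, 0.5), 0.3),
    ])
    def test_trinary(self, triple, expected):
        assert am.driver_expectation(np.array([triple]))[0] == pytest.approx(expected)

    def test_mutation_passthrough(self):
        x = np.array([0.0, 1.0, np.nan])
        out = am.driver_expectation(x)
        np.testing.assert_array_equal(out[:2], [0, 1])
        assert np.isnan(out[2])
        with pytest.raises(ValueError):
            am.driver_expectation(np.array([0.0, 0.5]))


class TestLoglik:
    def test_null_is_minus_n_ln3_for_any_data(self, rng):
        n = 17
        Q = rng.dirichlet(np.ones(3), size=n)
        X = rng.normal(size=(2, n))
        assert am.loglik([0, 0], [1, -1], X, Q) == pytest.approx(-n * np.log(3))

    def test_zero_driver_kills_exponent(self):
        val = am.loglik([1.0], [1], np.array([[0.0]]), np.array([[0, 0, 1.0]]))
        assert val == pytest.approx(-np.log(3))

    def test_single_sample_closed_form(self):
        # lambda=1, x=1, y=+1: loglik = 1 - ln(e^-1 + 1 + e^1)
        val = am.loglik([1.0], [1], np.array([[1.0]]), np.array([[0, 0, 1.0]]))
        assert val == pytest.approx(1 - np.log(np.exp(-1) + 1 + np.exp(1)))

    def test_zero_usable_samples_error(self):
        with pytest.raises(ValueError, match="usable"):
            am.loglik([1.0], [1], np.array([[np.nan]]), np.array([[0, 0, 1.0]]))


class TestFit:
    def test_uniform_passenger_gives_null(self, rng):
        n = 30
        Q = np.full((n, 3), 1 / 3)
        x = rng.normal(size=(1, n))
        m = am.fit("p", ["d"], [1], x, Q)
        assert m.lambdas[0] == pytest.approx(0.0, abs=1e-4)
        assert m.loglik == pytest.approx(-n * np.log(3), abs=1e-6)

    def test_separation_hits_cap_and_matches_grid_oracle(self):
        x = np.array([[1.0, 1, 1, 0, 0, 0]])
        Q = one_hot([1, 1, 1, -1, -1, -1])
        cap = 10.0
        m = am.fit("p", ["d"], [1], x, Q, lam_cap=cap, min_samples=6)
        grid = np.arange(0, cap + 1e-9, 0.01)
        lls = [am.loglik([g], [1], x, Q) for g in grid]
        assert m.lambdas[0] == pytest.approx(grid[int(np.argmax(lls))], abs=0.02)
        assert m.loglik == pytest.approx(max(lls), abs=1e-6)

    def test_duplicated_drivers_share_total_weight(self, rng):
        n = 60
        x = rng.choice([-1.0, 0.0, 1.0], size=n)
        y = [np.random.default_rng(4).choice((-1, 0, 1),
                                             p=conditional_probs(v, 1.2, 1))
             for v in x]
        Q = one_hot(y)
        single = am.fit("p", ["d"], [1], x[None, :], Q)
        dup = am.fit("p", ["d1", "d2"], [1, 1], np.vstack([x, x]), Q)
        assert dup.lambdas.sum() == pytest.approx(single.lambdas[0], abs=1e-3)
        assert dup.loglik == pytest.approx(single.loglik, abs=1e-6)

    def test_constant_driver_flagged_null(self):
        x = np.ones((1, 12))
        Q = one_hot([1] * 6 + [-1] * 6)
        m = am.fit("p", ["d"], [1], x, Q)
        assert m.degenerate and m.lambdas[0] == 0.0

    def test_sign_mismatch_yields_zero_weight(self, rng):
        n = 60
        x = rng.choice([-1.0, 0.0, 1.0], size=n)
        y = [rng.choice((-1, 0, 1), p=conditional_probs(v, 1.5, 1)) for v in x]
        m = am.fit("p", ["d"], [-1], x[None, :], one_hot(y))
        assert m.lambdas[0] == pytest.approx(0.0, abs=1e-4)

    def test_never_below_null(self, rng):
        for _ in range(10):
            n = 20
            x = rng.normal(size=(1, n))
            Q = rng.dirichlet(np.ones(3), size=n)
            m = am.fit("p", ["d"], [1], x, Q)
            assert m.loglik >= -n * np.log(3) - 1e-9


class TestScreenSingleDriver:
    def test_matches_generic_fit(self, rng):
        """The vectorized 1-D solver and L-BFGS-B agree (dual route)."""
        n = 40
        x = rng.choice([-1.0, 0.0, 1.0], size=n)
        Q = rng.dirichlet(np.ones(3), size=(12, n))
        lam, llr, p, n_use = am.screen_single_driver(x, Q, 1)
        for i in range(12):
            m = am.fit("p", ["d"], [1], x[None, :], Q[i])
            assert lam[i] == pytest.approx(m.lambdas[0], abs=1e-4)
            assert llr[i] == pytest.approx(
                2 * (m.loglik + n * np.log(3)), abs=1e-5)

    def test_missing_samples_dropped(self):
        x = np.array([1.0, np.nan, -1.0, 0.0])
        Q = one_hot([1, 1, -1, 0])
        _, _, _, n_use = am.screen_single_driver(x, Q, 1)
        assert n_use[0] == 3

    def test_mixture_halves_positive_p(self, rng):
        x = rng.choice([-1.0, 1.0], size=30)
        Q = rng.dirichlet(np.ones(3), size=(5, 30))
        _, llr, p, _ = am.screen_single_driver(x, Q, 1)
        _, _, pm, _ = am.screen_single_driver(x, Q, 1, mixture=True)
        pos = llr > 0
        np.testing.assert_allclose(pm[pos], p[pos] / 2)
        np.testing.assert_allclose(pm[~pos], 1.0)


class TestLrt:
    def test_identical_models(self):
        m = am.AssociationModel("p", ("d",), (1,), np.array([0.5]), -10.0, 9)
        r = am.lrt(m, m)
        assert (r.llr, r.p_value) == (0.0, 1.0)

    def test_chi2_quantile(self):
        m0 = am.AssociationModel("p", (), (), np.zeros(0), -10.0, 9)
        m1 = am.AssociationModel("p", ("d",), (1,), np.array([1.0]),
                                 -10.0 + 3.841 / 2, 9)
        assert am.lrt(m0, m1).p_value == pytest.approx(0.05, abs=2e-4)

    def test_non_nested_rejected(self):
        a = am.AssociationModel("p", ("d1",), (1,), np.array([1.0]), -9.0, 9)
        b = am.AssociationModel("p", ("d2",), (1,), np.array([1.0]), -8.0, 9)
        with pytest.raises(ValueError, match="nested"):
            am.lrt(a, b)

    def test_power_on_planted_effect(self):
        """Median screening p-value far below 1e-3 at lambda=1, n=60."""
        rng = np.random.default_rng(11)
        n, pvals = 60, []
        for _ in range(200):
            x = rng.choice([-1.0, 0.0, 1.0], size=n)
            y = [rng.choice((-1, 0, 1), p=conditional_probs(v, 1.0, 1))
                 for v in x]
            _, _, p, _ = am.screen_single_driver(x, one_hot(y), 1)
            pvals.append(p[0])
        assert np.median(pvals) < 1e-3


def test_type_one_error_is_conservative():
    """Independent driver/passenger pairs: rejection rate at 0.05 stays <= 0.07.

    The nonnegativity boundary makes the plain chi-square reference
    conservative, so the realized level sits at roughly half the nominal.
    """
    rng = np.random.default_rng(21)
    n, hits, total = 60, 0, 0
    for _ in range(50):
        x = rng.choice([-1.0, 0.0, 1.0], size=n)
        obs = rng.choice([-1.0, 0.0, 1.0], size=(20, n)) + rng.normal(0, 0.4, (20, n))
        tm = quantize_matrix(pd.DataFrame(obs, columns=[f"s{i}" for i in range(n)]))
        _, _, p, _ = am.screen_single_driver(x, tm.probs, 1)
        hits += int((p < 0.05).sum())
        total += 20
    assert total == 1000
    assert hits / total <= 0.07
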