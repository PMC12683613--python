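"""Regression machinery against independent oracles.

OLS is checked against an explicit normal-equations solution, logistic IRLS
against a likelihood grid search, stepwise selection against an
independently coded greedy walker, and Fisher's method against direct
evaluation of -2*sum(log p).
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import special, stats

from antcomp.inference import (AIC_TIE_TOL, ModelSpec, SeparationError,
                               droppable_terms, estimate_lv,
                               fishers_method, fit_logistic, fit_model,
                               fit_ols, standardize, stepwise_aic)
from antcomp.synthetic import TrueParameters, generate_growth_table


def design_from(arrays: dict, n: int | None = None) -> pd.DataFrame:
    if n is None:
        n = len(next(iter(arrays.values())))
    return pd.DataFrame({"(Intercept)": np.ones(n), **arrays})


class TestStandardize:
    def test_symmetric_triple(self):
        assert standardize([1, 2, 3]) == pytest.approx([-1, 0, 1])

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            standardize([2.0, 2.0, 2.0])

    @given(st.lists(
        st.floats(-1e6, 1e6).filter(lambda v: v == 0 or abs(v) > 1e-3),
        min_size=3, max_size=40, unique=True))
    def test_inverse_transform_recovers_input(self, xs):
        x = np.asarray(xs)
        z = standardize(x)
        assert np.abs(z.mean()) < 1e-9
        assert z.std(ddof=1) == pytest.approx(1.0)
        back = z * x.std(ddof=1) + x.mean()
        assert np.allclose(back, x, rtol=1e-9, atol=1e-6)


class TestOLS:
    def test_noise_free_coefficients_exact(self, rng):
        z1, z2 = rng.normal(size=50), rng.normal(size=50)
        y = 0.1 - 0.06 * z1 - 0.013 * z2
        fit = fit_ols(design_from({"z1": z1, "z2": z2}), y)
        assert fit.coefficients["(Intercept)"] == pytest.approx(0.1, abs=1e-12)
        assert fit.coefficients["z1"] == pytest.approx(-0.06, abs=1e-12)
        assert fit.coefficients["z2"] == pytest.approx(-0.013, abs=1e-12)

    def test_intercept_only_is_sample_mean(self, rng):
        y = rng.normal(size=25)
        fit = fit_ols(design_from({}, n=25), y)
        assert fit.coefficients["(Intercept)"] == pytest.approx(y.mean())

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(8, 21))
            p = int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            y = rng.normal(size=n)
            design = pd.DataFrame(
                {"(Intercept)": np.ones(n),
                 **{f"x{j}": X[:, j] for j in range(p)}})
            fit = fit_ols(design, y)
            Xd = design.to_numpy()
            beta_oracle = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
            est = np.array([fit.coefficients[c] for c in design.columns])
            assert np.allclose(est, beta_oracle, atol=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=20)
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(design_from({"x": x, "x2": 2 * x}), rng.normal(size=20))

    def test_aic_identity(self, rng):
        y = rng.normal(size=30)
        fit = fit_ols(design_from({"x": rng.normal(size=30)}), y)
        k = fit.n_params
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)
        assert k == 3  # intercept, slope, residual variance


class TestLogistic:
    def test_all_identical_outcomes_flagged(self):
        with pytest.raises(SeparationError):
            fit_logistic(design_from({}, n=20), np.ones(20))

    def test_complete_separation_flagged(self):
        x = np.r_[np.full(15, -2.0), np.full(15, 2.0)]
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(design_from({"x": x}), y)

    def test_null_slope_within_3se(self, rng):
        x = rng.normal(size=1000)
        y = rng.binomial(1, 0.5, size=1000).astype(float)
        fit = fit_logistic(design_from({"x": x}), y)
        assert abs(fit.coefficients["x"]) <= 3 * fit.standard_errors["x"]

    def test_beats_grid_search_oracle(self, rng):
        """IRLS log-likelihood is at least that of every point on a fine
        2-parameter grid (tolerance 1e-6)."""
        b0s = np.linspace(-4, 4, 161)
        b1s = np.linspace(-4, 4, 161)
        for _ in range(5):
            n = int(rng.integers(20, 51))
            x = rng.normal(size=n)
            p = special.expit(0.3 + 0.8 * x)
            y = rng.binomial(1, p).astype(float)
            if y.sum() in (0, n):
                continue
            fit = fit_logistic(design_from({"x": x}), y)
            eta = (b0s[:, None, None] + b1s[None, :, None] * x[None, None, :])
            ll_grid = np.sum(y * eta - np.logaddexp(0, eta), axis=2)
            assert fit.loglik >= ll_grid.max() - 1e-6

    def test_random_intercept_recovers_on_collapsed_binomial(self, rng):
        """Colony-level random intercept ML: slope estimate lands within 3 SE
        of the generating value on a moderate simulated dataset."""
        n = 300
        x = rng.normal(size=n)
        u = rng.normal(0, 0.5, size=n)
        trials = rng.integers(30, 300, size=n).astype(float)
        p = special.expit(1.0 - 0.3 * x + u)
        succ = rng.binomial(trials.astype(int), p).astype(float)
        fit = fit_logistic(design_from({"x": x}), succ, trials=trials,
                           cluster=np.arange(n))
        assert abs(fit.coefficients["x"] - (-0.3)) <= 3 * fit.standard_errors["x"]
        assert 0.3 < fit.extra["random_intercept_sd"] < 0.8


class TestStepwise:
    @staticmethod
    def _data_with_signal(rng, n=1000):
        df = pd.DataFrame({
            "A": rng.normal(size=n),
            "B": rng.normal(size=n),
        })
        df["y"] = 2.0 * df["A"] + rng.normal(size=n)
        return df

    def test_drops_inactive_predictor(self, rng):
        df = self._data_with_signal(rng)
        spec = ModelSpec("y", ("A", "B"), "gaussian")
        selected, fit, path = stepwise_aic(spec, df)
        assert selected.terms == ("A",)
        assert path[0]["action"] == "start"

    def test_fixed_point_returned_unchanged(self, rng):
        df = self._data_with_signal(rng)
        df["y"] = 1.5 * df["A"] - 1.5 * df["B"] + 0.1 * rng.normal(size=1000)
        spec = ModelSpec("y", ("A", "B"), "gaussian")
        selected, _, _ = stepwise_aic(spec, df)
        assert selected.terms == ("A", "B")

    def test_marginality_rules(self):
        assert droppable_terms(("A", "B", "A:B")) == ["A:B"]
        # a squared term needs no linear guard
        assert set(droppable_terms(("A^2", "B", "A^2:B"))) == {"A^2:B"}
        assert "A^2" in droppable_terms(("A^2", "B"))

    def test_matches_independent_greedy_walker(self, rng):
        """On exhaustive <=4-term problems the selection equals an
        independently coded downward walker, and the selected AIC is minimal
        along that walker's path."""
        for trial in range(5):
            n = 200
            df = pd.DataFrame({c: rng.normal(size=n) for c in "ABC"})
            coefs = rng.choice([0.0, 0.4], size=3)
            df["y"] = (df[["A", "B", "C"]].to_numpy() @ coefs
                       + 0.2 * df["A"] * df["B"] * (trial % 2)
                       + rng.normal(size=n))
            terms = ("A", "B", "C", "A:B")

            def aic_of(subset):
                return fit_model(ModelSpec("y", subset, "gaussian"), df).aic

            # independent walker: same rule, separate implementation
            cur = list(terms)
            visited = [tuple(cur)]
            while True:
                blocked = set()
                for t in cur:
                    if ":" in t:
                        blocked |= set(t.split(":"))
                options = [(aic_of(tuple(x for x in cur if x != t)), i, t)
                           for i, t in enumerate(cur) if t not in blocked]
                if not options:
                    break
                best = min(o[0] for o in options)
                if best >= aic_of(tuple(cur)) - AIC_TIE_TOL:
                    break
                tied = [o for o in options if o[0] <= best + AIC_TIE_TOL]
                drop = max(tied, key=lambda o: o[1])[2]
                cur = [x for x in cur if x != drop]
                visited.append(tuple(cur))

            selected, fit, _ = stepwise_aic(ModelSpec("y", terms, "gaussian"),
                                            df)
            assert selected.terms == tuple(cur)
            assert all(fit.aic <= aic_of(v) + AIC_TIE_TOL for v in visited)


class TestFisher:
    def test_single_certain_p(self):
        chi2, df, p = fishers_method([1.0])
        assert chi2 == 0.0 and df == 2 and p == pytest.approx(1.0)

    def test_two_printed_pvalues(self):
        chi2, df, p = fishers_method([0.018, 0.028])
        assert chi2 == pytest.approx(-2 * (np.log(0.018) + np.log(0.028)))
        assert chi2 == pytest.approx(15.186, abs=0.001)
        assert df == 4
        assert p == pytest.approx(stats.chi2.sf(chi2, 4))

    def test_additivity_for_identical_ps(self):
        chi1, _, _ = fishers_method([0.05])
        chik, dfk, _ = fishers_method([0.05] * 6)
        assert chik == pytest.approx(6 * chi1)
        assert dfk == 12

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fishers_method([0.5, 0.0])


class TestEstimateLV:
    def test_noise_free_ratio_matches_reported_scale(self):
        """Standardized slopes (-0.06, -0.013) give an intra/inter ratio of
        about 4.6."""
        t = generate_growth_table(200, TrueParameters(), seed=21,
                                  noise_sd=0.0)
        lv = estimate_lv(t)
        assert lv.alpha_ii_std == pytest.approx(-0.06, abs=1e-10)
        assert lv.alpha_ij_std == pytest.approx(-0.013, abs=1e-10)
        assert lv.ratio == pytest.approx(0.06 / 0.013, abs=1e-8)
        assert lv.ratio == pytest.approx(4.6, abs=0.05)

    def test_equal_slopes_give_unit_ratio(self, rng):
        n = 50
        con = rng.integers(0, 8, size=n).astype(float)
        het = rng.normal(100, 20, size=n)
        gw = 0.1 - 0.05 * standardize(con) - 0.05 * standardize(het)
        t = pd.DataFrame({"conspecific_nest_count": con,
                          "conspecific_worker_biomass": con * 10,
                          "heterospecific_total_biomass": het, "Gw": gw})
        assert estimate_lv(t).ratio == pytest.approx(1.0)

    def test_invariant_to_affine_rescaling_of_raw_units(self):
        t = generate_growth_table(120, TrueParameters(), seed=22)
        lv = estimate_lv(t)
        t2 = t.copy()
        t2["heterospecific_total_biomass"] *= 1000.0  # mg -> µg
        lv2 = estimate_lv(t2)
        assert lv2.alpha_ii_std == pytest.approx(lv.alpha_ii_std, rel=1e-10)
        assert lv2.alpha_ij_std == pytest.approx(lv.alpha_ij_std, rel=1e-10)
        assert lv2.ratio == pytest.approx(lv.ratio, rel=1e-10)

    def test_too_few_colonies_rejected(self):
        t = generate_growth_table(10, TrueParameters(), seed=23).head(2)
        with pytest.raises(ValueError, match="at least 3"):
            estimate_lv(t)

    def test_worker_biomass_metric_selects_other_column(self):
        t = generate_growth_table(120, TrueParameters(), seed=24)
        lv = estimate_lv(t, conspecific_metric="worker_biomass")
        assert lv.conspecific_metric == "worker_biomass"
        with pytest.raises(ValueError, match="unknown conspecific metric"):
            estimate_lv(t, conspecific_metric="nests")


class TestNullCalibration:
    def test_type_i_error_of_slope_tests_near_nominal(self):
        """Under the null generator (all effects zero), slope t-tests at the
        5% level reject between 3% and 7% of the time (2 slopes x 1500
        replicate experiments)."""
        truth = TrueParameters(growth_alpha_con=0.0, growth_alpha_het=0.0)
        hits, total = 0, 0
        for rep in range(1500):
            t = generate_growth_table(60, truth, seed=50_000 + rep)
            lv = estimate_lv(t)
            tcrit = stats.t.ppf(0.975, len(t) - 3)
            for est, se in ((lv.alpha_ii_std, lv.standard_errors["z_con"]),
                            (lv.alpha_ij_std, lv.standard_errors["z_het"])):
                hits += abs(est) > tcrit * se
                total += 1
        rate = hits / total
        assert 0.03 <= rate <= 0.07
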