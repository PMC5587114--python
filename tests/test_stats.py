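import numpy as np
import pandas as pd
import pytest

import hcasim as h
from hcasim import stats as hs


# --------------------------------------------------------------------------
# independent oracles

def icc1k_anova_oracle(m):
    """Brute-force one-way ANOVA sums of squares, no shortcuts."""
    m = np.asarray(m, dtype=float)
    n, k = m.shape
    grand = m.mean()
    ssb = sum(k * (m[i].mean() - grand) ** 2 for i in range(n))
    ssw = sum((m[i, j] - m[i].mean()) ** 2 for i in range(n) for j in range(k))
    bms = ssb / (n - 1)
    wms = ssw / (n * (k - 1))
    return (bms - wms) / bms


def ols_normal_equations(X, y):
    return np.linalg.solve(X.T @ X, X.T @ y)


# --------------------------------------------------------------------------
# ICC

class TestICC:
    def test_duplicated_column_gives_one(self):
        m = np.column_stack([np.arange(5.0)] * 3)
        assert h.icc_1k(m).icc == pytest.approx(1.0)

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(3, 11)
            k = rng.integers(2, 5)
            m = rng.normal(size=(n, k)) + rng.normal(size=(n, 1))
            assert h.icc_1k(m).icc == pytest.approx(icc1k_anova_oracle(m), abs=1e-12)

    def test_iid_noise_has_near_zero_icc(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(10_000, 2))
        assert abs(h.icc_1k(m).icc) < 0.05

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        m = rng.normal(size=(8, 3)) + rng.normal(size=(8, 1))
        df = pd.DataFrame({
            "targets": np.repeat(np.arange(8), 3),
            "raters": np.tile(np.arange(3), 8),
            "scores": m.ravel(),
        })
        res = pg.intraclass_corr(df, targets="targets", raters="raters",
                                 ratings="scores")
        icc1k = res.loc[res["Type"] == "ICC(1,k)", "ICC"].iloc[0]
        assert h.icc_1k(m).icc == pytest.approx(icc1k, abs=1e-9)
        icc_ak = res.loc[res["Type"] == "ICC(A,k)", "ICC"].iloc[0]
        assert h.icc_ak(m).icc == pytest.approx(icc_ak, abs=1e-9)

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            h.icc_1k(np.ones((1, 3)))
        with pytest.raises(ValueError):
            h.icc_1k(np.ones((3, 1)))

    def test_zero_variance_undefined(self):
        res = h.icc_1k(np.full((4, 2), 3.0))
        assert not res.defined()


# --------------------------------------------------------------------------
# Bland-Altman

class TestBlandAltman:
    def test_identical_series(self):
        x = np.arange(5.0)
        r = h.bland_altman(x, x)
        assert r.bias == 0 and r.loa_low == 0 and r.loa_high == 0

    def test_constant_shift(self):
        x = np.arange(5.0)
        r = h.bland_altman(x, x + 2.0)
        assert r.bias == pytest.approx(-2.0)
        assert r.sd_diff == pytest.approx(0.0)

    def test_hand_computed_triple(self):
        r = h.bland_altman([0.0, 1.0, 2.0], [1.0, 1.0, 1.0])
        # d = {-1, 0, 1}: bias 0, sd 1, LoA -/+ 1.96
        assert r.bias == pytest.approx(0.0)
        assert r.loa_low == pytest.approx(-1.96)
        assert r.loa_high == pytest.approx(1.96)

    def test_coverage_of_limits(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=10_000)
        y = x + rng.normal(0, 0.5, size=10_000)
        r = h.bland_altman(x, y)
        d = x - y
        frac = np.mean((d >= r.loa_low) & (d <= r.loa_high))
        assert frac == pytest.approx(0.95, abs=0.01)

    def test_too_short(self):
        with pytest.raises(ValueError):
            h.bland_altman([1.0], [2.0])


# --------------------------------------------------------------------------
# OLS

class TestOLS:
    def _random_df(self, rng, n=50):
        return pd.DataFrame({
            "readrate": rng.normal(size=n),
            "height": rng.uniform(4, 13, size=n),
            "shielded": rng.choice(["no", "yes"], size=n),
            "baseplate": rng.choice(["bp1", "bp2", "bp3"], size=n),
        })

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        df = self._random_df(rng)
        fit = h.fit_ols(df, "readrate", ["shielded", "height", "baseplate"],
                        label="eq1_ols")
        X, names = hs.build_design(df, ["shielded", "height", "baseplate"])
        beta = ols_normal_equations(X, df["readrate"].to_numpy())
        for i, name in enumerate(names):
            assert fit.estimate(name) == pytest.approx(beta[i], abs=1e-8)

    def test_noise_free_recovery(self):
        rng = np.random.default_rng(5)
        df = self._random_df(rng, n=30)
        y = 0.9 - 0.02 * df["height"].to_numpy() + 0.14 * (df["shielded"] == "yes")
        df["readrate"] = y
        fit = h.fit_ols(df, "readrate", ["shielded", "height"])
        assert fit.estimate("Intercept") == pytest.approx(0.9, abs=1e-10)
        assert fit.estimate("height") == pytest.approx(-0.02, abs=1e-10)
        assert fit.estimate("shielded[yes]") == pytest.approx(0.14, abs=1e-10)

    def test_intercept_only_is_mean(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 6.0]})
        fit = h.fit_ols(df, "y", [])
        assert fit.estimate("Intercept") == pytest.approx(3.0)

    def test_aliased_term_named(self):
        df = pd.DataFrame({"y": np.arange(6.0), "a": [0.0, 1, 2, 3, 4, 5],
                           "b": [0.0, 2, 4, 6, 8, 10]})
        with pytest.raises(ValueError, match="'b'"):
            h.fit_ols(df, "y", ["a", "b"])

    def test_invariant_to_response_shift(self):
        rng = np.random.default_rng(6)
        df = self._random_df(rng)
        f1 = h.fit_ols(df, "readrate", ["height", "shielded"])
        df2 = df.assign(readrate=df["readrate"] + 100.0)
        f2 = h.fit_ols(df2, "readrate", ["height", "shielded"])
        assert f2.estimate("height") == pytest.approx(f1.estimate("height"), abs=1e-9)
        assert f2.estimate("Intercept") == pytest.approx(f1.estimate("Intercept") + 100.0,
                                                         abs=1e-8)


# --------------------------------------------------------------------------
# mixed model

def _panel(rng, n_rats=6, n_weeks=4, tau=0.3, sigma=0.2, phase_effect=-0.25):
    rows = []
    intercepts = rng.normal(0, tau, n_rats)
    for r in range(n_rats):
        for w in range(n_weeks):
            for phase in ("dark", "light"):
                mu = 38.0 + intercepts[r] + (phase_effect if phase == "light" else 0.0)
                rows.append({"rat": f"r{r}", "week": str(w), "phase": phase,
                             "y": mu + rng.normal(0, sigma)})
    return pd.DataFrame(rows)


class TestRandomIntercept:
    def test_tau_zero_limit_matches_ols(self):
        rng = np.random.default_rng(7)
        df = _panel(rng, tau=0.0)
        mixed = h.fit_random_intercept(df, "y", ["phase", "week"], group="rat")
        ols = h.fit_ols(df, "y", ["phase", "week"])
        for name in ols.terms:
            assert mixed.estimate(name) == pytest.approx(ols.estimate(name), abs=1e-4)

    def test_tau2_nonnegative(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            df = _panel(rng, tau=rng.uniform(0, 0.5))
            fit = h.fit_random_intercept(df, "y", ["phase"], group="rat")
            assert fit.tau2 >= 0.0

    def test_phase_effect_coverage(self):
        """Known light-phase deficit recovered within 3 SEs in >=95% of
        replicates (6 rats x 4 weeks, 200 replicates)."""
        rng = np.random.default_rng(9)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            df = _panel(rng)
            fit = h.fit_random_intercept(df, "y", ["phase", "week"], group="rat")
            est = fit.estimate("phase[light]")
            se = fit.se("phase[light]")
            hits += abs(est - (-0.25)) <= 3 * se
        assert hits / n_rep >= 0.95

    def test_matches_statsmodels_mixedlm(self):
        sm = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(10)
        df = _panel(rng, tau=0.4)
        fit = h.fit_random_intercept(df, "y", ["phase", "week"], group="rat")
        ref = sm.mixedlm("y ~ phase + week", df, groups=df["rat"]).fit(reml=True)
        assert fit.estimate("phase[light]") == pytest.approx(
            ref.params["phase[T.light]"], abs=1e-4)
        assert fit.tau2 == pytest.approx(float(ref.cov_re.iloc[0, 0]), rel=0.05)

    def test_single_group_falls_back_to_ols(self):
        rng = np.random.default_rng(11)
        df = _panel(rng, n_rats=1)
        fit = h.fit_random_intercept(df, "y", ["phase"], group="rat")
        assert "ols_fallback" in fit.label
        assert "warning" in fit.extra


# --------------------------------------------------------------------------
# negative binomial

class TestNegBin:
    def test_intercept_only_fitted_mean(self):
        df = pd.DataFrame({"y": [2, 2, 2, 2]})
        fit = h.fit_negbin(df, "y", [])
        assert np.exp(fit.estimate("Intercept")) == pytest.approx(2.0, abs=1e-4)

    def test_near_poisson_limit_matches_poisson_ml(self):
        rng = np.random.default_rng(12)
        n = 400
        x = rng.uniform(0, 1, n)
        mu = np.exp(1.0 + 0.8 * x)
        y = rng.poisson(mu)
        df = pd.DataFrame({"y": y, "x": x})
        fit = h.fit_negbin(df, "y", ["x"])

        # independent Poisson ML oracle: Newton iterations on the score
        X = np.column_stack([np.ones(n), x])
        beta = np.zeros(2)
        for _ in range(50):
            eta = X @ beta
            w = np.exp(eta)
            grad = X.T @ (y - w)
            hess = X.T @ (X * w[:, None])
            beta = beta + np.linalg.solve(hess, grad)
        assert fit.estimate("x") == pytest.approx(beta[1], abs=1e-2)
        assert fit.extra["alpha"] < 0.05

    def test_rate_ratio_recovery(self):
        rng = np.random.default_rng(13)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            g = np.repeat(["a", "b"], 40)
            mu = np.where(g == "b", 12.0, 6.0)
            # gamma-Poisson mixture: NB with dispersion alpha = 0.3
            lam = rng.gamma(shape=1 / 0.3, scale=mu * 0.3)
            y = rng.poisson(lam)
            df = pd.DataFrame({"y": y, "g": g})
            fit = h.fit_negbin(df, "y", ["g"])
            est, se = fit.estimate("g[b]"), fit.se("g[b]")
            hits += abs(est - np.log(2.0)) <= 3 * se
        assert hits / n_rep >= 0.95

    def test_rejects_non_integer(self):
        df = pd.DataFrame({"y": [1.5, 2.0]})
        with pytest.raises(ValueError):
            h.fit_negbin(df, "y", [])
        with pytest.raises(ValueError):
            h.fit_negbin(pd.DataFrame({"y": [-1, 2]}), "y", [])


# --------------------------------------------------------------------------
# paired t

class TestPairedT:
    def test_hand_computed_triple(self):
        t, p = h.paired_t([2.0, 3.0, 4.0], [1.0, 1.0, 1.0])
        # d = {1, 2, 3}: t = 2 * sqrt(3)
        assert t == pytest.approx(2 * np.sqrt(3.0))
        from scipy import stats as sps
        assert p == pytest.approx(2 * sps.t.sf(2 * np.sqrt(3.0), df=2))

    def test_swap_flips_sign_only(self):
        rng = np.random.default_rng(14)
        x1, x2 = rng.normal(size=20), rng.normal(size=20)
        t12, p12 = h.paired_t(x1, x2)
        t21, p21 = h.paired_t(x2, x1)
        assert t21 == pytest.approx(-t12)
        assert p21 == pytest.approx(p12)

    def test_zero_mean_difference_gives_t_zero(self):
        t, p = h.paired_t([1.0, 2.0, 3.0], [3.0, 2.0, 1.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            h.paired_t([1.0, 2.0], [1.0, 2.0])


# --------------------------------------------------------------------------
# rubric

class TestRubric:
    @pytest.mark.parametrize("freq,score", [
        (0.74, 4), (0.80, 5), (0.75, 5), (0.5, 3), (0.35, 2), (0.1, 1)])
    def test_read_frequency_bands(self, freq, score):
        assert h.rubric_scores(read_freq_hz=freq).scores["read_frequency"] == score

    @pytest.mark.parametrize("icc,score", [
        (0.83, 4), (0.95, 5), (0.6, 3), (0.2, 2), (-0.1, 1)])
    def test_icc_bands(self, icc, score):
        assert h.rubric_scores(icc_tracking=icc).scores["tracking_icc"] == score

    @pytest.mark.parametrize("r2,score", [(0.95, 5), (0.8, 4), (0.6, 3), (0.4, 2), (0.1, 1)])
    def test_r2_bands(self, r2, score):
        assert h.rubric_scores(r2_sideview=r2).scores["sideview_r2"] == score

    def test_monotone_in_metric(self):
        grid = np.linspace(0, 1.0, 101)
        scores = [h.rubric_scores(read_freq_hz=v).scores["read_frequency"] for v in grid]
        assert (np.diff(scores) >= 0).all()
        scores = [h.rubric_scores(icc_tracking=v).scores["tracking_icc"]
                  for v in np.linspace(-0.5, 1.0, 101)]
        assert (np.diff(scores) >= 0).all()

    def test_implant_issue_scores(self):
        assert h.rubric_scores(implant_issue_count=0).scores["implantation_integrity"] == 5
        assert h.rubric_scores(implant_issue_count=1).scores["implantation_integrity"] == 4
        assert h.rubric_scores(implant_issue_count=9).scores["implantation_integrity"] == 1


# --------------------------------------------------------------------------
# light/dark summary

class TestLightDark:
    def _bins(self, dark_vals, light_vals):
        rows = []
        for i, v in enumerate(dark_vals):
            rows.append({"animal_id": "rat1", "phase": "dark", "v": v})
        for v in light_vals:
            rows.append({"animal_id": "rat1", "phase": "light", "v": v})
        return pd.DataFrame(rows)

    def test_uniform_activity_ratio_one(self):
        s = h.light_dark_summary(self._bins([5, 5], [5, 5]), "v")
        assert s.cage_ratio == pytest.approx(1.0)

    def test_worked_ratio(self):
        s = h.light_dark_summary(self._bins([14, 14], [10, 10]), "v")
        assert s.cage_ratio == pytest.approx(1.4)

    def test_zero_light_phase_undefined(self):
        s = h.light_dark_summary(self._bins([3, 3], [0, 0]), "v")
        assert s.cage_ratio is None
        assert np.isnan(s.per_animal["ratio"]).all()
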