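import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from embody.stats import (
    PREDICTORS,
    correlation_power,
    detectable_r,
    fit_clarity_zinb,
    fit_crossed_intercepts,
    fit_diffusion_lmm,
    simulate_zinb,
    spearman_holm,
)


def _frame(x, y, outcome="m"):
    df = pd.DataFrame({outcome: x})
    for p in PREDICTORS:
        df[p] = y
    return df


class TestSpearmanHolm:
    def test_perfect_inverse_monotonicity(self):
        res = spearman_holm(_frame([1, 2, 3, 4], [4, 3, 2, 1]), ["m"])
        assert all(r.estimate == pytest.approx(-1.0) for r in res)

    def test_midrank_ties_match_rank_pearson_oracle(self):
        x = [1.0, 1.0, 2.0, 3.0, 3.0, 4.0]
        y = [2.0, 1.0, 4.0, 4.0, 3.0, 6.0]
        res = spearman_holm(_frame(x, y), ["m"])[0]
        rx = stats.rankdata(x)  # mid-rank ties
        ry = stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert res.estimate == pytest.approx(oracle, abs=1e-12)

    def test_holm_step_down_hand_example(self):
        # three outcomes constructed to give fixed raw p-values is fiddly;
        # check the adjustment rule directly through the family machinery
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.02, 0.04], method="holm")[1]
        assert adj.tolist() == pytest.approx([0.03, 0.04, 0.04])

    def test_adjusted_never_below_raw_and_family_recorded(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(40, 5)),
                          columns=["a", "b", *PREDICTORS])
        res = spearman_holm(df, ["a", "b"], family="block")
        assert len(res) == 6
        for r in res:
            assert r.family_size == 6
            assert r.p_adjusted >= r.p_raw - 1e-15
            assert r.ci_low <= r.estimate <= r.ci_high

    def test_holm_equals_step_down_brute_force(self):
        rng = np.random.default_rng(9)
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=rng.integers(2, 10))
            adj = multipletests(p, method="holm")[1]
            # brute force: p_(i) adjusted = max over j<=i of (m-j+1) p_(j), capped
            order = np.argsort(p)
            m = len(p)
            running = np.maximum.accumulate((m - np.arange(m)) * p[order])
            expected = np.minimum(running, 1.0)
            assert adj[order] == pytest.approx(expected)

    def test_insufficient_or_constant_data_rejected(self):
        with pytest.raises(ValueError, match="4 complete pairs"):
            spearman_holm(_frame([1, 2, 3], [1, 2, 3]), ["m"])
        with pytest.raises(ValueError, match="constant"):
            spearman_holm(_frame([1, 1, 1, 1], [1, 2, 3, 4]), ["m"])


def _simulate_crossed(ns=30, ne=6, nr=4, beta=(0.5, 0.3, -0.2, 0.0),
                      sd=(0.5, 0.3, 0.4, 0.8), seed=5):
    rng = np.random.default_rng(seed)
    us, ue, ur = (rng.normal(0, sd[0], ns), rng.normal(0, sd[1], ne),
                  rng.normal(0, sd[2], nr))
    rows = []
    for s in range(ns):
        x = rng.normal(size=3)
        for e in range(ne):
            for r in range(nr):
                y = (beta[0] + beta[1] * x[0] + beta[2] * x[1] + beta[3] * x[2]
                     + us[s] + ue[e] + ur[r] + rng.normal(0, sd[3]))
                rows.append({"y": y, "x1": x[0], "x2": x[1], "x3": x[2],
                             "s": f"s{s}", "e": f"e{e}", "r": f"r{r}"})
    return pd.DataFrame(rows)


class TestCrossedLMM:
    def _fit(self, df, **kw):
        X = np.column_stack([np.ones(len(df)), df.x1, df.x2, df.x3])
        return fit_crossed_intercepts(
            df.y.to_numpy(), X,
            {"s": df.s.to_numpy(), "e": df.e.to_numpy(), "r": df.r.to_numpy()},
            fe_names=["const", "x1", "x2", "x3"], **kw)

    def test_matches_statsmodels_mixedlm(self):
        import warnings

        from statsmodels.formula.api import mixedlm

        df = _simulate_crossed()
        fit = self._fit(df)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = mixedlm("y ~ x1 + x2 + x3", df.assign(_one=1), groups="_one",
                             re_formula="0",
                             vc_formula={"s": "0 + C(s)", "e": "0 + C(e)",
                                         "r": "0 + C(r)"}).fit(reml=True)
        assert fit.beta == pytest.approx(sm_fit.params[:4].to_numpy(), abs=1e-4)
        assert fit.se == pytest.approx(sm_fit.bse[:4].to_numpy(), abs=1e-4)
        vc_sm = dict(zip(sm_fit.model.exog_vc.names, sm_fit.vcomp))
        for k in ("s", "e", "r"):
            assert fit.vc[k] == pytest.approx(vc_sm[k], abs=1e-3)

    def test_matches_lme4_oracle(self, tmp_path):
        df = _simulate_crossed(seed=7)
        df.to_csv(tmp_path / "df.csv", index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'df <- read.csv("{tmp_path}/df.csv")\n'
            'm <- lmer(y ~ x1 + x2 + x3 + (1|s) + (1|e) + (1|r), data=df, REML=TRUE)\n'
            'fe <- fixef(m); se <- sqrt(diag(vcov(m)))\n'
            f'write.csv(data.frame(est=fe, se=se), "{tmp_path}/out.csv", row.names=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.csv")
        fit = self._fit(df)
        assert fit.beta == pytest.approx(ref.est.to_numpy(), abs=1e-4)
        assert fit.se == pytest.approx(ref.se.to_numpy(), abs=1e-4)

    def test_zero_variance_ratios_reduce_to_ols(self):
        import statsmodels.api as sm

        df = _simulate_crossed(seed=11)
        fit = self._fit(df, theta_fix={"s": 0.0, "e": 0.0, "r": 0.0})
        X = np.column_stack([np.ones(len(df)), df.x1, df.x2, df.x3])
        ols = sm.OLS(df.y.to_numpy(), X).fit()
        assert fit.beta == pytest.approx(ols.params, abs=1e-10)
        assert fit.se == pytest.approx(ols.bse, abs=1e-10)

    def test_recovers_fixed_effect(self):
        hits = 0
        for seed in range(6):
            df = _simulate_crossed(ns=60, seed=seed)
            fit = self._fit(df)
            i = fit.fe_names.index("x1")
            if abs(fit.beta[i] - 0.3) < 2 * fit.se[i]:
                hits += 1
        assert hits >= 5

    def test_diffusion_interface_flags_and_errors(self):
        rng = np.random.default_rng(1)
        n_s, n_e, n_r = 25, 4, 3
        rows = []
        for s in range(n_s):
            z = rng.normal(size=3)
            for e in range(n_e):
                for r in range(n_r):
                    rows.append({"subject_id": f"s{s}", "emotion": f"e{e}",
                                 "roi": f"r{r}",
                                 "diffusion_raw": abs(rng.normal(3, 1) + 0.3 * z[0]),
                                 "z_interpersonal": z[0],
                                 "z_cognitive_perceptual": z[1],
                                 "z_disorganized": z[2]})
        res = fit_diffusion_lmm(pd.DataFrame(rows))
        assert len(res) == 3
        assert all("df=normal" in r.flags for r in res)
        with pytest.raises(ValueError, match="missing columns"):
            fit_diffusion_lmm(pd.DataFrame({"diffusion_raw": [1.0, 2.0]}))


class TestZinb:
    def test_without_inflation_matches_plain_nb(self):
        from statsmodels.discrete.discrete_model import NegativeBinomialP
        from statsmodels.tools import add_constant

        rng = np.random.default_rng(21)
        # no structural zeros: intercept_zero very negative
        X, y = simulate_zinb(3000, beta_count={"z_interpersonal": 0.4},
                             beta_zero={}, intercept_zero=-20.0,
                             intercept_count=0.3, rng=rng)
        res = fit_clarity_zinb(y, X)
        count_est = {r.predictor: r.estimate for r in res if r.method == "zinb_count"}
        nb = NegativeBinomialP(y, add_constant(X), p=2).fit(disp=0)
        for pred in PREDICTORS:
            assert count_est[pred] == pytest.approx(nb.params[pred], abs=0.05)

    def test_loglik_at_optimum_beats_truth(self):
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            X, y = simulate_zinb(1500, beta_count={"z_disorganized": 0.2},
                                 beta_zero={"z_interpersonal": -0.3}, rng=rng)
            _, fit = fit_clarity_zinb(y, X, return_fit=True)
            # generator parameters in statsmodels ordering:
            # [inflate const+slopes, count const+slopes, alpha=1/theta]
            truth = np.array([-0.5, -0.3, 0, 0, 1.5, 0, 0, 0.2, 1 / 1.5])
            if fit.model.loglike(fit.params.to_numpy()) >= fit.model.loglike(truth) - 1e-6:
                wins += 1
        assert wins >= 4

    def test_odds_ratio_of_reported_zero_part_coefficient(self):
        assert round(float(np.exp(-0.28)), 2) == 0.76

    def test_input_contracts(self):
        X = pd.DataFrame(np.zeros((10, 3)), columns=list(PREDICTORS))
        with pytest.raises(ValueError, match="zero counts"):
            fit_clarity_zinb(np.arange(1, 11), X)
        with pytest.raises(ValueError, match="all-zero"):
            fit_clarity_zinb(np.zeros(10, dtype=int), X)
        with pytest.raises(ValueError, match="integer"):
            fit_clarity_zinb(np.full(10, 0.5), X)


class TestCorrelationPower:
    def test_reported_sample_size_calculations(self):
        assert correlation_power(0.137, 419) == pytest.approx(0.80, abs=0.005)
        assert correlation_power(0.158, 419) == pytest.approx(0.90, abs=0.005)

    def test_size_of_test_at_null(self):
        assert correlation_power(0.0, 50, alpha=0.05) == pytest.approx(0.05)

    def test_monotone_in_effect_and_sample_size(self):
        rs = [0.05, 0.1, 0.2, 0.4]
        powers = [correlation_power(r, 200) for r in rs]
        assert np.all(np.diff(powers) > 0)
        ns = [10, 50, 200, 1000]
        powers_n = [correlation_power(0.15, n) for n in ns]
        assert np.all(np.diff(powers_n) > 0)

    @pytest.mark.parametrize("r", [0.05, 0.1, 0.3])
    def test_inversion_round_trip(self, r):
        p = correlation_power(r, 419, 0.05)
        assert detectable_r(p, 419, 0.05) == pytest.approx(r, abs=1e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            correlation_power(1.0, 100)
        with pytest.raises(ValueError):
            correlation_power(0.2, 3)
        with pytest.raises(ValueError):
            detectable_r(0.01, 419, alpha=0.05)
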