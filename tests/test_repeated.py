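"""AR(1) repeated-measures model: oracles, recovery, invariances."""

import json
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest

import rumengas as rg
from helpers import simulate_repeated


def dense_ar1_reml_loglik(df, response, var_cow, var_day, var_resid, rho):
    """Independent restricted log-likelihood with explicit dense matrices.

    V = var_cow Zc Zc' + var_day Zd Zd' + var_resid * C, with C the AR(1)
    correlation rho^|i-j| over the time-ordered observations of each
    cow x period x day series.  Shares no code with the package engine.
    """
    df = df.sort_values(["cow_id", "period", "day", "time"]).reset_index(drop=True)
    n = len(df)
    y = df[response].to_numpy(float)
    trt = np.where(df["treatment"] == "nitrate", 0.5, -0.5)
    times = np.sort(df["time"].unique())
    T = times.size
    tcols = []
    for t in times[:-1]:
        tcols.append((df["time"] == t).astype(float) - (df["time"] == times[-1]).astype(float))
    time_m = np.column_stack(tcols)
    # sum coding identical to the package design: period +1/-1
    per = np.where(df["period"] == df["period"].min(), 1.0, -1.0)
    X = np.column_stack([np.ones(n), trt, time_m, time_m * trt[:, None], per])

    def onehot(keys):
        _, codes = np.unique(keys, return_inverse=True)
        return np.eye(codes.max() + 1)[codes]

    Zc = onehot(df["cow_id"].to_numpy())
    Zd = onehot([f"{p}-{d}" for p, d in zip(df["period"], df["day"])])
    C = np.zeros((n, n))
    series = [f"{c}-{p}-{d}" for c, p, d in zip(df["cow_id"], df["period"], df["day"])]
    series = np.asarray(series)
    for s in np.unique(series):
        ix = np.flatnonzero(series == s)
        k = np.arange(ix.size)
        C[np.ix_(ix, ix)] = rho ** np.abs(k[:, None] - k[None, :])
    V = var_cow * Zc @ Zc.T + var_day * Zd @ Zd.T + var_resid * C
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return float(-0.5 * (np.linalg.slogdet(V)[1]
                         + np.linalg.slogdet(XtViX)[1]
                         + r @ Vi @ r))


class TestLikelihoodAgreement:
    def test_package_loglik_matches_dense_formula(self):
        rng = np.random.default_rng(21)
        df = simulate_repeated(rng, times=np.arange(6.0), n_days=2)
        fit = rg.fit_ar1_repeated(df, rg.RepeatedModelSpec("y"))
        model = fit.reml
        # rebuild the model to probe arbitrary points
        for vc, vd, ve, rho in [(1.0, 0.5, 1.0, 0.4), (0.2, 0.1, 2.0, -0.3),
                                (2.0, 1e-4, 0.5, 0.0), (0.7, 0.3, 1.2, 0.8)]:
            dense = dense_ar1_reml_loglik(df, "y", vc, vd, ve, rho)
            fast = _package_loglik(df, "y", [vc, vd, ve], rho)
            assert fast == pytest.approx(dense, abs=1e-7)

    def test_reduces_to_ols_without_correlation_or_groups(self):
        rng = np.random.default_rng(22)
        df = simulate_repeated(rng, times=np.arange(5.0), n_days=1,
                               cow_sd=0.0, day_sd=0.0, rho=0.0)
        fit = rg.fit_ar1_repeated(df, rg.RepeatedModelSpec("y"))
        # data carry no serial correlation or grouping: estimates approach OLS
        X, y, _ = _design(df, "y")
        beta_ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(fit.reml.beta, beta_ols, atol=0.05)
        assert abs(fit.rho_hat) < 0.2


def _design(df, response):
    df = df.sort_values(["cow_id", "period", "day", "time"]).reset_index(drop=True)
    y = df[response].to_numpy(float)
    trt = np.where(df["treatment"] == "nitrate", 0.5, -0.5)
    times = np.sort(df["time"].unique())
    cols = [(df["time"] == t).astype(float) - (df["time"] == times[-1]).astype(float)
            for t in times[:-1]]
    time_m = np.column_stack(cols)
    per = np.where(df["period"] == df["period"].min(), 1.0, -1.0)
    X = np.column_stack([np.ones(len(df)), trt, time_m, time_m * trt[:, None], per])
    return X, y, df


def _package_loglik(df, response, variances, rho):
    X, y, dfs = _design(df, response)
    cow = pd.factorize(dfs["cow_id"])[0]
    day = dfs.groupby(["period", "day"], sort=True).ngroup().to_numpy()
    series = dfs.groupby(["cow_id", "period", "day"], sort=True).ngroup().to_numpy()
    model = rg.MixedModel(y, X, groups={"cow": cow, "day": day}, series=series,
                          order=dfs["time"].to_numpy(float))
    return model.loglik(variances, rho)


class TestGridOracle:
    @pytest.mark.parametrize("seed", range(3))
    def test_optimum_beats_coarse_grid(self, seed):
        rng = np.random.default_rng(300 + seed)
        df = simulate_repeated(rng, times=np.arange(5.0), n_days=1)
        fit = rg.fit_ar1_repeated(df, rg.RepeatedModelSpec("y"))
        vc = fit.variance_components
        ll_opt = _package_loglik(
            df, "y",
            [max(vc["cow"], 1e-8), max(vc["day"], 1e-8), vc["residual"]],
            fit.rho_hat)
        vy = df["y"].var()
        axis = vy * np.array([0.02, 0.1, 0.3, 0.7, 1.5])
        best = -np.inf
        for a in axis:
            for b in axis:
                for c in axis:
                    for r in (-0.6, -0.2, 0.0, 0.2, 0.5, 0.8):
                        best = max(best, _package_loglik(df, "y", [a, b, c], r))
        assert ll_opt >= best - 1e-6


class TestParameterRecovery:
    def test_rho_and_effect_recovered(self):
        rng = np.random.default_rng(31)
        rhos, effs = [], []
        for _ in range(20):
            df = simulate_repeated(rng, rho=0.5, effect=-1.8)
            fit = rg.fit_ar1_repeated(df, rg.RepeatedModelSpec("y"))
            rhos.append(fit.rho_hat)
            effs.append(fit.treatment_lsmeans["nitrate"][0]
                        - fit.treatment_lsmeans["urea"][0])
        assert abs(np.mean(rhos) - 0.5) < 0.2
        se_mean = np.std(effs, ddof=1) / np.sqrt(len(effs))
        assert abs(np.mean(effs) - (-1.8)) < 3 * se_mean + 0.05


class TestLogTransformPath:
    def test_backtransform_unit_and_identity(self):
        m, se = rg.backtransform_lsmeans(0.0, 0.1)
        assert m == pytest.approx(1.0)
        assert se == pytest.approx(0.1)

    def test_constant_data_round_trips_exactly(self):
        rng = np.random.default_rng(41)
        df = simulate_repeated(rng, times=np.arange(4.0), n_days=1,
                               cow_sd=0, day_sd=0, resid_sd=0, baseline=0.0)
        df["y"] = 0.0073
        fit = rg.fit_ar1_repeated(df, rg.RepeatedModelSpec("y", transform="log"))
        for trt in ("urea", "nitrate"):
            assert fit.treatment_lsmeans[trt][0] == pytest.approx(0.0073, rel=1e-9)

    def test_lognormal_geometric_mean(self):
        # back-transform estimates the geometric mean exp(mu), below the
        # arithmetic mean exp(mu + sigma^2/2)
        rng = np.random.default_rng(42)
        x = rng.lognormal(mean=-4.8, sigma=0.5, size=10_000)
        m, _ = rg.backtransform_lsmeans(np.log(x).mean(), np.log(x).std() / 100)
        assert m == pytest.approx(np.exp(-4.8), rel=0.02)
        assert m < x.mean()

    def test_nonpositive_values_rejected(self):
        rng = np.random.default_rng(43)
        df = simulate_repeated(rng, times=np.arange(4.0), n_days=1, baseline=0.0)
        with pytest.raises(ValueError, match="positive"):
            rg.fit_ar1_repeated(df, rg.RepeatedModelSpec("y", transform="log"))


class TestInvariances:
    def test_additive_shift_leaves_variances_and_rho(self):
        rng = np.random.default_rng(51)
        df = simulate_repeated(rng, times=np.arange(5.0), n_days=1)
        f0 = rg.fit_ar1_repeated(df, rg.RepeatedModelSpec("y"))
        f1 = rg.fit_ar1_repeated(df.assign(y=df["y"] + 50.0),
                                 rg.RepeatedModelSpec("y"))
        assert f1.rho_hat == pytest.approx(f0.rho_hat, abs=1e-4)
        for k in ("cow", "day", "residual"):
            assert f1.variance_components[k] == pytest.approx(
                f0.variance_components[k], rel=1e-3, abs=1e-6)

    def test_cow_relabelling_is_irrelevant(self):
        rng = np.random.default_rng(52)
        df = simulate_repeated(rng, times=np.arange(5.0), n_days=1)
        f0 = rg.fit_ar1_repeated(df, rg.RepeatedModelSpec("y"))
        relabel = {c: f"x{i}" for i, c in enumerate(reversed(sorted(df.cow_id.unique())))}
        f1 = rg.fit_ar1_repeated(df.assign(cow_id=df["cow_id"].map(relabel)),
                                 rg.RepeatedModelSpec("y"))
        assert f1.rho_hat == pytest.approx(f0.rho_hat, abs=1e-4)
        assert f1.f_tests["treatment"]["F"] == pytest.approx(
            f0.f_tests["treatment"]["F"], rel=1e-4)


class TestContracts:
    def test_time_grid_mismatch_rejected(self):
        rng = np.random.default_rng(61)
        df = simulate_repeated(rng, times=np.arange(5.0), n_days=1)
        bad = df[~((df["treatment"] == "nitrate") & (df["time"] == 0.0))]
        with pytest.raises(ValueError, match="identical across treatments"):
            rg.fit_ar1_repeated(bad, rg.RepeatedModelSpec("y"))

    def test_short_series_rejected(self):
        rng = np.random.default_rng(62)
        df = simulate_repeated(rng, times=np.arange(2.0), n_days=1)
        with pytest.raises(ValueError, match=">= 3"):
            rg.fit_ar1_repeated(df, rg.RepeatedModelSpec("y"))

    def test_significance_labels(self):
        assert rg.significance_label(0.04) == "significant"
        assert rg.significance_label(0.06) == "tendency"
        assert rg.significance_label(0.27) == "ns"

    def test_significance_report_table(self):
        rng = np.random.default_rng(63)
        fit = rg.fit_crossover(
            pd.DataFrame({
                "cow_id": [f"c{i}" for i in range(4) for _ in (1, 2)],
                "period": [1, 2] * 4,
                "treatment": [rg.simulate.treatment_of(i, p)
                              for i in range(4) for p in (1, 2)],
                "y": rng.standard_normal(8),
            }), "y")
        rep = rg.significance_report([fit])
        assert set(rep["effect"]) == {"treatment", "period"}
        assert set(rep["label"]) <= {"significant", "tendency", "ns"}


class TestAgainstNlme:
    """Cross-check against R nlme::lme with corAR1 — the reference fitter."""

    def test_variances_rho_and_lsmeans_match_lme(self, tmp_path):
        rng = np.random.default_rng(71)
        df = simulate_repeated(rng, times=np.arange(8.0), n_days=2,
                               rho=0.5, effect=1.5, cow_sd=0.8, day_sd=0.3,
                               resid_sd=1.0)
        fit = rg.fit_ar1_repeated(df, rg.RepeatedModelSpec("y"))
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        script = textwrap.dedent(f"""
            suppressMessages(library(nlme)); suppressMessages(library(jsonlite))
            d <- read.csv("{csv}")
            d$treatment <- factor(d$treatment); d$timef <- factor(d$time)
            d$period <- factor(d$period)
            d$dayid <- factor(paste(d$period, d$day))
            m <- lme(y ~ treatment*timef + period,
                     random = list(cow_id = pdIdent(~1), dayid = pdIdent(~1)),
                     correlation = corAR1(form = ~1 | cow_id/dayid),
                     data = d, method = "REML")
            vc <- as.numeric(VarCorr(m)[c(2, 4, 5), "Variance"])
            rho <- as.numeric(coef(m$modelStruct$corStruct, unconstrained = FALSE))
            cat(toJSON(list(var_cow = vc[1], var_day = vc[2], var_resid = vc[3],
                            rho = rho), digits = 12))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        ref = {k: v[0] for k, v in json.loads(out.stdout).items()}
        vc = fit.variance_components
        ll_mine = dense_ar1_reml_loglik(df, "y", max(vc["cow"], 1e-12),
                                        max(vc["day"], 1e-12), vc["residual"],
                                        fit.rho_hat)
        ll_lme = dense_ar1_reml_loglik(df, "y", max(ref["var_cow"], 1e-12),
                                       max(ref["var_day"], 1e-12),
                                       ref["var_resid"], ref["rho"])
        # the REML surface can be multimodal; require our optimum to be at
        # least as good as lme's under the independent dense likelihood,
        # and the solutions to sit in the same region
        assert ll_mine >= ll_lme - 1e-4
        assert fit.rho_hat == pytest.approx(ref["rho"], abs=0.15)
        assert vc["residual"] == pytest.approx(ref["var_resid"], rel=0.25)
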