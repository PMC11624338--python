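"""The study's two mixed models: daily crossover and AR(1) repeated measures.

Model 1 (daily responses — DMI, gas productions, milk traits):

    y_ijk = mu + TREATMENT_i + PERIOD_j + COW_k + e_ijk,

cow random, residuals independent.  In the balanced 2x2 crossover the GLS
treatment estimate coincides with the classical sequence-contrast estimator
(half the difference between the two sequence groups' period-1 minus
period-2 means); the fit verifies that identity internally.  The treatment
t-test uses denominator df = n_cows - 2.

Model 2 (hourly chamber traces and headspace proportions):

    y_ijklm = mu + TREATMENT_i x TIME_j + PERIOD_k + COW_l + DAY_m + e_ijklm,

cow and sampling-day random, residuals AR(1)-correlated within each
cow x period x day series.  N2O proportions are log-transformed before the
fit and LSMEANS back-transformed by exponentiation (geometric means), with
delta-method standard errors.

Denominator degrees of freedom use a containment-style rule (documented in
each result): effects constant within a cow x period series are tested
against the between-series stratum, within-series effects against the
residual stratum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .mixedlm import MixedModel, REMLResult

SIGNIFICANT, TENDENCY = 0.05, 0.10


@dataclass(frozen=True)
class CrossoverModelSpec:
    """Model 1: fixed treatment + period, random cow, iid residual."""

    response: str
    fixed: tuple = ("treatment", "period")
    random: tuple = ("cow",)


@dataclass(frozen=True)
class RepeatedModelSpec:
    """Model 2: treatment x time + period fixed; cow, day random; AR(1).

    ``correlation='order'`` applies rho^|index gap| over the observation
    sequence (the default for the unequally spaced spot schedule);
    ``'time'`` uses rho^|dt| in clock hours.  ``transform='log'`` fits on
    the log scale and back-transforms LSMEANS.
    """

    response: str
    transform: str = "none"
    correlation: str = "order"
    log_offset: float = 0.0

    def __post_init__(self) -> None:
        if self.transform not in ("none", "log"):
            raise ValueError("transform must be 'none' or 'log'")


@dataclass
class CrossoverFit:
    """Daily-model estimates for one response."""

    response: str
    treatment_effect: float        # nitrate - urea, model scale
    se: float                      # SE of the treatment difference
    dfs: int                       # denominator df (n_cows - 2)
    t_stat: float
    p_treatment: float
    p_period: float
    lsmeans: dict                  # treatment -> LS mean
    se_lsmean: float               # SE of one treatment LS mean
    variance_components: dict      # cow, residual
    loglik: float
    reml: REMLResult = field(repr=False, default=None)


@dataclass
class RepeatedFit:
    """Repeated-measures estimates for one response."""

    response: str
    transform: str
    rho_hat: float
    variance_components: dict
    f_tests: dict                  # effect -> dict(F, ndf, ddf, p)
    lsmeans: pd.DataFrame          # treatment x time grid
    treatment_lsmeans: dict        # treatment -> (mean, se) on report scale
    df_method: str
    converged: bool
    boundary: bool
    reml: REMLResult = field(repr=False, default=None)


# --- model 1 ---------------------------------------------------------------


def _check_crossover(df: pd.DataFrame) -> None:
    trts = sorted(df["treatment"].unique())
    periods = sorted(df["period"].unique())
    if len(trts) != 2 or len(periods) != 2:
        raise ValueError(
            f"crossover model needs exactly 2 treatments and 2 periods; "
            f"found treatments={trts}, periods={periods}")
    counts = df.groupby(["cow_id", "period"]).size()
    if (counts != 1).any():
        raise ValueError("each cow must be observed exactly once per period")
    n_cows = df["cow_id"].nunique()
    if n_cows < 4:
        raise ValueError(f"crossover model needs >= 4 cows, found {n_cows}")
    per_cow = df.groupby("cow_id")["treatment"].nunique()
    if (per_cow != 2).any():
        raise ValueError("each cow must receive both treatments (one per period)")


def sequence_contrast_estimate(df: pd.DataFrame, response: str) -> float:
    """Closed-form balanced-crossover treatment estimate (nitrate - urea).

    Half the difference between the sequence groups' period-1 minus
    period-2 cow means: for cows starting on nitrate the within-cow
    difference carries +(nitrate - urea), for cows starting on urea the
    sign flips, and the period effect cancels.
    """
    wide = df.pivot_table(index="cow_id", columns="period", values=response)
    first_trt = df[df["period"] == df["period"].min()].set_index("cow_id")["treatment"]
    d = wide.iloc[:, 0] - wide.iloc[:, 1]
    d_nitrate_first = d[first_trt.reindex(d.index) == "nitrate"]
    d_urea_first = d[first_trt.reindex(d.index) == "urea"]
    if len(d_nitrate_first) == 0 or len(d_urea_first) == 0:
        raise ValueError("both treatment sequences must be present")
    return float((d_nitrate_first.mean() - d_urea_first.mean()) / 2.0)


def fit_crossover(summaries: pd.DataFrame, response: str) -> CrossoverFit:
    """REML fit of the daily crossover model for one response column."""
    needed = {"cow_id", "period", "treatment", response}
    missing = needed - set(summaries.columns)
    if missing:
        raise KeyError(f"summaries table lacks column(s) {sorted(missing)}")
    df = summaries[["cow_id", "period", "treatment", response]].dropna()
    _check_crossover(df)

    y = df[response].to_numpy(float)
    trt = (df["treatment"] == "nitrate").to_numpy(float)
    per = (df["period"] == sorted(df["period"].unique())[1]).to_numpy(float)
    X = np.column_stack([np.ones(len(df)), trt, per])
    cows, cow_codes = np.unique(df["cow_id"], return_inverse=True)
    n_cows = cows.size

    model = MixedModel(y, X, groups={"cow": cow_codes})
    res = model.fit()

    effect = float(res.beta[1])
    se = float(np.sqrt(max(res.cov_beta[1, 1], 0.0)))
    se_per = float(np.sqrt(max(res.cov_beta[2, 2], 0.0)))
    dfs = n_cows - 2

    # balanced-design identity check against the closed-form estimator
    counts = df.groupby(["treatment", "period"]).size()
    if counts.nunique() == 1:
        closed = sequence_contrast_estimate(df, response)
        scale = max(1.0, abs(closed))
        if abs(effect - closed) > 1e-6 * scale:
            raise AssertionError(
                f"GLS treatment estimate {effect!r} disagrees with the "
                f"sequence-contrast closed form {closed!r}")

    def p_of(est, s):
        if s == 0.0:
            return 1.0 if est == 0.0 else 0.0
        return float(2.0 * sps.t.sf(abs(est) / s, dfs))

    t_stat = effect / se if se > 0 else 0.0
    mu, b_per = float(res.beta[0]), float(res.beta[2])
    lsmeans = {"urea": mu + 0.5 * b_per, "nitrate": mu + effect + 0.5 * b_per}
    a = np.array([1.0, 0.0, 0.5])
    se_lsm = float(np.sqrt(max(a @ res.cov_beta @ a, 0.0)))

    return CrossoverFit(
        response=response, treatment_effect=effect, se=se, dfs=dfs,
        t_stat=t_stat, p_treatment=p_of(effect, se),
        p_period=p_of(b_per, se_per), lsmeans=lsmeans, se_lsmean=se_lsm,
        variance_components=dict(res.varcomp),
        loglik=res.loglik, reml=res)


# --- model 2 ---------------------------------------------------------------


def _sum_code(values: np.ndarray):
    """Sum-to-zero (deviation) coding; returns (matrix n x (L-1), levels)."""
    levels, codes = np.unique(values, return_inverse=True)
    L = levels.size
    M = np.zeros((values.size, L - 1))
    for j in range(L - 1):
        M[:, j] = (codes == j).astype(float) - (codes == L - 1).astype(float)
    return M, levels


def fit_ar1_repeated(data: pd.DataFrame, spec: RepeatedModelSpec,
                     time_col: str = "time") -> RepeatedFit:
    """REML fit of the repeated-measures model for one response.

    ``data`` is long format with columns cow_id, period, day, ``time_col``,
    treatment, and the response named by ``spec.response``.  Residuals are
    AR(1)-correlated within each cow x period x day series; cow and
    sampling day (period x day) are random.
    """
    response = spec.response
    needed = {"cow_id", "period", "day", time_col, "treatment", response}
    missing = needed - set(data.columns)
    if missing:
        raise KeyError(f"repeated-measures table lacks column(s) {sorted(missing)}")
    df = data.dropna(subset=[response]).copy()
    if df["cow_id"].nunique() < 2:
        raise ValueError("repeated model needs >= 2 cows per treatment")
    # identical time grid across treatments
    grids = df.groupby("treatment")[time_col].apply(lambda s: tuple(sorted(s.unique())))
    if grids.nunique() != 1:
        raise ValueError("time levels must be identical across treatments")
    if len(grids.iloc[0]) < 3:
        raise ValueError("repeated model needs series of length >= 3")

    y = df[response].to_numpy(float)
    if spec.transform == "log":
        y = y + spec.log_offset
        if np.any(y <= 0):
            raise ValueError(
                "log transform requires strictly positive responses; "
                "set RepeatedModelSpec.log_offset explicitly if zeros are expected")
        y = np.log(y)

    trt_s = np.where(df["treatment"].to_numpy() == "nitrate", 0.5, -0.5)
    time_m, time_levels = _sum_code(df[time_col].to_numpy(float))
    inter = time_m * trt_s[:, None]
    per_m, _ = _sum_code(df["period"].to_numpy())
    X = np.column_stack([np.ones(len(df)), trt_s, time_m, inter, per_m])
    T = time_levels.size

    cow_codes = pd.factorize(df["cow_id"])[0]
    day_codes = df.groupby(["period", "day"], sort=True).ngroup().to_numpy()
    series = df.groupby(["cow_id", "period", "day"], sort=True).ngroup().to_numpy()

    model = MixedModel(y, X, groups={"cow": cow_codes, "day": day_codes},
                       series=series, order=df[time_col].to_numpy(float),
                       correlation=spec.correlation)
    res = model.fit()
    beta, cov = res.beta, res.cov_beta

    # Wald F-tests per effect block (sum coding -> type-III-like tests)
    idx = {"treatment": [1],
           "time": list(range(2, 1 + T)),
           "treatment_x_time": list(range(1 + T, 2 * T)),
           "period": [2 * T]}
    n_cows = df["cow_id"].nunique()
    n_series = df.groupby(["cow_id", "period"]).ngroups
    n_day_levels = df.groupby(["period", "day"]).ngroups
    ddf_between = max(n_series - n_cows - 1, 1)
    ddf_within = max(len(df) - X.shape[1] - (n_cows - 1) - (n_day_levels - 1), 1)
    ddf_map = {"treatment": ddf_between, "period": ddf_between,
               "time": ddf_within, "treatment_x_time": ddf_within}

    f_tests = {}
    for name, cols in idx.items():
        b = beta[cols]
        Vb = cov[np.ix_(cols, cols)]
        q = len(cols)
        try:
            F = float(b @ np.linalg.solve(Vb, b) / q)
        except np.linalg.LinAlgError:
            F = np.inf
        ddf = ddf_map[name]
        f_tests[name] = {"F": max(F, 0.0), "ndf": q, "ddf": ddf,
                         "p": float(sps.f.sf(max(F, 0.0), q, ddf)) if np.isfinite(F) else 0.0}

    # LSMEANS on the treatment x time grid, period averaged out (sum coding)
    rows = []
    for trt, s in (("urea", -0.5), ("nitrate", 0.5)):
        for j, t in enumerate(time_levels):
            x = np.zeros(X.shape[1])
            x[0] = 1.0
            x[1] = s
            if j < T - 1:
                x[2 + j] = 1.0
                x[1 + T + j] = s
            else:
                x[2:1 + T] = -1.0
                x[1 + T:2 * T] = -s
            m = float(x @ beta)
            se = float(np.sqrt(max(x @ cov @ x, 0.0)))
            rows.append({"treatment": trt, "time": float(t), "mean": m, "se": se})
    lsm = pd.DataFrame(rows)
    if spec.transform == "log":
        bt_mean, bt_se = backtransform_lsmeans(lsm["mean"].to_numpy(),
                                               lsm["se"].to_numpy())
        lsm["backtransformed_mean"] = bt_mean - spec.log_offset
        lsm["backtransformed_se"] = bt_se

    trt_ls = {}
    for trt, s in (("urea", -0.5), ("nitrate", 0.5)):
        # averaging the grid contrasts over time zeroes the sum-coded
        # time and interaction columns, leaving [1, s, 0, ..., 0]
        x = np.zeros(X.shape[1])
        x[0], x[1] = 1.0, s
        m = float(x @ beta)
        se = float(np.sqrt(max(x @ cov @ x, 0.0)))
        if spec.transform == "log":
            bm, bse = backtransform_lsmeans(m, se)
            trt_ls[trt] = (float(bm) - spec.log_offset, float(bse))
        else:
            trt_ls[trt] = (m, se)

    return RepeatedFit(
        response=response, transform=spec.transform,
        rho_hat=float(res.rho), variance_components=dict(res.varcomp),
        f_tests=f_tests, lsmeans=lsm, treatment_lsmeans=trt_ls,
        df_method="containment-style (between-series / residual strata)",
        converged=res.converged, boundary=res.boundary, reml=res)


def backtransform_lsmeans(log_means, log_ses):
    """Geometric-mean back-transform of log-scale LSMEANS.

    Returns ``exp(mean)`` (no bias correction) and the delta-method SE
    ``exp(mean) * se``.
    """
    m = np.exp(np.asarray(log_means, float))
    return m, m * np.asarray(log_ses, float)


def significance_label(p: float) -> str:
    if p <= SIGNIFICANT:
        return "significant"
    if p <= TENDENCY:
        return "tendency"
    return "ns"


def significance_report(fits) -> pd.DataFrame:
    """P-value table across fits with significance / tendency / ns labels.

    Accepts :class:`CrossoverFit` and :class:`RepeatedFit` objects.
    """
    fits = list(fits)
    if not fits:
        raise ValueError("significance_report needs at least one fit")
    rows = []
    for f in fits:
        if isinstance(f, CrossoverFit):
            rows.append({"response": f.response, "effect": "treatment",
                         "p": f.p_treatment, "label": significance_label(f.p_treatment)})
            rows.append({"response": f.response, "effect": "period",
                         "p": f.p_period, "label": significance_label(f.p_period)})
        elif isinstance(f, RepeatedFit):
            for name, ft in f.f_tests.items():
                rows.append({"response": f.response, "effect": name,
                             "p": ft["p"], "label": significance_label(ft["p"])})
        else:
            raise TypeError(f"unsupported fit object {type(f).__name__}")
    return pd.DataFrame(rows)
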