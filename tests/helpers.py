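"""Shared simulation helpers for the model tests."""

import numpy as np
import pandas as pd

import rumengas as rg


def crossover_frame(values_by_cow_period, treatments=None):
    """Build a summaries-like frame from {cow: {period: y}} for model tests."""
    rows = []
    cows = sorted(values_by_cow_period)
    for i, cow in enumerate(cows):
        for period, y in sorted(values_by_cow_period[cow].items()):
            trt = (treatments[cow][period] if treatments
                   else rg.simulate.treatment_of(i, period))
            rows.append({"cow_id": cow, "period": period, "treatment": trt, "y": y})
    return pd.DataFrame(rows)


def simulate_crossover(rng, n_cows=4, effect=0.0, period_eff=0.5,
                       cow_sd=1.0, resid_sd=1.0):
    """Direct draw from the daily crossover model (balanced sequences)."""
    rows = []
    cow_effects = rng.standard_normal(n_cows) * cow_sd
    for c in range(n_cows):
        for period in (1, 2):
            trt = rg.simulate.treatment_of(c, period)
            y = (cow_effects[c]
                 + (period_eff if period == 2 else 0.0)
                 + (effect if trt == "nitrate" else 0.0)
                 + rng.standard_normal() * resid_sd)
            rows.append({"cow_id": f"c{c}", "period": period, "treatment": trt, "y": y})
    return pd.DataFrame(rows)


def simulate_repeated(rng, n_cows=4, n_days=2, times=None, effect=-1.8,
                      rho=0.5, cow_sd=1.0, day_sd=0.5, resid_sd=1.0,
                      baseline=20.0):
    """Direct draw from the repeated-measures model with AR(1) residuals."""
    times = np.asarray(rg.HEADSPACE_TIMES if times is None else times, float)
    T = times.size
    rows = []
    cow_eff = rng.standard_normal(n_cows) * cow_sd
    day_eff = rng.standard_normal((2, n_days)) * day_sd
    for c in range(n_cows):
        for period in (1, 2):
            trt = rg.simulate.treatment_of(c, period)
            shift = effect / 2 if trt == "nitrate" else -effect / 2
            for d in range(n_days):
                e = np.empty(T)
                z = rng.standard_normal(T)
                e[0] = resid_sd * z[0]
                for k in range(1, T):
                    e[k] = rho * e[k - 1] + np.sqrt(1 - rho**2) * resid_sd * z[k]
                y = (baseline + shift + 0.3 * np.sin(times / 24 * 2 * np.pi)
                     + cow_eff[c] + day_eff[period - 1, d] + e)
                for t, v in zip(times, y):
                    rows.append({"cow_id": f"c{c}", "period": period, "day": d + 1,
                                 "time": float(t), "treatment": trt, "y": float(v)})
    return pd.DataFrame(rows)
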