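"""Headspace air-contamination correction and the N2O:CH4 anchor ratio.

Spot samples drawn from the rumen headspace through a cannula are variably
diluted with atmospheric air.  Because the contaminating air is essentially
N2 and O2, the true rumen gas composition is recovered by assuming that
CO2, CH4 and N2O together make up 100% of the undiluted headspace: the
three fractions are renormalised to sum to 100 vol% and N2/O2 discarded.
The renormalisation is invariant to the (unknown) dilution fraction, which
is what makes spot sampling usable at all.

The corrected proportions feed the N2O:CH4 volume ratio that anchors N2O
production to the chamber-measured CH4 production.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ATMOSPHERE_VOL_PCT
from .tables import ANCHOR_RATIOS, CORRECTED_HEADSPACE, HEADSPACE

TRUE_GASES = ("co2", "ch4", "n2o")
RATIO_METHODS = ("per-sample-mean", "ratio-of-means", "time-weighted")


class DegenerateSampleError(ValueError):
    """A sample whose CO2 + CH4 + N2O content is zero cannot be corrected."""


@dataclass(frozen=True)
class AnchorRatio:
    """N2O:CH4 volume ratio (L/L) for one cow x period.

    ``method`` records the aggregation across the spot-sample schedule;
    ``n_samples`` the number of corrected samples used.
    """

    cow_id: str
    period: int
    ratio: float
    n_samples: int
    method: str

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("anchor ratio must be non-negative")
        if self.n_samples < 1:
            raise ValueError("anchor ratio needs at least one sample")


def correct_air_contamination(samples: pd.DataFrame) -> pd.DataFrame:
    """Correct raw headspace samples for atmospheric-air contamination.

    Each of CO2, CH4 and N2O is divided by their three-gas sum and rescaled
    to 100 vol%; N2 and O2 are discarded.  The output triplet sums to 100
    within 1e-9 per sample.  Idempotent, and invariant to dilution with
    N2/O2-only air by construction.

    Raises
    ------
    ValueError
        If any gas fraction is negative.
    DegenerateSampleError
        If CO2 + CH4 + N2O is zero for some sample.
    """
    df = HEADSPACE.validate(samples) if "n2" in samples.columns else samples.copy()
    gas_cols = [c for c in ("co2", "ch4", "n2o", "n2", "o2") if c in df.columns]
    vals = df[gas_cols].to_numpy(float)
    if np.any(vals < 0):
        raise ValueError("negative gas volume fraction in headspace sample")
    three = df[list(TRUE_GASES)].to_numpy(float)
    total = three.sum(axis=1)
    if np.any(total <= 0):
        bad = int(np.flatnonzero(total <= 0)[0])
        raise DegenerateSampleError(
            f"sample row {bad}: CO2 + CH4 + N2O sum is zero; cannot renormalise"
        )
    out = df[["cow_id", "period", "day", "time_rel_feeding"]].copy()
    for j, gas in enumerate(TRUE_GASES):
        out[gas] = three[:, j] / total * 100.0
    return CORRECTED_HEADSPACE.validate(out)


def dilute_with_air(samples: pd.DataFrame, f, air: dict | None = None) -> pd.DataFrame:
    """Dilute true headspace proportions with an air fraction ``f``.

    The forward model of contamination: every true gas is multiplied by
    ``(1 - f)`` and the air composition added at fraction ``f``.  ``f`` may
    be a scalar or a per-row array in [0, 1).  Used by the generator and by
    the dilution-invariance property tests.
    """
    air = dict(ATMOSPHERE_VOL_PCT) if air is None else air
    f = np.asarray(f, dtype=float)
    if np.any((f < 0) | (f >= 1)):
        raise ValueError("air fraction f must lie in [0, 1)")
    df = samples.copy()
    for gas in TRUE_GASES:
        df[gas] = df[gas].to_numpy(float) * (1 - f) + air.get(gas, 0.0) * f
    df["n2"] = air["n2"] * f * np.ones(len(df))
    df["o2"] = air["o2"] * f * np.ones(len(df))
    return HEADSPACE.validate(df)


def _cyclic_trapezoid_mean(times: np.ndarray, values: np.ndarray,
                           cycle: float = 24.0) -> float:
    """Time-weighted mean of an unevenly sampled 24-h cyclic series."""
    order = np.argsort(times)
    t = times[order]
    v = values[order]
    t = np.append(t, t[0] + cycle)
    v = np.append(v, v[0])
    dt = np.diff(t)
    return float(np.sum(dt * (v[:-1] + v[1:]) / 2.0) / cycle)


def anchor_ratio(corrected: pd.DataFrame, method: str = "time-weighted") -> AnchorRatio:
    """Aggregate one cow x period's corrected samples into an anchor ratio.

    Methods
    -------
    per-sample-mean
        Arithmetic mean of the per-sample N2O/CH4 ratios.
    ratio-of-means
        Mean N2O proportion divided by mean CH4 proportion.
    time-weighted (default)
        Trapezoidal time average of the per-sample ratios over the cyclic
        24-h schedule, computed per sampling day and averaged across days.
        Preferred because the spot schedule is front-loaded after the
        morning feeding, which an unweighted mean over-represents.
    """
    if method not in RATIO_METHODS:
        raise ValueError(f"unknown ratio method '{method}'; choose from {RATIO_METHODS}")
    if len(corrected) == 0:
        raise ValueError("anchor_ratio requires at least one corrected sample")
    for col in ("cow_id", "period"):
        if corrected[col].nunique() != 1:
            raise ValueError("anchor_ratio expects samples from a single cow x period")
    ch4 = corrected["ch4"].to_numpy(float)
    n2o = corrected["n2o"].to_numpy(float)
    if np.any(ch4 <= 0):
        raise DegenerateSampleError("a sample has zero CH4 proportion; ratio undefined")

    if method == "per-sample-mean":
        ratio = float(np.mean(n2o / ch4))
    elif method == "ratio-of-means":
        ratio = float(np.mean(n2o) / np.mean(ch4))
    else:
        per_day = []
        for _, day_df in corrected.groupby("day"):
            t = day_df["time_rel_feeding"].to_numpy(float)
            r = day_df["n2o"].to_numpy(float) / day_df["ch4"].to_numpy(float)
            per_day.append(_cyclic_trapezoid_mean(t, r))
        ratio = float(np.mean(per_day))
    return AnchorRatio(
        cow_id=str(corrected["cow_id"].iloc[0]),
        period=int(corrected["period"].iloc[0]),
        ratio=ratio,
        n_samples=len(corrected),
        method=method,
    )


def anchor_ratios(corrected: pd.DataFrame, method: str = "time-weighted") -> pd.DataFrame:
    """Anchor ratios for every cow x period present, as a table."""
    rows = []
    for (cow, period), grp in corrected.groupby(["cow_id", "period"], sort=True):
        ar = anchor_ratio(grp, method=method)
        rows.append({
            "cow_id": cow, "period": period, "ratio": ar.ratio,
            "n_samples": ar.n_samples, "method": ar.method,
        })
    return ANCHOR_RATIOS.validate(pd.DataFrame(rows))


def diurnal_profile(corrected: pd.DataFrame, gas: str,
                    treatments: pd.DataFrame | None = None,
                    transform: str = "none") -> pd.DataFrame:
    """Per time-point mean +/- SE of a gas proportion, by treatment.

    In the balanced designs this module targets, least-squares means reduce
    to arithmetic means over the cow x day replicates at each time point;
    that identity is what is computed here.  With ``transform='log'`` the
    mean and SE are computed on the log scale and a geometric-mean
    back-transform is reported alongside.

    ``treatments`` maps (cow_id, period) -> treatment; if omitted a single
    pooled profile is returned.
    """
    df = corrected.copy()
    if gas not in df.columns:
        raise KeyError(f"gas '{gas}' not in corrected table")
    if treatments is not None:
        df = df.merge(treatments[["cow_id", "period", "treatment"]],
                      on=["cow_id", "period"], how="left")
        if df["treatment"].isna().any():
            raise ValueError("treatment assignment missing for some cow x period")
        keys = ["treatment", "time_rel_feeding"]
    else:
        keys = ["time_rel_feeding"]
    y = df[gas].to_numpy(float)
    if transform == "log":
        if np.any(y <= 0):
            raise ValueError("log transform requires strictly positive proportions")
        df["_y"] = np.log(y)
    elif transform == "none":
        df["_y"] = y
    else:
        raise ValueError("transform must be 'none' or 'log'")
    g = df.groupby(keys)["_y"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    out["se"] = out["sd"] / np.sqrt(out["n"])
    if transform == "log":
        out["backtransformed_mean"] = np.exp(out["mean"])
    return out.drop(columns="sd")
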