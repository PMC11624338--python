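"""Synthetic crossover-study generator.

Emulates a 4-cow, 2-treatment (urea vs nitrate), 2-period crossover with:

* hourly respiration-chamber traces (CH4, CO2, H2, O2 mass flows) following
  an additive diurnal model — baseline plus two feeding-anchored exponential
  -decay peaks — with cow and day random effects and AR(1) hourly noise;
* 16 rumen-headspace spot samples per cow and sampling day on the study's
  front-loaded schedule, with true CO2/CH4/N2O proportions summing to 100
  vol% and random dilution by atmospheric air;
* per cow x period daily summaries (DMI, milk yield and composition, daily
  gas productions) feeding the derived emission metrics.

Default parameter values are calibrated to the study's reported treatment
means; all randomness flows from a single seed through named substreams so
any one stage is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ATMOSPHERE_VOL_PCT, DEFAULT_CONFIG, StudyConfig
from .tables import CHAMBER, CORRECTED_HEADSPACE, HEADSPACE, SUMMARY
from . import quantify

TREATMENTS = ("urea", "nitrate")

#: Spot-sampling schedule, hours relative to the morning feeding (0540 h):
#: clock times 0600..0930 every 30 min, then 1030, 1130, 1230, 1430, 1630,
#: 1830, 2030, and 0530 the next morning (cyclic point at 23.83 h).
HEADSPACE_TIMES = (
    1 / 3, 5 / 6, 4 / 3, 11 / 6, 7 / 3, 17 / 6, 10 / 3, 23 / 6,
    29 / 6, 35 / 6, 41 / 6, 53 / 6, 65 / 6, 77 / 6, 89 / 6, 143 / 6,
)

_STREAMS = {"chamber": 1, "headspace": 2, "summaries": 3}


@dataclass(frozen=True)
class GasParams:
    """Diurnal + variance parameters for one gas trace.

    ``hourly_mean`` (per treatment) is the 24-h grid mean the noise-free
    curve reproduces exactly; ``peak_frac`` scales the post-feeding peak
    relative to the mean (nitrate peaks are flatter); ``decay`` is the
    exponential decay constant (1/h) of each feeding peak.  ``cow_sd``,
    ``day_sd`` and ``resid_sd`` are on the response (g/h or vol%) scale;
    ``rho`` is the AR(1) correlation of successive residuals.
    """

    hourly_mean: dict
    peak_frac: dict
    decay: float = 0.5
    cow_sd: float = 0.0
    day_sd: float = 0.0
    resid_sd: float = 0.0
    rho: float = 0.5


@dataclass(frozen=True)
class TraitParams:
    """Per-treatment mean plus cow/residual SDs for a daily trait."""

    mean: dict
    cow_sd: float = 0.0
    resid_sd: float = 0.0


def _default_chamber_gases() -> dict:
    return {
        "ch4": GasParams(
            hourly_mean={"urea": 17.4, "nitrate": 15.1},
            peak_frac={"urea": 0.35, "nitrate": 0.15},
            cow_sd=1.2, day_sd=0.3, resid_sd=1.0, rho=0.5,
        ),
        "h2": GasParams(
            hourly_mean={"urea": 0.06, "nitrate": 0.19},
            peak_frac={"urea": 0.6, "nitrate": 0.6},
            cow_sd=0.01, day_sd=0.004, resid_sd=0.015, rho=0.5,
        ),
        "co2": GasParams(
            hourly_mean={"urea": 605.9, "nitrate": 622.7},
            peak_frac={"urea": 0.2, "nitrate": 0.2},
            cow_sd=35.0, day_sd=10.0, resid_sd=25.0, rho=0.5,
        ),
        "o2": GasParams(
            hourly_mean={"urea": 392.6, "nitrate": 401.0},
            peak_frac={"urea": 0.1, "nitrate": 0.1},
            cow_sd=22.0, day_sd=7.0, resid_sd=15.0, rho=0.5,
        ),
    }


def _default_headspace_ch4() -> GasParams:
    return GasParams(
        hourly_mean={"urea": 20.5, "nitrate": 18.7},
        peak_frac={"urea": 0.25, "nitrate": 0.12},
        cow_sd=1.5, day_sd=0.5, resid_sd=1.2, rho=0.5,
    )


def _default_headspace_n2o() -> GasParams:
    # N2O proportions are log-normal: SDs act on the log scale.
    return GasParams(
        hourly_mean={"urea": 0.001, "nitrate": 0.008},
        peak_frac={"urea": 0.0, "nitrate": 0.0},
        cow_sd=0.25, day_sd=0.10, resid_sd=0.30, rho=0.5,
    )


def _default_traits() -> dict:
    return {
        "dmi": TraitParams({"urea": 22.9, "nitrate": 23.0}, cow_sd=1.6, resid_sd=0.8),
        "milk": TraitParams({"urea": 24.5, "nitrate": 24.5}, cow_sd=3.5, resid_sd=1.0),
        "fat_pct": TraitParams({"urea": 4.54, "nitrate": 4.51}, cow_sd=0.40, resid_sd=0.10),
        "protein_pct": TraitParams({"urea": 3.91, "nitrate": 3.94}, cow_sd=0.24, resid_sd=0.06),
        "lactose_pct": TraitParams({"urea": 4.71, "nitrate": 4.75}, cow_sd=0.09, resid_sd=0.03),
    }


@dataclass(frozen=True)
class GeneratorParams:
    """All knobs of the synthetic study.

    Defaults are the study conditions: 4 cows in a balanced 2x2 crossover
    (2 cows per treatment sequence), 4 chamber days and 2 headspace sampling
    days per period, gas means calibrated to the reported treatment means,
    and headspace air contamination uniform on ``contamination_range``.
    """

    n_cows: int = 4
    n_periods: int = 2
    n_chamber_days: int = 4
    n_headspace_days: int = 2
    chamber_gases: dict = field(default_factory=_default_chamber_gases)
    headspace_ch4: GasParams = field(default_factory=_default_headspace_ch4)
    headspace_n2o: GasParams = field(default_factory=_default_headspace_n2o)
    traits: dict = field(default_factory=_default_traits)
    contamination_range: tuple = (0.0, 0.4)
    air: dict = field(default_factory=lambda: dict(ATMOSPHERE_VOL_PCT))
    headspace_times: tuple = HEADSPACE_TIMES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cows < 2 or self.n_cows % 2:
            raise ValueError("n_cows must be an even count >= 2 (balanced sequences)")
        if self.n_periods != 2:
            raise ValueError("the crossover generator supports exactly 2 periods")
        lo, hi = self.contamination_range
        if not (0.0 <= lo <= hi <= 0.9):
            raise ValueError("contamination_range must satisfy 0 <= lo <= hi <= 0.9")
        for gp in list(self.chamber_gases.values()) + [self.headspace_ch4, self.headspace_n2o]:
            if min(gp.cow_sd, gp.day_sd, gp.resid_sd) < 0:
                raise ValueError("variance components must be non-negative")
            if not -1 < gp.rho < 1:
                raise ValueError("rho must lie in (-1, 1)")

    def replace(self, **kw) -> "GeneratorParams":
        return dataclasses.replace(self, **kw)


# --- helpers ---------------------------------------------------------------


def _rng(params: GeneratorParams, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(params.seed), spawn_key=(_STREAMS[stream],))
    )


def cow_ids(params: GeneratorParams) -> list:
    return [f"cow{i + 1}" for i in range(params.n_cows)]


def sequence_of(cow_index: int) -> str:
    """Balanced sequence assignment: even cows urea->nitrate, odd reversed."""
    return "urea-nitrate" if cow_index % 2 == 0 else "nitrate-urea"


def treatment_of(cow_index: int, period: int) -> str:
    first, second = sequence_of(cow_index).split("-")
    return first if period == 1 else second


def diurnal_shape(t, decay: float, config: StudyConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Unnormalised two-peak diurnal shape at hours ``t`` after morning feeding.

    Each feeding launches an exponential decay ``exp(-decay * dt)`` where
    ``dt`` is the time since that feeding within the 24-h cycle.
    """
    t = np.asarray(t, dtype=float)
    evening = (config.feeding_times[1] - config.feeding_times[0]) % 24.0
    dt_m = np.mod(t, 24.0)
    dt_e = np.mod(t - evening, 24.0)
    return np.exp(-decay * dt_m) + np.exp(-decay * dt_e)


def diurnal_curve(t, mean: float, peak_frac: float, decay: float,
                  grid, config: StudyConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Noise-free diurnal trace with exact mean ``mean`` over ``grid``.

    ``curve(t) = mean * (1 + peak_frac * (g(t) - mean_grid(g)))`` where g is
    :func:`diurnal_shape`; normalising on the sampling grid makes the grid
    average of the noise-free curve equal ``mean`` exactly, so calibration
    targets are the grid means themselves.
    """
    g = diurnal_shape(t, decay, config)
    gbar = float(np.mean(diurnal_shape(np.asarray(grid, float), decay, config)))
    return mean * (1.0 + peak_frac * (g - gbar))


def _ar1_noise(rng: np.random.Generator, shape: tuple, sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) noise along the last axis."""
    z = rng.standard_normal(shape)
    if sd == 0:
        return np.zeros(shape)
    e = np.empty(shape)
    e[..., 0] = sd * z[..., 0]
    c = np.sqrt(1.0 - rho**2)
    for k in range(1, shape[-1]):
        e[..., k] = rho * e[..., k - 1] + c * sd * z[..., k]
    return e


def _effects(rng, n, sd):
    return rng.standard_normal(n) * sd


# --- generators ------------------------------------------------------------


def generate_chamber(params: GeneratorParams,
                     config: StudyConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Hourly chamber records for every cow x period x day (24 rows each)."""
    rng = _rng(params, "chamber")
    hours = np.arange(24, dtype=float)
    nc, np_, nd, nh = params.n_cows, params.n_periods, params.n_chamber_days, 24

    frames = {}
    for gas, gp in params.chamber_gases.items():
        cow_eff = _effects(rng, nc, gp.cow_sd)
        day_eff = _effects(rng, (np_, nd), gp.day_sd)  # shared across cows
        noise = _ar1_noise(rng, (nc, np_, nd, nh), gp.resid_sd, gp.rho)
        flow = np.empty((nc, np_, nd, nh))
        for c in range(nc):
            for p in range(np_):
                trt = treatment_of(c, p + 1)
                base = diurnal_curve(hours, gp.hourly_mean[trt], gp.peak_frac[trt],
                                     gp.decay, hours, config)
                flow[c, p] = base[None, :] + cow_eff[c] + day_eff[p][:, None] + noise[c, p]
        frames[gas] = np.clip(flow, 0.0, None)

    idx = pd.MultiIndex.from_product(
        [cow_ids(params), range(1, np_ + 1), range(1, nd + 1), hours],
        names=["cow_id", "period", "day", "hour_rel_feeding"],
    )
    df = pd.DataFrame(index=idx).reset_index()
    for gas in params.chamber_gases:
        df[gas] = frames[gas].reshape(-1)
    return CHAMBER.validate(df)


def generate_headspace(params: GeneratorParams,
                       config: StudyConfig = DEFAULT_CONFIG,
                       return_truth: bool = False):
    """Raw (air-diluted) headspace spot samples on the 16-point schedule.

    True proportions: CH4 follows the same two-peak diurnal model as the
    chamber trace (on the vol% scale), N2O is log-normal around its
    treatment mean, CO2 is the complement so the truth sums to 100 vol%.
    Each sample is then diluted by an air fraction ``f`` drawn uniformly
    from ``contamination_range``: gas * (1 - f) + air_composition * f.

    With ``return_truth=True`` also returns the undiluted proportions as a
    corrected-headspace table (the generator's ground truth).
    """
    rng = _rng(params, "headspace")
    times = np.asarray(params.headspace_times, dtype=float)
    nc, np_, nd, nt = params.n_cows, params.n_periods, params.n_headspace_days, len(times)

    gp4 = params.headspace_ch4
    cow4 = _effects(rng, nc, gp4.cow_sd)
    day4 = _effects(rng, (np_, nd), gp4.day_sd)
    e4 = _ar1_noise(rng, (nc, np_, nd, nt), gp4.resid_sd, gp4.rho)

    gpn = params.headspace_n2o
    cown = _effects(rng, nc, gpn.cow_sd)
    dayn = _effects(rng, (np_, nd), gpn.day_sd)
    en = _ar1_noise(rng, (nc, np_, nd, nt), gpn.resid_sd, gpn.rho)

    ch4 = np.empty((nc, np_, nd, nt))
    n2o = np.empty((nc, np_, nd, nt))
    for c in range(nc):
        for p in range(np_):
            trt = treatment_of(c, p + 1)
            curve4 = diurnal_curve(times, gp4.hourly_mean[trt], gp4.peak_frac[trt],
                                   gp4.decay, times, config)
            ch4[c, p] = curve4[None, :] + cow4[c] + day4[p][:, None] + e4[c, p]
            n2o[c, p] = np.exp(np.log(gpn.hourly_mean[trt])
                               + cown[c] + dayn[p][:, None] + en[c, p])
    ch4 = np.clip(ch4, 0.05, 95.0)
    co2 = 100.0 - ch4 - n2o
    if np.any(co2 <= 0):
        raise ValueError("headspace parameters leave no room for CO2 (truth < 0)")

    f = rng.uniform(*params.contamination_range, size=ch4.shape)
    air = params.air
    raw = {
        "co2": co2 * (1 - f) + air["co2"] * f,
        "ch4": ch4 * (1 - f) + air["ch4"] * f,
        "n2o": n2o * (1 - f) + air["n2o"] * f,
        "n2": air["n2"] * f,
        "o2": air["o2"] * f,
    }

    idx = pd.MultiIndex.from_product(
        [cow_ids(params), range(1, np_ + 1), range(1, nd + 1), times],
        names=["cow_id", "period", "day", "time_rel_feeding"],
    )
    df = pd.DataFrame(index=idx).reset_index()
    for gas, arr in raw.items():
        df[gas] = arr.reshape(-1)
    df = HEADSPACE.validate(df)
    if not return_truth:
        return df
    truth = df[["cow_id", "period", "day", "time_rel_feeding"]].copy()
    truth["co2"] = co2.reshape(-1)
    truth["ch4"] = ch4.reshape(-1)
    truth["n2o"] = n2o.reshape(-1)
    return df, CORRECTED_HEADSPACE.validate(truth)


def generate_summaries(params: GeneratorParams, chamber: pd.DataFrame,
                       config: StudyConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Cow x period daily summaries; gas productions are chamber averages.

    Daily production of each gas is the mean hourly flow over all recorded
    hours times 24.  DMI, milk yield and composition are drawn around the
    configured treatment means with cow and cow-x-period noise; ECM, FPCM
    and GEI are computed, never free inputs.
    """
    rng = _rng(params, "summaries")
    nc, np_ = params.n_cows, params.n_periods
    traits = params.traits
    cow_eff = {k: _effects(rng, nc, tp.cow_sd) for k, tp in traits.items()}
    res_eff = {k: _effects(rng, (nc, np_), tp.resid_sd) for k, tp in traits.items()}

    rows = []
    for c, cow in enumerate(cow_ids(params)):
        for p in range(1, np_ + 1):
            trt = treatment_of(c, p)
            sub = chamber[(chamber.cow_id == cow) & (chamber.period == p)]
            if len(sub) == 0:
                raise ValueError(f"no chamber records for {cow} period {p}")
            row = {
                "cow_id": cow,
                "period": p,
                "treatment": trt,
                "sequence": sequence_of(c),
            }
            for gas in ("ch4", "h2", "co2", "o2"):
                row[f"{gas}_g_d"] = float(sub[gas].mean() * 24.0)
            for k, tp in traits.items():
                row[k] = max(tp.mean[trt] + cow_eff[k][c] + res_eff[k][c, p - 1], 0.05)
            row["ecm"] = quantify.ecm(row["milk"], row["fat_pct"],
                                      row["protein_pct"], row["lactose_pct"])
            row["fpcm"] = quantify.fpcm(row["milk"], row["fat_pct"], row["protein_pct"])
            row["gei"] = row["dmi"] * config.diet_ge
            rows.append(row)
    return SUMMARY.validate(pd.DataFrame(rows))


def generate_study(params: GeneratorParams,
                   config: StudyConfig = DEFAULT_CONFIG) -> dict:
    """Generate the full study: chamber, headspace and summary tables."""
    chamber = generate_chamber(params, config)
    headspace = generate_headspace(params, config)
    summaries = generate_summaries(params, chamber, config)
    return {"chamber": chamber, "headspace": headspace, "summaries": summaries}
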