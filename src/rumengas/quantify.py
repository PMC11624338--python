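"""Emission quantities: daily productions, anchored N2O, yields, intensities.

Daily gas production is the chamber average over the last four whole
measurement days.  N2O — too dilute for the chamber analysers — is
quantified by anchoring: daily N2O (L/d) = daily CH4 (L/d) x the headspace
N2O:CH4 volume ratio (L/L), converted to grams with the ideal gas law.
Because both gases share the same molar volume the litre intermediates
cancel and the mass form is

    n2o (g/d) = ch4 (g/d) / M_CH4 * ratio * M_N2O,

which is exactly invariant to the reference temperature/pressure choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, StudyConfig
from .headspace import AnchorRatio
from .tables import METRICS


@dataclass(frozen=True)
class EmissionMetrics:
    """Derived per cow x period emission metrics (all non-negative)."""

    cow_id: str
    period: int
    treatment: str
    ch4_g_d: float
    h2_g_d: float
    co2_g_d: float
    n2o_g_d: float
    ch4_yield: float      # g/kg DMI
    h2_yield: float       # g/kg DMI
    ch4_per_ecm: float    # g/kg ECM
    ch4_per_fpcm: float   # g/kg FPCM
    ch4_gei_pct: float    # % of gross energy intake


def daily_production(hourly: pd.DataFrame, gas: str, n_days: int = 4) -> float:
    """Daily production (g/d) for one cow x period from hourly records.

    Mean hourly flow times 24, averaged over the last ``n_days`` whole
    (24-record) days.  Raises on incomplete final days, listing what is
    missing.
    """
    if gas not in hourly.columns:
        raise KeyError(f"gas '{gas}' not in chamber table")
    if len(hourly) < 24:
        raise ValueError("daily_production needs at least 24 hourly records")
    days = sorted(hourly["day"].unique())
    use = days[-n_days:]
    if len(use) < n_days:
        raise ValueError(f"only {len(use)} day(s) present; {n_days} required")
    daily = []
    for d in use:
        sub = hourly[hourly["day"] == d]
        if len(sub) != 24:
            missing = sorted(set(range(24)) - set(sub["hour_rel_feeding"].astype(int)))
            raise ValueError(f"day {d} incomplete: missing hour(s) {missing}")
        daily.append(sub[gas].mean() * 24.0)
    return float(np.mean(daily))


def n2o_daily_production(ch4_g_d: float, ratio, config: StudyConfig = DEFAULT_CONFIG,
                         diagnostics: bool = False):
    """Anchored daily N2O production (g/d).

    ``ratio`` may be an :class:`AnchorRatio` or a bare float (L/L).  With
    ``diagnostics=True`` also returns the L/d intermediates at the
    configured molar volume; the mass result does not depend on it.
    """
    r = ratio.ratio if isinstance(ratio, AnchorRatio) else float(ratio)
    if ch4_g_d < 0 or r < 0:
        raise ValueError("CH4 production and anchor ratio must be non-negative")
    if config.molar_mass_ch4 <= 0 or config.molar_mass_n2o <= 0:
        raise ValueError("molar masses must be strictly positive")
    mol_ch4 = ch4_g_d / config.molar_mass_ch4
    n2o_g = mol_ch4 * r * config.molar_mass_n2o
    if not diagnostics:
        return n2o_g
    ch4_l = mol_ch4 * config.molar_volume
    return n2o_g, {"ch4_l_d": ch4_l, "n2o_l_d": ch4_l * r,
                   "molar_volume": config.molar_volume}


def ecm(milk: float, fat_pct: float, protein_pct: float, lactose_pct: float) -> float:
    """Energy-corrected milk (kg/d), 3,140 kJ/kg reference energy.

    ECM = milk * (38.3*fat + 24.2*protein + 16.54*lactose + 20.7) / 3140
    with the components in g/kg.
    """
    _check_composition(milk, fat=fat_pct, protein=protein_pct, lactose=lactose_pct)
    energy = (38.3 * fat_pct * 10 + 24.2 * protein_pct * 10
              + 16.54 * lactose_pct * 10 + 20.7)
    return float(milk * energy / 3140.0)


def fpcm(milk: float, fat_pct: float, protein_pct: float) -> float:
    """Fat- and protein-corrected milk (kg/d).

    FPCM = milk * (0.337 + 0.116 * fat% + 0.06 * protein%).
    """
    _check_composition(milk, fat=fat_pct, protein=protein_pct)
    return float(milk * (0.337 + 0.116 * fat_pct + 0.06 * protein_pct))


def _check_composition(milk: float, **pcts: float) -> None:
    if milk <= 0:
        raise ValueError("milk yield must be strictly positive")
    for name, v in pcts.items():
        if not 0 < v < 15:
            raise ValueError(f"{name} percentage {v} outside the plausible (0, 15) range")


def emission_metrics(summary: pd.Series | dict, n2o_g_d: float,
                     config: StudyConfig = DEFAULT_CONFIG) -> EmissionMetrics:
    """Yields, intensities and the GEI fraction for one cow x period summary.

    GEI is DMI x dietary gross-energy concentration; the CH4 energy fraction
    uses the configured gross energy of methane (default 55.65 kJ/g).
    """
    s = dict(summary)
    dmi, ecm_v, fpcm_v = s["dmi"], s["ecm"], s["fpcm"]
    gei = s.get("gei") or dmi * config.diet_ge
    for name, v in (("dmi", dmi), ("ecm", ecm_v), ("fpcm", fpcm_v), ("gei", gei)):
        if v <= 0:
            raise ValueError(f"{name} must be strictly positive to form ratios")
    ch4 = s["ch4_g_d"]
    return EmissionMetrics(
        cow_id=str(s["cow_id"]),
        period=int(s["period"]),
        treatment=str(s["treatment"]),
        ch4_g_d=ch4,
        h2_g_d=s["h2_g_d"],
        co2_g_d=s["co2_g_d"],
        n2o_g_d=float(n2o_g_d),
        ch4_yield=ch4 / dmi,
        h2_yield=s["h2_g_d"] / dmi,
        ch4_per_ecm=ch4 / ecm_v,
        ch4_per_fpcm=ch4 / fpcm_v,
        ch4_gei_pct=ch4 * config.ch4_energy / gei * 100.0,
    )


def metrics_table(summaries: pd.DataFrame, ratios: pd.DataFrame,
                  config: StudyConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Emission metrics for every cow x period, joining anchor ratios."""
    r = ratios.set_index(["cow_id", "period"])["ratio"]
    rows = []
    for _, s in summaries.iterrows():
        key = (s["cow_id"], s["period"])
        if key not in r.index:
            raise ValueError(f"no anchor ratio for cow {key[0]} period {key[1]}")
        n2o = n2o_daily_production(s["ch4_g_d"], float(r.loc[key]), config)
        m = emission_metrics(s, n2o, config)
        rows.append(vars(m))
    return METRICS.validate(pd.DataFrame(rows))
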