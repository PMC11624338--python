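"""Nitrate -> methane stoichiometry and CO2-equivalent offset accounting.

Nitrate reduction to ammonium and methanogenesis compete for the same
ruminal hydrogen: each consumes 4 mol H2 (8 electrons), so one mole of
nitrate fully reduced prevents at most one mole of CH4.  The theoretical
mitigation potential of a dose of d g NO3-/kg DM is therefore

    d / M_NO3 * M_CH4   (g CH4 per kg DMI),

and efficacy is the observed yield reduction as a percentage of that
potential.  Because N2O has a far higher global warming potential than CH4
(273 vs 27 g CO2-eq/g), even a small N2O increase offsets part of the CH4
mitigation; :func:`gwp_offset` quantifies that trade in CO2 equivalents.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .config import DEFAULT_CONFIG, StudyConfig


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round half away from zero at ``ndigits`` decimals (reporting rule).

    Values are carried at full precision throughout the pipeline and only
    rounded at the reporting boundary, with ties going up — the convention
    the study's printed percentages follow.
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class StoichResult:
    """Theoretical vs observed CH4 yield reduction for a nitrate dose."""

    dose: float                  # g NO3-/kg DM
    theoretical_reduction: float  # g CH4/kg DMI
    observed_reduction: float     # g CH4/kg DMI
    efficacy_pct: float           # observed / theoretical * 100


@dataclass(frozen=True)
class GwpResult:
    """CO2-equivalent bookkeeping of the N2O increase vs the CH4 reduction."""

    delta_n2o: float     # g/d increase
    delta_ch4: float     # g/d reduction
    n2o_co2eq: float     # g CO2-eq/d
    ch4_co2eq: float     # g CO2-eq/d
    offset_pct: float    # n2o_co2eq / ch4_co2eq * 100


def theoretical_reduction(dose: float, config: StudyConfig = DEFAULT_CONFIG) -> float:
    """Stoichiometric CH4 reduction potential (g CH4/kg DMI) of a nitrate dose."""
    if dose < 0:
        raise ValueError("nitrate dose must be non-negative")
    return dose / config.molar_mass_no3 * config.molar_mass_ch4


def efficacy(observed: float, theoretical: float) -> float:
    """Observed CH4 yield reduction as % of the stoichiometric potential.

    ``observed`` may be negative (an increase); ``theoretical`` must be
    strictly positive.
    """
    if theoretical <= 0:
        raise ValueError("theoretical reduction must be strictly positive")
    return observed / theoretical * 100.0


def stoich_summary(observed: float, dose: float,
                   config: StudyConfig = DEFAULT_CONFIG) -> StoichResult:
    theo = theoretical_reduction(dose, config)
    return StoichResult(dose=dose, theoretical_reduction=theo,
                        observed_reduction=observed,
                        efficacy_pct=efficacy(observed, theo))


def gwp_offset(delta_n2o: float, delta_ch4: float,
               config: StudyConfig = DEFAULT_CONFIG) -> GwpResult:
    """CO2-equivalent offset of an N2O increase against a CH4 reduction.

    ``delta_ch4`` must be a strictly positive reduction; ``delta_n2o`` a
    non-negative increase.  The offset is scale-invariant in the pair.
    """
    if delta_ch4 <= 0:
        raise ValueError("gwp_offset requires a strictly positive CH4 reduction")
    if delta_n2o < 0:
        raise ValueError("delta_n2o must be non-negative")
    n2o_eq = delta_n2o * config.gwp_n2o
    ch4_eq = delta_ch4 * config.gwp_ch4
    return GwpResult(delta_n2o=delta_n2o, delta_ch4=delta_ch4,
                     n2o_co2eq=n2o_eq, ch4_co2eq=ch4_eq,
                     offset_pct=n2o_eq / ch4_eq * 100.0)


def reduction_summary(urea_metrics, nitrate_metrics) -> pd.DataFrame:
    """Per-metric percent reduction, (urea - nitrate) / urea * 100.

    Inputs are mappings (or Series) of metric name -> treatment-level value.
    Metrics with a zero urea value are skipped with a warning; a negative
    result means the metric increased under nitrate.
    """
    u = dict(urea_metrics)
    n = dict(nitrate_metrics)
    shared = [k for k in u if k in n]
    if not shared:
        raise ValueError("no shared metrics between the two treatment sets")
    rows = []
    for k in shared:
        if u[k] == 0:
            warnings.warn(f"metric '{k}' has zero urea value; reduction skipped")
            continue
        rows.append({
            "metric": k,
            "urea": float(u[k]),
            "nitrate": float(n[k]),
            "reduction_pct": (u[k] - n[k]) / u[k] * 100.0,
        })
    return pd.DataFrame(rows)
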