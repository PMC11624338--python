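"""Study-level physical constants and design metadata.

All downstream modules take a :class:`StudyConfig` rather than reaching for
module-level constants, so a study with different GWP horizons, gas
densities or diet energy content is a config edit, not a code change.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Volume composition (vol%) of the atmospheric air assumed to contaminate
#: headspace samples.  Argon is folded into N2; trace CH4/N2O are zero.
ATMOSPHERE_VOL_PCT = {"co2": 0.04, "ch4": 0.0, "n2o": 0.0, "n2": 79.01, "o2": 20.95}


@dataclass(frozen=True)
class StudyConfig:
    """Physical constants, GWP factors and design metadata for one study.

    Molar masses are carried at 4 significant figures, the precision at
    which the study's stoichiometric and gas-conversion results are
    reported; all are overridable for higher-precision work.

    Attributes
    ----------
    molar_mass_ch4, molar_mass_n2o, molar_mass_no3 : float
        Molar masses in g/mol (CH4, N2O, nitrate ion).
    molar_volume : float
        Molar gas volume (L/mol) at the reference state used for the
        diagnostic L/d intermediates.  Default 22.414 (0 degC, 101.325 kPa).
        The anchored N2O mass result does not depend on this value.
    gwp_n2o, gwp_ch4 : float
        100-year global warming potentials (g CO2-eq per g gas).
    ch4_energy : float
        Gross energy of methane, MJ/g (enthalpy of combustion).
    diet_ge : float
        Dietary gross-energy concentration, MJ/kg DM.
    nitrate_dose : float
        Nitrate supplementation level, g NO3-/kg DM.
    feeding_times : tuple[float, float]
        Clock times (decimal hours) of the two daily feedings.
    """

    molar_mass_ch4: float = 16.04
    molar_mass_n2o: float = 44.01
    molar_mass_no3: float = 62.00
    molar_volume: float = 22.414
    gwp_n2o: float = 273.0
    gwp_ch4: float = 27.0
    ch4_energy: float = 0.05565
    diet_ge: float = 18.9
    nitrate_dose: float = 8.6
    feeding_times: tuple[float, float] = (5.0 + 40.0 / 60.0, 16.0 + 50.0 / 60.0)

    def __post_init__(self) -> None:
        positive = (
            "molar_mass_ch4",
            "molar_mass_n2o",
            "molar_mass_no3",
            "molar_volume",
            "gwp_n2o",
            "gwp_ch4",
            "ch4_energy",
            "diet_ge",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"StudyConfig.{name} must be strictly positive")
        if self.nitrate_dose < 0:
            raise ValueError("StudyConfig.nitrate_dose must be non-negative")
        if not self.gwp_n2o > self.gwp_ch4:
            raise ValueError("StudyConfig requires gwp_n2o > gwp_ch4")
        if len(self.feeding_times) != 2:
            raise ValueError("StudyConfig.feeding_times must list the two daily feedings")

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["feeding_times"] = list(self.feeding_times)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            raise ValueError(f"unknown StudyConfig fields: {sorted(extra)}")
        d = dict(d)
        if "feeding_times" in d:
            d["feeding_times"] = tuple(d["feeding_times"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


DEFAULT_CONFIG = StudyConfig()
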