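"""Quantify daily N2O production by anchoring to chamber-measured CH4.

N2O is too dilute for chamber analysers, so production is inferred as
daily CH4 (L/d) x headspace N2O:CH4 volume ratio (L/L), converted to grams
with the ideal gas law.  Because both gases share the molar volume, the
mass form is independent of the reference temperature and pressure.
"""

import rumengas as rg

ch4_g_d = 357.0            # chamber-measured daily CH4, g/d
ratio = 0.008 / 18.7       # headspace N2O:CH4 volume ratio, L/L

n2o, diag = rg.n2o_daily_production(ch4_g_d, ratio, diagnostics=True)
print(f"CH4 production: {ch4_g_d:.0f} g/d = {diag['ch4_l_d']:.0f} L/d "
      f"(at {diag['molar_volume']} L/mol)")
print(f"N2O:CH4 ratio:  {ratio:.3e} L/L")
print(f"N2O production: {diag['n2o_l_d']:.3f} L/d = {n2o:.3f} g/d")

warm = rg.StudyConfig(molar_volume=25.616)  # rumen temperature reference
print(f"at 39 degC molar volume: {rg.n2o_daily_production(ch4_g_d, ratio, warm):.3f} g/d "
      "(identical - the litre intermediates cancel)")

# derived metrics for one cow x period summary
summary = {"cow_id": "cow1", "period": 1, "treatment": "nitrate", "dmi": 23.0,
           "ch4_g_d": 357.0, "h2_g_d": 4.61, "co2_g_d": 14944.0,
           "ecm": 27.2, "fpcm": 26.9, "gei": 434.7}
m = rg.emission_metrics(summary, n2o)
print(f"\nCH4 yield {m.ch4_yield:.1f} g/kg DMI; intensity {m.ch4_per_ecm:.1f} g/kg ECM; "
      f"{m.ch4_gei_pct:.2f}% of gross energy intake lost as CH4")
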