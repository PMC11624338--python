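"""Stoichiometric mitigation potential and the N2O trade-off in CO2-eq.

Nitrate reduction to ammonium consumes the same 4 mol H2 per mol as
methanogenesis, so each mole of nitrate can prevent at most one mole of
CH4.  Part of the win is given back because some nitrate nitrogen leaves
as N2O, a far stronger greenhouse gas.
"""

import rumengas as rg

dose = 8.6  # g NO3-/kg DM
theo = rg.theoretical_reduction(dose)
print(f"dose {dose} g NO3-/kg DM -> theoretical reduction "
      f"{rg.round_half_up(theo, 2):.2f} g CH4/kg DMI")

observed = 18.1 - 15.6  # observed CH4 yield drop, g/kg DMI
eff = rg.efficacy(observed, rg.round_half_up(theo, 2))
print(f"observed reduction {observed:.1f} g/kg DMI -> efficacy "
      f"{rg.round_half_up(eff, 0):.0f}% of the stoichiometric potential")
print("(>100%: consistent with nitrate also inhibiting methanogens directly)\n")

g = rg.gwp_offset(delta_n2o=0.47 - 0.10, delta_ch4=412 - 357)
print(f"N2O increase {g.delta_n2o:.2f} g/d x GWP 273 = {g.n2o_co2eq:.0f} g CO2-eq/d")
print(f"CH4 reduction {g.delta_ch4:.0f} g/d x GWP 27  = {g.ch4_co2eq:.0f} g CO2-eq/d")
print(f"offset: {rg.round_half_up(g.offset_pct, 0):.0f}% of the CH4 mitigation "
      "is counteracted by the extra N2O")
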